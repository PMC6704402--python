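"""Light/dark time-course expression analysis.

Implements the differential-expression rule used for the 16:8 light/dark
cell-cycle experiment — six timepoints (1/8/14 h after lights-on, 1/5/7 h
after dark), three replicates each: a gene is differentially expressed when
its |log2 fold change| between the first timepoint (1ALO) and any other
timepoint reaches the threshold (default 1.5) *and* it carries a protein
annotation.  Normalization is the median-of-ratios formula; a log2(x+1)
transform stands in for the estimator-dependent variance-stabilizing
transform; DE genes are grouped by average-linkage hierarchical clustering
of z-scored timepoint profiles, and each profile's peak phase is the
argmax timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .synthetic_data import N_REPS, TIMEPOINTS

__all__ = [
    "size_factors",
    "normalized_counts",
    "timepoint_means",
    "de_genes",
    "vst_like_transform",
    "cluster_profiles",
    "peak_phase",
    "DEResult",
    "PeakCall",
]


def _timepoint_of(sample: str) -> str:
    tp = sample.rsplit("_r", 1)[0]
    if tp not in TIMEPOINTS:
        raise ValueError(f"sample {sample!r} has unknown timepoint {tp!r}")
    return tp


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    factor_j = median over genes (nonzero in all samples) of
    count_gj / geometric_mean_g.  Scale-equivariant: doubling one sample's
    counts doubles its factor.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene with nonzero counts in all samples; supply a "
            "pseudo-reference or filter samples"
        )
    logs = np.log(mat[nonzero])
    log_gm = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts / factors


def timepoint_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean over replicates per timepoint; columns ordered as the
    experiment's six timepoints.  Every timepoint must be present."""
    groups: dict[str, list[str]] = {tp: [] for tp in TIMEPOINTS}
    for col in matrix.columns:
        groups[_timepoint_of(col)].append(col)
    missing = [tp for tp, cols in groups.items() if not cols]
    if missing:
        raise ValueError(f"missing timepoints: {missing}")
    return pd.DataFrame(
        {tp: matrix[cols].mean(axis=1) for tp, cols in groups.items()}
    )[list(TIMEPOINTS)]


@dataclass(frozen=True)
class DEResult:
    gene: str
    means: tuple[float, ...]  # normalized mean per timepoint
    max_abs_log2fc: float
    has_annotation: bool
    is_de: bool


def de_genes(
    counts: pd.DataFrame,
    annotations: Mapping[str, bool],
    fc_threshold: float = 1.5,
    factors: pd.Series | None = None,
) -> list[DEResult]:
    """Apply the DE rule to a raw count matrix.

    log2FC is computed between the 1ALO replicate-mean and each other
    timepoint's replicate-mean on normalized counts with a pseudocount of 1;
    a gene is DE iff max |log2FC| >= ``fc_threshold`` and it is annotated.
    """
    if factors is None:
        factors = size_factors(counts)
    means = timepoint_means(normalized_counts(counts, factors))
    base = means[TIMEPOINTS[0]].to_numpy()
    fc = np.log2(
        (means.to_numpy() + 1.0) / (base[:, None] + 1.0)
    )  # genes x 6; column 0 is identically zero
    max_abs = np.abs(fc[:, 1:]).max(axis=1)
    results = []
    for i, gene in enumerate(means.index):
        ann = bool(annotations.get(gene, False))
        results.append(
            DEResult(
                gene=gene,
                means=tuple(means.iloc[i]),
                max_abs_log2fc=float(max_abs[i]),
                has_annotation=ann,
                is_de=bool(max_abs[i] >= fc_threshold and ann),
            )
        )
    return results


def vst_like_transform(
    counts: pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """log2(count / size_factor + 1): a monotone variance-flattening
    stand-in for an estimator-dependent variance-stabilizing transform."""
    return np.log2(counts / factors + 1.0)


def cluster_profiles(
    tp_means: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
) -> pd.Series:
    """Agglomerative clustering (average linkage, Euclidean) of per-gene
    z-scored timepoint profiles.

    Genes are sorted lexicographically before linkage so tie-breaking is
    input-order independent.  Exactly one of ``n_clusters`` / ``height``
    selects the cut.
    """
    if (n_clusters is None) == (height is None):
        raise ValueError("specify exactly one of n_clusters or height")
    tp_means = tp_means.sort_index()
    if n_clusters is not None and n_clusters > len(tp_means):
        raise ValueError(
            f"n_clusters={n_clusters} exceeds {len(tp_means)} genes"
        )
    mat = tp_means.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if len(tp_means) == 1:
        return pd.Series([1], index=tp_means.index, name="cluster")
    link = linkage(z, method="average", metric="euclidean")
    if n_clusters is not None:
        labels = fcluster(link, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(link, t=height, criterion="distance")
    return pd.Series(labels, index=tp_means.index, name="cluster")


@dataclass(frozen=True)
class PeakCall:
    gene: str
    peak: str
    declining_from_start: bool  # maximum already at 1ALO
    flat: bool


def peak_phase(means: Sequence[float], gene: str = "") -> PeakCall:
    """Timepoint of maximum mean expression; ties break to the earliest
    timepoint.  A profile whose maximum sits at 1ALO is flagged
    declining-from-start; a constant profile is additionally flagged flat."""
    means = np.asarray(means, dtype=float)
    if means.shape != (len(TIMEPOINTS),):
        raise ValueError(f"expected {len(TIMEPOINTS)} means, got {means.shape}")
    idx = int(np.argmax(means))  # argmax takes the first maximum: earliest
    return PeakCall(
        gene=gene,
        peak=TIMEPOINTS[idx],
        declining_from_start=idx == 0,
        flat=bool(np.all(means == means[0])),
    )
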