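"""Seeded generators for fixtures with the statistical structure each
analysis stage assumes.

Every generator is a pure function of its config dataclass: the same config
(including seed) produces byte-identical output.  Each generator also
returns a *truth* object recording what was planted, which serves as a
perfect oracle for the downstream stage at zero/low noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import OrthoTable, SeqRecord, SupportTree, VariantRecord, parse_newick

__all__ = [
    "OrthogroupConfig",
    "OrthogroupTruth",
    "gen_orthogroups",
    "HgtTreeConfig",
    "HgtTreeTruth",
    "gen_hgt_tree",
    "gen_hgt_batch",
    "BidirConfig",
    "gen_bidir_transcripts",
    "VariantConfig",
    "gen_variant_set",
    "TimecourseConfig",
    "TimecourseTruth",
    "gen_timecourse_counts",
    "TIMEPOINTS",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_REV_STOPS = ("TTA", "CTA", "TCA")  # forward codons whose revcomp is a stop


# ===========================================================================
# orthogroup tables with planted filter truth


@dataclass(frozen=True)
class OrthogroupConfig:
    """Planted orthogroup table: ``n_taxa`` taxa over ``n_phyla`` phyla;
    ``pass_fraction`` of the ``n_ogs`` groups satisfy all three retention
    criteria (single-copy fraction > ``min_single_copy``, >= ``min_phyla``
    phyla, >= ``min_species`` species); each failing group violates exactly
    one criterion."""

    seed: int = 0
    n_taxa: int = 30
    n_phyla: int = 6
    n_ogs: int = 100
    pass_fraction: float = 0.4
    paralog_rate: float = 0.1
    min_single_copy: float = 0.80
    min_phyla: int = 4
    min_species: int = 10


@dataclass
class OrthogroupTruth:
    per_og: pd.DataFrame  # og_id, passes, fail_reason, n_species, n_phyla, single_copy_fraction
    phylum_map: dict[str, str]


def _taxon_pool(cfg: OrthogroupConfig) -> tuple[list[str], dict[str, str]]:
    taxa = [f"taxon{i:03d}" for i in range(1, cfg.n_taxa + 1)]
    phyla = [f"phylum{j:02d}" for j in range(1, cfg.n_phyla + 1)]
    phylum_map = {t: phyla[i % cfg.n_phyla] for i, t in enumerate(taxa)}
    return taxa, phylum_map


def _pick_species(
    rng: np.random.Generator,
    taxa: list[str],
    phylum_map: dict[str, str],
    n_species: int,
    phyla_allowed: list[str],
    min_phyla_present: int,
) -> list[str]:
    """Pick ``n_species`` taxa drawn only from ``phyla_allowed``, guaranteed
    to cover at least ``min_phyla_present`` distinct phyla."""
    by_phylum: dict[str, list[str]] = {p: [] for p in phyla_allowed}
    for t in taxa:
        if phylum_map[t] in by_phylum:
            by_phylum[phylum_map[t]].append(t)
    seed_phyla = list(rng.choice(phyla_allowed, size=min_phyla_present, replace=False))
    chosen = [by_phylum[p][rng.integers(len(by_phylum[p]))] for p in seed_phyla]
    pool = [t for p in phyla_allowed for t in by_phylum[p] if t not in chosen]
    extra = n_species - len(chosen)
    if extra > len(pool):
        raise ValueError(
            f"cannot place {n_species} species in {len(phyla_allowed)} phyla"
        )
    if extra > 0:
        chosen += list(rng.choice(pool, size=extra, replace=False))
    return sorted(chosen)


def gen_orthogroups(cfg: OrthogroupConfig) -> tuple[OrthoTable, OrthogroupTruth]:
    if cfg.n_taxa < 10 or cfg.n_phyla < 4:
        raise ValueError("need n_taxa >= 10 and n_phyla >= 4")
    if cfg.n_phyla > cfg.n_taxa:
        raise ValueError("more phyla than taxa is infeasible")
    rng = np.random.default_rng(cfg.seed)
    taxa, phylum_map = _taxon_pool(cfg)
    all_phyla = sorted(set(phylum_map.values()))

    n_pass = round(cfg.pass_fraction * cfg.n_ogs)
    fail_modes = ["paralogy", "few_phyla", "few_species"]
    if cfg.paralog_rate == 0:
        fail_modes = ["few_phyla", "few_species"]

    rows: dict[str, dict[str, list[str]]] = {}
    truth_rows = []
    for i in range(cfg.n_ogs):
        og_id = f"OG{i:07d}"
        passes = i < n_pass
        if passes:
            n_sp = int(rng.integers(cfg.min_species, cfg.n_taxa + 1))
            species = _pick_species(
                rng, taxa, phylum_map, n_sp, all_phyla, cfg.min_phyla
            )
            # multicopy taxa capped so single-copy fraction stays strictly
            # above the threshold: (s - m) / (s + m) > 0.8  <=>  m < s / 9
            m_max = (n_sp - 1) // 9
            m = min(int(rng.binomial(n_sp, cfg.paralog_rate)), m_max)
            fail_reason = ""
        else:
            mode = fail_modes[i % len(fail_modes)]
            if mode == "paralogy":
                n_sp = int(rng.integers(cfg.min_species, cfg.n_taxa + 1))
                species = _pick_species(
                    rng, taxa, phylum_map, n_sp, all_phyla, cfg.min_phyla
                )
                m_min = -(-n_sp // 9)  # ceil(s/9): fraction <= 0.8
                m = int(rng.integers(m_min, n_sp + 1))
                fail_reason = "paralogy"
            elif mode == "few_phyla":
                k = int(rng.integers(1, cfg.min_phyla))  # 1..3 phyla
                phyla_sub = list(rng.choice(all_phyla, size=k, replace=False))
                avail = sum(
                    1 for t in taxa if phylum_map[t] in phyla_sub
                )
                n_sp = int(
                    rng.integers(cfg.min_species, avail + 1)
                ) if avail >= cfg.min_species else avail
                if n_sp < cfg.min_species:
                    # not enough taxa in few phyla to also satisfy species
                    # minimum; that is fine, the first failed criterion
                    # reported is still phyla because we keep n_phyla < min
                    n_sp = avail
                species = _pick_species(rng, taxa, phylum_map, n_sp, phyla_sub, k)
                m_max = (n_sp - 1) // 9
                m = min(int(rng.binomial(n_sp, cfg.paralog_rate)), m_max)
                fail_reason = "few_phyla"
            else:
                n_sp = int(rng.integers(cfg.min_phyla, cfg.min_species))
                species = _pick_species(
                    rng, taxa, phylum_map, n_sp, all_phyla, cfg.min_phyla
                )
                m = 0  # any paralogy would also trip the fraction at small s
                fail_reason = "few_species"

        multi = set(rng.choice(species, size=m, replace=False)) if m else set()
        row = {t: [] for t in taxa}
        for t in species:
            n_prot = 2 if t in multi else 1
            row[t] = [f"{t}|{og_id}_p{j}" for j in range(1, n_prot + 1)]
        rows[og_id] = row

        n_prot_total = sum(len(v) for v in row.values())
        scf = (len(species) - len(multi)) / n_prot_total
        truth_rows.append(
            dict(
                og_id=og_id,
                passes=passes,
                fail_reason=fail_reason,
                n_species=len(species),
                n_phyla=len({phylum_map[t] for t in species}),
                single_copy_fraction=scf,
            )
        )

    table = OrthoTable(taxa=taxa, rows=rows)
    truth = OrthogroupTruth(
        per_og=pd.DataFrame(truth_rows).set_index("og_id"),
        phylum_map=phylum_map,
    )
    return table, truth


# ===========================================================================
# gene trees with planted chlamydial donors


LINEAGES = (
    "Chlamydiae",
    "Glaucophyta",
    "Rhodophyta",
    "Viridiplantae",
    "other_bacteria",
    "other_eukaryote",
)

SHARING_CATEGORIES = (
    "all_archaeplastida",
    "green_shared",
    "red_shared",
    "glaucophyte_specific",
    "other",
)


@dataclass(frozen=True)
class HgtTreeConfig:
    """One planted HGT gene tree: a recipient clade of the composition
    implied by ``category`` sits sister to a chlamydial clade, with the
    chosen support on the recipient clade's edge; bacterial and eukaryote
    decoys form a distant outgroup."""

    seed: int = 0
    category: str = "all_archaeplastida"
    support: float = 98.0
    donor: str | None = "Chlamydiae"
    n_glauco: int = 2
    n_red: int = 2
    n_green: int = 2
    n_chlam: int = 3
    n_other_bact: int = 3
    n_other_euk: int = 3
    has_introns: bool = True


@dataclass
class HgtTreeTruth:
    category: str
    donor: str | None
    support: float
    lineage_map: dict[str, str]
    has_introns: bool


def _subtree_newick(
    leaves: list[tuple[str, float]],
    rng: np.random.Generator,
    support_range=(90, 100),
) -> str:
    """Random caterpillar subtree for (name, branch_length) leaves.

    Interior nodes get random support labels; the outermost node is left
    unlabeled and without a branch length so the caller can attach its own
    (``"(a,b)"``).  A single leaf is returned as ``"name:bl"``.
    """
    items = [f"{n}:{bl:.4f}" for n, bl in leaves]
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    while len(items) > 2:
        a = items.pop()
        b = items.pop()
        sup = int(rng.integers(*support_range))
        items.append(f"({a},{b}){sup}:{rng.uniform(0.02, 0.1):.4f}")
    if len(items) == 2:
        return f"({items[0]},{items[1]})"
    return items[0]


def _recipient_leaves(cfg: HgtTreeConfig) -> list[str]:
    cat = cfg.category
    names: list[str] = []

    def add(lineage: str, n: int) -> None:
        names.extend(f"{lineage}_sp{i}" for i in range(1, n + 1))

    if cat == "all_archaeplastida":
        if min(cfg.n_glauco, cfg.n_red, cfg.n_green) < 1:
            raise ValueError("all_archaeplastida needs >=1 leaf per lineage")
        add("Glaucophyta", cfg.n_glauco)
        add("Rhodophyta", cfg.n_red)
        add("Viridiplantae", cfg.n_green)
    elif cat == "green_shared":
        if cfg.n_glauco < 1 or cfg.n_green < 1:
            raise ValueError("green_shared needs glaucophyte and green leaves")
        add("Glaucophyta", cfg.n_glauco)
        add("Viridiplantae", cfg.n_green)
    elif cat == "red_shared":
        if cfg.n_glauco < 1 or cfg.n_red < 1:
            raise ValueError("red_shared needs glaucophyte and red leaves")
        add("Glaucophyta", cfg.n_glauco)
        add("Rhodophyta", cfg.n_red)
    elif cat == "glaucophyte_specific":
        if cfg.n_glauco < 2:
            raise ValueError(
                "glaucophyte_specific requires at least 2 glaucophyte species"
            )
        if not cfg.has_introns:
            raise ValueError(
                "glaucophyte_specific requires intron evidence; use category "
                "'other' for intron-less cases"
            )
        add("Glaucophyta", cfg.n_glauco)
    elif cat == "other":
        # a single glaucophyte next to the donor fails the >=2 species rule
        add("Glaucophyta", 1)
    else:
        raise ValueError(f"unknown sharing category {cat!r}")
    return names


def _attach(subtree: str, label: str, bl: float) -> str:
    """Attach a node label and branch length to a multi-leaf subtree; a
    single leaf already carries its branch length and cannot be labelled."""
    if subtree.endswith(")"):
        return f"{subtree}{label}:{bl:.4f}"
    return subtree


def gen_hgt_tree(cfg: HgtTreeConfig) -> tuple[SupportTree, HgtTreeTruth]:
    if not 0 <= cfg.support <= 100:
        raise ValueError("support must be in [0, 100]")
    rng = np.random.default_rng(cfg.seed)
    recip = _recipient_leaves(cfg)
    recip_nwk = _subtree_newick([(n, rng.uniform(0.05, 0.15)) for n in recip], rng)
    sup = f"{cfg.support:g}"

    if cfg.donor == "Chlamydiae":
        chlam = [f"Chlamydiae_sp{i}" for i in range(1, cfg.n_chlam + 1)]
        chlam_nwk = _subtree_newick(
            [(n, rng.uniform(0.05, 0.15)) for n in chlam], rng
        )
        inner = (
            f"({_attach(recip_nwk, sup, 0.08)},"
            f"{_attach(chlam_nwk, sup, 0.08)}){sup}:0.3"
        )
    elif cfg.donor is None:
        inner = _attach(recip_nwk, sup, 0.3)
    else:
        raise ValueError(f"unsupported donor {cfg.donor!r}")

    # distant decoys: long branches put the midpoint root among the outgroup
    decoys = [f"other_bacteria_sp{i}" for i in range(1, cfg.n_other_bact + 1)]
    decoys += [f"other_eukaryote_sp{i}" for i in range(1, cfg.n_other_euk + 1)]
    if len(decoys) < 2:
        raise ValueError("need at least two decoy leaves")
    out_nwk = _subtree_newick([(n, rng.uniform(1.0, 1.5)) for n in decoys], rng)
    out_part = _attach(out_nwk, str(int(rng.integers(90, 100))), 0.1)

    newick = f"({inner},{out_part});"
    tree = parse_newick(newick)
    lineage_map = {
        name: next(l for l in LINEAGES if name.startswith(l))
        for name in tree.leaf_names
    }
    truth = HgtTreeTruth(
        category=cfg.category if cfg.donor == "Chlamydiae" else "other",
        donor=cfg.donor,
        support=cfg.support,
        lineage_map=lineage_map,
        has_introns=cfg.has_introns,
    )
    return tree, truth


def gen_hgt_batch(
    seed: int,
    counts: dict[str, int] | None = None,
    support_range: tuple[float, float] = (90.0, 100.0),
) -> list[tuple[SupportTree, HgtTreeTruth]]:
    """A batch of planted trees, ``counts`` per sharing category (defaults to
    the 17/3/5/10 well-supported composition)."""
    if counts is None:
        counts = {
            "all_archaeplastida": 17,
            "green_shared": 3,
            "red_shared": 5,
            "glaucophyte_specific": 10,
        }
    rng = np.random.default_rng(seed)
    out = []
    for cat, n in counts.items():
        for _ in range(n):
            cfg = HgtTreeConfig(
                seed=int(rng.integers(2**31)),
                category=cat,
                support=float(np.round(rng.uniform(*support_range), 1)),
            )
            out.append(gen_hgt_tree(cfg))
    return out


# ===========================================================================
# transcripts with planted bidirectional ORFs


@dataclass(frozen=True)
class BidirConfig:
    """Transcripts carrying planted opposite-strand overlapping ORFs.

    Positives embed a forward ORF and a fully contained reverse-strand ORF,
    both >= ``min_aa``; negatives carry a forward ORF whose reverse-strand
    readings are salted with stop codons.  Flanks are GC-only (echoing the
    high genomic GC content) so they can spawn neither starts nor stops.
    """

    seed: int = 0
    n_pos: int = 10
    n_neg: int = 10
    min_aa: int = 300
    extra_aa_max: int = 40
    flank_min: int = 30
    flank_max: int = 120
    rejection_budget: int = 10_000


def _dual_codon(rng: np.random.Generator, budget: int) -> str:
    """A codon that is stop-free on both strands (rejection sampling)."""
    for _ in range(budget):
        codon = "".join(_BASES[b] for b in rng.integers(0, 4, size=3))
        if codon not in _STOPS and codon not in _REV_STOPS:
            return codon
    raise RuntimeError(
        "rejection budget exhausted constructing dual-coding codons; "
        "request a shorter ORF"
    )


def _gc_flank(rng: np.random.Generator, n: int) -> str:
    return "".join("GC"[b] for b in rng.integers(0, 2, size=n))


def gen_bidir_transcripts(
    cfg: BidirConfig,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Returns (records, truth) where truth has one row per transcript with
    planted forward/reverse ORF coordinates (forward coordinate system)."""
    if cfg.min_aa < 2:
        raise ValueError("min_aa must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    records: list[SeqRecord] = []
    truth_rows = []

    for i in range(cfg.n_pos):
        seq_id = f"DN{i:05d}_pos"
        m = cfg.min_aa - 1 + int(rng.integers(0, cfg.extra_aa_max + 1))
        flank5 = _gc_flank(rng, int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
        flank3 = _gc_flank(rng, int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
        core = "".join(
            _dual_codon(rng, cfg.rejection_budget) for _ in range(m)
        )
        rev_stop = _REV_STOPS[rng.integers(len(_REV_STOPS))]
        fwd_stop = _STOPS[rng.integers(len(_STOPS))]
        # forward frame: ATG | rev-stop marker | m dual codons | CAT | stop
        # reverse frame (aligned): ATG | m dual codons | stop
        orf = "ATG" + rev_stop + core + "CAT" + fwd_stop
        seq = flank5 + orf + flank3
        p0 = len(flank5)
        plus = (p0, p0 + len(orf))
        minus = (p0 + 3, p0 + 3 + 3 * (m + 2))
        records.append(SeqRecord(id=seq_id, seq=seq))
        truth_rows.append(
            dict(
                seq_id=seq_id, is_positive=True,
                plus_start=plus[0], plus_end=plus[1],
                minus_start=minus[0], minus_end=minus[1],
            )
        )

    stop_spacing = max(5, cfg.min_aa // 4)
    for i in range(cfg.n_neg):
        seq_id = f"DN{i:05d}_neg"
        m = cfg.min_aa - 1 + int(rng.integers(0, cfg.extra_aa_max + 1))
        flank5 = _gc_flank(rng, int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
        flank3 = _gc_flank(rng, int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
        codons = []
        for j in range(m + 2):
            if j % stop_spacing == 0:
                # salt the aligned reverse frame with stops
                codons.append(_REV_STOPS[rng.integers(len(_REV_STOPS))])
            else:
                while True:
                    c = "".join(_BASES[b] for b in rng.integers(0, 4, size=3))
                    if c not in _STOPS:
                        break
                codons.append(c)
        orf = "ATG" + "".join(codons) + _STOPS[rng.integers(len(_STOPS))]
        seq = flank5 + orf + flank3
        p0 = len(flank5)
        records.append(SeqRecord(id=seq_id, seq=seq))
        truth_rows.append(
            dict(
                seq_id=seq_id, is_positive=False,
                plus_start=p0, plus_end=p0 + len(orf),
                minus_start=-1, minus_end=-1,
            )
        )

    truth = pd.DataFrame(truth_rows).set_index("seq_id")
    return records, truth


# ===========================================================================
# variant sets under haploid / diploid allele-frequency models


@dataclass(frozen=True)
class VariantConfig:
    """Variant calls under a ploidy model.

    Diploid: alt reads ~ Binomial(coverage, 0.5) per heterozygous site.
    Haploid: a mixture of sequencing-error sites (alt ~ Binomial(coverage,
    ``error_rate``)) and fixed differences at frequency ~1 (ref reads are
    the errors), so the 30-70% frequency band is depleted.  Sites are
    conditioned on >= 1 alt read (a caller emits no variant otherwise).
    """

    seed: int = 0
    ploidy: int = 2
    n_variants: int = 10_000
    coverage: int = 10
    coverage_model: str = "constant"  # or "poisson"
    error_rate: float = 0.01
    fixed_fraction: float = 0.5  # haploid only: share of freq~1 sites
    quality_mean: float = 45.0


def gen_variant_set(cfg: VariantConfig) -> list[VariantRecord]:
    if cfg.ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if cfg.error_rate >= 0.5:
        raise ValueError("error_rate must be < 0.5")
    if cfg.coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(cfg.seed)

    if cfg.coverage_model == "constant":
        cov = np.full(cfg.n_variants, cfg.coverage, dtype=np.int64)
    elif cfg.coverage_model == "poisson":
        cov = np.maximum(rng.poisson(cfg.coverage, size=cfg.n_variants), 1)
    else:
        raise ValueError(f"unknown coverage_model {cfg.coverage_model!r}")

    if cfg.ploidy == 2:
        alt = rng.binomial(cov, 0.5)
    else:
        fixed = rng.random(cfg.n_variants) < cfg.fixed_fraction
        err = rng.binomial(cov, cfg.error_rate)
        alt = np.where(fixed, cov - err, err)
    # a variant caller only reports sites with alt-read evidence
    alt = np.maximum(alt, 1)
    alt = np.minimum(alt, cov)

    quals = np.round(rng.normal(cfg.quality_mean, 5.0, size=cfg.n_variants), 1)
    quals = np.clip(quals, 20.0, 90.0)
    ref_idx = rng.integers(0, 4, size=cfg.n_variants)
    alt_off = rng.integers(1, 4, size=cfg.n_variants)

    records = []
    for i in range(cfg.n_variants):
        records.append(
            VariantRecord(
                contig="tig00000001",
                pos=100 + 37 * i,
                ref=_BASES[ref_idx[i]],
                alt=_BASES[(ref_idx[i] + alt_off[i]) % 4],
                coverage=int(cov[i]),
                alt_count=int(alt[i]),
                quality=float(quals[i]),
            )
        )
    return records


# ===========================================================================
# six-timepoint count matrices with planted expression patterns


TIMEPOINTS = ("1ALO", "8ALO", "14ALO", "1AD", "5AD", "7AD")
N_REPS = 3


@dataclass(frozen=True)
class TimecourseConfig:
    """Negative-binomially noised counts over the six light/dark timepoints
    (three replicates each).

    Planted DE genes carry a |log2 fold change| of exactly ``fold_change``
    between the first timepoint and their peak; flat genes are negatives.
    When ``n_patterns`` is set, DE genes are grouped into that many distinct
    profile prototypes (for clustering tests); otherwise each (peak,
    direction) combination is its own pattern.
    """

    seed: int = 0
    n_de: int = 200
    n_flat: int = 800
    fold_change: float = 2.0
    dispersion: float = 0.02
    base_mean_log: float = 5.0  # natural-log mean of lognormal base mean
    base_mean_sd: float = 0.7
    up_fraction: float = 0.5
    peak_times: tuple[str, ...] = ("8ALO", "14ALO", "1AD", "5AD", "7AD")
    size_factors: tuple[float, ...] | None = None
    n_patterns: int | None = None
    pattern_sd: float = 1.5
    pattern_min_sep: float = 1.2
    annotated_fraction: float = 1.0


@dataclass
class TimecourseTruth:
    per_gene: pd.DataFrame  # is_de, direction, peak_time, cluster, base_mean
    profiles: pd.DataFrame  # genes x timepoints planted mean (normalized scale)
    size_factors: np.ndarray
    annotations: pd.Series  # gene -> bool


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _pattern_prototypes(
    rng: np.random.Generator, n: int, sd: float, min_sep: float
) -> np.ndarray:
    """Random log2 profile prototypes with pairwise z-scored separation."""
    protos: list[np.ndarray] = []
    for _ in range(20_000):
        cand = rng.normal(0.0, sd, size=len(TIMEPOINTS))
        zc = _zscore(cand)
        if all(np.linalg.norm(zc - _zscore(p)) >= min_sep for p in protos):
            protos.append(cand)
        if len(protos) == n:
            return np.array(protos)
    raise RuntimeError(
        f"could not place {n} separated profile prototypes; lower min_sep"
    )


def gen_timecourse_counts(
    cfg: TimecourseConfig,
) -> tuple[pd.DataFrame, TimecourseTruth]:
    """Returns (counts, truth): counts is genes x 18 samples (columns
    ``<timepoint>_r<rep>``), truth records the planted structure."""
    if cfg.dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if not set(cfg.peak_times) <= set(TIMEPOINTS):
        raise ValueError(f"peak_times must be within {TIMEPOINTS}")
    rng = np.random.default_rng(cfg.seed)

    samples = [f"{tp}_r{r}" for tp in TIMEPOINTS for r in range(1, N_REPS + 1)]
    if cfg.size_factors is None:
        sf = np.ones(len(samples))
    else:
        sf = np.asarray(cfg.size_factors, dtype=float)
        if sf.shape != (len(samples),) or (sf <= 0).any():
            raise ValueError("size_factors must be 18 positive numbers")

    n_genes = cfg.n_de + cfg.n_flat
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sd, size=n_genes)
    base = np.maximum(base, 10.0)

    if cfg.n_patterns is not None:
        protos = _pattern_prototypes(
            rng, cfg.n_patterns, cfg.pattern_sd, cfg.pattern_min_sep
        )

    log2_profiles = np.zeros((n_genes, len(TIMEPOINTS)))
    rows = []
    for g in range(n_genes):
        is_de = g < cfg.n_de
        if not is_de:
            rows.append(
                dict(gene_id=gene_ids[g], is_de=False, direction="",
                     peak_time="", cluster=-1, base_mean=base[g])
            )
            continue
        if cfg.n_patterns is not None:
            k = g % cfg.n_patterns
            prof = protos[k].copy()
            prof -= prof[0]  # anchor at 1ALO
            log2_profiles[g] = prof
            peak = TIMEPOINTS[int(np.argmax(prof))]
            direction = "up" if prof.max() > 0 else "down"
            cluster = k
        else:
            peak = cfg.peak_times[int(rng.integers(len(cfg.peak_times)))]
            up = rng.random() < cfg.up_fraction
            delta = cfg.fold_change if up else -cfg.fold_change
            log2_profiles[g, TIMEPOINTS.index(peak)] = delta
            direction = "up" if up else "down"
            cluster = TIMEPOINTS.index(peak) * 2 + (0 if up else 1)
        rows.append(
            dict(gene_id=gene_ids[g], is_de=True, direction=direction,
                 peak_time=peak, cluster=cluster, base_mean=base[g])
        )

    means = base[:, None] * np.exp2(log2_profiles)  # genes x 6, normalized scale
    mu = np.repeat(means, N_REPS, axis=1) * sf[None, :]  # genes x 18
    # NB with var = mu + dispersion * mu^2
    n_param = 1.0 / cfg.dispersion
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    annotated = pd.Series(
        rng.random(n_genes) < cfg.annotated_fraction, index=gene_ids
    )
    truth = TimecourseTruth(
        per_gene=pd.DataFrame(rows).set_index("gene_id"),
        profiles=pd.DataFrame(means, index=gene_ids, columns=list(TIMEPOINTS)),
        size_factors=sf,
        annotations=annotated,
    )
    return counts_df, truth
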