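"""Orthogroup filtering and concatenated supermatrix construction.

Implements the retention rubric used to assemble a multi-gene dataset for
eukaryote tree-of-life inference: keep orthogroups with low paralogy
(single-copy fraction strictly above 0.80) that span at least 4 phyla and
at least 10 species; then drop multi-copy taxa from the kept groups and
concatenate the per-group alignments into a partitioned supermatrix.
Alignment and tree inference themselves are external (MAFFT / IQ-TREE);
this module builds their inputs and bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import FormatError, OrthoTable, SeqRecord, write_fasta, write_partitions

__all__ = [
    "OGStats",
    "FilterConfig",
    "Supermatrix",
    "compute_og_stats",
    "filter_ogs",
    "prune_multicopy",
    "concatenate_supermatrix",
    "stats_table",
]

GAP = "-"


@dataclass(frozen=True)
class OGStats:
    """Per-orthogroup retention statistics.

    ``single_copy_fraction`` is the share of member *proteins* contributed
    by taxa holding exactly one protein in the group.
    """

    og_id: str
    n_species: int
    n_phyla: int
    single_copy_fraction: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.single_copy_fraction <= 1.0
        assert self.n_phyla <= self.n_species


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds; the single-copy bound is strict (>), the phylum
    and species bounds are inclusive (>=)."""

    min_single_copy: float = 0.80
    min_phyla: int = 4
    min_species: int = 10

    def __post_init__(self) -> None:
        if self.min_single_copy <= 0 or self.min_phyla <= 0 or self.min_species <= 0:
            raise ValueError("thresholds must be positive")


def compute_og_stats(
    og_id: str,
    row: Mapping[str, Sequence[str]],
    phylum_map: Mapping[str, str],
) -> OGStats:
    """Species/phylum counts and single-copy fraction for one orthogroup row.

    Taxa with empty protein lists are absent and excluded from counts.
    """
    members = {t: ps for t, ps in row.items() if ps}
    for t in members:
        if t not in phylum_map:
            raise KeyError(f"taxon {t!r} missing from phylum map")
    n_species = len(members)
    n_phyla = len({phylum_map[t] for t in members})
    total = sum(len(ps) for ps in members.values())
    single = sum(len(ps) for ps in members.values() if len(ps) == 1)
    return OGStats(
        og_id=og_id,
        n_species=n_species,
        n_phyla=n_phyla,
        single_copy_fraction=single / total if total else 0.0,
    )


def filter_ogs(
    table: OrthoTable,
    phylum_map: Mapping[str, str],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[str], dict[str, str]]:
    """Partition orthogroups into kept ids and {rejected id: first failed
    criterion} (criteria checked in order: single_copy, phyla, species)."""
    kept: list[str] = []
    rejected: dict[str, str] = {}
    for og_id, row in table.rows.items():
        st = compute_og_stats(og_id, row, phylum_map)
        if not st.single_copy_fraction > cfg.min_single_copy:
            rejected[og_id] = "single_copy"
        elif not st.n_phyla >= cfg.min_phyla:
            rejected[og_id] = "phyla"
        elif not st.n_species >= cfg.min_species:
            rejected[og_id] = "species"
        else:
            kept.append(og_id)
    return kept, rejected


@dataclass
class PruneReport:
    og: dict[str, list[str]]  # pruned row (all taxa single-copy)
    removed: list[str]
    below_min_species: bool  # warning flag, not an error


def prune_multicopy(
    row: Mapping[str, Sequence[str]], min_species: int = 10
) -> PruneReport:
    """Remove taxa with more than one protein; idempotent.

    If the pruned group falls below ``min_species`` taxa, it is kept but
    flagged rather than rejected.
    """
    pruned = {t: list(ps) for t, ps in row.items() if len(ps) == 1}
    removed = sorted(t for t, ps in row.items() if len(ps) > 1)
    return PruneReport(
        og=pruned,
        removed=removed,
        below_min_species=len(pruned) < min_species,
    )


@dataclass
class Supermatrix:
    """Concatenated per-orthogroup alignments over a shared taxon set.

    ``blocks`` are (og_id, start, end), 1-based inclusive, partitioning the
    full row length exactly; taxa absent from a block are gap-filled.
    """

    taxa: list[str]
    matrix: dict[str, str]
    blocks: list[tuple[str, int, int]]

    @property
    def length(self) -> int:
        return self.blocks[-1][2] if self.blocks else 0

    def occupancy(self) -> pd.Series:
        """Per-taxon non-gap fraction."""
        return pd.Series(
            {
                t: 1.0 - self.matrix[t].count(GAP) / self.length
                for t in self.taxa
            },
            name="occupancy",
        )

    def to_records(self) -> list[SeqRecord]:
        return [SeqRecord(id=t, seq=self.matrix[t]) for t in self.taxa]

    def write(self, fasta_path: str | Path, partition_path: str | Path,
              model: str = "WAG") -> None:
        write_fasta(self.to_records(), fasta_path)
        write_partitions(self.blocks, partition_path, model=model)


def concatenate_supermatrix(
    alignments: Mapping[str, Mapping[str, str]],
    taxon_universe: Sequence[str],
) -> Supermatrix:
    """Concatenate per-OG alignments (og_id -> taxon -> aligned sequence).

    Blocks are ordered lexicographically by og_id; taxa missing from an OG
    receive all-gap characters for that block.  Within each OG all
    sequences must have equal length.
    """
    taxa = sorted(taxon_universe)
    taxon_set = set(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for og_id in sorted(alignments):
        aln = alignments[og_id]
        extra = set(aln) - taxon_set
        if extra:
            raise FormatError(
                f"OG {og_id}: taxa {sorted(extra)} outside taxon universe"
            )
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment in OG {og_id}: lengths {sorted(lengths)}")
        (length,) = lengths
        for t in taxa:
            parts[t].append(aln.get(t, GAP * length))
        blocks.append((og_id, pos + 1, pos + length))
        pos += length
    return Supermatrix(
        taxa=taxa,
        matrix={t: "".join(parts[t]) for t in taxa},
        blocks=blocks,
    )


def stats_table(
    table: OrthoTable, phylum_map: Mapping[str, str]
) -> pd.DataFrame:
    """All per-OG stats as a DataFrame (og_id index)."""
    rows = [
        compute_og_stats(og_id, row, phylum_map).__dict__
        for og_id, row in table.rows.items()
    ]
    return pd.DataFrame(rows).set_index("og_id")
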