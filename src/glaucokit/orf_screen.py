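"""Six-frame ORF detection and the bidirectional overlapping-ORF screen.

Detects maximal open reading frames of at least ``min_aa`` residues in all
six frames of a transcript, reports opposite-strand pairs whose spans
overlap, scores stranded RNA-Seq coverage support for each ORF of a pair,
and finds convergent gene pairs sharing a 3'-UTR on a contig.

All ORF coordinates are reported on the forward coordinate system of the
transcript, 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneModel, SeqRecord

__all__ = [
    "OrfHit",
    "BidirectionalPair",
    "StrandSupport",
    "find_orfs",
    "detect_bidirectional_pairs",
    "strand_support",
    "utr_overlap",
    "revcomp",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _is_stop(codon: str) -> bool:
    # codons containing N are neither start nor stop
    return codon in STOP_CODONS


def _is_start(codon: str) -> bool:
    return codon == START_CODON


@dataclass(frozen=True)
class OrfHit:
    """A maximal ORF; ``start``/``end`` are forward-strand coordinates,
    ``frame`` is 0|1|2 on the ORF's own strand, ``aa_len`` excludes the
    stop.  ``truncated`` marks ORFs cut off by the sequence boundary
    (span = 3*aa_len instead of 3*(aa_len+1))."""

    seq_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_len: int
    truncated: bool = False

    def __post_init__(self) -> None:
        expected = 3 * (self.aa_len + (0 if self.truncated else 1))
        assert self.end - self.start == expected, "span/aa_len mismatch"


def _scan_strand(
    seq: str, seq_id: str, strand: str, min_aa: int, mode: str
) -> list[OrfHit]:
    """Scan one strand (seq already reverse-complemented for '-')."""
    n = len(seq)
    hits: list[OrfHit] = []
    for frame in range(3):
        orf_start: int | None = None  # codon index of ORF start on this strand
        region_start = frame  # for stop_to_stop: start of current open region
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            stop = _is_stop(codon)
            if mode == "atg_to_stop":
                if orf_start is None and _is_start(codon):
                    orf_start = pos
                if stop and orf_start is not None:
                    aa = (pos - orf_start) // 3
                    if aa >= min_aa:
                        hits.append(
                            _to_forward(
                                seq_id, strand, frame, orf_start, pos + 3,
                                aa, False, n,
                            )
                        )
                    orf_start = None
            else:  # stop_to_stop
                if stop:
                    aa = (pos - region_start) // 3
                    if aa >= min_aa:
                        hits.append(
                            _to_forward(
                                seq_id, strand, frame, region_start, pos + 3,
                                aa, False, n,
                            )
                        )
                    region_start = pos + 3
            pos += 3
        # open-ended at the sequence boundary
        if mode == "atg_to_stop" and orf_start is not None:
            aa = (pos - orf_start) // 3
            if aa >= min_aa:
                hits.append(
                    _to_forward(seq_id, strand, frame, orf_start, pos, aa, True, n)
                )
        elif mode == "stop_to_stop":
            aa = (pos - region_start) // 3
            if aa >= min_aa:
                hits.append(
                    _to_forward(seq_id, strand, frame, region_start, pos, aa, True, n)
                )
    return hits


def _to_forward(
    seq_id: str, strand: str, frame: int, s: int, e: int, aa: int,
    truncated: bool, n: int,
) -> OrfHit:
    if strand == "+":
        start, end = s, e
    else:
        start, end = n - e, n - s
    return OrfHit(
        seq_id=seq_id, strand=strand, frame=frame,
        start=start, end=end, aa_len=aa, truncated=truncated,
    )


def find_orfs(
    record: SeqRecord, min_aa: int = 300, mode: str = "atg_to_stop"
) -> list[OrfHit]:
    """All maximal ORFs >= ``min_aa`` residues in all six frames.

    ``atg_to_stop``: from the first ATG after the previous stop to the next
    in-frame stop (stop optional at the sequence boundary; such hits are
    flagged truncated).  ``stop_to_stop``: full stop-free regions.  Codons
    containing N count as neither start nor stop.  Hits are sorted by
    (start, end, strand).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if mode not in ("atg_to_stop", "stop_to_stop"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = record.seq.upper()
    if not seq:
        raise ValueError(f"empty sequence {record.id!r}")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in {record.id!r}")
    hits = _scan_strand(seq, record.id, "+", min_aa, mode)
    hits += _scan_strand(revcomp(seq), record.id, "-", min_aa, mode)
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


@dataclass(frozen=True)
class BidirectionalPair:
    """A (+, -) ORF pair with overlapping spans; ``complete`` when one span
    contains the other, ``partial`` otherwise."""

    plus: OrfHit
    minus: OrfHit
    overlap_nt: int
    overlap_class: str

    def __post_init__(self) -> None:
        assert self.overlap_nt > 0


def detect_bidirectional_pairs(
    orfs: Iterable[OrfHit], min_overlap: int = 1
) -> list[BidirectionalPair]:
    """Every (+,-) ORF pair from one transcript whose spans overlap by at
    least ``min_overlap`` nt.  A transcript is bidirectional-positive when
    at least one pair exists."""
    orfs = list(orfs)
    ids = {h.seq_id for h in orfs}
    if len(ids) > 1:
        raise ValueError(f"ORFs from multiple transcripts: {sorted(ids)}")
    plus = [h for h in orfs if h.strand == "+"]
    minus = [h for h in orfs if h.strand == "-"]
    pairs: list[BidirectionalPair] = []
    for p in plus:
        for m in minus:
            ov = min(p.end, m.end) - max(p.start, m.start)
            if ov < min_overlap:
                continue
            contained = (
                (p.start <= m.start and m.end <= p.end)
                or (m.start <= p.start and p.end <= m.end)
            )
            pairs.append(
                BidirectionalPair(
                    plus=p, minus=m, overlap_nt=ov,
                    overlap_class="complete" if contained else "partial",
                )
            )
    return pairs


@dataclass(frozen=True)
class StrandSupport:
    """Fraction of each ORF's span with stranded read coverage >= min_depth;
    ``label`` is ``unsupported_minus`` when the antisense ORF lacks
    transcription evidence."""

    pair: BidirectionalPair
    plus_cov_fraction: float
    minus_cov_fraction: float
    label: str


def strand_support(
    pair: BidirectionalPair,
    plus_cov: Sequence[float],
    minus_cov: Sequence[float],
    min_depth: float = 1,
    min_fraction: float = 0.1,
) -> StrandSupport:
    """Per-strand covered fraction over each ORF's span.

    Coverage arrays are per-base over the whole transcript (forward
    coordinates); lengths must match between strands.
    """
    plus_cov = np.asarray(plus_cov, dtype=float)
    minus_cov = np.asarray(minus_cov, dtype=float)
    if plus_cov.shape != minus_cov.shape:
        raise ValueError("plus/minus coverage arrays differ in length")
    n = len(plus_cov)
    for h in (pair.plus, pair.minus):
        if h.end > n:
            raise ValueError(
                f"coverage array length {n} shorter than ORF end {h.end}"
            )
    p = pair.plus
    m = pair.minus
    pf = float((plus_cov[p.start : p.end] >= min_depth).mean())
    mf = float((minus_cov[m.start : m.end] >= min_depth).mean())
    label = "unsupported_minus" if mf < min_fraction else "supported"
    return StrandSupport(
        pair=pair, plus_cov_fraction=pf, minus_cov_fraction=mf, label=label
    )


@dataclass(frozen=True)
class UtrOverlap:
    gene_a: str
    gene_b: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def utr_overlap(
    a: GeneModel,
    b: GeneModel,
    min_overlap: int = 1,
    use_termini: bool = False,
    terminus_window: int = 200,
) -> UtrOverlap | None:
    """Shared-3'-UTR detection for a convergent gene pair.

    Reports an overlap iff the genes are on the same contig, on opposite
    strands, oriented convergently (3' ends face each other) and their
    3'-UTR intervals overlap by at least ``min_overlap`` nt.  When a gene
    lacks an annotated UTR and ``use_termini`` is set, a window of
    ``terminus_window`` nt at the gene's 3' terminus stands in.
    """
    if a.contig != b.contig or a.strand == b.strand:
        return None
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    # convergent: the + gene (3' end rightward) starts left of the - gene
    # (3' end leftward) so the two 3' ends face each other; anything else
    # (divergent or fully nested) is not a shared-3'-UTR configuration
    if not (plus.span[0] < minus.span[0] and plus.span[1] < minus.span[1]):
        return None

    def interval(g: GeneModel) -> tuple[int, int] | None:
        if g.utr3 is not None:
            return g.utr3
        if not use_termini:
            return None
        if g.strand == "+":
            return (g.span[1], g.span[1] + terminus_window)
        return (max(g.span[0] - terminus_window, 0), g.span[0])

    ia, ib = interval(plus), interval(minus)
    if ia is None or ib is None:
        return None
    s = max(ia[0], ib[0])
    e = min(ia[1], ib[1])
    if e - s < min_overlap:
        return None
    return UtrOverlap(gene_a=a.gene_id, gene_b=b.gene_id, start=s, end=e)
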