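"""Independent reference implementations used to cross-check the package.

These deliberately take different routes from the library code: the ORF
oracle goes through Biopython translation plus regex on the peptide, the
tree oracle builds random topologies while recording every clade it
creates, so monophyly answers are known by construction.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Seq import Seq


def brute_orfs(seq: str, min_aa: int, mode: str) -> set[tuple]:
    """All maximal ORFs >= min_aa as (strand, frame, start, end, aa_len,
    truncated) tuples in forward coordinates, via translate + regex."""
    out: set[tuple] = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            ncod = (n - frame) // 3
            if ncod == 0:
                continue
            pep = str(Seq(s[frame : frame + 3 * ncod]).translate())
            # split into stop-delimited segments, keeping offsets
            for m in re.finditer(r"[^*]+\*?", pep):
                seg = m.group(0)
                seg_start = m.start()
                has_stop = seg.endswith("*")
                body = seg[:-1] if has_stop else seg
                if mode == "atg_to_stop":
                    i = body.find("M")
                    if i < 0:
                        continue
                    aa = len(body) - i
                    c0 = seg_start + i
                else:
                    aa = len(body)
                    c0 = seg_start
                if aa < min_aa:
                    continue
                s_nt = frame + 3 * c0
                e_nt = frame + 3 * (seg_start + len(body)) + (3 if has_stop else 0)
                if strand == "-":
                    s_nt, e_nt = n - e_nt, n - s_nt
                out.add((strand, frame, s_nt, e_nt, aa, not has_stop))
    return out


def random_tree_with_clades(
    rng: np.random.Generator, n_leaves: int
) -> tuple[str, list[str], set[frozenset]]:
    """Random binary tree by repeated joins; returns (newick, leaves,
    clades) where ``clades`` are the leaf sets of every internal node
    created, known by construction."""
    leaves = [f"L{i}" for i in range(n_leaves)]
    items: list[tuple[str, frozenset]] = [(l, frozenset([l])) for l in leaves]
    clades: set[frozenset] = set()
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        merged = a[1] | b[1]
        sup = int(rng.integers(0, 101))
        bl = rng.uniform(0.01, 1.0)
        nwk = f"({a[0]}:{rng.uniform(0.01, 1.0):.4f},{b[0]}:{rng.uniform(0.01, 1.0):.4f}){sup}:{bl:.4f}"
        if len(items) > 0:
            clades.add(merged)
        items.append((nwk, merged))
    # strip the root's label/length for a clean top level
    top = items[0][0]
    top = top[: top.rfind(")") + 1]
    return top + ";", leaves, clades
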