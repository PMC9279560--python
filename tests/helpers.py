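"""Independent oracles used to check the fast implementations.

These are deliberately naive: exhaustive enumeration for alignment,
per-window Python loops for PWM scanning, direct point-mass summation for
the exact binomial test.  They share nothing with the implementation
paths they verify beyond the scoring inputs.
"""
from __future__ import annotations

import numpy as np


def oracle_global_align(a: str, b: str, score, gap_open: float,
                        gap_extend: float) -> float:
    """Best global alignment score by exhaustive enumeration of all
    alignments (affine gaps: first gap position costs gap_open, each
    further position gap_extend; a gap in one sequence immediately
    followed by a gap in the other opens anew)."""
    best = [-np.inf]
    la, lb = len(a), len(b)

    def rec(i, j, acc, state):  # state: 0 diagonal, 1 gap-in-b, 2 gap-in-a
        if i == la and j == lb:
            if acc > best[0]:
                best[0] = acc
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, acc + score(a[i], b[j]), 0)
        if i < la:
            rec(i + 1, j, acc - (gap_extend if state == 1 else gap_open), 1)
        if j < lb:
            rec(i, j + 1, acc - (gap_extend if state == 2 else gap_open), 2)

    rec(0, 0, 0.0, 0)
    return best[0]


def oracle_scan(seq: str, scores: np.ndarray, min_rel: float):
    """All PWM windows (both strands) at or above a relative score, by a
    plain per-window loop.  Returns {(start, strand): rel_score}."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    w = scores.shape[1]
    smax = sum(max(scores[b, j] for b in range(4)) for j in range(w))
    smin = sum(min(scores[b, j] for b in range(4)) for j in range(w))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = {}
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        for p in range(len(s) - w + 1):
            sc = 0.0
            for j in range(w):
                sc += scores[idx[s[p + j]], j]
            rel = (sc - smin) / (smax - smin)
            if rel >= min_rel:
                start = p if strand == "+" else len(seq) - p - w
                out[(start, strand)] = rel
    return out


def oracle_binom_p(k: int, n: int) -> float:
    """Two-sided exact binomial p (null 0.5) by point-mass summation."""
    from scipy.stats import binom

    pm = binom.pmf(np.arange(n + 1), n, 0.5)
    return float(pm[pm <= pm[k] * (1 + 1e-12)].sum())


def mutate_protein(seq: str, frac: float, rng: np.random.Generator) -> str:
    """Randomly substitute a fraction of residues (for decoy/duplicate
    fixtures)."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    arr = list(seq)
    k = int(round(frac * len(arr)))
    for i in rng.choice(len(arr), size=k, replace=False):
        choices = [x for x in aas if x != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def random_protein(length: int, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, size=length))


def newick_cherries(newick: str) -> set[frozenset]:
    """Tip pairs that share an immediate parent, via scikit-bio."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    out = set()
    for node in tree.traverse():
        kids = getattr(node, "children", [])
        tips = [c for c in kids if c.is_tip()]
        if len(kids) == 2 and len(tips) == 2:
            out.add(frozenset(t.name for t in tips))
    return out
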