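"""One-to-one allelic gene pairing between two haploid gene sets.

Allele pairs are found by global protein alignment (Needleman-Wunsch with
affine gaps, BLOSUM62 by default) and reciprocal-best-hit matching, kept
only when percent identity reaches the pairing threshold (95% by
default).  Within-haplotype duplications are grouped by the two-criterion
rule: alignment coverage of the longer sequence >= 75% and similarity
>= 90%.  A neighbor-joining tree over all proteins lets the allelic
sister relationship be checked topologically.

Identity here uses the alignment length (gap columns included) as its
denominator, BLAST-style; "similarity" defaults to identity, with a
substitution-matrix-positive definition available via
``similarity="positive"``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Default protein scoring: BLOSUM62, gap open 10, gap extend 1 (the open
#: score applies to the first gap position).
PROTEIN_SCORING = {"matrix": "BLOSUM62", "gap_open": 10.0, "gap_extend": 1.0}


@dataclass(frozen=True)
class AlignmentResult:
    """Summary statistics of one global pairwise protein alignment.

    ``identity_pct`` counts identical columns over all alignment columns
    (gaps included); ``similarity_pct`` additionally counts positive
    substitution-matrix pairs; ``coverage_pct`` is the fraction of the
    longer sequence's length covered by both-residue columns.
    """

    columns: int
    identities: int
    similarities: int
    score: float
    len_a: int
    len_b: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.columns

    @property
    def similarity_pct(self) -> float:
        return 100.0 * self.similarities / self.columns

    both_columns: int = 0

    @property
    def coverage_pct(self) -> float:
        """Both-residue columns over the longer sequence's length."""
        return 100.0 * self.both_columns / max(self.len_a, self.len_b)


@dataclass(frozen=True)
class AllelePair:
    id_h1: str
    id_h2: str
    result: AlignmentResult
    category: str = ""


@dataclass(frozen=True)
class DuplicationGroup:
    members: tuple[str, ...]
    stats: tuple[tuple[str, str, float, float], ...]  # (a, b, similarity, coverage)


def _aligner(scoring: dict | None = None) -> Align.PairwiseAligner:
    s = dict(PROTEIN_SCORING, **(scoring or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(s["matrix"])
    aligner.open_gap_score = -s["gap_open"]
    aligner.extend_gap_score = -s["gap_extend"]
    return aligner


def align_pair(a: str, b: str, scoring: dict | None = None) -> AlignmentResult:
    """Optimal global alignment of two protein sequences with statistics.

    Raises
    ------
    ValueError
        If either sequence is empty or contains a non-amino-acid symbol
        (the offending character is named).
    """
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{name} sequence contains non-amino-acid symbol "
                f"{sorted(bad)[0]!r}"
            )
    aligner = _aligner(scoring)
    matrix = aligner.substitution_matrix
    aln = aligner.align(a, b)[0]
    g1, g2 = str(aln[0]), str(aln[1])
    ident = sim = both = 0
    for x, y in zip(g1, g2):
        if x == "-" or y == "-":
            continue
        both += 1
        if x == y:
            ident += 1
        if matrix[x, y] > 0:
            sim += 1
    return AlignmentResult(
        columns=len(g1),
        identities=ident,
        similarities=sim,
        score=float(aln.score),
        len_a=len(a),
        len_b=len(b),
        both_columns=both,
    )


def pair_alleles(
    set_h1: Mapping[str, str],
    set_h2: Mapping[str, str],
    min_identity_pct: float = 95.0,
    scoring: dict | None = None,
):
    """Reciprocal-best-hit allele pairing between two haploid gene sets.

    Best hits are chosen by raw alignment score, ties broken toward the
    lexicographically smaller partner id, so the output is deterministic
    under any input ordering.  Pairs below ``min_identity_pct`` global
    identity are rejected.

    Returns
    -------
    (pairs, unpaired_h1, unpaired_h2)
        ``pairs`` is a list of :class:`AllelePair` sorted by haplotype-1
        id; the unpaired lists hold the remaining ids, sorted.
    """
    ids1, ids2 = sorted(set_h1), sorted(set_h2)
    results: dict[tuple[str, str], AlignmentResult] = {}
    for i in ids1:
        for j in ids2:
            results[(i, j)] = align_pair(set_h1[i], set_h2[j], scoring)

    def best(candidates, key):
        return max(candidates, key=lambda x: (key(x), _neg_lex(x)))

    def _neg_lex(s: str):
        return tuple(-ord(c) for c in s)

    best1 = {i: best(ids2, key=lambda j: results[(i, j)].score) for i in ids1}
    best2 = {j: best(ids1, key=lambda i: results[(i, j)].score) for j in ids2}

    pairs = []
    paired1, paired2 = set(), set()
    for i in ids1:
        j = best1[i]
        if best2[j] == i and results[(i, j)].identity_pct >= min_identity_pct:
            pairs.append(AllelePair(id_h1=i, id_h2=j, result=results[(i, j)]))
            paired1.add(i)
            paired2.add(j)
    unpaired1 = [i for i in ids1 if i not in paired1]
    unpaired2 = [j for j in ids2 if j not in paired2]
    return pairs, unpaired1, unpaired2


def detect_duplications(
    gene_set: Mapping[str, str],
    min_coverage_pct: float = 75.0,
    min_similarity_pct: float = 90.0,
    similarity: str = "identity",
    scoring: dict | None = None,
) -> list[DuplicationGroup]:
    """Group within-haplotype duplicated genes by single-linkage closure.

    A gene pair qualifies when (1) both-residue alignment columns cover at
    least ``min_coverage_pct`` of the longer protein and (2) the pair's
    similarity (percent identity by default, or substitution-matrix
    positive columns with ``similarity="positive"``) reaches
    ``min_similarity_pct``.  Singletons are omitted.
    """
    if similarity not in ("identity", "positive"):
        raise ValueError("similarity must be 'identity' or 'positive'")
    ids = sorted(gene_set)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    qualifying = []
    for n, i in enumerate(ids):
        for j in ids[n + 1 :]:
            r = align_pair(gene_set[i], gene_set[j], scoring)
            sim = r.identity_pct if similarity == "identity" else r.similarity_pct
            if r.coverage_pct >= min_coverage_pct and sim >= min_similarity_pct:
                qualifying.append((i, j, sim, r.coverage_pct))
                parent[find(i)] = find(j)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        mset = set(members)
        stats = tuple(
            (i, j, s, c) for i, j, s, c in qualifying if i in mset and j in mset
        )
        out.append(DuplicationGroup(members=tuple(sorted(members)), stats=stats))
    return sorted(out, key=lambda g: g.members)


# --------------------------------------------------------------------- #
# Neighbor joining


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Standard Saitou-Nei agglomeration with deterministic tie-breaking
    (smallest index pair).  On additive matrices the resulting tree's
    path lengths reproduce the input distances exactly; branch lengths
    are reported unclamped, so slightly negative values can occur on
    non-additive input.

    Raises
    ------
    ValueError
        If the matrix is not square/symmetric, has a nonzero diagonal,
        non-finite entries, or fewer than 3 taxa.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n != len(labels):
        raise ValueError("labels do not match matrix size")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite values")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    nodes = [f"{lab}" for lab in labels]
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new_label)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"


def p_distance_matrix(proteins: Mapping[str, str], scoring: dict | None = None):
    """Pairwise p-distances (1 - identity fraction) over a protein set.

    Returns ``(matrix, labels)`` ready for :func:`nj_tree`.
    """
    labels = sorted(proteins)
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            r = align_pair(proteins[labels[a]], proteins[labels[b]], scoring)
            d[a, b] = d[b, a] = 1.0 - r.identities / r.columns
    return d, labels
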