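"""Promoter extraction, JASPAR PWM scanning, and allele-differential sites.

Promoters are the 3 kb immediately upstream of the start codon.  Position
frequency matrices are converted to log2-odds position weight matrices
with a total pseudocount of 0.8 distributed by the background
(Wasserman-Sandelin convention) and scanned over both strands of each
allele's promoter; windows are kept at a relative score
(score - min) / (max - min) of at least 0.85 by default.  Hits are then
matched across the two allele promoters through the indel-aware
coordinate map derived from the promoter variant list, and unmatched or
score-shifted sites are reported as allele-differential, annotated with
the variants that overlap them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import GeneModel, Variant, revcomp
from .variants import position_map

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class Promoter:
    """One allele's promoter: the bases upstream of the start codon."""

    gene_id: str
    haplotype: str
    seq: str
    interval: tuple[int, int]
    strand: str
    truncated: bool = False


@dataclass(frozen=True)
class PFM:
    """A position frequency matrix: motif id, name, and 4 x w counts
    (rows A, C, G, T)."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x w")
        if (c < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log2-odds scoring matrix derived from a PFM."""

    motif_id: str
    name: str
    probs: np.ndarray
    scores: np.ndarray
    background: tuple[float, ...]

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.scores.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """One PWM window meeting the relative-score threshold.

    ``start`` is the forward-strand window start in promoter coordinates,
    for hits on either strand.
    """

    motif_id: str
    start: int
    strand: str
    score: float
    rel_score: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class DiffSite:
    """An allele-differential binding site.

    ``status`` is "lost" (present on allele 1 only), "gained" (allele 2
    only) or "score-shifted"; positions are promoter coordinates on the
    respective allele (None when absent).
    """

    motif_id: str
    status: str
    strand: str
    pos_h1: int | None
    pos_h2: int | None
    rel_h1: float | None
    rel_h2: float | None
    variants: tuple[Variant, ...] = ()


# --------------------------------------------------------------------- #
# Promoter extraction


def extract_promoter(
    contig_seq: str,
    model: GeneModel,
    length: int = 3000,
    haplotype: str = "h1",
) -> Promoter:
    """The ``length`` bases upstream of a gene's start codon, 5'->3'.

    Plus-strand genes yield the bases ending immediately before the start
    codon; minus-strand genes the reverse complement of the bases
    beginning immediately after the start codon's forward coordinate.
    Promoters truncated by the contig edge are returned shorter, with a
    warning.
    """
    cs = model.start_codon_pos
    if model.strand == "+":
        start = max(0, cs - length)
        iv = (start, cs)
        seq = contig_seq[start:cs]
    else:
        end = min(len(contig_seq), cs + length)
        iv = (cs, end)
        seq = revcomp(contig_seq[cs:end])
    truncated = len(seq) < length
    if truncated:
        warnings.warn(
            f"gene {model.gene_id}: promoter truncated to {len(seq)} bp at the "
            "contig edge"
        )
    return Promoter(
        gene_id=model.gene_id,
        haplotype=haplotype,
        seq=seq.upper(),
        interval=iv,
        strand=model.strand,
        truncated=truncated,
    )


# --------------------------------------------------------------------- #
# JASPAR parsing


def read_jaspar(source) -> list[PFM]:
    """Parse JASPAR-format motif text into PFMs.

    Accepts the bracketed 2016+ dialect (``A [ 1 2 3 ]``) and the
    bare whitespace dialect (``A 1 2 3`` or four unlabeled rows in
    A, C, G, T order) identically.  ``source`` is a path or file handle.

    Raises
    ------
    ValueError
        If a motif's rows have unequal lengths (the motif is named).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    motifs: list[PFM] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            if rows:
                raise ValueError("count rows before any >header line")
            return
        if len(rows) != 4:
            raise ValueError(
                f"motif {header[0]}: expected 4 count rows, got {len(rows)}"
            )
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"motif {header[0]}: rows of unequal length")
        motifs.append(PFM(motif_id=header[0], name=header[1],
                          counts=np.array(rows, dtype=float)))
        header, rows = None, []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
            continue
        line = line.replace("[", " ").replace("]", " ")
        fields = line.split()
        if fields and fields[0].upper() in "ACGT" and len(fields[0]) == 1:
            fields = fields[1:]
        rows.append([float(x) for x in fields])
    flush()
    return motifs


def pfm_to_pwm(
    pfm: PFM,
    background: tuple[float, float, float, float] = UNIFORM_BG,
    pseudocount_total: float = 0.8,
) -> PWM:
    """Log2-odds PWM from counts with a background-distributed pseudocount.

    Per cell: p = (count + bg_b * pseudocount_total) /
    (column_sum + pseudocount_total); score = log2(p / bg_b).

    Raises
    ------
    ValueError
        If a column sums to zero while the pseudocount is zero.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be four positive probabilities summing to 1")
    colsum = pfm.counts.sum(axis=0)
    if pseudocount_total <= 0 and (colsum == 0).any():
        raise ValueError(
            f"motif {pfm.motif_id}: zero column sum with zero pseudocount"
        )
    probs = (pfm.counts + bg[:, None] * pseudocount_total) / (
        colsum[None, :] + pseudocount_total
    )
    scores = np.log2(probs / bg[:, None])
    return PWM(
        motif_id=pfm.motif_id,
        name=pfm.name,
        probs=probs,
        scores=scores,
        background=tuple(bg),
    )


# --------------------------------------------------------------------- #
# Scanning


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def scan_pwm(
    promoter,
    pwm: PWM,
    min_relative_score: float = 0.85,
    strands: str = "both",
    n_policy: str = "background",
) -> list[MotifHit]:
    """Exhaustive sliding-window PWM scan of a promoter sequence.

    Every window on the requested strand(s) is scored; windows whose
    relative score reaches ``min_relative_score`` are returned sorted by
    forward-strand start position.  An N base contributes a log-odds of 0
    (it is scored at the background probability) under the default
    ``n_policy="background"``; ``n_policy="skip"`` drops windows that
    contain an N.

    ``promoter`` may be a :class:`Promoter` or a plain sequence string.
    """
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    if n_policy not in ("background", "skip"):
        raise ValueError("n_policy must be 'background' or 'skip'")
    seq = promoter.seq if hasattr(promoter, "seq") else str(promoter)
    w = pwm.width
    if len(seq) < w:
        raise ValueError("promoter shorter than motif width")
    span = pwm.max_score - pwm.min_score
    hits: list[MotifHit] = []
    # scores extended with an all-zero row for N
    ext = np.vstack([pwm.scores, np.zeros(w)])
    for strand in ("+", "-"):
        if strands != "both" and strand != strands:
            continue
        s = seq if strand == "+" else revcomp(seq)
        idx = _encode(s)
        n_win = len(s) - w + 1
        win_scores = np.zeros(n_win)
        has_n = np.zeros(n_win, dtype=bool)
        for j in range(w):
            col = idx[j : j + n_win]
            win_scores += ext[col, j]
            has_n |= col == 4
        rel = (win_scores - pwm.min_score) / span
        keep = rel >= min_relative_score
        if n_policy == "skip":
            keep &= ~has_n
        for p in np.flatnonzero(keep):
            start = int(p) if strand == "+" else len(seq) - int(p) - w
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    start=start,
                    strand=strand,
                    score=float(win_scores[p]),
                    rel_score=float(rel[p]),
                    width=w,
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.strand, h.motif_id))


# --------------------------------------------------------------------- #
# Differential sites


def differential_sites(
    hits_h1: list[MotifHit],
    hits_h2: list[MotifHit],
    promoter_variants: list[Variant] | None = None,
    match_tolerance: int = 0,
    min_rel_shift: float = 0.1,
) -> list[DiffSite]:
    """Compare two alleles' hit sets and report differential sites.

    Hits are paired by motif id and strand when the haplotype-1 start,
    mapped through the indel-aware coordinate map built from
    ``promoter_variants`` (haplotype-1 promoter coordinates), lands
    within ``match_tolerance`` bp of a haplotype-2 start.  A hit without
    a partner is "lost" (allele 1 only) or "gained" (allele 2 only);
    paired hits whose relative scores differ by at least
    ``min_rel_shift`` are "score-shifted".  Each site is annotated with
    the variants overlapping its window.  Swapping the two hit lists
    swaps gained and lost.
    """
    variants = promoter_variants or []
    map12 = position_map(variants)
    h2_pool: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits_h2:
        h2_pool.setdefault((h.motif_id, h.strand), []).append(h)

    out: list[DiffSite] = []
    matched2: set[int] = set()
    for h1 in sorted(hits_h1, key=lambda h: (h.start, h.strand, h.motif_id)):
        target = map12(h1.start)
        partner = None
        for h2 in h2_pool.get((h1.motif_id, h1.strand), []):
            if id(h2) in matched2:
                continue
            if abs(h2.start - target) <= match_tolerance:
                partner = h2
                break
        if partner is None:
            out.append(
                DiffSite(
                    motif_id=h1.motif_id,
                    status="lost",
                    strand=h1.strand,
                    pos_h1=h1.start,
                    pos_h2=None,
                    rel_h1=h1.rel_score,
                    rel_h2=None,
                    variants=_overlapping(variants, h1.start, h1.end),
                )
            )
            continue
        matched2.add(id(partner))
        if abs(h1.rel_score - partner.rel_score) >= min_rel_shift:
            out.append(
                DiffSite(
                    motif_id=h1.motif_id,
                    status="score-shifted",
                    strand=h1.strand,
                    pos_h1=h1.start,
                    pos_h2=partner.start,
                    rel_h1=h1.rel_score,
                    rel_h2=partner.rel_score,
                    variants=_overlapping(variants, h1.start, h1.end),
                )
            )

    # reverse map for unmatched haplotype-2 hits
    inv = _inverse_map(variants)
    for h2 in sorted(hits_h2, key=lambda h: (h.start, h.strand, h.motif_id)):
        if id(h2) in matched2:
            continue
        back = inv(h2.start)
        out.append(
            DiffSite(
                motif_id=h2.motif_id,
                status="gained",
                strand=h2.strand,
                pos_h1=None,
                pos_h2=h2.start,
                rel_h1=None,
                rel_h2=h2.rel_score,
                variants=_overlapping(variants, back, back + h2.width),
            )
        )
    return out


def _overlapping(variants, start: int, end: int) -> tuple[Variant, ...]:
    out = []
    for v in variants:
        span = max(len(v.ref), 1)
        if v.pos < end and start < v.pos + span:
            out.append(v)
    return tuple(out)


def _inverse_map(variants):
    """Haplotype-2 -> haplotype-1 coordinate map (indels mirrored)."""
    flipped = []
    map12 = position_map(variants)
    for v in variants:
        if v.vtype == "insertion":
            flipped.append(
                Variant(pos=map12(v.pos), vtype="deletion", ref=v.alt, alt="")
            )
        elif v.vtype == "deletion":
            flipped.append(
                Variant(pos=map12(v.pos), vtype="insertion", ref="", alt=v.ref)
            )
    return position_map(flipped)
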