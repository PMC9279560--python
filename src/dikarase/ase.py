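"""Allelic expression bias from SNP-locus read depths.

Reads placed on the allelic transcript pair vote for one allele at every
distinguishing SNP locus they cover; per-gene allele counts are tested
against a balanced-origin null with an exact two-sided binomial test,
Benjamini-Hochberg adjusted across genes within each growth condition.
A gene is called consistently biased when the same direction is
significant in a sufficient fraction of informative conditions, so a
single discordant condition (the XM-like case) does not veto the call.
Clone-sequencing counts are validated with the same exact binomial
machinery plus a Clopper-Pearson interval.

Caveat on aggregation: SNP loci of one gene share reads, so summed
per-locus depths are not independent observations; the binomial p-values
are exact for the counts as aggregated, not for unique fragments.  A
per-locus-ratio mode is provided for sensitivity analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, binomtest, false_discovery_control

from .models import GeneModel
from .variants import position_map

__all__ = [
    "SnpLocus",
    "build_snp_loci",
    "assign_reads_to_alleles",
    "depths_from_sam",
    "aggregate_gene_depths",
    "binomial_bias_test",
    "bias_table",
    "call_consistent_bias",
    "clone_binomial_validation",
    "required_clone_count",
]

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SnpLocus:
    """A transcribed SNP distinguishing the two alleles of one gene.

    ``pos_h1`` is the forward-strand genomic position on haplotype 1;
    ``tpos_h1``/``tpos_h2`` are the locus' coordinates on the two mature
    transcripts and ``tbase_h1``/``tbase_h2`` the transcript-strand bases
    there (complemented for minus-strand genes).
    """

    gene_id: str
    pos_h1: int
    base_h1: str
    base_h2: str
    tpos_h1: int
    tpos_h2: int
    tbase_h1: str
    tbase_h2: str


def build_snp_loci(
    variants, model_h1: GeneModel, model_h2: GeneModel
) -> list[SnpLocus]:
    """Lift the transcribed SNPs of one gene pair onto both transcripts.

    ``variants`` is the full variant list for the gene (haplotype-1
    coordinates); indels in the list are used only to shift the
    haplotype-2 coordinates of downstream SNPs (via the gene models).
    Only SNPs inside the mature transcript (UTRs and exons) are usable.
    """
    gene_vars = [v for v in variants if v.gene_id == model_h1.gene_id or not v.gene_id]
    map_pos = position_map(gene_vars)
    loci = []
    for v in gene_vars:
        if v.vtype != "SNP":
            continue
        t1 = model_h1.genomic_to_transcript(v.pos)
        if t1 is None:
            continue
        t2 = model_h2.genomic_to_transcript(map_pos(v.pos))
        if t2 is None:
            raise ValueError(
                f"SNP at {v.pos} transcribed on haplotype 1 but not on haplotype 2"
            )
        if model_h1.strand == "+":
            b1, b2 = v.ref, v.alt
        else:
            b1, b2 = v.ref.translate(_COMP), v.alt.translate(_COMP)
        loci.append(
            SnpLocus(
                gene_id=model_h1.gene_id,
                pos_h1=v.pos,
                base_h1=v.ref,
                base_h2=v.alt,
                tpos_h1=t1,
                tpos_h2=t2,
                tbase_h1=b1,
                tbase_h2=b2,
            )
        )
    return sorted(loci, key=lambda l: l.tpos_h1)


# --------------------------------------------------------------------- #
# Read assignment


def assign_reads_to_alleles(
    reads: pd.DataFrame,
    transcripts_h1: dict[str, str],
    transcripts_h2: dict[str, str],
    loci_by_gene: dict[str, list[SnpLocus]],
) -> pd.DataFrame:
    """Count allele votes at every SNP locus, per condition and gene.

    Reads (columns ``condition, gene, seq``) are placed by exact substring
    match, first on the haplotype-1 transcript and otherwise on the
    haplotype-2 transcript; reads matching neither (e.g. carrying
    sequencing errors) are left unassigned.  At each covered locus the
    read's base votes allele 1, allele 2, or "other"; a read whose loci
    votes conflict between the two alleles is discarded as ambiguous.

    Returns a frame with one row per (condition, gene, locus):
    ``depth_h1, depth_h2, depth_other``.

    Raises
    ------
    ValueError
        If a locus lies outside its transcript.
    """
    for gene, loci in loci_by_gene.items():
        for l in loci:
            if not (0 <= l.tpos_h1 < len(transcripts_h1[gene])) or not (
                0 <= l.tpos_h2 < len(transcripts_h2[gene])
            ):
                raise ValueError(f"locus {l.pos_h1} outside transcript of {gene}")

    counts: dict[tuple, np.ndarray] = {}
    for (cond, gene), sub in reads.groupby(["condition", "gene"], sort=True):
        loci = loci_by_gene.get(gene, [])
        if not loci:
            continue
        tx1, tx2 = transcripts_h1[gene], transcripts_h2[gene]
        arr = np.zeros((len(loci), 3), dtype=int)
        for seq in sub["seq"]:
            p1 = tx1.find(seq)
            if p1 >= 0:
                votes = _votes(seq, p1, loci, use_h1=True)
            else:
                p2 = tx2.find(seq)
                if p2 < 0:
                    continue
                votes = _votes(seq, p2, loci, use_h1=False)
            sides = {s for _, s in votes if s in (0, 1)}
            if len(sides) > 1:
                continue  # ambiguous: conflicting allele votes
            for idx, side in votes:
                arr[idx, side] += 1
        counts[(cond, gene)] = arr

    rows = []
    for (cond, gene), arr in counts.items():
        for idx, l in enumerate(loci_by_gene[gene]):
            rows.append(
                (cond, gene, l.pos_h1, int(arr[idx, 0]), int(arr[idx, 1]),
                 int(arr[idx, 2]))
            )
    return pd.DataFrame(
        rows,
        columns=["condition", "gene", "locus", "depth_h1", "depth_h2", "depth_other"],
    )


def _votes(seq: str, start: int, loci, use_h1: bool):
    L = len(seq)
    out = []
    for idx, l in enumerate(loci):
        tpos = l.tpos_h1 if use_h1 else l.tpos_h2
        if start <= tpos < start + L:
            base = seq[tpos - start]
            if base == l.tbase_h1:
                out.append((idx, 0))
            elif base == l.tbase_h2:
                out.append((idx, 1))
            else:
                out.append((idx, 2))
    return out


def depths_from_sam(
    sam_path, loci_by_gene: dict[str, list[SnpLocus]], condition: str = "NA"
) -> pd.DataFrame:
    """Build an allele depth table from externally aligned reads (text SAM).

    Alignments must target the haplotype-1 transcripts (reference names =
    gene ids); votes follow the same rules as
    :func:`assign_reads_to_alleles`.
    """
    import pysam

    counts: dict[str, np.ndarray] = {
        g: np.zeros((len(loci), 3), dtype=int) for g, loci in loci_by_gene.items()
    }
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in loci_by_gene:
                continue
            loci = loci_by_gene[aln.reference_name]
            pairs = dict(
                (r, q) for q, r in aln.get_aligned_pairs(matches_only=True)
            )
            votes = []
            for idx, l in enumerate(loci):
                q = pairs.get(l.tpos_h1)
                if q is None:
                    continue
                base = aln.query_sequence[q]
                if base == l.tbase_h1:
                    votes.append((idx, 0))
                elif base == l.tbase_h2:
                    votes.append((idx, 1))
                else:
                    votes.append((idx, 2))
            sides = {s for _, s in votes if s in (0, 1)}
            if len(sides) > 1:
                continue
            for idx, side in votes:
                counts[aln.reference_name][idx, side] += 1
    rows = []
    for gene, loci in loci_by_gene.items():
        for idx, l in enumerate(loci):
            c = counts[gene][idx]
            rows.append((condition, gene, l.pos_h1, int(c[0]), int(c[1]), int(c[2])))
    return pd.DataFrame(
        rows,
        columns=["condition", "gene", "locus", "depth_h1", "depth_h2", "depth_other"],
    )


# --------------------------------------------------------------------- #
# Aggregation and testing


def aggregate_gene_depths(table: pd.DataFrame, mode: str = "sum") -> pd.DataFrame:
    """Collapse per-locus depths to per (condition, gene) allele counts.

    ``mode="sum"`` (default) sums depths over loci; ``mode="mean_ratio"``
    reports the unweighted mean of per-locus allele-1 ratios instead of
    the pooled ratio (counts stay summed either way).  Genes without any
    informative depth are flagged ``informative=False`` and should be
    excluded from testing.
    """
    if mode not in ("sum", "mean_ratio"):
        raise ValueError("mode must be 'sum' or 'mean_ratio'")
    if table.empty:
        raise ValueError("empty depth table")
    g = table.groupby(["condition", "gene"], sort=True)
    out = g[["depth_h1", "depth_h2"]].sum().rename(
        columns={"depth_h1": "count_h1", "depth_h2": "count_h2"}
    )
    total = out["count_h1"] + out["count_h2"]
    out["informative"] = total > 0
    with np.errstate(invalid="ignore"):
        out["ratio_h1"] = out["count_h1"] / total
    if mode == "mean_ratio":
        def _mean_ratio(sub):
            t = sub["depth_h1"] + sub["depth_h2"]
            ok = t > 0
            if not ok.any():
                return np.nan
            return float((sub.loc[ok, "depth_h1"] / t[ok]).mean())

        out["ratio_h1"] = g.apply(_mean_ratio, include_groups=False)
    return out.reset_index()


def binomial_bias_test(count_h1: int, count_h2: int) -> tuple[float, float]:
    """Exact two-sided binomial test of allele balance (null p = 0.5).

    Returns ``(ratio_h1, p_value)``; the p-value sums all outcome
    probabilities not exceeding that of the observed count.
    """
    n = count_h1 + count_h2
    if n < 1:
        raise ValueError("need at least one informative read")
    r = binomtest(count_h1, n, 0.5)
    return count_h1 / n, float(r.pvalue)


def bias_table(agg: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-condition bias tests with BH adjustment across genes.

    Input is the output of :func:`aggregate_gene_depths`; uninformative
    rows are dropped.  Adds ``p``, ``q`` (BH within condition),
    ``direction`` (h1/h2/none) and ``significant`` columns.
    """
    df = agg[agg["informative"]].copy()
    ps = [
        binomial_bias_test(int(r.count_h1), int(r.count_h2))[1]
        for r in df.itertuples()
    ]
    df["p"] = ps
    df["q"] = np.nan
    for cond, idx in df.groupby("condition").groups.items():
        df.loc[idx, "q"] = false_discovery_control(df.loc[idx, "p"].to_numpy())
    df["direction"] = np.where(
        df["count_h1"] > df["count_h2"], "h1",
        np.where(df["count_h2"] > df["count_h1"], "h2", "none"),
    )
    df["significant"] = df["q"] < alpha
    return df


@dataclass(frozen=True)
class BiasCall:
    gene: str
    called: bool
    direction: str
    n_informative: int
    n_support: int
    supporting_conditions: tuple[str, ...]
    mean_ratio_h1: float


def call_consistent_bias(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_fraction_conditions: float = 0.9,
) -> list[BiasCall]:
    """Cross-condition consistency calls from per-condition bias tests.

    A gene is called biased when one direction is BH-significant
    (``q < alpha``) in at least ``min_fraction_conditions`` of its
    informative conditions (default 0.9, so 18 of 19 conditions suffice
    while an alternating pattern never does).  At least two informative
    conditions are required.
    """
    calls = []
    for gene, sub in results.groupby("gene", sort=True):
        n_inf = len(sub)
        best_dir, best_conds = "none", []
        for direction in ("h1", "h2"):
            conds = sub.loc[
                (sub["direction"] == direction) & (sub["q"] < alpha), "condition"
            ].tolist()
            if len(conds) > len(best_conds):
                best_dir, best_conds = direction, conds
        called = (
            n_inf >= 2 and len(best_conds) / n_inf >= min_fraction_conditions
        )
        calls.append(
            BiasCall(
                gene=gene,
                called=bool(called),
                direction=best_dir if called else "none",
                n_informative=n_inf,
                n_support=len(best_conds),
                supporting_conditions=tuple(sorted(best_conds)),
                mean_ratio_h1=float(sub["ratio_h1"].mean()),
            )
        )
    return calls


# --------------------------------------------------------------------- #
# Clone validation


@dataclass(frozen=True)
class CloneValidation:
    k_allele1: int
    n: int
    ratio: float
    p_value: float
    ci_low: float
    ci_high: float


def clone_binomial_validation(k: int, n: int) -> CloneValidation:
    """Exact binomial test and Clopper-Pearson 95% CI for clone counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    r = binomtest(k, n, 0.5)
    ci = r.proportion_ci(confidence_level=0.95, method="exact")
    return CloneValidation(
        k_allele1=k,
        n=n,
        ratio=k / n,
        p_value=float(r.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def required_clone_count(
    pi: float, alpha: float = 0.05, power: float = 0.8, max_n: int = 5000
) -> int:
    """Smallest clone count whose exact test detects a bias of size pi.

    Returns the minimal n such that the exact two-sided binomial test
    (reject when p < alpha) rejects the balanced null with probability at
    least ``power`` when the true allele-1 origin probability is ``pi``.
    Degenerate pi of 0 or 1 reduce to the smallest n with
    2 * 0.5**n <= alpha.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if pi == 0.5:
        raise ValueError("pi must differ from the null value 0.5")
    if pi in (0.0, 1.0):
        n = 1
        while 2 * 0.5**n > alpha:
            n += 1
        return n
    for n in range(1, max_n + 1):
        ks = np.arange(n + 1)
        pm_null = binom.pmf(ks, n, 0.5)
        # exact two-sided p for each k: sum of null masses <= pmf(k)
        order = pm_null[:, None] <= pm_null[None, :] * (1 + 1e-12)
        pvals = (pm_null[:, None] * order).sum(axis=0)
        reject = pvals < alpha
        if (binom.pmf(ks, n, pi) * reject).sum() >= power:
            return n
    raise ValueError(f"no n <= {max_n} reaches the requested power")
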