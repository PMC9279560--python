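"""Synthetic dikaryotic genomes with known allelic ground truth.

The generator emulates the study design for a dikaryotic fungus: two
haploid nuclei share a cytoplasm, every gene exists as an allelic pair,
and the two copies differ by SNPs and small indels at rates that are
higher in untranslated/intronic sequence than in coding sequence.  On top
of the genomes it simulates RNA-seq reads whose allele of origin follows a
latent per-gene probability pi (the quantity whose estimate is the allelic
read-count ratio), clone-sequencing draws, qPCR dilution plates, and
promoter motif occurrences disrupted on one allele.

Everything is driven by a single integer seed; identical configuration
yields byte-identical FASTA/GFF/FASTQ output.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import (
    EXON,
    GeneModel,
    PROMOTER,
    Variant,
    apply_variants,
    position_map,
    revcomp,
)
from .variants import normalize_variants, partition_regions

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}

#: The 19 growth conditions (carbon sources) of the default study design.
CONDITIONS = (
    "MM", "LM", "CM", "XM", "COM", "CHM", "WSM", "RSM", "BRM", "PWM",
    "PNM", "SWM", "SNM", "PTM", "CSM", "CLM", "BM", "OWM", "PDA",
)

#: Condition on which the biased gene reverts to balance (discordant case).
DISCORDANT_CONDITION = "XM"


@dataclass
class SimConfig:
    """Parameters of the synthetic dikaryon.

    Defaults encode the study conditions: 15 gene families (one biased
    family at pi = 0.626 on every carbon source except XM), 19 growth
    conditions, non-coding divergence three times the coding rate, and
    150 bp single-end reads.
    """

    n_families: int = 15
    snp_rate_coding: float = 0.005
    snp_rate_noncoding: float = 0.015
    indel_rate: float = 5e-4
    indel_len_range: tuple[int, int] = (1, 10)
    n_conditions: int = 19
    depth_per_gene: float = 800.0
    read_len: int = 150
    seq_error_rate: float = 0.0
    bias_map: dict = field(default_factory=dict)
    seed: int = 0
    # gene architecture
    cds_len_range: tuple[int, int] = (900, 1998)
    n_introns_range: tuple[int, int] = (1, 12)
    intron_len_range: tuple[int, int] = (50, 120)
    utr5_len: int = 150
    utr3_len: int = 200
    promoter_len: int = 3000
    pad: int = 100
    strands: str = "alternate"  # "alternate" | "plus" | "minus"
    biased_gene_index: int = 6  # 0-based family index carrying the planted bias
    biased_pi: float = 0.626
    condition_names: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        for name in ("snp_rate_coding", "snp_rate_noncoding", "indel_rate",
                     "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.depth_per_gene < 0:
            raise ValueError("depth_per_gene must be >= 0")
        for g, pi in self.bias_map.items():
            vals = pi.values() if isinstance(pi, dict) else [pi]
            for p in vals:
                if not 0.0 < p < 1.0:
                    raise ValueError(f"pi for {g} must lie in (0, 1)")
        if self.n_conditions < 1 or self.n_conditions > len(self.condition_names):
            raise ValueError("n_conditions outside the named-condition range")

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.condition_names[: self.n_conditions]

    def gene_ids(self) -> list[str]:
        return [f"lac{i + 1:02d}" for i in range(self.n_families)]

    def resolved_bias(self) -> dict[str, dict[str, float]]:
        """Per-gene, per-condition pi, with the planted-bias default.

        If ``bias_map`` is empty, one family (``biased_gene_index``)
        receives ``biased_pi`` on every condition except the discordant
        one; all other genes are balanced (pi = 0.5).
        """
        conds = self.conditions
        out: dict[str, dict[str, float]] = {}
        source = self.bias_map
        if not source:
            source = {}
            gid = self.gene_ids()[min(self.biased_gene_index, self.n_families - 1)]
            source[gid] = {
                c: (0.5 if c == DISCORDANT_CONDITION else self.biased_pi)
                for c in conds
            }
        for g in self.gene_ids():
            spec = source.get(g, 0.5)
            if isinstance(spec, dict):
                out[g] = {c: float(spec.get(c, 0.5)) for c in conds}
            else:
                out[g] = {c: float(spec) for c in conds}
        return out


@dataclass
class MotifTruth:
    """Record of an embedded (and possibly disrupted) promoter motif."""

    motif_id: str
    position: int
    width: int
    strand: str = "+"
    disrupt_allele: int | None = None
    disrupt_offset: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None


@dataclass
class TruthSet:
    """Ground truth of one simulated dikaryon.

    ``variants`` are expressed on haplotype-1 coordinates and, applied to
    the haplotype-1 contigs, reconstruct haplotype 2 exactly.
    """

    variants: list[Variant]
    contig_of: dict[str, str]
    bias: dict[str, dict[str, float]]
    models_h2: list[GeneModel] = field(default_factory=list)
    read_origins: pd.DataFrame | None = None
    motifs: list[MotifTruth] = field(default_factory=list)

    def variants_for(self, gene_id: str) -> list[Variant]:
        return [v for v in self.variants if v.gene_id == gene_id]

    def normalized_for(self, gene_id: str, seq_h1: str) -> list[Variant]:
        return normalize_variants(self.variants_for(gene_id), seq_h1)


# --------------------------------------------------------------------- #
# Genome construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in STOPS:
            codons.append(c)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)


def build_gene_models(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate haplotype-1 contigs and gene models, one family per contig.

    Each gene is laid out with a full-length promoter on either side of the
    transcribed region so that both orientations have the requested
    upstream space; minus-strand genes are produced by mirroring the whole
    contig.

    Returns ``(contigs, models)`` where ``contigs`` maps contig name to
    sequence.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo3, hi3 = config.cds_len_range[0] // 3, config.cds_len_range[1] // 3
    if lo3 < 3:
        raise ValueError("cds_len_range too short for start + stop codons")
    contigs: dict[str, str] = {}
    models: list[GeneModel] = []
    for i, gid in enumerate(config.gene_ids()):
        contig = f"chr_{gid}"
        n_codons = int(rng.integers(lo3, hi3 + 1))
        cds = _random_cds(rng, n_codons)
        n_intr = int(rng.integers(config.n_introns_range[0],
                                  config.n_introns_range[1] + 1))
        n_intr = min(n_intr, len(cds) - 1)
        cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_intr,
                                  replace=False)) if n_intr else np.array([], int)
        pieces = np.split(np.frombuffer(cds.encode(), dtype="S1"), cuts)
        intron_seqs = [
            _random_seq(rng, int(rng.integers(*config.intron_len_range)))
            for _ in range(n_intr)
        ]
        utr5 = _random_seq(rng, config.utr5_len)
        utr3 = _random_seq(rng, config.utr3_len)
        left = _random_seq(rng, config.pad + config.promoter_len)
        right = _random_seq(rng, config.promoter_len + config.pad)

        parts = [left, utr5]
        pos = len(left)
        utr5_iv = (pos, pos + len(utr5))
        pos += len(utr5)
        exon_ivs, intron_ivs = [], []
        for j, piece in enumerate(pieces):
            p = piece.tobytes().decode()
            exon_ivs.append((pos, pos + len(p)))
            parts.append(p)
            pos += len(p)
            if j < n_intr:
                intr = intron_seqs[j]
                intron_ivs.append((pos, pos + len(intr)))
                parts.append(intr)
                pos += len(intr)
        utr3_iv = (pos, pos + len(utr3))
        parts.append(utr3)
        pos += len(utr3)
        parts.append(right)
        seq = "".join(parts)

        cds_start = exon_ivs[0][0]
        if cds_start < config.promoter_len:
            raise ValueError(
                f"contig {contig} too short: start codon at {cds_start} leaves "
                f"no room for a {config.promoter_len} bp promoter"
            )
        model = GeneModel(
            gene_id=gid,
            contig=contig,
            strand="+",
            utr5=utr5_iv,
            exons=tuple(exon_ivs),
            introns=tuple(intron_ivs),
            utr3=utr3_iv,
            promoter=(cds_start - config.promoter_len, cds_start),
        )
        minus = config.strands == "minus" or (
            config.strands == "alternate" and i % 2 == 1
        )
        if minus:
            model = model.flipped(len(seq))
            seq = revcomp(seq)
        contigs[contig] = seq
        models.append(model)
    return contigs, models


# --------------------------------------------------------------------- #
# Divergence


def diverge_haplotypes(
    contigs_h1: dict[str, str],
    models: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    protected: dict[str, list[tuple[int, int]]] | None = None,
):
    """Mutate haplotype 1 into haplotype 2 with region-dependent rates.

    Substitutions are drawn per site (Bernoulli at the coding rate inside
    exons and at the non-coding rate in promoter/UTR/intron); the
    alternative base is uniform over the three non-reference bases.
    Indels are restricted to non-coding regions; a candidate indel that
    would cross a region boundary, or land within 10 bp of an already
    accepted indel, is re-drawn (up to ten attempts) so that every variant
    has a unique left-normalized representation.  ``protected`` maps
    contig names to intervals (e.g. planted motif sites) kept free of any
    mutation.

    Returns ``(contigs_h2, models_h2, truth)``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    truth_variants: list[Variant] = []
    contigs_h2: dict[str, str] = {}
    models_h2: list[GeneModel] = []
    contig_of = {m.gene_id: m.contig for m in models}
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)

    for contig, seq in contigs_h1.items():
        cvariants: list[Variant] = []
        blocked = np.zeros(len(seq), dtype=bool)
        for a, b in (protected or {}).get(contig, []):
            blocked[max(0, a - 10) : b + 10] = True
        regionss = [(m, partition_regions(m)) for m in by_contig.get(contig, [])]

        # indels first, so SNP draws can avoid their flanks
        for m, regions in regionss:
            for a, b, label in regions:
                if label == EXON:
                    continue
                n_events = rng.binomial(b - a, config.indel_rate)
                for _ in range(n_events):
                    v = _draw_indel(rng, seq, a, b, config, blocked)
                    if v is None:
                        continue
                    lo = max(0, v.pos - 10)
                    hi = min(len(seq), v.pos + max(len(v.ref), len(v.alt)) + 10)
                    blocked[lo:hi] = True
                    cvariants.append(replace(v, gene_id=m.gene_id, region=label))

        # per-site substitutions
        for m, regions in regionss:
            cds = m.cds_seq(seq)
            for a, b, label in regions:
                rate = (
                    config.snp_rate_coding if label == EXON
                    else config.snp_rate_noncoding
                )
                if rate <= 0:
                    continue
                hits = np.flatnonzero(rng.random(b - a) < rate) + a
                for pos in hits:
                    if blocked[pos]:
                        continue
                    ref = seq[pos]
                    if ref not in "ACGT":
                        continue
                    alts = [x for x in "ACGT" if x != ref]
                    alt = alts[rng.integers(0, 3)]
                    if label == EXON:
                        # purifying selection: keep the codon's stop status
                        alt = _nonsense_free_alt(m, cds, int(pos), ref, alt, alts)
                        if alt is None:
                            continue
                    cvariants.append(
                        Variant(pos=int(pos), vtype="SNP", ref=ref, alt=alt,
                                gene_id=m.gene_id, region=label)
                    )

        cvariants.sort(key=lambda v: v.pos)
        # two same-codon SNPs can jointly create a stop even though each is
        # individually harmless; drop one SNP of any such codon
        for m, _ in regionss:
            cvariants = _purge_joint_nonsense(seq, m, cvariants)
        contigs_h2[contig] = apply_variants(seq, cvariants)
        map_pos = position_map(cvariants)
        for m, _ in regionss:
            models_h2.append(m.shifted(map_pos))
        truth_variants.extend(cvariants)

    truth = TruthSet(
        variants=truth_variants,
        contig_of=contig_of,
        bias=config.resolved_bias(),
        models_h2=models_h2,
    )
    return contigs_h2, models_h2, truth


_COMP = str.maketrans("ACGT", "TGCA")


def _nonsense_free_alt(m, cds, pos, ref, alt, alts):
    """First alternative base (starting from ``alt``) that preserves the
    codon's stop status; None if all three change it."""
    cpos = m.genomic_to_cds(pos)
    codon_idx, within = cpos // 3, cpos % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    was_stop = codon in STOPS
    ordered = [alt] + [x for x in alts if x != alt]
    for cand in ordered:
        base = cand if m.strand == "+" else cand.translate(_COMP)
        new_codon = codon[:within] + base + codon[within + 1 :]
        if (new_codon in STOPS) == was_stop:
            return cand
    return None


def _purge_joint_nonsense(seq: str, m, cvariants: list[Variant]) -> list[Variant]:
    for _ in range(10):
        h2 = apply_variants(seq, cvariants)
        m2 = m.shifted(position_map(cvariants))
        cds2 = m2.cds_seq(h2)
        bad = [
            i for i in range(len(cds2) // 3 - 1)
            if cds2[3 * i : 3 * i + 3] in STOPS
        ]
        if not bad:
            return cvariants
        drop_idx = None
        for v in cvariants:
            if v.vtype != "SNP" or v.gene_id != m.gene_id or v.region != EXON:
                continue
            cpos = m.genomic_to_cds(v.pos)
            if cpos is not None and cpos // 3 in bad:
                drop_idx = v
        cvariants = [v for v in cvariants if v is not drop_idx]
    return cvariants


def _draw_indel(rng, seq, a, b, config, blocked) -> Variant | None:
    lmin, lmax = config.indel_len_range
    for _ in range(10):
        length = int(rng.integers(lmin, lmax + 1))
        is_del = rng.random() < 0.5
        # keep the event strictly inside the region so boundaries of the
        # haplotype-2 gene model map cleanly
        lo, hi = a + 1, b - 1 - (length if is_del else 0)
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        span = length if is_del else 0
        if blocked[max(0, pos - 10) : pos + span + 10].any():
            continue
        if is_del:
            return Variant(pos=pos, vtype="deletion", ref=seq[pos : pos + length],
                           alt="")
        return Variant(pos=pos, vtype="insertion", ref="",
                       alt=_random_seq(rng, length))
    return None


# --------------------------------------------------------------------- #
# Reads


def simulate_allelic_reads(
    contigs_h1: dict[str, str],
    contigs_h2: dict[str, str],
    models_h1: list[GeneModel],
    models_h2: list[GeneModel],
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw single-end transcript reads with a known allele of origin.

    For every gene and condition the number of reads is Poisson with mean
    ``depth_per_gene``; each read's allele of origin is Bernoulli(pi),
    its start is uniform over valid transcript positions, and sequencing
    errors are i.i.d. substitutions at ``seq_error_rate``.  Genes whose
    transcript is shorter than the read length are skipped with a warning.

    Returns a frame with columns ``read_id, condition, gene, origin,
    start, seq`` (origin is 1 or 2); the same frame is stored on
    ``truth.read_origins``.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    h2_by_id = {m.gene_id: m for m in models_h2}
    rows = []
    L = config.read_len
    for m1 in models_h1:
        m2 = h2_by_id[m1.gene_id]
        tx1 = m1.transcript_seq(contigs_h1[m1.contig])
        tx2 = m2.transcript_seq(contigs_h2[m2.contig])
        if min(len(tx1), len(tx2)) < L:
            warnings.warn(
                f"gene {m1.gene_id}: transcript shorter than read length, skipped"
            )
            continue
        for cond in config.conditions:
            pi = truth.bias[m1.gene_id][cond]
            n = int(rng.poisson(config.depth_per_gene))
            if n == 0:
                continue
            origins = np.where(rng.random(n) < pi, 1, 2)
            for k in range(n):
                tx = tx1 if origins[k] == 1 else tx2
                start = int(rng.integers(0, len(tx) - L + 1))
                read = tx[start : start + L]
                if config.seq_error_rate > 0:
                    read = _add_errors(rng, read, config.seq_error_rate)
                rows.append(
                    (
                        f"{m1.gene_id}:{cond}:{k}",
                        cond,
                        m1.gene_id,
                        int(origins[k]),
                        start,
                        read,
                    )
                )
    df = pd.DataFrame(
        rows, columns=["read_id", "condition", "gene", "origin", "start", "seq"]
    )
    truth.read_origins = df
    return df


def _add_errors(rng, read: str, rate: float) -> str:
    arr = np.array(list(read))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# --------------------------------------------------------------------- #
# Clones and qPCR


def simulate_clone_draws(pi: float, n: int, seed=None) -> tuple[int, int]:
    """Draw a clone-sequencing experiment: n clones, Binomial(n, pi) from
    allele 1, remainder from allele 2."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k1 = int(rng.binomial(n, pi))
    return k1, n - k1


def simulate_qpcr_plate(
    true_fold: dict[str, float],
    efficiency: float = 1.0,
    dilution_factor: float = 2.0,
    n_dilutions: int = 5,
    ct_noise_sd: float = 0.0,
    seed=None,
    *,
    n_replicates: int = 3,
    base_ct_target: float = 24.0,
    base_ct_ref: float = 18.0,
    calibrator: str = "MM",
) -> pd.DataFrame:
    """Simulate a qPCR plate: a dilution-series standard curve plus samples.

    The cycle model is Ct = base - log(template) / log(1 + E): with E = 1
    (perfect doubling) a twofold dilution step shifts Ct by exactly one
    cycle.  ``true_fold`` maps each sample/condition to its expression
    fold change relative to the calibrator; the reference gene is flat
    across samples.

    Returns a tidy frame with columns ``role`` (standard|sample),
    ``sample``, ``gene`` (target|reference), ``dilution``, ``replicate``
    and ``ct``.
    """
    if not 0.0 < efficiency <= 1.2:
        raise ValueError("efficiency must lie in (0, 1.2]")
    if n_dilutions < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    if calibrator not in true_fold:
        raise ValueError(f"calibrator sample {calibrator!r} missing from true_fold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slope_per_log10 = -1.0 / math.log10(1.0 + efficiency)
    rows = []
    for gene, base in (("target", base_ct_target), ("reference", base_ct_ref)):
        for i in range(n_dilutions):
            rel = dilution_factor ** (-i)
            ct0 = base - math.log10(rel) * (-slope_per_log10)
            for rep in range(n_replicates):
                ct = ct0 + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append(("standard", f"dil{i}", gene, rel, rep, ct))
    for sample, fold in true_fold.items():
        if fold <= 0:
            raise ValueError(f"fold for {sample} must be positive")
        ct_t0 = base_ct_target - math.log10(fold) * (-slope_per_log10)
        for gene, ct0 in (("target", ct_t0), ("reference", base_ct_ref)):
            for rep in range(n_replicates):
                ct = ct0 + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append(("sample", sample, gene, float("nan"), rep, ct))
    return pd.DataFrame(
        rows, columns=["role", "sample", "gene", "dilution", "replicate", "ct"]
    )


# --------------------------------------------------------------------- #
# Motif embedding


def embed_motif_with_disruption(
    promoter_h1: str,
    promoter_h2: str,
    pwm,
    position: int,
    disrupt_allele: int | None = None,
    existing: list[tuple[int, int]] | None = None,
) -> tuple[str, str, MotifTruth]:
    """Write a PWM's consensus site into both promoters, optionally broken.

    The consensus (per-column argmax) is placed at ``position`` on the
    forward strand of both allele promoters.  If ``disrupt_allele`` is 1
    or 2, the single-base change that destroys the most log-odds score is
    applied to that allele's copy and recorded in the returned truth
    (deterministic: ties break toward the first column / base order).

    Raises
    ------
    ValueError
        If the site would run past the promoter end or overlap a
        previously embedded site listed in ``existing``.
    """
    w = pwm.width
    if position + w > min(len(promoter_h1), len(promoter_h2)):
        raise ValueError("motif does not fit in the promoter at this position")
    for a, b in existing or []:
        if position < b and a < position + w:
            raise ValueError(f"embedded site at {position} overlaps existing ({a},{b})")
    cons = pwm.consensus
    p1 = promoter_h1[:position] + cons + promoter_h1[position + w :]
    p2 = promoter_h2[:position] + cons + promoter_h2[position + w :]
    truth = MotifTruth(motif_id=pwm.motif_id, position=position, width=w)
    if disrupt_allele in (1, 2):
        j, _, base = max_disruption(pwm)
        broken = cons[:j] + base + cons[j + 1 :]
        if disrupt_allele == 1:
            p1 = p1[:position] + broken + p1[position + w :]
        else:
            p2 = p2[:position] + broken + p2[position + w :]
        truth = replace(
            truth,
            disrupt_allele=disrupt_allele,
            disrupt_offset=j,
            ref_base=cons[j],
            alt_base=base,
        )
    return p1, p2, truth


def max_disruption(pwm) -> tuple[int, str, str]:
    """The single-base change destroying the most PWM score.

    Returns ``(column, consensus_base, worst_base)``; ties break toward
    the first column and alphabetical base, so the choice is
    deterministic for a given matrix.
    """
    cons = pwm.consensus
    best = None
    for j in range(pwm.width):
        for b_idx, base in enumerate("ACGT"):
            if base == cons[j]:
                continue
            drop = pwm.scores["ACGT".index(cons[j]), j] - pwm.scores[b_idx, j]
            if best is None or drop > best[0]:
                best = (drop, j, base)
    _, j, base = best
    return j, cons[j], base


def plant_motif_h1(
    contigs: dict[str, str],
    models: list[GeneModel],
    gene_id: str,
    pwm,
    position: int,
    promoter_len: int = 3000,
) -> tuple[dict[str, str], tuple[str, int, int]]:
    """Write a PWM consensus into a gene's haplotype-1 promoter.

    ``position`` is promoter-local (0 = the promoter's 5' end).  Done
    before divergence, so the site is inherited identically by both
    haplotypes; pass the returned genomic window to
    :func:`diverge_haplotypes` as protected so mutations spare it.

    Returns ``(edited_contigs, (contig, gstart, gend))``.
    """
    m = next(mm for mm in models if mm.gene_id == gene_id)
    w = pwm.width
    if not 0 <= position <= promoter_len - w:
        raise ValueError("motif does not fit in the promoter at this position")
    cs = m.start_codon_pos
    if m.strand == "+":
        gstart = cs - promoter_len + position
        insert = pwm.consensus
    else:
        gstart = cs + promoter_len - position - w
        insert = revcomp(pwm.consensus)
    seq = contigs[m.contig]
    if gstart < 0 or gstart + w > len(seq):
        raise ValueError("promoter window falls off the contig")
    out = dict(contigs)
    out[m.contig] = seq[:gstart] + insert + seq[gstart + w :]
    return out, (m.contig, gstart, gstart + w)


def disrupt_planted_motif(
    contigs_h1: dict[str, str],
    contigs_h2: dict[str, str],
    models: list[GeneModel],
    truth: TruthSet,
    gene_id: str,
    pwm,
    window: tuple[str, int, int],
    disrupt_allele: int,
    promoter_position: int,
) -> MotifTruth:
    """Break one allele's copy of a planted motif and record the truth SNP.

    The maximally score-destroying single-base change is written into the
    chosen allele's genome and appended to ``truth.variants`` so the
    haplotype round-trip invariant still holds.  Returns the motif truth
    record (also appended to ``truth.motifs``); the contig dicts are
    modified in place.
    """
    if disrupt_allele not in (1, 2):
        raise ValueError("disrupt_allele must be 1 or 2")
    m = next(mm for mm in models if mm.gene_id == gene_id)
    contig, gstart, _gend = window
    j, cons_base, worst = max_disruption(pwm)
    if m.strand == "+":
        gpos = gstart + j
        fwd_ref, fwd_alt = cons_base, worst
    else:
        gpos = gstart + (pwm.width - 1 - j)
        comp = str.maketrans("ACGT", "TGCA")
        fwd_ref, fwd_alt = cons_base.translate(comp), worst.translate(comp)
    contig_vars = [
        v for v in truth.variants if truth.contig_of.get(v.gene_id) == contig
    ]
    if disrupt_allele == 1:
        seq = contigs_h1[contig]
        assert seq[gpos] == fwd_ref
        contigs_h1[contig] = seq[:gpos] + fwd_alt + seq[gpos + 1 :]
        snp = Variant(pos=gpos, vtype="SNP", ref=fwd_alt, alt=fwd_ref,
                      gene_id=gene_id, region=PROMOTER)
    else:
        gpos2 = position_map(contig_vars)(gpos)
        seq = contigs_h2[contig]
        assert seq[gpos2] == fwd_ref
        contigs_h2[contig] = seq[:gpos2] + fwd_alt + seq[gpos2 + 1 :]
        snp = Variant(pos=gpos, vtype="SNP", ref=fwd_ref, alt=fwd_alt,
                      gene_id=gene_id, region=PROMOTER)
    truth.variants.append(snp)
    truth.variants.sort(key=lambda v: (truth.contig_of.get(v.gene_id, ""), v.pos))
    record = MotifTruth(
        motif_id=pwm.motif_id,
        position=promoter_position,
        width=pwm.width,
        strand="+",
        disrupt_allele=disrupt_allele,
        disrupt_offset=j,
        ref_base=cons_base,
        alt_base=worst,
    )
    truth.motifs.append(record)
    return record


# --------------------------------------------------------------------- #
# Convenience


def proteins_from_models(
    contigs: dict[str, str], models: list[GeneModel], prefix: str = ""
) -> dict[str, str]:
    """Translate every gene's CDS (stop stripped) into a protein dict."""
    from Bio.Seq import Seq

    out = {}
    for m in models:
        aa = str(Seq(m.cds_seq(contigs[m.contig])).translate())
        out[f"{prefix}{m.gene_id}"] = aa.rstrip("*")
    return out


def gene_read_counts(reads: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Total simulated reads per gene x condition (both alleles pooled)."""
    counts = (
        reads.groupby(["gene", "condition"]).size().unstack(fill_value=0)
    )
    return counts.reindex(columns=list(config.conditions), fill_value=0)
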