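"""End-to-end orchestration: simulate -> pair -> variants -> ASE -> motifs.

``run_pipeline`` executes the stages in dependency order on a synthetic
dikaryon, writing plain-text artifacts (FASTA/GFF3/VCF/TSV/JSON) plus a
manifest into one output directory.  Re-running with the same
configuration reproduces identical files byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import expression, io, motifs, pairing, simulate, variants as var_mod
from .simulate import SimConfig

logger = logging.getLogger("dikarase")

#: A compact synthetic zinc-finger-style PFM used when no JASPAR file is
#: supplied; counts are invented for demonstration, not taken from any
#: database.  Five highly informative columns dominate the score span, so
#: a single-base hit to one of them drops a site well below the default
#: relative-score threshold.
DEFAULT_PFM = motifs.PFM(
    motif_id="ZNF_SYN1",
    name="synthetic-zinc-finger",
    counts=np.array(
        [
            # G    A   w1   T   w2   C    G   w3
            [0,   50,  20,  0,  15,  0,   0,  12],
            [0,    0,  10,  0,  15,  50,  0,  14],
            [50,   0,  12,  0,  12,  0,  50,  10],
            [0,    0,   8, 50,   8,  0,   0,  14],
        ],
        dtype=float,
    ),
)

ALL_STAGES = ("simulate", "pairing", "variants", "ase", "expression", "motifs")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "dikarase_run"
    stages: tuple[str, ...] = ALL_STAGES
    min_identity_pct: float = 95.0
    min_coverage_pct: float = 75.0
    min_similarity_pct: float = 90.0
    alpha: float = 0.05
    min_fraction_conditions: float = 0.9
    min_relative_score: float = 0.85
    jaspar_path: str | None = None
    embed_motif: bool = True
    embed_position: int = 1500
    disrupt_allele: int | None = 2

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = SimConfig(**{k: _detuple(v) for k, v in raw.pop("sim", {}).items()})
        raw = {k: _detuple(v) for k, v in raw.items()}
        return cls(sim=sim, **raw)


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the report bundle.

    The returned dict maps stage names to their key in-memory results and
    contains ``paths`` (stage output files), ``warnings`` collected during
    the run, and the path of the JSON manifest.  A stage failure raises,
    naming the stage; files written by earlier stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.sim.seed,
        "stages": list(config.stages),
        "parameters": _jsonable(dataclasses.asdict(config)),
        "outputs": {},
    }
    report: dict = {"paths": {}, "warnings": []}
    state: dict = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s starting", stage)
            try:
                _STAGES[stage](config, state, report, out)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
            manifest["outputs"][stage] = sorted(report["paths"].get(stage, []))
    report["warnings"] = sorted({str(w.message) for w in caught})
    manifest["warnings"] = report["warnings"]
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = str(manifest_path)
    report["state"] = state
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# --------------------------------------------------------------------- #
# Stages


def _stage_simulate(config: RunConfig, state, report, out: Path):
    sim = config.sim
    contigs1, models1 = simulate.build_gene_models(sim)

    protected: dict[str, list[tuple[int, int]]] = {}
    window = None
    if config.embed_motif:
        pwm = _pwm(config)
        biased = sim.gene_ids()[min(sim.biased_gene_index, sim.n_families - 1)]
        # clamp into the promoter for short-promoter configurations
        embed_pos = min(config.embed_position, sim.promoter_len - pwm.width)
        config.embed_position = embed_pos
        contigs1, window = simulate.plant_motif_h1(
            contigs1, models1, biased, pwm, embed_pos, sim.promoter_len
        )
        protected[window[0]] = [(window[1], window[2])]
        state["embedded_gene"] = biased

    contigs2, models2, truth = simulate.diverge_haplotypes(
        contigs1, models1, sim, protected=protected or None
    )
    if config.embed_motif and config.disrupt_allele in (1, 2):
        simulate.disrupt_planted_motif(
            contigs1, contigs2, models1, truth, state["embedded_gene"],
            _pwm(config), window, config.disrupt_allele, config.embed_position,
        )

    reads = simulate.simulate_allelic_reads(
        contigs1, contigs2, models1, models2, truth, sim
    )
    state.update(
        contigs1=contigs1, contigs2=contigs2, models1=models1, models2=models2,
        truth=truth, reads=reads,
    )
    paths = []
    for name, obj in (("h1.fna", contigs1), ("h2.fna", contigs2)):
        io.write_fasta(obj, out / name)
        paths.append(str(out / name))
    io.write_gff(models1, out / "h1.gff3")
    io.write_gff(models2, out / "h2.gff3")
    io.write_fastq(zip(reads["read_id"], reads["seq"]), out / "reads.fastq")
    truth_df = pd.DataFrame(
        [
            (v.gene_id, truth.contig_of.get(v.gene_id, ""), v.pos, v.vtype,
             v.ref, v.alt, v.region)
            for v in truth.variants
        ],
        columns=["gene", "contig", "pos", "type", "ref", "alt", "region"],
    )
    truth_df.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    paths += [str(out / n) for n in ("h1.gff3", "h2.gff3", "reads.fastq",
                                     "truth_variants.tsv")]
    report["paths"]["simulate"] = paths


def _stage_pairing(config: RunConfig, state, report, out: Path):
    prot1 = simulate.proteins_from_models(state["contigs1"], state["models1"], "H1_")
    prot2 = simulate.proteins_from_models(state["contigs2"], state["models2"], "H2_")
    pairs, un1, un2 = pairing.pair_alleles(prot1, prot2, config.min_identity_pct)
    dups = pairing.detect_duplications(
        prot1, config.min_coverage_pct, config.min_similarity_pct
    )
    dist, labels = pairing.p_distance_matrix({**prot1, **prot2})
    newick = pairing.nj_tree(dist, labels) if len(labels) >= 3 else ""

    pair_df = pd.DataFrame(
        [
            (p.id_h1, p.id_h2, round(p.result.identity_pct, 3),
             round(p.result.coverage_pct, 3), p.result.score)
            for p in pairs
        ],
        columns=["id_h1", "id_h2", "identity_pct", "coverage_pct", "score"],
    )
    pair_df.to_csv(out / "allele_pairs.tsv", sep="\t", index=False)
    dup_df = pd.DataFrame(
        [(";".join(g.members),) for g in dups], columns=["members"]
    )
    dup_df.to_csv(out / "duplications.tsv", sep="\t", index=False)
    (out / "proteins.nwk").write_text(newick + "\n")
    state.update(pairs=pairs, unpaired=(un1, un2), duplications=dups, newick=newick)
    report["paths"]["pairing"] = [
        str(out / n) for n in ("allele_pairs.tsv", "duplications.tsv", "proteins.nwk")
    ]


def _stage_variants(config: RunConfig, state, report, out: Path):
    models2 = {m.gene_id: m for m in state["models2"]}
    all_calls = []
    summaries = []
    for m1 in state["models1"]:
        m2 = models2[m1.gene_id]
        c1, c2 = state["contigs1"][m1.contig], state["contigs2"][m2.contig]
        lo1 = min(m1.span[0], m1.promoter[0]) if m1.promoter else m1.span[0]
        hi1 = max(m1.span[1], m1.promoter[1]) if m1.promoter else m1.span[1]
        lo2 = min(m2.span[0], m2.promoter[0]) if m2.promoter else m2.span[0]
        hi2 = max(m2.span[1], m2.promoter[1]) if m2.promoter else m2.span[1]
        calls = var_mod.call_variants(
            c1[lo1:hi1], c2[lo2:hi2], m1, offset=lo1, gene_id=m1.gene_id
        )
        calls = var_mod.annotate_coding_effects(calls, m1, c1)
        regions = var_mod.partition_regions(m1)
        summary = var_mod.summarize_rates(calls, regions)
        summary.insert(0, "gene", m1.gene_id)
        summaries.append(summary.reset_index(names="region"))
        all_calls.extend(calls)
    contig_of = {m.gene_id: m.contig for m in state["models1"]}
    io.write_vcf(all_calls, contig_of, state["contigs1"], out / "variants.vcf")
    pd.concat(summaries, ignore_index=True).to_csv(
        out / "variant_summary.tsv", sep="\t", index=False
    )
    state["calls"] = all_calls
    report["paths"]["variants"] = [
        str(out / "variants.vcf"), str(out / "variant_summary.tsv")
    ]


def _stage_ase(config: RunConfig, state, report, out: Path):
    models2 = {m.gene_id: m for m in state["models2"]}
    tx1, tx2, loci = {}, {}, {}
    for m1 in state["models1"]:
        m2 = models2[m1.gene_id]
        tx1[m1.gene_id] = m1.transcript_seq(state["contigs1"][m1.contig])
        tx2[m1.gene_id] = m2.transcript_seq(state["contigs2"][m2.contig])
        gene_calls = [v for v in state["calls"] if v.gene_id == m1.gene_id]
        loci[m1.gene_id] = ase_mod.build_snp_loci(gene_calls, m1, m2)
    depths = ase_mod.assign_reads_to_alleles(state["reads"], tx1, tx2, loci)
    agg = ase_mod.aggregate_gene_depths(depths)
    tested = ase_mod.bias_table(agg, config.alpha)
    calls = ase_mod.call_consistent_bias(
        tested, config.alpha, config.min_fraction_conditions
    )
    depths.to_csv(out / "allele_depths.tsv", sep="\t", index=False)
    tested.to_csv(out / "bias_tests.tsv", sep="\t", index=False)
    call_df = pd.DataFrame(
        [
            (c.gene, c.called, c.direction, c.n_support, c.n_informative,
             round(c.mean_ratio_h1, 4))
            for c in calls
        ],
        columns=["gene", "called", "direction", "n_support", "n_informative",
                 "mean_ratio_h1"],
    )
    call_df.to_csv(out / "bias_calls.tsv", sep="\t", index=False)
    state.update(depths=depths, bias_tests=tested, bias_calls=calls)
    report["paths"]["ase"] = [
        str(out / n) for n in ("allele_depths.tsv", "bias_tests.tsv", "bias_calls.tsv")
    ]


def _stage_expression(config: RunConfig, state, report, out: Path):
    sim = config.sim
    counts = simulate.gene_read_counts(state["reads"], sim)
    lengths = pd.Series(
        {m.gene_id: m.tx_len for m in state["models1"]}, name="length"
    )
    tpm = expression.compute_tpm(counts, lengths.reindex(counts.index))
    tpm.to_csv(out / "tpm.tsv", sep="\t")
    state["tpm"] = tpm

    biased = state.get("embedded_gene", sim.gene_ids()[0])
    folds = {c: 1.0 for c in sim.conditions}
    induced = "RSM" if "RSM" in folds else list(folds)[-1]
    folds[induced] = 94.0
    calibrator = sim.conditions[0]
    plate = simulate.simulate_qpcr_plate(
        folds, efficiency=1.0, ct_noise_sd=0.05,
        seed=np.random.default_rng(sim.seed + 7), calibrator=calibrator,
    )
    curve, fold_est = expression.analyze_qpcr_plate(plate, calibrator)
    plate.to_csv(out / "qpcr_plate.tsv", sep="\t", index=False)
    fold_est.to_csv(out / "qpcr_folds.tsv", sep="\t")
    state.update(qpcr_curve=curve, qpcr_folds=fold_est, qpcr_gene=biased)
    report["paths"]["expression"] = [
        str(out / n) for n in ("tpm.tsv", "qpcr_plate.tsv", "qpcr_folds.tsv")
    ]


def _stage_motifs(config: RunConfig, state, report, out: Path):
    pwms = [_pwm(config)] if config.jaspar_path is None else [
        motifs.pfm_to_pwm(p) for p in motifs.read_jaspar(config.jaspar_path)
    ]
    models2 = {m.gene_id: m for m in state["models2"]}
    rows = []
    diff_rows = []
    for m1 in state["models1"]:
        m2 = models2[m1.gene_id]
        p1 = motifs.extract_promoter(
            state["contigs1"][m1.contig], m1, config.sim.promoter_len
        )
        p2 = motifs.extract_promoter(
            state["contigs2"][m2.contig], m2, config.sim.promoter_len, "h2"
        )
        pvars = var_mod.call_variants(p1.seq, p2.seq, gene_id=m1.gene_id)
        for pwm in pwms:
            h1 = motifs.scan_pwm(p1, pwm, config.min_relative_score)
            h2 = motifs.scan_pwm(p2, pwm, config.min_relative_score)
            for hap, hits in (("h1", h1), ("h2", h2)):
                rows += [
                    (m1.gene_id, hap, h.motif_id, h.start, h.end, h.strand,
                     round(h.score, 4), round(h.rel_score, 4))
                    for h in hits
                ]
            for d in motifs.differential_sites(h1, h2, pvars):
                diff_rows.append(
                    (m1.gene_id, d.motif_id, d.status, d.strand, d.pos_h1,
                     d.pos_h2, d.rel_h1, d.rel_h2, len(d.variants))
                )
    pd.DataFrame(
        rows,
        columns=["gene", "haplotype", "motif", "start", "end", "strand",
                 "score", "rel_score"],
    ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    diff_df = pd.DataFrame(
        diff_rows,
        columns=["gene", "motif", "status", "strand", "pos_h1", "pos_h2",
                 "rel_h1", "rel_h2", "n_variants"],
    )
    diff_df.to_csv(out / "diff_sites.tsv", sep="\t", index=False)
    state["diff_sites"] = diff_df
    report["paths"]["motifs"] = [
        str(out / "motif_hits.tsv"), str(out / "diff_sites.tsv")
    ]


def _pwm(config: RunConfig) -> motifs.PWM:
    if config.jaspar_path:
        return motifs.pfm_to_pwm(motifs.read_jaspar(config.jaspar_path)[0])
    return motifs.pfm_to_pwm(DEFAULT_PFM)


_STAGES = {
    "simulate": _stage_simulate,
    "pairing": _stage_pairing,
    "variants": _stage_variants,
    "ase": _stage_ase,
    "expression": _stage_expression,
    "motifs": _stage_motifs,
}
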