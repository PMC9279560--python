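"""Generator properties: determinism, truth round-trip, binomial envelopes."""
import numpy as np
import pandas as pd
import pytest

from dikarase import simulate as S
from dikarase.models import apply_variants, revcomp
from dikarase.motifs import pfm_to_pwm, scan_pwm
from dikarase.pipeline import DEFAULT_PFM

from .conftest import make_dikaryon


def contig_variants(truth, contig):
    return [v for v in truth.variants if truth.contig_of[v.gene_id] == contig]


class TestBuildGeneModels:
    def test_minimal_single_exon_gene(self):
        cfg = S.SimConfig(n_families=1, n_introns_range=(0, 0), seed=1,
                          cds_len_range=(300, 300), promoter_len=500)
        contigs, models = S.build_gene_models(cfg)
        (m,) = models
        assert len(m.exons) == 1 and len(m.introns) == 0

    def test_fifteen_families(self):
        cfg = S.SimConfig(n_families=15, seed=3, cds_len_range=(300, 600),
                          n_introns_range=(0, 2), promoter_len=300)
        contigs, models = S.build_gene_models(cfg)
        assert len(models) == 15
        assert len({m.contig for m in models}) == 15

    def test_promoter_is_full_length_upstream_of_start_codon(self):
        cfg = S.SimConfig(n_families=2, seed=5, cds_len_range=(300, 450),
                          n_introns_range=(1, 1), promoter_len=700)
        _, models = S.build_gene_models(cfg)
        for m in models:
            a, b = m.promoter
            assert b - a == 700
            if m.strand == "+":
                assert b == m.start_codon_pos
            else:
                assert a == m.start_codon_pos

    def test_cds_translates_cleanly_both_strands(self, dikaryon):
        prot = S.proteins_from_models(dikaryon.contigs1, dikaryon.models1)
        strands = {m.strand for m in dikaryon.models1}
        assert strands == {"+", "-"}
        for aa in prot.values():
            assert aa.startswith("M") and "*" not in aa

    def test_same_seed_reproduces_identical_output(self, small_config):
        a = S.build_gene_models(small_config)
        b = S.build_gene_models(small_config)
        assert a[0] == b[0] and a[1] == b[1]

    def test_rejects_invalid_rates(self):
        with pytest.raises(ValueError):
            S.SimConfig(snp_rate_coding=1.5)
        with pytest.raises(ValueError):
            S.SimConfig(bias_map={"lac01": 1.0})


class TestDivergeHaplotypes:
    def test_zero_rates_give_identical_haplotypes(self):
        cfg = S.SimConfig(n_families=1, seed=2, snp_rate_coding=0,
                          snp_rate_noncoding=0, indel_rate=0,
                          cds_len_range=(300, 450), promoter_len=300)
        d = make_dikaryon(cfg)
        assert d.contigs1 == d.contigs2
        assert d.truth.variants == []

    def test_truth_round_trip_reconstructs_haplotype2(self, dikaryon):
        for contig, seq in dikaryon.contigs1.items():
            vs = contig_variants(dikaryon.truth, contig)
            assert apply_variants(seq, vs) == dikaryon.contigs2[contig]

    def test_coding_snp_count_within_binomial_envelope(self):
        # one long single-exon CDS: ~n*p coding SNPs within 4 sigma
        cfg = S.SimConfig(n_families=1, seed=17, snp_rate_coding=0.01,
                          snp_rate_noncoding=0.0, indel_rate=0.0,
                          cds_len_range=(9999, 9999), n_introns_range=(0, 0),
                          promoter_len=200)
        d = make_dikaryon(cfg)
        n, p = 9999, 0.01
        sigma = np.sqrt(n * p * (1 - p))
        count = sum(1 for v in d.truth.variants if v.region == "exon")
        assert abs(count - n * p) <= 4 * sigma

    def test_noncoding_rate_exceeds_coding_rate_across_seeds(self):
        # configured 3x ratio should be realized in nearly every replicate
        wins = 0
        for seed in range(30):
            cfg = S.SimConfig(n_families=2, seed=seed, snp_rate_coding=0.005,
                              snp_rate_noncoding=0.015, indel_rate=0.0,
                              cds_len_range=(900, 1200), promoter_len=1000)
            d = make_dikaryon(cfg)
            from dikarase.variants import partition_regions, summarize_rates
            rates = {"coding": [0, 0], "noncoding": [0, 0]}
            for m in d.models1:
                regions = partition_regions(m)
                for a, b, lab in regions:
                    key = "coding" if lab == "exon" else "noncoding"
                    rates[key][1] += b - a
                for v in d.truth.variants_for(m.gene_id):
                    if v.vtype == "SNP":
                        key = "coding" if v.region == "exon" else "noncoding"
                        rates[key][0] += 1
            if (rates["noncoding"][0] / rates["noncoding"][1]
                    > rates["coding"][0] / rates["coding"][1]):
                wins += 1
        assert wins >= 28

    def test_indels_only_in_noncoding_regions(self, dikaryon):
        for v in dikaryon.truth.variants:
            if v.vtype != "SNP":
                assert v.region != "exon"

    def test_h2_models_consistent_with_h2_contigs(self, dikaryon):
        prot2 = S.proteins_from_models(dikaryon.contigs2, dikaryon.models2)
        for aa in prot2.values():
            assert aa.startswith("M") and "*" not in aa


class TestAllelicReads:
    def test_pi_one_reads_match_h1_exactly(self):
        cfg = S.SimConfig(n_families=1, n_conditions=2, depth_per_gene=60,
                          seed=31, bias_map={"lac01": 0.99},
                          cds_len_range=(600, 900), promoter_len=300)
        # force pi to 1 after validation (boundary value is the test point)
        d = make_dikaryon(cfg)
        d.truth.bias["lac01"] = {c: 1.0 for c in cfg.conditions}
        reads = S.simulate_allelic_reads(
            d.contigs1, d.contigs2, d.models1, d.models2, d.truth, cfg
        )
        tx1 = d.models1[0].transcript_seq(d.contigs1[d.models1[0].contig])
        assert (reads["origin"] == 1).all()
        assert all(tx1.find(s) >= 0 for s in reads["seq"])

    def test_balanced_pi_fraction_within_envelope(self):
        cfg = S.SimConfig(n_families=1, n_conditions=10, depth_per_gene=1000,
                          seed=37, cds_len_range=(900, 1200), promoter_len=300,
                          bias_map={"lac01": 0.5})
        d = make_dikaryon(cfg)
        reads = S.simulate_allelic_reads(
            d.contigs1, d.contigs2, d.models1, d.models2, d.truth, cfg
        )
        n = len(reads)
        frac = (reads["origin"] == 1).mean()
        assert abs(frac - 0.5) <= 4 * np.sqrt(0.25 / n)

    def test_error_free_reads_align_exactly_to_origin(self, dikaryon):
        cfg = dikaryon.config
        reads = S.simulate_allelic_reads(
            dikaryon.contigs1, dikaryon.contigs2, dikaryon.models1,
            dikaryon.models2, dikaryon.truth, cfg,
        )
        tx = {}
        for m1, m2 in zip(dikaryon.models1, dikaryon.models2):
            tx[(m1.gene_id, 1)] = m1.transcript_seq(dikaryon.contigs1[m1.contig])
            tx[(m1.gene_id, 2)] = m2.transcript_seq(dikaryon.contigs2[m2.contig])
        sample = reads.sample(n=min(300, len(reads)), random_state=0)
        for r in sample.itertuples():
            assert tx[(r.gene, r.origin)][r.start : r.start + cfg.read_len] == r.seq

    def test_short_transcript_skipped_with_warning(self):
        cfg = S.SimConfig(n_families=1, n_conditions=1, depth_per_gene=10,
                          seed=41, cds_len_range=(90, 90), utr5_len=10,
                          utr3_len=10, n_introns_range=(0, 0), read_len=150,
                          promoter_len=200)
        d = make_dikaryon(cfg)
        with pytest.warns(UserWarning, match="shorter than read length"):
            reads = S.simulate_allelic_reads(
                d.contigs1, d.contigs2, d.models1, d.models2, d.truth, cfg
            )
        assert reads.empty


class TestCloneDraws:
    def test_degenerate_pi_and_sum_invariant(self):
        assert S.simulate_clone_draws(1.0 - 1e-12, 33, seed=0) == (33, 0)
        rng = np.random.default_rng(5)
        for _ in range(50):
            k1, k2 = S.simulate_clone_draws(0.3, 20, seed=rng)
            assert k1 + k2 == 20

    def test_mean_matches_binomial_expectation(self):
        # pi and n mirror the 19-of-33 clone experiment
        rng = np.random.default_rng(12)
        draws = [S.simulate_clone_draws(0.576, 33, seed=rng)[0]
                 for _ in range(10_000)]
        assert abs(np.mean(draws) - 33 * 0.576) <= 0.3


class TestQpcrPlate:
    def test_perfect_doubling_gives_unit_ct_spacing(self):
        plate = S.simulate_qpcr_plate({"MM": 1.0}, efficiency=1.0,
                                      ct_noise_sd=0.0, seed=1)
        std = plate[(plate.role == "standard") & (plate.gene == "target")]
        cts = std.groupby("dilution")["ct"].mean().sort_index(ascending=False)
        spacing = np.diff(cts.to_numpy())
        assert np.allclose(spacing, 1.0)

    def test_unit_fold_everywhere_gives_zero_ddct(self):
        from dikarase.expression import analyze_qpcr_plate

        folds = {c: 1.0 for c in ("MM", "LM", "RSM")}
        plate = S.simulate_qpcr_plate(folds, ct_noise_sd=0.0, seed=2)
        _, est = analyze_qpcr_plate(plate, "MM")
        assert np.allclose(est["ddct"], 0.0) and np.allclose(est["fold"], 1.0)

    def test_seed_repeatability(self):
        a = S.simulate_qpcr_plate({"MM": 1.0, "RSM": 4.0}, ct_noise_sd=0.1, seed=9)
        b = S.simulate_qpcr_plate({"MM": 1.0, "RSM": 4.0}, ct_noise_sd=0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_configurations(self):
        with pytest.raises(ValueError, match="efficiency"):
            S.simulate_qpcr_plate({"MM": 1.0}, efficiency=1.5)
        with pytest.raises(ValueError, match="dilution"):
            S.simulate_qpcr_plate({"MM": 1.0}, n_dilutions=2)
        with pytest.raises(ValueError, match="calibrator"):
            S.simulate_qpcr_plate({"RSM": 2.0}, calibrator="MM")


class TestMotifEmbedding:
    def setup_method(self):
        self.pwm = pfm_to_pwm(DEFAULT_PFM)
        rng = np.random.default_rng(51)
        self.prom = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))

    def test_no_disruption_plants_identical_max_score_sites(self):
        p1, p2, truth = S.embed_motif_with_disruption(
            self.prom, self.prom, self.pwm, 100
        )
        assert p1 == p2
        w = self.pwm.width
        assert p1[100 : 100 + w] == self.pwm.consensus
        (hit,) = [h for h in scan_pwm(p1, self.pwm, 0.99) if h.strand == "+"]
        assert hit.start == 100 and hit.rel_score == pytest.approx(1.0)

    def test_disruption_lowers_the_disrupted_alleles_score(self):
        p1, p2, truth = S.embed_motif_with_disruption(
            self.prom, self.prom, self.pwm, 100, disrupt_allele=2
        )
        h1 = {h.start: h for h in scan_pwm(p1, self.pwm, 0.0) if h.strand == "+"}
        h2 = {h.start: h for h in scan_pwm(p2, self.pwm, 0.0) if h.strand == "+"}
        assert h2[100].rel_score < h1[100].rel_score
        assert truth.disrupt_allele == 2 and truth.ref_base != truth.alt_base

    def test_scan_recovers_embedded_position_and_strand(self):
        p1, _, truth = S.embed_motif_with_disruption(
            self.prom, self.prom, self.pwm, 231
        )
        hits = [h for h in scan_pwm(p1, self.pwm, 0.95)]
        assert any(h.start == 231 and h.strand == "+" for h in hits)

    def test_overlap_with_existing_site_fails(self):
        with pytest.raises(ValueError, match="overlap"):
            S.embed_motif_with_disruption(
                self.prom, self.prom, self.pwm, 100,
                existing=[(95, 110)],
            )
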