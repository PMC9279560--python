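"""Read-to-allele assignment, bias testing, consistency calls, clones."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from dikarase import ase as A
from dikarase import simulate as S
from dikarase import variants as V

from .conftest import make_dikaryon
from .helpers import oracle_binom_p


@pytest.fixture(scope="module")
def assigned(dikaryon):
    """Reads simulated from the session dikaryon, assigned at SNP loci."""
    cfg = dikaryon.config
    reads = S.simulate_allelic_reads(
        dikaryon.contigs1, dikaryon.contigs2, dikaryon.models1,
        dikaryon.models2, dikaryon.truth, cfg,
    )
    tx1, tx2, loci = {}, {}, {}
    for m1 in dikaryon.models1:
        m2 = next(x for x in dikaryon.models2 if x.gene_id == m1.gene_id)
        tx1[m1.gene_id] = m1.transcript_seq(dikaryon.contigs1[m1.contig])
        tx2[m1.gene_id] = m2.transcript_seq(dikaryon.contigs2[m2.contig])
        loci[m1.gene_id] = A.build_snp_loci(
            dikaryon.truth.variants_for(m1.gene_id), m1, m2
        )
    table = A.assign_reads_to_alleles(reads, tx1, tx2, loci)
    return reads, table, loci, tx1, tx2


class TestSnpLoci:
    def test_loci_bases_match_transcripts(self, assigned):
        _, _, loci, tx1, tx2 = assigned
        for gene, ll in loci.items():
            for l in ll:
                assert tx1[gene][l.tpos_h1] == l.tbase_h1
                assert tx2[gene][l.tpos_h2] == l.tbase_h2


class TestAssignReads:
    def test_pure_h1_origin_gives_zero_h2_depth(self, dikaryon):
        cfg = dikaryon.config
        truth = dikaryon.truth
        saved = truth.bias
        truth.bias = {g: {c: 1.0 - 1e-12 for c in cfg.conditions}
                      for g in truth.bias}
        try:
            reads = S.simulate_allelic_reads(
                dikaryon.contigs1, dikaryon.contigs2, dikaryon.models1,
                dikaryon.models2, truth, cfg,
            )
        finally:
            truth.bias = saved
        m1 = dikaryon.models1[0]
        m2 = next(x for x in dikaryon.models2 if x.gene_id == m1.gene_id)
        loci = {m1.gene_id: A.build_snp_loci(
            truth.variants_for(m1.gene_id), m1, m2)}
        tx1 = {m1.gene_id: m1.transcript_seq(dikaryon.contigs1[m1.contig])}
        tx2 = {m1.gene_id: m2.transcript_seq(dikaryon.contigs2[m2.contig])}
        table = A.assign_reads_to_alleles(
            reads[reads.gene == m1.gene_id], tx1, tx2, loci
        )
        assert (table["depth_h2"] == 0).all()
        assert table["depth_h1"].sum() > 0

    def test_conflicting_votes_discard_read(self):
        # two loci; a chimeric read votes h1 at one and h2 at the other
        tx1 = {"g": "AAAACAAAAGAAAA"}
        tx2 = {"g": "AAAATAAAACAAAA"}
        loci = {"g": [
            A.SnpLocus("g", 4, "C", "T", 4, 4, "C", "T"),
            A.SnpLocus("g", 9, "G", "C", 9, 9, "G", "C"),
        ]}
        chimera = "AACAAAACAA"  # h1 base at locus 4, h2 base at locus 9
        reads = pd.DataFrame(
            {"condition": ["c"], "gene": ["g"], "seq": [chimera]}
        )
        # the chimera matches neither transcript exactly; plant it into tx1
        tx1["g"] = "AA" + chimera + "AA"
        table = A.assign_reads_to_alleles(reads, tx1, tx2, loci)
        assert table[["depth_h1", "depth_h2", "depth_other"]].sum().sum() == 0

    def test_assignment_accuracy_perfect_without_errors(self, assigned):
        reads, table, loci, _, _ = assigned
        per_gene_truth = (
            reads.assign(h1=lambda d: d.origin == 1)
            .groupby("gene")["h1"].mean()
        )
        agg = A.aggregate_gene_depths(table)
        per_gene_est = agg.groupby("gene").apply(
            lambda d: d.count_h1.sum() / (d.count_h1.sum() + d.count_h2.sum()),
            include_groups=False,
        )
        for gene in per_gene_est.index:
            n = len(reads[reads.gene == gene])
            assert abs(per_gene_est[gene] - per_gene_truth[gene]) \
                <= 4 * np.sqrt(0.25 / n)

    def test_locus_outside_transcript_fails(self):
        loci = {"g": [A.SnpLocus("g", 0, "A", "C", 50, 50, "A", "C")]}
        reads = pd.DataFrame({"condition": [], "gene": [], "seq": []})
        with pytest.raises(ValueError, match="outside transcript"):
            A.assign_reads_to_alleles(reads, {"g": "ACGT"}, {"g": "ACGT"}, loci)


class TestAggregation:
    def test_sum_mode_matches_direct_recomputation(self):
        rng = np.random.default_rng(4)
        rows = []
        for cond in ("c1", "c2"):
            for gene in ("g1", "g2"):
                for locus in range(3):
                    rows.append((cond, gene, locus, rng.integers(0, 30),
                                 rng.integers(0, 30), 0))
        table = pd.DataFrame(
            rows, columns=["condition", "gene", "locus", "depth_h1",
                           "depth_h2", "depth_other"],
        )
        agg = A.aggregate_gene_depths(table)
        for r in agg.itertuples():
            sub = table[(table.condition == r.condition) & (table.gene == r.gene)]
            assert r.count_h1 == sub.depth_h1.sum()
            assert r.count_h2 == sub.depth_h2.sum()

    def test_two_locus_example_and_passthrough(self):
        table = pd.DataFrame(
            [("c", "g", 0, 10, 5, 0), ("c", "g", 1, 20, 15, 0)],
            columns=["condition", "gene", "locus", "depth_h1", "depth_h2",
                     "depth_other"],
        )
        agg = A.aggregate_gene_depths(table)
        assert (agg.count_h1[0], agg.count_h2[0]) == (30, 20)
        one = A.aggregate_gene_depths(table.iloc[:1])
        assert (one.count_h1[0], one.count_h2[0]) == (10, 5)

    def test_zero_depth_gene_flagged_uninformative(self):
        table = pd.DataFrame(
            [("c", "g", 0, 0, 0, 3)],
            columns=["condition", "gene", "locus", "depth_h1", "depth_h2",
                     "depth_other"],
        )
        agg = A.aggregate_gene_depths(table)
        assert not agg.informative[0]


class TestBinomialBias:
    def test_centered_counts_give_p_one(self):
        ratio, p = A.binomial_bias_test(50, 50)
        assert ratio == 0.5 and p == 1.0

    def test_clone_count_example_matches_oracle(self):
        ratio, p = A.binomial_bias_test(19, 14)
        assert ratio == pytest.approx(19 / 33)
        assert p == pytest.approx(oracle_binom_p(19, 33), rel=1e-12)

    def test_extreme_counts_closed_form(self):
        _, p = A.binomial_bias_test(0, 20)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(k=st.integers(0, 40), n=st.integers(1, 40))
    def test_symmetry_under_label_swap(self, k, n):
        if k > n:
            return
        r1, p1 = A.binomial_bias_test(k, n - k)
        r2, p2 = A.binomial_bias_test(n - k, k)
        assert p1 == pytest.approx(p2)
        assert r1 == pytest.approx(1 - r2)

    def test_bh_within_condition(self):
        agg = pd.DataFrame(
            {
                "condition": ["c"] * 3,
                "gene": ["g1", "g2", "g3"],
                "count_h1": [80, 52, 50],
                "count_h2": [20, 48, 50],
                "informative": [True] * 3,
                "ratio_h1": [0.8, 0.52, 0.5],
            }
        )
        out = A.bias_table(agg)
        assert (out["q"] >= out["p"] - 1e-15).all()
        assert out.loc[out.gene == "g1", "significant"].item()


class TestConsistency:
    def _results(self, directions, qs):
        n = len(directions)
        return pd.DataFrame(
            {
                "condition": [f"c{i}" for i in range(n)],
                "gene": ["g"] * n,
                "count_h1": [60] * n,
                "count_h2": [40] * n,
                "ratio_h1": [0.6] * n,
                "p": qs,
                "q": qs,
                "direction": directions,
            }
        )

    def test_eighteen_of_nineteen_fires(self):
        res = self._results(["h1"] * 18 + ["h2"], [0.001] * 18 + [0.5])
        (call,) = A.call_consistent_bias(res)
        assert call.called and call.direction == "h1" and call.n_support == 18

    def test_alternating_directions_not_called(self):
        res = self._results(["h1", "h2"] * 5, [0.001] * 10)
        (call,) = A.call_consistent_bias(res)
        assert not call.called

    def test_no_significance_not_called(self):
        res = self._results(["h1"] * 10, [0.5] * 10)
        (call,) = A.call_consistent_bias(res)
        assert not call.called and call.direction == "none"


class TestCloneValidation:
    def test_unanimous_clones_closed_form(self):
        cv = A.clone_binomial_validation(33, 33)
        assert cv.ratio == 1.0
        assert cv.p_value == pytest.approx(min(1.0, 2 * 0.5**33), rel=1e-9)

    def test_paper_scale_counts_ci_straddles_half(self):
        cv = A.clone_binomial_validation(19, 33)
        assert cv.ratio == pytest.approx(19 / 33)
        assert cv.ci_low < 0.5 < cv.ci_high
        # oracle: Clopper-Pearson bounds via the beta quantiles
        from scipy.stats import beta

        lo = beta.ppf(0.025, 19, 33 - 19 + 1)
        hi = beta.ppf(0.975, 19 + 1, 33 - 19)
        assert cv.ci_low == pytest.approx(lo, rel=1e-9)
        assert cv.ci_high == pytest.approx(hi, rel=1e-9)

    def test_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(21)
        n, pi = 40, 0.6
        hit = 0
        trials = 2000
        for k in rng.binomial(n, pi, size=trials):
            cv = A.clone_binomial_validation(int(k), n)
            hit += cv.ci_low <= pi <= cv.ci_high
        cover = hit / trials
        assert cover >= 0.95 - 4 * np.sqrt(0.05 * 0.95 / trials)

    def test_invalid_counts_fail(self):
        with pytest.raises(ValueError):
            A.clone_binomial_validation(1, 0)
        with pytest.raises(ValueError):
            A.clone_binomial_validation(5, 3)


class TestRequiredCloneCount:
    def _power(self, n, pi, alpha=0.05):
        ks = np.arange(n + 1)
        reject = np.array([oracle_binom_p(int(k), n) < alpha for k in ks])
        return float((binom.pmf(ks, n, pi) * reject).sum())

    def test_returned_n_satisfies_power_and_n_minus_one_fails(self):
        for pi in (0.9, 0.8):
            n = A.required_clone_count(pi)
            assert self._power(n, pi) >= 0.8
            if n > 1:
                assert self._power(n - 1, pi) < 0.8

    def test_monotone_in_effect_size(self):
        ns = [A.required_clone_count(pi) for pi in (0.9, 0.8, 0.7, 0.65)]
        assert ns == sorted(ns)

    def test_degenerate_pi(self):
        n = A.required_clone_count(1.0)
        assert 2 * 0.5**n <= 0.05 < 2 * 0.5 ** (n - 1)
        with pytest.raises(ValueError):
            A.required_clone_count(0.5)


class TestCalibration:
    def test_null_type_one_error_near_alpha(self):
        # test's own sampling model: k ~ Binom(200, 0.5) for 300 genes
        rng = np.random.default_rng(33)
        ks = rng.binomial(200, 0.5, size=300)
        ps = [A.binomial_bias_test(int(k), int(200 - k))[1] for k in ks]
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.015 <= frac <= 0.085


class TestSamReader:
    def test_depths_from_sam_match_direct_assignment(self, tmp_path):
        tx1 = {"g": "ACGTACGTACGTACGTACGT"}
        tx2 = {"g": "ACGTACGAACGTACGTACGT"}
        loci = {"g": [A.SnpLocus("g", 7, "T", "A", 7, 7, "T", "A")]}
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:g\tLN:20\n"
            "r1\t0\tg\t1\t60\t12M\t*\t0\t0\tACGTACGTACGT\tIIIIIIIIIIII\n"
            "r2\t0\tg\t1\t60\t12M\t*\t0\t0\tACGTACGAACGT\tIIIIIIIIIIII\n"
            "r3\t0\tg\t1\t60\t12M\t*\t0\t0\tACGTACGGACGT\tIIIIIIIIIIII\n"
        )
        table = A.depths_from_sam(sam, loci, condition="RSM")
        row = table.iloc[0]
        assert (row.depth_h1, row.depth_h2, row.depth_other) == (1, 1, 1)
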