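"""Replicate correlation, 3C-qPCR, eQTL regression, PWM scoring, overlap."""

import numpy as np
import pytest
from scipy import stats

from capture3c.integrative import (PWM, MonomorphicSNPError, QPCRMeasurement,
                                   UndefinedCorrelationError,
                                   annotate_overlap, eqtl_regress, eqtl_scan,
                                   pwm_allele_delta, qpcr_contact,
                                   replicate_correlation)


class TestReplicateCorrelation:
    def test_identical_vectors(self):
        assert replicate_correlation([1, 5, 9, 2], [1, 5, 9, 2]) == \
            pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert replicate_correlation([1, 2, 3], [3, 2, 1], min_count=1) == \
            pytest.approx(-1.0)

    def test_filter_leaves_too_few_points(self):
        with pytest.raises(UndefinedCorrelationError):
            replicate_correlation([0, 2, 5, 7], [1, 0, 4, 8], min_count=2)

    def test_constant_after_filter(self):
        with pytest.raises(UndefinedCorrelationError):
            replicate_correlation([3, 3, 3, 0], [1, 2, 3, 0], min_count=1)

    def test_dict_input_uses_union_of_fragments(self):
        a = {("b", 1): 4, ("b", 2): 8}
        b = {("b", 2): 8, ("b", 3): 2, ("b", 1): 4}
        # fragment 3 is 0 in a, so min_count=1 drops it -> only 2 points
        with pytest.raises(UndefinedCorrelationError):
            replicate_correlation(a, b, min_count=1)

    def test_min_count_filter_applied_jointly(self):
        x = np.array([10, 20, 30, 1, 40])
        y = np.array([11, 19, 29, 50, 2])
        r3 = replicate_correlation(x, y, min_count=3)
        expected = stats.pearsonr([10, 20, 30], [11, 19, 29]).statistic
        assert r3 == pytest.approx(expected)


class TestQPCR:
    def adj(self, ct3c=26.0, ctc=26.0):
        return QPCRMeasurement("adj", [ct3c], [ctc],
                               is_adjacent_reference=True)

    def test_equal_cts_give_unity(self):
        t = QPCRMeasurement("t", [30.0], [30.0])
        value, _ = qpcr_contact(t, self.adj(30.0, 30.0))
        assert value == pytest.approx(1.0)

    def test_delta_delta_ct_arithmetic(self):
        t = QPCRMeasurement("t", [30.0], [28.0])
        value, _ = qpcr_contact(t, self.adj())
        assert value == pytest.approx(0.25)  # 2^-2 / 2^0

    def test_swap_inverts(self):
        t = QPCRMeasurement("t", [31.0, 30.0], [28.5],
                            is_adjacent_reference=True)
        a = QPCRMeasurement("a", [27.0], [26.0, 26.5],
                            is_adjacent_reference=True)
        v1, _ = qpcr_contact(t, a)
        v2, _ = qpcr_contact(a, t)
        assert v1 * v2 == pytest.approx(1.0)

    def test_invariant_to_constant_ct_shift(self):
        t = QPCRMeasurement("t", [30.0, 30.4], [28.0, 28.2])
        a = self.adj(26.0, 25.5)
        v1, sd1 = qpcr_contact(t, a)
        t2 = QPCRMeasurement("t", [35.0, 35.4], [33.0, 33.2])
        a2 = QPCRMeasurement("adj", [31.0], [30.5],
                             is_adjacent_reference=True)
        v2, _ = qpcr_contact(t2, a2)
        assert v2 == pytest.approx(v1)
        assert sd1 > 0

    def test_requires_adjacent_flag(self):
        t = QPCRMeasurement("t", [30.0], [28.0])
        with pytest.raises(ValueError, match="adjacent"):
            qpcr_contact(t, QPCRMeasurement("x", [26.0], [26.0]))

    def test_bad_ct_rejected(self):
        with pytest.raises(ValueError):
            QPCRMeasurement("t", [30.0, float("nan")], [28.0])
        with pytest.raises(ValueError):
            QPCRMeasurement("t", [], [28.0])


def normal_equation_oracle(g, y):
    """Closed-form simple OLS: slope, stderr, t, two-sided p (n-2 df)."""
    g = np.asarray(g, float)
    y = np.asarray(y, float)
    n = g.size
    sxx = ((g - g.mean()) ** 2).sum()
    b = ((g - g.mean()) * (y - y.mean())).sum() / sxx
    a = y.mean() - b * g.mean()
    resid = y - a - b * g
    s2 = (resid ** 2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = b / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return b, se, t, p


class TestEqtl:
    def test_matches_normal_equation_oracle(self):
        g = [0, 0, 1, 1, 2, 2]
        y = [1.0, 1.2, 2.1, 1.9, 3.0, 2.8]
        rec = eqtl_regress(g, y)
        b, se, t, p = normal_equation_oracle(g, y)
        assert rec.slope == pytest.approx(b, abs=1e-10)
        assert rec.stderr == pytest.approx(se, abs=1e-10)
        assert rec.t == pytest.approx(t, abs=1e-8)
        assert rec.p == pytest.approx(p, abs=1e-10)

    def test_constant_expression(self):
        rec = eqtl_regress([0, 1, 2, 1], [5.0, 5.0, 5.0, 5.0])
        assert rec.slope == 0.0 and rec.p == 1.0

    def test_perfect_fit_saturates(self):
        g = np.array([0, 0, 1, 1, 2, 2])
        rec = eqtl_regress(g, g.astype(float))
        assert rec.slope == pytest.approx(1.0)
        assert 0 < rec.p <= np.finfo(float).tiny

    def test_monomorphic_snp(self):
        with pytest.raises(MonomorphicSNPError):
            eqtl_regress([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            eqtl_regress([0, 1], [1.0, 2.0])

    def test_null_pvalues_uniform(self):
        """Under b = 0 with Gaussian noise, p-values are U(0,1)."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            g = rng.integers(0, 3, size=100)
            if np.ptp(g) == 0:
                continue
            y = rng.normal(size=100)
            pvals.append(eqtl_regress(g, y).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_scan_adds_bh_column(self):
        rng = np.random.default_rng(23)
        records = []
        for i in range(5):
            g = rng.integers(0, 3, size=30)
            y = rng.normal(size=30) + (0.8 * g if i == 0 else 0)
            records.append((f"rs{i}", f"GENE{i}", g, y))
        df = eqtl_scan(records)
        assert "p_bh" in df.columns and len(df) == 5
        assert (df["p_bh"] >= df["p"] - 1e-15).all()


class TestPWM:
    def uniform(self, width=6):
        return PWM(np.full((width, 4), 0.25))

    def test_uniform_pwm_scores_zero(self):
        s1, s2, d = pwm_allele_delta(self.uniform(), "ACGTACGTAC", 4, "A", "C")
        assert s1 == s2 == d == 0.0

    def test_width_one_log_odds(self):
        pwm = PWM(np.array([[0.97, 0.01, 0.01, 0.01]]))
        s1, s2, d = pwm_allele_delta(pwm, "TTTAT", 2, "A", "C")
        # best window for C is the reverse strand (G column = 0.01) too
        assert s1 == pytest.approx(np.log2(0.97 / 0.25))
        assert d == pytest.approx(np.log2(0.97 / 0.01))

    def test_same_allele_zero_delta(self):
        pwm = PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]]))
        _, _, d = pwm_allele_delta(pwm, "ACGTA", 2, "G", "G")
        assert d == 0.0

    def test_antisymmetric_in_alleles(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            m = rng.dirichlet(np.ones(4), size=5)
            pwm = PWM(m)
            ctx = "".join(rng.choice(list("ACGT"), size=12))
            a1, a2 = rng.choice(list("ACGT"), size=2, replace=False)
            _, _, d12 = pwm_allele_delta(pwm, ctx, 6, a1, a2)
            _, _, d21 = pwm_allele_delta(pwm, ctx, 6, a2, a1)
            assert d12 == pytest.approx(-d21)

    def test_reverse_strand_scanned(self):
        # strong match only for the reverse complement of the context
        pwm = PWM(np.array([[0.94, 0.02, 0.02, 0.02],
                            [0.02, 0.94, 0.02, 0.02]]))  # motif AC
        # context GT; revcomp = AC scores high
        s1, _, _ = pwm_allele_delta(pwm, "GGTG", 2, "T", "T")
        assert s1 == pytest.approx(2 * np.log2(0.94 / 0.25))

    def test_invalid_allele(self):
        with pytest.raises(ValueError, match="allele"):
            pwm_allele_delta(self.uniform(), "ACGTACGTAC", 4, "N", "C")

    def test_counts_with_pseudocount_normalized(self):
        pwm = PWM.from_counts(np.array([[8, 0, 0, 0], [0, 0, 8, 0]]),
                              pseudocount=0.5)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        assert pwm.matrix[0, 0] == pytest.approx(8.5 / 10.0)


class TestAnnotateOverlap:
    def test_basic_overlap(self):
        hits = annotate_overlap([("c", 100, 200)],
                                {"peak": [("c", 150, 300)]})
        assert hits == [["peak"]]

    def test_half_open_boundary(self):
        hits = annotate_overlap([("c", 100, 200)],
                                {"peak": [("c", 200, 300)]})
        assert hits == [[]]

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            annotate_overlap([("c", 200, 100)], {})
        with pytest.raises(ValueError):
            annotate_overlap([("c", 1, 2)], {"t": [("c", 5, 5)]})

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(37)

        def random_intervals(n):
            start = rng.integers(0, 100_000, size=n)
            length = rng.integers(1, 500, size=n)
            chrom = rng.choice(["c1", "c2"], size=n)
            return [(c, int(s), int(s + l))
                    for c, s, l in zip(chrom, start, length)]

        feats = random_intervals(1000)
        tracks = {"t1": random_intervals(500), "t2": random_intervals(500)}
        got = annotate_overlap(feats, tracks)
        for feat, hits in zip(feats, got):
            expected = [name for name, ivs in tracks.items()
                        if any(c == feat[0] and s < feat[2] and e > feat[1]
                               for c, s, e in ivs)]
            assert hits == expected
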