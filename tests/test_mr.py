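"""Two-sample MR: harmonization, estimators, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabridge import mr
from metabridge.simulate import GwasPairSpec, generate_gwas_pair


def gwas_table(rows: list[dict]) -> mr.GwasSummary:
    defaults = {"eaf": 0.3, "se": 0.01, "pval": 1e-10, "n": 100000}
    return mr.GwasSummary(pd.DataFrame([{**defaults, **r} for r in rows]))


def harmonized(beta_x, beta_y, se_x=None, se_y=None) -> mr.HarmonizedSet:
    k = len(beta_x)
    table = pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(k)],
            "effect_allele": "A",
            "other_allele": "C",
            "eaf": 0.3,
            "beta_x": beta_x,
            "se_x": se_x if se_x is not None else np.full(k, 0.01),
            "beta_y": beta_y,
            "se_y": se_y if se_y is not None else np.full(k, 0.01),
        }
    )
    return mr.HarmonizedSet(table=table, exclusions=pd.DataFrame(columns=["rsid", "reason"]))


class TestSelectInstruments:
    def test_threshold_filters(self):
        rows = [{"rsid": f"rs{i}", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.1, "pval": 1e-9 if i < 12 else 0.01} for i in range(100)]
        selected = mr.select_instruments(gwas_table(rows), 5e-8)
        assert len(selected) == 12

    def test_threshold_one_keeps_all(self):
        rows = [{"rsid": f"rs{i}", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.1, "pval": 0.5} for i in range(10)]
        assert len(mr.select_instruments(gwas_table(rows), 1.0)) == 10

    def test_matches_brute_force_filter(self):
        exp, _ = generate_gwas_pair(GwasPairSpec(n_snps=80, seed=3, n_exposure=5000))
        thr = 1e-4
        selected = mr.select_instruments(exp, thr)
        brute = set(exp.table.loc[exp.table["pval"] < thr, "rsid"])
        assert set(selected.table["rsid"]) == brute

    def test_empty_selection_errors(self):
        rows = [{"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.0, "pval": 0.9}]
        with pytest.raises(ValueError, match="no instruments"):
            mr.select_instruments(gwas_table(rows), 5e-8)


class TestHarmonize:
    def test_identical_coding_unchanged(self):
        exp = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": -0.05}])
        h = mr.harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_order_swap_flips_sign_and_eaf(self):
        exp = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3}])
        out = gwas_table([{"rsid": "rs1", "effect_allele": "G", "other_allele": "A", "beta": -0.05, "eaf": 0.7}])
        h = mr.harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_strand_flip_aligned(self):
        exp = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = gwas_table([{"rsid": "rs1", "effect_allele": "T", "other_allele": "C", "beta": 0.04}])
        h = mr.harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(0.04)

    def test_ambiguous_palindrome_excluded(self):
        exp = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T", "beta": 0.1, "eaf": 0.50}])
        out = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T", "beta": 0.05, "eaf": 0.52}])
        h = mr.harmonize(exp, out)
        assert len(h) == 0
        assert list(h.exclusions["reason"]) == ["palindromic_ambiguous"]

    def test_resolvable_palindrome_kept(self):
        exp = gwas_table([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T", "beta": 0.1, "eaf": 0.2}])
        out = gwas_table([{"rsid": "rs1", "effect_allele": "T", "other_allele": "A", "beta": -0.05, "eaf": 0.8}])
        h = mr.harmonize(exp, out)
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_missing_and_mismatch_logged(self):
        exp = gwas_table([
            {"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1},
            {"rsid": "rs2", "effect_allele": "A", "other_allele": "G", "beta": 0.1},
        ])
        out = gwas_table([{"rsid": "rs2", "effect_allele": "A", "other_allele": "C", "beta": 0.1}])
        h = mr.harmonize(exp, out)
        reasons = dict(zip(h.exclusions["rsid"], h.exclusions["reason"]))
        assert reasons == {"rs1": "missing_in_outcome", "rs2": "allele_mismatch"}

    def test_involutive_on_aligned_set(self):
        exp, out = generate_gwas_pair(GwasPairSpec(n_snps=40, true_beta=0.1, seed=9))
        h1 = mr.harmonize(exp, out)
        # re-express the harmonized outcome as a GWAS table and re-harmonize
        out2 = mr.GwasSummary(pd.DataFrame({
            "rsid": h1.table["rsid"], "effect_allele": h1.table["effect_allele"],
            "other_allele": h1.table["other_allele"], "eaf": h1.table["eaf"],
            "beta": h1.table["beta_y"], "se": h1.table["se_y"], "pval": 0.5, "n": 1000,
        }))
        exp_kept = mr.GwasSummary(exp.table[exp.table["rsid"].isin(h1.table["rsid"])].reset_index(drop=True))
        h2 = mr.harmonize(exp_kept, out2)
        assert np.allclose(h2.beta_y, h1.beta_y)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            gwas_table([{"rsid": "rs1", "effect_allele": "I", "other_allele": "D", "beta": 0.1}])


class TestIVW:
    def test_wald_ratio_arithmetic(self):
        ratio, se = mr.wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert ratio == pytest.approx(0.2)
        assert se == pytest.approx(0.05)

    def test_homogeneous_ratios(self):
        bx = np.array([0.1, 0.2, 0.15])
        h = harmonized(bx, 0.3 * bx)
        est = mr.ivw(h)
        assert est.beta == pytest.approx(0.3)
        assert est.q == pytest.approx(0.0, abs=1e-20)

    def test_equal_weights_reduce_to_mean(self):
        bx = np.full(5, 0.1)
        by = np.array([0.01, 0.02, 0.03, 0.02, 0.01])
        est = mr.ivw(harmonized(bx, by))
        assert est.beta == pytest.approx(np.mean(by / bx))

    def test_or_ci_consistency(self):
        est = mr.ivw(harmonized(np.array([0.1, 0.2]), np.array([0.02, 0.05])))
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.96 * est.se))
        assert est.ci_high == pytest.approx(np.exp(est.beta + 1.96 * est.se))

    def test_zero_beta_x_excluded(self):
        h = harmonized(np.array([0.0, 0.1, 0.2]), np.array([0.0, 0.02, 0.04]))
        est = mr.ivw(h)
        assert est.n_snps == 2

    def test_too_few_snps_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            mr.ivw(harmonized(np.array([0.1]), np.array([0.02])))


class TestWeightedMedian:
    def test_degenerate_distribution(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = mr.weighted_median(harmonized(bx, 0.3 * bx), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_interpolation_formula_hand_value(self):
        # equal weights, ratios (0.1, 0.2, 0.9): weighted percentiles are
        # (1/6, 1/2, 5/6); the 0.5 point interpolates exactly to 0.2
        bx = np.full(3, 0.1)
        by = bx * np.array([0.1, 0.2, 0.9])
        est = mr.weighted_median(harmonized(bx, by), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_seed_determinism(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        by = 0.2 * bx + np.array([0.0, 0.001, -0.001, 0.002])
        e1 = mr.weighted_median(harmonized(bx, by), n_boot=200, seed=3)
        e2 = mr.weighted_median(harmonized(bx, by), n_boot=200, seed=3)
        assert e1.se == e2.se

    def test_too_few_snps(self):
        with pytest.raises(ValueError, match=">= 3"):
            mr.weighted_median(harmonized(np.array([0.1, 0.2]), np.array([0.0, 0.0])))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.05 + 0.3 * bx
        est = mr.mr_egger(harmonized(bx, by))
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_slope_equals_ivw_when_intercept_constrained(self):
        # oracle: zero-intercept WLS of beta_y on beta_x == IVW
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.25 * bx + rng.normal(0, 0.005, 20)
        h = harmonized(bx, by)
        w = bx**2 / h.se_y**2
        constrained = np.sum((by / bx) * w) / np.sum(w)
        assert mr.ivw(h).beta == pytest.approx(constrained)

    def test_no_spread_errors(self):
        bx = np.full(4, 0.1)
        with pytest.raises(ValueError, match="spread"):
            mr.mr_egger(harmonized(bx, 0.3 * bx))


class TestCochranQ:
    def test_homogeneous_q_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = harmonized(bx, 0.3 * bx)
        q, df, p = mr.cochran_q(h, mr.ivw(h))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_groups_exceed_quantile_with_brute_force(self):
        bx = np.full(10, 0.1)
        ratios = np.array([0.0] * 5 + [1.0] * 5)
        h = harmonized(bx, bx * ratios)
        est = mr.ivw(h)
        q, df, p = mr.cochran_q(h, est)
        brute = np.sum((bx**2 / h.se_y**2) * (ratios - est.beta) ** 2)
        assert q == pytest.approx(brute)
        assert q > stats.chi2.ppf(0.999, df)


class TestInstrumentStrength:
    def test_f_arithmetic_and_flag(self):
        rows = [
            {"rsid": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1, "se": 0.01},
            {"rsid": "rs2", "effect_allele": "A", "other_allele": "G", "beta": 0.03, "se": 0.01},
        ]
        out = mr.instrument_strength(gwas_table(rows))
        assert out["F"].tolist() == pytest.approx([100.0, 9.0])
        assert out.attrs["weak_instruments"] is True
        assert out.attrs["mean_F"] == pytest.approx(np.mean([100.0, 9.0]))

    def test_strong_batch_not_flagged(self):
        exp, _ = generate_gwas_pair(GwasPairSpec(n_snps=20, seed=1))
        out = mr.instrument_strength(exp)
        brute = np.mean((exp.table["beta"] / exp.table["se"]) ** 2)
        assert out.attrs["mean_F"] == pytest.approx(brute)


class TestBidirectional:
    def test_self_mr_rejected(self):
        exp, _ = generate_gwas_pair(GwasPairSpec(n_snps=10, seed=0))
        with pytest.raises(ValueError, match="self-MR"):
            mr.run_bidirectional(exp, exp)

    def test_one_way_causal_detected_forward(self):
        spec = GwasPairSpec(n_snps=50, true_beta=0.3, seed=5)
        exp, out = generate_gwas_pair(spec)
        report = mr.run_bidirectional(exp, out, n_boot=100, seed=2)
        fwd = report["forward"]["estimates"]["IVW"]
        assert fwd["p"] < 0.05
        assert abs(fwd["beta"] - 0.3) < 0.05
        assert "reverse" in report
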