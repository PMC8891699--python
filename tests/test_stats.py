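"""Permutation tests, Bonferroni, bootstrap CIs, volumes and the FGLS model."""
import itertools

import numpy as np
import pandas as pd
import pytest

from hippounet.errors import SpecError
from hippounet.grids import LabelMap
from hippounet.metrics import MetricsReport
from hippounet.stats import (
    bonferroni,
    bootstrap_ci_mean,
    compute_volumes,
    fit_volume_model,
    interhemispheric_differences,
    paired_permutation_test,
    simulate_volume_table,
)


def enum_permutation_p(d):
    """Exact two-sided sign-flip p-value by full enumeration."""
    d = np.asarray(d, dtype=float)
    obs = abs(d.mean())
    n = d.size
    hits = 0
    for signs in itertools.product((-1, 1), repeat=n):
        if abs(np.dot(signs, d) / n) >= obs - 1e-12:
            hits += 1
    return hits / 2**n


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert paired_permutation_test(x, x.copy()) == 1.0

    def test_all_positive_differences_exact(self):
        # n=5, all differences equal: only the two all-same sign patterns
        # reach |mean|, p = 2/32
        p = paired_permutation_test(np.ones(5))
        assert p == pytest.approx(2 / 32)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_enumeration_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=8)
        assert paired_permutation_test(d) == pytest.approx(enum_permutation_p(d))

    def test_monte_carlo_close_to_enumeration(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1.0, size=12)
        p_exact = enum_permutation_p(d)
        # force the Monte-Carlo path with fewer iterations than 2^12
        p_mc = paired_permutation_test(d, iterations=2000, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / 2000

    def test_two_sidedness_sign_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, size=9)
        assert paired_permutation_test(d) == pytest.approx(paired_permutation_test(-d))

    def test_degenerate_inputs(self):
        assert paired_permutation_test(np.zeros(6)) == 1.0
        with pytest.raises(SpecError):
            paired_permutation_test(np.array([1.0]))


def test_bonferroni():
    assert bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
    assert bonferroni([0.5], m=4)[0] == 1.0
    assert bonferroni([0.3], m=1)[0] == pytest.approx(0.3)
    with pytest.raises(SpecError):
        bonferroni([0.1, 0.2], m=1)


def _report(ipsi_dice, contra_dice):
    per = {
        "ipsi": {"dice": ipsi_dice, "hd95": 0.1, "vs": 1.0, "cs": 1.0,
                 "precision": 1.0, "recall": 1.0},
        "contra": {"dice": contra_dice, "hd95": 0.1, "vs": 1.0, "cs": 1.0,
                   "precision": 1.0, "recall": 1.0},
    }
    vols = {r: {"pred": 1.0, "truth": 1.0} for r in ("ipsi", "contra")}
    return MetricsReport(per_roi=per, reasons={}, volumes_mm3=vols)


class TestInterhemispheric:
    def test_identical_rois_give_zero_differences(self):
        reps = [_report(0.9, 0.9) for _ in range(5)]
        df = interhemispheric_differences(reps, n_boot=500, seed=0)
        assert (df["mean_diff"] == 0).all()
        assert (df["ci_lo"] <= 0).all() and (df["ci_hi"] >= 0).all()

    def test_constant_offset_recovered(self):
        reps = [_report(0.85, 0.90) for _ in range(4)]
        df = interhemispheric_differences(reps, n_boot=500, seed=0).set_index("metric")
        assert df.loc["dice", "mean_diff"] == pytest.approx(-0.05)

    def test_bootstrap_coverage(self):
        # percentile bootstrap CI covers the true mean in >= 93% of
        # replications under a Gaussian population
        rng = np.random.default_rng(42)
        cover = 0
        reps = 500
        for i in range(reps):
            sample = rng.normal(0.2, 1.0, size=50)
            lo, hi = bootstrap_ci_mean(sample, n_boot=1000, seed=i)
            cover += lo <= 0.2 <= hi
        assert cover / reps >= 0.93


def test_compute_volumes_arithmetic():
    lab = np.zeros((10, 10, 10), dtype=np.uint8)
    lab.ravel()[:100] = 1
    lm = LabelMap(labels=lab, brain=lab > 0, spacing=(0.16, 0.16, 0.16))
    ipsi, contra = compute_volumes(lm)
    assert ipsi == pytest.approx(100 * 0.16**3)
    assert contra == 0.0
    # volumes invariant under axis permutation
    lm2 = LabelMap(labels=lab.transpose(2, 0, 1), brain=lab.transpose(2, 0, 1) > 0,
                   spacing=(0.16, 0.16, 0.16))
    assert compute_volumes(lm2)[0] == pytest.approx(ipsi)


BETA = {"const": 30.0, "t": -0.01, "R": -2.0, "B": -3.0, "tR": -0.02,
        "tB": -0.015, "RB": -1.0}
VARS = {2: 1.0, 9: 2.0, 30: 3.0, 150: 5.0}


class TestVolumeModel:
    def test_homoscedastic_fgls_equals_ols(self):
        # residuals of exactly +-c at every design point make the estimated
        # per-timepoint variances identical, so the FGLS weights are equal
        # and the fit must coincide with OLS
        import statsmodels.api as sm

        from hippounet.stats import _design

        rows = []
        c = 1.5
        for B in (0, 1):
            for R in (0, 1):
                for t in (2, 9, 30, 150):
                    mu = (BETA["const"] + BETA["t"] * t + BETA["R"] * R
                          + BETA["B"] * B + BETA["tR"] * t * R
                          + BETA["tB"] * t * B + BETA["RB"] * R * B)
                    for sign in (+1, -1):
                        rows.append({"animal": 0, "B": B, "t": t, "R": R,
                                     "volume_mm3": mu + sign * c})
        tab = pd.DataFrame(rows)
        fit = fit_volume_model(tab)
        ols = sm.OLS(tab["volume_mm3"].astype(float), _design(tab)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(),
                                   rtol=1e-6, atol=1e-9)

    def test_parameter_recovery_within_3_se(self):
        # moderate replication count; the acceptance suite runs the full one
        hits = {k: 0 for k in BETA}
        reps = 60
        for i in range(reps):
            tab = simulate_volume_table(BETA, VARS, n_per_group=10, seed=1000 + i)
            fit = fit_volume_model(tab)
            for k in BETA:
                if abs(fit.params[k] - BETA[k]) <= 3 * fit.bse[k]:
                    hits[k] += 1
        for k, h in hits.items():
            assert h / reps >= 0.9, f"coefficient {k} recovered in only {h}/{reps}"

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats as sps

        beta0 = dict(BETA, B=0.0, tB=0.0, RB=0.0)
        ps = []
        for i in range(200):
            tab = simulate_volume_table(beta0, VARS, n_per_group=8, seed=5000 + i)
            fit = fit_volume_model(tab)
            ps.append(fit.pvalues["B"])
        # Kolmogorov-Smirnov against U(0,1); generous threshold for n=200
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_rank_deficient_design_raises(self):
        tab = simulate_volume_table(BETA, VARS, n_per_group=4, seed=0)
        tab["t"] = 5.0  # single timepoint value -> t collinear with const
        with pytest.raises(SpecError):
            fit_volume_model(tab)

    def test_variances_estimated_per_timepoint(self):
        tab = simulate_volume_table(BETA, VARS, n_per_group=40, seed=3)
        fit = fit_volume_model(tab)
        assert set(fit.timepoint_variances) == {float(t) for t in VARS}
        est = np.array([fit.timepoint_variances[float(t)] for t in sorted(VARS)])
        true = np.array([VARS[t] for t in sorted(VARS)])
        assert np.corrcoef(est, true)[0, 1] > 0.9
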