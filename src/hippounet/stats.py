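"""Statistical machinery: paired permutation tests, Bonferroni correction,
inter-hemispheric differences with bootstrap CIs, hippocampal volumes, and
the repeated-measures volume model.

The volume model expresses hippocampal volume V (mm^3) as fixed effects of
time t (days, continuous), hemisphere R (1 = ipsilateral to the injury),
group B (1 = TBI) and their pairwise interactions:

    V = a + b_t t + b_R R + b_B B + b_tR tR + b_tB tB + b_RB RB + E,

with a heteroscedastic diagonal error: Var(E) depends on the timepoint. The
fit is feasible generalized least squares — iterated weighted least squares
with per-timepoint variances estimated from residuals — which is exactly
this model class (only fixed effects, diagonal covariance). When all
per-timepoint variances are equal, FGLS coincides with OLS.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, SpecError
from .grids import CONTRA, IPSI, LabelMap

MODEL_TERMS = ("const", "t", "R", "B", "tR", "tB", "RB")


def paired_permutation_test(x, y=None, iterations: int = 10000, seed: int = 0) -> float:
    """Two-sided paired permutation test on the mean difference.

    With ``y`` given, tests mean(x - y); otherwise ``x`` is already the
    paired differences. The null randomly flips the sign of each paired
    difference. When the full 2^n enumeration is no larger than
    ``iterations``, the exact p-value is returned; otherwise a Monte-Carlo
    estimate with ``iterations`` random sign patterns.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if d.shape != y.shape:
            raise SpecError("paired samples must have equal length")
        d = d - y
    n = d.size
    if n < 2:
        raise SpecError("need at least two pairs")
    if np.all(d == 0):
        return 1.0
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    if 2**n <= iterations:
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
        means = np.abs(signs @ d) / n
        return float((means >= obs - tol).mean())
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 2000
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        signs = rng.choice((-1.0, 1.0), size=(m, n))
        means = np.abs(signs @ d) / n
        hits += int((means >= obs - tol).sum())
        done += m
    return float((hits + 1) / (iterations + 1))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """min(1, m * p) for each p; m defaults to the number of tests."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise SpecError("correction factor m smaller than the number of p-values")
    return np.minimum(1.0, m * p)


def bootstrap_ci_mean(values, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0):
    """Percentile bootstrap CI for the mean."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def interhemispheric_differences(reports, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Mean (ipsi - contra) per metric with percentile-bootstrap 95% CIs.

    ``reports`` is a sequence of MetricsReport; scans missing a value for
    either hemisphere are excluded pairwise, with the retained count
    reported.
    """
    from .metrics import METRIC_NAMES

    if len(reports) < 2:
        raise SpecError("need at least two reports")
    rows = []
    for j, metric in enumerate(METRIC_NAMES):
        diffs = []
        for rep in reports:
            a = rep.per_roi.get("ipsi", {}).get(metric)
            b = rep.per_roi.get("contra", {}).get(metric)
            if a is not None and b is not None:
                diffs.append(a - b)
        if len(diffs) < 2:
            rows.append({"metric": metric, "mean_diff": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "n": len(diffs)})
            continue
        diffs = np.asarray(diffs)
        lo, hi = bootstrap_ci_mean(diffs, n_boot=n_boot, seed=seed + j)
        rows.append({"metric": metric, "mean_diff": float(diffs.mean()),
                     "ci_lo": lo, "ci_hi": hi, "n": len(diffs)})
    return pd.DataFrame(rows)


def compute_volumes(labels: LabelMap) -> tuple[float, float]:
    """(ipsilateral, contralateral) hippocampal volume in mm^3."""
    vox = labels.voxel_volume
    return (
        float((labels.labels == IPSI).sum() * vox),
        float((labels.labels == CONTRA).sum() * vox),
    )


def volume_table(records) -> pd.DataFrame:
    """Long-format volume table from cohort records with labels.

    Columns: animal, B (1 = TBI), t (days), R (1 = ipsi), volume_mm3.
    """
    rows = []
    for r in records:
        ipsi, contra = compute_volumes(r["labels"])
        b = 1 if str(r.get("group", "TBI")).upper() == "TBI" else 0
        for R, vol in ((1, ipsi), (0, contra)):
            rows.append({"animal": r["animal"], "B": b, "t": r["timepoint_days"],
                         "R": R, "volume_mm3": vol})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class VolumeModelFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    timepoint_variances: dict
    n_iterations: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "z": self.tvalues, "p": self.pvalues})


def _design(tab: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "t": tab["t"].astype(float),
            "R": tab["R"].astype(float),
            "B": tab["B"].astype(float),
            "tR": tab["t"].astype(float) * tab["R"].astype(float),
            "tB": tab["t"].astype(float) * tab["B"].astype(float),
            "RB": tab["R"].astype(float) * tab["B"].astype(float),
        }
    )
    return X


def fit_volume_model(tab: pd.DataFrame, max_iter: int = 50, tol: float = 1e-8) -> VolumeModelFit:
    """FGLS fit of the volume model with per-timepoint error variances."""
    required = {"B", "t", "R", "volume_mm3"}
    if not required.issubset(tab.columns):
        raise SpecError(f"volume table must have columns {sorted(required)}")
    if tab["B"].nunique() < 2 or tab["t"].nunique() < 2 or tab["R"].nunique() < 2:
        raise SpecError("need both groups, both hemispheres, and >= 2 timepoints")
    X = _design(tab)
    y = tab["volume_mm3"].astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise SpecError("rank-deficient design; collinear terms among "
                        f"{list(X.columns)} (rank {rank} < {X.shape[1]})")
    tp = tab["t"].to_numpy()
    # start from OLS
    res = sm.OLS(y, X).fit()
    var_by_tp = {}
    converged = False
    it = 0
    prev = None
    for it in range(1, max_iter + 1):
        resid = y.to_numpy() - res.predict(X).to_numpy()
        var_by_tp = {}
        for t in np.unique(tp):
            r = resid[tp == t]
            var_by_tp[float(t)] = float(np.mean(r**2))
        w = np.array([1.0 / max(var_by_tp[float(t)], 1e-12) for t in tp])
        res = sm.WLS(y, X, weights=w).fit()
        cur = res.params.to_numpy()
        if prev is not None and np.max(np.abs(cur - prev)) <= tol * (1 + np.max(np.abs(cur))):
            converged = True
            break
        prev = cur
    return VolumeModelFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        timepoint_variances=var_by_tp,
        n_iterations=it,
        converged=converged,
    )


def simulate_volume_table(beta: dict, var_by_tp: dict, n_per_group: int = 10,
                          timepoints=(2, 9, 30, 150), seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic volume table from the model (for calibration checks).

    ``beta`` maps term names (const, t, R, B, tR, tB, RB) to coefficients;
    ``var_by_tp`` maps timepoint to error variance.
    """
    rng = np.random.default_rng(seed)
    rows = []
    animal = 0
    for B in (0, 1):
        for _ in range(n_per_group):
            for t in timepoints:
                for R in (0, 1):
                    mu = (
                        beta.get("const", 0.0)
                        + beta.get("t", 0.0) * t
                        + beta.get("R", 0.0) * R
                        + beta.get("B", 0.0) * B
                        + beta.get("tR", 0.0) * t * R
                        + beta.get("tB", 0.0) * t * B
                        + beta.get("RB", 0.0) * R * B
                    )
                    e = rng.normal(0.0, np.sqrt(var_by_tp[t]))
                    rows.append({"animal": animal, "B": B, "t": t, "R": R,
                                 "volume_mm3": mu + e})
            animal += 1
    return pd.DataFrame(rows)
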