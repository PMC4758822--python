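"""Group-level summary-statistic inference.

One-sample t-tests with Benjamini-Hochberg FDR over the modulatory (B)
parameters, and Tukey-biweight robust regression relating each extrinsic
modulation to subjective ratings. Robust regression protects the
individual-differences analysis against outlying subjects, a common issue
in neuroimaging cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.robust.norms import TukeyBiweight
from statsmodels.stats.multitest import multipletests

TUKEY_C = 4.685  # 95% Gaussian efficiency


@dataclass
class TTestEntry:
    mean: float
    t: float
    df: int
    p: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    weights: np.ndarray
    t: float
    df: int
    p: float
    r_squared: float
    converged: bool = True

    @property
    def r_squared_percent(self) -> float:
        return 100.0 * self.r_squared


@dataclass
class GroupAnalysisResult:
    ttests: pd.DataFrame
    difficulty_regressions: pd.DataFrame
    control_regressions: pd.DataFrame


def count_accuracy(counted: float, total: float) -> float:
    """Counting accuracy in percent (e.g. 156 of 158 counted -> 98.7...)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return 100.0 * counted / total


def summary_t(mean_diff: float, sd_diff: float, n: int) -> float:
    """t statistic recomputed from printed summary numbers: mean/(sd/sqrt(n))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be > 0")
    return mean_diff / (sd_diff / np.sqrt(n))


def one_sample_t(values: np.ndarray, null_mean: float = 0.0) -> TTestEntry:
    """Two-sided one-sample t-test against ``null_mean``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    mean = values.mean()
    t = (mean - null_mean) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestEntry(mean=float(mean), t=float(t), df=n - 1, p=float(p))


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def tukey_regression(x: np.ndarray, y: np.ndarray,
                     tol: float = 1e-10, maxiter: int = 300) -> RegressionResult:
    """Simple robust regression of y on x with Tukey's biweight.

    Iteratively reweighted least squares with the redescending biweight
    (c = 4.685) and MAD-based scale recomputed each iteration. The slope's t
    statistic uses n - 2 degrees of freedom. R^2 is the squared correlation
    between fitted and observed responses (unweighted: weighting by the
    biweight would systematically overstate the variance explained, since
    the weights are largest exactly where the fit is best); the final
    weights are returned as outlier diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0:
        raise ValueError("predictor has zero variance")

    X = sm.add_constant(x)
    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_beta
    if np.median(np.abs(ols_resid)) < 1e-10 * max(1.0, float(np.median(np.abs(y)))):
        # perfect (collinear) fit: the MAD scale is zero, so IRLS is
        # undefined; the least-squares line with unit weights is the answer
        slope = float(ols_beta[1])
        se = np.sqrt(max(np.sum(ols_resid ** 2), 1e-300) / (n - 2)
                     / np.sum((x - x.mean()) ** 2))
        t_stat = slope / se if se > 0 else np.inf
        return RegressionResult(
            slope=slope, intercept=float(ols_beta[0]),
            weights=np.ones(n), t=float(t_stat), df=n - 2,
            p=float(2.0 * stats.t.sf(abs(t_stat), df=n - 2)),
            r_squared=_weighted_corr_sq(X @ ols_beta, y, np.ones(n)),
        )
    model = sm.RLM(y, X, M=TukeyBiweight(c=TUKEY_C))
    res = model.fit(conv="coefs", tol=tol, maxiter=maxiter,
                    scale_est="mad", update_scale=True)
    converged = len(res.fit_history["params"]) < maxiter

    intercept, slope = res.params
    t_stat = slope / res.bse[1]
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)

    w = np.clip(res.weights, 0.0, 1.0)
    fitted = res.fittedvalues
    r2 = _weighted_corr_sq(fitted, y, np.ones_like(w))
    return RegressionResult(
        slope=float(slope), intercept=float(intercept), weights=w,
        t=float(t_stat), df=n - 2, p=float(p), r_squared=float(r2),
        converged=converged,
    )


def _weighted_corr_sq(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    am = a - (w @ a) / wsum
    bm = b - (w @ b) / wsum
    num = (w * am) @ bm
    den = np.sqrt(((w * am) @ am) * ((w * bm) @ bm))
    if den == 0:
        return 0.0
    return float(np.clip((num / den) ** 2, 0.0, 1.0))


def is_extrinsic(name: str) -> bool:
    """Extrinsic (between-region) parameter names look like 'B1(AIC<-MFG)'
    with distinct source and target."""
    if "(" not in name or "<-" not in name:
        return False
    inner = name[name.index("(") + 1:name.rindex(")")]
    target, source = inner.split("<-")
    return target != source


def run_group_analysis(
    params: pd.DataFrame,
    ratings: pd.DataFrame,
    q: float = 0.05,
) -> GroupAnalysisResult:
    """The full group-level battery.

    ``params``: subjects x named modulatory parameters (Hz). ``ratings``:
    per-subject 'difficulty' (mean VAS) and 'intensity_difference' (high -
    low VAS) columns. Runs a one-sample t-test per parameter (FDR within the
    family of all parameters) and a Tukey-biweight regression per extrinsic
    parameter predicting each rating outcome (FDR within each 20-regression
    family). The intensity-difference regressions are the null control.
    """
    if params.isna().any().any() or ratings.isna().any().any():
        raise ValueError("missing values in input tables")
    if len(params) != len(ratings) or not params.index.equals(ratings.index):
        raise ValueError("parameter and rating tables must share subjects")
    if len(params) < 2:
        raise ValueError("need at least 2 subjects")

    entries = {c: one_sample_t(params[c].to_numpy()) for c in params.columns}
    tt = pd.DataFrame(
        {
            "mean": [e.mean for e in entries.values()],
            "t": [e.t for e in entries.values()],
            "df": [e.df for e in entries.values()],
            "p": [e.p for e in entries.values()],
        },
        index=list(entries.keys()),
    )
    tt["p_fdr"], tt["significant"] = bh_fdr(tt["p"].to_numpy(), q)

    extrinsic = [c for c in params.columns if is_extrinsic(c)]

    def regress(outcome: str) -> pd.DataFrame:
        y = ratings[outcome].to_numpy(dtype=float)
        rows = {}
        for c in extrinsic:
            r = tukey_regression(params[c].to_numpy(), y)
            rows[c] = (r.slope, r.intercept, r.t, r.p, r.r_squared_percent)
        df = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["slope", "intercept", "t", "p", "r_squared_pct"])
        df["p_fdr"], df["significant"] = bh_fdr(df["p"].to_numpy(), q)
        return df

    return GroupAnalysisResult(
        ttests=tt,
        difficulty_regressions=regress("difficulty"),
        control_regressions=regress("intensity_difference"),
    )
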