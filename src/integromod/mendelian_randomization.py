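"""Summary-statistic two-sample Mendelian randomization estimators.

Inverse-variance weighted (IVW) regression is the primary estimator
(fixed-effect by default, multiplicative random effects optional);
MR-Egger regression and the weighted median serve as pleiotropy-robust
sensitivity analyses.  Instruments are assumed independent
(pre-clumped) and pre-harmonized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class MrEstimate:
    method: str  # ivw | egger | weighted_median | wald
    theta_hat: float
    se: float
    p: float
    n_snps: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def _two_sided_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _check(table: pd.DataFrame, min_snps: int) -> pd.DataFrame:
    if len(table) < min_snps:
        raise ValueError(f"need >= {min_snps} instruments, got {len(table)}")
    if ((table["SE_EXPOSURE"] <= 0) | (table["SE_OUTCOME"] <= 0)).any():
        raise ValueError("standard errors must be positive")
    return table


def wald_ratio(beta_exposure: float, beta_outcome: float, se_outcome: float) -> MrEstimate:
    """Single-instrument ratio estimate (first-order delta-method se)."""
    theta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return MrEstimate("wald", float(theta), float(se), _two_sided_p(theta / se), 1)


def ivw(table: pd.DataFrame, random_effects: bool = False) -> MrEstimate:
    """Fixed-effect inverse-variance weighted estimate.

    theta_hat = sum(bX bY / seY^2) / sum(bX^2 / seY^2);
    se = 1 / sqrt(sum(bX^2 / seY^2)).  With ``random_effects=True`` the
    se is inflated multiplicatively by sqrt(max(1, Cochran Q / (n-1))).
    """
    table = _check(table, 2)
    bx = table["BETA_EXPOSURE"].to_numpy(float)
    by = table["BETA_OUTCOME"].to_numpy(float)
    sy = table["SE_OUTCOME"].to_numpy(float)
    w = bx**2 / sy**2
    theta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if random_effects:
        q = float(np.sum(((by / bx - theta) ** 2) * w))
        phi = max(1.0, q / (len(bx) - 1))
        se *= np.sqrt(phi)
    return MrEstimate("ivw", theta, se, _two_sided_p(theta / se), len(bx))


def mr_egger(table: pd.DataFrame) -> MrEstimate:
    """MR-Egger: weighted regression of bY on bX with a free intercept.

    Exposure effects are oriented positive (bX, bY flipped together);
    weights are 1/seY^2.  The slope is the causal estimate; a nonzero
    intercept indicates directional pleiotropy.
    """
    table = _check(table, 3)
    bx = table["BETA_EXPOSURE"].to_numpy(float).copy()
    by = table["BETA_OUTCOME"].to_numpy(float).copy()
    sy = table["SE_OUTCOME"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    inter, slope = float(fit.params[0]), float(fit.params[1])
    # exact fits give zero residual variance; floor the se to keep z finite
    se_inter = max(float(fit.bse[0]), 1e-300)
    se_slope = max(float(fit.bse[1]), 1e-300)
    return MrEstimate("egger", slope, se_slope, _two_sided_p(slope / se_slope),
                      len(bx), egger_intercept=inter, intercept_se=se_inter,
                      intercept_p=_two_sided_p(inter / se_inter))


def weighted_median(table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
                    ) -> MrEstimate:
    """Weighted median of per-SNP ratio estimates.

    Ratio estimates bY/bX are ordered and the estimate interpolates the
    weighted cumulative distribution at 0.5 with weights proportional
    to bX^2/seY^2 (consistent while valid instruments carry > 50 % of
    the weight).  The se comes from a seeded parametric bootstrap.
    """
    table = _check(table, 3)
    nonzero = table["BETA_EXPOSURE"] != 0
    if not nonzero.all():
        table = table[nonzero]
        if len(table) < 3:
            raise ValueError("fewer than 3 instruments after dropping zero exposure betas")
    bx = table["BETA_EXPOSURE"].to_numpy(float)
    by = table["BETA_OUTCOME"].to_numpy(float)
    sx = table["SE_EXPOSURE"].to_numpy(float)
    sy = table["SE_OUTCOME"].to_numpy(float)
    theta = _wm_point(bx, by, sy)
    rng = np.random.default_rng(seed % (2**31 - 1))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boots[b] = _wm_point(bxb[ok], byb[ok], sy[ok])
    se = float(np.std(boots, ddof=1))
    return MrEstimate("weighted_median", float(theta), se,
                      _two_sided_p(theta / se), len(bx))


def _wm_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    ratio = by / bx
    w = bx**2 / sy**2
    order = np.argsort(ratio)
    ratio, w = ratio[order], w[order]
    # weighted percentile: cumulative weight at the midpoint of each step
    cum = (np.cumsum(w) - w / 2) / np.sum(w)
    return float(np.interp(0.5, cum, ratio))


def run_mr(table: pd.DataFrame, methods: list[str] | None = None,
           n_boot: int = 1000, seed: int = 0, random_effects: bool = False
           ) -> list[MrEstimate]:
    """Run the requested estimators (default: all three) on one table."""
    methods = methods or ["ivw", "egger", "weighted_median"]
    out = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(table, random_effects=random_effects))
        elif m == "egger":
            out.append(mr_egger(table))
        elif m in ("weighted_median", "wmedian"):
            out.append(weighted_median(table, n_boot=n_boot, seed=seed))
        else:
            raise ValueError(f"unknown MR method {m!r}")
    return out


def estimates_frame(estimates: list[MrEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{"METHOD": e.method, "THETA": e.theta_hat, "SE": e.se,
                          "P": e.p, "N_SNPS": e.n_snps,
                          "EGGER_INTERCEPT": e.egger_intercept,
                          "INTERCEPT_P": e.intercept_p} for e in estimates])
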