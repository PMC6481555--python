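"""Causal-effect estimators for summary-data Mendelian randomization.

Notation: for SNP j, ``gamma_j`` (``beta_exposure``) is the per-allele
effect on the exposure in SD units with standard error ``sigma_Xj``, and
``Gamma_j`` (``beta_outcome``) the per-allele log-odds effect on the outcome
with standard error ``sigma_Yj``. The per-SNP Wald ratio is
``beta_j = Gamma_j / gamma_j``; all pooled estimates are on the log-odds
per 1-SD-of-exposure scale and are exponentiated only for reporting.

Three pooled estimators with progressively weaker validity assumptions:

* :func:`ivw` — inverse-variance weighted mean of Wald ratios, equal to the
  slope of a weighted regression of ``Gamma`` on ``gamma`` through the
  origin; unbiased only when every SNP is a valid instrument.
* :func:`egger` — the same weighted regression with a free intercept; the
  intercept estimates net directional pleiotropy and the slope is consistent
  under the InSIDE assumption (pleiotropic effects independent of
  instrument strength).
* :func:`penalized_weighted_median` — weighted median of Wald ratios with
  heterogeneity-penalized weights; consistent when less than half the
  weight comes from invalid SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrkit")

#: normal 97.5% quantile used for all 95% confidence intervals
Z_95 = 1.959964


@dataclass
class MrResult:
    """A pooled (or single-SNP) causal estimate on the log-odds-per-SD scale."""

    method: str
    estimate: float
    se: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.estimate - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z_95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value against no causal effect."""
        return float(2 * stats.norm.sf(abs(self.estimate) / self.se))

    def to_dict(self) -> dict:
        d = {"method": self.method, "estimate": self.estimate, "se": self.se,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "or": self.odds_ratio, "or_low": self.or_low, "or_high": self.or_high,
             "p_value": self.p_value, "n_snps": self.n_snps}
        d.update(self.extras)
        return d

    def __str__(self) -> str:
        return (f"{self.method}: OR {self.odds_ratio:.2f} "
                f"(95% CI {self.or_low:.2f}-{self.or_high:.2f}) per 1-SD, "
                f"n_snps={self.n_snps}")


def _as_arrays(harmonized) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (rsid, gamma, sigma_X, Gamma, sigma_Y) from a HarmonizedInstrument
    or a DataFrame with the harmonized-record columns."""
    df = harmonized.retained if hasattr(harmonized, "retained") else harmonized
    return (df["rsid"].to_numpy(),
            df["beta_exposure"].to_numpy(float),
            df["se_exposure"].to_numpy(float),
            df["beta_outcome"].to_numpy(float),
            df["se_outcome"].to_numpy(float))


def wald_ratio(beta_outcome: float, se_outcome: float, beta_exposure: float,
               se_exposure: float = 0.0, second_order: bool = False,
               ) -> tuple[float, float]:
    """Per-SNP Wald ratio and its standard error.

    ``ratio = beta_outcome / beta_exposure``. The default standard error is
    the first-order delta approximation ``se_outcome / |beta_exposure|``,
    which ignores uncertainty in the SNP-exposure effect — the convention
    for strong instruments. ``second_order=True`` adds the exposure-side
    term ``beta_outcome^2 * se_exposure^2 / beta_exposure^4``.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exposure = 0")
    ratio = beta_outcome / beta_exposure
    var = (se_outcome / beta_exposure) ** 2
    if second_order:
        var += beta_outcome ** 2 * se_exposure ** 2 / beta_exposure ** 4
    return ratio, float(np.sqrt(var))


def wald_ratios(harmonized, second_order: bool = False) -> pd.DataFrame:
    """Wald ratio table for every retained SNP with ``beta_exposure != 0``.

    Returns a DataFrame with columns ``rsid, ratio, se_ratio, weight`` where
    ``weight = se_ratio ** -2`` (inverse-variance weight). SNPs with a zero
    exposure effect are excluded with a warning (the ratio is undefined).
    """
    rsid, gx, sx, gy, sy = _as_arrays(harmonized)
    nonzero = gx != 0
    if not nonzero.all():
        logger.warning("excluding %d SNP(s) with beta_exposure = 0 from ratio "
                       "estimation: %s", (~nonzero).sum(), list(rsid[~nonzero]))
    rsid, gx, sx, gy, sy = (a[nonzero] for a in (rsid, gx, sx, gy, sy))
    ratio = gy / gx
    var = (sy / gx) ** 2
    if second_order:
        var = var + gy ** 2 * sx ** 2 / gx ** 4
    se_ratio = np.sqrt(var)
    return pd.DataFrame({"rsid": rsid, "ratio": ratio, "se_ratio": se_ratio,
                         "weight": se_ratio ** -2.0})


def ivw(ratios: pd.DataFrame, model: str = "fixed") -> MrResult:
    """Inverse-variance weighted pooled estimate.

    ``estimate = sum(w_j * ratio_j) / sum(w_j)`` with ``w_j = se_ratio_j**-2``;
    equivalently the slope of a weighted zero-intercept regression of
    ``beta_outcome`` on ``beta_exposure`` with weights ``se_outcome**-2``.

    ``model="fixed"`` uses ``se = sum(w)**-0.5``; ``model="random"`` applies a
    multiplicative overdispersion factor ``max(1, sqrt(Q/(n-1)))`` to the
    standard error (point estimate unchanged).
    """
    if len(ratios) == 0:
        raise ValueError("ivw requires at least one ratio estimate")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    w = ratios["weight"].to_numpy(float)
    b = ratios["ratio"].to_numpy(float)
    est = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    extras = {"model": model}
    if model == "random" and len(ratios) > 1:
        q = float(np.sum(w * (b - est) ** 2))
        phi = max(1.0, np.sqrt(q / (len(ratios) - 1)))
        se *= phi
        extras["overdispersion"] = phi
    return MrResult("ivw", est, se, n_snps=len(ratios), extras=extras)


def _weighted_lsq(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                  intercept: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via normal equations.

    Returns (coef, se_unscaled, sigma) where coef is [slope] or
    [intercept, slope], se_unscaled are the model-based standard errors and
    sigma the residual standard deviation (sqrt of weighted RSS / dof).
    """
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ y)
    resid = y - X @ coef
    dof = len(x) - X.shape[1]
    sigma = float(np.sqrt(np.sum(w * resid ** 2) / dof)) if dof > 0 else np.nan
    se = np.sqrt(np.diag(np.linalg.inv(xtx)))
    return coef, se, sigma


def egger(harmonized) -> MrResult:
    """MR-Egger regression: weighted regression of outcome on exposure effects
    with a free intercept.

    Requires records oriented to the exposure-increasing allele
    (``beta_exposure >= 0``) — Egger's intercept is only meaningful under a
    consistent orientation — and at least 3 SNPs with spread in
    ``beta_exposure``. Standard errors are scaled by ``max(1, sigma)`` where
    sigma is the weighted residual standard deviation (multiplicative
    overdispersion with a floor at 1); the intercept's two-sided p-value is
    normal-based. ``extras`` carries ``intercept, intercept_se, intercept_p``.
    """
    rsid, gx, sx, gy, sy = _as_arrays(harmonized)
    if len(gx) < 3:
        raise ValueError(f"MR-Egger requires at least 3 SNPs, got {len(gx)}")
    if np.any(gx < 0):
        raise ValueError("MR-Egger requires orientation to the exposure-"
                         "increasing allele (beta_exposure >= 0)")
    if np.ptp(gx) == 0:
        raise ValueError("MR-Egger slope unidentified: all beta_exposure identical")
    w = sy ** -2.0
    coef, se_raw, sigma = _weighted_lsq(gx, gy, w, intercept=True)
    scale = max(1.0, sigma)
    intercept, slope = float(coef[0]), float(coef[1])
    intercept_se, slope_se = float(se_raw[0] * scale), float(se_raw[1] * scale)
    intercept_p = float(2 * stats.norm.sf(abs(intercept) / intercept_se))
    return MrResult("egger", slope, slope_se, n_snps=len(gx),
                    extras={"intercept": intercept, "intercept_se": intercept_se,
                            "intercept_p": intercept_p,
                            "intercept_ci_low": intercept - Z_95 * intercept_se,
                            "intercept_ci_high": intercept + Z_95 * intercept_se,
                            "overdispersion": scale})


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort values ascending; with normalized weights the standardized
    cumulative weight of the j-th value is ``s_j = (cumsum(w)_j - w_j/2) /
    sum(w)``; the weighted median interpolates linearly between the values
    bracketing ``s = 0.5``. With equal weights and odd n this is the sample
    median.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for (n_rows, n) arrays."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w, axis=1, keepdims=True)
    # vectorized piecewise-linear interpolation of each row's quantile at 0.5
    k = np.sum(s < 0.5, axis=1)  # first index with s >= 0.5
    n = values.shape[1]
    rows = np.arange(values.shape[0])
    out = np.empty(values.shape[0])
    lo_clip = k == 0          # 0.5 below the first point: clamp to smallest value
    hi_clip = k == n          # 0.5 above the last point: clamp to largest value
    mid = ~(lo_clip | hi_clip)
    out[lo_clip] = v[lo_clip, 0]
    out[hi_clip] = v[hi_clip, -1]
    km = k[mid]
    s0, s1 = s[rows[mid], km - 1], s[rows[mid], km]
    v0, v1 = v[rows[mid], km - 1], v[rows[mid], km]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out[mid] = v0 + frac * (v1 - v0)
    return out


def _penalized_weights(b: np.ndarray, w: np.ndarray,
                       penalty: float = 20.0) -> np.ndarray:
    """Down-weight SNPs by their heterogeneity contribution.

    Each SNP's contribution to Cochran's Q about the *unpenalized weighted
    median*, ``Q_j = w_j (b_j - b_wm)^2``, is referred to the chi-square(1)
    upper tail; the weight is multiplied by ``min(1, penalty * q_j)``. SNPs
    consistent with the anchor (large ``q_j``) keep their weight; strongly
    heterogeneous (pleiotropic) SNPs are driven toward zero weight. The
    published penalization anchors at the weighted median rather than the
    IVW estimate: the median anchor stays near the valid SNPs even when a
    large minority of invalid SNPs drags the IVW mean away, which is the
    regime the penalization exists for. Accepts (n,) or (reps, n) arrays.
    """
    b2 = np.atleast_2d(np.asarray(b, float))
    w2 = np.broadcast_to(np.asarray(w, float), b2.shape)
    anchor = _weighted_median_rows(b2, w2)[:, None]
    q_j = stats.chi2.sf(w2 * (b2 - anchor) ** 2, df=1)
    out = w2 * np.minimum(1.0, penalty * q_j)
    return out[0] if np.ndim(b) == 1 else out


def penalized_weighted_median(ratios: pd.DataFrame, n_boot: int = 10_000,
                              seed: int = 31, penalty: float = 20.0) -> MrResult:
    """Penalized weighted median (PWM) causal estimate.

    The point estimate is the interpolated weighted median of the Wald
    ratios after heterogeneity penalization of the inverse-variance weights
    (see :func:`_penalized_weights`); it is consistent when no more than 50%
    of the weight comes from invalid SNPs. The standard error comes from a
    parametric bootstrap: each ratio is resampled from
    ``Normal(ratio_j, se_ratio_j)``, the penalized weighted median is
    recomputed (penalization included), and the SE is the standard deviation
    of the bootstrap estimates. The point estimate is deterministic; only
    the SE/CI depend on ``n_boot`` and ``seed`` (both recorded in ``extras``).
    """
    if len(ratios) < 3:
        raise ValueError(f"penalized weighted median requires >= 3 SNPs, got {len(ratios)}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy",
                      stacklevel=2)
    b = ratios["ratio"].to_numpy(float)
    se = ratios["se_ratio"].to_numpy(float)
    w = ratios["weight"].to_numpy(float)

    est = weighted_median(b, _penalized_weights(b, w, penalty))

    rng = np.random.default_rng(seed)
    b_boot = rng.normal(b, se, size=(n_boot, len(b)))
    w_boot = _penalized_weights(b_boot, np.broadcast_to(w, b_boot.shape), penalty)
    boot = _weighted_median_rows(b_boot, w_boot)
    se_est = float(np.std(boot, ddof=1))
    return MrResult("pwm", est, se_est, n_snps=len(b),
                    extras={"n_boot": n_boot, "seed": seed, "penalty": penalty})


def single_snp_result(rsid: str, ratio: float, se_ratio: float) -> MrResult:
    """Wrap one SNP's Wald ratio as an :class:`MrResult` (forest-plot row)."""
    return MrResult("wald_single", float(ratio), float(se_ratio), n_snps=1,
                    extras={"rsid": rsid})
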