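"""Instrument-validity diagnostics: heterogeneity, leave-one-out, per-SNP table.

Heterogeneity among per-SNP Wald ratios beyond what their standard errors
explain is the signature of horizontal pleiotropy (or other instrument
invalidity); Cochran's Q quantifies it. Leave-one-out re-estimation and the
single-SNP table localize influence to individual variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (MrResult, Z_95, egger, ivw, penalized_weighted_median,
                         wald_ratios)


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test for the per-SNP causal estimates.

    ``q`` is the inverse-variance weighted sum of squared deviations of the
    Wald ratios from the fixed-effect IVW estimate; under instrument
    validity it is chi-square with ``df = n_snps - 1``.
    """

    q: float
    df: int
    p: float
    per_snp_q: pd.Series

    def __str__(self) -> str:
        return f"Cochran's Q = {self.q:.2f} (df = {self.df}, p = {self.p:.2g})"


def cochran_q(ratios: pd.DataFrame) -> HeterogeneityResult:
    """Cochran's Q test across per-SNP Wald ratios.

    Q is always computed about the *fixed-effect* IVW point estimate
    (its null distribution is defined under that fit), regardless of which
    pooled model is used for reporting.
    """
    if len(ratios) < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    b = ratios["ratio"].to_numpy(float)
    w = ratios["weight"].to_numpy(float)
    est = np.sum(w * b) / np.sum(w)
    per = w * (b - est) ** 2
    q = float(per.sum())
    df = len(b) - 1
    return HeterogeneityResult(q=q, df=df, p=float(stats.chi2.sf(q, df)),
                               per_snp_q=pd.Series(per, index=ratios["rsid"].to_numpy()))


_ESTIMATORS = {
    "ivw": lambda df, **kw: ivw(wald_ratios(df), **kw),
    "egger": lambda df, **kw: egger(df),
    "pwm": lambda df, **kw: penalized_weighted_median(wald_ratios(df), **kw),
}

_MIN_SNPS = {"ivw": 1, "egger": 3, "pwm": 3}


@dataclass
class LeaveOneOutTable:
    """Leave-one-out re-estimates: one row per excluded SNP plus the full fit."""

    rows: pd.DataFrame  # excluded_rsid, estimate, se, ci_low, ci_high, or..., n_snps
    full: MrResult
    method: str

    def estimate_range(self) -> tuple[float, float]:
        return (float(self.rows["estimate"].min()), float(self.rows["estimate"].max()))


def leave_one_out(harmonized, method: str = "ivw", **method_kwargs) -> LeaveOneOutTable:
    """Re-run the chosen estimator excluding each retained SNP in turn.

    A pooled estimate driven by a single pleiotropic variant reveals itself
    as one exclusion moving the estimate far more than the others.
    """
    if method not in _ESTIMATORS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_ESTIMATORS)}")
    df = harmonized.retained if hasattr(harmonized, "retained") else harmonized
    n = len(df)
    need = max(3, _MIN_SNPS[method] + 1)
    if n < need:
        raise ValueError(
            f"leave-one-out with method={method} needs >= {need} SNPs so every "
            f"reduced set keeps >= {_MIN_SNPS[method]}; got {n}")
    full = _ESTIMATORS[method](df, **method_kwargs)
    rows = []
    for i in range(n):
        sub = df.drop(df.index[i]).reset_index(drop=True)
        res = _ESTIMATORS[method](sub, **method_kwargs)
        rows.append({"excluded_rsid": df.iloc[i]["rsid"], "estimate": res.estimate,
                     "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "or": res.odds_ratio, "or_low": res.or_low,
                     "or_high": res.or_high, "n_snps": res.n_snps})
    return LeaveOneOutTable(rows=pd.DataFrame(rows), full=full, method=method)


def single_snp_table(harmonized) -> pd.DataFrame:
    """Per-SNP Wald-ratio estimates with 95% CIs, in input order.

    This is the data behind the forest plot: columns ``rsid, estimate, se,
    ci_low, ci_high, or, or_low, or_high, weight``.
    """
    ratios = wald_ratios(harmonized)
    est = ratios["ratio"]
    se = ratios["se_ratio"]
    return pd.DataFrame({
        "rsid": ratios["rsid"], "estimate": est, "se": se,
        "ci_low": est - Z_95 * se, "ci_high": est + Z_95 * se,
        "or": np.exp(est), "or_low": np.exp(est - Z_95 * se),
        "or_high": np.exp(est + Z_95 * se), "weight": ratios["weight"],
    })
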