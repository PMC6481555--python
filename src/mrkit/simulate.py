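"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generating model mirrors the data model the estimators assume. For SNP j
with true per-allele effect ``gamma_j`` on the exposure (SD units):

    gamma_hat_j ~ Normal(gamma_j, se_X_j^2)
    Gamma_hat_j ~ Normal(b * gamma_j + alpha_j, se_Y_j^2)

where ``b`` is the true causal log-OR per SD of exposure and ``alpha_j`` a
per-SNP direct (pleiotropic) effect on the outcome. Standard errors follow
the usual large-sample approximations for a quantitative exposure GWAS and
a case-control outcome GWAS:

    se_X_j = 1 / sqrt(2 * p_j * (1 - p_j) * n_exposure)
    se_Y_j = 1 / sqrt(N * k * (1 - k) * 2 * p_j * (1 - p_j)),  N = cases + controls

with ``p_j`` the effect-allele frequency and ``k`` the case fraction.

Pleiotropy regimes (``alpha_j`` for SNPs marked invalid):

* ``none`` — all alpha_j = 0 (every SNP a valid instrument).
* ``balanced`` — ±|Normal(0, pleio_sd)| with random sign: pleiotropy with
  zero mean, inflating heterogeneity but not biasing IVW.
* ``directional_inside`` — |Normal(0, pleio_sd)|, independent of gamma_j:
  directional pleiotropy satisfying InSIDE, biasing IVW but not MR-Egger.
* ``inside_violating`` — ``c * gamma_j + Normal(0, pleio_sd/2)``: direct
  effects correlated with instrument strength, breaking InSIDE.

Allele coding can be deliberately mangled — palindromic A/T-C/G assignment,
strand-flipped outcome rows, swapped effect/other alleles — to exercise
harmonization end-to-end. Generation is bit-reproducible given the seed;
replicate studies spawn independent per-replicate substreams from the
master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import cochran_q
from .estimators import egger, ivw, penalized_weighted_median, wald_ratios
from .io import CANONICAL_COLUMNS, load_urate_instrument

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]

PLEIOTROPY_REGIMES = ("none", "balanced", "directional_inside", "inside_violating")


@dataclass(frozen=True)
class ScenarioConfig:
    """A synthetic two-sample MR scenario.

    Defaults describe the urate -> Parkinson's disease design the packaged
    instrument comes from: 31 SNPs with the packaged instrument's effect
    sizes and allele frequencies, an exposure GWAS of ~110,000 individuals,
    and an outcome GWAS of 13,708 cases / 95,282 controls, with no
    pleiotropy and a null causal effect.
    """

    n_snps: int = 31
    true_effect: float = 0.0  # log-OR per SD of exposure
    instrument_betas: str | tuple[float, float] = "packaged"
    n_exposure: int = 110_000
    n_cases: int = 13_708
    n_controls: int = 95_282
    pleiotropy: str = "none"
    pleio_sd: float = 0.0
    invalid_fraction: float = 1.0
    inside_constant: float = 0.5  # c in the inside_violating regime
    eaf_range: tuple[float, float] = (0.1, 0.9)
    target_r_squared: float | None = None  # rescale gammas to hit this R^2
    palindromic_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ValueError(f"pleiotropy must be one of {PLEIOTROPY_REGIMES}")
        for name in ("invalid_fraction", "palindromic_fraction",
                     "strand_flip_fraction", "allele_swap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if min(self.n_exposure, self.n_cases, self.n_controls) <= 0:
            raise ValueError("sample sizes must be positive")
        if isinstance(self.instrument_betas, str):
            if self.instrument_betas != "packaged":
                raise ValueError("instrument_betas must be 'packaged' or a (low, high) range")
            if self.n_snps > 31:
                raise ValueError("the packaged instrument has 31 SNPs")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("instrument_betas", "eaf_range"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        return cls(**d)


def _latent_instrument(cfg: ScenarioConfig, rng: np.random.Generator):
    """True per-SNP exposure effects and allele frequencies (oriented gamma > 0)."""
    if cfg.instrument_betas == "packaged":
        tab = load_urate_instrument().head(cfg.n_snps)
        gamma = np.abs(tab["beta"].to_numpy(float))
        eaf = tab["eaf"].to_numpy(float)
        # orientation to the exposure-increasing allele flips the frequency
        eaf = np.where(tab["beta"].to_numpy(float) < 0, 1 - eaf, eaf)
    else:
        lo, hi = cfg.instrument_betas
        gamma = rng.uniform(lo, hi, cfg.n_snps)
        eaf = rng.uniform(*cfg.eaf_range, cfg.n_snps)
    if cfg.target_r_squared is not None:
        r2 = np.sum(2 * eaf * (1 - eaf) * gamma ** 2)
        gamma = gamma * np.sqrt(cfg.target_r_squared / r2)
    return gamma, eaf


def _draw_summary_stats(cfg: ScenarioConfig, seed) -> dict:
    """One replicate of latent truth + estimated summary statistics (arrays).

    Oriented to the exposure-increasing allele of the *estimated* exposure
    effect, as the harmonization step would do with real data.
    """
    rng = np.random.default_rng(seed)
    gamma, eaf = _latent_instrument(cfg, rng)
    n = cfg.n_snps
    se_x = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * cfg.n_exposure)
    n_total = cfg.n_cases + cfg.n_controls
    k = cfg.n_cases / n_total
    se_y = 1.0 / np.sqrt(n_total * k * (1 - k) * 2 * eaf * (1 - eaf))

    n_invalid = int(round(cfg.invalid_fraction * n)) if cfg.pleiotropy != "none" else 0
    invalid = np.zeros(n, bool)
    invalid[rng.choice(n, size=n_invalid, replace=False)] = True
    alpha = np.zeros(n)
    if cfg.pleiotropy == "balanced":
        mag = np.abs(rng.normal(0, cfg.pleio_sd, n))
        alpha = np.where(invalid, mag * rng.choice([-1.0, 1.0], n), 0.0)
    elif cfg.pleiotropy == "directional_inside":
        alpha = np.where(invalid, np.abs(rng.normal(0, cfg.pleio_sd, n)), 0.0)
    elif cfg.pleiotropy == "inside_violating":
        alpha = np.where(
            invalid,
            cfg.inside_constant * gamma + rng.normal(0, cfg.pleio_sd / 2, n), 0.0)

    gamma_hat = rng.normal(gamma, se_x)
    big_gamma_hat = rng.normal(cfg.true_effect * gamma + alpha, se_y)

    flip = gamma_hat < 0  # orient to the (estimated) exposure-increasing allele
    return {
        "gamma": gamma, "eaf": eaf, "alpha": alpha, "invalid": invalid,
        "se_exposure": se_x, "se_outcome": se_y,
        "gamma_hat": np.where(flip, -gamma_hat, gamma_hat),
        "big_gamma_hat": np.where(flip, -big_gamma_hat, big_gamma_hat),
    }


def _harmonized_frame(d: dict, rsids) -> pd.DataFrame:
    return pd.DataFrame({
        "rsid": rsids,
        "beta_exposure": d["gamma_hat"], "se_exposure": d["se_exposure"],
        "beta_outcome": d["big_gamma_hat"], "se_outcome": d["se_outcome"],
    })


def generate(cfg: ScenarioConfig):
    """Generate one synthetic dataset as (exposure table, outcome table, truth).

    Both tables use the canonical association-table columns of
    :mod:`mrkit.io`. The exposure table is written in its natural coding
    (effect allele = exposure-increasing allele when betas come from a
    distribution; the packaged coding when ``instrument_betas='packaged'``).
    The outcome table encodes the same physical associations but with the
    configured fractions of rows strand-flipped, allele-swapped, and (for
    distribution betas) palindromic allele pairs assigned, so the
    harmonization step has real work to do. The truth record holds every
    latent quantity.
    """
    rng_alleles = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    d = _draw_summary_stats(cfg, np.random.SeedSequence((cfg.seed, 0)))
    n = cfg.n_snps

    if cfg.instrument_betas == "packaged":
        tab = load_urate_instrument().head(n)
        rsids = tab["rsid"].tolist()
        ea = tab["effect_allele"].tolist()
        oa = tab["other_allele"].tolist()
        beta_x = tab["beta"].to_numpy(float)
        eaf_x = tab["eaf"].to_numpy(float)
        # the published coding may point at the exposure-decreasing allele;
        # express the drawn (oriented) estimates back in that coding
        sign = np.where(beta_x < 0, -1.0, 1.0)
        gamma_hat = sign * d["gamma_hat"]
        big_gamma = sign * d["big_gamma_hat"]
    else:
        rsids = [f"rs{900000 + j}" for j in range(n)]
        n_pal = int(round(cfg.palindromic_fraction * n))
        is_pal = np.zeros(n, bool)
        is_pal[rng_alleles.choice(n, size=n_pal, replace=False)] = True
        ea, oa = [], []
        for j in range(n):
            pool = _PALINDROMIC_PAIRS if is_pal[j] else _NON_PALINDROMIC_PAIRS
            a1, a2 = pool[rng_alleles.integers(len(pool))]
            ea.append(a1)
            oa.append(a2)
        eaf_x = d["eaf"]
        gamma_hat = d["gamma_hat"]
        big_gamma = d["big_gamma_hat"]

    exposure = pd.DataFrame({
        "rsid": rsids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf_x, "beta": gamma_hat, "se": d["se_exposure"],
    })[CANONICAL_COLUMNS]

    # outcome rows start in the exposure coding, then get mangled
    out_ea, out_oa = list(ea), list(oa)
    out_eaf = np.array(eaf_x, float)
    out_beta = np.array(big_gamma, float)
    flip_mask = rng_alleles.random(n) < cfg.strand_flip_fraction
    swap_mask = rng_alleles.random(n) < cfg.allele_swap_fraction
    for j in range(n):
        if swap_mask[j]:
            out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
            out_beta[j] = -out_beta[j]
            out_eaf[j] = 1 - out_eaf[j]
        if flip_mask[j]:
            out_ea[j] = _COMPLEMENT[out_ea[j]]
            out_oa[j] = _COMPLEMENT[out_oa[j]]
    outcome = pd.DataFrame({
        "rsid": rsids, "effect_allele": out_ea, "other_allele": out_oa,
        "eaf": out_eaf, "beta": out_beta, "se": d["se_outcome"],
    })[CANONICAL_COLUMNS]

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "true_effect": cfg.true_effect,
        "rsid": rsids,
        "gamma": d["gamma"].tolist(),
        "alpha": d["alpha"].tolist(),
        "invalid": d["invalid"].astype(bool).tolist(),
        "strand_flipped": flip_mask.tolist(),
        "allele_swapped": swap_mask.tolist(),
    }
    return exposure, outcome, truth


def save_scenario_data(cfg: ScenarioConfig, outdir: str | Path,
                       decoy_rows: int = 0) -> dict[str, Path]:
    """Write a scenario to disk in the exact dialect :mod:`mrkit.io` reads.

    ``decoy_rows`` appends that many non-instrument SNP rows to the outcome
    file (random alleles and effects near zero), emulating a genome-wide
    summary-statistics file from which the instrument must be filtered.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = generate(cfg)
    if decoy_rows:
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
        pairs = [_NON_PALINDROMIC_PAIRS[i]
                 for i in rng.integers(4, size=decoy_rows)]
        decoys = pd.DataFrame({
            "rsid": [f"rs{10_000_000 + i}" for i in range(decoy_rows)],
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": np.round(rng.uniform(0.01, 0.99, decoy_rows), 4),
            "beta": np.round(rng.normal(0, 0.02, decoy_rows), 6),
            "se": np.round(rng.uniform(0.005, 0.05, decoy_rows), 6),
        })
        outcome = pd.concat([outcome, decoys], ignore_index=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "truth": outdir / "truth.json",
        "scenario": outdir / "scenario.yaml",
    }
    exposure.to_csv(paths["exposure"], sep="\t", index=False, float_format="%.10g")
    outcome.to_csv(paths["outcome"], sep="\t", index=False, float_format="%.10g")
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    cfg.to_yaml(paths["scenario"])
    return paths


def _child_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-replicate integer seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1, np.uint32)[0] % 2 ** 31) for c in children]


def replicate_study(cfg: ScenarioConfig, n_reps: int,
                    estimators: tuple[str, ...] = ("ivw", "egger", "pwm"),
                    pwm_n_boot: int = 200,
                    ivw_model: str = "fixed") -> pd.DataFrame:
    """Monte-Carlo study of estimator performance under one scenario.

    Each replicate draws fresh summary statistics from the scenario's
    generating model (clean coding — harmonization is exercised elsewhere)
    and applies the requested estimators. Returns one row per estimator:

    bias, mc_se_bias        mean(estimate) - true_effect and its Monte-Carlo SE
    empirical_se, mean_se   SD of estimates across replicates; mean model SE
    coverage, coverage_mc_se    proportion of 95% CIs containing the truth
    rejection_rate, rejection_mc_se  proportion rejecting H0: effect = 0
    mean_q, mc_se_q         Cochran's Q across replicates (same in every row;
                            under a valid-instrument null its mean is n_snps - 1)
    """
    if n_reps < 100:
        raise ValueError("replicate_study needs n_reps >= 100 for usable Monte-Carlo SEs")
    need3 = {"egger", "pwm"} & set(estimators)
    if need3 and cfg.n_snps < 3:
        raise ValueError(f"{sorted(need3)} require n_snps >= 3, got {cfg.n_snps}")
    unknown = set(estimators) - {"ivw", "egger", "pwm"}
    if unknown:
        raise ValueError(f"unknown estimator(s) {sorted(unknown)}")

    rsids = [f"snp{j}" for j in range(cfg.n_snps)]
    seeds = _child_seeds(cfg.seed, n_reps)
    results: dict[str, list] = {m: [] for m in estimators}
    q_values = []
    for rep_seed in seeds:
        d = _draw_summary_stats(cfg, rep_seed)
        frame = _harmonized_frame(d, rsids)
        ratios = wald_ratios(frame)
        if cfg.n_snps >= 2:
            q_values.append(cochran_q(ratios).q)
        for m in estimators:
            if m == "ivw":
                res = ivw(ratios, model=ivw_model)
            elif m == "egger":
                res = egger(frame)
            else:
                res = penalized_weighted_median(ratios, n_boot=pwm_n_boot,
                                                seed=rep_seed)
            results[m].append((res.estimate, res.se, res.ci_low, res.ci_high))

    rows = []
    b0 = cfg.true_effect
    for m in estimators:
        arr = np.array(results[m])
        est, se, lo, hi = arr.T
        covered = (lo <= b0) & (b0 <= hi)
        reject = np.abs(est / se) > 1.959964
        rows.append({
            "estimator": m, "n_reps": n_reps, "true_effect": b0,
            "mean_estimate": est.mean(), "bias": est.mean() - b0,
            "mc_se_bias": est.std(ddof=1) / np.sqrt(n_reps),
            "empirical_se": est.std(ddof=1), "mean_se": se.mean(),
            "coverage": covered.mean(),
            "coverage_mc_se": np.sqrt(covered.mean() * (1 - covered.mean()) / n_reps),
            "rejection_rate": reject.mean(),
            "rejection_mc_se": np.sqrt(reject.mean() * (1 - reject.mean()) / n_reps),
            "mean_q": np.mean(q_values) if q_values else np.nan,
            "mc_se_q": (np.std(q_values, ddof=1) / np.sqrt(n_reps)
                        if q_values else np.nan),
        })
    return pd.DataFrame(rows)
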