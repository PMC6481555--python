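"""One-call analysis pipeline: harmonize, estimate, diagnose, report.

``run_full_analysis`` reproduces the standard layout of a summary-data MR
analysis: the three pooled estimates (IVW, MR-Egger, penalized weighted
median), Cochran's Q heterogeneity, the MR-Egger intercept test, the
per-SNP forest table, leave-one-out re-estimation, and — when a power
specification is supplied — the analytic power of the design. Machine
output (TSV/JSON) keeps full precision and is byte-reproducible for a given
configuration; the human-readable summary rounds ORs and CI bounds to two
decimals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import cochran_q, leave_one_out, single_snp_table
from .estimators import egger, ivw, penalized_weighted_median, wald_ratios
from .harmonize import harmonize_files
from .power import PowerSpec, minimum_detectable_or, mr_power

logger = logging.getLogger("mrkit")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    exposure_path: str
    outcome_path: str
    out_dir: str
    exposure_columns: dict | None = None
    outcome_columns: dict | None = None
    palindromic_window: float = 0.08
    ivw_model: str = "fixed"
    pwm_n_boot: int = 10_000
    pwm_seed: int = 31
    power: dict | None = None  # PowerSpec fields, e.g. from the design
    make_figures: bool = True
    leave_one_out_method: str = "ivw"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)


def _round2(x: float) -> str:
    return f"{x:.2f}"


def _summary_text(bundle: dict) -> str:
    lines = ["Two-sample Mendelian randomization analysis", "=" * 44, ""]
    h = bundle["harmonization"]
    lines.append(f"SNPs shared between exposure and outcome: {h['n_shared']}")
    lines.append(f"SNPs retained after harmonization:        {h['n_retained']}")
    for action, cnt in h["action_counts"].items():
        lines.append(f"  {action}: {cnt}")
    lines.append("")
    lines.append("Pooled causal estimates (OR per 1-SD increase in exposure):")
    for r in bundle["results"]:
        lines.append(f"  {r['method'].upper():5s} OR {_round2(r['or'])} "
                     f"(95% CI {_round2(r['or_low'])}-{_round2(r['or_high'])}); "
                     f"p = {r['p_value']:.2f}")
        if r["method"] == "egger":
            lines.append(f"        intercept {r['intercept']:.2f} "
                         f"(95% CI {r['intercept_ci_low']:.2f} to "
                         f"{r['intercept_ci_high']:.2f}; p = {r['intercept_p']:.2f})")
    het = bundle["heterogeneity"]
    lines.append("")
    lines.append(f"Heterogeneity: Cochran's Q = {het['q']:.2f} "
                 f"(df = {het['df']}, p = {het['p']:.2f})")
    loo = bundle["leave_one_out_range"]
    lines.append(f"Leave-one-out ({bundle['leave_one_out_method']}): OR range "
                 f"{_round2(np.exp(loo[0]))}-{_round2(np.exp(loo[1]))}")
    if "power" in bundle:
        p = bundle["power"]
        lines.append("")
        lines.append(f"Power at OR {p['odds_ratio_per_sd']:.2f} per SD "
                     f"(R^2 = {p['r_squared']:.2f}, alpha = {p['alpha']:.2f}): "
                     f"{p['power']:.2f}")
        lines.append(f"Minimum detectable OR at 80% power: "
                     f"<{p['mdor_protective']:.2f} or >{p['mdor_harmful']:.2f}")
    lines.append("")
    return "\n".join(lines)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle to ``out_dir``.

    Returns the bundle as a dict (the same content as results.json).
    Writes: harmonization_audit.tsv, harmonized.tsv, mr_results.tsv,
    single_snp.tsv, leave_one_out.tsv, heterogeneity per-SNP TSV,
    results.json, summary.txt, run.log, and figures (SVG+PNG) unless
    disabled.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inst = harmonize_files(config.exposure_path, config.outcome_path,
                           config.exposure_columns, config.outcome_columns,
                           config.palindromic_window)
    retained = inst.retained
    ratios = wald_ratios(inst)

    results = [ivw(ratios, model=config.ivw_model)]
    if len(retained) >= 3:
        results.append(egger(inst))
        results.append(penalized_weighted_median(
            ratios, n_boot=config.pwm_n_boot, seed=config.pwm_seed))
    else:
        logger.warning("only %d SNPs retained; Egger and PWM need >= 3, skipped",
                       len(retained))
    het = cochran_q(ratios) if len(ratios) >= 2 else None
    single = single_snp_table(inst)
    loo = leave_one_out(inst, method=config.leave_one_out_method)

    bundle: dict = {
        "mrkit_version": __version__,
        "config": dataclasses.asdict(config),
        "harmonization": {
            "n_shared": len(inst.records),
            "n_retained": inst.n_retained,
            "action_counts": inst.action_counts(),
            "provenance": inst.provenance,
        },
        "results": [r.to_dict() for r in results],
        "heterogeneity": (None if het is None else
                          {"q": het.q, "df": het.df, "p": het.p}),
        "leave_one_out_method": loo.method,
        "leave_one_out_range": list(loo.estimate_range()),
    }
    if config.power:
        spec = PowerSpec(**config.power)
        prot, harm = minimum_detectable_or(spec, target_power=0.8)
        bundle["power"] = {**dataclasses.asdict(spec), "power": mr_power(spec),
                           "mdor_protective": prot, "mdor_harmful": harm,
                           "mdor_target_power": 0.8}

    fmt = "%.12g"
    inst.audit.to_csv(out / "harmonization_audit.tsv", sep="\t", index=False)
    inst.records.to_csv(out / "harmonized.tsv", sep="\t", index=False,
                        float_format=fmt)
    pd.DataFrame([r.to_dict() for r in results]).to_csv(
        out / "mr_results.tsv", sep="\t", index=False, float_format=fmt)
    single.to_csv(out / "single_snp.tsv", sep="\t", index=False, float_format=fmt)
    loo.rows.to_csv(out / "leave_one_out.tsv", sep="\t", index=False,
                    float_format=fmt)
    if het is not None:
        het.per_snp_q.rename("q_contribution").to_csv(
            out / "heterogeneity_per_snp.tsv", sep="\t", index_label="rsid",
            float_format=fmt)
    (out / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    (out / "summary.txt").write_text(_summary_text(bundle))
    # timestamped provenance goes only in the log so data outputs stay
    # byte-identical across reruns of the same configuration
    (out / "run.log").write_text(
        f"mrkit {__version__} | python {platform.python_version()} | "
        f"numpy {np.__version__} | {datetime.now(timezone.utc).isoformat()}\n"
        f"exposure: {inst.provenance.get('exposure_path')} "
        f"sha256={inst.provenance.get('exposure_sha256')}\n"
        f"outcome: {inst.provenance.get('outcome_path')} "
        f"sha256={inst.provenance.get('outcome_sha256')}\n"
        f"pwm seed: {config.pwm_seed}, n_boot: {config.pwm_n_boot}\n")

    if config.make_figures:
        from .plots import forest_plot, save_figure, scatter_plot
        save_figure(scatter_plot(inst, results), out / "scatter")
        save_figure(forest_plot(single, pooled=results), out / "forest_single_snp")
        save_figure(forest_plot(loo.rows, label_col="excluded_rsid",
                                pooled=[loo.full]), out / "forest_leave_one_out")

    logger.info("report bundle written to %s", out)
    return bundle
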