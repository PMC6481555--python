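"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR pairs, for each SNP, the effect on the exposure from one GWAS
with the effect on the outcome from another. The two studies may report the
same variant with the alleles swapped (effect/other interchanged), on the
opposite strand (both alleles complemented), or both. Harmonization
reconciles the outcome row to the exposure row's allele coding and then
orients every pair to the exposure-*increasing* allele, so that
``beta_exposure >= 0`` for every retained record.

Palindromic SNPs (A/T or C/G) are their own strand complement, so allele
labels cannot distinguish strands; they are reconciled by comparing
effect-allele frequencies and dropped when either study's minor-allele
frequency is too close to 0.5 for the comparison to be informative.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization actions, in order of increasing intervention
ACTIONS = ("unchanged", "allele_swap", "strand_flip", "strand_flip_and_swap",
           "palindromic_kept", "dropped")

RECORD_COLUMNS = ["rsid", "effect_allele", "other_allele",
                  "beta_exposure", "se_exposure", "eaf_exposure",
                  "beta_outcome", "se_outcome", "eaf_outcome",
                  "action", "note"]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variants (alleles are mutual complements)."""
    return _COMPLEMENT[a1] == a2


@dataclass
class HarmonizedInstrument:
    """Paired exposure/outcome effects aligned to the exposure-increasing allele.

    ``records`` keeps every shared SNP, including dropped ones (with the
    reason in ``note``); ``retained`` is the analysis-ready subset.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        return self.records[self.records["action"] != "dropped"].reset_index(drop=True)

    @property
    def n_retained(self) -> int:
        return int((self.records["action"] != "dropped").sum())

    @property
    def audit(self) -> pd.DataFrame:
        """Per-SNP action table, suitable for writing as a TSV audit trail."""
        return self.records[["rsid", "action", "note"]].copy()

    def action_counts(self) -> dict[str, int]:
        counts = self.records["action"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ACTIONS if counts.get(a, 0)}


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _reconcile_one(exp: pd.Series, out: pd.Series, window: float):
    """Return (beta_outcome, eaf_outcome, action, note) for one shared SNP.

    The outcome row is re-expressed so that its effect allele is the
    exposure row's effect allele; orientation to the exposure-increasing
    allele happens afterwards, in :func:`harmonize`.
    """
    ea_x, oa_x = exp["effect_allele"], exp["other_allele"]
    ea_y, oa_y = out["effect_allele"], out["other_allele"]
    beta_y, eaf_y = out["beta"], out["eaf"]

    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return np.nan, np.nan, "dropped", (
                f"palindromic exposure alleles {ea_x}/{oa_x} but outcome reports "
                f"{ea_y}/{oa_y}")
        if ea_y == oa_x:  # labels swapped; re-express before the frequency check
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        eaf_x = exp["eaf"]
        if pd.isna(eaf_x) or pd.isna(eaf_y):
            return np.nan, np.nan, "dropped", (
                "palindromic SNP without allele frequency in both datasets")
        if min(eaf_x, 1 - eaf_x) >= 0.5 - window or min(eaf_y, 1 - eaf_y) >= 0.5 - window:
            return np.nan, np.nan, "dropped", (
                f"palindromic with minor-allele frequency within {window:g} of 0.5 "
                f"(exposure EAF {eaf_x:g}, outcome EAF {eaf_y:g}); strand ambiguous")
        # strands agree if the effect-allele frequencies agree; if the outcome
        # frequency matches 1-eaf_x better, the outcome is on the other strand,
        # which for a palindromic SNP is the same as an allele swap
        if abs(eaf_x - eaf_y) <= abs(eaf_x - (1 - eaf_y)):
            note = f"palindromic, frequencies concordant (EAF {eaf_x:g} vs {eaf_y:g})"
        else:
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            note = (f"palindromic, opposite-strand coding inferred from frequencies "
                    f"(EAF {eaf_x:g} vs oriented {eaf_y:g})")
        return beta_y, eaf_y, "palindromic_kept", note

    if {ea_y, oa_y} == {ea_x, oa_x}:
        if ea_y == ea_x:
            return beta_y, eaf_y, "unchanged", ""
        return -beta_y, 1.0 - eaf_y if pd.notna(eaf_y) else np.nan, "allele_swap", \
            "outcome effect/other alleles swapped"

    ea_f, oa_f = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if {ea_f, oa_f} == {ea_x, oa_x}:
        if ea_f == ea_x:
            return beta_y, eaf_y, "strand_flip", "outcome reported on opposite strand"
        return -beta_y, 1.0 - eaf_y if pd.notna(eaf_y) else np.nan, \
            "strand_flip_and_swap", "opposite strand and swapped alleles"

    return np.nan, np.nan, "dropped", (
        f"alleles irreconcilable: exposure {ea_x}/{oa_x} vs outcome {ea_y}/{oa_y}")


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_freq_window: float = 0.08,
              provenance: dict | None = None) -> HarmonizedInstrument:
    """Pair exposure and outcome associations on rsID and align alleles.

    Parameters
    ----------
    exposure, outcome
        Association tables with the canonical columns of :mod:`mrkit.io`.
    palindromic_freq_window
        Half-width of the ambiguity window around 0.5: a palindromic SNP is
        dropped when either study's minor-allele frequency is within this
        distance of 0.5, because the frequency comparison that resolves its
        strand is then uninformative. Default 0.08.

    Returns
    -------
    HarmonizedInstrument
        One record per shared rsID, in exposure order, each carrying the
        harmonization ``action`` taken and, for retained records,
        ``beta_exposure >= 0`` (oriented to the exposure-increasing allele).
    """
    if not 0 <= palindromic_freq_window <= 0.5:
        raise ValueError("palindromic_freq_window must be in [0, 0.5]")
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("exposure and outcome tables must both be non-empty")
    out_by_rsid = {r["rsid"].lower(): r for _, r in outcome.iterrows()}
    shared = [(_, row) for _, row in exposure.iterrows()
              if row["rsid"].lower() in out_by_rsid]
    if not shared:
        raise ValueError("no shared rsIDs between exposure and outcome tables")

    rows = []
    for _, exp in shared:
        out = out_by_rsid[exp["rsid"].lower()]
        beta_y, eaf_y, action, note = _reconcile_one(exp, out, palindromic_freq_window)
        beta_x, eaf_x = exp["beta"], exp["eaf"]
        ea, oa = exp["effect_allele"], exp["other_allele"]
        if action != "dropped" and beta_x < 0:
            # orient to the exposure-increasing allele (ties at 0 keep coding)
            beta_x, beta_y = -beta_x, -beta_y
            ea, oa = oa, ea
            eaf_x = 1.0 - eaf_x if pd.notna(eaf_x) else np.nan
            eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else np.nan
            note = (note + "; " if note else "") + "oriented to exposure-increasing allele"
        rows.append({
            "rsid": exp["rsid"], "effect_allele": ea, "other_allele": oa,
            "beta_exposure": beta_x, "se_exposure": exp["se"], "eaf_exposure": eaf_x,
            "beta_outcome": beta_y, "se_outcome": out["se"], "eaf_outcome": eaf_y,
            "action": action, "note": note,
        })
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)

    inst = HarmonizedInstrument(records=records, provenance=provenance or {})
    counts = inst.action_counts()
    logger.info("harmonized %d shared SNPs: %s", len(records),
                ", ".join(f"{k}={v}" for k, v in counts.items()))
    if inst.n_retained == 0:
        # dropping is never a hard error here; estimation will refuse an
        # empty instrument with its own message
        logger.warning("harmonization dropped every shared SNP; "
                       "downstream estimation will fail")
    return inst


def harmonize_files(exposure_path: str | Path, outcome_path: str | Path,
                    exposure_columns=None, outcome_columns=None,
                    palindromic_freq_window: float = 0.08) -> HarmonizedInstrument:
    """File-level convenience wrapper: read both tables, filter, harmonize.

    Records source paths and SHA-256 checksums in ``provenance``.
    """
    from .io import read_instrument, read_outcome_stats

    exposure = read_instrument(exposure_path, exposure_columns)
    if len(exposure) == 0:
        raise ValueError(f"instrument file {exposure_path} has no data rows")
    outcome, missing = read_outcome_stats(outcome_path, exposure["rsid"],
                                          outcome_columns)
    prov = {
        "exposure_path": str(exposure_path),
        "exposure_sha256": _file_sha256(exposure_path),
        "outcome_path": str(outcome_path),
        "outcome_sha256": _file_sha256(outcome_path),
        "missing_from_outcome": missing,
    }
    return harmonize(exposure, outcome, palindromic_freq_window, provenance=prov)
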