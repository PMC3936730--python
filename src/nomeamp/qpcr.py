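"""Quantification of ChIP, FAIRE and expression qPCR from Ct tables.

ChIP and FAIRE signals are expressed as percent of input chromatin via
the dilution-adjusted ΔCt,

    % input = 100 · input_fraction · E^(Ct_input − Ct_assay),

with amplification efficiency E = 2 by default.  Expression uses the
ΔΔCt method against a reference gene (e.g. GAPDH).  Replicate PCRs are
summarised as mean and range (min/max), and ranges propagate through
ratio computations by min/max arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Quantified",
    "percent_input",
    "faire_signal",
    "fold_enrichment",
    "induction_fold",
    "relative_expression",
    "quantify_chip_faire",
    "quantify_expression",
    "locus_scan_profile",
]

REQUIRED_COLUMNS = ["region", "position_bp", "assay", "condition",
                    "replicate", "ct", "input_fraction"]


@dataclass(frozen=True)
class Quantified:
    """A replicate-summarised measurement: mean with min/max range."""

    value: float
    low: float
    high: float

    @classmethod
    def from_values(cls, values) -> "Quantified":
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0 or np.isnan(arr).any():
            raise ValueError("cannot summarise empty or NaN measurements")
        return cls(float(arr.mean()), float(arr.min()), float(arr.max()))

    def ratio(self, denominator: "Quantified") -> "Quantified":
        if denominator.low <= 0:
            raise ZeroDivisionError(
                "denominator range includes zero or negative values")
        return Quantified(self.value / denominator.value,
                          self.low / denominator.high,
                          self.high / denominator.low)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float,
                  efficiency: float = 2.0) -> float:
    """Percent of input chromatin recovered by the IP.

    % = 100 · input_fraction · efficiency^(ct_input − ct_ip).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    return 100.0 * input_fraction * efficiency ** (ct_input - ct_ip)


def faire_signal(ct_faire: float, ct_input: float, input_fraction: float,
                 efficiency: float = 2.0) -> float:
    """FAIRE open-chromatin signal as percent of input DNA (the
    aqueous-phase DNA is the numerator)."""
    return percent_input(ct_faire, ct_input, input_fraction,
                         efficiency=efficiency)


def _as_quantified(x) -> Quantified:
    if isinstance(x, Quantified):
        return x
    return Quantified(float(x), float(x), float(x))


def fold_enrichment(target, control) -> Quantified:
    """Ratio of percent-input at a target region over a control region
    (e.g. enhancer vs. a distal low-CpG region)."""
    target, control = _as_quantified(target), _as_quantified(control)
    if control.value == 0:
        raise ZeroDivisionError("control percent-input is zero")
    return target.ratio(control)


def induction_fold(treated, vehicle) -> Quantified:
    """Ratio of percent-input after treatment over vehicle."""
    treated, vehicle = _as_quantified(treated), _as_quantified(vehicle)
    if vehicle.value == 0:
        raise ZeroDivisionError("vehicle percent-input is zero")
    return treated.ratio(vehicle)


def relative_expression(ct_target_a: float, ct_ref_a: float,
                        ct_target_b: float, ct_ref_b: float,
                        efficiency: float = 2.0) -> float:
    """ΔΔCt relative expression of condition A over condition B,
    normalised to a reference gene:

    fold = E^(−[(Ct_target − Ct_ref)_A − (Ct_target − Ct_ref)_B]).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    for name, value in (("ct_ref_a", ct_ref_a), ("ct_ref_b", ct_ref_b)):
        if value is None or np.isnan(value):
            raise ValueError(f"missing reference measurement {name}")
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return float(efficiency ** (-ddct))


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"Ct table is missing required column(s): {', '.join(missing)}")


def quantify_chip_faire(table: pd.DataFrame, assay: str = "CHIP",
                        efficiency: float = 2.0) -> pd.DataFrame:
    """Percent-of-input per (region, condition) with replicate ranges.

    Replicate k of the assay is paired with replicate k of the INPUT
    rows for the same region and condition; per-replicate percent-input
    values are summarised as mean and min/max range.
    """
    _validate_table(table)
    assay = assay.upper()
    out = []
    groups = table[table["assay"].str.upper() == assay] \
        .groupby(["region", "condition"], sort=True)
    for (region, condition), sub in groups:
        inputs = table[(table["assay"].str.upper() == "INPUT")
                       & (table["region"] == region)
                       & (table["condition"] == condition)]
        if inputs.empty:
            raise ValueError(
                f"no INPUT rows for region {region!r}, "
                f"condition {condition!r}")
        input_ct = inputs.set_index("replicate")["ct"]
        values = []
        for _, row in sub.iterrows():
            rep = row["replicate"]
            if rep not in input_ct.index:
                raise ValueError(
                    f"no INPUT replicate {rep} for region {region!r}, "
                    f"condition {condition!r}")
            values.append(percent_input(
                row["ct"], float(input_ct.loc[rep]),
                float(row["input_fraction"]), efficiency=efficiency))
        q = Quantified.from_values(values)
        out.append({
            "region": region,
            "position_bp": sub["position_bp"].iloc[0],
            "condition": condition,
            "percent_input": q.value,
            "percent_input_low": q.low,
            "percent_input_high": q.high,
            "n_replicates": len(values),
        })
    return pd.DataFrame(out)


def quantify_expression(table: pd.DataFrame, reference_gene: str,
                        baseline_condition: str,
                        efficiency: float = 2.0) -> pd.DataFrame:
    """ΔΔCt expression folds relative to ``baseline_condition``.

    RT rows are grouped by (region=gene, condition); replicate means of
    Ct are used; every gene/condition must have a matching
    reference-gene measurement or the record is rejected.
    """
    _validate_table(table)
    rt = table[table["assay"].str.upper() == "RT"]
    if rt.empty:
        raise ValueError("Ct table contains no RT rows")
    mean_ct = rt.groupby(["region", "condition"])["ct"].mean()

    def ref_ct(condition: str) -> float:
        key = (reference_gene, condition)
        if key not in mean_ct.index:
            raise ValueError(
                f"missing reference gene {reference_gene!r} measurement "
                f"for condition {condition!r}")
        return float(mean_ct.loc[key])

    rows = []
    for (gene, condition) in mean_ct.index:
        if gene == reference_gene:
            continue
        if (gene, baseline_condition) not in mean_ct.index:
            raise ValueError(
                f"missing baseline condition {baseline_condition!r} "
                f"for gene {gene!r}")
        fold = relative_expression(
            float(mean_ct.loc[(gene, condition)]), ref_ct(condition),
            float(mean_ct.loc[(gene, baseline_condition)]),
            ref_ct(baseline_condition), efficiency=efficiency)
        rows.append({"gene": gene, "condition": condition,
                     "fold_vs_baseline": fold})
    return pd.DataFrame(rows)


def locus_scan_profile(quantified: pd.DataFrame,
                       condition: str | None = None) -> pd.DataFrame:
    """Ordered locus-scanning profile from quantified percent-input
    records (one primer set per position, e.g. 1-kb spacing).

    Positions are sorted strictly increasing; a position mapped to two
    different region names is rejected.
    """
    frame = quantified
    if condition is not None:
        frame = frame[frame["condition"] == condition]
    frame = frame.dropna(subset=["position_bp"])
    if len(frame) and \
            frame.groupby("position_bp")["region"].nunique().max() > 1:
        raise ValueError("conflicting region names at the same position")
    if frame["position_bp"].nunique() < 2:
        raise ValueError("locus scan needs at least two primer positions")
    prof = frame.sort_values("position_bp").reset_index(drop=True)
    columns = ["position_bp", "region", "condition", "percent_input",
               "percent_input_low", "percent_input_high"]
    columns = [c for c in columns if c in prof.columns]
    return prof[columns]
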