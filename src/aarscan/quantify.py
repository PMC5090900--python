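"""Activity, solubility, expression and substrate-specificity quantification.

Turns two replicate-level measurement tables into per-variant profiles:

* a hydrocarbon table (GC-MS amounts of pentadecane C15:0, heptadecene
  C17:1 and heptadecane C17:0 per variant and replicate), and
* a western-blot densitometry table (soluble and insoluble band volumes
  per variant and replicate, with per-band detection flags).

Derived quantities, all relative to a designated reference variant:

relative activity
    (mean total hydrocarbons / mean soluble band volume) for the variant
    divided by the same index for the reference — the aldehyde-producing
    activity index.
solubility (%)
    100 x soluble / (soluble + insoluble) band volume.
relative expression
    mean (soluble + insoluble) volume over the reference's.
specificity fractions
    each hydrocarbon's share of the total amount; their ratios to the
    reference fractions give relative specificity.

Replicates are aggregated as ratios of means (normalising pooled
quantities), with standard errors combined by first-order relative-error
propagation.  A band flagged undetected is treated as missing; a variant
whose soluble band is never detected gets activity and solubility marked
"not determined" rather than zero or infinite.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HYDRO_REQUIRED = ("variant_id", "replicate", "amount_c15", "amount_c17_1", "amount_c17_0")
BLOT_REQUIRED = (
    "variant_id",
    "replicate",
    "soluble_volume",
    "insoluble_volume",
    "soluble_detected",
    "insoluble_detected",
)
ADO_COLUMN = "ado_soluble_volume"
ADO_CV_WARN = 0.25


class ConfigurationError(ValueError):
    """Missing reference variant or malformed pipeline configuration."""


class NotDetermined(ValueError):
    """Raised when a non-detected band makes a quantity undefined."""


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(("true", "1", "yes", "t"))


def read_hydrocarbon_table(path: str | Path) -> pd.DataFrame:
    """Read the hydrocarbon TSV; extra ``amount_*`` analyte columns pass through."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HYDRO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing hydrocarbon columns {missing}")
    amount_cols = [c for c in df.columns if c.startswith("amount_")]
    if (df[amount_cols] < 0).any().any():
        raise ValueError(f"{path}: negative hydrocarbon amounts")
    if df.duplicated(["variant_id", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (variant_id, replicate) rows")
    return df


def read_blot_table(path: str | Path) -> pd.DataFrame:
    """Read the densitometry TSV with detection flags."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing blot columns {missing}")
    for col in ("soluble_detected", "insoluble_detected"):
        df[col] = _as_bool(df[col])
    for col in ("soluble_volume", "insoluble_volume"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative band volumes")
    if df.duplicated(["variant_id", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (variant_id, replicate) rows")
    return df


def amount_columns(hydro: pd.DataFrame) -> list[str]:
    return [c for c in hydro.columns if c.startswith("amount_")]


def specificity_fractions(amounts) -> np.ndarray:
    """Each analyte's fraction of the total; requires a positive total."""
    amounts = np.asarray(amounts, dtype=float)
    total = amounts.sum()
    if total <= 0:
        raise ValueError("undefined fractions: all amounts are zero")
    return amounts / total


def solubility(soluble: float, insoluble: float) -> float:
    """Percent of the expressed protein in the soluble fraction."""
    if math.isnan(soluble):
        raise NotDetermined("soluble band not detected")
    if math.isnan(insoluble):
        raise NotDetermined("insoluble band not detected")
    total = soluble + insoluble
    if total <= 0:
        raise ValueError("undefined solubility: zero total band volume")
    return 100.0 * soluble / total


def relative_specificity(
    variant_fractions, reference_fractions
) -> np.ndarray:
    """Elementwise fraction ratios; NaN where the reference fraction is 0."""
    v = np.asarray(variant_fractions, dtype=float)
    r = np.asarray(reference_fractions, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, v / np.where(r > 0, r, 1.0), np.nan)
    return out


@dataclass
class MeasurementSet:
    """Replicate-level measurements for one variant."""

    variant_id: str
    hydro: pd.DataFrame
    blot: pd.DataFrame

    def replicate_totals(self) -> np.ndarray:
        cols = amount_columns(self.hydro)
        return self.hydro[cols].sum(axis=1).to_numpy(dtype=float)

    def soluble_volumes(self) -> np.ndarray:
        """Detected soluble band volumes (undetected replicates dropped)."""
        ok = self.blot["soluble_detected"]
        return self.blot.loc[ok, "soluble_volume"].to_numpy(dtype=float)

    def total_volumes(self) -> np.ndarray:
        """Soluble+insoluble per replicate where both bands were detected."""
        ok = self.blot["soluble_detected"] & self.blot["insoluble_detected"]
        sub = self.blot.loc[ok]
        return (sub["soluble_volume"] + sub["insoluble_volume"]).to_numpy(dtype=float)


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        raise NotDetermined("no usable replicates")
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, se


def _ratio_se(ratio: float, parts: list[tuple[float, float]]) -> float:
    """First-order SE of a product/quotient from (mean, se) components."""
    rel2 = 0.0
    for mean, se in parts:
        if mean == 0:
            return float("nan")
        rel2 += (se / mean) ** 2
    return abs(ratio) * math.sqrt(rel2)


def relative_activity(
    variant: MeasurementSet, reference: MeasurementSet
) -> tuple[float, float]:
    """Aldehyde-producing activity index relative to the reference.

    Raises :class:`NotDetermined` when either soluble band is never
    detected (the paper-style "not determined" outcome).
    """
    if variant.variant_id == reference.variant_id:
        return 1.0, 0.0
    va, va_se = _mean_se(variant.replicate_totals())
    vs, vs_se = _mean_se(variant.soluble_volumes())
    ra, ra_se = _mean_se(reference.replicate_totals())
    rs, rs_se = _mean_se(reference.soluble_volumes())
    if vs <= 0 or rs <= 0:
        raise NotDetermined("zero soluble volume")
    ratio = (va / vs) / (ra / rs)
    se = _ratio_se(ratio, [(va, va_se), (vs, vs_se), (ra, ra_se), (rs, rs_se)])
    return ratio, se


def relative_expression(
    variant: MeasurementSet, reference: MeasurementSet
) -> tuple[float, float]:
    """Total (soluble + insoluble) expression relative to the reference."""
    if variant.variant_id == reference.variant_id:
        return 1.0, 0.0
    vt, vt_se = _mean_se(variant.total_volumes())
    rt, rt_se = _mean_se(reference.total_volumes())
    if rt <= 0:
        raise NotDetermined("zero reference expression")
    ratio = vt / rt
    return ratio, _ratio_se(ratio, [(vt, vt_se), (rt, rt_se)])


@dataclass
class ActivityProfile:
    """Per-variant derived quantities, each as value ± standard error."""

    variant_id: str
    n_replicates: int
    relative_activity: float = float("nan")
    relative_activity_se: float = float("nan")
    solubility_pct: float = float("nan")
    solubility_se: float = float("nan")
    relative_expression: float = float("nan")
    relative_expression_se: float = float("nan")
    total_relative: float = float("nan")
    total_relative_se: float = float("nan")
    fractions: dict[str, float] = field(default_factory=dict)
    fraction_ses: dict[str, float] = field(default_factory=dict)
    relative_specificity: dict[str, float] = field(default_factory=dict)
    activity_determined: bool = True
    solubility_determined: bool = True
    expression_determined: bool = True


def _check_ado_covariate(blot: pd.DataFrame) -> None:
    """Warn when the optional ADO soluble amount drifts across variants.

    The ADO band is an internal control expected to be near-constant; it is
    never used in normalisation.
    """
    if ADO_COLUMN not in blot.columns:
        return
    means = blot.groupby("variant_id")[ADO_COLUMN].mean().dropna()
    if len(means) < 2 or means.mean() == 0:
        return
    cv = float(means.std(ddof=1) / means.mean())
    if cv > ADO_CV_WARN:
        warnings.warn(
            f"ADO soluble amount varies across variants (CV {cv:.2f} > "
            f"{ADO_CV_WARN}); it should be near-constant",
            stacklevel=2,
        )


def assemble_profiles(
    hydro: pd.DataFrame,
    blot: pd.DataFrame,
    reference_id: str,
) -> list[ActivityProfile]:
    """One :class:`ActivityProfile` per variant in the hydrocarbon table.

    The reference must be present in both tables with its soluble band
    detected; it reports ratios of exactly 1 ± 0.  Variants missing from
    the blot table, or with no detected soluble band, get activity /
    solubility / expression marked not determined while their specificity
    fractions are still computed.
    """
    _check_ado_covariate(blot)
    variants = list(dict.fromkeys(hydro["variant_id"]))
    if reference_id not in variants or reference_id not in set(blot["variant_id"]):
        raise ConfigurationError(
            f"reference variant {reference_id!r} missing from the input tables"
        )

    def mset(vid: str) -> MeasurementSet:
        return MeasurementSet(
            variant_id=vid,
            hydro=hydro[hydro["variant_id"] == vid],
            blot=blot[blot["variant_id"] == vid],
        )

    reference = mset(reference_id)
    if reference.soluble_volumes().size == 0 or reference.total_volumes().size == 0:
        raise ConfigurationError(
            f"reference variant {reference_id!r} has no fully detected replicates"
        )
    cols = amount_columns(hydro)
    analytes = [c[len("amount_"):] for c in cols]
    ref_means = reference.hydro[cols].mean().to_numpy(dtype=float)
    ref_fracs = specificity_fractions(ref_means)
    ref_total_mean, ref_total_se = _mean_se(reference.replicate_totals())

    profiles = []
    for vid in variants:
        v = mset(vid)
        profile = ActivityProfile(variant_id=vid, n_replicates=len(v.hydro))

        means = v.hydro[cols].mean().to_numpy(dtype=float)
        fracs = specificity_fractions(means)
        profile.fractions = dict(zip(analytes, fracs.tolist()))
        per_rep = v.hydro[cols].to_numpy(dtype=float)
        per_rep_fracs = per_rep / per_rep.sum(axis=1, keepdims=True)
        ses = (
            per_rep_fracs.std(axis=0, ddof=1) / math.sqrt(len(per_rep))
            if len(per_rep) > 1
            else np.zeros(len(cols))
        )
        profile.fraction_ses = dict(zip(analytes, ses.tolist()))
        profile.relative_specificity = dict(
            zip(analytes, relative_specificity(fracs, ref_fracs).tolist())
        )

        if vid == reference_id:
            profile.total_relative, profile.total_relative_se = 1.0, 0.0
        else:
            total_mean, total_se = _mean_se(v.replicate_totals())
            profile.total_relative = total_mean / ref_total_mean
            profile.total_relative_se = _ratio_se(
                profile.total_relative,
                [(total_mean, total_se), (ref_total_mean, ref_total_se)],
            )

        try:
            profile.relative_activity, profile.relative_activity_se = relative_activity(
                v, reference
            )
        except NotDetermined:
            profile.activity_determined = False
        try:
            profile.relative_expression, profile.relative_expression_se = (
                (1.0, 0.0) if vid == reference_id else relative_expression(v, reference)
            )
        except NotDetermined:
            profile.expression_determined = False

        ok = v.blot["soluble_detected"] & v.blot["insoluble_detected"]
        sub = v.blot.loc[ok]
        if len(sub) == 0:
            profile.solubility_determined = False
        else:
            s_mean = float(sub["soluble_volume"].mean())
            p_mean = float(sub["insoluble_volume"].mean())
            profile.solubility_pct = solubility(s_mean, p_mean)
            per_rep_sol = (
                100.0
                * sub["soluble_volume"]
                / (sub["soluble_volume"] + sub["insoluble_volume"])
            ).to_numpy(dtype=float)
            profile.solubility_se = (
                float(np.std(per_rep_sol, ddof=1) / math.sqrt(len(per_rep_sol)))
                if len(per_rep_sol) > 1
                else 0.0
            )
        profiles.append(profile)
    return profiles


def profiles_to_frame(profiles: list[ActivityProfile]) -> pd.DataFrame:
    """Flatten profiles into one row per variant."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "variant_id": p.variant_id,
            "n_replicates": p.n_replicates,
            "relative_activity": p.relative_activity,
            "relative_activity_se": p.relative_activity_se,
            "activity_determined": p.activity_determined,
            "solubility_pct": p.solubility_pct,
            "solubility_se": p.solubility_se,
            "solubility_determined": p.solubility_determined,
            "relative_expression": p.relative_expression,
            "relative_expression_se": p.relative_expression_se,
            "expression_determined": p.expression_determined,
            "total_relative": p.total_relative,
            "total_relative_se": p.total_relative_se,
        }
        for analyte, frac in p.fractions.items():
            row[f"fraction_{analyte}"] = frac
            row[f"fraction_{analyte}_se"] = p.fraction_ses.get(analyte, float("nan"))
            row[f"relative_specificity_{analyte}"] = p.relative_specificity.get(
                analyte, float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(
    profiles: list[ActivityProfile], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    frame = profiles_to_frame(profiles)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        payload = frame.to_dict(orient="records")
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=float)
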