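"""Antimicrobial growth-inhibition and NF-κB reporter assay summaries.

Two normalizations are implemented exactly as used for the functional data:

* Growth inhibition: OD600 curves are blank-subtracted, technical replicates
  averaged, and the treated signal at an evaluation time T (7 h default,
  12 h alternate) expressed as percent of the untreated control,

      percent = 100 * (OD_treated(T) - OD_blank(T))
                    / (OD_untreated(T) - OD_blank(T)).

* NF-κB induction: per well the firefly/renilla luciferase ratio r is
  formed; per treatment technical wells are averaged; induction is
  background-subtracted by the LPS+polymyxin-B control and normalized to
  the LPS positive control,

      induction = (r_treatment - r_LPS+PB) / (r_LPS - r_LPS+PB),

  so LPS maps to 1 and LPS+PB to 0 on every plate.

Both are aggregated as mean ± SEM over biological replicates (technical
replicates are averaged first; n = number of biological replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssayError",
    "GrowthCurveSet",
    "InhibitionSummary",
    "ReporterPlate",
    "InductionResult",
    "growth_inhibition",
    "nfkb_induction",
    "dose_series",
    "LPS", "LPS_PB", "MOCK", "UNTREATED", "BLANK",
]

LPS = "LPS"
LPS_PB = "LPS+PB"
MOCK = "mock"
UNTREATED = "untreated"
BLANK = "blank"


class AssayError(ValueError):
    pass


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


# ----------------------------------------------------------------- growth


@dataclass
class GrowthCurveSet:
    """OD600 time courses for a plate of wells.

    ``table`` is long-format with columns: well, time_min, od600, treatment,
    concentration_uM, bio_rep. Treatments include the reserved labels
    ``untreated`` and ``blank``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"well", "time_min", "od600", "treatment", "bio_rep"}
        if not req <= set(self.table.columns):
            raise AssayError(f"growth table needs columns {sorted(req)}")
        if "concentration_uM" not in self.table.columns:
            self.table = self.table.assign(concentration_uM=np.nan)
        labels = set(self.table["treatment"])
        for needed in (UNTREATED, BLANK):
            if needed not in labels:
                raise AssayError(f"no {needed!r} wells present")

    @classmethod
    def from_csv(cls, timeseries_path, platemap_path) -> "GrowthCurveSet":
        ts = pd.read_csv(timeseries_path)
        pm = pd.read_csv(platemap_path)
        return cls(ts.merge(pm, on="well", validate="many_to_one"))


@dataclass
class InhibitionSummary:
    """Percent-of-untreated growth per treatment at the evaluation time."""

    table: pd.DataFrame  # treatment, concentration_uM, percent, sem, n
    evaluation_time_min: float

    def percent(self, treatment: str) -> float:
        rows = self.table[self.table["treatment"] == treatment]
        if rows.empty:
            raise KeyError(treatment)
        return float(rows["percent"].iloc[0])


def growth_inhibition(
    curves: GrowthCurveSet,
    evaluation_time_hr: float = 7.0,
    tolerance_min: float = 7.5,
) -> InhibitionSummary:
    """Percent of untreated growth at the evaluation time (7 h default,
    12 h alternate), mean ± SEM across biological replicates.

    The nearest sampled time within ``tolerance_min`` (half the 15-min
    sampling interval) is used; no interpolation.
    """
    T = evaluation_time_hr * 60.0
    times = np.sort(curves.table["time_min"].unique())
    nearest = times[np.argmin(np.abs(times - T))]
    if abs(nearest - T) > tolerance_min:
        raise AssayError(
            f"no sample within {tolerance_min} min of t = {T} min "
            f"(nearest is {nearest} min)"
        )
    at_T = curves.table[curves.table["time_min"] == nearest]

    records = []
    for bio, plate in at_T.groupby("bio_rep"):
        # technical replicates averaged first
        means = (
            plate.groupby(["treatment", "concentration_uM"], dropna=False)["od600"]
            .mean()
            .reset_index()
        )
        blank = means.loc[means["treatment"] == BLANK, "od600"]
        untreated = means.loc[means["treatment"] == UNTREATED, "od600"]
        if blank.empty or untreated.empty:
            raise AssayError(f"bio replicate {bio} lacks blank or untreated wells")
        b = float(blank.mean())
        u = float(untreated.mean())
        if u - b <= 0:
            raise AssayError(
                f"untreated minus blank is {u - b:.4f} <= 0 at t = {nearest} min; "
                "no growth signal"
            )
        for _, row in means.iterrows():
            if row["treatment"] == BLANK:
                continue
            records.append(
                {
                    "bio_rep": bio,
                    "treatment": row["treatment"],
                    "concentration_uM": row["concentration_uM"],
                    "percent": 100.0 * (row["od600"] - b) / (u - b),
                }
            )
    per_bio = pd.DataFrame(records)
    summary = (
        per_bio.groupby(["treatment", "concentration_uM"], dropna=False)["percent"]
        .agg(percent="mean", sem=_sem, n="size")
        .reset_index()
    )
    return InhibitionSummary(table=summary, evaluation_time_min=float(nearest))


# --------------------------------------------------------------- reporter


@dataclass
class ReporterPlate:
    """Dual-luciferase wells: firefly and renilla counts per labeled well.

    ``table`` columns: well, treatment, concentration_uM (optional), firefly,
    renilla, bio_rep. Every biological replicate (plate) must carry LPS and
    LPS+PB anchor wells; renilla must be positive for retained wells.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"well", "treatment", "firefly", "renilla", "bio_rep"}
        if not req <= set(self.table.columns):
            raise AssayError(f"reporter table needs columns {sorted(req)}")
        if "concentration_uM" not in self.table.columns:
            self.table = self.table.assign(concentration_uM=np.nan)
        if (self.table["renilla"] <= 0).any():
            raise AssayError("renilla counts must be positive for retained wells")
        for bio, plate in self.table.groupby("bio_rep"):
            labels = set(plate["treatment"])
            if LPS not in labels or LPS_PB not in labels:
                raise AssayError(
                    f"plate (bio replicate {bio}) lacks LPS / LPS+PB anchor wells"
                )

    @classmethod
    def from_csv(cls, path) -> "ReporterPlate":
        return cls(pd.read_csv(path))


@dataclass
class InductionResult:
    """Normalized NF-κB induction per treatment, mean ± SEM over plates."""

    table: pd.DataFrame  # treatment, concentration_uM, induction, sem, n

    def induction(self, treatment: str) -> float:
        rows = self.table[self.table["treatment"] == treatment]
        if rows.empty:
            raise KeyError(treatment)
        return float(rows["induction"].iloc[0])


def nfkb_induction(plate: ReporterPlate) -> InductionResult:
    """Firefly/renilla ratios background-subtracted by LPS+PB and normalized
    to LPS, per plate, then aggregated across biological replicates.

    Mock wells are carried through and reported but play no role in the
    normalization. Negative inductions (below background) are kept as-is.
    """
    df = plate.table.assign(ratio=plate.table["firefly"] / plate.table["renilla"])
    records = []
    for bio, sub in df.groupby("bio_rep"):
        means = (
            sub.groupby(["treatment", "concentration_uM"], dropna=False)["ratio"]
            .mean()
            .reset_index()
        )
        r_lps = float(means.loc[means["treatment"] == LPS, "ratio"].mean())
        r_bg = float(means.loc[means["treatment"] == LPS_PB, "ratio"].mean())
        if r_lps <= r_bg:
            raise AssayError(
                f"failed positive control on plate {bio}: "
                f"LPS ratio {r_lps:.4f} <= LPS+PB ratio {r_bg:.4f}"
            )
        for _, row in means.iterrows():
            records.append(
                {
                    "bio_rep": bio,
                    "treatment": row["treatment"],
                    "concentration_uM": row["concentration_uM"],
                    "induction": (row["ratio"] - r_bg) / (r_lps - r_bg),
                }
            )
    per_bio = pd.DataFrame(records)
    summary = (
        per_bio.groupby(["treatment", "concentration_uM"], dropna=False)["induction"]
        .agg(induction="mean", sem=_sem, n="size")
        .reset_index()
    )
    return InductionResult(table=summary)


# ------------------------------------------------------------- dose series


def dose_series(results: list[InductionResult | InhibitionSummary]) -> pd.DataFrame:
    """Tidy long-format dose-response table sorted by concentration.

    Accepts any mixture of induction and inhibition summaries; the response
    column is named after the source quantity.
    """
    if not results:
        raise AssayError("no results supplied")
    frames = []
    for res in results:
        df = res.table.copy()
        value_col = "induction" if "induction" in df.columns else "percent"
        df = df.rename(columns={value_col: "response"})
        df["response_type"] = value_col
        frames.append(df[["treatment", "concentration_uM", "response", "sem",
                          "response_type"]])
    out = pd.concat(frames, ignore_index=True)
    out = out.dropna(subset=["concentration_uM"])
    dup = out.duplicated(subset=["treatment", "concentration_uM", "response_type"])
    if dup.any():
        raise AssayError("duplicate (treatment, concentration) rows")
    if out.empty or out["concentration_uM"].nunique() < 2:
        raise AssayError("need at least two concentrations for a dose series")
    return out.sort_values(
        ["treatment", "concentration_uM"], kind="stable"
    ).reset_index(drop=True)
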