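"""Quantification layer for the validation assays.

Covers four bookkeeping-heavy but error-prone steps of the follow-up work
on shortlisted compounds:

* bead-array (CBA) back-calculation of analyte concentrations from
  fluorescence through fitted 4PL standard curves, with explicit detection
  flags instead of imputation;
* per-cell normalization of secreted concentrations (pg/mL per 10^4 cells);
* fold changes versus the vehicle condition, switching to absolute
  reporting for analytes undetectable in vehicle;
* membrane antibody-array normalization (duplicate-spot averages over the
  mean of the six reference spots per blot) and qPCR ddCt fold changes
  against GAPDH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import ABOVE_RANGE, BELOW_LOD, OK, FourPL, back_calculate
from .errors import IntegrityError, ScreenError

# per-cell concentrations are expressed per this many cells
REFERENCE_CELLS = 10_000


@dataclass(frozen=True)
class AnalyteMeasurement:
    analyte: str
    condition: str
    concentration: float          # pg/mL; NaN when below LOD
    cells: int | None = None
    per_cell_conc: float = float("nan")   # pg/mL per 10^4 cells
    detection: str = OK

    @property
    def quantifiable(self) -> bool:
        return self.detection == OK


class SpotBlot:
    """A membrane array: labelled spots, duplicate analyte spots, and
    exactly six reference spots used for cross-blot normalization.
    """

    REFERENCE_LABEL = "REF"
    N_REFERENCE = 6

    def __init__(self, spots: pd.DataFrame):
        required = {"row", "col", "label", "intensity"}
        missing = required - set(spots.columns)
        if missing:
            raise IntegrityError(f"spot table missing columns: {sorted(missing)}")
        spots = spots.copy()
        spots["intensity"] = pd.to_numeric(spots["intensity"]).astype(float)
        if (spots["intensity"] < 0).any():
            raise IntegrityError("spot intensities must be >= 0")
        n_ref = int((spots["label"] == self.REFERENCE_LABEL).sum())
        if n_ref != self.N_REFERENCE:
            raise IntegrityError(
                f"blot layout error: expected {self.N_REFERENCE} reference "
                f"spots, found {n_ref}")
        ref = spots.loc[spots["label"] == self.REFERENCE_LABEL, "intensity"]
        if (ref <= 0).any():
            raise IntegrityError("reference spot intensities must be > 0")
        counts = spots.loc[spots["label"] != self.REFERENCE_LABEL, "label"].value_counts()
        bad = counts[(counts < 1) | (counts > 2)]
        if len(bad):
            raise IntegrityError(
                f"analytes must have 1 or 2 spots; offending: {sorted(bad.index)}")
        self.spots = spots.reset_index(drop=True)

    @property
    def analytes(self) -> list[str]:
        labels = self.spots.loc[self.spots["label"] != self.REFERENCE_LABEL, "label"]
        return sorted(labels.unique())

    @property
    def reference_mean(self) -> float:
        ref = self.spots.loc[self.spots["label"] == self.REFERENCE_LABEL, "intensity"]
        return float(ref.mean())

    def scaled(self, k: float) -> "SpotBlot":
        """The same blot at a different exposure (all intensities x k)."""
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        out = self.spots.copy()
        out["intensity"] *= k
        return SpotBlot(out)

    @classmethod
    def from_csv(cls, path) -> "SpotBlot":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.spots.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# bead-array quantification
# ---------------------------------------------------------------------------

def quantify_panel(
    raw: pd.DataFrame,
    curves: dict[str, FourPL],
    top_standard: float = 10_000.0,
) -> pd.DataFrame:
    """Convert raw panel fluorescence to concentrations via standard curves.

    ``raw`` needs columns ``analyte, condition, signal`` (a ``cells`` column
    is carried through if present).  Each analyte must have a fitted curve
    in ``curves``.  Readings at/below the curve bottom are flagged
    ``below_lod`` and carry no numeric concentration; readings at/above the
    top are flagged ``above_range`` and censored at ``top_standard``
    (extrapolating beyond the top asymptote is numerically unstable, so we
    never do it).
    """
    required = {"analyte", "condition", "signal"}
    missing = required - set(raw.columns)
    if missing:
        raise ScreenError(f"panel table missing columns: {sorted(missing)}")
    absent = sorted(set(raw["analyte"]) - set(curves))
    if absent:
        raise ScreenError(f"no standard curve for analyte(s): {absent}")
    out = raw.copy().reset_index(drop=True)
    conc = np.full(len(out), np.nan)
    flags = np.full(len(out), OK, dtype=object)
    for analyte, grp in out.groupby("analyte"):
        c, f = back_calculate(curves[analyte], grp["signal"].to_numpy(),
                              top_censor=top_standard)
        conc[grp.index] = c
        flags[grp.index] = f
    out["concentration"] = conc
    out["detection"] = flags
    return out


def normalize_per_cell(measurements: pd.DataFrame,
                       cells: int | None = None) -> pd.DataFrame:
    """Express concentrations per 10^4 cells.

    ``cells`` overrides a ``cells`` column if given.  Only ``ok`` rows get a
    numeric ``per_cell_conc`` (= concentration x 10^4 / cells) and its log10
    (``log10_per_cell``); flagged rows pass through with flags preserved and
    are never logged.
    """
    out = measurements.copy().reset_index(drop=True)
    if cells is not None:
        out["cells"] = cells
    if "cells" not in out.columns:
        raise ScreenError("no cell counts: pass `cells` or include a cells column")
    ok = out["detection"] == OK
    if (ok & ((out["cells"].isna()) | (out["cells"] <= 0))).any():
        bad = out.loc[ok & (out["cells"].fillna(0) <= 0), "analyte"].tolist()
        raise ScreenError(f"cell count must be > 0 to normalize: {bad}")
    out["per_cell_conc"] = np.nan
    out.loc[ok, "per_cell_conc"] = (
        out.loc[ok, "concentration"] * REFERENCE_CELLS / out.loc[ok, "cells"])
    out["log10_per_cell"] = np.nan
    loggable = ok & (out["per_cell_conc"] > 0)
    out.loc[loggable, "log10_per_cell"] = np.log10(out.loc[loggable, "per_cell_conc"])
    return out


def fold_vs_vehicle(
    measurements: pd.DataFrame,
    vehicle_label: str,
    value_col: str = "concentration",
) -> pd.DataFrame:
    """Fold change of each condition over the vehicle condition, per analyte.

    When the vehicle reading for an analyte is below detection no fold is
    defined; those analytes switch to ``mode='absolute'`` and report the raw
    value instead (below-LOD values are never substituted with LOD/2 or any
    other stand-in).
    """
    required = {"analyte", "condition", value_col}
    missing = required - set(measurements.columns)
    if missing:
        raise ScreenError(f"measurement table missing columns: {sorted(missing)}")
    m = measurements.copy().reset_index(drop=True)
    if "detection" not in m.columns:
        m["detection"] = OK
    rows = []
    for analyte, grp in m.groupby("analyte", sort=True):
        veh = grp[grp["condition"] == vehicle_label]
        if veh.empty:
            raise ScreenError(f"vehicle condition {vehicle_label!r} absent "
                              f"for analyte {analyte}")
        veh_ok = (veh["detection"] == OK).all()
        veh_val = float(veh[value_col].mean()) if veh_ok else np.nan
        for _, r in grp.iterrows():
            if veh_ok and veh_val != 0 and r["detection"] == OK:
                rows.append({"analyte": analyte, "condition": r["condition"],
                             "mode": "fold", "value": float(r[value_col]) / veh_val})
            else:
                rows.append({"analyte": analyte, "condition": r["condition"],
                             "mode": "absolute",
                             "value": float(r[value_col])
                             if r["detection"] == OK else np.nan})
    return pd.DataFrame(rows, columns=["analyte", "condition", "mode", "value"])


# ---------------------------------------------------------------------------
# membrane arrays
# ---------------------------------------------------------------------------

def normalize_blot(blot: SpotBlot) -> pd.DataFrame:
    """Mean of each analyte's duplicate spots over the mean of the six
    reference spots; invariant to global exposure scaling.
    """
    ref_mean = blot.reference_mean
    if ref_mean <= 0:
        raise IntegrityError("degenerate blot: reference mean is zero")
    df = blot.spots
    analyte = df[df["label"] != SpotBlot.REFERENCE_LABEL]
    out = (analyte.groupby("label", sort=True)["intensity"].mean() / ref_mean)
    return out.rename("normalized").reset_index().rename(columns={"label": "analyte"})


# ---------------------------------------------------------------------------
# qPCR dCt / ddCt
# ---------------------------------------------------------------------------

def delta_ct_fold(records: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Expression fold change by the dCt method against GAPDH.

    ``records`` needs columns ``gene, condition, ct_target, ct_gapdh``.
    Per gene: dCt = ct_target - ct_gapdh, and
    fold = 2**-(dCt_condition - dCt_reference); the reference condition
    (e.g. time zero or untreated) therefore has fold exactly 1.
    """
    required = {"gene", "condition", "ct_target", "ct_gapdh"}
    missing = required - set(records.columns)
    if missing:
        raise ScreenError(f"Ct table missing columns: {sorted(missing)}")
    rec = records.copy().reset_index(drop=True)
    if rec["ct_gapdh"].isna().any():
        bad = rec.loc[rec["ct_gapdh"].isna(), ["gene", "condition"]]
        raise ScreenError(
            "missing GAPDH Ct for: " +
            ", ".join(f"{g}/{c}" for g, c in bad.itertuples(index=False)))
    if rec["ct_target"].isna().any():
        raise ScreenError("missing target Ct values")
    rec["delta_ct"] = rec["ct_target"] - rec["ct_gapdh"]
    folds = []
    for gene, grp in rec.groupby("gene"):
        ref = grp[grp["condition"] == reference_condition]
        if ref.empty:
            raise ScreenError(
                f"gene {gene}: reference condition {reference_condition!r} missing")
        ref_dct = float(ref["delta_ct"].mean())
        folds.append(2.0 ** -(grp["delta_ct"] - ref_dct))
    rec["fold_vs_reference"] = pd.concat(folds).sort_index()
    return rec
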