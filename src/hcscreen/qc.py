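"""Per-plate normalization and assay-quality statistics.

Each plate is internally normalized to its own IL-1beta + vehicle control
wells, which removes multiplicative plate-to-plate variation in absolute
intensity and cell number.  Assay quality is summarized by the screening
window coefficient

    Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|

between the stimulated (positive) and unstimulated (negative) vehicle
controls, the control separation ratio, a TGFbeta1 positive-control
inhibition check, and the Pearson concordance between the two readout
channels over all compound wells.

Sample (n-1) standard deviations are used throughout: control-well counts
per plate are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateControlError,
    InsufficientReplicatesError,
    NormalizationError,
    ScreenError,
)
from .io import ScreenDataset

CHANNELS = ("ccl2", "icam1")

# media_only wells never enter any statistic
_EXCLUDED_ROLES = ("media_only",)


def normalize_plate(plate: pd.DataFrame,
                    reference_role: str = "vehicle_stim") -> pd.DataFrame:
    """Normalize one plate's wells to its reference control wells.

    Per channel, ``activity = per-cell intensity / mean per-cell intensity
    of reference wells``; ``cell_ratio`` is the analogous ratio on cell
    counts.  The reference is the IL-1beta + vehicle condition except on
    unstimulated (independence) runs, where it is the vehicle_only wells.
    Wells with zero cells get undefined (NaN) activities and cell_ratio 0,
    and are excluded from every plate statistic.  Invariant to multiplying
    every intensity on the plate by k > 0.
    """
    plate = plate.copy().reset_index(drop=True)
    usable = (plate["role"] == reference_role) & (plate["cell_count"] > 0)
    ref = plate[usable]
    if len(ref) < 2:
        raise NormalizationError(
            f"need >= 2 {reference_role} wells with cells on plate "
            f"{plate['plate_id'].iloc[0] if len(plate) else '?'}, found {len(ref)}")
    ref_cells = float(ref["cell_count"].mean())
    out = plate
    out["cell_ratio"] = out["cell_count"] / ref_cells
    for ch in CHANNELS:
        ref_mean = float(ref[f"intensity_{ch}"].mean())
        if not ref_mean > 0:
            raise DegenerateControlError(
                f"{reference_role} mean intensity_{ch} is not positive")
        out[f"activity_{ch}"] = out[f"intensity_{ch}"] / ref_mean
    zero = out["cell_count"] == 0
    out.loc[zero, [f"activity_{ch}" for ch in CHANNELS]] = np.nan
    out.loc[zero, "cell_ratio"] = 0.0
    return out


def normalize_screen(dataset: ScreenDataset,
                     reference_role: str | None = None) -> pd.DataFrame:
    """Apply :func:`normalize_plate` to every plate of a dataset."""
    if reference_role is None:
        reference_role = ("vehicle_only" if dataset.tier == "independence"
                          else "vehicle_stim")
    parts = [normalize_plate(dataset.plate(p), reference_role=reference_role)
             for p in dataset.plate_ids]
    return pd.concat(parts, ignore_index=True)


def zprime(positive, negative) -> float:
    """Screening-window coefficient Z' = 1 - 3(sd_p + sd_n)/|mean_p - mean_n|.

    Symmetric in its arguments, invariant to adding a constant to both
    groups or scaling both by k != 0, and always <= 1.  Uses sample (n-1)
    standard deviations.
    """
    p = np.asarray(list(positive), dtype=float)
    n = np.asarray(list(negative), dtype=float)
    if len(p) < 2 or len(n) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 values per group, got {len(p)} and {len(n)}")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise ScreenError("undefined screening window: group means are equal")
    return 1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep


def channel_concordance(activity_ccl2, activity_icam1):
    """Pearson correlation between the two channels' normalized activities.

    Returns ``(r, p)`` from the standard product-moment correlation over
    paired compound-well activities pooled across plates.
    """
    x = np.asarray(list(activity_ccl2), dtype=float)
    y = np.asarray(list(activity_icam1), dtype=float)
    if x.shape != y.shape:
        raise ScreenError("channel activity lists must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ScreenError(f"need >= 3 paired values, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ScreenError("zero variance in a channel: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class TgfbVerdict:
    """Positive-control check on the TGFbeta1 wells of one plate."""

    status: str                       # "pass" | "fail" | "not_evaluated"
    inhibition: dict = field(default_factory=dict)  # (dose role, channel) -> fraction
    message: str = ""


def control_check(plate_normalized: pd.DataFrame, min_inhibition: float = 0.2,
                  channels=CHANNELS) -> TgfbVerdict:
    """Verify TGFbeta1-dependent inhibition of the induced response.

    Observed inhibition per TGFbeta dose and channel is ``1 - mean
    activity`` of those wells; the plate passes if every evaluated
    (dose, channel) reaches ``min_inhibition``.  Plates without TGFbeta
    wells are skipped with a warning verdict, not failed.
    """
    inhibition = {}
    ok = True
    for role in ("tgfb_low", "tgfb_high"):
        wells = plate_normalized[(plate_normalized["role"] == role)
                                 & (plate_normalized["cell_count"] > 0)]
        if wells.empty:
            continue
        for ch in channels:
            inh = 1.0 - float(wells[f"activity_{ch}"].mean())
            inhibition[(role, ch)] = inh
            if inh < min_inhibition:
                ok = False
    if not inhibition:
        return TgfbVerdict(status="not_evaluated",
                           message="no TGFbeta1 wells on plate")
    return TgfbVerdict(status="pass" if ok else "fail", inhibition=inhibition)


@dataclass
class PlateQC:
    """Quality summary for one plate (or a whole screen when pooled)."""

    plate_id: str
    zprime_ccl2: float
    zprime_icam1: float
    control_separation_ccl2: float
    control_separation_icam1: float
    tgfb: TgfbVerdict
    passed: bool

    def as_row(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "zprime_ccl2": self.zprime_ccl2,
            "zprime_icam1": self.zprime_icam1,
            "control_separation_ccl2": self.control_separation_ccl2,
            "control_separation_icam1": self.control_separation_icam1,
            "tgfb_status": self.tgfb.status,
            "pass": self.passed,
        }


def _qc_one(label: str, normalized: pd.DataFrame, min_zprime: float,
            min_inhibition: float) -> PlateQC:
    zp = {}
    sep = {}
    pos = normalized[(normalized["role"] == "vehicle_stim")
                     & (normalized["cell_count"] > 0)]
    neg = normalized[(normalized["role"] == "vehicle_only")
                     & (normalized["cell_count"] > 0)]
    for ch in CHANNELS:
        zp[ch] = zprime(pos[f"activity_{ch}"], neg[f"activity_{ch}"])
        neg_mean = float(neg[f"activity_{ch}"].mean())
        if neg_mean <= 0:
            raise DegenerateControlError(f"vehicle_only mean activity_{ch} <= 0")
        sep[ch] = float(pos[f"activity_{ch}"].mean()) / neg_mean
    tgfb = control_check(normalized, min_inhibition=min_inhibition)
    passed = all(z >= min_zprime for z in zp.values()) and tgfb.status != "fail"
    return PlateQC(plate_id=label, zprime_ccl2=zp["ccl2"], zprime_icam1=zp["icam1"],
                   control_separation_ccl2=sep["ccl2"],
                   control_separation_icam1=sep["icam1"], tgfb=tgfb, passed=passed)


@dataclass
class ScreenQC:
    per_plate: list[PlateQC]
    pooled: PlateQC                   # controls pooled across plates, post-normalization
    concordance_r: float
    concordance_p: float

    def table(self) -> pd.DataFrame:
        rows = [q.as_row() for q in self.per_plate]
        rows.append(self.pooled.as_row())
        return pd.DataFrame(rows)


def screen_qc(dataset: ScreenDataset, min_zprime: float = 0.0,
              min_inhibition: float = 0.2) -> ScreenQC:
    """Normalize a screen and compute plate-level and pooled QC.

    The screening window is reported at both granularities: one Z' per
    channel per plate, and one per channel for the whole screen with
    control wells pooled across plates after normalization (the pooled
    figure is the screen-level analogue of the published per-channel
    values).
    """
    normalized = normalize_screen(dataset)
    stats_wells = normalized[~normalized["role"].isin(_EXCLUDED_ROLES)]
    per_plate = [
        _qc_one(pid, grp, min_zprime, min_inhibition)
        for pid, grp in stats_wells.groupby("plate_id", sort=True)
    ]
    pooled = _qc_one("ALL", stats_wells, min_zprime, min_inhibition)
    cmp = stats_wells[(stats_wells["role"] == "compound")
                      & (stats_wells["cell_count"] > 0)]
    r, p = channel_concordance(cmp["activity_ccl2"], cmp["activity_icam1"])
    return ScreenQC(per_plate=per_plate, pooled=pooled,
                    concordance_r=r, concordance_p=p)
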