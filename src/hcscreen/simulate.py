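"""Synthetic screen generator with known ground truth.

Emulates a 96-well high-content screen of an FDA-approved compound library
on IL-1beta-stimulated pericytes: per-plate internal controls (IL-1beta +
vehicle, unstimulated vehicle, TGFbeta1 at two doses, media-only wells),
multiplicative per-plate effects, log-normal well noise, Poisson cell
counts, planted bidirectional modulators and cytotoxic compounds, 4PL
dose-response structure, bead-array standard curves and membrane blots.

Every generator returns its ground truth alongside the data, so each
downstream stage can be tested for exact recovery at zero noise and for
calibrated recovery under noise.

Noise model choices (the study reports no noise parameters, so these are
the package's own): intensities carry multiplicative log-normal noise
(fluorescence is positive and heteroscedastic); plate effects are
log-normal and shared across channels within a plate, which is precisely
the nuisance that internal plate normalization removes; cell counts are
Poisson.  Truth effect multipliers are defined on the stimulated response
scale at the 10 uM screening dose; at lower doses they shrink toward 1
through a saturating occupancy factor anchored so the full effect is
attained at 10 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .doseresponse import FourPL
from .io import ScreenDataset, WELL_COLUMNS
from .quantify import SpotBlot

# well-address layout of one 96-well screen plate: compounds in columns
# 1-10 (80 wells), controls in columns 11-12
_ROWS = "ABCDEFGH"
COMPOUND_WELLS_PER_PLATE = 80
PLATE_SIZE = 96

# 11-point bead-array standard grid, 0 - 10,000 pg/mL (two-fold serial
# dilutions from the top standard, plus a zero/blank point)
CBA_STANDARD_GRID = tuple([0.0] + [10_000.0 / 2 ** k for k in range(9, -1, -1)])

SCREEN_DOSE_UM = 10.0          # single-dose screening concentration
DEFAULT_DOSE_GRID = (0.1, 1.0, 10.0)
BASAL_INTENSITY = 100.0        # arbitrary fluorescence units per cell
_DOSE_K_UM = 1.0               # half-saturation of the dose-effect factor


def _control_layout(tier: str) -> dict[str, str]:
    """Map well address -> role for the two control columns."""
    layout: dict[str, str] = {}
    stim_role = "vehicle_only" if tier == "independence" else "vehicle_stim"
    for r in "ABCD":
        layout[f"{r}11"] = stim_role
    for r in "EFGH":
        layout[f"{r}11"] = "vehicle_only"
    layout["A12"] = layout["B12"] = "tgfb_low"
    layout["C12"] = layout["D12"] = "tgfb_high"
    for r in "EFGH":
        layout[f"{r}12"] = "media_only"
    return layout


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance-variation parameters of the screen generator.

    plate_sigma : SD of the log-normal per-plate multiplicative factor
    well_cv : coefficient of variation of log-normal well noise
    cell_lambda : expected cells per well (Poisson)
    induction_fold_* : stimulated / basal per-cell intensity ratio; the
        default 5.0 puts unstimulated vehicle wells at ~0.2x the stimulated
        controls.  At the default noise settings this yields usable
        screening windows (per-plate Z' roughly 0.55-0.95); published
        screens of this kind often sit lower
    tgfb_inhibition : fractional inhibition of the induced response in the
        high-dose TGFbeta1 control wells (the low dose inhibits 0.6x this)
    """

    plate_sigma: float = 0.1
    well_cv: float = 0.05
    cell_lambda: float = 2000.0
    induction_fold_ccl2: float = 5.0
    induction_fold_icam1: float = 5.0
    tgfb_inhibition: float = 0.5

    def __post_init__(self):
        if self.plate_sigma < 0 or self.well_cv < 0:
            raise ConfigError("plate_sigma and well_cv must be >= 0")
        if self.cell_lambda <= 0:
            raise ConfigError("cell_lambda must be > 0")
        if self.induction_fold_ccl2 <= 1 or self.induction_fold_icam1 <= 1:
            raise ConfigError("induction folds must be > 1")
        if not 0 < self.tgfb_inhibition < 1:
            raise ConfigError("tgfb_inhibition must be in (0, 1)")

    @property
    def log_sigma_well(self) -> float:
        # exact log-normal sigma for a target CV
        return float(np.sqrt(np.log1p(self.well_cv ** 2)))


@dataclass(frozen=True)
class SimConfig:
    """What to plant in the screen.

    Modulators get the same truth effect on both channels (the two readouts
    are strongly correlated in the real screen); half are inhibitors, half
    inducers, with |effect - 1| drawn uniformly on
    [effect_min, effect_max].  Cytotoxic compounds (disjoint from the
    modulators) get viability drawn on [viability_min, viability_max];
    keeping the upper bound below the 0.5 exclusion boundary means Poisson
    cell-count sampling cannot flip a planted truth label.
    """

    n_compounds: int = 1280
    fraction_modulators: float = 0.1
    fraction_cytotoxic: float = 0.05
    effect_min: float = 0.3
    effect_max: float = 0.6
    viability_min: float = 0.10
    viability_max: float = 0.45
    fraction_basal: float = 0.0       # compounds active without stimulation
    dose_grid: tuple = DEFAULT_DOSE_GRID
    replicates: dict = field(default_factory=lambda: {
        "primary": 2, "secondary": 3, "tertiary": 2, "independence": 2})
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_modulators", "fraction_cytotoxic", "fraction_basal"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if not 0 < self.effect_min <= self.effect_max:
            raise ConfigError("need 0 < effect_min <= effect_max")
        if not 0 < self.viability_min <= self.viability_max <= 1:
            raise ConfigError("need 0 < viability_min <= viability_max <= 1")
        doses = tuple(self.dose_grid)
        if any(d <= 0 for d in doses) or list(doses) != sorted(set(doses)):
            raise ConfigError("dose grid must be strictly positive and increasing")


class ScreenTruth:
    """Ground-truth multipliers per compound: the latent quantities the
    funnel estimates, and the oracle for recovery tests.

    ``table`` is indexed by compound_id with columns ``effect_ccl2``,
    ``effect_icam1`` (multiplicative modulation of the stimulated response;
    1.0 = inert, 0.6 = 40% inhibition), ``viability`` (multiplicative
    cell-count factor in (0, 1]) and ``basal_effect`` (multiplier without
    stimulation).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"effect_ccl2", "effect_icam1", "viability", "basal_effect"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(f"truth table missing columns: {sorted(missing)}")
        if (table[list(required)] <= 0).any().any():
            raise ConfigError("all truth multipliers must be > 0")
        self.table = table.copy()

    def __len__(self) -> int:
        return len(self.table)

    def expected_hits(self, effect_threshold: float = 0.2,
                      viability_threshold: float = 0.5) -> list[str]:
        """Compound ids the funnel should call, per the planted truth:
        |effect - 1| >= threshold on either channel and viability above the
        cytotoxicity exclusion boundary."""
        t = self.table
        active = ((t["effect_ccl2"] - 1).abs() >= effect_threshold - 1e-12) | (
            (t["effect_icam1"] - 1).abs() >= effect_threshold - 1e-12)
        viable = t["viability"] > viability_threshold
        return sorted(t.index[active & viable])

    def effect_at_dose(self, compound_id: str, channel: str, dose: float) -> float:
        """Truth multiplier at an arbitrary dose: the full effect at the
        10 uM screening dose, shrinking toward 1 at lower doses through a
        saturating factor s(d) = (d/(d+K)) / (D/(D+K)), K = 1 uM."""
        e = float(self.table.loc[compound_id, f"effect_{channel}"])
        return 1.0 + (e - 1.0) * _dose_factor(dose)

    def viability_at_dose(self, compound_id: str, dose: float) -> float:
        v = float(self.table.loc[compound_id, "viability"])
        return 1.0 + (v - 1.0) * _dose_factor(dose)

    def to_csv(self, path) -> None:
        self.table.rename_axis("compound_id").to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ScreenTruth":
        return cls(pd.read_csv(path, index_col="compound_id"))


def _dose_factor(dose: float) -> float:
    return (dose / (dose + _DOSE_K_UM)) / (
        SCREEN_DOSE_UM / (SCREEN_DOSE_UM + _DOSE_K_UM))


def draw_truth(config: SimConfig, rng: np.random.Generator) -> ScreenTruth:
    """Sample a ground-truth table for ``config.n_compounds`` compounds."""
    n = config.n_compounds
    ids = [f"C{i:04d}" for i in range(1, n + 1)]
    eff = np.ones(n)
    via = np.ones(n)
    basal = np.ones(n)

    n_mod = int(round(config.fraction_modulators * n))
    n_tox = int(round(config.fraction_cytotoxic * n))
    n_bas = int(round(config.fraction_basal * n))
    picked = rng.permutation(n)
    mod_idx = picked[:n_mod]
    tox_idx = picked[n_mod:n_mod + n_tox]      # disjoint from modulators
    bas_idx = picked[n_mod + n_tox:n_mod + n_tox + n_bas]

    mag = rng.uniform(config.effect_min, config.effect_max, size=n_mod)
    sign = np.where(np.arange(n_mod) % 2 == 0, -1.0, 1.0)  # half down, half up
    eff[mod_idx] = 1.0 + sign * mag
    via[tox_idx] = rng.uniform(config.viability_min, config.viability_max, size=n_tox)
    bmag = rng.uniform(config.effect_min, config.effect_max, size=n_bas)
    bsign = np.where(np.arange(n_bas) % 2 == 0, -1.0, 1.0)
    basal[bas_idx] = 1.0 + bsign * bmag

    table = pd.DataFrame(
        {"effect_ccl2": eff, "effect_icam1": eff.copy(), "viability": via,
         "basal_effect": basal},
        index=pd.Index(ids, name="compound_id"))
    return ScreenTruth(table)


def simulate_screen(
    config: SimConfig,
    noise: NoiseModel | None = None,
    tier: str = "primary",
    truth: ScreenTruth | None = None,
    compound_ids: list[str] | None = None,
) -> tuple[ScreenDataset, ScreenTruth]:
    """Generate one tier of the screen.

    The tier sets the replicate count (primary 2, secondary 3) and whether
    IL-1beta is applied (the independence tier is unstimulated and carries
    no vehicle_stim wells).  The tertiary tier lays out one set of plates
    per dose in the config's dose grid.  Passing ``truth`` (e.g. from the
    primary run) and ``compound_ids`` re-screens a subset of compounds
    against the same ground truth.  Identical seeds give identical output.
    """
    noise = noise or NoiseModel()
    if tier not in ("primary", "secondary", "tertiary", "independence"):
        raise ConfigError(f"unknown tier {tier!r}")
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = draw_truth(config, rng)
    ids = list(compound_ids) if compound_ids is not None else list(truth.table.index)
    unknown = sorted(set(ids) - set(truth.table.index))
    if unknown:
        raise ConfigError(f"compounds absent from truth table: {unknown}")

    n_rep = int(config.replicates[tier])
    doses = list(config.dose_grid) if tier == "tertiary" else [SCREEN_DOSE_UM]
    stimulated = tier != "independence"
    layout = _control_layout(tier)
    induction = {"ccl2": noise.induction_fold_ccl2, "icam1": noise.induction_fold_icam1}
    sig_w = noise.log_sigma_well

    rows: list[dict] = []
    n_empty = 0
    for dose in doses:
        per_plate = COMPOUND_WELLS_PER_PLATE // n_rep
        n_plates = -(-len(ids) // per_plate)
        for p in range(n_plates):
            if tier == "tertiary":
                plate_id = f"{tier}-{dose:g}uM-p{p + 1:02d}"
            else:
                plate_id = f"{tier}-p{p + 1:02d}"
            plate_factor = float(np.exp(rng.normal(0.0, noise.plate_sigma))) \
                if noise.plate_sigma > 0 else 1.0
            plate_ids_here = ids[p * per_plate:(p + 1) * per_plate]
            # compound wells fill columns 1-10 row-major; replicates adjacent
            cmp_slots = [(r, c) for r in _ROWS for c in range(1, 11)]
            slot = 0
            for cid in plate_ids_here:
                for _ in range(n_rep):
                    r, c = cmp_slots[slot]
                    slot += 1
                    rows.append(_make_well(
                        rng, plate_id, r, c, "compound", cid, dose,
                        truth, noise, plate_factor, induction,
                        stimulated, sig_w))
            n_empty += len(cmp_slots) - slot
            for addr, role in layout.items():
                r, c = addr[0], int(addr[1:])
                rows.append(_make_well(
                    rng, plate_id, r, c, role, "", 0.0, truth, noise,
                    plate_factor, induction, stimulated, sig_w))

    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    dataset = ScreenDataset(wells, tier=tier)
    dataset.n_empty_wells = n_empty
    dataset.n_plates = wells["plate_id"].nunique()
    return dataset, truth


def _make_well(rng, plate_id, row, col, role, cid, dose, truth, noise,
               plate_factor, induction, stimulated, sig_w) -> dict:
    if role == "media_only":
        return {"plate_id": plate_id, "row": row, "col": col, "role": role,
                "compound_id": "", "concentration_um": 0.0, "cell_count": 0,
                "intensity_ccl2": np.nan, "intensity_icam1": np.nan}
    viability = 1.0
    if role == "compound":
        viability = truth.viability_at_dose(cid, dose)
    lam = noise.cell_lambda * viability
    cells = int(rng.poisson(lam))
    intens = {}
    for ch in ("ccl2", "icam1"):
        base = BASAL_INTENSITY * plate_factor
        induced = stimulated and role in ("compound", "vehicle_stim",
                                          "tgfb_low", "tgfb_high")
        if induced:
            base *= induction[ch]
        if role == "compound":
            if stimulated:
                base *= truth.effect_at_dose(cid, ch, dose)
            else:
                base *= float(truth.table.loc[cid, "basal_effect"])
        elif role == "tgfb_high" and induced:
            base *= 1.0 - noise.tgfb_inhibition
        elif role == "tgfb_low" and induced:
            base *= 1.0 - 0.6 * noise.tgfb_inhibition
        if sig_w > 0:
            base *= float(np.exp(rng.normal(0.0, sig_w)))
        intens[ch] = base
    if cells == 0:
        intens = {"ccl2": np.nan, "icam1": np.nan}
    return {"plate_id": plate_id, "row": row, "col": col, "role": role,
            "compound_id": cid, "concentration_um": dose if role == "compound" else 0.0,
            "cell_count": cells, "intensity_ccl2": intens["ccl2"],
            "intensity_icam1": intens["icam1"]}


# ---------------------------------------------------------------------------
# dose-response series
# ---------------------------------------------------------------------------

def simulate_dose_series(truth_curve: FourPL, doses, noise_cv: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Responses drawn log-normally around a 4PL curve at each dose.

    Zero noise reproduces the curve exactly.  Returns a DataFrame with
    columns ``dose, response``.
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ConfigError("empty dose list")
    if np.any(doses < 0):
        raise ConfigError("doses must be >= 0")
    rng = np.random.default_rng(seed)
    resp = truth_curve(doses).astype(float)
    if noise_cv > 0:
        sig = float(np.sqrt(np.log1p(noise_cv ** 2)))
        resp = resp * np.exp(rng.normal(0.0, sig, size=doses.shape))
    return pd.DataFrame({"dose": doses, "response": resp})


# ---------------------------------------------------------------------------
# bead-array panel
# ---------------------------------------------------------------------------

@dataclass
class CbaPanel:
    """Simulated bead-array run: standards, sample signals, and truth."""

    standards: pd.DataFrame   # analyte, conc_pgml, signal
    samples: pd.DataFrame     # analyte, condition, signal, cells
    truth: pd.DataFrame       # analyte, condition, true_conc_pgml, cells, true_per_cell


def simulate_cba_panel(
    true_conc,
    curves,
    cells: int | dict = 10_000,
    noise_cv: float = 0.0,
    seed: int = 0,
    standard_grid=CBA_STANDARD_GRID,
) -> CbaPanel:
    """Generate bead-array fluorescence through per-analyte standard curves.

    ``true_conc`` maps analyte -> {condition: pg/mL} (a bare number means a
    single ``"sample"`` condition).  ``curves`` maps analyte -> FourPL (a
    single curve is shared by all analytes).  Emits the 11 standard points
    on the 0-10,000 pg/mL grid per analyte plus sample signals generated
    through the curve, with the truth retained (including the per-cell
    normalized truth, pg/mL per 10^4 cells) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if isinstance(curves, FourPL):
        curves = {a: curves for a in true_conc}
    sig = float(np.sqrt(np.log1p(noise_cv ** 2))) if noise_cv > 0 else 0.0

    std_rows, sample_rows, truth_rows = [], [], []
    for analyte in sorted(true_conc):
        curve = curves[analyte]
        conds = true_conc[analyte]
        if not isinstance(conds, dict):
            conds = {"sample": conds}
        for c in standard_grid:
            s = float(curve(c))
            if sig > 0:
                s *= float(np.exp(rng.normal(0.0, sig)))
            std_rows.append({"analyte": analyte, "conc_pgml": c, "signal": s})
        for cond in sorted(conds):
            conc = float(conds[cond])
            if conc < 0:
                raise ConfigError(
                    f"true concentration must be >= 0 ({analyte}/{cond})")
            n_cells = cells[cond] if isinstance(cells, dict) else cells
            s = float(curve(conc))
            if sig > 0:
                s *= float(np.exp(rng.normal(0.0, sig)))
            sample_rows.append({"analyte": analyte, "condition": cond,
                                "signal": s, "cells": n_cells})
            truth_rows.append({"analyte": analyte, "condition": cond,
                               "true_conc_pgml": conc, "cells": n_cells,
                               "true_per_cell": conc * 10_000 / n_cells})
    return CbaPanel(standards=pd.DataFrame(std_rows),
                    samples=pd.DataFrame(sample_rows),
                    truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# membrane blots
# ---------------------------------------------------------------------------

def simulate_blot(
    n_analytes: int,
    duplicate: bool = True,
    reference_value: float = 50.0,
    effects=None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[SpotBlot, dict[str, float]]:
    """A membrane array with duplicate analyte spots and six reference spots.

    Analyte spot intensity = reference_value x effect x log-normal noise, so
    at zero noise the normalized readout equals the planted effect exactly,
    and multiplying the whole blot by any k > 0 leaves normalized values
    unchanged.  Returns ``(blot, effects)``.
    """
    if n_analytes < 1:
        raise ConfigError("need at least one analyte")
    if reference_value <= 0:
        raise ConfigError("reference_value must be > 0")
    rng = np.random.default_rng(seed)
    labels = [f"A{i:02d}" for i in range(1, n_analytes + 1)]
    if effects is None:
        effects = {lab: 1.0 for lab in labels}
    else:
        effects = {lab: float(effects.get(lab, 1.0)) for lab in labels}
    sig = float(np.sqrt(np.log1p(noise_cv ** 2))) if noise_cv > 0 else 0.0

    spot_labels = [SpotBlot.REFERENCE_LABEL] * SpotBlot.N_REFERENCE
    for lab in labels:
        spot_labels += [lab] * (2 if duplicate else 1)
    width = 10
    rows = []
    for i, lab in enumerate(spot_labels):
        value = reference_value * effects.get(lab, 1.0)
        if sig > 0:
            value *= float(np.exp(rng.normal(0.0, sig)))
        rows.append({"row": i // width, "col": i % width,
                     "label": lab, "intensity": value})
    return SpotBlot(pd.DataFrame(rows)), effects


def zero_noise(noise: NoiseModel | None = None) -> NoiseModel:
    """A copy of ``noise`` with plate and well noise switched off."""
    return replace(noise or NoiseModel(), plate_sigma=0.0, well_cv=0.0)
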