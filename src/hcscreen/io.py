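"""Data model and readers/writers for screen well tables.

The canonical interchange format is a long (tidy) CSV: one row per well,
columns ``plate_id,row,col,role,compound_id,concentration_um,cell_count,
intensity_ccl2,intensity_icam1``.  Wells are addressed by row letter (A-H)
plus 1-based column (1-12), the universal 96-well convention; the storage
key is ``(plate_id, row, col)``, never a flat well index.

``media_only`` wells are retained in files but excluded from every
downstream statistic.  A zero cell count makes per-cell intensity
meaningless: such wells get undefined (NaN) intensities and are flagged.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ControlCoverageError,
    IntegrityError,
    SchemaError,
)

ROLES = (
    "compound",
    "vehicle_stim",   # IL-1beta + DMSO: the normalization reference
    "vehicle_only",   # 0.01% BSA + DMSO: unstimulated negative control
    "tgfb_low",       # TGFbeta1 at 1 ng/mL
    "tgfb_high",      # TGFbeta1 at 10 ng/mL
    "media_only",
)

TIERS = ("primary", "secondary", "tertiary", "independence")

WELL_COLUMNS = [
    "plate_id", "row", "col", "role", "compound_id",
    "concentration_um", "cell_count", "intensity_ccl2", "intensity_icam1",
]

_ROW_LETTERS = "ABCDEFGH"


@dataclass(frozen=True)
class WellRecord:
    """One well: the screen's atomic observation.

    ``intensity_ccl2`` / ``intensity_icam1`` are integrated fluorescence per
    cell (arbitrary units); ``cell_count`` is the Hoechst-positive nucleus
    count for the well.
    """

    plate_id: str
    row: str
    col: int
    role: str
    compound_id: str = ""
    concentration_um: float = 0.0
    cell_count: int = 0
    intensity_ccl2: float = float("nan")
    intensity_icam1: float = float("nan")

    def __post_init__(self) -> None:
        if self.row not in _ROW_LETTERS:
            raise IntegrityError(f"row must be one of A-H, got {self.row!r}")
        if not 1 <= self.col <= 12:
            raise IntegrityError(f"col must be 1-12, got {self.col}")
        if self.role not in ROLES:
            raise IntegrityError(f"unknown role {self.role!r}")

    @property
    def well(self) -> str:
        return f"{self.row}{self.col}"


@dataclass(frozen=True)
class CompoundAnnotation:
    compound_id: str
    therapeutic_class: str


class ScreenDataset:
    """A validated collection of wells (one tier of the screen).

    Wells live in a :class:`pandas.DataFrame` with the canonical columns;
    ``annotations`` optionally maps compounds to therapeutic classes.
    Construction validates all dataset invariants and raises on violations,
    listing offending rows by ``plate/well``.
    """

    def __init__(
        self,
        wells: pd.DataFrame,
        annotations: pd.DataFrame | None = None,
        tier: str = "primary",
        require_controls: bool = True,
    ):
        if tier not in TIERS:
            raise IntegrityError(f"unknown tier {tier!r}")
        self.tier = tier
        self.wells = _validate_wells(wells, tier=tier, require_controls=require_controls)
        if annotations is not None:
            annotations = annotations.copy()
            missing = {"compound_id", "therapeutic_class"} - set(annotations.columns)
            if missing:
                raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
            if annotations["compound_id"].duplicated().any():
                dup = annotations.loc[annotations["compound_id"].duplicated(), "compound_id"]
                raise IntegrityError(f"duplicate compound annotations: {sorted(set(dup))}")
        self.annotations = annotations

    # -- convenience accessors -------------------------------------------
    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        mask = self.wells["role"] == "compound"
        return sorted(self.wells.loc[mask, "compound_id"].unique())

    def plate(self, plate_id: str) -> pd.DataFrame:
        out = self.wells[self.wells["plate_id"] == plate_id]
        if out.empty:
            raise KeyError(f"no plate {plate_id!r} in dataset")
        return out

    def __len__(self) -> int:
        return len(self.wells)

    @classmethod
    def from_records(
        cls,
        records,
        annotations=None,
        tier: str = "primary",
        require_controls: bool = True,
    ) -> "ScreenDataset":
        rows = [
            {
                "plate_id": r.plate_id, "row": r.row, "col": r.col, "role": r.role,
                "compound_id": r.compound_id, "concentration_um": r.concentration_um,
                "cell_count": r.cell_count, "intensity_ccl2": r.intensity_ccl2,
                "intensity_icam1": r.intensity_icam1,
            }
            for r in records
        ]
        ann = None
        if annotations is not None:
            ann = pd.DataFrame(
                [{"compound_id": a.compound_id, "therapeutic_class": a.therapeutic_class}
                 for a in annotations]
            )
        return cls(pd.DataFrame(rows, columns=WELL_COLUMNS), ann, tier=tier,
                   require_controls=require_controls)

    def to_csv(self, path) -> None:
        out = self.wells.copy()
        out.to_csv(path, index=False, float_format="%.17g")


def _validate_wells(wells: pd.DataFrame, tier: str, require_controls: bool) -> pd.DataFrame:
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise SchemaError(f"well table missing columns: {sorted(missing)}")
    wells = wells[WELL_COLUMNS].copy()
    wells["plate_id"] = wells["plate_id"].astype(str)
    wells["row"] = wells["row"].astype(str).str.strip().str.upper()
    wells["compound_id"] = wells["compound_id"].fillna("").astype(str)
    for c in ("col", "cell_count"):
        try:
            wells[c] = pd.to_numeric(wells[c]).astype(int)
        except (ValueError, TypeError) as e:
            raise SchemaError(f"column {c!r} is not integer-parseable: {e}") from e
    for c in ("concentration_um", "intensity_ccl2", "intensity_icam1"):
        try:
            wells[c] = pd.to_numeric(wells[c]).astype(float)
        except (ValueError, TypeError) as e:
            raise SchemaError(f"column {c!r} is not numeric: {e}") from e
    wells["concentration_um"] = wells["concentration_um"].fillna(0.0)

    problems: list[str] = []
    addr = wells["plate_id"] + "/" + wells["row"] + wells["col"].astype(str)

    bad_row = ~wells["row"].isin(list(_ROW_LETTERS))
    bad_col = ~wells["col"].between(1, 12)
    bad_role = ~wells["role"].isin(ROLES)
    for mask, what in ((bad_row, "row not in A-H"), (bad_col, "col not in 1-12"),
                       (bad_role, "unknown role")):
        for i in wells.index[mask]:
            problems.append(f"row {i}: {what} ({addr[i]})")

    is_cmp = wells["role"] == "compound"
    no_id = is_cmp & (wells["compound_id"] == "")
    stray_id = ~is_cmp & (wells["compound_id"] != "")
    stray_conc = ~is_cmp & (wells["concentration_um"] > 0)
    neg_conc = wells["concentration_um"] < 0
    zero_conc = is_cmp & (wells["concentration_um"] <= 0)
    neg_cells = wells["cell_count"] < 0
    for mask, what in (
        (no_id, "compound well without compound_id"),
        (stray_id, "non-compound well carries a compound_id"),
        (stray_conc, "non-compound well has concentration > 0"),
        (neg_conc, "negative concentration"),
        (zero_conc, "compound well needs concentration > 0"),
        (neg_cells, "negative cell count"),
    ):
        for i in wells.index[mask]:
            problems.append(f"row {i}: {what} ({addr[i]})")

    # per-cell intensity is undefined at zero cells: blank + flag, never an error
    zero_cells = wells["cell_count"] == 0
    wells.loc[zero_cells, ["intensity_ccl2", "intensity_icam1"]] = np.nan
    wells["flag_no_cells"] = zero_cells

    missing_int = (~zero_cells) & (
        wells["intensity_ccl2"].isna() | wells["intensity_icam1"].isna()
    )
    for i in wells.index[missing_int]:
        problems.append(f"row {i}: missing intensity with nonzero cell count ({addr[i]})")
    neg_int = (wells[["intensity_ccl2", "intensity_icam1"]] < 0).any(axis=1)
    for i in wells.index[neg_int]:
        problems.append(f"row {i}: negative intensity ({addr[i]})")
    if problems:
        raise IntegrityError("invalid well rows:\n  " + "\n  ".join(problems))

    dup = wells.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        keys = sorted(set(addr[dup]))
        raise IntegrityError(f"duplicate wells: {', '.join(keys)}")

    if require_controls:
        # the independence tier is run without IL-1beta and is normalized to
        # vehicle_only, so vehicle_stim wells are not required there
        required = ("vehicle_only",) if tier == "independence" else (
            "vehicle_stim", "vehicle_only")
        for plate_id, grp in wells.groupby("plate_id"):
            counts = grp["role"].value_counts()
            short = [r for r in required if counts.get(r, 0) < 2]
            if short:
                raise ControlCoverageError(
                    f"plate {plate_id} lacks >=2 wells of role(s) {short} "
                    "required for normalization")
    return wells.reset_index(drop=True)


def read_well_table(
    path,
    schema: dict[str, str] | None = None,
    tier: str = "primary",
    annotations: pd.DataFrame | None = None,
) -> ScreenDataset:
    """Read a long-format well CSV into a validated :class:`ScreenDataset`.

    Parameters
    ----------
    path : file path or buffer
    schema : optional mapping of file column names to canonical names,
        e.g. ``{"Plate": "plate_id"}``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns=schema)
    return ScreenDataset(df, annotations=annotations, tier=tier)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"compound_id", "therapeutic_class"} - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
    return df


def read_plate_matrix(path, plate_id: str, role_map: dict[str, str],
                      **kwargs) -> pd.DataFrame:
    """Convenience reader: melt an 8x12 plate matrix CSV (rows A-H, columns
    1-12, one value per well) into long rows for one measured quantity.

    Returns a long DataFrame ``plate_id,row,col,value``; roles/compound ids
    must be joined from ``role_map`` keyed by well address (e.g. ``"A1"``).
    """
    mat = pd.read_csv(path, index_col=0, **kwargs)
    long = mat.reset_index().melt(id_vars=mat.index.name or "index",
                                  var_name="col", value_name="value")
    long.columns = ["row", "col", "value"]
    long["col"] = long["col"].astype(int)
    long["plate_id"] = plate_id
    long["role"] = [role_map.get(f"{r}{c}", "media_only")
                    for r, c in zip(long["row"], long["col"])]
    return long[["plate_id", "row", "col", "role", "value"]]


# ---------------------------------------------------------------------------
# layout validation (report-only, never mutates)
# ---------------------------------------------------------------------------

@dataclass
class LayoutReport:
    control_counts: pd.DataFrame     # plate_id x role
    replicate_counts: pd.DataFrame   # compound_id, n_wells
    media_only_wells: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def complete_controls(self) -> bool:
        return not any(w.startswith("plate") for w in self.warnings)

    def __str__(self) -> str:
        lines = ["Layout validation"]
        lines.append(self.control_counts.to_string())
        if self.warnings:
            lines += ["warnings:"] + [f"  - {w}" for w in self.warnings]
        else:
            lines.append("complete controls")
        return "\n".join(lines)


# expected replicate wells per compound by tier (duplicate primary screen,
# triplicate confirmation; tertiary/independence run in duplicate per plate)
EXPECTED_REPLICATES = {"primary": 2, "secondary": 3, "tertiary": 2, "independence": 2}


def validate_layout(dataset: ScreenDataset) -> LayoutReport:
    """Report per-plate control coverage and per-compound replicate counts.

    Pure: the dataset is never mutated.  A compound present with fewer wells
    than its tier expects draws a warning, not an error.
    """
    wells = dataset.wells
    counts = (wells.groupby(["plate_id", "role"]).size()
              .unstack(fill_value=0).reindex(columns=list(ROLES), fill_value=0))
    warnings: list[str] = []
    required = ("vehicle_only",) if dataset.tier == "independence" else (
        "vehicle_stim", "vehicle_only")
    for plate_id, row in counts.iterrows():
        short = [r for r in required if row[r] < 2]
        if short:
            warnings.append(f"plate {plate_id}: fewer than 2 wells of {short}")

    cmp = wells[wells["role"] == "compound"]
    if dataset.tier == "tertiary":
        rep = (cmp.groupby(["compound_id", "concentration_um"]).size()
               .rename("n_wells").reset_index())
        group_desc = rep["compound_id"] + " @ " + rep["concentration_um"].astype(str) + " uM"
    else:
        rep = cmp.groupby("compound_id").size().rename("n_wells").reset_index()
        group_desc = rep["compound_id"]
    expected = EXPECTED_REPLICATES[dataset.tier]
    word = {2: "duplicate", 3: "triplicate"}.get(expected, f"{expected} replicates")
    for desc, n in zip(group_desc, rep["n_wells"]):
        if n < expected:
            warnings.append(f"compound {desc}: expected {word}, found {n} well(s)")

    media = wells[wells["role"] == "media_only"]
    media_wells = sorted(media["plate_id"] + "/" + media["row"] + media["col"].astype(str))
    return LayoutReport(control_counts=counts, replicate_counts=rep,
                        media_only_wells=media_wells, warnings=warnings)


# ---------------------------------------------------------------------------
# funnel report writer
# ---------------------------------------------------------------------------

TIER_REPORT_COLUMNS = [
    "compound_id", "mean_ccl2", "mean_icam1", "percent_change_ccl2",
    "percent_change_icam1", "cv_ccl2", "cv_icam1", "cell_ratio",
    "verdict", "reason",
]


def write_funnel_report(results: dict[str, pd.DataFrame], path,
                        n_screened: int | None = None) -> str:
    """Write per-tier CSVs plus a plain-text funnel summary.

    ``results`` maps tier name to a tier-summary table (the output of the
    funnel filters).  ``path`` is a directory; it is created if needed.
    Returns the summary text.  The reference shape of the original study's
    funnel was 1280 screened -> 82 primary -> 44 secondary -> 10 shortlisted.
    """
    if not results:
        raise ValueError("need results from at least one tier")
    os.makedirs(path, exist_ok=True)
    lines = ["Screen funnel summary"]
    if n_screened is not None:
        lines.append(f"  screened: {n_screened}")
    for tier, df in results.items():
        cols = [c for c in TIER_REPORT_COLUMNS if c in df.columns]
        extra = [c for c in df.columns if c not in cols]
        out = df[cols + extra].sort_values(
            list(df.columns[:1])).reset_index(drop=True)
        out.to_csv(os.path.join(path, f"{tier}.csv"), index=False,
                   float_format="%.17g")
        if "verdict" in df.columns:
            n_hits = int(df["verdict"].isin(["hit_up", "hit_down"]).sum())
            lines.append(f"  {tier}: {len(df)} evaluated, {n_hits} hits")
        else:
            lines.append(f"  {tier}: {len(df)} compounds")
    text = "\n".join(lines) + "\n"
    with open(os.path.join(path, "summary.txt"), "w") as fh:
        fh.write(text)
    return text


def funnel_counts(results: dict[str, pd.DataFrame]) -> dict[str, int]:
    """Hit count per tier (``hit_up`` + ``hit_down`` verdicts)."""
    out = {}
    for tier, df in results.items():
        if "verdict" in df.columns:
            out[tier] = int(df["verdict"].isin(["hit_up", "hit_down"]).sum())
        else:
            out[tier] = len(df)
    return out
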