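"""Domain types, validation and CSV I/O for survey, habitat and range data.

The survey design is hierarchical: plots nested in settlements nested in
regions.  Each plot carries a land-use category (paddy field is the baseline,
dry crop field and built-up area are dummy-coded), an abandonment status
inherited from its settlement, the settlement's years since abandonment
(0 for inhabited settlements), a mean annual temperature (MAT, degC) and the
survey month (May-August).  Occupancy is a species x plot binary matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical habitat-preference columns, fixed order.
HABITAT_TYPES = [
    "forest",
    "forest_edge",
    "open_forest",
    "grassland",
    "crop_field",
    "garden",
    "built_up",
    "river",
    "wetland",
    "alpine",
    "rocky",
]

LAND_USES = ["paddy", "dry_field", "built_up"]

SURVEY_COLUMNS = [
    "plot_id",
    "region_id",
    "settlement_id",
    "land_use",
    "abandoned",
    "years_since_abandonment",
    "mat",
    "month",
]


class SchemaError(ValueError):
    """A required column is missing or an unknown column is present."""


class ConsistencyError(ValueError):
    """Cross-field invariant violated (e.g. settlement in two regions)."""


@dataclass
class SurveyTable:
    """Plot-level covariates plus a species x plot presence/absence matrix.

    Parameters
    ----------
    plots
        One row per plot with the columns in :data:`SURVEY_COLUMNS`.
    occupancy
        Binary DataFrame indexed by species id, columns = plot ids in the
        same order as ``plots['plot_id']``.
    """

    plots: pd.DataFrame
    occupancy: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_species(self) -> int:
        return len(self.occupancy)

    @property
    def species(self) -> list[str]:
        return list(self.occupancy.index)

    def occupancy_matrix(self) -> np.ndarray:
        """Species x plot 0/1 matrix as int array (Y_ij)."""
        return self.occupancy.to_numpy(dtype=int)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.plots.columns]
        if missing:
            raise SchemaError(f"survey table missing columns: {missing}")
        problems = self.violations()
        if problems:
            raise ConsistencyError("; ".join(problems))

    def violations(self) -> list[str]:
        """All invariant violations (empty list if valid)."""
        p = self.plots
        out: list[str] = []
        if p["plot_id"].duplicated().any():
            dup = p.loc[p["plot_id"].duplicated(), "plot_id"].iloc[0]
            out.append(f"duplicate plot_id {dup!r}")
        bad_lu = set(p["land_use"]) - set(LAND_USES)
        if bad_lu:
            out.append(f"unknown land_use values: {sorted(bad_lu)}")
        regions_per_set = p.groupby("settlement_id")["region_id"].nunique()
        multi = regions_per_set[regions_per_set > 1]
        if len(multi):
            out.append(
                f"settlement(s) mapped to multiple regions: {list(multi.index)}"
            )
        aban_per_set = p.groupby("settlement_id")["abandoned"].nunique()
        mixed = aban_per_set[aban_per_set > 1]
        if len(mixed):
            out.append(
                f"settlement(s) with mixed abandoned flags: {list(mixed.index)}"
            )
        if not p["abandoned"].isin([0, 1]).all():
            out.append("abandoned must be 0/1")
        years = p["years_since_abandonment"]
        if (years < 0).any():
            out.append("years_since_abandonment must be >= 0")
        incons = (years > 0) != (p["abandoned"] == 1)
        if incons.any():
            rows = p.index[incons].tolist()[:5]
            out.append(
                "years_since_abandonment > 0 iff abandoned = 1 violated at "
                f"rows {rows}"
            )
        if not p["month"].between(1, 12).all():
            out.append("month must be a calendar month integer")
        for col in ("mat", "month", "years_since_abandonment"):
            if p[col].isna().any():
                out.append(f"missing values in {col}")
        occ = self.occupancy.to_numpy()
        if not np.isin(occ, [0, 1]).all():
            bad = np.argwhere(~np.isin(occ, [0, 1]))[0]
            out.append(
                f"non-binary occupancy value at species "
                f"{self.occupancy.index[bad[0]]!r}, plot "
                f"{self.occupancy.columns[bad[1]]!r}"
            )
        if list(self.occupancy.columns) != list(p["plot_id"]):
            out.append("occupancy columns do not match plot_id order")
        return out


@dataclass
class HabitatMatrix:
    """Species x 11 binary habitat-preference matrix H_ik plus red-list flag."""

    H: pd.DataFrame  # index = species_id, columns = HABITAT_TYPES
    red_list: pd.Series  # 0/1 per species

    def __post_init__(self) -> None:
        extra = [c for c in self.H.columns if c not in HABITAT_TYPES]
        if extra:
            raise SchemaError(f"unknown habitat column(s): {extra}")
        missing = [c for c in HABITAT_TYPES if c not in self.H.columns]
        if missing:
            raise SchemaError(f"missing habitat column(s): {missing}")
        self.H = self.H[HABITAT_TYPES]
        vals = self.H.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("habitat matrix entries must be 0/1")
        empty = self.H.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"species with no habitat type: {list(self.H.index[empty])}"
            )
        self.red_list = self.red_list.reindex(self.H.index).fillna(0).astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.H.index)

    def matrix(self) -> np.ndarray:
        return self.H.to_numpy(dtype=float)


@dataclass
class RangeStack:
    """Cell x species binary presence stack with optional coordinates."""

    presence: pd.DataFrame  # index = cell_id, columns = species_id
    coords: pd.DataFrame | None = None  # optional lon/lat/elevation per cell

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("range-stack presence entries must be 0/1")
        if self.coords is not None:
            self.coords = self.coords.reindex(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_cells(self) -> int:
        return len(self.presence)


@dataclass
class DesignInputs:
    """Model design arrays built from a :class:`SurveyTable`.

    ``x`` columns are (aban, temp, month, lu_dry, lu_built); group index
    arrays are dense 0-based codes for region, settlement and
    settlement x land-use combination.  ``scaling_record`` holds the
    (center, scale) applied to each standardized covariate so natural-unit
    values round-trip exactly.
    """

    aban: np.ndarray
    temp: np.ndarray
    month: np.ndarray
    lu_dry: np.ndarray
    lu_built: np.ndarray
    region_idx: np.ndarray
    settlement_idx: np.ndarray
    lu_group_idx: np.ndarray
    n_regions: int
    n_settlements: int
    n_lu_groups: int
    aban_coding: str
    scaling_record: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        """Plot x 5 covariate matrix in (aban, temp, month, dry, built) order."""
        return np.column_stack(
            [self.aban, self.temp, self.month, self.lu_dry, self.lu_built]
        )

    @property
    def n_plots(self) -> int:
        return len(self.aban)

    def unstandardize(self, name: str, values: np.ndarray) -> np.ndarray:
        center, scale = self.scaling_record.get(name, (0.0, 1.0))
        return values * scale + center


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def load_survey(path, species_prefix: str = "sp_") -> SurveyTable:
    """Read a plot-level survey CSV.

    Wide layout (canonical): one row per plot, occupancy in one column per
    species named ``<species_prefix><species_id>``.  Long layout is also
    accepted (columns ``species_id`` and ``presence``, one row per
    plot x species) and pivoted to wide on load.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey CSV missing column(s): {missing}")
    if {"species_id", "presence"}.issubset(df.columns):
        occ = (
            df.pivot_table(index="species_id", columns="plot_id",
                           values="presence", fill_value=0)
            .astype(int)
        )
        plots = df.drop_duplicates("plot_id")[SURVEY_COLUMNS].reset_index(
            drop=True
        )
        occ = occ[plots["plot_id"]]
        occ.index.name = None
        occ.columns = plots["plot_id"]
        return SurveyTable(plots=plots, occupancy=occ)
    sp_cols = [c for c in df.columns if c.startswith(species_prefix)]
    if not sp_cols:
        raise SchemaError(
            f"no species columns found with prefix {species_prefix!r}"
        )
    occ = df[sp_cols].T
    occ.index = [c[len(species_prefix):] for c in sp_cols]
    occ.columns = df["plot_id"]
    return SurveyTable(plots=df[SURVEY_COLUMNS].copy(), occupancy=occ)


def write_survey(table: SurveyTable, path, species_prefix: str = "sp_") -> None:
    df = table.plots.copy()
    occ = table.occupancy.T.reset_index(drop=True)
    for sp in table.species:
        df[f"{species_prefix}{sp}"] = occ[sp].to_numpy()
    df.to_csv(path, index=False)


def load_habitats(path) -> HabitatMatrix:
    """Read a species x habitat CSV with the 11 canonical columns."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise SchemaError("habitat CSV missing 'species_id' column")
    df = df.set_index("species_id")
    df.index.name = None
    red = df.pop("red_list") if "red_list" in df.columns else pd.Series(
        0, index=df.index
    )
    return HabitatMatrix(H=df, red_list=red)


def write_habitats(hab: HabitatMatrix, path) -> None:
    df = hab.H.copy()
    df["red_list"] = hab.red_list
    df.to_csv(path, index_label="species_id")


def load_range_stack(path) -> RangeStack:
    """Read a range-stack CSV; accepts wide (cell x species) or long format.

    Long format needs columns (cell_id, species_id, presence); wide format
    needs cell_id plus one column per species, with optional lon/lat/elevation.
    """
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise SchemaError("range-stack CSV missing 'cell_id' column")
    if {"species_id", "presence"}.issubset(df.columns):
        presence = (
            df.pivot_table(
                index="cell_id", columns="species_id", values="presence",
                fill_value=0,
            )
            .astype(int)
        )
        coord_cols = [c for c in ("lon", "lat", "elevation") if c in df.columns]
        coords = (
            df.drop_duplicates("cell_id").set_index("cell_id")[coord_cols]
            if coord_cols else None
        )
        presence.index.name = None
        presence.columns.name = None
        if coords is not None:
            coords.index.name = None
        return RangeStack(presence=presence, coords=coords)
    df = df.set_index("cell_id")
    df.index.name = None
    coord_cols = [c for c in ("lon", "lat", "elevation") if c in df.columns]
    coords = df[coord_cols] if coord_cols else None
    presence = df.drop(columns=coord_cols)
    return RangeStack(presence=presence, coords=coords)


def write_range_stack(stack: RangeStack, path) -> None:
    df = stack.presence.copy()
    if stack.coords is not None:
        for c in stack.coords.columns:
            df[c] = stack.coords[c]
    df.to_csv(path, index_label="cell_id")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _dense_codes(values: pd.Series) -> tuple[np.ndarray, int]:
    # sorted-label assignment keeps codes invariant to row order
    cats = pd.Categorical(values, categories=sorted(values.unique()))
    return cats.codes.astype(int), len(cats.categories)


def build_design(
    table: SurveyTable,
    aban_coding: str = "binary",
    standardize: bool = True,
) -> DesignInputs:
    """Dummy-code covariates and group indices for the occurrence model.

    ``aban_coding`` selects between the two candidate abandonment variables:
    ``"binary"`` (abandoned or not) and ``"years"`` (years since abandonment,
    0 for inhabited settlements).  With ``standardize=True`` the continuous
    covariates (temperature, month, and years under the years coding) are
    centered and scaled; the transform is recorded.
    """
    if aban_coding not in ("binary", "years"):
        raise ValueError(f"unknown aban_coding {aban_coding!r}")
    p = table.plots
    scaling: dict[str, tuple[float, float]] = {}

    def _std(name: str, raw: np.ndarray) -> np.ndarray:
        center = float(raw.mean())
        scale = float(raw.std(ddof=0))
        if scale == 0.0:
            scale = 1.0
        scaling[name] = (center, scale)
        return (raw - center) / scale

    if aban_coding == "binary":
        aban = p["abandoned"].to_numpy(dtype=float)
    else:
        aban = p["years_since_abandonment"].to_numpy(dtype=float)
        if standardize:
            aban = _std("aban", aban)
    temp = p["mat"].to_numpy(dtype=float)
    month = p["month"].to_numpy(dtype=float)
    if standardize:
        temp = _std("temp", temp)
        month = _std("month", month)

    lu_dry = (p["land_use"] == "dry_field").to_numpy(dtype=float)
    lu_built = (p["land_use"] == "built_up").to_numpy(dtype=float)

    region_idx, n_regions = _dense_codes(p["region_id"])
    settlement_idx, n_settlements = _dense_codes(p["settlement_id"])
    lu_combo = p["settlement_id"].astype(str) + "::" + p["land_use"].astype(str)
    lu_group_idx, n_lu_groups = _dense_codes(lu_combo)

    return DesignInputs(
        aban=aban,
        temp=temp,
        month=month,
        lu_dry=lu_dry,
        lu_built=lu_built,
        region_idx=region_idx,
        settlement_idx=settlement_idx,
        lu_group_idx=lu_group_idx,
        n_regions=n_regions,
        n_settlements=n_settlements,
        n_lu_groups=n_lu_groups,
        aban_coding=aban_coding,
        scaling_record=scaling,
    )
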