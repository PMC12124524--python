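"""Data model and I/O for plate-based morphological screens.

The central object is the :class:`WellFeatureTable`: a tidy wide table with one
row per observation (cell, well, or donor-drug aggregate), a fixed block of
metadata columns, and one numeric column per morphological feature.  Wells
treated with the carrier control (``drug_id == "DMSO"``) define the null
phenotype used by all downstream normalization.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import pandas as pd

#: Mandatory metadata columns, in canonical on-disk order.
META_COLUMNS = [
    "run_id",
    "plate_id",
    "well",
    "donor_id",
    "drug_id",
    "dose_uM",
    "bioreplicate",
    "tech_replicate",
    "n_cells",
]

#: Drug label of carrier-control wells.
CONTROL_DRUG = "DMSO"

LEVELS = ("cell", "well", "donor_drug")

#: Grouping keys that define uniqueness / aggregation at each level.
GROUP_KEYS = {
    "well": ["run_id", "plate_id", "well"],
    "donor_drug": ["run_id", "donor_id", "drug_id"],
}

PLATE_ROWS = string.ascii_uppercase[:16]  # 384-well: rows A-P x columns 1-24
PLATE_COLS = 24


class SchemaError(ValueError):
    """A mandatory metadata column is missing or malformed."""


class TableIntegrityError(ValueError):
    """Table content violates a structural invariant (e.g. duplicate wells)."""


def well_name(index: int) -> str:
    """Row-major well label on a 384-well plate: 0 -> 'A01', 24 -> 'B01'."""
    if not 0 <= index < len(PLATE_ROWS) * PLATE_COLS:
        raise ValueError(f"well index {index} outside 384-well plate")
    row, col = divmod(index, PLATE_COLS)
    return f"{PLATE_ROWS[row]}{col + 1:02d}"


@dataclass
class LoadReport:
    n_records: int = 0
    n_features: int = 0
    n_coerced_missing: int = 0


@dataclass
class WellFeatureTable:
    """Wells x features matrix plus plate/well/donor/drug metadata.

    ``data`` holds META_COLUMNS followed by one numeric column per feature;
    ``feature_names`` fixes the feature order; ``level`` records the
    granularity of each row.
    """

    data: pd.DataFrame
    feature_names: list[str]
    level: str = "well"
    load_report: LoadReport | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.feature_names = list(self.feature_names)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing mandatory metadata columns: {missing}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise TableIntegrityError("duplicate feature names")
        absent = [f for f in self.feature_names if f not in self.data.columns]
        if absent:
            raise SchemaError(f"feature columns absent from data: {absent[:5]}")
        if self.level == "well":
            dup = self.data.duplicated(subset=GROUP_KEYS["well"])
            if dup.any():
                bad = self.data.loc[dup, GROUP_KEYS["well"]].iloc[0].tolist()
                raise TableIntegrityError(
                    f"duplicate (run_id, plate_id, well) record: {bad}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        """Feature block as a DataFrame (rows aligned with metadata)."""
        return self.data[self.feature_names]

    @property
    def is_control(self) -> pd.Series:
        return self.data["drug_id"] == CONTROL_DRUG

    def subset_features(self, features: list[str]) -> "WellFeatureTable":
        keep = [f for f in self.feature_names if f in set(features)]
        return WellFeatureTable(
            self.data[META_COLUMNS + keep].copy(), keep, level=self.level
        )

    def copy(self) -> "WellFeatureTable":
        return WellFeatureTable(
            self.data.copy(), list(self.feature_names), level=self.level
        )

    # -- I/O ----------------------------------------------------------------
    def write_csv(self, path, float_format: str = "%.10g") -> None:
        cols = META_COLUMNS + self.feature_names
        self.data[cols].to_csv(path, index=False, float_format=float_format)


def read_feature_table(
    path,
    schema: dict[str, str] | None = None,
    level: str = "well",
) -> WellFeatureTable:
    """Read a wide CSV/TSV feature table.

    ``schema`` maps canonical metadata names to the file's column names, e.g.
    ``{"drug_id": "compound"}``.  Every non-metadata column is treated as a
    feature; non-numeric feature cells are coerced to missing and counted in
    the attached :class:`LoadReport`.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    rename = {}
    if schema:
        rename = {src: canonical for canonical, src in schema.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in META_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory metadata columns: {missing}")
    raw["dose_uM"] = raw["dose_uM"].astype(float)
    for col in ("bioreplicate", "tech_replicate", "n_cells"):
        raw[col] = raw[col].astype(int)
    feature_names = [c for c in raw.columns if c not in META_COLUMNS]
    n_coerced = 0
    for col in feature_names:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            n_coerced += int(coerced.isna().sum() - raw[col].isna().sum())
            raw[col] = coerced
    table = WellFeatureTable(raw, feature_names, level=level)
    table.load_report = LoadReport(len(raw), len(feature_names), n_coerced)
    return table


def aggregate(
    table: WellFeatureTable,
    to_level: str,
    statistic: str = "median",
) -> WellFeatureTable:
    """Collapse a table to a coarser level (cell->well or well->donor_drug).

    Features take the per-group ``statistic`` (median by default, robust to
    outlier cells); ``n_cells`` is summed.  Aggregating a table to its own
    level returns it unchanged.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be median or mean, got {statistic!r}")
    if to_level == table.level:
        return table.copy()
    order = {lvl: i for i, lvl in enumerate(LEVELS)}
    if order[to_level] < order[table.level]:
        raise ValueError(f"cannot disaggregate {table.level} to {to_level}")
    keys = GROUP_KEYS[to_level]
    if table.n_rows == 0:
        raise ValueError("cannot aggregate an empty table")

    grouped = table.data.groupby(keys, sort=True)
    feats = grouped[table.feature_names].agg(statistic)
    n_cells = grouped["n_cells"].sum()
    meta_cols = [c for c in META_COLUMNS if c not in keys and c != "n_cells"]
    meta = grouped[meta_cols].first()
    if to_level == "donor_drug":
        # plate/replicate identity is dissolved at this level
        meta["plate_id"] = "*"
        meta["well"] = "*"
        meta["bioreplicate"] = 0
        meta["tech_replicate"] = 0
    out = pd.concat([meta, n_cells, feats], axis=1).reset_index()
    out = out[META_COLUMNS + table.feature_names]
    return WellFeatureTable(out, list(table.feature_names), level=to_level)


@dataclass
class RunManifest:
    """Declared design of one assay run (donor panel x drug panel)."""

    run_id: str
    donors: list[str]
    drugs: dict[str, float]  # drug_id -> dose (uM); may include the control
    n_plates: int | None = None
    imaging_system: str = ""

    def validate(self) -> None:
        if not self.donors:
            raise ValueError("manifest has no donors")
        if len(set(self.donors)) != len(self.donors):
            raise ValueError("duplicate donor ids in manifest")
        if not self.drugs:
            raise ValueError("manifest has no drugs")


def count_pairs(manifest: RunManifest) -> int:
    """Number of drug-donor pairs: |donors| x |drugs excluding the control|."""
    manifest.validate()
    n_drugs = sum(1 for d in manifest.drugs if d != CONTROL_DRUG)
    return len(manifest.donors) * n_drugs


def observed_pairs(table: WellFeatureTable) -> int:
    """Distinct (donor, drug != control) combinations present in a table."""
    mask = ~table.is_control
    return int(
        table.data.loc[mask, ["donor_id", "drug_id"]].drop_duplicates().shape[0]
    )
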