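"""Unit-level biomarker table: the container every pipeline stage consumes.

The statistical unit is a replicate-aquarium mean, not an individual animal,
which avoids pseudo-replication of crabs held in the same tank.  A dataset is
a tidy table with one row per unit: an id, the exposure treatment, the
exposure time in days, and the nine-biomarker vector.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

#: Canonical biomarker battery: acetylcholinesterase in thoracic ganglion and
#: muscle, lactate / isocitrate dehydrogenase in muscle, glutathione
#: S-transferases and lipid peroxidation in digestive gland and gills, and
#: glutathione peroxidase in the digestive gland.
BIOMARKERS: tuple[str, ...] = (
    "AChEg", "AChEm", "LDH", "IDH", "GSTdg", "GSTgl", "GPx", "LPOdg", "LPOgl",
)

META_COLUMNS: tuple[str, ...] = ("unit_id", "treatment", "time_days")

GROUP_COLUMN = "group"
CONTROL_LABEL = "control"


class DatasetError(ValueError):
    """Raised when a biomarker table violates the unit-level data contract."""


@dataclass
class BiomarkerDataset:
    """Tidy unit-level table of design factors plus the biomarker vector.

    Parameters
    ----------
    table:
        DataFrame with columns ``unit_id, treatment, time_days`` followed by
        one column per biomarker.  One row per statistical unit; no missing
        biomarker values.
    biomarker_names:
        Ordered biomarker columns; defaults to the nine-marker battery.
    units_of_measure:
        Optional free-form metadata (biomarker -> unit string).
    """

    table: pd.DataFrame
    biomarker_names: tuple[str, ...] = BIOMARKERS
    units_of_measure: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.biomarker_names = tuple(self.biomarker_names)
        missing = [c for c in (*META_COLUMNS, *self.biomarker_names)
                   if c not in self.table.columns]
        if missing:
            raise DatasetError(f"dataset missing column(s): {', '.join(missing)}")
        block = self.table[list(self.biomarker_names)]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise DatasetError(f"missing biomarker values in column(s): {bad}")
        for col in self.biomarker_names:
            if not pd.api.types.is_numeric_dtype(self.table[col]):
                raise DatasetError(f"non-numeric biomarker column: {col}")
        if self.table["unit_id"].duplicated().any():
            dup = self.table.loc[self.table["unit_id"].duplicated(), "unit_id"]
            raise DatasetError(f"duplicate unit_id(s): {sorted(set(dup))}")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def values(self):
        """Unit x biomarker value matrix (numpy view)."""
        return self.table[list(self.biomarker_names)].to_numpy(float)

    @property
    def has_grouping(self) -> bool:
        return GROUP_COLUMN in self.table.columns

    @property
    def groups(self) -> pd.Series:
        if not self.has_grouping:
            raise DatasetError("dataset has no pooled-control grouping; "
                               "call pool_controls() first")
        return self.table[GROUP_COLUMN]

    def copy(self) -> "BiomarkerDataset":
        return BiomarkerDataset(self.table.copy(), self.biomarker_names,
                                dict(self.units_of_measure))

    # -- I/O -------------------------------------------------------------------

    def to_csv(self, path_or_buf=None) -> str | None:
        cols = [*META_COLUMNS,
                *( [GROUP_COLUMN] if self.has_grouping else [] ),
                *self.biomarker_names]
        return self.table[cols].to_csv(path_or_buf, index=False)


def read_dataset(path_or_buf, biomarker_names: tuple[str, ...] = BIOMARKERS,
                 sep: str | None = None) -> BiomarkerDataset:
    """Read a unit-level biomarker CSV/TSV.

    The header must contain ``unit_id,treatment,time_days`` plus one column per
    biomarker; decimal point dialect.  Row order is preserved.  Errors name the
    offending column or row.
    """
    if sep is None:
        sep = _sniff_sep(path_or_buf)
    df = pd.read_csv(path_or_buf, sep=sep, float_precision="round_trip")
    for col in biomarker_names:
        if col not in df.columns:
            raise DatasetError(f"input file is missing biomarker column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise DatasetError(
                f"non-numeric or missing value in column {col!r} at row {row}")
        df[col] = coerced
    return BiomarkerDataset(df, biomarker_names)


def _sniff_sep(path_or_buf) -> str:
    try:
        if hasattr(path_or_buf, "read"):
            pos = path_or_buf.tell()
            head = path_or_buf.readline()
            path_or_buf.seek(pos)
        else:
            with open(path_or_buf) as fh:
                head = fh.readline()
    except OSError as exc:  # pragma: no cover - filesystem failure
        raise DatasetError(str(exc)) from exc
    return "\t" if "\t" in head else ","


def write_dataset(dataset: BiomarkerDataset, path) -> None:
    dataset.to_csv(path)


def round_trip_text(dataset: BiomarkerDataset) -> str:
    """Serialize to CSV text (used for byte-level reproducibility checks)."""
    buf = io.StringIO()
    dataset.to_csv(buf)
    return buf.getvalue()
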