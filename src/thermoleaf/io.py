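"""Reading and writing per-pixel thermal temperature grids and sample manifests.

A radiometric thermal image is stored as a plain CSV of H rows by W columns,
each cell a surface temperature in degrees Celsius (the export format of
common thermal-camera desktop software). Because such exports vary by locale,
a small :class:`CsvDialect` controls the cell delimiter and the decimal mark.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CsvDialect",
    "ThermalFrame",
    "SampleManifest",
    "ThermalFormatError",
    "ThermalValidationError",
    "ManifestError",
    "parse_thermal_csv",
    "write_thermal_csv",
    "load_manifest",
]

MIN_SIDE = 8  # smallest grid on which the FFT/gradient stages are meaningful

TREATMENTS = ("WW", "DD", "unknown")
TIMEPOINTS = ("predawn", "midday", "unknown")
DROUGHT_STAGES = ("mild", "severe", "none", "unknown")


class ThermalFormatError(ValueError):
    """Structural problem in a thermal CSV (ragged rows, non-numeric cells)."""


class ThermalValidationError(ValueError):
    """Parsed grid violates the physical-plausibility contract."""


class ManifestError(ValueError):
    """Malformed sample manifest."""


@dataclass(frozen=True)
class CsvDialect:
    """Cell delimiter and decimal mark of a thermal CSV export.

    Defaults match the plain international export: comma-delimited cells,
    ``.`` decimal mark, no header. European locale exports use ``;`` between
    cells and ``,`` as the decimal mark.
    """

    delimiter: str = ","
    decimal: str = "."
    skip_header_lines: int = 0

    def __post_init__(self) -> None:
        if self.delimiter == self.decimal:
            raise ValueError("delimiter and decimal mark must differ")


@dataclass
class ThermalFrame:
    """A 2D grid of per-pixel leaf/backdrop temperatures in °C plus metadata.

    ``values`` is row-major with row index running top to bottom and column
    index left to right; no flips are applied on input or output.
    """

    values: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ThermalValidationError(
                f"thermal grid must be 2D, got ndim={self.values.ndim}"
            )
        meta = {
            "genotype": "unknown",
            "treatment": "unknown",
            "timepoint": "unknown",
            "drought_stage": "unknown",
        }
        meta.update(self.metadata)
        self.metadata = meta

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def validate(
        self,
        temp_range: tuple[float, float] | None = (-40.0, 120.0),
        min_side: int | None = None,
    ) -> "ThermalFrame":
        """Check finiteness, the plausible temperature range, and (when
        ``min_side`` is given) the minimum grid size the FFT/gradient stages
        need — that check is also enforced at the filtering stage itself."""
        h, w = self.values.shape
        if h == 0 or w == 0:
            raise ThermalValidationError("empty thermal grid")
        if min_side is not None and (h < min_side or w < min_side):
            raise ThermalValidationError(
                f"grid {h}x{w} below minimum {min_side}x{min_side}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ThermalValidationError(
                f"non-finite temperature at row {bad[0]}, col {bad[1]}"
            )
        if temp_range is not None:
            lo, hi = temp_range
            if self.values.min() < lo or self.values.max() > hi:
                raise ThermalValidationError(
                    f"temperatures outside plausible range [{lo}, {hi}] °C: "
                    f"min={self.values.min():.2f}, max={self.values.max():.2f}"
                )
        return self


def parse_thermal_csv(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    sample_id: str | None = None,
    metadata: Mapping | None = None,
    temp_range: tuple[float, float] | None = (-40.0, 120.0),
) -> ThermalFrame:
    """Parse a thermal CSV grid into a validated :class:`ThermalFrame`.

    Raises
    ------
    ThermalFormatError
        Ragged rows or non-numeric cells (with coordinates).
    ThermalValidationError
        Grid too small, non-finite, or outside ``temp_range`` (pass
        ``temp_range=None`` to disable the range check).
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for i, raw in enumerate(reader):
            if i < dialect.skip_header_lines:
                continue
            if not raw or (len(raw) == 1 and raw[0].strip() == ""):
                continue  # blank line
            parsed_row = []
            for j, cell in enumerate(raw):
                text = cell.strip()
                if dialect.decimal != ".":
                    text = text.replace(dialect.decimal, ".")
                try:
                    parsed_row.append(float(text))
                except ValueError:
                    raise ThermalFormatError(
                        f"{path}: non-numeric cell {cell!r} at row {i}, col {j}"
                    ) from None
            rows.append(parsed_row)
    if not rows:
        raise ThermalFormatError(f"{path}: no data rows")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ThermalFormatError(
                f"{path}: ragged row {i}: expected {width} cells, got {len(r)}"
            )
    frame = ThermalFrame(
        np.asarray(rows, dtype=float),
        sample_id=sample_id if sample_id is not None else path.stem,
        metadata=dict(metadata or {}),
    )
    return frame.validate(temp_range)


def write_thermal_csv(
    frame: ThermalFrame, path: str | Path, dialect: CsvDialect = CsvDialect()
) -> Path:
    """Write a frame as a thermal CSV; round-trips through
    :func:`parse_thermal_csv` to within 1e-6 °C."""
    frame.validate(temp_range=None)
    path = Path(path)
    with path.open("w", newline="") as fh:
        for row in frame.values:
            cells = [format(v, ".6f") for v in row]
            if dialect.decimal != ".":
                cells = [c.replace(".", dialect.decimal) for c in cells]
            fh.write(dialect.delimiter.join(cells) + "\n")
    return path


MANIFEST_COLUMNS = [
    "sample_id",
    "path",
    "genotype",
    "treatment",
    "timepoint",
    "drought_stage",
    "replicate",
]

_TREATMENT_ALIASES = {"WW": "WW", "DD": "DD"}


@dataclass
class SampleManifest:
    """Table of samples: id, thermal-CSV path, genotype, treatment labels."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        ids = self.table["sample_id"]
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ManifestError(f"duplicate sample_id values: {dup}")
        bad = sorted(
            set(self.table["treatment"]) - set(_TREATMENT_ALIASES.values())
        )
        if bad:
            raise ManifestError(f"unknown treatment tokens: {bad}")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def load_manifest(path: str | Path) -> SampleManifest:
    """Load and validate a sample manifest CSV.

    Treatments are normalized to the canonical {WW, DD} tokens
    (case-insensitive); anything else is rejected with the offending token.
    """
    table = pd.read_csv(path, dtype=str).fillna("unknown")
    if "treatment" in table.columns:
        norm = table["treatment"].str.strip().str.upper()
        unknown = sorted(set(norm) - set(_TREATMENT_ALIASES))
        if unknown:
            raise ManifestError(
                f"unknown treatment tokens in {path}: {unknown} "
                f"(expected one of {sorted(_TREATMENT_ALIASES)})"
            )
        table = table.assign(treatment=norm.map(_TREATMENT_ALIASES))
    return SampleManifest(table)


def write_manifest(manifest: SampleManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, index=False)
    return path
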