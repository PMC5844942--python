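"""Image and plate-metadata I/O.

Defines the shared data model for a two-channel high-content field (a nuclear
"Hoechst-like" channel and an extracellular-DNA "Sytox-like" channel) and the
plate layout table that maps wells to experimental conditions, compounds,
doses and timepoints.

File convention: one grayscale TIFF per field per channel, named
``<plate>_<well>_f<field>_<ch>.tif`` with ``ch`` in ``{nuc, dna}``.
Intensities are stored as 16-bit unsigned integers; the nominal dynamic range
is 12-bit (0-4095) but other depths load unchanged. Areas throughout the
package are pixel counts; ``pixel_size_um`` is carried as metadata only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FieldImage",
    "PlateLayout",
    "CONDITIONS",
    "parse_well",
    "read_field",
    "write_field",
    "field_paths",
    "find_fields",
    "read_layout",
    "write_layout",
]

#: Recognised experimental conditions for layout rows.
CONDITIONS = frozenset(
    ["unstimulated", "PMA", "media_control", "celastrol_control", "toxicity_control"]
)

_WELL_RE = re.compile(r"^([A-P])(\d{2})$")

#: Multipliers to molar for the dose_unit column.
_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
    "pM": 1e-12,
}


def parse_well(well: str) -> tuple[int, int]:
    """Parse a well name like ``"B07"`` to 0-based (row, column) indices.

    Rows A-P and columns 1-24 are accepted (96- and 384-well layouts).
    """
    m = _WELL_RE.match(well)
    if not m:
        raise ValueError(
            f"well {well!r} is not a valid well name (expected row A-P + 2-digit column)"
        )
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2))
    if not 1 <= col <= 24:
        raise ValueError(f"well {well!r}: column {col} outside 1-24")
    return row, col - 1


@dataclass
class FieldImage:
    """One acquired microscope field: two aligned intensity rasters.

    ``channel_nuclear`` images the nuclear stain, ``channel_dna`` images all
    accessible DNA including extracellular NET filaments. Both rasters share
    one shape; values are non-negative arbitrary intensity units.
    """

    plate_id: str
    well: str
    field_index: int
    channel_nuclear: np.ndarray
    channel_dna: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.channel_nuclear = np.asarray(self.channel_nuclear)
        self.channel_dna = np.asarray(self.channel_dna)
        if self.channel_nuclear.ndim != 2 or self.channel_dna.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if self.channel_nuclear.shape != self.channel_dna.shape:
            raise ValueError(
                "channel shape mismatch: nuclear "
                f"{self.channel_nuclear.shape} vs dna {self.channel_dna.shape}"
            )
        if self.field_index < 0:
            raise ValueError("field_index must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if (self.channel_nuclear < 0).any() or (self.channel_dna < 0).any():
            raise ValueError("intensities must be non-negative")
        parse_well(self.well)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channel_nuclear.shape


def field_paths(directory: Path | str, plate_id: str, well: str, field_index: int) -> tuple[Path, Path]:
    """Return the (nuclear, dna) TIFF paths for a field under the naming convention."""
    d = Path(directory)
    stem = f"{plate_id}_{well}_f{field_index}"
    return d / f"{stem}_nuc.tif", d / f"{stem}_dna.tif"


def write_field(field: FieldImage, directory: Path | str) -> tuple[Path, Path]:
    """Write both channels of a field as 16-bit grayscale TIFFs.

    Values are clipped to the uint16 range; returns the two paths written.
    """
    nuc_path, dna_path = field_paths(directory, field.plate_id, field.well, field.field_index)
    nuc_path.parent.mkdir(parents=True, exist_ok=True)
    for path, arr in ((nuc_path, field.channel_nuclear), (dna_path, field.channel_dna)):
        out = np.clip(np.asarray(arr), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, out)
    return nuc_path, dna_path


def _read_raster(path: Path | str) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"image {path} is not a single 2-D grayscale raster (shape {arr.shape})")
    return arr


def read_field(
    nuclear_path: Path | str,
    dna_path: Path | str,
    plate_id: str,
    well: str,
    field_index: int,
    pixel_size_um: float = 1.0,
) -> FieldImage:
    """Read a two-channel field from a pair of grayscale TIFFs.

    Intensities are preserved bit-exactly. Raises on unreadable files and on
    shape mismatch between the two channels.
    """
    nuc = _read_raster(nuclear_path)
    dna = _read_raster(dna_path)
    if nuc.shape != dna.shape:
        raise ValueError(
            f"shape mismatch between {nuclear_path} {nuc.shape} and {dna_path} {dna.shape}"
        )
    return FieldImage(
        plate_id=plate_id,
        well=well,
        field_index=field_index,
        channel_nuclear=nuc,
        channel_dna=dna,
        pixel_size_um=pixel_size_um,
    )


_FNAME_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})_f(?P<field>\d+)_(?P<ch>nuc|dna)\.tif$")


def find_fields(directory: Path | str) -> list[dict]:
    """Scan a directory for field file pairs following the naming convention.

    Returns a sorted list of dicts with keys plate_id, well, field_index,
    nuclear_path, dna_path. Fields missing one of the two channels raise.
    """
    pairs: dict[tuple[str, str, int], dict] = {}
    for path in sorted(Path(directory).glob("*.tif")):
        m = _FNAME_RE.match(path.name)
        if not m:
            continue
        key = (m.group("plate"), m.group("well"), int(m.group("field")))
        entry = pairs.setdefault(
            key,
            {"plate_id": key[0], "well": key[1], "field_index": key[2],
             "nuclear_path": None, "dna_path": None},
        )
        entry["nuclear_path" if m.group("ch") == "nuc" else "dna_path"] = path
    out = []
    for key in sorted(pairs):
        entry = pairs[key]
        if entry["nuclear_path"] is None or entry["dna_path"] is None:
            raise FileNotFoundError(
                f"field {key} is missing one channel file in {directory}"
            )
        out.append(entry)
    return out


@dataclass
class PlateLayout:
    """Validated plate layout: one row per imaged well.

    ``table`` columns: plate, well, condition, compound, dose_molar,
    timepoint_min, replicate. Doses are stored in molar units; compound is
    the empty string for control wells.
    """

    table: pd.DataFrame = dc_field(repr=False)

    def __post_init__(self) -> None:
        required = {"plate", "well", "condition", "compound", "dose_molar", "timepoint_min", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")

    def wells(self, **filters) -> pd.DataFrame:
        """Rows matching equality filters, e.g. ``wells(condition='PMA')``."""
        df = self.table
        for key, val in filters.items():
            df = df[df[key] == val]
        return df.copy()

    def doses_for(self, compound: str) -> list[float]:
        """The finite ordered dose set (molar, ascending) used for a compound."""
        d = sorted(set(self.table.loc[self.table["compound"] == compound, "dose_molar"]))
        return [float(x) for x in d]

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateLayout):
            return NotImplemented
        a = self.table.sort_values(["plate", "well"]).reset_index(drop=True)
        b = other.table.sort_values(["plate", "well"]).reset_index(drop=True)
        return a.equals(b)


def read_layout(path: Path | str) -> PlateLayout:
    """Read and validate a layout CSV.

    Expected header: well, condition, compound, dose, dose_unit,
    timepoint_min, replicate; an optional plate column (default "plate01").
    Doses are converted to molar. Raises on duplicate wells (per plate),
    out-of-grid well names, unknown conditions and unparseable doses.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"well", "condition", "compound", "dose", "dose_unit", "timepoint_min", "replicate"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
    if "plate" not in raw.columns:
        raw["plate"] = "plate01"
    raw.loc[raw["plate"] == "", "plate"] = "plate01"

    rows = []
    for i, rec in enumerate(raw.to_dict("records")):
        rownum = i + 2  # 1-based, after header
        well = rec["well"].strip()
        try:
            parse_well(well)
        except ValueError as exc:
            raise ValueError(f"layout row {rownum}: {exc}") from exc
        condition = rec["condition"].strip()
        if condition not in CONDITIONS:
            raise ValueError(
                f"layout row {rownum}: unknown condition {condition!r} "
                f"(expected one of {sorted(CONDITIONS)})"
            )
        dose_str = rec["dose"].strip()
        unit = rec["dose_unit"].strip()
        if dose_str in ("", "0"):
            dose_molar = 0.0
        else:
            try:
                dose_val = float(dose_str)
            except ValueError as exc:
                raise ValueError(f"layout row {rownum}: unparseable dose {dose_str!r}") from exc
            if dose_val < 0:
                raise ValueError(f"layout row {rownum}: negative dose {dose_val}")
            if unit not in _UNIT_TO_MOLAR:
                raise ValueError(
                    f"layout row {rownum}: unknown dose unit {unit!r} "
                    f"(expected one of {sorted(_UNIT_TO_MOLAR)})"
                )
            dose_molar = dose_val * _UNIT_TO_MOLAR[unit]
        try:
            timepoint = int(rec["timepoint_min"])
            replicate = int(rec["replicate"]) if rec["replicate"].strip() else 1
        except ValueError as exc:
            raise ValueError(f"layout row {rownum}: {exc}") from exc
        if timepoint < 0:
            raise ValueError(f"layout row {rownum}: negative timepoint {timepoint}")
        rows.append(
            {
                "plate": rec["plate"].strip(),
                "well": well,
                "condition": condition,
                "compound": rec["compound"].strip(),
                "dose_molar": dose_molar,
                "timepoint_min": timepoint,
                "replicate": replicate,
            }
        )

    table = pd.DataFrame(rows)
    dup = table.duplicated(subset=["plate", "well"], keep=False)
    if dup.any():
        dups = sorted(set(zip(table.loc[dup, "plate"], table.loc[dup, "well"])))
        raise ValueError(f"duplicate wells in layout: {dups}")
    table = table.sort_values(["plate", "well"]).reset_index(drop=True)
    return PlateLayout(table=table)


def write_layout(layout: PlateLayout | pd.DataFrame, path: Path | str) -> Path:
    """Write a layout back to CSV in the reader's schema (dose in molar)."""
    table = layout.table if isinstance(layout, PlateLayout) else layout
    out = table.copy()
    out["dose"] = out["dose_molar"].map(lambda x: format(x, ".6g"))
    out["dose_unit"] = "M"
    cols = ["plate", "well", "condition", "compound", "dose", "dose_unit", "timepoint_min", "replicate"]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out[cols].to_csv(path, index=False)
    return path
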