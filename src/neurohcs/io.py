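"""Data model and I/O for well-organized multi-channel microscopy data.

A well is imaged at several stage positions ("fields", by default a 4x4
grid of 16), each field as a multi-channel z-stack.  One well therefore
yields a 5-D dataset (XYZCF).  Fields stay independent throughout the
analysis: metrics are computed per field and averaged per well, and the
well mean is the statistical unit.

All physical parameters in the analysis modules are expressed in
micrometres; this module owns the conversion to pixels via the stack's
calibration.  Conversions are exact floats -- any rounding is the
caller's documented decision.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

#: Fallback pixel calibration (µm/px) for a 40x objective class when file
#: metadata carries no calibration.  Always overridable via config.
DEFAULT_PIXEL_SIZE_UM = 0.325

#: Default axial spacing between z-planes (µm).
DEFAULT_Z_SPACING_UM = 1.0

#: Default file naming pattern: tokens {well}, {field} (0-based integer).
DEFAULT_NAMING = "{well}_f{field:02d}.tif"


class StructuralError(ValueError):
    """Raised when a well dataset violates its structural invariants."""


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateLayoutEntry:
    well_id: str
    treatment: str
    dose: float
    dose_unit: str = ""
    biological_replicate: int = 1
    well_replicate: int = 1


@dataclass
class PlateLayout:
    """Treatment map of a multi-well plate.

    Wells are uniquely identified; each carries a treatment label, a dose
    with its unit, and the biological (``n_b``) / well (``n_w``) replicate
    indices used to document the experimental design.
    """

    entries: list[PlateLayoutEntry]

    def __post_init__(self) -> None:
        ids = [e.well_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise StructuralError("well_id values must be unique")
        for e in self.entries:
            if e.biological_replicate < 1 or e.well_replicate < 1:
                raise StructuralError(
                    f"replicate counts must be >= 1 (well {e.well_id})"
                )

    def __getitem__(self, well_id: str) -> PlateLayoutEntry:
        for e in self.entries:
            if e.well_id == well_id:
                return e
        raise KeyError(well_id)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def well_ids(self) -> list[str]:
        return [e.well_id for e in self.entries]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        """Read a layout CSV with columns well, treatment, dose, n_b, n_w.

        An optional ``dose_unit`` column is honoured.
        """
        df = pd.read_csv(path)
        required = {"well", "treatment", "dose", "n_b", "n_w"}
        missing = required - set(df.columns)
        if missing:
            raise StructuralError(f"layout CSV missing columns: {sorted(missing)}")
        entries = [
            PlateLayoutEntry(
                well_id=str(r.well),
                treatment=str(r.treatment),
                dose=float(r.dose),
                dose_unit=str(getattr(r, "dose_unit", "") or ""),
                biological_replicate=int(r.n_b),
                well_replicate=int(r.n_w),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "well": [e.well_id for e in self.entries],
                "treatment": [e.treatment for e in self.entries],
                "dose": [e.dose for e in self.entries],
                "dose_unit": [e.dose_unit for e in self.entries],
                "n_b": [e.biological_replicate for e in self.entries],
                "n_w": [e.well_replicate for e in self.entries],
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image containers
# ---------------------------------------------------------------------------

@dataclass
class FieldImage:
    """A single-channel 2D image with physical calibration (µm/px)."""

    pixels: np.ndarray
    channel: str
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise StructuralError("FieldImage pixels must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise StructuralError("FieldImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FieldStack:
    """A multi-channel z-stack for one field, shaped (C, Z, Y, X)."""

    voxels: np.ndarray
    channel_names: list[str]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    z_spacing: float = DEFAULT_Z_SPACING_UM
    #: True when pixel_size came from a config default rather than metadata.
    calibration_from_default: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise StructuralError("FieldStack voxels must be 4D (C, Z, Y, X)")
        if self.voxels.shape[0] != len(self.channel_names):
            raise StructuralError(
                f"channel axis ({self.voxels.shape[0]}) does not match "
                f"channel_names ({len(self.channel_names)})"
            )
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise ValueError("pixel_size and z_spacing must be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise StructuralError("FieldStack intensities must be finite")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.voxels[idx]


@dataclass
class WellDataset:
    """All field stacks of one well, plus its plate-layout entry."""

    well_id: str
    fields: list[FieldStack]
    layout_ref: PlateLayoutEntry | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fields:
            raise StructuralError("a WellDataset needs at least one field")
        ref = self.fields[0]
        for i, f in enumerate(self.fields):
            if f.channel_names != ref.channel_names:
                raise StructuralError(
                    f"field {i} channel set {f.channel_names} differs from "
                    f"field 0 {ref.channel_names}"
                )
            if f.pixel_size != ref.pixel_size:
                raise StructuralError("fields must share pixel calibration")

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def channel_names(self) -> list[str]:
        return self.fields[0].channel_names

    @property
    def pixel_size(self) -> float:
        return self.fields[0].pixel_size


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def max_project(stack: FieldStack, channel: str) -> FieldImage:
    """Maximum-intensity projection of one channel along z.

    This is the only projection offered: all downstream 2D analysis runs
    on maximum projections of the confocal stacks.
    """
    vol = stack.channel(channel)
    return FieldImage(
        pixels=vol.max(axis=0), channel=channel, pixel_size=stack.pixel_size
    )


def um_to_px(length_um: float, pixel_size: float) -> float:
    """Convert a length in µm to pixels (float; caller rounds if needed)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return length_um / pixel_size


def px_to_um(length_px: float, pixel_size: float) -> float:
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return length_px * pixel_size


def um2_to_px_area(area_um2: float, pixel_size: float) -> float:
    """Convert an area in µm² to squared pixels."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return area_um2 / pixel_size**2


def area_um2(px_count: float, pixel_size: float) -> float:
    """Area in µm² of ``px_count`` pixels: count x pixel_size²."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return px_count * pixel_size**2


# ---------------------------------------------------------------------------
# TIFF read/write
# ---------------------------------------------------------------------------

def write_field_stack(path: str | Path, stack: FieldStack) -> None:
    """Write a field stack as multi-page TIFF with CZYX axes metadata."""
    tifffile.imwrite(
        str(path),
        stack.voxels,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "channel_names": list(stack.channel_names),
            "pixel_size_um": stack.pixel_size,
            "z_spacing_um": stack.z_spacing,
        },
    )


def read_field_stack(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    default_pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> FieldStack:
    """Read a multi-page TIFF as a FieldStack.

    Accepts 4D (C,Z,Y,X), 3D (Z,Y,X or C,Y,X — disambiguated by the
    channel list) and plain 2D files.  Calibration and channel names come
    from the shaped-metadata written by :func:`write_field_stack` when
    present; otherwise ``channel_names``/``default_pixel_size`` apply and
    the stack is flagged ``calibration_from_default``.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc

    names = meta.get("channel_names")
    pixel_size = meta.get("pixel_size_um")
    z_spacing = meta.get("z_spacing_um", DEFAULT_Z_SPACING_UM)
    from_default = pixel_size is None
    if from_default:
        pixel_size = default_pixel_size
    if names is None:
        names = list(channel_names) if channel_names is not None else None

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        # ZYX single channel unless the leading axis matches the channel list
        if names is not None and len(names) == arr.shape[0] and len(names) > 1:
            arr = arr[:, None]
        else:
            arr = arr[None]
    elif arr.ndim != 4:
        raise StructuralError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")

    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    return FieldStack(
        voxels=arr,
        channel_names=list(names),
        pixel_size=float(pixel_size),
        z_spacing=float(z_spacing),
        calibration_from_default=from_default,
    )


def write_movie(path: str | Path, movie: np.ndarray, frame_interval_s: float,
                pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> None:
    """Write a 2D+T movie (T, Y, X) as multi-page TIFF."""
    tifffile.imwrite(
        str(path),
        np.asarray(movie),
        photometric="minisblack",
        metadata={
            "axes": "TYX",
            "frame_interval_s": frame_interval_s,
            "pixel_size_um": pixel_size,
        },
    )


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a 2D+T movie; returns (array (T,Y,X), metadata dict)."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            meta = dict(tf.shaped_metadata[0]) if tf.shaped_metadata else {}
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr, meta


def load_well_dataset(
    root_path: str | Path,
    layout: PlateLayout,
    well_id: str,
    naming: str = DEFAULT_NAMING,
    n_fields_expected: int = 16,
    channel_names: Sequence[str] | None = None,
    default_pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> WellDataset:
    """Load one well's field stacks from a directory.

    Missing fields are reported in ``WellDataset.warnings`` (and via
    ``warnings.warn``), never silently dropped.  Inconsistent channel
    sets across fields raise :class:`StructuralError`.
    """
    root = Path(root_path)
    stacks: list[FieldStack] = []
    notes: list[str] = []
    for i in range(n_fields_expected):
        fpath = root / naming.format(well=well_id, field=i)
        if not fpath.exists():
            msg = f"well {well_id}: expected field file missing: {fpath.name}"
            notes.append(msg)
            warnings.warn(msg)
            continue
        stacks.append(
            read_field_stack(
                fpath, channel_names=channel_names,
                default_pixel_size=default_pixel_size,
            )
        )
    if not stacks:
        raise IOError(f"no field files found for well {well_id} under {root}")
    entry = layout[well_id] if well_id in layout.well_ids else None
    return WellDataset(well_id=well_id, fields=stacks, layout_ref=entry,
                       warnings=notes)
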