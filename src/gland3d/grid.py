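"""Voxel-grid containers and TIFF/OME-TIFF + CSV input/output.

Conventions used throughout the package:

* axis order is ``(channel, z, y, x)`` for intensity volumes and
  ``(z, y, x)`` for masks/labels;
* voxel indices are 0-based and a voxel's physical position is
  ``index * spacing_um`` (voxel-centre convention);
* all physical quantities are in micrometres (μm), μm² and μm³.

The default spacing, used when neither the file nor the caller provides
one, is ``(0.82, 0.69, 0.69)`` μm for (dz, dy, dx) — the z-interval and
in-plane pixel size of single-cell-resolution confocal acquisition of
thick endocrine-gland sections.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: (dz, dy, dx) in μm used when no spacing is available anywhere.
DEFAULT_SPACING_UM: tuple[float, float, float] = (0.82, 0.69, 0.69)

#: fixed, documented column order of quantification tables
QUANT_COLUMNS = ("sample_id", "group", "region", "metric_name", "value", "units")


def _validate_spacing(spacing_um: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing_um)
    if len(sp) != 3:
        raise ValueError(f"spacing_um must have 3 components (dz, dy, dx), got {sp}")
    if any(s <= 0 for s in sp):
        raise ValueError(f"spacing components must be > 0, got {sp}")
    return sp  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """Multi-channel 3D intensity volume with anisotropic physical spacing.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)``; intensities are
        non-negative.
    spacing_um
        ``(dz, dy, dx)`` voxel spacing in μm; anisotropy is allowed and
        typical (dz ≠ dy = dx).
    channel_names
        One marker name per channel, e.g. ``["Emcn", "aSMA", "nuclei"]``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"data must be (channel, z, y, x), got shape {self.data.shape}")
        self.spacing_um = _validate_spacing(self.spacing_um)
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.channel_names)} channel names"
            )

    # -- convenience ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass
class RegionMask:
    """Integer label volume annotating regions (0 = background).

    Shares grid shape and spacing with the :class:`VoxelGrid` it
    annotates; ``label_names`` maps label values to region names such as
    ``{1: "islet", 2: "exocrine"}``.
    """

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be (z, y, x), got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_um = _validate_spacing(self.spacing_um)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def name_of(self, label: int) -> str:
        return self.label_names.get(label, f"region_{label}")


# ---------------------------------------------------------------------------
# OME-TIFF volume I/O
# ---------------------------------------------------------------------------

def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as an OME-TIFF stack (axes CZYX).

    Spacing and channel names are stored in the OME metadata so that
    ``read_volume(write_volume(g)) == g`` bit-exactly.
    """
    path = Path(path)
    dz, dy, dx = grid.spacing_um
    tifffile.imwrite(
        path,
        grid.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(grid.channel_names)},
        },
    )
    return path


def _parse_ome_metadata(ome_xml: str) -> tuple[tuple[float, ...] | None, list[str] | None]:
    """Extract (dz, dy, dx) and channel names from OME-XML, if present."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pixels is None:
        return None, None
    spacing = None
    try:
        spacing = (
            float(pixels.attrib["PhysicalSizeZ"]),
            float(pixels.attrib["PhysicalSizeY"]),
            float(pixels.attrib["PhysicalSizeX"]),
        )
    except (KeyError, ValueError):
        spacing = None
    chans = pixels.findall("ome:Channel" if ns else "Channel", ns)
    names = [c.attrib["Name"] for c in chans if "Name" in c.attrib]
    if len(names) != len(chans):
        names = None  # incomplete naming: fall back to caller's names
    return spacing, (names or None)


def read_volume(
    path: str | Path,
    spacing_um: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> VoxelGrid:
    """Read a TIFF / OME-TIFF stack into a :class:`VoxelGrid`.

    Spacing and channel names are taken from OME metadata when present;
    explicit arguments override file metadata (with a logged warning when
    they disagree). When neither source provides a spacing, the
    acquisition default :data:`DEFAULT_SPACING_UM` is used.

    Raises
    ------
    ValueError
        If the channel count disagrees with ``channel_names`` or spacing
        is non-positive.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        # S (samples) are channels; Q (unknown) is assumed to be a z-stack
        axes = series.axes.upper().replace("S", "C").replace("Q", "Z")
        file_spacing = file_names = None
        if tf.ome_metadata:
            file_spacing, file_names = _parse_ome_metadata(tf.ome_metadata)

    # normalize axis order to CZYX
    if data.ndim == 2:
        data = data[None, None]
        axes = "CZYX"
    elif data.ndim == 3:
        if "C" in axes and "Z" not in axes:   # CYX
            data = data[:, None]
        else:                                  # ZYX
            data = data[None]
        axes = "CZYX"
    elif data.ndim == 4:
        if axes not in ("CZYX", "ZCYX"):
            axes = "CZYX" if data.shape[0] <= data.shape[1] else "ZCYX"
        if axes == "ZCYX":
            data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"cannot interpret {data.ndim}-dimensional TIFF as a volume")

    n_channels = data.shape[0]
    if channel_names is not None and len(channel_names) != n_channels:
        raise ValueError(
            f"file has {n_channels} channels but {len(channel_names)} channel names given"
        )
    if channel_names is not None:
        if file_names and list(channel_names) != list(file_names):
            logger.warning(
                "channel names %s override file metadata %s", list(channel_names), file_names
            )
        names = list(channel_names)
    elif file_names and len(file_names) == n_channels:
        names = list(file_names)
    else:
        names = [f"ch{i}" for i in range(n_channels)]

    if spacing_um is not None:
        if file_spacing and tuple(float(s) for s in spacing_um) != file_spacing:
            logger.warning("spacing %s overrides file metadata %s", spacing_um, file_spacing)
        spacing = _validate_spacing(spacing_um)
    elif file_spacing is not None:
        spacing = _validate_spacing(file_spacing)
    else:
        spacing = DEFAULT_SPACING_UM

    return VoxelGrid(data=data, spacing_um=spacing, channel_names=names)


def write_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Write a 3D label/binary mask as a plain TIFF (ZYX)."""
    path = Path(path)
    arr = np.asarray(labels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(path, arr)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

class QuantTable:
    """Long-format table of scalar quantification results.

    Fixed column order: ``sample_id, group, region, metric_name, value,
    units``. Rows accumulate via :meth:`add`; CSV round-trips are
    lossless.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=list(QUANT_COLUMNS))
        missing = set(QUANT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.df = df[list(QUANT_COLUMNS)].reset_index(drop=True)

    def add(
        self,
        metric_name: str,
        value: float,
        units: str = "",
        sample_id: str = "sample",
        group: str = "",
        region: str = "all",
    ) -> "QuantTable":
        row = pd.DataFrame(
            [[sample_id, group, region, metric_name, float(value), units]],
            columns=list(QUANT_COLUMNS),
        )
        self.df = row if len(self.df) == 0 else pd.concat([self.df, row], ignore_index=True)
        return self

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantTable):
            return NotImplemented
        if len(self.df) != len(other.df):
            return False
        if len(self.df) == 0:
            return True
        a, b = self.df, other.df
        return bool(
            (a[["sample_id", "group", "region", "metric_name", "units"]]
             .eq(b[["sample_id", "group", "region", "metric_name", "units"]]).all().all())
            and np.allclose(a["value"].to_numpy(float), b["value"].to_numpy(float),
                            rtol=0, atol=0, equal_nan=True)
        )


def write_table(table: QuantTable, path: str | Path) -> Path:
    """Write a :class:`QuantTable` as CSV in the fixed column order."""
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> QuantTable:
    df = pd.read_csv(
        path,
        dtype={c: str for c in ("sample_id", "group", "region", "metric_name", "units")},
        keep_default_na=False,
    )
    if len(df):
        df["value"] = df["value"].astype(float)
    return QuantTable(df)
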