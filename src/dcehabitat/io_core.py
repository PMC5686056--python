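"""Shared domain types, NIfTI I/O, mask algebra, and geometry utilities.

Conventions used throughout the package:

* voxel grids are index-addressed, 0-based, axis order ``(x, y, z)``;
* masks and series must share the spatial grid exactly — no resampling
  happens inside the pipeline;
* all volumes are reported in cc, all times in seconds, and intensities
  are arbitrary units that are never rescaled implicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "TimeGrid",
    "DceSeries",
    "MaskVolume",
    "GleasonLabel",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "volume_cc",
    "dilate_mask",
    "derive_tz",
]

#: default acquisition: 12 frames at 30 s spacing, 2 pre-contrast frames
DEFAULT_N_FRAMES = 12
DEFAULT_FRAME_SPACING_S = 30.0
DEFAULT_N_PRE = 2
#: in-plane/through-plane voxel size of the acquisition protocol (mm)
DEFAULT_SPACING_MM = (1.25, 1.25, 2.5)


@dataclass(frozen=True)
class TimeGrid:
    """Frame timing of a dynamic series.

    Parameters
    ----------
    times
        Acquisition time of each frame in seconds, strictly increasing,
        starting at 0.
    n_pre
        Number of pre-contrast (baseline) frames at the start of the series.
    """

    times: np.ndarray
    n_pre: int = DEFAULT_N_PRE

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("times must be a 1D array with at least 2 frames")
        if t[0] != 0.0:
            raise ValueError("times must start at 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.n_pre < t.size):
            raise ValueError("n_pre must satisfy 1 <= n_pre < number of frames")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @classmethod
    def default(
        cls,
        n_frames: int = DEFAULT_N_FRAMES,
        spacing_s: float = DEFAULT_FRAME_SPACING_S,
        n_pre: int = DEFAULT_N_PRE,
    ) -> "TimeGrid":
        """Uniform grid: ``n_frames`` frames at ``spacing_s`` seconds."""
        return cls(times=np.arange(n_frames) * float(spacing_s), n_pre=n_pre)

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(), "n_pre": self.n_pre}

    @classmethod
    def from_dict(cls, d: dict) -> "TimeGrid":
        return cls(times=np.asarray(d["times"], dtype=float), n_pre=int(d["n_pre"]))


@dataclass
class DceSeries:
    """A 4D dynamic contrast-enhanced series: ``data[x, y, z, t]``."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("expected 4D series")
        if self.data.shape[3] != self.grid.n_frames:
            raise ValueError(
                f"series has {self.data.shape[3]} frames but time grid has "
                f"{self.grid.n_frames}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite voxels")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame(self, j: int) -> np.ndarray:
        return self.data[..., j]


MASK_LABELS = frozenset(
    {"prostate", "PZ", "TZ", "GM", "ROI", "NAT_PZ", "NAT_TZ", "biopsy"}
)


@dataclass
class MaskVolume:
    """A 3D binary mask on the series' spatial grid."""

    data: np.ndarray
    label: str = "ROI"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("expected 3D mask")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "MaskVolume") -> np.ndarray:
        return self.data & other.data


# ordinal Gleason groupings used for association statistics
_GROUP3 = {"6": 1, "3+4": 2, ">3+4": 3}
_GROUP4 = {"6": 1, "3+4": 2, "4+3": 3, "8-10": 4}


@dataclass(frozen=True)
class GleasonLabel:
    """Histopathological grade with the ordinal groupings used for statistics.

    ``group3`` codes {6, 3+4, >3+4} as {1, 2, 3}; ``group4`` codes
    {6, 3+4, 4+3, 8–10} as {1, 2, 3, 4}; ``binary`` is "indolent" for
    total grade 6 and "aggressive" for total grade ≥ 7.
    """

    primary: int
    secondary: int

    def __post_init__(self) -> None:
        for g in (self.primary, self.secondary):
            if not (1 <= g <= 5):
                raise ValueError("Gleason grades must be in 1..5")
        if self.total < 6:
            raise ValueError("only clinically reported totals (>= 6) supported")

    @property
    def total(self) -> int:
        return self.primary + self.secondary

    @property
    def group3(self) -> int:
        if self.total == 6:
            return _GROUP3["6"]
        if self.total == 7 and self.primary == 3:
            return _GROUP3["3+4"]
        return _GROUP3[">3+4"]

    @property
    def group4(self) -> int:
        if self.total == 6:
            return _GROUP4["6"]
        if self.total == 7:
            return _GROUP4["3+4"] if self.primary == 3 else _GROUP4["4+3"]
        return _GROUP4["8-10"]

    @property
    def binary(self) -> str:
        return "indolent" if self.total == 6 else "aggressive"


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_series(
    path: str | Path,
    grid: TimeGrid | None = None,
) -> DceSeries:
    """Read a 4D NIfTI series.

    Voxel spacing is taken from the NIfTI header.  The time grid is taken,
    in order of precedence, from the ``grid`` argument, from a JSON sidecar
    ``<name>.json`` with keys ``times`` and ``n_pre``, or the default
    12-frame 30 s grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError("series contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if grid is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            grid = TimeGrid.from_dict(json.loads(sidecar.read_text()))
        else:
            grid = TimeGrid.default(n_frames=data.shape[3])
    return DceSeries(data=data, spacing=spacing, grid=grid)


def write_series(series: DceSeries, path: str | Path) -> None:
    """Write a 4D series plus its JSON time-grid sidecar."""
    path = Path(path)
    affine = np.diag(list(series.spacing) + [1.0])
    img = nib.Nifti1Image(series.data, affine)
    img.header.set_zooms(tuple(series.spacing) + (0.0,))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(series.grid.to_dict()))


def read_mask(path: str | Path, label: str = "ROI") -> MaskVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D")
    return MaskVolume(data=data > 0, label=label)


def write_mask(mask: MaskVolume, path: str | Path, spacing=DEFAULT_SPACING_MM) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(Path(path)))


# ---------------------------------------------------------------------------
# Mask algebra


def volume_cc(mask: MaskVolume | np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Volume of a binary mask in cc (voxel count x voxel volume / 1000)."""
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    data = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask, dtype=bool)
    return float(data.sum()) * spacing[0] * spacing[1] * spacing[2] / 1000.0


def _disk_structure(radius_px: int) -> np.ndarray:
    """In-plane disc: pixels with centre distance <= radius, 1 voxel thick in z."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx * xx + yy * yy) <= r * r
    return disk[:, :, None]


def dilate_mask(
    mask: MaskVolume, radius_mm: float, spacing: tuple[float, float, float]
) -> MaskVolume:
    """Binary dilation by ``ceil(radius_mm / dx)`` pixels, slice-wise in-plane.

    The dilation is 2D because the registration region radius is specified
    in pixels of the in-plane resolution (15 px x 1.25 mm = 18.75 mm holds
    only in-plane).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    radius_px = int(np.ceil(radius_mm / spacing[0]))
    if radius_px == 0:
        return MaskVolume(mask.data.copy(), label=mask.label)
    out = ndimage.binary_dilation(mask.data, structure=_disk_structure(radius_px))
    return MaskVolume(out, label=mask.label)


def derive_tz(prostate: MaskVolume, pz: MaskVolume) -> MaskVolume:
    """Transition zone = prostate minus peripheral zone."""
    if np.any(pz.data & ~prostate.data):
        raise ValueError("PZ mask is not contained in the prostate mask")
    return MaskVolume(prostate.data & ~pz.data, label="TZ")
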