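"""Synthetic pelvic DCE-MRI phantom with ground-truth anatomy and kinetics.

The phantom emulates the acquisition geometry of the clinical protocol
(12 frames at 30 s, 1.25 x 1.25 x 2.5 mm voxels) with a simple anatomy:
an axial ellipsoidal prostate whose posterior half is the peripheral zone
(PZ), a cuboid gluteus-maximus (GM) muscle sample outside the gland, and
spherical lesions of programmable Gleason grade.  Each tissue enhances
according to a bi-exponential contrast curve

    S(t) = s0                                            for t <= t0
    S(t) = s0 + A (exp(-k2 (t - t0)) - exp(-k1 (t - t0)))  for t > t0

with uptake rate ``k1``, washout rate ``k2`` and onset ``t0``.  Gaussian or
Rician noise and per-frame rigid in-plane motion can be injected, and every
generated quantity (masks, per-tissue kinetics, injected transforms) is
returned as ground truth so downstream stages can be tested quantitatively.

The default tissue presets are package constants chosen so that wash-in
slope, washout magnitude and all derived enhancement features increase
strictly with lesion grade 6 < 3+4 < 4+3 < 8 — the monotonicity contract
that the evaluation tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_core import (
    DEFAULT_SPACING_MM,
    DceSeries,
    MaskVolume,
    TimeGrid,
)

__all__ = [
    "TissueKinetics",
    "LesionSpec",
    "RigidTransform2D",
    "PhantomConfig",
    "PhantomTruth",
    "DEFAULT_KINETICS",
    "LESION_GRADES",
    "kinetic_curve",
    "make_phantom",
    "make_anatomy",
    "lesion_mask",
    "inject_motion",
    "noise_sigma_for_snr",
    "default_config",
    "cohort_configs",
    "simulate_biopsies",
    "GRADE_TO_GLEASON",
    "PZ_LESION_CENTER",
    "TZ_LESION_CENTER",
    "COHORT_RADIUS_MM",
]


@dataclass(frozen=True)
class TissueKinetics:
    """Generative bi-exponential enhancement parameters of one tissue class.

    ``s0`` is the pre-contrast baseline intensity, ``amplitude`` the
    enhancement amplitude A, ``k1``/``k2`` the uptake/washout rates (1/s)
    with k1 > k2 >= 0, and ``t0`` the enhancement onset (s).
    """

    s0: float
    amplitude: float
    k1: float
    k2: float
    t0: float

    def __post_init__(self) -> None:
        if self.k1 <= self.k2 or self.k2 < 0:
            raise ValueError("require k1 > k2 >= 0")
        if self.amplitude < 0 or self.s0 < 0 or self.t0 < 0:
            raise ValueError("s0, amplitude and t0 must be non-negative")

    @property
    def tau(self) -> float:
        """Time from onset to peak: ln(k1/k2) / (k1 - k2); inf when k2 = 0."""
        if self.k2 == 0:
            return np.inf
        return float(np.log(self.k1 / self.k2) / (self.k1 - self.k2))

    @property
    def sm(self) -> float:
        """Peak intensity s0 + A (e^(-k2 tau) - e^(-k1 tau))."""
        if self.amplitude == 0:
            return self.s0
        if self.k2 == 0:
            return self.s0 + self.amplitude
        t = self.tau
        return float(
            self.s0
            + self.amplitude * (np.exp(-self.k2 * t) - np.exp(-self.k1 * t))
        )


def kinetic_curve(p: TissueKinetics, grid: TimeGrid) -> np.ndarray:
    """Sample the tissue's bi-exponential enhancement curve on a time grid."""
    dt = np.maximum(grid.times - p.t0, 0.0)
    return p.s0 + p.amplitude * (np.exp(-p.k2 * dt) - np.exp(-p.k1 * dt))


#: lesion grades in increasing aggressiveness order
LESION_GRADES = ("6", "3+4", "4+3", "8")

#: default tissue kinetics preset (arbitrary intensity units); muscle
#: enhances slowest and lowest, lesions faster/higher with grade
DEFAULT_KINETICS: dict[str, TissueKinetics] = {
    # muscle peaks before the 270-330 s late window so its late linear
    # slope is a (small) genuine washout, keeping ratio features sign-safe
    "muscle": TissueKinetics(s0=100.0, amplitude=60.0, k1=0.012, k2=0.0022, t0=70.0),
    "pz": TissueKinetics(s0=100.0, amplitude=120.0, k1=0.013, k2=0.0012, t0=65.0),
    "tz": TissueKinetics(s0=100.0, amplitude=150.0, k1=0.016, k2=0.0014, t0=65.0),
    "lesion_6": TissueKinetics(s0=100.0, amplitude=260.0, k1=0.030, k2=0.0018, t0=60.0),
    "lesion_3+4": TissueKinetics(s0=100.0, amplitude=320.0, k1=0.040, k2=0.0022, t0=60.0),
    "lesion_4+3": TissueKinetics(s0=100.0, amplitude=380.0, k1=0.050, k2=0.0026, t0=60.0),
    "lesion_8": TissueKinetics(s0=100.0, amplitude=450.0, k1=0.065, k2=0.0030, t0=60.0),
}


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: centre in voxel indices, radius in mm."""

    center: tuple[int, int, int]
    radius_mm: float
    zone: str = "PZ"  # PZ | TZ
    grade: str = "3+4"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.zone not in ("PZ", "TZ"):
            raise ValueError("zone must be PZ or TZ")
        if self.grade not in LESION_GRADES:
            raise ValueError(f"grade must be one of {LESION_GRADES}")


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: shifts in pixels, rotation in degrees."""

    shift_x_px: float = 0.0
    shift_y_px: float = 0.0
    rotation_deg: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (
            self.shift_x_px == 0.0
            and self.shift_y_px == 0.0
            and self.rotation_deg == 0.0
        )


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = DEFAULT_SPACING_MM
    grid: TimeGrid = field(default_factory=TimeGrid.default)
    lesions: tuple[LesionSpec, ...] = ()
    kinetics: dict[str, TissueKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    noise: str = "gaussian"  # gaussian | rician
    sigma: float = 0.0
    motion: tuple[RigidTransform2D, ...] | None = None  # one per frame >= 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.noise not in ("gaussian", "rician"):
            raise ValueError("noise must be gaussian or rician")
        if self.motion is not None and len(self.motion) != self.grid.n_frames - 1:
            raise ValueError("need one motion transform per frame >= 1")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    masks: dict[str, MaskVolume]  # prostate, PZ, TZ, GM, lesion_0, ...
    lesion_kinetics: list[TissueKinetics]
    lesion_grades: list[str]
    transforms: tuple[RigidTransform2D, ...] | None = None


def noise_sigma_for_snr(k: TissueKinetics, snr: float) -> float:
    """Noise sigma for a given baseline signal-to-noise ratio.

    SNR follows the standard MRI convention: the tissue's unenhanced
    (baseline) signal divided by the noise standard deviation.  Thermal
    noise in MRI is signal-independent, so one sigma applies to the whole
    series.
    """
    return k.s0 / float(snr)


# ---------------------------------------------------------------------------
# Anatomy

# ellipsoid centre and semi-axes in mm within the default 80 x 80 x 30 mm FOV
_PROSTATE_CENTER_FRAC = (0.5, 0.53, 0.5)
_PROSTATE_SEMIAXES_MM = (22.0, 17.0, 11.0)


def _mm_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def make_anatomy(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> dict[str, MaskVolume]:
    """Deterministic anatomy: prostate ellipsoid, posterior-half PZ, GM cuboid."""
    xm, ym, zm = _mm_coords(shape, spacing)
    fov = [n * s for n, s in zip(shape, spacing)]
    cx, cy, cz = [f * c for f, c in zip(fov, _PROSTATE_CENTER_FRAC)]
    ax, ay, az = _PROSTATE_SEMIAXES_MM
    e = ((xm - cx) / ax) ** 2 + ((ym - cy) / ay) ** 2 + ((zm - cz) / az) ** 2
    prostate = e <= 1.0
    pz = prostate & (ym > cy)
    tz = prostate & ~pz
    gm = (
        (xm >= 0.05 * fov[0])
        & (xm <= 0.22 * fov[0])
        & (ym >= 0.72 * fov[1])
        & (ym <= 0.95 * fov[1])
        & (zm >= 0.2 * fov[2])
        & (zm <= 0.8 * fov[2])
    )
    gm &= ~prostate
    return {
        "prostate": MaskVolume(prostate, "prostate"),
        "PZ": MaskVolume(pz, "PZ"),
        "TZ": MaskVolume(tz, "TZ"),
        "GM": MaskVolume(gm, "GM"),
    }


def lesion_mask(
    spec: LesionSpec,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Voxelized sphere: voxel centres within radius_mm of the lesion centre."""
    xm, ym, zm = _mm_coords(shape, spacing)
    cx, cy, cz = [c * s for c, s in zip(spec.center, spacing)]
    d2 = (xm - cx) ** 2 + (ym - cy) ** 2 + (zm - cz) ** 2
    return d2 <= spec.radius_mm**2


# ---------------------------------------------------------------------------
# Series generation


def make_phantom(cfg: PhantomConfig) -> tuple[DceSeries, PhantomTruth]:
    """Generate a synthetic DCE series and its ground truth.

    Every voxel's time course is its tissue's :func:`kinetic_curve` plus
    noise; lesions overwrite the background kinetics of their zone.  The
    same seed always produces a bit-identical series.
    """
    anatomy = make_anatomy(cfg.shape, cfg.spacing)
    prostate = anatomy["prostate"].data
    zone_masks = {"PZ": anatomy["PZ"].data, "TZ": anatomy["TZ"].data}

    lesion_masks: list[np.ndarray] = []
    occupied = np.zeros(cfg.shape, dtype=bool)
    for spec in cfg.lesions:
        m = lesion_mask(spec, cfg.shape, cfg.spacing)
        if not np.all(prostate[m]):
            raise ValueError(f"lesion at {spec.center} extends outside the prostate")
        m = m & zone_masks[spec.zone]  # enforce lesion within its declared zone
        if not zone_masks[spec.zone][spec.center]:
            raise ValueError(f"lesion centre {spec.center} not in zone {spec.zone}")
        if np.any(m & occupied):
            raise ValueError("overlapping lesions")
        occupied |= m
        lesion_masks.append(m)

    T = cfg.grid.n_frames
    data = np.zeros(cfg.shape + (T,), dtype=float)
    # background air/soft tissue: small constant baseline
    data[...] = 20.0
    curves = {name: kinetic_curve(k, cfg.grid) for name, k in cfg.kinetics.items()}
    for region, name in (
        (anatomy["GM"].data, "muscle"),
        (anatomy["PZ"].data, "pz"),
        (anatomy["TZ"].data, "tz"),
    ):
        data[region] = curves[name]
    lesion_kin: list[TissueKinetics] = []
    for spec, m in zip(cfg.lesions, lesion_masks):
        k = cfg.kinetics[f"lesion_{spec.grade}"]
        data[m] = kinetic_curve(k, cfg.grid)
        lesion_kin.append(k)

    rng = np.random.default_rng(cfg.seed)
    if cfg.sigma > 0:
        if cfg.noise == "gaussian":
            data = data + rng.normal(0.0, cfg.sigma, size=data.shape)
        else:  # rician: magnitude of complex signal with Gaussian channels
            n1 = rng.normal(0.0, cfg.sigma, size=data.shape)
            n2 = rng.normal(0.0, cfg.sigma, size=data.shape)
            data = np.sqrt((data + n1) ** 2 + n2**2)
    np.clip(data, 0.0, None, out=data)

    series = DceSeries(data=data, spacing=cfg.spacing, grid=cfg.grid)
    truth = PhantomTruth(
        masks={
            **anatomy,
            **{
                f"lesion_{i}": MaskVolume(m, "ROI")
                for i, m in enumerate(lesion_masks)
            },
        },
        lesion_kinetics=lesion_kin,
        lesion_grades=[s.grade for s in cfg.lesions],
        transforms=cfg.motion,
    )
    if cfg.motion is not None:
        series = inject_motion(series, cfg.motion)
    return series, truth


def _warp_frame(frame: np.ndarray, t: RigidTransform2D, center_px=None) -> np.ndarray:
    """Move frame content by (shift_x, shift_y) px and rotate about center."""
    if t.is_identity:
        return frame.copy()
    if center_px is None:
        center_px = ((frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0)
    th = np.deg2rad(t.rotation_deg)
    # output(o) = input(R^{-1}(o - s - c) + c): content rotated by th about
    # the centre, then shifted by s pixels
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rinv = rot.T
    c = np.asarray(center_px)
    s = np.array([t.shift_x_px, t.shift_y_px])
    matrix = np.eye(3)
    matrix[:2, :2] = rinv
    offset = np.zeros(3)
    offset[:2] = c - rinv @ (s + c)
    cval = float(frame.min())
    return ndimage.affine_transform(
        frame, matrix, offset=offset, order=1, mode="constant", cval=cval
    )


def inject_motion(
    series: DceSeries, transforms: tuple[RigidTransform2D, ...]
) -> DceSeries:
    """Apply one rigid in-plane transform per frame >= 1 (frame 0 fixed)."""
    if len(transforms) != series.grid.n_frames - 1:
        raise ValueError("need one transform per frame >= 1")
    out = series.data.copy()
    for j, t in enumerate(transforms, start=1):
        out[..., j] = _warp_frame(series.data[..., j], t)
    return DceSeries(data=out, spacing=series.spacing, grid=series.grid)


# ---------------------------------------------------------------------------
# Convenience configurations


#: default lesion centres (voxel indices on the 64 x 64 x 12 grid)
PZ_LESION_CENTER = (32, 41, 6)
TZ_LESION_CENTER = (32, 28, 6)


def default_config(
    grade: str = "3+4",
    zone: str = "PZ",
    radius_mm: float = 6.2,
    snr: float | None = None,
    seed: int = 0,
    motion: tuple[RigidTransform2D, ...] | None = None,
) -> PhantomConfig:
    """One-lesion phantom at the standard acquisition geometry.

    ``snr`` sets the noise level relative to the lesion's peak enhancement;
    ``None`` means noiseless.
    """
    center = PZ_LESION_CENTER if zone == "PZ" else TZ_LESION_CENTER
    lesion = LesionSpec(center=center, radius_mm=radius_mm, zone=zone, grade=grade)
    kin = DEFAULT_KINETICS[f"lesion_{grade}"]
    sigma = 0.0 if snr is None else noise_sigma_for_snr(kin, snr)
    return PhantomConfig(lesions=(lesion,), sigma=sigma, seed=seed, motion=motion)


#: Gleason primary+secondary pattern for each phantom lesion grade
GRADE_TO_GLEASON = {"6": (3, 3), "3+4": (3, 4), "4+3": (4, 3), "8": (4, 4)}


def simulate_biopsies(
    truth: PhantomTruth,
    shape: tuple[int, int, int],
    n_per_lesion: int = 6,
    seed: int = 0,
) -> list:
    """Simulate targeted biopsy tracks in the phantom's lesion cores.

    Each track is a 3 x 3 x 1 voxel footprint centred at a random voxel of
    the lesion interior (eroded by one in-plane voxel so the footprint
    stays inside the lesion, as a targeted biopsy samples the core).
    Returns ``(name, MaskVolume, GleasonLabel)`` triples.
    """
    from scipy import ndimage as _ndi

    from .io_core import GleasonLabel

    rng = np.random.default_rng(seed)
    out = []
    i = 0
    while f"lesion_{i}" in truth.masks:
        core = _ndi.binary_erosion(
            truth.masks[f"lesion_{i}"].data, structure=np.ones((3, 3, 1), bool)
        )
        coords = np.argwhere(core)
        if coords.size == 0:
            i += 1
            continue
        grade = truth.lesion_grades[i]
        gs = GleasonLabel(*GRADE_TO_GLEASON[grade])
        for b in range(n_per_lesion):
            x, y, z = coords[rng.integers(len(coords))]
            m = np.zeros(shape, dtype=bool)
            m[max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, z] = True
            out.append((f"lesion{i}_track{b}", MaskVolume(m, "biopsy"), gs))
        i += 1
    return out


#: lesion radius by grade (mm): aggressive tumors are larger, mirroring
#: the positive volume-grade association the segmentation sweep probes
COHORT_RADIUS_MM = {"6": 5.4, "3+4": 6.2, "4+3": 6.8, "8": 7.4}


def cohort_configs(
    n: int = 24, snr: float | None = 20.0, seed: int = 0
) -> list[PhantomConfig]:
    """A cohort of one-lesion phantoms cycling through the four grades.

    Grades cycle 6, 3+4, 4+3, 8; three of every four lesions sit in the
    PZ (matching the ~76 % PZ prevalence of prostate tumors); radii follow
    :data:`COHORT_RADIUS_MM` with a +-0.3 mm jitter.  Per-case seeds are
    derived from ``seed`` so the whole cohort is reproducible.
    """
    rng = np.random.default_rng(seed)
    cfgs = []
    for i in range(n):
        grade = LESION_GRADES[i % 4]
        zone = "PZ" if rng.random() < 0.76 else "TZ"
        radius = COHORT_RADIUS_MM[grade] + rng.uniform(-0.3, 0.3)
        kin = DEFAULT_KINETICS[f"lesion_{grade}"]
        sigma = 0.0 if snr is None else noise_sigma_for_snr(kin, snr)
        center = PZ_LESION_CENTER if zone == "PZ" else TZ_LESION_CENTER
        cfgs.append(
            PhantomConfig(
                lesions=(
                    LesionSpec(
                        center=center, radius_mm=radius, zone=zone, grade=grade
                    ),
                ),
                sigma=sigma,
                seed=int((seed * 100003 + i * 911) % (2**31 - 1)),
            )
        )
    return cfgs
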