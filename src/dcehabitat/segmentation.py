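"""Segmentation of the well-perfused ROI from the W_wp weight map.

Two families of methods are supported: Otsu thresholding of the positive
weights, and the beta-purity rule that keeps a voxel when the well-perfused
weight exceeds beta % of the voxel's total NMF weight.  The raw ROI is then
cleaned of disconnected components smaller than 0.05 cc, gated (an ROI
below 0.5 cc is rejected from further processing), assigned as a whole to
the peripheral or transition zone by its PZ overlap fraction, and the
remaining zone voxels become the normal-appearing-tissue (NAT) masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .decomposition import NmfResult
from .io_core import MaskVolume, volume_cc

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "otsu_threshold",
    "otsu_segment",
    "purity_segment",
    "cleanup_components",
    "gate_and_assign",
    "segment_wp",
]

BETA_MENU = (40, 50, 60, 70)
PZ_FRACTION_MENU = (10, 15, 20)


@dataclass(frozen=True)
class SegmentationConfig:
    """Operating point of the segmentation stage.

    Defaults are the selected clinical operating point: beta = 60 % purity
    with a 10 % PZ-fraction rule, 0.05 cc component cleanup and a 0.5 cc
    minimum ROI volume.
    """

    method: str = "purity"  # purity | otsu
    beta: float = 60.0
    pz_fraction: float = 10.0
    cleanup_cc: float = 0.05
    min_roi_cc: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("purity", "otsu"):
            raise ValueError("method must be 'purity' or 'otsu'")
        if self.method == "purity" and self.beta not in BETA_MENU:
            raise ValueError(f"beta must be one of {BETA_MENU}")
        if self.pz_fraction not in PZ_FRACTION_MENU:
            raise ValueError(f"pz_fraction must be one of {PZ_FRACTION_MENU}")
        if self.cleanup_cc < 0 or self.min_roi_cc <= 0:
            raise ValueError("volume thresholds must be positive")


@dataclass
class SegmentationResult:
    roi_wp: MaskVolume
    zone: str | None  # "PZ" | "TZ" | None when rejected with empty ROI
    pz_roi_wp: MaskVolume
    tz_roi_wp: MaskVolume
    nat_pz: MaskVolume
    nat_tz: MaskVolume
    volume_cc_before: float
    volume_cc_after: float
    rejected: bool

    def to_dict(self) -> dict:
        return {
            "zone": self.zone,
            "volume_cc_before": self.volume_cc_before,
            "volume_cc_after": self.volume_cc_after,
            "rejected": self.rejected,
        }


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold (256-bin between-class-variance maximization)."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold requires at least 2 distinct values")
    return float(threshold_otsu(values, nbins=256))


def otsu_segment(nmf: NmfResult) -> MaskVolume:
    """ROI = voxels whose W_wp exceeds the Otsu threshold of the weights."""
    w = nmf.W[:, nmf.wp_index]
    thr = otsu_threshold(w)
    mask = np.zeros(nmf.shape, dtype=bool)
    mask[tuple(nmf.coords[w > thr].T)] = True
    return MaskVolume(mask, "ROI")


def purity_segment(nmf: NmfResult, beta: float) -> MaskVolume:
    """Voxels whose well-perfused weight is > beta % of their total weight.

    The inequality is strict, and voxels with zero total weight are
    excluded.
    """
    if not (0 < beta < 100):
        raise ValueError("beta must be in (0, 100)")
    if nmf.wp_index is None:
        raise ValueError("well-perfused pattern not selected")
    total = nmf.W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, nmf.W[:, nmf.wp_index] / total, 0.0)
    keep = (total > 0) & (purity > beta / 100.0)
    mask = np.zeros(nmf.shape, dtype=bool)
    mask[tuple(nmf.coords[keep].T)] = True
    return MaskVolume(mask, "ROI")


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def cleanup_components(
    mask: MaskVolume, min_cc: float, spacing: tuple[float, float, float]
) -> MaskVolume:
    """Drop 26-connected components with volume < ``min_cc`` (strict)."""
    if min_cc < 0:
        raise ValueError("min_cc must be >= 0")
    labels, n = ndimage.label(mask.data, structure=_CONN26)
    if n == 0:
        return MaskVolume(mask.data.copy(), mask.label)
    voxel_cc = spacing[0] * spacing[1] * spacing[2] / 1000.0
    counts = np.bincount(labels.ravel())
    keep_ids = np.flatnonzero(counts * voxel_cc >= min_cc)
    keep_ids = keep_ids[keep_ids != 0]
    out = np.isin(labels, keep_ids)
    return MaskVolume(out, mask.label)


def gate_and_assign(
    roi: MaskVolume,
    pz: MaskVolume,
    tz: MaskVolume,
    cfg: SegmentationConfig,
    spacing: tuple[float, float, float],
    volume_cc_before: float | None = None,
) -> SegmentationResult:
    """Volume-gate the cleaned ROI and assign it to PZ or TZ.

    The whole ROI is assigned to PZ when its PZ overlap fraction strictly
    exceeds ``pz_fraction`` %, else to TZ.  NAT masks are the zone voxels
    outside the ROI and are derived for both zones regardless of the
    assignment.  An ROI below ``min_roi_cc`` is flagged rejected.
    """
    vol = volume_cc(roi, spacing)
    if volume_cc_before is None:
        volume_cc_before = vol
    n_roi = roi.n_voxels
    empty = np.zeros(roi.data.shape, dtype=bool)
    nat_pz = MaskVolume(pz.data & ~roi.data, "NAT_PZ")
    nat_tz = MaskVolume(tz.data & ~roi.data, "NAT_TZ")
    if n_roi == 0:
        return SegmentationResult(
            roi_wp=roi,
            zone=None,
            pz_roi_wp=MaskVolume(empty, "ROI"),
            tz_roi_wp=MaskVolume(empty, "ROI"),
            nat_pz=nat_pz,
            nat_tz=nat_tz,
            volume_cc_before=volume_cc_before,
            volume_cc_after=0.0,
            rejected=True,
        )
    rejected = vol < cfg.min_roi_cc
    frac_pz = float((roi.data & pz.data).sum()) / n_roi
    zone = "PZ" if frac_pz > cfg.pz_fraction / 100.0 else "TZ"
    pz_roi = MaskVolume(roi.data.copy() if zone == "PZ" else empty.copy(), "ROI")
    tz_roi = MaskVolume(roi.data.copy() if zone == "TZ" else empty.copy(), "ROI")
    return SegmentationResult(
        roi_wp=roi,
        zone=zone,
        pz_roi_wp=pz_roi,
        tz_roi_wp=tz_roi,
        nat_pz=nat_pz,
        nat_tz=nat_tz,
        volume_cc_before=volume_cc_before,
        volume_cc_after=vol,
        rejected=rejected,
    )


def segment_wp(
    nmf: NmfResult,
    pz: MaskVolume,
    tz: MaskVolume,
    cfg: SegmentationConfig | None = None,
    spacing: tuple[float, float, float] = (1.25, 1.25, 2.5),
) -> SegmentationResult:
    """Full stage: threshold W_wp, clean up, gate and assign the zone."""
    cfg = cfg or SegmentationConfig()
    if cfg.method == "purity":
        raw = purity_segment(nmf, cfg.beta)
    else:
        raw = otsu_segment(nmf)
    vol_before = volume_cc(raw, spacing)
    cleaned = cleanup_components(raw, cfg.cleanup_cc, spacing)
    return gate_and_assign(
        cleaned, pz, tz, cfg, spacing, volume_cc_before=vol_before
    )
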