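"""Per-voxel 1-10 aggressiveness maps and biopsy-overlap scoring.

Given the value ``F`` of a kinetic feature for the well-perfused ROI and
the ``W_wp`` weight map, each voxel's weight is scaled by ``F / omega``
where ``omega`` is the mean of ``W_wp`` over the ROI — so the continuous
map averages exactly to ``F`` inside the ROI and generalizes the feature
to the whole prostate.  For display and comparison the continuous values
are binned to a 1-10 scale bounded by the 5th and 95th percentiles of a
cohort's feature values: values below/above the bounds score 1/10, the
interval in between is divided into ten uniform half-open bins (the top
bin closed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decomposition import NmfResult
from .io_core import DceSeries, GleasonLabel, MaskVolume
from .kinetics import FeatureSet, SignalCurve, feature_set, mean_raw_curve
from .segmentation import SegmentationResult

__all__ = [
    "ScoreScale",
    "AggressivenessMap",
    "BiopsyRegion",
    "fit_scale",
    "score_value",
    "make_map",
    "score_biopsies",
]


@dataclass(frozen=True)
class ScoreScale:
    """Cohort-derived 1-10 binning of a feature: 5th/95th percentile bounds.

    The percentile convention (linear interpolation) is declared in the
    persisted JSON so scales are portable across implementations.
    """

    feature: str
    lower: float
    upper: float
    percentile_interpolation: str = "linear"

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError("scale requires lower < upper")

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / 10.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature": self.feature,
                    "lower": self.lower,
                    "upper": self.upper,
                    "percentiles": [5, 95],
                    "percentile_interpolation": self.percentile_interpolation,
                    "n_bins": 10,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreScale":
        d = json.loads(Path(path).read_text())
        return cls(feature=d["feature"], lower=d["lower"], upper=d["upper"])


@dataclass
class AggressivenessMap:
    """Continuous W_wp * F / omega map and its 1-10 binned version.

    Scores are defined wherever W_wp > 0; background voxels carry the
    sentinel 0, never a 1-10 score.
    """

    continuous: np.ndarray
    scores: np.ndarray
    omega: float
    feature: str
    F: float


@dataclass
class BiopsyRegion:
    """A biopsy track intersected with the well-perfused ROI."""

    name: str
    biopsy: MaskVolume
    us_roi: MaskVolume  # biopsy ∩ ROI_wp
    gleason: GleasonLabel
    features: FeatureSet | None  # None when usROI is empty
    map_mean: float
    empty: bool


def fit_scale(cohort_values, name: str) -> ScoreScale:
    """Bounds at the cohort's empirical 5th/95th percentiles."""
    v = np.asarray(cohort_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise ValueError("need at least 20 cohort values to fit a scale")
    lower, upper = np.percentile(v, [5, 95])
    if lower == upper:
        raise ValueError("degenerate cohort: all values equal")
    return ScoreScale(feature=name, lower=float(lower), upper=float(upper))


def score_value(x, scale: ScoreScale):
    """Bin feature value(s) to the 1-10 scale.

    Values below the lower bound score 1, above the upper bound 10; the
    bounded interval is divided into ten uniform half-open bins
    [edge, next-edge) with the top bin closed, so x = upper scores 10.
    Accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot score non-finite values")
    rel = (arr - scale.lower) / (scale.upper - scale.lower)
    s = 1 + np.floor(10.0 * rel).astype(int)
    s = np.clip(s, 1, 10)
    if arr.ndim == 0:
        return int(s)
    return s


def make_map(
    nmf: NmfResult,
    seg: SegmentationResult,
    F: float,
    scale: ScoreScale,
) -> AggressivenessMap:
    """Scale W_wp by F / omega and bin to 1-10.

    ``omega`` is the mean well-perfused weight over the segmented ROI, so
    the continuous map averages to F over the ROI by construction.
    """
    if seg.rejected:
        raise ValueError("cannot map a rejected segmentation")
    if not np.isfinite(F):
        raise ValueError("feature value F must be finite")
    w = nmf.W_wp
    inside = seg.roi_wp.data
    omega = float(w[inside].mean())
    if omega == 0:
        raise ValueError("omega is zero: no well-perfused weight in the ROI")
    continuous = w * (F / omega)
    scores = np.zeros(w.shape, dtype=int)
    defined = w > 0
    scores[defined] = score_value(continuous[defined], scale)
    return AggressivenessMap(
        continuous=continuous, scores=scores, omega=omega,
        feature=scale.feature, F=float(F),
    )


def score_biopsies(
    amap: AggressivenessMap,
    nmf: NmfResult,
    seg: SegmentationResult,
    series: DceSeries,
    biopsies: list[tuple[str, MaskVolume, GleasonLabel]],
    muscle: SignalCurve | None = None,
    curve_mode: str = "raw",
) -> list[BiopsyRegion]:
    """Score biopsy-track regions against the aggressiveness map.

    For each biopsy the overlap with the well-perfused ROI (usROI) yields
    a kinetic feature set from the average raw signal (``curve_mode``
    "raw", the default) or from the NMF-reconstructed curve
    ("reconstructed"), and the continuous map is averaged over the biopsy
    track (within the prostate, where the map is defined).  Biopsies with
    an empty usROI are flagged and carry no features.
    """
    if curve_mode not in ("raw", "reconstructed"):
        raise ValueError("curve_mode must be 'raw' or 'reconstructed'")
    prostate = nmf.prostate_mask
    out: list[BiopsyRegion] = []
    for name, bmask, gs in biopsies:
        us = MaskVolume(bmask.data & seg.roi_wp.data, "ROI")
        in_prostate = bmask.data & prostate
        map_mean = (
            float(amap.continuous[in_prostate].mean())
            if in_prostate.any()
            else np.nan
        )
        if us.n_voxels == 0:
            out.append(
                BiopsyRegion(
                    name=name, biopsy=bmask, us_roi=us, gleason=gs,
                    features=None, map_mean=map_mean, empty=True,
                )
            )
            continue
        if curve_mode == "raw":
            curve = mean_raw_curve(series, us, source="roi_raw_mean")
        else:
            from .kinetics import reconstruct_curve

            curve = reconstruct_curve(nmf, us)
        fs = feature_set(curve, muscle)
        out.append(
            BiopsyRegion(
                name=name, biopsy=bmask, us_roi=us, gleason=gs,
                features=fs, map_mean=map_mean, empty=False,
            )
        )
    return out
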