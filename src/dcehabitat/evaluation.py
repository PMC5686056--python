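"""Association statistics and the segmentation-method sweep.

Spearman rank correlation (average ranks for ties, t-approximation
p-value, exact permutation available for small n), ROC AUC by the
Mann-Whitney statistic with half-credit for ties, a Pearson concordance
between biopsy map means and usROI features, and a sweep of segmentation
operating points (method/beta x PZ fraction) reporting, per cell, the
correlation of ROI volume with Gleason group and the PZ/TZ/rejected
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MaskVolume, volume_cc
from .segmentation import (
    BETA_MENU,
    PZ_FRACTION_MENU,
    SegmentationConfig,
    segment_wp,
)

__all__ = [
    "spearman",
    "roc_auc",
    "concordance",
    "SweepCase",
    "sweep_segmentation",
]


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method='t'`` gives the usual t-approximation p-value;
    ``method='exact'`` enumerates all permutations of ``y`` (n <= 10)
    and returns the two-sided permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    rho, p = stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p)
    if method != "exact":
        raise ValueError("method must be 't' or 'exact'")
    if n > 10:
        raise ValueError("exact permutation p-value limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return float(rho), count / total


def roc_auc(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney statistic, ties get half credit.

    ``labels`` are "indolent"/"aggressive" strings or a boolean/0-1 array
    with the aggressive class positive.
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "US":
        pos = lab == "aggressive"
    else:
        pos = lab.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def concordance(biopsies, feature: str, normalized: bool = True):
    """Pearson r and least-squares slope of map means vs usROI features.

    ``biopsies`` is a list of scored biopsy regions; those with an empty
    usROI or an invalid feature are excluded.  Requires >= 3 valid points
    with non-degenerate variance.
    """
    xs, ys = [], []
    for b in biopsies:
        if b.empty or b.features is None:
            continue
        try:
            f = b.features.value(feature, normalized=normalized)
        except (ValueError, KeyError):
            continue
        if np.isfinite(f) and np.isfinite(b.map_mean):
            xs.append(f)
            ys.append(b.map_mean)
    if len(xs) < 3:
        raise ValueError("need at least 3 biopsies with a non-empty usROI")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in features or map means")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope


@dataclass
class SweepCase:
    """One cohort member for the segmentation sweep."""

    nmf: object  # NmfResult with wp_index set
    pz: MaskVolume
    tz: MaskVolume
    gs_group: int  # ordinal Gleason group code
    spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)


def sweep_segmentation(
    cases: list[SweepCase],
    methods: tuple = ("otsu",) + tuple(f"purity{b}" for b in BETA_MENU),
    fractions: tuple = PZ_FRACTION_MENU,
) -> pd.DataFrame:
    """Run every (method x PZ-fraction) cell over a cohort.

    Per cell: Spearman rho of cleaned ROI volume vs Gleason group over the
    non-rejected cases, its p-value, and the PZ / TZ / rejected counts
    (which always sum to the cohort size).
    """
    records = []
    for method in methods:
        if method == "otsu":
            base = dict(method="otsu")
        else:
            base = dict(method="purity", beta=float(method.removeprefix("purity")))
        for frac in fractions:
            cfg = SegmentationConfig(pz_fraction=float(frac), **base)
            vols, groups = [], []
            n_pz = n_tz = n_rej = 0
            for case in cases:
                seg = segment_wp(case.nmf, case.pz, case.tz, cfg, case.spacing)
                if seg.rejected:
                    n_rej += 1
                    continue
                if seg.zone == "PZ":
                    n_pz += 1
                else:
                    n_tz += 1
                vols.append(seg.volume_cc_after)
                groups.append(case.gs_group)
            if len(vols) >= 4 and np.ptp(vols) > 0 and np.ptp(groups) > 0:
                rho, p = spearman(vols, groups)
            else:
                rho, p = np.nan, np.nan
            records.append(
                {
                    "method": method,
                    "pz_fraction": frac,
                    "rho": rho,
                    "p": p,
                    "n_pz": n_pz,
                    "n_tz": n_tz,
                    "n_rejected": n_rej,
                }
            )
    return pd.DataFrame.from_records(records)
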