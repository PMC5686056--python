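"""Cohort-level association of DCE features with Gleason grade.

Runs the full pipeline over a 24-phantom cohort with grades cycling
6, 3+4, 4+3, 8 and computes the Spearman correlation of the
muscle-normalized early AUFC with the grade group, plus the ROC AUC for
the indolent (GS 6) vs aggressive (GS >= 7) split.
"""

import warnings

import numpy as np

warnings.filterwarnings("ignore")

from dcehabitat.decomposition import decompose
from dcehabitat.evaluation import roc_auc, spearman
from dcehabitat.io_core import GleasonLabel
from dcehabitat.kinetics import feature_set, mean_raw_curve, reconstruct_curve
from dcehabitat.phantom import GRADE_TO_GLEASON, cohort_configs, make_phantom
from dcehabitat.segmentation import SegmentationConfig, segment_wp

feats, groups, binaries = [], [], []
for cfg in cohort_configs(n=24, snr=20, seed=0):
    series, truth = make_phantom(cfg)
    nmf = decompose(series, truth.masks["prostate"], k=3)
    seg = segment_wp(
        nmf, truth.masks["PZ"], truth.masks["TZ"],
        SegmentationConfig(), series.spacing,
    )
    if seg.rejected:  # ROI_wp < 0.5 cc: excluded, as in clinical use
        continue
    fs = feature_set(
        reconstruct_curve(nmf, seg.roi_wp),
        mean_raw_curve(series, truth.masks["GM"]),
    )
    gl = GleasonLabel(*GRADE_TO_GLEASON[truth.lesion_grades[0]])
    feats.append(fs.value("early_aufc"))
    groups.append(gl.group4)
    binaries.append(gl.binary)

rho, p = spearman(feats, groups)
auc = roc_auc(np.asarray(feats), np.asarray(binaries))
print(f"cases analysed: {len(feats)} / 24 (rest rejected at the 0.5 cc gate)")
print(f"Spearman rho(early AUFC ratio, grade group) = {rho:.3f} (p = {p:.2g})")
print(f"ROC AUC indolent vs aggressive = {auc:.3f}")
# Positive rho and high AUC reflect the phantom's grade-monotone kinetics
# propagating through NMF, segmentation and feature extraction.
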