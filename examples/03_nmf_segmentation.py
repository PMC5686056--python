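"""Decompose prostate curves by NMF and segment the well-perfused ROI.

The three temporal patterns are ranked by their area under the curve over
the first 90 s; the winner is the well-perfused pattern S_wp and its
weight map W_wp is thresholded by the 60 % purity rule, cleaned of
components below 0.05 cc, and gated at 0.5 cc.
"""

import numpy as np

from dcehabitat.decomposition import auc_0_90, decompose
from dcehabitat.phantom import default_config, make_phantom
from dcehabitat.segmentation import SegmentationConfig, segment_wp

series, truth = make_phantom(default_config(snr=20, seed=0))
nmf = decompose(series, truth.masks["prostate"], k=3)

print(f"relative reconstruction residual: {nmf.residual:.3g}")
for m in range(nmf.k):
    tag = "  <- well-perfused" if m == nmf.wp_index else ""
    print(f"pattern {m}: AUC(0-90 s) = {auc_0_90(nmf.S[m], series.grid):6.2f}{tag}")

seg = segment_wp(
    nmf, truth.masks["PZ"], truth.masks["TZ"],
    SegmentationConfig(method="purity", beta=60, pz_fraction=10),
    series.spacing,
)
lesion = truth.masks["lesion_0"].data
dice = 2 * np.sum(seg.roi_wp.data & lesion) / (seg.roi_wp.data.sum() + lesion.sum())
print(
    f"ROI_wp: {seg.volume_cc_after:.2f} cc, zone {seg.zone}, "
    f"rejected={seg.rejected}"
)
print(f"Dice overlap with the true lesion: {dice:.3f}")
# Dice well above 0.6 means the purity rule isolated the programmed lesion.
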