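"""Multi-rater label fusion with MRF regularization.

Simulates 17 rater segmentations with boundary-localized label errors and
fuses them by voxelwise majority voting, with and without the Potts
smoothness prior, measuring agreement with the true template labels.
"""

import numpy as np

import taumap as tm

template = tm.make_template((32, 24, 24), (0.5, 0.5, 0.5), seed=0,
                            skeleton_shape=(8, 6))
votes = tm.simulate_label_votes(template, n_raters=17, flip_rate=0.2, seed=5)

truth = template.label_volume
rater_err = np.mean([(v != truth).mean() for v in votes])
print(f"17 raters, 20% boundary flip rate: "
      f"mean per-rater error {100 * rater_err:.2f}% of voxels")

plain = tm.consensus_labels(votes, mrf_beta=0.0)
smooth = tm.consensus_labels(votes, mrf_beta=0.1)
print(f"majority vote (beta=0):   {int((plain != truth).sum())} "
      f"voxels differ from the true labels")
print(f"with MRF prior (beta=0.1): {int((smooth != truth).sum())} "
      f"voxels differ")
print("The smoothness prior cleans up isolated boundary errors that "
      "survive plurality voting.")
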