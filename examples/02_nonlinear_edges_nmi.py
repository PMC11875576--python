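"""Detect a nonlinear (quadratic) coupling that linear correlation cannot see.

ROI 1 receives the band-limited second harmonic of ROI 0's band component:
the two signals are linearly uncorrelated but share their amplitude
envelope, so mutual information on coefficient magnitudes picks the edge
up while the complex correlation stays near its noise baseline.
"""

import numpy as np

import wavefbn as wf

cfg = wf.SyntheticConfig(
    n_per_group=1,
    n_rois=6,
    n_timepoints=240,
    nonlinear_edges=[wf.NonlinearEdge(0, 1, 2, "quadratic", 0.8)],
    seed=1,
)
subject = wf.generate_cohort(cfg).subjects[0]
dec = wf.fcwt_decompose(wf.resample_to_unit_rate(subject))

raw_nmi = wf.build_raw_fbn(dec, "nmi")
raw_ccc = wf.build_raw_fbn(dec, "ccc")

iu = np.triu_indices(6, 1)
rank_nmi = (raw_nmi.weights[iu] >= raw_nmi.weights[0, 1]).sum()
print(f"planted edge (0,1): NMIf weight {raw_nmi.weights[0, 1]:.3f} "
      f"(rank {rank_nmi} of {iu[0].size} edges, 1 = strongest)")
print(f"selected band pair: ({raw_nmi.band_k[0, 1]}, {raw_nmi.band_l[0, 1]}) "
      f"- the source band and (about) its second harmonic")
print(f"planted edge (0,1): CCCf weight {raw_ccc.weights[0, 1]:.3f} vs "
      f"cohort median {np.median(raw_ccc.weights[iu]):.3f}")
print(
    "A top NMIf rank with an unremarkable CCCf weight is the signature of a\n"
    "purely nonlinear dependence: the mutual-information network adds\n"
    "information the correlation network cannot represent."
)
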