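"""Resample an ROI time series to the unit-rate axis and inspect band structure.

Builds a two-ROI subject sharing a narrowband component at band 4 of the
default 0.03-0.24 analysis grid, decomposes both signals with the Morlet
wavelet transform, and reports the band combination where their complex
correlation peaks.
"""

import numpy as np

import wavefbn as wf

cfg = wf.SyntheticConfig(
    n_per_group=1,
    n_rois=2,
    linear_edges=[wf.LinearEdge(0, 1, 4, 1.0)],
    seed=1,
)
subject = wf.generate_cohort(cfg).subjects[0]
print(f"raw series: {subject.n_timepoints} points at TR = {subject.tr} s")

unit = wf.resample_to_unit_rate(subject)
print(f"unit-rate series: {unit.n_timepoints} points (physical f -> f x TR)")

dec = wf.fcwt_decompose(unit)
print(f"decomposition: {dec.n_bands} bands, centres {np.round(dec.band_freqs, 3)}")

edge = wf.best_band_pair(dec, 0, 1, measure="ccc")
print(
    f"best band pair for ROI 0 vs ROI 1: ({edge.band_k}, {edge.band_l}) "
    f"with |rc| = {edge.value:.3f}"
)
p = wf.ccc_permutation_pvalue(
    dec.coeffs[0, edge.band_k - 1], dec.coeffs[1, edge.band_l - 1], n_iter=1000, seed=1
)
print(f"permutation p-value at that pair: {p:.4f}")
print(
    "The coupling was planted at band 4, so the selected pair should be (4, 4)\n"
    "with a large correlation magnitude and a small p-value; unrelated bands\n"
    "would give |rc| near the smooth-noise baseline instead."
)
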