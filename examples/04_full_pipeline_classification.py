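"""Full pipeline on a small synthetic cohort: networks -> features -> classifier.

Generates a 14-subject cohort whose group-1 members carry three extra
linear couplings, runs the complete pipeline (wavelet decomposition, band-adaptive
CCC and NMI networks, thresholding, feature combination, nested-LOOCV
boosted trees) and prints the pooled classification metrics.

The cohort here is deliberately tiny so the example finishes in a couple
of minutes; `wavefbn.fast_preset("strong")` is the 40-subject
configuration used by the acceptance run.
"""

import wavefbn as wf

cfg = wf.SyntheticConfig(
    n_per_group=7,
    n_rois=10,
    group_diff_edges=[
        wf.LinearEdge(0, 1, 2, 0.9),
        wf.LinearEdge(2, 3, 5, 0.9),
        wf.LinearEdge(4, 5, 8, 0.9),
    ],
    seed=4,
)
cohort = wf.generate_cohort(cfg)

run_cfg = wf.RunConfig(
    permutation=wf.PermutationConfig(n_iter=200),
    grid=wf.HyperparameterGrid(n_random_draws=5),
    k_features=10,
    seed=4,
)
report = wf.run_pipeline(cohort.subjects, cohort.labels, run_cfg)

print(f"confusion counts: TP={report.tp} FP={report.fp} TN={report.tn} FN={report.fn}")
print(f"accuracy  {report.accuracy:.3f}")
print(f"precision {report.precision:.3f}")
print(f"recall    {report.recall:.3f}")
print(f"F1        {report.f1:.3f}")
print(f"AUC       {report.auc:.3f}")
print(
    "Group 1 subjects carry three planted couplings group 0 lacks, so the\n"
    "edge features at those ROI pairs separate the classes; accuracy and AUC\n"
    "well above 0.5 show the pipeline recovered that difference from the\n"
    "time series alone."
)
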