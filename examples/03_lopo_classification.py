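"""Leave-one-patient-out evaluation of one descriptor/classifier cell.

Generates a texture-separable phantom cohort, extracts the
wavelet-Haralick descriptor (all 12 subbands, 4 coefficients), and runs
the recursive-partitioning tree under LOPO with per-fold
standardization and per-cut majority voting. Cohen's kappa discounts
the agreement expected by chance, so 0 means "no better than guessing"
and 100 a perfect prediction.
"""

from irtex import (
    EffectSpec,
    build_dataset,
    extract_cohort_features,
    generate_cohort,
    lopo_cv,
)

patients = generate_cohort(EffectSpec(texture_effect=0.2, n_pos=15, n_neg=13, seed=9))
features = extract_cohort_features(patients, ["WDCF_fAllm4"])
dataset = build_dataset(patients, "WDCF_fAllm4", features)

predictions, report = lopo_cv(dataset, "rpart", seed=9)

print(f"cohort: {len(patients)} patients, descriptor WDCF_fAllm4 "
      f"({dataset.n_features} features per cut), classifier rpart\n")
print(f"kappa       {report.kappa:6.1f} %   (chance-corrected agreement)")
print(f"accuracy    {report.accuracy:6.1f} %")
print(f"sensitivity {report.sensitivity:6.1f} %   (KRAS+ detection rate)")
print(f"specificity {report.specificity:6.1f} %   (KRAS- detection rate)")
print(f"AUC         {report.auc:6.1f} %   (mean slice probability as patient score)")

cm = report.confusion
print(f"\nconfusion matrix (rows=biopsy, cols=computer): "
      f"[[{cm.tp} {cm.fn}] [{cm.fp} {cm.tn}]]")
mismatch = [pid for pid, t, v in zip(predictions.patient_ids,
                                     predictions.true_labels,
                                     predictions.voted_labels) if t != v]
print(f"misclassified patients: {mismatch if mismatch else 'none'}")
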