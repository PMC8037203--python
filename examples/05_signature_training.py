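"""SVM-RFE signature building and the published four-miRNA score.

Trains linear SVM classifiers over the up-regulated markers with
recursive feature elimination, reporting apparent and leave-one-out
accuracy per model size (elimination re-run inside every fold), then
applies the fixed published four-miRNA score to the same cohort.
"""

import warnings

from mirsig import (
    SynthConfig,
    calibrate_threshold,
    classify,
    generate_cq_dataset,
    livak_normalize_global,
    published_signature,
    quantile_normalize,
    score_samples,
    train_svm_rfe,
)

cq, sheet, truth = generate_cq_dataset(SynthConfig(n_per_group=15, seed=5))
controls = sheet.loc[sheet["group"] == "healthy", "sample_id"].tolist()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    expr = quantile_normalize(livak_normalize_global(cq, control_sample_ids=controls))
labels = sheet.set_index("sample_id").loc[expr.columns, "cancer"].to_numpy()

result = train_svm_rfe(expr, labels, truth.planted_up_assays, sizes=range(1, 7))
print("size  apparent  LOOCV   markers")
for k in result.sizes:
    print(f"{k:>4}  {result.apparent_accuracy[k]:.3f}     {result.loocv_accuracy[k]:.3f}"
          f"   {', '.join(m.replace('hsa-', '') for m in result.markers_by_size[k])}")

model = published_signature("tlda")
scores = score_samples(expr, model)
pred = classify(scores, model)
print(f"\npublished score (threshold > {model.threshold}): "
      f"{int(pred.sum())}/{len(pred)} called cancer "
      f"({int(labels.sum())} truly cancer)")
t_opt = calibrate_threshold(scores.to_numpy(), labels)
print(f"accuracy-optimal threshold on this cohort: {t_opt:.3f}")
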