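"""Train and evaluate the gain-ratio decision tree on screened candidates.

Runs the whole workflow in one call: simulate, screen on the training
split, 5-fold stratified cross-validation, final tree on all 105 training
samples, and one evaluation on the held-out 47-sample test split.
"""

from metabroscreen import GeneratorConfig, PipelineConfig, run_full_pipeline

cfg = PipelineConfig(generator=GeneratorConfig(n_ions=2000, n_markers=6, seed=42))
report = run_full_pipeline(cfg)

print(f"candidates selected: {report['screening']['n_candidates']}")

cv = report["cross_validation"]
print("\n5-fold cross-validation (training split):")
print("fold\taccuracy\tsensitivity\tspecificity")
for row in cv["per_fold"]:
    print(f"{row['iteration']}\t{row['accuracy']:.2f}%\t{row['sensitivity']:.2f}%\t"
          f"{row['specificity']:.2f}%")
print(f"mean\t{cv['mean']['accuracy']:.2f}%\t{cv['mean']['sensitivity']:.2f}%\t"
      f"{cv['mean']['specificity']:.2f}%")
print(f"sample SD\t{cv['sd_sample']['accuracy']:.2f}\t"
      f"{cv['sd_sample']['sensitivity']:.2f}\t{cv['sd_sample']['specificity']:.2f}")

t = report["independent_test"]
print(f"\nindependent test (32 case / 15 control): "
      f"accuracy={t['accuracy']:.2f}%  sensitivity={t['sensitivity']:.2f}%  "
      f"specificity={t['specificity']:.2f}%")
print(f"confusion counts: {t['counts']}")
# Sensitivity is the fraction of case samples called case; specificity the
# fraction of controls called control; accuracy their prevalence-weighted mix.
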