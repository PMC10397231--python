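"""Cohort study: detect diffuse vessel narrowing from hemodynamic features.

Generates 20 synthetic subjects, half with every vessel radius multiplied by
0.7 (a diffuse vasoconstrictive condition), runs each through the full
image -> graph -> surface -> simulation pipeline, selects features with the
F-test threshold scan, and reports leave-one-out accuracy for the whole
classifier battery.
"""

from sklearn.svm import SVC

from fvs3d import pipeline as pl
from fvs3d.selection import evaluate_classifiers, ftest_threshold_scan
from fvs3d.synthetic import make_cohort

cfg = pl.PipelineConfig(seed=1, px_size=10e-4)
bundles = make_cohort(n_subjects=20, narrowed_fraction=0.5, narrowing=0.7,
                      seed=1)
table = pl.cohort_feature_table(bundles, cfg)
print(f"feature table: {table.n_subjects} subjects x "
      f"{table.features.shape[1]} features")

sel = ftest_threshold_scan(table, classifier=SVC(random_state=0), seed=0)
print(f"F-test scan: kept {len(sel.selected)} features at "
      f"p < {sel.details['threshold']:.3f}; "
      f"scan LOOCV accuracy {sel.accuracies['scan_classifier']:.2f}")

accs = evaluate_classifiers(table, sel, seed=0)
print("leave-one-out accuracy per classifier:")
for name, acc in sorted(accs.items(), key=lambda kv: -(kv[1] or 0)):
    print(f"  {name:20s} {acc if acc is None else round(acc, 3)}")
print("accuracy 1.0 means every held-out subject's narrowing status was "
      "recovered from simulated pressures/flows alone.")
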