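"""Full protocol on a small synthetic cohort (a few minutes of compute).

Generates 60 adult subjects as phantoms with a known %BF model, extracts
BV_PHOTO and trunk curves from their images, and runs the 3-fold
cross-validation: per-fold shape clustering, coarse-grid nu-SVR training
for three feature sets, pooled out-of-fold predictions.
"""

from photobf import agreement, pipeline, synthetic
from photobf.model import SVRConfig, cross_validate

spec = synthetic.CohortSpec(n=60, seed=7)
subjects = synthetic.generate_cohort(spec)
records = pipeline.records_from_synthetic(subjects)
result = cross_validate(records, SVRConfig.coarse(seed=0), seed=0)

print("pooled out-of-fold Pearson r vs the DXA criterion:")
for name, r in result.pearson_r.items():
    print(f"  {name:14s} r = {r:.3f}")
preds = result.predictions
cmp_ = agreement.compare_methods(preds["bf_dxa"], preds["bf_photo"], preds["bf_nophoto"])
print(agreement.comparison_table(cmp_))
print("Meng's Z tests whether the photographic model correlates with the")
print("criterion better than the demographic baseline. At n=60 the planted")
print("shape effect is usually within noise; at the study-scale n=200 used in")
print("scripts/acceptance.py the gain is consistently significant (p < 0.05).")
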