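"""The orchestrated pipeline on the two stated worlds.

One call runs impute -> weight -> balance -> fit -> pool -> calibrate ->
classify and writes CSV/JSON artifacts stamped with the config hash.  The
vocabulary world has equal joint effects (the constant model should win);
the syntax world has opposite-signed effects (differing-effects evidence).
"""

from pathlib import Path

import quantiptw as q

out = Path("scratch_pipeline")

vocab = q.run_pipeline(q.PipelineConfig(
    outdir=str(out / "vocab"), preset="vocab", n=64, seed=1,
    z1_covariates=("parent_verbal_iq", "income"), z2_covariates=("z1", "x1"),
    m=5,
))
syntax = q.run_pipeline(q.PipelineConfig(
    outdir=str(out / "syntax"), preset="syntax", n=64, seed=1,
    z1_covariates=("parent_verbal_iq", "birth_order", "child_word_types_14"),
    z2_covariates=("z1", "x1", "parent_verbal_iq"),
    m=5,
))

for name, man in (("vocab", vocab), ("syntax", syntax)):
    eq = man["equal_effects_test"]
    cal = man["calibration"]
    print(f"[{name}]")
    print(f"  best model by mean AICc : {man['best_model']}")
    print(f"  equal-effects test      : diff {eq['estimate']:+.3f}, p = {eq['p']:.3f}")
    print(f"  calibrated profile gap  : {cal['standardized_difference']:+.2f} outcome SDs")
    print(f"  artifacts               : {man['artifacts']}")
print("\nclassification.csv labels each child's predicted outcome "
      "(high/mid/low) for the scatter of earlier vs later input; the "
      "equal-effects p separates the 'cumulative input' world from the "
      "'sequence matters' world.")
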