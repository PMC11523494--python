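"""Compare left vs right sides and two species with the exact-test and
model-selection layer, on a small simulated study.

Twelve individuals of two species, both molars each; species shifts DNE by
-80 units.  The paired signed-rank test checks sides, and the eight-model
AICc family asks which factors (side, sex, species) predict DNE.
"""

import numpy as np

import molartopo as mt

rng = np.random.default_rng(0)
records = []
for i in range(12):
    species = "cuspy" if i < 6 else "cresty"
    sex = "F" if i % 2 else "M"
    base = 500.0 - 80.0 * (species == "cresty") + rng.normal(0, 15)  # individual
    for side in ("L", "R"):
        records.append(mt.SpecimenRecord(
            f"ind{i}", species, sex, side,
            {"dne": base + rng.normal(0, 10)}))

df = mt.records_to_frame(records)
wide = df.pivot(index="individual_id", columns="side", values="dne")
test = mt.signed_rank_exact((wide["L"] - wide["R"]).to_numpy())
print(f"side (L vs R): W = {test.statistic:.0f}, exact p = {test.p_two_sided:.3f}"
      f"  (n = {test.n} pairs; no side effect was simulated)")

fits = mt.fit_model_family(df, "dne", estimator="random_intercept")
print("\nmodel selection for DNE (8 fixed-effect subsets, AICc):")
for f in fits:
    effects = "+".join(f.fixed_effects) or "(intercept)"
    print(f"  {effects:<22} k={f.k}  AICc={f.aicc:8.2f}  "
          f"dAICc={f.delta_aicc:6.2f}  w={f.akaike_weight:.3f}")
best = fits[0]
coef = best.coefficients.get("species[cuspy]", float("nan"))
se = best.stderr.get("species[cuspy]", float("nan"))
print(f"\nbest model: {'+'.join(best.fixed_effects) or '(intercept)'};"
      f" species[cuspy] = {coef:.1f} +- {se:.1f}"
      "\n(true cuspy-minus-cresty difference is +80; 'cresty' is the"
      " reference level, so the sign is positive)")
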