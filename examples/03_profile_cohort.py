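"""Full profiling spine on the default synthetic cohort.

Feature tables are simulated directly from the latent-factor generator
(the fast equivalent of render -> segment -> featurize), then z-scored per
plate, reduced by factor analysis to ~80% of total variance, averaged per
well, and scored by an LDA trained only on albumin-free conditions.
"""

import warnings

from ecmorph.profiles import (
    arm_shift,
    factor_component_map,
    per_factor_tests,
    profile_cohort,
)
from ecmorph.synthetic import (
    LayoutConfig,
    default_latent_spec,
    generate_feature_table,
    generate_study_layout,
)

layout = generate_study_layout(LayoutConfig(), seed=1)
spec = default_latent_spec(seed=0)
table = generate_feature_table(spec, cells_per_well=60, layout=layout, seed=1)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    run = profile_cohort(table, n_max=16)

print(f"factor analysis kept {run.factor_model.n_factors} factors "
      f"({run.factor_model.cumulative_variance:.1%} of total variance)")
print("\nmedian LD1 per condition (low = healthy-like):")
print(run.median_ld1().round(2))

shift, sd = arm_shift(run.lda_scores, "HC", "none", "supraphysiological")
print(f"\nHC supraphysiological-albumin shift: {abs(shift) / sd:.2f} pooled SD "
      "(null, as expected — albumin does not change healthy plasma responses)")

tests = per_factor_tests(run.well_profiles, group="DC")
attribution = factor_component_map(run.factor_model, spec.tags_map())
top = tests.sort_values(["q_value", "p_value", "factor"]).iloc[0]
row = attribution.set_index("factor").loc[top["factor"]]
print(f"\nmost significantly restored factor: {top['factor']} "
      f"(q = {top['q_value']:.2e}), dominated by '{row['dominant']}' features "
      f"(weight {row['weight_mitochondria']:.2f}) — albumin restores the "
      "mitochondrial component of the profile.")
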