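"""Attach an exploratory permutation p-value to one parameter pair.

Generates a cohort with a quadratic P1-P2 relation at 5 % noise plus an
unrelated noise parameter, and runs the permutation test on both the
planted and a null pair.  The planted pair should get the smallest
attainable p-value (1/(B+1)); the noise pair a large one.
"""

from pairscreen import (CohortSpec, PlantedRelation, generate_cohort,
                        permutation_significance, population_by_name)

spec = CohortSpec(n_treated=15, n_control=15, survival_rate_treated=1.0,
                  survival_rate_control=1.0, n_parameters=3,
                  time_grid=(0,), n_studies=2, missing_rate=0.0,
                  rng_seed=23)
relation = PlantedRelation("P1", "P2", "quadratic", (1.0, -8.0, 18.0),
                           populations=("VII",), noise_sd=0.05)
db, _ = generate_cohort(spec, [relation])
pop = population_by_name("VII")

for px, py in [("P1", "P2"), ("P1", "P3")]:
    pair = db.extract_clean_pair(px, py, 0, pop)
    p_best = permutation_significance(pair, policy="refit-best",
                                      n_permutations=19, seed=1)
    p_lin = permutation_significance(pair, policy="refit-linear",
                                     n_permutations=199, seed=1)
    print(f"{px}~{py}: n={pair.n}  p={p_best:.3f} (refit-best, B=19)  "
          f"p={p_lin:.4f} (refit-linear, B=199)")

print("\np = 1/(B+1) is the smallest value B permutations can resolve "
      "(0.05 at B=19, 0.005 at B=199).  The planted U-shaped quadratic "
      "has little *linear* correlation, so the cheap refit-linear policy "
      "barely flags it while the full refit-best policy pins it at the "
      "resolution floor — exactly why non-linear refitting matters.  "
      "These p-values are exploratory — no correction is applied for "
      "the many cells a full screen tests.")
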