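"""Classify pairs as lockstep, early or late markers from gof time courses.

Plants two relations in a four-time-point cohort: P3-P4 coupled at
every time point (a lockstep pair, like bicarbonate and base excess)
and P1-P2 coupled only at the last two time points (a late marker,
like the glucose-pH coupling that emerges with disease progression).
Screens all time points, ranks pairs by how much their best-fit gof
changes (max - min), and labels each profile.
"""

from pairscreen import (CohortSpec, FitConfig, PlantedRelation, TaskGrid,
                        classify_marker_timing, generate_cohort,
                        list_prototypes, population_by_name, rank_by_change,
                        run_screen, time_course)

TIMES = (0, 60, 120, 180)
spec = CohortSpec(n_treated=30, n_control=0, survival_rate_treated=1.0,
                  n_parameters=4, time_grid=TIMES, n_studies=2,
                  missing_rate=0.0, rng_seed=42)
relations = [
    PlantedRelation("P1", "P2", "linear", (2.0, 1.0), populations=("III",),
                    time_points=(120, 180), noise_sd=0.01),
    PlantedRelation("P3", "P4", "linear", (1.5, 2.0), populations=("III",),
                    noise_sd=0.01),
]
db, _ = generate_cohort(spec, relations)

pop = population_by_name("III")
grid = TaskGrid.build(db.parameters, TIMES, [pop], list_prototypes())
screen = run_screen(db, grid, FitConfig(rng_seed=1))

profiles = {}
for i, px in enumerate(db.parameters):
    for py in db.parameters[i + 1:]:
        profiles[f"{px}~{py}"] = time_course(screen.best_results, px, py,
                                             "III", TIMES)

print("gof change ranking (max - min across time points):")
print(rank_by_change(profiles).round(3).to_string(index=False))
print("\nper-pair profiles and labels:")
for cell, prof in profiles.items():
    label = classify_marker_timing(prof, high=0.7, low=0.3)
    pretty = "  ".join(f"{g:5.2f}" for g in prof)
    print(f"  {cell}: [{pretty}]  ->  {label}")
print("\nP1~P2 should rank first and be labeled 'late' (coupling emerges "
      "at 120-180 min); P3~P4 is 'lockstep'; noise pairs are 'other'.")
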