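"""From raw records to balanced training data.

Occurrence filtering (stream buffer, accuracy, dates), survey-based
absences, the kernel-density sampling-bias surface and bias-matched
pseudoabsence draws.
"""

from streamsdm.labels import (LabelSet, assign_presences, build_replicates, derive_absences,
                              kde_bias_surface)
from streamsdm.pipeline import simulate_study

study = simulate_study(seed=42, nrows=120, ncols=120, accum_threshold_cells=50,
                       n_records=200, n_survey_units=40)

presences = assign_presences(study.occurrences, study.streams, study.grid,
                             buffer_m=50, max_accuracy_m=160)
recent = assign_presences(study.occurrences, study.streams, study.grid,
                          buffer_m=50, max_accuracy_m=160, date_window=(2005, 2013))
absences = derive_absences(study.surveys, recent, min_night=8, min_day=5)
print(f"{len(study.occurrences)} records -> {len(presences)} presence units (all years), "
      f"{len(recent)} recent (2005-2013)")
print(f"surveys -> {len(absences)} verified-absence units "
      f"(>=8 night or >=5 day visits, never detected)")

pool = set(study.grid.uids) - recent - absences
bias = kde_bias_surface(recent, study.grid, candidates=pool)
print(f"bias surface: bandwidth {bias.bandwidth_m:.0f} m, "
      f"weight ratio max/min = {bias.weights.max() / bias.weights.min():.1f}")

labels = LabelSet(recent, absences, "current")
replicates = build_replicates(labels, bias, study.grid, n_replicates=10, seed=1)
counts = replicates[0].rows["label_source"].value_counts()
print(f"each replicate: {counts.get('presence', 0)} presences + "
      f"{counts.get('absence', 0)} absences + {counts.get('pseudoabsence', 0)} "
      f"pseudoabsences (balanced 1:1)")
# Pseudoabsences are drawn where sampling effort was, not uniformly, so
# the forest contrasts habitat and background under the same bias.
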