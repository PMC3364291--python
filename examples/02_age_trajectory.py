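"""Exclude developmental regulation from a variance screen.

A gene whose mean tracks age would inflate young-group variance without
being genuinely more variable between individuals.  The quadratic age
model flags such genes among the screen's hits.
"""

import devvar as dv

cfg = dv.SimulationConfig(
    n_probes=3000, frac_dv=0.05, frac_dev=0.05, sd_ratio=3.0, seed=29
)
matrix, samples, truth = dv.simulate_expression_study(cfg)
log2, subjects, _ = dv.preprocess_study(
    matrix, samples, dv.StudyConfig(simulation=cfg, seed=29)
)

screen = dv.run_variance_screen(log2, subjects, fraction=0.1)
hits = list(screen.index[screen["significant"]])
print(f"{len(hits)} probes significant in the variance screen")

table = dv.screen_age_regulated(log2, subjects, probes=hits, q_cutoff=0.25)
flagged = table.index[table["developmentally_regulated"]]
print(f"{len(flagged)} of them are developmentally regulated at pFDR<0.25")

dev_truth = set(truth.probes_of_class("dev"))
print(f"of the flagged, {len(set(flagged) & dev_truth)} carry a planted "
      "quadratic age trajectory")
# Hits surviving this exclusion are variable across same-age individuals
# rather than merely changing with age.
print(f"surviving differential-variability candidates: "
      f"{len(hits) - len(flagged)}")
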