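"""The full subsampling comparison: two series of random subsamples at
sizes 50..220 from a 243-subject base cohort, both models fitted and scored
on each subsample, plus a total-sample row per series."""

import discrimbench as db

base = db.generate_cohort(db.paper_like(seed=7))
table = db.run_comparison(base, db.ExperimentConfig(seed=7))
print("selected predictors:", table.metadata["selected_predictors"])
print(db.render_table(table, fmt="markdown"))
# Each row: one subsample. Q/B higher = better, %CE lower = better.
# Note how %CE flips between LR and LDA across rows while B and Q rank
# the models far more consistently.
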