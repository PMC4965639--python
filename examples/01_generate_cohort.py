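"""Generate the default study-like cohort and look at its structure.

The preset draws 243 subjects with a binary depression outcome and three
predictors (satisfaction, family history, duration of cancer), calibrated so
that the best achievable misclassification rate is near one third.
"""

import discrimbench as db

cohort = db.generate_cohort(db.paper_like(seed=7))
print(f"n = {cohort.n}, prevalence = {cohort.outcome.mean():.3f}")
print("schema:")
for p in cohort.schema:
    print(f"  {p.name}: {p.kind}")
print(cohort.data.head())
# prevalence is the fraction of depressed subjects; the three predictor
# columns are the inputs both classifiers will see
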