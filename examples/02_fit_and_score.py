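"""Fit both classifiers on one cohort and score them with CE, B and Q.

CE counts hard misclassifications; B (Brier-complement) and Q (base-2 log
score) also reward well-calibrated probabilities, so they can separate two
models that CE cannot.
"""

import discrimbench as db

cohort = db.generate_cohort(db.paper_like(seed=7))
y = cohort.outcome

lr = db.fit_logistic(cohort)
lda = db.fit_lda(cohort)
print("LR coefficients:", {k: round(v, 3) for k, v in lr.coefficients.items()})
print("LDA priors:", tuple(round(p, 3) for p in lda.priors))

for name, pred in [
    ("LR", db.predict_logistic(lr, cohort)),
    ("LDA", db.predict_lda(lda, cohort)),
]:
    rep = db.index_report(pred, y)
    print(f"{name}: CE={100*rep.ce:.1f}%  B={rep.b:.5f}  Q={rep.q:.5f}")
# higher B and Q are better (1 = perfect); for CE lower is better.
# Expect the two models to differ more on B/Q than on CE.
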