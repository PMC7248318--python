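"""Fit HUSDOS-Boost on a synthetic rare-event table and evaluate it.

Generates a 20-minority / 2,000-majority dataset (1% imbalance, two
informative variables shifted by 1.5 within-class SDs), fits the boosted
ensemble, and scores it on an independently generated test sample. The
printed G-mean is the geometric mean of sensitivity (minority recall) and
specificity; an all-majority classifier would score 0.
"""

import logging

import husdosboost as hb

logging.disable(logging.WARNING)

train, truth = hb.generate_eism(hb.SynthConfig(seed=1))
test, _ = hb.generate_eism(hb.SynthConfig(seed=2))

model = hb.fit(train, hb.BoostConfig(seed=1))

print(f"training rows: {train.n} ({train.labels.sum()} minority)")
print(f"weak classifiers fitted: {model.n_rounds_fitted}")
print(f"informative variables: {', '.join(truth.informative)}")
print()
report = hb.evaluate(test.labels, model.predict(test.features),
                     model.score(test.features))
print("held-out performance:")
print(report.to_text())
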