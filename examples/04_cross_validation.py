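"""Leakage-safe five-fold cross-validation on the synthetic benchmark.

Known interactions are the positives; an equal number of random non-edges
are negatives.  Each fold holds out 20% of the pairs; held-out interactions
are removed from the graph before meta-path walks are generated, so the
structure embeddings never see a test edge.  Takes about a minute.
"""

import logging

from dtifusion import SyntheticSpec, cross_validate, gen_dataset
from dtifusion.pipeline import benchmark_config

logging.basicConfig(level=logging.WARNING)

dataset, _ = gen_dataset(SyntheticSpec(seed=0))
report = cross_validate(dataset, benchmark_config(), seed=0)
print(report.summary_frame().to_string())
# Columns: accuracy, precision, sensitivity, F1, Matthews correlation, AUC —
# one row per fold plus the mean +/- sample standard deviation.  On this
# planted-block fixture the AUC sits far above the 0.5 chance level but below
# the fixture's block-equality oracle (~0.87): one fifth of the sampled
# negatives are same-block pairs indistinguishable from held-out edges.
print("\nmean AUC:", round(report.mean("AUC"), 4))
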