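"""Build a heterogeneous drug/target/disease network and generate meta-path walks.

Creates a small synthetic tripartite network, prints its composition, and
shows a schema-constrained walk: node types alternate according to the
meta-path template, and each step moves uniformly among typed neighbors.
"""

import numpy as np

from dtifusion import MetaPathSchema, SyntheticSpec, build_corpus, gen_dataset, generate_walk

dataset, blocks = gen_dataset(SyntheticSpec(seed=0))
print("network composition:", dataset.graph.summary())
# n_DTI counts the known drug-target interactions (the prediction targets);
# n_DDI / n_DDA are the auxiliary drug-drug and drug-disease relations.

schema = MetaPathSchema.from_string("dr-t-dr")
walk = generate_walk(
    dataset.graph, schema, start=dataset.drugs[0], n_instances=4,
    rng=np.random.default_rng(0),
)
print("\nschema dr-t-dr, 4 chained instances ->", len(walk.tokens), "tokens:")
print(" ".join(walk.tokens))
# 4 instances of a length-3 template chained head-to-tail give 4*2+1 = 9
# tokens; drug and target ids alternate.

corpus = build_corpus(dataset.graph, restarts=10, n_instances=8, seed=0)
print(f"\ncorpus: {len(corpus.walks)} walks over {len(corpus.vocabulary)} distinct nodes")
# One coverage walk per eligible start node per schema plus 10 random
# restarts per schema; these sentences feed the CBOW embedding stage.
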