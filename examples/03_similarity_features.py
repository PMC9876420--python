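"""Similarity-modality features: Jaccard over substructures, normalized
Smith-Waterman over protein sequences.

Each entity's feature vector is its row of the similarity matrix, so close
entities share similar rows.
"""

import numpy as np

from dtifusion.similarity import (
    drug_similarity,
    jaccard,
    normalized_sw,
    protein_similarity,
    substructure_sets,
)

smiles = {"dr:eth": "CCO", "dr:prop": "CCCO", "dr:ben": "c1ccccc1"}
sets = substructure_sets(smiles)  # Morgan fingerprints when RDKit parses
print("Jaccard(ethanol, propanol) =", round(jaccard(sets["dr:eth"], sets["dr:prop"]), 3))
print("Jaccard(ethanol, benzene)  =", round(jaccard(sets["dr:eth"], sets["dr:ben"]), 3))
# Shared substructures dominate the first pair; the aromatic ring shares
# almost nothing with ethanol.

dsim = drug_similarity(smiles)
print("\ndrug similarity matrix (rows are feature vectors):")
print(np.round(dsim.values, 3))

proteins = {
    "t:a": "MKTAYIAKQRQISFVKSHFSRQ",
    "t:b": "MKTAYIAKQRQISFVKAHFSRQ",  # one substitution from t:a
    "t:c": "GGGGGGPPPPPPWWWWWW",
}
print("\nnormalized SW(t:a, t:b) =", round(normalized_sw(proteins["t:a"], proteins["t:b"]), 3))
print("normalized SW(t:a, t:c) =", round(normalized_sw(proteins["t:a"], proteins["t:c"]), 3))
psim = protein_similarity(proteins)
print("protein similarity diagonal:", np.diag(psim.values))
# Self-normalization makes every self-similarity exactly 1 and bounds the
# off-diagonal values by [0, 1].
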