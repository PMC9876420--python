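"""Sequence-modality features: SMILES symbol embeddings and conjoint triads.

Drugs: each SMILES string is a sentence of symbols; CBOW embeddings of the
symbols are mean-pooled into one vector per drug.  Proteins: residues are
reduced to 7 physicochemical classes, triad occurrences form a sparse
343 x (n-2) indicator matrix, and the scaled leading left singular vector
is the 343-dim protein descriptor.
"""

import numpy as np

from dtifusion import TokenCorpus, embed_mean, tokenize_smiles, train_cbow
from dtifusion.proteins import protein_vector, reduce_alphabet, triad_matrix

smiles = {"dr:eth": "CCO", "dr:ace": "CC(=O)O", "dr:ben": "c1ccccc1"}
sentences = {d: tokenize_smiles(s) for d, s in smiles.items()}
print("tokens of CC(=O)O:", sentences["dr:ace"])

table = train_cbow(
    TokenCorpus.from_sentences(sentences.values()), dim=8, window=5, epochs=20, seed=0
)
for drug, toks in sentences.items():
    vec = embed_mean(toks, table)
    print(f"{drug}: mean symbol embedding, first 3 dims = {np.round(vec[:3], 3)}")
# Each drug vector is the row-average of its symbols' embeddings (dim 8 here
# for display; the pipeline default is 343).

protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
reduced = reduce_alphabet(protein)
print("\nfirst 10 residue classes:", reduced.classes[:10])
L = triad_matrix(reduced)
print("triad indicator matrix:", L.shape, "with", L.nnz, "ones (one per column)")
v = protein_vector(protein)
print(f"protein vector: dim {v.shape[0]}, norm {np.linalg.norm(v):.3f} (= top singular value)")
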