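"""Atom signatures: canonical neighborhood keys and occurrence vectors.

Builds the height-1..3 signature vocabulary of three small molecules and
shows the sparse count vector of aspirin under it.
"""

import confomer as cf

mols = {name: cf.parse_smiles(s) for name, s in [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("benzene", "c1ccccc1"),
]}

print("height-1 signatures of ethanol (one per heavy atom):")
ethanol = cf.parse_smiles("CCO")
for i in range(ethanol.GetNumAtoms()):
    print(f"  atom {i}: {cf.atom_signature(ethanol, i, 1).canonical}")

vocab = cf.build_vocabulary(list(mols.values()), heights=(1, 2, 3),
                            min_count=1)
print(f"\nvocabulary over 3 molecules: {len(vocab)} distinct signatures")

fv = cf.vectorize(mols["aspirin"], vocab)
print(f"aspirin vector: {len(fv.counts)} nonzero features, "
      f"novelty {fv.novelty:.2f} (0 = fully in-vocabulary)")

# every height contributes exactly one signature per heavy atom
n_heavy = mols["aspirin"].GetNumHeavyAtoms()
per_height = {h: sum(c for s, i in vocab.entries.items()
                     if s.height == h for c in [fv.counts.get(i, 0)])
              for h in (1, 2, 3)}
print(f"per-height occurrence sums {per_height} == heavy atoms ({n_heavy})")
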