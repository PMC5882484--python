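"""Atom-level interpretation of a prediction.

Computes the perturbation gradient of a trained model for atenolol and
writes a 2D depiction where red atoms push the predicted property up and
blue atoms push it down.
"""

import numpy as np

import confomer as cf

compounds = cf.make_molecule_dataset(300, seed=11)
vocab = cf.build_vocabulary(compounds, heights=(1, 2, 3), min_count=1)
X = [cf.vectorize(c.mol, vocab) for c in compounds]
y = np.array([c.y for c in compounds])
ccp = cf.ccp_fit((X, y), k=10, seed=11, vocabulary=vocab)

comp = cf.fixtures.exemplar("atenolol")
result = cf.atom_gradient(ccp, comp.mol)

print(f"atenolol predicted midpoint: {result.midpoint:+.2f}")
print("per-atom contributions (positive -> raises the prediction):")
for atom, value in sorted(result.per_atom.items()):
    symbol = comp.mol.GetAtomWithIdx(atom).GetSymbol()
    print(f"  atom {atom:2d} ({symbol}): {value:+.3f}")

cf.render_gradient(comp.mol, result, "atenolol_gradient.svg")
print("\nwrote atenolol_gradient.svg (blue = negative, red = positive)")
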