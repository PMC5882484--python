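"""Per-descriptor prediction gradients and per-atom contribution coloring.

The gradient of a prediction with respect to a signature descriptor is
estimated by perturbation: the occurrence count of that descriptor is
incremented by one, the molecule is re-predicted, and the change in the
endpoint prediction is the gradient.  Only descriptors actually present in
the molecule are perturbed.  Each CCP member yields its own gradient; the
reported value is the member median.  Per-atom contributions are obtained
by summing, for each atom, the gradients of every descriptor whose
subgraph contains that atom — positive (red) atoms push the prediction up,
negative (blue) atoms push it down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .conformal import CcpModel, ccp_predict
from .errors import RenderError
from .linear_model import predict
from .signatures import FeatureVector, SignatureVocabulary, vectorize


@dataclass
class GradientResult:
    per_descriptor: dict[int, float]
    per_atom: dict[int, float]
    midpoint: float

    @property
    def scale(self) -> float:
        """Max absolute per-atom value, for symmetric color normalization."""
        if not self.per_atom:
            return 0.0
        return max(abs(v) for v in self.per_atom.values())


def descriptor_gradient(ccp: CcpModel, x: FeatureVector) -> dict[int, float]:
    """Median-over-members prediction change from one extra occurrence of
    each descriptor present in the molecule."""
    if not x.counts:
        raise ValueError("feature vector has no nonzero entry")
    out: dict[int, float] = {}
    for j in x.counts:
        grads = []
        for icp in ccp.members:
            base = predict(icp.endpoint, x.counts)
            bumped = dict(x.counts)
            bumped[j] = bumped[j] + 1
            grads.append(predict(icp.endpoint, bumped) - base)
        out[j] = float(np.median(grads))
    return out


def atom_gradient(ccp: CcpModel, mol: Chem.Mol,
                  vocabulary: SignatureVocabulary | None = None,
                  confidence: float = 0.8) -> GradientResult:
    """Vectorize, compute descriptor gradients and fold them onto atoms."""
    vocab = vocabulary if vocabulary is not None else ccp.vocabulary
    if vocab is None:
        raise ValueError("a signature vocabulary is required")
    fv = vectorize(mol, vocab)
    per_desc = descriptor_gradient(ccp, fv) if fv.counts else {}
    per_atom = {
        a: sum(per_desc.get(j, 0.0) for j in feats)
        for a, feats in fv.atom_map.items()
    }
    midpoint = ccp_predict(ccp, fv, confidence).midpoint
    return GradientResult(per_descriptor=per_desc, per_atom=per_atom,
                          midpoint=midpoint)


def _diverging_color(v: float, scale: float) -> tuple[float, float, float]:
    """Blue (negative) -> white (zero) -> red (positive)."""
    if scale <= 0:
        return (1.0, 1.0, 1.0)
    t = max(-1.0, min(1.0, v / scale))
    if t >= 0:
        return (1.0, 1.0 - 0.8 * t, 1.0 - 0.8 * t)
    return (1.0 + 0.8 * t, 1.0 + 0.8 * t, 1.0)


def render_gradient(mol: Chem.Mol, result: GradientResult,
                    path: str) -> None:
    """Write a 2D depiction with atoms colored by signed contribution.

    SVG output always works; PNG requires an RDKit build with Cairo.
    """
    from rdkit.Chem.Draw import rdMolDraw2D

    path = str(path)
    try:
        if path.endswith(".png"):
            drawer = rdMolDraw2D.MolDraw2DCairo(450, 400)
        else:
            drawer = rdMolDraw2D.MolDraw2DSVG(450, 400)
        scale = result.scale
        colors = {
            a: _diverging_color(v, scale)
            for a, v in result.per_atom.items()
        }
        mol2d = Chem.Mol(mol)
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer, mol2d,
            highlightAtoms=list(colors),
            highlightAtomColors=colors,
            highlightBonds=[],
        )
        drawer.FinishDrawing()
        data = drawer.GetDrawingText()
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
    except Exception as exc:  # depiction failures become RenderError
        raise RenderError(f"cannot render gradient image: {exc}") from exc
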