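"""Canonical atom signatures and sparse occurrence vectors.

An *atom signature* of height h is a canonical string encoding the subgraph
induced by all atoms within h bonds of a root atom.  Counting signature
occurrences over a molecule (at heights 1-3 by default) yields the sparse
integer descriptor vector driving the QSPR models; the atom-to-feature map
kept alongside the counts supports per-atom attribution of predictions.

Serialization dialect
---------------------
Rooted, layered DFS string.  Atom label ``[El]`` with the element symbol
lowercased iff aromatic and an optional formal-charge suffix (``[O-]``,
``[N+]``).  Bond symbols: ``""`` single, ``=`` double, ``#`` triple, ``:``
aromatic.  Children of each node are visited in lexicographic order of
(bond symbol, atom label, serialized subtree); each child is wrapped in
parentheses.  Atoms revisited within the height window (rings) emit
numbered back-reference markers, assigned in visit order: the marker is
appended inside the bracket of both occurrences, e.g. height-3 benzene is
``[c,1](:[c](:[c](:[c](:[c](:[c,1]))))(:[c,1])``-style.  Hydrogens are
implicit and never appear.  The vocabulary key is the pair
(serialization, height), so an identical-looking neighborhood declared at a
different height is a distinct feature.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

logger = logging.getLogger(__name__)

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class AtomSignature:
    """Canonical serialization of a rooted neighborhood plus its height."""

    canonical: str
    height: int


def _atom_label_core(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    q = atom.GetFormalCharge()
    if q == 0:
        charge = ""
    elif q == 1:
        charge = "+"
    elif q == -1:
        charge = "-"
    else:
        charge = f"{q:+d}"
    return sym + charge


def _bond_symbol(bond: Chem.Bond) -> str:
    sym = _BOND_SYMBOL.get(bond.GetBondType())
    if sym is None:  # exotic bond orders: fall back to the numeric order
        sym = f"~{bond.GetBondTypeAsDouble():g}~"
    return sym


def _neighborhood(mol: Chem.Mol, root: int, height: int) -> set[int]:
    """Atom indices within `height` bonds of the root (BFS)."""
    dist = {root: 0}
    queue = deque([root])
    while queue:
        a = queue.popleft()
        if dist[a] == height:
            continue
        for nb in mol.GetAtomWithIdx(a).GetNeighbors():
            j = nb.GetIdx()
            if j not in dist:
                dist[j] = dist[a] + 1
                queue.append(j)
    return set(dist)


class _Node:
    __slots__ = ("atom", "bond", "children", "closure")

    def __init__(self, atom: int, bond: str, closure: bool = False):
        self.atom = atom
        self.bond = bond
        self.children: list[_Node] = []
        self.closure = closure


def _probe(mol, atom: int, parent: int, allowed: set[int], visited: set[int]) -> str:
    """Order-invariant serialization of a subtree used only for sibling
    ordering; ring closures are rendered with a generic ``&`` marker."""
    visited = visited | {atom}
    items = []
    for nb in mol.GetAtomWithIdx(atom).GetNeighbors():
        j = nb.GetIdx()
        if j == parent or j not in allowed:
            continue
        bond = _bond_symbol(mol.GetBondBetweenAtoms(atom, j))
        if j in visited:
            items.append((bond, f"[{_atom_label_core(nb)}&]", ""))
        else:
            items.append(
                (bond, f"[{_atom_label_core(nb)}]",
                 _probe(mol, j, atom, allowed, visited))
            )
    items.sort()
    out = f"[{_atom_label_core(mol.GetAtomWithIdx(atom))}]"
    for bond, label, sub in items:
        out += f"({bond}{sub or label})"
    return out


def _build_tree(mol, atom: int, parent: int, bond: str, allowed: set[int],
                visited: set[int], order: list[int],
                emitted: set[frozenset]) -> _Node:
    visited.add(atom)
    order.append(atom)
    node = _Node(atom, bond)
    candidates = []
    for nb in mol.GetAtomWithIdx(atom).GetNeighbors():
        j = nb.GetIdx()
        if j == parent or j not in allowed:
            continue
        bsym = _bond_symbol(mol.GetBondBetweenAtoms(atom, j))
        key = (bsym, f"[{_atom_label_core(nb)}]",
               _probe(mol, j, atom, allowed, set(visited)))
        candidates.append((key, j, bsym))
    candidates.sort(key=lambda t: t[0])
    for _key, j, bsym in candidates:
        edge = frozenset((atom, j))
        if edge in emitted:
            continue
        emitted.add(edge)
        if j in visited:
            node.children.append(_Node(j, bsym, closure=True))
        else:
            node.children.append(
                _build_tree(mol, j, atom, bsym, allowed, visited, order, emitted)
            )
    return node


def _serialize_rooted(mol: Chem.Mol, root: int, allowed: set[int]) -> str:
    order: list[int] = []
    tree = _build_tree(mol, root, -1, "", allowed, set(), order, set())

    closure_targets: set[int] = set()

    def collect(node: _Node) -> None:
        if node.closure:
            closure_targets.add(node.atom)
        for c in node.children:
            collect(c)

    collect(tree)
    markers = {a: i + 1 for i, a in
               enumerate(a for a in order if a in closure_targets)}

    def render(node: _Node) -> str:
        core = _atom_label_core(mol.GetAtomWithIdx(node.atom))
        n = markers.get(node.atom)
        label = f"[{core},{n}]" if n is not None else f"[{core}]"
        out = node.bond + label
        for c in node.children:
            out += "(" + render(c) + ")"
        return out

    return render(tree)


def atom_signature(mol: Chem.Mol, atom_index: int, height: int) -> AtomSignature:
    """Canonical signature of the given root atom at the given height.

    Deterministic and independent of the input atom ordering.
    """
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    if height < 0:
        raise ValueError("height must be >= 0")
    allowed = _neighborhood(mol, atom_index, height)
    return AtomSignature(_serialize_rooted(mol, atom_index, allowed), height)


def iter_signatures(
    mol: Chem.Mol, heights: Iterable[int]
) -> Iterator[tuple[AtomSignature, int, frozenset[int]]]:
    """Yield (signature, root atom, covered atom set) for every heavy atom
    and every height."""
    for h in sorted(set(heights)):
        for atom in mol.GetAtoms():
            root = atom.GetIdx()
            allowed = _neighborhood(mol, root, h)
            sig = AtomSignature(_serialize_rooted(mol, root, allowed), h)
            yield sig, root, frozenset(allowed)


def molecule_signatures(
    mol: Chem.Mol, heights: Iterable[int] = (1, 2, 3)
) -> Counter:
    """Multiset of atom signatures over all heavy atoms and heights.

    The multiset size is ``len(heights) * num_heavy_atoms``.
    """
    heights = set(heights)
    if not heights or any(h < 0 for h in heights):
        raise ValueError("heights must be non-empty with all values >= 0")
    return Counter(sig for sig, _root, _atoms in iter_signatures(mol, heights))


@dataclass
class SignatureVocabulary:
    """Ordered map from atom signatures to 0-based feature indices."""

    entries: dict[AtomSignature, int]
    heights: frozenset[int]
    min_count: int
    support: dict[AtomSignature, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sig: AtomSignature) -> bool:
        return sig in self.entries

    def index(self, sig: AtomSignature) -> int:
        return self.entries[sig]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("index\theight\tcount\tcanonical\n")
            for sig, idx in self.entries.items():
                fh.write(
                    f"{idx}\t{sig.height}\t{self.support.get(sig, 0)}"
                    f"\t{sig.canonical}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureVocabulary":
        entries: dict[AtomSignature, int] = {}
        support: dict[AtomSignature, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("index\t"):
                raise ValueError(f"{path}: not a vocabulary TSV")
            for line in fh:
                idx, height, count, canonical = line.rstrip("\n").split("\t")
                sig = AtomSignature(canonical, int(height))
                entries[sig] = int(idx)
                support[sig] = int(count)
        heights = frozenset(s.height for s in entries) or frozenset({1, 2, 3})
        return cls(entries=entries, heights=heights, min_count=1,
                   support=support)


def build_vocabulary(
    compounds: Sequence,
    heights: Iterable[int] = (1, 2, 3),
    min_count: int = 1,
) -> SignatureVocabulary:
    """Enumerate all signatures over the dataset and keep those present in
    at least ``min_count`` distinct compounds.

    Feature indices follow first-appearance order over the input sequence.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    heights = frozenset(heights)
    first_seen: dict[AtomSignature, int] = {}
    support: Counter = Counter()
    pos = 0
    for comp in compounds:
        mol = getattr(comp, "mol", comp)
        sigs = set(molecule_signatures(mol, heights))
        for sig, _root, _atoms in iter_signatures(mol, heights):
            if sig not in first_seen:
                first_seen[sig] = pos
                pos += 1
        support.update(sigs)
    kept = [s for s in sorted(first_seen, key=first_seen.get)
            if support[s] >= min_count]
    entries = {s: i for i, s in enumerate(kept)}
    return SignatureVocabulary(
        entries=entries,
        heights=heights,
        min_count=min_count,
        support={s: support[s] for s in kept},
    )


@dataclass
class FeatureVector:
    """Sparse occurrence counts plus atom-to-feature provenance.

    ``counts`` maps feature index to a positive occurrence count.
    ``atom_map`` maps each heavy-atom index to the set of in-vocabulary
    feature indices whose subgraph contains that atom.  ``n_oov`` counts
    signature occurrences that were absent from the vocabulary (the
    per-molecule novelty diagnostic).
    """

    counts: dict[int, int]
    atom_map: dict[int, set[int]] = field(default_factory=dict)
    n_oov: int = 0
    n_total: int = 0

    @property
    def novelty(self) -> float:
        """Fraction of this molecule's signature occurrences not in the
        vocabulary (0 for a fully in-domain molecule)."""
        return self.n_oov / self.n_total if self.n_total else 0.0


def vectorize(mol: Chem.Mol, vocabulary: SignatureVocabulary) -> FeatureVector:
    """Occurrence-count vector of a molecule under a fixed vocabulary.

    Out-of-vocabulary signatures are dropped from the counts (the linear
    model has no weight for them) but tallied into the novelty ratio.
    """
    counts: dict[int, int] = {}
    atom_map: dict[int, set[int]] = {
        a.GetIdx(): set() for a in mol.GetAtoms()
    }
    n_oov = 0
    n_total = 0
    for sig, _root, atoms in iter_signatures(mol, vocabulary.heights):
        n_total += 1
        if sig in vocabulary:
            idx = vocabulary.index(sig)
            counts[idx] = counts.get(idx, 0) + 1
            for a in atoms:
                atom_map[a].add(idx)
        else:
            n_oov += 1
            logger.debug("out-of-vocabulary signature: %s", sig)
    return FeatureVector(counts=counts, atom_map=atom_map,
                         n_oov=n_oov, n_total=n_total)
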