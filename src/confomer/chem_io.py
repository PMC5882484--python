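"""Molecular input parsing, standardization and deduplication.

Input formats are the usual cheminformatics triad: SMILES files (``.smi``,
one ``SMILES [id]`` record per line), SDF (V2000, label read from a named
data tag) and CSV tables with a ``smiles`` column.  Standardization is
deliberately minimal: keep the largest fragment (salts and solvents are
discarded) and deduplicate on canonical SMILES.  Tautomer canonicalization,
charge neutralization and stereo normalization are out of scope.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import (
    EmptyMoleculeError,
    FormatError,
    MissingLabelError,
    ParseError,
    ValenceError,
)

logger = logging.getLogger(__name__)

# RDKit's C++ logging is noisy on intentionally malformed test inputs.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


@dataclass
class LabeledCompound:
    """A standardized molecule with an observed (or assigned) property value.

    Attributes
    ----------
    mol : rdkit.Chem.Mol
        Parsed molecular graph (heavy atoms only; hydrogens implicit).
    y : float
        Property value in log units (dimensionless).
    id : str or None
        Optional record identifier.
    """

    mol: Chem.Mol
    y: float
    id: str | None = None
    _canonical: str | None = field(default=None, repr=False, compare=False)

    @property
    def canonical_smiles(self) -> str:
        if self._canonical is None:
            self._canonical = Chem.MolToSmiles(self.mol)
        return self._canonical


def parse_smiles(text: str) -> Chem.Mol:
    """Parse a SMILES string into a molecular graph.

    Aromaticity is perceived by RDKit's default model.  Raises
    :class:`ParseError` on syntactically invalid input and
    :class:`ValenceError` on chemically impossible structures.
    """
    if not text or not text.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {text!r}")
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        raise ValenceError(f"impossible valence in {text!r}: {exc}") from exc
    except (Chem.KekulizeException, ValueError) as exc:
        raise ParseError(f"cannot sanitize {text!r}: {exc}") from exc
    return mol


def standardize(mol: Chem.Mol) -> Chem.Mol:
    """Keep only the fragment with the most heavy atoms.

    Ties are broken by larger molecular weight, then by lexicographically
    smaller canonical SMILES.  Raises :class:`EmptyMoleculeError` if no
    heavy atom remains.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    candidates = [f for f in frags if f.GetNumHeavyAtoms() > 0]
    if not candidates:
        raise EmptyMoleculeError("no heavy atom in molecule")

    def key(f: Chem.Mol):
        return (
            -f.GetNumHeavyAtoms(),
            -Descriptors.MolWt(f),
            Chem.MolToSmiles(f),
        )

    return min(candidates, key=key)


def deduplicate(
    compounds: Sequence[LabeledCompound],
) -> tuple[list[LabeledCompound], int]:
    """Keep the first occurrence per canonical-SMILES key, preserving order.

    Returns the retained list and the number of removed duplicates.
    """
    seen: set[str] = set()
    kept: list[LabeledCompound] = []
    for c in compounds:
        key = c.canonical_smiles
        if key in seen:
            continue
        seen.add(key)
        kept.append(c)
    return kept, len(compounds) - len(kept)


def _iter_smi(path: Path) -> Iterable[tuple[str, str | None]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            yield parts[0], (parts[1].strip() if len(parts) > 1 else None)


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    label_field: str = "label",
) -> tuple[list[LabeledCompound], int]:
    """Read, standardize and parse a labeled dataset.

    Parameters
    ----------
    path : path to a ``.smi``, ``.sdf`` or ``.csv`` file.
    fmt : one of ``{"smi", "sdf", "csv"}``; inferred from the suffix when
        omitted.
    label_field : SDF data-tag or CSV column holding the numeric label.
        For ``.smi`` files no label is available and y is set to ``nan``.

    Returns the list of standardized compounds and the number of records
    skipped because they failed to parse (each skip is logged).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in {"smi", "sdf", "csv"}:
        raise FormatError(f"unsupported format: {fmt!r}")

    out: list[LabeledCompound] = []
    skipped = 0

    def add(smiles_or_mol, y, ident):
        nonlocal skipped
        try:
            mol = (
                parse_smiles(smiles_or_mol)
                if isinstance(smiles_or_mol, str)
                else smiles_or_mol
            )
            out.append(LabeledCompound(standardize(mol), float(y), ident))
        except (ParseError, EmptyMoleculeError, TypeError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping record %r: %s", ident or smiles_or_mol, exc)

    if fmt == "smi":
        for smiles, ident in _iter_smi(path):
            add(smiles, float("nan"), ident)
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise FormatError(f"{path}: CSV needs a 'smiles' column")
            if label_field not in reader.fieldnames:
                raise MissingLabelError(
                    f"{path}: no column {label_field!r} in {reader.fieldnames}"
                )
            for row in reader:
                add(row["smiles"], row[label_field], row.get("id"))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("skipping unreadable SDF record %d", i)
                continue
            if not mol.HasProp(label_field):
                raise MissingLabelError(
                    f"{path}: SDF record {i} lacks tag {label_field!r}"
                )
            ident = mol.GetProp("_Name") or None if mol.HasProp("_Name") else None
            add(mol, mol.GetProp(label_field), ident)
    return out, skipped


def write_smi(compounds: Iterable[LabeledCompound], path: str | Path) -> None:
    """Write compounds as a ``.smi`` file (canonical SMILES + id)."""
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(c.canonical_smiles + (f" {c.id}" if c.id else "") + "\n")


def write_csv(compounds: Iterable[LabeledCompound], path: str | Path,
              label_field: str = "label") -> None:
    """Write compounds as a CSV with columns smiles,<label>,id."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", label_field, "id"])
        for c in compounds:
            writer.writerow([c.canonical_smiles, repr(c.y), c.id or ""])
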