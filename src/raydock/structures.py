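"""Protein and ligand structure input with per-atom van der Waals radii.

Readers are thin wrappers over :mod:`gemmi` (PDB) and, optionally, RDKit
(SDF).  All downstream geometry works on bare arrays of atom centers and
radii; no bond perception, protonation or charges are performed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "ProteinStructure",
    "LigandConformer",
    "RadiiTable",
    "DEFAULT_RADII",
    "read_protein_pdb",
    "read_ligand_conformers",
    "assign_radii",
    "write_ligand_pdb",
]


class InputError(ValueError):
    """Missing file or invalid user input."""


class FormatError(ValueError):
    """A file existed but could not be interpreted."""


@dataclass(frozen=True)
class Atom:
    """A hard sphere: element symbol, center (Å) and radius (Å)."""

    element: str
    position: np.ndarray  # shape (3,), Å
    radius: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad atom position {self.position!r}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class RadiiTable:
    """Element → van der Waals radius (Å) lookup with a default fallback.

    The defaults follow common molecular-mechanics vdW radii (C 1.70,
    N 1.55, O 1.52, S 1.80 ...); the table is deliberately a plain mapping
    so users can swap in any set from a YAML file.
    """

    radii: Dict[str, float]
    default: float = 1.70

    def __post_init__(self):
        for el, r in self.radii.items():
            if not (0.5 < r < 3.0):
                raise ValueError(f"radius for {el} out of range (0.5, 3.0): {r}")
        if not (0.5 < self.default < 3.0):
            raise ValueError(f"default radius out of range: {self.default}")

    def lookup(self, element: str) -> float:
        el = element.strip().capitalize()
        if el in self.radii:
            return self.radii[el]
        log.warning("element %r not in radii table; using default %.2f Å", element, self.default)
        return self.default

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RadiiTable":
        data = yaml.safe_load(Path(path).read_text())
        default = float(data.pop("default", 1.70))
        return cls({str(k).capitalize(): float(v) for k, v in data.items()}, default=default)


DEFAULT_RADII = RadiiTable(
    {
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "P": 1.80,
        "F": 1.47,
        "Cl": 1.75,
        "Br": 1.85,
        "I": 1.98,
        "H": 1.20,
    }
)


@dataclass
class ProteinStructure:
    """A rigid protein: atoms, a (chain, resseq) residue index, and its center of mass.

    The center of mass is the unweighted mean of atom positions; mass
    weighting would move it by far less than the 30 Å ray-origin offset it
    feeds into.
    """

    atoms: List[Atom]
    residue_index: Dict[Tuple[str, int], List[int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("ProteinStructure needs at least one atom")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def residue_atoms(self, chain: str, resseq: int) -> List[Atom]:
        key = (chain, resseq)
        if key not in self.residue_index:
            raise InputError(f"residue {chain}{resseq} not found in structure")
        return [self.atoms[i] for i in self.residue_index[key]]


@dataclass
class LigandConformer:
    """One rigid heavy-atom conformation of a small molecule."""

    conformer_id: int
    atoms: List[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("LigandConformer needs at least one atom")
        if any(a.element.strip().capitalize() == "H" for a in self.atoms):
            raise ValueError("LigandConformer must contain heavy atoms only")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def assign_radii(atoms: Sequence[Atom], table: RadiiTable = DEFAULT_RADII) -> List[Atom]:
    """Return copies of *atoms* with radii filled in from *table*."""
    if not table.radii:
        raise ValueError("radii table is empty")
    return [Atom(a.element, a.position, table.lookup(a.element)) for a in atoms]


def _element_of(gemmi_atom) -> str:
    el = gemmi_atom.element.name
    return el if el and el != "X" else gemmi_atom.name.strip()[:1]


def read_protein_pdb(
    path: str | Path,
    table: RadiiTable = DEFAULT_RADII,
    include_hetatm: bool = False,
) -> ProteinStructure:
    """Parse a protein PDB file into a :class:`ProteinStructure`.

    Only altloc '' or 'A' atoms are kept.  HETATM records (waters, ions,
    bound ligands) are excluded by default so that pocket mapping reflects
    the protein surface alone.
    """
    import gemmi

    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    st = gemmi.read_pdb(str(p))
    atoms: List[Atom] = []
    index: Dict[Tuple[str, int], List[int]] = {}
    model = st[0] if len(st) else None
    if model is None:
        raise FormatError(f"{p}: no models found")
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and not include_hetatm:
                continue
            for at in res:
                if at.altloc not in ("", "A", "\x00"):
                    continue
                pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                atoms.append(Atom(_element_of(at), pos))
                index.setdefault((chain.name, res.seqid.num), []).append(len(atoms) - 1)
    if not atoms:
        raise FormatError(f"{p}: no ATOM records parsed")
    return ProteinStructure(assign_radii(atoms, table), index)


def _conformer_from_gemmi_model(model, cid: int, table: RadiiTable) -> LigandConformer:
    atoms = []
    for chain in model:
        for res in chain:
            for at in res:
                if at.altloc not in ("", "A", "\x00"):
                    continue
                el = _element_of(at)
                if el.capitalize() == "H":
                    continue
                atoms.append(Atom(el, np.array([at.pos.x, at.pos.y, at.pos.z])))
    if not atoms:
        raise FormatError(f"conformer block {cid}: no heavy atoms")
    return LigandConformer(cid, assign_radii(atoms, table))


def read_ligand_conformers(
    path: str | Path,
    fmt: str = "pdb",
    table: RadiiTable = DEFAULT_RADII,
) -> List[LigandConformer]:
    """Read a multi-conformer ligand file.

    ``fmt='pdb'`` expects MODEL/ENDMDL blocks (a single un-modelled block
    yields one conformer); ``fmt='sdf'`` reads V2000 molecule blocks via
    RDKit.  Hydrogens are dropped; conformer ids are 1-based ordinals.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    if fmt == "pdb":
        import gemmi

        st = gemmi.read_pdb(str(p))
        if len(st) == 0:
            raise FormatError(f"{p}: no models found")
        confs = [_conformer_from_gemmi_model(m, i + 1, table) for i, m in enumerate(st)]
    elif fmt == "sdf":
        from rdkit import Chem

        confs = []
        for i, mol in enumerate(Chem.SDMolSupplier(str(p), removeHs=False, sanitize=False)):
            if mol is None:
                raise FormatError(f"{p}: unparseable SDF block {i + 1}")
            conf = mol.GetConformer()
            atoms = []
            for at in mol.GetAtoms():
                if at.GetSymbol() == "H":
                    continue
                pos = conf.GetAtomPosition(at.GetIdx())
                atoms.append(Atom(at.GetSymbol(), np.array([pos.x, pos.y, pos.z])))
            if not atoms:
                raise FormatError(f"{p}: SDF block {i + 1} has no heavy atoms")
            confs.append(LigandConformer(i + 1, assign_radii(atoms, table)))
        if not confs:
            raise FormatError(f"{p}: no molecules found")
    else:
        raise InputError(f"unknown ligand format {fmt!r} (expected 'pdb' or 'sdf')")
    counts = {len(c.atoms) for c in confs}
    if len(counts) > 1:
        raise FormatError(f"{p}: conformers have differing heavy-atom counts {sorted(counts)}")
    return confs


def write_ligand_pdb(conformers: Sequence[LigandConformer], path: str | Path) -> None:
    """Write conformers as a multi-MODEL PDB file (fixed-column HETATM records)."""
    lines = []
    multi = len(conformers) > 1
    for conf in conformers:
        if multi:
            lines.append(f"MODEL     {conf.conformer_id:4d}")
        for i, a in enumerate(conf.atoms, start=1):
            x, y, z = a.position
            el = a.element.strip().capitalize()
            name = f"{el}{i}"[:4]
            lines.append(
                f"HETATM{i:5d} {name:<4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
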