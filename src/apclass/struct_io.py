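"""Reading and writing of protein structure models.

The package works on single-chain structure models: AlphaFold-style predicted
models (per-residue pLDDT confidence stored in the B-factor column) and
experimental PDB entries.  Everything downstream — disulfide detection,
superposition, domain annotation — consumes the uniform
:class:`StructureModel` produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureParseError",
    "UnknownChainError",
    "read_pdb",
    "write_pdb",
    "sequence_of",
    "slice_model",
    "structure_summary",
]

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


class StructureParseError(ValueError):
    """File exists but holds no usable ATOM records."""


class UnknownChainError(KeyError):
    """Requested chain identifier is absent from the file."""


@dataclass
class Atom:
    """A single atom: name (e.g. ``CA``, ``SG``), element and coordinates in Å."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")


@dataclass
class Residue:
    """One residue with its atoms and a pLDDT-style confidence in [0, 100]."""

    seq_index: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    plddt: float = 100.0

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError("plddt must lie in [0, 100]")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"residue {self.seq_index}: duplicate atom names")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class StructureModel:
    """Ordered single-chain residue model.

    ``source`` is ``"predicted"`` (pLDDT read from B-factors) or
    ``"experimental"`` (confidence fixed at 100).
    """

    id: str
    residues: list[Residue]
    source: str = "predicted"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("StructureModel must contain at least one residue")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residues must be strictly increasing in seq_index")
        self._by_index = {r.seq_index: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_index: int) -> Residue:
        return self._by_index[seq_index]

    @property
    def sequence(self) -> str:
        return sequence_of(self)

    def ca_coords(self) -> dict[int, np.ndarray]:
        """seq_index -> Cα coordinate, for residues that have a Cα."""
        return {r.seq_index: r.ca.coord for r in self.residues if r.ca is not None}


def _pick_altloc(bio_atom):
    """Resolve a possibly-disordered atom: highest occupancy, tie -> first seen."""
    if not bio_atom.is_disordered():
        return bio_atom
    best = None
    for child in bio_atom.disordered_get_list():
        occ = child.get_occupancy() or 0.0
        if best is None or occ > (best.get_occupancy() or 0.0):
            best = child
    return best


def read_pdb(path: str | Path, chain: str = "first", source: str = "predicted",
             model_id: str | None = None) -> StructureModel:
    """Parse one chain of a PDB file into a :class:`StructureModel`.

    HETATM records are skipped; altloc duplicates are resolved to the highest
    occupancy conformer (tie broken by file order); insertion-coded or
    non-monotonic residue numbers are renumbered sequentially from the
    preceding residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id or path.stem, str(path))
    models = list(structure)
    if not models:
        raise StructureParseError(f"{path}: no ATOM records")
    chains = {c.id: c for c in models[0]}
    if not chains:
        raise StructureParseError(f"{path}: no ATOM records")
    if chain == "first":
        bio_chain = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise UnknownChainError(f"{path}: no chain {chain!r} (has {sorted(chains)})")
        bio_chain = chains[chain]

    residues: list[Residue] = []
    prev_index = 0
    for res in bio_chain:
        hetflag, resseq, icode = res.get_id()
        if hetflag.strip():
            continue  # HETATM (waters, ligands, the pepstatin inhibitor of 1pso)
        atoms = []
        seen = set()
        for bio_atom in res:
            picked = _pick_altloc(bio_atom)
            name = picked.get_name()
            if name in seen:
                continue
            seen.add(name)
            atoms.append(Atom(name=name,
                              element=(picked.element or "").strip() or name[0],
                              coord=np.array(picked.get_coord(), dtype=float)))
        if not atoms:
            continue
        if icode.strip() or resseq <= prev_index:
            seq_index = prev_index + 1
        else:
            seq_index = resseq
        prev_index = seq_index
        aa = _THREE_TO_ONE.get(res.get_resname().strip().upper(), "X")
        if source == "predicted":
            bvals = [a.get_bfactor() for a in res if a.get_bfactor() is not None]
            plddt = float(np.clip(np.mean(bvals) if bvals else 0.0, 0.0, 100.0))
        else:
            plddt = 100.0
        residues.append(Residue(seq_index=seq_index, aa=aa, atoms=atoms, plddt=plddt))
    if not residues:
        raise StructureParseError(f"{path}: chain {bio_chain.id!r} has no ATOM records")
    return StructureModel(id=model_id or path.stem, residues=residues, source=source)


_ONE_TO_THREE = {v: k.upper() for k, v in protein_letters_3to1.items()}


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model back out as minimal wwPDB-style ATOM records."""
    lines = []
    serial = 1
    for res in model.residues:
        resname = _ONE_TO_THREE.get(res.aa, "UNK")
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} A{res.seq_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{res.plddt:6.2f}          "
                f"{atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def sequence_of(model: StructureModel) -> str:
    """One-letter sequence; unknown residues are 'X'."""
    return "".join(r.aa if r.aa in _ONE_TO_THREE else "X" for r in model.residues)


def slice_model(model: StructureModel, start: int, end: int) -> StructureModel:
    """Sub-model covering ordinal residue positions start..end (1-based inclusive)."""
    subset = model.residues[start - 1:end]
    if not subset:
        raise ValueError(f"empty slice {start}..{end}")
    return StructureModel(id=f"{model.id}[{start}:{end}]", residues=subset,
                          source=model.source)


def structure_summary(models: list[StructureModel], path: str | Path) -> None:
    """TSV summary: id, n_residues, mean pLDDT."""
    rows = ["id\tn_residues\tmean_plddt"]
    for m in models:
        mean = float(np.mean([r.plddt for r in m.residues]))
        rows.append(f"{m.id}\t{len(m)}\t{mean:.2f}")
    Path(path).write_text("\n".join(rows) + "\n")
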