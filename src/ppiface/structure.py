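"""Coordinate substrate: PDB I/O, atom/residue chemistry, ligand extraction.

All geometry stages operate on the light-weight :class:`Structure` container
defined here.  Parsing of the fixed-column PDB format is delegated to
:mod:`gemmi`; the container keeps only what the interface descriptors need
(identity, coordinates, occupancy/altloc bookkeeping).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

try:
    import gemmi
except ImportError as exc:  # pragma: no cover
    raise ImportError("ppiface requires gemmi for PDB parsing") from exc

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: residue-level chemistry, His counted among the charged (basic) residues
CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIS"}
POLAR_RESIDUES = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "TRP"}
NONPOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "GLY"}

#: common covalent modifications mapped to their parent residue
MODIFIED_PARENT = {
    "MSE": "MET", "SEC": "CYS", "CSO": "CYS", "CME": "CYS", "OCS": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "MLY": "LYS", "HYP": "PRO",
    "KCX": "LYS", "LLP": "LYS", "PCA": "GLU", "CGU": "GLU", "FME": "MET",
}

#: element -> polar / non-polar (hydrogens follow their bonded heavy atom)
_POLAR_ELEMENTS = {"N", "O"}
_NONPOLAR_ELEMENTS = {"C", "S", "SE", "P"}


class PDBParseError(ValueError):
    """Raised when a PDB source cannot be interpreted."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Structure:
    """An ordered list of atoms plus chain/residue indexing."""

    atoms: list[Atom]
    id: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise PDBParseError("empty structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.chain_id, []).append(i)
        return out

    def coords(self, indices: Sequence[int] | None = None) -> np.ndarray:
        if indices is None:
            return np.array([a.coords for a in self.atoms], dtype=float)
        return np.array([self.atoms[i].coords for i in indices], dtype=float)

    def atom_indices(
        self,
        chain_ids: Iterable[str] | None = None,
        heavy_only: bool = False,
        hetero: bool | None = None,
    ) -> list[int]:
        chains = set(chain_ids) if chain_ids is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chains is not None and a.chain_id not in chains:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            if hetero is not None and a.is_hetero != hetero:
                continue
            out.append(i)
        return out

    def residues(self, chain_id: str | None = None) -> list[tuple[tuple, list[int]]]:
        """Residues in file order as ((chain, seq, icode), atom indices)."""
        order: list[tuple] = []
        table: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = a.residue_id
            if key not in table:
                table[key] = []
                order.append(key)
            table[key].append(i)
        return [(k, table[k]) for k in order]

    def subset(self, indices: Sequence[int], id_suffix: str = "") -> "Structure":
        atoms = [self.atoms[i] for i in indices]
        return Structure(atoms=atoms, id=self.id + id_suffix, title=self.title)


@dataclass
class PartnerSelection:
    """Which chains form each side of the complex, plus an optional ligand.

    The ligand is addressed as ``(residue_name, chain_id, residue_seq)``
    where chain and sequence number may be ``None`` to match any copy.
    """

    side_a: set[str]
    side_b: set[str]
    ligand: tuple[str, str | None, int | None] | None = None

    def __post_init__(self) -> None:
        self.side_a = set(self.side_a)
        self.side_b = set(self.side_b)
        if self.side_a & self.side_b:
            raise ValueError(
                f"partner sides overlap: {sorted(self.side_a & self.side_b)}"
            )

    @classmethod
    def from_string(cls, spec: str, ligand: str | None = None) -> "PartnerSelection":
        """Parse ``"A:B"`` / ``"AB:CD"`` chain selections and ``"LIG[:chain[:seq]]"``."""
        try:
            a, b = spec.split(":")
        except ValueError as exc:
            raise ValueError(f"selection {spec!r} is not of the form 'A:B'") from exc
        lig = None
        if ligand:
            parts = ligand.split(":")
            lig = (
                parts[0],
                parts[1] if len(parts) > 1 else None,
                int(parts[2]) if len(parts) > 2 else None,
            )
        return cls(side_a=set(a), side_b=set(b), ligand=lig)


def _element_from_name(name: str, residue_name: str) -> str:
    """Infer the element when the PDB element column is blank."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if stripped[:1] in ("H", "D") and residue_name not in ("HG", "HO"):
        return "H"
    for two in ("CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE", "CA", "CU", "NI"):
        if stripped[:2].upper() == two and name[:1] != " ":
            return two[0] + two[1].lower()
    return stripped[0].upper()


def read_pdb(source, model: int = 0, keep_waters: bool = False) -> Structure:
    """Read a PDB file or string into a :class:`Structure`.

    Waters are excluded by default, only the highest-occupancy altloc of
    each atom is retained and multi-MODEL files yield the first model.
    Hydrogens present in the input are kept (the hydrogen-bond detector
    uses them); SASA and volume stages ignore them downstream.
    """
    if hasattr(source, "read"):
        text = source.read()
        st = gemmi.read_pdb_string(text)
        name = getattr(source, "name", "")
    else:
        source = str(source)
        if "\n" in source or source.lstrip()[:6] in ("ATOM  ", "HETATM", "HEADER", "MODEL "):
            st = gemmi.read_pdb_string(source)
            name = ""
        else:
            try:
                st = gemmi.read_structure(source, format=gemmi.CoorFormat.Pdb)
            except (RuntimeError, ValueError, FileNotFoundError) as exc:
                raise PDBParseError(f"cannot parse PDB source {source!r}: {exc}") from exc
            name = st.name
    if len(st) == 0:
        raise PDBParseError("no MODEL found in PDB source")
    mdl = st[min(model, len(st) - 1)]

    atoms: list[Atom] = []
    # per-residue altloc resolution: keep highest occupancy per atom name
    for chain in mdl:
        for res in chain:
            if not keep_waters and res.name in WATER_NAMES:
                continue
            best: dict[str, gemmi.Atom] = {}
            for a in res:
                prev = best.get(a.name)
                if prev is None or a.occ > prev.occ:
                    best[a.name] = a
            for a in res:  # preserve file order among the kept atoms
                if best.get(a.name) is not a:
                    continue
                elem = a.element.name if a.element.name != "X" else ""
                if not elem:
                    elem = _element_from_name(a.name, res.name)
                if not elem:
                    raise PDBParseError(
                        f"cannot infer element for atom {a.name!r} in "
                        f"{res.name} {chain.name}{res.seqid.num}"
                    )
                altloc = a.altloc if a.altloc not in ("\x00", " ") else ""
                atoms.append(Atom(
                    serial=a.serial,
                    name=a.name,
                    element=elem,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    is_hetero=(res.het_flag == "H"),
                    occupancy=a.occ,
                    altloc=altloc,
                ))
    if not atoms:
        raise PDBParseError("structure contains no atoms after filtering")
    for a in atoms:
        if not np.all(np.isfinite(a.coords)):
            raise PDBParseError(f"non-finite coordinates for atom serial {a.serial}")
    return Structure(atoms=atoms, id=name or st.name, title=st.name)


def write_pdb(structure: Structure, target=None) -> str:
    """Serialize a :class:`Structure` to fixed-column PDB text.

    Coordinates are written at the PDB's native 3-decimal precision.
    Returns the text; if *target* is a path or file object it is written
    there as well.
    """
    lines = []
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:>5d} {name}{a.altloc or ' '}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_seq:>4d}{a.insertion_code or ' '}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as fh:
                fh.write(text)
    return text


def classify_atom(atom: Atom) -> str:
    """Classify an atom as ``"polar"`` (N, O) or ``"non_polar"`` (C, S).

    Hydrogens are not classified directly; callers resolve them through
    their bonded heavy atom.  Follows the interface-composition convention
    used throughout the protein-interface literature.
    """
    el = atom.element.upper()
    if el in ("H", "D"):
        raise ValueError(
            f"hydrogen {atom.name} (serial {atom.serial}) must be classified "
            "through its bonded heavy atom"
        )
    if el in _POLAR_ELEMENTS:
        return "polar"
    if el in _NONPOLAR_ELEMENTS:
        return "non_polar"
    raise ValueError(f"unknown element {atom.element!r} for atom serial {atom.serial}")


def classify_residue(residue_name: str) -> str:
    """Classify a residue as ``charged`` / ``polar`` / ``non_polar``.

    Charged covers Asp, Glu, Lys, Arg and His (His grouped with the basics,
    matching the salt-bridge convention); Ser, Thr, Asn, Gln, Tyr, Cys and
    Trp are polar; the remaining eight standard residues are non-polar.
    Known covalent modifications are classified by their parent residue.
    """
    name = residue_name.upper()
    if name in MODIFIED_PARENT:
        name = MODIFIED_PARENT[name]
    if name in CHARGED_RESIDUES:
        return "charged"
    if name in POLAR_RESIDUES:
        return "polar"
    if name in NONPOLAR_RESIDUES:
        return "non_polar"
    raise ValueError(f"cannot classify non-standard residue {residue_name!r}")


def extract_ligand(
    structure: Structure,
    selection: PartnerSelection,
    covalent_cutoff: float = 1.9,
) -> list[int]:
    """Return atom indices of the selected hetero ligand.

    Enforces the dataset rule that the inhibitor must not be covalently
    bound: the minimum heavy-atom distance between ligand and protein must
    exceed *covalent_cutoff* (default 1.9 Angstrom).
    """
    if selection.ligand is None:
        raise ValueError("selection has no ligand identifier")
    lig_name, lig_chain, lig_seq = selection.ligand
    idx = []
    for i, a in enumerate(structure.atoms):
        if not a.is_hetero or a.residue_name in WATER_NAMES:
            continue
        if a.residue_name != lig_name:
            continue
        if lig_chain is not None and a.chain_id != lig_chain:
            continue
        if lig_seq is not None and a.residue_seq != lig_seq:
            continue
        idx.append(i)
    if not idx:
        raise ValueError(f"ligand absent: no hetero atoms match {selection.ligand}")

    lig_heavy = [i for i in idx if not structure.atoms[i].is_hydrogen]
    prot_heavy = [
        i for i, a in enumerate(structure.atoms)
        if i not in set(idx) and not a.is_hetero and not a.is_hydrogen
    ]
    if lig_heavy and prot_heavy:
        from scipy.spatial import cKDTree

        tree = cKDTree(structure.coords(prot_heavy))
        dmin = tree.query(structure.coords(lig_heavy), k=1)[0].min()
        if dmin <= covalent_cutoff:
            raise ValueError(
                "covalent ligand excluded by dataset rules: minimum ligand-"
                f"protein heavy-atom distance {dmin:.2f} A <= {covalent_cutoff} A"
            )
    return idx
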