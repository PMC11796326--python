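"""Active-site extraction: functional atoms per catalytic residue and templates.

Each catalytic residue is reduced to exactly three *functional atoms* — the
side-chain atoms that carry its mechanistic chemistry, or the backbone
N/CA/C for residues that contribute their main chain.  An active site is the
ordered list of these 3-atom sets; *templates* are all sub-constellations of
2, 3 or 4 residues, the unit of geometric matching between sites.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .entries import CatalyticResidue, EnzymeEntry

__all__ = [
    "ResidueID",
    "FunctionalAtomSet",
    "ActiveSite",
    "Template",
    "FUNCTIONAL_ATOMS",
    "BACKBONE_ATOMS",
    "functional_atoms_for",
    "load_atom_table",
    "read_structure",
    "extract_active_site",
    "enumerate_templates",
    "SiteExtractionError",
]

logger = logging.getLogger(__name__)


class SiteExtractionError(ValueError):
    """Raised when catalogued residues/atoms cannot be resolved in a structure."""


# Backbone triple used for main-chain contributors and for "ANY" residues.
BACKBONE_ATOMS: tuple[str, str, str] = ("N", "CA", "C")

# Mechanism-informed functional-atom triples, one per residue type.  The
# choice follows the convention of picking the terminal chemistry-bearing
# side-chain atoms; shipped as data and overridable via load_atom_table().
FUNCTIONAL_ATOMS: dict[str, tuple[str, str, str]] = {
    "GLY": ("N", "CA", "C"),
    "ALA": ("N", "CA", "CB"),
    "SER": ("OG", "CB", "CA"),
    "THR": ("OG1", "CB", "CA"),
    "CYS": ("SG", "CB", "CA"),
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "ASN": ("CG", "OD1", "ND2"),
    "GLN": ("CD", "OE1", "NE2"),
    "HIS": ("ND1", "CE1", "NE2"),
    "LYS": ("NZ", "CE", "CD"),
    "ARG": ("CZ", "NH1", "NH2"),
    "TYR": ("OH", "CZ", "CE1"),
    "PHE": ("CG", "CZ", "CE1"),
    "TRP": ("NE1", "CE2", "CD1"),
    "MET": ("SD", "CG", "CE"),
    "PRO": ("N", "CA", "CD"),
    "VAL": ("CB", "CG1", "CG2"),
    "ILE": ("CB", "CG1", "CD1"),
    "LEU": ("CG", "CD1", "CD2"),
}


def load_atom_table(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """Load a JSON override of the functional-atom table (name3 -> 3 names)."""
    with Path(path).open() as fh:
        raw = json.load(fh)
    table: dict[str, tuple[str, str, str]] = {}
    for name3, atoms in raw.items():
        if len(atoms) != 3:
            raise ValueError(f"atom table entry {name3!r} must list exactly 3 atoms")
        table[name3.upper()] = tuple(str(a).upper() for a in atoms)  # type: ignore[assignment]
    return table


def functional_atoms_for(
    name3: str,
    backbone: bool = False,
    table: Optional[dict[str, tuple[str, str, str]]] = None,
) -> tuple[str, str, str]:
    """The three functional atom names for a residue type.

    Backbone contributors ("ANY" residues, or any residue with the backbone
    flag set) use N/CA/C regardless of type.
    """
    name3 = name3.upper()
    if backbone or name3 == "ANY":
        return BACKBONE_ATOMS
    table = table if table is not None else FUNCTIONAL_ATOMS
    try:
        return table[name3]
    except KeyError:
        raise KeyError(
            f"no functional-atom triple for residue {name3!r}; known: {sorted(table)}"
        ) from None


# ---------------------------------------------------------------------------
# Coordinate model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueID:
    chain: str
    number: int
    icode: Optional[str] = None
    name3: str = "ANY"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode or "")

    def __str__(self) -> str:
        return f"{self.name3.capitalize()}{self.number}{self.icode or ''}"


class CoordinateModel:
    """Atoms of one model of a structure, addressable by residue and atom name.

    Alternate locations follow an "A-or-blank" policy by default: for each
    atom name the blank-altloc record wins, then the configured altloc,
    ties broken by highest occupancy then file order.
    """

    def __init__(self, structure: gemmi.Structure, model_index: int = 0, altloc: str = "A"):
        if len(structure) == 0:
            raise SiteExtractionError(f"structure {structure.name!r} has no models")
        if model_index >= len(structure):
            raise SiteExtractionError(
                f"model {model_index + 1} not present in {structure.name!r} "
                f"({len(structure)} model(s))"
            )
        self.name = structure.name
        self._atoms: dict[tuple[str, int, str], dict[str, np.ndarray]] = {}
        self._resnames: dict[tuple[str, int, str], str] = {}
        model = structure[model_index]
        for chain in model:
            for residue in chain:
                key = (chain.name, residue.seqid.num, (residue.seqid.icode or "").strip())
                info = gemmi.find_tabulated_residue(residue.name)
                if residue.het_flag == "H" and not (info is not None and info.is_amino_acid()):
                    continue
                atoms = self._atoms.setdefault(key, {})
                self._resnames.setdefault(key, residue.name)
                best: dict[str, tuple[int, float]] = {}
                for atom in residue:
                    alt = atom.altloc if atom.altloc not in ("\x00", " ") else ""
                    if alt not in ("", altloc):
                        continue
                    rank = 0 if alt == "" else 1
                    prev = best.get(atom.name)
                    if prev is None or (rank, -atom.occ) < prev:
                        best[atom.name] = (rank, -atom.occ)
                        pos = atom.pos
                        atoms[atom.name] = np.array([pos.x, pos.y, pos.z])

    @property
    def n_residues(self) -> int:
        return len(self._atoms)

    def residue_name(self, chain: str, number: int, icode: str = "") -> Optional[str]:
        return self._resnames.get((chain, number, icode))

    def atom(self, chain: str, number: int, icode: str, atom_name: str) -> np.ndarray:
        key = (chain, number, icode or "")
        if key not in self._atoms:
            raise SiteExtractionError(f"residue {chain}/{number}{icode or ''} not in model {self.name!r}")
        try:
            return self._atoms[key][atom_name]
        except KeyError:
            raise SiteExtractionError(
                f"atom {atom_name!r} missing from residue {chain}/{number}{icode or ''} "
                f"({self._resnames.get(key, '?')}) in {self.name!r}"
            ) from None


def read_structure(path: str | Path, model: int = 1, altloc: str = "A") -> CoordinateModel:
    """Read a PDB or mmCIF file (optionally gzipped) into a coordinate model.

    ``model`` is 1-based (crystallographic convention).
    """
    path = Path(path)
    if not path.exists():
        raise SiteExtractionError(f"structure file not found: {path}")
    try:
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                text = fh.read()
            inner = path.with_suffix("").suffix.lower()
            if inner == ".pdb" or inner == ".ent":
                structure = gemmi.read_pdb_string(text)
            else:
                structure = gemmi.make_structure_from_block(
                    gemmi.cif.read_string(text).sole_block()
                )
        else:
            structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise SiteExtractionError(f"cannot parse structure {path}: {exc}") from None
    structure.setup_entities()
    return CoordinateModel(structure, model_index=model - 1, altloc=altloc)


# ---------------------------------------------------------------------------
# Active sites and templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionalAtomSet:
    """The three functional atoms of one catalytic residue, with coordinates."""

    residue: ResidueID
    atom_names: tuple[str, str, str]
    coords: np.ndarray  # shape (3, 3), Å

    def __post_init__(self) -> None:
        if len(self.atom_names) != 3:
            raise ValueError("exactly 3 functional atoms per residue")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3, 3) or not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be a finite (3, 3) array")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class ActiveSite:
    """Ordered catalytic residues of one enzyme, three functional atoms each."""

    entry_id: str
    residues: tuple[FunctionalAtomSet, ...]
    structure_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("active site needs at least one residue")
        keys = [r.residue.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residues in active site")

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Stacked functional-atom coordinates, shape (3*k, 3)."""
        sets = self.residues if indices is None else [self.residues[i] for i in indices]
        return np.vstack([fas.coords for fas in sets])


@dataclass(frozen=True)
class Template:
    """A 2-4 residue sub-constellation of an active site (site order kept)."""

    site: ActiveSite
    residue_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.residue_indices) <= 4:
            raise ValueError("template size must be 2..4")
        if list(self.residue_indices) != sorted(set(self.residue_indices)):
            raise ValueError("residue indices must be strictly increasing")
        if self.residue_indices[-1] >= len(self.site):
            raise ValueError("residue index out of range")

    @property
    def size(self) -> int:
        return len(self.residue_indices)

    @property
    def residues(self) -> tuple[FunctionalAtomSet, ...]:
        return tuple(self.site.residues[i] for i in self.residue_indices)

    def coords(self) -> np.ndarray:
        return self.site.coords(self.residue_indices)


def extract_active_site(
    model: CoordinateModel,
    entry: EnzymeEntry,
    atom_table: Optional[dict[str, tuple[str, str, str]]] = None,
    skip_missing: bool = False,
) -> ActiveSite:
    """Join an entry's catalogued catalytic residues to structure coordinates.

    Each residue contributes the triple chosen by :func:`functional_atoms_for`.
    Unresolvable residues/atoms raise; with ``skip_missing`` they are dropped
    with a warning instead (the site must still end up non-empty).
    """
    if not entry.catalytic_residues:
        raise SiteExtractionError(f"entry {entry.entry_id} has no catalytic residues")
    sets: list[FunctionalAtomSet] = []
    for res in entry.catalytic_residues:
        chain = res.chain or (entry.chain or "A")
        names = functional_atoms_for(res.name3, res.backbone, atom_table)
        try:
            coords = np.vstack([model.atom(chain, res.number, res.icode or "", nm) for nm in names])
        except SiteExtractionError as exc:
            if skip_missing:
                msg = f"entry {entry.entry_id}: skipping residue {res.name3}{res.number}: {exc}"
                logger.warning(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            raise
        sets.append(
            FunctionalAtomSet(
                residue=ResidueID(chain, res.number, res.icode, res.name3),
                atom_names=names,
                coords=coords,
            )
        )
    if not sets:
        raise SiteExtractionError(f"entry {entry.entry_id}: no catalytic residue could be resolved")
    return ActiveSite(entry_id=entry.entry_id, residues=tuple(sets), structure_id=model.name)


def enumerate_templates(site: ActiveSite, sizes: Sequence[int] = (2, 3, 4)) -> list[Template]:
    """All residue combinations of the requested sizes, in deterministic order.

    Order: size ascending, then lexicographic by residue indices.  For a site
    of n residues and default sizes this yields C(n,2)+C(n,3)+C(n,4) templates.
    """
    n = len(site)
    if n < 2:
        raise ValueError(f"site {site.entry_id} has {n} residue(s); need >= 2 to build templates")
    out: list[Template] = []
    for size in sorted(sizes):
        for idx in combinations(range(n), size):
            out.append(Template(site=site, residue_indices=idx))
    return out
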