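"""Domain types and catalogue I/O for enzyme entries.

An enzyme *entry* is one curated enzyme: its EC number (the reaction it
catalyses), the CATH code(s) of its catalytic domain (the fold), a reference
structure, its catalytic residues with mechanistic roles, and the cofactors
directly involved in catalysis.  Catalogues are JSON documents modelled on
the payloads of mechanism-annotation databases such as M-CSA: one record per
enzyme, residues addressed by author numbering in the reference structure.

Two enzymes with the same EC number are *isofunctional*; if their catalytic
domains additionally belong to different CATH superfamilies they are
*analogues* -- candidate products of convergent evolution.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ECNumber",
    "CATHCode",
    "CofactorSet",
    "CatalyticResidue",
    "EnzymeEntry",
    "CofactorRelation",
    "CatalogueError",
    "read_catalogue",
    "write_catalogue",
    "ec_match_level",
    "compare_cofactors",
]


class CatalogueError(ValueError):
    """Raised when a catalogue record violates the schema."""


# ---------------------------------------------------------------------------
# EC numbers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ECNumber:
    """Four-level Enzyme Commission code; ``None`` marks an undetermined level.

    Level 1 (class) runs 1..7; levels 2-3 narrow the reaction chemistry
    (sub-subclass = "reaction level"); level 4 is the substrate-specific
    serial.  A level written ``-`` or ``n`` in source data parses to ``None``.
    """

    class_: Optional[int]
    subclass: Optional[int]
    subsubclass: Optional[int]
    serial: Optional[int]

    def __post_init__(self) -> None:
        for level in self.components:
            if level is not None and level < 1:
                raise ValueError(f"EC components must be positive, got {level}")
        if self.class_ is not None and not 1 <= self.class_ <= 7:
            raise ValueError(f"EC class must be in 1..7, got {self.class_}")

    @property
    def components(self) -> tuple[Optional[int], ...]:
        return (self.class_, self.subclass, self.subsubclass, self.serial)

    @property
    def is_complete(self) -> bool:
        """True when all four levels are determined."""
        return all(c is not None for c in self.components)

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if not 1 <= len(parts) <= 4:
            raise ValueError(f"cannot parse EC number {text!r}")
        levels: list[Optional[int]] = []
        for part in parts:
            part = part.strip()
            if part in {"-", "", "n"} or part.startswith("n"):
                levels.append(None)
            elif part.isdigit():
                levels.append(int(part))
            else:
                raise ValueError(f"cannot parse EC component {part!r} in {text!r}")
        levels.extend([None] * (4 - len(levels)))
        return cls(*levels)

    def __str__(self) -> str:
        return ".".join("-" if c is None else str(c) for c in self.components)


def ec_match_level(a: ECNumber, b: ECNumber) -> int:
    """Deepest level k (0..4) at which the two EC numbers agree.

    A level counts only if it is determined in *both* operands and equal;
    the comparison stops at the first disagreement or undetermined level, so
    a full (level-4) match requires all four components determined in both.
    """
    level = 0
    for ca, cb in zip(a.components, b.components):
        if ca is None or cb is None or ca != cb:
            break
        level += 1
    return level


# ---------------------------------------------------------------------------
# CATH codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CATHCode:
    """CATH domain classification: Class.Architecture.Topology.Homology.

    Equality at the homologous-superfamily (H) level requires all four
    numbers equal; comparisons at shallower levels are prefix comparisons.
    """

    class_level: int
    architecture: int
    topology: int
    homology: int

    def __post_init__(self) -> None:
        for level in self.components:
            if level < 1:
                raise ValueError(f"CATH components must be positive, got {level}")

    @property
    def components(self) -> tuple[int, int, int, int]:
        return (self.class_level, self.architecture, self.topology, self.homology)

    @classmethod
    def parse(cls, text: str) -> "CATHCode":
        parts = text.strip().split(".")
        if len(parts) != 4 or not all(p.strip().isdigit() for p in parts):
            raise ValueError(f"cannot parse CATH code {text!r}")
        return cls(*(int(p) for p in parts))

    def match_level(self, other: "CATHCode") -> int:
        """Deepest level (0..4) at which the two codes agree as a prefix."""
        level = 0
        for ca, cb in zip(self.components, other.components):
            if ca != cb:
                break
            level += 1
        return level

    def __str__(self) -> str:
        return ".".join(str(c) for c in self.components)


# ---------------------------------------------------------------------------
# Cofactors
# ---------------------------------------------------------------------------

# Canonical display spellings; keys are the casefolded, markup-stripped form.
_COFACTOR_SPELLINGS = {
    "plp": "PLP",
    "nad": "NAD",
    "nadh": "NADH",
    "nadp": "NADP",
    "nadph": "NADPH",
    "fad": "FAD",
    "fmn": "FMN",
    "coa": "CoA",
    "acetyl-coa": "acetyl-CoA",
    "heme": "heme",
    "haem": "heme",
    "vo4": "VO4",
}

_MARKUP = re.compile(r"[\^_{}\s]+")


def normalise_cofactor(label: str) -> str:
    """Case- and markup-normalise a cofactor label.

    Charge-state spellings collapse ("Zn^2+" == "Zn2+"); metals end up as
    element+charge with the element capitalised; organic cofactors map to a
    canonical name where known, otherwise the casefolded spelling is kept
    verbatim (curated labels are trusted, e.g. NADH vs NADPH stay distinct).
    """
    stripped = _MARKUP.sub("", label.strip())
    if not stripped:
        raise ValueError("empty cofactor label")
    folded = stripped.casefold()
    if folded in _COFACTOR_SPELLINGS:
        return _COFACTOR_SPELLINGS[folded]
    m = re.fullmatch(r"([a-z]{1,2})(\d*[+-]?)", folded)
    if m and m.group(2):  # looks like an ion, e.g. zn2+, fe3+, cl-
        return m.group(1).capitalize() + m.group(2)
    return folded


@dataclass(frozen=True)
class CofactorSet:
    """Set of catalysis-relevant cofactor labels (normalised, duplicate-free)."""

    labels: frozenset[str]

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "CofactorSet":
        normalised = [normalise_cofactor(lab) for lab in labels]
        if len(normalised) != len(set(normalised)):
            raise ValueError(f"duplicate cofactor labels after normalisation: {normalised}")
        return cls(frozenset(normalised))

    def __bool__(self) -> bool:
        return bool(self.labels)

    def __iter__(self):
        return iter(sorted(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CofactorRelation:
    """Outcome of a pairwise cofactor comparison.

    category: "same" | "different"; subcategory refines it:
    same -> both_present_identical | both_absent;
    different -> both_present_different | one_present_one_absent.
    """

    category: str
    subcategory: str

    _VALID = {
        "both_present_identical": "same",
        "both_absent": "same",
        "both_present_different": "different",
        "one_present_one_absent": "different",
    }

    def __post_init__(self) -> None:
        if self._VALID.get(self.subcategory) != self.category:
            raise ValueError(
                f"inconsistent cofactor relation {self.category}/{self.subcategory}"
            )


def compare_cofactors(a: "EnzymeEntry | CofactorSet", b: "EnzymeEntry | CofactorSet") -> CofactorRelation:
    """Compare the cofactor complements of two enzymes.

    Identical non-empty sets are "same"; both empty is also "same" (neither
    needs a cofactor).  Any set inequality is "different", split by whether
    one side has no cofactor at all.
    """
    sa = a.cofactors if isinstance(a, EnzymeEntry) else a
    sb = b.cofactors if isinstance(b, EnzymeEntry) else b
    if sa.labels == sb.labels:
        if sa:
            return CofactorRelation("same", "both_present_identical")
        return CofactorRelation("same", "both_absent")
    if bool(sa) != bool(sb):
        return CofactorRelation("different", "one_present_one_absent")
    return CofactorRelation("different", "both_present_different")


# ---------------------------------------------------------------------------
# Enzyme entries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalyticResidue:
    """One catalytic residue as catalogued: location, identity, role.

    ``name3`` is the 3-letter amino-acid code, or "ANY" for residues that
    contribute only their main chain (printed "AnyNNN" in survey tables).
    ``backbone`` marks residues whose mechanistic contribution is through
    backbone atoms.
    """

    chain: str
    number: int
    icode: Optional[str] = None
    name3: str = "ANY"
    role: str = ""
    backbone: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode or "")


@dataclass(frozen=True)
class EnzymeEntry:
    """One catalogued enzyme.

    Entries with more than one catalytic-domain CATH code are flagged
    multi-domain (active site formed at a domain interface); entries whose
    EC or CATH information could not be fully parsed are flagged incomplete.
    Both kinds are *retained* in the catalogue and excluded later, at pair
    filtering, so catalogue round-trips stay lossless.
    """

    entry_id: str
    ec: ECNumber
    cath_codes: tuple[CATHCode, ...]
    pdb_id: str
    chain: Optional[str] = None
    catalytic_residues: tuple[CatalyticResidue, ...] = ()
    cofactors: CofactorSet = field(default_factory=lambda: CofactorSet(frozenset()))
    mechanism_ref: Optional[str] = None
    sequence: Optional[str] = None
    incomplete: bool = False
    incomplete_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")
        if not self.catalytic_residues:
            raise ValueError(f"entry {self.entry_id}: at least one catalytic residue required")
        keys = [r.key for r in self.catalytic_residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"entry {self.entry_id}: duplicate catalytic residues")

    @property
    def multi_domain(self) -> bool:
        return len(self.cath_codes) > 1


# ---------------------------------------------------------------------------
# Catalogue I/O
# ---------------------------------------------------------------------------

def _parse_record(rec: dict, index: int) -> EnzymeEntry:
    entry_id = rec.get("entry_id")
    if not entry_id:
        raise CatalogueError(f"record {index}: missing entry_id")

    def fail(field_name: str, message: str) -> CatalogueError:
        return CatalogueError(f"record {index} ({entry_id}): field {field_name!r}: {message}")

    incomplete = False
    reason = None
    try:
        ec = ECNumber.parse(str(rec.get("ec", "")))
    except ValueError:
        raise fail("ec", f"unparseable EC {rec.get('ec')!r}") from None
    if not ec.is_complete:
        incomplete, reason = True, "not all 4 EC levels determined"

    raw_cath = rec.get("cath", [])
    if not isinstance(raw_cath, list):
        raise fail("cath", "must be a list of C.A.T.H strings")
    cath_codes: list[CATHCode] = []
    for code in raw_cath:
        try:
            cath_codes.append(CATHCode.parse(str(code)))
        except ValueError:
            raise fail("cath", f"unparseable CATH code {code!r}") from None
    if not cath_codes:
        incomplete, reason = True, "no CATH mapping"

    residues = []
    for j, res in enumerate(rec.get("residues", [])):
        try:
            residues.append(
                CatalyticResidue(
                    chain=str(res.get("chain", "A")),
                    number=int(res["number"]),
                    icode=res.get("icode") or None,
                    name3=str(res.get("name3", "ANY")).upper(),
                    role=str(res.get("role", "")),
                    backbone=bool(res.get("backbone", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise fail(f"residues[{j}]", str(exc)) from None

    try:
        cofactors = CofactorSet.from_labels(rec.get("cofactors", []))
    except ValueError as exc:
        raise fail("cofactors", str(exc)) from None

    try:
        return EnzymeEntry(
            entry_id=str(entry_id),
            ec=ec,
            cath_codes=tuple(cath_codes),
            pdb_id=str(rec.get("pdb_id", "")),
            chain=rec.get("chain") or None,
            catalytic_residues=tuple(residues),
            cofactors=cofactors,
            mechanism_ref=rec.get("mechanism") or None,
            sequence=rec.get("sequence") or None,
            incomplete=incomplete,
            incomplete_reason=reason,
        )
    except ValueError as exc:
        raise CatalogueError(f"record {index} ({entry_id}): {exc}") from None


def read_catalogue(path: str | Path) -> list[EnzymeEntry]:
    """Read and validate a JSON enzyme catalogue.

    Entries with undetermined EC levels or no CATH mapping are returned
    flagged ``incomplete`` rather than dropped (removal is a filtering
    decision, not an I/O one).  Schema violations raise
    :class:`CatalogueError` naming the offending record and field.
    """
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    records = doc["entries"] if isinstance(doc, dict) else doc
    entries = [_parse_record(rec, i) for i, rec in enumerate(records)]
    seen: set[str] = set()
    for e in entries:
        if e.entry_id in seen:
            raise CatalogueError(f"duplicate entry_id {e.entry_id!r}")
        seen.add(e.entry_id)
    return entries


def entry_to_record(entry: EnzymeEntry) -> dict:
    return {
        "entry_id": entry.entry_id,
        "ec": str(entry.ec),
        "cath": [str(c) for c in entry.cath_codes],
        "pdb_id": entry.pdb_id,
        "chain": entry.chain,
        "residues": [
            {
                "chain": r.chain,
                "number": r.number,
                "icode": r.icode,
                "name3": r.name3,
                "role": r.role,
                "backbone": r.backbone,
            }
            for r in entry.catalytic_residues
        ],
        "cofactors": list(entry.cofactors),
        "mechanism": entry.mechanism_ref,
        "sequence": entry.sequence,
    }


def write_catalogue(entries: Sequence[EnzymeEntry], path: str | Path) -> None:
    """Write a catalogue back to JSON (inverse of :func:`read_catalogue`)."""
    doc = {"entries": [entry_to_record(e) for e in entries]}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
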