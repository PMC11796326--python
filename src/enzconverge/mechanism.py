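"""Curly-arrow mechanism abstraction and Jaccard mechanism similarity.

A catalytic mechanism is a sequence of steps, each a small molecular graph
(atoms with element/charge/role, bonds with order) plus curly arrows that
move one or two electrons from a source (a bond or a lone pair) to a sink
(an atom, an existing bond, or a new bond).  Each arrow is abstracted into
an *arrow environment*: a canonical string encoding the arrow's endpoint
atoms together with two shells of neighbouring atoms and bonds.  A
mechanism's profile is the set of its arrow-environment keys over all
steps, and two mechanisms are compared by the Jaccard index of their
profiles.  Because curation depth varies, a curated similar/not-similar
override can replace the computed call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "Atom",
    "Bond",
    "CurlyArrow",
    "MechanismStep",
    "MechanismGraph",
    "MechanismProfile",
    "MechanismSimilarity",
    "read_mechanism",
    "extract_arrow_environments",
    "jaccard_similarity",
    "classify_mechanism",
    "DEFAULT_SIMILARITY_THRESHOLD",
    "MechanismError",
]

# Computed profiles count as "similar" at or above this Jaccard score.
DEFAULT_SIMILARITY_THRESHOLD = 0.2

SHELL_DEPTH = 2  # shells of atoms/bonds encoded around arrow endpoints


class MechanismError(ValueError):
    """Raised for malformed mechanism graphs or arrows."""


@dataclass(frozen=True)
class Atom:
    id: str
    element: str
    charge: int = 0
    role: str = ""  # protein | substrate | cofactor | water | ""

    @property
    def descriptor(self) -> str:
        return f"{self.element}{self.charge:+d}[{self.role}]"


@dataclass(frozen=True)
class Bond:
    a1: str
    a2: str
    order: int = 1

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.a1, self.a2))


@dataclass(frozen=True)
class CurlyArrow:
    """One electron movement: source (bond | lone pair) to sink (atom | bond | new bond)."""

    source_kind: str                 # "bond" | "lone_pair"
    source_atoms: tuple[str, ...]    # 2 ids for a bond, 1 for a lone pair
    sink_kind: str                   # "atom" | "bond" | "new_bond"
    sink_atoms: tuple[str, ...]      # 1 id for atom, 2 for (new_)bond
    electrons: int = 2

    def __post_init__(self) -> None:
        if self.source_kind not in ("bond", "lone_pair"):
            raise MechanismError(f"bad arrow source kind {self.source_kind!r}")
        if self.sink_kind not in ("atom", "bond", "new_bond"):
            raise MechanismError(f"bad arrow sink kind {self.sink_kind!r}")
        if len(self.source_atoms) != (2 if self.source_kind == "bond" else 1):
            raise MechanismError("arrow source atom count inconsistent with kind")
        if len(self.sink_atoms) != (1 if self.sink_kind == "atom" else 2):
            raise MechanismError("arrow sink atom count inconsistent with kind")
        if self.electrons not in (1, 2):
            raise MechanismError("arrows move 1 or 2 electrons")
        if set(self.source_atoms) == set(self.sink_atoms):
            raise MechanismError("arrow source and sink coincide")


@dataclass(frozen=True)
class MechanismStep:
    atoms: dict[str, Atom]
    bonds: tuple[Bond, ...]
    arrows: tuple[CurlyArrow, ...]

    def __post_init__(self) -> None:
        bond_keys = set()
        for b in self.bonds:
            for aid in (b.a1, b.a2):
                if aid not in self.atoms:
                    raise MechanismError(f"bond references missing atom {aid!r}")
            if b.key in bond_keys:
                raise MechanismError(f"duplicate bond {sorted(b.key)}")
            bond_keys.add(b.key)
        for arrow in self.arrows:
            for aid in arrow.source_atoms + arrow.sink_atoms:
                if aid not in self.atoms:
                    raise MechanismError(f"arrow references missing atom {aid!r}")
            if arrow.source_kind == "bond" and frozenset(arrow.source_atoms) not in bond_keys:
                raise MechanismError(
                    f"arrow source bond {arrow.source_atoms} not present in step graph"
                )
            if arrow.sink_kind == "bond" and frozenset(arrow.sink_atoms) not in bond_keys:
                raise MechanismError(
                    f"arrow sink bond {arrow.sink_atoms} not present in step graph"
                )

    def neighbours(self, atom_id: str) -> list[tuple[int, str]]:
        out = []
        for b in self.bonds:
            if b.a1 == atom_id:
                out.append((b.order, b.a2))
            elif b.a2 == atom_id:
                out.append((b.order, b.a1))
        return out


@dataclass(frozen=True)
class MechanismGraph:
    entry_id: str
    steps: tuple[MechanismStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise MechanismError(f"mechanism for {self.entry_id!r} has no steps")


@dataclass(frozen=True)
class MechanismProfile:
    """Set of canonical arrow-environment keys for one enzyme's mechanism."""

    entry_id: str
    keys: frozenset[str]


@dataclass(frozen=True)
class MechanismSimilarity:
    """Similar/not-similar call with its provenance.

    ``score`` is the Jaccard index of the two arrow-environment sets, or
    None when not computable (a profile is empty/missing).  ``similar`` is
    None for "unknown" (not computable, no curated call).
    """

    score: Optional[float]
    similar: Optional[bool]
    provenance: str  # "computed" | "curated_override" | "unknown"


# ---------------------------------------------------------------------------
# Canonical arrow environments
# ---------------------------------------------------------------------------

def _encode_atom(step: MechanismStep, atom_id: str, depth: int, visited: frozenset[str]) -> str:
    """Bounded-depth canonical encoding of an atom and its bond neighbourhood.

    Neighbour encodings are sorted, so the key is invariant under any
    relabelling of atom ids.  A trailing ``*`` marks truncation at the depth
    limit while unexplored neighbours remain, so a truncated shell can never
    collide with a genuinely terminal atom.
    """
    atom = step.atoms[atom_id]
    nbrs = [(order, nid) for order, nid in step.neighbours(atom_id) if nid not in visited]
    if depth == 0:
        return atom.descriptor + ("*" if nbrs else "")
    inner = sorted(
        f"-{order}-" + _encode_atom(step, nid, depth - 1, visited | {atom_id})
        for order, nid in nbrs
    )
    return atom.descriptor + "(" + ",".join(inner) + ")"


def _encode_endpoint(step: MechanismStep, kind: str, atoms: tuple[str, ...]) -> str:
    encs = sorted(_encode_atom(step, a, SHELL_DEPTH, frozenset()) for a in atoms)
    return f"{kind}:" + "&".join(encs)


def arrow_environment(step: MechanismStep, arrow: CurlyArrow) -> str:
    """Canonical key for one curly arrow in its step graph."""
    src = _encode_endpoint(step, arrow.source_kind, arrow.source_atoms)
    snk = _encode_endpoint(step, arrow.sink_kind, arrow.sink_atoms)
    return f"{src}>>{snk}|e{arrow.electrons}"


def extract_arrow_environments(mech: MechanismGraph) -> frozenset[str]:
    """One canonical key per curly arrow, unioned over all steps (set semantics)."""
    keys = set()
    for step in mech.steps:
        for arrow in step.arrows:
            keys.add(arrow_environment(step, arrow))
    return frozenset(keys)


def profile_for(mech: MechanismGraph) -> MechanismProfile:
    return MechanismProfile(entry_id=mech.entry_id, keys=extract_arrow_environments(mech))


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def jaccard_similarity(a: MechanismProfile, b: MechanismProfile) -> Optional[float]:
    """|A n B| / |A u B|, or None ("not computable") if either set is empty.

    An empty profile means no detailed mechanism description, which is not
    evidence of dissimilarity -- hence None rather than 0.
    """
    if not a.keys or not b.keys:
        return None
    inter = len(a.keys & b.keys)
    union = len(a.keys | b.keys)
    return inter / union


def classify_mechanism(
    score: Optional[float],
    override: Optional[bool] = None,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> MechanismSimilarity:
    """Turn a Jaccard score and an optional curated call into a decision.

    A curated override always wins (curation sees similarity structure the
    set-based score misses, and vice versa).  Otherwise the computed score
    is thresholded; a non-computable score with no override stays unknown.
    """
    if override is not None:
        return MechanismSimilarity(score=score, similar=override, provenance="curated_override")
    if score is None:
        return MechanismSimilarity(score=None, similar=None, provenance="unknown")
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"similarity score must lie in [0, 1], got {score}")
    return MechanismSimilarity(score=score, similar=score >= threshold, provenance="computed")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_arrow(raw: dict) -> CurlyArrow:
    src, snk = raw["source"], raw["sink"]
    src_kind = src["type"]
    src_atoms = tuple(src["atoms"]) if src_kind == "bond" else (src["atom"],)
    snk_kind = snk["type"]
    snk_atoms = (snk["atom"],) if snk_kind == "atom" else tuple(snk["atoms"])
    return CurlyArrow(
        source_kind=src_kind,
        source_atoms=src_atoms,
        sink_kind=snk_kind,
        sink_atoms=snk_atoms,
        electrons=int(raw.get("electrons", 2)),
    )


def read_mechanism(path: str | Path) -> MechanismGraph:
    """Read a mechanism JSON document (steps -> atoms, bonds, arrows)."""
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    steps = []
    try:
        for raw_step in doc["steps"]:
            atoms = {
                a["id"]: Atom(
                    id=a["id"],
                    element=str(a["element"]),
                    charge=int(a.get("charge", 0)),
                    role=str(a.get("role", "")),
                )
                for a in raw_step.get("atoms", [])
            }
            bonds = tuple(
                Bond(b["a1"], b["a2"], int(b.get("order", 1)))
                for b in raw_step.get("bonds", [])
            )
            arrows = tuple(_parse_arrow(a) for a in raw_step.get("arrows", []))
            steps.append(MechanismStep(atoms=atoms, bonds=bonds, arrows=arrows))
    except KeyError as exc:
        raise MechanismError(f"{path}: missing field {exc}") from None
    return MechanismGraph(entry_id=str(doc.get("entry_id", path.stem)), steps=tuple(steps))


def write_profile(profile: MechanismProfile, path: str | Path) -> None:
    """Export a profile as a sorted key list (text), diff-friendly."""
    Path(path).write_text("\n".join(sorted(profile.keys)) + "\n")
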