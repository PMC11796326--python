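"""Synthetic catalogues, active sites and mechanisms with known ground truth.

Every pipeline stage is testable without downloads: active-site pairs are
generated as rigid transforms plus Gaussian coordinate noise (so the
planted residue mapping and transform are known exactly), mechanism
profiles are built with exact shared/private arrow-environment counts (so
the Jaccard score is known in closed form), and whole catalogues mix
homologue and analogue pairs of each convergence paradigm together with
multi-domain and incomplete entries for filter tests.

Synthetic sites can be written as minimal PDB files so the real structure
reader is exercised rather than bypassed.  All sampling flows from one
seeded numpy PCG64 generator: a fixed seed reproduces byte-identical
output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .entries import (
    CatalyticResidue,
    CATHCode,
    CofactorSet,
    ECNumber,
    EnzymeEntry,
    write_catalogue,
)
from .geometry import DEFAULT_RMSD_CUTOFF, DEFAULT_RULES, EquivalenceRules, best_site_mapping
from .mechanism import (
    Atom,
    Bond,
    CurlyArrow,
    MechanismGraph,
    MechanismProfile,
    MechanismStep,
    profile_for,
)
from .sites import FUNCTIONAL_ATOMS, ActiveSite, FunctionalAtomSet, ResidueID, functional_atoms_for

__all__ = [
    "SyntheticConfig",
    "SitePair",
    "SyntheticCatalogue",
    "make_site_pair",
    "make_decoy_site",
    "make_mechanism_pair",
    "toy_mechanism",
    "make_catalogue",
    "classify_catalogue",
    "write_site_pdb",
    "write_fixture_dir",
]

# Residue types drawn for synthetic sites, spread across equivalence classes.
_SITE_RESIDUE_POOL = ("HIS", "ASP", "GLU", "SER", "CYS", "LYS", "ARG", "TYR", "ASN")

# Class-disjoint composition pools: a site built from _POOL_X shares no
# residue equivalence class with one built from _POOL_Y, so no template
# match between them is admissible -- used to plant "no structural
# convergence" ground truth exactly.
_POOL_X = ("HIS", "CYS", "ASP")
_POOL_Y = ("SER", "LYS", "TYR")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generators; defaults emulate a small curated survey.

    Geometry: catalytic sites of 3-6 residues spread over ~8 Å with 0.1 Å
    per-axis coordinate noise between the two copies (the order of
    coordinate uncertainty in well-resolved crystal structures).  Mechanism
    profiles default to 3 shared + 2/2 private arrow environments (Jaccard
    ~0.43, comfortably above the 0.2 similarity threshold), drawn from a
    30-key alphabet.  Paradigm mix mirrors the curated survey's balance.
    """

    seed: int = 0
    n_groups: int = 6
    residues_per_site: tuple[int, int] = (3, 6)
    spread: float = 8.0          # Å, linear extent of a site
    noise_sigma: float = 0.1     # Å, per-axis Gaussian noise
    subset_size: Optional[int] = None  # residues of A kept in B (None = all)
    substitute_names: bool = False     # swap residue names within equivalence classes
    alphabet_size: int = 30
    shared_keys: int = 3
    private_keys_a: int = 2
    private_keys_b: int = 2
    paradigm_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    n_homologue_groups: int = 1
    fraction_multi_domain: float = 0.0
    fraction_incomplete: float = 0.0
    ec_pool: int = 50
    cath_pool: int = 200

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.spread <= 4 * self.noise_sigma:
            raise ValueError("spread must exceed 4x noise_sigma")
        if abs(sum(self.paradigm_mix) - 1.0) > 1e-9:
            raise ValueError("paradigm_mix must sum to 1")
        if min(self.paradigm_mix) < 0:
            raise ValueError("paradigm_mix proportions must be >= 0")
        lo, hi = self.residues_per_site
        if lo < 2 or hi < lo:
            raise ValueError("residues_per_site must be a range with min >= 2")


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SyntheticConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation from a normalised random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_centres(
    rng: np.random.Generator, n: int, spread: float, min_dist: float = 2.0, max_tries: int = 2000
) -> np.ndarray:
    """Residue centres in a cube of side ``spread``, pairwise >= ``min_dist`` Å apart."""
    centres: list[np.ndarray] = []
    tries = 0
    while len(centres) < n:
        c = rng.uniform(0.0, spread, size=3)
        if all(np.linalg.norm(c - prev) >= min_dist for prev in centres):
            centres.append(c)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} residue centres >= {min_dist} Å apart in a {spread} Å cube"
            )
    return np.array(centres)


def _residue_atoms(rng: np.random.Generator, centre: np.ndarray) -> np.ndarray:
    """Three functional-atom positions around a centre, guaranteed non-collinear."""
    for _ in range(100):
        offsets = rng.normal(scale=0.9, size=(3, 3))
        coords = centre + offsets
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        area = 0.5 * np.linalg.norm(np.cross(coords[1] - coords[0], coords[2] - coords[0]))
        if min(d01, d02, d12) > 0.8 and area > 0.4:
            return coords
    raise RuntimeError("could not generate a non-degenerate functional-atom triple")


def _build_site(
    rng: np.random.Generator,
    entry_id: str,
    n_residues: int,
    spread: float,
    pool: Sequence[str] = _SITE_RESIDUE_POOL,
) -> ActiveSite:
    centres = _sample_centres(rng, n_residues, spread)
    residues = []
    for i in range(n_residues):
        name3 = str(rng.choice(pool))
        residues.append(
            FunctionalAtomSet(
                residue=ResidueID("A", i + 1, None, name3),
                atom_names=functional_atoms_for(name3),
                coords=_residue_atoms(rng, centres[i]),
            )
        )
    return ActiveSite(entry_id=entry_id, residues=tuple(residues), structure_id=f"SYN-{entry_id}")


@dataclass(frozen=True)
class SitePair:
    site_a: ActiveSite
    site_b: ActiveSite
    mapping: tuple[tuple[int, int], ...]  # planted (index in A, index in B)
    rotation: np.ndarray
    translation: np.ndarray


def make_site_pair(
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    rules: EquivalenceRules = DEFAULT_RULES,
) -> SitePair:
    """A site and a rigidly moved, noisy copy (of a subset), mapping known.

    Site B takes ``cfg.subset_size`` residues of A (all by default), applies
    a uniform random proper rotation + translation, and adds independent
    per-axis Gaussian noise ``cfg.noise_sigma``.  With ``substitute_names``
    residue names are swapped within their equivalence class, which must not
    break matching.
    """
    rng = rng if rng is not None else _rng(cfg)
    n = int(rng.integers(cfg.residues_per_site[0], cfg.residues_per_site[1] + 1))
    site_a = _build_site(rng, "synthA", n, cfg.spread)
    k = cfg.subset_size if cfg.subset_size is not None else n
    if not 2 <= k <= n:
        raise ValueError(f"subset_size must be in 2..{n}")
    chosen = sorted(rng.choice(n, size=k, replace=False).tolist())
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    residues_b = []
    for bi, ai in enumerate(chosen):
        src = site_a.residues[ai]
        name3 = src.residue.name3
        if cfg.substitute_names:
            cls = sorted(rules.residue_class(name3) & set(FUNCTIONAL_ATOMS))
            if cls:
                name3 = str(rng.choice(cls))
        coords = src.coords @ R.T + t + rng.normal(scale=cfg.noise_sigma, size=(3, 3))
        residues_b.append(
            FunctionalAtomSet(
                residue=ResidueID("A", bi + 1, None, name3),
                atom_names=functional_atoms_for(name3),
                coords=coords,
            )
        )
    site_b = ActiveSite(entry_id="synthB", residues=tuple(residues_b), structure_id="SYN-synthB")
    mapping = tuple((ai, bi) for bi, ai in enumerate(chosen))
    return SitePair(site_a=site_a, site_b=site_b, mapping=mapping, rotation=R, translation=t)


def make_decoy_site(
    cfg: SyntheticConfig,
    source: ActiveSite,
    rng: Optional[np.random.Generator] = None,
    rules: EquivalenceRules = DEFAULT_RULES,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
    max_tries: int = 50,
) -> ActiveSite:
    """A site with the source's residue composition but resampled geometry,
    checked by construction to admit no 3+-residue match against the source.

    Size-2 (motif-level) matches may still occur -- that is the point: small
    templates often match spuriously, which is why motif-level hits are
    flagged and never alone justify structural convergence.
    """
    rng = rng if rng is not None else _rng(cfg)
    names = [fas.residue.name3 for fas in source.residues]
    # Wider, sparser geometry than the source: inter-residue distances in the
    # decoy then disagree with the source's by construction, which the
    # explicit check below turns into a guarantee.
    spread = max(2.5 * cfg.spread, 20.0)
    for _ in range(max_tries):
        centres = _sample_centres(rng, len(names), spread, min_dist=8.0)
        residues = tuple(
            FunctionalAtomSet(
                residue=ResidueID("A", i + 1, None, name3),
                atom_names=functional_atoms_for(name3),
                coords=_residue_atoms(rng, centres[i]),
            )
            for i, name3 in enumerate(names)
        )
        decoy = ActiveSite(entry_id="decoy", residues=residues, structure_id="SYN-decoy")
        if len(source) < 3:
            return decoy
        hit = best_site_mapping(source, decoy, rules=rules, rmsd_cutoff=rmsd_cutoff, min_size=3)
        if hit is None:
            return decoy
    raise RuntimeError("could not build a decoy without a 3+-residue match")


# ---------------------------------------------------------------------------
# Mechanisms
# ---------------------------------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S", "P")
_ROLES = ("protein", "substrate")


def toy_mechanism(entry_id: str, key_indices: Sequence[int], alphabet_size: int = 30) -> MechanismGraph:
    """A toy mechanism whose arrow environments are exactly ``key_indices``.

    Each index becomes one step: a three-atom chain whose element, charge,
    role and bond-order pattern are derived from the index, with a single
    lone-pair -> new-bond arrow.  Distinct indices give distinct canonical
    keys; equal indices give identical keys, so profile overlaps are exact.
    """
    steps = []
    for idx in key_indices:
        if not 0 <= idx < alphabet_size:
            raise ValueError(f"key index {idx} outside alphabet 0..{alphabet_size - 1}")
        el = _ELEMENTS[idx % len(_ELEMENTS)]
        charge = (idx // len(_ELEMENTS)) % 3 - 1
        role = _ROLES[(idx // (len(_ELEMENTS) * 3)) % len(_ROLES)]
        order = 1 + (idx // (len(_ELEMENTS) * 3 * len(_ROLES))) % 2
        atoms = {
            "a1": Atom("a1", el, charge, role),
            "a2": Atom("a2", "C", 0, "substrate"),
            "a3": Atom("a3", "O", 0, "water"),
        }
        bonds = (Bond("a1", "a2", order),)
        arrows = (
            CurlyArrow(
                source_kind="lone_pair",
                source_atoms=("a3",),
                sink_kind="new_bond",
                sink_atoms=("a3", "a2"),
                electrons=2,
            ),
        )
        steps.append(MechanismStep(atoms=atoms, bonds=bonds, arrows=arrows))
    return MechanismGraph(entry_id=entry_id, steps=tuple(steps))


def make_mechanism_pair(
    k: int, a: int, b: int, seed: int = 0, alphabet_size: int = 30
) -> tuple[MechanismProfile, MechanismProfile]:
    """Two profiles with exactly k shared and a/b private keys.

    By construction their Jaccard index is k / (k + a + b).
    """
    if k + a < 1 or k + b < 1:
        raise ValueError("each profile needs at least one key")
    if k + a + b > alphabet_size:
        raise ValueError("alphabet too small for requested key counts")
    rng = np.random.default_rng(seed)
    indices = rng.choice(alphabet_size, size=k + a + b, replace=False).tolist()
    shared, priv_a, priv_b = indices[:k], indices[k:k + a], indices[k + a:]
    prof_a = profile_for(toy_mechanism("mechA", shared + priv_a, alphabet_size))
    prof_b = profile_for(toy_mechanism("mechB", shared + priv_b, alphabet_size))
    assert len(prof_a.keys & prof_b.keys) == k and len(prof_a.keys | prof_b.keys) == k + a + b
    return prof_a, prof_b


# ---------------------------------------------------------------------------
# Catalogues
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCatalogue:
    entries: list[EnzymeEntry]
    sites: dict[str, ActiveSite]
    mechanisms: dict[str, MechanismGraph]
    truth: list[tuple[str, str, str]]  # (entry_a, entry_b, planted paradigm)
    excluded_ids: list[str] = field(default_factory=list)


def _entry_for_site(
    entry_id: str,
    ec: ECNumber,
    cath: tuple[CATHCode, ...],
    site: ActiveSite,
    incomplete_ec: bool = False,
) -> EnzymeEntry:
    residues = tuple(
        CatalyticResidue(
            chain=fas.residue.chain, number=fas.residue.number, name3=fas.residue.name3
        )
        for fas in site.residues
    )
    if incomplete_ec:
        ec = ECNumber(ec.class_, ec.subclass, ec.subsubclass, None)
    return EnzymeEntry(
        entry_id=entry_id,
        ec=ec,
        cath_codes=cath,
        pdb_id=site.structure_id,
        catalytic_residues=residues,
        cofactors=CofactorSet(frozenset()),
        incomplete=incomplete_ec,
        incomplete_reason="not all 4 EC levels determined" if incomplete_ec else None,
    )


def _rename_site(site: ActiveSite, entry_id: str) -> ActiveSite:
    return ActiveSite(
        entry_id=entry_id, residues=site.residues, structure_id=f"SYN-{entry_id}"
    )


def make_catalogue(cfg: SyntheticConfig) -> SyntheticCatalogue:
    """A catalogue with planted paradigm ground truth per analogue pair.

    Each analogue group draws a paradigm from ``cfg.paradigm_mix``:

    * structural_and_mechanistic -- site B is a noisy rigid copy of A and the
      mechanism profiles share keys well above the similarity threshold;
    * mechanistic_only -- similar mechanisms, but the two sites are built
      from equivalence-class-disjoint residue pools, so no template match
      is admissible;
    * reaction_only -- class-disjoint sites and disjoint mechanism profiles.

    Homologue groups (same CATH code) and, optionally, multi-domain /
    incomplete entries are added for enumeration and filter tests; the
    latter are recorded in ``excluded_ids``.
    """
    rng = _rng(cfg)
    labels = ("structural_and_mechanistic", "mechanistic_only", "reaction_only")
    entries: list[EnzymeEntry] = []
    sites: dict[str, ActiveSite] = {}
    mechanisms: dict[str, MechanismGraph] = {}
    truth: list[tuple[str, str, str]] = []
    excluded: list[str] = []

    ec_codes = [(3, 5, 1 + i // 10, 1 + i % 10) for i in range(cfg.ec_pool)]
    cath_counter = iter(range(1, cfg.cath_pool + 1))

    def next_cath() -> CATHCode:
        i = next(cath_counter)
        return CATHCode(1 + i % 4, 10 + i % 7, 100 + i, 10)

    k, pa, pb = cfg.shared_keys, cfg.private_keys_a, cfg.private_keys_b
    n_res = lambda: int(rng.integers(cfg.residues_per_site[0], cfg.residues_per_site[1] + 1))

    for gi in range(cfg.n_groups):
        label = labels[int(rng.choice(3, p=cfg.paradigm_mix))]
        ec = ECNumber(*ec_codes[gi % len(ec_codes)])
        id_a, id_b = f"e{gi:03d}a", f"e{gi:03d}b"
        if label == "structural_and_mechanistic":
            pair_cfg = SyntheticConfig(
                seed=cfg.seed,
                residues_per_site=cfg.residues_per_site,
                spread=cfg.spread,
                noise_sigma=cfg.noise_sigma,
            )
            sp = make_site_pair(pair_cfg, rng=rng)
            site_a = _rename_site(sp.site_a, id_a)
            site_b = _rename_site(sp.site_b, id_b)
            idx = rng.choice(cfg.alphabet_size, size=k + pa + pb, replace=False).tolist()
            mech_a = toy_mechanism(id_a, idx[: k + pa], cfg.alphabet_size)
            mech_b = toy_mechanism(id_b, idx[:k] + idx[k + pa:], cfg.alphabet_size)
        else:
            site_a = _build_site(rng, id_a, n_res(), cfg.spread, pool=_POOL_X)
            site_b = _build_site(rng, id_b, n_res(), cfg.spread, pool=_POOL_Y)
            site_a = _rename_site(site_a, id_a)
            site_b = _rename_site(site_b, id_b)
            if label == "mechanistic_only":
                idx = rng.choice(cfg.alphabet_size, size=k + pa + pb, replace=False).tolist()
                mech_a = toy_mechanism(id_a, idx[: k + pa], cfg.alphabet_size)
                mech_b = toy_mechanism(id_b, idx[:k] + idx[k + pa:], cfg.alphabet_size)
            else:  # reaction_only: disjoint profiles
                idx = rng.choice(cfg.alphabet_size, size=2 * max(1, pa + k), replace=False).tolist()
                half = len(idx) // 2
                mech_a = toy_mechanism(id_a, idx[:half], cfg.alphabet_size)
                mech_b = toy_mechanism(id_b, idx[half:], cfg.alphabet_size)
        entries.append(_entry_for_site(id_a, ec, (next_cath(),), site_a))
        entries.append(_entry_for_site(id_b, ec, (next_cath(),), site_b))
        sites[id_a], sites[id_b] = site_a, site_b
        mechanisms[id_a], mechanisms[id_b] = mech_a, mech_b
        truth.append((id_a, id_b, label))

    for hi in range(cfg.n_homologue_groups):
        ec = ECNumber(*ec_codes[(cfg.n_groups + hi) % len(ec_codes)])
        cath = (next_cath(),)
        for suffix in "ab":
            eid = f"h{hi:03d}{suffix}"
            site = _rename_site(_build_site(rng, eid, n_res(), cfg.spread), eid)
            entries.append(_entry_for_site(eid, ec, cath, site))
            sites[eid] = site
            mechanisms[eid] = toy_mechanism(eid, [0, 1], cfg.alphabet_size)

    n_bad = int(round(cfg.fraction_multi_domain * len(entries)))
    for i in range(n_bad):
        eid = f"m{i:03d}"
        ec = ECNumber(*ec_codes[i % len(ec_codes)])
        site = _rename_site(_build_site(rng, eid, n_res(), cfg.spread), eid)
        entries.append(_entry_for_site(eid, ec, (next_cath(), next_cath()), site))
        sites[eid] = site
        excluded.append(eid)
    n_inc = int(round(cfg.fraction_incomplete * len(entries)))
    for i in range(n_inc):
        eid = f"i{i:03d}"
        ec = ECNumber(*ec_codes[i % len(ec_codes)])
        site = _rename_site(_build_site(rng, eid, n_res(), cfg.spread), eid)
        entries.append(_entry_for_site(eid, ec, (next_cath(),), site, incomplete_ec=True))
        sites[eid] = site
        excluded.append(eid)

    return SyntheticCatalogue(
        entries=entries, sites=sites, mechanisms=mechanisms, truth=truth, excluded_ids=excluded
    )


def classify_catalogue(cat: SyntheticCatalogue, **populate_kwargs) -> dict[tuple[str, str], str]:
    """Run the full pair pipeline on a synthetic catalogue in memory.

    Enumerates and filters same-EC pairs from the catalogue entries,
    populates each with superposition and mechanism metrics from the
    generated sites and mechanisms, and returns the assigned paradigm per
    analogue pair -- directly comparable with ``cat.truth``.
    """
    from .pairs import assign_paradigm, enumerate_pairs, filter_pairs, populate_pair

    pairs, _ = filter_pairs(enumerate_pairs(cat.entries, ec_level=4))
    out: dict[tuple[str, str], str] = {}
    for pair in pairs:
        if pair.homology != "analogue":
            continue
        id_a, id_b = pair.ids
        populate_pair(
            pair,
            site_a=cat.sites[id_a],
            site_b=cat.sites[id_b],
            profile_a=profile_for(cat.mechanisms[id_a]) if id_a in cat.mechanisms else None,
            profile_b=profile_for(cat.mechanisms[id_b]) if id_b in cat.mechanisms else None,
            **populate_kwargs,
        )
        out[(id_a, id_b)] = assign_paradigm(pair)
    return out


# ---------------------------------------------------------------------------
# Fixture output (PDB / JSON / TSV)
# ---------------------------------------------------------------------------

def write_site_pdb(site: ActiveSite, path: str | Path) -> None:
    """Write a site as a minimal single-chain PDB file (functional atoms only)."""
    structure = gemmi.Structure()
    structure.name = site.structure_id or site.entry_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for fas in site.residues:
        res = gemmi.Residue()
        res.name = fas.residue.name3 if fas.residue.name3 != "ANY" else "GLY"
        res.seqid = gemmi.SeqId(fas.residue.number, " ")
        for name, xyz in zip(fas.atom_names, fas.coords):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def _mechanism_to_json(mech: MechanismGraph) -> dict:
    return {
        "entry_id": mech.entry_id,
        "steps": [
            {
                "atoms": [
                    {"id": a.id, "element": a.element, "charge": a.charge, "role": a.role}
                    for a in step.atoms.values()
                ],
                "bonds": [
                    {"a1": b.a1, "a2": b.a2, "order": b.order} for b in step.bonds
                ],
                "arrows": [
                    {
                        "source": (
                            {"type": "bond", "atoms": list(ar.source_atoms)}
                            if ar.source_kind == "bond"
                            else {"type": "lone_pair", "atom": ar.source_atoms[0]}
                        ),
                        "sink": (
                            {"type": "atom", "atom": ar.sink_atoms[0]}
                            if ar.sink_kind == "atom"
                            else {"type": ar.sink_kind, "atoms": list(ar.sink_atoms)}
                        ),
                        "electrons": ar.electrons,
                    }
                    for ar in step.arrows
                ],
            }
            for step in mech.steps
        ],
    }


def write_fixture_dir(cat: SyntheticCatalogue, outdir: str | Path) -> None:
    """Write a catalogue as on-disk fixtures: catalogue JSON, one PDB per
    entry, one mechanism JSON per entry, and a ground-truth TSV."""
    import json

    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    (outdir / "mechanisms").mkdir(parents=True, exist_ok=True)
    entries = []
    for entry in cat.entries:
        mech_ref = None
        if entry.entry_id in cat.mechanisms:
            mech_ref = f"mechanisms/{entry.entry_id}.json"
            (outdir / mech_ref).write_text(
                json.dumps(_mechanism_to_json(cat.mechanisms[entry.entry_id]), indent=1) + "\n"
            )
        entries.append(
            EnzymeEntry(
                **{
                    **entry.__dict__,
                    "mechanism_ref": mech_ref,
                    "pdb_id": f"structures/{entry.entry_id}.pdb",
                }
            )
        )
        write_site_pdb(cat.sites[entry.entry_id], outdir / "structures" / f"{entry.entry_id}.pdb")
    write_catalogue(entries, outdir / "catalogue.json")
    with (outdir / "ground_truth.tsv").open("w") as fh:
        fh.write("entry_a\tentry_b\tparadigm\n")
        for id_a, id_b, label in cat.truth:
            fh.write(f"{id_a}\t{id_b}\t{label}\n")
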