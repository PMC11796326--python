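"""Template matching and Gaussian-weighted superposition of active sites.

Matching works on equal-size templates (2-4 residues, 3 functional atoms
each).  Residues may pair across *equivalence classes* of chemically similar
types (Asp~Glu, Ser~Thr, ...), and chemically symmetric atoms within a
residue (the two carboxylate oxygens, His ND1/NE2, Arg NH1/NH2) may swap.
Every admissible residue bijection x atom pairing is scored with an
unweighted Kabsch fit; the lowest-RMSD candidate under a cutoff wins.

The best match over all template sizes (largest size, then lowest RMSD)
becomes the reference atom-atom mapping for *dynamic fitting*: an iterative
Kabsch superposition where each atom pair is weighted
``w_i = exp(-d_i^2 / (2 sigma^2))`` so poorly fitting pairs are
progressively down-weighted.  It reports an unweighted RMSD, a weighted
wRMSD and a coverage (mapped residues over the larger site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Iterable, Optional, Sequence

import numpy as np

from .sites import ActiveSite, Template, enumerate_templates

__all__ = [
    "KabschResult",
    "EquivalenceRules",
    "DEFAULT_RULES",
    "TemplateMatch",
    "SuperpositionResult",
    "kabsch_fit",
    "match_templates",
    "best_site_mapping",
    "iterative_weighted_fit",
    "DEFAULT_RMSD_CUTOFF",
    "DEFAULT_SIGMA",
]

DEFAULT_RMSD_CUTOFF = 3.5  # Å; templates matching above this are rejected
DEFAULT_SIGMA = 2.0        # Å; Gaussian weighting width for dynamic fitting


# ---------------------------------------------------------------------------
# Weighted Kabsch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KabschResult:
    rotation: np.ndarray     # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float              # unweighted, Å
    wrmsd: float             # weighted, Å
    degenerate: bool = False

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_fit(
    points_a: np.ndarray,
    points_b: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> KabschResult:
    """Weighted least-squares rigid fit of ``points_a`` onto ``points_b``.

    Returns the proper rotation R and translation t minimising
    ``sum_i w_i |R a_i + t - b_i|^2`` (reflections are corrected by flipping
    the smallest singular direction).  RMSD is the unweighted root mean
    square residual; wRMSD uses the supplied weights.

    Fewer than 3 points, or (near-)collinear points, cannot pin down all
    rotational degrees of freedom; the fit is still returned but flagged
    ``degenerate``.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must share shape (k, 3); got {A.shape} vs {B.shape}")
    k = A.shape[0]
    if k == 0:
        raise ValueError("cannot fit zero points")
    if weights is None:
        w = np.ones(k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,):
            raise ValueError(f"weights must have shape ({k},)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")

    ca = (w[:, None] * A).sum(axis=0) / wsum
    cb = (w[:, None] * B).sum(axis=0) / wsum
    Ac, Bc = A - ca, B - cb
    H = (w[:, None] * Ac).T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca

    residuals = A @ R.T + t - B
    sq = np.einsum("ij,ij->i", residuals, residuals)
    rmsd = float(np.sqrt(sq.mean()))
    wrmsd = float(np.sqrt((w * sq).sum() / wsum))

    degenerate = k < 3 or S[1] < 1e-9 * max(S[0], 1e-30)
    return KabschResult(rotation=R, translation=t, rmsd=rmsd, wrmsd=wrmsd, degenerate=degenerate)


def gaussian_weights(distances: np.ndarray, sigma: float) -> np.ndarray:
    """``w_i = exp(-d_i^2 / (2 sigma^2))``; 1 at d=0, decaying with misfit."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(distances, dtype=float)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


# ---------------------------------------------------------------------------
# Equivalence rules
# ---------------------------------------------------------------------------

_IDENTITY = (0, 1, 2)

# Default residue equivalence classes (chemically interchangeable in matching).
_DEFAULT_CLASSES: tuple[frozenset[str], ...] = (
    frozenset({"ASP", "GLU"}),
    frozenset({"ASN", "GLN"}),
    frozenset({"SER", "THR"}),
    frozenset({"HIS"}),
    frozenset({"CYS"}),
    frozenset({"LYS", "ARG"}),
    frozenset({"TYR", "PHE", "TRP"}),
    frozenset({"VAL", "LEU", "ILE", "MET", "ALA"}),
    frozenset({"ANY"}),
)

# Per-residue-type automorphisms of the functional triple: permutations that
# exchange chemically indistinguishable atoms (indices into the 3 functional
# atoms of sites.FUNCTIONAL_ATOMS).
_DEFAULT_AUTOMORPHISMS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "ASP": (_IDENTITY, (0, 2, 1)),   # OD1 <-> OD2
    "GLU": (_IDENTITY, (0, 2, 1)),   # OE1 <-> OE2
    "ARG": (_IDENTITY, (0, 2, 1)),   # NH1 <-> NH2
    "HIS": (_IDENTITY, (2, 1, 0)),   # ND1 <-> NE2 (imidazole tautomers)
    "TYR": (_IDENTITY, (0, 2, 1)),   # ring direction
    "PHE": (_IDENTITY, (0, 2, 1)),
    "TRP": (_IDENTITY, (0, 2, 1)),
}


@dataclass(frozen=True)
class EquivalenceRules:
    """Which residue types may pair, and which atom pairings are admissible.

    ``classes`` must be disjoint; residue types not in any class form
    implicit singletons (they match only themselves).  ``automorphisms``
    lists, per residue type, the index permutations of its functional triple
    that leave its chemistry unchanged; the admissible atom pairings between
    two residues are all compositions of their automorphism groups.
    """

    classes: tuple[frozenset[str], ...] = _DEFAULT_CLASSES
    automorphisms: dict[str, tuple[tuple[int, int, int], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_AUTOMORPHISMS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls in self.classes:
            if seen & cls:
                raise ValueError(f"equivalence classes overlap on {sorted(seen & cls)}")
            seen |= cls

    def residue_class(self, name3: str) -> frozenset[str]:
        name3 = name3.upper()
        for cls in self.classes:
            if name3 in cls:
                return cls
        return frozenset({name3})

    def compatible(self, name_a: str, name_b: str) -> bool:
        return name_b.upper() in self.residue_class(name_a)

    def atom_pairings(self, name_a: str, name_b: str) -> tuple[tuple[int, int, int], ...]:
        """Admissible pairings: atom i of A pairs with atom p[i] of B."""
        auts_a = self.automorphisms.get(name_a.upper(), (_IDENTITY,))
        auts_b = self.automorphisms.get(name_b.upper(), (_IDENTITY,))
        out = {tuple(pb[pa[i]] for i in range(3)) for pa in auts_a for pb in auts_b}
        return tuple(sorted(out))  # type: ignore[return-value]


DEFAULT_RULES = EquivalenceRules()


# ---------------------------------------------------------------------------
# Template matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateMatch:
    """A residue/atom correspondence between two sites with its rigid fit.

    ``residue_index_pairs`` index into the parent ActiveSites; ``atom_pairings``
    gives, per residue pair, the permutation p with atom i of A paired to
    atom p[i] of B.  Size-2 matches are flagged motif-level: small templates
    often match spuriously and never alone justify structural convergence.
    """

    site_a: ActiveSite
    site_b: ActiveSite
    residue_index_pairs: tuple[tuple[int, int], ...]
    atom_pairings: tuple[tuple[int, int, int], ...]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    @property
    def size(self) -> int:
        return len(self.residue_index_pairs)

    @property
    def motif_level(self) -> bool:
        return self.size == 2

    @property
    def residue_pairs(self):
        return tuple(
            (self.site_a.residues[ia].residue, self.site_b.residues[ib].residue)
            for ia, ib in self.residue_index_pairs
        )

    def mapped_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Paired functional-atom coordinates (A-array, B-array), (3k, 3) each."""
        pa, pb = [], []
        for (ia, ib), perm in zip(self.residue_index_pairs, self.atom_pairings):
            ra = self.site_a.residues[ia].coords
            rb = self.site_b.residues[ib].coords
            for i in range(3):
                pa.append(ra[i])
                pb.append(rb[perm[i]])
        return np.array(pa), np.array(pb)


def _candidate_pairings(
    t_a: Template, t_b: Template, rules: EquivalenceRules
) -> Iterable[tuple[tuple[int, ...], tuple[tuple[int, int, int], ...]]]:
    """All admissible (residue bijection, per-pair atom pairing) candidates."""
    res_a = t_a.residues
    res_b = t_b.residues
    k = len(res_a)
    for perm in permutations(range(k)):
        if not all(
            rules.compatible(res_a[i].residue.name3, res_b[perm[i]].residue.name3)
            for i in range(k)
        ):
            continue
        options = [
            rules.atom_pairings(res_a[i].residue.name3, res_b[perm[i]].residue.name3)
            for i in range(k)
        ]
        for atom_perms in product(*options):
            yield perm, atom_perms


def _pair_coords(
    t_a: Template,
    t_b: Template,
    perm: tuple[int, ...],
    atom_perms: tuple[tuple[int, int, int], ...],
) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = [], []
    res_a, res_b = t_a.residues, t_b.residues
    for i, (j, aperm) in enumerate(zip(perm, atom_perms)):
        ca, cb = res_a[i].coords, res_b[j].coords
        for ai in range(3):
            pa.append(ca[ai])
            pb.append(cb[aperm[ai]])
    return np.array(pa), np.array(pb)


def match_templates(
    t_a: Template,
    t_b: Template,
    rules: EquivalenceRules = DEFAULT_RULES,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
) -> Optional[TemplateMatch]:
    """Best rigid match between two equal-size templates, or None.

    Exhausts every residue bijection admitted by the equivalence classes and
    every admissible atom pairing, scoring each with a unit-weight Kabsch
    fit; returns the minimum-RMSD candidate if it passes the cutoff.
    Ties break deterministically (residue bijection, then atom pairing).
    """
    if t_a.size != t_b.size:
        raise ValueError(f"template sizes differ: {t_a.size} vs {t_b.size}")
    best: Optional[tuple[float, tuple, tuple, KabschResult]] = None
    for perm, atom_perms in _candidate_pairings(t_a, t_b, rules):
        pa, pb = _pair_coords(t_a, t_b, perm, atom_perms)
        fit = kabsch_fit(pa, pb)
        key = (fit.rmsd, perm, atom_perms)
        if best is None or key < (best[0], best[1], best[2]):
            best = (fit.rmsd, perm, atom_perms, fit)
    if best is None or best[0] > rmsd_cutoff:
        return None
    rmsd, perm, atom_perms, fit = best
    index_pairs = tuple(
        (t_a.residue_indices[i], t_b.residue_indices[perm[i]]) for i in range(t_a.size)
    )
    return TemplateMatch(
        site_a=t_a.site,
        site_b=t_b.site,
        residue_index_pairs=index_pairs,
        atom_pairings=atom_perms,
        rotation=fit.rotation,
        translation=fit.translation,
        rmsd=rmsd,
    )


def best_site_mapping(
    site_a: ActiveSite,
    site_b: ActiveSite,
    rules: EquivalenceRules = DEFAULT_RULES,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
    min_size: int = 2,
) -> Optional[TemplateMatch]:
    """Reference atom-atom mapping between two sites, or None.

    Templates of equal size are compared all-against-all; among accepted
    matches the largest size wins, then the lowest RMSD (a larger
    correspondence makes a better reference frame than a marginally lower
    RMSD on fewer residues).  Ties break lexicographically on residue
    indices.  Searches size 4, then 3, then 2; smaller sizes are skipped
    once a larger size has produced an accepted match.
    """
    if len(site_a) < 2 or len(site_b) < 2:
        return None
    max_size = min(4, len(site_a), len(site_b))
    for size in range(max_size, min_size - 1, -1):
        templates_a = enumerate_templates(site_a, sizes=(size,))
        templates_b = enumerate_templates(site_b, sizes=(size,))
        accepted: list[TemplateMatch] = []
        for ta in templates_a:
            for tb in templates_b:
                m = match_templates(ta, tb, rules, rmsd_cutoff)
                if m is not None:
                    accepted.append(m)
        if accepted:
            return min(accepted, key=lambda m: (m.rmsd, m.residue_index_pairs))
    return None


# ---------------------------------------------------------------------------
# Dynamic (iteratively weighted) fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    """Converged weighted superposition of two active sites.

    ``rmsd`` is the unweighted RMSD over the mapped functional atoms in the
    final frame (the value comparable across pairs); ``wrmsd`` is the
    Gaussian-weighted value the iteration optimises; ``coverage`` is mapped
    residues over the residue count of the larger site.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    wrmsd: float
    coverage: float
    iterations: int
    converged: bool
    aligned_residue_pairs: tuple[tuple[str, str], ...]
    n_mapped: int
    motif_level: bool = False


def iterative_weighted_fit(
    site_a: ActiveSite,
    site_b: ActiveSite,
    mapping: TemplateMatch,
    sigma: float = DEFAULT_SIGMA,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> SuperpositionResult:
    """Gaussian-weighted iterative Kabsch superposition on a fixed mapping.

    Starting from unit weights, alternately (a) fit A onto B with the
    current weights and (b) reset ``w_i = exp(-d_i^2/(2 sigma^2))`` from the
    residual distances, until the largest weight change drops below ``tol``
    or ``max_iter`` is hit.  On converging runs the wRMSD is non-increasing
    between steps; an increase is recorded as non-convergence, never an
    exception.
    """
    if mapping.site_a.entry_id != site_a.entry_id or mapping.site_b.entry_id != site_b.entry_id:
        raise ValueError("mapping does not belong to the given sites")
    for ia, ib in mapping.residue_index_pairs:
        if ia >= len(site_a) or ib >= len(site_b):
            raise ValueError("mapping indexes residues outside the sites")

    pa, pb = mapping.mapped_coords()
    n_atoms = pa.shape[0]
    w = np.ones(n_atoms)
    fit = kabsch_fit(pa, pb, w)
    prev_wrmsd = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d = np.linalg.norm(fit.transform(pa) - pb, axis=1)
        new_w = gaussian_weights(d, sigma)
        delta = float(np.max(np.abs(new_w - w)))
        w = new_w
        fit = kabsch_fit(pa, pb, w)
        if fit.wrmsd > prev_wrmsd + 1e-9:
            converged = False
            break
        prev_wrmsd = fit.wrmsd
        if delta < tol:
            converged = True
            break

    coverage = mapping.size / max(len(site_a), len(site_b))
    pairs = tuple((str(ra), str(rb)) for ra, rb in mapping.residue_pairs)
    return SuperpositionResult(
        rotation=fit.rotation,
        translation=fit.translation,
        rmsd=fit.rmsd,
        wrmsd=fit.wrmsd,
        coverage=coverage,
        iterations=iterations,
        converged=converged,
        aligned_residue_pairs=pairs,
        n_mapped=mapping.size,
        motif_level=mapping.motif_level,
    )
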