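import numpy as np
import pytest

from enzconverge.sites import ActiveSite, FunctionalAtomSet, ResidueID, functional_atoms_for


def build_site(entry_id, names, coords):
    """Assemble an ActiveSite from residue names and (k, 3, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    residues = tuple(
        FunctionalAtomSet(
            residue=ResidueID("A", i + 1, None, name),
            atom_names=functional_atoms_for(name),
            coords=coords[i],
        )
        for i, name in enumerate(names)
    )
    return ActiveSite(entry_id=entry_id, residues=residues, structure_id=f"SYN-{entry_id}")


def random_site(rng, names, spread=8.0, entry_id="rand"):
    """Random, well-separated site with the given residue names."""
    centres = []
    while len(centres) < len(names):
        c = rng.uniform(0, spread, size=3)
        if all(np.linalg.norm(c - p) >= 2.0 for p in centres):
            centres.append(c)
    coords = np.array([c + rng.normal(scale=0.9, size=(3, 3)) for c in centres])
    return build_site(entry_id, names, coords)


def random_rotation(rng):
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


def transform_site(site, R, t):
    residues = tuple(
        FunctionalAtomSet(
            residue=fas.residue, atom_names=fas.atom_names, coords=fas.coords @ R.T + t
        )
        for fas in site.residues
    )
    return ActiveSite(entry_id=site.entry_id, residues=residues, structure_id=site.structure_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
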