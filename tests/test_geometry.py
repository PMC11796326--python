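import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from enzconverge.geometry import (
    DEFAULT_RULES,
    EquivalenceRules,
    best_site_mapping,
    gaussian_weights,
    iterative_weighted_fit,
    kabsch_fit,
    match_templates,
)
from enzconverge.sites import enumerate_templates
from enzconverge.synthetic import SyntheticConfig, make_decoy_site, make_site_pair

from conftest import build_site, random_rotation, random_site, transform_site


# --- independent oracles -----------------------------------------------------

def quaternion_fit_rmsd(A, B, weights=None):
    """Closed-form weighted superposition RMSD via the Horn quaternion method.

    Builds the 4x4 key matrix from the weighted cross-covariance of the
    centred point sets; the largest eigenvalue gives the optimal rotation.
    Completely independent of the SVD-based implementation under test.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    w = np.ones(len(A)) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    a = A - (w[:, None] * A).sum(0) / wsum
    b = B - (w[:, None] * B).sum(0) / wsum
    M = (w[:, None] * a).T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigval = np.linalg.eigvalsh(N)[-1]
    e2 = (w * (np.einsum("ij,ij->i", a, a) + np.einsum("ij,ij->i", b, b))).sum() - 2 * eigval
    return float(np.sqrt(max(e2, 0.0) / wsum))


def grid_refine_min_rmsd(A, B, n_grid=14):
    """Brute-force rotation-space minimiser: coarse rotation-vector grid,
    then local refinement of the best grid points."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    a = A - A.mean(0)
    b = B - B.mean(0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1)))

    lin = np.linspace(-np.pi, np.pi, n_grid)
    candidates = sorted(
        ((rmsd_of(v), v) for v in
         (np.array([x, y, z]) for x in lin for y in lin for z in lin)),
        key=lambda t: t[0],
    )[:5]
    best = np.inf
    for _, v in candidates:
        res = minimize(rmsd_of, v, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


# --- kabsch_fit --------------------------------------------------------------

class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        A = rng.normal(size=(5, 3))
        fit = kabsch_fit(A, A)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.translation, 0.0, atol=1e-12)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_motion(self, rng):
        A = rng.normal(size=(6, 3))
        R, t = random_rotation(rng), rng.normal(size=3) * 10
        fit = kabsch_fit(A, A @ R.T + t)
        assert fit.rmsd < 1e-10
        np.testing.assert_allclose(fit.rotation, R, atol=1e-8)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            k = int(rng.integers(3, 13))
            A = rng.normal(size=(k, 3)) * 5
            B = rng.normal(size=(k, 3)) * 5
            w = rng.uniform(0.1, 1.0, size=k)
            assert kabsch_fit(A, B).rmsd == pytest.approx(
                quaternion_fit_rmsd(A, B), abs=1e-8
            )
            fit = kabsch_fit(A, B, w)
            assert fit.wrmsd == pytest.approx(quaternion_fit_rmsd(A, B, w), abs=1e-8)

    def test_matches_grid_refine_oracle(self):
        rng = np.random.default_rng(42)
        A = rng.normal(size=(6, 3)) * 4
        B = rng.normal(size=(6, 3)) * 4
        assert kabsch_fit(A, B).rmsd == pytest.approx(grid_refine_min_rmsd(A, B), abs=1e-6)

    def test_reflection_corrected(self):
        # mirror image: a proper rotation cannot reach rmsd 0
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        B = A * np.array([1, 1, -1])
        fit = kabsch_fit(A, B)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)
        assert fit.rmsd > 0.1

    def test_degenerate_flag_for_collinear_points(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        fit = kabsch_fit(A, A)
        assert fit.degenerate

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.empty((0, 3)), np.empty((0, 3)))
        A = np.eye(3)
        with pytest.raises(ValueError, match="weight"):
            kabsch_fit(A, A, np.zeros(3))

    def test_weight_bounds(self):
        d = np.array([0.0, 1.0, 3.0])
        w = gaussian_weights(d, sigma=2.0)
        assert w[0] == 1.0
        assert np.all((0 < w) & (w <= 1))


# --- template matching -------------------------------------------------------

class TestMatching:
    def test_self_match_is_exact_identity(self, rng):
        site = random_site(rng, ["HIS", "GLU", "SER"])
        (t,) = [x for x in enumerate_templates(site) if x.size == 3]
        m = match_templates(t, t)
        assert m is not None
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert m.residue_index_pairs == ((0, 0), (1, 1), (2, 2))

    def test_pairing_follows_geometry_not_order(self, rng):
        site = random_site(rng, ["HIS", "GLU"])
        flipped = build_site(
            "flip",
            ["GLU", "HIS"],
            np.array([site.residues[1].coords, site.residues[0].coords]),
        )
        (ta,) = enumerate_templates(site, sizes=(2,))
        (tb,) = enumerate_templates(flipped, sizes=(2,))
        m = match_templates(ta, tb)
        assert m is not None and m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert m.residue_index_pairs == ((0, 1), (1, 0))

    def test_equivalence_classes_allow_asp_glu(self, rng):
        site = random_site(rng, ["ASP", "HIS", "SER"])
        swapped = build_site("sw", ["GLU", "HIS", "THR"], np.array([r.coords for r in site.residues]))
        m = best_site_mapping(site, swapped)
        assert m is not None and m.size == 3 and m.rmsd < 1e-9

    def test_incompatible_classes_never_match(self, rng):
        a = random_site(rng, ["HIS", "CYS", "ASP"])
        b = build_site("b", ["SER", "LYS", "TYR"], np.array([r.coords for r in a.residues]))
        assert best_site_mapping(a, b) is None

    def test_size_mismatch_errors(self, rng):
        site = random_site(rng, ["HIS", "GLU", "SER"])
        t2 = enumerate_templates(site, sizes=(2,))[0]
        t3 = enumerate_templates(site, sizes=(3,))[0]
        with pytest.raises(ValueError, match="sizes differ"):
            match_templates(t2, t3)

    def test_decoy_with_inflated_distances_rejected(self, rng):
        """Scaling every inter-atom distance far beyond the cutoff bounds the
        best achievable rmsd from below, so no match can be accepted."""
        site = random_site(rng, ["HIS", "GLU", "SER"])
        centre = site.coords().mean(0)
        scaled = build_site(
            "big",
            ["HIS", "GLU", "SER"],
            np.array([(r.coords - centre) * 6.0 + centre for r in site.residues]),
        )
        (ta,) = enumerate_templates(site, sizes=(3,))
        (tb,) = enumerate_templates(scaled, sizes=(3,))
        assert match_templates(ta, tb, rmsd_cutoff=3.5) is None

    def test_motif_level_flag_on_size2(self, rng):
        site = random_site(rng, ["HIS", "GLU"])
        m = best_site_mapping(site, site)
        assert m.size == 2 and m.motif_level


class TestBestMapping:
    def test_identical_sites_give_size4(self, rng):
        site = random_site(rng, ["HIS", "GLU", "SER", "CYS"])
        m = best_site_mapping(site, site)
        assert m.size == 4 and m.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_of_rmsd_and_size(self, rng):
        for _ in range(5):
            a = random_site(rng, ["HIS", "GLU", "SER", "CYS", "ASP"])
            b = random_site(rng, ["HIS", "ASP", "THR", "CYS"])
            mab = best_site_mapping(a, b)
            mba = best_site_mapping(b, a)
            if mab is None:
                assert mba is None
            else:
                assert mab.size == mba.size
                assert mab.rmsd == pytest.approx(mba.rmsd, abs=1e-8)

    def test_rigid_motion_invariance(self, rng):
        pair = make_site_pair(SyntheticConfig(seed=5, residues_per_site=(4, 4)))
        m0 = best_site_mapping(pair.site_a, pair.site_b)
        for _ in range(3):
            R, t = random_rotation(rng), rng.uniform(-30, 30, 3)
            moved = transform_site(pair.site_b, R, t)
            m1 = best_site_mapping(pair.site_a, moved)
            assert m1.size == m0.size
            assert m1.rmsd == pytest.approx(m0.rmsd, abs=1e-8)


# --- iterative weighted fitting ---------------------------------------------

class TestIterativeFit:
    def test_identical_sets_converge_immediately(self, rng):
        site = random_site(rng, ["HIS", "GLU", "SER"])
        m = best_site_mapping(site, site)
        res = iterative_weighted_fit(site, site, m)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.wrmsd == pytest.approx(0.0, abs=1e-9)
        assert res.converged and res.iterations == 1

    def test_coverage_uses_larger_site(self):
        pair = make_site_pair(SyntheticConfig(seed=9, residues_per_site=(7, 7), subset_size=3))
        m = best_site_mapping(pair.site_a, pair.site_b)
        res = iterative_weighted_fit(pair.site_a, pair.site_b, m)
        assert res.n_mapped == 3
        assert res.coverage == pytest.approx(3 / 7)

    def test_wrmsd_below_max_residual_and_sigma_limit(self, rng):
        pair = make_site_pair(SyntheticConfig(seed=13, residues_per_site=(5, 5), noise_sigma=0.3))
        m = best_site_mapping(pair.site_a, pair.site_b)
        res = iterative_weighted_fit(pair.site_a, pair.site_b, m, sigma=1.0)
        pa, pb = m.mapped_coords()
        residuals = np.linalg.norm(pa @ res.rotation.T + res.translation - pb, axis=1)
        assert res.wrmsd <= residuals.max() + 1e-12
        # sigma -> infinity: weights flatten, wrmsd -> unweighted rmsd
        flat = iterative_weighted_fit(pair.site_a, pair.site_b, m, sigma=1e6)
        assert flat.wrmsd == pytest.approx(flat.rmsd, rel=1e-9)

    def test_foreign_mapping_rejected(self, rng):
        a = random_site(rng, ["HIS", "GLU"], entry_id="siteA")
        b = random_site(rng, ["HIS", "GLU"], entry_id="siteB")
        m = best_site_mapping(a, a)
        with pytest.raises(ValueError, match="does not belong"):
            iterative_weighted_fit(b, b, m)


class TestDecoys:
    def test_decoy_has_no_3plus_match_but_may_match_at_motif_level(self, rng):
        cfg = SyntheticConfig(seed=21, residues_per_site=(4, 4))
        source = make_site_pair(cfg).site_a
        decoy = make_decoy_site(cfg, source, rng=rng)
        assert best_site_mapping(source, decoy, min_size=3) is None
        m2 = best_site_mapping(source, decoy)  # size-2 spurious hits allowed
        if m2 is not None:
            assert m2.motif_level

    def test_decoy_vs_itself_is_exact(self, rng):
        cfg = SyntheticConfig(seed=22, residues_per_site=(4, 4))
        source = make_site_pair(cfg).site_a
        decoy = make_decoy_site(cfg, source, rng=rng)
        assert best_site_mapping(decoy, decoy).rmsd == pytest.approx(0.0, abs=1e-9)


class TestRules:
    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EquivalenceRules(classes=(frozenset({"ASP"}), frozenset({"ASP", "GLU"})))

    def test_atom_pairings_include_symmetric_swaps(self):
        pairings = DEFAULT_RULES.atom_pairings("ASP", "GLU")
        assert (0, 1, 2) in pairings and (0, 2, 1) in pairings
        assert DEFAULT_RULES.atom_pairings("SER", "THR") == ((0, 1, 2),)

    def test_any_matches_only_any(self):
        assert DEFAULT_RULES.compatible("ANY", "ANY")
        assert not DEFAULT_RULES.compatible("ANY", "GLY")
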