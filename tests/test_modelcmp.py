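import numpy as np
import pytest

from hornspike.modelcmp import (AtomSet, HexamerGroup, hexamer_rmsd, kabsch,
                                load_hexamer_config, pruned_superpose,
                                rotational_self_rmsd)
from hornspike.transforms import RigidTransform


def _atoms(coords, chain="A", start=1):
    coords = np.asarray(coords, float)
    n = len(coords)
    return AtomSet(np.array([chain] * n, dtype=object),
                   np.arange(start, start + n),
                   np.array(["CA"] * n, dtype=object), coords)


def _synthetic_hexamer(rng, perturb=None, radius=30.0, n_res=40):
    """Six chains on a hexagon; chains i and i+2 related by exact 120°."""
    template = rng.normal(scale=4.0, size=(n_res, 3))
    chains, resnums, names, coords = [], [], [], []
    for i in range(6):
        ang = np.radians(60.0 * i)
        Rz = RigidTransform.about_axis([0, 0, 1], np.degrees(ang)).rotation
        c = Rz @ np.array([radius, 0.0, 0.0])
        pts = template @ Rz.T + c
        if perturb is not None and i in perturb:
            pts = pts + perturb[i]
        cid = "ABCDEF"[i]
        chains += [cid] * n_res
        resnums += list(range(1, n_res + 1))
        names += ["CA"] * n_res
        coords.append(pts)
    return AtomSet(np.array(chains, dtype=object), np.array(resnums),
                   np.array(names, dtype=object), np.vstack(coords))


TYPE_III = HexamerGroup("central", tuple("ABCDEF"),
                        ("VP4", "VP7", "VP4", "VP7", "VP4", "VP7"))
TYPE_II = HexamerGroup("2-fold", tuple("ABCDEF"),
                       ("VP4", "VP7", "VP7", "VP4", "VP7", "VP7"))


class TestKabsch:
    def test_identity(self, rng):
        A = _atoms(rng.normal(size=(50, 3)))
        T, rmsd = kabsch(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rigid_motion(self, rng):
        A = _atoms(rng.normal(size=(60, 3)) * 10)
        G = RigidTransform.from_euler(25.0, 70.0, -110.0, (5.0, -3.0, 8.0))
        B = _atoms(G.apply(A.coords))
        T, rmsd = kabsch(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(T.rotation, G.rotation, atol=1e-9)
        assert np.allclose(T.translation, G.translation, atol=1e-9)

    def test_matches_brute_force_minimiser_under_jitter(self, rng):
        # independent numerical oracle: direct minimisation over the
        # rotation vector + translation with scipy.optimize
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        A = rng.normal(size=(500, 3)) * 12
        G = RigidTransform.from_euler(40.0, 30.0, 10.0, (2.0, 1.0, -4.0))
        B = G.apply(A) + rng.normal(scale=0.5, size=A.shape)

        def cost(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return np.sqrt((((A @ R.T + x[3:]) - B) ** 2).sum() / len(A))

        res = min((minimize(cost, x0, method="Nelder-Mead",
                            options=dict(maxiter=4000, fatol=1e-10,
                                         xatol=1e-8))
                   for x0 in (np.r_[Rotation.from_matrix(G.rotation)
                                    .as_rotvec(), G.translation],
                              np.zeros(6))),
                  key=lambda r: r.fun)
        _, rmsd = kabsch(A, B)
        assert rmsd <= res.fun + 1e-9
        assert rmsd == pytest.approx(res.fun, rel=0.05)

    def test_reflection_degenerate_input_stays_proper(self):
        A = _atoms([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        B = _atoms([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, -1]])
        T, _ = kabsch(A, B)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_atoms_raises(self):
        with pytest.raises(ValueError):
            kabsch(_atoms([[0, 0, 0], [1, 1, 1]]), _atoms([[0, 0, 0],
                                                           [1, 1, 1]]))

    def test_rigid_motion_invariance(self, rng):
        A = _atoms(rng.normal(size=(80, 3)) * 9)
        B = _atoms(A.coords + rng.normal(scale=1.0, size=(80, 3)))
        _, r0 = kabsch(A, B)
        G = RigidTransform.from_euler(12.0, 85.0, -40.0, (20.0, 5.0, -7.0))
        _, r1 = kabsch(_atoms(G.apply(A.coords)), B)
        _, r2 = kabsch(A, _atoms(G.apply(B.coords)))
        assert r1 == pytest.approx(r0, abs=1e-6)
        assert r2 == pytest.approx(r0, abs=1e-6)


class TestHexamerRmsd:
    def test_hexamer_against_itself(self, rng):
        model = _synthetic_hexamer(rng)
        rmsd, pairs = hexamer_rmsd(model, TYPE_III, TYPE_III)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        model = _synthetic_hexamer(rng, perturb={2: np.array([1.0, 0.5, 0.0])})
        g2 = HexamerGroup("other", tuple("ABCDEF"), TYPE_III.types)
        a, _ = hexamer_rmsd(model, TYPE_III, g2)
        b, _ = hexamer_rmsd(model, g2, TYPE_III)
        assert a == pytest.approx(b, abs=1e-6)

    def test_no_type_respecting_correspondence_raises(self, rng):
        model = _synthetic_hexamer(rng)
        with pytest.raises(ValueError):
            hexamer_rmsd(model, TYPE_III, TYPE_II)

    def test_class_labels(self):
        assert TYPE_II.class_label == "II"
        assert TYPE_III.class_label == "III"


class TestRotationalSelfRmsd:
    def test_perfect_threefold_hexamer(self, rng):
        model = _synthetic_hexamer(rng)  # exact 3-fold by construction
        r120, r240 = rotational_self_rmsd(model, TYPE_III)
        assert r120 == pytest.approx(0.0, abs=1e-9)
        assert r240 == pytest.approx(0.0, abs=1e-9)

    def test_displaced_subunit_breaks_symmetry(self, rng):
        model = _synthetic_hexamer(rng, perturb={0: np.array([2.0, 0, 0])})
        r120, r240 = rotational_self_rmsd(model, TYPE_III)
        assert r120 > 0.1 and r240 > 0.1
        assert r120 == pytest.approx(r240, rel=0.3)

    def test_type_ii_raises(self, rng):
        model = _synthetic_hexamer(rng)
        with pytest.raises(ValueError):
            rotational_self_rmsd(model, TYPE_II)


class TestPrunedSuperpose:
    def test_identical_structures(self, rng):
        A = _atoms(rng.normal(size=(100, 3)) * 10)
        frac, rmsd, _ = pruned_superpose(A, A, correspondence=(range(100),
                                                               range(100)))
        assert frac == pytest.approx(1.0)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_outliers_are_pruned(self, rng):
        core = rng.normal(size=(200, 3)) * 15
        jitter = rng.normal(scale=0.3, size=(200, 3))
        B = core + jitter
        out = rng.choice(200, 40, replace=False)
        B[out] += 20.0 * rng.normal(size=(40, 3))
        frac, rmsd, _ = pruned_superpose(_atoms(core), _atoms(B),
                                         distance_cutoff=5.0,
                                         correspondence=(range(200),
                                                         range(200)))
        assert frac == pytest.approx(0.8, abs=0.05)
        assert rmsd < 0.8

    def test_fixed_point_termination(self, rng):
        core = rng.normal(size=(120, 3)) * 12
        B = core + rng.normal(scale=0.4, size=core.shape)
        frac1, rmsd1, T1 = pruned_superpose(_atoms(core), _atoms(B),
                                            correspondence=(range(120),
                                                            range(120)))
        # applying the procedure to the already-superposed set changes nothing
        A2 = _atoms(T1.apply(core))
        frac2, rmsd2, _ = pruned_superpose(A2, _atoms(B),
                                           correspondence=(range(120),
                                                           range(120)))
        assert frac2 == pytest.approx(frac1, abs=1e-9)
        assert rmsd2 == pytest.approx(rmsd1, abs=1e-9)

    def test_seeded_without_correspondence(self, rng):
        A = rng.normal(size=(150, 3)) * np.array([18, 9, 5])
        G = RigidTransform.from_euler(15.0, 30.0, -5.0, (3.0, 1.0, 2.0))
        B = G.apply(A) + rng.normal(scale=0.3, size=A.shape)
        frac, rmsd, _ = pruned_superpose(_atoms(A), _atoms(B),
                                         distance_cutoff=3.8)
        assert frac > 0.8
        assert rmsd < 1.0


class TestIO:
    def test_hexamer_config_yaml(self, tmp_path):
        cfg = tmp_path / "hex.yaml"
        cfg.write_text(
            "central:\n  chains: [A, B, C, D, E, F]\n"
            "  types: [VP4, VP7, VP4, VP7, VP4, VP7]\n")
        groups = load_hexamer_config(cfg)
        assert groups["central"].class_label == "III"

    def test_atomset_from_pdb(self, tmp_path, rng):
        lines = []
        coords = rng.normal(size=(5, 3)) * 10
        for i, c in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00 20.00           C")
        lines.append("END")
        path = tmp_path / "m.pdb"
        path.write_text("\n".join(lines) + "\n")
        atoms = AtomSet.from_file(path).select(atom_name="CA")
        assert len(atoms) == 5
        assert np.allclose(atoms.coords, np.round(coords, 3), atol=1e-3)
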