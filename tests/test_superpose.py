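import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from btherm import (TemperatureSeries, align_series, displacement_profile,
                    global_displacement, kabsch_fit)
from conftest import quaternion_rmsd, random_proper_rotation


class TestKabsch:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        tf = kabsch_fit(X, X)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0, atol=1e-12)
        assert tf.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        R = random_proper_rotation(rng)
        t = rng.normal(size=3) * 10
        Y = X @ R.T + t
        tf = kabsch_fit(X, Y)
        assert tf.rmsd < 1e-10
        assert np.allclose(tf.rotation, R, atol=1e-8)
        assert np.allclose(tf.translation, t, atol=1e-8)
        assert np.allclose(tf.apply(X), Y, atol=1e-8)

    def test_beats_brute_force_rotation_sampling(self):
        """Fitted RMSD never exceeds the best of thousands of random
        rotations with the translation optimized in closed form."""
        rng = np.random.default_rng(2)
        from scipy.spatial.transform import Rotation
        Rs = Rotation.random(2000, rng=rng).as_matrix()
        for _ in range(20):
            X = rng.normal(size=(5, 3)) * 3
            Y = rng.normal(size=(5, 3)) * 3
            fitted = kabsch_fit(X, Y).rmsd
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            rot = np.einsum("mij,nj->mni", Rs, Xc)
            brute = np.sqrt(((rot - Yc) ** 2).sum(axis=(1, 2)).min() / len(X))
            assert fitted <= brute + 1e-12

    def test_matches_quaternion_formulation(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(4, 30)
            X = rng.normal(size=(n, 3)) * 5
            Y = rng.normal(size=(n, 3)) * 5
            assert kabsch_fit(X, Y).rmsd == pytest.approx(
                quaternion_rmsd(X, Y), abs=1e-8)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_reflection_never_returned(self):
        # mirror-image point sets tempt the SVD into a reflection
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        Y = X.copy()
        Y[:, 0] = -Y[:, 0]
        tf = kabsch_fit(X, Y)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rmsd_invariant_under_prior_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 3))
        R = random_proper_rotation(rng)
        t = rng.normal(size=3)
        assert kabsch_fit(X @ R.T + t, Y).rmsd == pytest.approx(
            kabsch_fit(X, Y).rmsd, abs=1e-8)


class TestAlignSeries:
    def test_identical_copies_align_with_identity(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        ref = series.reference
        sub = TemperatureSeries(models=[ref, ref, ref], reference_id=ref.structure_id)
        for model, tf in align_series(sub):
            assert tf.rmsd == pytest.approx(0.0, abs=1e-9)
            assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_recovered_rmsd_reflects_noise_not_transform(self, base40):
        """Replicate frames are rigid: after alignment the residual RMSD is
        the coordinate-noise scale, far below the transform magnitude."""
        from btherm import TruthConfig, generate_ensemble
        cfg = TruthConfig(coord_noise_sd=0.02, b_noise_frac=0.0,
                          retention_p_start=1.0, retention_p_end=1.0,
                          transform_max_angle_deg=15.0, transform_max_shift=4.0)
        series, truth = generate_ensemble(base40, cfg, temperatures=(100, 150, 200),
                                          n_replicates=3, seed=5)
        aligned = align_series(series)
        # 100 K structures differ from the reference only by noise + frame
        for model, tf in aligned:
            if model.temperature_K == 100.0 and model.structure_id != series.reference_id:
                assert tf.rmsd < 6 * 0.02 * np.sqrt(2)
        # while the generating transforms moved atoms by several Angstrom
        R, t = truth.transform_of(2)
        assert np.linalg.norm(t) > 0.5 or abs(np.trace(R) - 3) > 1e-3

    def test_single_structure_series(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        ref = series.reference
        sub = TemperatureSeries(models=[ref], reference_id=ref.structure_id)
        out = align_series(sub)
        assert len(out) == 1 and out[0][1].n_fit_atoms == 0


class TestDisplacementProfile:
    def test_reference_against_itself_is_zero(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        ref = series.reference
        prof = displacement_profile(ref, ref)
        assert (prof["d_calpha"].dropna() == 0).all()
        assert (prof["d_side_chain"].dropna() == 0).all()

    def test_glycine_has_no_side_chain_displacement(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        prof = displacement_profile(series.models[5], series.reference)
        gly = prof[prof["resname"] == "GLY"]
        assert len(gly) > 0 and gly["d_side_chain"].isna().all()

    def test_translated_side_chain_measures_one_angstrom(self, noiseless_ensemble):
        series, _ = noiseless_ensemble
        ref = series.reference
        moved = ref.with_coords(ref.coords().copy())
        atoms = moved.atoms
        target = (atoms["resseq"] == 5) & (atoms["atom_class"] == "side_chain")
        atoms.loc[target, "x"] += 1.0
        prof = displacement_profile(moved, ref)
        r5 = prof[prof["resseq"] == 5]
        assert r5["d_side_chain"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        others = prof[prof["resseq"] != 5]
        assert others["d_side_chain"].dropna().max() == pytest.approx(0.0, abs=1e-9)

    def test_recovers_linear_displacement_field(self, noiseless_ensemble):
        """Noiseless generator truth: residue i moves delta_i*(T-100).

        The global rigid refit absorbs the net (mean) component of the
        displacement field, so per-residue distances deviate from the
        planted field by up to roughly |mean displacement vector|; the
        profile must still track the field closely."""
        series, truth = noiseless_ensemble
        aligned = dict((m.structure_id, m) for m, _ in align_series(series))
        model = aligned["S300R1"]
        prof = displacement_profile(model, series.reference)
        merged = prof.merge(truth.residues, on="resseq")
        expected = (merged["delta"] * 200.0).to_numpy()
        got = merged["d_calpha"].to_numpy()
        field = (merged[["ux", "uy", "uz"]].to_numpy()
                 * expected[:, None])
        leakage = np.linalg.norm(field.mean(axis=0))
        assert np.abs(got - expected).max() <= 3 * leakage + 6e-3
        assert np.corrcoef(got, expected)[0, 1] > 0.9


class TestGlobalDisplacement:
    def test_uniform_profile_mean(self, noiseless_ensemble):
        import pandas as pd
        prof = pd.DataFrame({"chain": "A", "resseq": [1, 2], "icode": "",
                             "d_calpha": [0.0, 1.0], "d_side_chain": [0.5, 0.5]})
        ca, sc = global_displacement(prof, (1, 2))
        assert ca == pytest.approx(0.5)
        assert sc == pytest.approx(0.5)

    def test_single_residue_range(self):
        import pandas as pd
        prof = pd.DataFrame({"chain": "A", "resseq": [1, 2], "icode": "",
                             "d_calpha": [0.25, 1.0], "d_side_chain": [np.nan, 0.5]})
        ca, _sc = global_displacement(prof, (1, 1))
        assert ca == pytest.approx(0.25)

    def test_empty_range_rejected(self):
        import pandas as pd
        prof = pd.DataFrame({"chain": "A", "resseq": [1], "icode": "",
                             "d_calpha": [0.1], "d_side_chain": [0.1]})
        with pytest.raises(ValueError):
            global_displacement(prof, (50, 60))
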