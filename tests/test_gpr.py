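"""GP training and prediction: interpolation, recovery, consistency of
forces/charges/dipoles with energy derivatives, delta learning, CV, metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpmlmm.descriptors import esp_descriptor
from gpmlmm.geometry import Geometry, MMEnvironment
from gpmlmm.gpr import (
    HierarchicalModel,
    LabelledSample,
    ValidationError,
    grid_search_cv,
    predict_charges,
    predict_dipole,
    predict_environment,
    predict_vacuum,
    score,
    train_delta,
    train_environment,
    train_vacuum,
)
from gpmlmm.oracle import build_dataset, default_toy_params, toy_reference
from gpmlmm.units import BOHR_PER_ANGSTROM, KCALMOL_PER_HARTREE

TOY = default_toy_params()


class TestVacuumModel:
    def test_single_sample_interpolation_limit(self, vacuum_dataset):
        s = vacuum_dataset[0]
        m = train_vacuum([s], lengthscale=1.0, sigma_f=1e-10)
        _, f = predict_vacuum(m, s.geom)
        scale = np.abs(s.vacuum_forces).max()
        assert np.abs(f - s.vacuum_forces).max() / scale < 1e-6

    def test_heldout_force_recovery(self, vacuum_dataset):
        m = train_vacuum(vacuum_dataset[:60], lengthscale=1.0, sigma_f=1e-4)
        test = vacuum_dataset[60:]
        pred = np.stack([predict_vacuum(m, s.geom)[1] for s in test])
        ref = np.stack([s.vacuum_forces for s in test])
        assert score(pred, ref, "forces").rmse < 0.1 * ref.std()

    def test_energy_differences_independent_of_offset(self, vacuum_model, vacuum_dataset):
        a, b = vacuum_dataset[60], vacuum_dataset[61]
        de_pred = (
            predict_vacuum(vacuum_model, a.geom)[0]
            - predict_vacuum(vacuum_model, b.geom)[0]
        )
        de_ref = a.vacuum_energy - b.vacuum_energy
        assert de_pred == pytest.approx(de_ref, abs=0.15)

    def test_forces_are_negative_energy_gradient(self, vacuum_model, vacuum_dataset):
        h = 1e-4
        geom = vacuum_dataset[65].geom
        _, forces = predict_vacuum(vacuum_model, geom)
        for g in range(6):  # a subset of coordinates is enough at FD cost
            d = np.zeros((geom.n_atoms, 3))
            d.reshape(-1)[g] = h
            ep = predict_vacuum(vacuum_model, geom.with_coords(geom.coords + d))[0]
            em = predict_vacuum(vacuum_model, geom.with_coords(geom.coords - d))[0]
            assert -(ep - em) / (2 * h) == pytest.approx(
                forces.reshape(-1)[g], rel=1e-5, abs=1e-8
            )

    def test_rotation_covariance(self, vacuum_model, vacuum_dataset):
        geom = vacuum_dataset[70].geom
        e0, f0 = predict_vacuum(vacuum_model, geom)
        rot = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        e1, f1 = predict_vacuum(vacuum_model, geom.with_coords(geom.coords @ rot.T))
        assert e1 == pytest.approx(e0, abs=1e-8)
        np.testing.assert_allclose(f1, f0 @ rot.T, atol=1e-8)

    def test_permutation_invariance_of_symmetrized_model(self, vacuum_dataset):
        m = train_vacuum(
            vacuum_dataset[:30], lengthscale=1.0, sigma_f=1e-4,
            permutations=((0, 1, 2, 3), (0, 1, 3, 2)),
        )
        geom = vacuum_dataset[40].geom
        e0, _ = predict_vacuum(m, geom)
        e1, _ = predict_vacuum(m, geom.permuted(np.array([0, 1, 3, 2])))
        assert e1 == pytest.approx(e0, abs=1e-10)

    def test_joint_energy_force_training(self, vacuum_dataset):
        m = train_vacuum(
            vacuum_dataset[:40], lengthscale=1.0, sigma_f=1e-4,
            include_energies=True,
        )
        test = vacuum_dataset[60:]
        pe = np.array([predict_vacuum(m, s.geom)[0] for s in test])
        re = np.array([s.vacuum_energy for s in test])
        assert score(pe, re, "energy").rmse < 0.1 * re.std()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            train_vacuum([], 1.0, 1e-4)


class TestEnvironmentModel:
    def test_charge_sum_constraint_on_heldout(self, environment_model, solvated_dataset):
        for s in solvated_dataset[40:]:
            q = predict_charges(environment_model, s.geom, s.env)
            assert abs(q.sum() - s.total_charge) < 1e-3

    def test_interpolation_limit(self, solvated_dataset):
        sub = solvated_dataset[:6]
        m = train_environment(
            sub, lengthscale=1.0, sigma_e=1e-10, sigma_q=1e-10
        )
        for s in sub:
            e, f, _ = predict_environment(m, s.geom, s.env)
            e_ref = s.energy - s.vacuum_energy
            f_ref = s.forces_qm - s.vacuum_forces
            assert e == pytest.approx(e_ref, rel=1e-5, abs=1e-7)
            assert np.abs(f - f_ref).max() / max(np.abs(f_ref).max(), 1e-9) < 1e-5

    def test_vacuum_limit_is_exactly_zero(self, environment_model, solvated_dataset):
        geom = solvated_dataset[50].geom
        e, fq, fm = predict_environment(
            environment_model, geom, MMEnvironment.empty()
        )
        assert e == 0.0
        assert np.all(fq == 0.0)
        q = predict_charges(environment_model, geom, MMEnvironment.empty())
        assert np.abs(q).max() > 1e-3  # gas-phase charges stay finite

    def test_forces_match_energy_gradient(self, environment_model, solvated_dataset):
        h = 1e-4
        s = solvated_dataset[45]
        _, fq, fm = predict_environment(environment_model, s.geom, s.env)
        for g in range(6):
            d = np.zeros((s.geom.n_atoms, 3))
            d.reshape(-1)[g] = h
            ep = predict_environment(
                environment_model, s.geom.with_coords(s.geom.coords + d), s.env
            )[0]
            em = predict_environment(
                environment_model, s.geom.with_coords(s.geom.coords - d), s.env
            )[0]
            assert -(ep - em) / (2 * h) == pytest.approx(
                fq.reshape(-1)[g], rel=1e-5, abs=1e-7
            )
        for g in range(6):
            d = np.zeros((s.env.n_sites, 3))
            d.reshape(-1)[g] = h
            ep = predict_environment(
                environment_model, s.geom, MMEnvironment(s.env.coords + d, s.env.charges)
            )[0]
            em = predict_environment(
                environment_model, s.geom, MMEnvironment(s.env.coords - d, s.env.charges)
            )[0]
            assert -(ep - em) / (2 * h) == pytest.approx(
                fm.reshape(-1)[g], rel=1e-5, abs=1e-7
            )

    def test_joint_translation_leaves_energy_unchanged(
        self, environment_model, solvated_dataset
    ):
        s = solvated_dataset[42]
        t = np.array([2.0, -1.0, 3.0])
        e0 = predict_environment(environment_model, s.geom, s.env)[0]
        e1 = predict_environment(
            environment_model,
            s.geom.with_coords(s.geom.coords + t),
            MMEnvironment(s.env.coords + t, s.env.charges),
        )[0]
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_negated_charges_keep_force_energy_consistency(
        self, environment_model, solvated_dataset
    ):
        s = solvated_dataset[47]
        env = MMEnvironment(s.env.coords, -s.env.charges)
        e, fq, fm = predict_environment(environment_model, s.geom, env)
        h = 1e-4
        d = np.zeros((env.n_sites, 3))
        d[0, 0] = h
        ep = predict_environment(
            environment_model, s.geom, MMEnvironment(env.coords + d, env.charges)
        )[0]
        em = predict_environment(
            environment_model, s.geom, MMEnvironment(env.coords - d, env.charges)
        )[0]
        assert -(ep - em) / (2 * h) == pytest.approx(fm[0, 0], rel=1e-5, abs=1e-7)

    def test_missing_vacuum_labels_reported(self, solvated_dataset):
        s = solvated_dataset[0]
        bad = LabelledSample(
            geom=s.geom, env=s.env, energy=s.energy, forces_qm=s.forces_qm,
            total_charge=s.total_charge,
        )
        with pytest.raises(ValidationError, match=r"\[0\]"):
            train_environment([bad], 1.0)


class TestChargesAndDipoles:
    def test_charges_match_potential_derivative(
        self, environment_model, solvated_dataset
    ):
        """q_a equals the finite-difference derivative of the predicted
        energy under a per-site potential perturbation of 1e-4 a.u."""
        s = solvated_dataset[55]
        q = predict_charges(environment_model, s.geom, s.env)
        h = 1e-4
        feats = environment_model.features
        from gpmlmm.kernels import env_pair_blocks, featurize

        # evaluate the predicted energy on explicitly shifted potentials
        def energy_with_shift(dv):
            f = featurize(s.geom, s.env, np.arange(s.geom.n_atoms))
            d2 = {
                "chi": f.chi[None], "jchi": f.jchi[None],
                "v": (f.v + dv)[None], "jv": f.jv_qm[None],
            }
            b = env_pair_blocks(
                feats.as_dict(), d2,
                environment_model.spec.lengthscale,
                environment_model.spec.theta,
                grad1=True,
            )
            ae = np.repeat(environment_model.alpha_e, feats.s)
            af = np.repeat(
                environment_model.alpha_f.reshape(feats.n, -1), feats.s, axis=0
            )
            aq = np.repeat(environment_model.alpha_q, feats.s)
            w = 1.0 / feats.s
            return float(
                (np.einsum("x,xy->", ae, b["k"])
                 + np.einsum("xg,xyg->", af, b["g1"])
                 + np.einsum("x,xy->", aq, b["sq1"])) * w
            )

        for a in range(s.geom.n_atoms):
            dv = np.zeros(s.geom.n_atoms)
            dv[a] = h
            fd = (energy_with_shift(dv) - energy_with_shift(-dv)) / (2 * h)
            fd /= KCALMOL_PER_HARTREE
            assert fd == pytest.approx(q[a], rel=1e-4, abs=1e-8)

    def test_uniform_field_realizes_dipole(self, environment_model, solvated_dataset):
        """Perturbing V_a by -E.r_a for a uniform field E changes the
        energy by -mu.E to second order."""
        s = solvated_dataset[57]
        mu = predict_dipole(environment_model, s.geom, s.env)
        field = np.array([1e-4, -0.7e-4, 0.4e-4])  # a.u.
        r_bohr = s.geom.coords * BOHR_PER_ANGSTROM
        dv = -(r_bohr @ field)

        from gpmlmm.kernels import env_pair_blocks, featurize

        feats = environment_model.features

        def energy_with_shift(shift):
            f = featurize(s.geom, s.env, np.arange(s.geom.n_atoms))
            d2 = {
                "chi": f.chi[None], "jchi": f.jchi[None],
                "v": (f.v + shift)[None], "jv": f.jv_qm[None],
            }
            b = env_pair_blocks(
                feats.as_dict(), d2,
                environment_model.spec.lengthscale,
                environment_model.spec.theta, grad1=True,
            )
            ae = np.repeat(environment_model.alpha_e, feats.s)
            af = np.repeat(
                environment_model.alpha_f.reshape(feats.n, -1), feats.s, axis=0
            )
            aq = np.repeat(environment_model.alpha_q, feats.s)
            return float(
                (np.einsum("x,xy->", ae, b["k"])
                 + np.einsum("xg,xyg->", af, b["g1"])
                 + np.einsum("x,xy->", aq, b["sq1"])) / feats.s
            )

        de = (energy_with_shift(dv) - energy_with_shift(-dv)) / 2.0
        de_au = de / KCALMOL_PER_HARTREE
        assert de_au == pytest.approx(-float(mu @ field), rel=1e-3)

    def test_direct_dipole_arithmetic(self):
        q = np.array([0.5, -0.5])
        r_bohr = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert float((q @ r_bohr)[0]) == pytest.approx(1.0)

    def test_neutral_molecule_dipole_translation_stability(
        self, environment_model, solvated_dataset
    ):
        s = solvated_dataset[58]
        mu0 = predict_dipole(environment_model, s.geom, s.env)
        t = np.array([10.0, 0.0, 0.0])
        mu1 = predict_dipole(
            environment_model,
            s.geom.with_coords(s.geom.coords + t),
            MMEnvironment(s.env.coords + t, s.env.charges),
        )
        assert np.abs(mu1 - mu0).max() < 1e-2

    def test_distant_weak_charge_barely_perturbs_charges(
        self, environment_model, solvated_dataset
    ):
        geom = solvated_dataset[59].geom
        q0 = predict_charges(environment_model, geom, MMEnvironment.empty())
        far = MMEnvironment([[60.0, 55.0, 58.0]], [0.05])
        q1 = predict_charges(environment_model, geom, far)
        assert np.abs(q1 - q0).max() < 1e-4

    def test_heldout_dipole_recovery(self, environment_model, solvated_dataset):
        test = solvated_dataset[40:]
        pred = np.stack(
            [predict_dipole(environment_model, s.geom, s.env) for s in test]
        )
        ref = np.stack([s.dipole for s in test])
        fluct = ref.std()
        assert score(pred, ref, "dipole").rmse < 0.1 * fluct


class TestDeltaLearning:
    def test_zero_residual_gives_null_correction(self, vacuum_model, vacuum_dataset):
        base = HierarchicalModel(vacuum=vacuum_model)
        delta = train_delta(base, vacuum_dataset[:20], kind="vacuum", sigma_f=1e-8)
        for s in vacuum_dataset[60:65]:
            de, df = predict_vacuum(delta, s.geom)
            # residual targets are ~0 up to the base model's own test error
            assert abs(de - delta.energy_offset) < 1e-4
            assert np.abs(df).max() < 0.2  # small vs ~12 kcal/mol/A force std

    def test_composed_model_beats_base_against_scaled_oracle(self, toy_params):
        high = toy_params.scaled(1.1)
        base_data = build_dataset(toy_params, None, 90, rng=21)
        high_data = build_dataset(high, None, 30, rng=22)
        high_test = build_dataset(high, None, 25, rng=23)
        vac = train_vacuum(base_data[:90], 1.0, 1e-4)
        base = HierarchicalModel(vacuum=vac)
        delta = train_delta(base, high_data, kind="vacuum")
        ref = np.stack([s.vacuum_forces for s in high_test])
        pred_base = np.stack([predict_vacuum(vac, s.geom)[1] for s in high_test])
        pred_comp = np.stack(
            [
                predict_vacuum(vac, s.geom)[1] + predict_vacuum(delta, s.geom)[1]
                for s in high_test
            ]
        )
        rmse_base = score(pred_base, ref, "forces").rmse
        rmse_comp = score(pred_comp, ref, "forces").rmse
        assert rmse_comp < rmse_base

    def test_composition_is_strict_addition(self, vacuum_model, vacuum_dataset):
        base = HierarchicalModel(vacuum=vacuum_model)
        delta = train_delta(base, vacuum_dataset[:15], kind="vacuum")
        hier = HierarchicalModel(vacuum=vacuum_model, delta_vacuum=delta)
        geom = vacuum_dataset[70].geom
        e_sum = predict_vacuum(vacuum_model, geom)[0] + predict_vacuum(delta, geom)[0]
        assert hier.predict(geom)["energy"] == e_sum

    def test_environment_delta_reduces_env_error(self, toy_params, envgen_config, solvated_dataset):
        high = toy_params.scaled(1.0, charge_shift=0.05)
        high_data = build_dataset(high, envgen_config, 30, rng=31)
        env_base = train_environment(solvated_dataset[:40], 1.0, sigma_e=1e-3)
        base = HierarchicalModel(
            vacuum=train_vacuum(solvated_dataset[:20], 1.0, 1e-4),
            environment=env_base,
        )
        delta = train_delta(base, high_data[:20], kind="environment")
        test = high_data[20:]
        ref = np.stack([s.dipole for s in test])
        pred_base = np.stack(
            [predict_dipole(env_base, s.geom, s.env) for s in test]
        )
        pred_comp = pred_base + np.stack(
            [predict_dipole(delta, s.geom, s.env) for s in test]
        )
        assert (
            score(pred_comp, ref, "dipole").rmse
            < score(pred_base, ref, "dipole").rmse
        )


class TestModelSelection:
    def test_cv_table_shape_and_determinism(self, vacuum_dataset):
        sub = vacuum_dataset[:24]
        lam_grid, sig_grid = (0.5, 1.0), (1e-4, 1e-3)
        _, _, t1 = grid_search_cv(sub, lam_grid, sig_grid, k_folds=4, seed=5)
        _, _, t2 = grid_search_cv(sub, lam_grid, sig_grid, k_folds=4, seed=5)
        assert len(t1) == len(lam_grid) * len(sig_grid)
        assert np.isfinite(t1["mean_force_rmse"]).all()
        assert (t1["seed"] == 5).all()
        pd_equal = t1.equals(t2)
        assert pd_equal

    def test_noise_free_labels_prefer_small_sigma(self, vacuum_dataset):
        sub = vacuum_dataset[:32]
        sig_grid = (1e-5, 1e-2, 10.0)
        _, best_sigma, _ = grid_search_cv(sub, (1.0,), sig_grid, k_folds=4, seed=1)
        assert best_sigma != max(sig_grid)

    def test_too_few_samples_rejected(self, vacuum_dataset):
        with pytest.raises(ValidationError):
            grid_search_cv(vacuum_dataset[:3], (1.0,), (1e-4,), k_folds=4)


class TestScores:
    def test_perfect_prediction(self):
        x = np.arange(12.0).reshape(4, 3)
        s = score(x, x, "dipole")
        assert s.rmse == 0.0 and s.mae == 0.0

    def test_single_scalar_pair(self):
        s = score([3.0], [1.0], "energy")
        assert s.rmse == pytest.approx(2.0)
        assert s.mae == pytest.approx(2.0)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            a = rng.normal(size=(7, 4, 3))
            b = rng.normal(size=(7, 4, 3))
            s = score(a, b, "forces")
            assert s.rmse >= s.mae - 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            score(np.zeros(3), np.zeros(4), "energy")
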