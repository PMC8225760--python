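import numpy as np
import pytest
from scipy import stats

from classf import synthetic_data as syn
from classf.conformation import three_point_angle
from classf.structure_io import StructureError

#: Three-point N angle of the default ideal helix at (i, i+4, i+8), frozen
#: from direct evaluation of the helix geometry (screw symmetry makes it
#: independent of i).
IDEAL_HELIX_N_ANGLE = 173.38990637834124


def _n_pos(frame, residue):
    mask = (frame.residue_indices == residue) & (frame.names == "N")
    return frame.coords[np.flatnonzero(mask)[0]]


class TestIdealHelix:
    def test_ca_rise_is_exact(self):
        frame = syn.build_ideal_helix(syn.HelixSpec(n_res=12))
        ca_z = frame.coords[(frame.names == "CA")][:, 2]
        np.testing.assert_allclose(np.diff(ca_z), 1.5, atol=1e-12)

    def test_successive_ca_distances_equal(self, ideal_helix):
        ca = ideal_helix.coords[ideal_helix.names == "CA"]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(d, d[0], atol=1e-12)

    def test_screw_symmetric_n_angle_matches_frozen_constant(self, ideal_helix, helix_spec):
        for i in range(helix_spec.residue_start, helix_spec.residue_start + helix_spec.n_res - 8):
            ang = three_point_angle(
                _n_pos(ideal_helix, i), _n_pos(ideal_helix, i + 4), _n_pos(ideal_helix, i + 8)
            )
            assert ang == pytest.approx(IDEAL_HELIX_N_ANGLE, abs=1e-9)

    def test_too_short_helix_rejected(self):
        with pytest.raises(ValueError):
            syn.HelixSpec(n_res=8)


class TestApplyKink:
    def test_unkinked_target_is_a_fixed_point(self, ideal_helix, vertex_residue):
        bent = syn.apply_kink(ideal_helix, vertex_residue, IDEAL_HELIX_N_ANGLE)
        assert np.abs(bent.coords - ideal_helix.coords).max() < 1e-3

    @pytest.mark.parametrize("target", [158.5, 168.4, 175.0, 150.0])
    def test_round_trip_through_angle_measurement(self, ideal_helix, vertex_residue, target):
        bent = syn.apply_kink(ideal_helix, vertex_residue, target)
        measured = three_point_angle(
            _n_pos(bent, vertex_residue - 4),
            _n_pos(bent, vertex_residue),
            _n_pos(bent, vertex_residue + 4),
        )
        assert measured == pytest.approx(target, abs=0.01)

    def test_upstream_coordinates_untouched_exactly(self, ideal_helix, vertex_residue):
        bent = syn.apply_kink(ideal_helix, vertex_residue, 158.5)
        upstream = ideal_helix.residue_indices <= vertex_residue
        assert np.array_equal(bent.coords[upstream], ideal_helix.coords[upstream])

    def test_target_outside_domain_rejected(self, ideal_helix, vertex_residue):
        with pytest.raises(syn.KinkError):
            syn.apply_kink(ideal_helix, vertex_residue, 30.0)

    def test_vertex_near_terminus_rejected(self, ideal_helix, helix_spec):
        with pytest.raises(syn.KinkError):
            syn.apply_kink(ideal_helix, helix_spec.residue_start + 1, 158.5)


class TestEnsembleGeneration:
    def test_zero_sd_gives_constant_angle(self, helix_spec, helix_map):
        trajs = syn.generate_trajectory(
            helix_spec,
            syn.KinkSpec(158.5, 0.0),
            syn.EnsembleSpec(replica_lengths_ns=(1.0,), seed=0),
        )
        from classf.conformation import tm6_kink_series

        series = tm6_kink_series(trajs[0], helix_map)
        np.testing.assert_allclose(series.angles_deg, 158.5, atol=0.01)

    def test_same_seed_bitwise_identical(self):
        ens = syn.EnsembleSpec(replica_lengths_ns=(2.0, 1.0), seed=42)
        kink = syn.kink_preset("smo")
        a = syn.ar1_angle_series(kink, ens)
        b = syn.ar1_angle_series(kink, ens)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_iid_sample_mean_within_clt_bound(self):
        """phi = 0, n = 12,504 frames at the FZD6 law: the sample mean must
        fall within 4 sigma / sqrt(n) of the preset mean."""
        ens = syn.EnsembleSpec(seed=5)
        angles = np.concatenate(syn.ar1_angle_series(syn.kink_preset("fzd6"), ens))
        n = len(angles)
        assert abs(angles.mean() - 158.5) < 4 * 4.5 / np.sqrt(n)

    def test_iid_marginal_is_normal_by_ks(self):
        """For phi = 0 the per-frame angles are iid Normal(mu, sigma^2):
        KS at n = 5,000 must not reject at alpha = 0.01 for >= 95% of
        100 seeds."""
        ens_lengths = (499.9,)  # 5,000 frames
        passed = 0
        for seed in range(100):
            a = syn.ar1_angle_series(
                syn.kink_preset("smo"),
                syn.EnsembleSpec(replica_lengths_ns=ens_lengths, seed=seed),
            )[0]
            _, p = stats.kstest(a, "norm", args=(168.4, 4.2))
            passed += p > 0.01
        assert passed >= 95

    def test_ar1_autocorrelation_sign(self):
        """A positive AR(1) coefficient must induce positive lag-1
        autocorrelation while keeping the marginal mean."""
        ens = syn.EnsembleSpec(replica_lengths_ns=(500.0,), seed=9)
        a = syn.ar1_angle_series(syn.kink_preset("fzd6", ar1_phi=0.8), ens)[0]
        r1 = np.corrcoef(a[:-1], a[1:])[0, 1]
        assert r1 > 0.7
        assert abs(a.mean() - 158.5) < 0.5

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            syn.KinkSpec(158.5, 4.5, ar1_phi=1.0)


class TestSubsampling:
    def test_printed_pose_count_for_default_ensemble(self):
        """[500, 250, 250, 250] ns at one frame / 10 ns with replica 1
        start-inclusive yields 126 poses."""
        trajs = syn.generate_trajectory(
            syn.HelixSpec(n_res=9), syn.KinkSpec(158.5, 0.0), syn.EnsembleSpec(seed=0)
        )
        _, count = syn.subsample_frames(trajs, 10.0)
        assert count == 126

    def test_single_replica_start_inclusive(self):
        trajs = syn.generate_trajectory(
            syn.HelixSpec(n_res=9),
            syn.KinkSpec(158.5, 0.0),
            syn.EnsembleSpec(replica_lengths_ns=(100.0,), seed=0),
        )
        frames, count = syn.subsample_frames(trajs, 10.0)
        assert count == 11
        assert frames[0].time_ps == 0.0

    def test_count_matches_closed_form(self):
        lengths = (50.0, 20.0, 30.0)
        trajs = syn.generate_trajectory(
            syn.HelixSpec(n_res=9),
            syn.KinkSpec(158.5, 0.0),
            syn.EnsembleSpec(replica_lengths_ns=lengths, seed=0),
        )
        delta = 10.0
        _, count = syn.subsample_frames(trajs, delta)
        assert count == sum(int(np.floor(t / delta)) for t in lengths) + 1

    def test_non_commensurate_interval_rejected(self):
        trajs = syn.generate_trajectory(
            syn.HelixSpec(n_res=9),
            syn.KinkSpec(158.5, 0.0),
            syn.EnsembleSpec(replica_lengths_ns=(2.0,), seed=0),
        )
        with pytest.raises(ValueError, match="multiple"):
            syn.subsample_frames(trajs, 0.15)


class TestToyBundle:
    def test_sevenfold_symmetry_of_axis_distances(self):
        bundle, _ = syn.build_toy_bundle()
        centers = []
        for c in sorted(set(bundle.chains)):
            mask = bundle.chains == c
            centers.append(bundle.coords[mask][:, :2].mean(axis=0))
        centers = np.array(centers)
        adjacent = [
            np.linalg.norm(centers[i] - centers[(i + 1) % 7]) for i in range(7)
        ]
        np.testing.assert_allclose(adjacent, adjacent[0], atol=1e-9)

    def test_seed_point_clear_of_atoms(self):
        bundle, seed = syn.build_toy_bundle()
        d = np.linalg.norm(bundle.coords - seed, axis=1)
        assert d.min() > 2.0

    def test_clashing_radius_rejected(self):
        with pytest.raises(StructureError, match="clash"):
            syn.build_toy_bundle(ring_radius=2.0)


class TestAssayGenerators:
    def test_noise_free_responses_on_the_curve(self):
        spec = syn.binding_preset("smo_wt", noise_sd=0.0)
        table = syn.generate_binding_table(spec)
        labelled = table[~table["is_control"]]
        kd = 10.0 ** (-spec.pKd)
        expected = spec.baseline + spec.amplitude * labelled["concentration_M"] / (
            kd + labelled["concentration_M"]
        )
        np.testing.assert_allclose(labelled["response"], expected, rtol=1e-12)

    def test_half_saturation_identity(self):
        """At C = Kd with Hill slope 1 the response is exactly
        baseline + amplitude / 2."""
        spec = syn.BindingSpec(
            pKd=6.0, noise_sd=0.0, concentrations=(1e-6,), n_replicates=1
        )
        table = syn.generate_binding_table(spec)
        labelled = table[~table["is_control"]]
        assert labelled["response"].iloc[0] == pytest.approx(
            spec.baseline + spec.amplitude / 2, rel=1e-12
        )

    def test_controls_sit_at_baseline(self):
        spec = syn.binding_preset("fzd6_wt", noise_sd=0.0)
        table = syn.generate_binding_table(spec)
        controls = table[table["is_control"]]
        assert len(controls) == spec.n_controls
        np.testing.assert_allclose(controls["response"], spec.baseline, atol=1e-12)
        assert controls["concentration_M"].isna().all()

    def test_generator_determinism(self):
        spec = syn.binding_preset("smo_F643P", seed=77)
        a = syn.generate_binding_table(spec)
        b = syn.generate_binding_table(spec)
        assert a.equals(b)

    def test_flat_linear_table(self):
        t = syn.generate_dose_response(
            "linear", dict(intercept=0.5, slope=0.0, doses=[1, 2, 3], noise_sd=0.0)
        )
        np.testing.assert_allclose(t["response"], 0.5, atol=1e-15)

    def test_bell_maximum_at_interior_concentration(self):
        conc = np.logspace(-10, -4, 25)
        t = syn.generate_dose_response(
            "bell",
            dict(p0=0.0, p1=10.0, p2=1.0, m1=-8.0, m2=-6.0,
                 concentrations=conc, noise_sd=0.0),
        )
        peak = int(np.argmax(t["response"].to_numpy()))
        assert 0 < peak < len(conc) - 1

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_dose_response("sigmoid", {})

    def test_unknown_preset_names_rejected(self):
        with pytest.raises(KeyError):
            syn.kink_preset("fzd99")
        with pytest.raises(KeyError):
            syn.binding_preset("fzd99")
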