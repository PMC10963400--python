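"""Forward solver: analytic oracle, physical invariances, error handling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from eeguq.forward import (
    SeriesConvergenceWarning,
    assemble_leadfield,
    dipole_forward,
    homogeneous_sphere_potential,
)
from eeguq.model import (
    ConductivitySet,
    Layer,
    SensorMontage,
    SphereModel,
    generate_montage,
    generate_source_spaces,
    read_positions,
    source_depth,
    write_positions,
)


@pytest.fixture(scope="module")
def sigma_homog(model):
    return ConductivitySet.from_dict({t: 330.0 for t in model.tissues})


def _random_sources(model, rng, n_per_depth=3, depths=(2.5, 5, 10, 20, 30, 45)):
    out = []
    for depth in depths:
        r = model.inner_skull_radius - depth
        for _ in range(n_per_depth):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            out.append((u * r, rng.normal(size=3)))
    return out


class TestHomogeneousOracle:
    def test_matches_closed_form_at_all_depths(self, model, montage, sigma_homog):
        rng = np.random.default_rng(0)
        for pos, mom in _random_sources(model, rng):
            series = dipole_forward(model, sigma_homog, pos, mom, montage).values
            closed = homogeneous_sphere_potential(model.skin_radius, 330.0, pos, mom, montage.positions)
            closed = closed - closed.mean()
            err = np.max(np.abs(series - closed)) / np.max(np.abs(closed))
            assert err < 1e-6

    def test_grouped_layers_match_coarser_model(self, model, montage):
        """A 5-shell model with tissues sharing conductivities must equal
        the equivalent 2-shell model (checks interface bookkeeping)."""
        two = SphereModel(layers=(Layer("brain", 80.0), Layer("shell", 92.0)))
        s5 = ConductivitySet.from_dict({"wm": 330.0, "gm": 330.0, "csf": 330.0, "skull": 10.0, "skin": 10.0})
        s2 = ConductivitySet.from_dict({"brain": 330.0, "shell": 10.0})
        pos, mom = np.array([20.0, 25.0, 30.0]), np.array([1.0, -2.0, 0.5])
        va = dipole_forward(model, s5, pos, mom, montage).values
        vb = dipole_forward(two, s2, pos, mom, montage).values
        assert np.max(np.abs(va - vb)) < 1e-12 * np.max(np.abs(va))


class TestPhysicalInvariances:
    def test_linear_in_moment(self, model, montage, sigma_st):
        pos, mom = np.array([30.0, 40.0, 20.0]), np.array([1.0, -2.0, 0.5])
        v1 = dipole_forward(model, sigma_st, pos, mom, montage).values
        v2 = dipole_forward(model, sigma_st, pos, 2 * mom, montage).values
        assert np.allclose(v2, 2 * v1, rtol=0, atol=1e-14 * np.max(np.abs(v1)))

    def test_global_conductivity_scaling(self, model, montage, sigma_st):
        pos, mom = np.array([30.0, 40.0, 20.0]), np.array([1.0, -2.0, 0.5])
        v1 = dipole_forward(model, sigma_st, pos, mom, montage).values
        doubled = ConductivitySet.from_dict({t: 2 * v for t, v in sigma_st.as_dict().items()})
        v2 = dipole_forward(model, doubled, pos, mom, montage).values
        assert np.allclose(v2, v1 / 2, rtol=0, atol=1e-14 * np.max(np.abs(v1)))

    def test_average_reference(self, model, montage, sigma_st):
        rng = np.random.default_rng(1)
        for pos, mom in _random_sources(model, rng, n_per_depth=1):
            v = dipole_forward(model, sigma_st, pos, mom, montage).values
            assert abs(v.sum()) <= 1e-9 * np.linalg.norm(v)

    def test_joint_rotation_invariance(self, model, montage, sigma_st):
        pos, mom = np.array([30.0, 40.0, 20.0]), np.array([1.0, -2.0, 0.5])
        v1 = dipole_forward(model, sigma_st, pos, mom, montage).values
        R = Rotation.from_rotvec([0.3, -0.5, 1.1]).as_matrix()
        mon2 = SensorMontage(montage.labels, montage.positions @ R.T)
        v2 = dipole_forward(model, sigma_st, R @ pos, R @ mom, mon2).values
        assert np.max(np.abs(v2 - v1)) < 1e-9 * np.max(np.abs(v1))

    def test_depth_decay_homogeneous(self, model, montage, sigma_homog):
        ray = np.array([0.2, 0.3, 0.93])
        ray /= np.linalg.norm(ray)
        depths = [2.5, 5, 10, 15, 20, 25, 30, 35, 40, 45]
        norms = [
            np.linalg.norm(dipole_forward(model, sigma_homog, ray * (model.inner_skull_radius - d), ray, montage).values)
            for d in depths
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_depth_decay_within_layers_standard(self, model, montage, sigma_st):
        """At standard conductivities the decay holds within each brain
        layer (the GM->WM conductivity drop may break it across the
        interface, which is physical, not a solver artifact)."""
        ray = np.array([0.2, 0.3, 0.93])
        ray /= np.linalg.norm(ray)
        for depths in ([2.5, 5, 7.5, 10, 12], [15, 20, 30, 40, 45]):
            norms = [
                np.linalg.norm(dipole_forward(model, sigma_st, ray * (model.inner_skull_radius - d), ray, montage).values)
                for d in depths
            ]
            assert all(a > b for a, b in zip(norms, norms[1:]))


class TestLeadfield:
    def test_block_times_moment_matches_forward(self, model, montage, sigma_st, spaces_small):
        primary, _ = spaces_small
        lf = assemble_leadfield(model, sigma_st, primary, montage)
        mom = np.array([0.3, 0.2, -0.5])
        for i in (0, 7, 23):
            direct = dipole_forward(model, sigma_st, primary.positions[i], mom, montage).values
            assert np.max(np.abs(lf.values[i] @ mom - direct)) < 1e-12 * np.max(np.abs(direct))

    def test_single_source_shape(self, model, montage, sigma_st, sources_mini):
        lf = assemble_leadfield(model, sigma_st, sources_mini.subset([0]), montage)
        assert lf.values.shape == (1, montage.n_sensors, 3)

    def test_differs_between_prior_endpoints(self, model, montage, priors, sources_mini):
        lo = ConductivitySet.from_dict({t: p.sigma_min for t, p in priors.items()})
        hi = ConductivitySet.from_dict({t: p.sigma_max for t, p in priors.items()})
        a = assemble_leadfield(model, lo, sources_mini, montage).values
        b = assemble_leadfield(model, hi, sources_mini, montage).values
        assert np.max(np.abs(a - b)) > 1e-6 * np.max(np.abs(a))


class TestRejections:
    def test_source_outside_brain(self, model, montage, sigma_st):
        with pytest.raises(ValueError, match="brain"):
            dipole_forward(model, sigma_st, [0.0, 0.0, 81.0], [1, 0, 0], montage)

    def test_source_on_interface(self, model, montage, sigma_st):
        with pytest.raises(ValueError, match="interface"):
            dipole_forward(model, sigma_st, [0.0, 0.0, 67.0], [1, 0, 0], montage)

    def test_nonpositive_conductivity(self, model, montage, sigma_st):
        bad = dict(sigma_st.as_dict())
        bad["skull"] = -1.0
        with pytest.raises(ValueError, match="skull"):
            dipole_forward(model, ConductivitySet.from_dict(bad), [0, 0, 50.0], [1, 0, 0], montage)

    def test_truncation_warning(self, montage, sigma_st):
        low = SphereModel(series_truncation=12, truncation_tol=1e-12)
        with pytest.warns(SeriesConvergenceWarning):
            dipole_forward(low, sigma_st, [0.0, 0.0, 75.0], [1, 0, 0], montage)

    def test_leadfield_error_names_source(self, model, montage, sigma_st, sources_mini):
        from dataclasses import replace

        bad = replace(
            sources_mini,
            positions=np.vstack([sources_mini.positions[:1], [[0.0, 0.0, 85.0]]]),
            orientations=np.vstack([sources_mini.orientations[:1], [[0.0, 0.0, 1.0]]]),
            depths=np.array([sources_mini.depths[0], 0.0]),
            nn_to_companion=None,
        )
        with pytest.raises(ValueError, match="source 1"):
            assemble_leadfield(model, sigma_st, bad, montage)


class TestGeometry:
    def test_montage_count_radius_determinism(self, model):
        m1 = generate_montage(model, 80, 110.0)
        m2 = generate_montage(model, 80, 110.0)
        assert m1.n_sensors == 80
        assert np.allclose(np.linalg.norm(m1.positions, axis=1), model.skin_radius, rtol=1e-12)
        assert np.array_equal(m1.positions, m2.positions)
        assert m1.labels[0] == "E001" and m1.labels[-1] == "E080"

    def test_montage_rejects_bad_args(self, model):
        with pytest.raises(ValueError):
            generate_montage(model, 3)
        with pytest.raises(ValueError):
            generate_montage(model, 10, 0.0)

    def test_source_depths_exact(self, model, spaces_small):
        primary, _ = spaces_small
        r = np.linalg.norm(primary.positions, axis=1)
        assert np.allclose(model.inner_skull_radius - r, primary.depths, atol=1e-9)

    def test_grids_disjoint_and_nn_matches_bruteforce(self, model, spaces_small):
        primary, dual = spaces_small
        diff = primary.positions[:, None, :] - dual.positions[None, :, :]
        d2 = np.sqrt((diff**2).sum(-1))
        assert d2.min() > 0
        assert np.allclose(d2.min(axis=1), primary.nn_to_companion, atol=1e-9)

    def test_depth_beyond_skull_rejected(self, model):
        with pytest.raises(ValueError, match="inner skull"):
            generate_source_spaces(model, [(80.0, 4)])

    def test_source_depth_values(self, model):
        assert source_depth(model, [0, 0, 75.0]) == pytest.approx(5.0)
        assert source_depth(model, [0, 0, model.inner_skull_radius]) == pytest.approx(0.0)
        assert source_depth(model, [0, 0, 0]) == pytest.approx(model.inner_skull_radius)
        with pytest.raises(ValueError):
            source_depth(model, [0, 0, 90.0])


class TestModelValidation:
    def test_bad_radii(self):
        with pytest.raises(ValueError, match="increasing"):
            SphereModel(layers=(Layer("a", 10.0), Layer("b", 5.0)))

    def test_duplicate_tissue(self):
        with pytest.raises(ValueError, match="duplicate"):
            SphereModel(layers=(Layer("a", 10.0), Layer("a", 20.0)))

    def test_truncation_floor(self):
        with pytest.raises(ValueError, match="series_truncation"):
            SphereModel(series_truncation=5)


def test_position_io_roundtrip(tmp_path, montage):
    path = tmp_path / "electrodes.tsv"
    write_positions(path, montage.labels, montage.positions)
    labels, pos = read_positions(path)
    assert labels == list(montage.labels)
    assert np.allclose(pos, montage.positions)
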