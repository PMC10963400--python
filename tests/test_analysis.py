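"""Correlation summaries and depth profiles against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from eeguq.analysis import (
    build_correlation_profile,
    corr_deviation_vs_scatter,
    corr_rdm_vs_locerror,
    corr_sigma_vs_depth,
    depth_profile,
    summarize_sweeps,
)
from eeguq.model import ConductivityPrior
from eeguq.scan import SweepResult


def hand_pearson(x, y):
    """Direct textbook formula, the oracle for every correlation here."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def make_sweep(sig_skull, sig_skin, reco, rdm_vals=None, loc_error=None, depth0=10.0):
    reco = np.asarray(reco, float)
    pos = np.array([0.0, 0.0, 70.0])
    err = np.linalg.norm(reco - pos, axis=1) if loc_error is None else np.asarray(loc_error, float)
    df = pd.DataFrame(
        {
            "draw": np.arange(len(sig_skull)),
            "sigma_skull": sig_skull,
            "sigma_skin": sig_skin,
            "reco_x": reco[:, 0],
            "reco_y": reco[:, 1],
            "reco_z": reco[:, 2],
            "loc_error": err,
            "reco_depth": 80.0 - np.linalg.norm(reco, axis=1),
            "depth_change": np.zeros(len(sig_skull)),
            "ratio": np.zeros(len(sig_skull)),
            "rdm": np.zeros(len(sig_skull)) if rdm_vals is None else np.asarray(rdm_vals, float),
            "gof": np.ones(len(sig_skull)),
        }
    )
    return SweepResult(0, pos, np.array([0.0, 0.0, 1.0]), depth0, df, reco.mean(axis=0))


PRIORS = {
    "skull": ConductivityPrior("skull", 1.6, 33.0, 10.0),
    "skin": ConductivityPrior("skin", 280.0, 870.0, 430.0),
}


class TestDeviationVsScatter:
    def test_pure_skull_driven_scatter_gives_one(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(1.6, 33.0, 30)
        skull = np.concatenate([half, half])
        dev = np.abs(skull - PRIORS["skull"].mean)
        # symmetric +-x displacements proportional to the deviation keep
        # the centroid fixed, so distance-to-centroid = 3*dev exactly
        signs = np.concatenate([np.ones(30), -np.ones(30)])
        reco = np.column_stack([3.0 * dev * signs, np.zeros(60), np.full(60, 60.0)])
        sw = make_sweep(skull, rng.uniform(280, 870, 60), reco)
        out = corr_deviation_vs_scatter(sw, PRIORS).set_index("tissue")
        assert out.loc["skull", "r"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_tissue_uncorrelated(self):
        rng = np.random.default_rng(1)
        n = 400
        skull = rng.uniform(1.6, 33.0, n)
        skin = rng.uniform(280, 870, n)
        reco = np.column_stack([3 * np.abs(skull - 17.3), np.zeros(n), np.full(n, 60.0)])
        sw = make_sweep(skull, skin, reco)
        out = corr_deviation_vs_scatter(sw, PRIORS).set_index("tissue")
        assert abs(out.loc["skin", "r"]) < 3 / np.sqrt(n)

    def test_matches_hand_pearson_on_five_rows(self):
        skull = np.array([2.0, 8.0, 12.0, 20.0, 30.0])
        skin = np.array([300.0, 400.0, 500.0, 600.0, 700.0])
        reco = np.array([[1, 0, 60], [4, 1, 60], [2, 5, 61], [7, 2, 59], [3, 3, 60]], float)
        sw = make_sweep(skull, skin, reco)
        out = corr_deviation_vs_scatter(sw, PRIORS).set_index("tissue")
        dev = np.abs(skull - PRIORS["skull"].mean)
        scatter = np.linalg.norm(reco - reco.mean(axis=0), axis=1)
        assert out.loc["skull", "r"] == pytest.approx(hand_pearson(dev, scatter), abs=1e-12)

    def test_half_range_center_variant(self):
        skull = np.array([2.0, 8.0, 12.0, 20.0, 30.0])
        reco = np.array([[1, 0, 60], [4, 1, 60], [2, 5, 61], [7, 2, 59], [3, 3, 60]], float)
        sw = make_sweep(skull, np.full(5, 400.0), reco)
        out = corr_deviation_vs_scatter(sw, PRIORS, center="half_range").set_index("tissue")
        dev = np.abs(skull - PRIORS["skull"].half_range)
        scatter = np.linalg.norm(reco - reco.mean(axis=0), axis=1)
        assert out.loc["skull", "r"] == pytest.approx(hand_pearson(dev, scatter), abs=1e-12)


class TestSigmaVsDepth:
    def test_linear_negative_relation(self):
        skull = np.linspace(2, 30, 50)
        # reconstructed radius grows with skull sigma -> depth shrinks
        reco = np.column_stack([np.zeros(50), np.zeros(50), 50.0 + skull])
        sw = make_sweep(skull, np.full(50, 400.0), reco)
        out = corr_sigma_vs_depth(sw).set_index("tissue")
        assert out.loc["skull", "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_depth_flagged_undefined(self):
        skull = np.linspace(2, 30, 10)
        reco = np.tile([0.0, 0.0, 60.0], (10, 1))
        sw = make_sweep(skull, np.full(10, 400.0), reco)
        out = corr_sigma_vs_depth(sw).set_index("tissue")
        assert bool(out.loc["skull", "undefined"]) and out.loc["skull", "r"] == 0.0


class TestRdmVsLocError:
    def test_proportional_gives_one(self):
        rng = np.random.default_rng(2)
        rdmv = rng.uniform(0, 0.4, 30)
        reco = np.tile([0.0, 0.0, 60.0], (30, 1))
        sw = make_sweep(np.full(30, 10.0), np.full(30, 400.0), reco, rdm_vals=rdmv, loc_error=5 * rdmv)
        r, undef = corr_rdm_vs_locerror(sw)
        assert not undef and r == pytest.approx(1.0, abs=1e-12)

    def test_constant_error_flagged(self):
        reco = np.tile([0.0, 0.0, 60.0], (10, 1))
        sw = make_sweep(np.full(10, 10.0), np.full(10, 400.0), reco,
                        rdm_vals=np.linspace(0, 1, 10), loc_error=np.full(10, 2.0))
        r, undef = corr_rdm_vs_locerror(sw)
        assert undef and r == 0.0

    def test_five_row_hand_table(self):
        rdmv = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        errv = np.array([1.0, 2.5, 1.7, 4.0, 3.1])
        reco = np.tile([0.0, 0.0, 60.0], (5, 1))
        sw = make_sweep(np.full(5, 10.0), np.full(5, 400.0), reco, rdm_vals=rdmv, loc_error=errv)
        r, _ = corr_rdm_vs_locerror(sw)
        assert r == pytest.approx(hand_pearson(rdmv, errv), abs=1e-12)


class TestDepthProfile:
    def test_constant_values(self):
        depths = np.array([1.0, 2.0, 6.0, 7.0, 11.0])
        prof = depth_profile(np.full(5, 3.3), depths, bin_width=5.0, depth_range=(0.0, 15.0))
        occupied = prof[prof["count"] > 0]
        assert (occupied["median"] == 3.3).all()
        assert (occupied["q25"] == 3.3).all() and (occupied["q75"] == 3.3).all()

    def test_quartile_rule_on_four_values(self):
        prof = depth_profile(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0, 4.0]),
                             bin_width=5.0, depth_range=(0.0, 5.0))
        row = prof.iloc[0]
        assert row["median"] == pytest.approx(2.5)
        # numpy linear-interpolation percentile rule
        assert row["q25"] == pytest.approx(np.percentile([1, 2, 3, 4], 25))
        assert row["q75"] == pytest.approx(np.percentile([1, 2, 3, 4], 75))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            depth_profile(np.ones(3), np.array([1.0, 2.0, 50.0]), 2.5, (0.0, 45.0))

    def test_empty_bins_emitted_and_order_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=20)
        depths = rng.uniform(0, 10, 20)
        a = depth_profile(vals, depths, 2.5, (0.0, 45.0))
        perm = rng.permutation(20)
        b = depth_profile(vals[perm], depths[perm], 2.5, (0.0, 45.0))
        pd.testing.assert_frame_equal(a, b)
        assert (a[a.bin_lo >= 10.0]["count"] == 0).all()
        assert a[a.bin_lo >= 10.0]["median"].isna().all()


class TestSummaries:
    def test_single_draw_means_equal_draw(self):
        reco = np.array([[1.0, 0.0, 60.0]])
        sw = make_sweep(np.array([10.0]), np.array([400.0]), reco, rdm_vals=np.array([0.2]))
        out = summarize_sweeps([sw])
        assert out.mean_rdm.iloc[0] == pytest.approx(0.2)
        assert out.mean_loc_error.iloc[0] == pytest.approx(np.linalg.norm(reco[0] - sw.position))

    def test_two_draw_mean(self):
        reco = np.tile([0.0, 0.0, 60.0], (2, 1))
        sw = make_sweep(np.array([5.0, 10.0]), np.array([400.0, 500.0]), reco,
                        loc_error=np.array([2.0, 4.0]))
        assert summarize_sweeps([sw]).mean_loc_error.iloc[0] == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_sweeps([])


def test_build_correlation_profile_structure():
    rng = np.random.default_rng(4)
    sweeps = []
    for sid, depth in enumerate([5.0, 15.0, 25.0]):
        skull = rng.uniform(1.6, 33, 40)
        reco = np.column_stack([rng.normal(size=40), rng.normal(size=40), 80 - depth + rng.normal(size=40)])
        sw = make_sweep(skull, rng.uniform(280, 870, 40), reco, rdm_vals=rng.uniform(0, 0.5, 40), depth0=depth)
        sw.source_id = sid
        sw.depth = depth
        sweeps.append(sw)
    prof = build_correlation_profile(sweeps, PRIORS, bin_width=5.0)
    assert set(prof.per_source.analysis) == {"deviation_vs_scatter", "sigma_vs_depth", "rdm_vs_locerror"}
    assert prof.per_source.r.between(-1, 1).all()
    assert "sigma_vs_depth:skull" in prof.profiles
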