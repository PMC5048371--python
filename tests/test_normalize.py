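"""Normalization formula, binning and correction-factor families."""

import numpy as np
import pandas as pd
import pytest

from capcall import SimConfig, Viewpoint, simulate_capture_library
from capcall import normalize as N
from capcall.fragmap import FragmentMap, RawCounts
from conftest import make_raw_counts


def make_profile(values_by_key, n_bins=20, cell_line="CL1"):
    """Construct a tidy profile table from {(experiment, viewpoint): array}."""
    rows = []
    for (exp, vp), vals in values_by_key.items():
        vals = np.asarray(vals, dtype=float)
        for arm in ("L", "R"):
            for i in range(n_bins):
                rows.append({
                    "cell_line": cell_line, "experiment": exp, "condition": "c",
                    "replicate": 1, "viewpoint": vp, "arm": arm, "bin": i + 1,
                    "distance": 2000 + (i + 0.5) * 2000, "value": vals[i],
                })
    return pd.DataFrame(rows)


DECAY = 100.0 / np.arange(1, 21)  # noise-free reference profile


class TestFragmentNormalization:
    def test_formula_direct_evaluation(self, toy_fragmap):
        # Y=10, Y_j=1e6, W=500, NF=1e8 -> Ybar = 10/(1e6*500)*1e8 = 2.0
        rc = make_raw_counts([("e1", "vpT", 0, 10), ("e1", "vpT", 1, 10**6 - 10)])
        norm = N.normalize_fragment_counts(rc, toy_fragmap, nf=1e8)
        val = norm.loc[norm["fragment_id"] == 0, "norm"].iloc[0]
        assert val == pytest.approx(2.0)

    def test_zero_count_zero_norm(self, toy_fragmap):
        rc = make_raw_counts([("e1", "vpT", 0, 0), ("e1", "vpT", 1, 5)])
        norm = N.normalize_fragment_counts(rc, toy_fragmap)
        assert norm.loc[norm["fragment_id"] == 0, "norm"].iloc[0] == 0.0
        assert (norm["norm"] == 0).equals(norm["count"] == 0)

    def test_depth_scale_invariance(self, toy_fragmap):
        rc1 = make_raw_counts([("e1", "vpT", i, c) for i, c in enumerate([3, 7, 11])])
        doubled = rc1.frame.copy()
        doubled["count"] *= 2
        rc2 = RawCounts(doubled)
        n1 = N.normalize_fragment_counts(rc1, toy_fragmap)
        n2 = N.normalize_fragment_counts(rc2, toy_fragmap)
        np.testing.assert_allclose(n1["norm"], n2["norm"])

    def test_missing_fragment_error(self, toy_fragmap):
        rc = make_raw_counts([("e1", "vpT", 99, 5)])
        with pytest.raises(KeyError):
            N.normalize_fragment_counts(rc, toy_fragmap)

    def test_zero_total_viewpoint_dropped(self, toy_fragmap):
        rc = make_raw_counts([("e1", "vpT", 0, 0), ("e1", "vpU", 1, 5)])
        with pytest.warns(UserWarning, match="zero total"):
            norm = N.normalize_fragment_counts(rc, toy_fragmap)
        assert set(norm["viewpoint"]) == {"vpU"}


class TestBinning:
    vp = Viewpoint("vpT", "chrB", anchor=50_000, exclusion_radius=2000)

    def _fragmap(self):
        starts = np.arange(0, 100_000, 500)
        return FragmentMap(pd.DataFrame({
            "chrom": "chrB", "start": starts, "end": starts + 500,
            "fragment_id": np.arange(len(starts)),
        }))

    def _norm(self, frag_values):
        rows = []
        for fid, v in frag_values.items():
            rows.append({
                "experiment": "e1", "cell_line": "CL1", "condition": "c",
                "replicate": 1, "viewpoint": "vpT", "fragment_id": fid,
                "count": 1, "width": 500, "total": 1000, "norm": v,
            })
        return pd.DataFrame(rows)

    def test_two_fragments_one_bin_sum(self):
        fmap = self._fragmap()
        # fragments with midpoints 52250 and 52750 are both in bin 1 (R arm)
        norm = self._norm({104: 1.5, 105: 2.5})
        prof = N.bin_profile(norm, [self.vp], fmap, span=20_000)
        val = prof[(prof["arm"] == "R") & (prof["bin"] == 1)]["value"].iloc[0]
        assert val == 4.0

    def test_boundary_midpoint_goes_right(self):
        fmap = self._fragmap()
        # fragment 107 spans [53500,54000): midpoint 53750, distance 3750 -> bin 1
        # fragment 108 spans [54000,54500): midpoint 54250, distance 4250 -> bin 2
        prof = N.bin_profile(self._norm({107: 1.0, 108: 1.0}), [self.vp], fmap,
                             span=20_000)
        r = prof[prof["arm"] == "R"].set_index("bin")["value"]
        assert r[1] == 1.0 and r[2] == 1.0

    def test_empty_region_zero_bins_present(self):
        fmap = self._fragmap()
        prof = N.bin_profile(self._norm({104: 1.0}), [self.vp], fmap, span=20_000)
        n_bins = (20_000 - 2000) // 2000
        assert len(prof) == 2 * n_bins
        assert (prof["value"] == 0).sum() == 2 * n_bins - 1

    def test_binning_conserves_signal_within_span(self, default_sim):
        cfg, sim = default_sim
        norm = N.normalize_fragment_counts(sim.counts, sim.fragmap)
        prof = N.bin_profile(norm, sim.viewpoints, sim.fragmap, span=cfg.span)
        mids = dict(zip(sim.fragmap.frame["fragment_id"],
                        (sim.fragmap.frame["start"] + sim.fragmap.frame["end"]) // 2))
        vp = sim.viewpoints[0]
        n_bins = (cfg.span - vp.exclusion_radius) // 2000
        sub = norm[(norm["viewpoint"] == vp.viewpoint_id)
                   & (norm["experiment"] == "cond1_rep1")]
        d = np.abs(sub["fragment_id"].map(mids) - vp.anchor)
        expected = sub[(d >= vp.exclusion_radius)
                       & (d < vp.exclusion_radius + n_bins * 2000)]["norm"].sum()
        got = prof[(prof["viewpoint"] == vp.viewpoint_id)
                   & (prof["experiment"] == "cond1_rep1")]["value"].sum()
        assert got == pytest.approx(expected)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            N.bin_profile(self._norm({104: 1.0}), [self.vp], self._fragmap(),
                          bin_width=0)


class TestBackgroundCurve:
    def test_identical_profiles_mean_equals_each(self):
        prof = make_profile({("e1", "v1"): DECAY, ("e1", "v2"): DECAY})
        curve = N.estimate_background_curve(prof)
        np.testing.assert_allclose(curve.sort_values("bin")["expected"], DECAY)

    def test_two_probes_average(self):
        prof = make_profile({("e1", "v1"): np.full(20, 2.0),
                             ("e1", "v2"): np.full(20, 4.0)})
        curve = N.estimate_background_curve(prof)
        assert (curve["expected"] == 3.0).all()

    def test_simulated_curve_follows_power_law(self, fitted_background, default_sim):
        cfg, _ = default_sim
        curve = fitted_background["curve"]
        slope = np.polyfit(np.log(curve["bin"]), np.log(curve["expected"]), 1)[0]
        assert slope == pytest.approx(-cfg.decay_delta, abs=0.1)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            N.estimate_background_curve(pd.DataFrame(columns=["cell_line", "bin",
                                                              "distance", "value"]))


class TestExperimentFactors:
    def test_identical_experiments_exactly_one(self):
        prof = make_profile({("e1", "v1"): DECAY, ("e1", "v2"): 2 * DECAY,
                             ("e2", "v1"): DECAY, ("e2", "v2"): 2 * DECAY})
        ce = N.experiment_correction_factors(prof, N.estimate_background_curve(prof))
        np.testing.assert_allclose(ce.to_numpy(), 1.0)

    def test_doubled_experiment_factor_ratio_two(self):
        keys = {}
        for i in range(8):
            keys[(f"e{i}", "v1")] = DECAY if i else 2 * DECAY
        prof = make_profile(keys)
        ce = N.experiment_correction_factors(prof, N.estimate_background_curve(prof))
        assert ce["e0"] / ce["e1"] == pytest.approx(2.0)
        assert ce["e0"] == pytest.approx(2.0, rel=0.15)

    def test_single_experiment_single_probe_is_one(self):
        prof = make_profile({("e1", "v1"): DECAY})
        ce = N.experiment_correction_factors(prof, N.estimate_background_curve(prof))
        assert ce["e1"] == pytest.approx(1.0)

    def test_all_zero_experiment_error(self):
        prof = make_profile({("e1", "v1"): DECAY, ("e2", "v1"): np.zeros(20)})
        with pytest.raises(ValueError, match="e2"):
            N.experiment_correction_factors(prof, N.estimate_background_curve(prof))

    def test_simulated_factors_near_one(self, fitted_background):
        ce = fitted_background["c_e"]
        np.testing.assert_allclose(ce.to_numpy(), 1.0, atol=0.05)


class TestProbeFactors:
    def test_identical_probes_exactly_one(self):
        prof = make_profile({("e1", "v1"): DECAY, ("e1", "v2"): DECAY,
                             ("e2", "v1"): DECAY, ("e2", "v2"): DECAY})
        cj = N.probe_correction_factors(prof)
        np.testing.assert_allclose(cj.to_numpy(), 1.0)

    def test_bright_probe_ratio_and_collapse(self):
        prof = make_profile({("e1", "v1"): DECAY, ("e1", "v2"): 3 * DECAY})
        cj = N.probe_correction_factors(prof)
        assert cj[("CL1", "v2")] / cj[("CL1", "v1")] == pytest.approx(3.0)
        xbar = N.apply_probe_correction(prof, cj)
        v1 = xbar[xbar["viewpoint"] == "v1"].sort_values(["arm", "bin"])["value"]
        v2 = xbar[xbar["viewpoint"] == "v2"].sort_values(["arm", "bin"])["value"]
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy())

    def test_simulator_efficiency_recovery(self):
        # geometric mean of the configured efficiencies is 1, so the relative
        # factors C_j estimate the efficiencies directly
        cfg = SimConfig(seed=23, n_viewpoints=4, n_replicates=3,
                        probe_efficiencies={"vp1": 0.5, "vp2": 1.0,
                                            "vp3": 2.0, "vp4": 1.0})
        sim = simulate_capture_library(cfg)
        norm = N.normalize_fragment_counts(sim.counts, sim.fragmap)
        prof = N.bin_profile(norm, sim.viewpoints, sim.fragmap, span=cfg.span)
        cj = N.probe_correction_factors(prof)
        for vp, eff in cfg.probe_efficiencies.items():
            assert cj[("CL1", vp)] == pytest.approx(eff, rel=0.10)


class TestCellLineFactors:
    def test_identical_cell_lines_one(self):
        a = make_profile({("e1", "v1"): DECAY}, cell_line="A")
        b = make_profile({("e2", "v1"): DECAY}, cell_line="B")
        ccl = N.cellline_correction_factors(pd.concat([a, b]))
        np.testing.assert_allclose(ccl.to_numpy(), 1.0)

    def test_double_depth_cell_line_ratio_two(self):
        a = make_profile({("e1", "v1"): DECAY}, cell_line="A")
        b = make_profile({("e2", "v1"): 2 * DECAY}, cell_line="B")
        ccl = N.cellline_correction_factors(pd.concat([a, b]))
        assert ccl["B"] / ccl["A"] == pytest.approx(2.0)
        corrected = N.apply_cellline_correction(pd.concat([a, b]), ccl)
        med = corrected.groupby("cell_line")["value"].median()
        assert med["A"] == pytest.approx(med["B"], rel=0.05)

    def test_single_cell_line_warns_identity(self):
        prof = make_profile({("e1", "v1"): DECAY})
        with pytest.warns(UserWarning):
            ccl = N.cellline_correction_factors(prof)
        assert ccl["CL1"] == 1.0


def test_zero_masking_tally():
    vals = DECAY.copy()
    vals[5] = 0.0
    prof = make_profile({("e1", "v1"): vals})
    assert N.count_masked_zeros(prof) == 2  # both arms
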