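import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from capcall import (
    FragmentMap,
    RawCounts,
    SimConfig,
    Viewpoint,
    simulate_capture_library,
)
from capcall import normalize as N
from capcall import background as B


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic library shared across the suite."""
    cfg = SimConfig(seed=11, n_replicates=3)
    return cfg, simulate_capture_library(cfg)


@pytest.fixture(scope="session")
def fitted_background(default_sim):
    """Normalized profile, correction factors and fitted models for the
    shared default library."""
    cfg, sim = default_sim
    norm = N.normalize_fragment_counts(sim.counts, sim.fragmap)
    profile = N.bin_profile(norm, sim.viewpoints, sim.fragmap, span=cfg.span)
    curve = N.estimate_background_curve(profile)
    c_e = N.experiment_correction_factors(profile, curve)
    c_j = N.probe_correction_factors(profile)
    decay = B.fit_decay_model(curve)
    xbar = N.apply_probe_correction(profile, c_j)
    obs = pd.DataFrame({
        "y": xbar["value"].to_numpy(),
        "mu": xbar["experiment"].map(c_e).to_numpy()
        * decay.predict(xbar["bin"].to_numpy(dtype=float)),
    })
    disp = B.fit_dispersion_model(obs, cell_line=decay.cell_line)
    return {
        "norm": norm, "profile": profile, "curve": curve,
        "c_e": c_e, "c_j": c_j, "decay": decay, "disp": disp,
    }


@pytest.fixture()
def toy_fragmap():
    """Ten 500-bp fragments on one 5-kb chromosome."""
    starts = np.arange(0, 5000, 500)
    frame = pd.DataFrame({
        "chrom": "chrT", "start": starts, "end": starts + 500,
        "fragment_id": np.arange(10),
    })
    return FragmentMap(frame)


def make_raw_counts(rows):
    """rows: (experiment, viewpoint, fragment_id, count) with defaults for
    the remaining design columns."""
    frame = pd.DataFrame(
        rows, columns=["experiment", "viewpoint", "fragment_id", "count"]
    )
    frame["cell_line"] = "CL1"
    frame["condition"] = "cond1"
    frame["replicate"] = 1
    return RawCounts(frame[
        ["experiment", "cell_line", "condition", "replicate",
         "viewpoint", "fragment_id", "count"]
    ])
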