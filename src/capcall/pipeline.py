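"""End-to-end orchestration: simulate/load -> normalize -> fit -> call ->
differential, with a machine-readable run manifest.

Runs are deterministic given the inputs and seeds; every stage's parameters
and outputs are logged to ``manifest.json`` in the output directory, and a
re-run from the same config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import background, caller, differential, fragmap, normalize, simulate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Either ``counts``/``fragments``/``viewpoints`` paths are given, or a
    ``simulate`` section provides :class:`~capcall.simulate.SimConfig`
    fields and the inputs are generated.
    """

    out_dir: str = "capcall_out"
    counts: str | None = None
    fragments: str | None = None
    viewpoints: str | None = None
    simulate: dict[str, Any] | None = None
    nf: float = normalize.DEFAULT_NF
    bin_width: int = 2000
    window_width: int = 2000
    window_step: int = 200
    span: int = 250_000
    q_threshold: float = 0.05
    min_stratum_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nf", "bin_width", "window_width", "window_step", "span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sim_config(config: RunConfig) -> simulate.SimConfig:
    spec = dict(config.simulate or {})
    spikes = [simulate.Spike(**s) for s in spec.pop("spiked_interactions", [])]
    spec.setdefault("seed", config.seed)
    spec.setdefault("span", config.span)
    spec.setdefault("bin_width", config.bin_width)
    return simulate.SimConfig(spiked_interactions=tuple(spikes), **spec)


def analyze(
    counts: fragmap.RawCounts,
    fmap: fragmap.FragmentMap,
    viewpoints: list[fragmap.Viewpoint],
    nf: float = normalize.DEFAULT_NF,
    bin_width: int = 2000,
    window_width: int = 2000,
    window_step: int = 200,
    span: int = 250_000,
    q_threshold: float = 0.05,
    min_stratum_size: int = 50,
    run_differential: bool = True,
) -> dict[str, Any]:
    """The in-memory analysis chain shared by the pipeline, tests and
    reproduction scripts: normalize -> bin -> correction factors -> fit
    background -> window calls -> stratified FDR -> regions -> (optional)
    differential LRT.
    """
    norm = normalize.normalize_fragment_counts(counts, fmap, nf=nf)
    profile = normalize.bin_profile(
        norm, viewpoints, fmap, bin_width=bin_width, span=span
    )
    curve = normalize.estimate_background_curve(profile)
    c_e = normalize.experiment_correction_factors(profile, curve)
    c_j = normalize.probe_correction_factors(profile)

    cell_lines = sorted(profile["cell_line"].unique())
    models: dict[str, tuple[background.DecayModel, background.DispersionModel]] = {}
    for cl in cell_lines:
        decay = background.fit_decay_model(curve, cell_line=cl)
        xbar = normalize.apply_probe_correction(profile[profile["cell_line"] == cl], c_j)
        obs = pd.DataFrame({
            "y": xbar["value"].to_numpy(),
            "mu": xbar["experiment"].map(c_e).to_numpy()
            * decay.predict(xbar["bin"].to_numpy(dtype=float)),
        })
        disp = background.fit_dispersion_model(obs, cell_line=cl)
        models[cl] = (decay, disp)

    grid = pd.concat([
        caller.enumerate_windows(
            vp, span=span - vp.exclusion_radius,
            width=window_width, step=window_step,
            bin_width=bin_width, chrom_length=fmap.chrom_length(vp.chrom),
        ) for vp in viewpoints
    ], ignore_index=True)
    all_calls = []
    for cl in cell_lines:
        decay, disp = models[cl]
        wc = caller.window_counts(norm[norm["cell_line"] == cl], fmap, grid, c_j)
        all_calls.append(caller.call_interactions(
            wc, decay, disp, c_e, width=window_width, bin_width=bin_width,
        ))
    calls = pd.concat(all_calls, ignore_index=True)
    calls = caller.stratified_fdr(
        calls, bin_width=bin_width, min_stratum_size=min_stratum_size
    )
    calls["significant"] = calls["q"] <= q_threshold
    regions = caller.merge_significant_regions(calls, q_threshold=q_threshold)

    diff = None
    conditions = sorted(norm["condition"].unique())
    if run_differential and len(conditions) == 2:
        per_rep = [
            caller.merge_significant_regions(
                calls[calls["experiment"] == e], q_threshold=q_threshold
            )
            for e in calls["experiment"].unique()
        ]
        union = differential.union_significant_regions(per_rep)
        if len(union):
            obs = differential.region_counts(union, norm, fmap, c_j)
            disp = models[cell_lines[0]][1]
            diff = differential.lrt_differential(obs, disp)
            diff = differential.differential_fdr(diff, q_threshold=q_threshold)

    return {
        "norm": norm, "profile": profile, "curve": curve,
        "c_e": c_e, "c_j": c_j, "models": models,
        "calls": calls, "regions": regions, "differential": diff,
        "fragmap": fmap, "viewpoints": viewpoints,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write the result bundle under ``out_dir``.

    Returns the :func:`analyze` bundle plus the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": [], "parameters": {
        k: v for k, v in asdict(config).items() if k != "simulate"
    }}

    # -- inputs ------------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = _sim_config(config)
        sim = simulate.simulate_capture_library(sim_cfg)
        counts, fmap, vps = sim.counts, sim.fragmap, sim.viewpoints
        manifest["stages"].append({"stage": "simulate", "seed": sim_cfg.seed,
                                   "n_records": len(counts)})
    else:
        if not (config.counts and config.fragments and config.viewpoints):
            raise FileNotFoundError(
                "counts, fragments and viewpoints paths are all required "
                "when no simulate section is given"
            )
        for p in (config.counts, config.fragments, config.viewpoints):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        fmap = fragmap.FragmentMap.read_bed(config.fragments)
        vps = fragmap.read_viewpoint_table(config.viewpoints)
        counts = fragmap.read_count_table(config.counts, fmap, vps)
        manifest["stages"].append({"stage": "load", "n_records": len(counts),
                                   "trans_dropped": counts.n_trans_dropped})

    result = analyze(
        counts, fmap, vps, nf=config.nf, bin_width=config.bin_width,
        window_width=config.window_width, window_step=config.window_step,
        span=config.span, q_threshold=config.q_threshold,
        min_stratum_size=config.min_stratum_size,
    )
    profile, calls, regions = result["profile"], result["calls"], result["regions"]

    profile.to_csv(out / "profile.tsv", sep="\t", index=False)
    manifest["stages"].append({
        "stage": "normalize", "n_bins": int(len(profile)),
        "zero_bins_masked": normalize.count_masked_zeros(profile),
        "C_e": {k: float(v) for k, v in result["c_e"].items()},
        "C_j": {f"{k[0]}:{k[1]}": float(v) for k, v in result["c_j"].items()},
    })
    for cl, (decay, disp) in result["models"].items():
        background.save_models(decay, disp, out / f"model_{cl}.json")
        manifest["stages"].append({
            "stage": "fit-background", "cell_line": cl,
            "delta": decay.delta, "intercept": decay.intercept,
            "alpha": disp.alpha, "k_disp": disp.k_disp,
        })

    signal = calls.rename(columns={"xbar": "value"})[
        ["chrom", "start", "end", "value"]
    ].groupby(["chrom", "start", "end"], as_index=False).mean()
    fragmap.write_bedgraph(signal.sort_values(["chrom", "start"]), out / "signal.bedGraph")
    if len(regions):
        fragmap.write_calls_bed(regions, out / "calls.bed")
    manifest["stages"].append({
        "stage": "call", "n_windows": int(len(calls)),
        "n_significant_windows": int(calls["significant"].sum()),
        "n_regions": int(len(regions)),
    })
    if result["differential"] is not None:
        diff = result["differential"]
        diff.to_csv(out / "differential.tsv", sep="\t", index=False)
        manifest["stages"].append({
            "stage": "differential", "n_regions": int(len(diff)),
            "n_significant": int(diff["significant"].sum()),
        })

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result["manifest"] = manifest
    return result
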