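"""Synthetic Capture-C libraries with known ground truth.

The generator emulates the statistical structure the calling pipeline
assumes: power-law decay of ligation-junction counts with distance from the
viewpoint, negative-binomial overdispersion whose variance-to-mean ratio
grows linearly with the mean (var = (alpha*mu + k)*mu), probe-specific
capture efficiency, experiment-specific library depth, spiked true
interactions at chosen distances and fold-enrichments, and read-pair strand
orientations including short-range undigested self-circles.

Scale conventions
-----------------
Distances enter the decay law in 2-kb bin units: a position at genomic
distance D from the anchor has model distance d = (D - exclusion)/bin_width
+ 1/2, so bin midpoints land on the integers and ``decay_intercept`` is the
expected total count in the first bin beyond the exclusion zone (per unit
depth and efficiency).

The overdispersion law is specified at the 2-kb aggregation scale the
background model is fitted at: each fragment is drawn from a negative
binomial whose dispersion equals the bin-scale dispersion at its distance,
so that the sum over any 2-kb window obeys var = (alpha*mu + k)*mu on the
normalized-count scale.

Each probe's library total is pinned to ``depth_factor *
total_per_viewpoint`` (sequencing depth); probe efficiency scales only the
proximal (within-span) signal and the remaining mass is placed as flat
distal cis background.  Capture-efficiency differences therefore survive
total-count normalization as proximal-yield differences — exactly the
residual effect the probe correction factor C_j is designed to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .fragmap import FragmentMap, RawCounts, Viewpoint

ORIENTATIONS = ("same", "inward", "outward")


@dataclass(frozen=True)
class Spike:
    """A true interaction: ``fold``-enriched window at ``distance`` from a
    viewpoint (signed: negative = left arm).  ``fold_by_condition`` overrides
    the fold per condition for differential designs."""

    viewpoint: str
    distance: int
    fold: float = 1.0
    width: int = 2000
    fold_by_condition: Mapping[str, float] | None = None

    def fold_for(self, condition: str) -> float:
        if self.fold_by_condition is not None:
            return float(self.fold_by_condition.get(condition, self.fold))
        return self.fold


@dataclass(frozen=True)
class ExperimentDesign:
    experiment_id: str
    cell_line: str = "CL1"
    condition: str = "cond1"
    replicate: int = 1


@dataclass
class SimConfig:
    """Study conditions for a synthetic Capture-C library.

    Defaults describe one 3-Mb chromosome carrying 4 viewpoints profiled
    over +/-250 kb, ~6000 expected junctions in the first 2-kb bin, a decay
    exponent of 1, dispersion law beta = 0.05*mu + 2, and 4e5 total captured
    junctions per viewpoint (so that with NF = 1e8 normalized counts land on
    the same scale as raw bin counts).
    """

    chrom: str = "chr1"
    chrom_length: int = 3_000_000
    recognition_site: str = "GATC"
    mean_fragment_size: int = 256
    fragment_jitter: float = 0.25
    n_viewpoints: int = 4
    viewpoint_positions: Sequence[int] | None = None
    span: int = 250_000
    exclusion_radius: int = 2_000
    bin_width: int = 2_000
    decay_delta: float = 1.0
    decay_intercept: float = 6_000.0
    alpha_true: float = 0.05
    k_disp_true: float = 2.0
    probe_efficiencies: Mapping[str, float] | Sequence[float] | None = None
    depth_factors: Mapping[str, float] | None = None
    experiment_yields: Mapping[str, float] | None = None
    replicate_yield_sd: float = 0.0
    total_per_viewpoint: float = 400_000.0
    nf: float = 1e8
    spiked_interactions: Sequence[Spike] = field(default_factory=tuple)
    experiments: Sequence[ExperimentDesign] | None = None
    n_replicates: int = 2
    conditions: Sequence[str] = ("cond1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_viewpoints < 1 and not self.viewpoint_positions:
            raise ValueError("at least one viewpoint is required")
        if self.decay_delta < 0:
            raise ValueError("decay_delta must be >= 0")
        if self.k_disp_true < 1:
            raise ValueError("k_disp_true must be >= 1 (variance >= mean)")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be >= 0")
        for s in self.spiked_interactions:
            folds = [s.fold] + list((s.fold_by_condition or {}).values())
            if any(f < 1 for f in folds):
                raise ValueError("spike fold_enrichment must be >= 1")

    def resolved_experiments(self) -> list[ExperimentDesign]:
        if self.experiments is not None:
            return list(self.experiments)
        out = []
        for cond in self.conditions:
            for r in range(1, self.n_replicates + 1):
                out.append(ExperimentDesign(
                    experiment_id=f"{cond}_rep{r}", condition=cond, replicate=r,
                ))
        return out


@dataclass
class TruthTable:
    """Ground truth of a simulated library, for recovery tests."""

    spikes: pd.DataFrame
    probe_efficiencies: dict[str, float]
    depth_factors: dict[str, float]
    experiment_yields: dict[str, float]
    params: dict[str, float]


class SimResult(NamedTuple):
    counts: RawCounts
    truth: TruthTable
    fragmap: FragmentMap
    viewpoints: list[Viewpoint]


# ---------------------------------------------------------------------------

def _build_fragment_map(config: SimConfig, rng: np.random.Generator) -> FragmentMap:
    lo = config.mean_fragment_size * (1 - config.fragment_jitter)
    hi = config.mean_fragment_size * (1 + config.fragment_jitter)
    n_est = int(config.chrom_length / lo) + 2
    spacings = rng.uniform(lo, hi, size=n_est)
    cuts = np.cumsum(spacings).astype(np.int64)
    cuts = cuts[cuts < config.chrom_length]
    return FragmentMap.from_boundaries(
        {config.chrom: cuts.tolist()}, {config.chrom: config.chrom_length},
        config.recognition_site,
    )


def _place_viewpoints(config: SimConfig, fragmap: FragmentMap) -> list[Viewpoint]:
    if config.viewpoint_positions is not None:
        positions = list(config.viewpoint_positions)
    else:
        n = config.n_viewpoints
        positions = [
            int(round(config.chrom_length * (i + 1) / (n + 1))) for i in range(n)
        ]
    vps = []
    for i, pos in enumerate(positions):
        frag = fragmap.containing(config.chrom, pos)
        anchor = int((frag["start"] + frag["end"]) // 2)
        vps.append(Viewpoint(
            viewpoint_id=f"vp{i + 1}", chrom=config.chrom, anchor=anchor,
            exclusion_radius=config.exclusion_radius,
        ))
    return vps


def _as_probe_map(config: SimConfig, vps: list[Viewpoint]) -> dict[str, float]:
    eff = config.probe_efficiencies
    if eff is None:
        return {v.viewpoint_id: 1.0 for v in vps}
    if isinstance(eff, Mapping):
        return {v.viewpoint_id: float(eff.get(v.viewpoint_id, 1.0)) for v in vps}
    return {v.viewpoint_id: float(e) for v, e in zip(vps, eff)}


def _inv_width_mean(config: SimConfig) -> float:
    """E[1/W] for fragment widths uniform on [mean(1-j), mean(1+j)]."""
    j, m = config.fragment_jitter, config.mean_fragment_size
    if j <= 0:
        return 1.0 / m
    return math.log((1 + j) / (1 - j)) / (2 * j * m)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """NB draws parameterized by mean and dispersion beta = var/mean (>= 1)."""
    mean = np.asarray(mean, dtype=float)
    beta = np.maximum(np.asarray(beta, dtype=float), 1.0)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = beta <= 1.0 + 1e-9
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = mean[nb] / (beta[nb] - 1.0)
        p = 1.0 / beta[nb]
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_capture_library(config: SimConfig) -> SimResult:
    """Draw a fragment-level junction-count library with known truth.

    Fully reproducible from ``config.seed``: the same config yields
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    fragmap = _build_fragment_map(config, rng)
    viewpoints = _place_viewpoints(config, fragmap)
    if not viewpoints:
        raise ValueError("zero viewpoints")
    experiments = config.resolved_experiments()
    eff = _as_probe_map(config, viewpoints)
    depth = {
        e.experiment_id: float((config.depth_factors or {}).get(e.experiment_id, 1.0))
        for e in experiments
    }
    yields = {}
    for e in experiments:
        y = float((config.experiment_yields or {}).get(e.experiment_id, 1.0))
        if config.replicate_yield_sd > 0:
            y *= float(rng.lognormal(0.0, config.replicate_yield_sd))
        yields[e.experiment_id] = y

    mids = fragmap.midpoints
    widths = fragmap.widths.astype(float)
    bw = float(config.bin_width)
    h_inv = _inv_width_mean(config)
    n_bar = bw / config.mean_fragment_size

    spike_rows = []
    for s in config.spiked_interactions:
        vp = next(v for v in viewpoints if v.viewpoint_id == s.viewpoint)
        center = vp.anchor + s.distance
        spike_rows.append({
            "viewpoint": s.viewpoint, "chrom": vp.chrom,
            "start": int(center - s.width // 2), "end": int(center + s.width // 2),
            "distance": s.distance, "width": s.width, "fold": s.fold,
        })
    spikes_df = pd.DataFrame(
        spike_rows,
        columns=["viewpoint", "chrom", "start", "end", "distance", "width", "fold"],
    )

    frames = []
    for e in experiments:
        t_total = depth[e.experiment_id] * config.total_per_viewpoint
        c_prox = config.nf * n_bar / (bw * t_total)   # normalized/raw bin-scale ratio
        gamma = config.nf * h_inv / t_total           # dispersion transfer factor
        for vp in viewpoints:
            dist = np.abs(mids - vp.anchor)
            prox = (dist > vp.exclusion_radius) & (dist <= config.span)
            d_units = (dist[prox] - vp.exclusion_radius) / bw + 0.5
            m_bin = (
                depth[e.experiment_id] * eff[vp.viewpoint_id]
                * yields[e.experiment_id]
                * config.decay_intercept * d_units ** (-config.decay_delta)
            )
            for s in config.spiked_interactions:
                if s.viewpoint != vp.viewpoint_id:
                    continue
                center = vp.anchor + s.distance
                in_spike = (
                    (mids[prox] >= center - s.width // 2)
                    & (mids[prox] < center + s.width // 2)
                )
                m_bin = np.where(in_spike, m_bin * s.fold_for(e.condition), m_bin)
            m_frag = m_bin * widths[prox] / bw
            prox_mass = float(m_frag.sum())
            far = ~prox
            far_mass = t_total - prox_mass
            if far_mass < 0:
                raise ValueError(
                    "proximal signal mass exceeds total_per_viewpoint; "
                    "lower decay_intercept or raise total_per_viewpoint"
                )
            w_far = widths[far]
            m_far = far_mass * w_far / w_far.sum()
            m_far_bin = far_mass * bw / w_far.sum()

            beta_prox = np.maximum(
                1.0, (config.alpha_true * c_prox * m_bin + config.k_disp_true) / gamma
            )
            beta_far = max(
                1.0, (config.alpha_true * c_prox * m_far_bin + config.k_disp_true) / gamma
            )
            y_prox = _nb_draw(rng, m_frag, beta_prox)
            y_far = _nb_draw(rng, m_far, np.full(m_far.shape, beta_far))

            counts = np.zeros(len(fragmap), dtype=np.int64)
            counts[prox] = y_prox
            counts[far] = y_far
            nz = counts > 0
            frames.append(pd.DataFrame({
                "experiment": e.experiment_id, "cell_line": e.cell_line,
                "condition": e.condition, "replicate": e.replicate,
                "viewpoint": vp.viewpoint_id,
                "fragment_id": fragmap.frame["fragment_id"].to_numpy()[nz],
                "count": counts[nz],
            }))

    frame = pd.concat(frames, ignore_index=True)
    truth = TruthTable(
        spikes=spikes_df, probe_efficiencies=eff, depth_factors=depth,
        experiment_yields=yields,
        params={
            "delta": config.decay_delta, "intercept": config.decay_intercept,
            "alpha": config.alpha_true, "k_disp": config.k_disp_true,
        },
    )
    return SimResult(RawCounts(frame), truth, fragmap, viewpoints)


def simulate_two_condition(
    config: SimConfig,
    differential: Sequence[tuple[str, int, float]] | Sequence[Spike] = (),
) -> SimResult:
    """Two-condition library sharing decay and dispersion parameters.

    ``differential`` entries are either :class:`Spike` objects with
    ``fold_by_condition`` set, or ``(viewpoint, distance, fold_ratio)``
    tuples meaning fold 1 in the first condition and ``fold_ratio`` in the
    second.  Both conditions are drawn independently with the configured
    number of replicates each.
    """
    conditions = tuple(config.conditions)
    if len(conditions) < 2:
        conditions = ("condA", "condB")
    spikes = list(config.spiked_interactions)
    for entry in differential:
        if isinstance(entry, Spike):
            spikes.append(entry)
        else:
            vp_id, distance, ratio = entry
            spikes.append(Spike(
                viewpoint=vp_id, distance=int(distance),
                fold=max(1.0, ratio),
                fold_by_condition={conditions[0]: 1.0, conditions[1]: float(ratio)},
            ))
    cfg = replace(
        config, conditions=conditions, spiked_interactions=tuple(spikes),
    )
    return simulate_capture_library(cfg)


# ---------------------------------------------------------------------------

def simulate_read_pairs(
    n_pairs: int,
    self_circle_fraction: float = 0.0,
    self_circle_max_span: int = 2000,
    seed: int = 0,
    genome_length: int = 3_000_000,
) -> pd.DataFrame:
    """Read-pair spans and strand orientations for library QC.

    Random re-ligations draw the four strand combinations equiprobably, so
    same : inward : outward = 2 : 1 : 1 at every span.  Self-circles
    (undigested, re-circularized fragments) are exclusively outward-oriented
    and confined to spans below ``self_circle_max_span``.

    Returns a table with a signed ``distance`` (bp between mate fragment
    midpoints) and an ``orientation`` in {same, inward, outward}.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not 0.0 <= self_circle_fraction <= 1.0:
        raise ValueError("self_circle_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sc = int(round(self_circle_fraction * n_pairs))
    n_rand = n_pairs - n_sc

    a = rng.integers(0, genome_length, size=n_rand)
    b = rng.integers(0, genome_length, size=n_rand)
    span_rand = np.abs(a - b) + 1
    orient_rand = rng.choice(
        np.array(ORIENTATIONS), size=n_rand, p=[0.5, 0.25, 0.25]
    )
    span_sc = rng.integers(1, max(2, self_circle_max_span), size=n_sc)
    sign = rng.choice(np.array([-1, 1]), size=n_pairs)
    distance = np.concatenate([span_rand, span_sc]) * sign
    orientation = np.concatenate([orient_rand, np.full(n_sc, "outward")])
    return pd.DataFrame({"distance": distance, "orientation": orientation})


# ---------------------------------------------------------------------------

def synthetic_reference(config: SimConfig) -> dict[str, str]:
    """A DNA sequence whose in-silico digest reproduces the simulated
    fragment map: recognition sites planted at the map's internal
    boundaries, motif-free random filler elsewhere.

    Intended for small configurations (IO round-trip and digestion tests);
    building multi-megabase strings is slow in pure Python.
    """
    rng = np.random.default_rng(config.seed)
    fragmap = _build_fragment_map(config, rng)
    site = config.recognition_site.upper()
    length = config.chrom_length
    letters = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(letters, size=length)
    site_b = np.frombuffer(site.encode(), dtype="S1")
    k = len(site)
    bounds = fragmap.frame["start"].to_numpy()[1:]

    def plant(positions: np.ndarray) -> None:
        for p in positions:
            seq[p:p + k] = site_b[: length - p]

    plant(bounds)
    planted = set(int(b) for b in bounds)
    # scrub accidental motif occurrences, keeping planted ones intact
    for _ in range(20):
        text = seq.tobytes()
        hits = []
        start = 0
        while True:
            i = text.find(site.encode(), start)
            if i < 0:
                break
            if i not in planted:
                hits.append(i)
            start = i + 1
        if not hits:
            break
        for i in hits:
            # mutate one base not inside a planted site
            for off in range(k):
                pos = i + off
                if not any(b <= pos < b + k for b in planted):
                    cur = seq[pos]
                    choices = [c for c in letters if c != cur]
                    seq[pos] = choices[int(rng.integers(0, len(choices)))]
                    break
    return {config.chrom: seq.tobytes().decode()}
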