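"""Count normalization, 2-kb binning and geometric-mean correction factors.

The observed junction count Y_{x,j} between fragment x and capture probe j
is normalized to the probe's total captured interactions Y_j and to the
fragment width W_x,

    Ybar_{x,j} = Y_{x,j} / (Y_j * W_x) * NF,

with NF = 1e8 bringing the values onto a convenient common scale.  Profiles
are then summed into 2-kb distance bins anchored at the edge of the
viewpoint exclusion zone; the left and right arms share the distance index.
Three families of DESeq-style median-of-ratio factors remove residual
scale: per experiment (C_e), per capture probe (C_j) and per cell line
(C_cl).  Geometric means are taken over strictly positive values only
(zeros are masked and tallied, the DESeq convention).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fragmap import FragmentMap, RawCounts, Viewpoint

log = logging.getLogger(__name__)

DEFAULT_NF = 1e8

PROFILE_KEYS = ["cell_line", "experiment", "condition", "replicate", "viewpoint"]


def normalize_fragment_counts(
    raw: RawCounts, fragmap: FragmentMap, nf: float = DEFAULT_NF
) -> pd.DataFrame:
    """Fragment-level depth- and width-normalized counts.

    Returns the raw table with added columns ``width``, ``total`` (Y_j) and
    ``norm`` (Ybar).  Viewpoint/experiment pairs with zero total are dropped
    with a warning.
    """
    frame = raw.frame.merge(
        fragmap.frame[["fragment_id", "chrom", "start", "end"]],
        on="fragment_id", how="left", validate="many_to_one",
    )
    if frame["chrom"].isna().any():
        missing = frame.loc[frame["chrom"].isna(), "fragment_id"].iloc[0]
        raise KeyError(f"fragment_id {missing} absent from fragment map")
    frame["width"] = frame["end"] - frame["start"]
    totals = frame.groupby(["experiment", "viewpoint"])["count"].transform("sum")
    zero = totals == 0
    if zero.any():
        dropped = frame.loc[zero, ["experiment", "viewpoint"]].drop_duplicates()
        warnings.warn(
            f"dropping {len(dropped)} (experiment, viewpoint) pairs with zero total"
        )
        frame = frame[~zero]
        totals = totals[~zero]
    frame["total"] = totals
    frame["norm"] = frame["count"] / (frame["total"] * frame["width"]) * nf
    return frame


def bin_profile(
    norm: pd.DataFrame,
    viewpoints: Iterable[Viewpoint],
    fragmap: FragmentMap,
    bin_width: int = 2000,
    span: int = 250_000,
) -> pd.DataFrame:
    """Sum normalized fragment counts into 2-kb distance bins per arm.

    Bin 1 starts at the edge of the exclusion zone on each side of the
    viewpoint; fragments are assigned by midpoint with half-open bins
    (boundary midpoints go to the higher-index bin).  Empty bins are present
    with value 0.  Returns tidy rows (profile keys, arm, bin, distance,
    value) where ``distance`` is the genomic distance of the bin midpoint
    from the anchor and ``bin`` is the 1-based shared distance index.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vps = {v.viewpoint_id: v for v in viewpoints}
    mid_by_frag = dict(zip(
        fragmap.frame["fragment_id"].to_numpy(),
        (fragmap.frame["start"].to_numpy() + fragmap.frame["end"].to_numpy()) // 2,
    ))
    out = []
    for keys, grp in norm.groupby(PROFILE_KEYS, sort=False):
        vp = vps[keys[PROFILE_KEYS.index("viewpoint")]]
        n_bins = (span - vp.exclusion_radius) // bin_width
        mids = grp["fragment_id"].map(mid_by_frag).to_numpy()
        offset = mids - vp.anchor
        dist = np.abs(offset)
        usable = (dist >= vp.exclusion_radius) & (dist < vp.exclusion_radius + n_bins * bin_width)
        idx = ((dist[usable] - vp.exclusion_radius) // bin_width).astype(int) + 1
        arm = np.where(offset[usable] < 0, "L", "R")
        vals = grp["norm"].to_numpy()[usable]
        acc = pd.DataFrame({"arm": arm, "bin": idx, "value": vals}) \
            .groupby(["arm", "bin"])["value"].sum()
        full = pd.MultiIndex.from_product(
            [["L", "R"], np.arange(1, n_bins + 1)], names=["arm", "bin"]
        )
        acc = acc.reindex(full, fill_value=0.0).reset_index()
        for k, v in zip(PROFILE_KEYS, keys):
            acc[k] = v
        acc["distance"] = vp.exclusion_radius + (acc["bin"] - 0.5) * bin_width
        out.append(acc)
    profile = pd.concat(out, ignore_index=True)
    return profile[PROFILE_KEYS + ["arm", "bin", "distance", "value"]]


def estimate_background_curve(profile: pd.DataFrame) -> pd.DataFrame:
    """Expected background E[Ybar_i] per distance bin and cell line.

    The mean over all probes (and arms), pooling every experiment of the
    cell line — the empirical decay curve the power-law model is fitted to.
    """
    if profile.empty:
        raise ValueError("no profiles supplied")
    curve = (
        profile.groupby(["cell_line", "bin"], sort=True)["value"]
        .mean().rename("expected").reset_index()
    )
    dist = profile.groupby(["cell_line", "bin"])["distance"].first().reset_index()
    return curve.merge(dist, on=["cell_line", "bin"])


def _geomean(values: np.ndarray) -> float:
    """Geometric mean over strictly positive entries; NaN if none."""
    pos = values[values > 0]
    if len(pos) == 0:
        return np.nan
    return float(np.exp(np.mean(np.log(pos))))


def experiment_correction_factors(
    profile: pd.DataFrame, curve: pd.DataFrame | None = None
) -> pd.Series:
    """C_e: DESeq-style median-of-ratio scale factor per experiment.

    The experiment's geometric-mean profile across probes, GYbar_{e,i}, is
    compared per bin with a geometric reference over the experiments of the
    same cell line, and C_e is the median of the ratio over bins.  Using a
    geometric reference (rather than the pooled arithmetic curve) makes
    identical experiments come out at exactly 1 and keeps the product
    C_e * E[Ybar_i] an unbiased background scale; a mixed geometric/
    arithmetic ratio would carry a shared downward Jensen bias.  The
    background expected for experiment e is E[Ybar_i] * C_e.
    """
    out = {}
    for cl, grp in profile.groupby("cell_line", sort=False):
        gm = (
            grp.groupby(["experiment", "bin"])["value"]
            .apply(lambda v: _geomean(v.to_numpy()))
            .unstack("experiment")
        )
        for exp in gm.columns:
            if gm[exp].isna().all():
                raise ValueError(f"experiment {exp!r} has no positive bins")
        ref = np.exp(np.log(gm).mean(axis=1, skipna=False))
        ratios = gm.div(ref, axis=0).dropna()
        if ratios.empty:
            raise ValueError(
                f"cell line {cl!r}: no bins with positive counts in every experiment"
            )
        for exp in gm.columns:
            out[exp] = float(ratios[exp].median())
    return pd.Series(out, name="C_e")


def probe_correction_factors(profile: pd.DataFrame) -> pd.Series:
    """C_j: capture-probe efficiency factors within each cell line.

    For each experiment e, the probe's geometric mean over bins is compared
    with the geometric mean over all probes and bins of that experiment's
    cell line; C_j is the median of the ratio over experiments.  Probe
    profiles are subsequently divided by C_j (Xbar = Ybar / C_j).
    """
    out = {}
    for cl, grp in profile.groupby("cell_line", sort=False):
        g_ej = grp.groupby(["experiment", "viewpoint"])["value"].apply(
            lambda v: _geomean(v.to_numpy())
        )
        g_e = grp.groupby("experiment")["value"].apply(
            lambda v: _geomean(v.to_numpy())
        )
        ratios = g_ej / g_e.reindex(g_ej.index.get_level_values("experiment")).to_numpy()
        cj = ratios.groupby("viewpoint").median()
        for vp, v in cj.items():
            out[(cl, vp)] = float(v)
    s = pd.Series(out, name="C_j")
    s.index = pd.MultiIndex.from_tuples(s.index, names=["cell_line", "viewpoint"])
    return s


def apply_probe_correction(profile: pd.DataFrame, c_j: pd.Series) -> pd.DataFrame:
    """Xbar profiles: divide each probe's values by its C_j."""
    factors = profile.set_index(["cell_line", "viewpoint"]).index.map(c_j)
    out = profile.copy()
    out["value"] = out["value"] / np.asarray(factors, dtype=float)
    return out


def cellline_correction_factors(profile: pd.DataFrame) -> pd.Series:
    """C_cl: median over probes of the ratio of the probe's geometric mean
    within one cell line to its geometric mean across all cell lines.

    Applied as XCbar = Xbar / C_cl so that median interaction counts agree
    across the cell lines being compared.  With a single cell line the
    factors are identity (with a warning).
    """
    cell_lines = profile["cell_line"].unique()
    if len(cell_lines) < 2:
        warnings.warn("only one cell line: C_cl factors are identity")
        return pd.Series({cl: 1.0 for cl in cell_lines}, name="C_cl")
    g_j = profile.groupby("viewpoint")["value"].apply(lambda v: _geomean(v.to_numpy()))
    out = {}
    for cl, grp in profile.groupby("cell_line", sort=False):
        g_cl_j = grp.groupby("viewpoint")["value"].apply(
            lambda v: _geomean(v.to_numpy())
        )
        ratios = (g_cl_j / g_j.reindex(g_cl_j.index)).dropna()
        out[cl] = float(np.median(ratios))
    return pd.Series(out, name="C_cl")


def apply_cellline_correction(profile: pd.DataFrame, c_cl: pd.Series) -> pd.DataFrame:
    out = profile.copy()
    out["value"] = out["value"] / out["cell_line"].map(c_cl).to_numpy()
    return out


def count_masked_zeros(profile: pd.DataFrame) -> int:
    """How many zero-valued bins the geometric means exclude."""
    return int((profile["value"] <= 0).sum())
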