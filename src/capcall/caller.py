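"""Sliding-window interaction calling with stratified FDR.

The cis territory around each viewpoint is segmented into overlapping 2-kb
windows stepped every 200 bp.  Each window's probe-normalized count Xbar is
tested against the null negative binomial at the window's distance
(mean C_e * intercept * d**-delta, dispersion alpha*mu + k_disp), giving an
upper-tail p-value.  Because the null p-value distribution differs across
distances, Benjamini-Hochberg correction is applied within distance strata
(the 2-kb bin index), pooling windows across probes.  Runs of overlapping
significant windows are merged into maximal regions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .background import DecayModel, DispersionModel, nb_upper_tail
from .fragmap import FragmentMap, Viewpoint

WINDOW_WIDTH = 2000
WINDOW_STEP = 200


def enumerate_windows(
    viewpoint: Viewpoint,
    span: int,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    bin_width: int = 2000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Overlapping windows tiling both arms beyond the exclusion zone.

    ``span`` is the tested territory per arm, measured from the exclusion
    edge; each arm carries floor((span - width)/step) + 1 windows.  Windows
    extending past the chromosome ends are dropped when ``chrom_length`` is
    given.  ``d_model`` is the window-center distance in bin units.
    """
    if width < step or step <= 0:
        raise ValueError("need width >= step > 0")
    if span < width:
        raise ValueError("span must be at least the window width")
    n = (span - width) // step + 1
    offsets = np.arange(n) * step
    right_start = viewpoint.anchor + viewpoint.exclusion_radius + offsets
    left_end = viewpoint.anchor - viewpoint.exclusion_radius - offsets
    starts = np.concatenate([left_end - width, right_start])
    ends = starts + width
    arms = np.array(["L"] * n + ["R"] * n)
    frame = pd.DataFrame({
        "chrom": viewpoint.chrom, "start": starts, "end": ends, "arm": arms,
        "viewpoint": viewpoint.viewpoint_id,
    })
    center = (frame["start"] + frame["end"]) / 2
    frame["distance"] = np.abs(center - viewpoint.anchor)
    frame["d_model"] = (
        (frame["distance"] - viewpoint.exclusion_radius) / bin_width + 0.5
    )
    if chrom_length is not None:
        frame = frame[(frame["start"] >= 0) & (frame["end"] <= chrom_length)]
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


def window_counts(
    norm: pd.DataFrame,
    fragmap: FragmentMap,
    grid: pd.DataFrame,
    c_j: pd.Series | Mapping,
) -> pd.DataFrame:
    """Probe-normalized window counts Xbar = sum(Ybar in window) / C_j.

    Fragments are assigned to every window containing their midpoint
    (windows overlap); the sum over each window uses prefix sums on the
    midpoint-sorted fragment table, so the cost is independent of overlap.
    """
    mid_by_frag = pd.Series(
        ((fragmap.frame["start"] + fragmap.frame["end"]) // 2).to_numpy(),
        index=fragmap.frame["fragment_id"].to_numpy(),
    )
    out = []
    group_cols = ["cell_line", "experiment", "condition", "replicate", "viewpoint"]
    for keys, grp in norm.groupby(group_cols, sort=False):
        vp_id = keys[group_cols.index("viewpoint")]
        cl = keys[group_cols.index("cell_line")]
        wins = grid[grid["viewpoint"] == vp_id]
        if wins.empty:
            continue
        try:
            cj = float(c_j[(cl, vp_id)])
        except (KeyError, TypeError):
            try:
                cj = float(c_j[vp_id])
            except KeyError as exc:
                raise KeyError(f"missing C_j for viewpoint {vp_id!r}") from exc
        mids = grp["fragment_id"].map(mid_by_frag).to_numpy()
        order = np.argsort(mids)
        mids = mids[order]
        vals = grp["norm"].to_numpy()[order]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.searchsorted(mids, wins["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, wins["end"].to_numpy(), side="left")
        w = wins.copy()
        w["xbar"] = (csum[hi] - csum[lo]) / cj
        for k, v in zip(group_cols, keys):
            w[k] = v
        out.append(w)
    if not out:
        raise ValueError("no windows matched the normalized counts")
    return pd.concat(out, ignore_index=True)


def call_interactions(
    windows: pd.DataFrame,
    decay: DecayModel,
    dispersion: DispersionModel,
    c_e: pd.Series | Mapping,
    width: int = WINDOW_WIDTH,
    bin_width: int = 2000,
) -> pd.DataFrame:
    """NB upper-tail p-value per window against the fitted null.

    mu = C_e * intercept * d**-delta, scaled proportionally if the window
    width differs from the bin width; beta = alpha*mu + k_disp clamped to
    >= 1.  Windows beyond the fitted distance domain are scored with the
    extrapolated mean and flagged.
    """
    calls = windows.copy()
    ce = calls["experiment"].map(dict(c_e) if not isinstance(c_e, pd.Series) else c_e)
    if ce.isna().any():
        raise KeyError("missing C_e for some experiments")
    mu = ce.to_numpy() * np.asarray(decay.predict(calls["d_model"].to_numpy()))
    mu = mu * (width / bin_width)
    beta = np.asarray(dispersion.beta(mu))
    calls["mu"] = mu
    calls["beta"] = beta
    calls["p"] = nb_upper_tail(calls["xbar"].to_numpy(), mu, beta)
    calls["extrapolated"] = calls["d_model"] > decay.n_bins
    return calls


def stratified_fdr(
    calls: pd.DataFrame,
    bin_width: int = 2000,
    min_stratum_size: int = 50,
) -> pd.DataFrame:
    """Benjamini-Hochberg within distance strata, pooled across probes.

    The stratum is the 2-kb distance-bin index of the window center.
    Strata smaller than ``min_stratum_size`` are merged with the next
    stratum outward before correction, to avoid degenerate BH in tiny
    strata.  Adds ``stratum`` and ``q`` columns; q-values within a stratum
    depend only on that stratum's p-values.
    """
    calls = calls.copy()
    calls["stratum"] = np.ceil(calls["d_model"].to_numpy()).astype(int)
    sizes = calls["stratum"].value_counts().sort_index()
    groups: list[list[int]] = []
    cur: list[int] = []
    acc = 0
    for stratum, n in sizes.items():
        cur.append(int(stratum))
        acc += int(n)
        if acc >= min_stratum_size:
            groups.append(cur)
            cur, acc = [], 0
    if cur:  # trailing small strata join the previous group
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    merged_label = {s: g[0] for g in groups for s in g}
    calls["stratum"] = calls["stratum"].map(merged_label)
    calls["q"] = np.nan
    for _, idx in calls.groupby("stratum").groups.items():
        p = calls.loc[idx, "p"].to_numpy()
        _, q, _, _ = multipletests(p, method="fdr_bh")
        calls.loc[idx, "q"] = q
    return calls


def merge_significant_regions(
    calls: pd.DataFrame,
    q_threshold: float = 0.05,
    group_cols: Iterable[str] = ("experiment", "viewpoint"),
) -> pd.DataFrame:
    """Merge runs of overlapping/abutting significant windows into maximal
    regions.  Region p (and q) is the minimum over its windows."""
    group_cols = list(group_cols)
    sig = calls[calls["q"] <= q_threshold]
    regions = []
    for keys, grp in sig.groupby(group_cols, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        grp = grp.sort_values(["chrom", "start"])
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["p"] = min(cur["p"], row.p)
                cur["q"] = min(cur["q"], row.q)
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": row.chrom, "start": int(row.start), "end": int(row.end),
                    "p": row.p, "q": row.q, "n_windows": 1,
                    **dict(zip(group_cols, keys)),
                }
        if cur is not None:
            regions.append(cur)
    cols = ["chrom", "start", "end"] + group_cols + ["p", "q", "n_windows"]
    frame = pd.DataFrame(regions, columns=cols)
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)
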