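"""Differential interaction testing between conditions or cell lines.

Significant regions from all conditions and replicates are merged into a
union set; every union region carries the probe-normalized counts from all
experiments, including those where it was not itself significant.  At each
region a negative-binomial GLM restricted to a single shared mean (null) is
compared with one fitting a mean per condition (alternative) by a
likelihood-ratio test; twice the log-likelihood difference is referred to a
chi-squared distribution with 1 degree of freedom.  The dispersion is fixed
from the pipeline's fitted linear mean-dispersion law rather than
re-estimated per region (few replicates make free dispersion
unidentifiable).  P-values are Benjamini-Hochberg adjusted across regions.

Cross-cell-line comparisons use counts pre-normalized by the cell-line
factors C_cl, which makes the test invariant to a global depth difference
between the cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .background import DispersionModel, _nb_loglik
from .fragmap import FragmentMap


def union_significant_regions(
    region_sets: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Union of significant regions across conditions and replicates.

    Overlapping or abutting regions (end of one = start of the next) are
    merged per (chrom, viewpoint).  Input region tables come from
    :func:`capcall.caller.merge_significant_regions`.
    """
    frames = [r for r in region_sets if r is not None and len(r)]
    if not frames:
        import warnings

        warnings.warn("no significant regions in any condition")
        return pd.DataFrame(columns=["chrom", "start", "end", "viewpoint"])
    allr = pd.concat(frames, ignore_index=True)
    out = []
    for (chrom, vp), grp in allr.groupby(["chrom", "viewpoint"], sort=False):
        grp = grp.sort_values("start")
        cur_start, cur_end = None, None
        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end = int(row.start), int(row.end)
            elif row.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, int(row.end))
            else:
                out.append((chrom, cur_start, cur_end, vp))
                cur_start, cur_end = int(row.start), int(row.end)
        if cur_start is not None:
            out.append((chrom, cur_start, cur_end, vp))
    frame = pd.DataFrame(out, columns=["chrom", "start", "end", "viewpoint"])
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


def region_counts(
    regions: pd.DataFrame,
    norm: pd.DataFrame,
    fragmap: FragmentMap,
    c_j: pd.Series | dict,
    c_cl: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-region, per-experiment probe-normalized counts.

    The region value is the sum of fragment-level normalized counts whose
    midpoints fall in the region (not a sum over overlapping windows, which
    would double-count), divided by the probe's C_j and, when ``c_cl`` is
    given, by the cell-line factor C_cl.
    """
    mid_by_frag = pd.Series(
        ((fragmap.frame["start"] + fragmap.frame["end"]) // 2).to_numpy(),
        index=fragmap.frame["fragment_id"].to_numpy(),
    )
    rows = []
    group_cols = ["cell_line", "experiment", "condition", "replicate", "viewpoint"]
    for keys, grp in norm.groupby(group_cols, sort=False):
        key = dict(zip(group_cols, keys))
        sub = regions[regions["viewpoint"] == key["viewpoint"]]
        if sub.empty:
            continue
        try:
            cj = float(c_j[(key["cell_line"], key["viewpoint"])])
        except (KeyError, TypeError):
            cj = float(c_j[key["viewpoint"]])
        ccl = 1.0
        if c_cl is not None:
            ccl = float(pd.Series(c_cl)[key["cell_line"]])
        mids = grp["fragment_id"].map(mid_by_frag).to_numpy()
        order = np.argsort(mids)
        mids = mids[order]
        csum = np.concatenate([[0.0], np.cumsum(grp["norm"].to_numpy()[order])])
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        vals = (csum[hi] - csum[lo]) / (cj * ccl)
        for (region_row, v) in zip(sub.itertuples(index=False), vals):
            rows.append({
                "chrom": region_row.chrom, "start": region_row.start,
                "end": region_row.end, "viewpoint": key["viewpoint"],
                **{k: key[k] for k in ("cell_line", "experiment", "condition", "replicate")},
                "value": v,
            })
    return pd.DataFrame(rows)


@dataclass
class DifferentialResult:
    chrom: str
    start: int
    end: int
    viewpoint: str
    mean_a: float
    mean_b: float
    fold: float
    lrt: float
    p: float


def _mle_mean(y: np.ndarray, dispersion: DispersionModel) -> tuple[float, float]:
    """1-D ML fit of a common NB mean under the fixed dispersion law.

    Returns (mu_hat, loglik).  The dispersion at the candidate mean follows
    beta(mu) = alpha*mu + k_disp, so the profile likelihood is optimized
    numerically on log(mu).
    """
    ybar = float(np.mean(y))
    if ybar <= 0:
        # all-zero observations: likelihood increases monotonically as mu -> 0
        mu = 1e-8
        return mu, _nb_loglik(y, np.full(len(y), mu), np.asarray(dispersion.beta(mu)) * np.ones(len(y)))

    def nll(logmu: float) -> float:
        mu = float(np.exp(logmu))
        beta = np.full(len(y), dispersion.beta(mu))
        return -_nb_loglik(y, np.full(len(y), mu), beta)

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(max(ybar, 1e-6)) - 8, np.log(max(ybar, 1e-6)) + 8),
        method="bounded", options={"xatol": 1e-10},
    )
    return float(np.exp(res.x)), float(-res.fun)


def lrt_differential(
    observations: pd.DataFrame,
    dispersion: DispersionModel,
    rounding: str = "floor",
) -> pd.DataFrame:
    """NB-GLM likelihood-ratio test per union region.

    ``observations`` has one row per (region, experiment) with columns
    chrom/start/end/viewpoint, ``condition`` and ``value`` (the region's
    probe-normalized count).  Values are rounded to integers (the NB
    response requires counts; ``rounding`` is "floor" or "round").  Exactly
    two conditions are required; the LRT statistic is invariant to their
    labels.
    """
    rounder = np.floor if rounding == "floor" else np.round
    results = []
    for (chrom, start, end, vp), grp in observations.groupby(
        ["chrom", "start", "end", "viewpoint"], sort=False
    ):
        conditions = sorted(grp["condition"].unique())
        if len(conditions) != 2:
            raise ValueError(
                f"region {chrom}:{start}-{end} needs exactly 2 conditions, "
                f"got {conditions}"
            )
        y_by_cond = {
            c: rounder(grp.loc[grp["condition"] == c, "value"].to_numpy(dtype=float))
            for c in conditions
        }
        for c, yc in y_by_cond.items():
            if len(yc) == 0:
                raise ValueError(
                    f"region {chrom}:{start}-{end}: no observations for {c!r}"
                )
        y_all = np.concatenate([y_by_cond[c] for c in conditions])
        _, ll_null = _mle_mean(y_all, dispersion)
        mu_a, ll_a = _mle_mean(y_by_cond[conditions[0]], dispersion)
        mu_b, ll_b = _mle_mean(y_by_cond[conditions[1]], dispersion)
        stat = max(0.0, 2.0 * (ll_a + ll_b - ll_null))
        p = float(stats.chi2.sf(stat, df=1))
        results.append({
            "chrom": chrom, "start": start, "end": end, "viewpoint": vp,
            "condition_a": conditions[0], "condition_b": conditions[1],
            "mean_a": mu_a, "mean_b": mu_b,
            "fold": mu_b / max(mu_a, 1e-12),
            "lrt": stat, "p": p,
        })
    return pd.DataFrame(results)


def differential_fdr(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Plain Benjamini-Hochberg across all union regions."""
    out = results.copy()
    if len(out) == 0:
        out["q"] = []
        out["significant"] = []
        return out
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] <= q_threshold
    return out
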