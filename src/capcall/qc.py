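"""Library QC and descriptive annotation of interaction calls.

Self-circle check: in a well-digested 3C library, random re-ligation makes
the four read-pair strand combinations equiprobable, so the ratios of
outward/same-strand and inward/same-strand pairs are both 0.5 at every
span.  Undigested self-circles are exclusively outward-oriented and
short-range, so an excess of outward pairs confined to short spans flags
them.

Annotation: interacting regions are classified by >= 1 bp overlap with
annotation interval sets (TSS, H3K4me1/H3K4me3/H3K27ac peaks, CTCF...),
summarized per viewpoint; distance histograms and GC/mappability
confounder comparisons are descriptive, not thresholded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .fragmap import Viewpoint


def orientation_ratios(
    pairs: pd.DataFrame,
    bin_edges: Sequence[int] = (0, 1000, 2000, 5000, 10_000, 50_000, 10**9),
    alert_threshold: float = 0.75,
    self_circle_span: int = 2000,
) -> pd.DataFrame:
    """Per-span-bin orientation counts and outward/same, inward/same ratios.

    Raises a self-circle ``alert`` on bins below ``self_circle_span`` whose
    outward/same ratio exceeds ``alert_threshold``.
    """
    if pairs.empty:
        raise ValueError("empty read-pair table")
    span = np.abs(pairs["distance"].to_numpy())
    idx = np.digitize(span, bin_edges[1:-1])
    rows = []
    for i in range(len(bin_edges) - 1):
        sel = pairs["orientation"].to_numpy()[idx == i]
        n_same = int((sel == "same").sum())
        n_in = int((sel == "inward").sum())
        n_out = int((sel == "outward").sum())
        out_same = n_out / n_same if n_same else np.inf if n_out else np.nan
        in_same = n_in / n_same if n_same else np.inf if n_in else np.nan
        rows.append({
            "span_lo": bin_edges[i], "span_hi": bin_edges[i + 1],
            "n_same": n_same, "n_inward": n_in, "n_outward": n_out,
            "outward_same": out_same, "inward_same": in_same,
            "alert": (
                bin_edges[i + 1] <= self_circle_span
                and n_same + n_in + n_out > 0
                and (out_same if np.isfinite(out_same) else np.inf) > alert_threshold
            ),
        })
    return pd.DataFrame(rows)


def _build_tree(intervals: pd.DataFrame) -> IntervalTree:
    tree = IntervalTree()
    for row in intervals.itertuples(index=False):
        if row.end > row.start:
            tree.addi(int(row.start), int(row.end))
    return tree


def classify_interacting_regions(
    regions: pd.DataFrame,
    annotations: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Overlap flags per region for each named annotation set.

    A flag is set iff the region overlaps >= 1 bp of an interval of that
    set (half-open coordinates).  Adds a boolean column per annotation name
    plus ``unannotated``.  Invariant to annotation ordering and to splitting
    intervals into adjacent pieces.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, table in annotations.items():
        trees[name] = {
            chrom: _build_tree(grp) for chrom, grp in table.groupby("chrom")
        }
    out = regions.copy()
    for name in annotations:
        flags = []
        for row in regions.itertuples(index=False):
            tree = trees[name].get(row.chrom)
            flags.append(bool(tree.overlap(int(row.start), int(row.end))) if tree else False)
        out[name] = flags
    ann_cols = list(annotations)
    out["unannotated"] = ~out[ann_cols].any(axis=1) if ann_cols else True
    return out


def classification_summary(
    classified: pd.DataFrame, annotation_names: Sequence[str]
) -> pd.DataFrame:
    """Per-viewpoint average number of interacting regions per class.

    Reports both tallies the "average sites per viewpoint" bar chart could
    mean: ``per_mark`` counts a region once per overlapping mark,
    ``any_mark`` counts regions with at least one mark once.
    """
    rows = []
    for vp, grp in classified.groupby("viewpoint"):
        row = {"viewpoint": vp, "n_regions": len(grp)}
        for name in annotation_names:
            row[name] = int(grp[name].sum())
        row["per_mark_total"] = int(sum(row[n] for n in annotation_names))
        row["any_mark"] = int(grp[list(annotation_names)].any(axis=1).sum())
        row["unannotated"] = int(grp["unannotated"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def distance_histogram(
    regions: pd.DataFrame,
    viewpoints: Sequence[Viewpoint],
    bin_width: int = 20_000,
) -> pd.DataFrame:
    """Histogram of |region center - viewpoint anchor|; totals conserve the
    region count for any bin width."""
    anchors = {v.viewpoint_id: v.anchor for v in viewpoints}
    centers = (regions["start"].to_numpy() + regions["end"].to_numpy()) / 2
    dist = np.abs(centers - regions["viewpoint"].map(anchors).to_numpy())
    if len(dist) == 0:
        return pd.DataFrame(columns=["dist_lo", "dist_hi", "count"])
    n_bins = int(np.floor(dist.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dist, bins=edges)
    return pd.DataFrame({
        "dist_lo": edges[:-1], "dist_hi": edges[1:], "count": counts,
    })


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def _region_gc(regions: pd.DataFrame, genome: Mapping[str, str]) -> np.ndarray:
    vals = []
    for row in regions.itertuples(index=False):
        seq = genome[row.chrom]
        if row.start < 0 or row.end > len(seq):
            raise ValueError(f"region {row.chrom}:{row.start}-{row.end} outside genome")
        vals.append(gc_fraction(seq[int(row.start):int(row.end)]))
    return np.asarray(vals)


def _region_track_mean(regions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    vals = []
    for row in regions.itertuples(index=False):
        sub = track[
            (track["chrom"] == row.chrom)
            & (track["end"] > row.start) & (track["start"] < row.end)
        ]
        if sub.empty:
            vals.append(np.nan)
            continue
        ov = np.minimum(sub["end"], row.end) - np.maximum(sub["start"], row.start)
        vals.append(float(np.average(sub["value"], weights=ov)))
    return np.asarray(vals)


def gc_mappability_compare(
    significant: pd.DataFrame,
    control: pd.DataFrame,
    genome: Mapping[str, str],
    mappability: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compare GC content (and optionally mean mappability) of significant
    regions against control regions with a two-sample rank test.

    Returns one row per metric with per-set means and the Mann-Whitney U
    statistic and p-value — reported, not thresholded.  When no mappability
    track is supplied, only GC is compared.
    """
    rows = []
    gc_sig = _region_gc(significant, genome)
    gc_ctl = _region_gc(control, genome)
    if np.array_equal(gc_sig, gc_ctl):
        stat, p = np.nan, 1.0
    else:
        stat, p = stats.mannwhitneyu(gc_sig, gc_ctl, alternative="two-sided")
    rows.append({
        "metric": "gc", "mean_significant": float(np.nanmean(gc_sig)),
        "mean_control": float(np.nanmean(gc_ctl)), "statistic": stat, "p": p,
    })
    if mappability is not None:
        m_sig = _region_track_mean(significant, mappability)
        m_ctl = _region_track_mean(control, mappability)
        ok_s, ok_c = m_sig[~np.isnan(m_sig)], m_ctl[~np.isnan(m_ctl)]
        if len(ok_s) and len(ok_c) and not np.array_equal(ok_s, ok_c):
            stat, p = stats.mannwhitneyu(ok_s, ok_c, alternative="two-sided")
        else:
            stat, p = np.nan, 1.0
        rows.append({
            "metric": "mappability", "mean_significant": float(np.nanmean(m_sig)),
            "mean_control": float(np.nanmean(m_ctl)), "statistic": stat, "p": p,
        })
    return pd.DataFrame(rows)


def sample_control_regions(
    significant: pd.DataFrame,
    viewpoints: Sequence[Viewpoint],
    n: int | None = None,
    max_distance: int = 500_000,
    width: int | None = None,
    seed: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Distance-matched non-significant control regions within
    ``max_distance`` of the bait sites, avoiding the significant set."""
    rng = np.random.default_rng(seed)
    n = n or len(significant)
    sig_tree: dict[str, IntervalTree] = {}
    for chrom, grp in significant.groupby("chrom"):
        sig_tree[chrom] = _build_tree(grp)
    widths = (significant["end"] - significant["start"]).to_numpy()
    rows = []
    attempts = 0
    while len(rows) < n and attempts < 50 * n:
        attempts += 1
        vp = viewpoints[int(rng.integers(0, len(viewpoints)))]
        w = int(width or widths[int(rng.integers(0, len(widths)))])
        offset = int(rng.integers(vp.exclusion_radius, max_distance))
        side = 1 if rng.integers(0, 2) else -1
        start = vp.anchor + side * offset - w // 2
        end = start + w
        if start < 0:
            continue
        if chrom_lengths and end > chrom_lengths.get(vp.chrom, np.inf):
            continue
        tree = sig_tree.get(vp.chrom)
        if tree is not None and tree.overlap(start, end):
            continue
        rows.append({"chrom": vp.chrom, "start": start, "end": end,
                     "viewpoint": vp.viewpoint_id})
    return pd.DataFrame(rows)
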