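"""Restriction fragment maps, count-table ingestion and BED/bedGraph output.

The coordinate backbone of the pipeline is the in-silico digest of a
reference genome with a restriction enzyme (DpnII, ``GATC``, by default).
Every downstream quantity — counts, bins, windows — is expressed on this
fragment grid.  All coordinates are 0-based half-open, BED-style.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_VALID_MOTIF = re.compile(r"^[ACGT]+$")

COUNT_TABLE_COLUMNS = [
    "experiment", "cell_line", "condition", "replicate",
    "viewpoint", "chrom", "start", "end", "count",
]


@dataclass(frozen=True)
class Viewpoint:
    """A capture probe: the restriction fragment targeted by capture oligos.

    ``anchor`` is the midpoint of the capture fragment; distances of all
    interactions are measured from it.  ``exclusion_radius`` removes the
    short-range zone dominated by undigested self-circles (< 2 kb).
    """

    viewpoint_id: str
    chrom: str
    anchor: int
    exclusion_radius: int = 2000

    def __post_init__(self) -> None:
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")


class FragmentMap:
    """Ordered restriction fragments per chromosome.

    Fragments tile each chromosome without gaps or overlaps; every internal
    boundary coincides with a recognition-site occurrence (cut placed at the
    first base of the motif, blunt convention).
    """

    def __init__(self, frame: pd.DataFrame, recognition_site: str = "GATC"):
        required = {"chrom", "start", "end", "fragment_id"}
        if not required.issubset(frame.columns):
            raise ValueError(f"fragment frame needs columns {sorted(required)}")
        self.frame = frame.reset_index(drop=True)
        self.recognition_site = recognition_site
        self._by_chrom = {c: g for c, g in self.frame.groupby("chrom", sort=False)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_digest(
        cls, sequences: Mapping[str, str], recognition_site: str = "GATC"
    ) -> "FragmentMap":
        """In-silico digest of named DNA sequences.

        Ambiguity codes and lowercase are tolerated in the sequence (matching
        is case-insensitive; non-ACGT letters never match the motif).
        """
        if not sequences:
            raise ValueError("no sequences supplied for digestion")
        site = recognition_site.upper()
        if not _VALID_MOTIF.match(site):
            raise ValueError(f"recognition site must be ACGT only, got {recognition_site!r}")
        records: list[tuple[str, int, int]] = []
        for chrom, seq in sequences.items():
            s = str(seq).upper()
            if len(s) == 0:
                raise ValueError(f"empty sequence for {chrom}")
            cuts = [m.start() for m in re.finditer(re.escape(site), s)]
            bounds = [0] + [c for c in cuts if 0 < c < len(s)] + [len(s)]
            bounds = sorted(set(bounds))
            for a, b in zip(bounds[:-1], bounds[1:]):
                records.append((chrom, a, b))
        frame = pd.DataFrame(records, columns=["chrom", "start", "end"])
        frame["fragment_id"] = np.arange(len(frame), dtype=np.int64)
        return cls(frame, site)

    @classmethod
    def from_boundaries(
        cls, boundaries: Mapping[str, Iterable[int]], lengths: Mapping[str, int],
        recognition_site: str = "GATC",
    ) -> "FragmentMap":
        """Build a map from explicit cut positions (used by the simulator)."""
        records = []
        for chrom, length in lengths.items():
            cuts = sorted({int(c) for c in boundaries.get(chrom, []) if 0 < c < length})
            bounds = [0] + cuts + [int(length)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                records.append((chrom, a, b))
        frame = pd.DataFrame(records, columns=["chrom", "start", "end"])
        frame["fragment_id"] = np.arange(len(frame), dtype=np.int64)
        return cls(frame, recognition_site)

    @classmethod
    def from_fasta(cls, path: str | Path, recognition_site: str = "GATC") -> "FragmentMap":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls.from_digest(seqs, recognition_site)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def widths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.frame["start"] + self.frame["end"]) // 2).to_numpy()

    def chrom_length(self, chrom: str) -> int:
        return int(self._by_chrom[chrom]["end"].max())

    def fragments_for(self, chrom: str) -> pd.DataFrame:
        return self._by_chrom[chrom]

    def containing(self, chrom: str, pos: int) -> pd.Series:
        """The fragment containing position ``pos`` (half-open)."""
        g = self._by_chrom[chrom]
        idx = np.searchsorted(g["start"].to_numpy(), pos, side="right") - 1
        row = g.iloc[idx]
        if not (row["start"] <= pos < row["end"]):
            raise KeyError(f"{chrom}:{pos} not covered by the fragment map")
        return row

    def to_bed(self, path: str | Path) -> None:
        self.frame.to_csv(
            path, sep="\t", header=False, index=False,
            columns=["chrom", "start", "end", "fragment_id"],
        )

    @classmethod
    def read_bed(cls, path: str | Path, recognition_site: str = "GATC") -> "FragmentMap":
        frame = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "fragment_id"],
        )
        return cls(frame, recognition_site)


@dataclass
class RawCounts:
    """Per (experiment, viewpoint, fragment) ligation-junction counts.

    Only cis records (fragment on the viewpoint's chromosome) are retained;
    ``n_trans_dropped`` logs how many rows the cis filter removed.
    ``totals`` is Y_j, the total captured interactions per (experiment,
    viewpoint) — the denominator of the depth normalization.
    """

    frame: pd.DataFrame
    n_trans_dropped: int = 0

    def __post_init__(self) -> None:
        if (self.frame["count"] < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def totals(self) -> pd.Series:
        return self.frame.groupby(["experiment", "viewpoint"], sort=False)["count"].sum()

    def __len__(self) -> int:
        return len(self.frame)


def read_count_table(
    path: str | Path,
    fragmap: FragmentMap,
    viewpoints: Iterable[Viewpoint],
) -> RawCounts:
    """Ingest a CCanalyser-style per-fragment count table (TSV with header).

    Columns: experiment, cell_line, condition, replicate, viewpoint, chrom,
    start, end, count.  Fragment coordinates must match the map exactly;
    rows on a chromosome different from their viewpoint's (trans junctions)
    are dropped and tallied.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (table["count"] < 0).any():
        bad = table.index[table["count"] < 0][0]
        raise ValueError(f"negative count at row {bad}")
    vp_chrom = {v.viewpoint_id: v.chrom for v in viewpoints}
    unknown = set(table["viewpoint"]) - set(vp_chrom)
    if unknown:
        raise ValueError(f"viewpoints absent from viewpoint table: {sorted(unknown)}")
    cis = table["chrom"] == table["viewpoint"].map(vp_chrom)
    n_trans = int((~cis).sum())
    if n_trans:
        log.info("dropped %d trans records at ingestion", n_trans)
    table = table[cis]
    merged = table.merge(
        fragmap.frame, on=["chrom", "start", "end"], how="left", validate="many_to_one"
    )
    if merged["fragment_id"].isna().any():
        row = merged[merged["fragment_id"].isna()].iloc[0]
        raise ValueError(
            "coordinates match no fragment: "
            f"{row['chrom']}:{row['start']}-{row['end']} (viewpoint {row['viewpoint']})"
        )
    merged["fragment_id"] = merged["fragment_id"].astype(np.int64)
    frame = merged[
        ["experiment", "cell_line", "condition", "replicate",
         "viewpoint", "fragment_id", "count"]
    ].copy()
    return RawCounts(frame, n_trans_dropped=n_trans)


def write_count_table(
    counts: RawCounts, fragmap: FragmentMap, path: str | Path
) -> None:
    """Inverse of :func:`read_count_table` (round-trip exact)."""
    out = counts.frame.merge(
        fragmap.frame[["fragment_id", "chrom", "start", "end"]], on="fragment_id"
    )
    out[COUNT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_viewpoint_table(path: str | Path) -> list[Viewpoint]:
    """TSV with header: viewpoint, chrom, anchor[, exclusion_radius]."""
    table = pd.read_csv(path, sep="\t")
    excl = table["exclusion_radius"] if "exclusion_radius" in table.columns else None
    vps = []
    for i, row in table.iterrows():
        vps.append(Viewpoint(
            viewpoint_id=str(row["viewpoint"]), chrom=str(row["chrom"]),
            anchor=int(row["anchor"]),
            exclusion_radius=int(excl.iloc[i]) if excl is not None else 2000,
        ))
    return vps


def write_viewpoint_table(viewpoints: Iterable[Viewpoint], path: str | Path) -> None:
    pd.DataFrame(
        [(v.viewpoint_id, v.chrom, v.anchor, v.exclusion_radius) for v in viewpoints],
        columns=["viewpoint", "chrom", "anchor", "exclusion_radius"],
    ).to_csv(path, sep="\t", index=False)


def _check_sorted(frame: pd.DataFrame) -> None:
    key = frame[["chrom", "start"]]
    if not key.equals(key.sort_values(["chrom", "start"]).reset_index(drop=True)):
        raise ValueError("records must be sorted by (chrom, start)")


def write_bedgraph(frame: pd.DataFrame, path: str | Path, name: str = "capcall_signal") -> None:
    """Write a (chrom, start, end, value) signal track as bedGraph."""
    _check_sorted(frame.reset_index(drop=True))
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", skiprows=1, header=None,
        names=["chrom", "start", "end", "value"],
    )


def write_calls_bed(calls: pd.DataFrame, path: str | Path, name: str = "capcall_regions") -> None:
    """Write significant regions as BED6: name = viewpoint, score = q-value."""
    _check_sorted(calls.reset_index(drop=True))
    with open(path, "w") as fh:
        fh.write(f'track name="{name}"\n')
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                f"{row.viewpoint}\t{row.q:.6g}\t.\n"
            )


def read_calls_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", skiprows=1, header=None,
        names=["chrom", "start", "end", "viewpoint", "q", "strand"],
    )
    return frame.drop(columns=["strand"])


def write_calls(calls: pd.DataFrame, path: str | Path, format: str = "BED") -> None:
    """Dispatch on output format: ``BED`` (regions) or ``bedGraph`` (signal)."""
    if format.lower() == "bed":
        write_calls_bed(calls, path)
    elif format.lower() == "bedgraph":
        write_bedgraph(calls, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Plain BED3+ reader for annotation interval sets (TSS, ChIP peaks...)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED at line {ln}: {line!r}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"malformed BED at line {ln}: {line!r}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
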