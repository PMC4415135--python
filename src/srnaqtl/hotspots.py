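"""Bin-level trait/QTL density tracks, hotspot calling and consecutive runs.

Density is items per Mb of bin; a bin is a hotspot when its density is
strictly greater than a multiplier times the genome-average density
(traits 3x, QTLs 6x, cluster traits 2x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinMap

MULTIPLIERS = {"trait": 3.0, "qtl": 6.0, "sc_trait": 2.0}


@dataclass
class DensityTrack:
    """Per-bin item counts and densities plus the genome average."""

    track: pd.DataFrame  # chrom, start, end, count, length_mb, density
    genome_average: float
    multiplier: float | None = None

    @property
    def flags(self) -> np.ndarray:
        if self.multiplier is None:
            raise ValueError("call hotspots first")
        return (
            self.track["density"].to_numpy()
            > self.multiplier * self.genome_average
        )


def density_per_bin(anchors: pd.DataFrame, binmap: BinMap) -> DensityTrack:
    """Count anchors (columns ``chrom``, ``position``) per containing bin.

    QTL items should be anchored at their peak-bin position. Anchors outside
    every bin raise, since bins tile the genome.
    """
    bins = binmap.bins
    counts = np.zeros(len(bins), dtype=np.int64)
    for chrom, sub in anchors.groupby("chrom", sort=False):
        sel = bins["chrom"] == chrom
        if not sel.any():
            raise ValueError(f"anchor on unknown chromosome {chrom}")
        b = bins[sel]
        starts = b["start"].to_numpy()
        ends = b["end"].to_numpy()
        pos = sub["position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        bad = (idx < 0) | (pos >= ends[np.clip(idx, 0, len(ends) - 1)])
        if bad.any():
            raise ValueError(
                f"anchor outside all bins at {chrom}:{pos[bad][0]}"
            )
        np.add.at(counts, b.index.to_numpy()[idx], 1)
    length_mb = (bins["end"] - bins["start"]).to_numpy() / 1e6
    track = bins.copy()
    track["count"] = counts
    track["length_mb"] = length_mb
    track["density"] = counts / length_mb
    genome_average = counts.sum() / length_mb.sum()
    return DensityTrack(track, genome_average)


def call_hotspots(track: DensityTrack, multiplier: float) -> DensityTrack:
    """Flag bins with density strictly above multiplier x genome average."""
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    out = DensityTrack(track.track.copy(), track.genome_average, multiplier)
    out.track["hotspot"] = out.flags
    return out


def consecutive_hotspots(track: DensityTrack) -> pd.DataFrame:
    """Maximal runs of adjacent hotspot bins on one chromosome.

    Returns one row per run: chrom, first/last bin index, bp span, n_bins.
    """
    t = track.track
    flags = track.flags
    rows = []
    run_start = None
    for i in range(len(t)):
        new_chrom = i > 0 and t["chrom"].iloc[i] != t["chrom"].iloc[i - 1]
        if run_start is not None and (not flags[i] or new_chrom):
            rows.append((run_start, i - 1))
            run_start = None
        if flags[i] and run_start is None:
            run_start = i
    if run_start is not None:
        rows.append((run_start, len(t) - 1))
    return pd.DataFrame(
        [
            {
                "chrom": t["chrom"].iloc[a],
                "first_bin": a,
                "last_bin": b,
                "start_bp": int(t["start"].iloc[a]),
                "end_bp": int(t["end"].iloc[b]),
                "n_bins": b - a + 1,
            }
            for a, b in rows
        ],
        columns=["chrom", "first_bin", "last_bin", "start_bp", "end_bp", "n_bins"],
    )


def hotspot_report(track: DensityTrack) -> pd.DataFrame:
    """Full per-bin report with run membership."""
    t = track.track.copy()
    t["genome_average"] = track.genome_average
    t["multiplier"] = track.multiplier
    runs = consecutive_hotspots(track)
    run_id = np.full(len(t), -1)
    for k, r in runs.iterrows():
        run_id[r["first_bin"] : r["last_bin"] + 1] = k
    t["run_id"] = run_id
    return t
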