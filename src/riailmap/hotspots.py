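"""QTL hotspot detection: empirical genetic map, equal-cM bins, Poisson threshold.

The genetic map is estimated directly from the recombinant panel: the cM
length of each adjacent-marker interval is 100 x the fraction of strains
whose calls switch across it (no map-function correction — the panel's switch
fractions already reflect the accumulated recombination of the intercross).
The genome is tiled with half-open equal-cM bins per chromosome; QTL peaks
are counted per bin, and a bin is a hotspot when its count exceeds the 99th
percentile of a Poisson distribution with mean lambda = total QTL / total
bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from riailmap.mapping import QTLRecord
from riailmap.sim import GenotypeMatrix


def estimate_genetic_map(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker cumulative cM positions from observed recombination events.

    Interval cM = 100 x (strains switching between the two adjacent markers)
    / (strains called at both); cumulative within chromosome from 0.  Returns
    the marker table with an ``est_cM`` column.
    """
    if geno.n_strains < 2:
        raise ValueError("need >= 2 strains")
    mk = geno.markers.copy()
    est = np.zeros(len(mk))
    for _, grp in mk.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = 0.0
        est[idx[0]] = 0.0
        for a, b in zip(idx[:-1], idx[1:]):
            ga, gb = geno.calls[:, a], geno.calls[:, b]
            ok = ~np.isnan(ga) & ~np.isnan(gb)
            if ok.sum() == 0:
                warnings.warn(f"no complete strains across interval ending at {mk.iloc[b]['marker']}; 0 cM")
                d = 0.0
            else:
                d = 100.0 * float((ga[ok] != gb[ok]).sum()) / int(ok.sum())
            pos += d
            est[b] = pos
    mk["est_cM"] = est
    return mk


@dataclass
class BinSet:
    """Equal-cM genome bins with QTL counts and hotspot flags."""

    bins: pd.DataFrame  # chrom, start_cM, end_cM, partial[, count, hotspot]
    bin_size_cM: float
    lam: float | None = None
    threshold: int | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def bin_genome(
    chrom_lengths: pd.Series | dict[str, float] | pd.DataFrame,
    bin_size_cM: float = 26.0,
) -> BinSet:
    """Tile each chromosome with half-open [start, end) bins of equal cM width.

    Accepts chromosome lengths directly, or a marker table with ``chrom`` and
    a cM column (``est_cM`` preferred, else ``pos_cM``) whose per-chromosome
    maximum is the length.  A terminal partial bin is kept and flagged.
    """
    if bin_size_cM <= 0:
        raise ValueError("bin size must be positive")
    if isinstance(chrom_lengths, pd.DataFrame):
        col = "est_cM" if "est_cM" in chrom_lengths.columns else "pos_cM"
        lengths = chrom_lengths.groupby("chrom", sort=False)[col].max()
    else:
        lengths = pd.Series(chrom_lengths)
    if lengths.empty:
        raise ValueError("empty map")
    rows = []
    for chrom, L in lengths.items():
        n_full = int(np.floor(L / bin_size_cM + 1e-9))
        edges = [i * bin_size_cM for i in range(n_full + 1)]
        if edges[-1] < L - 1e-9:
            edges.append(float(L))
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append(
                {
                    "chrom": chrom,
                    "start_cM": s,
                    "end_cM": e,
                    "partial": bool(e - s < bin_size_cM - 1e-9),
                }
            )
    return BinSet(pd.DataFrame(rows), bin_size_cM)


def poisson_hotspot_threshold(lam: float, percentile: float = 0.99) -> int:
    """Smallest integer q with Poisson CDF(q; lam) >= percentile."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    q = 0
    while poisson.cdf(q, lam) < percentile:
        q += 1
    return q


def detect_hotspots(
    qtls: list[QTLRecord] | pd.DataFrame,
    bins: BinSet,
    percentile: float = 0.99,
) -> BinSet:
    """Count QTL peaks per bin and flag bins exceeding the Poisson threshold.

    Each QTL's peak (chrom, cM) is assigned to the half-open bin containing
    it; peaks outside the binned territory are dropped with a warning.
    lambda = total assigned QTL / total bins; the hotspot rule is strict
    (count > q where q is the ``percentile`` Poisson quantile of lambda).
    """
    if isinstance(qtls, pd.DataFrame):
        peaks = qtls[["chrom", "peak_pos_cM"]]
    else:
        if not qtls:
            raise ValueError("need at least one QTL")
        peaks = pd.DataFrame(
            {"chrom": [q.chrom for q in qtls], "peak_pos_cM": [q.peak_pos_cM for q in qtls]}
        )
    df = bins.bins.copy()
    counts = np.zeros(len(df), dtype=int)
    dropped = 0
    for _, row in peaks.iterrows():
        on = df.index[df["chrom"] == row["chrom"]]
        pos = row["peak_pos_cM"]
        hit = None
        for b in on:
            last = b == on[-1]
            if df.at[b, "start_cM"] <= pos and (
                pos < df.at[b, "end_cM"] or (last and pos <= df.at[b, "end_cM"] + 1e-9)
            ):
                hit = b
                break
        if hit is None:
            dropped += 1
            continue
        counts[hit] += 1
    if dropped:
        warnings.warn(f"{dropped} QTL peak(s) outside the binned map; dropped")
    total = int(counts.sum())
    lam = total / len(df)
    q = poisson_hotspot_threshold(lam, percentile)
    df["count"] = counts
    df["hotspot"] = counts > q
    return BinSet(df, bins.bin_size_cM, lam=lam, threshold=q)


def hotspot_membership(
    qtls: list[QTLRecord],
    region: tuple[str, float, float],
) -> list[QTLRecord]:
    """QTL whose confidence interval overlaps a (chrom, start_cM, end_cM) region.

    Intervals are treated as half-open [start, end); a QTL whose CI spans the
    whole region is of course included.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError("empty region")
    out = []
    for q in qtls:
        if q.chrom != chrom:
            continue
        if max(q.ci_left_cM, start) < min(q.ci_right_cM, end):
            out.append(q)
    return out
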