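"""Replication-fork direction around oriented loci (tRNA genes) and a stall
score.

Profiles are transcription-oriented: offsets are measured from the locus
midpoint with positive offsets downstream of transcription, and the value at
each offset bin is the pooled fraction of forks moving codirectionally with
transcription (rightward forks, i.e. Crick fragments, for plus-strand loci;
after reflection, Watson for minus-strand loci).  Counts are pooled across
loci before taking the fraction because individual loci are shallow.

A replication barrier at a locus shows up as a drop in the codirectional
fraction at or after the locus midpoint; :func:`stall_score` summarises this
as mean(downstream) - mean(upstream), negative under stalling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import OriginTable
from .strand_coverage import StrandedCoverage


@dataclass
class DirectionProfile:
    offsets: np.ndarray      # bin-center offsets, transcription-oriented, bp
    fraction: np.ndarray     # codirectional-fork fraction; NaN on zero counts
    co_counts: np.ndarray    # pooled codirectional counts per bin
    total_counts: np.ndarray
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "fraction": self.fraction,
                             "n": self.total_counts})


def fork_direction_profile(cov: StrandedCoverage, loci: pd.DataFrame,
                           window: int = 5000,
                           bin_size: int = 200) -> DirectionProfile:
    """Pooled fork-direction profile around oriented loci.

    ``loci`` needs columns ``chrom, start, end, strand``; strand is the
    transcription direction.  Minus-strand loci are reflected (offsets
    negated, strands swapped) before pooling so transcription always points
    toward positive offsets.
    """
    if len(loci) == 0:
        raise ValidationError("empty locus list")
    if window < bin_size:
        raise ValidationError("window must be >= bin_size")
    if window % bin_size:
        raise ValidationError("bin_size must divide window")
    n_off = 2 * (window // bin_size)
    edges = np.arange(-window, window + bin_size, bin_size)
    co = np.zeros(n_off)
    tot = np.zeros(n_off)
    for row in loci.itertuples(index=False):
        chrom = row.chrom
        mid = (int(row.start) + int(row.end)) // 2
        length = cov.genome.length(chrom)
        for k in range(n_off):
            if row.strand == "+":
                lo, hi = mid + edges[k], mid + edges[k + 1]
            else:
                lo, hi = mid - edges[k + 1], mid - edges[k]
            if lo < 0 or hi > length:
                continue
            w, c = cov.counts_in(chrom, int(lo), int(hi))
            codir = c if row.strand == "+" else w
            co[k] += codir
            tot[k] += w + c
    with np.errstate(invalid="ignore"):
        frac = np.where(tot > 0, co / np.maximum(tot, 1e-300), np.nan)
    return DirectionProfile(offsets=(edges[:-1] + edges[1:]) // 2,
                            fraction=frac, co_counts=co, total_counts=tot,
                            n_loci=len(loci))


def stall_score(profile: DirectionProfile, flank: int = 2000) -> float:
    """mean(codirectional fraction over (0, +flank]) - mean over [-flank, 0).

    Negative values indicate a stalling signature at the locus.  Undefined
    bins are excluded; all-undefined flanks raise.
    """
    off = profile.offsets
    down = profile.fraction[(off > 0) & (off <= flank)]
    up = profile.fraction[(off < 0) & (off >= -flank)]
    down = down[~np.isnan(down)]
    up = up[~np.isnan(up)]
    if len(down) == 0 or len(up) == 0:
        raise ValidationError("no defined bins within the stall-score flanks")
    return float(down.mean() - up.mean())


def filter_origin_distal(loci: pd.DataFrame, origins: OriginTable,
                         min_distance: int = 10000) -> pd.DataFrame:
    """Keep loci whose midpoints lie at least ``min_distance`` from every
    origin midpoint (the origin-distal pre-selection for stall analysis)."""
    keep = []
    odf = origins.df
    for row in loci.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        near = odf[odf["chromosome"] == row.chrom]
        dist = np.abs(near["midpoint"].to_numpy() - mid)
        keep.append(len(dist) == 0 or dist.min() >= min_distance)
    return loci[np.asarray(keep)].reset_index(drop=True)
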