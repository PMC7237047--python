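"""S-phase copy-number processing: masking, normalization to G1, loess
smoothing, and meta-origin coverage.

Normalization pipeline (order fixed so the ratio is invariant to sequencing
depth): mask exclusion-list bins -> scale each sample to reads-per-million
-> divide each sample by its own median unmasked bin -> ratio = S / G1.
Bins with zero G1 coverage are masked.  Masked bins are NaN throughout and
are omitted from bedGraph output.

Smoothing is local linear (degree-1) regression with tricube weights over a
window of ``span_fraction`` x the chromosome's bin count, computed per
chromosome.  Masked bins carry no weight; the fit is reported only where at
least ``min_support`` unmasked bins fall inside the window.  Implemented
with FFT-free convolutions of the distance kernel against the masked moment
sequences, which makes the smoother exact for linear data and O(n * window).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import BinnedTrack, GenomeLayout
from .origin_efficiency import MetaProfile
from .genome_io import OriginTable


def mask_bins(track: BinnedTrack, exclusion: pd.DataFrame | None) -> BinnedTrack:
    """NaN-mask every bin overlapping an exclusion interval."""
    out = track.copy()
    if exclusion is None or len(exclusion) == 0:
        return out
    bs = track.bin_size
    for row in exclusion.itertuples(index=False):
        if row.chrom not in track.genome:
            raise ValidationError(f"exclusion on unknown chromosome {row.chrom!r}")
        b0 = int(row.start) // bs
        b1 = -(-int(row.end) // bs)
        out.values[row.chrom][b0:b1] = np.nan
    return out


def normalize_track(s_counts: BinnedTrack, g1_counts: BinnedTrack,
                    exclusion: pd.DataFrame | None = None) -> BinnedTrack:
    """Masked, depth- and median-normalized S/G1 copy-number ratio track."""
    if s_counts.bin_size != g1_counts.bin_size:
        raise ValidationError("S and G1 tracks use different bin sizes")
    if s_counts.genome.sizes != g1_counts.genome.sizes:
        raise ValidationError("S and G1 tracks use different genomes")
    s = mask_bins(s_counts, exclusion)
    g1 = mask_bins(g1_counts, exclusion)
    # G1-empty bins are unusable for the ratio
    for c in g1.genome.chromosomes:
        zero = g1.values[c] == 0
        g1.values[c][zero] = np.nan
        s.values[c][zero] = np.nan

    def _rpm_median(track: BinnedTrack) -> BinnedTrack:
        total = track.total()
        if not np.isfinite(total) or total <= 0:
            raise ValidationError("track has no unmasked signal")
        for c in track.genome.chromosomes:
            track.values[c] *= 1e6 / total
        med = np.nanmedian(track.flat())
        if med <= 0:
            raise ValidationError("median of unmasked bins is not positive")
        for c in track.genome.chromosomes:
            track.values[c] /= med
        return track

    s = _rpm_median(s)
    g1 = _rpm_median(g1)
    ratio = BinnedTrack.zeros(s.genome, s.bin_size, state="normalized")
    n_unmasked = 0
    for c in s.genome.chromosomes:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio.values[c] = s.values[c] / g1.values[c]
        n_unmasked += int(np.count_nonzero(~np.isnan(ratio.values[c])))
    if n_unmasked == 0:
        raise ValidationError("all bins masked after normalization")
    return ratio


def _loess_chrom(y: np.ndarray, half: int, min_support: int) -> np.ndarray:
    """Tricube-weighted local linear fit at every bin of one chromosome."""
    n = len(y)
    m = (~np.isnan(y)).astype(float)
    y0 = np.where(np.isnan(y), 0.0, y)
    k = np.arange(-half, half + 1)
    tri = (1 - (np.abs(k) / (half + 1)) ** 3) ** 3

    def conv(seq, kernel):
        return np.convolve(seq, kernel[::-1], mode="same")

    # weighted moments around each centre: offsets d = j - i
    w0 = conv(m, tri)
    w1 = conv(m, tri * k)          # sum w * d
    w2 = conv(m, tri * k * k)
    t0 = conv(m * y0, tri)
    t1 = conv(m * y0, tri * k)
    support = conv(m, np.ones_like(tri))

    det = w0 * w2 - w1 * w1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta0 = (w2 * t0 - w1 * t1) / det        # intercept at d = 0
    out = np.where((support >= min_support) & (det > 1e-12) & (w0 > 0),
                   beta0, np.nan)
    # degenerate windows (single distinct offset) fall back to weighted mean
    fallback = (support >= min_support) & ((det <= 1e-12) & (w0 > 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(fallback, t0 / np.where(w0 > 0, w0, 1.0), out)
    return out


def loess_smooth(track: BinnedTrack, span_fraction: float = 0.02,
                 min_support: int = 10) -> BinnedTrack:
    """Loess-smooth a normalized copy-number track, per chromosome."""
    if not 0 < span_fraction <= 1:
        raise ValidationError("span_fraction must lie in (0, 1]")
    if track.state not in ("normalized", "smoothed"):
        raise ValidationError("track must be normalized before smoothing")
    out = track.copy()
    out.state = "smoothed"
    for c in track.genome.chromosomes:
        y = track.values[c]
        window = max(int(round(span_fraction * len(y))), 3)
        half = max(window // 2, 1)
        out.values[c] = _loess_chrom(y, half, min_support)
    return out


def rebin_mean(track: BinnedTrack, new_bin: int) -> BinnedTrack:
    """Block-average a track to a coarser bin size (NaN-aware means)."""
    if new_bin % track.bin_size:
        raise ValidationError("new bin size must be a multiple of the old")
    factor = new_bin // track.bin_size
    out_vals = {}
    for c in track.genome.chromosomes:
        v = track.values[c]
        n_out = -(-len(v) // factor)
        padded = np.full(n_out * factor, np.nan)
        padded[:len(v)] = v
        blocks = padded.reshape(n_out, factor)
        good = ~np.isnan(blocks)
        n_good = good.sum(axis=1)
        sums = np.where(good, blocks, 0.0).sum(axis=1)
        out_vals[c] = np.where(n_good > 0, sums / np.maximum(n_good, 1), np.nan)
    return BinnedTrack(track.genome, new_bin, out_vals, track.state)


def meta_origin_coverage(track: BinnedTrack, origins: OriginTable,
                         window: int = 10000, smooth_bin: int = 1000,
                         t_rep_max: float | None = None,
                         complement: bool = False) -> MetaProfile:
    """Equal-weight mean copy-number ratio around origin midpoints.

    The ratio track is first block-averaged to ``smooth_bin`` ("smoothed to
    1 kb").  ``t_rep_max`` restricts to origins with T_rep below the
    threshold (the earliest-origin subset); ``complement=True`` takes the
    remaining origins instead.
    """
    if window < smooth_bin or window % smooth_bin:
        raise ValidationError("window must be a positive multiple of smooth_bin")
    odf = origins.df
    if t_rep_max is not None:
        sel = odf["t_rep"] < t_rep_max
        odf = odf[~sel.fillna(False)] if complement else odf[sel.fillna(False)]
    if len(odf) == 0:
        raise ValidationError("empty origin subset")
    coarse = rebin_mean(track, smooth_bin)
    n_off = 2 * (window // smooth_bin)
    offs = np.arange(-window, window, smooth_bin) + smooth_bin // 2
    sums = np.zeros(n_off)
    counts = np.zeros(n_off, dtype=int)
    for row in odf.itertuples(index=False):
        vals = coarse.values[row.chromosome]
        centre_bin = int(row.midpoint) // smooth_bin
        for k in range(n_off):
            b = centre_bin - window // smooth_bin + k
            if 0 <= b < len(vals) and not np.isnan(vals[b]):
                sums[k] += vals[b]
                counts[k] += 1
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaProfile(offsets=offs, values=values, n_origins=counts)
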