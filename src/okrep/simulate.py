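"""Stochastic whole-genome replication simulator with known ground truth.

Model
-----
Each simulated cell replicates its genome from a fixed set of licensed
origins.  Origin *i* is competent in a given cell with probability
``p_i * competence_scale`` and, if competent, draws a firing time from a
normal law ``N(mu_i, firing_sd)`` truncated at zero (``mu_i`` is the origin's
T_rep).  Forks move bidirectionally at constant speed ``v`` (bp/min) and a
position is replicated by the earliest-arriving fork.  Because fork speed is
constant, the earliest-arrival lower envelope over competent origins is
exactly equivalent to explicit passive suppression: an origin whose locus is
reached by a neighbouring fork before its own firing time is dominated
everywhere (triangle inequality) and never contributes a fork.

Lagging-strand synthesis: within each fork's territory the Okazaki-fragment
junction positions form a renewal process with exponential spacings of mean
``priming_mean / pol_alpha_level`` — the effective inter-priming distance set
by the available DNA polymerase alpha/primase.  With probability
``snap_prob`` a junction is relocated to the nearest nucleosome dyad plus
``N(0, snap_sd)`` noise, modelling chromatin-coupled positioning of fragment
termini.  Consecutive junctions tile each territory exactly; fragments in
leftward-fork territories map to the Watson strand, rightward to Crick.

Replication-fork barriers: each stall site arrests the first fork to reach
it with probability ``stall_prob`` (one draw per cell and site); an arrested
site becomes a hard boundary and the region beyond is replicated from the
other side.

Two Pol alpha knobs are deliberately separable: ``competence_scale``
multiplies every origin's firing competence (the origin-firing arm) while
``pol_alpha_level`` divides the priming rate (the lagging-strand arm), so
priming can be impaired at full origin firing and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .genome_io import (CRICK, WATSON, BinnedTrack, GenomeLayout, OkFragmentSet,
                        OriginTable)

LEFTWARD = -1
RIGHTWARD = 1
UNREPLICATED = 0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Full parameterisation of the replication simulator.

    Parameters
    ----------
    genome, origins:
        Genome layout and origin table.  ``origins.true_competence`` is the
        per-origin firing probability p_i; ``origins.t_rep`` is the mean
        firing time mu_i in minutes (missing values fall back to
        ``default_t_rep``).
    fork_speed:
        Replication fork speed, bp/min.
    priming_mean:
        Mean inter-priming distance (bp) on the lagging strand at
        ``pol_alpha_level`` 1.
    pol_alpha_level:
        Effective Pol alpha availability for lagging-strand priming in
        (0, 1]; the realised mean spacing is ``priming_mean / pol_alpha_level``.
    competence_scale:
        Scalar multiplying every origin competence (origin-firing arm of
        Pol alpha depletion).
    firing_sd:
        Cell-to-cell s.d. of origin firing times, minutes.
    snap_prob, snap_sd:
        Probability that a junction is relocated to the nearest nucleosome
        dyad, and the s.d. (bp) of the residual offset after relocation.
    dyads:
        Sorted dyad positions per chromosome (required when snap_prob > 0).
    stall_sites:
        DataFrame ``chrom, start, end, name, strand`` of replication-barrier
        loci (e.g. tRNA genes); ``stall_prob`` is the per-cell arrest
        probability at each site midpoint.
    n_cells, subsample_rate, seed:
        Library size controls; each fragment is kept independently with
        probability ``subsample_rate``.
    s_phase_duration:
        Length of S phase (minutes) used for "uniform" S-pool sampling.
    wgs_depth:
        Expected WGS reads per 100 bp bin per cell per copy.
    """

    genome: GenomeLayout
    origins: OriginTable
    fork_speed: float = 1500.0
    priming_mean: float = 165.0
    pol_alpha_level: float = 1.0
    competence_scale: float = 1.0
    firing_sd: float = 4.0
    snap_prob: float = 0.0
    snap_sd: float = 15.0
    dyads: dict[str, np.ndarray] | None = None
    stall_sites: pd.DataFrame | None = None
    stall_prob: float = 0.0
    n_cells: int = 1000
    s_phase_duration: float = 45.0
    subsample_rate: float = 1.0
    wgs_depth: float = 0.2
    default_t_rep: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.fork_speed <= 0:
            raise ConfigError("fork_speed must be > 0")
        if self.priming_mean <= 0 or self.pol_alpha_level <= 0:
            raise ConfigError("priming_mean and pol_alpha_level must be > 0")
        for name in ("snap_prob", "stall_prob", "competence_scale"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0 < self.subsample_rate <= 1:
            raise ConfigError("subsample_rate must lie in (0, 1]")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if self.snap_prob > 0 and self.dyads is None:
            raise ConfigError("snap_prob > 0 requires a dyad list")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def cell_rng(self, cell_index: int) -> np.random.Generator:
        """Independent, order-invariant stream for one cell."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(cell_index,))
        return np.random.default_rng(ss)

    def competences(self) -> np.ndarray:
        p = self.origins.df["true_competence"].to_numpy(dtype=float)
        p = np.where(np.isnan(p), 1.0, p)
        return np.clip(p * self.competence_scale, 0.0, 1.0)

    def mean_firing_times(self) -> np.ndarray:
        t = self.origins.df["t_rep"].to_numpy(dtype=float)
        return np.where(np.isnan(t), self.default_t_rep, t)


# ---------------------------------------------------------------------------
# Per-cell replication program
# ---------------------------------------------------------------------------

@dataclass
class ChromProgram:
    """Piecewise description of one chromosome's replication in one cell.

    ``bounds`` has len(n_segments)+1 breakpoints starting at 0 and ending at
    the chromosome length; segment k spans ``[bounds[k], bounds[k+1])`` and is
    replicated by a single fork: ``direction[k]`` is -1 (leftward fork,
    Watson lagging strand), +1 (rightward, Crick) or 0 (unreplicated);
    ``source_pos``/``source_time`` give the fired origin the fork came from,
    so the replication time at x is ``source_time + |x - source_pos| / v``.
    """

    bounds: np.ndarray
    direction: np.ndarray
    source_pos: np.ndarray
    source_time: np.ndarray


@dataclass
class ReplicationProgram:
    """One cell's genome-wide replication outcome."""

    genome: GenomeLayout
    fork_speed: float
    chroms: dict[str, ChromProgram]
    fired: dict[str, float]  # origin name -> firing time, actively fired only

    def _segment_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        cp = self.chroms[chrom]
        return np.clip(np.searchsorted(cp.bounds, pos, side="right") - 1,
                       0, len(cp.direction) - 1)

    def time_at(self, chrom: str, pos) -> np.ndarray:
        """Replication time (minutes) at positions; inf where unreplicated."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        cp = self.chroms[chrom]
        k = self._segment_index(chrom, pos)
        t = cp.source_time[k] + np.abs(pos - cp.source_pos[k]) / self.fork_speed
        return np.where(cp.direction[k] == UNREPLICATED, np.inf, t)

    def direction_at(self, chrom: str, pos) -> np.ndarray:
        """Fork direction at positions: -1 leftward, +1 rightward, 0 none."""
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        k = self._segment_index(chrom, pos)
        return self.chroms[chrom].direction[k]


def _envelope_segments(xs: np.ndarray, ts: np.ndarray, v: float,
                       lo: float, hi: float):
    """Earliest-arrival segments on [lo, hi) for fired origins at xs, times ts.

    Returns (bounds, direction, source_pos, source_time) with origins already
    reduced to the active set (those appearing in the lower envelope).
    """
    if len(xs) == 0:
        return (np.array([lo, hi]), np.array([UNREPLICATED]),
                np.array([np.nan]), np.array([np.inf]), np.array([], bool))
    order = np.argsort(xs, kind="stable")
    xs, ts = xs[order], ts[order]
    # arrival time at each origin from any other origin
    n = len(xs)
    active = np.ones(n, dtype=bool)
    # left-to-right and right-to-left scans of min(t_k + (x_j - x_k)/v)
    best_left = np.full(n, np.inf)
    cur = np.inf
    for j in range(n):
        if j > 0:
            cur += (xs[j] - xs[j - 1]) / v
        best_left[j] = cur
        cur = min(cur, ts[j])
    best_right = np.full(n, np.inf)
    cur = np.inf
    for j in range(n - 1, -1, -1):
        if j < n - 1:
            cur += (xs[j + 1] - xs[j]) / v
        best_right[j] = cur
        cur = min(cur, ts[j])
    arrival_other = np.minimum(best_left, best_right)
    active = ts <= arrival_other
    xa, ta = xs[active], ts[active]

    bounds = [lo]
    direction, source_pos, source_time = [], [], []
    for j in range(len(xa)):
        if j == 0:
            left_edge = lo
        else:
            # collision with previous active origin
            left_edge = 0.5 * (xa[j - 1] + xa[j]) + 0.5 * v * (ta[j] - ta[j - 1])
            left_edge = min(max(left_edge, xa[j - 1]), xa[j])
        if j > 0:
            bounds.append(left_edge)
            direction.append(RIGHTWARD)
            source_pos.append(xa[j - 1])
            source_time.append(ta[j - 1])
        # leftward territory of origin j: from left_edge to xa[j]
        bounds.append(xa[j])
        direction.append(LEFTWARD)
        source_pos.append(xa[j])
        source_time.append(ta[j])
    # final rightward territory to hi
    bounds.append(hi)
    direction.append(RIGHTWARD)
    source_pos.append(xa[-1])
    source_time.append(ta[-1])

    bounds = np.asarray(bounds, dtype=float)
    keep = np.diff(bounds) > 0
    order_map = (np.asarray(direction)[keep], np.asarray(source_pos, dtype=float)[keep],
                 np.asarray(source_time, dtype=float)[keep])
    return (np.concatenate([bounds[:-1][keep], bounds[-1:]]),) + order_map + (active,)


def simulate_cell(config: SimConfig, rng: np.random.Generator) -> ReplicationProgram:
    """Simulate one cell's replication program.

    Cells in which no origin fires anywhere are rejected and redrawn
    (conditioning on genome replication, as in any viable sampled cell);
    a genome with all competences zero raises immediately.
    """
    p = config.competences()
    if not np.any(p > 0):
        raise ConfigError("unreplicatable genome: all origin competences are 0")
    mu = config.mean_firing_times()
    odf = config.origins.df
    v = config.fork_speed

    for _attempt in range(10000):
        competent = rng.random(len(p)) < p
        if not competent.any():
            continue
        times = mu + config.firing_sd * rng.standard_normal(len(mu))
        # truncate at zero by redrawing the negative draws
        bad = competent & (times < 0)
        while bad.any():
            times[bad] = mu[bad] + config.firing_sd * rng.standard_normal(int(bad.sum()))
            bad = competent & (times < 0)

        chroms: dict[str, ChromProgram] = {}
        fired: dict[str, float] = {}
        any_active = False
        for chrom in config.genome.chromosomes:
            length = float(config.genome.length(chrom))
            sel = (odf["chromosome"] == chrom).to_numpy() & competent
            xs = odf["midpoint"].to_numpy(dtype=float)[sel]
            ts = times[sel]
            names = odf["name"].to_numpy()[sel]

            # arrested barriers partition the chromosome
            cuts = [0.0, length]
            if config.stall_sites is not None and config.stall_prob > 0:
                ss = config.stall_sites
                sub = ss[ss["chrom"] == chrom]
                mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(float)
                arrested = rng.random(len(mids)) < config.stall_prob
                cuts.extend(sorted(mids[arrested]))
            cuts = np.unique(np.asarray(cuts, dtype=float))

            all_bounds, all_dir, all_sp, all_st = [], [], [], []
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                inside = (xs >= lo) & (xs < hi)
                seg = _envelope_segments(xs[inside], ts[inside], v, lo, hi)
                bounds, direction, sp, st, active = seg
                if len(all_bounds) == 0:
                    all_bounds.append(bounds)
                else:
                    all_bounds.append(bounds[1:])
                all_dir.append(direction)
                all_sp.append(sp)
                all_st.append(st)
                for nm, tt in zip(np.asarray(names)[inside][active],
                                  ts[inside][active]):
                    fired[str(nm)] = float(tt)
                    any_active = True
            chroms[chrom] = ChromProgram(
                np.concatenate(all_bounds), np.concatenate(all_dir),
                np.concatenate(all_sp), np.concatenate(all_st))
        if any_active:
            return ReplicationProgram(config.genome, v, chroms, fired)
    raise ConfigError("rejected 10000 consecutive cells with no fired origin")


# ---------------------------------------------------------------------------
# Fragments from a replication program
# ---------------------------------------------------------------------------

def _snap_to_dyads(pos: np.ndarray, dyads: np.ndarray, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Relocate positions to their nearest dyad plus N(0, sd) noise."""
    idx = np.searchsorted(dyads, pos)
    left = np.clip(idx - 1, 0, len(dyads) - 1)
    right = np.clip(idx, 0, len(dyads) - 1)
    nearest = np.where(np.abs(pos - dyads[left]) <= np.abs(dyads[right] - pos),
                       dyads[left], dyads[right])
    return nearest + (sd * rng.standard_normal(len(pos)) if sd > 0 else 0.0)


def fragments_from_cell(program: ReplicationProgram, config: SimConfig,
                        rng: np.random.Generator) -> OkFragmentSet:
    """Generate this cell's Okazaki fragments, tiling every replicated base.

    Every position is lagging-strand on exactly one strand (set by the local
    fork direction), so the emitted fragments cover each replicated base
    exactly once.
    """
    rate = config.pol_alpha_level / config.priming_mean
    chrom_col, start_col, end_col, strand_col = [], [], [], []
    for chrom in program.genome.chromosomes:
        cp = program.chroms[chrom]
        length = program.genome.length(chrom)
        # exponential renewal == Poisson process; draw once per chromosome,
        # territory boundaries cut the process without changing its law
        n = rng.poisson(rate * length)
        junc = np.sort(rng.uniform(0, length, n))
        if config.snap_prob > 0 and len(junc):
            dyads = config.dyads.get(chrom) if config.dyads else None
            if dyads is not None and len(dyads):
                snap = rng.random(len(junc)) < config.snap_prob
                moved = _snap_to_dyads(junc[snap], np.asarray(dyads, float),
                                       config.snap_sd, rng)
                # keep each junction inside its own fork territory
                terr = np.clip(np.searchsorted(cp.bounds, junc[snap], side="right") - 1,
                               0, len(cp.direction) - 1)
                lo = cp.bounds[terr] + 1.0
                hi = cp.bounds[terr + 1] - 1.0
                junc = junc.copy()
                junc[snap] = np.where(lo <= hi, np.clip(moved, lo, hi), junc[snap])
                junc.sort()

        breaks = np.unique(np.concatenate([cp.bounds, junc]))
        breaks = np.floor(breaks).astype(np.int64)
        breaks = np.unique(np.clip(breaks, 0, length))
        if breaks[0] != 0:
            breaks = np.concatenate([[0], breaks])
        if breaks[-1] != length:
            breaks = np.concatenate([breaks, [length]])
        starts, ends = breaks[:-1], breaks[1:]
        mids = (starts + ends) / 2.0
        terr = np.clip(np.searchsorted(cp.bounds, mids, side="right") - 1,
                       0, len(cp.direction) - 1)
        direction = cp.direction[terr]
        keep = direction != UNREPLICATED
        starts, ends, direction = starts[keep], ends[keep], direction[keep]
        chrom_col.append(np.full(len(starts), chrom, dtype=object))
        start_col.append(starts)
        end_col.append(ends)
        strand_col.append(np.where(direction == LEFTWARD, WATSON, CRICK))

    if not chrom_col:
        return OkFragmentSet.empty(program.genome)
    return OkFragmentSet.from_arrays(
        np.concatenate(chrom_col), np.concatenate(start_col),
        np.concatenate(end_col), np.concatenate(strand_col),
        genome=program.genome, validate=False)


# ---------------------------------------------------------------------------
# Pooled libraries
# ---------------------------------------------------------------------------

def iter_cells(config: SimConfig):
    """Yield (cell_index, program, fragments) with per-cell reproducible RNG."""
    for i in range(config.n_cells):
        rng = config.cell_rng(i)
        program = simulate_cell(config, rng)
        frags = fragments_from_cell(program, config, rng)
        if config.subsample_rate < 1.0:
            keep = rng.random(len(frags)) < config.subsample_rate
            frags = OkFragmentSet(frags.df[keep], genome=config.genome,
                                  validate=False)
        yield i, program, frags


def simulate_okseq_library(config: SimConfig,
                           include_cell_id: bool = False) -> OkFragmentSet:
    """Pool Okazaki fragments over ``n_cells`` cells into one library."""
    parts = []
    for i, _program, frags in iter_cells(config):
        df = frags.df
        if include_cell_id:
            df = df.assign(name=f"cell{i}")
        parts.append(df)
    if not parts:
        return OkFragmentSet.empty(config.genome)
    return OkFragmentSet(pd.concat(parts, ignore_index=True),
                         genome=config.genome, validate=False)


def true_efficiency(config: SimConfig, programs=None) -> pd.Series:
    """Fraction of cells in which each origin fires actively (ground truth)."""
    names = config.origins.names()
    counts = dict.fromkeys(names, 0)
    n = 0
    if programs is None:
        programs = (p for _i, p, _f in iter_cells(config))
    for program in programs:
        n += 1
        for nm in program.fired:
            counts[nm] += 1
    if n == 0:
        raise ConfigError("no cells simulated")
    return pd.Series({nm: counts[nm] / n for nm in names}, name="true_efficiency")


def simulate_okseq_counts(config: SimConfig, bin_size: int = 100):
    """Simulate a pooled library directly into binned stranded midpoint counts.

    Memory-friendly path for large ``n_cells``: fragments are never pooled in
    memory.  Returns ``(StrandedCoverage, true_efficiency Series)``.
    """
    from .strand_coverage import StrandedCoverage

    cov = StrandedCoverage.zeros(config.genome, bin_size, mode="midpoint")
    names = config.origins.names()
    counts = dict.fromkeys(names, 0)
    n = 0
    for _i, program, frags in iter_cells(config):
        n += 1
        for nm in program.fired:
            counts[nm] += 1
        cov.add_fragments(frags)
    eff = pd.Series({nm: counts[nm] / max(n, 1) for nm in names},
                    name="true_efficiency")
    return cov, eff


# ---------------------------------------------------------------------------
# WGS-style pools
# ---------------------------------------------------------------------------

def simulate_wgs_pool(config: SimConfig, sampling_times="uniform",
                      bin_size: int = 100):
    """Simulate binned WGS read counts for an S-phase pool and a G1 control.

    Each cell is frozen at a sampled time t; the copy number at x is 2 if x
    is replicated by t, else 1.  Bin counts are Poisson with mean
    ``wgs_depth x copy`` per cell; the G1 control has copy 1 everywhere.
    ``sampling_times`` is "uniform" (uniform over [0, s_phase_duration]), a
    scalar, or an array of per-cell times.
    """
    genome = config.genome
    rng_master = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2**31,)))
    if isinstance(sampling_times, str):
        if sampling_times != "uniform":
            raise ConfigError(f"unknown sampling_times {sampling_times!r}")
        times = rng_master.uniform(0, config.s_phase_duration, config.n_cells)
    else:
        times = np.broadcast_to(np.asarray(sampling_times, dtype=float),
                                (config.n_cells,)).copy()
    if np.any(times < 0):
        raise ConfigError("sampling times must be >= 0")

    expected = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chromosomes}
    mids = {c: np.arange(genome.n_bins(c, bin_size)) * bin_size + bin_size / 2
            for c in genome.chromosomes}
    for i in range(config.n_cells):
        rng = config.cell_rng(i)
        program = simulate_cell(config, rng)
        t = times[i]
        for c in genome.chromosomes:
            rep = program.time_at(c, mids[c]) <= t
            expected[c] += 1.0 + rep

    s_track = BinnedTrack.zeros(genome, bin_size)
    g1_track = BinnedTrack.zeros(genome, bin_size)
    for c in genome.chromosomes:
        s_track.values[c] = rng_master.poisson(
            config.wgs_depth * expected[c]).astype(float)
        g1_track.values[c] = rng_master.poisson(
            config.wgs_depth * 1.0 * config.n_cells,
            size=len(expected[c])).astype(float)
    return s_track, g1_track
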