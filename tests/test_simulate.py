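"""Replication-simulator correctness: kinetics, fragments, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest

import okrep
from okrep import ConfigError, SimConfig, simulate_cell, simulate_okseq_library
from okrep.simulate import fragments_from_cell

from conftest import multi_origin_config, single_origin_config


class TestSimulateCell:
    def test_single_origin_time_and_direction(self):
        # fork from 50 kb moving left at 1000 bp/min reaches 20 kb at t=30
        cfg = single_origin_config(t_rep=0.0, fork_speed=1000.0)
        prog = simulate_cell(cfg, cfg.cell_rng(0))
        assert prog.time_at("chrI", 20_000)[0] == pytest.approx(30.0)
        assert prog.direction_at("chrI", 20_000)[0] == -1
        assert prog.direction_at("chrI", 80_000)[0] == 1

    def test_two_origin_collision_against_brute_force(self):
        # brute-force earliest-arrival over a grid as independent oracle
        mids, times, v = [25_000, 75_000], [3.0, 1.0], 1500.0
        cfg = multi_origin_config(mids, [1, 1], times, length=100_000,
                                  fork_speed=v)
        prog = simulate_cell(cfg, cfg.cell_rng(0))
        grid = np.arange(500, 100_000, 997)
        arrivals = np.stack([t + np.abs(grid - m) / v
                             for m, t in zip(mids, times)])
        expect_t = arrivals.min(axis=0)
        winner = arrivals.argmin(axis=0)
        expect_dir = np.where(grid < np.asarray(mids)[winner], -1, 1)
        assert np.allclose(prog.time_at("chrI", grid), expect_t)
        ties = np.isclose(arrivals[0], arrivals[1])
        assert np.array_equal(prog.direction_at("chrI", grid)[~ties],
                              expect_dir[~ties])

    def test_all_zero_competence_is_unreplicatable(self):
        cfg = single_origin_config(competence=0.0)
        with pytest.raises(ConfigError):
            simulate_cell(cfg, cfg.cell_rng(0))

    def test_passive_suppression_matches_enumeration(self):
        """3-origin truth: simulator efficiencies match exhaustive enumeration
        of competence outcomes under deterministic firing times."""
        mids = [50_000, 80_000, 110_000]
        ps = [0.6, 0.5, 0.3]
        ts = [10.0, 25.0, 12.0]   # middle origin often passively replicated
        v = 1500.0

        def active_set(competent):
            idx = [i for i in range(3) if competent[i]]
            return {i for i in idx
                    if all(ts[i] <= ts[j] + abs(mids[i] - mids[j]) / v
                           for j in idx if j != i)}

        num = np.zeros(3)
        denom = 0.0
        for comp in itertools.product([0, 1], repeat=3):
            w = np.prod([p if c else 1 - p for p, c in zip(ps, comp)])
            if not any(comp):
                continue  # rejected cells are redrawn
            denom += w
            for i in active_set(comp):
                num[i] += w
        expected = num / denom

        cfg = multi_origin_config(mids, ps, ts, length=160_000, fork_speed=v,
                                  n_cells=4000, seed=5)
        eff = okrep.true_efficiency(cfg)
        assert np.allclose(eff.to_numpy(), expected, atol=0.03)

    def test_efficiency_monotone_in_neighbor_competence(self):
        """Raising a neighbour's competence can only lower the others'
        true efficiency (exhaustive enumeration, no sampling noise)."""
        mids, ts, v = [50_000, 80_000, 110_000], [10.0, 25.0, 12.0], 1500.0

        def enum_eff(ps):
            def active_set(comp):
                idx = [i for i in range(3) if comp[i]]
                return {i for i in idx
                        if all(ts[i] <= ts[j] + abs(mids[i] - mids[j]) / v
                               for j in idx if j != i)}
            num, denom = np.zeros(3), 0.0
            for comp in itertools.product([0, 1], repeat=3):
                if not any(comp):
                    continue
                w = np.prod([p if c else 1 - p for p, c in zip(ps, comp)])
                denom += w
                for i in active_set(comp):
                    num[i] += w
            return num / denom

        for bumped in range(3):
            lo = enum_eff([0.4, 0.4, 0.4])
            hi_ps = [0.4, 0.4, 0.4]
            hi_ps[bumped] = 0.9
            hi = enum_eff(hi_ps)
            for other in range(3):
                if other != bumped:
                    assert hi[other] <= lo[other] + 1e-12

    def test_stall_barrier_splits_replication(self):
        loci = pd.DataFrame([{"chrom": "chrI", "start": 59_900, "end": 60_100,
                              "name": "t0", "strand": "+"}])
        cfg = multi_origin_config([30_000, 90_000], [1, 1], [5.0, 15.0],
                                  length=120_000, stall_prob=1.0)
        cfg = cfg.with_(stall_sites=loci)
        prog = simulate_cell(cfg, cfg.cell_rng(0))
        # without the barrier the early left fork would sweep to ~67.5 kb;
        # arrested at 60 kb, the region beyond is replicated leftward instead
        assert prog.direction_at("chrI", 61_000)[0] == -1
        assert prog.direction_at("chrI", 59_000)[0] == 1
        assert prog.time_at("chrI", 61_000)[0] == pytest.approx(
            15.0 + 29_000 / 1500.0)


class TestFragments:
    def test_leftward_territory_emits_watson(self):
        cfg = single_origin_config(t_rep=0.0, n_cells=1)
        prog = simulate_cell(cfg, cfg.cell_rng(0))
        frags = fragments_from_cell(prog, cfg, cfg.cell_rng(0))
        df = frags.df
        left = df[df["end"] <= 50_000]
        right = df[df["start"] >= 50_000]
        assert (left["strand"] == "+").all()
        assert (right["strand"] == "-").all()

    def test_fragments_tile_chromosome_exactly(self):
        cfg = single_origin_config(t_rep=0.0, snap_prob=0.9,
                                   dyads={"chrI": np.arange(82, 100_000, 165)})
        prog = simulate_cell(cfg, cfg.cell_rng(3))
        frags = fragments_from_cell(prog, cfg, cfg.cell_rng(3))
        df = frags.canonical()
        assert df["start"].iloc[0] == 0
        assert df["end"].iloc[-1] == 100_000
        assert (df["start"].iloc[1:].to_numpy()
                == df["end"].iloc[:-1].to_numpy()).all()

    def test_snapped_junctions_sit_on_dyads(self):
        dyads = {"chrI": np.arange(82, 100_000, 165, dtype=np.int64)}
        cfg = single_origin_config(t_rep=0.0, snap_prob=1.0, snap_sd=0.0,
                                   dyads=dyads)
        prog = simulate_cell(cfg, cfg.cell_rng(1))
        frags = fragments_from_cell(prog, cfg, cfg.cell_rng(1))
        df = frags.canonical()
        internal = df["start"].to_numpy()[1:]
        # junctions: internal boundaries except the origin/territory edges
        special = {0, 50_000, 100_000}
        junctions = np.array([b for b in internal if b not in special])
        on_dyad = np.isin(junctions, dyads["chrI"])
        assert on_dyad.mean() > 0.999

    def test_halving_pol_alpha_doubles_mean_length(self):
        means = {}
        for lvl, seed in [(1.0, 11), (0.5, 12)]:
            cfg = single_origin_config(t_rep=0.0, pol_alpha_level=lvl,
                                       n_cells=4, seed=seed)
            lib = simulate_okseq_library(cfg)
            means[lvl] = lib.lengths().mean()
        assert means[0.5] / means[1.0] == pytest.approx(2.0, rel=0.08)


class TestLibrary:
    def test_zero_cells_empty_library(self):
        cfg = single_origin_config(n_cells=0)
        assert len(simulate_okseq_library(cfg)) == 0

    def test_base_coverage_conservation(self):
        cfg = single_origin_config(length=60_000, midpoint=30_000,
                                   firing_sd=4.0, n_cells=25, seed=9)
        lib = simulate_okseq_library(cfg)
        cov = np.zeros(60_000, dtype=int)
        for s, e in zip(lib.df["start"], lib.df["end"]):
            cov[s:e] += 1
        assert (cov == 25).all()

    def test_seed_determinism_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            cfg = single_origin_config(firing_sd=4.0, competence=0.8,
                                       n_cells=10, seed=42)
            p = tmp_path / f"r{run}.bed"
            okrep.write_fragments(simulate_okseq_library(cfg), p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_subsampling_thins_library(self):
        full = simulate_okseq_library(single_origin_config(n_cells=10, seed=3))
        thin = simulate_okseq_library(
            single_origin_config(n_cells=10, seed=3, subsample_rate=0.25))
        assert 0.15 < len(thin) / len(full) < 0.35


class TestWgsPool:
    def test_time_zero_pool_matches_g1(self):
        cfg = single_origin_config(n_cells=300, seed=7, wgs_depth=2.0)
        s, g1 = okrep.simulate_wgs_pool(cfg, 0.0, bin_size=1000)
        ratio = s.flat().sum() / g1.flat().sum()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_copy_number_matches_analytic_integral(self):
        """Uniform sampling over [0, T]: expected relative copy at distance d
        from an always-on origin is 1 + max(0, 1 - d/(vT))."""
        v, T = 1500.0, 20.0
        cfg = single_origin_config(midpoint=50_000, length=100_000, t_rep=0.0,
                                   fork_speed=v, n_cells=3000, seed=13,
                                   s_phase_duration=T, wgs_depth=5.0)
        s, g1 = okrep.simulate_wgs_pool(cfg, "uniform", bin_size=1000)
        mids = np.arange(100) * 1000 + 500
        d = np.abs(mids - 50_000)
        expect = 1 + np.clip(1 - d / (v * T), 0, None)
        measured = s.values["chrI"] / (g1.values["chrI"].mean())
        assert np.allclose(measured, expect, rtol=0.05, atol=0.05)

    def test_wgs_seed_determinism(self):
        cfg = single_origin_config(n_cells=50, seed=21, firing_sd=3.0)
        a = okrep.simulate_wgs_pool(cfg, "uniform", bin_size=1000)
        b = okrep.simulate_wgs_pool(cfg, "uniform", bin_size=1000)
        assert np.array_equal(a[0].flat(), b[0].flat())
        assert np.array_equal(a[1].flat(), b[1].flat())
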