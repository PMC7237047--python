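"""OEM definition, exact geometries, meta profiles, group tests, replicates."""

import numpy as np
import pandas as pd
import pytest

import okrep
from okrep import (GenomeLayout, OkFragmentSet, OriginTable, ValidationError,
                   meta_origin_profile, oem, oem_table, replicate_correlation,
                   split_and_compare)
from okrep.origin_efficiency import average_oem_tables, oem_summary
from okrep.simulate import simulate_cell
from okrep.strand_coverage import (coverage_from_program, pool_coverages,
                                   stranded_counts)

from conftest import multi_origin_config, single_origin_config


def _program_cov(cfg, bin_size=100):
    prog = simulate_cell(cfg, cfg.cell_rng(0))
    return coverage_from_program(prog, bin_size)


class TestOemExactGeometries:
    def test_isolated_always_firing_origin_oem_1(self):
        cfg = single_origin_config(t_rep=10.0)
        rec = oem(_program_cov(cfg), "chrI", 50_000)
        assert rec.oem == pytest.approx(1.0, abs=1e-12)

    def test_uniform_fork_direction_oem_0(self):
        # locus swept by a rightward fork from a distant origin
        cfg = single_origin_config(midpoint=10_000, length=200_000, t_rep=5.0)
        rec = oem(_program_cov(cfg), "chrI", 120_000)
        assert rec.oem == pytest.approx(0.0, abs=1e-12)

    def test_two_synchronous_origins_10kb_apart_oem_half(self):
        cfg = multi_origin_config([100_000, 110_000], [1, 1], [10.0, 10.0],
                                  length=220_000)
        rec = oem(_program_cov(cfg), "chrI", 100_000)
        assert rec.oem == pytest.approx(0.5, abs=1e-12)

    def test_partially_firing_origin_oem_equals_firing_fraction(self):
        """f = 0.6: pool the two deterministic cell classes analytically."""
        f = 0.6
        # class 1: focal origin fires together with a distant left anchor
        both = multi_origin_config([20_000, 120_000], [1, 1], [10.0, 10.0],
                                   length=240_000)
        # class 2: focal origin passive, swept rightward by the anchor fork
        solo = multi_origin_config([20_000], [1], [10.0], length=240_000)
        cov = pool_coverages(
            [_program_cov(both), _program_cov(solo)], weights=[f, 1 - f])
        rec = oem(cov, "chrI", 120_000)
        assert rec.oem == pytest.approx(f, abs=1e-12)

    def test_oem_bounds_and_reflection_antisymmetry(self):
        """Mirroring coordinates while keeping strand labels (reading the
        genome in the opposite orientation) negates the OEM; a full
        reflection with strands also swapped maps an origin back onto an
        origin and leaves the OEM unchanged."""
        cfg = single_origin_config(firing_sd=4.0, competence=0.7, n_cells=30,
                                   seed=8)
        lib = okrep.simulate_okseq_library(cfg)
        L = 100_000
        mirror = OkFragmentSet.from_arrays(
            lib.df["chrom"], L - lib.df["end"].to_numpy(),
            L - lib.df["start"].to_numpy(),
            lib.df["strand"].to_numpy(), genome=cfg.genome)
        full = OkFragmentSet.from_arrays(
            lib.df["chrom"], L - lib.df["end"].to_numpy(),
            L - lib.df["start"].to_numpy(),
            np.where(lib.df["strand"] == "+", "-", "+"), genome=cfg.genome)
        fwd = oem(stranded_counts(lib, cfg.genome, 100), "chrI", 50_000)
        mir = oem(stranded_counts(mirror, cfg.genome, 100), "chrI", 50_000)
        ful = oem(stranded_counts(full, cfg.genome, 100), "chrI", 50_000)
        assert -1 <= fwd.oem <= 1
        assert mir.oem == pytest.approx(-fwd.oem, abs=0.02)
        assert ful.oem == pytest.approx(fwd.oem, abs=0.02)


class TestOemTable:
    def test_min_count_marks_undefined_and_summary_excludes(self, tiny_genome):
        from okrep.strand_coverage import StrandedCoverage
        cov = StrandedCoverage.zeros(tiny_genome, 100)
        cov.watson["chrI"][350:400] = 2.0   # only left flank of 40 kb origin
        origins = OriginTable(pd.DataFrame([
            {"chromosome": "chrI", "midpoint": 40_000, "name": "starved"},
            {"chromosome": "chrII", "midpoint": 25_000, "name": "empty"}]),
            genome=tiny_genome)
        table = oem_table(cov, origins, min_count=50)
        assert np.isnan(table["oem"]).all()
        with pytest.raises(ValidationError):
            oem_summary(table)

    def test_empty_origin_table_rejected(self, tiny_genome):
        from okrep.strand_coverage import StrandedCoverage
        cov = StrandedCoverage.zeros(tiny_genome, 100)
        with pytest.raises(Exception):
            oem_table(cov, OriginTable(pd.DataFrame(
                columns=["chromosome", "midpoint", "name"])))

    def test_all_origins_defined_at_depth(self):
        cfg = okrep.preset_config("baseline", seed=3, n_cells=60)
        cov, _ = okrep.simulate_okseq_counts(cfg, 100)
        table = oem_table(cov, cfg.origins)
        assert len(table) == len(cfg.origins)
        assert not table["oem"].isna().any()
        s = oem_summary(table)
        assert -1 <= s["min"] <= s["median"] <= s["max"] <= 1


class TestMetaProfile:
    def test_deterministic_origin_step_profile(self):
        cfg = single_origin_config(t_rep=10.0)
        prof = meta_origin_profile(_program_cov(cfg), cfg.origins,
                                   bin_size=500)
        assert np.allclose(prof.values[prof.offsets < 0], 1.0)
        assert np.allclose(prof.values[prof.offsets > 0], 0.0)

    def test_normalize_max_sets_peak_to_one(self):
        cfg = single_origin_config(firing_sd=4.0, competence=0.6, n_cells=25,
                                   seed=6)
        cov, _ = okrep.simulate_okseq_counts(cfg, 100)
        raw = meta_origin_profile(cov, cfg.origins, bin_size=500)
        assert np.nanmax(raw.values) <= 1.0
        assert np.nanmin(raw.values) >= 0.0
        normed = meta_origin_profile(cov, cfg.origins, bin_size=500,
                                     normalize_max=True)
        assert np.nanmax(normed.values) == pytest.approx(1.0)

    def test_mirror_image_reflects_profile(self):
        """Reflected fragments + reflected origins give the profile mirrored
        with values v -> 1 - v."""
        cfg = single_origin_config(firing_sd=4.0, competence=0.7, n_cells=30,
                                   seed=8)
        lib = okrep.simulate_okseq_library(cfg)
        L = 100_000
        refl = OkFragmentSet.from_arrays(
            lib.df["chrom"], L - lib.df["end"].to_numpy(),
            L - lib.df["start"].to_numpy(),
            np.where(lib.df["strand"] == "+", "-", "+"), genome=cfg.genome)
        fwd = meta_origin_profile(stranded_counts(lib, cfg.genome, 100),
                                  cfg.origins, bin_size=500)
        rev = meta_origin_profile(stranded_counts(refl, cfg.genome, 100),
                                  cfg.origins, bin_size=500)
        assert np.allclose(rev.values, 1.0 - fwd.values[::-1], atol=0.02)


class TestSplitAndCompare:
    @staticmethod
    def _table(names, oems):
        return pd.DataFrame({"name": names, "oem": oems,
                             "w_l": 100, "c_l": 10, "w_r": 10, "c_r": 100})

    @staticmethod
    def _origins(names, t_reps=None, fkh=None):
        df = pd.DataFrame({"chromosome": "chrI",
                           "midpoint": 10_000 * (1 + np.arange(len(names))),
                           "name": names})
        if t_reps is not None:
            df["t_rep"] = t_reps
        if fkh is not None:
            df["fkh_class"] = fkh
        return OriginTable(df)

    def test_identical_groups_t0_p1(self):
        names = [f"o{i}" for i in range(6)]
        res = split_and_compare(
            self._table(names, [0.5, 0.6, 0.7, 0.5, 0.6, 0.7]),
            self._origins(names, t_reps=[10, 11, 12, 30, 31, 32]),
            scheme="timing_median")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_welch_t_against_closed_form(self):
        # {1,2,3} vs {4,5,6}: t = -3/sqrt(2/3) = -3.6742, df = 4, p = 0.02131
        names = [f"o{i}" for i in range(6)]
        res = split_and_compare(
            self._table(names, [1, 2, 3, 4, 5, 6]),
            self._origins(names, t_reps=[10, 11, 12, 30, 31, 32]),
            scheme="timing_median")
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.02131, abs=1e-4)

    def test_earliest_k_split_sizes_22_of_283(self):
        rng = np.random.default_rng(1)
        t_rep = np.concatenate([rng.uniform(10, 17.5, 22),
                                rng.uniform(18.5, 45, 261)])
        rng.shuffle(t_rep)
        names = [f"o{i}" for i in range(283)]
        res = split_and_compare(
            self._table(names, rng.uniform(0, 1, 283)),
            self._origins(names, t_reps=t_rep),
            scheme="earliest_k", theta=18.0)
        assert len(res.groups["earliest"]) == 22
        assert len(res.groups["rest"]) == 261

    def test_fkh_scheme_excludes_unknown(self):
        names = [f"o{i}" for i in range(7)]
        fkh = ["activated", "activated", "repressed", "repressed",
               "independent", "independent", "unknown"]
        res = split_and_compare(
            self._table(names, [0.8, 0.7, 0.2, 0.3, 0.5, 0.55, 0.9]),
            self._origins(names, fkh=fkh), scheme="fkh")
        assert res.n_excluded == 1
        assert res.pair == ("activated", "repressed")
        assert res.t > 0

    def test_small_group_rejected(self):
        # median of {10, 30, 31} leaves a single early origin
        names = [f"o{i}" for i in range(3)]
        with pytest.raises(ValidationError):
            split_and_compare(
                self._table(names, [0.1, 0.2, 0.3]),
                self._origins(names, t_reps=[10, 30, 31]),
                scheme="timing_median")


class TestReplicates:
    @staticmethod
    def _table(oems):
        return pd.DataFrame({"name": [f"o{i}" for i in range(len(oems))],
                             "oem": oems, "w_l": 100, "c_l": 0,
                             "w_r": 0, "c_r": 100})

    def test_self_correlation_is_one(self):
        t = self._table([0.1, 0.4, 0.8, 0.6])
        r, joint, dropped = replicate_correlation(t, t)
        assert r == pytest.approx(1.0)
        assert dropped == 0

    def test_anti_ordered_tables_give_minus_one(self):
        a = self._table([0.1, 0.2, 0.3])
        b = self._table([0.9, 0.8, 0.7])
        r, _, _ = replicate_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_too_few_joint_origins_rejected(self):
        a = self._table([0.1, np.nan, 0.3])
        b = self._table([0.9, 0.8, np.nan])
        with pytest.raises(ValidationError):
            replicate_correlation(a, b)

    def test_independent_replicates_strongly_correlated(self):
        tables = []
        for seed in (101, 102):
            cfg = okrep.preset_config("baseline", seed=seed, n_cells=250)
            cov, _ = okrep.simulate_okseq_counts(cfg, 100)
            tables.append(oem_table(cov, cfg.origins))
        r, joint, _ = replicate_correlation(*tables)
        assert len(joint) >= 20
        assert r >= 0.95

    def test_average_of_replicate_tables(self):
        a = self._table([0.2, 0.4, np.nan])
        b = self._table([0.4, 0.6, 0.5])
        avg = average_oem_tables([a, b])
        assert avg["oem"].tolist() == pytest.approx([0.3, 0.5, 0.5])
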