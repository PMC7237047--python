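"""Run orchestration: fixture generation, stage execution, manifest.

A run is described by a :class:`RunConfig` (JSON on disk): either real input
paths or an embedded simulation block (preset + overrides) that generates
the inputs first.  Every output is a plain-text table or bedGraph; the
manifest records the seed, parameters, input digests and per-stage counts so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .copy_number import loess_smooth, meta_origin_coverage, normalize_track
from .end_phasing import dyad_offset_histogram, fragment_end_positions, length_distribution
from .errors import ConfigError
from .fork_direction import fork_direction_profile, stall_score
from .genome_io import (GenomeLayout, OriginTable, read_bedgraph, read_chrom_sizes,
                        read_dyads, read_fragments, read_intervals, read_loci,
                        read_origins, write_bedgraph, write_chrom_sizes,
                        write_fragments, write_intervals, write_loci, write_origins)
from .origin_efficiency import meta_origin_profile, oem_summary, oem_table
from .simulate import SimConfig, simulate_okseq_library, simulate_wgs_pool, true_efficiency, iter_cells
from .strand_coverage import stranded_counts

ALL_STAGES = ("oem", "meta", "ends", "forkdir", "cnv")

DEFAULT_PARAMS = {
    "bin_size": 100,
    "oem_window": 10000,
    "min_count": 50,
    "meta_bin": 500,
    "end_window": 200,
    "length_bin": 10,
    "forkdir_window": 5000,
    "forkdir_bin": 200,
    "stall_flank": 2000,
    "cnv_bin": 100,
    "loess_span": 0.02,
    "cnv_window": 10000,
    "cnv_smooth_bin": 1000,
}


# ---------------------------------------------------------------------------
# Fixture presets: the simulated study conditions
# ---------------------------------------------------------------------------

#: Scaled-down budding-yeast-like fixture: 3 chromosomes of 500 kb with
#: origins every ~45 kb, nucleosome repeat 165 bp, fork speed 1.5 kb/min.
FIXTURE_GENOME = {"chrI": 500_000, "chrII": 500_000, "chrIII": 500_000}
NUCLEOSOME_REPEAT = 165

#: Presets differ only in the two Pol alpha arms and chromatin/stall knobs.
PRESETS = {
    # normal Pol alpha supply: full competence, tight nucleosome phasing
    "baseline": {"pol_alpha_level": 1.0, "competence_scale": 1.0,
                 "snap_prob": 0.9, "stall_prob": 0.0},
    # severe depletion: both arms reduced, phasing degraded
    "depleted": {"pol_alpha_level": 0.4, "competence_scale": 0.5,
                 "snap_prob": 0.3, "stall_prob": 0.0},
    # Ctf4-uncoupled: lagging-arm priming halved at full origin firing
    "ctf4_like": {"pol_alpha_level": 0.5, "competence_scale": 1.0,
                  "snap_prob": 0.9, "stall_prob": 0.0},
    # replication barriers armed at the tRNA-like loci
    "stall": {"pol_alpha_level": 1.0, "competence_scale": 1.0,
              "snap_prob": 0.9, "stall_prob": 0.6},
}


def fixture_genome() -> GenomeLayout:
    return GenomeLayout(dict(FIXTURE_GENOME))


def fixture_origins(table_seed: int = 0) -> OriginTable:
    """Deterministic origin table: ~45 kb spacing, competences in
    [0.1, 0.95], T_rep spread over 10-38 min, Fkh classes assigned.

    The table plays the role of a fixed published origin annotation, so it
    is keyed by its own ``table_seed`` (default 0) rather than the run seed:
    libraries simulated with different run seeds share the same origins.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=table_seed,
                                                       spawn_key=(101,)))
    genome = fixture_genome()
    rows = []
    idx = 0
    fkh_cycle = ["activated", "independent", "repressed", "independent"]
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        pos = np.arange(25_000, length - 20_000, 45_000)
        jitter = rng.integers(-5_000, 5_000, len(pos))
        for p, j in zip(pos, jitter):
            comp = float(rng.uniform(0.1, 0.95))
            t_rep = float(rng.uniform(10.0, 38.0))
            rows.append({"chromosome": chrom, "midpoint": int(p + j),
                         "name": f"ori{idx:03d}", "t_rep": t_rep,
                         "fkh_class": fkh_cycle[idx % len(fkh_cycle)],
                         "true_competence": comp})
            idx += 1
    return OriginTable(pd.DataFrame(rows), genome=genome)


def fixture_dyads(genome: GenomeLayout | None = None,
                  repeat: int = NUCLEOSOME_REPEAT) -> dict[str, np.ndarray]:
    genome = genome or fixture_genome()
    return {c: np.arange(repeat // 2, genome.length(c), repeat, dtype=np.int64)
            for c in genome.chromosomes}


def fixture_loci(origins: OriginTable) -> pd.DataFrame:
    """Oriented stall loci placed midway between origin pairs (origin-distal)."""
    rows = []
    odf = origins.df
    i = 0
    for chrom, sub in odf.groupby("chromosome", sort=False):
        mids = sub["midpoint"].to_numpy()
        for a, b in zip(mids[:-1:3], mids[1::3]):
            centre = int((a + b) // 2)
            rows.append({"chrom": chrom, "start": centre - 150,
                         "end": centre + 150, "name": f"tL{i:02d}",
                         "strand": "+" if i % 2 == 0 else "-"})
            i += 1
    return pd.DataFrame(rows)


def fixture_exclusions(genome: GenomeLayout | None = None) -> pd.DataFrame:
    genome = genome or fixture_genome()
    rows = [{"chrom": c, "start": 0, "end": 2_000} for c in genome.chromosomes]
    rows += [{"chrom": c, "start": genome.length(c) - 2_000,
              "end": genome.length(c)} for c in genome.chromosomes]
    return pd.DataFrame(rows)


def preset_config(preset: str, seed: int = 0, n_cells: int = 400,
                  table_seed: int = 0, **overrides) -> SimConfig:
    """Simulator configuration for a named fixture preset.

    ``seed`` drives the cells; ``table_seed`` the fixed origin annotation.
    """
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; "
                          f"choose from {sorted(PRESETS)}")
    genome = fixture_genome()
    origins = fixture_origins(table_seed)
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return SimConfig(genome=genome, origins=origins, dyads=fixture_dyads(genome),
                     stall_sites=fixture_loci(origins), n_cells=n_cells,
                     seed=seed, **kw)


def recovery_config(seed: int = 0, n_origins: int = 20, n_cells: int = 2000,
                    unit: int = 100_000) -> SimConfig:
    """Parameter-recovery benchmark geometry for OEM vs true efficiency.

    Each variable-competence test origin (competences spread over
    [0.1, 0.95]) sits 35 kb from a fully competent anchor origin, one anchor
    per 100 kb unit, with every origin sharing the same mean firing time.
    When a test origin stays passive, the anchor forks sweep through its
    locus instead of converging on it, so the ±10 kb flanks report firing
    polarity rather than termination structure; test origins keep >= 20 kb
    clearance from all neighbours.  Test origins are the names starting
    with "test".
    """
    comps = np.linspace(0.1, 0.95, n_origins)
    rows = []
    for i in range(n_origins):
        rows.append({"chromosome": "chrS", "midpoint": i * unit + 1_000,
                     "name": f"anchor{i:02d}", "t_rep": 20.0,
                     "true_competence": 1.0})
        rows.append({"chromosome": "chrS", "midpoint": i * unit + 36_000,
                     "name": f"test{i:02d}", "t_rep": 20.0,
                     "true_competence": float(comps[i])})
    genome = GenomeLayout({"chrS": n_origins * unit + 2_000})
    origins = OriginTable(pd.DataFrame(rows), genome=genome)
    return SimConfig(genome=genome, origins=origins, n_cells=n_cells,
                     seed=seed)


def stall_benchmark_config(stall_prob: float, seed: int = 0,
                           n_cells: int = 2000) -> SimConfig:
    """Replication-barrier benchmark: a locus swept by elongating forks.

    A 130 kb chromosome with always-firing co-timed origins at 10 kb and
    110 kb and one plus-strand locus at 35 kb: the left origin's rightward
    fork reaches the locus long before the termination zone (~60 kb), so
    without arrest the direction profile is flat at the locus and the stall
    score sits at zero up to sampling noise; with arrest probability s the
    region just downstream flips to leftward forks in a fraction s of cells
    and the score drops by about -s.
    """
    genome = GenomeLayout({"chrT": 130_000})
    origins = OriginTable(pd.DataFrame([
        {"chromosome": "chrT", "midpoint": 10_000, "name": "oL",
         "t_rep": 12.0, "true_competence": 1.0},
        {"chromosome": "chrT", "midpoint": 110_000, "name": "oR",
         "t_rep": 12.0, "true_competence": 1.0},
    ]), genome=genome)
    loci = pd.DataFrame([{"chrom": "chrT", "start": 34_850, "end": 35_150,
                          "name": "tRNA0", "strand": "+"}])
    return SimConfig(genome=genome, origins=origins, stall_sites=loci,
                     stall_prob=stall_prob, n_cells=n_cells, seed=seed)


def generate_fixture(preset: str, seed: int, outdir,
                     n_cells: int = 400, **overrides) -> dict[str, Path]:
    """Write a complete on-disk synthetic dataset plus ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = preset_config(preset, seed=seed, n_cells=n_cells, **overrides)

    paths = {k: outdir / v for k, v in [
        ("chrom_sizes", "genome.chrom.sizes"), ("origins", "origins.tsv"),
        ("fragments", "fragments.bed"), ("dyads", "dyads.bed"),
        ("exclusions", "exclusions.bed"), ("loci", "trna_loci.bed"),
        ("wgs_s", "wgs_s.bedgraph"), ("wgs_g1", "wgs_g1.bedgraph"),
        ("truth", "truth.tsv"), ("config", "sim_config.json")]}

    write_chrom_sizes(config.genome, paths["chrom_sizes"])
    write_origins(config.origins, paths["origins"])
    with open(paths["dyads"], "w") as fh:
        for chrom, pos in (config.dyads or {}).items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")
    write_intervals(fixture_exclusions(config.genome), paths["exclusions"])
    write_loci(config.stall_sites, paths["loci"])

    programs = []
    parts = []
    for _i, program, frags in iter_cells(config):
        programs.append(program)
        parts.append(frags.df)
    from .genome_io import OkFragmentSet
    library = OkFragmentSet(pd.concat(parts, ignore_index=True),
                            genome=config.genome, validate=False)
    write_fragments(library, paths["fragments"])
    eff = true_efficiency(config, programs=programs)
    eff.rename_axis("name").reset_index().to_csv(paths["truth"], sep="\t",
                                                 index=False)

    s_track, g1_track = simulate_wgs_pool(config, "uniform",
                                          bin_size=DEFAULT_PARAMS["cnv_bin"])
    write_bedgraph(s_track, paths["wgs_s"])
    write_bedgraph(g1_track, paths["wgs_g1"])

    with open(paths["config"], "w") as fh:
        json.dump({"preset": preset, "seed": seed, "n_cells": n_cells,
                   "overrides": {k: overrides[k] for k in overrides},
                   "knobs": PRESETS[preset]}, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Inputs, parameters and stage selection for one reproducible run."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: dict | None = None     # {"preset": ..., "n_cells": ..., overrides}
    params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - {"outdir", "seed", "stages", "inputs", "simulate",
                              "params"}
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config requires 'outdir'")
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)

    def param(self, name: str):
        return self.params.get(name, DEFAULT_PARAMS[name])


def _display_path(path, outdir) -> str:
    """Paths under the output directory are recorded relative to it, so two
    identically configured runs produce identical manifests."""
    try:
        return str(Path(path).resolve().relative_to(Path(outdir).resolve()))
    except ValueError:
        return str(path)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


STAGE_REQUIREMENTS = {
    "oem": ("chrom_sizes", "fragments", "origins"),
    "meta": ("chrom_sizes", "fragments", "origins"),
    "ends": ("chrom_sizes", "fragments", "dyads"),
    "forkdir": ("chrom_sizes", "fragments", "loci"),
    "cnv": ("chrom_sizes", "wgs_s", "wgs_g1", "origins"),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns the manifest (also written to
    ``outdir/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.inputs)

    if config.simulate is not None:
        sim = dict(config.simulate)
        preset = sim.pop("preset", "baseline")
        n_cells = sim.pop("n_cells", 400)
        paths = generate_fixture(preset, config.seed, outdir / "inputs",
                                 n_cells=n_cells, **sim)
        for key in ("chrom_sizes", "fragments", "origins", "dyads",
                    "exclusions", "loci", "wgs_s", "wgs_g1"):
            inputs.setdefault(key, str(paths[key]))

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        missing = [k for k in STAGE_REQUIREMENTS[stage] if k not in inputs]
        if missing:
            raise ConfigError(f"stage {stage!r} requires inputs {missing}")

    genome = read_chrom_sizes(inputs["chrom_sizes"])
    log: dict[str, dict] = {}
    frags = cov = None
    if any(s in config.stages for s in ("oem", "meta", "ends", "forkdir")):
        frags = read_fragments(inputs["fragments"], genome)
        cov = stranded_counts(frags, genome, config.param("bin_size"))
        log["input"] = {"n_fragments": len(frags)}
    origins = (read_origins(inputs["origins"], genome)
               if "origins" in inputs else None)

    if "oem" in config.stages:
        table = oem_table(cov, origins, window=config.param("oem_window"),
                          min_count=config.param("min_count"))
        table.to_csv(outdir / "oem.tsv", sep="\t", index=False, na_rep="NA")
        log["oem"] = oem_summary(table)
    if "meta" in config.stages:
        prof = meta_origin_profile(cov, origins,
                                   window=config.param("oem_window"),
                                   bin_size=config.param("meta_bin"),
                                   normalize_max=True)
        prof.to_frame().to_csv(outdir / "meta_profile.tsv", sep="\t",
                               index=False, na_rep="NA")
        log["meta"] = {"n_origins": len(origins)}
    if "ends" in config.stages:
        dyads = read_dyads(inputs["dyads"], genome)
        for which, fname in (("five_prime", "ends_5p.tsv"),
                             ("three_prime", "ends_3p.tsv")):
            ends = fragment_end_positions(frags, which)
            hist = dyad_offset_histogram(ends, dyads,
                                         window=config.param("end_window"))
            hist.to_frame().to_csv(outdir / fname, sep="\t", index=False)
        ld = length_distribution(frags, bin_size=config.param("length_bin"))
        ld.to_frame().to_csv(outdir / "lengths.tsv", sep="\t", index=False)
        log["ends"] = {"mean_length": ld.mean, "median_length": ld.median,
                       "mode_length": ld.mode}
    if "forkdir" in config.stages:
        loci = read_loci(inputs["loci"], genome)
        prof = fork_direction_profile(cov, loci,
                                      window=config.param("forkdir_window"),
                                      bin_size=config.param("forkdir_bin"))
        prof.to_frame().to_csv(outdir / "fork_direction.tsv", sep="\t",
                               index=False, na_rep="NA")
        log["forkdir"] = {"n_loci": int(prof.n_loci),
                          "stall_score": stall_score(
                              prof, flank=config.param("stall_flank"))}
    if "cnv" in config.stages:
        bin_size = config.param("cnv_bin")
        s_track = read_bedgraph(inputs["wgs_s"], genome, bin_size)
        g1_track = read_bedgraph(inputs["wgs_g1"], genome, bin_size)
        exclusion = (read_intervals(inputs["exclusions"], genome)
                     if "exclusions" in inputs else None)
        ratio = normalize_track(s_track, g1_track, exclusion)
        write_bedgraph(ratio, outdir / "cnv_ratio.bedgraph")
        smoothed = loess_smooth(ratio, span_fraction=config.param("loess_span"))
        write_bedgraph(smoothed, outdir / "cnv_smoothed.bedgraph")
        prof = meta_origin_coverage(ratio, origins,
                                    window=config.param("cnv_window"),
                                    smooth_bin=config.param("cnv_smooth_bin"))
        prof.to_frame().to_csv(outdir / "cnv_meta.tsv", sep="\t", index=False,
                               na_rep="NA")
        n_masked = int(sum(np.isnan(v).sum() for v in ratio.values.values()))
        log["cnv"] = {"n_masked_bins": n_masked}

    manifest = {
        "okrep_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "params": {k: config.param(k) for k in DEFAULT_PARAMS},
        "simulate": config.simulate,
        "inputs": {k: {"path": _display_path(v, outdir),
                       "sha256": _digest(v)}
                   for k, v in inputs.items()},
        "log": log,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
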