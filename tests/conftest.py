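import numpy as np
import pandas as pd
import pytest

from okrep import GenomeLayout, OkFragmentSet, OriginTable, SimConfig


@pytest.fixture
def tiny_genome():
    return GenomeLayout({"chrI": 100_000, "chrII": 50_000})


@pytest.fixture
def tiny_fragments(tiny_genome):
    df = pd.DataFrame({
        "chrom": ["chrI", "chrI", "chrII"],
        "start": [100, 5_000, 200],
        "end": [250, 5_160, 420],
        "name": ["f1", "f2", "f3"],
        "score": [0, 0, 0],
        "strand": ["+", "-", "+"],
    })
    return OkFragmentSet(df, genome=tiny_genome)


def single_origin_config(midpoint=50_000, length=100_000, competence=1.0,
                         t_rep=10.0, firing_sd=0.0, n_cells=1, seed=0, **kw):
    """One-origin deterministic-by-default configuration."""
    genome = GenomeLayout({"chrI": length})
    origins = OriginTable(pd.DataFrame([{
        "chromosome": "chrI", "midpoint": midpoint, "name": "o0",
        "t_rep": t_rep, "true_competence": competence}]), genome=genome)
    return SimConfig(genome=genome, origins=origins, firing_sd=firing_sd,
                     n_cells=n_cells, seed=seed, **kw)


def multi_origin_config(midpoints, competences, t_reps, length=None,
                        firing_sd=0.0, n_cells=1, seed=0, chrom="chrI", **kw):
    length = length or (max(midpoints) + 50_000)
    genome = GenomeLayout({chrom: length})
    rows = [{"chromosome": chrom, "midpoint": int(m), "name": f"o{i}",
             "t_rep": float(t), "true_competence": float(p)}
            for i, (m, p, t) in enumerate(zip(midpoints, competences, t_reps))]
    origins = OriginTable(pd.DataFrame(rows), genome=genome)
    return SimConfig(genome=genome, origins=origins, firing_sd=firing_sd,
                     n_cells=n_cells, seed=seed, **kw)
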