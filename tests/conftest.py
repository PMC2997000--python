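import pandas as pd
import pytest

import cghtax as cx


@pytest.fixture(scope="session")
def small_genome():
    """200-gene genome with its probe map (5-6 probes per gene)."""
    return cx.simulate_genome(200, seed=7)


@pytest.fixture(scope="session")
def self_hyb(small_genome):
    """Self-hybridization spots: all genes conserved, no efficiency shift."""
    genome, probe_map = small_genome
    truth = cx.simulate_strain(genome, conserved_fraction=1.0, seed=7)
    spots = cx.simulate_hybridization(genome, probe_map, truth, seed=7)
    return genome, probe_map, truth, spots


def simulate_profile(n_genes, conserved, shift, seed, config=None):
    """Full simulate -> pipeline run for one strain; returns (truth, profile)."""
    genome, probe_map = cx.simulate_genome(n_genes, seed=seed)
    truth = cx.simulate_strain(genome, conserved, efficiency_shift=shift, seed=seed + 1000)
    spots = cx.simulate_hybridization(genome, probe_map, truth, seed=seed + 2000)
    result = cx.run_pipeline(config or cx.PipelineConfig(), {"strain": spots}, probe_map)
    return truth, result.profiles["strain"]


def make_profile(calls, strain_id="A", reference_id="ref", threshold=-3.5):
    """Build a ConservationProfile from a list of (gene_id, median_log2)
    tuples (median None -> no_call)."""
    df = pd.DataFrame(
        [(g, i, m, 6 if m is not None else 0) for i, (g, m) in enumerate(calls)],
        columns=["gene_id", "genome_index", "median_log2", "n_probes_used"],
    )
    return cx.call_conservation(df, threshold=threshold, strain_id=strain_id,
                                reference_id=reference_id)
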