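"""Synthetic two-color array generator with known ground truth.

Emulates comparative genomic hybridization (CGH) of a test strain against a
reference genome printed as 60-mer oligo probes, 5-6 probes per coding
sequence.  Every gene of the reference carries a conservation status in the
test strain (``conserved`` / ``diverged`` / ``absent``); the generator turns
that truth into per-spot two-channel foreground and local-background
statistics so the downstream QC / ratio / calling pipeline can be validated
against a known answer.

Signal model (log2 scale, per spot):

    ref channel:   log2(signal) = A_g + P_p + e_ref
    test channel:  log2(signal) = A_g + P_p + shift - att * n_mm + e_test

where ``A_g`` is a per-gene abundance effect, ``P_p`` a per-probe effect
shared by both channels (same physical spot), ``e`` independent channel
noise, ``shift`` the strain-level hybridization-efficiency shift (log2
units; ~0 within a species, ~-1 between close species), ``att`` the log2
signal loss per mismatched base and ``n_mm = round(divergence * 60)`` the
mismatch count over the 60-mer.  Foregrounds are signal plus a per-spot
lognormal local background shared by both channels; absent genes emit test
foreground drawn from the background distribution alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_LENGTH = 60

#: column order of the emitted probe intensity table
INTENSITY_COLUMNS = [
    "probe_id", "gene_id", "genome_index",
    "ref_fg", "ref_bg_mean", "ref_bg_sd",
    "test_fg", "test_bg_mean", "test_bg_sd",
]

TRUTH_COLUMNS = ["gene_id", "status", "divergence"]

STATUS_CONSERVED = "conserved"
STATUS_DIVERGED = "diverged"
STATUS_ABSENT = "absent"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    genome_index: int
    length_bp: int


@dataclass
class GenomeModel:
    """Ordered reference gene complement.

    ``genes`` are sorted by ``genome_index`` (0-based, unique, consecutive);
    every gene is at least 60 bp so a full-length probe fits.
    """

    genes: list[Gene]

    def __post_init__(self) -> None:
        idx = [g.genome_index for g in self.genes]
        if idx != list(range(len(self.genes))):
            raise ValueError("genome_index values must be 0-based and consecutive")
        if any(g.length_bp < PROBE_LENGTH for g in self.genes):
            raise ValueError(f"gene length must be >= {PROBE_LENGTH} bp")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class StrainTruth:
    """Per-gene conservation truth of one test strain vs the reference.

    ``table`` has columns gene_id, status, divergence (fraction of
    mismatched positions per probe; 0 for conserved genes, ignored for
    absent genes).  ``efficiency_shift`` is the global log2 shift applied to
    every non-absent gene, modelling the species-level hybridization
    efficiency difference.
    """

    table: pd.DataFrame
    efficiency_shift: float = 0.0

    def __post_init__(self) -> None:
        conserved = self.table["status"] == STATUS_CONSERVED
        if (self.table.loc[conserved, "divergence"] != 0).any():
            raise ValueError("conserved genes must have divergence 0")

    def status_counts(self) -> pd.Series:
        return self.table["status"].value_counts()

    @property
    def conserved_fraction(self) -> float:
        return float((self.table["status"] == STATUS_CONSERVED).mean())


@dataclass
class NoiseModel:
    """Noise parameters of the simulated hybridization (log2-scale sigmas,
    linear-scale background)."""

    sigma_gene: float = 1.0       # per-gene abundance spread
    sigma_probe: float = 0.5      # per-probe effect, shared across channels
    sigma_channel: float = 0.25   # independent per-channel spot noise
    bg_mean: float = 100.0        # local background mean (linear intensity)
    bg_sd: float = 30.0           # local background SD (linear intensity)
    mismatch_attenuation: float = 0.35  # log2 loss per mismatched base

    def __post_init__(self) -> None:
        if min(self.sigma_gene, self.sigma_probe, self.sigma_channel) < 0:
            raise ValueError("sigmas must be >= 0")
        if self.bg_mean <= 0 or self.bg_sd <= 0:
            raise ValueError("bg_mean and bg_sd must be > 0")


# ---------------------------------------------------------------------------
# genome / probe simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int,
    probes_per_gene_choices: set[int] = frozenset({5, 6}),
    seed: int = 0,
) -> tuple[GenomeModel, pd.DataFrame]:
    """Simulate an ordered reference genome and its probe->gene map.

    Each gene is assigned k probes, k drawn uniformly from
    ``probes_per_gene_choices``.  Returns the genome and a probe map with
    columns probe_id, gene_id, genome_index.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    choices = sorted(probes_per_gene_choices)
    if not choices:
        raise ValueError("probes_per_gene_choices must be nonempty")
    rng = np.random.default_rng(seed)
    genes = []
    rows = []
    for i in range(n_genes):
        gid = f"g{i:05d}"
        length = int(rng.integers(300, 3000))
        genes.append(Gene(gid, i, length))
        k = int(rng.choice(choices))
        for p in range(k):
            rows.append((f"{gid}_p{p}", gid, i))
    probe_map = pd.DataFrame(rows, columns=["probe_id", "gene_id", "genome_index"])
    return GenomeModel(genes), probe_map


def _place_variable_genes(
    n: int, m: int, n_regions: int, rng: np.random.Generator,
    block_size_range: tuple[int, int] = (3, 15), separation: int = 3,
) -> np.ndarray:
    """Pick m variable genome positions: ``n_regions`` contiguous blocks
    (sizes uniform in block_size_range) plus scattered singletons, keeping
    placements >= ``separation`` apart where space allows."""
    variable = np.zeros(n, dtype=bool)
    blocked = np.zeros(n, dtype=bool)  # variable or too close to variable
    placed = 0

    def mark(start: int, stop: int) -> None:
        variable[start:stop] = True
        blocked[max(0, start - separation):min(n, stop + separation)] = True

    lo, hi = block_size_range
    for _ in range(n_regions):
        remaining = m - placed
        if remaining < lo:
            break
        size = int(rng.integers(lo, min(hi, remaining) + 1))
        for _attempt in range(200):
            start = int(rng.integers(0, max(1, n - size)))
            if not blocked[start:start + size].any():
                mark(start, start + size)
                placed += size
                break

    # scattered singletons, separated where possible
    free = np.flatnonzero(~blocked)
    rng.shuffle(free)
    for pos in free:
        if placed >= m:
            break
        if blocked[pos]:
            continue
        mark(pos, pos + 1)
        placed += 1
    if placed < m:  # dense truth: separation no longer satisfiable
        remaining_pos = np.flatnonzero(~variable)
        extra = rng.choice(remaining_pos, size=m - placed, replace=False)
        variable[extra] = True
    return variable


def simulate_strain(
    genome: GenomeModel,
    conserved_fraction: float,
    absent_fraction: float | None = None,
    divergence_level: float = 0.3,
    efficiency_shift: float = 0.0,
    n_variable_regions: int = 6,
    seed: int = 0,
) -> StrainTruth:
    """Simulate a test strain's per-gene conservation truth.

    Non-conserved genes are split between ``absent`` and ``diverged``
    (``absent_fraction`` of all genes absent; default: half of the
    non-conserved remainder) and concentrated in ``n_variable_regions``
    contiguous genome blocks with the rest scattered singly, mirroring the
    clustering of strain-variable loci in real genomes.
    """
    if not 0 <= conserved_fraction <= 1:
        raise ValueError("conserved_fraction must be in [0, 1]")
    if absent_fraction is None:
        absent_fraction = (1.0 - conserved_fraction) / 2.0
    if not 0 <= absent_fraction <= 1:
        raise ValueError("absent_fraction must be in [0, 1]")
    if conserved_fraction + absent_fraction > 1 + 1e-12:
        raise ValueError("conserved_fraction + absent_fraction must be <= 1")
    if not 0 <= divergence_level <= 1:
        raise ValueError("divergence_level must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n = genome.n_genes
    m_variable = round((1.0 - conserved_fraction) * n)
    m_absent = min(round(absent_fraction * n), m_variable)

    variable = _place_variable_genes(n, m_variable, n_variable_regions, rng)
    var_idx = np.flatnonzero(variable)
    absent_idx = set(rng.choice(var_idx, size=m_absent, replace=False)) if m_absent else set()

    status = np.full(n, STATUS_CONSERVED, dtype=object)
    divergence = np.zeros(n)
    for i in var_idx:
        if i in absent_idx:
            status[i] = STATUS_ABSENT
        else:
            status[i] = STATUS_DIVERGED
            divergence[i] = divergence_level
    table = pd.DataFrame({
        "gene_id": genome.gene_ids,
        "status": status,
        "divergence": divergence,
    })
    return StrainTruth(table, efficiency_shift=efficiency_shift)


# ---------------------------------------------------------------------------
# hybridization simulation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-matched underlying normal parameters
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def simulate_hybridization(
    genome: GenomeModel,
    probe_map: pd.DataFrame,
    truth: StrainTruth,
    noise: NoiseModel | None = None,
    seed: int = 0,
    mu_signal: float = 13.0,
) -> pd.DataFrame:
    """Simulate a two-channel probe intensity table for one array.

    Returns a DataFrame with :data:`INTENSITY_COLUMNS`.  Channels are on a
    common absolute scale (equal labelled-DNA input, equal scanner gain), so
    self-hybridization ratios center on zero and an inter-species
    ``efficiency_shift`` of -1 puts the conserved peak near -1.
    """
    noise = noise or NoiseModel()
    known = set(genome.gene_ids)
    unknown = set(probe_map["gene_id"]) - known
    if unknown:
        raise ValueError(f"probe map references genes absent from genome: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    tr = truth.table.set_index("gene_id")
    n_spots = len(probe_map)
    gene_ids = probe_map["gene_id"].to_numpy()

    # per-gene effects
    uniq = genome.gene_ids
    a_g = pd.Series(mu_signal + rng.normal(0, noise.sigma_gene, len(uniq)), index=uniq)
    p_p = rng.normal(0, noise.sigma_probe, n_spots)

    status = tr.loc[gene_ids, "status"].to_numpy()
    divergence = tr.loc[gene_ids, "divergence"].to_numpy(dtype=float)
    n_mm = np.round(divergence * PROBE_LENGTH)

    log2_ref = a_g.loc[gene_ids].to_numpy() + p_p + rng.normal(0, noise.sigma_channel, n_spots)
    shift = np.where(status == STATUS_ABSENT, 0.0, truth.efficiency_shift)
    atten = np.where(status == STATUS_DIVERGED, noise.mismatch_attenuation * n_mm, 0.0)
    log2_test = (a_g.loc[gene_ids].to_numpy() + p_p + shift - atten
                 + rng.normal(0, noise.sigma_channel, n_spots))

    # per-spot lognormal local background, shared by both channels (same
    # physical spot location)
    mu_bg, s_bg = _lognormal_params(noise.bg_mean, noise.bg_sd)
    bg = np.exp(mu_bg + s_bg * rng.normal(0, 1, n_spots)) if s_bg > 0 else np.full(n_spots, noise.bg_mean)
    bg_sd_spot = noise.bg_sd * bg / noise.bg_mean

    ref_fg = bg + np.exp2(log2_ref)
    test_signal = np.exp2(log2_test)
    absent = status == STATUS_ABSENT
    # absent genes: test channel sees background only
    test_bg_only = np.exp(mu_bg + s_bg * rng.normal(0, 1, n_spots)) if s_bg > 0 else np.full(n_spots, noise.bg_mean)
    test_fg = np.where(absent, test_bg_only, bg + test_signal)

    out = pd.DataFrame({
        "probe_id": probe_map["probe_id"],
        "gene_id": probe_map["gene_id"],
        "genome_index": probe_map["genome_index"],
        "ref_fg": ref_fg,
        "ref_bg_mean": bg,
        "ref_bg_sd": bg_sd_spot,
        "test_fg": test_fg,
        "test_bg_mean": bg,
        "test_bg_sd": bg_sd_spot,
    })
    return out[INTENSITY_COLUMNS]


# ---------------------------------------------------------------------------
# taxonomy fixtures
# ---------------------------------------------------------------------------

def generate_fixture_tables(
    seed: int = 0,
    n_strains: int = 8,
    n_characters: int = 12,
    n_replicates: int = 3,
    allow_constant: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate random analogues of a phenotype character table and a raw
    DDH (dot-blot) intensity set for property tests.

    Returns ``(character_table, ddh_raw)``.  The character table is strains
    x characters with values in {+, -, d} and, unless ``allow_constant``,
    no column constant across strains.  ``ddh_raw`` is a long table
    (probe_strain, target_strain, replicate, signal) in which every probe
    strain's self-target signal is the row maximum by construction.
    """
    rng = np.random.default_rng(seed)
    strains = [f"S{i:02d}" for i in range(n_strains)]
    chars = [f"char{j:02d}" for j in range(n_characters)]
    vals = rng.choice(["+", "-", "d"], size=(n_strains, n_characters), p=[0.45, 0.45, 0.10])
    if not allow_constant:
        for j in range(n_characters):
            while len(set(vals[:, j])) == 1:
                vals[rng.integers(n_strains), j] = rng.choice(["+", "-", "d"])
    char_table = pd.DataFrame(vals, index=strains, columns=chars)

    rows = []
    for probe in strains:
        self_level = rng.uniform(5e4, 1e5)
        for target in strains:
            # relatedness decays with index distance; self is maximal
            rel = 1.0 if target == probe else rng.uniform(0.02, 0.8)
            for rep in range(n_replicates):
                signal = self_level * rel * rng.uniform(0.85, 1.15)
                if target == probe:
                    signal = max(signal, self_level)  # keep self the maximum
                rows.append((probe, target, rep, signal))
    ddh_raw = pd.DataFrame(rows, columns=["probe_strain", "target_strain", "replicate", "signal"])
    return char_table, ddh_raw
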