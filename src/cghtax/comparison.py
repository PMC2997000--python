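"""Multi-strain comparison of conservation profiles against a shared
reference genome: differential gene sets, three-way joint classification,
variable-region run detection and genome-order conservation maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .calling import CALL_ABSENT, CALL_CONSERVED, CALL_NONE, ConservationProfile

# single-letter call codes used in joint category keys
_CODE = {CALL_CONSERVED: "C", CALL_ABSENT: "A"}


@dataclass
class ComparisonResult:
    """Joint per-gene classification of 2-3 strains.

    ``categories`` maps a category key (e.g. ``"C|A"`` = conserved in the
    first strain, absent/divergent in the second) to the sorted gene-id
    list; ``excluded`` holds genes that were no_call in at least one
    strain, which are left out of every joint category.
    """

    strain_ids: tuple[str, ...]
    categories: dict[str, list[str]]
    excluded: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.categories.items()}

    def count(self, *calls: str) -> int:
        """Count of genes with the given per-strain calls, e.g.
        ``count("conserved", "absent_divergent")``."""
        key = "|".join(_CODE[c] for c in calls)
        return len(self.categories[key])


def _aligned_calls(profiles: list[ConservationProfile]) -> pd.DataFrame:
    ref_ids = {p.reference_id for p in profiles}
    if len(ref_ids) != 1:
        raise ValueError(f"profiles reference different genomes: {sorted(ref_ids)}")
    base = profiles[0].calls[["gene_id"]]
    merged = base.copy()
    for i, p in enumerate(profiles):
        calls = p.calls[["gene_id", "call"]].rename(columns={"call": f"call_{i}"})
        merged = merged.merge(calls, on="gene_id", how="inner", validate="1:1")
    if len(merged) != len(base):
        raise ValueError("profiles do not share an identical gene complement")
    return merged


def _joint_classify(profiles: list[ConservationProfile]) -> ComparisonResult:
    merged = _aligned_calls(profiles)
    k = len(profiles)
    call_cols = [f"call_{i}" for i in range(k)]
    no_call = (merged[call_cols] == CALL_NONE).any(axis=1)
    excluded = sorted(merged.loc[no_call, "gene_id"])
    categories = {
        "|".join(combo): []
        for combo in product("CA", repeat=k)
    }
    called = merged[~no_call]
    if len(called):
        keys = called[call_cols].apply(lambda row: "|".join(_CODE[c] for c in row), axis=1)
        for key, group in called.groupby(keys):
            categories[key] = sorted(group["gene_id"])
    return ComparisonResult(
        strain_ids=tuple(p.strain_id for p in profiles),
        categories=categories,
        excluded=excluded,
    )


def differential_sets(a: ConservationProfile, b: ConservationProfile) -> ComparisonResult:
    """Partition genes called in both strains into {both conserved, A-only
    conserved, B-only conserved, both absent/divergent}."""
    return _joint_classify([a, b])


def three_way_classify(
    a: ConservationProfile, b: ConservationProfile, c: ConservationProfile
) -> ComparisonResult:
    """Joint call triples over three strains: 8 categories from
    ``C|C|C`` (core) to ``A|A|A``.  A gene conserved in the first strain
    and absent in the other two is ``C|A|A``."""
    return _joint_classify([a, b, c])


@dataclass(frozen=True)
class VariableRegion:
    """Maximal genome-order run of genes of one call class.

    ``start`` / ``end`` are 0-based half-open genome indices.
    """

    start: int
    end: int
    gene_ids: tuple[str, ...]
    region_class: str

    @property
    def span(self) -> int:
        return self.end - self.start


def detect_runs(
    profile: ConservationProfile,
    target_class: str = CALL_ABSENT,
    min_run: int = 3,
    max_gap: int = 1,
) -> list[VariableRegion]:
    """Detect maximal genome-order runs of ``target_class`` genes.

    Up to ``max_gap`` consecutive genes of another class may be bridged
    inside a run; runs always start and end on a target gene.  Runs with
    fewer than ``min_run`` target genes are discarded.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    calls = profile.calls
    idx = calls["genome_index"].to_numpy()
    if not (idx[1:] > idx[:-1]).all():
        raise ValueError("profile must be strictly ordered by genome_index")

    regions: list[VariableRegion] = []
    run: list[int] = []  # row positions of target genes in current run
    gap = 0

    def flush() -> None:
        if len(run) >= min_run:
            rows = calls.iloc[run[0]:run[-1] + 1]
            regions.append(VariableRegion(
                start=int(idx[run[0]]),
                end=int(idx[run[-1]]) + 1,
                gene_ids=tuple(rows["gene_id"]),
                region_class=target_class,
            ))

    for pos, call in enumerate(calls["call"]):
        if call == target_class:
            run.append(pos)
            gap = 0
        elif run:
            gap += 1
            if gap > max_gap:
                flush()
                run, gap = [], 0
    if run:
        flush()
    return regions


def export_genome_map(profiles: list[ConservationProfile]) -> pd.DataFrame:
    """Genome-order conservation matrix: one row per reference gene, per
    strain a median_log2 and a call column."""
    if not profiles:
        raise ValueError("no profiles to export")
    out = profiles[0].calls[["gene_id", "genome_index"]].copy()
    for p in profiles:
        cols = p.calls[["gene_id", "median_log2", "call"]].rename(columns={
            "median_log2": f"{p.strain_id}_median_log2",
            "call": f"{p.strain_id}_call",
        })
        out = out.merge(cols, on="gene_id", how="left", validate="1:1")
    return out.sort_values("genome_index").reset_index(drop=True)
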