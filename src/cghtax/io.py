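"""File formats, configuration, and the end-to-end pipeline.

All on-disk formats are plain text: tab-separated tables, newick trees,
BED-like interval files (0-based half-open over genome gene index) and
JSON summaries.  Output files carry a header comment stating the
coordinate convention and a hash of the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import probes as _probes
from . import calling as _calling
from . import comparison as _comparison
from .synthetic import INTENSITY_COLUMNS

log = logging.getLogger("cghtax")

NUMERIC_SPOT_COLUMNS = [
    "ref_fg", "ref_bg_mean", "ref_bg_sd", "test_fg", "test_bg_mean", "test_bg_sd",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    ``normalization`` is ``"none"`` (channels already on a common absolute
    scale — the default, and the only choice that preserves a genuine
    inter-species efficiency shift) or ``"total"`` (equalize channel
    totals; for uncalibrated intra-species arrays).
    """

    threshold: float = _calling.DEFAULT_THRESHOLD
    bin_width: float = _calling.DEFAULT_BIN_WIDTH
    min_probes: int = 2
    normalization: str = "none"
    qc_channel: str = "ref"
    run_min: int = 3
    run_gap: int = 1
    encoding: str = "half"
    seed: int = 0

    def to_text(self) -> str:
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: type(getattr(cls(), f.name)) for f in cls.__dataclass_fields__.values()}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise SchemaError(f"unknown config key: {key!r}")
            kwargs[key] = types[key](value)
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def _header(config: PipelineConfig | None, convention: str | None = None) -> str:
    lines = []
    if convention:
        lines.append(f"# coordinates: {convention}")
    if config is not None:
        lines.append(f"# config_hash: {config.config_hash()}")
    return "".join(f"{l}\n" for l in lines)


# ---------------------------------------------------------------------------
# tab-separated tables
# ---------------------------------------------------------------------------

def read_intensity_table(path) -> pd.DataFrame:
    """Read a probe intensity table, validating the schema.

    Raises :class:`SchemaError` naming any missing column; a non-numeric
    value in a numeric column raises an error carrying its line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"intensity table {path} missing column(s): {missing}")
    if len(df) == 0:
        warnings.warn(f"intensity table {path} has an empty data section")
    for col in ["genome_index"] + NUMERIC_SPOT_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise SchemaError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column {col!r} "
                f"at line {line} of {path}"
            )
        df[col] = converted
    df["genome_index"] = df["genome_index"].astype(int)
    return df[INTENSITY_COLUMNS]


def write_intensity_table(df: pd.DataFrame, path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, "genome_index: 0-based gene order"))
        df.to_csv(fh, sep="\t", index=False)


def write_gene_ratios(df: pd.DataFrame, path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, "genome_index: 0-based gene order"))
        df.to_csv(fh, sep="\t", index=False)


def write_calls(profile: _calling.ConservationProfile, path, config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, "genome_index: 0-based gene order"))
        profile.calls.to_csv(fh, sep="\t", index=False)


def read_calls(path, strain_id="test", reference_id="reference",
               threshold=_calling.DEFAULT_THRESHOLD,
               bin_width=_calling.DEFAULT_BIN_WIDTH) -> _calling.ConservationProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    hist = _calling.ratio_histogram(
        df.loc[df["call"] != _calling.CALL_NONE, "median_log2"], bin_width)
    return _calling.ConservationProfile(strain_id, reference_id, df, threshold, hist)


def write_summary(summary: dict, path, config: PipelineConfig | None = None) -> None:
    payload = dict(summary)
    if config is not None:
        payload["config_hash"] = config.config_hash()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_newick(tree, path, config: PipelineConfig | None = None) -> None:
    """Write a dendrogram as plain newick (branch lengths are similarity
    drops / 2, internal labels the join similarity percent).

    Unlike the tabular writers, no header comment is emitted: ``#`` lines
    are not legal newick and would break standard readers.  The convention
    and config hash travel in the accompanying summary instead.
    """
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_intervals(regions, path, config: PipelineConfig | None = None) -> None:
    """BED-like interval file over gene indices (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(_header(config, "0-based half-open over genome gene index"))
        fh.write("start\tend\tclass\tn_genes\tgene_ids\n")
        for r in regions:
            fh.write(f"{r.start}\t{r.end}\t{r.region_class}\t{len(r.gene_ids)}\t"
                     f"{','.join(r.gene_ids)}\n")


def read_intervals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# GEO series-matrix ingestion
# ---------------------------------------------------------------------------

@dataclass
class GeoSeries:
    """Parsed GEO series-matrix content.

    ``values`` is features x samples (the series' processed values; for CGH
    series these are typically already normalized log2 ratios, so probe QC
    and normalization no longer apply and downstream results that depend on
    them are approximate).  ``level`` records which pipeline stages remain
    applicable; ``n_unmapped`` counts features absent from the annotation.
    """

    values: pd.DataFrame
    level: str  # "probe_ratio" once mapped
    sample_ids: list[str]
    n_unmapped: int = 0
    n_duplicates: int = 0


def read_geo_series_matrix(path, probe_annotation: pd.DataFrame | None = None) -> GeoSeries:
    """Parse a GEO series-matrix (or SOFT-style) text file.

    ``probe_annotation`` maps array feature ids to genes: columns
    probe_id, gene_id, genome_index.  Without it the features cannot be
    placed on the reference genome and an error explains what to supply.
    Duplicate feature ids follow a last-wins rule with a warning.
    """
    if probe_annotation is None:
        raise ValueError(
            "a probe annotation (probe_id, gene_id, genome_index) is required "
            "to map array features to reference genes; supply the series' "
            "platform table"
        )
    lines = Path(path).read_text().splitlines()
    table: list[str] = []
    in_table = False
    for line in lines:
        low = line.lower()
        if low.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if low.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table and line.strip():
            table.append(line)
    if not table:
        raise SchemaError(f"{path}: no series_matrix_table section found")
    df = pd.read_csv(_io.StringIO("\n".join(table)), sep="\t")
    df.columns = [str(c).strip('"') for c in df.columns]
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str).str.strip('"')

    n_dup = int(df[id_col].duplicated().sum())
    if n_dup:
        warnings.warn(f"{n_dup} duplicate feature id(s); keeping the last occurrence")
        df = df.drop_duplicates(id_col, keep="last")

    ann = probe_annotation.set_index("probe_id")
    mapped = df[df[id_col].isin(ann.index)].copy()
    n_unmapped = len(df) - len(mapped)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} feature(s) not in the probe annotation; skipped")
    sample_ids = [c for c in df.columns if c != id_col]
    values = mapped.set_index(id_col)[sample_ids].apply(pd.to_numeric, errors="coerce")
    values.insert(0, "gene_id", ann.loc[values.index, "gene_id"])
    values.insert(1, "genome_index", ann.loc[values.index, "genome_index"])
    return GeoSeries(
        values=values.reset_index(names="probe_id"),
        level="probe_ratio",
        sample_ids=sample_ids,
        n_unmapped=n_unmapped,
        n_duplicates=n_dup,
    )


def geo_sample_profile(series: GeoSeries, sample_id: str,
                       config: PipelineConfig | None = None,
                       strain_id: str | None = None,
                       reference_id: str = "reference") -> _calling.ConservationProfile:
    """Build a conservation profile from one GEO sample's probe-level log2
    ratios (probe QC and channel normalization are skipped: the deposited
    values are already processed)."""
    config = config or PipelineConfig()
    ratios = pd.DataFrame({
        "probe_id": series.values["probe_id"],
        "gene_id": series.values["gene_id"],
        "genome_index": series.values["genome_index"],
        "log2_ratio": series.values[sample_id],
    }).dropna(subset=["log2_ratio"])
    probe_map = series.values[["probe_id", "gene_id", "genome_index"]]
    gene_ratios = _probes.summarize_gene_ratios(ratios, probe_map, config.min_probes)
    return _calling.call_conservation(
        gene_ratios, config.threshold, config.bin_width,
        strain_id=strain_id or sample_id, reference_id=reference_id)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    profiles: dict[str, _calling.ConservationProfile]
    qc_reports: dict[str, _probes.QCReport]
    normalization_shifts: dict[str, float]
    comparison: _comparison.ComparisonResult | None = None
    regions: dict[str, list] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "strains": {s: p.summary() for s, p in self.profiles.items()},
            "normalization_shifts": self.normalization_shifts,
            "qc": {s: {"n_input": r.n_input, "n_retained": r.n_retained}
                   for s, r in self.qc_reports.items()},
        }
        if self.comparison is not None:
            out["comparison"] = {
                "strains": list(self.comparison.strain_ids),
                "counts": self.comparison.counts,
                "n_excluded_no_call": len(self.comparison.excluded),
            }
        out["variable_regions"] = {s: len(r) for s, r in self.regions.items()}
        return out


def run_pipeline(
    config: PipelineConfig,
    inputs: dict[str, pd.DataFrame],
    probe_map: pd.DataFrame,
    reference_id: str = "reference",
) -> PipelineResult:
    """Run filter -> ratio -> normalize -> summarize -> call (-> compare)
    on one probe intensity table per strain.

    With two strains the result includes their differential gene sets; with
    three, the 8-way joint classification.  Any stage error aborts with the
    stage and strain named.
    """
    if not inputs:
        raise ValueError("at least one hybridization input is required")
    profiles: dict[str, _calling.ConservationProfile] = {}
    reports: dict[str, _probes.QCReport] = {}
    shifts: dict[str, float] = {}
    regions: dict[str, list] = {}
    for strain, spots in inputs.items():
        stage = "filter_probes"
        try:
            retained, report = _probes.filter_probes(spots, config.qc_channel)
            log.info("%s: QC retained %d/%d spots", strain, report.n_retained, report.n_input)
            stage = "compute_probe_ratios"
            ratios = _probes.compute_probe_ratios(retained)
            stage = "normalize_ratios"
            ratios, s = _probes.normalize_ratios(ratios, retained, config.normalization)
            log.info("%s: normalization (%s) shift %.4f", strain, config.normalization, s)
            stage = "summarize_gene_ratios"
            gene_ratios = _probes.summarize_gene_ratios(ratios, probe_map, config.min_probes)
            stage = "call_conservation"
            profile = _calling.call_conservation(
                gene_ratios, config.threshold, config.bin_width,
                strain_id=strain, reference_id=reference_id)
            log.info("%s: conserved fraction %.4f, mode %.3f",
                     strain, profile.conserved_fraction, profile.mode)
            stage = "detect_runs"
            regions[strain] = _comparison.detect_runs(
                profile, _calling.CALL_ABSENT, config.run_min, config.run_gap)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed for strain {strain!r}: {exc}") from exc
        profiles[strain] = profile
        reports[strain] = report
        shifts[strain] = s

    comparison = None
    plist = list(profiles.values())
    if len(plist) == 2:
        comparison = _comparison.differential_sets(*plist)
    elif len(plist) == 3:
        comparison = _comparison.three_way_classify(*plist)
    return PipelineResult(config, profiles, reports, shifts, comparison, regions)
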