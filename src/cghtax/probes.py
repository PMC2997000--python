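"""Probe-level CGH data treatment: QC filtering, log2 ratios, channel
normalization and per-gene median summarization.

The processing chain mirrors standard two-color array CGH practice:

1. eliminate spots whose reference-channel foreground is lower than twice
   the standard deviation of the local background (the test channel is not
   consulted by default: a weak test signal is biology, not a bad spot);
2. per retained spot, log2(test_fg / ref_fg) **without** background
   subtraction;
3. optional global channel normalization (a single additive log2 shift);
4. per gene, the median of its surviving probes' log2 ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-gene ratio table
GENE_RATIO_COLUMNS = ["gene_id", "genome_index", "median_log2", "n_probes_used"]


@dataclass
class QCReport:
    """Spot-filtering report: global and per-gene retained/eliminated counts
    plus per-spot errors (e.g. missing background SD)."""

    n_input: int
    n_retained: int
    n_eliminated: int
    per_gene: pd.DataFrame  # gene_id, n_retained, n_eliminated
    errors: list[str] = field(default_factory=list)

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def as_text(self) -> str:
        lines = [
            "# probe QC report",
            f"n_input\t{self.n_input}",
            f"n_retained\t{self.n_retained}",
            f"n_eliminated\t{self.n_eliminated}",
            f"retained_fraction\t{self.retained_fraction:.6f}",
            f"n_errors\t{len(self.errors)}",
        ]
        lines += [f"# error: {e}" for e in self.errors]
        return "\n".join(lines) + "\n"


def filter_probes(
    spots: pd.DataFrame, channel: str = "ref"
) -> tuple[pd.DataFrame, QCReport]:
    """Eliminate spots with foreground below twice the local-background SD.

    The rule is strict ("lower than"): a spot at exactly 2 x SD is
    retained.  ``channel`` selects which channel(s) must pass: ``"ref"``
    (default) or ``"both"``.  Spots with missing background SD are
    eliminated and recorded as per-spot errors; the run continues.
    """
    if channel not in ("ref", "both"):
        raise ValueError("channel must be 'ref' or 'both'")
    errors: list[str] = []

    def channel_ok(fg: pd.Series, bg_sd: pd.Series, name: str) -> pd.Series:
        missing = bg_sd.isna() | fg.isna()
        for pid in spots.loc[missing, "probe_id"]:
            errors.append(f"probe {pid}: missing {name} statistics; spot eliminated")
        return ~missing & (fg >= 2.0 * bg_sd)

    keep = channel_ok(spots["ref_fg"], spots["ref_bg_sd"], "reference-channel")
    if channel == "both":
        keep &= channel_ok(spots["test_fg"], spots["test_bg_sd"], "test-channel")

    retained = spots[keep].copy()
    per_gene = (
        pd.DataFrame({"gene_id": spots["gene_id"], "retained": keep})
        .groupby("gene_id", sort=True)["retained"]
        .agg(n_retained="sum", n_eliminated=lambda s: int((~s).sum()))
        .reset_index()
    )
    report = QCReport(
        n_input=len(spots),
        n_retained=int(keep.sum()),
        n_eliminated=int((~keep).sum()),
        per_gene=per_gene,
        errors=errors,
    )
    return retained, report


def compute_probe_ratios(spots: pd.DataFrame) -> pd.DataFrame:
    """Raw per-spot log2(test/ref) ratios, computed without background
    subtraction.

    Spots with nonpositive foreground in either channel cannot yield a
    finite log ratio and are dropped with a warning.
    """
    ok = (spots["ref_fg"] > 0) & (spots["test_fg"] > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} retained spot(s) with nonpositive foreground")
    kept = spots[ok]
    out = pd.DataFrame({
        "probe_id": kept["probe_id"],
        "gene_id": kept["gene_id"],
        "genome_index": kept["genome_index"],
        "log2_ratio": np.log2(kept["test_fg"].to_numpy() / kept["ref_fg"].to_numpy()),
    })
    return out.reset_index(drop=True)


def normalize_ratios(
    ratios: pd.DataFrame, spots: pd.DataFrame, method: str = "total"
) -> tuple[pd.DataFrame, float]:
    """Apply a global channel normalization to probe log2 ratios.

    ``method="total"`` adds the single shift s = log2(sum ref_fg / sum
    test_fg) over the retained spots, equalizing channel totals.  That is
    appropriate when the two genomes share most of their gene content and
    channel gains are uncalibrated; it deliberately removes *any* global
    ratio offset, including a genuine species-level efficiency shift, so
    inter-species arrays scanned on a calibrated absolute scale should use
    ``method="none"`` (s = 0).  Returns (normalized ratios, s).
    """
    if len(ratios) == 0:
        raise ValueError("cannot normalize an empty ratio list")
    if method == "none":
        s = 0.0
    elif method == "total":
        tot_ref = float(spots["ref_fg"].sum())
        tot_test = float(spots["test_fg"].sum())
        if tot_ref <= 0 or tot_test <= 0:
            raise ValueError("channel totals must be positive for total normalization")
        s = float(np.log2(tot_ref / tot_test))
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    out = ratios.copy()
    out["log2_ratio"] = out["log2_ratio"] + s
    return out, s


def summarize_gene_ratios(
    ratios: pd.DataFrame, probe_map: pd.DataFrame, min_probes: int = 2
) -> pd.DataFrame:
    """Per-gene median of surviving probe log2 ratios.

    Every gene of ``probe_map`` appears in the output (genes with no
    surviving probe get ``n_probes_used`` 0).  Genes with fewer than
    ``min_probes`` surviving probes get no median (NaN) and are flagged
    ``no_call`` downstream; even probe counts use the midpoint of the two
    central values.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    genes = probe_map[["gene_id", "genome_index"]].drop_duplicates("gene_id")
    grouped = ratios.groupby("gene_id")["log2_ratio"]
    med = grouped.median()
    n = grouped.size()
    out = genes.copy()
    out["median_log2"] = out["gene_id"].map(med)
    out["n_probes_used"] = out["gene_id"].map(n).fillna(0).astype(int)
    out.loc[out["n_probes_used"] < min_probes, "median_log2"] = np.nan
    return out.sort_values("genome_index").reset_index(drop=True)[GENE_RATIO_COLUMNS]
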