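"""Numerical taxonomy: ternary phenotype encoding, Pearson similarity,
UPGMA dendrograms on a similarity-percentage scale, and DNA-DNA
hybridization (DDH) relative re-association tables.

The clustering convention follows classical phenotypic taxonomy: pairwise
Pearson correlation r between character vectors, expressed as a percentage,
clustered by UPGMA (unweighted pair-group method with arithmetic averages);
dendrogram node heights are the similarity percentages at which clusters
join, so heights decrease from the leaves (100%) toward the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: default ternary encoding: positive, negative, variable ("d")
ENCODINGS = {
    "half": {"+": 1.0, "-": 0.0, "d": 0.5},
    "negative": {"+": 1.0, "-": 0.0, "d": 0.0},
    "positive": {"+": 1.0, "-": 0.0, "d": 1.0},
}


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("cghtax").joinpath("data", name)

def load_phenotype_table() -> pd.DataFrame:
    """Packaged phenotype character table (26 Lactobacillus strains x 29
    characters: API 50 CH carbohydrate fermentation plus growth tests),
    returned strains x characters with values in {+, -, d}."""
    with resources.as_file(_data_path("phenotype_characters.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    return df.T  # printed table is characters x strains

def load_ddh_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged DDH relative re-association table (26 target strains x 6
    probe strains; percent of the probe strain's self signal).

    Returns ``(mean, sd)`` DataFrames; self cells are 100 with SD NaN.
    """
    with resources.as_file(_data_path("ddh_reassociation.tsv")) as p:
        wide = pd.read_csv(p, sep="\t", index_col=0)
    probes = sorted({c.rsplit("_", 1)[0] for c in wide.columns})
    mean = pd.DataFrame({pr: wide[f"{pr}_mean"] for pr in probes})
    sd = pd.DataFrame({pr: wide[f"{pr}_sd"] for pr in probes})
    return mean, sd


# ---------------------------------------------------------------------------
# encoding and similarity
# ---------------------------------------------------------------------------

def encode_phenotypes(table: pd.DataFrame, scheme: str | dict = "half") -> pd.DataFrame:
    """Encode a ternary {+, -, d} character table as numbers.

    The default maps + -> 1, - -> 0 and the variable state d -> 0.5 (the
    symmetric choice); alternatives treat d as negative or positive.
    Unknown symbols raise a parse error naming the offending cell.
    """
    mapping = ENCODINGS[scheme] if isinstance(scheme, str) else dict(scheme)
    out = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    for col in table.columns:
        for row in table.index:
            v = table.at[row, col]
            v = v.strip() if isinstance(v, str) else v
            if v not in mapping:
                raise ValueError(f"unknown symbol {v!r} at strain {row!r}, character {col!r}")
            out.at[row, col] = mapping[v]
    return out


def pearson_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between strain character vectors, as percent.

    Rows are strains.  A zero-variance strain vector has no defined
    correlation; its off-diagonal similarities are set to 0 with a warning.
    The diagonal is exactly 100.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 strains and >= 2 characters")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        names = list(matrix.index[degenerate])
        warnings.warn(f"zero-variance strain vector(s) {names}; their similarities set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    sim = r * 100.0
    np.fill_diagonal(sim, 100.0)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# UPGMA on the similarity scale
# ---------------------------------------------------------------------------

@dataclass
class DendrogramNode:
    """Node of a rooted UPGMA dendrogram.

    ``height`` is the similarity percentage at which the node's children
    join (100 for leaves); heights are non-increasing from leaves to root.
    """

    height: float
    name: str | None = None  # leaf name; None for internal nodes
    children: tuple["DendrogramNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self) -> str:
        """Newick string; branch lengths are similarity drops between a node
        and its parent divided by two (ultrametric depth (100 - h) / 2),
        internal node labels carry the join similarity."""

        def fmt(node: DendrogramNode, parent_height: float) -> str:
            # similarity increases toward the leaves; depth below a node is
            # (100 - height)/2, so a child's branch spans half the similarity gain
            bl = (node.height - parent_height) / 2.0
            if node.is_leaf:
                return f"{node.name}:{bl:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}){node.height:g}:{bl:g}"

        if self.is_leaf:
            return f"{self.name}:0;"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner}){self.height:g};"


def upgma_tree(sim: pd.DataFrame) -> DendrogramNode:
    """UPGMA dendrogram from a symmetric similarity-percentage matrix.

    Iteratively joins the pair of clusters with maximal similarity; the new
    cluster's similarity to any other is the size-weighted arithmetic mean
    of its members' similarities.  Ties are broken by lexicographic
    strain-id order (each cluster represented by its smallest leaf id).
    """
    n = len(sim)
    if n < 2:
        raise ValueError("need >= 2 strains to cluster")
    if list(sim.index) != list(sim.columns):
        raise ValueError("similarity matrix index and columns must match")
    s = sim.to_numpy(dtype=float)
    if not np.allclose(s, s.T):
        raise ValueError("similarity matrix must be symmetric")

    clusters: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=100.0, name=str(sim.index[i])) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: str(sim.index[i]) for i in range(n)}  # smallest leaf id
    simd = {(min(i, j), max(i, j)): s[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(clusters) > 1:
        # maximal similarity; ties by lexicographic (sorted) representative pair
        best_key = None
        best = None
        for (i, j), v in simd.items():
            rep = tuple(sorted((reps[i], reps[j])))
            cand = (-v, rep)
            if best is None or cand < best:
                best = cand
                best_key = (i, j)
        i, j = best_key
        height = simd[(i, j)]
        node = DendrogramNode(height=height, children=(clusters[i], clusters[j]))
        ni, nj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            sik = simd.pop((min(i, k), max(i, k)))
            sjk = simd.pop((min(j, k), max(j, k)))
            simd[(min(next_id, k), max(next_id, k))] = (ni * sik + nj * sjk) / (ni + nj)
        del simd[(i, j)]
        for old in (i, j):
            del clusters[old], sizes[old], reps[old]
        clusters[next_id] = node
        sizes[next_id] = ni + nj
        reps[next_id] = min(node.leaves())
        next_id += 1

    return clusters.popitem()[1]


@dataclass
class SubclusterResult:
    height: float | None
    monophyletic: bool
    intruders: list[str]


def subcluster_similarity(tree: DendrogramNode, strain_ids) -> SubclusterResult:
    """Similarity at the smallest clade containing all ``strain_ids``.

    If that clade contains no other leaves the strains are monophyletic and
    the clade's join similarity is returned (a single strain returns the
    leaf height, 100).  Otherwise the intruding leaves are reported.
    """
    wanted = set(map(str, strain_ids))
    all_leaves = set(tree.leaves())
    unknown = wanted - all_leaves
    if unknown:
        raise ValueError(f"unknown strain id(s): {sorted(unknown)}")

    best = None
    for node in tree.walk():
        lv = set(node.leaves())
        if wanted <= lv and (best is None or len(lv) < len(best[1])):
            best = (node, lv)
    node, lv = best
    intruders = sorted(lv - wanted)
    return SubclusterResult(
        height=node.height if not intruders else node.height,
        monophyletic=not intruders,
        intruders=intruders,
    )


# ---------------------------------------------------------------------------
# DDH relative re-association
# ---------------------------------------------------------------------------

def ddh_relative_values(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DDH table from raw dot-blot signals.

    ``raw`` is a long table (probe_strain, target_strain, replicate,
    signal); replicates pool membranes and DNA aliquot amounts equally.
    Per replicate, value = 100 * signal(target) / signal(self); cells are
    the mean and SD over replicates.  Self cells are fixed at exactly 100
    with SD omitted (NaN).  Values above 100 are legal.
    """
    required = {"probe_strain", "target_strain", "replicate", "signal"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw DDH table missing column(s): {sorted(missing)}")

    probes = sorted(raw["probe_strain"].unique())
    targets = sorted(raw["target_strain"].unique())
    mean = pd.DataFrame(index=targets, columns=probes, dtype=float)
    sd = pd.DataFrame(index=targets, columns=probes, dtype=float)
    for probe, sub in raw.groupby("probe_strain"):
        self_sig = (
            sub[sub["target_strain"] == probe]
            .set_index("replicate")["signal"]
        )
        if len(self_sig) == 0 or (self_sig <= 0).any():
            raise ValueError(f"probe strain {probe!r} lacks a positive self-target signal")
        for target, tt in sub.groupby("target_strain"):
            rel = 100.0 * tt.set_index("replicate")["signal"] / self_sig.reindex(tt["replicate"]).to_numpy()
            mean.at[target, probe] = float(rel.mean())
            sd.at[target, probe] = float(rel.std(ddof=1)) if len(rel) > 1 else 0.0
        mean.at[probe, probe] = 100.0
        sd.at[probe, probe] = np.nan
    return mean, sd
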