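"""Downstream analysis of interaction scores.

Thresholding into synthetic-lethal calls, the annotated interaction
network, interaction-profile clustering and embedding, cross-cell-line
overlap, and the additive-expectation phenotype used to benchmark
validation growth assays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

DEFAULT_SL_CUTOFF = -1.0
DEFAULT_N_CLUSTERS = 20


def call_synthetic_lethal(
    scores: pd.DataFrame, cutoff: float = DEFAULT_SL_CUTOFF
) -> pd.DataFrame:
    """Pairs with sensitive score <= cutoff, strongest (most negative) first."""
    hits = scores[scores["sensitive_score"] <= cutoff]
    return hits.sort_values("sensitive_score").reset_index(drop=True)


def build_network(
    pairs: pd.DataFrame,
    cancer_genes: set[str] | None = None,
    drug_targets: set[str] | None = None,
) -> nx.Graph:
    """Synthetic-lethal network with user-supplied annotation flags.

    Edge weight is |sensitive_score| (interaction strength; drawn as
    edge width). Nodes carry ``cancer_gene`` / ``druggable`` membership
    flags; an edge is ``actionable`` when one endpoint is a cancer gene
    and the other a small-molecule target.
    """
    cancer_genes = cancer_genes or set()
    drug_targets = drug_targets or set()
    g = nx.Graph()
    n_actionable = 0
    for row in pairs.to_dict("records"):
        a, b = row["gene_a"], row["gene_b"]
        weight = abs(float(row["sensitive_score"]))
        actionable = (a in cancer_genes and b in drug_targets) or (
            b in cancer_genes and a in drug_targets
        )
        n_actionable += actionable
        g.add_edge(a, b, weight=weight, actionable=bool(actionable))
    for node in g.nodes:
        g.nodes[node]["cancer_gene"] = node in cancer_genes
        g.nodes[node]["druggable"] = node in drug_targets
    g.graph["n_actionable"] = int(n_actionable)
    return g


def symmetric_score_matrix(
    scores: pd.DataFrame, column: str = "sensitive_score"
) -> pd.DataFrame:
    """Gene x gene symmetric score matrix; unqueried pairs sit at 0.

    Zero is the non-interacting value under the clipping convention, so
    unqueried pairs are indistinguishable from measured non-interactors
    by construction.
    """
    genes = sorted(set(scores["gene_a"]) | set(scores["gene_b"]))
    mat = pd.DataFrame(0.0, index=genes, columns=genes)
    for row in scores.to_dict("records"):
        v = float(row[column])
        mat.loc[row["gene_a"], row["gene_b"]] = v
        mat.loc[row["gene_b"], row["gene_a"]] = v
    return mat


@dataclass
class ClusterResult:
    genes: list[str]
    matrix: pd.DataFrame  # symmetric sensitive-score matrix over retained genes
    linkage: np.ndarray
    labels: pd.Series  # gene -> cluster id (1..k)
    filter_mean: float
    filter_sd: float


def cluster_profiles(
    scores: pd.DataFrame,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    two_sided: bool = True,
) -> ClusterResult:
    """Ward clustering of interaction profiles of strong interactors.

    Genes are retained when at least one of their pairs scores 2 s.d.
    or more away from the mean of all non-zero sensitive scores
    (``two_sided=False`` keeps only the low tail). Rows of the retained
    symmetric score matrix are then clustered with Ward variance
    minimization; output is deterministic.
    """
    nz = scores.loc[scores["sensitive_score"] != 0, "sensitive_score"]
    if nz.empty:
        raise ValueError("no non-zero sensitive scores; nothing to cluster")
    m = float(nz.mean())
    sd = float(nz.std(ddof=1)) if len(nz) > 1 else 0.0

    keep: set[str] = set()
    for row in scores.to_dict("records"):
        v = float(row["sensitive_score"])
        dev = v - m
        extreme = abs(dev) >= 2 * sd if two_sided else dev <= -2 * sd
        if extreme:
            keep.update((row["gene_a"], row["gene_b"]))
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} genes pass the 2-s.d. filter "
            f"(mean {m:.3g}, sd {sd:.3g}); need at least 2"
        )
    mat = symmetric_score_matrix(scores).loc[sorted(keep), sorted(keep)]
    link = sch.linkage(mat.values, method="ward")
    k = min(n_clusters, len(mat))
    labels = sch.fcluster(link, t=k, criterion="maxclust")
    return ClusterResult(
        genes=list(mat.index),
        matrix=mat,
        linkage=link,
        labels=pd.Series(labels, index=mat.index, name="cluster"),
        filter_mean=m,
        filter_sd=sd,
    )


def embed_profiles(
    scores: pd.DataFrame,
    method: Callable[[np.ndarray], np.ndarray] | None = None,
    column: str = "strong_score",
    random_state: int = 0,
) -> pd.DataFrame:
    """2-D embedding of the symmetric strong-score profiles.

    The backend is pluggable: ``method`` maps an (n_genes, n_genes)
    array to (n_genes, 2) coordinates. The default is UMAP on the raw
    symmetric matrix (no prior dimension reduction) with a fixed random
    state, so repeated runs give identical coordinates.
    """
    mat = symmetric_score_matrix(scores, column=column)
    if len(mat) < 3:
        raise ValueError("need at least 3 genes to embed")
    if method is None:
        import umap  # heavy import; deferred

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(15, len(mat) - 1),
            min_dist=0.1,
            random_state=random_state,
        )
        coords = reducer.fit_transform(mat.values)
    else:
        coords = np.asarray(method(mat.values))
    if coords.shape != (len(mat), 2):
        raise ValueError(f"embedder returned shape {coords.shape}, expected ({len(mat)}, 2)")
    return pd.DataFrame(coords, index=mat.index, columns=["umap1", "umap2"])


@dataclass
class OverlapResult:
    flagged: dict[str, set[tuple[str, str]]]  # per line, over the common universe
    partition: dict[frozenset, int]  # Venn partition: lines present -> pair count
    fractions_vs_reference: dict[str, float]
    universe_size: int
    reference: str


def cross_line_overlap(
    tables: Mapping[str, pd.DataFrame],
    cutoffs: Mapping[str, float],
    reference: str | None = None,
) -> OverlapResult:
    """Compare synthetic-lethal calls across cell lines.

    Each line's score table is thresholded at its own cutoff (screens in
    different lines have different dynamic ranges, hence per-line
    cutoffs); comparisons run over the intersection of the gene-pair
    universes. The Venn partition maps each non-empty line combination
    to its exclusive pair count; fractions are shares of the reference
    line's flagged set recovered in each other line.
    """
    if reference is None:
        reference = next(iter(tables))
    if reference not in tables:
        raise ValueError(f"reference line {reference!r} not among tables")
    missing = set(tables) - set(cutoffs)
    if missing:
        raise ValueError(f"no cutoff for lines: {sorted(missing)}")

    def pairs_of(df: pd.DataFrame) -> dict[tuple[str, str], float]:
        return {
            tuple(sorted((r["gene_a"], r["gene_b"]))): float(r["sensitive_score"])
            for r in df.to_dict("records")
        }

    per_line = {line: pairs_of(df) for line, df in tables.items()}
    universe = set.intersection(*(set(p) for p in per_line.values()))
    if not universe:
        raise ValueError("gene-pair universes have empty intersection")

    flagged = {
        line: {p for p in universe if per_line[line][p] <= cutoffs[line]}
        for line in tables
    }
    lines = list(tables)
    partition: dict[frozenset, int] = {}
    union = set().union(*flagged.values())
    for p in union:
        key = frozenset(line for line in lines if p in flagged[line])
        partition[key] = partition.get(key, 0) + 1
    ref_set = flagged[reference]
    fractions = {
        line: (len(flagged[line] & ref_set) / len(ref_set)) if ref_set else float("nan")
        for line in lines
    }
    return OverlapResult(
        flagged=flagged,
        partition=partition,
        fractions_vs_reference=fractions,
        universe_size=len(universe),
        reference=reference,
    )


def additive_expectation(phenotype_a: float, phenotype_b: float) -> float:
    """Expected double-knockdown phenotype under additivity of log2 FCs."""
    return phenotype_a + phenotype_b
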