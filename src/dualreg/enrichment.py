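"""Over-representation analysis with direction merging and term clustering.

The workflow mirrors a common enrichment post-processing recipe: run the
hypergeometric over-representation test separately on the upregulated,
downregulated and complete gene lists; merge the three runs keeping, per
term, the row with the largest intersection; filter to terms with more
than three hits and FDR-adjusted p below 0.05; build a term-term
similarity matrix from the overlapping intersection gene ids; and group
terms by k-means over the similarity matrix rows with the number of
clusters selected by mean silhouette (distance = 1 - similarity), plus an
average-linkage ordering for display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import GeneSetCollection, bh_adjust

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term_name", "p_value", "adj_p", "hits", "term_size",
                      "gene_ratio", "direction", "intersection"]
DIRECTION_PRECEDENCE = {"all": 0, "up": 1, "down": 2}


def ora_test(
    query: set,
    universe: set,
    gene_sets: GeneSetCollection,
    direction: str = "all",
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For each term, p is the upper-tail probability of observing at least
    the realized overlap between the query and the term's genes restricted
    to the universe, drawing |query| genes from the universe.  Terms with
    zero hits are retained with p = 1 (they fall to downstream filtering).
    ``gene_ratio`` is hits / term size (the full annotated set size).
    Benjamini-Hochberg adjustment is applied across the tested terms.

    Returns a DataFrame indexed by term_id with columns term_name,
    p_value, adj_p, hits, term_size, gene_ratio, direction, intersection.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = set(query) - set(universe)
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")

    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term_id in sorted(gene_sets.sets):
        members = gene_sets.sets[term_id]
        in_universe = members & universe
        hits_set = in_universe & query
        hits = len(hits_set)
        if hits == 0 or not in_universe:
            p = 1.0
        else:
            p = float(hypergeom.sf(hits - 1, n_universe, len(in_universe), n_query))
        term_size = len(members)
        rows.append({
            "term_id": term_id,
            "term_name": gene_sets.names.get(term_id, term_id),
            "p_value": min(p, 1.0),
            "hits": hits,
            "term_size": term_size,
            "gene_ratio": hits / term_size,
            "direction": direction,
            "intersection": frozenset(hits_set),
        })
    table = pd.DataFrame(rows).set_index("term_id")
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    return table[ENRICHMENT_COLUMNS]


def merge_direction_runs(
    up: pd.DataFrame,
    down: pd.DataFrame,
    all_genes: pd.DataFrame,
) -> pd.DataFrame:
    """Combine up/down/complete enrichment runs, one row per term.

    Redundant rows for the same term are collapsed keeping the largest
    intersection size (hits); ties broken by smaller adjusted p, then by
    direction precedence all > up > down.
    """
    combined = pd.concat([all_genes, up, down])
    if combined.empty:
        return combined
    combined = combined.reset_index()
    combined["_prec"] = combined["direction"].map(DIRECTION_PRECEDENCE)
    combined = combined.sort_values(
        ["hits", "adj_p", "_prec"], ascending=[False, True, True], kind="stable")
    merged = combined.drop_duplicates("term_id").drop(columns="_prec")
    return merged.set_index("term_id").sort_index()[ENRICHMENT_COLUMNS]


def filter_terms(
    table: pd.DataFrame,
    min_hits: int = 4,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Retain terms with hits >= min_hits (i.e. more than 3) and adj_p < fdr_max."""
    if table.empty:
        return table
    keep = (table["hits"] >= min_hits) & (table["adj_p"] < fdr_max)
    return table[keep]


def term_similarity(table: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise term similarity from overlapping intersection gene ids.

    ``jaccard``: |A n B| / |A u B|;  ``overlap``: |A n B| / min(|A|, |B|).
    Requires at least two retained terms.
    """
    if len(table) < 2:
        raise ValueError(f"need >= 2 terms for a similarity matrix, got {len(table)}")
    if metric not in ("jaccard", "overlap"):
        raise ValueError(f"unknown similarity metric {metric!r}")
    terms = list(table.index)
    sets = [set(s) for s in table["intersection"]]
    n = len(terms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if metric == "jaccard":
                denom = len(sets[i] | sets[j])
            else:
                denom = min(len(sets[i]), len(sets[j]))
            sim[i, j] = sim[j, i] = inter / denom if denom else 0.0
    return pd.DataFrame(sim, index=terms, columns=terms)


@dataclass
class TermClusterResult:
    """Similarity matrix with cluster labels, silhouette curve and ordering."""

    similarity: pd.DataFrame
    labels: pd.Series
    k: int
    silhouette_curve: dict
    order: list = field(default_factory=list)


class TermClusterer(BaseEstimator):
    """Group enrichment terms by k-means with silhouette-selected k.

    Terms are embedded as rows of their similarity matrix; k-means is run
    for each candidate k with a fixed seed and multiple restarts, and the
    k maximizing the mean silhouette (on distance = 1 - similarity) is
    selected.  An average-linkage ordering of the terms is also computed
    for display.  A degenerate matrix (all rows equal) yields a single
    cluster with a warning.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : pd.Series          cluster label per term
    k_ : int                     selected number of clusters
    silhouette_curve_ : dict     candidate k -> mean silhouette
    order_ : list                term ids in average-linkage leaf order
    """

    def __init__(self, k_min: int = 2, k_max: int | None = None,
                 restarts: int = 50, random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, similarity: pd.DataFrame, y=None) -> "TermClusterer":
        sim = np.asarray(similarity, dtype=float)
        terms = list(similarity.index)
        n = len(terms)
        if sim.shape != (n, n) or not np.allclose(sim, sim.T, atol=1e-9):
            raise ValueError("similarity must be a square symmetric matrix")

        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
        self.order_ = [terms[i] for i in hierarchy.leaves_list(linkage)]

        if np.allclose(sim, sim[0], atol=1e-12):
            warnings.warn("degenerate similarity matrix (all rows equal); "
                          "returning a single cluster")
            self.k_ = 1
            self.labels_ = pd.Series(0, index=terms, name="cluster")
            self.silhouette_curve_ = {}
            return self

        k_max = self.k_max if self.k_max is not None else n - 1
        if k_max > n - 1:
            raise ValueError(f"k_max={k_max} exceeds n_terms - 1 = {n - 1}")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")

        curve: dict = {}
        labelings: dict = {}
        for k in range(self.k_min, k_max + 1):
            km = KMeans(n_clusters=k, n_init=self.restarts,
                        random_state=self.random_state)
            labels = km.fit_predict(sim)
            if len(np.unique(labels)) < 2:
                continue
            curve[k] = float(silhouette_score(dist, labels, metric="precomputed"))
            labelings[k] = labels
        if not curve:
            raise ValueError("no candidate k produced a valid clustering")

        self.k_ = max(curve, key=lambda k: (curve[k], -k))
        self.labels_ = pd.Series(labelings[self.k_], index=terms, name="cluster")
        self.silhouette_curve_ = curve
        return self

    def result(self, similarity: pd.DataFrame) -> TermClusterResult:
        return TermClusterResult(similarity=similarity, labels=self.labels_,
                                 k=self.k_, silhouette_curve=self.silhouette_curve_,
                                 order=self.order_)


def cluster_terms(
    similarity: pd.DataFrame,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    restarts: int = 50,
) -> TermClusterResult:
    """Functional wrapper over :class:`TermClusterer`."""
    clusterer = TermClusterer(k_min=k_min, k_max=k_max, restarts=restarts,
                              random_state=seed).fit(similarity)
    return clusterer.result(similarity)


def cluster_unique_genes(table: pd.DataFrame, labels: pd.Series) -> dict:
    """Unique gene ids per cluster.

    The union of intersection genes of the cluster's terms, minus any gene
    appearing in a term of another cluster.
    """
    unions: dict = {}
    for term, cluster in labels.items():
        unions.setdefault(cluster, set()).update(table.loc[term, "intersection"])
    unique = {}
    for cluster, genes in unions.items():
        others = set().union(*(g for c, g in unions.items() if c != cluster)) \
            if len(unions) > 1 else set()
        unique[cluster] = genes - others
    return unique


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    """Write an enrichment table as TSV, intersections comma-joined."""
    out = table.copy()
    out["intersection"] = [",".join(sorted(s)) for s in out["intersection"]]
    out.rename_axis("term_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g")
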