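"""DEG calling, L/S/LS set classification and co-regulation statistics.

Genes are called differentially expressed in a contrast when
|log2FC| >= ``lfc_min`` (closed bound) and adjusted p < ``fdr_max`` (open
bound).  Classification over the three contrasts follows the epistasis
set rules: a gene is an L-DEG when detected in the L and LS contrasts but
not S, an S-DEG when detected in S and LS but not L, an LS-DEG when
detected in all three, and OTHER for every remaining detection pattern.
Co-regulation statistics compare the LS-DEGs' fold changes between the
two single-mutant contrasts: Pearson correlation of the scatter plus the
inversely-regulated subset (opposite signs, both magnitudes beyond the
fold-change threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .io import DETable

logger = logging.getLogger(__name__)

DEG_LABELS = ("L_DEG", "S_DEG", "LS_DEG", "OTHER")
CONCORDANCE_LABELS = ("concordant", "inverse", "sub-threshold")


@dataclass(frozen=True)
class Thresholds:
    """DEG-calling thresholds: fold-change floor and FDR ceiling.

    ``lfc_min`` (default 0.5) is applied as |log2FC| >= lfc_min;
    ``fdr_max`` (default 0.05) as adjusted p < fdr_max.
    """

    lfc_min: float = 0.5
    fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise ValueError("lfc_min must be > 0")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")


@dataclass
class CoregulationSummary:
    """Pearson correlation and inverse-regulation statistics over LS-DEGs."""

    pearson_r: float
    n_ls: int
    n_inverse: int
    frac_inverse: float
    scatter: pd.DataFrame  # columns lfc_L, lfc_S, concordance; indexed by gene


def call_degs(table: DETable, thresholds: Thresholds | None = None) -> set:
    """Genes called DEGs: |log2fc| >= lfc_min and adj_p < fdr_max."""
    thresholds = thresholds or Thresholds()
    data = table.data
    mask = (data["log2fc"].abs() >= thresholds.lfc_min) & \
           (data["adj_p"] < thresholds.fdr_max)
    return set(data.index[mask])


def classify_pattern(in_l: bool, in_s: bool, in_ls: bool) -> str:
    """Class label for one detection pattern (the three-contrast rule)."""
    if in_l and in_ls and not in_s:
        return "L_DEG"
    if in_s and in_ls and not in_l:
        return "S_DEG"
    if in_l and in_s and in_ls:
        return "LS_DEG"
    return "OTHER"


class DEGClassifier(BaseEstimator):
    """Classify genes into L/S/LS/other from three mutant-vs-WT DE tables.

    Parameters
    ----------
    lfc_min : float, default 0.5
        Fold-change floor; a gene is detected when |log2FC| >= lfc_min.
    fdr_max : float, default 0.05
        Significance ceiling; detection additionally requires
        adjusted p < fdr_max.

    Attributes (after :meth:`fit`)
    ------------------------------
    universe_ : pd.Index
        Genes present in all three tables (the classification universe).
    detected_ : pd.DataFrame
        Boolean detection triple per gene (columns L, S, LS).
    labels_ : pd.Series
        Per-gene class label in {L_DEG, S_DEG, LS_DEG, OTHER}.
    counts_ : dict
        Class label -> count.
    pattern_counts_ : pd.Series
        Count per raw detection pattern (e.g. "L only", "LS only").
    n_dropped_ : int
        Genes absent from at least one table, excluded from the universe.
    """

    def __init__(self, lfc_min: float = 0.5, fdr_max: float = 0.05):
        self.lfc_min = lfc_min
        self.fdr_max = fdr_max

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(lfc_min=self.lfc_min, fdr_max=self.fdr_max)

    def fit(self, tables: dict, y=None) -> "DEGClassifier":
        """Fit from a dict with keys 'L', 'S', 'LS' mapping to DETable."""
        for key in ("L", "S", "LS"):
            if key not in tables:
                raise ValueError(f"tables must contain contrast {key!r}")
        thresholds = self.thresholds

        universe = tables["L"].genes
        for key in ("S", "LS"):
            universe = universe.intersection(tables[key].genes)
        universe = universe.sort_values()
        n_union = len(tables["L"].genes.union(tables["S"].genes)
                      .union(tables["LS"].genes))
        self.n_dropped_ = n_union - len(universe)
        if self.n_dropped_:
            logger.info("%d gene(s) absent from at least one table excluded "
                        "from the universe", self.n_dropped_)

        called = {key: call_degs(tables[key], thresholds) for key in ("L", "S", "LS")}
        detected = pd.DataFrame(
            {key: universe.isin(list(called[key])) for key in ("L", "S", "LS")},
            index=universe,
        )
        self.universe_ = universe
        self.detected_ = detected
        self.labels_ = self.predict_from_detection(detected)
        counts = self.labels_.value_counts()
        self.counts_ = {lab: int(counts.get(lab, 0)) for lab in DEG_LABELS}

        pattern = detected.apply(
            lambda row: "+".join([c for c in ("L", "S", "LS") if row[c]]) or "none",
            axis=1)
        self.pattern_counts_ = pattern.value_counts().sort_index()
        return self

    @staticmethod
    def predict_from_detection(detected: pd.DataFrame) -> pd.Series:
        """Vectorized label assignment from a boolean detection triple."""
        in_l = detected["L"].to_numpy()
        in_s = detected["S"].to_numpy()
        in_ls = detected["LS"].to_numpy()
        labels = np.full(len(detected), "OTHER", dtype=object)
        labels[in_l & in_ls & ~in_s] = "L_DEG"
        labels[in_s & in_ls & ~in_l] = "S_DEG"
        labels[in_l & in_s & in_ls] = "LS_DEG"
        return pd.Series(labels, index=detected.index, name="label")

    def genes_of(self, label: str) -> set:
        if label not in DEG_LABELS:
            raise ValueError(f"unknown label {label!r}")
        return set(self.labels_.index[self.labels_ == label])


def classify_degs(deg_L: set, deg_S: set, deg_LS: set, universe: set) -> pd.DataFrame:
    """Classify an explicit gene universe from three called-DEG sets.

    Returns a DataFrame indexed by gene with boolean columns L, S, LS and
    the class ``label``.  Genes in a DEG set but outside the universe are
    an error.
    """
    universe_idx = pd.Index(sorted(universe), name="gene")
    for name, deg in (("L", deg_L), ("S", deg_S), ("LS", deg_LS)):
        stray = set(deg) - set(universe)
        if stray:
            raise ValueError(f"genes in {name} DEG set but not in universe: "
                             f"{sorted(stray)[:5]}")
    detected = pd.DataFrame({
        "L": universe_idx.isin(list(deg_L)),
        "S": universe_idx.isin(list(deg_S)),
        "LS": universe_idx.isin(list(deg_LS)),
    }, index=universe_idx)
    detected["label"] = DEGClassifier.predict_from_detection(detected[["L", "S", "LS"]])
    return detected


def coregulation_stats(
    classification: pd.Series | DEGClassifier,
    table_L: DETable,
    table_S: DETable,
    thresholds: Thresholds | None = None,
) -> CoregulationSummary:
    """Co-/inverse-regulation statistics for LS-DEGs across the two contrasts.

    Pearson r is computed over the (log2FC in L, log2FC in S) pairs of all
    LS-DEGs.  A gene is *inverse* when its two fold changes have opposite
    signs and both magnitudes are >= ``lfc_min``; *sub-threshold* when
    either magnitude is below ``lfc_min``; *concordant* otherwise.
    """
    thresholds = thresholds or Thresholds()
    labels = classification.labels_ if isinstance(classification, DEGClassifier) \
        else classification
    ls_genes = labels.index[labels == "LS_DEG"]
    missing = [g for g in ls_genes
               if g not in table_L.genes or g not in table_S.genes]
    if missing:
        raise ValueError(f"LS-DEGs absent from a contrast table: {missing[:5]}")
    if len(ls_genes) < 2:
        raise ValueError(f"correlation undefined: only {len(ls_genes)} LS-DEG(s)")

    lfc_l = table_L.data.loc[ls_genes, "log2fc"].to_numpy()
    lfc_s = table_S.data.loc[ls_genes, "log2fc"].to_numpy()
    r = float(pearsonr(lfc_l, lfc_s)[0])

    opposite = np.sign(lfc_l) * np.sign(lfc_s) < 0
    beyond = (np.abs(lfc_l) >= thresholds.lfc_min) & \
             (np.abs(lfc_s) >= thresholds.lfc_min)
    concordance = np.full(len(ls_genes), "concordant", dtype=object)
    concordance[~beyond] = "sub-threshold"
    concordance[opposite & beyond] = "inverse"

    n_inverse = int((concordance == "inverse").sum())
    scatter = pd.DataFrame(
        {"lfc_L": lfc_l, "lfc_S": lfc_s, "concordance": concordance},
        index=pd.Index(ls_genes, name="gene"),
    )
    return CoregulationSummary(
        pearson_r=r,
        n_ls=len(ls_genes),
        n_inverse=n_inverse,
        frac_inverse=n_inverse / len(ls_genes),
        scatter=scatter,
    )
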