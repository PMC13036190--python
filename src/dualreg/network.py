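"""Annotate protein-interaction network nodes with DEG classes and directions.

Edges below the confidence cutoff (default 600, medium stringency on the
STRING 0-1000 scale) are dropped; each remaining node is annotated with
its DEG class (L_DEG / S_DEG / LS_DEG / OTHER) and a regulation direction:
``up`` or ``down`` when the gene's log2FC sign agrees across the contrasts
in which it was detected, ``inconsistent`` when the signs differ, ``none``
when the gene is detected in no contrast.  ``display_code`` is the
semantic token "<class>/<direction>" standing in for the figure color
scheme.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import DETable, InteractionEdgeList

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 600


def _direction_for_gene(gene: str, detected_row, tables: dict) -> str:
    """Direction from log2FC signs over the contrasts where the gene is detected.

    Falls back to all three contrasts when the gene is detected in none
    but is present in the tables; 'none' when no sign information exists.
    """
    contrasts = [c for c in ("L", "S", "LS")
                 if detected_row is not None and bool(detected_row[c])]
    if not contrasts:
        contrasts = [c for c in ("L", "S", "LS") if gene in tables[c].genes]
    signs = set()
    for c in contrasts:
        if gene in tables[c].genes:
            s = np.sign(tables[c].data.loc[gene, "log2fc"])
            if s != 0:
                signs.add(int(s))
    if not signs:
        return "none"
    if signs == {1}:
        return "up"
    if signs == {-1}:
        return "down"
    return "inconsistent"


def annotate_network_nodes(
    edges: InteractionEdgeList,
    classification,
    tables: dict,
    min_score: int = DEFAULT_MIN_SCORE,
) -> tuple:
    """Filter edges by confidence and annotate nodes with class and direction.

    Parameters
    ----------
    edges
        Interaction edge list with 0-1000 confidence scores.
    classification
        A fitted :class:`~dualreg.classify.DEGClassifier` or a DataFrame
        with boolean columns L, S, LS and a ``label`` column indexed by
        gene (``classify_degs`` output).  Genes not covered are OTHER.
    tables
        Dict with keys 'L', 'S', 'LS' of :class:`~dualreg.io.DETable`.
    min_score
        Minimum confidence; edges strictly below are dropped (600 keeps a
        score of exactly 600).

    Returns ``(node_table, filtered_edges)``.
    """
    for key in ("L", "S", "LS"):
        if key not in tables:
            raise ValueError(f"tables must contain contrast {key!r}")
    if hasattr(classification, "labels_"):
        labels = classification.labels_
        detected = classification.detected_
    else:
        labels = classification["label"]
        detected = classification[["L", "S", "LS"]]

    kept = edges.edges[edges.edges["score"] >= min_score].reset_index(drop=True)
    if kept.empty:
        logger.warning("no edges with confidence >= %d; network is empty", min_score)
        node_table = pd.DataFrame(
            columns=["deg_class", "direction", "display_code"]).rename_axis("gene")
        return node_table, InteractionEdgeList(edges=kept)

    nodes = sorted(set(kept["node_a"]) | set(kept["node_b"]))
    rows = []
    for gene in nodes:
        deg_class = labels.get(gene, "OTHER") if gene in labels.index else "OTHER"
        detected_row = detected.loc[gene] if gene in detected.index else None
        direction = _direction_for_gene(gene, detected_row, tables)
        rows.append({
            "gene": gene,
            "deg_class": deg_class,
            "direction": direction,
            "display_code": f"{deg_class}/{direction}",
        })
    node_table = pd.DataFrame(rows).set_index("gene")
    return node_table, InteractionEdgeList(edges=kept)
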