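"""Hub-gene screening by intramodular connectivity.

A gene's intramodular connectivity k_within is the sum of its weighted
adjacency (post soft-threshold power) to all other genes of its own
module.  Within each trait-specific module, the hubs are the top-ranked
annotated genes by k_within; genes without a usable functional annotation
are skipped rather than counted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GREY

logger = logging.getLogger(__name__)

__all__ = [
    "HubResult",
    "intramodular_connectivity",
    "select_hubs",
    "is_annotated",
    "hub_edge_list",
]

UNINFORMATIVE_PATTERNS = ("uncharacterized", "hypothetical")


@dataclass
class HubResult:
    gene_id: str
    module: str
    k_within: float
    annotation: str
    rank: int
    is_hub: bool


def intramodular_connectivity(adj: pd.DataFrame, modules: pd.Series) -> pd.Series:
    """k_within per gene: summed adjacency to same-module genes (self excluded).

    Grey genes are reported as NaN — connectivity among unassigned genes is
    not meaningful.
    """
    missing = adj.index.difference(modules.index)
    if len(missing):
        raise ValueError(f"module assignment missing for genes: {missing.tolist()[:10]}")
    a = adj.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    labels = modules.reindex(adj.index)
    k = pd.Series(np.nan, index=adj.index, name="k_within")
    for color in labels.unique():
        if color == GREY:
            continue
        idx = np.flatnonzero((labels == color).to_numpy())
        block = a[np.ix_(idx, idx)]
        k.iloc[idx] = block.sum(axis=1)
    return k


def is_annotated(description, patterns=UNINFORMATIVE_PATTERNS) -> bool:
    """True when a gene has a usable functional description.

    Empty/missing descriptions and those matching an uninformative pattern
    ("uncharacterized ...", "hypothetical protein") do not count.
    """
    if description is None or (isinstance(description, float) and np.isnan(description)):
        return False
    text = str(description).strip()
    if not text:
        return False
    return not any(re.search(p, text, flags=re.IGNORECASE) for p in patterns)


def select_hubs(
    k_within: pd.Series,
    modules: pd.Series,
    annotations: pd.Series,
    trait_modules: list[str],
    top_n: int = 5,
) -> pd.DataFrame:
    """Top annotated genes by connectivity within each trait-specific module.

    Within each module in ``trait_modules``, genes are ranked by k_within
    descending (ties broken lexicographically by gene id), unannotated
    genes are skipped, and the first ``top_n`` are flagged as hubs.  A
    module with fewer than ``top_n`` annotated genes yields all of them
    plus a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    rows = []
    for module in trait_modules:
        members = modules.index[modules == module]
        if len(members) == 0:
            raise ValueError(f"module {module!r} absent from the assignment")
        ranked = sorted(
            members,
            key=lambda g: (-float(k_within.get(g, np.nan)), g),
        )
        n_hubs = 0
        for rank, gene in enumerate(ranked, start=1):
            desc = annotations.get(gene, "")
            annotated = is_annotated(desc)
            hub = annotated and n_hubs < top_n
            if hub:
                n_hubs += 1
            rows.append(
                HubResult(
                    gene_id=gene, module=module,
                    k_within=float(k_within.get(gene, np.nan)),
                    annotation=str(desc) if annotated else "",
                    rank=rank, is_hub=hub,
                )
            )
        if n_hubs < top_n:
            logger.warning(
                "module %s has only %d annotated genes (top_n=%d)", module, n_hubs, top_n
            )
    return pd.DataFrame([vars(r) for r in rows])


def hub_edge_list(
    adj: pd.DataFrame, hub_genes: list[str], threshold: float = 0.1
) -> pd.DataFrame:
    """Edges between hub genes and their neighbours above a display threshold."""
    rows = []
    for g in hub_genes:
        if g not in adj.index:
            continue
        weights = adj.loc[g].drop(g)
        for other, w in weights[weights > threshold].items():
            if other in hub_genes and other < g:
                continue  # avoid duplicating hub-hub edges
            rows.append((g, other, float(w)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
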