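"""Category over-representation analysis by Fisher's exact test with BH FDR.

Given a gene list (e.g. the TE-specific hypomethylated genes), a gene ->
category map and a background universe, each category is tested with the
one-sided hypergeometric tail P(X >= k) and the p-values are adjusted with
the Benjamini-Hochberg step-up procedure.  Fold enrichment (k/n)/(K/N) is
reported alongside; no annotation-cluster enrichment score is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CategoryMap:
    """category_id -> set of gene symbols, plus the background universe."""

    categories: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for cat, genes in self.categories.items():
            if not genes:
                raise ValueError(f"category {cat!r} is empty")
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"category {cat!r} holds genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def read_category_map(path, universe: set | None = None) -> CategoryMap:
    """Read a category map from two-column TSV (category_id, gene) or GMT.

    GMT is detected by the ``.gmt`` suffix (category, description, genes...).
    When no universe is given it defaults to the union of all category genes.
    """
    path = Path(path)
    categories: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                categories[parts[0]] = set(g for g in parts[2:] if g)
    else:
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["category_id", "gene_symbol"], header=None)
        for cat, grp in df.groupby("category_id"):
            categories[cat] = set(grp["gene_symbol"])
    if universe is None:
        universe = set().union(*categories.values()) if categories else set()
    return CategoryMap(categories=categories, universe=set(universe))


def fisher_overrepresentation(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p-value: hypergeometric tail P(X >= k).

    k hits in a list of n genes, against a category of size K in a universe
    of N genes.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(gene_list, category_map: CategoryMap) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in every category with >= 1 hit.

    Genes outside the universe are logged and dropped.  Returns one row per
    tested category sorted by p-value, with columns
    ``category_id, k, K, n, N, fold_enrichment, p_value, q_value``.
    """
    if not category_map.universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    outside = genes - category_map.universe
    if outside:
        logger.warning("dropping %d genes outside the universe", len(outside))
        genes -= outside
    n, N = len(genes), len(category_map.universe)
    rows = []
    for cat, members in category_map.categories.items():
        k = len(genes & members)
        if k == 0:
            continue
        K = len(members)
        rows.append({
            "category_id": cat,
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "fold_enrichment": (k / n) / (K / N) if n else np.nan,
            "p_value": fisher_overrepresentation(k, K, n, N),
        })
    out = pd.DataFrame(
        rows, columns=["category_id", "k", "K", "n", "N",
                       "fold_enrichment", "p_value"]
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(
            ["p_value", "category_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["q_value"] = np.array([], dtype=float)
    return out


def write_enrichment(results: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = results.copy()
    for col in ("fold_enrichment",):
        if col in out and len(out):
            out[col] = out[col].map(lambda v: f"{v:.4f}")
    for col in ("p_value", "q_value"):
        if col in out and len(out):
            out[col] = out[col].map(lambda v: f"{v:.6e}")
    with open(path, "w") as fh:
        fh.write("# medipchip enrichment; one-sided Fisher exact "
                 "(hypergeometric tail), Benjamini-Hochberg q-values\n")
        out.to_csv(fh, sep="\t", index=False)
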