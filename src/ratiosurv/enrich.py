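"""Over-representation analysis of significant genes against gene sets,
function deduplication, group-composition labeling, and membership-based
hierarchical clustering of enriched functions.

The enrichment here is plain hypergeometric over-representation against
user-supplied GMT collections, with the universe defined as the set of
features the screen actually tested.  Functions are represented as rows of a
DataFrame (``function_id, description, p_value, p_adjusted, fold_enrichment,
member_hits, n_opcml_plus, n_genei_plus, majority_class, cluster_id``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

__all__ = [
    "ora_test",
    "bh_adjust",
    "enrich_collection",
    "annotate_composition",
    "dedup_functions",
    "label_majority",
    "cluster_functions",
]


def ora_test(query, gene_set, universe) -> tuple[float, float]:
    """Hypergeometric upper-tail p and fold enrichment of a query/set overlap.

    ``p = P(overlap >= k)`` drawing ``|query|`` genes without replacement
    from ``|universe|`` of which ``|gene_set|`` are marked;
    ``fold = (k/|query|) / (|gene_set|/|universe|)``.
    """
    query = set(query)
    members = set(gene_set)
    uni = set(universe)
    if not uni or not query:
        raise ValueError("query and universe must be nonempty")
    if not query <= uni or not members <= uni:
        raise ValueError("query and gene set must be subsets of the universe")
    N, K, n = len(uni), len(members), len(query)
    k = len(query & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K else 0.0
    return p, float(fold)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich_collection(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA of one query gene list against every set of a collection.

    Set members outside the universe are harmonized away before testing.
    Returns all tested functions with BH-adjusted p-values and a
    ``significant`` flag at the given alpha; ``member_hits`` holds the query
    genes found in each set.
    """
    uni = set(universe)
    query = [g for g in query if g in uni]
    rows = []
    for s in collection:
        members = tuple(g for g in s.members if g in uni)
        if not members:
            continue
        p, fold = ora_test(query, members, uni)
        hits = tuple(sorted(set(query) & set(members)))
        rows.append(
            {
                "function_id": s.set_id,
                "description": s.description,
                "p_value": p,
                "fold_enrichment": fold,
                "set_size": len(members),
                "member_hits": hits,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "function_id", "description", "p_value", "fold_enrichment",
            "set_size", "member_hits",
        ],
    )
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
        df["significant"] = df["p_adjusted"] <= alpha
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def annotate_composition(functions: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Count OPCML_plus / GENEi_plus genes among each function's hits.

    ``groups`` maps gene ID -> screen group label.
    """
    out = functions.copy()
    out["n_opcml_plus"] = [
        sum(groups.get(g) == "OPCML_plus" for g in hits)
        for hits in out["member_hits"]
    ]
    out["n_genei_plus"] = [
        sum(groups.get(g) == "GENEi_plus" for g in hits)
        for hits in out["member_hits"]
    ]
    return out


def dedup_functions(functions: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated function IDs, keeping the highest (most conservative)
    p-value; ties keep the first encountered; otherwise stable order."""
    if not len(functions):
        return functions.copy()
    df = functions.reset_index(drop=True)
    keep_idx = []
    for _, grp in df.groupby("function_id", sort=False):
        keep_idx.append(grp["p_value"].idxmax())  # first occurrence wins ties
    return df.loc[sorted(keep_idx)].reset_index(drop=True)


def label_majority(functions: pd.DataFrame, ratio_threshold: float = 4.0) -> pd.DataFrame:
    """Label each function's group composition.

    ``dependent`` iff n_opcml_plus > ratio_threshold * n_genei_plus (strict;
    a zero GENEi+ count with at least one OPCML+ gene qualifies), else
    ``independent``; functions with no classified genes are flagged
    ``undefined``.
    """
    out = functions.copy()
    n_op = out["n_opcml_plus"].to_numpy(dtype=float)
    n_ge = out["n_genei_plus"].to_numpy(dtype=float)
    label = np.where(n_op > ratio_threshold * n_ge, "dependent", "independent")
    label = np.where((n_op == 0) & (n_ge == 0), "undefined", label)
    out["majority_class"] = label
    return out


def cluster_functions(functions: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Cut an average-linkage tree over Jaccard distances into k clusters.

    Distance between two functions is the Jaccard distance of their
    ``member_hits`` sets; identical membership means distance 0.  Cluster IDs
    are deterministic given input order and depend only on the set structure
    (relabeling gene IDs leaves assignments unchanged).
    """
    if len(functions) < 2:
        raise ValueError("need at least 2 functions to cluster")
    if k > len(functions):
        raise ValueError("k exceeds the number of functions")
    hits = [set(h) for h in functions["member_hits"]]
    if any(not h for h in hits):
        raise ValueError("every function needs nonempty member_hits")
    genes = sorted(set().union(*hits))
    mat = np.array([[g in h for g in genes] for h in hits], dtype=bool)
    dist = pdist(mat, metric="jaccard")
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=k, criterion="maxclust")
    out = functions.copy()
    out["cluster_id"] = labels.astype(int)
    return out
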