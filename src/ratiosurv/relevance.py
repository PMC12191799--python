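"""Literature-relevance (OVca) scoring and triage of enriched functions.

Each gene's relevance is a citation count — the number of publications
linking the gene to the disease topic over a fixed date window.  A
function's OVca score is the geometric mean of the counts of its significant
member genes; a pseudocount keeps zero-count genes from annihilating the
mean and is subtracted back so round-number fixtures behave intuitively.
Counts can come from a TSV, an injected offline mapping, or (optionally) a
live PubMed E-utilities client; nothing in the pipeline requires network
access.
"""

from __future__ import annotations

import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "build_query",
    "StaticCitationClient",
    "EntrezCitationClient",
    "fetch_counts",
    "CitationTable",
    "ovca_score",
    "triage",
]


def build_query(
    gene_id: str,
    topic: str = "ovarian cancer",
    window: tuple[int, int] = (1998, 2023),
) -> str:
    """Deterministic literature query: gene + topic clause + date clause.

    ``("KIT", "ovarian cancer", (1998, 2023))`` ->
    ``"KIT AND [ovarian cancer] AND 1998:2023[PDAT]"`` (URL-encoding happens
    only on the wire).
    """
    if not gene_id:
        raise ValueError("gene_id must be nonempty")
    parts = [gene_id]
    if topic:
        parts.append(f"[{topic}]")
    parts.append(f"{window[0]}:{window[1]}[PDAT]")
    return " AND ".join(parts)


@dataclass
class CitationTable:
    """Per-gene publication counts plus the query provenance."""

    counts: dict[str, int]
    missing: tuple[str, ...] = ()
    query_template: str = ""
    date_window: tuple[int, int] = (1998, 2023)

    def get(self, gene_id: str, default: int | None = None) -> int | None:
        return self.counts.get(gene_id, default)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.counts), "count": list(self.counts.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "CitationTable":
        return cls(
            counts={str(g): int(c) for g, c in zip(df["gene_id"], df["count"])},
            **kwargs,
        )


class StaticCitationClient:
    """Offline client backed by a fixed gene -> count mapping.

    Records every lookup in ``calls`` so caching behaviour is testable.
    Genes absent from the mapping return None (recorded as missing upstream).
    """

    def __init__(self, counts: dict[str, int]):
        self._counts = dict(counts)
        self.calls: list[str] = []

    def count(self, gene_id: str, query: str) -> int | None:
        self.calls.append(gene_id)
        return self._counts.get(gene_id)


class EntrezCitationClient:
    """Minimal live PubMed E-utilities client (strictly optional).

    Uses only the standard library; throttles requests; any failure returns
    None so the affected gene is reported missing rather than fabricated.
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

    def __init__(self, email: str, delay_s: float = 0.4, timeout_s: float = 10.0):
        self.email = email
        self.delay_s = delay_s
        self.timeout_s = timeout_s

    def count(self, gene_id: str, query: str) -> int | None:
        params = urllib.parse.urlencode(
            {
                "db": "pubmed",
                "term": query,
                "rettype": "count",
                "retmode": "json",
                "email": self.email,
            }
        )
        try:
            with urllib.request.urlopen(
                f"{self.BASE}?{params}", timeout=self.timeout_s
            ) as resp:
                payload = json.load(resp)
            time.sleep(self.delay_s)
            return int(payload["esearchresult"]["count"])
        except Exception:
            return None


def fetch_counts(
    genes,
    client,
    topic: str = "ovarian cancer",
    window: tuple[int, int] = (1998, 2023),
) -> CitationTable:
    """Query a citation count for each gene (deduplicated, cached).

    Failures or absent genes are recorded in ``missing`` — never fabricated.
    Repeated gene IDs trigger a single client call.
    """
    counts: dict[str, int] = {}
    missing: list[str] = []
    seen: set[str] = set()
    for gene in genes:
        gene = str(gene)
        if gene in seen:
            continue
        seen.add(gene)
        value = client.count(gene, build_query(gene, topic, window))
        if value is None:
            missing.append(gene)
        else:
            counts[gene] = int(value)
    return CitationTable(
        counts=counts,
        missing=tuple(missing),
        query_template=build_query("<gene>", topic, window),
        date_window=window,
    )


def ovca_score(
    member_hits,
    counts: CitationTable | dict,
    pseudocount: float = 1.0,
    default_count: int = 0,
) -> float:
    """Geometric mean of member-gene citation counts.

    ``geomean(count_g + pseudocount) - pseudocount`` over the function's
    significant member genes, floored at 0.  Genes without a count use
    ``default_count``.
    """
    hits = list(member_hits)
    if not hits:
        raise ValueError("member_hits must be nonempty")
    lookup = counts.counts if isinstance(counts, CitationTable) else counts
    vals = np.array(
        [lookup.get(str(g), default_count) + pseudocount for g in hits], dtype=float
    )
    if (vals <= 0).any():
        return 0.0
    score = float(np.exp(np.mean(np.log(vals))) - pseudocount)
    return max(score, 0.0)


def triage(
    functions: pd.DataFrame,
    counts: CitationTable | dict,
    top_n: int = 30,
    pseudocount: float = 1.0,
    max_per_cluster: int = 4,
) -> pd.DataFrame:
    """Rank enriched functions by literature relevance.

    Scores every function; inside any cluster with more than
    ``max_per_cluster`` members only the ``max_per_cluster`` highest-OVca
    functions are retained; the survivors are ordered dependent-majority
    first, then OVca descending, ties broken by ascending adjusted p and
    function ID; the top ``top_n`` are returned.  Fully deterministic.
    """
    if not len(functions):
        out = functions.copy()
        out["ovca_score"] = pd.Series(dtype=float)
        return out
    out = functions.copy()
    out["ovca_score"] = [
        ovca_score(h, counts, pseudocount=pseudocount) for h in out["member_hits"]
    ]
    if "cluster_id" in out.columns:
        retained = []
        for _, grp in out.groupby("cluster_id", sort=False):
            if len(grp) > max_per_cluster:
                grp = grp.sort_values(
                    ["ovca_score", "p_adjusted", "function_id"],
                    ascending=[False, True, True],
                    kind="stable",
                ).head(max_per_cluster)
            retained.append(grp)
        out = pd.concat(retained)
    class_rank = out.get("majority_class", pd.Series("independent", index=out.index))
    out = out.assign(_cls=(class_rank != "dependent").astype(int))
    out = out.sort_values(
        ["_cls", "ovca_score", "p_adjusted", "function_id"],
        ascending=[True, False, True, True],
        kind="stable",
    ).drop(columns="_cls")
    return out.head(top_n).reset_index(drop=True)
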