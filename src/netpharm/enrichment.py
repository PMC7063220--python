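"""Over-representation analysis of target sets against annotation collections.

Given a query set of gene symbols (a module's candidate targets) and a
collection of annotation categories (KEGG pathways, GO terms) with a
background gene universe, each category is scored by the one-sided
hypergeometric tail P(X >= k), where k is the query/category overlap, and
p-values are adjusted across categories by Benjamini-Hochberg FDR.  An EASE
mode mirrors DAVID's conservative variant, which discounts one overlapping
gene before taking the tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MODES = ("standard", "ease")


@dataclass
class AnnotationCollection:
    """Named gene-set collection with a background universe.

    ``sets`` maps category id -> (category name, member gene symbols).  The
    background defaults to the union of all annotated genes; a wider user
    universe may be supplied, but members must be contained in it.
    """

    name: str
    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.background:
            self.background = frozenset().union(
                *(members for _, members in self.sets.values())
            ) if self.sets else frozenset()
        for cid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"annotation category {cid!r} is empty")
            if not members <= self.background:
                raise ValueError(
                    f"category {cid!r} has members outside the background"
                )

    @classmethod
    def from_sets(
        cls,
        name: str,
        sets: Mapping[str, Iterable[str]],
        background: Iterable[str] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> "AnnotationCollection":
        descriptions = descriptions or {}
        packed = {
            cid: (descriptions.get(cid, cid), frozenset(members))
            for cid, members in sets.items()
        }
        return cls(name, packed, frozenset(background or ()))


def hypergeometric_test(
    k: int, n: int, K: int, N: int, mode: str = "standard"
) -> float:
    """Upper-tail hypergeometric p-value for a k-gene overlap.

    A query of ``n`` genes drawn from a background of ``N`` genes overlaps a
    category of ``K`` genes in ``k``.  Standard mode returns ``P(X >= k)``
    for X ~ Hypergeometric(N, K, n); EASE mode discounts one overlapping
    gene, returning ``P(X >= k - 1)`` (p = 1 when k <= 1).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if mode == "ease":
        if k <= 1:
            return 1.0
        k = k - 1
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    query: Iterable[str],
    collection: AnnotationCollection,
    mode: str = "standard",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every annotation category against a query gene set.

    Returns one row per category with at least one query hit, sorted by
    ascending p (category id breaking ties), with columns ``category, name,
    k, n, K, N, p, q, significant, hits``.  q is BH-adjusted across the
    tested (k >= 1) categories; ``significant`` flags q <= alpha.
    """
    cols = ["category", "name", "k", "n", "K", "N", "p", "q", "significant", "hits"]
    query = frozenset(query) & collection.background
    if not query:
        logger.warning("enrich: query has no genes in the %s background", collection.name)
        return pd.DataFrame(columns=cols)
    n, N = len(query), len(collection.background)
    rows = []
    for cid in sorted(collection.sets):
        cname, members = collection.sets[cid]
        hit = query & members
        if not hit:
            continue
        p = hypergeometric_test(len(hit), n, len(members), N, mode=mode)
        rows.append(
            {
                "category": cid,
                "name": cname,
                "k": len(hit),
                "n": n,
                "K": len(members),
                "N": N,
                "p": p,
                "hits": ";".join(sorted(hit)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    df = df.sort_values(["p", "category"], kind="mergesort").reset_index(drop=True)
    return df[cols]
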