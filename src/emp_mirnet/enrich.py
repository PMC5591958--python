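"""Hypergeometric overrepresentation tests.

Used twice in the pipeline: positional enrichment of network miRNAs in
genomic regions (is a 14q32-like cluster overrepresented among the
co-expressed miRNAs?) and generic gene-set enrichment over user-supplied
annotations (GMT).  The upper-tail probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

is evaluated in log-space (log-gamma + log-sum-exp) for numerical
stability; an exact rational-arithmetic evaluation is provided as an
independent verification path for moderate N.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .assoc import bh_adjust
from .ioformats import GeneSetCollection

__all__ = [
    "hypergeom_upper",
    "hypergeom_upper_exact",
    "positional_enrichment",
    "set_enrichment",
]


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(K, n) and K, n <= N)"
        )


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log-space.

    The observed overlap is included in the tail (the standard
    overrepresentation convention), so k = 0 gives p = 1 exactly.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    hi = min(K, n)
    i = np.arange(k, hi + 1)
    log_terms = (
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact rational P(X >= k); verification path for moderate N."""
    _check_counts(k, K, n, N)
    total = comb(N, n)
    acc = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(acc, total)


def positional_enrichment(
    network_nodes: list[str],
    loci: pd.DataFrame,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region overrepresentation of network nodes, BH across regions.

    ``universe`` defaults to every feature in the locus annotation (the
    assay platform); pass the detection-filtered feature list to restrict
    it.  Every network node must be annotated.  Regions without universe
    members are excluded (nothing to test).
    """
    if universe is None:
        universe = list(loci["feature_id"])
    universe_set = set(universe)
    nodes = set(network_nodes)
    missing = sorted(nodes - universe_set)
    if missing:
        raise ValueError(f"network node(s) absent from the universe: {missing[:10]}")
    ann = loci[loci["feature_id"].isin(universe_set)]
    region_members = ann.groupby("region", sort=True)["feature_id"].apply(set)

    N = len(universe_set)
    n = len(nodes)
    rows = []
    for region, members in region_members.items():
        K = len(members)
        if K == 0:
            continue
        k = len(members & nodes)
        rows.append(
            {
                "region_or_set": region,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["region_or_set", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "region_or_set"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = []
    return table


def set_enrichment(
    query_genes: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    target_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Gene-set overrepresentation of a query, BH across sets.

    When ``target_map`` is given, ``query_genes`` is interpreted as a
    miRNA list and the query becomes the union of their target genes —
    the usual construction for miRNA functional enrichment.
    """
    if not universe:
        raise ValueError("empty universe")
    if target_map is not None:
        query = set()
        for mir in query_genes:
            query.update(target_map.get(mir, ()))
    else:
        query = set(query_genes)
    universe_set = set(universe)
    outside = sorted(query - universe_set)
    if outside:
        raise ValueError(f"query gene(s) outside the universe: {outside[:10]}")

    N = len(universe_set)
    n = len(query)
    rows = []
    for name, members in sets:
        member_set = set(members) & universe_set
        K = len(member_set)
        if K == 0:
            continue
        k = len(member_set & query)
        rows.append(
            {
                "region_or_set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["region_or_set", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "region_or_set"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = []
    return table
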