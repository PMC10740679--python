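"""Over-representation analysis: upper-tail hypergeometric + Benjamini-Hochberg.

Given a query gene set (e.g. the combined strictly phenotype-specific genes
of one phenotype), each annotated set is tested for overlap enrichment
against a background universe with the one-sided hypergeometric test,
P(X >= k) for X ~ Hypergeom(N, K, n), and p values are adjusted across the
collection by the BH step-up procedure. The universe defaults to the genes
expressed in the abundance table (a guard against expression-background
bias) rather than the whole annotation.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, ValidationError


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(
            f"inconsistent hypergeometric arguments: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # survival function, evaluated from log-pmf internally by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_i = min_{j>=i} p_(j) * m / j, order kept."""
    p = np.asarray(list(p), dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    top_k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every collection set for over-representation in ``query``.

    Returns ``(records, report)``: one record per set with overlap >= 1
    (overlap, sizes, p, BH q) and the top-``top_k`` report sorted by p
    ascending with ties broken by set name.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        raise ValidationError(
            f"query genes outside the universe: {sorted(outside)[:10]}"
        )
    restricted = collection.restricted_to(universe)

    rows = []
    for name in restricted:
        members = restricted[name]
        overlap = len(members & query)
        if overlap == 0:
            continue
        p = hypergeom_upper(overlap, len(members), len(query), len(universe))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p": p,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "p",
        ],
    )
    if len(records):
        records["q_bh"] = bh_adjust(records["p"])
    else:
        records["q_bh"] = pd.Series(dtype=float)
    report = records.sort_values(
        ["p", "set_name"], kind="mergesort"
    ).head(top_k).reset_index(drop=True)
    return records.reset_index(drop=True), report
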