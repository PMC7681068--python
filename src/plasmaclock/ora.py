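"""Overrepresentation analysis (ORA).

For a query set of size n drawn from a background universe of size N, the
overlap k with a pathway of size K is tested against the hypergeometric
upper tail P(X >= k), one pathway at a time; Benjamini-Hochberg FDR is
applied across all tested pathways.  Upper tail only: the question is
overrepresentation.  The default universe is the measured panel, not the
genome — results state the background size used.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import adjust_fdr
from .simulate import PathwayCollection

logger = logging.getLogger("plasmaclock")

__all__ = ["overrepresentation_test"]


def overrepresentation_test(
    query: Iterable[str],
    background: Iterable[str],
    collection: PathwayCollection,
) -> pd.DataFrame:
    """Hypergeometric upper-tail test per pathway, BH-corrected.

    Returns a DataFrame indexed by pathway_id with k (overlap), n (query
    size), K (pathway size within the background), N (background size),
    p_value, fdr and the overlapping ids, sorted by (fdr, p_value).
    """
    query_set = set(query)
    background_set = set(background)
    offenders = query_set - background_set
    if offenders:
        raise ValueError(
            f"query ids outside the background: {sorted(offenders)[:10]}"
        )
    N = len(background_set)
    n = len(query_set)
    rows = []
    for pid in collection:
        members = collection.members(pid) & background_set
        K = len(members)
        overlap = sorted(query_set & members)
        k = len(overlap)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "pathway_id": pid,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": min(p, 1.0),
                "overlap_ids": ";".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["k", "n", "K", "N", "p_value", "fdr", "overlap_ids"]
        )
    df = pd.DataFrame(rows).set_index("pathway_id")
    df.insert(5, "fdr", adjust_fdr(df["p_value"].to_numpy(), method="bh"))
    return df.sort_values(["fdr", "p_value"], kind="stable")
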