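"""Over-representation analysis (ORA) of gene lists.

For each gene set, the overlap k between a query gene list (size n) and
the set's members restricted to the universe (size K out of N) is
scored by the hypergeometric upper tail P(X >= k), with an enrichment
ratio k / (n * K / N) (observed over expected overlap).  P-values are
BH-corrected across the retained sets.  Only over-representation is
tested; depletion is not.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .stats import bh_adjust

__all__ = ["run_ora"]


def run_ora(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    min_set: int = 5,
    max_set: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in gene sets.

    Query genes outside the universe are dropped with a warning.  Sets
    are restricted to the universe and retained when their effective
    size lies in [min_set, max_set].  Returns a table indexed by set_id
    with N, K, n, k, ratio, p, q sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty gene universe")
    q_in = set(query) & uni
    dropped = set(query) - uni
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    N = len(uni)
    n = len(q_in)
    rows = []
    for sid, (desc, members) in sets:
        hit = set(members) & uni
        K = len(hit)
        if K < min_set or K > max_set:
            continue
        k = len(q_in & hit)
        expected = n * K / N
        ratio = k / expected if expected > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(set_id=sid, description=desc, N=N, K=K, n=n, k=k,
                 ratio=ratio, p=min(p, 1.0))
        )
    table = pd.DataFrame(
        rows, columns=["set_id", "description", "N", "K", "n", "k", "ratio", "p"]
    ).set_index("set_id")
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("p", kind="mergesort")
    else:
        table["q"] = []
    return table
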