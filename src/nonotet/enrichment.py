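"""Gene-set over-representation analysis (hypergeometric) with BH adjustment.

Annotation-agnostic: the caller supplies named gene sets and a universe;
the simulator emits toy "pathway" sets enriched in the planted dependent
genes so the whole route can be exercised end to end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValidationError(
                    f"set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _rej, q, _a, _b = multipletests(p, method="fdr_bh")
    return q


def ora_hypergeometric(query: set[str],
                       collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    For a universe of N genes, a set of K and a query of n sharing k genes,
    p = P[X >= k] with X ~ Hypergeometric(N, K, n). Returns a DataFrame
    (set_name, k, K, n, N, p_value, q_value) sorted by ascending p.
    """
    extra = query - collection.universe
    if extra:
        raise ValidationError(
            f"query genes outside the universe: {sorted(extra)[:10]}"
        )
    N, n = len(collection.universe), len(query)
    rows = []
    for name, members in sorted(collection.sets.items()):
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df.sort_values(["p_value", "set_name"], kind="mergesort",
                          ignore_index=True)
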