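"""Gene-set over-representation via the one-sided hypergeometric test.

For a DE list of size K drawn from a universe of size N and a set of size
m with overlap k, the enrichment p-value is the hypergeometric upper tail
P[X >= k].  Odds ratios come from the 2x2 table with a Haldane 0.5
correction when any cell is zero.  BH adjustment is applied across sets
within each contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from autoreg.diffexp import bh_adjust
from autoreg.errors import ValidationError
from autoreg.io import GeneSetCollection


def ora_test(
    de_genes: set[str] | list[str],
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
) -> dict:
    """One-sided over-representation test of *gene_set* in *de_genes*.

    The set is intersected with the universe first; DE genes must be a
    subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    de = set(de_genes)
    if not de:
        raise ValidationError("empty DE list")
    if not de <= universe:
        raise ValidationError("DE genes must be a subset of the universe")
    members = set(gene_set) & universe

    N, m, K = len(universe), len(members), len(de)
    k = len(de & members)
    p = float(stats.hypergeom.sf(k - 1, N, m, K))

    a, b = k, K - k                # DE in set / DE out of set
    c, d = m - k, N - m - K + k    # non-DE in set / non-DE out of set
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)

    return {"k": k, "m": m, "K": K, "N": N, "odds_ratio": odds_ratio, "p": p}


def enrich_all(
    de_lists: dict[str, set[str] | list[str]],
    sets: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """ORA of every gene set against every contrast's DE list.

    Returns one row per (set, contrast) with BH-adjusted p across sets
    within each contrast.
    """
    rows = []
    for contrast, de in de_lists.items():
        for name in sets.names():
            res = ora_test(de, sets[name], universe)
            res.update(set_name=name, contrast=contrast)
            rows.append(res)
    table = pd.DataFrame(rows, columns=["set_name", "contrast", "k", "m", "K",
                                        "N", "odds_ratio", "p"])
    table["fdr"] = np.nan
    for contrast in de_lists:
        idx = table["contrast"] == contrast
        table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    return table
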