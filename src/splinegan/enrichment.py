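"""Pathway over-representation by one-sided Fisher's exact test.

For each gene set the 2x2 table (in query / in set vs complements) is
summarized by the hypergeometric upper tail P(X >= matches); p-values are
Benjamini-Hochberg adjusted across all tested sets and rows ordered by
ascending FDR.  The default gene universe is the set of measured genes.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection
from .diffexpr import adjust_bh

logger = logging.getLogger(__name__)


def fisher_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each gene set.

    ``query`` must be a subset of ``universe``; gene sets are intersected
    with the universe before testing, and sets with no overlap are skipped
    with a log entry.  Returns one row per tested set: total (set size in
    the universe), matches, percent match, p, FDR, significance flag and
    the matching genes, ordered by ascending FDR.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from the universe: {sorted(stray)}")
    rows = []
    n_skipped = 0
    for name, members in collection.sets.items():
        in_universe = members & universe
        if not in_universe:
            n_skipped += 1
            continue
        matched = query & in_universe
        k = len(matched)
        p = float(hypergeom.sf(k - 1, len(universe), len(in_universe), len(query)))
        rows.append(
            {
                "pathway": name,
                "total": len(in_universe),
                "matches": k,
                "percent_match": 100.0 * k / len(in_universe),
                "p_value": min(p, 1.0),
                "genes": ",".join(sorted(matched)),
            }
        )
    if n_skipped:
        logger.info("skipped %d gene set(s) with no overlap with the universe", n_skipped)
    result = pd.DataFrame(rows, columns=["pathway", "total", "matches", "percent_match", "p_value", "genes"])
    if result.empty:
        result["fdr"] = []
        result["significant"] = []
        return result
    result["fdr"] = adjust_bh(result["p_value"].to_numpy())
    result["significant"] = result["fdr"] < fdr_threshold
    result = result.sort_values(["fdr", "p_value", "pathway"], kind="mergesort").reset_index(drop=True)
    return result[["pathway", "total", "matches", "percent_match", "p_value", "fdr", "significant", "genes"]]
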