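"""Pathway-level statistics: Fisher over-representation and a competitive
fold-change gene-set test.

Two complementary tests:

* :func:`fisher_enrichment` — one-sided (over-representation)
  hypergeometric test of a foreground gene list against each set of a
  collection, restricted to a stated universe, BH-adjusted across the
  collection.
* :func:`gene_set_test` — a competitive test on a quantitative signature:
  the observed mean statistic of a set's genes is compared against the
  means of random same-size gene samples from the universe, with separate
  "up" and "down" alternatives and add-one-corrected empirical p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection
from .ksea import Signature
from .regulation import bh_adjust


def fisher_enrichment(
    foreground: set[str],
    universe: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation per gene set.

    The foreground must be a subset of the universe; sets are intersected
    with the universe before testing. p-values are hypergeometric upper
    tails (equivalent to Fisher's exact with alternative "greater") and are
    BH-adjusted across the collection.
    """
    foreground = set(foreground)
    universe = set(universe)
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    n_uni = len(universe)
    n_fore = len(foreground)
    rows = []
    for name, members in collection.items():
        in_uni = set(members) & universe
        k_uni = len(in_uni)
        k_fore = len(in_uni & foreground)
        # P(X >= k_fore), X ~ Hypergeom(n_uni, k_uni, n_fore)
        p = float(stats.hypergeom.sf(k_fore - 1, n_uni, k_uni, n_fore))
        rows.append((name, k_fore, n_fore, k_uni, n_uni, p))
    res = pd.DataFrame(rows, columns=["set_name", "k_in_fore", "n_fore",
                                      "k_in_universe", "n_universe", "p_raw"])
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["direction"] = "over"
    return res


def gene_set_test(
    statistics: Signature | pd.Series,
    collection: GeneSetCollection,
    n_samples: int = 9999,
    alternative: str = "up",
    seed: int = 0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Competitive gene-set test against random same-size gene samples.

    For each set, the mean signature statistic over the set's genes (or the
    mean of ranks with ``statistic="rank"``) is compared with the means of
    ``n_samples`` random same-size subsets of the universe;
    p = (1 + exceedances) / (n_samples + 1), where an exceedance is a null
    mean >= the observed mean for "up" and <= for "down".
    """
    if alternative not in {"up", "down"}:
        raise ValueError("alternative must be 'up' or 'down'")
    scores = statistics.scores if isinstance(statistics, Signature) else statistics
    values = scores.to_numpy(float)
    if statistic == "rank":
        values = stats.rankdata(values)
    elif statistic != "mean":
        raise ValueError("statistic must be 'mean' or 'rank'")
    index = {g: i for i, g in enumerate(scores.index)}
    n_uni = len(values)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in collection.items():
        idx = [index[m] for m in members if m in index]
        m = len(idx)
        if m == 0:
            rows.append((name, 0, n_uni, np.nan, alternative))
            continue
        obs = values[idx].mean()
        if m == n_uni:
            p = 1.0
        else:
            # null means of random same-size subsets (chunked partial sorts)
            null = np.empty(n_samples)
            chunk = max(1, int(2_000_000 / max(n_uni, 1)))
            done = 0
            while done < n_samples:
                b = min(chunk, n_samples - done)
                keys = rng.random((b, n_uni))
                pick = np.argpartition(keys, m - 1, axis=1)[:, :m]
                null[done:done + b] = values[pick].mean(axis=1)
                done += b
            if alternative == "up":
                n_exc = int(np.sum(null >= obs))
            else:
                n_exc = int(np.sum(null <= obs))
            p = (1.0 + n_exc) / (n_samples + 1.0)
        rows.append((name, m, n_uni, p, alternative))
    res = pd.DataFrame(rows, columns=["set_name", "k_in_universe",
                                      "n_universe", "p_raw", "direction"])
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    return res
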