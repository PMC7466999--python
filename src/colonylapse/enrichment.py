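"""Hypergeometric gene-set enrichment with Storey q-values.

For a nominated strain set of size N drawn from a screen universe of K
genes, a term with M annotated genes in the universe and x of them among
the nominated strains has upper-tail probability P(X >= x) under the
hypergeometric null, computed as 1 - F(x - 1; K, M, N).  Fold enrichment
is (x/N)/(M/K): term frequency among nominations over term frequency in
the whole screen.  Genes absent from the screen are never counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .diffstats import storey_qvalues

__all__ = [
    "GeneSet",
    "read_gmt",
    "restrict_to_universe",
    "hypergeom_upper_tail",
    "fold_enrichment",
    "enrich",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need id, name, >=1 gene): {line[:80]!r}")
        sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def restrict_to_universe(sets: Iterable[GeneSet], universe: set[str]) -> list[GeneSet]:
    """Intersect every term with the screen universe; drop emptied terms."""
    if not universe:
        raise ValueError("universe must be non-empty")
    out = []
    for s in sets:
        members = s.members & universe
        if members:
            out.append(GeneSet(s.term_id, s.term_name, frozenset(members)))
    return out


def _check_query(x: int, big_k: int, big_m: int, n: int) -> None:
    if not (0 <= big_m <= big_k and 0 <= n <= big_k):
        raise ValueError(f"need 0 <= M <= K and 0 <= N <= K; got M={big_m}, K={big_k}, N={n}")
    if not 0 <= x <= min(n, big_m):
        raise ValueError(f"need 0 <= x <= min(N, M); got x={x}, N={n}, M={big_m}")


def hypergeom_upper_tail(x: int, big_k: int, big_m: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(population K, M marked, N drawn)."""
    _check_query(x, big_k, big_m, n)
    return float(stats.hypergeom.sf(x - 1, big_k, big_m, n))


def fold_enrichment(x: int, big_k: int, big_m: int, n: int) -> float:
    """(x/N)/(M/K): nominated-set term frequency over screen-wide frequency."""
    _check_query(x, big_k, big_m, n)
    if n == 0 or big_m == 0:
        raise ValueError("fold enrichment needs N > 0 and M > 0")
    return (x / n) / (big_m / big_k)


def enrich(
    nominated: set[str],
    sets: Sequence[GeneSet],
    universe: set[str],
    q_cutoff: float = 0.05,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Test every term for over-representation in the nominated set.

    Genes outside ``universe`` are dropped from both the nominated set and
    every term.  Returns a frame (term_id, term_name, x, N, M, K, p, q,
    fold, significant) sorted by p; q-values are Storey pFDR across all
    tested terms.
    """
    nominated = set(nominated) & set(universe)
    if not nominated:
        warnings.warn("nominated set is empty after universe restriction", stacklevel=2)
        return pd.DataFrame(columns=["term_id", "term_name", "x", "N", "M", "K",
                                     "p", "q", "fold", "significant"])
    restricted = [s for s in restrict_to_universe(sets, set(universe))
                  if len(s.members) >= min_term_size]
    big_k = len(set(universe))
    n = len(nominated)
    rows = []
    for s in restricted:
        big_m = len(s.members)
        x = len(s.members & nominated)
        p = hypergeom_upper_tail(x, big_k, big_m, n)
        fold = (x / n) / (big_m / big_k)
        rows.append((s.term_id, s.term_name, x, n, big_m, big_k, p, fold))
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_name", "x", "N", "M", "K",
                                     "p", "q", "fold", "significant"])
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "x", "N", "M", "K", "p", "fold"])
    df["q"] = storey_qvalues(df["p"].to_numpy())
    df["significant"] = df["q"] < q_cutoff
    df = df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    return df[["term_id", "term_name", "x", "N", "M", "K", "p", "q", "fold", "significant"]]
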