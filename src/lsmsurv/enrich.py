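"""Hypergeometric over-representation analysis of gene lists against GMT sets.

Given a list of differentially expressed genes, a gene universe (all genes
measured on the platform after probe collapse) and a GMT collection, each set
gets a one-sided hypergeometric upper-tail p-value ``P[X >= k]`` — the chance
of drawing at least ``k`` set members when sampling ``n`` genes without
replacement from a universe of ``N`` containing ``K`` set members — followed
by Benjamini–Hochberg FDR across the tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "ora"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: ``sets[name] = (description, frozenset of members)``."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-delimited GMT file (name, description, member genes...).

    Duplicate members within a line are collapsed; empty sets are dropped
    with a log entry; a line with fewer than 3 fields is an error naming the
    line number; duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    lines = path.read_text().splitlines()
    if not any(l.strip() for l in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-delimited fields"
            )
        name, desc, *members = fields
        members = frozenset(g.strip() for g in members if g.strip())
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not members:
            logger.info("read_gmt: dropping empty set %r (line %d)", name, lineno)
            continue
        sets[name] = (desc, members)
    if not sets:
        raise ValueError(f"{path}: no non-empty gene sets")
    return GeneSetCollection(sets)


def ora(
    degs: Sequence[str],
    universe: Sequence[str],
    gsc: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation of ``degs`` within each collection set.

    Gene sets are intersected with the universe first; sets with no universe
    member (K = 0) are skipped.  DEGs outside the universe are dropped with a
    warning.  Returns one row per tested set with k, K, n, N, p_value and BH
    fdr, sorted by p-value (ties by set name).
    """
    universe_set = set(universe)
    if len(universe_set) < 10:
        raise ValueError("universe must contain at least 10 genes")
    deg_set = set(degs)
    stray = deg_set - universe_set
    if stray:
        logger.warning("ora: dropping %d DEGs not in universe", len(stray))
        deg_set &= universe_set
    if not deg_set:
        raise ValueError("no DEGs remain after restricting to the universe")
    N, n = len(universe_set), len(deg_set)
    rows = []
    for name, (_, members) in gsc.sets.items():
        in_universe = members & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & deg_set)
        # upper tail P[X >= k]; survival function is P[X > k-1]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(set_name=name, k=k, K=K, n=n, N=N, p_value=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)
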