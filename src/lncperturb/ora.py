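"""Gene-set over-representation analysis (right-tailed Fisher's exact test).

For a universe of N tested genes, a gene set of size K and a
differentially-expressed list of size n overlapping the set in k genes, the
enrichment p-value is the upper hypergeometric tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n),

identical to a right-tailed Fisher's exact test on the 2x2 overlap table.
Sets are read from GMT files and intersected with the universe (the genes
that survived the expression filter, not the whole genome).  Significance is
flagged at -log10 p > 1.3 (p < 0.05); BH-adjusted p-values are reported
alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "fisher_ora", "read_gene_sets", "NEGLOG10_CUTOFF"]

logger = logging.getLogger(__name__)

#: -log10 p significance cutoff (p < 0.05).
NEGLOG10_CUTOFF = 1.3


class OraError(ValueError):
    """Contract violation in over-representation input."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a tested universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise OraError(f"gene set {name!r} empty after universe intersection")
            if not members <= self.universe:
                raise OraError(f"gene set {name!r} not restricted to the universe")

    @classmethod
    def from_sets(cls, sets: dict[str, set[str]], universe: set[str]) -> "GeneSetCollection":
        """Intersect raw sets with the universe, dropping emptied sets with a warning."""
        uni = frozenset(universe)
        kept: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            inter = frozenset(members) & uni
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %r is disjoint from the universe; dropped", name)
        return cls(kept, uni)


def fisher_ora(de_genes: set[str] | list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Right-tailed Fisher's exact enrichment of every set in the collection.

    Returns a frame indexed by set name with columns k (overlap), K (set
    size), n (DE list size), N (universe size), p, neglog10_p, p_adj and
    the ``significant`` flag at -log10 p > 1.3.
    """
    de = frozenset(de_genes)
    outside = de - collection.universe
    if outside:
        raise OraError(f"DE genes outside the universe: {sorted(outside)[:10]}")
    big_n, n = len(collection.universe), len(de)
    rows = []
    for name, members in collection.sets.items():
        big_k = len(members)
        k = len(de & members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        p = min(p, 1.0)
        rows.append({"set": name, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    if table.empty:
        table["neglog10_p"] = table["p_adj"] = table["significant"] = []
        return table
    with np.errstate(divide="ignore"):
        table["neglog10_p"] = -np.log10(table["p"])
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["neglog10_p"] > NEGLOG10_CUTOFF
    return table.sort_values("p", kind="stable")


def read_gene_sets(path: str | Path, universe: set[str]) -> GeneSetCollection:
    """Read a GMT file (set name, description, member ids per tab-separated line)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OraError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name = fields[0].strip()
            if not name:
                raise OraError(f"{path}:{lineno}: empty set name")
            if name in sets:
                raise OraError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g.strip() for g in fields[2:] if g.strip()}
    return GeneSetCollection.from_sets(sets, universe)
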