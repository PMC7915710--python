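"""Gene-set over-representation analysis (hypergeometric tail + BH).

A generic stand-in for GO-style enrichment: gene sets come from a GMT
file, the background universe is an explicit argument (typically all
genes passing the expression filter), and each set's p-value is the
upper hypergeometric tail P(X >= k) for the observed query overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable

import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: Dict[str, frozenset]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __eq__(self, other):
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def load_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, members...).

    Duplicate members within a set are stored once; a line without any
    member is a parse error naming the line number.
    """
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValueError(f"{path}:{lineno}: GMT line has no gene members")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(p.strip() for p in parts[2:] if p.strip())
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def hypergeom_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    With N = |universe|, K = |set ∩ universe|, n = |query| and k the
    query/set overlap, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    Query members outside the universe are dropped with a warning; set
    members outside the universe do not count toward K.  Results are
    BH-adjusted across sets and sorted by padj then name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped"
        )
        query &= universe
        if not query:
            raise ValueError("no query genes remain inside the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        inset = members & universe
        K = len(inset)
        k = len(query & inset)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["padj"] = adjust_bh(out["p"].to_numpy())
    return out.sort_values(["padj", "p", "set"]).reset_index(drop=True)
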