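"""GMT-driven gene-set over-representation (hypergeometric upper tail + BH).

Only overrepresentation counts: a set is flagged enriched when its raw
p-value is below alpha *and* the observed overlap exceeds the expected
overlap under random draws; BH-adjusted p-values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .preprocess import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name}")
            if not members <= self.universe:
                raise ValueError(f"gene set {name} not contained in universe")

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a new universe, dropping emptied sets."""
        sets = {}
        for name, members in self.sets.items():
            kept = members & universe
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, universe=set(universe))


def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...; tab-separated).

    If ``universe`` is given, members outside it are dropped (count logged)
    and it becomes the collection universe; otherwise the union of all
    members is used.
    """
    sets: dict[str, set[str]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if universe is not None:
                kept = [m for m in members if m in universe]
                n_dropped += len(set(members)) - len(set(kept))
                members = kept
            if members:
                sets[name] = set(members)
    if n_dropped:
        logger.info("read_gmt: dropped %d members outside the universe", n_dropped)
    uni = set(universe) if universe is not None else set().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(gsc: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gsc.sets):
            members = "\t".join(sorted(gsc.sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def hypergeom_tail(overlap: int, universe: int, set_size: int, draw: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, draw)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, draw))


def overrepresentation(
    module_genes: dict[int | str, set[str]],
    gsc: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every (module, gene set) pair for overrepresentation.

    Returns records with overlap, sizes, raw p (one-sided hypergeometric
    upper tail), BH padj across all tests, and the enriched flag
    (p < alpha and overlap > expected).
    """
    universe_n = len(gsc.universe)
    rows = []
    for module_id, genes in module_genes.items():
        present = set(genes) & gsc.universe
        if not set(genes):
            raise ValueError(f"empty module: {module_id}")
        for name, members in sorted(gsc.sets.items()):
            overlap = len(present & members)
            expected = len(members) * len(present) / universe_n
            p = hypergeom_tail(overlap, universe_n, len(members), len(present))
            rows.append(
                {
                    "module": module_id,
                    "set": name,
                    "overlap": overlap,
                    "module_size": len(present),
                    "set_size": len(members),
                    "universe_size": universe_n,
                    "expected": expected,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df["padj"] = []
        df["enriched"] = []
        return df
    df["padj"] = bh_adjust(df["p"].to_numpy())
    df["enriched"] = (df["p"] < alpha) & (df["overlap"] > df["expected"])
    return df
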