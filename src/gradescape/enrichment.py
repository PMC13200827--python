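"""Hypergeometric over-representation analysis and pathway mutation coverage.

Given a query gene set (e.g. genes mutated in one grade) and a pathway
collection, each pathway is tested for over-representation with the one-sided
upper-tail hypergeometric probability P(X >= overlap), where the population
is the gene universe, successes are the pathway members and draws are the
query genes inside the universe.  P-values are Benjamini-Hochberg adjusted
across the tested pathways.  The default universe is the union of all genes
in the collection; a cohort-derived universe can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class PathwayDB:
    """Named gene sets plus the background universe they are tested against."""

    pathways: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    dropped_outside_universe: int = 0

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.pathways.values()) if self.pathways else set()
        cleaned = {}
        dropped = 0
        for name, genes in self.pathways.items():
            inside = genes & self.universe
            dropped += len(genes) - len(inside)
            cleaned[name] = inside
        if dropped:
            warnings.warn(f"dropped {dropped} pathway genes outside the universe")
        self.pathways = cleaned
        self.dropped_outside_universe = dropped

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "PathwayDB":
        return cls(read_gmt(path), set(universe) if universe is not None else set())


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}")
        pathways[parts[0]] = {g for g in parts[2:] if g}
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(set(genes))]) for name, genes in pathways.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_ora(query: Iterable[str], db: PathwayDB) -> pd.DataFrame:
    """Over-representation of the query in every pathway of the collection.

    Returns a table (pathway, overlap, pathway_size, query_size, p, q) sorted
    by p ascending, ties by name.  Query genes outside the universe are
    dropped and counted in the ``dropped_query`` attribute of the frame.
    """
    if not db.universe:
        raise ValueError("pathway universe is empty")
    q_all = set(query)
    q = q_all & db.universe
    n_universe = len(db.universe)
    rows = []
    for name in sorted(db.pathways):
        genes = db.pathways[name]
        overlap = len(q & genes)
        # P(X >= overlap) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(overlap - 1, n_universe, len(genes), len(q))) if q else 1.0
        rows.append(
            {
                "pathway": name,
                "overlap": overlap,
                "pathway_size": len(genes),
                "query_size": len(q),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "pathway"]).reset_index(drop=True)
    df.attrs["dropped_query"] = len(q_all - q)
    return df


def pathway_mutation_coverage(mutated: Iterable[str], db: PathwayDB) -> pd.DataFrame:
    """Per-pathway count and fraction of member genes that are mutated.

    The intended use is summarizing how much of each curated oncogenic
    pathway carries at least one mutation in the cohort.  Genes outside the
    pathway definitions never affect the fractions.
    """
    if not db.pathways:
        raise ValueError("pathway collection is empty")
    m = set(mutated)
    rows = []
    for name in sorted(db.pathways):
        genes = db.pathways[name]
        hit = len(genes & m)
        rows.append(
            {
                "pathway": name,
                "pathway_size": len(genes),
                "mutated": hit,
                "fraction": hit / len(genes) if genes else 0.0,
            }
        )
    return pd.DataFrame(rows)
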