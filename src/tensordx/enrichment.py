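"""Local gene-set overlap enrichment and method-overlap (Venn) reporting.

Selected probes are mapped to gene symbols through a user-supplied
annotation table and tested for over-representation in GMT gene-set
libraries with a one-sided hypergeometric (Fisher) test against a stated
background universe, BH-adjusted across terms.  Overlaps between the gene
sets selected by different methods are summarized as exclusive Venn-region
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        restricted = {}
        for term, genes in self.sets.items():
            genes = set(genes) & self.universe
            if genes:
                restricted[term] = genes
        self.sets = restricted
        if not self.sets:
            raise ValueError("no gene set overlaps the universe")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT library: one `term <tab> description <tab> genes...` per line.

    The universe defaults to the union of all genes in the file.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            genes = {g for g in fields[2:] if g}
            if genes:
                sets[fields[0]] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    if universe is None:
        universe = set().union(*sets.values())
    return GeneSetCollection(sets, set(universe))


def map_probes_to_symbols(probe_ids, annotation: pd.DataFrame
                          ) -> tuple[set[str], dict]:
    """Collapse probe IDs to unique gene symbols via an annotation table.

    The table needs ``probe_id`` and ``symbol`` columns; probes with a
    missing or empty symbol are counted as unmapped in the report.
    """
    for col in ("probe_id", "symbol"):
        if col not in annotation.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    lookup = dict(zip(annotation["probe_id"].astype(str),
                      annotation["symbol"]))
    symbols: set[str] = set()
    unmapped = 0
    for probe in probe_ids:
        sym = lookup.get(str(probe))
        if sym is None or pd.isna(sym) or str(sym) == "":
            unmapped += 1
        else:
            symbols.add(str(sym))
    report = {"n_probes": len(list(probe_ids)), "n_symbols": len(symbols),
              "n_unmapped": unmapped}
    return symbols, report


@dataclass
class EnrichmentRow:
    term: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_raw: float
    p_adj: float

    @property
    def overlap_label(self) -> str:
        return f"{self.overlap}/{self.set_size}"


def enrich(query: set[str], collection: GeneSetCollection
           ) -> tuple[list[EnrichmentRow], dict]:
    """Hypergeometric over-representation of ``query`` in every set.

    p_raw for a term with set size K in a universe of size M, query size n
    and overlap a is the upper tail P[X >= a] of Hypergeom(M, K, n); BH
    adjusts across terms.  Rows are sorted by (p_adj, p_raw, term).
    """
    dropped = {g for g in query if g not in collection.universe}
    query = set(query) & collection.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    m = len(collection.universe)
    n = len(query)
    terms = sorted(collection.sets)
    rows = []
    p_raws = []
    for term in terms:
        genes = collection.sets[term]
        a = len(query & genes)
        p = float(stats.hypergeom.sf(a - 1, m, len(genes), n))
        p = min(p, 1.0)
        rows.append((term, a, len(genes)))
        p_raws.append(p)
    p_adj = multipletests(p_raws, method="fdr_bh")[1]
    out = [EnrichmentRow(term=t, overlap=a, set_size=k, query_size=n,
                         universe_size=m, p_raw=p, p_adj=float(q))
           for (t, a, k), p, q in zip(rows, p_raws, p_adj)]
    out.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    report = {"n_query": n, "n_dropped_from_universe": len(dropped)}
    return out, report


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "Term": [r.term for r in rows],
        "Overlap": [r.overlap_label for r in rows],
        "P": [r.p_raw for r in rows],
        "AdjP": [r.p_adj for r in rows],
    })


def overlap_report(selections: dict[str, set[str]]) -> dict:
    """Exclusive Venn-region counts plus all intersection cardinalities.

    ``regions`` maps a frozenset of method names to the number of elements
    belonging to exactly those methods; counts satisfy inclusion-exclusion
    by construction and sum to the size of the union.
    """
    if len(selections) < 2:
        raise ValueError("need >= 2 sets for an overlap report")
    names = sorted(selections)
    universe = set().union(*selections.values())
    regions: dict[frozenset, int] = {}
    for element in universe:
        membership = frozenset(n for n in names if element in selections[n])
        regions[membership] = regions.get(membership, 0) + 1
    intersections = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(selections[n] for n in combo))
            intersections[combo] = len(inter)
    return {"regions": regions, "intersections": intersections,
            "union_size": len(universe),
            "set_sizes": {n: len(selections[n]) for n in names}}
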