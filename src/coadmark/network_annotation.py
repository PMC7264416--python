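"""Gene-symbol mapping and PPI degree/hub analysis of essential features.

Feature ids (exon loci, methylation probes, mutation ids) are mapped to
gene symbols via a user-supplied annotation map; symbols are deduplicated
across omics with provenance kept. Degrees against a user-supplied
undirected edge list count distinct interaction partners (self-loops and
duplicate edges ignored); hubs are symbols with degree >= 5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class SymbolMapping:
    symbols: list  # deduplicated union, first-seen order
    provenance: dict  # symbol -> sorted list of contributing omics
    unmapped: dict  # omics -> features without an annotation


def map_to_symbols(features_per_omics: dict, annotation: dict) -> SymbolMapping:
    """Map per-omics essential features to a deduplicated symbol list.

    Unmapped features are reported per omics, never silently dropped.
    """
    symbols: list = []
    seen: set = set()
    provenance: dict = {}
    unmapped: dict = {}
    for omics, feats in features_per_omics.items():
        for f in feats:
            sym = annotation.get(f)
            if sym is None or sym == "":
                unmapped.setdefault(omics, []).append(f)
                continue
            if sym not in seen:
                seen.add(sym)
                symbols.append(sym)
            provenance.setdefault(sym, set()).add(omics)
    return SymbolMapping(
        symbols, {s: sorted(o) for s, o in provenance.items()}, unmapped
    )


def compute_degrees(symbols: list, edges: list, min_degree: int = 5) -> pd.DataFrame:
    """Degree of each symbol in the (deduplicated, loop-free) PPI graph.

    Symbols absent from the network get degree 0 and ``annotated=False``.
    Returns a DataFrame indexed by symbol with ``degree``, ``annotated``
    and ``hub`` (degree >= min_degree) columns.
    """
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    rows = {}
    for s in symbols:
        annotated = s in g
        deg = g.degree(s) if annotated else 0
        rows[s] = {"degree": int(deg), "annotated": annotated, "hub": deg >= min_degree}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("symbol")


def hub_filter(degree_table: pd.DataFrame, min_degree: int = 5) -> list:
    """Symbols with degree >= min_degree, sorted by descending degree then
    symbol."""
    hubs = degree_table[degree_table["degree"] >= min_degree]
    return sorted(hubs.index, key=lambda s: (-hubs.at[s, "degree"], str(s)))
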