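"""Genus-level co-occurrence networks.

Nodes are genera passing a mean-relative-abundance filter; edges connect
pairs whose Pearson correlation across samples exceeds a hard cutoff in
absolute value (0.28 in the reference workflow), with the sign retained.
Correlations are computed on CLR-transformed abundances by default, which
mitigates the spurious negative correlation that raw proportions induce;
a raw-proportion mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coda import clr_table, zero_replace
from .composition import mean_relative_abundance, to_relative
from .tableio import CountTable, CountTableError, TaxonomyMap, collapse_to_rank

__all__ = ["CorrelationNetwork", "pearson_correlation_matrix", "build_network"]


@dataclass
class CorrelationNetwork:
    """Thresholded signed correlation graph over genera."""

    graph: nx.Graph                 # node attr "mra"; edge attr "r"
    r_cutoff: float
    n_samples: int
    correlations: pd.DataFrame      # full genus x genus r matrix
    zero_variance: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["r"]) for a, b, d in self.graph.edges(data=True)]

    def positive_edges(self) -> list[tuple[str, str, float]]:
        return [e for e in self.edges if e[2] > 0]

    def negative_edges(self) -> list[tuple[str, str, float]]:
        return [e for e in self.edges if e[2] < 0]

    def edge_r(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["r"]
        return None


def pearson_correlation_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Product-moment correlation between the rows of ``values``.

    ``values`` is genus x sample.  Rows with zero variance have no defined
    correlation; their entries are NaN and their names are returned for
    flagging.
    """
    if values.shape[1] < 3:
        raise CountTableError("need >= 3 samples for correlations")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    zero_var = [g for g, s in zip(values.index, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = pd.DataFrame(r, index=values.index, columns=values.index)
    for g in zero_var:
        r.loc[g, :] = np.nan
        r.loc[:, g] = np.nan
    np.fill_diagonal(r.to_numpy(), 1.0)
    return r, zero_var


def build_network(
    table: CountTable,
    tax: TaxonomyMap,
    mra_threshold: float = 0.005,
    r_cutoff: float = 0.28,
    subset: list[str] | None = None,
    use_clr: bool = True,
    alpha: float = 0.5,
) -> CorrelationNetwork:
    """Build the co-occurrence network for a sample subset.

    Pipeline: collapse the table to genus level, keep genera with MRA
    above ``mra_threshold`` (recomputed within the subset), zero-replace
    and CLR-transform (or use raw proportions when ``use_clr=False``),
    correlate genus pairs across samples, and keep edges with
    ``|r| > r_cutoff``.  Node sizes carry each genus's subset MRA.
    """
    if not 0 <= r_cutoff < 1:
        raise CountTableError("r_cutoff must be in [0, 1)")
    if subset is not None:
        table = table.subset_samples(subset)
    bio = table.biological_samples
    if len(bio) < 3:
        raise CountTableError("need >= 3 biological samples")
    table = table.subset_samples(bio)
    genus_table, _ = collapse_to_rank(table, tax, "genus")
    comp = to_relative(genus_table)
    mra = mean_relative_abundance(comp)
    keep = [g for g in genus_table.feature_ids if mra[g] > mra_threshold]
    if len(keep) < 2:
        raise CountTableError("fewer than 2 genera pass the abundance filter")
    filtered = CountTable(
        genus_table.counts.loc[keep].copy(), dict(genus_table.sample_roles))
    if use_clr:
        values = clr_table(zero_replace(filtered, alpha=alpha))
    else:
        values = to_relative(filtered).proportions
    r, zero_var = pearson_correlation_matrix(values)
    g = nx.Graph()
    for genus in keep:
        g.add_node(genus, mra=float(mra[genus]))
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            rv = r.loc[a, b]
            if np.isfinite(rv) and abs(rv) > r_cutoff:
                g.add_edge(a, b, r=float(rv))
    return CorrelationNetwork(g, r_cutoff, len(bio), r, zero_var)
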