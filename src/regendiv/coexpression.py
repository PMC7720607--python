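"""Co-expression of candidate genes on their log2FC-to-EP profiles.

Pairwise Pearson correlation of the six-point fold-change profiles, a
threshold network (edge when r^2 strictly exceeds the threshold, default
0.7), node weights as the sum of |r| over incident edges, and the per-gene
correlation-quartile summaries used to relate candidate regulators to the
AO-high and NM-high divergence gene groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class CoexpressionNetwork:
    """Threshold co-expression graph plus the r^2 cutoff that built it."""

    graph: nx.Graph
    r2_threshold: float

    @property
    def node_weights(self) -> pd.Series:
        return pd.Series(
            {n: d.get("weight", 0.0) for n, d in self.graph.nodes(data=True)},
            name="weight",
        )

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d["r"], "r2": d["r2"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "r2"])

    def write_edges(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def profile_correlation(profiles: pd.DataFrame,
                        genes=None) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of gene profiles (rows).

    Profiles need at least three dimensions; genes whose profile has zero
    variance have undefined correlation and are excluded with a warning.
    """
    sub = profiles if genes is None else profiles.loc[list(genes)]
    if sub.shape[1] < 3:
        raise ValueError("profiles need at least 3 dimensions")
    if sub.isna().to_numpy().any():
        raise ValueError("NaN entries in profiles")
    sd = sub.std(axis=1, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        warnings.warn(
            f"excluding {len(flat)} zero-variance profile(s): {flat[:10]}"
        )
        sub = sub.drop(index=flat)
    r = np.corrcoef(sub.to_numpy())
    r = (r + r.T) / 2.0  # enforce exact symmetry
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=sub.index, columns=sub.index)


def build_network(r_matrix: pd.DataFrame, r2_threshold: float = 0.7,
                  groups: pd.Series | None = None) -> CoexpressionNetwork:
    """Threshold network: edge for every unordered pair with r^2 > threshold.

    The inequality is strict, so boundary pairs (r^2 exactly at the cutoff)
    are excluded.  Node weight = sum of |r| over incident edges; isolated
    genes keep weight 0.  ``groups`` optionally labels nodes (e.g. AO_high /
    NM_high / regulator).
    """
    genes = list(r_matrix.index)
    g = nx.Graph()
    for gene in genes:
        label = groups.get(gene, "") if groups is not None else ""
        g.add_node(gene, group=str(label), weight=0.0)
    arr = r_matrix.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    r2 = arr[iu, ju] ** 2
    for i, j in zip(iu[r2 > r2_threshold], ju[r2 > r2_threshold]):
        r = float(arr[i, j])
        g.add_edge(genes[i], genes[j], r=r, r2=r * r)
        g.nodes[genes[i]]["weight"] += abs(r)
        g.nodes[genes[j]]["weight"] += abs(r)
    return CoexpressionNetwork(graph=g, r2_threshold=r2_threshold)


def correlation_summary(r_matrix: pd.DataFrame, focal_genes,
                        group_a, group_b,
                        group_names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Median and quartiles of each focal gene's correlations to two groups.

    Quartiles use linear interpolation (R's default quantile type 7).  A
    focal gene that belongs to a group is excluded from its own comparison
    set (self-correlation of 1 would bias the quartiles).  A reported median
    m means the focal gene correlates above m with half the group.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("comparison groups must be non-empty")
    universe = set(r_matrix.index)
    for name, members in zip(group_names, (group_a, group_b)):
        missing = [g for g in members if g not in universe]
        if missing:
            raise KeyError(f"group {name} gene(s) absent from r matrix: {missing}")
    rows = []
    for focal in focal_genes:
        if focal not in universe:
            raise KeyError(f"focal gene {focal!r} absent from r matrix")
        row: dict[str, float | str] = {"gene": focal}
        for name, members in zip(group_names, (group_a, group_b)):
            others = [g for g in members if g != focal]
            if not others:
                raise ValueError(
                    f"group {name} has no members besides focal gene {focal!r}"
                )
            vals = r_matrix.loc[focal, others].to_numpy(dtype=float)
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7
            row[f"median_{name}"] = med
            row[f"q1_{name}"] = q1
            row[f"q3_{name}"] = q3
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
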