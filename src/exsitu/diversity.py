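"""Taxonomic accumulation and Faith's phylogenetic diversity through time.

Phylogenetic diversity (PD) is the total branch length of the minimum
spanning path connecting a set of tips in a rooted phylogeny; the convention
here is root-inclusive (the path from each tip up to the root counts), which
makes single-tip PD nonzero and PD of the full tip set equal to the total
branch length. Because collection species lists never match a published
phylogeny exactly, PD is computed at the genus level on a tree trimmed to one
tip per genus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from exsitu.series import DEFAULT_WINDOW, Window, annual_series, validate_window


def load_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


@dataclass
class GenusTree:
    """A rooted genus-level tree pre-indexed for fast PD evaluation.

    Each tip (genus) maps to the set of edges on its root-to-tip path, held as
    a boolean incidence matrix so per-year PD reduces to an OR plus a dot
    product with the edge-length vector.
    """

    tree: dendropy.Tree
    edge_lengths: np.ndarray = field(repr=False)
    tip_paths: dict[str, np.ndarray] = field(repr=False)  # genus -> bool mask

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "GenusTree":
        edges = []
        edge_index: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # the root's own edge does not separate any tips
            edge_index[id(node)] = len(edges)
            edges.append(node.edge.length if node.edge.length is not None else 0.0)
        lengths = np.asarray(edges, dtype=float)
        if (lengths < 0).any():
            raise ValueError("tree has negative branch lengths")
        paths: dict[str, np.ndarray] = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if label is None:
                raise ValueError("tree has an unlabeled tip")
            if label in paths:
                raise ValueError(f"duplicate tip label {label!r}")
            mask = np.zeros(len(edges), dtype=bool)
            node = leaf
            while node.parent_node is not None:
                mask[edge_index[id(node)]] = True
                node = node.parent_node
            paths[label] = mask
        return cls(tree=tree, edge_lengths=lengths, tip_paths=paths)

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self.tip_paths)

    @property
    def total_branch_length(self) -> float:
        return float(self.edge_lengths.sum())


def default_genus_of_tip(label: str) -> str:
    """Genus = first whitespace/underscore-separated word of the tip label."""
    return label.replace("_", " ").strip().split(" ")[0]


def trim_to_genus_tree(
    tree: dendropy.Tree,
    genus_of_tip: Mapping[str, str] | Callable[[str], str] = default_genus_of_tip,
) -> tuple[GenusTree, list[str]]:
    """Trim a species tree to one tip per genus.

    The alphabetically first tip label of each genus is retained (a
    deterministic choice) and relabeled to the genus name; pruning collapses
    degree-2 nodes with branch lengths summed, so path lengths among retained
    tips are preserved. Tips without a genus mapping are dropped and returned.
    """
    if callable(genus_of_tip):
        mapper = genus_of_tip
    else:
        table = dict(genus_of_tip)
        mapper = table.get  # returns None for missing
    by_genus: dict[str, str] = {}
    dropped: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        genus = mapper(label)
        if not genus:
            dropped.append(label)
            continue
        if genus not in by_genus or label < by_genus[genus]:
            by_genus[genus] = label
    keep = set(by_genus.values())
    # work on an independent copy (own taxon namespace) so relabeling tips
    # cannot touch the caller's tree
    pruned = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                               schema="newick")
    pruned.retain_taxa_with_labels(sorted(keep))
    # relabel retained tips to their genus
    label_to_genus = {v: k for k, v in by_genus.items()}
    for leaf in pruned.leaf_node_iter():
        leaf.taxon.label = label_to_genus[leaf.taxon.label]
    return GenusTree.from_tree(pruned), sorted(dropped)


def faith_pd(tree: GenusTree, present: Iterable[str]) -> float:
    """Faith's PD of ``present`` tips: branch-length sum of the union of
    root-to-tip paths (root-inclusive). Empty set -> 0."""
    present = set(present)
    if not present:
        return 0.0
    unknown = present - tree.tip_labels
    if unknown:
        raise KeyError(f"genera not in tree: {', '.join(sorted(unknown))}")
    mask = np.zeros(len(tree.edge_lengths), dtype=bool)
    for genus in present:
        mask |= tree.tip_paths[genus]
    return float(tree.edge_lengths[mask].sum())


def _presence_long(intervals: pd.DataFrame, column: str, window: Window) -> pd.DataFrame:
    """Long (year, taxon) table of taxa existing per year within the window."""
    start_w, end_w = validate_window(window)
    df = intervals.dropna(subset=[column])
    df = df[df["matched"]] if "matched" in df.columns else df
    if not len(df):
        return pd.DataFrame({"year": [], column: []})
    s = df["start_year"].clip(lower=start_w).to_numpy()
    e = df["end_year"].clip(upper=end_w).to_numpy()
    keep = s <= e
    s, e = s[keep], e[keep]
    taxa = df[column].to_numpy()[keep]
    reps = (e - s + 1).astype(int)
    years = np.concatenate([np.arange(a, b + 1) for a, b in zip(s, e)]) \
        if len(s) else np.array([], dtype=int)
    return pd.DataFrame({"year": years, column: np.repeat(taxa, reps)})


RANK_COLUMN = {"SPECIES": "species", "GENUS": "genus", "FAMILY": "family"}


def accumulation_series(
    intervals: pd.DataFrame,
    rank: str = "SPECIES",
    window: Window = DEFAULT_WINDOW,
) -> pd.Series:
    """Distinct accepted taxa at ``rank`` existing in each year.

    Only records matched to the backbone contribute (unmatched names carry no
    accepted taxonomy).
    """
    column = RANK_COLUMN[rank.upper()]
    start_w, end_w = validate_window(window)
    long = _presence_long(intervals, column, window)
    counts = long.groupby("year")[column].nunique() if len(long) else pd.Series(dtype=int)
    values = np.zeros(end_w - start_w + 1)
    if len(counts):
        idx = counts.index.to_numpy(dtype=int) - start_w
        values[idx] = counts.to_numpy()
    return annual_series(values, start_w, name=f"n_{column}")


def pd_series(
    intervals: pd.DataFrame,
    tree: GenusTree,
    window: Window = DEFAULT_WINDOW,
) -> tuple[pd.Series, dict]:
    """Faith's PD of the genera existing in each year.

    Genera absent from the tree are excluded from PD and reported in the
    coverage dict (``covered``/``missing`` genus sets).
    """
    start_w, end_w = validate_window(window)
    long = _presence_long(intervals, "genus", window)
    all_genera = set(long["genus"].unique()) if len(long) else set()
    missing = sorted(all_genera - tree.tip_labels)
    covered = all_genera & tree.tip_labels
    values = np.zeros(end_w - start_w + 1)
    if len(long):
        long = long[long["genus"].isin(covered)]
        for year, group in long.groupby("year"):
            values[int(year) - start_w] = faith_pd(tree, set(group["genus"]))
    coverage = {"covered": sorted(covered), "missing": missing,
                "n_covered": len(covered), "n_missing": len(missing)}
    return annual_series(values, start_w, name="faith_pd"), coverage
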