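"""Rooted-tree I/O and interrogation.

Trees are held as :class:`dendropy.Tree` objects throughout the package.  Two
flavours are distinguished by how branch lengths are read:

* *phylogram* — branch lengths are expected substitutions per site (the input
  to penalized-likelihood dating);
* *chronogram* — branch lengths are millions of years (Ma); the tree must be
  ultrametric and every node carries an ``age`` attribute (Ma before present).

Chronograms are the substrate for ancestral-range reconstruction,
state-dependent diversification and lineage-through-time curves.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "parse_newick",
    "write_newick",
    "node_ages",
    "is_binary",
    "require_binary",
    "tip_labels",
    "clade_key",
    "ltt_curve",
    "ltt_table",
    "clade_ages_across_trees",
]

#: tolerance (Ma) for ultrametricity checks
ULTRAMETRIC_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def _read_tree(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse failure: {exc}") from exc
    return tree


def parse_newick(text: str, mode: str = "phylogram",
                 repair_tip_ages: bool = True,
                 ultrametric_tol: float = ULTRAMETRIC_TOL) -> dendropy.Tree:
    """Parse a rooted newick string and validate it.

    Parameters
    ----------
    text
        Newick string with branch lengths on all non-root edges.
    mode
        ``"phylogram"`` (lengths in substitutions/site) or ``"chronogram"``
        (lengths in Ma; the tree must be ultrametric and node ages are
        computed and attached as ``node.age``).
    repair_tip_ages
        For chronograms, snap tip ages within tolerance of zero to exactly
        zero (floating-point drift in external files).
    ultrametric_tol
        Maximum allowed spread (Ma) of root-to-tip path lengths.

    Returns
    -------
    dendropy.Tree
        With ``node.age`` set on every node when ``mode="chronogram"``.
    """
    if mode not in ("phylogram", "chronogram"):
        raise ValueError(f"unknown mode {mode!r}")
    tree = _read_tree(text)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None]
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise TreeError("unlabeled tip in newick input")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            tok = node.taxon.label if node.taxon else "<internal>"
            raise TreeError(f"missing branch length on edge to {tok}")
        if node.edge.length < 0:
            tok = node.taxon.label if node.taxon else "<internal>"
            raise TreeError(f"negative branch length on edge to {tok}")
    if mode == "chronogram":
        _assign_ages(tree, repair_tip_ages=repair_tip_ages, tol=ultrametric_tol)
    return tree


def _assign_ages(tree: dendropy.Tree, repair_tip_ages: bool = True,
                 tol: float = ULTRAMETRIC_TOL) -> None:
    """Compute node ages from root-to-node path lengths; enforce ultrametricity."""
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length
    tip_depths = [depth[leaf] for leaf in tree.leaf_node_iter()]
    T = max(tip_depths)
    if T - min(tip_depths) > tol:
        raise TreeError(
            "tree is not ultrametric: tip depth spread "
            f"{T - min(tip_depths):.3g} exceeds tolerance {tol:g}"
        )
    for node in tree.preorder_node_iter():
        age = T - depth[node]
        if node.is_leaf() and repair_tip_ages:
            age = 0.0
        node.age = age


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to newick with branch lengths (round-trips parse_newick)."""
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True,
               unquoted_underscores=True, real_value_format_specifier=".12g")
    return out.getvalue().strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_ages(tree: dendropy.Tree) -> dict:
    """Map node -> age (Ma); nodes must carry ``age`` (chronogram)."""
    try:
        return {nd: nd.age for nd in tree.preorder_node_iter()}
    except AttributeError as exc:
        raise TreeError("tree has no node ages (parse with mode='chronogram')") from exc


def is_binary(tree: dendropy.Tree) -> bool:
    return all(len(nd.child_nodes()) in (0, 2) for nd in tree.preorder_node_iter())


def require_binary(tree: dendropy.Tree, context: str = "this analysis") -> None:
    for nd in tree.preorder_node_iter():
        k = len(nd.child_nodes())
        if k not in (0, 2):
            raise TreeError(
                f"{context} requires a fully resolved (binary) tree; "
                f"found a node with {k} children"
            )


def clade_key(node: dendropy.Node) -> frozenset:
    """The set of tip labels descending from ``node`` (clade identity)."""
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def ltt_curve(tree: dendropy.Tree) -> list[tuple[float, int]]:
    """Lineage-through-time step function under the crown convention.

    Returns (age, lineage count) pairs ordered from the root age to the
    present: the count is 2 at the crown (root) age, increments by one at
    each subsequent internal-node age, and equals the tip count at age 0.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 2:
        raise TreeError("LTT requires at least 2 tips")
    ages = sorted(
        (nd.age for nd in tree.preorder_internal_node_iter()), reverse=True
    )
    if not hasattr(tree.seed_node, "age"):
        raise TreeError("LTT requires a chronogram with node ages")
    curve: list[tuple[float, int]] = []
    count = 1
    for age in ages:
        count += 1
        curve.append((age, count))
    curve.append((0.0, n_tips))
    return curve


def ltt_table(tree: dendropy.Tree) -> pd.DataFrame:
    """LTT curve as a plot-ready (age, lineages) table."""
    return pd.DataFrame(ltt_curve(tree), columns=["age_ma", "lineages"])


def clade_ages_across_trees(
    reference: dendropy.Tree,
    sample: Sequence[dendropy.Tree],
) -> pd.DataFrame:
    """Summarize node ages of a tree sample on a reference chronogram.

    For each internal node of ``reference`` the matching clade (identical
    tip-label set) is searched in every sample tree; matched ages are
    summarized by their mean and 2.5%/97.5% quantiles.  Nodes matched in no
    sample tree are flagged (``support == 0``, NaN estimates).

    All trees must share the reference's tip set exactly.
    """
    ref_tips = frozenset(tip_labels(reference))
    for i, t in enumerate(sample):
        tips = frozenset(tip_labels(t))
        if tips != ref_tips:
            diff = sorted(tips.symmetric_difference(ref_tips))
            raise TreeError(f"tip-set mismatch in sample tree {i}: {diff}")
    sample_maps = []
    for t in sample:
        sample_maps.append({clade_key(nd): nd.age
                            for nd in t.preorder_internal_node_iter()})
    rows = []
    for nd in reference.preorder_internal_node_iter():
        key = clade_key(nd)
        ages = [m[key] for m in sample_maps if key in m]
        if ages:
            arr = np.asarray(ages)
            mean, lo, hi = arr.mean(), *np.percentile(arr, [2.5, 97.5])
        else:
            mean = lo = hi = np.nan
        rows.append({
            "clade": ",".join(sorted(key)),
            "reference_age": nd.age,
            "mean_age": mean,
            "q2.5": lo,
            "q97.5": hi,
            "support": len(ages),
        })
    return pd.DataFrame(rows)
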