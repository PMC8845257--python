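"""Tabular and tree I/O plus phylogenetic covariance structure.

Species tables are plain CSV (comma separated, UTF-8, header row, first
column holding species labels).  Trees are Newick, read through dendropy;
polytomies are retained as true multifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "MicrohabitatMatrix",
    "PhyloTree",
    "PhyloCov",
    "read_trait_table",
    "read_microhabitat_table",
    "read_newick",
    "grafen_branch_lengths",
    "phylo_vcv",
    "align_species",
]

STAGES = ("raw", "reduced", "log", "size_corrected")


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class TraitTable:
    """Species-by-continuous-measurement table.

    ``stage`` records where the table sits in the measurement pipeline:
    ``raw`` (mm), ``reduced`` (mm, after variable combination), ``log``
    (natural log), or ``size_corrected`` (regression residuals).
    """

    species_ids: list[str]
    values: np.ndarray
    variable_names: list[str]
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self.species_ids = [str(s).strip() for s in self.species_ids]
        self.variable_names = [str(v).strip() for v in self.variable_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.species_ids):
            raise ValueError("row count does not match species_ids")
        if p != len(self.variable_names):
            raise ValueError("column count does not match variable_names")
        _check_unique(self.species_ids, "species label")
        _check_unique(self.variable_names, "variable name")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait table contains missing or non-finite cells")
        if self.stage in ("raw", "reduced") and np.any(self.values <= 0):
            raise ValueError(f"stage={self.stage} requires strictly positive values")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.species_ids, columns=self.variable_names
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    def reorder(self, species_ids: list[str]) -> "TraitTable":
        idx = [self.species_ids.index(s) for s in species_ids]
        return TraitTable(
            [self.species_ids[i] for i in idx],
            self.values[idx],
            list(self.variable_names),
            self.stage,
        )


@dataclass
class MicrohabitatMatrix:
    """Species-by-binary-descriptor presence matrix (entries in {0, 1})."""

    species_ids: list[str]
    values: np.ndarray
    descriptor_names: list[str]

    def __post_init__(self) -> None:
        self.species_ids = [str(s).strip() for s in self.species_ids]
        self.descriptor_names = [str(v).strip() for v in self.descriptor_names]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isin(self.values, (0, 1))):
            raise ValueError("microhabitat entries must be 0 or 1")
        self.values = self.values.astype(int)
        n, m = self.values.shape
        if n != len(self.species_ids):
            raise ValueError("row count does not match species_ids")
        if m != len(self.descriptor_names):
            raise ValueError("column count does not match descriptor_names")
        _check_unique(self.species_ids, "species label")
        _check_unique(self.descriptor_names, "descriptor name")
        zero = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero.size:
            bad = ", ".join(self.species_ids[i] for i in zero)
            raise ValueError(f"species has no recorded microhabitat: {bad}")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.species_ids, columns=self.descriptor_names
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    def reorder(self, species_ids: list[str]) -> "MicrohabitatMatrix":
        idx = [self.species_ids.index(s) for s in species_ids]
        return MicrohabitatMatrix(
            [self.species_ids[i] for i in idx],
            self.values[idx],
            list(self.descriptor_names),
        )


class PhyloTree:
    """Rooted tree over uniquely labelled tips; polytomies permitted."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label.strip() for leaf in tree.leaf_node_iter()]
        _check_unique(labels, "tip label")
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = leaf.taxon.label.strip()

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def has_branch_lengths(self) -> bool:
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                return False
        return True

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.as_newick() + "\n")

    def prune_to(self, labels: list[str]) -> "PhyloTree":
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tree lacks tips: {sorted(missing)}")
        pruned = self._tree.clone(depth=1)
        pruned.retain_taxa_with_labels(list(keep))
        return PhyloTree(pruned)


@dataclass
class PhyloCov:
    """Brownian-motion expected covariance among tips.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j;
    the diagonal holds tip depths.
    """

    C: np.ndarray
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.species_ids)
        if self.C.shape != (n, n):
            raise ValueError("C shape does not match species_ids")
        if not np.allclose(self.C, self.C.T, atol=1e-12):
            raise ValueError("C must be symmetric")

    def reorder(self, species_ids: list[str]) -> "PhyloCov":
        idx = [self.species_ids.index(s) for s in species_ids]
        return PhyloCov(self.C[np.ix_(idx, idx)], list(species_ids))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.C, index=self.species_ids, columns=self.species_ids).to_csv(
            path, index_label="species"
        )


# ---------------------------------------------------------------------------
# readers


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def read_trait_table(path, stage: str = "raw") -> TraitTable:
    """Load a species x measurement CSV and validate it for ``stage``."""
    df = _read_csv(path)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in trait table {path}: {exc}") from exc
    return TraitTable(list(df.index), values, list(df.columns), stage)


def read_microhabitat_table(path) -> MicrohabitatMatrix:
    """Load a species x binary-descriptor CSV; all-zero rows are rejected."""
    df = _read_csv(path)
    return MicrohabitatMatrix(list(df.index), df.to_numpy(), list(df.columns))


def read_newick(path_or_string) -> PhyloTree:
    """Read a rooted Newick tree (file path or literal string)."""
    src = str(path_or_string)
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, **kwargs)
        else:
            tree = dendropy.Tree.get(path=src, **kwargs)
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc):
            raise ValueError(f"duplicate tip labels in Newick input: {exc}") from exc
        raise ValueError(f"cannot parse Newick input: {exc}") from exc
    tree.is_rooted = True
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# tree utilities


def grafen_branch_lengths(ptree: PhyloTree, rho: float = 1.0) -> PhyloTree:
    """Assign node heights from descendant-tip counts.

    A node subtending ``t`` tips sits at height ``((t - 1)/(n - 1))**rho``
    above the tips; branch lengths are parent minus child heights.  The
    result is ultrametric with root-to-tip depth 1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    out = ptree.copy()
    tree = out.tree
    n = out.n_tips
    if n < 2:
        raise ValueError("Grafen scaling needs at least 2 tips")
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_tips = 1
            node._height = 0.0
        else:
            node._n_tips = sum(ch._n_tips for ch in node.child_nodes())
            node._height = ((node._n_tips - 1) / (n - 1)) ** rho
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = node.parent_node._height - node._height
    for node in tree.preorder_node_iter():
        del node._n_tips, node._height
    return out


def phylo_vcv(ptree: PhyloTree) -> PhyloCov:
    """Brownian-motion covariance matrix of a tree with branch lengths."""
    if not ptree.has_branch_lengths():
        raise ValueError("tree has missing branch lengths")
    tree = ptree.tree
    labels = ptree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            # a root edge (e.g. left behind by pruning) is shared by all tips
            node._depth = node.edge.length or 0.0
        else:
            node._depth = node.parent_node._depth + node.edge.length
    # collect tip index sets bottom-up; pairs split across children share
    # the current node as MRCA
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = node._depth
            node._tips = [i]
        else:
            children = [ch._tips for ch in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = node._depth
            node._tips = [i for tips in children for i in tips]
    for node in tree.preorder_node_iter():
        del node._depth, node._tips
    return PhyloCov(C, labels)


def align_species(
    trait: TraitTable | None = None,
    habitat: MicrohabitatMatrix | None = None,
    tree: PhyloTree | None = None,
):
    """Reorder tables and prune the tree to a shared species order.

    Species match by exact label after whitespace trimming.  The common
    order follows the first table supplied (or the tree's tip order if
    only a tree plus one table is given).  Dropping species raises a
    warning, an empty intersection an error.  Returns the given objects
    in (trait, habitat, tree) order, omitting the ones not supplied.
    """
    objects = [o for o in (trait, habitat, tree) if o is not None]
    if len(objects) < 2:
        raise ValueError("align_species needs at least two objects")
    sets = []
    for obj in objects:
        labels = obj.tip_labels if isinstance(obj, PhyloTree) else obj.species_ids
        sets.append(set(labels))
    common = set.intersection(*sets)
    if not common:
        raise ValueError("no species shared between inputs")
    ref = next(o for o in objects if not isinstance(o, PhyloTree))
    order = [s for s in ref.species_ids if s in common]
    dropped = sorted(set.union(*sets) - common)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} species absent from some input: {dropped}",
            stacklevel=2,
        )
    out = []
    if trait is not None:
        out.append(trait.reorder(order))
    if habitat is not None:
        out.append(habitat.reorder(order))
    if tree is not None:
        out.append(tree.prune_to(order))
    return tuple(out)
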