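"""Synthetic trees, clustered binary ecologies, and morphologies.

Generates data with the statistical structure the analysis assumes:
pure-birth tree topologies Grafen-scaled to depth 1, latent ecological
clusters emitting Bernoulli descriptor profiles, and log-scale
morphology built from an isometric size component, Brownian motion on
the tree, cluster-linked mean shifts on a trait subset, and observation
noise.  Everything is reproducible from (scenario, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from ecomorph.io_formats import (
    MicrohabitatMatrix,
    PhyloTree,
    TraitTable,
    grafen_branch_lengths,
)

__all__ = [
    "SyntheticScenario",
    "simulate_tree",
    "simulate_microhabitat",
    "simulate_morphology",
    "simulate_dataset",
]


def default_profiles(k: int, m: int, p_on: float = 0.95, p_off: float = 0.02) -> np.ndarray:
    """Block profiles: each cluster 'owns' a contiguous descriptor block."""
    profiles = np.full((k, m), p_off)
    bounds = np.linspace(0, m, k + 1).astype(int)
    for c in range(k):
        profiles[c, bounds[c] : bounds[c + 1]] = p_on
    return profiles


@dataclass
class SyntheticScenario:
    """Generator settings; defaults mirror the analysis' matrix shapes
    (61 species, 12 binary descriptors, 36 traits, 4 latent clusters)."""

    n_species: int = 61
    n_descriptors: int = 12
    k_true: int = 4
    cluster_profiles: np.ndarray | None = None
    n_traits: int = 36
    size_sd: float = 1.0
    bm_rate: float = 1.0
    effect_size: float = 2.0
    shifted_trait_indices: tuple[int, ...] = tuple(range(10))
    noise_sd: float = 0.05
    seed: int = 20220214

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_descriptors, self.k_true, self.n_traits) < 1:
            raise ValueError("all counts must be positive")
        if self.cluster_profiles is None:
            self.cluster_profiles = default_profiles(self.k_true, self.n_descriptors)
        self.cluster_profiles = np.asarray(self.cluster_profiles, dtype=float)
        if self.cluster_profiles.shape != (self.k_true, self.n_descriptors):
            raise ValueError("cluster_profiles must be k_true x n_descriptors")
        if np.any((self.cluster_profiles < 0) | (self.cluster_profiles > 1)):
            raise ValueError("Bernoulli probabilities must lie in [0, 1]")
        if np.any(self.cluster_profiles.sum(axis=1) == 0):
            raise ValueError("a cluster profile of all zeros cannot emit species")
        bad = [j for j in self.shifted_trait_indices if not 0 <= j < self.n_traits]
        if bad:
            raise ValueError(f"shifted trait indices out of range: {bad}")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["cluster_profiles"] = self.cluster_profiles.tolist()
        d["shifted_trait_indices"] = list(self.shifted_trait_indices)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticScenario":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("cluster_profiles") is not None:
            d["cluster_profiles"] = np.asarray(d["cluster_profiles"], dtype=float)
        d["shifted_trait_indices"] = tuple(d.get("shifted_trait_indices", ()))
        return cls(**d)


def simulate_tree(n: int, seed: int | None = None) -> PhyloTree:
    """Pure-birth (Yule) topology on n tips, Grafen-scaled to depth 1.

    Under constant-rate pure birth every extant lineage is equally likely
    to split next, so repeatedly splitting a uniformly chosen tip yields
    the Yule topology distribution.  Branch lengths come from Grafen
    scaling, not the birth process, matching the analysis convention.
    """
    if n < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    while len(leaves) < n:
        split = leaves.pop(int(rng.integers(len(leaves))))
        leaves.append(split.new_child())
        leaves.append(split.new_child())
    order = rng.permutation(n)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{order[i] + 1}")
    tree.is_rooted = True
    return grafen_branch_lengths(PhyloTree(tree))


def simulate_microhabitat(
    scn: SyntheticScenario, seed: int | None = None
) -> tuple[MicrohabitatMatrix, np.ndarray]:
    """Bernoulli descriptor matrix plus true cluster labels (1..k).

    Species are dealt to clusters round-robin so every cluster is
    populated; all-zero descriptor rows are resampled to satisfy the
    loader's invariant.
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    labels = np.arange(scn.n_species) % scn.k_true + 1
    rng.shuffle(labels)
    probs = scn.cluster_profiles[labels - 1]
    values = (rng.random((scn.n_species, scn.n_descriptors)) < probs).astype(int)
    for i in np.flatnonzero(values.sum(axis=1) == 0):
        while values[i].sum() == 0:
            values[i] = (rng.random(scn.n_descriptors) < probs[i]).astype(int)
    species = [f"t{i + 1}" for i in range(scn.n_species)]
    names = [f"descriptor_{j + 1}" for j in range(scn.n_descriptors)]
    return MicrohabitatMatrix(species, values, names), labels


def _simulate_bm(ptree: PhyloTree, q: int, rate: float, rng) -> np.ndarray:
    """Brownian motion from root value 0, increments drawn pre-order."""
    tree = ptree.tree
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._bm = np.zeros(q)
        else:
            bl = node.edge.length
            node._bm = node.parent_node._bm + rng.normal(
                0.0, np.sqrt(rate * bl), q
            )
    out = np.array([leaf._bm for leaf in tree.leaf_node_iter()])
    for node in tree.preorder_node_iter():
        del node._bm
    return out


def simulate_morphology(
    tree: PhyloTree,
    labels: np.ndarray,
    scn: SyntheticScenario,
    seed: int | None = None,
) -> TraitTable:
    """Log-scale trait table: size + Brownian motion + cluster shifts + noise.

    Trait j of species i is ``size_i + BM_ij + shift[c(i), j] + noise``.
    The shifted trait subset is split into one block per cluster; each
    cluster's block is raised by ``effect_size`` tip-BM standard
    deviations, giving every cluster a distinct mean vector.
    """
    labels = np.asarray(labels)
    tips = tree.tip_labels
    if labels.shape != (len(tips),):
        raise ValueError("labels must align with the tree's tips")
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    n, q = len(tips), scn.n_traits
    bm_order = {lab: i for i, lab in enumerate(tips)}

    size = rng.normal(0.0, scn.size_sd, n)
    bm = _simulate_bm(tree, q, scn.bm_rate, rng)
    tip_sd = np.sqrt(scn.bm_rate)  # Grafen trees have depth 1
    shift = np.zeros((scn.k_true, q))
    if scn.shifted_trait_indices:
        blocks = np.array_split(
            np.asarray(scn.shifted_trait_indices, dtype=int), scn.k_true
        )
        for c, block in enumerate(blocks):
            shift[c, block] = scn.effect_size * tip_sd
    noise = rng.normal(0.0, scn.noise_sd, (n, q))
    values = size[:, None] + bm + shift[labels - 1] + noise
    names = [f"trait_{j + 1}" for j in range(q)]
    return TraitTable(list(tips), values, names, "log")


def simulate_dataset(scn: SyntheticScenario):
    """Tree, habitat matrix, morphology and truth for one scenario draw."""
    rng = np.random.default_rng(scn.seed)
    tree_seed, hab_seed, morph_seed = rng.integers(0, 2**31 - 1, 3)
    tree = simulate_tree(scn.n_species, int(tree_seed))
    habitat, labels = simulate_microhabitat(scn, int(hab_seed))
    # habitat rows are t1..tn; align labels to the tree's tip order
    order = [habitat.species_ids.index(lab) for lab in tree.tip_labels]
    labels_tree = labels[order]
    traits = simulate_morphology(tree, labels_tree, scn, int(morph_seed))
    return tree, habitat, traits, labels
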