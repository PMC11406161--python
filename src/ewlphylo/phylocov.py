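"""Phylogenetic and temporal covariance structure.

The species-level correlation matrix is derived from a sample of ultrametric
trees under a Brownian-motion expectation (shared root-to-ancestor path
length), and residuals within an individual decay with a Gaussian kernel in
the time difference between weighings.  ``residual_covariance`` assembles
the observation-level covariance the Gaussian likelihood uses, with random
effects for frog, housing, date and species marginalized into it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import dendropy
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .hmodel import VarianceComponents
    from .prep import ModelFrame


@dataclass
class KernelParams:
    """Gaussian temporal kernel, parameterized by the correlation ``rho``
    at the reference lag (default 20 min, the nominal weighing interval)."""

    rho: float
    reference_lag: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.reference_lag <= 0:
            raise ValueError("reference_lag must be positive")


@dataclass
class CorrelationMatrix:
    """Species-by-species phylogenetic correlation (unit diagonal, PSD)."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.species)
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix shape does not match species list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [0, 1]")
        if np.linalg.eigvalsh(self.values).min() < -1e-8:
            raise ValueError("correlation matrix must be positive semidefinite")

    def loc(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(species=list(df.index), values=df.to_numpy())


def _clade_map(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each edge (keyed by the set of tip labels below it) to its length."""
    out: dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out[tips] = float(node.edge.length or 0.0)
    return out


def mean_branch_tree(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Average edge lengths across a tree sample sharing one topology.

    Trees are grouped by rooted topology (the set of tip-label clades); the
    strict-majority topology is kept and each of its edges is set to the
    across-tree mean length.  An empty sample or the absence of a majority
    topology is an error.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree sample")
    maps = [_clade_map(t) for t in trees]
    keys = [frozenset(m.keys()) for m in maps]
    counts = Counter(keys)
    topo, n_major = counts.most_common(1)[0]
    if n_major * 2 <= len(trees) and len(counts) > 1:
        raise ValueError("no majority topology in tree sample")
    sums: dict[frozenset, list[float]] = defaultdict(list)
    for key, m in zip(keys, maps):
        if key == topo:
            for clade, length in m.items():
                sums[clade].append(length)
    template = trees[keys.index(topo)].clone(depth=1)
    for node in template.postorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        node.edge.length = float(np.mean(sums[tips]))
    return template


def phylo_correlation(tree: dendropy.Tree) -> CorrelationMatrix:
    """Brownian-motion correlation: shared root-to-MRCA path length scaled
    by the geometric mean of the two tip depths."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = sorted(lf.taxon.label for lf in leaves)
    depth = {lf.taxon.label: float(lf.root_distance) for lf in leaves}
    if any(d <= 0 for d in depth.values()):
        raise ValueError("zero root-to-tip depth; cannot scale to a correlation")
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two tips")
    # shared root-to-MRCA path from patristic distances:
    # shared(i, j) = (depth_i + depth_j - d_ij) / 2
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in depth}
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            d_ij = float(pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
            shared = max(0.0, 0.5 * (depth[labels[i]] + depth[labels[j]] - d_ij))
            values[i, j] = values[j, i] = shared / np.sqrt(
                depth[labels[i]] * depth[labels[j]]
            )
    return CorrelationMatrix(species=labels, values=values)


def temporal_correlation(dt, params: KernelParams):
    """Correlation between residuals ``dt`` minutes apart:
    ``rho ** (dt / reference_lag) ** 2`` (1 at zero lag, ``rho`` at the
    reference lag, Gaussian decay beyond)."""
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be nonnegative")
    out = params.rho ** ((dt / params.reference_lag) ** 2)
    return float(out) if out.ndim == 0 else out


def residual_covariance(
    frame: "ModelFrame",
    phylo: CorrelationMatrix,
    params: KernelParams,
    variances: "VarianceComponents",
    mode: str = "nested",
    nugget: float | None = None,
) -> np.ndarray:
    """Observation-by-observation covariance with random effects marginalized.

    ``nested`` (default): the error term ``sigma2_e * k(|dt|)`` applies only
    within an individual; shared frog/housing/date groups contribute their
    variances and every pair receives ``sigma2_species * Phi[s_a, s_b]``.
    ``composite`` applies the literal composite error term
    ``sigma2_e * Phi[s_a, s_b] * k(|dt|)`` across all pairs instead, with the
    same group-variance terms.  A small diagonal nugget keeps the matrix
    invertible when two rows share a timestamp.
    """
    if mode not in ("nested", "composite"):
        raise ValueError(f"unknown covariance mode {mode!r}")
    data = frame.data
    missing = set(data["species"].unique()) - set(phylo.species)
    if missing:
        raise ValueError(f"species absent from the correlation matrix: {sorted(missing)}")
    if nugget is None:
        nugget = frame.coding.nugget

    t = data["time_min"].to_numpy(float)
    frog = pd.factorize(data["frog"])[0]
    housing = pd.factorize(data["housing"])[0]
    date = pd.factorize(data["date"])[0]
    sp_idx = np.array([phylo.species.index(s) for s in data["species"]])

    same_frog = frog[:, None] == frog[None, :]
    same_housing = housing[:, None] == housing[None, :]
    same_date = date[:, None] == date[None, :]
    phi = phylo.values[np.ix_(sp_idx, sp_idx)]
    kernel = temporal_correlation(np.abs(t[:, None] - t[None, :]), params)

    cov = (
        variances.frog * same_frog
        + variances.housing * same_housing
        + variances.date * same_date
        + variances.species * phi
    )
    if mode == "nested":
        cov = cov + variances.error * kernel * same_frog
    else:
        cov = cov + variances.error * kernel * phi
    cov = cov + nugget * np.eye(len(t))
    return cov
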