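"""Phylogenetic signal in allometric divergence and in species mean shapes.

Congruence between allometric and phylogenetic divergence is probed three
ways: (1) the Pearson matrix correlation between pairwise trajectory
angles and patristic distances from a chronogram (descriptive only — no
permutation test); (2) a UPGMA phenogram (see :mod:`allotraj.divergence`)
inspected for taxonomic clustering; and (3) the multivariate extension of
Blomberg's K, computed on the principal coordinates of the angle matrix,
with a permutation test shuffling trait rows across the tips. K = 1
matches a Brownian-motion expectation on the given tree; K near 0 means
no signal. The same machinery applied to species mean shapes (Procrustes
distances between per-species mean configurations; K on mean tangent
coordinates) provides the contrast case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .dataset import StudyConfig
from .divergence import AngleMatrix, upgma_phenogram
from .procrustes import procrustes_distance

logger = logging.getLogger("allotraj")

PCOA_EIG_RTOL = 1e-8


def patristic_distances(tree: dendropy.Tree, species) -> np.ndarray:
    """Summed branch lengths between every pair of the given tips."""
    species = list(species)
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise KeyError(f"species not in tree (run match_taxa first): {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    s = len(species)
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
    return out


def tree_vcv(tree: dendropy.Tree, species) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length per tip pair."""
    species = list(species)
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    leaf = {n.taxon.label: n for n in tree.leaf_node_iter()}
    s = len(species)
    c = np.zeros((s, s))
    for i in range(s):
        c[i, i] = leaf[species[i]].root_distance
        for j in range(i + 1, s):
            mrca = tree.mrca(taxa=[taxa[species[i]], taxa[species[j]]])
            c[i, j] = c[j, i] = mrca.root_distance or 0.0
    return c


def matrix_correlation(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation between the strictly-lower triangles of two matrices."""
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square with identical shapes")
    if m1.shape[0] < 3:
        raise ValueError("matrix correlation needs at least 3 species")
    i, j = np.tril_indices(m1.shape[0], k=-1)
    v1, v2 = m1[i, j], m2[i, j]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero variance in a lower triangle: correlation undefined")
    return float(np.corrcoef(v1, v2)[0, 1])


@dataclass
class PCoAResult:
    """Principal coordinates of a distance matrix (Gower double-centering)."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    dropped_negative: int
    species: list[str]


def pcoa_from_angles(matrix: AngleMatrix) -> PCoAResult:
    """Metric embedding of the angle matrix.

    Gower-centers -0.5 * D^2, eigendecomposes, and keeps axes with
    eigenvalue above 1e-8 x largest; negative-eigenvalue axes (angle
    matrices need not be Euclidean) are dropped and counted, with no
    Cailliez/Lingoes correction. Coordinates are eigenvectors scaled by
    square-rooted eigenvalues, so their pairwise Euclidean distances
    approximate the input angles.
    """
    d = np.asarray(matrix.angles, float)
    s = d.shape[0]
    if s < 3:
        raise ValueError("PCoA needs at least 3 species")
    if np.allclose(d, 0):
        raise ValueError("all distances zero: no variation to embed")
    j = np.eye(s) - np.ones((s, s)) / s
    b = -0.5 * j @ (d**2) @ j
    eig, vec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    keep = eig > PCOA_EIG_RTOL * eig[0]
    dropped_negative = int((eig < 0).sum())
    eig_kept, vec_kept = eig[keep], vec[:, keep]
    for col in range(vec_kept.shape[1]):  # deterministic sign
        i_max = int(np.argmax(np.abs(vec_kept[:, col])))
        if vec_kept[i_max, col] < 0:
            vec_kept[:, col] = -vec_kept[:, col]
    coords = vec_kept * np.sqrt(eig_kept)
    if dropped_negative:
        logger.info("PCoA: dropped %d negative-eigenvalue axes", dropped_negative)
    return PCoAResult(
        coordinates=coords, eigenvalues=eig_kept,
        dropped_negative=dropped_negative, species=list(matrix.species),
    )


@dataclass
class KResult:
    """Multivariate Blomberg's K with its tip-permutation test."""

    k_stat: float
    p_value: float
    n_permutations: int
    seed: int
    n_species: int


def _k_statistic(y: np.ndarray, c_inv: np.ndarray, denom_expected: float) -> float:
    s = y.shape[0]
    ones = np.ones(s)
    w = c_inv @ ones
    a = (w @ y) / (ones @ w)          # GLS root state, one value per trait
    yc = y - a
    num = float((yc * yc).sum())
    den = float(np.einsum("ij,ik,kj->", yc, c_inv, yc))
    return (num / den) / denom_expected


def kmult(traits: np.ndarray, tree: dendropy.Tree, species,
          n_permutations: int = 1000, seed: int = 0) -> KResult:
    """Multivariate Blomberg's K with a tip-permutation significance test.

    ``traits`` rows must be ordered as ``species`` (tree tip labels).
    K is the ratio of observed to Brownian-expected phylogenetic
    similarity:  [tr(Yc'Yc) / tr(Yc'C^-1 Yc)] / [(tr C - s / 1'C^-1 1) / (s - 1)]
    with Yc the traits centered on the GLS root state and C the tree
    covariance. The permutation test shuffles trait rows across tips;
    p = (#{K_perm >= K_obs} + 1) / (n_permutations + 1).
    """
    y = np.atleast_2d(np.asarray(traits, float))
    if y.ndim == 2 and y.shape[0] == 1 and len(list(species)) > 1:
        y = y.T
    species = list(species)
    s = y.shape[0]
    if s != len(species):
        raise ValueError(f"{s} trait rows but {len(species)} species labels")
    if s < 4:
        raise ValueError("K needs at least 4 species")
    if s < 20:
        logger.warning(
            "K permutation test has low power below 20 species (s=%d)", s
        )
    c = tree_vcv(tree, species)
    try:
        c_inv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular tree covariance (zero-length branches?)") from exc
    ones = np.ones(s)
    denom_expected = (float(np.trace(c)) - s / float(ones @ c_inv @ ones)) / (s - 1)
    k_obs = _k_statistic(y, c_inv, denom_expected)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(s)
        if _k_statistic(y[perm], c_inv, denom_expected) >= k_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return KResult(
        k_stat=float(k_obs), p_value=float(p),
        n_permutations=n_permutations, seed=seed, n_species=s,
    )


@dataclass
class MeanShapeSignal:
    """Phylogenetic signal of species mean shapes (the contrast to angles)."""

    matrix_r: float
    k: KResult
    distance_matrix: np.ndarray
    species: list[str]
    phenogram: dendropy.Tree


def species_mean_shapes(aligned_coords: np.ndarray, species_labels):
    """Per-species averages of aligned configurations; returns (species, means)."""
    species_labels = np.asarray(species_labels)
    sp = sorted(set(species_labels))
    means = np.stack([aligned_coords[species_labels == s].mean(axis=0) for s in sp])
    return sp, means


def mean_shape_signal(aligned_coords: np.ndarray, scores: np.ndarray, species_labels,
                      tree: dendropy.Tree, config: StudyConfig,
                      species_subset=None) -> MeanShapeSignal:
    """Matrix correlation and K using species mean shapes instead of angles.

    Mean shapes are per-species averages of the aligned configurations
    (and of the tangent scores). The distance matrix holds pairwise
    Procrustes distances between mean configurations and is correlated
    with patristic distances; K is computed directly on the mean tangent
    coordinates (Euclidean in tangent space). A UPGMA phenogram of the
    mean-shape distances is also built.
    """
    species_labels = np.asarray(species_labels)
    sp_all, mean_cfg = species_mean_shapes(aligned_coords, species_labels)
    _, mean_scores = species_mean_shapes(scores, species_labels)
    if species_subset is not None:
        keep = [i for i, s in enumerate(sp_all) if s in set(species_subset)]
        sp_all = [sp_all[i] for i in keep]
        mean_cfg, mean_scores = mean_cfg[keep], mean_scores[keep]
    if len(sp_all) < 4:
        raise ValueError("mean-shape signal needs at least 4 species")
    s = len(sp_all)
    dmat = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            dmat[i, j] = dmat[j, i] = procrustes_distance(mean_cfg[i], mean_cfg[j])
    if np.allclose(dmat, 0):
        raise ValueError("identical species mean shapes: no variation")
    pat = patristic_distances(tree, sp_all)
    r = matrix_correlation(dmat, pat)
    k = kmult(mean_scores, tree, sp_all,
              n_permutations=config.n_permutations, seed=config.seed)
    pheno = upgma_phenogram(_as_distance_matrix(sp_all, dmat))
    return MeanShapeSignal(matrix_r=r, k=k, distance_matrix=dmat,
                           species=list(sp_all), phenogram=pheno)


def _as_distance_matrix(species, dmat) -> AngleMatrix:
    # AngleMatrix doubles as a generic labelled symmetric distance matrix,
    # but Procrustes distances are far below its 180-degree cap, so reuse is safe.
    return AngleMatrix(species=list(species), angles=dmat)
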