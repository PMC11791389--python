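"""Divergence between allometric trajectories: pairwise angles and their structure.

The divergence between two species' static allometries is the angle (in
degrees) between their slope-coefficient vectors. Direction sense is
retained, so angles run from 0 to 180: trajectories are treated as
oriented, and empirically obtuse angles do occur.

Summaries mirror the field's reporting conventions: mean, SD, median,
10th/90th percentiles (linear interpolation of order statistics), min and
max over the strictly-lower-triangle pairs; medians are also split into
within- vs between-genus species pairs; and a UPGMA phenogram summarizes
the full angle matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .dataset import genus_of

QUANTILE_METHOD = "linear"  # h = (n - 1) p + 1 interpolation of order statistics


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees (arccos of the normalized dot product)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 1e-300 or nb <= 1e-300:
        raise ValueError("angle with a zero vector is undefined")
    cosine = np.clip(float(a @ b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


@dataclass
class AngleMatrix:
    """Symmetric matrix of pairwise trajectory angles (degrees) for one dataset."""

    species: list[str]
    angles: np.ndarray
    sex: str = ""
    min_n: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, float)
        s = len(self.species)
        if a.shape != (s, s):
            raise ValueError(f"angle matrix shape {a.shape} does not match {s} species")
        if not np.allclose(a, a.T, atol=1e-9) or not np.allclose(np.diag(a), 0):
            raise ValueError("angle matrix must be symmetric with zero diagonal")
        if a.min() < -1e-9 or a.max() > 180 + 1e-9:
            raise ValueError("angles must lie in [0, 180] degrees")
        self.angles = (a + a.T) / 2
        np.fill_diagonal(self.angles, 0.0)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n_species, k=-1)
        return self.angles[i, j]

    def pair_labels(self) -> list[tuple[str, str]]:
        i, j = np.tril_indices(self.n_species, k=-1)
        return [(self.species[b], self.species[a]) for a, b in zip(i, j)]


@dataclass
class AngleSummary:
    """Location/spread statistics over the pairwise angles of one dataset."""

    mean: float
    sd: float
    median: float
    q10: float
    q90: float
    min: float
    max: float
    n_species: int
    n_pairs: int

    @classmethod
    def from_values(cls, values: np.ndarray, n_species: int) -> "AngleSummary":
        v = np.asarray(values, float)
        return cls(
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
            median=float(np.quantile(v, 0.5, method=QUANTILE_METHOD)),
            q10=float(np.quantile(v, 0.10, method=QUANTILE_METHOD)),
            q90=float(np.quantile(v, 0.90, method=QUANTILE_METHOD)),
            min=float(v.min()),
            max=float(v.max()),
            n_species=n_species,
            n_pairs=int(v.size),
        )


def pairwise_angle_matrix(fits, only_non_negligible: bool = True,
                          sex: str = "", min_n: int = 0) -> AngleMatrix:
    """Angles between slope vectors for every pair of eligible species.

    Species order is alphabetical. With ``only_non_negligible`` (the
    default), species whose regression fails the inclusion rule are left
    out.
    """
    eligible = [f for f in fits if (not only_non_negligible) or f.non_negligible]
    if len(eligible) < 2:
        raise ValueError(
            f"need at least 2 eligible species, got {len(eligible)} "
            f"(of {len(list(fits))} fits)"
        )
    eligible = sorted(eligible, key=lambda f: f.species)
    s = len(eligible)
    angles = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            ang = vector_angle(eligible[i].slope, eligible[j].slope)
            angles[i, j] = angles[j, i] = ang
    return AngleMatrix(
        species=[f.species for f in eligible], angles=angles,
        sex=sex or (eligible[0].sex if eligible[0].sex else ""), min_n=min_n,
    )


def summarize_angles(matrix: AngleMatrix) -> AngleSummary:
    """Summary statistics over the strictly-lower-triangle angles."""
    if matrix.n_species < 2:
        raise ValueError("need at least 2 species")
    return AngleSummary.from_values(matrix.lower_triangle(), matrix.n_species)


def genus_partition_medians(matrix: AngleMatrix, genus_map: dict | None = None):
    """Median angle within vs between genera.

    Returns ``(within_median, between_median, n_within, n_between)``;
    an empty partition yields NaN (undefined), never zero. Genus defaults
    to the text before the underscore of each species label.
    """
    if genus_map is None:
        genus_map = {sp: genus_of(sp) for sp in matrix.species}
    within, between = [], []
    s = matrix.n_species
    for i in range(s):
        for j in range(i + 1, s):
            same = genus_map[matrix.species[i]] == genus_map[matrix.species[j]]
            (within if same else between).append(matrix.angles[i, j])
    wm = float(np.median(within)) if within else float("nan")
    bm = float(np.median(between)) if between else float("nan")
    return wm, bm, len(within), len(between)


def upgma_phenogram(matrix: AngleMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) phenogram of the angle matrix.

    Node heights are half the merge distance, so the output is ultrametric
    with root-to-tip paths equal to half the final merge. Ties are broken
    by the alphabetical order of cluster labels (a cluster is labelled by
    its alphabetically first member), making the topology reproducible.
    """
    if matrix.n_species < 3:
        raise ValueError("UPGMA needs at least 3 species")
    d = np.asarray(matrix.angles, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite entries in the distance matrix")
    # cluster state: label -> (newick, height, size); distances between labels
    clusters = {sp: (sp, 0.0, 1) for sp in matrix.species}
    dist: dict[frozenset, float] = {}
    for i in range(matrix.n_species):
        for j in range(i + 1, matrix.n_species):
            dist[frozenset((matrix.species[i], matrix.species[j]))] = d[i, j]
    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                key = (dist[frozenset((labels[i], labels[j]))], labels[i], labels[j])
                if best is None or key < best:
                    best = key
        dmin, a, b = best
        height = dmin / 2.0
        na, ha, sa = clusters.pop(a)
        nb, hb, sb = clusters.pop(b)
        merged_label = min(a, b)
        newick = f"({na}:{height - ha:.17g},{nb}:{height - hb:.17g})"
        for other in list(clusters):
            dab = (
                sa * dist.pop(frozenset((a, other))) + sb * dist.pop(frozenset((b, other)))
            ) / (sa + sb)
            dist[frozenset((merged_label, other))] = dab
        clusters[merged_label] = (newick, height, sa + sb)
    (newick, _, _), = clusters.values()
    tree = dendropy.Tree.get(data=newick + ";", schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def cophenetic_distances(tree: dendropy.Tree, labels) -> np.ndarray:
    """Patristic distances of a dendrogram, ordered to match ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    s = len(labels)
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return out
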