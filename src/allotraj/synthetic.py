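"""Synthetic landmark datasets with known allometric and phylogenetic structure.

The generator emulates the data structure the pipeline assumes: per
species, adult specimens with a 6-landmark 2D midplane cranial
configuration (prosthion, posterior palate, basion, rhinion, nasion,
inion wireframe), log-normal-ish size variation, and linear static
allometry — tangent shape = species mean + slope * (lnCS - species mean
lnCS) + isotropic noise. Species mean shapes evolve by Brownian motion on
a (supplied or pure-birth-simulated) tree; slope vectors are a shared
base trend plus a mixture of tree-structured Brownian and fully
independent deviations, controlled by ``signal_mix`` (1 = slopes fully
Brownian, i.e. maximal phylogenetic signal; 0 = no signal).

Simulation happens in the tangent space at the template through an
orthonormal basis, so true slope vectors are exactly representable in the
analysis space and recovery error is attributable to sampling alone.
Specimens are emitted at true size (centroid size = exp(lnCS)) under a
random proper rotation and bounded translation, so the Procrustes
superimposition is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.spatial.distance import pdist

from .dataset import LandmarkDataset, SpecimenRecord
from .io import write_tps
from .phylosignal import tree_vcv
from .procrustes import centroid_size

_RAW_TEMPLATE = np.array(
    [
        [1.00, -0.30],   # prosthion
        [0.45, -0.35],   # posterior palate on the midline
        [-0.60, -0.35],  # basion
        [0.95, 0.05],    # rhinion
        [0.40, 0.25],    # nasion
        [-0.90, 0.30],   # inion
    ]
)

_BASE_SLOPE_DIRECTION = np.array([1.5, -1.0, 0.8, -0.6, 1.2, -0.9, 0.5, -1.1])


def default_template() -> np.ndarray:
    """Hexagonal 6-landmark midplane cranial template, centered, unit centroid size."""
    t = _RAW_TEMPLATE - _RAW_TEMPLATE.mean(axis=0)
    return t / centroid_size(_RAW_TEMPLATE)


def tangent_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (m x k*d rows) of the tangent space at a template.

    The tangent space is the orthogonal complement of the directions
    consumed by superimposition at the template: the two translations,
    the scaling direction (the template itself) and the infinitesimal
    rotation (the template rotated 90 degrees), leaving m = 2k - 4
    dimensions for k 2D landmarks.
    """
    template = np.asarray(template, float)
    k, d = template.shape
    if d != 2:
        raise ValueError("tangent_basis currently supports 2D templates")
    flat = template.reshape(-1)
    flat = flat / np.linalg.norm(flat)
    tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    rot = template @ np.array([[0.0, 1.0], [-1.0, 0.0]])
    rot = rot.reshape(-1)
    rot = rot / np.linalg.norm(rot)
    constraints = np.vstack([tx, ty, flat, rot])
    basis = null_space(constraints).T   # (2k-4, 2k), orthonormal rows
    for i in range(basis.shape[0]):     # deterministic sign
        j = int(np.argmax(np.abs(basis[i])))
        if basis[i, j] < 0:
            basis[i] = -basis[i]
    return basis


def default_base_slope(m: int = 8, norm: float = 0.063) -> np.ndarray:
    """Shared allometric trend: fixed direction, norm tuned to moderate effect size."""
    if m != len(_BASE_SLOPE_DIRECTION):
        raise ValueError(f"default base slope is defined for m=8, got m={m}")
    v = _BASE_SLOPE_DIRECTION / np.linalg.norm(_BASE_SLOPE_DIRECTION)
    return v * norm


def simulate_pure_birth_tree(n_tips: int, seed: int, depth: float = 1.0,
                             labels=None) -> dendropy.Tree:
    """Yule (pure-birth) tree with ``n_tips`` extant tips, scaled to given depth.

    Lineages split at exponential waiting times; every tip reaches the
    present, so the tree is ultrametric with strictly positive branch
    lengths. Tips are labelled in leaf order from ``labels`` or as
    ``GenA_sp1``-style defaults grouping neighbouring tips into pseudo-genera.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    tree = dendropy.Tree()
    tree.is_rooted = True
    active = [(tree.seed_node, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.edge.length = t - birth if node.parent_node is not None else None
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.extend([(left, t), (right, t)])
    t += rng.exponential(1.0 / len(active))
    for node, birth in active:
        node.edge.length = t - birth
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    current_depth = max(l.root_distance for l in tree.leaf_node_iter())
    scale = depth / current_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    leaves = list(tree.leaf_node_iter())
    if labels is None:
        labels = _default_labels(n_tips)
    if len(labels) != n_tips:
        raise ValueError(f"{len(labels)} labels for {n_tips} tips")
    ns = tree.taxon_namespace
    for leaf, label in zip(leaves, labels):
        leaf.taxon = ns.new_taxon(label=label)
    return tree


def _default_labels(n_tips: int, genus_size: int = 3) -> list[str]:
    labels = []
    for i in range(n_tips):
        genus = chr(ord("A") + i // genus_size)
        labels.append(f"Gen{genus}_sp{i % genus_size + 1}")
    return labels


@dataclass
class SimulationSpec:
    """All knobs of the generator, with study-condition defaults.

    Defaults give, at n = 30 per species: within-species Rsq mostly in
    the 4-31% band (median near 10%), pairwise trajectory angles of a few
    tens of degrees, and tangent distortion r > 0.99 — the regime the
    pipeline is meant for.
    """

    tree: dendropy.Tree | None = None
    n_species: int = 6
    n_per_species: int | dict = 30
    template_shape: np.ndarray = field(default_factory=default_template)
    base_slope: np.ndarray = field(default_factory=default_base_slope)
    sigma_bm_mean: float = 0.02      # BM rate (SD per tangent component per unit depth)
    sigma_bm_slope: float = 0.018
    signal_mix: float = 1.0          # 1 = slopes fully Brownian on the tree
    sigma_residual: float = 0.01     # within-species isotropic tangent noise SD
    lncs_mean_range: tuple[float, float] = (4.2, 5.2)  # species mean lnCS span (CS in mm)
    lncs_sd: float = 0.15
    sex: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_bm_mean", "sigma_bm_slope", "sigma_residual", "lncs_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.signal_mix <= 1:
            raise ValueError("signal_mix must be in [0, 1]")
        if centroid_size(self.template_shape) <= 0:
            raise ValueError("degenerate template")

    def resolved_tree(self) -> dendropy.Tree:
        if self.tree is None:
            self.tree = simulate_pure_birth_tree(self.n_species, seed=self.seed)
        return self.tree

    def species_list(self) -> list[str]:
        return sorted(t.label for t in self.resolved_tree().taxon_namespace)

    def n_for(self, species: str) -> int:
        if isinstance(self.n_per_species, dict):
            return int(self.n_per_species[species])
        return int(self.n_per_species)


@dataclass
class TrueParams:
    """Ground truth behind one simulated dataset."""

    species: list[str]
    mean_shapes: np.ndarray       # (s, m) tangent vectors
    slopes: np.ndarray            # (s, m)
    lncs_mean: np.ndarray
    lncs_sd: float
    expected_rsq: np.ndarray
    tree: dendropy.Tree
    basis: np.ndarray             # (m, k*d) orthonormal tangent basis at the template
    template: np.ndarray


def simulate_species_params(spec: SimulationSpec) -> TrueParams:
    """Evolve species mean shapes and slope vectors on the tree.

    Mean shapes: Brownian motion from the tangent-space origin (the
    template). Slopes: base trend + sqrt(signal_mix) * BM + sqrt(1 -
    signal_mix) * iid normal with matched marginal variance
    (sigma_bm_slope^2 * tree depth), so changing the mix moves signal,
    not magnitude.
    """
    tree = spec.resolved_tree()
    species = spec.species_list()
    s = len(species)
    if s < 2:
        raise ValueError("need at least 2 species")
    c = tree_vcv(tree, species)
    depth = float(np.max(np.diag(c)))
    if depth <= 0:
        raise ValueError("zero-depth tree")
    chol = np.linalg.cholesky(c + 1e-12 * depth * np.eye(s))
    basis = tangent_basis(spec.template_shape)
    m = basis.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    mean_shapes = spec.sigma_bm_mean * (chol @ rng.standard_normal((s, m)))
    bm_part = spec.sigma_bm_slope * (chol @ rng.standard_normal((s, m)))
    iid_part = spec.sigma_bm_slope * np.sqrt(depth) * rng.standard_normal((s, m))
    slopes = (
        spec.base_slope
        + np.sqrt(spec.signal_mix) * bm_part
        + np.sqrt(1.0 - spec.signal_mix) * iid_part
    )
    lncs_mean = np.linspace(*spec.lncs_mean_range, num=s)
    slope_var = (slopes**2).sum(axis=1) * spec.lncs_sd**2
    expected_rsq = slope_var / (slope_var + m * spec.sigma_residual**2)
    return TrueParams(
        species=species, mean_shapes=mean_shapes, slopes=slopes,
        lncs_mean=lncs_mean, lncs_sd=spec.lncs_sd, expected_rsq=expected_rsq,
        tree=tree, basis=basis, template=np.asarray(spec.template_shape, float),
    )


def simulate_dataset(params: TrueParams, spec: SimulationSpec) -> LandmarkDataset:
    """Draw specimens under the linear static-allometry model.

    Per specimen: lnCS ~ N(species mean, lncs_sd); tangent vector =
    species mean + slope * (lnCS - species mean lnCS) + N(0,
    sigma_residual^2 I); mapped to landmarks through the template basis,
    scaled so centroid size is exactly exp(lnCS), then randomly rotated
    (proper) and translated. Per-species random streams are derived from
    the master seed as SeedSequence([seed, 1 + species_index]).
    """
    k, d = params.template.shape
    records: list[SpecimenRecord] = []
    min_gap = 0.05  # landmark-collision tolerance, in unit-CS template units
    for si, sp in enumerate(params.species):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1 + si]))
        n = spec.n_for(sp)
        for j in range(n):
            for _ in range(100):
                lncs = rng.normal(params.lncs_mean[si], params.lncs_sd)
                tvec = (
                    params.mean_shapes[si]
                    + params.slopes[si] * (lncs - params.lncs_mean[si])
                    + rng.normal(0.0, spec.sigma_residual, size=params.basis.shape[0])
                )
                shape = params.template + (tvec @ params.basis).reshape(k, d)
                if pdist(shape).min() > min_gap:
                    break
            else:
                raise RuntimeError(f"species {sp!r}: persistent degenerate configurations")
            shape = shape * (np.exp(lncs) / centroid_size(shape))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rot = np.array([[np.cos(theta), np.sin(theta)],
                            [-np.sin(theta), np.cos(theta)]])
            shape = shape @ rot + rng.uniform(-100.0, 100.0, size=2)
            records.append(
                SpecimenRecord(
                    specimen_id=f"{sp}_{spec.sex}{j:03d}",
                    coords=shape, species=sp, sex=spec.sex,
                )
            )
    return LandmarkDataset(records)


def true_angle_matrix(params: TrueParams) -> np.ndarray:
    """Pairwise angles (degrees) between the true slope vectors."""
    from .divergence import vector_angle

    s = len(params.species)
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            out[i, j] = out[j, i] = vector_angle(params.slopes[i], params.slopes[j])
    return out


# Species sample sizes for the study-like fixtures: 6 large female-like
# samples and 9 male-like, echoing the heterogeneous museum-series design
# (n from ~30 to ~280 per species).
FEMALES_LIKE_N = (49, 65, 51, 67, 184, 54)
MALES_LIKE_N = (30, 44, 74, 78, 281, 123, 59, 40, 44)


def make_fixture_suite(seed: int, out_dir=None) -> dict:
    """Standard test fixtures: survey counts, study-like datasets, signal pairs.

    Returns a dict with keys ``counts`` (species x sex count table),
    ``females_like`` / ``males_like`` (6- and 9-species datasets with
    heterogeneous n and their ground truth) and ``signal_pair`` (8-species
    n=30 datasets at signal_mix 0 and 1 sharing a tree). If ``out_dir``
    is given, TPS + metadata CSV + Newick files are written there;
    regeneration with the same seed is byte-identical.
    """
    from .io import load_survey_counts

    suite: dict = {"counts": load_survey_counts()}

    def build(name, n_species, n_map, sex, signal_mix, sub_seed, tree=None):
        spec = SimulationSpec(
            tree=tree, n_species=n_species, n_per_species=n_map, sex=sex,
            signal_mix=signal_mix, seed=sub_seed,
        )
        params = simulate_species_params(spec)
        data = simulate_dataset(params, spec)
        return {"spec": spec, "params": params, "dataset": data}

    f_spec_tree = simulate_pure_birth_tree(6, seed=seed * 7 + 1)
    f_n = dict(zip(sorted(t.label for t in f_spec_tree.taxon_namespace), FEMALES_LIKE_N))
    suite["females_like"] = build("females_like", 6, f_n, "F", 1.0, seed * 7 + 1,
                                  tree=f_spec_tree)
    m_tree = simulate_pure_birth_tree(9, seed=seed * 7 + 2)
    m_n = dict(zip(sorted(t.label for t in m_tree.taxon_namespace), MALES_LIKE_N))
    suite["males_like"] = build("males_like", 9, m_n, "M", 1.0, seed * 7 + 2, tree=m_tree)
    pair_tree = simulate_pure_birth_tree(8, seed=seed * 7 + 3)
    suite["signal_pair"] = {
        "mix1": build("mix1", 8, 30, "F", 1.0, seed * 7 + 3, tree=pair_tree),
        "mix0": build("mix0", 8, 30, "F", 0.0, seed * 7 + 4, tree=pair_tree.clone(depth=1)),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        suite["counts"].to_csv(out / "survey_counts.csv", index=False)
        for name in ("females_like", "males_like"):
            _write_bundle(suite[name], out, name)
        for name in ("mix0", "mix1"):
            _write_bundle(suite["signal_pair"][name], out, f"signal_{name}")
    return suite


def _write_bundle(bundle: dict, out: Path, name: str) -> None:
    data: LandmarkDataset = bundle["dataset"]
    write_tps(data, out / f"{name}.tps")
    pd.DataFrame(
        {"specimen_id": data.specimen_ids, "species": data.species, "sex": data.sexes}
    ).to_csv(out / f"{name}_metadata.csv", index=False)
    bundle["params"].tree.write(
        path=str(out / f"{name}.nwk"), schema="newick", suppress_rooting=True
    )
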