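"""Balanced bootstrapped subsampling: how sample size biases trajectory angles.

For each selected species (large total samples with non-negligible
allometry), a replicate first resamples the species' specimens with
replacement back to the original n, then draws ``target_n`` of those
bootstrap draws without replacement — a bootstrap followed by a random
selection, giving a perfectly balanced design across species. The
regression slope is refit on the fixed shape-score basis of the total
dataset (angles are only comparable within one coordinate system) and all
pairwise angles recomputed. After ``n_replicates`` rounds, the per-pair
median angle minus the observed total-sample angle quantifies the bias:
positive differences mean small samples overestimate divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .divergence import AngleMatrix, AngleSummary, vector_angle

logger = logging.getLogger("allotraj")

_MAX_REDRAWS = 100


@dataclass
class SubsampleDesign:
    """Design of one balanced subsampling experiment."""

    species: list[str]
    target_n: int
    n_replicates: int = 100
    seed: int = 0
    sex: str = ""
    bootstrap: bool = True     # diagnostic mode: False disables the bootstrap stage
    one_step: bool = False     # sensitivity variant: draw target_n with replacement directly

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.target_n < 2:
            raise ValueError("target_n must be >= 2")


@dataclass
class SubsampleSummary:
    """Per-pair median-angle differences (subsampled minus observed) and their summary."""

    per_pair_median_difference: np.ndarray
    pairs: list[tuple[str, str]]
    stats: AngleSummary
    target_n: int
    n_replicates: int
    n_redraws: int = 0
    angles_archive: np.ndarray | None = None


def summarize_differences(differences: np.ndarray, n_species: int = 0) -> AngleSummary:
    """Mean, SD, median, q10, q90, min, max of the per-pair differences."""
    v = np.asarray(differences, float)
    if v.size < 1:
        raise ValueError("need at least one difference")
    return AngleSummary.from_values(v, n_species)


def run_subsample_experiment(scores: np.ndarray, ln_cs: np.ndarray, species_labels,
                             observed: AngleMatrix, design: SubsampleDesign,
                             keep_archive: bool = False) -> SubsampleSummary:
    """Run the balanced bootstrapped subsampling experiment.

    ``scores``/``ln_cs``/``species_labels`` are the total-dataset shape
    scores (the fixed basis), log sizes and species of every specimen;
    ``observed`` is the total-sample angle matrix for the designed
    species. Replicates with a degenerate refit (constant lnCS after
    resampling) are redrawn and counted.
    """
    species_labels = np.asarray(species_labels)
    order = list(observed.species)
    if sorted(design.species) != sorted(order):
        raise ValueError("design species and observed angle matrix disagree")
    idx_by_species = {}
    for sp in order:
        idx = np.flatnonzero(species_labels == sp)
        if len(idx) < design.target_n:
            raise ValueError(
                f"species {sp!r}: total n={len(idx)} below target_n={design.target_n}"
            )
        idx_by_species[sp] = idx
    rng = np.random.default_rng(design.seed)
    s = len(order)
    i_low, j_low = np.tril_indices(s, k=-1)
    all_angles = np.empty((design.n_replicates, len(i_low)))
    n_redraws = 0
    for rep in range(design.n_replicates):
        slopes = np.empty((s, scores.shape[1]))
        for si, sp in enumerate(order):
            idx = idx_by_species[sp]
            for attempt in range(_MAX_REDRAWS + 1):
                if design.one_step:
                    sub = rng.choice(idx, size=design.target_n, replace=True)
                elif design.bootstrap:
                    boot = rng.choice(idx, size=len(idx), replace=True)
                    sub = rng.choice(boot, size=design.target_n, replace=False)
                else:
                    sub = rng.choice(idx, size=design.target_n, replace=False)
                assert len(sub) == design.target_n  # balanced design
                x = ln_cs[sub]
                xc = x - x.mean()
                sxx = float(xc @ xc)
                if sxx > 1e-12:
                    break
                n_redraws += 1
            else:
                raise RuntimeError(
                    f"species {sp!r}: {_MAX_REDRAWS} degenerate redraws in a row"
                )
            y = scores[sub]
            slopes[si] = (xc @ (y - y.mean(axis=0))) / sxx
        for p, (i, j) in enumerate(zip(i_low, j_low)):
            all_angles[rep, p] = vector_angle(slopes[i], slopes[j])
    observed_low = observed.angles[i_low, j_low]
    diffs = np.median(all_angles, axis=0) - observed_low
    if n_redraws:
        logger.info("subsampling: %d degenerate replicates redrawn", n_redraws)
    pairs = [(order[j], order[i]) for i, j in zip(i_low, j_low)]
    return SubsampleSummary(
        per_pair_median_difference=diffs,
        pairs=pairs,
        stats=summarize_differences(diffs, n_species=s),
        target_n=design.target_n,
        n_replicates=design.n_replicates,
        n_redraws=n_redraws,
        angles_archive=all_angles if keep_archive else None,
    )
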