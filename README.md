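# allotraj

**Do static allometric trajectories of cranial shape diverge in step with
phylogeny?** `allotraj` is a geometric-morphometrics pipeline for asking
that question in a clade of related species — built around the
6-landmark midplane cranial configuration (prosthion, posterior palate,
basion, rhinion, nasion, inion) classically used to capture relative
face/braincase proportions in Old World monkeys and other mammals.

It is aimed at morphometricians and evolutionary biologists who have
specimen-level landmark data (TPS), species/sex metadata (CSV) and a
dated molecular phylogeny (Newick), and want a reproducible, tested path
from raw coordinates to phylogenetic-signal statistics — including an
honest account of how sampling error biases the answer.

## The analysis

1. **Superimposition.** Generalized Procrustes analysis (full GPA:
   centering, unit-centroid-size scaling, proper rotations to the
   iterated mean). Shape variables are the principal components of the
   tangent-space residuals: for *k* 2D landmarks, exactly 2*k* − 4
   non-zero components (8 for the cranial configuration). A diagnostic
   reports the matrix correlation between tangent and Procrustes
   distances (it should exceed 0.99).
2. **Static allometry.** Within each species and sex, multivariate
   regression of all shape PCs **Y** on log centroid size *x*:
   **Y** = **1b₀**ᵀ + *x***b**ᵀ + **E**. Effect size is the trace-based
   R² (shape variance explained, summed over PCs); significance is
   Wilks' Λ = |**E**ᵀ**E**| / |**T**ᵀ**T**| with Rao's exact
   F = ((1 − Λ)/Λ)(df₂/df₁), df₁ = m, df₂ = n − m − 1. An allometry is
   *non-negligible* when p < 0.005 or R² > 0.05.
3. **Divergence.** The trajectory of a species is its slope vector
   **b**; divergence between two species is the angle
   θ = arccos(**b₁**·**b₂** / |**b₁**||**b₂**|) in degrees. Angles are
   summarized (mean, SD, median, q10/q90, range), split within/between
   genera, and clustered into a UPGMA phenogram.
4. **Phylogenetic signal.** Angles are compared with patristic distances
   from the chronogram by matrix correlation, and the multivariate
   Blomberg's K statistic (computed on the principal coordinates of the
   angle matrix, with a tip-permutation test) measures whether
   trajectory similarity tracks a Brownian-motion expectation (K = 1).
   The same machinery on species *mean shapes* provides the contrast.
5. **Sampling error.** Balanced bootstrapped subsampling: per species,
   resample to the original n, draw N ∈ {30, 20, 10} specimens, refit,
   recompute all pairwise angles; repeat 100×, take per-pair medians and
   subtract the observed total-sample angles. Positive differences mean
   small samples overestimate divergence.
6. **Synthetic data.** A generator with known ground truth — species
   mean shapes and slope vectors evolving by Brownian motion on a tree,
   a `signal_mix` dial between tree-structured and independent slope
   evolution, linear within-species allometry and isotropic tangent
   noise — makes every stage testable without any external data.

## Worked example

Simulate a 6-species dataset and run the pipeline (all commands are
deterministic given `--seed`):

```sh
$ allotraj --seed 5 simulate --out-dir demo --n-species 6 --n-per-species 35
simulated 210 specimens of 6 species into demo

$ allotraj --seed 5 fit-allometry --landmarks demo/landmarks.tps \
    --metadata demo/metadata.csv --out demo/fits.csv
6 species fitted (6 non-negligible), 0 untestable

$ allotraj --seed 5 angles --landmarks demo/landmarks.tps \
    --metadata demo/metadata.csv --out-prefix demo/ang
6 species, median angle 41.2 deg (within-genus 34.0 over 6 pairs, between 44.0 over 9)

$ allotraj --seed 5 phylosignal --landmarks demo/landmarks.tps \
    --metadata demo/metadata.csv --tree demo/tree.nwk --out demo/sig.csv
angles: r=-0.560 K=0.632 p=0.884 | mean shapes: r=0.809 K=1.044 p=0.009
```

Reading the output: every species shows a real (non-negligible) size
effect on shape; pairwise trajectories still differ by ~41° on average,
and those angles are *not* structured by the tree (K = 0.63, permutation
p = 0.88 — no detectable signal, and note the test has little power with
only 6 taxa). Species mean shapes, by contrast, do track the phylogeny
(K = 1.04 ≈ the Brownian expectation, p = 0.009). That dissociation —
phylogenetically structured mean shapes but freely swinging allometric
directions — is exactly the pattern the pipeline is designed to detect,
and here it is recovered from data simulated with Brownian mean shapes.

The `subsample` subcommand quantifies how much of an observed angle is
sampling noise: with the defaults, subsamples of N = 10 inflate pairwise
angles by ~15–18° on average, roughly twice the bias at N = 30.

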