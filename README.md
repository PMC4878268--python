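# calclust

Clustering functional sub-types from simultaneously recorded single-cell
Ca²⁺ imaging traces.

## The problem

Dispersed pancreatic islet preparations (and stem-cell-derived cultures
meant to mimic them) are functionally heterogeneous: under a timed
glucose/KCl perfusion protocol some cells respond to high glucose with
rhythmic Ca²⁺ oscillations, some rise rapidly to a plateau without
oscillating, some respond only to KCl depolarization, and a few respond to
nothing at all.  Comparing "representative traces" by eye does not scale and
is biased.  `calclust` provides an unbiased, quantitative pipeline for
Fura-2 340/380 ratio recordings:

1. **Preprocess** — per-cell linear drift correction (robust slope from the
   baseline window) and viability QC: a cell is removed when its median KCl
   signal rises less than 5% over its baseline *b* (the median of the first
   low-glucose epoch).
2. **Feature extraction** — nine per-cell response features, all normalised
   by the cell's own depolarization response *N* = median(KCl) − *b*:
   high-glucose response (median elevation / *N*), oscillation magnitudes
   (MAD / *N*) in the high-glucose and both flanking low-glucose epochs,
   response speed (1 / time to first peak), counted peaks, oscillation
   frequency (1 / mean inter-peak interval), return to baseline, and KCl
   response (max / *N*).  A local maximum counts as a peak when it rises at
   least *N*/3 above its surroundings.  Every feature is invariant under
   per-cell affine rescaling *a*·x + *b* (a > 0), so dye loading and gain
   cancel.
3. **Model-free clustering** — classical (Torgerson) MDS on the Spearman
   distance d(i,j) = (1 − ρᵢⱼ)/2 between full traces, with embedding
   dimensions rankable by field-separating silhouette width; hierarchical
   clustering of cells (Ward on z-scored features) and of the features
   themselves (1 − |ρ| distance) for heatmap display.
4. **Model-based clustering** — Gaussian mixtures of the two headline
   features (high-glucose response and oscillation) fitted by EM for
   K = 1..8 across four covariance families, selected by
   BIC = −2 log L + p log n (minimised).  The K = 3 solution is labelled
   biologically: non-responders, oscillating responders, non-oscillating
   responders; the glucose-responder proportion is reported over QC-passing
   cells.
5. **Inference** — Spearman correlation tests between features (exact
   permutation null for n ≤ 10, t approximation beyond) and a χ²/LRT/Fisher
   test of responder-proportion homogeneity across imaging fields, reported
   as −log₁₀ P.

A seeded synthetic generator (`calclust.synthetic`) produces labelled
datasets with this exact population structure — oscillators,
non-oscillating rapid responders, non-responders, and a ~5% KCl-dead
fraction — for testing and demonstration without any recordings.

## Worked example

```sh
python examples/03_cluster_subtypes.py
```

prints (abridged):

```
three lowest-BIC candidates (family, K, BIC):
family  k          bic  converged
  diag  3 -1986.310563       True
  full  3 -1986.126319       True
  diag  4 -1962.637122       True

selected: K=3, diag covariance
  cluster 1: non_responder              69 cells
  cluster 2: oscillating_responder      127 cells
  cluster 3: non_oscillating_responder  86 cells
responder proportion among QC-passing cells: 0.76
agreement with the generator's planted sub-types: 100.0%
```

Reading: on a simulated 300-cell run (18 KCl-dead cells removed by QC),
BIC is minimised at three mixture components, and the component means sort
the cells into the three planted behaviours — the cluster with the lowest
mean high-glucose response is the non-responder group, and of the two
responder groups the one with higher oscillation magnitude is the
oscillating sub-type.  76% of QC-passing cells are glucose responders,
matching the simulated mixture.  The other examples cover QC
(`01_simulate_and_qc.py`), the feature definitions (`02_extract_features.py`)
and field-effect screening (`04_field_effects.py`).

The same pipeline runs from the shell:

```sh
calclust run --preset paperlike --seed 1 -o out/
calclust run --traces my_traces.csv --protocol protocol.yaml -o out/
```

writing the QC report, feature table, BIC table, cluster assignments, test
results, PNG figures (feature heatmap, GMM scatter, MDS scatter, BIC
curves) and a run-metadata JSON.  `simulate`, `qc`, `features` and
`cluster` expose the stages individually.

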