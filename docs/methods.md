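# Methods

This note records the model, its assumptions, the tunable parameters, and
the numerical and design choices made where the procedure was genuinely
open. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Labeling model

Each variant carries four normalized electrophysiological parameters in %WT.
The classification criteria are held in `CriteriaTable`:

| parameter | normal band (%WT) | LOF | GOF |
|---|---|---|---|
| I_Ks | (55, 115) | < 55 | > 115 |
| V1/2 | (80, 130) | > 130 | < 80 |
| τ_act | (70, 170) | > 170 | < 70 |
| τ_deact | (75, 125) | < 75 | > 125 |

Inequalities are strict: a value exactly at a bound is normal. Unmeasurable
parameters (blank, `NA`, `ND`) are dysfunctional — a voltage-insensitive
variant has no V1/2 to report precisely because it is dysfunctional. When
I_Ks ≤ 17 %WT all four parameters are labeled dysfunctional regardless of
their values: with essentially no current, kinetic and voltage-dependence
readouts are not meaningful. The τ_act band is the widened one; the
narrower historical band (80–120 %WT) remains available
(`ORIGINAL_TAU_ACT_CRITERIA`) because a handful of otherwise WT-like
variants activate slowly and make the narrow band noisy to learn.

Non-perturbing augmentation adds, for every residue resolved in the
structure, an identity substitution labeled normal on all four outputs.
These records anchor "zero change in every feature ⇒ benign" and give the
network coverage of all structural neighborhoods.

## Feature extraction

The structure must arrive membrane-oriented (normal = z, mid-plane z = 0);
the package does not embed structures itself. Each residue is reduced to a
representative point: the side-chain heavy-atom centroid, with Cα fallback
(glycine, missing side chains). A sub-residue representative point is what
makes the 1 Å functional-density radius meaningful; a Cβ mode is available
for comparison.

* **Pore-axis distance** — perpendicular distance to the z axis through the
  x–y centroid of all representative points; overridable with an explicit
  axis or a set of pore-lining residues. Distinguishes pore-domain from
  voltage-sensor sites.
* **Membrane burial** — three-layer slab: weight 1 for |z| ≤ 15 Å
  (hydrophobic core half-thickness), half-cosine decay to 0 across a 5 Å
  polar interface, 0 in solution. The functional form is a smooth, bounded
  stand-in chosen by this package; the layer widths are the conventional
  30 Å core + 5 Å interfaces and both are configurable (`MembraneModel`).
* **Functional density** FD_p(i; r) — inverse-distance-weighted mean of
  property p over residues j ≠ i within r, distances floored at 1 Å to
  bound the weight. An empty neighborhood (always, in practice, at r = 1 Å)
  falls back to p(mutant), so the tightest-radius densities track the
  substituted residue itself while the 6.5/12 Å densities describe the
  native microenvironment.
* **Neighbor vector** — ‖Σ w_j û_j‖ / Σ w_j with w = 1 below 3.3 Å, 0 above
  11.4 Å, cosine-smooth between; 0 = evenly surrounded (buried), 1 =
  one-sided or isolated (exposed). Defined as 1.0 with no neighbors.
* **ΔPSSM** — mutant minus wild-type log-odds score at the variant position,
  parsed from PSI-BLAST ASCII matrices (log-odds block only). PSSM
  generation is out of process: database versions and iteration counts vary,
  so matrices are user inputs.

Amino-acid scalars ship as a TSV resource (`data/aa_properties.tsv`):
polarizability (Charton & Charton 1982 normalized parameter), graph shape
index, donor counts and normalized vdW volumes (Fauchère et al. 1988), an
acceptor-atom count, and a hydrophobicity scale with the convention
"more positive = more hydrophobic" (shipped default: Fauchère–Pliska
octanol–water scale; any membrane-transfer scale with the same convention
can be substituted via `--aa-table` — results that depend on absolute
hydrophobicity values will track the chosen scale).

Features are z-scored with a scaler fitted on the (oversampled) training
fold only; constant features map to 0.

## Network and training

Architecture per feature set (inputs → 32 → h2 → 4 sigmoid outputs, leaky
ReLU slope 0.05 elsewhere):

| set | inputs | h2 | input dropout | hidden dropout |
|---|---|---|---|---|
| BIOPHYS14 | 14 | 8 | 20% | 33% / none |
| EVO2 | 2 | 12 | 5% | 33% / 33% |
| COMBINED12 | 12 | 12 | 5% | 33% / 33% |

Hidden units alone cannot bound the outputs, so the four output neurons are
logistic — the only choice consistent with scores in [0, 1] and a 0.5
decision threshold. Dropout uses inverted scaling, so inference needs no
rescaling. Weights initialize uniform in ±√(6/(fan_in+fan_out)), seeded.

Optimization is momentum SGD (learning rate 0.001, momentum 0.5, 1200
iterations). One *iteration* is one pass over the shuffled training fold in
mini-batches (default 32; full-batch available via `batch_size=None`), and
the surrogate loss follows the classic total-error convention — binary
cross-entropy summed over patterns and the four output neurons — which is
the normalization under which a per-pattern learning rate of 0.001 produces
meaningful weight movement in 1200 passes. (With a batch-and-output-mean
loss the same rate moves the weights by a vanishing amount and the model
never leaves its initialization; the mean-MSE alternative is available via
`loss="mse"`.) Classification accuracy at threshold 0.5, averaged over the
four outputs on the monitor fold, is recorded every 10 iterations and the
best snapshot is returned (ties keep the later snapshot, i.e. the most
trained weights). Accuracy is the selection criterion, not the training
gradient — it is not differentiable.

## Evaluation protocol

25-fold cross-validation: a seeded shuffle is partitioned round-robin into
25 near-equal subsets; rotation r trains on 23 subsets, monitors on subset
r+1, and predicts held-out subset r, so pooled test predictions cover every
record exactly once. Training folds replicate each experimental record 3×
(non-perturbing once), countering the 345:125 class imbalance. Headline
metrics (MCC, ROC/AUC) are computed on the experimental variants only;
non-perturbing accuracy is reported separately as the mean over outputs of
the fraction scored below threshold.

Decision thresholds are scanned over 0…1 (step 0.01, smallest threshold on
ties, prediction positive iff score ≥ threshold) to maximize MCC per
output on the pooled test predictions — the published procedure reports the
best achievable MCC; a fully held-out variant that tunes on pooled monitor
predictions is available (`threshold_on="monitor"`). MCC with a vanishing
denominator is defined as 0. AUC is the trapezoidal area under the ROC
constructed over all score thresholds, which equals the concordant-pair
rank statistic with ties counted ½ (asserted against an independent oracle
in the tests).

Entropy separation quantifies how well non-perturbing and experimental-
benign predictions separate at a 0.05 score boundary: the occupancy-weighted
mean of the binary Shannon entropies (base 2) of the class mix on each side
— 0 for pure sides, 1 for maximal mixing. The exact formula used by the
original analysis is not published; split entropy is this package's choice,
exact at both endpoints.

Input sensitivity: for each feature and output, every member model of every
replicate ensemble is probed on every instance with a +δ perturbation
applied after scaling (δ = 0.1 standardized units by default); the net
consistency is (n_up − n_down)/n_total, with |Δŷ| < 1e-12 counting to
neither side. Only the sign is interpretable — magnitudes depend on input
rescaling. Replicate ensembles come from independent shuffle seeds; the
count is a parameter (320 replicates in the original protocol; desk runs
here use 5–20).

## Synthetic data

The generator (`kvarpred.synthetic`) emulates the study's inputs at full
dataset scale:

* **Structure**: 15 idealized α-helices (1.5 Å rise, 100°/residue, 2.3 Å
  helix radius) arranged symmetrically at 15 Å from the pore (z) axis,
  345 residues total, centered on the membrane — matching the resolved-model
  size, with residues crossing core and interface layers. Sequence sampled
  uniformly, seeded.
* **PSSMs**: per-position conservation c_i ~ Beta(mean = `conservation`,
  concentration 4) — real profiles mix conserved and variable positions —
  with WT scores ≈ 2 + 9c_i and non-WT ≈ −1 − 4c_i plus integer-rounded
  noise; at conservation 1.0 the WT score is strictly maximal everywhere.
* **Variants**: 125 unique missense variants sampled uniformly over resolved
  positions and non-identical substitutions, plus one non-perturbing variant
  per residue. Missense labels follow a planted monotone rule per output:
  label = 1{Σ_f β_f·z(f) + σ·ε > 0} on features standardized over the
  missense set, with a dominant |β| = 4 and a secondary |β| = 2 delta-type
  feature per output and σ = 0.5 Gaussian logit noise. Delta features
  vanish for identity substitutions, keeping the rule consistent with the
  all-normal non-perturbing labels. The manifest records β, σ, seed and the
  standardization, so recovery tests are falsifiable.

What the generator does *not* emulate: real secondary-structure packing and
side-chain geometry (representative points are CA-only in the written PDB),
phylogenetic correlation between positions, measurement-error structure of
patch-clamp assays, and the clustering of real variants in the
voltage-sensor domain. Passing recovery tests therefore demonstrates that
the pipeline's machinery (features → training → evaluation → sensitivity)
recovers a known monotone signal at realistic size and noise — not that
real KCNQ1 accuracy matches any particular value; real-data accuracy
additionally depends on the databases, structure conventions, and assay
quality.

## Problem sizes

Desk-scale defaults were chosen so the full suite and the acceptance script
each run in minutes on one core: parameter recovery uses one 470-record
25-fold run; the sensitivity sign analysis uses 5 replicate ensembles
(125 models); the metric oracles use 1000 random cases each. The replicate
count and CV granularity scale up by flag.

## Degenerate inputs and tie-breaks

* Single-class label vectors make ROC/threshold scans undefined → explicit
  errors, surfaced per output with the rotation index.
* Records with I_Ks ≤ 17 %WT dominate all other values by design.
* Empty functional-density neighborhoods fall back to the mutant property;
  isolated residues have neighbor vector 1.0.
* Threshold grid values are rounded to 10 decimals so accumulated float
  error cannot shift a threshold past a score sitting exactly on it.
* Training raises on non-finite loss, reporting the iteration.

## Known limitations

* Predictions apply to the homozygous variant state; dominant-negative
  effects in heterozygous channels are out of scope.
* A single static conformation; no multi-state or dynamics-derived features.
* Positions outside the resolved structural model cannot be featurized.
* The hydrophobicity scale is a substitutable default (above); absolute
  feature values — e.g. the worked functional-density value at a specific
  residue — depend on the scale and representative-point convention chosen.
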