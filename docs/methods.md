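# Methods

This note describes the scientific model implemented in `hdx2ss`: how
peptide-level hydrogen–deuterium exchange (HDX-MS) uptake data are turned
into per-residue exchange rates, how confidence in those rates is
quantified, and how residue-level secondary structure is predicted and
validated from them.

## 1. Uptake correction

A raw relative fractional uptake (RFU) measurement is distorted by
back-exchange during quench/digestion and by any deuterium picked up
before labelling starts. Both are removed with a two-point control
normalization: a fully exchanged control (FEX, the asymptote the
instrument can actually reach) and a back-exchange/zero-time control
(BEX). The corrected value is

```
RFU_corr = (RFU_exp − RFU_FEX) / (RFU_BEX − RFU_FEX)
```

mapped so that the BEX control lands at 1 and the FEX control at 0 on the
stored scale, then clamped to [0, 1]. Clamps are counted and reported
(`UptakeTable.n_clamped`) rather than silently absorbed: a high clamp
count means the controls do not bracket the data. Degenerate controls
(FEX ≈ BEX) raise an error instead of producing infinities.

## 2. Exchange forward model

Amide hydrogen exchange under EX2 conditions is first-order per residue:
at exposure time `t` (minutes), the deuterium occupancy of residue `r` is
`1 − exp(−k_obs,r · t)` with

```
k_obs,r = k_int,r · exp(−lnP_r)
```

where `k_int,r` is the sequence-determined intrinsic rate and
`P_r = exp(lnP_r) ≥ 1` is the protection factor contributed by structure.
A peptide spanning residues `s..e` reports the mean occupancy over its
*exchanging* residues: positions `s+2..e` (the first two residues lose
their label during digestion) minus prolines (no backbone amide
hydrogen). Predicted peptide RFU is therefore

```
RFU(peptide, t) = (1/|E|) · Σ_{r∈E} (1 − exp(−k_int,r · exp(−lnP_r) · t))
```

Exposure times are recorded in seconds and converted to minutes to match
the rate units.

## 3. Intrinsic rates

Intrinsic rates follow the standard poly-DL-alanine reference-rate scheme
with sequence corrections: acid-, base- and water-catalysed terms, each
scaled by the side chains of the residue and its left neighbour through
tabulated log-factors, plus N-terminal and C-terminal adjustments.
Temperature enters through Arrhenius scaling of each catalytic term with
its own activation energy; pD enters through the catalyst concentrations.
Residue 1 and prolines have no exchangeable backbone amide and are
omitted. Rates are returned in min⁻¹.

## 4. Residue-level rate optimization

### Objective

Given a corrected uptake table and intrinsic rates, the package estimates
one `lnP_r` per exchanging residue by least squares over all
(peptide, exposure) observations:

```
L(lnP) = Σ_obs ( RFU_corr,obs − RFU_model,obs(lnP) )²
```

with box bounds `0 ≤ lnP ≤ 14`. The gradient is analytic; predictions and
gradients are accumulated with sparse index arrays (`np.bincount`), so a
full evaluation is linear in the number of (observation, residue) pairs.

### Why the landscape is hard, and what the optimizer does about it

The loss is non-convex: peptides average over residues, so swapping which
residue inside a peptide carries the protection can leave the fit almost
(or exactly) unchanged. Three mechanisms address this, in order of what
they can and cannot fix:

1. **Multi-start quasi-Newton.** Each replicate starts from an
   independent uniform draw over the bounds and runs bounded L-BFGS-B.
2. **Windowed refinement.** After the global fit, the optimizer sweeps
   overlapping windows of residues; within each window it re-solves the
   reduced subproblem (only the observations touching the window, with
   the fixed residues' contribution precomputed) from the current point
   and from several random restarts, keeping the best. Passes use
   escalating window widths and staggered offsets so basin boundaries do
   not align across passes, and each pass ends with a full-vector polish.
   This escapes local minima that differ from the global basin only in a
   localized block of residues — the dominant failure mode of plain
   multi-start on this objective.
3. **Honest reporting of what remains.** If the peptide map itself is
   degenerate (see §6), no optimizer can prefer one equally-good solution
   over another. That is detected, not hidden, by the replicate-agreement
   score below.

### The R-matrix confidence score

The fit is repeated `n_replicates` times (default 10) from independent
starts. For every contiguous, jointly-fitted subsection of sequence, the
score is the mean pairwise Pearson correlation of the replicate lnP
vectors, with negative pair correlations clamped to 0, giving a value in
[0, 1]. Replicates with zero variance score 0 against every partner and
trigger a warning. The interpretation is operational: a subsection with
R-matrix near 1 is determined by the data; a low score means independent
fits of equal quality disagree, so the residue-level rates there should
not be trusted regardless of how small the residual is. The returned
point estimate is the replicate with the lowest loss.

Peptide maps with coverage gaps are split into independent subsections
first; residues never covered by any peptide's exchanging set are not
fitted at all.

## 5. Structure labels and classification

### Labels

Backbone dihedrals φ and ψ are computed from atomic coordinates with the
standard signed-dihedral construction (normals of the two planes, sign
from the first bond vector). Residues are labelled helix or strand by
which Ramachandran basin (centred near (−63°, −43°) and (−120°, +130°)
respectively, with angular wrapping) their (φ, ψ) pair falls closest to;
a fitted mode estimates the basin centres from the data instead of using
the canonical ones. Chain breaks and termini yield missing angles and no
label.

### Features

Each labelled, fitted residue contributes a feature row
`(k_obs, k_int, r_matrix, aa_code)`: the fitted observed rate, the
intrinsic rate (so the model can learn protection rather than raw
speed), the subsection confidence score, and an integer-encoded amino
acid identity.

### Classifier

The classifier is gradient-boosted trees for binary log-loss, written
from first principles:

- Initial score `f₀ = ln(p₀/(1−p₀))` from the base rate.
- Per stage: pseudo-residuals `y − p`, a regression tree grown best-first
  (largest impurity improvement next) to at most 8 leaves with at least
  5 samples per leaf, split thresholds at midpoints between sorted
  feature values, ties broken toward the lowest feature index then the
  lowest threshold.
- Newton leaf values `γ = Σr / Σ p(1−p)`, capped at ±10 for stability,
  scaled by learning rate ν = 0.2; 500 stages by default.
- Feature importance is impurity-improvement accumulated per feature,
  normalized to sum to 1.

Models serialize to and from plain JSON.

## 6. Identifiability and the synthetic fixtures

The synthetic generator exists to make every failure mode above
reproducible on demand, so it is built around the identifiability
structure of the problem rather than around convenience:

- **Truth process.** Per-residue lnP is drawn segment-wise (helix
  segments protected, strand segments less so) as a stationary AR(1)
  process within each segment (ρ = 0.7, marginal mean and SD preserved,
  clipped to the optimization bounds). Real protection is spatially
  correlated; independent draws would make the recovery problem
  unrealistically easy for smoothness-agnostic fits and unrealistically
  hard to interpret.
- **Exact degeneracies.** Two residues covered by *exactly the same set*
  of peptides are exchangeable in the likelihood: any permutation of
  their lnP values gives the identical loss. These symmetry groups are
  computable from the map alone (runs of consecutive residues with
  identical peptide-membership signatures). The generator, by default,
  adds short peptides whose boundaries split every such run, because an
  experiment whose map has exact symmetries cannot be rescued by any
  amount of optimization. Setting `break_degeneracies=False` produces
  deliberately underdetermined maps, which is how the low-R-matrix
  regime is exercised.
- **Exposure grid.** Nine log-spaced exposures from 5 s to 24 h. With
  fewer, well-separated rate pairs become indistinguishable at realistic
  noise and the *global* minimum itself drifts away from the truth — a
  data-design failure no optimizer can correct.
- **Noise.** Gaussian noise on peptide RFUs (default SD 0.01), clipped to
  physical range, plus simulated FEX/BEX controls so the correction step
  is exercised, not bypassed.

A separate gated-feature generator tests the intended semantics of the
confidence score: it produces residues whose `k_obs` is informative only
where `r_matrix` is high and whose labels are noise where it is low, with
`k_int` pure decoupled noise. A classifier trained on it should rank
`r_matrix` above `k_int` in importance and lose accuracy when `r_matrix`
is ablated.

## 7. Validation

All metrics are implemented directly:

- **Stratified k-fold CV.** Within each class, shuffled indices are dealt
  round-robin to folds, so per-fold class counts differ by at most one.
  Reported metrics pool the held-out predictions across folds.
- **Confusion matrix.** Row-normalized (per-true-class rates) at the 0.5
  threshold.
- **Brier score and skill.** Mean squared error of the predicted
  probability, with skill `1 − Brier/Brier_ref` against the climatology
  reference `p₀(1−p₀)`; 0 means no better than predicting the base rate.
- **Calibration.** Predictions binned into 20 equal-width probability
  bins; per-bin mean prediction vs. observed frequency.
- **ROC/AUC.** Exact trapezoidal integration over all score thresholds,
  with proper tie handling (equal scores contribute the trapezoid, so a
  constant score gives AUC 0.5).

scikit-learn appears only in the test suite, as an independent oracle for
the boosting model and the metrics; it is not used by the package.

## 8. Limitations

- The forward model assumes EX2 kinetics and a single protection factor
  per residue; EX1 behaviour, proline isomerization and conformational
  mixtures are out of scope.
- The correction uses two global controls per peptide; per-residue
  back-exchange variation is not modelled.
- The R-matrix score measures *self-consistency across restarts*, not
  accuracy: a map that is misinformative in the same way for every
  replicate can score high while being wrong. It is a necessary, not
  sufficient, condition for trusting residue-level rates.
- The classifier is binary (helix vs. strand); loops, turns and
  disordered regions are not modelled and are excluded from the labels.
- Intrinsic-rate corrections are tabulated for the 20 standard amino
  acids; modified residues are not supported.
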