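# Methods

## Overview

`tadfold` turns single-cell chromatin-tracing tables (per-cell 3D probe
positions) into (i) a one-dimensional *folding coordinate* that orders
structures by their degree of TAD formation, and (ii) a free-energy
decomposition of contact formation.  Every stage can be exercised without
external data: a coarse-grained polymer simulation plus an imaging-noise
layer generates two-population datasets with known ground truth.

## Chromatin representation

A cell's structure is reduced to a binary contact matrix **Q**: probes are
coarsened to 90 kb bins (every third 30 kb probe), pairwise Euclidean
distances are thresholded at 450 nm (ties count as contacts), and the strict
upper triangle (378 entries for 28 bins) is the feature vector.  Contacts are
rotation- and translation-invariant, which is why they are preferred over raw
coordinates.  Entries touching a missing probe are imputed by Bernoulli draws
from the dataset's separation-specific mean contact probabilities — imputation
never alters observed entries, and imputed entries are flagged and excluded
when those probabilities are re-estimated.  The separation profile is pooled
over both cell populations by default (a per-population profile is available
by flag); pooling avoids building the class label into the features.

## Deep generative model

The density model is a variational autoencoder with a standard-normal latent
prior, a Bernoulli decoder, and a diagonal-Gaussian encoder; encoder and
decoder each have one hidden layer of 200 ReLU units, with a logistic output
layer.  Training maximizes the evidence lower bound (ELBO)

    log P_VAE(Q) >= E_q(z|Q)[log p(Q|z)] - KL[q(z|Q) || p(z)]

with the reparameterization trick and Adam (learning rate 1e-3, batch 500).
The trained ELBO, estimated with 20 posterior samples, is used as the
structure's log-probability.  It is a lower bound, not the exact likelihood;
consequences are discussed under *Energy decomposition*.

Two model roles are kept separate: a 2-latent model for the visualizable
embedding that defines the folding coordinate, and 25-latent models (one per
condition/ensemble) for all probability and energy estimates.

The implementation is plain NumPy (forward pass, analytic backward pass,
Adam) in float32.  The networks are small enough that this trains in minutes
on one CPU, and it makes training and evaluation bit-reproducible under a
seed, which the pipeline's determinism guarantees rely on.  Weights use He
initialization for ReLU layers and fan-in scaling for linear heads.

## Folding coordinate

The two cell populations separate in the 2-D latent embedding.  A soft-margin
linear SVM (C = 1) fit to the labeled embeddings defines the decision
boundary; the folding coordinate of a structure is the signed Euclidean
distance of its embedding from that boundary, with the sign fixed so the
WT-like mean is positive.  Separation is quantified by a histogram KL
divergence (50 shared equal-width bins over the pooled range, one pseudo-count
per bin, reported in nats).  PCA (first principal component) and K-means
(k = 10, overlap = summed per-cluster minority mass / N) are the baselines.
Profiles along the coordinate use 0.4-wide bins centered on multiples of 0.4.

## Energy decomposition

With P(Q) = Z^-1 exp(-F(Q)/k_B T), the negative log-probability estimates the
contact free energy F(Q) = U(Q) - T S(Q) up to a constant.  The entropy
S(Q) is a generic polymer property (length, flexibility), so for two polymers
of equal length and comparable excluded volume it cancels in the difference:

    -log[P_VAE(Q) / P_VAE_ref(Q)] ~ U(Q) - U_ref(Q) = Delta U(Q),

where the reference model is a VAE trained on an equal-length homopolymer
ensemble.  When differencing, both models are evaluated with the *same*
latent-noise draws (their latent dimensions match), which cancels most
Monte-Carlo noise of the ratio and makes the self-difference exactly zero.
Energies are reported in k_B T = nats (T = 1).

The free energy of the coordinate itself differs from the conditional mean
free energy by the mixing entropy
S(q) = sum_ij Q_ij(q) log Q_ij(q) + (1 - Q_ij(q)) log(1 - Q_ij(q)),
computed from the per-bin mean contact probabilities;
F(q) = <F(Q)>_q - T S(q), and P(q) is its normalized Boltzmann weight.
The reference model's log-probability binned along the coordinate (shifted to
the lowest occupied bin) estimates the entropy change Delta S(q), because the
homopolymer's interaction energy is nearly flat across folding states.

## In-silico validation models

A 28-bead chain (one bead per 90 kb of a 2.5 Mb region) in reduced units
(sigma, epsilon, tau), with:

- harmonic bonds U = k (r - r0)^2, k = 1 epsilon/sigma^2, r0 = 2 sigma (the
  convention without the 1/2 factor; the equivalent half-convention constant
  would be 2 epsilon/sigma^2);
- a capped soft-core repulsion on non-bonded pairs (|i - j| >= 2): a purely
  repulsive truncated-shifted Lennard-Jones wall with bead diameter 1 sigma
  and depth 1 epsilon, blended into a finite plateau via
  U_sc = cap/2 * [1 + tanh(2 U_WCA / cap - 1)] with cap = 4 epsilon.  The
  finite cap permits occasional chain crossing, and the 1-sigma diameter
  (half the bond length) lets the 90-kb "blobs" interpenetrate — a folded
  14-bead half then packs densely enough that most same-half pairs sit inside
  the 3-sigma contact range, which is what produces two clearly folded
  domains;
- a weak collapse attraction on all non-bonded pairs,
  u(r) = (alpha_pair/2)(1 + tanh[eta (r_c - r)]), eta = 10/sigma,
  r_c = 3 sigma.  Interaction strengths are conventionally quoted through a
  symmetric double sum in which each pair appears twice; the per-pair well
  depths are therefore alpha_pair = 2 x (-0.04) = -0.08 epsilon (reference)
  and an additional 2 x (-0.1) = -0.2 epsilon between pairs within the same
  half of the chain (chromatin-like model, split at bead 14).  The same-half
  sum evaluated on a configuration is the ground-truth interaction-energy
  difference Delta U(Q).

The collapse strength reproduces an adjacent-bead contact probability of
~0.8 at the 3-sigma cutoff, matching the neighboring-segment contact
probability of 90-kb imaging data — this, not any downstream result, is the
tuning target of the reference model.

Dynamics: underdamped Langevin (BAOAB splitting), dt = 0.01 tau, damping time
0.5 tau (friction rate 2/tau), T = 1, unit mass, counter-based RNG (Philox)
for bitwise reproducibility.  Initial condition: straight chain at the bond
rest length with 0.1-sigma Gaussian jitter; 10^4 equilibration steps are
discarded.  At these parameters the kinetic temperature of long runs is
within 5% of the target and the chain equilibrates within the discarded
prefix (block means of Delta U and the radius of gyration are stationary from
the first saved frame).

## Synthetic imaging layer

Simulated frames become imaging-like cell traces: coordinates scaled by
150 nm/sigma (so the 3-sigma simulation cutoff maps exactly onto the 450-nm
imaging cutoff), Gaussian localization noise of 30 nm per axis (typical
multiplexed-FISH localization precision at this scale), and probes masked
missing-completely-at-random with probability 0.1 (a placeholder rate; real
missingness is not characterized).  "WT-like" cells are chromatin-like
frames; "depleted-like" cells mix 85% reference and 15% chromatin-like
frames, emulating the observation that a substantial minority of
cohesin-depleted cells retains TAD-like structures.  The generator does not
emulate optical PSFs, chromatic offsets, segment-level registration errors,
or structured missingness — so passing tests demonstrate the correctness of
the analysis chain and the recoverability of energetics under idealized
noise, not robustness to all imaging artifacts.

## Problem sizes

Default "desk" scale, chosen so the full validation runs in minutes on one
CPU: 5 x 10^5 production steps per polymer with a frame every 50 steps
(10^4 frames), 300 training epochs for 25-latent models, 150 for the 2-latent
embedding model, 800-2000 cells per population.  The full-scale settings
(5 x 10^7 steps, 10^5 frames, 1000 epochs) remain configurable via
`PolymerModelParams`, `TrainConfig`, and the `full` preset of the pipeline
config.  At desk scale the energy-recovery correlation is somewhat below, and
the regression slope above, their full-scale counterparts, because the
reference VAE underfits the probability of rare strongly folded
configurations; both move toward the full-scale values as data and epochs
grow.

## Numerical choices and degenerate inputs

- Distance ties at a cutoff count as contacts (both 450 nm and 3 sigma).
- The contact-matrix diagonal is 1 by convention and excluded from features.
- 0 log 0 = 0 in the mixing entropy; probabilities outside [0, 1] are errors.
- Histogram KL uses one pseudo-count per bin, so it is finite and >= 0.
- tad_contact_fraction returns NaN (not an error) for a matrix with no
  eligible contacts; contacts with |i - j| <= 1 are excluded by default so
  the ~0.8 adjacent-contact background does not swamp the TAD signal.
- Boundary scores need a window of >= 2 bins on each side (within-window
  mean distances are otherwise empty); edge bins are NaN.
- The Langevin integrator raises a named integration-failure error on
  non-finite coordinates rather than silently saving bad frames.
- Single global seed fans out per stage as CRC32(stage name) XOR seed mod
  2^31, so stages rerun independently yet reproducibly.

## Known limitations

- The ELBO is a lower bound; its slack varies across configurations, which
  inflates the scale of inferred energies (regression slope > 1 against the
  ground truth) and caps the achievable correlation at small training-set
  sizes.
- The reference-subtraction identity assumes the two ensembles share their
  entropic functional; it degrades if the compared polymers differ in
  flexibility or excluded volume.
- Effective-equilibrium language (free energies, Boltzmann weights) is a
  modeling device for steady-state distributions; no claim is made that real
  nuclei are at thermodynamic equilibrium.
- The trace reader accepts real multiplexed-imaging tables in the documented
  TSV layout, but no external dataset ships with the package and no test
  depends on one.
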