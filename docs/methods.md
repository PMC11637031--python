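# Methods

## Feature extraction

Images are standardized before any texture statistic: color inputs are
collapsed by the unweighted RGB mean, optionally resized (bilinear, then
rounded back to integers), min–max stretched to [0,1] and re-quantized to
L = 256 levels with the round-half-up rule floor(v·(L−1)+0.5).  Stretching
is exposed as a config switch (default on) because the inter-scan use case
needs it while single-scanner data may not; a constant image is rejected
as degenerate rather than silently mapped to zero, since a zero dynamic
range would corrupt entropy and co-occurrence statistics downstream.

First-order statistics use the population convention (divisor N).  The
variance is defined as std², keeping variance, skewness and kurtosis
mutually consistent; kurtosis is not excess-corrected.  On a constant
image the standardized moments are 0/0 and are returned as 0 by
convention so constant fixtures remain usable.  Entropy is computed in
nats over the L-bin histogram with 0·ln 0 := 0.

The co-occurrence matrix counts *ordered* (reference, neighbor) pairs at
a single offset per orientation — 0° → (0,+d), 45° → (−d,+d),
90° → (−d,0), 135° → (−d,−d) — and is normalized to sum to one before
features are computed (homogeneity ∈ (0,1] requires this).  Features are
concatenated per orientation (6 × 4 = 24 values) rather than pooled;
angle-averaging and symmetric accumulation are available as flags.  When
a marginal standard deviation is zero the correlation is returned as 1
(a constant field is perfectly predictable) and flagged.

LBP codes use P = 8 neighbors on the circle of radius R = 1.0, sampled
counter-clockwise starting east, with bilinear interpolation at
non-integer coordinates and the comparison S(x) = 1 iff x ≥ 0.  Border
pixels within ⌈R⌉ of the edge are excluded.  Interpolated samples carry a
1e-9 comparison guard so float rounding on flat patches cannot clear a
bit; genuine differences on integer-valued images are orders of magnitude
larger.  A "grid" mode replaces the circle with the 3×3 Moore
neighborhood.  The histogram uses the full 2⁸ = 256 bins (no
uniform-pattern folding), giving the default 6 + 24 + 256 = 286 features.

## Optimizers

All optimizers minimize over [0,1]^D with population P, horizon T, a
globally tracked elite, and out-of-bounds proposals clipped to the box.
The recorded trace is the best-so-far fitness per iteration, hence
non-increasing by construction.

Sea-horse movement draws a standard-normal branch variable r1: when
r1 > 0 a logarithmic-spiral step is taken, X + Levy·((X_e − X)·x·y·z +
X_e) with spiral geometry x = ρcosθ, y = ρsinθ, z = ρθ, ρ = u·e^{θv},
θ ~ U[0,2π] drawn once per agent (a per-coordinate mode exists behind a
flag); otherwise a Brownian drift X + rand·l·β·(X − β·X_e) with the
standard-normal density β evaluated at a fresh normal draw per
coordinate.  The Lévy step uses the Mantegna scheme
s·wσ/|K|^{1/λ} with w, K ~ N(0,1), λ = 1.5 and σ carrying the outer 1/λ
exponent (σ(1.5) ≈ 0.6966); a `levy_literal` flag reproduces the variant
without the exponent (σ ≈ 0.5813), and `random_lambda` redraws λ on
(0,2].  Defaults l = u = v = 0.05, s = 0.01.

Predation succeeds when a uniform draw exceeds the threshold 0.1 (success
probability 0.9) and anneals with α = (1 − t/T)^{2t/T}.  The success
branch is α·((X_e − rand·X) + (1−α)·X_e) and the failure branch
(1−α)·((X − rand·X_e) + α·X), with the α factor applied outside the inner
sum; at t = T the success branch therefore proposes the origin, which the
elitist selection simply discards.  A consequence worth knowing: the
perturbation around the elite is coordinate-wise non-positive, so plain
SHO carries a drift toward the lower corner of the box and performs
poorly on objectives whose optimum sits mid-box (see the sphere results
below).

The sine–cosine update moves each coordinate by
b1·sin(b2)·|b3·X_e − X| (or cos, chosen per coordinate by b4 < 0.5), with
amplitude b1 = a(1 − t/T), a = 2, b2 ~ U[0,2π], b3 ~ U[0,2]; a
`literal_ranges` mode restricts b2, b3 to [0,1], which cripples the
cosine branch and is provided for comparison only.

Breeding sorts the population ascending by fitness, takes the best ⌈P/2⌉
as fathers and the rest as mothers, pairs each mother with a distinct
random father, and produces one child per pair by convex recombination
with a scalar r3 ~ U[0,1].  The next generation is the best P of the
updated agents and the offspring.  Fitness is evaluated once per
iteration, after all position updates.

The SHOSCA hybrids substitute the SCA update for one SHO phase: the full
hybrid replaces predation, the motor variant replaces movement, the
breeding variant replaces mating (SCA applied to every agent, no
offspring).  In the full hybrid the SCA step acts as a repair operator
for the population's worst outcomes: by default only agents whose fitness
falls in the worse half of the current population take the step, while
the better half keep their movement result.  This retention is what makes
the hybrid converge: applying the step to every agent (available via
`worst_half_only=False`) re-randomizes good solutions each iteration and
roughly quadruples the final sphere fitness at T = 50.

On the 10-D sphere centered at 0.5 (P = 10, T = 50), the committed pilot
(tests/fixtures/sphere_pilot.json, one shot, never revised) places the
full hybrid at 3e-3–2.7e-2 across ten seeds, plain SHO and SCA near
0.3–0.5 — the center-optimum box exposes SHO's corner drift, which the
usual benchmark suites with optima at the origin do not.

## Wrapper feature selection

A position binarizes by strict comparison with the threshold 0.5.  The
fitness is α·E + (1−α)·S/D with α = 0.99; a `literal_weights` mode scores
α·E + α·S/D for the variant in which both weights coincide.  E is the
misclassification rate of Euclidean 5-NN trained on the selected columns,
measured on the run's stratified 20% hold-out split by default; an
internal stratified cross-validation mode on the 80% partition decouples
selection from the reported split at extra cost.  The empty mask scores
exactly 1.0 without fitting.  Inside optimizer loops the 5-NN error is
computed by a masked-distance scorer that precomputes per-feature squared
differences once per split and reproduces scikit-learn's
KNeighborsClassifier prediction exactly (odd k prevents vote ties;
distance ties have probability zero on continuous features); the
reporting path and public `subset_fitness` use scikit-learn directly.

One agent of every initial population is pinned at 0.75 in all
coordinates so the full-feature mask is always reachable and the returned
fitness can never exceed the full-mask baseline.  Each run draws a fresh
stratified 80/20 split; repeated experiments (default R = 25) seed run r
with base+r, so different algorithms launched from the same base seed see
identical splits run-for-run and their runs form paired blocks for the
Friedman test.  The reporting classifier (5-NN, or random forest with 100
trees) is independent of the fitness classifier.

## Evaluation

Precision and recall treat the MS/lesioned label as positive and are
returned as 0 with a flag when undefined (macro-averaging is available).
Aggregates over runs: accuracy pooled over runs and test samples;
mean/best/worst of per-run best fitness; sample standard deviation
(divisor R−1); selected size both as raw count and fraction of D; mean
wall-clock time (reported, never asserted).  The Friedman test ranks
within blocks with mean ranks for ties and uses the tie-corrected
chi-square statistic with k−1 degrees of freedom; it is implemented
directly (scipy's version rejects k = 2, which the two-algorithm
comparison needs) and matches scipy for k ≥ 3.  An all-equal table
returns statistic 0 and p = 1 rather than the 0/0 of the raw formula.

## Synthetic data

The image generator emulates the one property of T2/FLAIR slices the
pipeline relies on — hyperintense lesions on smoother parenchyma — and
nothing else: no bias fields, partial-volume effects or sequence
contrast.  Each pair shares a blurred-uniform background (σ = 6) rescaled
to [30,160] and re-anchored to mean 95, plus a shared Gaussian noise
field (σ = 8 levels); the lesioned member adds 2–4 ellipses with
semi-axes 5–8 px at +70 levels.  Anchoring the background mean and
bounding the lesion load are what make the class means of `fo_mean` and
GLCM contrast separate by more than two standard deviations over 20
pairs — a deliberately easy regime: passing tests demonstrate the
pipeline's mechanics, not clinical performance.

The table generator plants k informative columns (class shift δ = 1.5
within-class standard deviations) among D−k N(0,1) noise columns, with
balanced labels and a recorded column shuffle.  δ = 1.5 at n = 300,
D = 50 is the regime where 5-NN on all columns is noticeably degraded by
noise while the planted subset supports near-perfect classification —
i.e. where wrapper selection demonstrably helps.  The analytic
planted-mask objective (α·Hamming/D + (1−α)·S/D) has the planted mask as
its unique binary minimizer and lets optimizer tests run without any
classifier.

## Numerical and testing choices

Default protocol constants: P = 10, T = 50, R = 25, k = 5, threshold 0.5,
α = 0.99, l = u = v = 0.05, λ = 1.5, a = 2.  Tests exercise the full
protocol at its native size (the heaviest check, 25 paired runs of two
algorithms at D = 50, completes in well under a minute thanks to the
masked-distance scorer); image-based tests use 64–128 px slices.
Reproducibility is bitwise from seeds on fixed hardware.  Degenerate
inputs fail loudly: constant images in the stretch, empty class
directories, non-finite objective values, unevaluated populations in
breeding.
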