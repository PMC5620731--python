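# Methods

## Problem and data model

The task is to label every moment of a smartphone-carrying person's
travel with one of five modes — walk, bike, car, bus, rail — in near
real time, using only the sensors every phone has: GPS, reduced to a
1 Hz speed series S(t) in mph, and the tri-axial accelerometer at 5 Hz,
reduced to the orientation-free magnitude A(t) = √(ax²+ay²+az²) in
m/s². The magnitude is used because device orientation is uncontrolled
in pockets and handbags; it is invariant to rotation and axis
permutation. A *trip* is a contiguous single-mode stretch carrying both
channels on their nominal grids.

## Preprocessing

Raw streams jitter around their nominal rates and drop out; each stream
is snapped to its grid by nearest-sample assignment (speed to whole
seconds, acceleration to 0.2 s slots). A second with no usable GPS fix,
or with fewer than three of its five accelerometer slots filled, is
missing; trips are split at missing seconds so no analysis window ever
spans one. Data within 10 s of a mode change (two adjacent annotations
with different modes) are removed — boarding a bus looks like neither
walking nor bus — and trips shorter than 120 s are dropped, because
they cannot host the longest analysis window and are unlikely to be
characteristic of their mode. A label transition across a time gap
longer than the trim margin is treated as a recording break rather than
a mode change, which makes the trimming operation idempotent. Speed
from coordinates uses the haversine distance on a 6,371 km sphere;
1 mph = 0.44704 m/s. Units are split 60/20/20 into train/validation/
test by seeded simple random sampling. The default split unit is the
individual window (movelet or feature row); because consecutive windows
overlap heavily, this split is optimistic about generalization to new
recordings, and a trip-level split (`split_unit="trip"`) is provided
for leakage-free estimates.

## Movelet dictionaries

Window length H ∈ {30, 60, 90, 120} s, slide Δ = 5 s; a trip of T
seconds yields ⌊(T−H)/Δ⌋+1 movelets and each interior second lies in
H/Δ of them. Channels are scaled to [0, 1] by the *global* training
min/max per channel — per-window scaling would erase the absolute speed
level that separates modes — and out-of-range values in new data are
clipped. The distance between two movelets is the sum of per-channel ℓ2
norms each divided by its sampling rate, so the 5H-point acceleration
window does not dominate the H-point speed window. The same distance is
used for validation matching and prediction so training-time and
test-time geometry coincide.

Refinement: every validation movelet is matched to its nearest training
movelet; for each mode m the chapter is formed from training movelets
matched by that mode, and its size κ_m is frozen; movelets matched by
more than one mode are ambiguous and removed everywhere; then the
least-matched movelets are dropped while the chapter exceeds
`keep_fraction · κ_m`. `keep_fraction` ∈ (0, 1] (default 0.5) is
exposed directly. Prediction is the mode of the chapter containing the
globally nearest movelet; ties break by canonical mode order
(walk < bike < car < bus < rail) then earliest source time, for
determinism. Predictions are reported per movelet; aggregation over the
several movelets covering a time point (latest window, or a vote) is
left to the caller.

## Feature pipeline

Rows are emitted every 5 s from 120 s into each trip, so all four
window lengths exist at every row. Per row: 8 statistics × 4 windows ×
4 processes (S, A, and their successive differences ΔS, ΔA, newer
minus older) = 128 features, plus the acceleration-only lag-1
autocorrelation and the sums of the first six real and first six
imaginary DFT components per window = 12 more, total 140. Numerical
conventions, chosen where the method statement is silent and recorded
as this package's choices: sample variance (n−1); quantiles by linear
interpolation between order statistics; IQR = p75 − p25;
autocorrelation is the Pearson correlation of the window with its
one-sample shift, 0 for zero-variance windows; the DFT is unnormalized
with components indexed 1..6, DC excluded since it duplicates the mean.

## Models and selection

Features are standardized (training mean/sd). PCA components are
ordered by variance fraction; the PCA family spans 1..i₉₅ components
(95% variance cap). RFE eliminates one feature at a time using random-
forest importance (mean decrease in Gini), yielding a total ranking;
the accuracy of each top-j subset is estimated by stratified seeded
10-fold CV. One ranking, computed once on the training set, serves both
downstream classifier families; this differs from implementations that
re-rank inside every CV fold, and is noted as a deliberate
simplification. kNN uses Euclidean distance on the reduced coordinates,
k tuned by leave-one-out CV over 1..100 (vote ties broken by seeded
randomness, smaller k preferred on curve ties). Random forests use 500
trees, √p candidate features per split, Gini impurity, bootstrap
sampling. The CV accuracy curves may use a lighter 100-tree forest
(`cv_trees`) since fold-level accuracy estimates are insensitive to
tree count at these sizes; ranking and final fits always use the full
500.

MEM = α(1−γ) with γ the variance retained (PCA: summed component
fractions; feature selection: i/140, as standardized features carry
equal variance). Selection maximizes MEM subject to α ≥ 0.9·α_max; the
α_max model is always feasible, so the feasible set is never empty; MEM
ties prefer the smaller dimension. α is the 10-fold CV accuracy (RF)
or LOOCV accuracy (kNN) on training data; held-out test accuracy and
confusion are reported alongside and labeled as such. The default
experiment sweeps dimensions 1..30, which covers the compact-model
region of interest and the PCA variance cap while keeping a full run in
minutes; the dimension grid is configurable up to all 140.

## Synthetic data generator

The generator exists so every stage is testable without the original
field recordings. Speed is a discretized Ornstein-Uhlenbeck pull
(reversion 0.15 per s) toward a target that is the mode's cruise level
while moving and zero during stop episodes (Poisson arrivals, uniform
durations), truncated at zero. Acceleration magnitude is gravity
(9.81 m/s²) plus a dominant-frequency sinusoid (step cadence ~2 Hz for
walking, pedaling ~1.5 Hz for biking, low-frequency sway for motorized
modes — all below the 2.5 Hz Nyquist limit of the 5 Hz channel) plus
Gaussian noise, with the sinusoid amplified while speed is changing.
Default profiles (invented, fixed once): walk 3±1 mph, strong 2 Hz
vibration; bike 10±3 mph, moderate 1.5 Hz; car 28±9 mph stop-and-go;
bus 17±6 mph with 20–40 s stops every ~50 s and the *same* road
vibration as car, so only speed patterns separate them; rail 40±8 mph,
sustained and very smooth. Default volume is two hours split in the
per-mode ratios 2.64 : 6.91 : 8.25 : 7.30 : 21.62 (bike : bus : car :
rail : walk), the proportions of the emulated field study.

What the generator does **not** emulate: GPS noise and urban-canyon
dropouts, route geometry, device-orientation dynamics beyond a slowly
rotating random axis (used only when emitting tri-axial raw files),
within-mode heterogeneity across people and vehicles, and mode
transitions. Passing tests therefore demonstrate that the pipeline
recovers the structure the generator encodes — speed levels, stop
patterns, vibration signatures — not that field accuracy would match;
on real data the motorized modes are substantially harder.

## Degenerate inputs and tie-breaks

Constant channels abort scaler fitting and standardization with an
error naming the channel/column; trips shorter than H (movelets) or
120 s (features) contribute nothing, with a log notice; an empty
refined chapter is logged (error only if all five are empty);
equal-distance predictions and equal-MEM models resolve by the
deterministic orders above; all stochastic steps (splits, forests, kNN
tie votes, simulation) flow from a single configured seed.

## Known limitations

Window-level splitting inflates accuracy via overlap leakage (kept as
the default to match the protocol this package emulates; the trip-level
alternative is one flag away). The movelet dictionary's prediction cost
scales with dictionary size. MEM's variance-retained currency favors
feature selection over PCA, which necessarily concentrates variance in
few components. The 10-fold curves reuse one feature ranking rather
than re-ranking per fold, slightly optimistic for small subset sizes.
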