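# Methods

This note records the modelling choices behind `eitgest`: what is
simulated, which parameters matter, what the synthetic data can and
cannot stand in for, and where the design was genuinely open.

## Forward model

The forearm cross-section is idealised as the unit disk — the standard
2-D EIT idealisation; a real forearm is irregular and the armband sits
on a ~22 cm circumference, but none of the questions studied here
depend on the outline. Conductivity is real-valued (a single 100 kHz
stimulation frequency is modelled as one resistive value per element;
capacitive electrode and tissue components are out of scope).

The mesh is a structured triangulation on concentric rings whose node
counts are multiples of the electrode count, so the mesh is exactly
16-fold rotationally symmetric. The outermost rings share an
electrode-aligned angular pattern in which every electrode arc is
delimited by nodes exactly at its edges. Electrodes follow a gap model:
a uniform current density over each arc, imposed through the consistent
(tent-function) nodal load, with measurement weights equal to the
injection weights — this makes transfer reciprocity exact up to solver
precision and keeps the electrode model structurally identical across
refinement levels. Contact impedance is deliberately *not* part of the
FEM: contact effects are injected at the measurement level by the
session generator (see confounders), which decouples the physics core
from hardware artifacts.

Refinement levels 1/2/3 give ~500/~900/~1500 elements. Against a
closed-form oracle (Neumann Green's function of the disk integrated
over the electrode arcs) the homogeneous-disk voltages agree to 1.6% at
level 3, converging further with refinement; the worst channels are
always the measurement pairs adjacent to the drive, where the
electrode-edge field is hardest to resolve. Successive-level agreement
is below 1% except between levels 2 and 3, where the number of nodes
interior to each electrode changes (2 → 3 segments); this is a known
discretisation step, not a physics change.

One sparse LU factorisation per conductivity serves all 16 drives; the
per-electrode fields also yield every measurement field, so a frame
costs 16 triangular solves. The sensitivity matrix J uses the
adjoint-field identity dV/dσ_e = −area_e · ∇u_drive·∇u_meas and is
validated against central finite differences (<1% relative error).

Current amplitude defaults to 1 mA. Only differenced and globally
scaled voltages matter downstream: a per-participant global gain maps
the rest baseline onto the instrument's 20–800 mV span (the gain sets
max |V| = 800 mV; the simulated geometry then places the smallest
baseline channels near 100 mV — the circular homogeneous idealisation
compresses the dynamic range relative to a layered forearm, which
reaches lower minima; all baselines remain inside the printed span).

## Phantoms and sessions

Gestures are 2–4 circular inclusions (radius 0.12–0.17 of the domain,
contrast ±20–40% of background σ₀ = 0.3 S/m) placed at the angular
positions of the muscles that drive each gesture, with electrode 0 over
the extensor carpi radialis. These contrasts put steady-state channel
changes in the few-percent range (≈2–11% across channels), matching the
magnitude of gesture-induced voltage changes in armband recordings.
Two bone-like low-conductivity inclusions make the rest phantom
inhomogeneous so that armband rotation shifts the baseline pattern.
"power" and "thumb" share three of four inclusions (the common
four-finger flexor chain) and differ in onset-lag ordering, so their
steady states are similar while their transients differ — the pair is
deliberately the hardest.

A session repeats each gesture instruction with a 3 s hold and a 5 s
interval at 23 frames/s (10 repetitions per gesture in training
sessions, 5 in confounder blocks). Activation ramps follow a normalised
logistic with duration drawn uniformly from 0.4–1.2 s per repetition,
per-inclusion onset lags up to 0.3 s (jittered ±0.05 s), and ±5%
per-repetition amplitude jitter. Only frames inside the instructed 3 s
carry the gesture label (floor(3 s × 23 fps) = 69 per repetition);
interval frames are unlabelled. Activations are quantised to 0.01 so
neighbouring ramp frames can share a FEM solve — the step is far below
the noise floor. Measurement noise is additive Gaussian per channel at
40 dB SNR relative to the rest baseline (no instrument noise figure is
available; 40 dB makes the closest gesture pair statistically but not
trivially separable at the single-frame level).

Participants are emulated as seeds: template geometry jittered by up to
0.04 domain radii with ±10% radius/contrast scaling.

Confounder defaults (none are quantified by any published measurement;
all are exposed in the config):

- **Limb position (L/R/U/D)** — a smooth background blob (|Δσ/σ₀| = 6%,
  radius 0.5, centred 0.45 towards the direction) plus a rigid 0.04
  shift of all inclusion centres.
- **Time** — multiplicative per-channel drift g(t) = 1 + A_ch(1 −
  e^(−t/τ)), A_ch ~ N(0, 2%), τ = 60 s. The real phenomenon evolves
  over two hours; τ is scaled to the simulated block length.
- **Contact** — armband rotation by half an electrode pitch,
  implemented as the equivalent counter-rotation of the phantom
  geometry (the mesh and its electrode discretisation stay fixed, which
  avoids re-meshing artifacts), plus per-electrode contact-gain
  perturbations δ_e ~ N(0, 2%) applied to every channel touching the
  electrode — the measurement-level trace of the disturbed
  electrode–skin interface.

## Reconstruction

Difference images solve the regularised normal equations
(JᵀJ + αI)Δσ = JᵀΔV by a symmetric positive-definite solve (no explicit
inverse). α defaults to 10⁻² λ_max(JᵀJ); the reference is the mean of
rest-interval frames. α = 0 is allowed only when JᵀJ is numerically
well conditioned (condition number < 10¹²), otherwise an
ill-conditioning error is raised. Images are element-wise on the mesh;
rasterisation to a pixel grid is plotting plumbing only.

## Dataset construction

Frames reshape to 16 × 16 matrices with drive-major rows (13 true
measurements per row, 3 zero-padded columns) — this keeps drive
locality along rows and is exactly invertible. Windows are 480 ms = 11
frames (0.480 × 23 = 11.04, rounded down) and the canonical stride is 1
frame (the closest not-less-overlapping option to 87.5%: stride 1 gives
90.9%). Windows straddling a label change are discarded (unambiguous
supervision); transition frames inside an instructed period keep the
instructed label, so transient windows are retained. The 70-15-15 split
permutes pooled windows with a fixed seed. Raw voltages are the model
input by default; the experiment harness enables per-channel
standardisation from training statistics (flagged in the config) so
that mV-scale inputs do not saturate the first layer.

## Classifier architectures

Only one architectural constraint is printed anywhere: the total
parameter counts (0.65 M for FASPP-GRU, 0.88 M for CNN-LSTM). Widths
are otherwise free and were chosen for single-CPU tractability:

- FASPP-GRU: upsample 16×16 → 32×32 (bilinear ×2) → fold → 16×16×4 →
  ASPP (1×1 branch + 3×3 branches at dilations 1, 2, 4; 8 channels per
  branch; concat → 1×1 projection to 16 channels; ReLU) → unfold →
  32×32×4 → 4×4 average-pool grid flattened (256) → linear embedding
  (64) → GRU (hidden 128) → MLP (4043 → 9). Total 649,959 parameters.
- CNN-LSTM: two conv3×3+pool2 stages (8, 16 channels) → embedding 64 →
  LSTM (128) → MLP (5532 → 9). Total 879,937 parameters.

The spatial-to-vector interface after the unfold is a coarse 8×8
average-pool grid rather than a single global average: pooling the
unfolded 4-channel map to one vector of 4 numbers would discard nearly
all spatial information; the 8×8 grid keeps coarse spatial layout at
negligible cost. Most parameters sit in the MLP head, where a
parameter costs one multiply per window rather than one per frame and
position — this is how the budget is met without making CPU training
impractical. Gates use one bias per gate (GRU: 3h(d+h+1) parameters;
LSTM: 4h(d+h+1), forget bias 1). Everything runs in float32; gradients
of every layer are validated against central finite differences in
float64.

Training: Adam at the 5·10⁻⁵ initial learning rate, batch 64,
cross-entropy, early stopping on validation loss (patience 10 in the
harness, max 60 epochs), best-validation weights restored. Training is
deterministic given the seed.

## Evaluation

Accuracy is trace/total (the multiclass reduction of the one-vs-rest
micro form — the equivalence is asserted numerically in the tests).
F1 is computed one-vs-rest per class with 0/0 defined as 0 and
aggregated as the **macro** average: with balanced class counts in
every test block, macro and weighted averages coincide, and macro keeps
the degenerate-class convention explicit. Models are compared with the
Friedman rank test (mid-ranks for ties, χ² approximation) over paired
participant-condition blocks; the implementation is cross-checked
against an independent statistics library. UMAP projects GRU/LSTM
hidden states to 2-D; decision regions in those plots are rendered by
classifying a grid through a nearest-centroid map — a visualisation
approximation, as the true decision surface lives in the hidden space,
not the 2-D embedding.

## Problem sizes

The end-to-end experiment in the test suite and in
`scripts/acceptance.py` uses: two emulated participants, three clean
training sessions (10 reps) plus six confounder blocks (5 reps) each,
the ~500-element level-1 mesh, window stride 11 (one window per 480 ms
of instructed data, 3,240 training-pool windows), and at most 60
training epochs. These sizes were chosen so that a full run completes
in roughly a quarter of an hour on a single CPU while leaving every
qualitative contrast (clean vs confounded, sequence models vs static
baselines) intact.

## What the synthetic data does and does not show

The generator reproduces the *structure* of armband sessions — channel
count and ordering, frame rate, block protocol, labelled instructed
periods, transient dynamics, baseline span, and three confounder
families with plausible magnitudes. It does not reproduce real tissue
anatomy, electrode-skin electrochemistry, motion artifacts, or
inter-participant variability beyond geometric jitter; and the
confounder magnitudes are declared defaults, not fitted to any
recording. Passing the end-to-end tests therefore demonstrates that the
pipeline is correct and that the classifier ordering holds under the
modelled interference — it does not certify accuracy figures on real
forearms. Reconstructed images are likewise for visual inspection only;
no anatomical claims are attached.

## Known limitations

- Point/gap electrode model; no complete-electrode contact impedance in
  the FEM.
- The disk geometry compresses the baseline dynamic range (min ≈100 mV
  rather than 20 mV).
- Voltage convergence between refinement levels 2 and 3 is ~1.1% due to
  the electrode-interior discretisation step.
- The time-drift and limb-position magnitudes are unvalidated defaults.
- With two emulated participants the Friedman test has minimal power;
  it is wired for the general paired design.
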