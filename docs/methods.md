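# Methods

This note documents the models, parameters and design choices behind
`gliomaft`: what the synthetic data emulates, how the network and the
fine-tuning protocol are defined, what the statistics compute, and what
the desk-scale experiments do and do not demonstrate.

## 1. The problem being modeled

A segmentation network trained on MR volumes from facility A (domain A)
is applied to volumes from facility B. Facilities differ in scanner,
field strength, protocol and slice thickness; the induced distribution
shift degrades accuracy unpredictably. The package studies one remedy:
continue training a small, named subset of network blocks on a handful
(≤ 20) of facility-B cases.

Real multi-facility glioma data is private; the package therefore
includes a phantom generator whose *purpose* is to reproduce the
phenomenon — a measurable Dice gap between an in-domain and an
out-of-domain model, recoverable by fine-tuning — in minutes on a CPU.

## 2. Synthetic phantoms

**Geometry.** The brain is an axis-aligned ellipsoid (semi-axes 0.42 of
each volume dimension) containing a three-compartment tumor of
concentric ellipsoids: necrotic core (label 1), enhancing rim (label 4,
width `rim_width`), and an edema shell (label 2, width `edema_width`).
Label codes follow the BraTS convention so real BraTS label volumes and
phantoms share one code path. Voxels outside the brain are exactly
zero; inside they are strictly positive (required by the gamma
transform). The whole-tumor VOI is the union of the three compartments.

**Appearance.** Per-channel class intensities (normalized units) follow
the usual glioma pattern — tumor and edema hyperintense on T2/FLAIR,
rim bright on GdT1, necrotic core dark on T1 and GdT1 — with
deliberately modest contrasts (0.05–0.15 between neighboring classes):

| channel | tissue | edema | rim | core |
|---|---|---|---|---|
| T1 | 0.55 | 0.48 | 0.51 | 0.42 |
| T2 | 0.45 | 0.55 | 0.57 | 0.60 |
| FLAIR | 0.48 | 0.58 | 0.57 | 0.53 |
| GdT1 | 0.50 | 0.50 | 0.62 | 0.42 |

Two Gaussian-random-field textures are added per channel: a fine
component (amplitude 0.05, smoothing sigma 2 voxels) for local tissue
heterogeneity and a coarse component (amplitude 0.12, sigma 6) for
anatomical intensity gradients. The coarse component matters: it
spreads *absolute* intensity levels across the brain, so a nonlinear
acquisition effect (gamma) produces a spatially varying contrast gain
(γ·v^(γ−1)) that per-case Z-scoring cannot undo. With weak or
fine-only texture a convolutional network is effectively invariant to
the facility transforms below and no degradation is measurable — the
contrasts and texture amplitudes were calibrated once to put the task
in the regime where domain match matters, and are not tuned per
experiment.

**Facility transform.** A `FacilitySpec` applies, in this fixed order
(the stages do not commute; the order is part of the contract):

1. per-channel affine `v → scale·v + offset` (in-brain voxels only);
2. gamma `v → v^γ` (requires positive in-brain intensities);
3. multiplicative bias field `1 + a·P(x,y,z)`, with `P` a random
   degree-≤2 polynomial normalized to max |P| = 1 — drawn
   *independently per channel*, since each MR sequence is a separate
   acquisition with its own coil/shim state;
4. slice-thickness degradation: block-average groups of k slices along
   z and replicate them back (k = 3…9 at 1 mm base spacing covers the
   3.3–9 mm slice thickness range seen across real scanners);
5. additive Gaussian noise (in-brain only).

Stages at their identity value are skipped, so an identity spec returns
a bit-identical volume. Bias and noise use independent seed substreams,
so disabling one stage does not change the other's draw. Labels are
never touched.

**Determinism.** Every generator output is a pure function of its seed
arguments; per-case seeds derive from (dataset seed, case index,
facility seed offset) via `numpy` `SeedSequence`.

## 3. Preprocessing

Images are cropped to the tight bounding box of the in-brain support
(any channel nonzero; half-open 0-based boxes), resampled trilinearly
to the network input shape, and Z-score normalized per channel over the
support (population SD; out-of-support voxels set to 0). Masks use the
box computed from their paired image and nearest-neighbor resampling,
staying binary. Normalization runs *after* resizing so the network
always sees zero-mean/unit-variance input regardless of interpolation;
whether the original pipeline normalized before or after resizing is
unrecorded, so this is a documented convention of this package, not an
inference. Z-score statistics exclude the empty background (it would
otherwise dominate both moments).

The clinical-scale input shape is 176×192×160; the package default is
32×32×32 so that full training loops run on a desktop CPU. The shape is
a config value; nothing in the code depends on the specific choice
beyond divisibility by 2^(depth−1).

## 4. The block-named network

A U-Net-style encoder–decoder on 4-channel volumes. Each *block* is
`convs_per_block` shape-preserving 3×3×3 convolutions with ReLU, one
dropout layer, and a residual element-wise sum around the block where
input and output channel widths agree. Resolution halves between
encoder blocks (strided 2×2×2 convolution) and doubles between decoder
blocks (transposed 2×2×2 convolution); mirrored resolutions are joined
by skip connections (concatenation by default, element-wise sum
optional). A 1×1×1 convolution plus sigmoid produces a single-channel
voxelwise tumor probability; the evaluated target is one binary
whole-tumor VOI, so there is no multi-class head.

Blocks are named `1st down` … `Nth down` from shallow to deep and
`1st up` … `Nth up` from **deep to shallow** — i.e. `1st up` is the
deepest decoder block. Every learnable parameter belongs to exactly one
block; resampling transitions belong to the block they feed, the input
stem to `1st down`, and the output head to the shallowest up block. The
registry (block → parameter names, shapes, counts) is serialized next
to every checkpoint.

Defaults: `convs_per_block` 3, dropout rate 0.2 (the desk-scale
experiment configuration uses 1 and 0.1 — see §7), He initialization,
float32 throughout.

## 5. Training and fine-tuning

**Loss.** Soft Dice, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1.0,
aligning the training objective with the evaluation metric; ε is part
of the contract. Batch size defaults to 1 (3D volumes; also removes
batch-statistics nondeterminism).

**Base training** uses RMSprop at learning rate 5e-4 and retains the
best-validation-Dice parameter state.

**Fine-tuning** uses AdaGrad at learning rate 5e-3 for a fixed 20
epochs, no validation split, on at most 20 target-facility cases
(callers subsample explicitly with a seeded sampler). Optimizers follow
the Keras conventions — AdaGrad's accumulator starts at 0.1 with
epsilon 1e-7. This is not a detail: with a zero-initialized
accumulator the first AdaGrad steps are approximately lr·sign(g) per
parameter, which destroys an already-trained model at lr 5e-3 (observed
Dice 0 after 20 epochs in early testing).

**Freezing strategies.** `fine_all`, `down_only`, `up_only`,
`down1_up1`, `down2_up2` mark whole blocks (un)trainable; frozen
parameters remain bit-identical through any number of optimization
steps. Because up blocks are *named* deepest-first, "up1"/"up2" in a
strategy name is ambiguous. The `up_convention` switch resolves it:
`"shallow"` (default) selects the shallowest up blocks, `"literal"` the
blocks literally named `1st up`/`2nd up` (the deepest). The default
follows the interpretation that scanner-level image differences are
low-level features, best adapted in the shallow layers nearest input
and output; both readings are implemented and tested, and neither is
asserted to be the original authors' intent.

**Determinism.** One integer seed drives initialization, case order and
dropout through named `SeedSequence` substreams. The convolution
kernels are single-threaded numba JIT with fixed summation order, so
training is bit-reproducible on a given machine. Probabilities are
clamped to [1e-12, 1−1e-12] and sub-1e-30 loss-gradient entries
flushed to zero: saturated sigmoids otherwise emit denormal floats
whose hardware penalty slows training severalfold.

## 6. Evaluation and statistics

Per-case Dice `2|A∩B|/(|A|+|B|)`; two empty masks are an error rather
than 1.0 (silently scoring absent tumors as perfect would inflate
means). Tumor volume is nonzero-voxel count × voxel volume / 1000 (mL).
Aggregation is always per case, then grouped mean ± sample (n−1) SD —
never pooled voxelwise. Welch's ANOVA (Welch–Satterthwaite denominator
df) and Games–Howell pairs (studentized-range distribution, pairwise
Welch df) compare the three model types without assuming equal
variances or group sizes; both are backed by `pingouin` and
cross-checked in the tests against directly-coded formulas. The group
comparison can run on pooled per-case Dice (default) or on facility
means (`stats_on="facility_means"`). Histogram profiles bin Z-scores
into 60 uniform bins over [−3, 3] (out-of-range values clipped into the
edge bins so counts conserve the support size) and report the
VOI-restricted histogram, VOI fraction and VOI median Z for a chosen
channel.

## 7. The degradation–recovery experiment

`workflow.recovery_config()` fixes the study conditions:

* facility A: near-pristine (noise sigma 0.005, no bias/gamma/slab);
* facility B: gamma 1.8, per-channel bias amplitude 0.2,
  slice-thickness factor 2, noise sigma 0.08;
* volumes 32³, tumors radius 3–5.5 voxels; 40 A-train / 8 A-val cases,
  32/8 B pre-training pool, 20 B-test cases;
* network depth 3, base width 8, 1 convolution per block, dropout 0.1;
* base training 8 epochs (validation Dice plateaus by epoch ~3; the
  best-validation state is retained), fine-tuning on 10 B cases
  sampled from the B pre-training pool.

Per seed, the experiment trains the source (A) model and the target (B)
model, fine-tunes the source model per strategy (`down2_up2`, plus
`fine_all` for comparison), and evaluates all models on the *same* 20
B-test cases. The B pool (32 cases) deliberately exceeds the 10-case
fine-tuning quota: the regime of interest is a target facility with
enough data to define its domain but where only a small annotation
budget is assumed for adaptation.

Typical outcome over seeds 0–4: the source model loses ≈ 0.07 mean
Dice relative to the target model, `down2_up2` recovers roughly half of
the gap, and matches `fine_all` within ≈ 0.01 while updating fewer
parameters. `scripts/acceptance.py` recomputes these numbers from
scratch.

Problem sizes (32³ volumes, depth-3/8-channel network, 1 conv per
block, 8 base epochs, 3 acceptance-script seeds) were chosen so the
full study runs in minutes on one CPU core; they are the package's
desk-scale defaults, and every size is a config value for larger runs.

## 8. What the synthetic experiments do and do not show

They show that the *machinery* behaves as specified: frozen blocks are
bit-frozen, the freezing strategies order by capacity, domain shift of
the simulated kind measurably degrades an unadapted model, and
small-sample selective fine-tuning recovers accuracy with `down2_up2`
on par with full fine-tuning. They do **not** show clinical
performance: phantoms have ellipsoidal anatomy, piecewise-constant
classes and within-distribution tumor shapes, no annotation noise or
inter-rater variability, no skull, CSF, motion or ghosting, and the
facility transforms are a low-dimensional surrogate for real protocol
diversity. Published clinical Dice values are not reproducible from
this package and are not targets of its tests.

Other known limitations: the gap between an in-domain and out-of-domain
model at desk scale (~0.05–0.1 Dice) is of the same order as per-seed
training noise, so single-seed comparisons are meaningless — all
experiment-level claims are made across seeds with paired test cases.
The slice-thickness surrogate uses block averaging with nearest
replication (no through-plane interpolation model), and the brain
ellipsoid's in-plane/through-plane geometry does not vary by facility.
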