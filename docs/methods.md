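# Methods

This note documents the models implemented in `svcsim`, the parameter
choices that matter, what the synthetic data emulate (and what they do
not), and the numerical decisions taken where the underlying theory leaves
the implementation open.

## Pattern algebra and elementary networks

Activity patterns are non-negative firing-rate vectors, binary in all
experiments. Population sparseness is `a = (Σ r_i)² / (N Σ r_i²)`, which
for a binary pattern is the active fraction. Throughout, inhibitory
feedback is abstracted as k-winners-take-all (k-WTA): exactly
`ceil(a·N)` most-driven units are active, ties resolved toward the lowest
unit index so that every operation is bit-reproducible. Retrieval quality
is cosine overlap.

Three network types compose everything else:

* **Competitive net** — unit-norm weight rows, k-WTA inference, Hebbian
  learning on winners followed by renormalisation. Because rows are
  unit-norm, a trained unit responds to any input in proportion to the
  cosine with its training history; this generalisation is what lets a
  partial cue (25% of a stored pattern's active units) select the same
  output winners as the full pattern, and equally why inputs correlated at
  ~50% tend to be *categorised together* rather than separated (see
  pattern separation below).
* **Autoassociator** — covariance-rule storage
  `ΔW = lr·(r−a)(r−a)ᵀ` (zero diagonal, symmetric), synchronous k-WTA
  iteration to a fixed point, 20 iterations maximum. Hebb-only storage is a
  constructor option. The covariance form is the default because the sparse
  capacity scaling `p ∝ C/(a ln(1/a))` holds for it; plain Hebb saturates
  far earlier from un-subtracted crosstalk means.
  A temporally asymmetric variant `ΔW = lr·r(t+1) r(t)ᵀ` (plain products)
  stores short sequences; one recurrent pass per item replays them forward.
* **Pattern associator** — `ΔW = lr·post⊗pre` (the default), or a
  covariance variant that subtracts the expected sparseness from both
  factors. The circuit's perforant path, Schaffer projection and all
  backprojections use the covariance variant, again because it is the form
  under which the capacity formula applies.

Numerical notes. Retrieval at overload does **not** decay to chance: a
covariance k-WTA attractor loaded far beyond capacity settles into mixture
states that remain correlated with the cue (overlap ≈ 0.5 at 4–20×
capacity), so "failure" is operationalised everywhere as falling below the
retrieval criterion (0.75 overlap), not as chance-level output. Similarly,
a pattern associator probed with an unrelated cue produces a mixture
dominated by the largest random crosstalk coefficient rather than a flat
output.

Sequence replay uses an activity floor at half the full-cue drive
(`0.5·lr·m`, m = active units): a reversed cue drives the net only through
accidental pattern overlaps (integer counts of shared units), and without a
floor the parameter-free k-WTA would reconstruct an item from a single
shared unit.

## The episodic circuit

Layer sizes default to what/where = 200 (reward 50), EC segments matching,
DG = 1000, CA3 = 500, CA1 = 500, with sparseness 0.1 at the neocortical
input, 0.05 in EC/CA3/CA1 and 0.02 in DG (expansion recoding). The
reward stream is a third input merged at the EC level and is optional
(layer size 0 removes it).

Storage: the full forward sweep is computed with current weights, then all
associative updates are applied, so the stored associations refer to one
consistent set of states. Mossy fibers are a fixed random fan-in of 50 DG
cells per CA3 cell with heterogeneous strengths drawn once from
U(0.5, 1.5); they are never modified, and `mossy_checksum()` witnesses
this. The strengths matter: with uniform (binary) mossy weights the drive
onto CA3 is a small-integer count, k-WTA ties resolve by unit index, and
the "random" CA3 sets become index-correlated across episodes, silently
destroying both separation and capacity.

Recall seeds CA3 through the perforant path (mossy fibers are storage-only),
completes the attractor, reads CA1 from the concatenation of CA3 and the
direct EC path with equal weight (the relative strength is open in the
theory; equal is the default), and reinstates EC and then the neocortical
patterns through the backprojection associators.

Competitive learning defaults: EC and DG learn at rate 0.3 with 3
repetitions per stored episode — this is what turns a 25% partial cue into
the exact stored EC pattern at recall. CA1's learning rate defaults to 0
(a fixed random expansion recode): with strong one-shot competitive
updates, units trained on an earlier episode capture later episodes that
share ~25% of their input, mapping distinct episodes onto identical CA1
codes and corrupting backprojection recall. A non-zero `ca1_lr` is
available for studying that regime.

## Capacity measurements

`eq1_recall_capacity` evaluates `p = k·C/(a·ln(1/a))` with k defaulting
to 0.25 (the middle of the cited 0.2–0.3 range).

`empirical_recall_capacity` stores `p` random what–where episodes in a
fresh circuit and measures mean recalled-what overlap from full where cues
(20–25 probes); `p_hat` is the largest grid value whose mean overlap meets
the 0.75 criterion. Two deliberate experiment-design choices:

* The competitive maps are frozen (learning rate 0) for this measurement.
  The formula describes pattern-association capacity; competitive-map drift
  under hundreds of one-shot stores is a distinct phenomenon that would
  confound the scaling being measured.
* The sweep varies EC size (with full connectivity, EC size = C, the
  backprojection synapses per neocortical cell) while CA3 is held at 1600
  cells so that the associative stages, not the attractor, saturate first.
  At the default sizes the measured `p_hat` runs at roughly half the
  closed-form prediction (an effective k ≈ 0.12–0.25) and doubles with C.

`empirical_ca3_capacity` measures attractor completion from 50% cues on a
stand-alone autoassociator at the configured CA3 size and sparseness —
patterns are stored directly, since the claim it quantifies concerns the
recurrent network itself. Measured capacity again scales linearly with N
(k ≈ 0.125 with the 0.75-overlap criterion).

## Place/view emergence

The arena is a unit square; the `four-wall-12` layout places 3 cues per
wall clustered at 0.35/0.5/0.65 of the wall length. The clustering is
load-bearing: a cue triple spread over a full wall subtends more than 30°
from everywhere inside the arena and can never be co-visible to a narrow
field of view, which would make the fovea-like condition degenerate.

Cell model: a template is a set of 3 landmark identities plus a reference
subtended angle for each cue pair, with Gaussian tuning (σ_φ = 10°) and a
hard conjunction rule — zero response unless at least 3 template cues are
inside the field of view. The response is the product of the pair-angle
Gaussians over co-visible pairs. The underlying theory states only that
rates depend on the subtended angles; this concrete form, the tuning
width, and the learning schedule are this package's interpretation.

Training initialises each template from a randomly sampled pose (a random
visible triple and its observed angles) and refines it by winner-take-all
competition over a shuffled pass through the pose stream (learning rate
0.1 toward the observed angles).

Maps and classification: the place map is the mean rate per grid place
over head directions; the view map is the mean rate per wall bin at the
point the head-direction ray strikes (36 bins; there is no separate eye
position in this model). Classification compares Skaggs information
`Σ p_i (λ_i/λ̄) log2(λ_i/λ̄)` between a 6×6 place binning and the 36 wall
bins — matched numbers of bins, because plug-in spatial information grows
with bin count and a 1600-bin place map is not comparable to a 36-bin wall
map. A cell is labelled place- or view-like when one information measure
exceeds the other by the ratio threshold (default 2×), mixed otherwise,
unresponsive at zero rate.

Desk scale is a 40×40 place grid with 15° head-direction steps (38,400
poses); the full 200×200 grid at 5° steps (2.88 M poses) runs through the
same code path by passing `grid_n=200, dtheta=5`.

## Gain-field transform chain

Angles use compass convention (0° = north, clockwise positive); the
geometric oracle is `head_centred = ep + rp`, `bearing = hd + head_centred
(mod 360)`, and the viewed location is the bearing ray's intersection with
the arena boundary, expressed on the unrolled perimeter.

Each stage forms the outer product of a Gaussian ring code of its driving
variable (36 centers, σ = spacing) — or, for stages 2–3, the previous
stage's output code — with a ring/grid code of its modulator (8×8 place
grid), selects `ceil(0.06·320)` winners that retain their (rectified)
drive, and learns Hebbian increments whose post-synaptic factor is the
activity trace (η = 0.8), reset between groups. Training presents groups
in which the stage's invariant quantity is fixed while the inputs vary
(5° group steps; 24 exemplars per group; 8 epochs with the learning rate
decaying ×0.7 per epoch from 0.2, so early epochs allocate units and late
epochs consolidate). The graded winners matter for decoding granularity;
the learning-rate schedule and the slow rate favour units that generalise
across a group over units that specialise on single input combinations.

Decoding uses exemplar codebooks — 64 sampled output codes per invariant
bin (16 wall bins, i.e. four per wall, matching the reported scale of
spatial-view fields of roughly a sixteenth of the walls) — with a
5-nearest-exemplar, similarity-weighted circular mean. Exemplars rather
than mean vectors because one bin's code manifold is multimodal across the
nuisance variables (different places produce different codes for the same
viewed location), and averaging the modes blurs neighbouring bins.

`idiothetic_predict` runs the chain along the fovea ray (rp = 0) from eye
position, head direction and place alone — the model's account of
spatial-view firing when the view is obscured. Self-motion noise can be
studied by perturbing those inputs; slow drift over minutes is not
modelled.

## Population information

Leave-one-out cross-validation throughout (the small-sample standard; the
per-trial exclusion is computed analytically, not by refitting). Decoding
is by cosine between the held-out trial and per-stimulus mean training
vectors — the biologically plausible dot-product readout — with raw dot
product behind a flag; exact ties go to the lowest stimulus index, and
near-ties are resolved by nearest mean (Euclidean), which keeps amplitude
information in degenerate cases such as duplicated cells where every
cosine ties. A single cell is decoded by nearest mean rate, since angular
similarity is undefined in one dimension.

Mutual information is the plug-in estimator on the confusion matrix, with
`0·log 0 = 0`. No bias correction is applied by default — fixtures use ≥50
trials per stimulus — and a leave-one-out jackknife correction is available
by flag (`info_from_confusion(..., jackknife=True)`).

The simulated view population places Gaussian view fields (σ = 1 location,
peak 20 Hz) on 16 locations, 20 cells, Gaussian trial noise of 5 Hz
rectified at zero (Poisson optional). This emulates partly overlapping
view fields with independent tuning; it does not emulate noise
correlations, firing-rate distributions with heavy tails, or temporal
codes, so passing tests speak to the decoding pipeline and to the
independence-driven linear information growth, not to those properties of
real recordings.

## Synthetic data: what it does and does not emulate

Random sparse binary patterns stand in for neocortical activity vectors:
they match the sparseness statistics the capacity theory assumes but have
none of the correlation structure of real cortical codes, so measured
capacities are upper bounds for correlated inputs. The arena emulates an
open laboratory with discrete wall cues — no occlusion, no depth, no
retinal image. Correlated episode pairs are generated by keeping a fixed
fraction of a base pattern's active units.

The pattern-separation experiment controls the EC correlation directly
(frozen competitive maps, input pairs sharing 80% of active units, giving
EC overlap ≈ 0.5): with learning on, the unit-norm competitive EC
categorises 50%-correlated inputs onto the same code — the very
generalisation that supports partial-cue recall — so the DG→CA3
decorrelation must be probed downstream of a controlled EC representation.

## Reproducibility and problem sizes

Every experiment takes a seed; a single `numpy` Generator per experiment
is either used directly or split into deterministic child streams. CSV
outputs carry a JSON sidecar with the config echo and hash. The test suite
and the acceptance script run the following sizes: 10-episode recall at
CA3 = 500 over 5–10 seeds; capacity sweeps C ∈ {100, 200, 400} with
CA3 = 1600 over 2–3 seeds; 20 correlated pairs for separation; 40×40×24
pose sweeps with 100 cells for the field-of-view experiment; one trained
transform chain with 200–300 held-out poses plus 3-seed stage-level trace
comparisons; 16 × 20 × 50 information datasets with 5 resamples per
ensemble size; 5-seed sequence replay at CA3 = 200.

## Known limitations

* No spiking dynamics, membrane time constants, theta phase, or graded-rate
  attractors; k-WTA stands in for all inhibition.
* Weights are unbounded reals; no synaptic clipping or decay, so very long
  storage sequences rescale weights without forgetting gracefully.
* The competitive stages either categorise (learning on) or preserve
  similarity (frozen); the model has no intermediate novelty-gated regime,
  which is why separation and partial-cue cleanup are demonstrated in
  different configurations.
* The transform chain is trained with oracle-grouped episodes (temporal
  contiguity of the invariant quantity is assumed, not discovered), and its
  decode resolution is one wall-sixteenth bin; finer bins would need larger
  stages.
* The emergence model has no eye variable: the gaze target is the
  head-direction ray, and view maps are accordingly coarser than
  fixation-resolved data.
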