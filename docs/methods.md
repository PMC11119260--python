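# Methods

## Problem setting

The package targets unsupervised domain adaptation for binary,
class-imbalanced image classification: a labeled source domain
S = {(x_i^s, y_i^s)} with majority class X_maj^s and minority class
X_min^s, and an unlabeled target domain T = {x_j^t} whose class
distribution is also imbalanced.  The goal is a classifier for the
target domain.  The motivating application is cross-site radiograph
screening, where the dominant acquisition difference between sites is
well modelled as a global intensity change and where the clinically
positive class (lesion present) is the rare one.

## Pipeline

Training proceeds in four stages (one outer iteration by default):

1. **Adversarial adaptation (CDA).**  A feature generator F, a
   two-layer class head C and a domain discriminator D are trained by
   alternating updates.  D ascends the domain-confusion objective
   `E_s[log D(F(x))] + E_t[log(1 − D(F(x)))]`; F descends it while F
   and C also descend the supervised/entropy objective
   `−E_s[log C(F(x))_y] + λ · E_t[H(C(F(x)))]` with λ = 0.1.  The
   entropy term sharpens target predictions; an optional
   marginal-diversity bonus (off by default) counteracts class collapse
   if a user needs it.
2. **Pseudo-labeling.**  The trained C∘F argmax-labels every target
   sample; exact ties go to the majority class.  This partitions T into
   X_maj^t and X_min^t.
3. **Minority translation (CMT).**  Two residual encoder–decoder
   generators G: X_maj^s → X_min^t and G′: X_maj^t → X_min^s train
   against patch discriminators D_t, D_s under the objective
   `L_GAN + λ_DT·L_DT + λ_MCC·L_MCC + λ_IDE·L_IDE` with
   (λ_DT, λ_MCC, λ_IDE) = (1, 10, 5) — cycle consistency weighted
   strongest, then identity, then the direct-translation penalty,
   following image-translation convention.  The direct-translation
   penalty is taken over target-majority inputs; a `dt_on_source_majority`
   switch moves it to source-majority inputs.  Discriminator "real"
   pools default to the minority subsets (`real_pool="minority"`) —
   the discriminators exist to judge *minority* realism, and this
   choice produces measurably stronger lesion structure in the
   translations; `real_pool="domain"` instead feeds each discriminator
   its whole opposite domain as real.  After training,
   `X_gen^t = G(X_maj^s)` gives one synthetic target-minority candidate
   per source-majority image.
4. **Selection and balanced training (BTL).**  Each candidate is scored
   with the minority probability C(F(x)).  Samples scoring above
   p_max = 0.95 are discarded (too far from the decision boundary on
   the minority side to be informative) and samples scoring below
   p_min = 0.5 are discarded: a candidate whose argmax class is
   majority would be pseudo-labeled majority by the framework's own
   labeling rule, so giving it the minority label would contradict that
   rule and inject noise — in particular on runs where the translation
   GAN converges to an intensity-only mapping and every candidate still
   looks like a majority image (p_min = 0 disables the floor and
   restores the pure upper-threshold rule).  The remainder are ranked
   by descending score and the top ⌊s·|X_min^t|⌋ kept (s = 1, roughly
   doubling the minority pool).  The
   balanced set T′ = X_maj^t ∪ X_min^t ∪ X_selected^t then fine-tunes
   F and C with plain cross-entropy; class balance comes from the
   resampling itself, not from loss weights.

Evaluation reports Mann–Whitney AUC (minority positive), per-class
recall and balanced accuracy on a stratified 20 % held-out target
slice whose hidden labels are used only for splitting and scoring.

## Adversarial updates: saturation and the non-saturating surrogate

Both adversarial couplings are written in the literal min–max form, but
the literal generator-side gradient `∂/∂z log(1 − σ(z))` vanishes once
the discriminator wins — which it does almost immediately here, because
the raw domain gap (a brightness/contrast offset) is trivially
detectable.  Both the feature-alignment update and the translation
generators therefore default to the standard non-saturating surrogate
(descend `−log D(·)` on the fooled side), which has the same fixed
points but non-vanishing gradients; the literal form remains available
via `adversarial_mode="literal"` / `generator_mode="literal"`.  The
feature-alignment update additionally carries a weight of 0.3 with a
10-epoch linear ramp, so early training is dominated by the supervised
term and alignment strengthens once the class structure is in place.
Without these two choices the adaptation stage reliably *reduced*
target AUC below the source-only baseline in development runs.

## Networks and optimisation

All networks are intentionally small and run on one CPU core:

* F: three stride-2 3×3 conv blocks (16/32/64) + global average
  pooling; C: 64→32→2 dense head; D: 64→32→1 dense with ReLU and
  Dropout 0.5.
* G, G′: two stride-2 conv blocks (8/16), a residual block, two
  sub-pixel (pixel-shuffle) upsampling blocks; the output is
  `clip(x + delta(x), 0, 1)` with the last convolution zero-initialised,
  so an untrained generator is exactly the identity.  D_s, D_t are
  patch discriminators whose spatial-mean logit is squashed to a
  probability.
* Optimiser: Adam, learning rate 2×10⁻⁴ (alignment and balanced
  stages) and 1×10⁻³ (translation stage — the zero-initialised output
  layer needs a faster takeoff at these network sizes), weight decay
  5×10⁻⁴, mini-batch 16.
* Stopping: each stage stops when the moving-average epoch-loss
  variation drops below 5×10⁻⁴ or at the stage's epoch cap
  (60 / 25 / 15 for alignment / translation / balanced training —
  desk-scale caps chosen so a full run takes on the order of a minute;
  the 200-epoch regime remains reachable through configuration).
* Probabilities are clamped to [10⁻⁷, 1 − 10⁻⁷] before every log.
* All randomness derives from a single run seed via named substreams;
  single-threaded runs are bit-reproducible.

The network layers themselves (im2col convolution, dense, dropout,
pixel shuffle, the Adam optimiser) are implemented in NumPy inside the
package with hand-written backward passes; every backward pass is
checked against central finite differences in the test suite.  Layer
caches are LIFO stacks, which lets the translation step run several
forwards through one generator and unwind them in reverse order.

## Synthetic cohorts: what they emulate, and what they do not

`dttl.synthetic` generates the study conditions: 32×32 grayscale
images, 400 majority / 100 minority per domain (imbalance 0.25:1,
matching the order of real screening cohorts), smoothed-noise textured
backgrounds (mean 0.35, amplitude 0.10), bright-disc "lesions" of
amplitude 0.35 and radius 3–6 px at random interior positions, pixel
noise σ = 0.05, and a target-domain shift of contrast 1.4 plus
brightness +0.15 applied before clipping to [0, 1].  Target renderings
reuse the source per-(class, index) seed streams, so at identity shift
the domains coincide exactly and the configured shift is the only
systematic domain difference — convenient for no-gap sanity checks,
though it means the two domains share content variation in a way real
site pairs do not.

The cohort family captures the intensity-shift mechanism of domain gap
and prevalence imbalance, but not anatomy, lesion morphology
variability, annotation noise, or resolution effects.  Passing the
bundled experiments therefore demonstrates that the pipeline's
machinery behaves as designed under a controlled, known shift; it does
not certify performance on clinical data.  A fixed matched-filter
(disc-template) score serves as a training-free separability oracle for
these cohorts and as an independent check that translated images
acquire lesion structure.

On these cohorts the adaptation problem is easier than a real
cross-site transfer: pseudo-labels after alignment are nearly perfect
and held-out AUCs approach 1, so the translation stage's expected net
contribution is close to zero — across seeds its measured effect
fluctuates within about ±0.01 AUC around zero, and with the
argmax-consistent selection floor a failed translation degrades
gracefully to an exact tie with the no-translation ablation.  The
stage is therefore asserted as "does no harm" (full ≥ no-translation)
rather than as a large gain, while the adaptation stage's contribution
(full > no-adaptation, full > source-only) remains clearly visible.

## Numerical and design choices

* Tie-breaks: pseudo-label ties go to the majority class; selection
  ranks by descending score with ascending pool index on ties; the
  retention count uses the floor.
* The selection threshold reads C(F(x)) as the minority-class
  probability, and |X_min| as the pseudo-minority count of the target
  partition.
* Degenerate cases: an empty pseudo-minority (or pseudo-majority) skips
  translation with a warning; a single-class balanced set skips the
  final fine-tune with a warning rather than failing the run; empty
  batches and single-class evaluation sets raise errors.
* The outer loop of the training procedure defaults to one iteration;
  `outer_iterations` re-runs all stages with fresh pseudo-labels, and
  every iteration's partition is archived.
* AUC/ROC are computed through scikit-learn (threshold sweep without
  intermediate-point dropping, so the trapezoidal area reproduces the
  Mann–Whitney statistic exactly); an O(n²) concordance oracle guards
  the equivalence in tests.

## Known limitations

* The adversarial stages are first-order alternating schemes; on hard
  shifts or with aggressive weights they can oscillate.  The defaults
  are chosen for the bundled cohort family and small networks.
* Multi-class targets, perceptual losses, large pretrained backbones
  and DICOM ingestion are out of scope; `arch` accepts a named backbone
  identifier, but none is bundled.
* The translation stage's adversarial pools admit two readings
  (whole-domain vs minority-restricted "real" samples); both are
  implemented.  The whole-domain reading produces weaker lesion
  structure, which is why the minority-restricted reading is the
  default.
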