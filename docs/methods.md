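# Methods

## Scope and model of the data

The package evaluates instance segmentation of cyanobacteria in timelapse
microscopy and classifies per-cell phenotypes from multi-channel images.
Its unit of data is the *labeled mask*: a 2D non-negative integer image in
which 0 is background and each positive value identifies one cell.
Labels are opaque identifiers — they need not be contiguous integers and a
label's pixel set need not be connected, because exported model outputs
can be fragmented. The evaluator therefore keys objects by label, never by
connectivity. Masks travel as multi-page integer TIFF (one page per
frame); image frames are ordered channel stacks of up to 6 channels
(brightfield plus fluorescence), the limit the classification framework
accepts.

## Pixel-level scores

Pixel metrics binarize both masks to foreground and count shared
(`tp`), pred-only (`fp`) and gt-only (`fn`) pixels:

    IoU = tp / (tp + fp + fn),  precision = tp / (tp + fp),
    recall = tp / (tp + fn).

Zero-denominator ratios are reported as 0, except comparison of two
entirely empty movies, which is reported as 1 with a `vacuous` flag:
empty-against-empty is truthfully perfect agreement, and returning NaN
would poison aggregation. Movie-level scores are micro-averaged — counts
are pooled over frames before ratios are formed — so sparse frames do not
dominate. One known ambiguity: IoU over instance *bounding boxes* is an
alternative definition sometimes attached to these scores; the pixel-set
reading implemented here is the self-consistent one (it satisfies
`IoU <= min(precision, recall)` on the same counts) and is what the
per-pixel counting procedure actually computes.

These scores deliberately under-report instance-level mistakes: a
single-pixel cut splitting one cell into two moves a handful of pixels but
doubles the object count. That failure mode motivates the object-level
taxonomy.

## Object-level error taxonomy

Predicted and ground-truth objects are matched into a bipartite *overlap
graph*: an edge `(g, p, w)` exists iff labels `g` (gt) and `p` (pred)
share exactly `w > 0` pixels. Insignificant overlaps are pruned by the
rule

    keep (g, p, w)  iff  w > tol * min(area(g), area(p)),   tol = 0.10,

i.e. roughly 10% discrepancy between masks is ignored. Referencing the
*smaller* area keeps the rule symmetric under gt/pred exchange and
prevents a tiny spurious object from "matching" a large cell through a
sliver of overlap. The inequality is strict so `tol = 0` degenerates to
keeping every positive overlap. Connected components of the pruned graph
are then classified: a 1:1 component is a correct match; 1:n (n ≥ 2) is
one over-segmentation; m:1 (m ≥ 2) one under-segmentation; m:n (both ≥ 2)
one of each; an isolated gt node is a false negative and an isolated pred
node a false positive. Per-frame reports sum element-wise into a movie
report.

Counting is per *event* by default: a cell split into five fragments is
one over-segmentation, not four. The alternative per-*fragment* convention
(n−1 and m−1 per component) is available as `count_mode="fragment"`,
because published error totals do not always state which convention they
use. Under event counting the taxonomy has a clean symmetry — swapping gt
and pred exchanges over/under-segmentation and false negatives/positives
— which the test suite checks on random instances, along with invariance
under arbitrary relabeling.

## Synthetic fixtures and the planted-error oracle

Real benchmark movies are typically unavailable, so correctness is
established against generators with exactly known answers.

**Geometry.** Rod masks place capsule-shaped cells (default length 12–22
px, width 5–8 px, ≥ 2 px mutual clearance) by rejection sampling,
emulating dispersed unicellular strains at typical 60×–100× magnification
scales. Filament masks chain touching capsules along smoothly curving
paths with distinct labels per cell, emulating filamentous strains whose
neighboring cells share boundaries; each filament's contact graph is a
path.

**Corruptions.** `corrupt_mask` plants a requested number of each error:
splits cut one object with a 1-px background line through its centroid
(the fragment on each side keeps/receives a label); merges relabel one
member of a near-touching pair to its neighbor's label and paint a thin
cosmetic bridge; deletions remove an object; additions grow 3–8 px blobs
in background with ≥ 2 px clearance. Sub-tolerance *jitter* then perturbs
each untouched object's boundary by strictly less than `jitter_frac` of
its area. The operators are constructed so the planted counts are provably
what the evaluator must report, not just usually: split fragments stay
inside the parent footprint (each retains > tol of its own area by
construction), bridges and jitter additions are painted only where both
masks are background (so no unplanned overlap edge can appear), spurious
blobs keep clearance from everything, and disjoint object sets are used
for the different operators. When a mask cannot support a plan (no
bridgeable pair, too few objects) the counts are reduced with a warning
and the *achieved* plan is returned — the oracle remains exact. The
acceptance suite verifies exact agreement on 500 random
(mask, plan) instances over both geometries.

**Phenotype patches.** The 4-class localization dataset renders one
centered capsule cell per 32×32 patch. The brightfield-like channel shows
a dark rim with a flat, near-background interior (the low-contrast look of
transmitted light) for every class; the fluorescence channel follows the
class model: *none* (detector noise only), *diffuse* (uniform fill over
the footprint), *puncta* (several σ ≈ 1.3 px Gaussian spots with a ≥ 4 px
pairwise separation so the class genuinely shows multiple distinct spots),
*focus* (one brighter σ ≈ 1.8 px spot). Intensities carry Gaussian read
noise and optional Poisson shot noise. Default levels (background 100/10
ADU, rim 60, signals 45–160 ADU) give signal-to-noise comparable to
routine fluorescence imaging — separable, but not trivially so through
the per-patch standardization the network applies. `generate_classified_frame`
renders whole frames with the same per-cell models and the same cell
morphology distribution as the patch generator, and spaces cells widely
enough (≥ 12 px) that a 32×32 centroid crop contains essentially one
cell — the training patches are single-cell by construction, so the frame
fixture tests transfer under matched conditions. Densely packed fields
break that match: a crop then carries neighboring cells' fluorescence,
and an unlabeled cell with a neighbor's focus in view is prone to be
called a focus. That degradation is expected of centroid-crop
classification generally, not a defect of this implementation, and dense
packing is deliberately out of this fixture's scope.

What the fixtures do *not* model: optics (PSF beyond isolated Gaussian
spots), uneven illumination, focus drift, cell growth and division,
photobleaching, autofluorescence gradients, and the dense colony packing
of late-movie frames. Passing these tests shows the algorithms are
correct and the pipeline is wired properly; it does not certify
performance on any particular real dataset.

## The patch classifier

The network is four blocks of [3×3 convolution → batch normalization →
leaky ReLU → 2×2 max pooling, stride 2] followed by one fully connected
layer over the flattened 2×2 features, softmax on the logits. Default
filter widths are (16, 32, 64, 128), so the fully connected layer sees
512 features; widths are configurable. The input is fixed at 32×32 pixels
(about 1.5–2 cell lengths, so a crop carries some neighborhood context)
and at most 6 channels. Training minimizes cross-entropy with Adam at
learning rate 1e−4 for exactly 60 epochs — no early stopping — with batch
size 64. No augmentation is applied by default. Patches are standardized
per patch and channel (zero mean, unit variance) so the network sees
contrast, not camera offsets.

The layers are implemented directly in numpy with explicit
forward/backward passes (convolution as im2col matrix multiplication,
batch-norm with running statistics for inference, max-pool gradients
routed by window-max comparison). The network is small enough that a full
60-epoch run on the 2,000-patch default dataset takes a few minutes on
one CPU core; gradient correctness is established by finite-difference
tests per layer. Initialization is He-normal from a seeded generator, and
batch shuffling uses a generator derived from the same seed, so training
is bit-reproducible on a fixed platform.

Inference crops a 32×32 window at each object's mask centroid (unweighted
mean of pixel coordinates, rounded half-away-from-zero; window
`[c−16, c+16)`), with reflection padding at image borders. The output
table has one row per (frame, label): centroid, the full probability
vector, and the argmax class (ties broken toward the lowest class index).
Class maps recolor each object's pixels to `class index + 1`, keeping
class 0 distinct from background.

Classification is scored by a truth-by-prediction confusion matrix and
micro-averaged precision, recall and Jaccard (IoU) pooled over cells. For
single-label multi-class data the pooled precision and recall both equal
the accuracy `a`, and the pooled Jaccard equals `a / (2 − a)`; reporting
all three keeps the output comparable with conventions that report them
separately.

## Numerical and design choices

- Overlap tallies use one sparse contingency accumulation over the two
  flattened label images; component analysis uses an explicit bipartite
  graph, so the cost is linear in pixels plus near-linear in objects.
- The tolerance default 0.10 is deliberately approximate and exposed
  everywhere (`ToleranceConfig`, `--tol`); it applies to overlap fraction
  of the smaller object, one of several readings of "10% discrepancy" —
  area-difference and boundary-displacement readings exist but are harder
  to make symmetric and scale-free.
- Empty inputs: empty masks are valid everywhere (empty inventories,
  vacuous-perfect pixel scores, all-zero error reports); writing an empty
  movie is refused; labels that would overflow the chosen TIFF bit depth
  raise rather than wrap.
- Jitter changes strictly fewer than `jitter_frac · area` pixels
  (`floor`, decremented at exact multiples), which is what makes the
  "jitter below tolerance ⇒ zero errors" property provable rather than
  statistical.
- Train/validation handling is left to the caller (the bundled runs use
  disjointly seeded generator draws); the trainer only warns when a class
  is absent from the training set.

## Problem sizes in bundled runs

The test suite and the acceptance script size their runs for a single CPU
core: 500 planted-error instances on 160² images with 8–26 cells, 100
jitter masks, 100 pixel-oracle pairs, 50 symmetry/permutation instances,
and classifier runs with 500 training + 125 held-out patches per class
(three seeds) plus a 200-patch-per-class negative control. These are the
package's reference conditions; all counts are parameters, so larger
studies are one function call away.

## Known limitations

- The error taxonomy reports event counts, not severities; a 2-cell merge
  and a 10-cell merge both count one under-segmentation (per-fragment
  mode refines this but still ignores geometry).
- Chained partial overlaps collapse into one m:n component; the taxonomy
  does not attribute which specific boundary caused the chain.
- The classifier processes cells independently per frame; no temporal
  smoothing across a track, although phenotypes are often persistent.
- Synthetic fluorescence classes are cleanly separable by construction;
  real intermediate phenotypes (e.g. partially condensed foci) will land
  between classes and are not modeled.
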