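# Methods

This note documents the models, conventions and numerical choices behind
`ivus_texturekit`, in the spirit of a package reference manual: what is
computed, under which assumptions, and where the design was genuinely open.

## Feature extraction

All features are computed per plaque pixel from a window centered on it.
The plaque mask constrains window *centers* only; window *contents* near the
frame border are obtained by reflect-padding the frame (mirror without edge
repetition, `numpy.pad(mode="reflect")`). Discarding border pixels instead
would silently shrink the labeled set, and the mask region is thin enough
that this matters.

**First-order statistics (5).** Population moments over all 25 window
pixels (normalizer 1/25): mean, variance, standard deviation, skewness, and
*excess* kurtosis. For a zero-variance window skewness and kurtosis are
defined as 0 rather than NaN, keeping feature vectors finite.

**GLCM (17).** The window is quantized to Ng = 16 uniform bins over
[0, 255] (`level = floor(g·Ng/256)`); 256 raw levels over 25 pixels would
give a near-diagonal degenerate matrix, and 16 is a standard radiomics
default. Ordered pairs are accumulated at distance d = 1 and angle 135°,
i.e. (r, c) paired with its upper-left neighbor (r−1, c−1), single
direction, normalized by the number of valid pairs (16 in a 5×5 window); a
symmetric mode is available via config. The 17 features follow the standard
Haralick definitions with 1-based bin indices and natural logarithms;
0·log 0 := 0. Two names needed a variant choice: "information measure of
correlation" is the first Haralick variant IMC1 = (HXY − HXY1)/max(HX, HY),
defined as 0 when both marginal entropies vanish, and "normalized inverse
difference moment" is Σ p(i,j) / (1 + (i−j)²/Ng²). Sum/difference-based
features use the distributions of i+j and |i−j|; "difference variance" is
the variance of the |i−j| distribution.

**Laws energy measures (18).** The nine 5×5 masks are outer products of the
standard vectors L5 = [1,4,6,4,1], E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1],
R5 = [1,−4,6,−4,1]: E5L5, S5L5, R5L5, E5E5, S5E5, R5E5, S5S5, R5S5, R5R5,
with asymmetric pairs replaced by the mean of mask and transpose. (W5 is
part of Laws' original family but not of this nine-mask set.) Each mask is
cross-correlated with the reflect-padded window, yielding a same-size 5×5
texture image — the energy statistics average over I×J responses, which
requires an image, not a single valid sample. MSS is the mean of squared
responses, MAS the mean of absolute responses. Correlation versus true
convolution only flips the sign of masks with one E5 factor, which the
energy statistics ignore.

**Extended GLRLM (11).** Runs of equal quantized level (Ng = 16) are
extracted along horizontal scan lines by default (θ configurable; 0°/90°
run vectorized, diagonal angles through the per-window path). From the
run-length matrix P(i, j) with Nr runs over Np = 25 pixels: SRE, LRE, GLN,
RLN, RP = Nr/Np, plus the six gray-level-weighted extensions LGRE, HGRE,
SRLGE, SRHGE, LRLGE, LRHGE, all with the standard normalizations (1/Nr) and
the 1-based bin index as the gray-level weight.

**LBP (2).** The 8 neighbors of the 3×3 window are read clockwise from the
top-left; bit n carries weight 2^n. The sign function maps a *nonnegative*
difference to 1, so a flat neighborhood codes as 255. LBP^riu2 is the
number of set bits when the circular 0/1 transition count U is at most 2,
else N+1 = 9. U is even for any circular pattern, so the U ≤ 2 / U > 2
dichotomy is the only self-consistent reading of the uniform criterion.

**Intensity (1)** is the raw center-pixel value, never quantized — it later
drives the routing threshold, which is why frames with out-of-range values
are rejected at load time instead of clipped.

Two implementations of the features coexist: definitional per-window
functions and a vectorized whole-frame path used by `extract_all` (dense
per-chunk co-occurrence/run-length accumulation, Laws responses as a single
25×25 linear operator per mask that encodes the window-local reflect
padding). The test suite pins both to each other and to independent
brute-force oracles (exhaustive pair enumeration, scan-line traversal,
nested-loop convolution, literal moment formulas) to 1e-9.

## Feature selection

PCA does not by itself select named features; the package maps retained
components back to the originals. Columns are z-scored (population std;
zero-variance columns are excluded from standardization and can never be
selected), the correlation matrix is eigendecomposed, and the fewest
components with cumulative explained variance ≥ 0.95 are retained. Each
feature's score is its maximum absolute loading (eigenvector entry ×
√eigenvalue) over the retained components; the selection is the top-k by
score (defaults k = 21/15/18 for nets 1–3) or, without k, all features
above a score quantile. Determinism is enforced by a sign convention (the
largest-magnitude entry of each eigenvector is made positive) and a
canonical-order tie-break for scores equal within 1e-12. The stored
(center, scale) pair is reused verbatim at prediction time. An
`always_include` list can guarantee named features a slot regardless of
rank; the pipeline uses it to keep raw intensity in the two leaf nets (see
the appendix for why no unsupervised loading rule surfaces it reliably).

## Multi-level classifier

The routing threshold is the maximum gray value over training-FT pixels
(`percentile=100`); a lower nearest-rank percentile is available as a guard
against single outlier FT pixels. Routing is strict — intensity > T goes
high — so the FT maximum itself stays on the low side. Consequences of this
architecture worth knowing: any FFT pixel brighter than every training FT
pixel is structurally forced into NC/DC, and the NC/DC pixels *below* T are
exactly the dark speckle tail of the bright classes, which is why net 1's
sensitivity (positives = NC/DC among low-intensity pixels) trails its
specificity on the phantom.

Nets are `sklearn` random forests with 100 trees, depth ≤ 10 and a fixed
seed (`random_state = seed + net_id`); other forest details are library
defaults recorded in the model JSON. Training pools follow tissue identity,
not cascaded routing: net 1 trains on low-intensity pixels with the group
label, net 2 on all FT/FFT pixels, net 3 on all NC/DC pixels. Positive
classes are NC/DC-group, FFT, and DC respectively. Scores are
positive-class probabilities (tree-averaged vote fractions, granularity
~1/100). Each net's pool is optionally subsampled to a seeded random
40 000 pixels by default — forests saturate well before the full ~10^5-pixel
pools, and this keeps end-to-end runs to minutes.

## Evaluation

Sensitivity, specificity and accuracy are percentages of the per-net binary
confusion counts; accuracy is algebraically the prevalence-weighted mix of
the other two (property-tested). ROC curves sweep every distinct observed
score and AUC is the trapezoid area, equal to the tie-adjusted pairwise
concordance probability (oracle-tested to 1e-12). Per-net evaluation pools
follow ground truth by default, mirroring the training-pool convention;
`routed_pools=True` evaluates each net on the pixels the cascade actually
sent it. High-intensity pixels with FT/FFT ground truth have no defined
NC-vs-DC truth; they are excluded from net-3 binary metrics and reported as
`n_foreign_high`. Reports record the split used, since any train/test
partition convention (per-frame here) must travel with the numbers.

## Phantom generator

The phantom emulates one annotated IVUS cross-section: an annulus
r1 < r ≤ r2 (defaults 70/120 px in a 400×400 frame, ≈ 30 k plaque pixels)
partitioned into contiguous class blobs by nearest-seed assignment with two
Lloyd relaxation passes to even out blob areas; classes then claim cells
largest-first by remaining target deficit, so empirical class fractions
track the requested mixing proportions (1/4 each by default, 6 blobs per
class) to within about a point.
Pixel values are μ_class × speckle with unit-mean gamma speckle
(shape 1/σ², sd σ, default σ = 0.1) — multiplicative, so local contrast
scales with brightness as in coherent ultrasound, and texture features gain
class information beyond the raw mean. Default means 60/90/150/210 for
FFT/FT/NC/DC are artifact conventions respecting the clinical brightness
ordering (DC most echogenic). The lumen (15) and exterior (35) are filled
with the same speckle law. Everything derives from the spec seed; datasets
use per-frame child seeds from `numpy.random.SeedSequence`.

The `hard_ft_fft` preset narrows the FT/FFT brightness gap (86 vs 80) while
separating their speckle scales (σ 0.05 vs 0.16), making intensity nearly
uninformative for net 2 and forcing texture-driven discrimination.

What the phantom does *not* model: beam-formed point-spread anisotropy,
attenuation with depth, catheter ring-down and guidewire artifacts,
speckle's spatial correlation, or the irregular geometry of real plaque.
Passing the held-out recovery checks therefore demonstrates that the
pipeline is implemented correctly and that texture carries class signal
under controlled conditions — not that clinical-grade accuracy would be
reached on patient pullbacks.

## Problem sizes and defaults

The default study runs 5 training + 2 held-out 400×400 frames
(≈ 210 k feature rows) with per-net training capped at 40 k pixels; the
hard-regime comparison uses 3 + 1 frames. These sizes give stable estimates
(held-out metrics move by well under a point across seeds) at a few minutes
of single-core compute. `RunConfig` exposes every knob (window sizes, Ng,
GLCM distance/angle, GLRLM angle, variance target, per-net k, forest
parameters, threshold percentile, seed), and defaults reproduce the stated
method settings throughout.

## Known limitations

* GLCM uses a single direction/offset; no multi-angle averaging.
* The FT-max threshold is brittle to labeling noise in real data (one
  mislabeled bright FT pixel raises T for every frame); the percentile
  option mitigates but its clinical calibration is out of scope.
* The PCA-loading selection rule is one defensible reading of
  "PCA selects original features"; supervised selectors are out of scope.
* Evaluation does not implement cross-validation protocols; the caller owns
  the split.

## Appendix: why intensity is force-included in the leaf nets

Under multiplicative speckle the window standard deviation is proportional
to the local mean, so the brightness features (intensity, window mean,
autocorrelation, sum average) are strongly collinear with the much larger
texture-energy block and never dominate a retained principal component on
their own. A purely loading-ranked subset can therefore drop every
brightness feature for a leaf net, crippling FT-vs-FFT discrimination even
though brightness is its single best input. Because the cascade is
intensity-based by design — the routing stage already treats intensity as
special — the pipeline guarantees the raw intensity feature a slot in nets
2 and 3 (`always_include`), leaving net 1, whose input pool the threshold
has already confined to a narrow brightness band, fully loading-ranked.
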