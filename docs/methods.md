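# Methods

## Measurand and geometry conventions

The central measurand is the minimal Feret diameter of a particle's 2-D
projection — the smallest caliper width over all directions — used as a
proxy for the minimal external dimension of a constituent particle.
All geometry runs on simple polygons in nm with the origin at the
top-left pixel corner, x right, y down, and pixel centers at
half-integers.  Segmentation masks are converted to polygons by the
*pixel-corner* convention (the outline is the boundary of the union of
pixel squares), which makes the 10-pixel lower quantification rule
exact: a particle spanning 10 pixels has a hull caliper width of
exactly 10 pixel edges.  Whether the original interactive software
measures on pixel corners or centers is not documented; the corner
convention is fixed here and stated.

Feret diameters are evaluated on the convex hull.  The minimal width of
a convex polygon is attained with one caliper flush against a hull edge,
so the rotating-calipers evaluation (minimum over edges of the
farthest-vertex distance to the edge line) is exact; the maximal Feret
diameter is the hull diameter (maximum pairwise vertex distance).  The
independent test oracle is a directional sweep: widths on a 0.01° grid,
sharpened by a ternary search around the best grid angle because the
width function is V-shaped (not smooth) at its minimum and a bare grid
is only step-accurate.

Ellipse axes come from second-order moments (polygon moments via
Green's theorem, or `regionprops` on masks); for an exact ellipse the
fitted axes equal the true axes.  Convexity of a polygon is
area/hull-area; convexity of a digitised mask uses pixel solidity
(particle pixels over convex-image pixels) so that a digitised convex
particle scores ≈ 1 despite corner-cutting.  The equivalent circular
diameter is `ECD = √(4A/π)`.

## Working range

For an n-pixel camera imaging a field of view F: LOD = F/n (one pixel),
LLOQ = 10·F/n (10-pixel rule, below which digitisation bias dominates),
ULOQ = F/10 (border-truncation risk).  ULOQ/LLOQ = n/100 independent of
magnification (≈ 40 for n = 4096).  Report rounding: LOD to two
decimals, LLOQ/ULOQ to one.  The microscope's own line resolution is
metadata only; at practical magnifications the pixel size is the
binding limit.

## Segmentation

Preprocessing: total-variation denoising scaled by a single smoothing
factor (exactly the identity at zero), polarity inversion (bright-field
particles dark → objects positive), and background flattening by grey
opening with a flat structuring element of a quarter of the image edge
— several times larger than any quantifiable particle — followed by a
median re-zeroing, since the opening rides the lower noise envelope.
Thresholding is Otsu's inter-class-variance criterion; each connected
candidate must additionally clear a minimum object-to-background
contrast (min-OTB, in normalised [0,1] intensity units, default 0.15)
measured as its median corrected intensity, which suppresses
noise-level detections and makes detection count monotone
non-increasing in min-OTB.

Mode dispatch:

* **default** — per-component distance-transform watershed with peaks
  at least 0.7 × (max inscribed radius) apart; splits touching
  near-convex blobs, leaves single blobs alone.
* **irregular_watershed** — deliberate over-segmentation (0.35 factor)
  followed by greedy merging of adjacent fragments while the union's
  solidity stays ≥ 0.92 (configurable) and does not fall below the
  parts'; elongated irregular particles (rods) are re-assembled while
  genuinely distinct touching particles, whose union is concave, stay
  split.  The original plugin's merge criterion is not published; this
  convexity rule is this package's own design and is config-exposed.
* **ellipse_fitting** — watershed splitting as in default, then a
  moment-fitted ellipse per fragment; the reported minimal Feret
  diameter in this mode is the fitted short axis (the hull caliper
  width is kept in a separate column for provenance).
* **single_particle** — no splitting; only blobs with solidity ≥ 0.95
  (configurable, logged) are retained, i.e. the free-lying particles
  used as size proxies for constituent particles of dense aggregates.
  Star-convex irregular singletons sit around solidity 0.9, so
  analyses of such materials use a material-optimised cut (~0.88), the
  same settings-optimisation step the measurement procedure prescribes
  for real materials.

Quantification filters retain `LLOQ ≤ F_min ≤ ULOQ` (lower bound
inclusive) and by default drop border-touching particles, whose
truncated outlines bias F_min low.  All stages are deterministic.

## Distribution summaries

Specimen statistic: the sample median of the pooled minimal Feret
diameters of one TEM specimen's image set (even-n rule: mean of the two
central order statistics).  For trueness against certified *modal* ECD
values, the mode is the location of a maximum-likelihood normal fit to
the raw ECD values (equal to the sample mean), deliberately independent
of histogram binning; Freedman–Diaconis histograms are display-only,
and on skewed samples the fitted location intentionally differs from
the histogram peak (both are available).

## Uncertainty budget and trueness

Design: 5 days × 3 replicate specimens (matrix of 15 specimen medians).
One-way ANOVA with day as factor gives, relative to the grand mean C_m
(components in %):

    u_r   = 100·√MS_within / C_m
    u_day = 100·√((MS_between − MS_within)/n_r) / C_m        if MS_between > MS_within
          = 100·√(MS_within/n_r)·(2/ν)^(1/4) / C_m           otherwise (ν = n_days(n_r−1))

The degenerate branch is the standard upper estimate for an
undetectable day effect, keeping u_day real and non-negative.  Then
u_IP = √(u_r²+u_day²), u_t = √(u_t,CRM² + u_IP²),
u_c = √(u_IP² + u_t² + u_cal²), U = 2·u_c (coverage factor 2, ≈95%).
Budgets are carried in relative %, trueness in nm:
Δ_m = |C_m − C_CRM|, u_Δ = √(u_c² + u_CRM²), U_Δ = 2u_Δ, and "no
significant bias" iff Δ_m ≤ U_Δ.

u_cal is a supplied per-magnification constant (1.0% at 18,500×, 0.8%
at 9,300×, 0.2% at 68,000×, 0.1% at 30,000× by default); magnification
calibration itself is out of scope.  u_t,CRM defaults: for the two
silica CRMs, their own k=1 modal-ECD uncertainty relative to the
certified value (0.65 nm/19.4 nm ≈ 3.35% and 0.75 nm/27.8 nm ≈ 2.70%
— the published budget components back-solve to these values, whose
rounded forms 0.7/0.8 nm appear in the trueness table); materials
without a reference get the mean of the two (≈ 3.02%).

Ruggedness versus particle count: each specimen pool is subsampled to N
particles without replacement (n_boot times, averaged), the medians
matrix and u_IP recomputed per draw, and the curve fitted piecewise
(single breakpoint chosen by least total residual over candidate grid
points — the breakpoint rule is this package's choice) in
log10–log10 space.  For iid pools the sample-median standard error
scales as N^(−1/2), so the slope is −0.5; a real day effect puts a
floor under the curve.  The reported rule is the smallest grid N with
mean u_IP < 5%.

## Interlaboratory evaluation (ISO 5725-2)

Outlier screening per pass: Cochran (largest internal variance over the
sum of variances), internal Grubbs (one replicate within a lab), single
Grubbs (one lab mean), double Grubbs (the two most extreme lab means).
One finding is removed per pass — a single anomalous replicate before
any whole laboratory, since a gross replicate would otherwise cost the
entire lab via Cochran — then the battery re-runs; stragglers (between
the 5% and 1% critical values) are logged but kept, and exclusion stops
at the ISO practice bound of 2/9 of the laboratories.  The exact
iteration order used in the original study is not published; this order
is fixed and logged.

Critical values are computed, not tabulated: Grubbs from the
t-quantile closed form G = (n−1)/√n · √(t²/(n−2+t²)) with
t = t(1−α/2n, n−2); Cochran from the F-quantile relation
C = F/(F+k−1) with F = F(1−α/k; ν, (k−1)ν).  Both reproduce published
tables to ~2·10⁻³.  The double-Grubbs statistic (trimmed-SS ratio) has
no closed-form null; its critical values are the lower α-quantiles of
the *minimum* of the two pair ratios for n standard normals, by seeded
Monte Carlo (2·10⁵ draws, cached per n) — this min-of-pairs convention
reproduces the published ISO values (e.g. 0.1150 at 1%, n=10).

Precision: lab-factor ANOVA with the unbalanced effective replicate
count n̄ = (N − Σnᵢ²/N)/(p−1); S_r² = MS_within,
S_L² = max(0, (MS_between − MS_within)/n̄), S_R² = S_r² + S_L² (so
S_R ≥ S_r by construction), r = 2.8·S_r, R = 2.8·S_R
(2.8 ≈ 1.96·√2).

## Synthetic scenes

The generator emulates the four morphology classes: disjoint
near-spherical colloids; touching/slightly overlapping ellipsoids
(aspect 1.2–1.8, pairwise overlap ≤ 10% of the smaller area);
agglomerated stadium-shaped rods (aspect 2.5–3.5); and dense aggregates
of perturbed star-convex particles (mean cluster size 6, overlap up to
35%).  The size law governs the minimal Feret diameter exactly: each
96-gon outline is scaled so its caliper width equals the drawn size,
then randomly rotated; stored truth values are computed from the exact
polygon, so the truth table is an oracle for the measurand chain.
Cluster members are attached by bisecting the center distance to a
target overlap fraction; clusters and free particles stay disjoint with
a minimum gap of 3 pixels so rasterised masks cannot fuse.  Rendering
is bright-field (particles multiply the background by a transmittance
of 0.30 against a 0.78 background level; overlap does not darken
twice), with an optional low-order planar background gradient, Poisson
shot noise (default dose 2000 counts at full scale, SNR ≈ 40) and
Gaussian read noise (default 0.01) — a minimal CCD model.  Everything
derives from one integer seed and is bit-reproducible.

What the simulator does *not* emulate: electron-optical image
formation (defocus, astigmatism, diffraction or thickness contrast),
specimen drift, partial-volume edge profiles (rasterisation is binary
at pixel centers), matrix/contaminant phases, and truly fused
aggregates without boundary concavities.  Passing recovery tests
therefore demonstrates correctness of the analysis chain on idealised
contrast, not performance on difficult real materials; the noise and
background amplitudes are free knobs, not calibrated to any instrument.

## Verification design and problem sizes

Tests pin exact hand-derivable geometry (altitudes, hull areas, moment
algebra), compare the calipers against the refined sweep oracle and
shapely's rotated rectangle (as a bound), and check the statistics
against scipy's one-way ANOVA and published critical-value tables.
Synthetic recovery studies use: a 2048² scene of 520 disjoint lognormal
disks (median 20 nm at 0.6 nm/pixel, ≈ 33 pixels across, where the
half-pixel digitisation bias is ≈ 1.5%) requiring exact detection count
and median error < 2%; a 1024² touching-ellipsoid scene (200 particles)
requiring ellipse-mode median error < 5%; 10⁴ Monte-Carlo 5×3 designs
for variance-component recovery, compared on the variance scale (u²),
where the ANOVA estimators are unbiased, within 3 MC standard errors;
ruggedness pools of 16 000 particles per specimen over N = 25…800; and
10⁴ homogeneous interlaboratory tables for the 1% type-I calibration of
Cochran (10 labs × 3 replicates) and Grubbs (15 lab means).

Published-table closure is asserted to the half-ULP rounding
propagation bound of each cell: every printed input carries ±0.05, so a
recomputed combination can differ from the printed result by up to
0.05·Σ|∂f/∂xᵢ| plus 0.05 for the printed output's own rounding; the
published budget table is internally inconsistent beyond plain
one-decimal re-rounding (e.g. one column prints u_r = 1.7, u_day = 0.6
next to u_IP = 1.7, while √(1.7²+0.6²) = 1.80), and the bound is the
tightest claim the printed precision supports.

## Known limitations

Watershed peak spacing (0.7 × inscribed radius) can split very
elongated convex particles in default mode — by design, that morphology
belongs to irregular-watershed mode.  Ellipse-mode axes inherit the
moment distortion of watershed cut lines in heavily overlapping
clusters.  The min-OTB veto uses the median component contrast, so a
particle half in a dark gradient is kept or dropped as a whole.  The
uncertainty calculus assumes a balanced complete day×replicate design;
incomplete designs are rejected rather than approximated.
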