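# Methods

## Exact-mass arithmetic

Monoisotopic masses use the NIST/IUPAC isotope table shipped with
pyteomics (≥ 6 decimal places) and the CODATA electron mass. Positive ions
subtract one electron mass per charge; without this correction a singly
charged ion is off by ~0.55 mTh and 4-decimal annotations such as
cholesterol [M+NH₄]⁺ 404.3887 fail at the last digit. Display rounding is
half-even at 4 decimals; internal values are never rounded. The built-in
adducts are [M+H]⁺, [M+H−H₂O]⁺, [M+NH₄]⁺, [M+Na]⁺ and the radical cation
[M]⁺˙ (used for the fluoranthene lock mass); charge states above 1 and
negative mode are out of scope.

Isotope envelopes are computed by per-element self-convolution (binary
exponentiation) of single-atom isotope distributions, aggregated by integer
nucleon-number offset with abundance-weighted centroid masses, truncated to
the requested number of peaks and renormalised. Aggregation by nucleon
offset (rather than resolving fine structure) matches how an
Orbitrap-resolution envelope is displayed and compared. The test suite
checks the convolution against an exhaustive isotopologue-enumeration
oracle on formulas up to ~80 atoms (agreement ≤ 10⁻⁶ in relative
abundance). Ion envelopes are computed on the ion composition with the
electron-mass correction, not by shifting the neutral envelope.

## imzML model

Only processed-mode (per-pixel centroid) imzML 1.1 is supported, the form
centroided Orbitrap MSI data takes; m/z is stored as float64, intensity as
float32. imzML coordinates are 1-based (x = column, y = row); internal
indices are 0-based. Missing pixels inside the grid are legal (damaged or
thin sections leave holes); they contribute nothing to masks or means.
Empty spectra cannot be represented in processed imzML, so acquired-but-
empty pixels read back as missing. Metadata with no imzML controlled
vocabulary (condition, replicate, solvent, ice matrix) travels in a YAML
sidecar next to the file. When a dataset UUID is supplied (the cohort
writer derives one from the seed and replicate id), writing is
byte-deterministic; the embedded run id is the bare file stem so the bytes
do not depend on the output directory.

## Ion-image extraction

The extraction window is half-open, [mz·(1−tol·10⁻⁶), mz·(1+tol·10⁻⁶)), so
adjacent windows partition the axis and a centroid can never be counted
twice. The default tolerance is ±5 ppm — twice the instrument's stated
±2.5 ppm mass accuracy, leaving headroom for jitter at the window edge.
The default reducer sums in-window centroids, matching abundance semantics
in charges/s; `max` is available. Extraction runs off a cached global m/z
sort of the image with comparisons on the raw m/z values, and the test
suite asserts bitwise equality with a per-pixel linear scan. No TIC
normalization is applied by default (raw abundances are reported); the CLI
exposes `--tic-normalize`.

Colocalization reports Pearson r over masked acquired pixels plus an
overlap fraction: pixels above each image's own Otsu threshold in both
images over those above threshold in either. Overlay rendering normalises
each channel to its own maximum and blends additively.

## ROI statistics

Ten disjoint square ROIs per quadrant (40 total) are placed by
uniform-random rejection sampling over the positions whose full footprint
lies inside the tissue mask and the region, deterministically per seed.
The ROI side defaults to 3 pixels — the largest size that comfortably fits
ten disjoint squares in the smallest quadrant at the default grid — and
the ROI statistic is the mean (not the sum) over acquired ROI pixels, so
results are invariant to ROI size. Log abundance is log₁₀(mean + floor)
with the detection floor as additive offset, keeping fully censored ROIs
finite.

The three z-score schemes stratify by (replicate, species), by
(condition, species) and by (condition, region, species); each stratum is
centred and scaled by its sample SD, computed within condition exactly
because the two tissue conditions are normalised separately. A
zero-variance stratum (a species fully censored in a region) yields z = 0
with a warning. By construction the replicate scheme removes per-replicate
systematic offsets while the global and region-global schemes retain them
— an offset replicate shows the same elevated mean in all four regions
under region-global normalization, which is the diagnostic signature of a
systematic (non-biological) offset. The ±0.5 SD homogeneity statement is
therefore a property of the replicate-normalised scheme and is tested
there.

## Differential analysis

Whole-tissue species abundance is the per-replicate mean of the species'
summed-adduct image over an Otsu TIC tissue mask. The volcano statistic is
the difference in mean log₂ abundance; the test is Welch's two-sample
t-test on log₂ values (the choice of test is open in this design — Welch
is the volcano convention for heteroscedastic small samples; Mann–Whitney
is available via `test="mannwhitney"`). Benjamini–Hochberg adjustment runs
across all tested panel species; significance requires |log₂fc| > 0.6 and
adjusted p < 0.05; effect bands (0.6, 1.5, 2.0) are reported as labels
only. log₂fc is defined on replicate-mean logs, not the log of a ratio of
means, keeping it symmetric under group swap. Non-positive abundances are
excluded with a warning before the log.

Regional volcanoes aggregate each replicate's ten ROI means into one
regional value and add the detection floor before the log: a sub-floor
regional mean is treated as "at the floor", which keeps fully censored
species testable and shrinks — rather than explodes — fold changes built
on censored zeros.

The two-solvent comparison is descriptive (no hypothesis test): per-species
log₂(doped/standard) on-tissue means (defined only where both are
positive), box statistics per LMSD category, and three mass-range groups
carrying explicit member-ion lists (3 + 2 + 9 = 14 ions; the nominal
window labels are descriptive — the heaviest configured member of the
upper group sits nominally just above its 745–770 Th label). The
preference fraction is the share of member ions more abundant under the
standard solvent; ties are not preferences. Reflection data bins each
image's on-tissue mean spectrum at a fixed width; total bin content equals
the mean on-tissue TIC.

## PRM model and analysis

The fragmentation model is phenomenological: precursor survival decays
logistically in NCE (midpoint defaulting to crossover + 2 %, slope 4 %);
the fragment pool splits between the galactose-loss ion (m/z 282) and the
galactose-plus-water-loss ion (m/z 264) by a logistic conversion curve
(slope 8 %) centred at the crossover NCE, where the two are exactly equal.
Above ~35 % NCE the 282 series is non-increasing while 264 keeps rising,
reproducing the observed high-energy behaviour while both fragments remain
quantitative at the optimum. "Optimal NCE" is formalised as the grid point
minimising |fraction(264) − fraction(282)| subject to a minimum total
fragment yield (default 25 % of the ion population), ties to the lower
energy; an alternative criterion (maximum fragment yield) would pick the
top of the grid and is deliberately not the default. The 5 Th isolation
width and the ±2.5 ppm mass accuracy are distinct settings and are kept
separate.

Ion-ratio analysis reports each ion's fraction of the
precursor + quantitative fragment total and the min/max equality ratio of
the two fragments. Isotope matching assigns observed peaks to theoretical
envelope entries by nearest m/z within tolerance and reports the cosine of
the abundance vectors, unmatched theoretical entries contributing zero.

## The synthetic phantom

The phantom emulates the *structure* of a sagittal-brain MSI study, not
its anatomy: a parametric silhouette (cerebral ellipse, cerebellar lobe,
brain-stem lobe) partitioned by fractional-coordinate cuts into four
quadrants plus a small visual-cortex hotspot inside the cerebrum. Default
grid 120×80 pixels at 100 µm; scan range m/z 200–800; 3 healthy and 4
diseased replicates.

Per pixel and species, expected abundance is
baseline(region) × 2^log2fc(region) (diseased only) × 2^offset(replicate)
× 2^suppression (doped solvent only), multiplied by mean-one log-normal
pixel noise (σ = 0.5 natural log) and split across the species' adducts;
each peak's m/z gets Gaussian jitter (SD 1 ppm, truncated at ±2.5 ppm, the
instrument's stated accuracy). Poisson decoy peaks (2 per pixel per
100 Th) cover the whole grid, and a 5 charges/s detection floor censors
everything below it. Replicate offsets are drawn once per replicate
(log₂ SD 0.3) or set explicitly for signature tests. A shared latent field
(σ = 0.6) anti-correlates psychosine and cholesterol in the diseased
posterior regions, emulating the observed spatial interleaving of the two
lipids.

The default panel (~24 species) carries the named analytes — psychosine
(C₂₄H₄₇NO₇), cholesterol (C₂₇H₄₆O), two galactosylceramides, a
sphingomyelin, five free fatty acids — plus the 14 solvent-comparison ions
as m/z-only putative annotations with their printed masses and LMSD
categories. Psychosine is scarce (near the floor) everywhere in the
healthy brain, baseline-concentrated in cerebellum/brain stem, and carries
log₂fc = 2.5 in cerebellum, brain stem and the hotspot of the diseased
brain; the fatty acids carry 0.7–1.1; cholesterol carries none but is
suppressed −1 log₂ under the doped solvent. Arachidonic acid's [M+H]⁺
coincides with the printed 305.2475 annotation — a deliberate isobaric
overlap of the kind putative annotation lists contain.

What the phantom does **not** emulate: real anatomy or atlas geometry,
isotope envelopes for panel species (only the PRM precursor carries one),
chemical noise structure, matrix/suppression effects beyond a single
per-species solvent factor, or between-animal biological variance beyond
the replicate offset. Passing recovery tests therefore demonstrates that
the analysis pipeline correctly inverts the generative model it targets —
fold changes, offsets, spatial contrasts, crossover energies — not that it
would be robust to every artefact of real acquisitions.

## Problem sizes and numerical choices

Simulation-based tests use the sizes the statistics need rather than
instrument-scale data: whole-tissue recovery runs 50 cohorts at 120×80
pixels; the type-I-error check runs 200 cohorts at 60×40 (pixel count does
not enter the per-replicate noise model, so the smaller grid tests the
same property); regional contrasts use 20 cohorts; NCE recovery 25 seeds
per crossover at a 2 % grid step. Determinism everywhere derives from a
single integer seed via named NumPy seed-sequence streams (one per
replicate). Ties in optimal-NCE selection break to the lower energy;
zero-variance strata z-score to 0; σ in all z-scores is the sample SD
(ddof = 1).

## Known limitations

Single z per ion (positive mode); no profile-mode or continuous imzML; no
image registration between sections; the tissue mask assumes one connected
section per image (largest component kept); the solvent comparison assumes
both images share a panel and comparable masks; PRM co-isolation within the
5 Th window is not simulated by default.
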