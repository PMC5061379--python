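# Methods

## The imaging model

Each microscope field carries two channels: a DNA stain with high-contrast
nuclear labeling plus faint cytoplasmic background (DRAQ5-like), and the
target-protein immunofluorescence. The analysis follows the classic
high-content-screening ROI scheme:

1. **Nuclei** are connected components of pixels at or above an intensity
   threshold on the DNA channel, with components below a minimum area
   (default 10 px, configurable) discarded as specks. The `"auto"`
   threshold is a hierarchical Otsu: a first cut separates background from
   stained pixels, a second Otsu over the stained pixels separates the dim
   cytoplasmic stain from bright nuclei; if the stained pixels have no
   contrast the first cut is used. A fixed numeric threshold can always be
   supplied instead for exactly reproducible runs.
2. **Cells** are grown from the nuclei over the cytoplasmic foreground
   (DNA-channel pixels at or above a lower cytoplasm threshold; `"auto"` is
   Otsu over the non-nucleus pixels). Each foreground pixel is assigned to
   the nearest nucleus under the geodesic Chebyshev distance measured
   *within* the foreground, implemented as iterated one-step label dilation
   (multi-source BFS). Distance ties go to the larger label, which is
   deterministic; foreground components containing no nucleus stay
   background and are counted in the log. Cell labels equal their nucleus
   labels, so every nucleus has exactly one cell and is contained in it.
3. **Ring ROIs.** Ring widths are morphological steps: under the default
   Chebyshev metric, width *w* means *w* erosions/dilations with a 3×3
   square element, i.e. all pixels within Chebyshev distance *w* of the
   reference set. The plasma-membrane ring of a cell is its pixels within
   distance ≤ 2 (default) of the nearest non-cell pixel (neighboring
   cells and the field edge count as non-cell); the perinuclear ring is
   the set of pixels outside the nucleus, inside the cell, within
   distance ≤ 5 (default) of the nucleus. A Manhattan (4-connected)
   metric is available. In small cells the two rings may overlap; both are
   computed independently and the overlap is reported
   (`imaging.roi_overlap`) rather than resolved by fiat, since no single
   precedence rule is canonical.
4. **Measurement.** Per cell, the arithmetic mean of the target channel
   over each ROI, with pixel areas; "total" is the mean over the whole
   cell mask (an integrated-intensity column is kept as an auxiliary
   readout). Cells touching the field border are excluded — their membrane
   ring is truncated — and counted in the log. Empty compartments yield
   missing values (NaN), never zeros.
5. **Well summary.** All cells from all of a well's fields (default 9) are
   pooled with equal weight per cell — a pooled cell-level mean, not a
   mean of per-field means — with missing compartment means excluded from
   their compartment's pool.

## The plate model

Each plate is read twice (immunostain, viability) and normalized entirely
within the plate:

* fold increase = value / median(cell-control wells);
* viability fraction = (value − median Hyamine) / (median cell control −
  median Hyamine), reported both as a fraction and as a percent; values
  below the Hyamine median go negative and are reported, not clipped;
* normalized fold increase = fold increase / viability fraction.

Medians use the standard midpoint rule for even counts. Wells missing
either read are flagged, excluded from control medians, and carry NaN
scores; missingness is never encoded as 0. The formulas imply *fractional*
viability in the denominator (an unscaled ratio), which is what the code
divides by; the percent form is carried alongside. Division by near-zero
viability is unbounded, so normalized fold increase is reported missing
when viability is at or below a configurable floor (default 0.1); the raw
ratio is retained in `normalized_fold_increase_raw`, and the ratio below
the death anchor (viability ≤ 0) is treated as meaningless and left
missing.

Dilution accounting composes steps that either divide by a factor or
multiply by transfer/(transfer+receiving) volume; the two screening
schemes shipped as constants are a 10 mM stock diluted 500-fold then added
in equal volume (10 µM final) and a 150 µM working solution, 5 µl into
25 µl (25 µM final).

## Screen statistics

The Z factor (screening-window coefficient, Zhang et al. 1999) is computed
per plate from designated control well sets, Z = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|,
with sample SDs (ddof = 1 throughout the package), then aggregated as
mean ± SEM (sample SD/√n; SEM undefined for one plate). Equal control
means make the separation undefined; in a screen report such plates are
recorded as per-plate errors rather than aborting the run. Which well sets
form the positive and negative arms is configuration (roles in the layout),
not biology hard-coded in the package — a screen may contrast in-plate
controls or designated wells of different cell lines.

Hits are compounds with readout strictly greater than mean + k·SD
(default k = 3) where mean and SD are computed over all test compounds,
controls excluded; a compound measured in several wells enters as its mean
readout. Ties at the threshold are non-hits. No multiple-testing
correction is applied — the k-SD cut *is* the selection rule, and under a
Gaussian null it fires at ≈0.135% per compound, which the test suite and
acceptance script verify against the binomial interval.

## Synthetic data

The generators stand in for the instruments and define the conditions the
tests run under.

**Fields.** Cells are concentric structures on integer-pixel centers: a
Euclidean disk cell (default radius 14 px, roughly a HeLa cell at 20×), a
nucleus disk (default radius 5 px), a perinuclear band (Chebyshev dilation
of the nucleus, width 5), and a membrane band (cell pixels within
Chebyshev 2 of background) — the same geometry the analysis derives, so
noiseless recovery is exact by construction. Integer centers make every
cell's pixel geometry identical, so painted compartment means are
independent of placement. Centers are rejection-sampled with Euclidean
separation ≥ 2·radius + 2 (at least one background pixel between cells)
and a border margin, and the generator raises rather than silently drops
cells when placement fails. Paint order in the target channel is
cytoplasm < perinuclear < membrane; ground-truth means are *measured* from
the painted noiseless image over the painted masks, so they stay exact
even where bands overlap. The DNA channel paints background 2, cytoplasmic
stain 200, nucleus 1000 AFU (synthetic working values). Noise is additive
Gaussian (default SD 20 AFU), clipped at zero; Poisson statistics, PSF
blur, vignetting and autofluorescence are deliberately not modeled, so
passing tests demonstrate correctness of the geometry and statistics, not
robustness to real microscope artifacts. One seed drives each simulator
through a fixed sub-seeding rule (`default_rng([seed, k])`, k = 0
placement, 1 image noise, 2 plate noise), so changing the noise level
never changes placement or ground truth.

**Plates.** The default 384-well layout frames a 320-compound block with
control columns (columns 1/24 cell controls, 2 positive, 23 viability;
the 96-well variant is analogous with 64 test wells). Well values are
drawn Normal(µ, cv·µ) and clipped at zero, with role-dependent means:
immunostain — cell controls at µ_cc (default 2×10⁵ AFU), positive controls
at 6×10⁵, Hyamine wells at 10% of baseline, test wells at µ_cc times a
per-compound multiplier (1 unless spiked); viability — live wells at
4×10⁶ (the order of the plate-reader counts the protocol targets), Hyamine
wells at 4×10⁵. Spiked hits do not perturb the viability read, emulating
hits without measurable toxicity. The default CV is 5%, the condition
under which spiked-hit recovery is assessed. None of these magnitudes are
estimates of the original screens — no control distributions were ever
published — they are synthetic working values chosen to give a clearly
passing but not degenerate assay window (the implied Z at 5% CV is ≈0.7,
the same regime as a well-behaved production screen).

## Numerical and design choices

* Chebyshev as the default ring metric reads "n pixels wide" as n
  morphological steps with the full 3×3 neighborhood; it is the
  convention under which a "2 pixel wide" margin band is exactly two
  erosions. The metric is a parameter, not an assumption.
* Sample SD (n−1) everywhere a spread is estimated.
* Strict inequality at the hit threshold.
* Missing values propagate as NaN and are excluded from medians, pools and
  hit populations; they are never silently zero.
* Pixels are 0-based row-major; a pixel is in or out of a mask (no
  sub-pixel geometry).
* Well names are normalized to zero-padded form ("A1" → "A01") on every
  input path.
* The report directory (`report.json`, `zfactors.tsv`,
  `hits_<readout>.tsv`) round-trips losslessly through
  `ScreenReport.from_dir`.

## Problem sizes

The shipped defaults keep everything desk-scale: ring-oracle checks use
100 random blobs at 64×64; imaging recovery uses 160×160 fields with six
radius-14 cells; hit-recovery uses 100 single-plate 384-well screens at 5%
CV with four 3× spikes; null calibration uses 10⁴ compounds. The whole
test suite and the acceptance script each run in seconds on one CPU.

## Limitations

* Segmentation is threshold-based by design (matching the screen's
  described analysis); crowded or low-contrast real images would need
  dedicated methods out of scope here.
* The hit rule's mean and SD are computed from the full compound
  population including any true hits; with many strong hits the threshold
  inflates and sensitivity drops — the rule is the screen's, reproduced
  faithfully, not an optimal detector.
* Kinetic (multi-timepoint) viability reads, dose–response fitting and
  liquid-handling worklists are non-goals.
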