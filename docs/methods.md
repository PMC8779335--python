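# Methods

## Scope and data model

`eimseval` evaluates predicted unit-mass 70 eV EI spectra against
experimental references.  A spectrum is a list of `(m/z, intensity)` peaks
at integer (nominal) mass with intensities as **percent of base peak**
(base = 100), plus an id, a nominal molecular weight (MW) and an optional
structural-subclass label.  All comparisons assume nominal binning
(`bin_nominal`: round half away from zero, merge, renormalize) and base-peak
normalization; peak matching across spectra is exact integer m/z equality
with no tolerance window, which is the correct model for classic EI library
spectra.

When an MSP record lacks an MW field it is inferred as the largest observed
m/z and flagged `mw_inferred`; this is appropriate for the aromatic
heteroaromatics the package targets, whose molecular ion survives
ionization and is the heaviest peak.

## Similarity scores

Both scores are cosines of intensity vectors formed over the union of the
two spectra's m/z values, scaled by `A = 1000`.  The weighted dot product
uses Stein–Scott per-peak weights `I^0.6 * mz^3`.  Defaults
(`intensity_exponent = 0.6`, `mass_exponent = 3.0`, `scale_a = 1000`) are
the long-standing EI library-search values; both are exposed in
`SimilarityWeights` for sensitivity studies.  Properties guaranteed (and
property-tested): symmetry, range [0, 1000], invariance to overall intensity
rescaling, and 1000 exactly iff the (weighted) vectors are proportional.

Numerical choices: a cosine ratio within 1e-12 of 1 is snapped to exactly 1
so identical spectra score exactly 1000 despite float round-off, and ratios
are clamped at 1 from above.  Scores are carried at full precision and only
rounded to integers for display.

Two banding schemes are provided: `fig_bands` (>800 excellent, >600 good,
>400 fair, else poor; thresholds exclusive) used for all class summaries,
and the coarser `classic` library-search rule of thumb (>850 good, >600
moderate, else poor).

## Library search

A query is scored against every library entry and the true compound's rank
reported.  Decisions made here, since search engines differ and no single
convention is canonical:

* **Ties** share the *worst* tied position, so top-N rates are lower bounds.
* **Replicate entries** of one compound (matched by id or name): the
  compound ranks at its best-scoring replicate by default (`strictest=True`
  uses the worst), reflecting that an analyst accepts any replicate hit.
* Ranks beyond `search_depth = 100` are "out of range".
* Cumulative percentages are rounded **half up** (57.5 → 58, 73.75 → 74);
  banker's rounding would disagree with the published convention this
  mirrors.

## Peak concordance

Both spectra are thresholded at `threshold_pct` percent of base peak
(default 2%, alternative 20%) and reduced to m/z sets.  The threshold is
applied to the predicted side too, so "extra" ions are counted at the same
abundance floor as missing ones.  The base peak is always retained.  The
molecular ion is included by default (`include_molecular_ion=False`
restricts the comparison to fragment ions; cohort-level dropout analyses
use that mode, since the quantity of interest is the fraction of *fragment*
ions reproduced).  Jaccard uses presence only — abundances deliberately do
not enter.  Spearman correlation (tie-averaged ranks, two-sided p) is
delegated to `scipy.stats.spearmanr`; per-spectrum summary means are
unweighted by spectrum size.

## Molecular-ion accuracy

The M⁺ abundance is the intensity at `m/z == nominal_mw` (0 if absent; no
M+1 isotope handling).  Differences are `pred − exp` in percentage points
of base-peak-relative abundance; "accurate within ±w" means
`|diff| ≤ w` with w = 2 or 10.  Class summaries report the mean of
**absolute** differences, rounded half up to one decimal — this is the
definition that reproduces the packaged reference table's printed class
averages exactly, which a signed mean does not.  The packaged 38-row table
stores the printed values verbatim; one row whose printed difference
disagrees in sign with `pred − exp` is flagged `printed_sign_mismatch`
(the absolute-value summary is unaffected).

## Neutral-loss annotation

Losses are pure integer arithmetic: a generation-1 hit is an observed peak
at `MW − delta` with intensity ≥ `min_intensity` (default 2%, aligned with
the concordance threshold, to avoid annotating noise); generation 2 chains
exactly one further loss from each generation-1 fragment and is capped
there — deeper cascades are chemically plausible but unconstrained.  The
43 u loss is reported as the single ambiguous `HNCO_or_NCOH` since
unit-mass spectra cannot distinguish cyanic from isocyanic acid.
Annotation is evidence of *consistency* with a loss, not a mechanistic
assignment: a coincidental fragment at MW−27 is indistinguishable from a
true HCN loss.

## Synthetic data: what it emulates, and what a green test establishes

The generator emulates the statistical structure of a predicted/experimental
comparison of purine- and pyrimidine-like compounds, not their chemistry:

* **Reference spectra**: MW uniform on a per-subclass range within
  110–210 u; molecular ion is the base peak with probability 0.75
  (roughly the observed fraction in the compound class this emulates),
  otherwise its survival is drawn uniformly (default 5–95% and pinned
  exactly, with the strongest fragment at 100).  10–18 fragment ions above
  the 2% floor — fragment-rich, as real purine EI spectra are — at
  subclass-specific neutral-loss offsets (HCN emission probability 0.89
  for purine-like classes, 0.57 for pyrimidines, 0 where the ring chemistry
  forbids it) padded with random positions kept off the known loss offsets,
  so the configured loss profile is the exact prevalence oracle.  Fragment
  intensities are log-uniform on [5, 95); 1–3 noise peaks at 0.3–1.9% sit
  below the 2% analysis floor.
* **Perturbation** (the "predicted" partner): per-fragment dropout, Poisson
  extra peaks on unoccupied m/z in [26, MW−1] (intensity log-uniform
  [2, 20)), multiplicative log-normal intensity noise, and a normal additive
  molecular-ion shift clipped to (0, 100].  The molecular ion is never
  dropped.  Dropout is **abundance-tilted**: weak fragment ions are dropped
  more often, reflecting that trajectory- or rule-based predictors
  under-sample rare fragmentation channels — this is what makes the matched
  fraction rise when the abundance threshold is raised from 2% to 20%.  The
  tilt `p_i = clip(d + tilt·d(1−d)(c̄ − log10 I_i), 0, 1)` is centered on
  the mean log-intensity of the spectrum's ≥2% fragments, so the configured
  `dropout_prob` is exactly the mean removal probability of the observable
  fragment population, and the d = 0 / d = 1 limits are exact identities.
* **Decoys**: near-duplicates of a reference spectrum keeping ≥50% of its
  fragment m/z (jittered intensities, resampled molecular-ion abundance,
  ~40% new fragments, same MW), operationalising "structurally similar
  compound" at the spectrum level — spectra, not structures, drive
  search-rank confusability.

All randomness flows from per-spectrum streams split off a master seed
(`numpy.random.SeedSequence.spawn`), so libraries are order-independent and
every artefact is reproducible from `(spec, cfg, seed)`.

A green cohort test therefore establishes that the pipeline's statistics
respond correctly to *known, configured* error rates.  It does not
establish anything about real predictor accuracy: real prediction errors
are correlated across related compounds, intensity errors are not
log-normal, decoy libraries of >250k spectra are far harder than 500-entry
ones, and real spectra carry isotope peaks, which the generator omits.

## Known limitations

* Unit-mass only; no profile-mode data, no isotope patterns, no
  mzML/mzXML.
* No probabilistic match factors, hybrid/modified-cosine shifts, or
  retention-index re-ranking.
* Molecular-ion lookup requires the metadata MW; formula-based exact masses
  are out of scope.
* The cohort-level concordance and prevalence guarantees are statistical
  (3-sigma bands at the tested n), not per-spectrum bounds.
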