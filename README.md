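# eimseval

Evaluation machinery for judging **predicted 70 eV electron-ionization (EI)
mass spectra** against experimental reference spectra, aimed at people who
generate in-silico EI libraries (quantum-chemistry, rule-based or
machine-learned) and need to quantify how usable those spectra are for
compound identification in GC-MS workflows.

The package covers the full evaluation chain for unit-mass spectra of small
heteroaromatics such as purine and pyrimidine derivatives:

* **Similarity scoring** — plain cosine and the mass-weighted dot product
  (Wdot) on the 0–1000 scale.  With intensities *I* paired over the union of
  the two spectra's m/z values, per-peak weights

  $$W = I^{m}\,(m/z)^{n}, \qquad m = 0.6,\; n = 3.0,$$

  the score is $A\,\cos(\mathbf{W}_\text{pred}, \mathbf{W}_\text{ref})$ with
  $A = 1000$.  The $(m/z)^3$ weighting emphasises heavy ions — above all the
  molecular ion — which is why Wdot discriminates isomers better than the
  unweighted cosine.  Quality bands: >800 excellent, >600 good, >400 fair,
  otherwise poor.
* **Library rank** — each predicted spectrum queried against a reference
  library; cumulative top-1/2/3/4/5/10/100 identification counts and
  percentages (round-half-up), entries beyond rank 100 marked out of range,
  ties broken conservatively.
* **Peak concordance** — after a 2% (or 20%) base-peak abundance threshold,
  matched / missing / extra fragment-ion counts, the Jaccard index of the
  m/z sets, and Spearman correlation of concordance with the scores.
* **Molecular-ion accuracy** — signed difference of the M⁺ abundance
  (percent of base peak), accurate/under/overestimated classification within
  ±2 or ±10 points, per-subclass mean absolute differences.  A 38-row
  published reference table ships with the package and is reproduced exactly
  by `molion.class_summary`.
* **Neutral-loss annotation** — characteristic losses from the molecular ion
  (HCN 27 u, CO 28 u, H₂O 18 u, CN₂H₂ 42 u, HNCO/NCOH 43 u, CH₃NCO 57 u),
  including two-step chains such as M−54 from sequential HCN losses.
* **Synthetic data** — a seeded generator for reference spectra,
  perturbation-derived "predicted" partners, and decoy libraries with
  structurally similar near-duplicates, so the whole pipeline is testable
  without licensed reference libraries.

Spectra are read and written as NIST-style MSP text (both the
`mz intensity` and `mz:intensity;` peak dialects are accepted).

## Worked example

Generate a small synthetic benchmark (10 compounds, 2 decoys each) and
evaluate it:

```bash
eimseval simulate --n 10 --decoys 2 --seed 42 --out-dir sim/
eimseval evaluate --pred sim/predicted.msp --exp sim/experimental.msp \
                  --library sim/search.msp --out-dir report/
```

prints

```
mean Wdot 957.3 over 10 pairs
top-1 90%, top-10 100%
```

i.e. under the default mild perturbation (10% fragment dropout, ~3 spurious
peaks, 0.2 log-intensity noise) the predicted spectra still average Wdot 957
against their references, and 9 of 10 queries identify the correct compound
as the top hit in the 50-entry decoy library.  Peak-level agreement:

```bash
eimseval concordance --pred sim/predicted.msp --exp sim/experimental.msp
# overall mean pct_matched 70.7, mean extra 2.7
```

so on average 70.7% of reference fragment ions above the 2% threshold are
reproduced and 2.7 extra ions per spectrum are predicted.  The same
operations are available as library calls (`eimseval.similarity.wdot_score`,
`eimseval.search.rank_query`, `eimseval.concordance.concordance`, ...).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation from scratch: it generates an 80-compound
synthetic cohort with a 500-entry decoy library, evaluates every pair
(scores, ranks, concordance at 2%/20%, molecular-ion comparison,
neutral-loss annotation) and recomputes the packaged molecular-ion
reference-table summaries, then writes its JSON result object to `--out`.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
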