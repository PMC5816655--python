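# Methods

This note documents the models and procedures implemented in `nanosar`, the
design decisions taken where several reasonable options existed, and what
the synthetic-data generator does and does not emulate.

## Endpoint and schema

Each record is one exposure observation.  The classification endpoint is
derived from the viability column alone: `Toxic` iff viability < 50 %, with
exactly 50 % classified `Nontoxic` (the toxic side is a strict inequality).
Viability values above 100 % are retained — they are common assay readouts —
and follow the same rule.  `cell_name` is carried in the schema for
provenance but never used as a modeling feature: free-text cell-line names
have far too many levels to generalize.  Units are fixed by the column
dictionary (nm, mV, m²/g, eV, µg/mL, hours); no unit inference is attempted.

## Quality scoring

Per PChem attribute, the data-source score (experimental 3 / manufacturer 2 /
reference 1 / absent 0) and the data-method score (gold-standard technique 2 /
other-or-estimated 1 / none 0) are summed; the record's final score is the
arithmetic mean over the four attributes.  The gold-standard techniques are
TEM (core size), DLS/NTA (hydrodynamic size), zeta potential (surface
charge) and BET (surface area); SEM/AFM count as "other" methods for core
size.  Scoring depends only on provenance columns, so value imputation never
changes a score.

Screening keeps the top `floor(keep_fraction · n)` records (minimum 1) under
a descending-score ordering with ties broken by ascending `record_id`.  The
count-based reading of "top X %" plus the deterministic tie-break makes
dataset membership reproducible across runs; because scores are discrete
(multiples of 0.25), the boundary usually falls inside a tie block and the
tie-break decides which of the equal-scored records are kept.

## Gap filling

Priority order: manufacturer catalog → reference catalog → estimation.  The
order mirrors the source-score ladder (2 > 1); estimation is tried last and
only between core size and specific surface area through the dense-sphere
relation SSA = 6/(d·ρ).  With d in nm and ρ in g/cm³ the SI reduction gives
SSA = 6000/(d·ρ) in m²/g; the relation is self-inverse, and
`estimate_core_from_ssa ∘ estimate_ssa_from_core` is the identity to
machine precision.

Provenance of filled values: catalog fills carry their catalog's source
level; a catalog entry without a stated method is labeled `other`
(method score 1) rather than a gold standard — the conservative choice.
Estimated values are labeled `estimated_from_core` / `estimated_from_ssa`
(method score 1) and inherit the *source level of the basis value*: the
scoring rules grade estimation on the method axis only, and tying the source
axis to the basis value keeps an estimate from outranking its own input.

QM descriptors are constants per oxide composition and are filled from a
lookup table regardless of particle size; a warning is emitted when the core
diameter is below 5 nm, where size-dependent deviations of electronic
properties are expected.

Building the fully-filled dataset (II) drops rows that still contain any
absent PChem or QM value and rescores the survivors.  Filling can only move
source levels up from `absent`, so no surviving record's score decreases.

Mean substitution (the dataset-I path) replaces absent numeric PChem values
with the attribute mean over *present* values of a statistics source.  The
statistics are computed on the training partition only and applied to both
partitions, avoiding train/test leakage; provenance is untouched, so scores
are unchanged.

## Modeling protocol

* Features: dose; the four PChem values; the four QM values; assay, cell
  species, cell origin, cell type (one-hot encoded) and exposure time.
  Exposure time is grouped with the Tox attributes (it is an experimental
  condition); dose forms its own category.
* Normalization: mean-centering and scaling by the sample SD (ddof = 1) of
  the training partition; a constant column is centered only.  Statistics
  ignore missing entries; any gaps left unimputed are passed to the forest,
  which handles missing values natively.
* Split: simple (unstratified) random 60/40, `round(0.6·n)` training rows;
  replication i uses seed `base_seed + i`, five replications by default.
* Classifier: random forest, 500 trees by default (tests and the worked
  example use 150 for speed; results are insensitive beyond ~100 trees at
  these sizes), `sqrt(p)` features per split, out-of-bag scoring enabled,
  fixed `random_state` per replication.
* Validation: stratified k-fold cross-validation on the training partition
  (default 5 folds, reduced when a class has fewer members than folds) and
  external validation on the test partition; precision, sensitivity,
  accuracy and F1 are computed with `Toxic` positive and averaged
  arithmetically over replications.  F1 is the harmonic mean of precision
  and sensitivity, defined as 0 when both vanish.  Reports carry raw values
  plus whole-percent roundings.

## Applicability domain

Distances are weighted Euclidean on the z-normalized numeric attributes,
uniform weights by default (normalization already equalizes scales; weights
remain configurable).  The per-sample statistic is the mean distance to the
k nearest neighbours, self excluded, k = 5 by default.  The cutoff is
D_c = D̄ + Z·s with D̄ and s the mean and sample SD (ddof = 1) of those
per-sample statistics; Z defaults to 1.645, the one-tailed 95 % normal
quantile.  The retained subset is {samples with statistic ≤ D_c}; numeric
ranges are reported over the retained subset in original units, with
inclusive bounds for membership tests.  Nominal attributes are excluded from
the distance; their domain is the observed level set of the training table.
For Z ≥ 0 at least the below-average samples are always retained, and both
the retained subset and every numeric range are monotone in Z.

## Attribute importance

Leave-one-out OOB importance removes one modeling attribute at a time
(an entire nominal attribute, not single dummy columns), refits on the same
replicated training partitions with the same seeds, and reports the OOB
error (1 − OOB accuracy) averaged over replications; attributes are ranked
by descending error.  The protocol measures *marginal* loss: a duplicated or
strongly correlated attribute can rank low even when informative, because
its partner absorbs the signal.  The category study runs the full
replicated validation protocol on dose plus chosen attribute categories and
reports averaged accuracy and F1 per combination.

## Synthetic-data generator

The generator emulates a literature-curated compilation at the level of
structure, not of any particular published dataset:

* **Materials.** 26 oxide compositions with real bulk densities; material
  true core sizes are log-normal (median 30 nm, log-SD 0.6, clipped to
  3–400 nm); true SSA is exactly the sphere relation; hydrodynamic size is
  core size times (1 + log-normal agglomeration factor), hence always ≥
  core size; surface charge is normal (SD 30 mV, clipped at ±65 mV).
* **Dose–response.** Viability follows a log-logistic (Hill) curve,
  V = 100/(1 + (dose/EC50)^h), the minimal monotone model consistent with a
  50 %-viability endpoint.  log10 EC50 = composition effect (SD 0.05) +
  3·log10(d/30 nm) − 0.2·log10(t/24 h) + material effect (SD 0.05).  The
  d³ scaling reflects per-mass particle number/surface: at fixed mass dose,
  smaller particles present more surface and are more toxic.  The steep
  default slope (h = 4) and small viability noise (SD 2 %) make the label a
  near-deterministic function of dose and the true attributes, so model
  error is dominated by *feature* error — which is what the quality-scoring
  experiments are about.  The composition-level EC50 field is shifted by a
  deterministic quantile so the noiseless toxic fraction equals the target
  (default 0.15, a clear Nontoxic majority).
* **Missingness.** Per-attribute Bernoulli, missing completely at random,
  at the literature-profile default rates 18/39/41/74 % for core size,
  hydrodynamic size, surface charge, surface area.
* **Provenance and noise.** Each material × attribute belongs to one of
  four strata — experimental, manufacturer-recoverable,
  reference-recoverable, unfillable (default mix 0.40/0.25/0.25/0.10).
  Observed values carry multiplicative log-normal error (additive in mV for
  charge, scaled by 25 mV) with log-SD 0.02 / 0.6 / 1.2 for experimental /
  manufacturer / reference sources: values measured in the reporting lab
  track the tested suspension closely, while specifications and values
  borrowed from other publications of "the same" material routinely differ
  by factors of two to three.  Non-gold methods double the noise scale
  (e.g. SEM/AFM vs TEM).  Catalogs are populated exactly for the
  recoverable strata, with the same noise model, so every
  manufacturer/reference-stratum gap is fillable and estimation covers the
  core↔SSA pair.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  configurations produce byte-identical tables.

Under these defaults the full pipeline reproduces the qualitative ordering
F1(I) < F1(II) ≤ F1(III-A) ≤ F1(III-B) at the default seed
(0.678 / 0.741 / 0.769 / 0.801 at n = 6,842 with 150 trees): mean
substitution is uninformative, catalog fills are informative but noisy, and
score screening concentrates accurately-measured records.  The first two
inequalities are robust across seeds; the III-A/III-B comparison is a
*tendency* — the 20 % subset pays a real sample-size cost against its
quality gain and can dip below III-A at other seeds, mirroring the
predictivity-versus-domain compromise that screening entails.

What the generator does **not** emulate, and what passing tests therefore
do not show about real compilations: informative (non-random) missingness;
per-article correlation structure (shared labs, shared protocols, batch
effects); composition-specific toxicity mechanisms (the default
composition-level EC50 variance is deliberately small so that desk-scale
sample sizes suffice for the forest to learn the size-driven surface —
real oxides differ far more); assay-specific interference artifacts; and
dose–response shapes beyond the log-logistic family.

## Numerical choices and degenerate inputs

* Sample SDs use ddof = 1 throughout; a single observation yields SD 0.
* Constant columns normalize to zero (scale 1), never divide by zero.
* Screening keeps at least one record; `keep_fraction` must lie in (0, 1].
* kNN requires n ≥ k + 1; tied neighbour distances cannot change the mean
  distance statistic, so index tie-breaking is observational only.
* Metrics define precision/sensitivity as 0 when their denominator is 0.
* Problem sizes: unit and property tests run on 200–400-record synthetic
  tables with 25–80-tree forests; the end-to-end ordering check and the
  worked example use the full default 6,842 records with 150 trees.
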