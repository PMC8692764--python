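# Methods

This note documents the models, conventions and numerical choices behind
`oceanpack`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Descriptor dialect

Descriptors follow the Frictionless Data Package layout: a top-level
`name`, `resources` list, optional `title`/`homepage`/`licenses`/
`sources`. Each resource declares a relative `path` (absolute paths and
`..` escapes are rejected), an MD5 checksum, an optional dialect block
(delimiter; tab is the default since resources are TSV), and a `schema`
with ordered fields. Field types come from the closed set {string,
number, integer, datetime}. Datetime conformance is checked against the
declared strftime-style pattern only (default `%Y-%m-%dT%H:%M:%SZ`);
there is no ISO auto-detection, because silently accepting a different
layout would mask inconsistent source formatting.

Annotation keys: `rdfType` (unprefixed, as commonly printed) or
`pm:rdfType`; `pm:unitRdfType`; the device key is accepted in both the
canonical spelling `pm:measurementSourceRdfType` and the misspelled
variant `pm:measurmentSourceRdfType` seen in the wild, and always
written canonically. Unknown keys at any level are preserved verbatim so
load → save → load is the identity. Serialization uses a fixed key order
and two-space indentation, so structurally equal descriptors are
byte-identical — which is what makes checksum-based golden files viable.

Missing-value substitution is an exact string match: `"NA "` is not
`"NA"`. Cells that fail to parse become in-table typed-error markers
rather than exceptions, so the validator can report exact (resource,
row, column) coordinates and a single bad cell never aborts a load.

## Validation

Three families, merged into one deterministically ordered report
(sorted by resource, row, column, code):

* **Transferability** — every resource file exists and matches its MD5.
* **Cell conformance** — type errors, datetime format errors, and
  numeric constraint violations. Bounds are inclusive: latitude −90 and
  90 pass. The latitude/longitude constraints exist chiefly to catch
  swapped-coordinate errors.
* **Annotation audit** — every field should carry an `rdfType`; numeric
  fields should also carry a unit and a device term; any annotation
  whose CURIE is missing from the term graph is an error.

Severity policy: broken files, bad cells and unknown terms are errors;
incomplete triads are warnings, because deposited packages routinely
lack device information and the data remain usable, just less
comparable. Validation never raises for data problems — it reports — so
a single missing file cannot hide the cell-level findings in the other
resources. A deleted resource is the one exception: its cells cannot be
inspected at all, which the fixture generator accounts for when
predicting expected issues.

## Term graph

Only is-a (subclass) edges are modeled. Subsumption is all that
attribute discovery requires; part-of and located-in relations would add
reasoning complexity without changing any query this package supports.
Term tables are flat TSVs (`curie`, `label`, pipe-separated parents)
rather than OWL; users of released ontologies can export such tables
with standard tooling. The bundled `data/pm_terms.tsv` is a small
synthetic extract — real ENVO/UO/OBI/CHEBI/PATO identifiers for the
concepts the package exercises, plus fixture-local terms in a `TEMP:`
namespace (e.g. a phosphate-concentration attribute and plumbing
concepts like a sample-identifier datum). `TEMP:` marks every
provisional identifier; the package never fabricates identifiers in
real ontology namespaces.

Cycles are a hard error (one cycle is named); dangling parents are
tolerated and recorded, since ontology extracts routinely reference
terms above the cut. Label resolution is exact and case-insensitive —
no stemming or synonym expansion, which would risk silent
mis-annotation; ambiguity (one label, two terms) is an error listing
the candidates.

Concentration-term minting follows the design-pattern recipe: label
`concentration of <solute> in <material>`, equivalence expression tying
the PATO quality `concentration of` (PATO:0000033) to a CHEBI solute
and an ENVO environmental material. The solute must be CHEBI-prefixed
and the material must sit under `environmental material`
(ENVO:00010483) when the graph encodes that branch. Minted IDs are
deterministic `TEMP:` hashes of the input pair, so minting is a pure
function and distinct inputs get distinct labels and IDs.

## Harmonization

* **Search.** A query term matches fields annotated with exactly that
  term, or with any is-a descendant when requested. Subsumption results
  are always a superset of exact results.
* **Units.** Conversions are affine maps (`factor`, `offset`) on a
  graph of registered pairs; inverses and chains are derived. Units in
  disconnected components are *not* convertible: in particular,
  micromolar (amount per volume) and micromole-per-kilogram (amount per
  mass) stay apart unless the caller enables the seawater-density
  bridge (default 1.025 kg/L, `value[µmol/kg] = value[µmol/L] /
  density`). Making that assumption explicit avoids silent
  over-harmonization of data that differ by water density.
* **Table building.** The row key is the value of a designated
  sample-identifier field (exact string match across packages; no fuzzy
  joins). Duplicate identifiers within one resource are an error. When
  two sources feed one (sample, attribute) cell, the winner is chosen
  by: exact-term annotation over descendant-term, then device-annotated
  over not, then package order; every losing value is logged as a
  conflict. Each column ends up in a single unit — the explicit target
  if given, else the unit of the first contributing field. Per-cell
  provenance (package, resource, field, original unit, device) is kept,
  and a device summary per column surfaces mixed instrumentation
  without blocking the merge: instrument heterogeneity limits
  comparability but is a judgement for the analyst, not the merger.
* **Climate zones.** The tropical/temperate/polar cutoffs are the
  astronomical tropic and polar circles, 23.5° and 66.5°, with
  boundaries going poleward; the three bins partition [−90, 90]
  exactly. Both cutoffs are parameters.

## Statistics

* **OLS** (`scipy.stats.linregress`): slope, intercept, R²; constant
  predictors are rejected rather than returning NaN.
* **Spearman** (`scipy.stats.spearmanr`): Pearson correlation on
  mean-ranked data; constant vectors are rejected.
* **Relative abundance**: contaminant taxa are dropped first, then
  samples whose remaining total is below the read threshold (default
  100 000 reads — the conventional cutoff for shallow metagenomes),
  then rows are normalized to sum to one.
* **Bray–Curtis** (`scipy.spatial.distance.pdist`), returned as a
  `skbio.DistanceMatrix` with sample ids. Two all-zero rows make the
  distance undefined and raise.
* **dbRDA.** Squared distances are Gower-centered, G = −½ J D² J with
  J = I − 11ᵀ/n. For a single centered covariate x the model sum of
  squares is tr(HG) = xᵀGx/xᵀx with H the hat matrix, total is tr(G),
  R² their ratio, and the pseudo-F uses n − 2 residual degrees of
  freedom. Significance comes from whole-row permutations of the
  covariate with the (b+1)/(n_perm+1) estimator, so p is never zero and
  is exactly reproducible for a given seed (at least 99 permutations
  are required). Per-taxon coefficients follow the adonis convention:
  each centered taxon column regressed on the centered covariate,
  yᵀx/xᵀx. With Euclidean distances this machinery reduces exactly to
  the classical linear model — the test suite checks R² agreement to
  1e-9, and separately cross-checks Bray–Curtis R² and the coefficient
  vector against R vegan's `adonis2` on the same instance. Top-taxa
  ranking is by |coefficient| descending with lexical tie-breaks.
* The depth-window restriction used when studying upper-water-column
  communities is expressed through the generator's `depth_range` and
  the table filters, not hard-coded.

All stochastic operations take an explicit seed; there is no global
random state anywhere in the package.

## Synthetic generators

The generators define the study conditions for every test and for the
acceptance script; their manifests record ground truth so each check has
an exact oracle.

* **Packages** (`generate_package`): two resources (a samples table
  with identifiers, INSDC-style accessions, coordinates, datetimes and
  ENVO context PURLs; a chemistry table with depth, temperature,
  nitrate, phosphate), every numeric field fully triad-annotated, ~10%
  of nutrient cells set to `NA`. Defect injections are split by stage:
  content-level defects (bad cells, out-of-range latitude, stripped or
  unknown annotations) are planted *before* checksumming so only the
  intended issue fires; byte corruption (flipping the last digit in the
  file — a one-byte change that keeps every cell parseable) and file
  deletion happen *after*. Contradictory combinations (corrupting a
  deleted file) are rejected.
* **Nutrients** (`generate_redfield_data`): nitrate ~ Gamma(shape 2,
  scale 8), spanning the 0–40 µM regime of open-ocean profiles (the
  exact family is a documented constant, not load-bearing);
  phosphate = nitrate/16 + N(0, sd), floored at zero; default noise sd
  0.2 µM. Optional freshwater-like outliers at 37–40 µM nitrate and
  near-zero phosphate, tagged with freshwater-lake ENVO context so a
  context filter can remove them. The zero floor censors slightly at
  low nitrate, biasing the fitted slope down by ~0.0003 at sd 0.2 —
  about half a single-fit standard deviation at n = 1000 and well
  inside every tolerance used.
* **Communities** (`generate_community_depth_data`): per-taxon expected
  shares follow logistic-in-depth curves with configured sign and
  steepness, renormalized, then multinomial counts at totals drawn from
  150k–1M reads; optionally some samples get totals below 100k to
  exercise the shallow filter. Non-zero trends must include both signs,
  since shares are compositional: all-same-sign trends cancel under
  renormalization.

What passing these tests shows — and does not. The generators reproduce
the *structural* features of real survey data: annotated multi-resource
packages, missingness, a stoichiometric law with noise and contextual
outliers, monotone depth trends in compositional data, library-size
variation. They do not mimic real covariance between physicochemical
variables, spatial/temporal autocorrelation, overdispersion beyond
multinomial sampling, or taxonomic richness of real communities. Green
tests therefore demonstrate correctness of the machinery under known
truth, not oceanographic conclusions.

## Problem sizes

Test and acceptance runs use deliberately small instances — 50 packages
of 10 samples for the validator oracle sweep, n = 1000 for the nutrient
regression, 40-sample communities with 999 permutations for the dbRDA
recovery check, and 200 replicates of 20-sample null communities at 99
permutations for calibration. These sizes give the checks their stated
statistical resolution (e.g. the exact binomial 95% interval on a 5%
rejection rate over 200 replicates) while keeping the whole suite in
seconds.

## Known limitations

* No OWL reasoning, no remote PURL dereferencing, no ontology release
  tooling; the term graph is only as good as the exported table.
* No support for non-tabular resources or remote (URL) resources.
* Harmonization does no geospatial joining, temporal interpolation or
  imputation; samples match only on exact identifier equality.
* dbRDA supports a single continuous covariate, matching its use here;
  multi-covariate PERMANOVA, strata, and phylogenetic distances are out
  of scope.
* The portal semantics of the `pm:searchable` flag (whether it gates
  discovery, display, or both) are not replicated; the flag is parsed,
  stored and exposed.
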