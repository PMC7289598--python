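# Methods

## The problem

Large loss-of-function screens (CRISPR or shRNA) across panels of cancer cell
lines produce gene-level sensitivity scores: for each gene and cell line, a
dimensionless summary of how much inhibiting that gene impairs growth (lower =
stronger fitness defect). A *genetic interaction* is an association between a
driver gene's alteration status and sensitivity to inhibition of another gene;
a *synthetic lethal* interaction is one where altered lines are selectively
killed. Individual screens are noisy and their hit lists overlap poorly, so
`robustgi` operationalizes robustness directly: an interaction counts only if
it is discovered in one dataset and *reproduced* in a second dataset whose
cell-line panel shares no lines with the first.

## The association model

Within one dataset, each (driver Y, target X) pair is tested with ordinary
least squares:

    sensitivity(X) ~ MSI_status + C(Tissue) + driver_status(Y)

- The driver coefficient is the mean sensitivity-score shift in altered lines
  after covariate adjustment; its two-sided t-test p-value is the test
  statistic (equivalent to the 1-df ANOVA F for that term).
- Tissue enters as one-hot dummies with the lexicographically first level as
  reference; constant columns (single tissue, uniform MSI) are dropped; a
  design left singular by a collinear term is reported as an error naming the
  term. Tissues represented by a single line are kept and absorb one df.
- Tissue and MSI are covariates because lineage-restricted essentialities
  masquerade as driver associations when the driver is lineage-enriched (the
  classic example: SOX10 essentiality in melanoma naively "associates" with
  BRAF mutation). The synthetic generator plants exactly this hazard, and the
  test suite checks that the model absorbs it while a naive t-test is fooled.
- Effect size is the common-language effect size (CLES): the probability that
  a random altered line scores *lower* (is more sensitive) than a random
  wild-type line, ties counting half — identical to Mann–Whitney U/(n1·n2).
  Orientation is fixed here: larger CLES = altered lines more sensitive.
- Benjamini–Hochberg FDR is applied once per association run; in the
  discovery/validation engine the BH family is re-derived per dataset pair
  over exactly the pair's testable universe.

`fit_association` fits a single pair through statsmodels OLS.
`run_screen_associations` is a vectorized normal-equations engine that shares
one design matrix across all targets with the same missingness pattern; a test
asserts agreement with the statsmodels route to 1e-9, so speed never
substitutes for correctness.

## Discovery/validation engine

For every ordered pair of datasets:

1. remove from the validation dataset every cell line present in the
   discovery dataset (so validation tests genuinely new genetic backgrounds);
2. limit the analysis to the testable universe — targets screened in both
   datasets and drivers functionally altered in ≥ `min_altered` (default 5)
   lines of *both* resulting panels;
3. call hits in discovery at BH FDR < `fdr_threshold` (default 0.2; 0.1 and
   0.3 supported for robustness scans);
4. an association is reproduced when its validation FDR < threshold, its raw
   validation p < 0.05, and the direction (sensitivity/resistance, i.e. the
   sign of the coefficient) agrees.

An interaction validated in ≥ 1 ordered pair is *robust*. Self associations
(driver = target) are classified separately — an oncogene whose alteration
increases sensitivity to its own inhibition is an oncogene-addiction effect —
and are excluded from the genetic-interaction view.

Two alternative pairing modes support reproducibility decompositions:
`split_common_lines` restricts both datasets to their shared panel (same
biology, different platform → technical reproducibility), and
`split_within_dataset` partitions one dataset into disjoint halves (same
platform, different biology → genetic robustness).

The validation BH family defaults to all associations testable in the pair's
validation run; a `discovered`-subset family is available behind a flag. The
full family was chosen as the default because the criteria combine an FDR cut
with a raw-p cut, which only makes sense when the FDR is computed over a
family larger than the discovered subset.

## Alteration calling

Driver genes are called functionally altered by class: oncogenes require a
protein-altering mutation at a recurrently altered residue (residue lists are
an input table; positions are parsed from the protein change and unparseable
strings never match); a small class of amplification-only oncogenes requires
copy number ≥ `amp_threshold`; tumour suppressors count any non-silent
mutation or copy number < `hom_del_threshold` (default −1.28). There is no
canonical amplification cut-off in the literature for the relative copy-number
scale, so `amp_threshold` defaults to +1.0 and is configuration, not
inference. Passenger genes use a stricter rule — nonsense/frameshift/splice
or homozygous deletion only — and driver genes are excluded from the
passenger matrix entirely. Every positive call carries a reason code
(recurrent_mutation, amplification, lof_mutation, homozygous_deletion) and an
audit test re-derives calls from their codes. Missing copy-number values
never trigger calls.

## Selectively lethal genes

Association testing is restricted to genes with a usable sensitive/resistant
contrast: score below −0.6 in at least 10 lines but in no more than half of
the panel ("half" is parameterized as `max_fraction` of the current panel
rather than a fixed line count, because the absolute cap depends on panel
size). The set is augmented with a user-supplied outlier-gene list and purged
of commonly essential genes. The missingness filter that precedes this is
inclusive at the boundary (a line with exactly the threshold fraction of
missing scores is retained), and the panel-size denominator is the full panel
including lines with missing scores — a convention, stated rather than
implied.

## PPI enrichment

PPI edge lists are read as scored TSVs; integer scores above 1 are taken to be
on the 0–1000 scale and divided by 1000, and the confidence threshold is
strict (score > 0.4 keeps an edge scored 0.401, not 0.4). The enrichment
ladder reports the fraction of PPI-supported pairs among the nested groups
tested ⊇ discovered-in-≥1-screen ⊇ validated. The two Fisher exact tests
compare *disjoint* complements (tested\discovered vs discovered,
discovered\validated vs validated) so each comparison is between
non-overlapping groups; the reported odds ratio is the plain cross-product
ratio (infinite/NaN on zero cells; a Haldane-corrected OR is available for
plotting). Degree-matched null networks are generated by double-edge swaps
(10 per edge, rejecting swaps that would create self-loops or parallel
edges), which preserves each node's degree exactly and thereby controls for
hub/ascertainment bias; the empirical enrichment p uses the add-one
convention (1 + #{null ≥ observed})/(1 + n_null). The swap budget is a
standard mixing heuristic, chosen here, not prescribed by any external
convention.

## Extensions

- **Chemogenetic screens**: genes are grouped by the number of cell-line
  screens calling them synthetic lethal with an inhibited target; per group
  the fraction of PPI partners of the target is reported with all pairwise
  Fisher tests. Hit calling upstream is the data producer's responsibility.
- **Passenger search**: candidate pairs are restricted to PPI partners of
  passengers lost in ≥ 10 lines with selectively lethal targets; the
  significance of the robust-hit count is assessed against repeated uniform
  samples of equally many pairs from the same search space run through the
  identical pipeline (default 100 replicates).
- **Pathway ORA**: one-sided hypergeometric over-representation of a query
  set in GMT gene sets restricted to a declared background (the selectively
  lethal genes), BH across sets.
- **siRNA normalization**: viability is anchored per cell line between the
  scramble-control mean (→ 1) and the PLK1-control mean (→ 0):
  `1 − (mean(siCTRL) − raw) / (mean(siCTRL) − mean(siPLK1))`, using per-line
  control means over replicates (three in the standard design). The
  transform is invariant to rescaling a line's raw luminescence. A Welch
  t-test utility supports two-group comparisons of normalized values.

## Synthetic worlds

`SyntheticConfig` defaults define the reference study conditions used
throughout the tests: 4 studies × 120 lines, each panel drawing 50% from a
pool shared by all studies; 4 tissues (uniform) and MSI frequency 0.15;
10 drivers altered independently at frequency 0.2; 200 target genes;
20 planted sensitivity interactions of −1.0 score units; measurement noise
SD 0.5; gene-specific tissue effects SD 0.3 and MSI effects SD 0.2 (the
confounding structure the covariate model must absorb); gene baselines
SD 0.25; a PPI background of 1750 edges over the 210 genes (background pair
probability ≈ 0.08) with planted pairs included as edges at 5× the background
rate. Tissue/MSI frequencies and effect SDs are realistic moderate choices
for pan-cancer panels — strong enough that ignoring them breaks the naive
analysis, weak enough not to swamp planted effects. Biology (baselines,
tissue/MSI effects, planted effects) is shared across studies; measurement
noise is drawn independently per study. All randomness flows from one seed
through five named substreams (panel, alterations, effects, noise, network),
so identical configs produce byte-identical worlds on disk.

Scenario variants used by the acceptance checks: the oncogene-addiction
scenario plants 3 self-effects of −1.5 against other effects of −0.8 (the
ranking property needs a clear magnitude gap); the enrichment-ladder scenario
plants 40 interactions at −0.8 so that false discoveries accumulated across
the 12 ordered pair-discovery analyses populate the discovered-but-not-
validated group, which is what gives the ladder its middle rung; the
degree-matched calibration scenario uses 2 studies × 60 lines with planting
enrichment 1× so validated pairs exist but carry no PPI signal.

What the generator deliberately does **not** emulate: CERES/DEMETER2 score
distributions and their heavy tails, guide-level structure and off-target
effects, copy-number artefacts of CRISPR cutting, correlated alterations
(co-deletion of neighbours), or ascertainment bias in PPI databases beyond
what degree matching controls. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated model, not
that real screens satisfy that model.

## Numerical choices and degenerate inputs

- OLS is solved by normal equations after a rank check; rank-deficient
  designs are skipped (batch runs, with a log entry) or raised (single fits,
  naming the collinear column).
- CLES uses midranks, so ties contribute exactly 0.5 without enumeration.
- BH is delegated to statsmodels; an independent hand-written step-up serves
  as the oracle in tests (agreement to 1e-12; the two differ by one ulp
  because one divides by i/n where the other multiplies by n/i).
- Fisher's exact p is delegated to scipy; the odds ratio is computed directly
  as a·d/(b·c) with infinity/NaN conventions for zero cells.
- Sensitivity matrices are written with 17 significant digits and parsed with
  exact float conversion, so write→read round-trips are bit-exact.
- Drivers altered in all or none of the retained lines are a "no contrast"
  error for single fits and a logged skip in screen-wide runs; lines with a
  missing target score are dropped per test, and group sizes are re-checked
  after dropping.

## Problem sizes

The test suite and acceptance script run entirely on synthetic worlds of the
default conditions above (and the scenario variants), with 10–20 seeds per
property and 100 runs for the empirical-p calibration; these sizes give
stable averages for the properties checked while keeping a full run of the
suite in a few minutes. Counts from any real, versioned screen datasets
depend on those releases and are out of scope here.

## Known limitations

- No meta-analytic pooling across datasets: robustness is a binary
  "validated in ≥ 1 pair" criterion, as in the underlying design.
- No within-tissue discovery mode; the analysis is pan-cancer with tissue as
  a covariate.
- Alteration calls are rule-based; no variant-effect prediction or hotspot
  statistics.
- The amplification threshold and residue-recurrence criteria are
  configuration inputs, not inferred.
- `harmonize_cell_lines` applies a user-supplied alias map; no external
  identifier service is consulted, and harmonization is only idempotent when
  the map itself is (canonical values must not be remapped).
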