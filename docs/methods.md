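# Methods

## The evaluation design

The pipeline targets a two-shipment, multi-platform ring trial on human
plasma. Each platform receives two identical blinded shipments containing
duplicate aliquots of every parent sample (6 PTSD and 6 control donors by
default), undiluted NIST SRM 1950 pooled reference plasma, and the
reference plasma diluted with saline to 80, 60 and 40% of full strength.
The two biological groups are carried through every stage separately and
are never contrasted statistically — a dozen donors cannot support
case–control inference, and group-specific technical performance is itself
the quantity of interest.

Stages run in a fixed order: harmonize → 80% rule → precision (intra per
shipment, then inter) → accuracy → linearity → coverage. Every exclusion is
logged with its reason, and output metadata records the CV, R² and banding
conventions used.

## Harmonization and coverage

Raw vendor names are joined against a user-supplied (platform, raw name) →
HMDB ID + class map; no fuzzy matching and no online lookups, so a given
input always resolves the same way. Names without an ID remain
*platform-scoped* keys (`platform::raw_name`). This is deliberate: when
nomenclature cannot be reconciled, an honest overlap estimate must place
such metabolites in their platform's exclusive Venn region rather than
guess at cross-platform identity. Venn regions are computed by per-key
bitmask membership over 2–5 platforms (all 2^k − 1 regions are reported and
sum to the union). Class labels come from the map, never from an ontology
at runtime. Shipment coverage drift is the signed percent change
100·(n₂−n₁)/n₁, reported to one decimal; a class is "consistently reported"
by a platform only if at least one of its metabolites is observed in both
shipments.

## Missingness: the modified 80% rule, no substitution

Missing values stay missing. Imputation is rejected by design because the
source of missingness differs between platforms (left-censoring at the
detection limit vs annotation dropout vs true absence) and substitution
distorts distributions and deflates group SDs. Where a vendor already
imputed, those cells pass through unmodified and count as observed.
A metabolite is retained only if its non-missing fraction is ≥ 0.80 within
*every* biological group; the boundary is inclusive (exactly 80% present is
kept) because only proportions *below* 80% indicate an unreliable variable.
Each replicate aliquot counts as one data element, pooled across shipments
by default; a `per_shipment` switch applies the rule within each shipment
instead for stricter longitudinal designs. Reference (NIST) samples never
form a filtering group.

## Precision

For a duplicate pair (a, b): CV% = 100·s/m with m = (a+b)/2 and s the
two-point **sample** SD, s = |a−b|/√2. The n−1 convention is the standard
duplicate-CV choice; a `ddof=0` switch (s = |a−b|/2) reproduces the
population-SD variant where needed. Intra-assay pairs are a parent sample's
duplicates within one shipment; inter-assay pairs match the same
(parent sample, aliquot slot) across shipments, so they include both the
within-run noise and the run-to-run drift. Pairs with a missing member are
skipped. Metabolite-level CV is the unweighted mean over complete pairs;
class tables take the unweighted mean over metabolites (not pooled over
pairs) with an n−1 SD across metabolites, reported NA for singleton
classes, plus both per-group and pooled min–max ranges. Bands:
HIGH ≤ 10% < MODERATE < 20% ≤ LOW, applied to the class mean.

### Estimator bias and parameter recovery

For two points the sample SD is biased: E[s] = √(2/π)·σ ≈ 0.798σ. The mean
of duplicate-pair CVs therefore sits ~20% below the generative lognormal
CV, which is fine for a comparative report table (every platform and class
is biased identically) but wrong for recovering a noise parameter. The
recovery report consequently aggregates on the root-mean-square scale:
squared pair CVs are (scaled) variance estimates, variances pool linearly,
and √mean(CV²) converges to the closed-form 100·√(exp(σ²)−1) without the
c₄ bias. Both aggregates are carried (`cv_pct` and `cv_pct_rms`) so the
report tables and the recovery diagnostics each use the right one.

## Accuracy and linearity

Accuracy is scored on shipment-1 reference plasma only (the first shipment
is the one analysed before any algorithm updates) as the signed percent
difference from the Certificate of Analysis; negative means the platform
reports below the certified concentration. The reported value defaults to
the mean over undiluted reference aliquots; a config switch selects a
single designated aliquot. Only absolute-unit (µM) platforms are scored —
a relative-unit platform has no comparable scale — and bands are applied to
|percent difference|. The packaged COA fixture carries the 23 certified
analytes used (amino acids, two fatty acids, clinical markers). A second
packaged fixture holds published per-platform reported values for those
analytes as a worked example; for platforms whose reported values were
published rounded to integers, the published percent differences were
evidently computed before rounding and cannot all be reproduced from the
rounded values — these rows are flagged `matches_printed=False` rather than
treated as errors.

Linearity fits value ~ 0 + fraction by OLS over the four design points.
Slope solves Σxy/Σx²; R² is the uncentered through-origin definition
1 − Σ(y−ŷ)²/Σy² — the only coherent R² when the model has no intercept —
clipped to [0, 1] and snapped to exactly 1.0 when the residual sum is
below 1e−24 of Σy² (a pure floating-point residue on proportional data).
If any design point is missing the curve is not assessed at all: a 3-point
fit would silently change the estimand.

## Synthetic data generator

Measurements are simulated as y = c · bias(platform, class) · exp(u + e),
with u ~ N(0, σ²_between) drawn once per (platform, metabolite, shipment)
and e ~ N(0, σ²_within) per aliquot. Multiplicative lognormal noise is the
natural error model here: concentrations stay positive, CVs are
scale-free, and expectations are closed-form — intra CV
100·√(exp(σ²_w)−1), inter CV 100·√(exp(σ²_w+σ²_b)−1). Between-shipment
drift is a per-metabolite random effect, not a global shift, because drift
is class-specific in practice. Parent samples get a biological lognormal
factor (σ = 0.30 by default, a typical inter-individual spread for plasma
metabolites); it cancels out of every duplicate-based CV. Dilution samples
scale the reference concentration by the nominal fraction before noise.
Values below a platform's LOD are censored to missing; further cells drop
out MCAR (default rate 0.02). Run order is block-randomized within
25-sample boxes (the 5×5 shipment-box layout), identically across
platforms. Random streams are keyed (seed, purpose, platform index,
shipment), so adding a platform never perturbs existing draws and identical
(config, seed) give byte-identical tables.

Default design sizes follow the emulated study: 6 parents per group,
duplicate aliquots, 2 shipments, 2 reference replicates plus 3 dilution
points per shipment. The five-platform demo configuration uses class noise
levels of σ_within 0.04–0.09 and σ_between 0.08–0.20 (amino acids tight,
glycerophospholipids/organooxygen compounds drift-prone), one platform with
an arbitrary relative scale, and deliberate class-specific bias (e.g. 0.80
on one platform's fatty acids) so the accuracy stage has structure to find.
Population concentrations span ~0.5–500 µM. What the generator does *not*
emulate: chromatographic drift within a run, correlated missingness across
metabolites, isomer/subspecies mismatch between platforms, or any
case–control biological effect. Passing tests therefore demonstrate that
the estimators recover known variance components, biases and linearity
under the stated noise model — not that any real platform performs at
these levels.

Recovery checks and the acceptance script use a single platform with 500
metabolites, 6 parents per group and σ_within = σ_between = 0.10; at that
size the RMS-recovered CVs have sampling error of a few tenths of a
percentage point, comfortably resolving the intra (≈10.0%) vs inter
(≈14.2%) separation, while a full run stays in seconds.

## Degenerate inputs and tie-breaks

A pair (0, 0) has no defined CV and raises; a pair with one zero is valid
(CV ≈ 141%). Metabolites with zero complete pairs are reported
not-assessable (`n_pairs=0`), never silently dropped. Classes with no
assessable metabolites are omitted from summaries. Single-shipment tables
skip the inter-assay and shipment-consistency stages with a warning rather
than failing. Strict table validation rejects negative values, duplicate
(platform, shipment, sample, metabolite) keys and inconsistent missing
flags with row-indexed diagnostics; a lenient mode drops and reports the
offending rows, preserving count(in) = count(kept) + count(diagnosed).

## Known limitations

- Harmonization is lookup-only; synonym resolution and lipid shorthand
  parsing are out of scope, so overlap counts are lower bounds under messy
  nomenclature.
- Accuracy requires absolute units; no attempt is made to rescale
  relative-unit platforms onto µM.
- The class-average statistics treat metabolites as exchangeable within a
  class; heavily skewed class compositions will dominate their class mean.
- LOD censoring is a hard threshold per platform, not a probabilistic
  detection curve.
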