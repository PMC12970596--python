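# Methods

## The functional-index model

`lipidindex` treats a quantitative lipidomics profile not as hundreds of
independent species but as a small panel of biochemically defined readouts.
Each of the 42 packaged indices is a ratio (or abundance-weighted sum) over
lipid classes, molecular species or individual fatty chains, chosen so that
its numerator and denominator sit on opposite sides of one biochemical
process (storage vs membrane, saturation vs desaturation, intact vs lyso,
substrate vs product of a sphingolipid conversion, …). Ratio-based
definitions make the indices invariant to per-sample global scaling, so they
are comparable across platforms and do not require absolute quantification.
The assumptions are correspondingly explicit: an index is meaningful only
when its constituent lipids are measured with reasonable class coverage, and
indices sharing lipids are correlated by construction and should be read as
a panel, not as independent tests.

### Nomenclature and membership rules

Row labels are parsed with a shorthand grammar covering sum compositions
("PC 34:1"), molecular species with "/" or "_" chain separators, O-/P-
ether prefixes (with the "PC O 34:2" and "PC-O 34:2" spellings accepted and
canonicalised to "PC O-34:2"), ";O"-style suffixes and the Chol /
Cholesterol / "ST 27:1;O" aliases for free cholesterol. Parsing is total
over this grammar: a name either yields a structured record or a structured
rejection carrying the offending token; unparseable rows are skipped with a
logged count and the run aborts only when more than half of the rows fail.
Two deliberate interpretation rules:

* the ";O" suffix counts as **oxidation** only on the ester
  glycerophospholipid classes PC/PE/PG/PI/PS (the scope of the OxPL index);
  on sphingolipids and sterols it is backbone hydroxylation;
* "PL" in class-ratio denominators means the ester set {PC, PE, PG, PI, PS};
  ether species count separately (the PI/PL row explicitly adds PI O to its
  numerator, and the ether-lipid index collects all O-/P- forms of
  PC/PE/LPC/LPE).

Chain-level indices (saturation, MUFA/PUFA, parity, chain-length bins,
named C:DB keys) operate on *chain-level totals*: every resolved chain of a
species contributes the full species abundance to its C:DB key, with
positional multiplicity (a TG 16:0_16:0_18:1 contributes 16:0 twice). The
ω-position of a double bond is not encoded in shorthand, so the ω6/ω3 and
AA/DHA indices are defined purely by the conventional C:DB keys
(18:2, 20:4 vs 18:3, 22:6). Chain-length bins are the conventional
short C2–C9, medium C10–C15, long C16–C25. Sum-composition species
contribute nothing at chain level; a dataset annotated only as sum
compositions therefore yields NA for all chain-resolved indices while the
class-level panel stays computable. Two indices that name chain properties
remain species-level by design so that they survive sum-composition data:
the Double Bond Index uses the nominal species DB count written in the name
(the plasmalogen vinyl-ether bond is not added), and PC Unsat/Sat splits PC
species on total DB ≥ 1 vs = 0.

The three chain-matched lyso/intact ratios pair a lyso species with intact
species that actually contain its chain: the numerator sums lyso species
(of the given linkage — ester, alkyl or alkenyl) whose single chain occurs
among the resolved chains of at least one intact PC/PE of the same linkage,
and the denominator sums intact species containing at least one chain seen
as a lyso. This restricts the ratio to the part of the pool that can
actually interconvert by deacylation/reacylation.

### Missing-value semantics

NA is a value, never an exception: an index is NA in a sample when its
denominator is zero there, and NA everywhere when the lipids it requires are
absent from the dataset (the GM3/GM2 ratio additionally requires both
gangliosides detected in the sample). Zeros are kept as zeros; no
pseudocounts are added and nothing is imputed at the index-computation
stage — ratio inflation at low abundance is acknowledged as a limitation
rather than papered over. Indices NA in every sample are flagged "not
evaluated" and excluded from downstream statistics.

## Statistics

Two-group comparison uses Welch's unequal-variance *t* test per index with
unadjusted p-values by default: the panel is small (≤ 42 pre-defined,
correlated readouts), so raw p-values are reported for interpretability and
an optional Benjamini–Hochberg flag is provided. Effect size is the log₂
fold change of group means with a first-order delta-method SE
(1/ln 2)·√(s²₁/(n₁m₁²) + s²₂/(n₂m₂²)), which works from the same
within-group means/variances/sizes as the Welch test; rows lacking two
non-NA values per group or a positive mean in either group are flagged
not-comparable. An index is "significant" when p < 0.05 and |log₂FC| ≥ 1
(both thresholds configurable). With more than two groups the comparison
switches to a per-index one-way Welch ANOVA (no fold change).

Functional dominance per category is Σ|log₂FC| over significant indices
divided by the number of indices *effectively evaluated* in that category,
so missing or filtered indices do not bias the normalisation; a category
with nothing evaluated is NA. Biomarker ranking reports Welch *p*,
ROC AUC from the Mann–Whitney statistic polarity-corrected to
max(AUC, 1 − AUC), classic pooled-SD Cohen's *d*, and post-hoc power of the
two-sample *t* test at the observed |d| computed exactly from the
noncentral-*t* distribution (with a normal approximation when the
noncentrality is too extreme for the quadrature); rows are ordered by
ascending *p*, then descending AUC, then descending |d| (a pragmatic
composite ordering), and the table is truncated to 20 rows.
Constant indices score AUC 0.5, d = 0, p = 1 and rank last. The bubble-plot
"top ten" are the ten smallest p-values. Degenerate zero-variance groups in
the Welch test resolve by the separation limit (p = 1 on equal means, p = 0
otherwise).

## Multivariate views

PCA and PLS-DA need a complete matrix: indices with more than 20% NA are
dropped (logged), remaining NAs are imputed with the per-index median,
zero-variance columns are removed, and the matrix is centered and
auto-scaled by default (center-only and Pareto available; PLS-DA uses the
same default scaling as PCA). PCA is the SVD solution; PLS-DA is NIPALS
PLS2 on one-hot group membership with 2 components by default (matching 2-D
score plots) and 95% Hotelling-T² ellipses per group. VIP follows
VIP_j = √(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a), so Σ VIP² = p exactly —
an identity asserted for every fit. The clustered heatmap offers seven
distances — Euclidean, Manhattan, Chebyshev, Canberra, Minkowski (p = 3),
correlation (1 − r) and Spearman (1 − ρ) — with complete (default), average,
single or Ward linkage on both samples and indices, keeping the top-n
indices by variance (clamped when n exceeds the panel).

## From indices to proteins

Each index carries a curated human protein list (enzymes, transporters and
regulators with a direct mechanistic link to its lipids); the union over
significant indices, with per-index provenance, seeds a STRING association
query whose request payload (network type full/physical, confidence score
0–1000, added neighbour count, one of eight node-annotation sources,
organism field defaulting to human and reserved for future orthology
support) is serialised to disk — no network call is ever made by the
analysis or the tests; an explicit opt-in helper can post it.

Enzyme direction calls are reaction-based: for each curated reaction
A + B → C + D (a packaged minimal table of ~16 human reactions covering the
recurrent enzymes of the index panel; completeness is not claimed) the
product and substrate weights are the group means of per-sample summed
abundances, the balance is product/substrate per group, and the call is
forward-increased (decreased) when |log(B_exp/B_ctrl)| exceeds log(1.1) —
a 10% relative tolerance chosen as the indifference band, making calls
exactly antisymmetric under group swap. Any zero sum gives "indeterminate";
reactions with no measurable lipids are skipped. These are
activity-oriented hypotheses from stoichiometry and observed abundances,
not kinetic measurements, and non-lipid co-substrates are ignored.

## Synthetic studies

The generator emulates a multi-group lipidomics study from a 52-species
template pool covering every class used by the library at both annotation
levels, with class-typical base abundances spanning ~3 orders of magnitude
(ratio indices must be exercised across the realistic dynamic range).
Abundances are lognormal with mean exactly the base level: the noise factor
is exp(N(−σ²/2, σ²)) with σ² = ln(1 + CV²), default CV 0.2 and 10 samples
per group — typical biological variability for a well-powered lipidomics
cohort. A planted effect multiplies the numerator lipids of one index by
2^δ in the experimental group; because those lipids are disjoint from the
index's denominator (fraction indices subtract the numerator from the
total), the planted log₂FC is recovered exactly in the noise-free limit and
unbiasedly under noise. Effects touching shared lipids with different
factors are rejected. What the generator does **not** emulate — missing
values, instrument artifacts (in-source fragmentation, isotopes, adducts),
class-correlated noise, batch effects — bounds what passing tests show: they
validate the algebra, calibration and plumbing of the method, not its
robustness to real acquisition artifacts.

A fixed 30-species, 3 + 3-sample toy study backs the worked example and the
golden-file determinism check. Its within-group spread is a deterministic
species-dependent perturbation (±7%, factors indexed by (3i + 7j) mod 11, a
coprime scheme so no sample is a scalar multiple of another and every ratio
index has within-group variance); planted contrasts are 2.2-fold so that
the resulting |log₂FC| ≈ 1.14 sits clearly away from the default
significance boundary of 1.

## Numerical choices and problem sizes

All index evaluation reduces to per-lipid weight vectors and dot products; a
reference dictionary-based implementation of every membership rule is kept
alongside and the two are held to 1e-12 relative agreement against an
independent brute-force oracle. CSV exports use 6 significant digits and the
literal "NA", making full runs byte-reproducible under a fixed seed. The
statistical calibration checks use 1000 null studies (type-I error, judged
against the 99% binomial interval around 0.05), a 10,000-replicate bootstrap
(delta-method SE, 15% agreement band) and 500 replicate studies for
planted-effect recovery (|bias| < 0.05, top-20 membership > 95%) — sizes at
which the Monte-Carlo error is well below the tested tolerances while the
whole suite stays interactive.

## Known limitations

Sum-composition-only data reduce index coverage; vendor nomenclature support
is a minimal translation table, not a full translator; protein lists are
human-only (the organism field is reserved); the reaction table is a
curated minimal set; ω-position, sn-position semantics beyond separator
recognition, isotope labels and oxidized-lipid sub-speciation are out of
scope; and no mixed-effects, longitudinal or covariate-adjusted models are
provided.
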