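# Methods

## Overview

`oligoscreen` implements a pharmacogenomic screen for pro-oligodendrogenic
compounds as four composable stages: signed-signature construction from
DEG tables, connectivity scoring against a perturbation compendium,
curated gene × process scoring (OligoScore), and rule-based
pharmacological filtering. A synthetic-data generator produces every
input kind with planted ground truth, which is how the pipeline is
validated end to end.

## Signature construction

A DEG table carries gene symbols, a fold-change (linear `fc` or
`log2fc`; exactly one per table), a p-value, and optionally an
expression level in FPKM-like units. Filtering keeps genes with
`pvalue < p_max` and linear fold-change `> fc_min` (up, +1) or
`< 1/fc_min` (down, −1). Defaults are `fc_min = 1.2`, `p_max = 0.05`,
expression floor `0.5`, all applied as **strict** inequalities,
following the printed operators of the screening protocol this package
operationalises. The down-side cutoff `1/fc_min` is the symmetric
reciprocal on the log scale; protocols of this kind typically leave the
down rule implicit, so the symmetric choice is documented here as a
design decision. Log-scale input is converted internally, and filtering
a log2 table is exactly equivalent to filtering the linear table.

Gene symbols are canonicalised by stripping whitespace and upper-casing.
This doubles as a pragmatic mouse↔human match (compendium profiles are
typically human, signatures mouse); no alias or orthology resolution is
attempted, and an alias map can be applied by the caller before
construction.

Set algebra is concordance-aware: `intersect` keeps genes present in
both sets **with the same sign** (discordant genes are excluded and
reported in provenance), `exclude` removes by symbol. For a
progenitor/mature stage pair, `specification = intersect(mature,
progenitor)` and `differentiation = mature \ specification`, which
partitions the mature set exactly even when stages disagree on a gene's
direction (such genes stay on the differentiation side). The combined
signature is the union of sources under a `RefineConfig`: a minimum
number of supporting sources (default 1) and a direction-conflict rule
(default: drop the gene and report; optional majority vote with ties
dropped). The defaults make refinement the identity union, because the
exact refinement criteria used to produce published combined signatures
of this kind are generally not enumerable from their description; every
criterion applied is recorded in the output's provenance.

## Connectivity statistic

Profiles are discretised to signs (mode `sign`, zeros dropped; mode
`topk` tags the k most up- and down-regulated genes, deterministic
(value, symbol) tie-break). Over the n genes shared by query and
discretised profile, with m concordant and x = n − m discordant signs,

    s = (m − x)/n,   z = s·√n.

`s` equals the Pearson correlation of the two ±1 vectors when each has
balanced signs, which is the sense in which platform descriptions of
such scores call them "Pearson-type"; for unbalanced sign distributions
the two differ, and this package's statistic is the concordance form
above. Three null models for m under random signs (m ~ Binomial(n, ½))
are provided:

* `analytic` — two-sided normal p from z. Fast; biased for small or
  fixed even n (the concordance count is discrete, with an atom at
  p = 1 of mass ≈ 0.8/√n when n is even).
* `binomial` — exact two-sided binomial test (scipy). The default.
* `permutation` — query-sign resampling. For n ≤ 12 all 2ⁿ sign
  assignments are enumerated, which coincides exactly with the binomial
  p; above that, a seeded Monte-Carlo estimate with the add-one
  correction (count + 1)/(n_perm + 1).

Because the analytic approximation is never load-bearing (exact nulls
are always available), its calibration is asserted only in the regime it
is used for: random queries of varying size against random profiles,
where the mixture over overlap sizes smooths the discreteness and the
p-distribution is uniform to within Monte-Carlo error.

Profiles sharing fewer than `min_overlap = 5` genes with the query get
no call (score 0, p = 1, flagged "insufficient overlap") rather than an
unstable score; the floor is a package default, not a published
constant. Genes of the query absent from a profile are dropped from
that comparison only and recorded in `n_overlap`.

Across a compendium, p-values are Benjamini–Hochberg corrected by
default (α = 0.05); a profile is called correlated/anticorrelated by the
sign of s among q ≤ α survivors. Rankings sort by z descending with
lexicographic id tie-break so output files are deterministic. Hub-gene
queries run the same machinery over a gene-perturbation compendium and
partition significant profiles by sign.

## OligoScore

The curation table maps (gene, process) pairs to signed integers in
{−3…−1, +1…+3}; 0 is not a valid stored value (absence = not curated),
matching the 1–3 low/medium/strong convention scored positively or
negatively. Seven processes, fixed order: specification, proliferation,
migration, survival, differentiation, myelination, remyelination.

A signed query scores S_p = Σ_g direction(g) × score(g, p). The sign
convention — down-regulating an inhibitor contributes positively — is
stated explicitly here because resources of this kind usually imply it
without writing it down. All arithmetic is integer; every nonzero term
is recorded in a ledger, and each S_p equals its ledger sum exactly.
The total Σ_p S_p is the compound's pharmacogenomic score. Scoring is
linear over disjoint queries and sign-equivariant, and |S_p| is bounded
by 3 × (curated genes hit).

Compound target sets are derived from the profile's discretised signs
restricted to curated genes, either all of them (`all`, the default) or
only those concordant with the query signature (`concordant`); both
modes are exposed because published compound rankings of this kind do
not state which set they used. An optional normalisation by
`n_genes_hit` exists but is off by default; ranking uses raw totals.

The bundled `data/oligoscore_demo.csv` is a **synthetic demo resource**
(~24 well-known regulators with illustrative magnitudes: strongest
specification score on Olig2, strongest differentiation score on Sox10,
negative survival/differentiation scores on Tnf and Tlr2). It exists so
examples and tests run self-contained; real analyses should load the
full curated resource from the same CSV dialects.

## Screening and filter policy

Candidates are the sorted id-intersection of the correlated calls from
the two query routes. Ranking is by total pharmacogenomic score,
descending, ties by id. The blocklist (known pro-oligodendrogenic
agents) matches case-folded names.

The ADMET filter consumes a prediction table (it never computes
properties from structure): BBB pass/fail with probability, logPS/logBB
carried as metadata only, five toxicity endpoints (mutagenicity,
clastogenicity, carcinogenicity, reprotoxicity, hERG cardiotoxicity)
with probabilities, and a reliability index (RI) per prediction.
Predictions with RI < 0.3 (strict, per the cutoff convention "under
0.3") are discarded — the endpoint is simply not evaluated for that
compound. A compound passes iff it has ADMET data, is predicted to
cross the BBB when required (a missing or unreliable BBB prediction
fails the compound: brain penetration needs positive evidence), and
every reliable toxicity probability is ≤ its endpoint maximum (default
0.5 — a tunable package default; published filters of this kind show a
qualitative gradient rather than a numeric cutoff). Every failure
lists its violated rules; every input compound lands in exactly one of
pass/fail. Tightening probability bounds or requiring BBB can only
shrink the pass list; note that *raising* `ri_cutoff` discards more
predictions and can therefore grow it — RI is an evidence gate, not a
severity dial.

Shortlisting takes the first k of the ranked pass list (the published
two-stage selection used k = 40 then k = 11).

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the validation conditions: a universe of
2000 genes, a 200-gene signature (half up, half down), 100 compounds
with 5 planted mimics, per-gene sign-concordance `effect = 0.9` for
planted compounds (0.5 = null), DEG noise `noise_sd = 0.08`, and a
40-gene curation table. The 200/5/100/0.9 values are the planted-recovery
study conditions; `curation_size = 40` scales the >430-gene real
resource to the 10×-smaller simulated universe. One global seed fans
out into fixed per-generator substreams, so adding a generator never
perturbs existing fixtures, and all file output is byte-stable.

DEG tables place |log2FC| = 1.5 on truth genes (signed by direction)
plus Gaussian noise; p-values are the two-sided normal tail of
z = log2fc/noise_sd, i.e. derived from the same statistic as the
fold-change, which makes filter sensitivity and FDR analytically
tunable (at the defaults: sensitivity ≈ 100%, FDR ≈ 1%). Compendium
profiles cover the signature genes plus a random background slice, with
uniform magnitudes in [0.5, 2]. ADMET fixtures make each doomed
compound violate exactly one named rule.

The generator does **not** emulate: count-level single-cell data,
batch or cell-line effects, dose–response structure, correlated genes
(each gene's behaviour is independent), or realistic p-value/logFC
joint distributions from finite-replicate designs. Passing the planted
recovery checks therefore demonstrates the pipeline's statistical
machinery and plumbing, not performance on real transcriptomes.

## Numerical choices

* All thresholds strict; boundary rows (fc = 1.2, p = 0.05, FPKM = 0.5,
  RI exactly 0.3 retained) behave per the printed operators.
* Binomial and enumeration nulls are exact rational tails evaluated in
  float; permutation Monte-Carlo uses (hits + 1)/(n + 1).
* Rankings and file outputs break all ties deterministically
  (lexicographic id); re-running any stage with identical inputs and
  seed is byte-identical.
* Degenerate inputs: empty query → all-zero score vector; empty
  compendium → empty result list; all-zero profile → empty sign map
  with a warning; overlap below the floor → flagged null call, never an
  exception.
* p-values are clipped to [0, 1] after the two-sided doubling.

## Validation sizes

The planted-recovery validation runs 100 seeded end-to-end screens in
the test suite (and 50 in `scripts/acceptance.py`) at the default
conditions, plus 100 (50) null-calibration runs at effect 0.5; the
analytic-null uniformity check uses 2000 simulated query/profile pairs.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted bounds while keeping the whole validation in tens of seconds.

## Known limitations

* The connectivity statistic is the sign-concordance score; platforms
  that weight genes by rank magnitude will order borderline compounds
  differently (the `topk` discretisation approximates but does not
  reproduce such weighting).
* Symbol-level matching across species ignores paralogy and aliasing.
* The demo curation table is illustrative, not the curated resource;
  absolute scores computed against it have no biological meaning.
* The ADMET stage is only as good as the consumed prediction table;
  the package applies policy, it does not model pharmacology.
* Published compound/gene list cardinalities can be checked with the
  package's set operations only when the published supplementary lists
  are supplied by the user (see `tests/test_acceptance.py`); they are
  not redistributable here.
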