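# Methods

## Model and procedure

The analysis treats a protein feature (a PTM, motif or domain
annotation) as defining a *group* of carrier proteins, and asks whether
that group's EV:cell abundance-ratio distribution is displaced upward
relative to all detected proteins. The pipeline is, per dataset (one
producer cell line with matched EV and cell runs):

1. **Pseudocount.** Add 1 to every raw area measurement, per replicate,
   before any aggregation. This removes zeros (missing label-free
   measurements are recorded as 0 area) while exactly preserving
   pairwise differences between samples. The shift is not idempotent,
   so the `AbundanceMatrix` records whether it has been applied and
   refuses a second application.
2. **Ratios.** Aggregate pseudocounted areas across replicates within
   each compartment (arithmetic mean by default) and take
   r = log10(EV/CELL) per protein. A protein absent from both
   compartments gets r = 0 exactly.
3. **Size filter.** Intersect each feature's carrier set with the
   detected-protein set and drop features with fewer than
   `min_group_size` (default 5) detected carriers.
4. **KS test.** Two-sided two-sample Kolmogorov–Smirnov statistic of
   carriers vs background, p-value per the method table below.
5. **Benjamini–Yekutieli.** Step-up correction with
   c(m) = Σ_{i=1..m} 1/i, applied within each category family (PTM,
   MOTIF, DOMAIN; pooled features join the family of their members).
   BY is chosen over BH because features overlap heavily in carriers,
   so the test statistics are dependent in an uncontrolled way; BY
   controls FDR under arbitrary dependence, at the price of
   conservatism.
6. **Call.** enriched ⇔ p_adj < alpha (default 0.05) and
   median(carrier ratios) > median(background ratios). The KS test is
   two-sided; enrichment direction comes only from the median
   criterion, so a significantly *depleted* feature is never flagged.
7. **Intersection.** Enriched feature sets from k ≥ 2 datasets are
   decomposed into exact Venn regions keyed by frozen subsets of
   dataset names; the all-datasets region holds the cross-line robust
   features.
8. **Candidates.** For a feature of interest, detected carriers are
   ranked ascending by sequence length (ties broken lexicographically
   by accession): the smallest carrier is the proposed minimal
   scaffold. No secondary biological criteria (topology, signal
   peptides) are applied; length is deliberately the only key, with an
   optional ratio annotation carried along for inspection.

## Assumptions

- Abundances are protein-level label-free areas; no peptide roll-up,
  between-run normalisation, or imputation beyond the pseudocount.
- Carrier membership is per protein: sites are parsed and retained, but
  a protein with three glycosylation sites counts once. Counts in all
  outputs are protein counts.
- Isoform accessions (P12345-2) collapse to the parent accession so
  annotation and abundance tables join on one key.
- The background for the KS test includes the carriers themselves
  (default `all_including_carriers`): the reference distribution is
  "all proteins", and carrier groups are typically a small fraction of
  it. `all_excluding_carriers` is available for sensitivity analysis;
  with small prevalent groups the two differ negligibly, but exclusion
  removes the (small) contamination of the background median by the
  group under test.

## Kolmogorov–Smirnov details

D is computed with an integer numerator: with group size n and
background size m, every ECDF difference at a pooled sample point is a
multiple of 1/(nm), so D = D_num/(nm) with
D_num = max |A·m − B·n| over pooled points (A, B cumulative counts).
ECDFs are right-continuous and evaluated at pooled sorted points, so
ties need no jittering and D is exact.

P-value methods:

| method | when (default `auto`) | description |
|---|---|---|
| `exact_small_n` | min(n, m) ≤ 25 | Exact *conditional* null: dynamic programming over all C(n+m, n) assignments of the observed pooled multiset, integer arithmetic throughout. Conditions on ties, so it agrees exactly with full permutation enumeration; on tie-free data it reproduces the classical distribution-free null. |
| `asymptotic` | min(n, m) > 25 | Kolmogorov limiting distribution (scipy). |
| `permutation` | on request | Seeded Monte-Carlo label shuffles with the (hits+1)/(rounds+1) estimator; the reference oracle for the exact method. |

The conditional (tie-aware) exact null was chosen over the classical
continuity-assuming exact null because ratio data contain ties —
notably the r = 0 atom from proteins undetected in both compartments —
and the continuity assumption is anti-conservative there; the
permutation test, which is correct under ties, is what the exact method
must agree with.

## Parameters

| parameter | default | unit / scale | why |
|---|---|---|---|
| pseudocount `c` | 1 | area units | removes zeros, preserves distances; negligible against typical areas (~10^6) |
| aggregation | mean | — | replicate combination; median available (robust to one dropped-out replicate) |
| `min_group_size` | 5 | proteins | below this the KS test has essentially no power |
| `alpha` | 0.05 | — | threshold on BY-adjusted p by default; a flag restores the raw-p reading |
| log base | 10 | — | fixed; ratios are reported in decades |

## Synthetic data

The generator emulates the structure the pipeline consumes: per-protein
baseline log10 areas b_i ~ N(mu_cell, sigma_between); each replicate
measurement is 10^(b_i + ε) with replicate noise ε ~ N(0, sigma_within);
EV replicates add the protein's planted shift (the sum of deltas of the
features carrying it); each raw measurement is independently zeroed
with probability `zero_rate`. Defaults — 1000 proteins, 20 features of
50 carriers, 3 replicates per compartment, sigma_within = 0.3,
mu_cell = 6.0, sigma_between = 1.0, zero_rate = 0.1 — describe a
mid-sized label-free experiment: areas spanning roughly four decades
around 10^6 with ~0.3-decade replicate scatter and ~10% missingness.
Carrier assignment and measurement noise run on independent seeded
sub-streams (`SeedSequence.spawn`), and `carrier_seed` can pin the
catalog while noise varies, so several simulated cell lines share one
annotation catalog the way real cell lines share UniProt.

What the generator does **not** emulate: intensity-dependent
missingness (an option exists for uniform zeroing only),
peptide-level identification, shared-peptide ambiguity, batch effects,
and correlated features (carrier sets are drawn independently, so
feature overlap is only by chance). Passing the simulation-based tests
therefore demonstrates correctness of the statistical machinery under
the stated generative model, not performance on any real dataset —
real-data feature counts depend on the proteomics tables and the
annotation snapshot used.

A known property of the median-difference summary: with prevalence
π of shifted carriers in the background, `median_all` is itself pulled
up by O(π·δ), so `median_group − median_all` under-estimates the
planted δ by a few percent at π = 0.05 (measured ≈ 0.47–0.48 for
δ = 0.5). This is a property of the estimand — the background is
deliberately *all proteins* — not an implementation artefact; the
`all_excluding_carriers` mode removes it.

## Numerical and design choices

- All tabular outputs are UTF-8 TSV, fixed column order, floats at 6
  significant digits, with full-precision JSON twins; result rows sort
  by (p_adj, category, name) with a stable sort so identical inputs
  give byte-identical outputs.
- The run directory records the resolved configuration, SHA-256 input
  checksums and a config hash (analysis-relevant fields only — output
  paths and log level are excluded, so runs into different directories
  remain byte-identical).
- "Manual curation" of duplicate features is operationalised as
  deterministic normalisation: trim/collapse whitespace, drop qualifier
  text after the first ";", case-sensitive matching, exact-tuple
  deduplication; an optional synonym TSV merges known variant labels.
- Default UniProt feature classes: CARBOHYD, MOD_RES, LIPID → PTM;
  MOTIF → MOTIF; DOMAIN → DOMAIN. Cross-links and disulfides are out by
  default (covalent topology rather than decoration) but any class can
  be opted in with an explicit class → category mapping.
- Default pooling map: "glycosylation" (all CARBOHYD-class names) and
  "lipidation" (all LIPID-class names). A pool whose rule matches no
  annotation is omitted rather than emitted empty.
- Degenerate inputs: empty catalog after filtering yields an empty
  result table (logged, not an error); a feature whose carriers are the
  whole background gives D = 0, p = 1; empty samples are a validation
  error.

## Limitations

- No effect-size modelling beyond D and the median difference; no
  protein-level differential abundance testing.
- BY conservatism plus the median criterion makes the empirical
  type-I error far below alpha (measured ~0 at the defaults); power at
  small deltas or small carrier groups is correspondingly modest.
- The candidate ranking mirrors a deliberately simple heuristic
  (smallest detected carrier); real scaffold selection involves
  topology and biology outside this package's scope.
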