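# Methods

## Model and procedure

The pipeline links protein targets to adverse drug reactions (ADRs)
through drugs.  Evidence arrives on two sides: drug–ADR pairs (from
spontaneous-reporting or curated sources) and drug–target pairs (from
bioactivity or interaction-score sources).  After curation and
filtering, every (protein, ADR) pair is tested for enrichment over the
unified drug universe by a one-sided Fisher exact test, corrected to
q-values per evidence set.  The core assumption is causal transitivity
with family confounding: a single family member typically causes an ADR,
but family-mates inherit the drug evidence through shared binding, so
family-aware pruning is required to avoid wholesale false positives.

### Disproportionality screen

Spontaneous reports are normalized (case-fold, trim, punctuation-strip,
synonym lookup; unresolvable names dropped), deduplicated on the exact
key (sorted drug ids, sorted preferred terms, age, sex, weight, event
date, country; the lexicographically smallest report id survives; absent
demographics only collapse with equally absent ones), and screened with
a per-drug multinomial likelihood-ratio test.  For drug *i* with *nᵢ*
reports and ADR *j* with margin *mⱼ* among *N* reports,

    E  = nᵢ mⱼ / N
    llr = n ln(n/E) + (nᵢ − n) ln((nᵢ − n)/(nᵢ − E)),   llr = 0 if n ≤ E.

The statistic is one-sided because signal detection seeks over-reporting
only.  Its null is the per-drug **maximum** llr over ADRs under
multinomial allocation of the drug's reports across ADRs with
probabilities proportional to the ADR margins (margins are normalized to
sum to one because multi-ADR reports make raw margins exceed N).  The
critical value is the empirical (1 − α) quantile of `lrt_mc_reps`
Monte-Carlo replicates (default 1000, α = 0.05), deterministic per seed.
Reading the cut as the upper (1 − α) quantile is the only reading
consistent with keeping *statistically significant* signals — the literal
lower 5th percentile would flag 95% of pairs.  A (drug, ADR) pair is
kept only if significant in **both** self-reporting sources; its evidence
statistic is the smaller of the two llr values.  The alternative —
intersecting all pairs before testing — was considered and rejected
because per-source margins differ and a pooled test would mix reporting
cultures.

### ADR term filtering

Terms are removed when their *primary* system organ class is one of the
eight unspecific classes (general disorders, injury/poisoning,
investigations, neoplasms, product issues, social circumstances,
surgical procedures, infections), plus the listed psychiatric high-level
(group) terms, matched case-insensitively at either the HLT or HLGT
level since vocabularies differ in which level stores the phrase.
Secondary SOC links are ignored (each term has one primary parent).

### Drug unification

Precedence: (1) identical full 27-character InChIKey (the 14-character
skeleton would merge stereoisomers); (2) identical case-folded standard
name, gated — whenever both sides carry structures — on Tanimoto ≥ 0.7
over 2048-bit radius-2 circular fingerprints, the de-facto 2D standard;
(3) same name below the threshold is a logged conflict, not a merge.
Every name match is gated, not only ambiguous ones: the gate is cheap
and an unconditional rule is easier to reason about.  Names carried by
two distinct InChIKeys on one side disable name-matching for that name.
Matching is greedy over records sorted by id, so input order is
irrelevant.  Drugs with fewer than 10 distinct post-filter preferred
terms are discarded (counted after SOC filtering and signal screening,
per the workflow order).

### Target filtering

Potency-typed pairs survive at affinity ≤ 100 nM ("or better" = boundary
kept); confidence-typed pairs at score ≥ 0.8 on the [0, 1] scale (the
score cut-off is interpreted on the normalized scale; the 0–1000 integer
convention is the same number scaled).  Proteins annotated to drug
catabolism/metabolism (GO:0042737, GO:0017144) are removed — binding to
metabolizing enzymes reflects pharmacokinetics, not the pharmacology
that causes ADRs.  Sequence identity is identities in a global alignment
divided by the **shorter** length (the convention of greedy-clustering
tools); alignment uses match +1 / mismatch −1 / gap open −2 / extend
−0.5.  Clustering is greedy and incremental over sequences sorted by
decreasing length (ties by accession): each sequence joins the first
cluster whose *centroid* it matches at or above the threshold, else
founds a cluster — the centroid is therefore the founder, deterministic.
Redundancy is collapsed at 90%; removed members' drugs are re-attributed
to the centroid (union) so no drug evidence is lost — discarding instead
is available behind `merge_redundant_evidence: false` since the original
behaviour of such pipelines is ambiguous.  Families form at 70% on the
post-90% centroids.  A drug binding strictly more than 10 members of one
family keeps only the pair to the family centroid.  The main target of a
family is approximated as the member bound by the most unified drugs
(ties: smallest accession) — literature-curated main-target annotations
are not programmatically available, so the proxy is overridable via a
per-family TSV — and other members are kept only when sharing at least
50% of the main target's drugs.

### Association statistics

The drug universe per evidence set is the intersection of drugs with
surviving ADR evidence and surviving target evidence, recomputed after
all filters.  Pairs with zero overlap (cell a = 0) are not tested by
default: a one-sided test cannot reject there, and skipping them keeps
the multiple-testing burden honest (`test_zero_overlap` reverses this).
The Fisher tail is summed from exact log-pmf terms (log-gamma based,
max-shifted); an exact rational oracle bounds the absolute error below
1e-12 for all N ≤ 30 (measured ~3e-14).  The one-sided (greater)
alternative is the default because the resource models harms, not
protection; `fisher_alternative: two-sided` is available.  Storey
q-values use π̂₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05…0.95 with a cubic
polynomial smoother read off at λ = 0.95, clipped into (0, 1]; below 100
tests the estimate is unstable and π₀ = 1 is used, which reduces exactly
to Benjamini–Hochberg.  Significance is q ≤ 0.05, equality inclusive.

## Synthetic ecosystem

The generator emulates what the pipeline needs and nothing more:

- **Vocabulary** — `n_adrs` preferred terms over `n_socs` SOCs, the
  excluded SOC names verbatim, a psychiatric SOC with both excluded and
  kept HLGTs.
- **Proteome** — families of point-mutated founder sequences.  Per
  family: the founder (centroid), one near-duplicate (92–97% identity,
  collapsed at 90%), and siblings in a band around
  `within_family_identity` = 0.78 (clustered at 70%, distinct at 90%);
  cross-family identity is verified < 0.60.  All bands are enforced by
  rejection sampling against the pipeline's own identity function, so
  both thresholds are exercised from both sides.  One family is
  annotated with the metabolism GO terms.
- **Chemistry** — valid SMILES composed from scaffold/chain/tail parts;
  InChIKey-like identifiers are deterministic hashes of the SMILES in
  the 14-10-1 format (real InChI derivation adds nothing for
  unification-logic testing).  Founders act as promiscuous hub targets:
  drugs choose a primary target with founder bias 0.6, bind family-mates
  at 0.35 and other families' founders at 0.10 — values chosen so that a
  causal founder has roughly 35–44 binding drugs, which a power
  calculation shows is needed for the planted effect (below) to clear
  the multiple-testing threshold.  85% of sampled affinities pass the
  potency filters; one pair sits exactly at 100 nM and one exactly at
  0.8.  A few drugs are planted as name conflicts (same name, dissimilar
  structures) and as single-sided records.
- **Truth and evidence** — ADRs are caused by *targets*: each planted
  (founder, ADR) link gives every binding drug probability
  `causal_adr_rate` = 0.35 of truly presenting the ADR.  Each drug also
  carries ~Poisson(20) idiosyncratic ADRs from a 40-term common pool
  (12 of them in excluded SOCs), giving drugs realistic ADR counts — so
  the 10-ADR filter is survivable — without creating protein-level
  signal, because idiosyncratic terms are per-drug independent.  Planted
  ADRs are drawn outside the pool so their drug margins stay clean.
  All four sources draw from the same drug-level truth: curated sources
  emit truth pairs at 95% / 90% coverage plus 0.2% noise pairs; report
  sources mention each truth term with probability 0.5 per report and
  other terms at the background rate 0.02.  Exact duplicate reports are
  injected at 5% and name misspellings at 5%; demographic keys of
  originals are kept collision-free so the deduplication count is exact.
- **Bookkeeping** — every deterministic stage's expected survivor set is
  computed at generation time by independent set arithmetic
  (affinity/GO survivors from the sampled pass flags, clusters by
  replaying greedy clustering on the generator's identity matrix, and so
  on) and written to `ground_truth.json`.  Stages downstream of the
  Monte-Carlo screen on the self-reporting branch are stochastic and are
  validated statistically (planted-pair containment, end-to-end
  recovery) rather than by set equality.

What the generator does **not** emulate: real reporting-rate
heterogeneity across drugs, multi-country coding differences, real
chemical-space structure, indel variation between homologues, and real
MedDRA term counts.  Passing tests therefore demonstrate the pipeline's
logic and statistical calibration, not its behaviour on any particular
licensed database release.

## Problem sizes and numerical choices

The default ecosystem is 300 drugs, 60 targets in 12 families, 120
preferred terms, 20 000 + 10 000 reports, 15 planted links at 0.35
causal vs 0.02 background — sizes at which every stage is exercised and
the full pipeline runs in well under a minute.  The screen uses 1000
Monte-Carlo replicates per drug; the calibration check uses 40 drugs ×
20 seeds of a single-term-per-report null generator (one term per
report makes the multinomial null exact).  Fisher p-values are clipped
at 1.0 after summation; q-values are made monotone by the usual
running-minimum from the largest p.  Degenerate inputs: empty universes
and empty margins return empty results or p = 1 rather than errors;
zero-report drugs are excluded from the screen with a warning.

## Known limitations

- The main-target proxy (most bound drugs) can disagree with
  literature-curated main targets; the override file is the escape
  hatch.
- The LLR screen's multinomial null treats ADR mentions within a report
  as exchangeable with mentions across reports; with many terms per
  report it is mildly conservative (measured null flag rate ≈ 0.036 at
  α = 0.05).
- Greedy clustering is order-dependent by design (longest first); it
  matches the behaviour of the standard tools but is not a globally
  optimal partition.
- Name normalization is dictionary-based; misspellings absent from the
  synonym table are dropped, not fuzzily recovered.
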