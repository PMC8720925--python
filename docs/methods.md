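# Methods

## Scope

`pvnet` implements a two-arm pharmacovigilance analysis as a reusable
pipeline: (A) disproportionality signal detection on spontaneous
adverse-event reports via reporting odds ratios (RORs), and (B) drug–gene
interaction network analysis — one-hop interactome expansion from a seed
gene list, MCODE molecular-complex detection, and hypergeometric
over-representation analysis against pathway and disease gene-set
collections. A synthetic-data module generates inputs with known ground
truth so every stage can be validated end to end without external
databases.

## Report store and preprocessing

Reports are ingested from DEMO/DRUG/REAC tables in either the classic
`$`-delimited quarterly-file layout or an equivalent tab-separated dialect.
Input text is decoded as UTF-8 with replacement of undecodable bytes
(replacements are counted in provenance). Drug names are normalized by
case-folding, trimming, and collapsing internal whitespace; no
active-ingredient dictionary is applied, so distinct trade-name spellings
remain distinct.

Deduplication keys on the case identifier and keeps the report with the
highest version rank — the case version number when present, otherwise the
receipt date, otherwise file order — with ties broken deterministically by
the lexicographically greatest report key. This mirrors the standard
"latest case version" practice for spontaneous-report databases. The store
applies no date windowing; callers subset before ingest if needed.

Role filtering retains only drug entries with the requested role codes
(primary suspect, secondary suspect, concomitant, interacting); reports
left with no drug entry are excluded because they carry no exposure
information under the chosen role policy. Event preferred terms (PTs) are
mapped to system organ classes (SOCs) through a flat user-supplied TSV; an
unmapped PT is an explicit miss handled by policy (drop / keep / error),
never a silent empty string. Reports whose events all drop remain in the
store and contribute to the unexposed/no-event margins of contingency
tables.

## Signal detection

For drug D and event term E the deduplicated store is partitioned into the
2×2 table (a, b, c, d); a report is exposed if any retained drug entry
matches D and event-positive if any event matches E at the requested level
(PT or SOC), so each report contributes exactly once. The statistic is

    ROR = (a·d) / (b·c),
    95% CI = exp( ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.959964.

The interval is the Wald interval on the log scale, the standard choice in
the ROR literature. A pair is a signal when the CI lower bound exceeds 1
and a ≥ 2. Zero cells make the ROR non-estimable; the default reports it
(and the CI) as undefined rather than silently correcting, with the
Haldane–Anscombe +0.5 correction available as an explicit option. The
signal rule always evaluates the observed a, so a corrected table cannot
manufacture a signal from a single report. No multiplicity adjustment is
applied across event terms — the signal criterion is exactly the rule
above. Scan output is ordered by descending ROR with alphabetical
tie-breaks (undefined RORs last), making the TSV stable across runs.

## Network arm

Seed genes are read as uppercase symbols; the packaged fixture carries the
26 published montelukast-interacting genes, including the truncated symbol
"SLCO2B" exactly as printed in its source (documented, not silently
corrected). The interactome reader consumes PSI-MITAB (≥15 columns,
tolerant of extras), resolving symbols from the alias columns (5/6) with
fallback to alternative-ID and unique-ID columns, filtering by taxon on
columns 10/11 when requested, dropping self-interactions, and collapsing
repeated pairs into one edge with a supporting-record count. Expansion is
the subgraph *induced* on the seeds plus their direct interactors:
neighbor–neighbor edges are kept. One-hop induced expansion is the only
reading consistent with published seed→subnetwork size ratios; transitive
closure would engulf the giant component.

## MCODE

The molecular-complex-detection algorithm is reimplemented from its
published description, parameterized as commonly used in Cytoscape
analyses (degree cutoff 2, node score cutoff 0.2, k-core 2, max depth 100,
haircut on, fluff off):

1. **Vertex weighting.** For each vertex v with degree ≥ degree_cutoff,
   take the induced subgraph on the closed neighborhood N[v], find its
   highest k-core, and set weight(v) = k_max × density of that core, with
   loop-free density 2E/(n(n−1)). K_n vertices therefore weigh n−1.
2. **Complex prediction.** Seed from the unvisited vertex of highest
   weight (lexicographic tie-break), grow breadth-first to max_depth,
   admitting an unvisited neighbor u iff
   weight(u) ≥ weight(seed)·(1 − node_score_cutoff); admitted vertices are
   marked visited.
3. **Post-processing.** Discard candidates without a k-core at the
   configured k; haircut iteratively removes members with in-cluster
   degree < 2; optional fluff adds unvisited neighbors with closed-
   neighborhood density above the fluff cutoff (fluffed vertices may be
   shared). Cluster score = density × size; output is sorted by descending
   score with seed-id tie-breaks.

Traversal order, tie-breaking, and visitation rules are fixed
deterministically; exact concordance with any particular plug-in version
is not promised. One documented consequence of the weighting: vertices
bridging two dense regions keep the full weight of their densest side, so
two cliques joined by a single edge merge into one complex — the admission
rule has no mechanism to cut high-weight bridges.

**Recovery limits.** On planted-partition graphs (two 12-node modules,
within-module edge probability 0.9, background/cross probability 0.02 over
100 background nodes) the top-2 clusters recover both modules at Jaccard
≥ 0.8 in only about two thirds of seeded replicates at node score cutoff
0.2. This is a property of the algorithm, not a defect of the
implementation: member weights track within-module degree, which is
Binomial(11, 0.9) and spreads ~33% in relative terms, so one to four
members per module fall below the 20% admission band around the seed
weight, and a pure 9-of-12 capture already gives Jaccard 0.75. At node
score cutoff ≥ 0.3 the same experiment recovers 50/50. We keep 0.2 as the
default because it is the parameterization of record for this pipeline and
report the measured recovery rate as-is.

## Enrichment

Over-representation uses the hypergeometric upper tail: with a universe of
N genes of which K carry the term, and a query of n universe genes with k
hits, p = P(X ≥ k). The universe defaults to the union of collection genes
(the behavior of common enrichment tools when no background is supplied)
and can be overridden. All terms with k ≥ 1 enter Benjamini–Hochberg
step-up adjustment; the q-value equals the BH-adjusted p by default
(π₀ = 1), with Storey's π₀ smoother available as an option — the
reproducible default is preferred because π₀ estimation is unstable for
the short term lists typical here. A term is significant at p ≤ 0.05 and
q ≤ 0.1 (both configurable). Disease collections are ingested from a
3-column disease–gene TSV into the same collection type; results carry
GeneRatio (k/n) and BgRatio (K/N) columns. Per-cluster enrichment is the
pipeline default, mirroring cluster-stratified reporting.

## Synthetic-data generators

*Reports.* Each of n reports exposes every drug independently with its
exposure probability; each event occurs with probability odds/(1+odds),
where odds = baseline_odds × ∏ (injected OR over injected pairs whose drug
is exposed). Multiplying odds (not probabilities) makes the injected OR
exactly the estimand the ROR targets. One uniformly chosen exposed drug is
marked primary suspect, the rest concomitant; a configured fraction of
cases additionally emits an earlier case version with identical content,
giving deduplication real work. Default study conditions: 20,000 reports,
one drug of interest plus nine comparators at 5% exposure, eight PTs
across three SOCs at baseline odds 0.01, one injected association
(OR = 10), 10% duplicate versions. These defaults were chosen as a
realistic rare-exposure / rare-event regime in which a ≈ 100.

Estimator-recovery experiments evaluate the ROR on the deduplicated store
with all roles retained, because the injected OR is defined on actual
exposure. Under primary-suspect-only filtering the estimand differs:
co-exposed reports whose randomly assigned suspect is another drug carry
the elevated event rate into the comparator, attenuating the estimate by
roughly 20% in these conditions (median ≈ 7.7 instead of ≈ 9.9). The CLI
pipeline nevertheless defaults to suspect-only filtering, which is the
convention for real spontaneous-report analyses; the attenuation is a
property of suspect masking, not of the estimator.

*Interactome.* A planted-module graph: within-module pairs are wired with
p_in; pairs involving a background node with p_out; pairs spanning two
distinct planted modules are left unwired, so module recovery measures
dense-region detection rather than bridge-following (with direct
inter-module wiring at p_out the modules would be linked in ~95% of
replicates and the MCODE admission rule would merge them — see above).
Emitted as minimal PSI-MITAB with taxid:9606 plus a seed-gene file and a
plain-text truth sidecar.

*Gene sets.* One planted set per module (members plus 10% random decoys)
among uniform-random noise sets, emitted identically as GMT and as a
disease–gene TSV.

All generators draw from a single numpy Generator seeded once per run; no
global random state is touched. None of the generators attempt to match
real FAERS marginals, MedDRA term inventories, or interactome degree
distributions — passing recovery tests demonstrates estimator and
algorithm correctness under the stated models, not performance on real
data.

## Numerical and implementation choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf` and are
  verified against exact rational summation for all parameter
  combinations with N ≤ 12; BH step-up is implemented directly per its
  definition and cross-checked against `statsmodels`.
- k-core extraction delegates to `networkx.k_core` and is verified against
  a brute-force minimum-degree-deletion fixed point.
- Undefined statistics serialize as "NA"; floats as 6 significant digits.
- All orderings (scan output, cluster tables, edge lists) carry explicit
  deterministic tie-breaks; repeated runs with one seed are byte-identical.
- Validation problem sizes (2,000 null tables; 50 planted-graph and 100
  report/enrichment replicates; 20,000 reports per replicate) were chosen
  so that binomial noise on the reported rates is ~1–3 percentage points.

## Known limitations

- No PRR/IC/EBGM statistics, no stratified or adjusted RORs, no
  time-to-onset analysis.
- Drug identity is string-normalized only; gene identity is by uppercase
  symbol with no alias resolution.
- The term map is a flat PT→SOC table, not a full terminology hierarchy.
- MCODE concordance with specific plug-in builds is not guaranteed where
  their tie-breaking is undocumented; bridge-merging and the recovery
  ceiling at node score cutoff 0.2 are documented above.
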