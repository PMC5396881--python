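# Methods

## The model

`meshddi` screens a drug's PubMed literature for MeSH terms associated
with drug–drug interactions (DDIs).  The unit of analysis is the bare
MeSH descriptor: subheading qualifiers (`/pharmacokinetics`) and the
major-topic marker (`*`) are stripped everywhere, and all name matching
is case-insensitive on NFC-normalized text while stored names keep the
vocabulary's canonical casing.

**Partition.**  An article belongs to the DDI-related group A iff at
least one of eight interaction-type descriptors (drug interactions,
drug agonism, drug partial agonism, drug antagonism, drug inverse
agonism, drug synergism, food-drug interactions, herb-drug
interactions) appears among its headings; otherwise it is in group B.
Only these eight literal descriptors are used — descendants of the
Drug Interactions tree node are not auto-included — and matching is by
MeSH heading only, never by abstract text, because heading-based
assignment is the only reproducible rule given how the records are
indexed.  The split is a deterministic bipartition and idempotent.

**Candidate categories.**  Candidates are the descriptors occurring in
group A, bucketed by: *interaction* (the eight descriptors; excluded
from candidacy since they define the partition), *drug* (membership in
a user-supplied FDA-approved drug list matched to vocabulary
descriptors by normalized name), *protein* (any tree number under
`D08` or `D12.776`, prefix-matched per dot segment), *phenomena*
(`G03`, `G04`, `G06`, `G07`), else *other*.  Precedence is
interaction > drug > protein > phenomena: interaction terms must never
be candidates, and explicit drug-list identity outranks tree position.
The query drug's own descriptor is excluded from the drug bucket (it
appears in essentially every record of its own corpus).  The drug-list
restriction is applied *before* counting, so drug candidates outside
the FDA list never enter the test.

**The resampling test.**  For term *t* with observed group A count
`c_A`, the null distribution is built by drawing `|A|` articles from
group B uniformly **without replacement** (a draw is a set of articles)
in each of `n_resamples` iterations (default 1000) and counting *t* in
each draw.  One shared set of draws serves every candidate term: all
terms are counted per draw, which preserves the cross-term correlation
structure and makes the cost independent of the number of terms.  With
sample mean μ and sample SD σ (unbiased, `n−1` denominator),

    z = (c_A − μ) / σ,        p = P(Z ≥ z)  (standard normal upper tail).

The test is one-sided because the scientific hypothesis is directional
— the term is *over*-represented in DDI-related literature; depletion
is never significant.  Degenerate nulls (σ = 0) yield p = 0 when
`c_A > μ` and p = 1 otherwise, with a ±∞ sentinel for z.  A term is
selected when `c_A > min_freq` (default 5, strict inequality on the
group A count) and `p < α` (default 0.1, raw p-values).  No
multiple-testing correction is applied by default, matching the
original selection rule; a Benjamini–Hochberg option
(`correction="bh"`) tightens selection when asked.  Results are sorted
by ascending p, ties broken by descending count then term name, and a
fixed seed makes the full result list bit-identical across runs.

**Co-occurrence.**  The binary term–article incidence matrix `M`
(articles × terms) gives the term–term adjacency `A = MᵀM` in exact
integer arithmetic: entry (i, j) counts articles containing both terms,
and the diagonal holds document frequencies.  Heatmap exports use
cross-category count matrices (selected drug rows × selected protein or
phenomena columns, counted over group A), row-normalized so each
drug's profile sums to 1 (`normalized count = count / row total`;
all-zero rows stay zero and are logged).  Row and column orders come
from agglomerative hierarchical clustering on Euclidean distances of
the **normalized** matrix; the linkage method is complete by default
(single/average available) — the distance metric is fixed by the
procedure, the linkage was an open choice and is recorded here.  The
numeric artifact of record is the ordered TSV; rendered images are
optional presentation.

**Pair networks.**  For a query drug and a selected partner drug, the
article subset is group A ∩ {articles mentioning the partner}: these
articles carry an interaction descriptor by construction and the query
drug by corpus construction, so co-mentions inside them are the natural
evidence base for the pair's mechanism.  Nodes are the two drugs, the
selected protein and phenomena terms, and the interaction descriptors
present in the subset; edges connect terms co-occurring in at least
`min_weight` subset articles (default 2 — unthresholded co-mention
networks on real corpora are near-cliques), weighted by the
co-occurrence count.  Edge weights equal the corresponding adjacency
entries on the same subset by construction, and raising the threshold
can only remove edges.

**ROC validation.**  Candidate terms are ranked by p-value (ascending;
any strictly monotone transform — e.g. ranking by z instead — yields
the same curve) against user-supplied 0/1 gold labels.  Curve points
are computed at every distinct score threshold with tied scores moving
together, so the trapezoidal area equals the pairwise Mann–Whitney
statistic P(positive outranks negative) + ½P(tie) exactly.  The
frequency-cutoff sweep re-restricts the ranking to terms with count
above each cutoff (1–6 in the standard sensitivity analysis) and
recomputes the curve; a cutoff that empties one label class is
reported as undefined rather than failing the sweep.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_resamples` | 1000 | draws from group B building the null; Monte-Carlo error of μ scales as σ/√n_resamples |
| `alpha` | 0.1 | selection level on the (raw) one-sided p-value |
| `min_freq` | 5 | group A count must strictly exceed this |
| `seed` | 0 | resampling RNG seed; fixes the entire output bit-for-bit |
| `correction` | none | optional `"bh"` FDR adjustment of selection |
| `min_weight` | 2 | pair-network edge threshold (co-occurrence count) |
| `date_end` | — | inclusive publication cutoff; year-only dates compared by year |
| `exclude_reviews` | off | drop records typed `Review` before partitioning |

## The synthetic test-bed

The generator emulates exactly the structure the test assumes: articles
are i.i.d. within group, each content term enters an article by an
independent Bernoulli draw at the group's prevalence, planted terms
have group A prevalence `min(1, risk_ratio × prevalence_b)`, and an
optional co-mention excess forces joint inclusion of a term pair with
the stated probability.  Group A articles get one interaction
descriptor chosen uniformly from the eight; every article carries the
query drug's descriptor.  Each corpus ships a truth record with the
exact realized per-term, per-group counts, review counts and group
memberships, so pipeline bookkeeping is auditable cell by cell.

The standard study conditions used across the tests and the acceptance
script are |A| = 200, |B| = 1000, 1000 resamples, planted terms at
`prevalence_b = 0.05` with risk ratio 4, decoys at matched prevalence —
sizes at which the test's behavior is clearly resolved while a full
100-replicate experiment runs in seconds.

What the generator does *not* emulate: real MeSH indexing density
(tens of headings per record), correlated term usage beyond the planted
pairs, entry-term synonymy, or temporal drift.  Passing tests therefore
demonstrate correctness of the bookkeeping and the statistic's behavior
under its own assumptions — not retrieval quality on real literature.

## Calibration of the test: a known property

Under the generator's null (identical prevalences in both groups), the
resampling Z-test is **anti-conservative**: the realized fraction of
p < 0.1 is ≈ 0.14–0.15, not 0.10.  The reason is structural.  The null
resampling captures only the hypergeometric variability of drawing
`|A|` articles from the *realized* group B — variance
`n·p(1−p)·(N−n)/(N−1)`, conditioned on B's composition — while the
observed group A count is an independent binomial draw with the larger
variance `n·p(1−p)`, plus the across-corpus variability of B's
composition that the per-corpus μ̂ absorbs.  The z denominator is
therefore systematically too small (variance ratio ≈ 1.2 at
|A|/|B| = 0.2), and the nominal level understates the false-positive
rate.  This is a property of the published procedure itself, faithfully
implemented; the acceptance suite measures it honestly rather than
recalibrating the test.  With only ~30 terms per corpus, a
Kolmogorov–Smirnov uniformity check at the 1% level does not resolve
the ~0.03 CDF deviation, which is why the per-corpus uniformity test
passes while the pooled type-I fraction sits above nominal.  Users who
need calibrated error control should enable the BH correction and/or
treat the p-values as a ranking score (the use the ROC validation
makes of them), not as calibrated tail probabilities.

## Numerical and I/O choices

* Flat-text MEDLINE parsing is delegated to Biopython's `Bio.Medline`
  (records split on blank lines, continuation lines rejoined with
  single spaces); the writer emits one line per field value so the
  round trip `parse(write(x)) == x` is exact.  Records without a PMID
  are collected as record-level errors, never silently dropped.
* PubMed XML parsing/writing uses `lxml`; malformed documents fail
  fatally with the parser's reported position.  The live fetcher pages
  through E-utilities (Biopython's Entrez), retries with exponential
  backoff, discards partial results on persistent failure, and caches
  raw pages keyed by (query, cutoff, page) so reruns are offline.
* The publication-date cutoff is inclusive (≤ `date_end`), and a
  record is compared at the precision it carries: year-only records by
  year, year-month records by (year, month).  Records with no parsable
  year are excluded from date-filtered sets and logged.
* ROC points come from scikit-learn's `roc_curve` with
  `drop_intermediate=False`; the area is `numpy.trapezoid`.  The BH
  adjustment is `scipy.stats.false_discovery_control`.  Hierarchical
  clustering uses `scipy.cluster.hierarchy` on `pdist` Euclidean
  distances; axes with fewer than two entries get the identity order.
* Degenerate inputs are handled explicitly: empty corpora parse to
  empty lists, all-zero rows normalize to zero, a partner drug absent
  from group A yields an empty network with a warning, a label set
  with one class raises naming the missing class.

## Known limitations

* MeSH indexing lag and curation choices bound what any heading-based
  method can see; associations found are indirect co-annotation
  evidence, hypotheses rather than demonstrations.
* The enrichment p-values are anti-conservative under the method's own
  null (see above); selected-term counts at α = 0.1 should be read as
  a ranking cutoff, not a false-positive guarantee.
* Entry-term (synonym) resolution is off by default; corpora whose
  headings are not canonical descriptor names need it switched on.
* The fetcher applies only the date cutoff — no language or record
  status restriction.
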