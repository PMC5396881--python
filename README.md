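# meshddi

Mining the mechanisms of drug–drug interactions (DDIs) from PubMed MeSH
annotations.

A drug–drug interaction occurs when one drug alters the pharmacologic
effect of another; PubMed holds on the order of 150,000 DDI-related
records, far more than can be read manually.  Every PubMed record
carries curated MeSH (Medical Subject Headings) descriptors, and those
annotations encode which drugs, proteins and physiological phenomena a
paper is about.  `meshddi` turns that structure into a statistical
screen for DDI mechanisms:

1. **Partition.**  A query drug's articles are split into DDI-related
   literature (*group A*: any of the eight interaction-type descriptors —
   drug interactions, drug agonism, drug partial agonism, drug
   antagonism, drug inverse agonism, drug synergism, food-drug
   interactions, herb-drug interactions — appears among the MeSH
   headings) and DDI-unrelated literature (*group B*).
2. **Categorize.**  Candidate descriptors from group A are bucketed by
   MeSH tree position: *drugs* (an FDA-approved drug list matched to
   descriptors), *proteins* (tree branches `D08`, `D12.776`) and
   *phenomena* (`G03`, `G04`, `G06`, `G07`).
3. **Test.**  For each candidate term with observed group A count
   `c_A`, a null distribution is built by repeatedly drawing `|A|`
   articles from group B without replacement and counting the term in
   each draw.  With null mean μ and SD σ,

       z = (c_A − μ) / σ,     p = P(Z ≥ z)   (one-sided upper tail)

   and a term is reported as DDI-associated when `c_A > 5` and `p < 0.1`.
4. **Relate.**  Selected terms are linked through term–article incidence
   and term–term co-occurrence matrices (row-normalized, ordered by
   hierarchical clustering on Euclidean distances), weighted drug-pair
   networks, and validated by ROC/AUC against user-supplied
   gold-standard labels.

The package is aimed at pharmacology / drug-safety informatics users who
want a reproducible, scriptable version of this literature screen, plus
a synthetic-corpus generator so every stage can be exercised and audited
offline with known ground truth.

## Worked example

Generate a synthetic corpus with five planted drug terms (baseline
prevalence 0.05 in group B, risk ratio 4 in group A, |A| = 200,
|B| = 1000) plus matched null decoys, then run the enrichment test:

```bash
meshddi simulate --n-a 200 --n-b 1000 --n-planted 5 --seed 7 --outdir demo
meshddi enrich --corpus demo/corpus.medline --vocab demo/vocab.tsv \
               --drug-list demo/drugs.txt --n-resamples 1000 --seed 1
```

```text
MeSH term enrichment (resampled null, Z-statistic)
==========================================================
group A (DDI-related):      200 articles
group B (DDI-unrelated):   1000 articles
resamples: 1000   seed: 1   alpha: 0.1   min freq: >5
candidates: 55 (drug 25, protein 15, phenomena 15)
selected:   14
----------------------------------------------------------
                term  category  count_a  null_mean  null_sd      z   p_value  selected
    Planted Drug 000      drug       41      9.541    2.701  11.65 1.188e-31      True
    Planted Drug 004      drug       37      9.106    2.626  10.62 1.172e-26      True
    Planted Drug 002      drug       41      11.56    2.942     10 7.283e-24      True
    Planted Drug 003      drug       41      11.84    2.984  9.774 7.304e-23      True
    Planted Drug 001      drug       36      10.26    2.694  9.555 6.171e-22      True
   Decoy Protein 001   protein       17      8.173    2.479   3.56 0.0001853      True
...
```

Reading the table: `Planted Drug 000` appears in 41 of the 200
DDI-related articles, while random draws of 200 DDI-unrelated articles
contain it only 9.5 ± 2.7 times — the observed count sits 11.6 null SDs
above the null mean, so the term is flagged (`selected = True`).  All five planted terms top the
ranking; the handful of flagged decoys reflects the test's ~0.1
significance level.  The same objects are available from Python:

```python
from meshddi import parse_medline, partition, TermEnrichment, SamplingConfig
from meshddi.pipeline import load_vocabulary

articles = parse_medline("demo/corpus.medline")
vocab = load_vocabulary("demo/vocab.tsv", "demo/drugs.txt")
corpus = partition(articles, drug="Examplinib")
results = TermEnrichment(corpus, vocab, config=SamplingConfig(seed=1)).fit()
print(results.summary())
results.to_frame()          # pandas DataFrame of all per-term estimates
```

For a real drug, `meshddi fetch --query "cyclosporine [MeSH Terms]"
--date-end 2015-12-31 --out cyclosporine.medline` downloads and caches
the corpus (network required once), and `meshddi run --config run.cfg`
executes the whole workflow — partition, enrichment, drug×protein and
drug×phenomena co-occurrence heatmap matrices, pair networks, ROC — from
a flat key=value config file.

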