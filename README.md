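# treatminer

Pattern-learning extraction of drug–disease **treatment** pairs from
sentence corpora, for building machine-readable treatment knowledge bases
that support computational drug repurposing.

Biomedical abstracts are full of sentences like *"Gabapentin for the
treatment of tinnitus: a case report"* — treatment relationships (including
off-label and experimental uses) that never make it into structured drug
databases. `treatminer` implements a distant-supervision bootstrap to mine
them:

1. **Parse** a citation corpus (MEDLINE-style XML or sentence TSV) and a
   clinical-trial registry (ClinicalTrials.gov-style study XML).
2. **Build lexicons** of drug and disease terms: merge term sources,
   drop terms with zero corpus frequency, apply exclusion lists, and
   normalize trade names to generic names.
3. **Tag** sentences by case-insensitive exact dictionary matching with a
   word-boundary constraint and longest-match-first overlap resolution.
4. **Learn patterns**: for every sentence containing a drug mention *d*
   and a disease mention *z*, record the infix between them as an
   orientation-tagged pattern (`DRUG p DISEASE` or `DISEASE p DRUG`), and
   rank patterns by the number of distinct *known* treatment pairs (seeds
   from the trial registry) they link:

   `rank(p) = |{(d, z) ∈ seeds : p links d and z in some sentence}|`

   Treatment-specific patterns ("in the treatment of") rise to the top;
   adverse-effect patterns ("-induced") do not.
5. **Extract** new pairs wherever a curated treatment-specific pattern
   (17 DRUG-first infixes ship as the default) links a drug and a disease.
6. **Evaluate and analyze**: precision/recall/F1 against anchored gold
   standards, with recall stratified by sentence co-occurrence frequency
   (P = TP/|extracted|, R = TP/|gold ≥ cutoff|, F1 = 2PR/(P+R)); and
   semantic validation — drug pairs sharing extracted disease indications
   should share more target genes and ATC codes.

Because the real corpora are external and licensed, the package ships a
first-class synthetic-fixture generator (`treatminer.synthetic_fixtures`)
that plants patterns between nonsense-vocabulary entities with controlled
per-pair sentence counts, giving exact ground truth for every stage.

## Worked example

```python
from treatminer import (tag_corpus, extract_pattern_observations,
                        extract_pairs, default_treatment_patterns)
from treatminer.corpus_io import SentenceRecord
from treatminer.lexicon import Lexicon

drugs = Lexicon("DRUG", frozenset({"gabapentin", "imatinib", "tamoxifen"}))
diseases = Lexicon("DISEASE", frozenset(
    {"tinnitus", "follicular dendritic sarcoma", "endometrial cancer"}))
corpus = [
    SentenceRecord("11233342", 0, "Gabapentin for the treatment of tinnitus: a case report"),
    SentenceRecord("17596748", 0, "Imatinib in the treatment of follicular dendritic sarcoma"),
    SentenceRecord("12701962", 0, "Tamoxifen-induced endometrial cancer"),
]
tagged = list(tag_corpus(corpus, drugs, diseases))
for ts in tagged:
    for obs in extract_pattern_observations(ts):
        print(obs.pattern.orientation, repr(obs.pattern.infix),
              "->", (obs.pair.drug, obs.pair.disease))
for e in extract_pairs(tagged, default_treatment_patterns()):
    print(e.pair, "support", e.support, sorted(p.infix for p in e.matched_patterns))
```

prints

```
DRUG_FIRST 'for the treatment of' -> ('gabapentin', 'tinnitus')
DRUG_FIRST 'in the treatment of' -> ('imatinib', 'follicular dendritic sarcoma')
DRUG_FIRST '-induced' -> ('tamoxifen', 'endometrial cancer')
DrugDiseasePair(drug='gabapentin', disease='tinnitus') support 1 ['for the treatment of']
DrugDiseasePair(drug='imatinib', disease='follicular dendritic sarcoma') support 1 ['in the treatment of']
```

All three inter-entity patterns are observed, but only the two pairs
linked by curated treatment-specific patterns are extracted — the
"-induced" adverse-effect pair is correctly left out.

## Command line

```bash
treatminer simulate --seed 42 --out-dir work/          # synthetic world
treatminer tag --corpus work/sentences.tsv \
    --drug-lexicon work/drug_lexicon.tsv \
    --disease-lexicon work/disease_lexicon.tsv \
    --synonyms work/synonyms.tsv --out work/tagged.tsv
treatminer mine-patterns ... --seeds work/seeds.tsv --out work/stats.tsv
treatminer extract-pairs ... --out work/extracted.tsv
treatminer evaluate ... --cutoffs 1,5,10,20,30 --out work/eval.tsv
treatminer semantic --pairs work/extracted.tsv --genes genes.tsv --atc atc.tsv \
    --out-genes work/mean_genes.tsv --out-atc work/mean_atc.tsv
treatminer run --config pipeline.json                  # all stages at once
```

All subcommands are deterministic: identical inputs and seeds produce
byte-identical outputs.

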