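# sumohydro

Sumoylation site prediction from protein sequence. The package builds
labeled 25-residue lysine-centred fragment datasets, encodes them under
eight feature schemes — one-hot ("binary"), k-spaced amino-acid pair
counts (CKSAAP), PSI-BLAST PSSM rows, BLOSUM62 nearest-neighbour ratios
(KNN), six- and nine-letter reduced alphabets, Z-scales, and the
headline "hydrobinary" scheme (one-hot plus hydrophobicity over the
motif's hydrophobic region) — and trains/evaluates an RBF-SVM under
class imbalance with negative subsampling, 10-fold / leave-one-out
cross-validation and ROC/AUC reporting. A seeded synthetic-proteome
generator with planted hydrophobic-K-x-E motifs makes every stage
testable without downloads.

## Command line

```sh
# generate a synthetic fixture with 100 planted sites
sumohydro simulate --out fixture/ --positives 100 --seed 1

# build a filtered fragment dataset from FASTA + site annotations
sumohydro build fixture/proteins.fasta fixture/sites.tsv --out dataset/ --seed 1

# repeated 10-fold cross-validation + final model
sumohydro train-eval dataset/positive_fragments.txt dataset/negative_fragments.txt \
    --scheme hydrobinary --out run/ --seed 1

# score every lysine in new sequences at the low/medium/high thresholds
sumohydro predict run/model.joblib query.fasta --out predictions.tsv --level medium

# ratio-selection curve (train at 1:r, test on the whole dataset)
sumohydro sweep dataset/positive_fragments.txt dataset/negative_fragments.txt \
    --scheme binary --ratios 1-25 --out sweep.tsv
```

Site tables are TSV (`protein_id`, 1-based `position`, `label` in
{1,0}); fragment lists hold one 25-mer per line over the alphabet
`ACDEFGHIKLMNPQRSTVWYO` (`O` pads windows that overrun the termini).
Every run writes a `run.json` with its parameters and seed.

## Library sketch

- `sumohydro.dataset` — FASTA/site-table/fragment-list I/O, window
  extraction with `O` padding, greedy 40%-identity redundancy filtering,
  seeded 1:10 negative subsampling.
- `sumohydro.encoders` — the eight encoding schemes, hydrophobicity and
  Z-scale tables, normalized BLOSUM62, NCBI ASCII PSSM parser.
- `sumohydro.model` — RBF-SVM training, (C, γ) grid search by
  cross-validated MCC, decision scores, low/−0.2 medium/0 high/+0.2
  threshold calls, versioned model archives.
- `sumohydro.evaluation` — Sn/Sp/Ac/MCC, ROC/AUC, stratified k-fold and
  leave-one-out protocols, repeated negative-resampling evaluation,
  ratio sweep.
- `sumohydro.synthetic` — seeded proteome generator with planted
  consensus/non-consensus positive lysines and fixture writer.
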