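# transfacpred

Hybrid prediction of transcription factors (TFs) from protein sequence.

Transcription factors — DNA-binding proteins that switch transcription on
and off — are routinely annotated by homology, but many genuine TFs have
no close labelled relative. This package combines two complementary lines
of evidence into one call, for bioinformaticians annotating proteomes or
benchmarking TF predictors:

- an **alignment-free arm**: the sequence's amino-acid composition
  (`AAC_i = R_i/L`, 20 features), dipeptide composition
  (`DPC_i = D_ij/(L−j)`, 400 features) or both (420) feed a supervised
  classifier (extra trees by default; eight families available) that
  outputs a TF probability `p ∈ [0,1]`;
- an **alignment-based arm**: the query is searched against a labelled
  reference database built from the training set, and the class of the
  top hit (lowest e-value, then highest bit score) becomes a vote
  `v ∈ {+w, 0, −w}` (TF hit / no hit / non-TF hit, `w = 0.5` by default).

The **hybrid score** is simply `p + v`; the call is TF iff it reaches the
decision threshold (default 0.5). A confident agreeing hit is decisive, a
missing hit defers entirely to the classifier. Performance is reported as
sensitivity, specificity, accuracy, F1, Cohen's kappa, MCC and ROC-AUC,
with stratified five-fold cross-validation and exhaustive grid search
built in.

## Worked example

Generate a labelled synthetic dataset (biased composition + homolog
families), train, build the reference database, and predict:

```bash
transfacpred simulate --n-pos 40 --n-neg 40 --seed 3 \
    --out-fasta d.fasta --out-labels d.tsv
transfacpred train    --fasta d.fasta --labels d.tsv --seed 3 --out model.joblib
transfacpred build-db --fasta d.fasta --labels d.tsv --out refdb
transfacpred predict  --fasta d.fasta --model model.joblib --db refdb \
    --mode hybrid --out pred.tsv
transfacpred evaluate --predictions pred.tsv --labels d.tsv
```

which prints

```
generated 40 TF + 40 nonTF sequences -> d.fasta
trained extra_trees on 80 sequences (aac); saved to model.joblib
built blast reference db with 80 sequences at refdb
80 sequences: 40 TF, 40 nonTF -> pred.tsv
Sens	Spec	Acc	AUC	F1	K	MCC
100.0000	100.0000	100.0000	1.0000	1.0000	1.0000	1.0000
```

and `pred.tsv` holds one row per input sequence:

```
id	ml_score	blast_vote	hybrid_score	label	mode
TF00001	1.0	0.5	1.5	TF	hybrid
TF00001_m1	1.0	0.5	1.5	TF	hybrid
```

Here `ml_score` is the classifier's TF probability, `blast_vote` the
±0.5/0 top-hit vote, and `hybrid_score` their sum — 1.5 means both arms
agree confidently on TF. (Resubstitution on clean synthetic data is
perfectly separable; held-out evaluation is what the test suite and
acceptance script measure.) The same operations are available as library
functions (`transfacpred.predict_pipeline`, `train_classifier`,
`build_reference_db`, `evalue_scan`, …).

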