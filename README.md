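# snopred

Sequence-feature toolkit for predicting protein **S-nitrosylation (SNO)
sites** — cysteines whose thiol group is covalently modified by nitric
oxide. Experimental SNO-site mapping (biotin-switch and related
chemistries) is slow and low-throughput, so sequence-based classifiers
are the standard first-pass screen. `snopred` provides the full
machinery such a predictor needs, as composable scikit-learn
estimators:

- **Window extraction** — every cysteine in a protein becomes a
  `2t + 1`-residue peptide window `R₋t … R₋1 (C) R₊1 … R₊t`
  (default `t = 10`, 21-mers), with flanks past the protein ends padded
  by the dummy residue `X`.
- **Nine encoders** mapping a window to a numeric vector
  (dimensions at `t = 10`, `λ = 5`):

  | encoder | idea | dim |
  |---|---|---|
  | PC-PseAAC | amino-acid composition + λ physicochemical tier correlations | 25 |
  | kmer1 / kmer2 | residue and dipeptide frequencies | 20 / 400 |
  | PC-PseAAC_G | PC-PseAAC with arbitrary user index sets | 25 |
  | BPB | per-position residue posteriors, one block per class | 40 |
  | ANBPB | BPB with positional z-scores pushed through the normal CDF | 40 |
  | DBPB | per-position adjacent-pair posteriors | 38 |
  | IAAPair | adjacent + next-nearest pair posteriors, positive − negative | 39 |
  | PSTAAP | adjacent-triplet posteriors, positive − negative | 18 |

  Concatenated: **645** features with named block structure.
- **Feature selection** — information gain
  `IG(X|Y) = H(X) − H(X|Y)` (bits, plug-in 2×2 counts) of binarized
  features, and MRMD (max-relevance max-distance:
  `w_r·|PCC(f, y)| + w_d·MD(f)` with Euclidean, cosine, Tanimoto or
  mean distance), plus incremental dimension selection under
  cross-validation.
- **Evaluation** — jackknife, repeated stratified k-fold and
  independent-test protocols reporting Sn, Sp, Acc and MCC, with
  leakage-free per-fold refitting of every supervised stage by default.
- **Synthetic data** — a seeded generator of labeled windows with
  controllable position-specific enrichment, so the whole pipeline is
  testable without any external download.

## Worked example

```python
import snopred as sp

dataset = sp.simulate_dataset(500, 500, t=10, seed=1)
print("windows:", len(dataset), "| positives:", dataset.n_positive)

ranked = sp.rank_residue_ig(dataset)
for name, score in list(zip(ranked.order, ranked.scores))[:3]:
    print(f"IG({name}) = {score:.4f}")

cv = sp.cross_validate(dataset, sp.SNOPredictor(random_state=1),
                       scheme="kfold", k=10, seed=1)
m = cv.mean
print(f"10-fold CV: Sn={m['sn']:.3f} Sp={m['sp']:.3f} "
      f"Acc={m['acc']:.3f} MCC={m['mcc']:.3f}")
```

Output:

```
windows: 1000 | positives: 500
IG(K) = 0.1255
IG(R) = 0.0066
IG(L) = 0.0061
10-fold CV: Sn=0.888 Sp=0.896 Acc=0.892 MCC=0.784
```

The generator plants a lysine-enrichment gradient around the site, and
the toolkit recovers it: K tops the information-gain ranking by an
order of magnitude, and the end-to-end predictor (all nine encoders,
standardized RBF-SVM) reaches ~0.89 accuracy under leakage-free
10-fold cross-validation — against a Bayes ceiling of ~0.93 for these
generator settings.

`SNOPredictor` is a scikit-learn classifier over raw window strings,
so `clone`, `Pipeline` and the model-selection utilities all apply.
To reproduce a published-style configuration — kmer2 reduced to its
top-180 IG features, 425 dimensions total:

```python
est = sp.SNOPredictor(selection="ig", selection_dim=180,
                      selection_block="kmer2", random_state=1)
```

A command line mirrors the stages:

```bash
snopred simulate --n-pos 500 --n-neg 500 --seed 1 --out sim.tsv
snopred extract --fasta proteins.fasta --t 10 --out windows.tsv
snopred encode --in sim.tsv --encoders pcpseaac,kmer2,bpb --out X.tsv
snopred rank --in sim.tsv --method ig --out ranking.tsv
snopred eval --config cfg.json --train sim.tsv [--test test.tsv]
snopred run --config run.json --outdir results/   # end-to-end + manifest
```

Real labeled datasets load from two-column TSV (`peptide<TAB>label`)
or FASTA with `|label=0/1` headers via `sp.load_dataset`.

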