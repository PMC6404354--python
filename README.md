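# glycopu

Positive-unlabelled (PU) learning for protein glycosylation-site
prediction: sequence-window descriptors, mRMR feature selection,
class-prior estimation (Elkan–Noto and AlphaMax), the PU Bayesian
classifier family (PNB, PAODE, PAnDE — PA2DE at n=2 — and PTAN), and the
benchmark protocols, all runnable end-to-end on synthetic data with known
ground truth.

## What it does

Experimentally verified glycosylation sites are reliable positives, but
"negative" sites are merely unexplored: a substantial fraction of them turn
positive in later database snapshots. The package treats those sites as
*unlabelled* under the "selected completely at random" (SCAR) assumption
and trains averaged n-dependence Bayesian classifiers whose negative-class
conditionals are derived by mixture inversion,
`P(v|y=0) = (P(v) − α·P(v|y=1)) / (1−α)`, using a class prior α estimated
from held-out scores (Elkan–Noto `c = mean score on labelled positives`, or
an AlphaMax-style profile-likelihood mixture-proportion estimator).

Modules (`src/glycopu/`):

| module        | contents |
| ------------- | -------- |
| `seqio`       | FASTA + site-table I/O, 15-residue peptide windows, candidate enumeration with the N[!P][ST][!P] sequon split, annotation-snapshot comparison |
| `descriptors` | AAC, DPC, Moreau-Broto/Moran/Geary autocorrelation, CTD, sequence-order-coupling + quasi-sequence-order, type I/II pseudo-amino-acid composition, AAindex per-position encodings |
| `preprocess`  | equal-frequency discretization, two-stage unlabelled sampling (20 sites/protein, 10,000 cap), greedy mRMR (MID scheme, top-100 default) |
| `prior`       | Platt-calibrated naive-Bayes scorer, Elkan–Noto and AlphaMax prior estimation |
| `pubayes`     | PNB / PAODE / PAnDE / PTAN with m-estimate smoothing, order-degeneracy fallback (PA2DE → PA1DE → PNB), JSON model serialization |
| `evaluate`    | F1/ACC/AUC, 100× randomization protocol (50/20/30 split, trainingV retrain), stratified k-fold CV, RF/SVM/one-class-SVM baseline adapters (optional scikit-learn) |
| `synthetic`   | SCAR dataset generator with known α and c; motif-bearing protein generator with flank enrichment |

"PA2DE (V2.0)" is PAnDE at n=2 with the AlphaMax prior; plain "PA2DE" uses
the Elkan–Noto prior — that is the only difference.

Notes on vendored data: the AAindex block ships with a small genuine
AAindex1-format snapshot (9 complete indices); point
`DescriptorConfig(aaindex_path=...)` at a full `aaindex1` file to reproduce
the full 8400-feature block (560 indices × 15 positions). The two
sequence-order distance matrices are the Grantham distance (recomputed from
its published formula) and a documented z-scored physicochemical Euclidean
distance.

## CLI

```
glycopu simulate --kind proteins --seed 1 --out-prefix work/sim
glycopu extract-features --fasta work/sim.fasta --sites work/sim.sites.tsv \
    --glyco-type N --seed 1 --out work/features.tsv
glycopu select-features --features work/features.tsv --k 100 --out work/ranking.tsv
glycopu estimate-prior --features work/features.tsv --selection work/ranking.tsv \
    --method alphamax --seed 1 --out work/prior.json
glycopu train --features work/features.tsv --selection work/ranking.tsv \
    --family pande --n 2 --prior-json work/prior.json --out work/model.json
glycopu predict --model work/model.json --features work/features.tsv \
    --out work/predictions.tsv
glycopu benchmark --features work/features.tsv --repeats 100 --mrmr-k 100 \
    --seed 1 --out work/report.json
```

All commands read/write plain text (FASTA, TSV, JSON, YAML), log to
stderr, and are byte-reproducible given the same `--seed`.

## Conventions and caveats

- Positions are 1-based; windows are exactly 15 symbols with `'X'` padding
  past the termini. `'X'` is excluded from composition counts and carries
  the mean (zero after z-scoring) property value in numeric encodings.
- Lag-based descriptors keep fixed dimensionality (240/60/100/50 per
  group); lags infeasible on a 15-mer are structural zeros. With the
  documented group sizes the full printed set totals 9947 (= 20 + 400 +
  720 + 147 + 160 + 100 + 8400); the default config reports its own exact
  `DescriptorConfig.total_dim` for whatever AAindex set is loaded.
- Discretization is equal-frequency (5 bins), fit on training rows only;
  mRMR is the MID difference scheme with natural-log plug-in mutual
  information; these defaults are exposed in config.
- Estimated priors below 1e-4 are clamped to that floor with a warning.
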