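# seqsol

Sequence-based protein solubility prediction.

`seqsol` predicts the solubility of a protein from its amino-acid sequence
alone — solubility in the cell-free expression sense: the percentage of
expressed protein recovered in the supernatant after centrifugation,
a quantity that is bimodally distributed over a proteome and can exceed
100%.  It is aimed at people screening constructs for recombinant
expression, prioritising targets at proteome scale, or engineering
solubility (e.g. deciding which residues to swap), where structure-based
methods are unavailable or too slow.

## The model

For every sequence, 35 order-free features are computed: the 20 amino-acid
composition fractions; 7 composites on them (K−R, D−E, K+R, D+E, K+R−D−E,
K+R+D+E, F+W+Y); and length, pI, mean Kyte–Doolittle hydropathy, absolute
net charge at pH 7 per residue, fold propensity (signed distance from the
Uversky charge–hydropathy boundary, ⟨H⟩ − (⟨R⟩ + 1.151)/2.785), mean
disorder propensity, normalised sequence entropy, and mean β-strand
propensity.

Training ranks a solubility-labelled population and contrasts its lower
and higher 5% tails.  Each feature's weight is the normalised magnitude
of its tail z-score,

    z_f = (mean_high,f − mean_low,f) / sd_f(tail union),    w_f = |z_f| / Σ|z|,

and a query value x_f contributes the linear scaling
s_f = clamp((x_f − mean_low,f)/(mean_high,f − mean_low,f), 0, 1).  The
prediction is the convex combination Σ w_f s_f ∈ [0, 1], mapped to percent
between the mean measured solubilities of the two tails.  Backward
elimination then drops low-weight features while the training correlation
holds up.  Proteins with a predicted transmembrane segment (mean
hydropathy > 1.6 in any 21-residue window) are excluded from training and
flagged — with a warning, but still scored — at prediction time.
Each result carries per-feature deviations from the population average
(in SD units) and windowed hydropathy / fold-propensity / net-charge
profiles for subdomain interpretation.  See `docs/methods.md` for the
full account.

## Worked example

Generate a synthetic solubility-labelled training set (2395 proteins,
bimodal solubility with known feature structure), train, and predict:

```bash
seqsol synth --out train.tsv --fasta train.fa --seed 1
seqsol train --table train.tsv --out model.psol
seqsol predict --model model.psol --fasta query.fa
```

Training reports what it kept and selected:

```
read 2395 training records from train.tsv
excluding 515 record(s) with a predicted transmembrane segment
active features (25): A, C, D, E, F, H, I, K, L, N, Q, R, W, Y, KmR, KpR,
  DpE, KpRmDmE, KpRpDpE, FpWpY, pI, hydropathy, fold_propensity, disorder,
  beta_strand
model (format version 1) written to model.psol
```

Prediction writes one TSV row per sequence — scaled solubility in [0, 1],
the percent calibration, pI, the transmembrane flag, then 35 deviation
columns (here the first two training sequences, first five columns):

```
id        scaled    percent  pI     tm_flag
syn00000  0.845065  82.467   4.375  0
syn00001  0.415268  43.273   7.874  0
```

`syn00000` scores 0.85 on the 0–1 scale (≈82% solubility): well above the
population average, as expected for a sequence generated in the soluble
mode; its low pI reflects the D+E enrichment the generator ties to
solubility.  Evaluating the model against the labelled table:

```bash
seqsol evaluate --model model.psol --table train.tsv
{"n": 1880, "per_tail": 94, "pearson_r": 0.610086, "auc": 0.992078,
 "accuracy_at_58": 0.93617, "best_threshold_percent": 42.788595,
 "accuracy_at_best": 0.957447}
```

i.e. r = 0.61 between predicted and measured solubility over the 1880
non-TM proteins, AUC 0.99 for separating the 5% tails, and 96% accuracy
at the best separating threshold.  `seqsol profile --fasta query.fa
--kind charge` emits the windowed net-charge profile (and `--kind
hydropathy|fold` the others) as TSV.

The same operations are available as a library, sklearn-style:

```python
from seqsol import SyntheticSpec, generate, TailContrastRegressor

records = generate(SyntheticSpec(), seed=1)
model = TailContrastRegressor().fit(
    [r.sequence for r in records], [r.solubility for r in records])
model.predict(["MKVIFLDGEEK..."])          # scaled, in [0, 1]
model.active_, model.stats_                # selected features, tail stats
```

To train on real data, supply your own three-column TSV
(`id<TAB>sequence<TAB>solubility`), e.g. a measured cell-free expression
solubility table.

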