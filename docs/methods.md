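# Methods

## The prediction problem

The package predicts protein *solubility in the cell-free expression
sense*: the percentage of an expressed protein found in the supernatant
after centrifugation, relative to the total amount expressed.  This is an
operational, not thermodynamic, quantity; because of measurement
normalisation it can exceed 100%, and over a proteome it is strikingly
bimodal — most proteins are either mostly soluble or mostly pelleted.
Prediction uses the amino-acid sequence alone, through 35 order-free
features, so it is applicable at proteome scale and to engineering
questions ("which residues should I change?") where structure is
unavailable or irrelevant.

## The 35 features

* **20 composition fractions**, one per residue.
* **7 composites** on those fractions: K−R, D−E, K+R, D+E, K+R−D−E,
  K+R+D+E, F+W+Y (TSV column names use `m`/`p` for minus/plus, e.g. `KmR`).
* **8 derived quantities**: length; pI; mean Kyte–Doolittle hydropathy;
  absolute net charge at pH 7 per residue; fold propensity; mean disorder
  propensity; normalised sequence entropy; mean β-strand propensity.

Charge is modelled by Henderson–Hasselbalch titration of D, E, C, Y
(acids), H, K, R (bases) and, where termini are included, the two chain
ends; the default pKa values are the EMBOSS set.  Histidine contributes
its small fractional positive charge at pH 7 rather than being rounded to
neutral.  The termini are included in the pI (a property of the whole
chain) and excluded from the per-residue absolute charge and from all
windowed charges (windows are sequence-internal).  The pI is found by
bisection of the strictly decreasing charge–pH curve on (0, 14); the
interval is narrowed to ~1e-10 pH units, far below the 1e-4 reporting
tolerance, so the residual charge at the returned pI is negligible.

**Sequence entropy** is the Shannon entropy of the composition
distribution divided by log 20: 0 for a homopolymer, 1 for uniform use of
all 20 residues.  It is computed whole-sequence (order-free), the simplest
definition consistent with the other features.

**Fold propensity** is the signed distance from the Uversky
charge–hydropathy boundary that separates natively folded from
intrinsically unstructured sequences:

    FP = <H> − (<R> + 1.151) / 2.785

with `<H>` the mean Kyte–Doolittle hydropathy rescaled to [0, 1] and `<R>`
the mean absolute net charge per residue at pH 7 (termini excluded).
Positive values favour a compact fold.

**Normalisation choices.** The absolute charge feature is divided by
length so that it sits on the same per-residue footing as the composition
fractions; an unnormalised value would be nearly collinear with length,
which is itself a feature.

**Swappable scales.** The hydropathy scale is Kyte–Doolittle and is load-
bearing (the transmembrane rule and fold-propensity normalisation are
defined on it).  The disorder scale defaults to TOP-IDP and the β-strand
scale to Chou–Fasman P(β); neither enters the final prediction model —
they only inform the 35-feature deviation display — and both can be
replaced via a two-column `residue<TAB>value` file.

## Profiles and the transmembrane rule

Hydropathy, fold propensity and net charge are profiled over a sliding
window (default 21 residues, the only window length the transmembrane rule
fixes; a CLI parameter otherwise).  Only full windows are reported — no
residues are invented at the edges — so for window w the profile covers
centres ⌈w/2⌉…L−⌊w/2⌋ and a sequence shorter than the window yields an
empty profile with an explicit flag.  Every window value equals the
corresponding whole-sequence feature computed on the window's substring;
this cross-module consistency is enforced by tests.

A protein is flagged as containing a predicted transmembrane segment when
any 21-residue window has mean hydropathy **strictly** greater than 1.6.
Flagged proteins are excluded from training; at prediction time they are
still scored but carry a warning, since the solubility model is not valid
for membrane proteins.  Sequences shorter than 21 residues cannot be
tested and are never flagged.

## The tail-contrast model

Training records (TM-excluded) are ranked by measured solubility and the
bottom and top ⌈tail_fraction·n⌉ records form the contrast classes
(default tail_fraction 0.05; a parameter so that small sets can use larger
tails).  Per feature:

    z = (mean_high − mean_low) / sd(union of the two tails)

The union SD (sample SD, ddof = 1) is the simplest single contrast scale;
a feature that is constant over the tails gets z = 0 and carries no
weight.  Weights are |z| normalised to sum to 1 over the active features
(the normalised weight vector is nudged by one float ulp so it sums to
exactly 1.0, making the anchor predictions below exact).

A query feature value x contributes

    s = clamp((x − mean_low) / (mean_high − mean_low), 0, 1)

— a linear scaling anchored at the tail means.  For solubility-lowering
features mean_high < mean_low and the map reverses automatically.  The
predicted scaled solubility is the weight-convex combination of the
contributions, hence guaranteed to lie in [0, 1] for *any* input sequence:
an input at the low-tail means scores exactly 0, at the high-tail means
exactly 1.  Percent solubility is the affine map of the scaled value onto
[mean solubility of the low tail, mean solubility of the high tail]; the
calibration constants are always estimated from the training tails, never
hard-coded.

Each prediction also reports, for all 35 features, the signed deviation of
the sequence's value from the training-population mean in population-SD
units — the diagnostic a user inspects to choose residue changes (K/R
swaps being the classic near-neutral lever on the K−R feature).
Population statistics are computed over the TM-excluded training set.

## Backward feature elimination

Starting from all 35 features, the lowest-weight active feature is
removed (ties broken by dropping the one later in the canonical feature
ordering, for determinism), weights are renormalised, and the Pearson
correlation between scaled predictions and measured solubility over the
full TM-excluded training population is recomputed.  Elimination stops
when the correlation falls more than `elimination_tol` (default 0.01)
below the best value seen, and the best-so-far model is returned.

The tolerance is a deliberate numerical choice.  Removing a feature that
carries no real signal perturbs the training correlation by ~1e-4 with an
essentially random sign (the tail-derived anchors give even null features
a little in-sample correlation), while removing a genuinely informative
feature costs ~0.05 or more; judging "performance falls" by a strict
decrease would stop the elimination within a step or two on any realistic
data.  The default 0.01 is about one standard error of r at n = 2000 and
sits an order of magnitude between those two scales.

Feature collinearity limits what elimination can decide.  Compositions,
composites and the mean-scale features overlap structurally (K carries
most of K−R's signal; the disorder mean moves whenever charged or
aromatic composition moves), so when solubility is driven by entangled
features the selected subset is one of several near-equivalent optima —
which is also why the final subset on real data should be read as "a
sufficient feature set", not "the causal features".

## The synthetic data generator

The generator emulates the statistical shape of a cell-free solubility
dataset so the whole pipeline is testable without downloads.  Defaults,
chosen once as the study conditions: n = 2395 proteins (the size of a
TM-excluded cell-free training population), lengths uniform on 50–500,
five informative features with the composition signatures reported for
soluble proteins (K−R up, D+E up, F+W+Y down, V up, hydropathy down),
effect 1.0 with solubility noise SD 0.25, and a bimodal mixture with a
70-point gap on a base of 50% — modes near 15% and 85%, the low mode
truncated at 0, the high tail exceeding 100% as real data does.

Each informative feature carries its own independent standard-normal
latent per protein; residues are sampled i.i.d. from a composition whose
log-odds are shifted along that feature's direction vector (coupling 0.4
per unit latent × effect), and solubility is an affine function of the
standardized *realized* feature values plus Gaussian noise, with half the
gap added on each side of zero.  Only features that are linear in residue
composition (or length) can be used as informative targets; entropy and
pI have no residue-odds direction and are rejected.

What the generator does *not* emulate: real proteome composition, homology
structure, domain architecture, or any sequence-order signal.  Passing
tests on synthetic data therefore demonstrate that the machinery is
correct and that the statistical procedure recovers planted structure;
they say nothing about predictive accuracy on real proteomes, which
depends entirely on training with a real measured-solubility table.

For the structure-recovery experiment (20 replicates, n = 2000) the
informative set is {G+, I+, M−, N+, T−}: single-residue features over
non-titratable residues outside every composite, with direction signs
chosen so the *centered* scale leak Σ(scale_r − mean scale)·d_r is near
zero for hydropathy, disorder and β-strand.  This is what makes the other
30 features genuinely uninformative — the premise of a recovery
experiment.  With composite or scale features as targets, half the
feature set becomes structural proxies and exact subset identification is
ill-posed (see above).

## Numerical conventions

* Ranking ties (records with equal solubility at a tail boundary, and
  tail labelling generally) are broken by stable input order.
* ROC: the sweep visits every unique prediction value; AUC is the
  trapezoid area, identical to the Mann–Whitney pair statistic with ties
  counted one half (cross-checked against brute-force pair counting).
  Accuracy at a threshold t is (TP+TN)/(P+N) over the tail members only,
  with "predicted soluble" meaning prediction ≥ t; the best threshold is
  the lowest maximiser.
* Model files are versioned key-value text; floats are written with
  `repr` (shortest round-trip form), so save/load is lossless.
* Degenerate inputs fail loudly: empty sequences, non-standard residues
  (B, J, O, U, X, Z, `*`, digits — rejected, never silently mapped),
  solubility < 0, fewer than 40 usable training records, all-equal
  solubilities, single-class ROC labels, zero-variance correlations.

## Problem sizes used in the checks

The bundled verification suite runs the feature oracles on 1000 random
sequences, bound checks on 10,000, and the recovery experiment at
20 × n = 2000; the acceptance script re-runs the training-population
evaluation at the default n = 2395 and the 20-replicate recovery
experiment.  These sizes give stable statistics (tail size ≥ 100 where
tail contrasts are measured) while keeping a full run in the order of a
minute.

## Known limitations

* Trained weights depend on the training table; the package ships no
  pre-trained model, and numbers obtained on synthetic data do not
  transfer to real proteins.
* The titration model ignores post-translational modifications, bound
  ligands and local electrostatic environment; pI is a sequence-level
  estimate.
* The transmembrane screen is a single-scale hydropathy rule, not a
  topology predictor; signal peptides are not modelled.
* The elimination procedure is greedy and order-dependent by design; it
  returns a good subset, not a certified optimum.
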