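# Methods

This note documents the models, conventions and numerical choices behind
`gagbind`: what each descriptor means physically, how the benchmarking
protocol is defined, what the synthetic generators do and do not emulate,
and where genuinely open design questions were settled.

## Units and conventions

Coordinates, radii and all distance cutoffs are in Ångström; masses in amu;
partial charges in elementary-charge units; energies in kcal/mol. These are
the conventions of the AMBER-family force fields (ff14SB for proteins,
GLYCAM06j for glycans) whose parameters the topology sidecar is expected to
carry. Receptor/ligand roles come from the sidecar's `role` column, never
from chain IDs: glycan residue names are non-standard and chain conventions
vary between preparation pipelines. Periodic images are ignored throughout —
the engine assumes solute-only structures whose interface never crosses a
box boundary. Water and ions are assumed stripped before extraction.

## Descriptors

A residue is "near the GAG" when *any* of its atoms lies within the radius
(5 or 10 Å) of *any* ligand atom — the minimum atom–atom distance
criterion, the usual reading of distance-based selections in trajectory
tools. Charged classes are Lys/Arg/His/Hie positive and Asp/Glu negative
(His and Hie are accepted as alternate spellings of the same protonation
family); hydrophobic is Ala/Val/Leu/Ile/Phe/Trp/Met/Tyr and hydrophilic
Ser/Thr/Asn/Gln/Asp/Glu/Lys/Arg/His/Hie. Net charge is positives minus
negatives; polarity is hydrophilics minus hydrophobics. Residues in neither
class (e.g. Gly, Pro, Cys) count toward nothing.

Contacts are unique (receptor heavy atom, ligand heavy atom) pairs within
3.5 Å (short) or 5.0 Å (medium) — pair counting, not unique-ligand-atom
counting, matching the atom-pair notion of native-contact analysis.
Hydrogen bonds are (donor N/O, bonded H, acceptor N/O) triples across the
interface with donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor angle
≥ 135°; bonded hydrogens are inferred by a 1.2 Å covalent cutoff because
the sidecar carries no bond table. With the default cutoffs every counted
bond's heavy-atom pair is also a short contact, which the tests assert.

The end-to-end distance uses the first and last ligand atoms in topology
(chain) order as anchors; anchors are configurable. Radius of gyration and
centres of mass are mass-weighted, matching the defaults of the standard
trajectory-analysis tools. The orientation angle is the angle between the
largest-variance eigenvectors of the mass-weighted coordinate covariance of
receptor and ligand; principal axes carry no sign, so the angle is folded
to [0°, 90°] and antiparallel rods score 0°. Coincident geometry (zero
spatial variance) yields NaN, and any frame with a NaN descriptor is
dropped — never imputed — before training, mirroring the exclusion of
dissociated frames from MD datasets.

### Energetics

The linear interaction energy is the raw receptor–ligand pairwise sum at
dielectric 1: Coulomb with k = 332.0522 kcal·Å/(mol·e²) and Lennard-Jones
in Rmin/ε form with Rmin_ij = Rmin_i/2 + Rmin_j/2 and ε_ij = √(ε_i ε_j).
The 12 Å default cutoff is the documented default of the trajectory tool
that popularised the command; it is a config field because published
protocols rarely state it. No exclusions are needed (interface pairs are
never bonded) and no switching/smoothing is applied. A pair closer than
0.1 Å raises an error — such geometry is corrupt, and a 1/r or (1/r)^12
term there would silently poison the feature table.

SASA uses the Shrake–Rupley rolling-probe construction with a deterministic
golden-spiral lattice (default 960 points, probe 1.4 Å), so values are
bit-reproducible. The lattice is fixed in the laboratory frame; SASA is
therefore exactly translation invariant but only approximately rotation
invariant (well under 1 % at 960 points, and the 960- vs 3840-point
difference is below 1 % on the test complexes). All other descriptors are
rigid-body invariant to machine precision.

## The benchmarking protocol

All models see standardised features: per-feature mean/std (population
variant) fitted on the training split only and applied unchanged to test
and validation rows; constant columns are dropped with a warning. Metrics
are R² (against the evaluated set's own mean — the conventional
definition), MSE and MAE. The main loop regenerates a random 80/20
train/test split for every repetition (10 by default), retrains from a
fresh seed, and reports mean ± std over repetitions; an entire receptor
subtype (group holdout) serves as the external validation set and is never
touched during training or scaling.

Default hyperparameters per family are the winning values of the searched
grids (the grids themselves ship as `GRID_PRESETS`): ElasticNet α = 1.0,
l1_ratio = 0.5; LinearSVR C = 1.0, ε = 0.1, 10,000 iterations (a
non-converged SVR yields a usable partial model plus a warning);
RBFSampler with 100 components and γ = 1/n_features feeding the same SVR;
LightGBM with 200 rounds, depth 8, learning rate 0.1, row/column subsample
0.8; histogram gradient boosting with 200 iterations, depth 6, learning
rate 0.1, L2 0.1; random forest with 200 trees, depth 30, min split 2, min
leaf 1, 'sqrt' features.

### The neural network

The FCNN is implemented natively in NumPy: arbitrary hidden stacks
(`24-1`-style zero-hidden up to three hidden layers), six activations
(ReLU, ELU, GELU, LeakyReLU, Sigmoid, Tanh), inverted dropout applied to
the input layer and after every hidden activation (for the zero-hidden
architecture dropout therefore acts on the inputs and the activation is
irrelevant), MSE loss, Adam (lr 0.001, L2 weight decay 1e-4 added to the
gradient), early stopping with patience 15 on a 10 % carve-out of the
training rows, and plateau learning-rate halving with patience 7. Batch
size 256 and a 200-epoch cap are conventional choices; both are config
fields, and small-data experiments raise the epoch cap because Adam's
per-step displacement is bounded by the learning rate, so few-batch
regimes need more epochs to travel the same parameter distance. Two
numerical choices matter: the target is standardised internally (and
back-transformed at predict time) so optimisation distances do not scale
with the energy units, and the output layer starts at zero so the net
begins at the target mean. Monte Carlo dropout re-enables dropout at
inference and reports the per-row mean and std over 30 stochastic passes;
at dropout 0 every pass is identical and the std is exactly zero by
construction. All randomness — initialisation, shuffling, masks, carve-out
and MC passes — flows from one seed, making training bit-reproducible.

### Uncertainty, importance, experiments

Repeated-CV uncertainty runs 30 rounds of seeded 10-fold cross-validation
and reports the per-row std of out-of-fold predictions. Feature importance
comes in four mechanisms: absolute standardised coefficients (linear
families, normalised to max 1), built-in tree importances, permutation
importance (mean MSE increase over seeded shuffles; cross-checked against
scikit-learn's implementation in the tests), and leave-one-feature-out
retraining (ΔMSE on an evaluation set; a perfectly redundant duplicate
scores ~0 — the classic correlated-feature caveat, which the tests
document for tree importances too). Shapley-value importance has no
bundled engine; the report substitutes permutation importance and says so
in its `note` field. Importance values are normalised per (model, method)
by the maximum absolute value so different models are comparable on one
axis.

Hierarchical clustering of the correlation matrix uses average linkage on
the distance 1 − |r|: redundancy between descriptors is a question of
correlation magnitude, not sign. Predicted-vs-actual scatter is coloured
by a 2-D Gaussian kernel density estimate.

The LIE ablation re-runs the full repetition protocol with `lie_elec` and
`lie_vdw` removed from the schema (asserted by schema inspection of every
trained model). The data-reduction experiment subsamples every kth row —
because rows are ordered (system, trajectory, frame), this thins
time-correlated frames first — and retrains from scratch per point,
skipping points below 50 rows. Trajectory-mean evaluation averages frame
predictions per trajectory and correlates them with averaged targets;
first-frame screening compares the frame-0 prediction against the
trajectory-mean target and splits trajectories into strong binders
(prediction at or below a configurable energy threshold; more negative =
stronger) and weak binders.

## Synthetic data

Two generators make the package testable end to end with exact ground
truth; neither attempts physical realism beyond what the mathematics
needs.

**Toy complexes** are built from rigid residue templates (a five/six-atom
amino-acid caricature whose side-chain pseudo-atom carries the residue's
formal charge) arranged on a helix or rod, plus a linear
sulfated-sugar-unit analogue whose per-unit charges sum exactly to a
configurable value (−2 e per unit by default, a heparin-like sulfation
level). The ligand is placed at one of six pose directions at a
configurable centre-of-mass offset (11 Å default — a bound pose with
several contacts); one donor and one acceptor hydrogen bond are posed
explicitly because rigid templates essentially never satisfy the angular
criterion by accident. Frames carry small seeded jitter and rigid ligand
drift; clashed placements are retried with jitter and fail loudly after
100 attempts. Every frame's descriptors are recomputed by an independent
brute-force oracle (explicit all-pairs scans, no spatial indexing, its own
lattice derivation) and the engine must agree exactly on counts and to
1e-8 relative on continuous values.

**Feature tables** are drawn from a joint Gaussian latent vector with
equicorrelated blocks; features are quadratic expressions of the latents
and the target is linear in features plus optional pairwise products plus
Gaussian noise. Because first and second moments of such expressions
follow from Wick's theorem, the generator reports closed-form signal
variance, the R² ceiling of any regressor, the ceiling of the best purely
linear regressor, both ceilings after removing feature subsets, and every
feature–target correlation. Optional trajectory structure splits latent
variance into a between-trajectory component plus AR(1)-correlated
within-trajectory deviations (marginal covariance preserved), with AR(1)
target noise; a validation group can be generated with shifted latent
means to emulate a held-out receptor subtype whose physico-chemical
landscape differs from the development data.

The default "paper-like" preset encodes the qualitative structure observed
in real protein–GAG descriptor tables: a dominant positive lie_elec–target
association (implied correlation ≈ 0.83), anti-correlated contacts,
H-bond and charge descriptors, co-varying blocks (the two SASA columns,
gyration/end-to-end, the two contact counts), exact count identities
(net charge = positives − negatives, polarity = hydrophilic − hydrophobic),
a −40 kcal/mol mean target with ≈ 4 kcal/mol noise, and a CatS validation
group with shifted GAG-SASA/charge/contact distributions. Its `lie_elec`
column mixes a *product* of two structural latents with a private latent:
after LIE ablation the product part remains recoverable by non-linear
models while no linear model can see it (a product of zero-mean Gaussians
is uncorrelated with both factors), so linear families lose strictly more
validation R² than boosting models — a constructed analogue, with known
effect direction, of the empirical finding that LIE removal hurts linear
models most.

What passing tests on these tables does **not** show: that real MM-GBSA
data is Gaussian, that real descriptor–energy relations are
linear-plus-products, or that real validation shifts are mean shifts.
The generators validate the *machinery* — protocol correctness, ceiling
attainment, effect directions — not field accuracy on MD data.

## Problem sizes

The shipped experiments use deliberately modest sizes chosen once as
realistic desk-scale instances of the protocol: 20 toy complexes of
~60–120 atoms for oracle equivalence (a ~500-atom toy for the all-pairs
LIE check), 2,000 rows for weight recovery, 40,000 for ceiling recovery,
6,000 + 2,000 for the eight-family ablation with 2 repetitions, and a
50,000-row table for the data-reduction curve down to 2 % retention
(1,000 rows). The acceptance script prints each quantity with the problem
size it was measured at.

## Known limitations

* The descriptor engine targets solute-only, hydrogen-complete structures;
  frames without hydrogens yield zero H-bond counts with a warning.
* SASA rotation invariance is approximate at finite lattice resolution
  (see above); raise `sasa_points` if sub-0.1 % invariance matters.
* The LIE cutoff and the question of solvent in the LIE surroundings are
  not standardised in published protocols; this implementation sums
  solute–solute pairs only, within a configurable cutoff.
* The FCNN is a CPU NumPy implementation: ideal for the shallow
  architectures benchmarked here, not for deep networks or GPU-scale data.
* `ceiling_without()` requires the retained features to be identity
  latents and the removed features' private latents to be independent of
  them; it raises otherwise rather than returning a wrong number.
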