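# Methods

## Problem and model

The package quantifies how a small biogenic-amine ligand engages the
orthosteric pocket of a TAAR receptor across an ensemble of docked
poses.  The observable per pose is the residue bond set: the receptor
residues that form at least one hydrogen bond to the ligand.  Over an
ensemble, bond sets are treated as i.i.d. draws from a joint Bernoulli
contact model on a small panel of target residues (the pocket
aspartates), parameterised by per-residue marginal contact
probabilities p_r, pairwise simultaneity probabilities q_rs, and a
triple simultaneity (zero throughout the default study).  Estimation is
the empirical fraction; uncertainty is binomial, with Wilson 95 %
intervals in `ContactOccupancyResults`.  Nothing in the estimator
assumes the generator's independence structure beyond exchangeability
of poses.

A residue pair is called a binding site for a ligand when its joint
occupancy is strictly positive in every one of the receptor's
structural models, pooling replicates and every pocket-constrained run
whose pocket contains the pair.  "Strictly positive in all models" is
deliberately conservative and is configurable (`ClassificationRule`:
`min_models`, and `min_fraction` for a floor above zero); unconstrained
control runs are excluded from the default call because their joint
occupancy is model-dependent and much weaker.

## Hydrogen-bond criterion

Docking output rarely carries hydrogens, so the primary criterion is
heavy-atom: a donor–acceptor pair with exactly one ligand member at
distance ≤ `max_da_distance` (default 3.5 Å, the standard
distance-based criterion; valid range 2.0–5.0 Å).  When
`use_hydrogens` is set and a hydrogen is covalently bound to the donor
(≤ 1.3 Å, same residue), the D–H···A angle must additionally be
≥ `min_dha_angle` (default 120°).  Amine–carboxylate salt bridges
count as hydrogen bonds; intra-receptor and intra-ligand pairs never
do.  Donor/acceptor chemistry is table-driven
(`data/chem_typing.tsv`), editable without code changes; carbons are
never polar, and a ligand whose residue name is missing from the table
is an error rather than silently bond-free.  The implementation uses a
KD-tree neighbour search, but the contract is the all-pairs predicate,
and the test suite holds the two equal on randomised poses.

## Generic numbering and superposition

Ballesteros–Weinstein numbers are computed from per-receptor
configuration (7 helix ranges plus the x.50 anchor of each helix):
position = 50 + (residue − anchor).  The shipped configuration places
the literature numbers (TAAR1 Asp68 = 2.50, Asp102 = 3.32,
Asp284 = 6.61; TAAR6 Asp78 = 2.50, Asp112 = 3.32, Asp202 = 5.42); the
actual helix spans of the receptors are not published, so the ranges
around those anchors are plausible placeholders and are configuration,
not code.  (The source analysis itself is internally inconsistent about
Asp284 — labelled 6.61 in one place, helix 7 in another; the label is
whatever the configuration says.)  Model comparison uses Kabsch
superposition (SVD with the det = +1 reflection correction) over the
intersection of Cα residue numbers; no sequence alignment is attempted
because all models share one sequence.

## Synthetic study generator

No receptor models or docked poses were ever deposited, so the study
design is emulated with known ground truth.  The generator's defaults
*are* the study conditions: per receptor, 5 structural models × 5
ligands × 5 pocket options (one Asp triplet, three Asp pairs, one
unconstrained control) × 3 replicates × 10 poses = 3750 complexes, 7500
over both receptors.

The receptor stand-in is an idealised 7-helix bundle: Cα traces of
ideal α-helices (1.5 Å rise, 100° per residue, helix radius 2.3 Å) on
an 11 Å ring, with CB/CG/OD1/OD2 pseudo-carboxylates planted on the
designated aspartates pointing into the central pore.  Models 2–5 add
0.35 Å per-residue Gaussian jitter so the model set is structurally
distinct.  Ligands are simplified heavy-atom templates (amine
nitrogens, carbon chain/ring, tyramine hydroxyl, GABA carboxylate);
only donor/acceptor placement matters to the analysis, so no attempt
is made at physical bond lengths or clash avoidance.

Contact states are drawn from the explicit joint table of the contact
model (inclusion–exclusion over marginals, pairwise joints and the
triple joint; any negative cell or Fréchet violation is an error
naming the bound).  Ligand atoms are then placed constructively:
contacted residues receive a donor atom at uniform [2.7, 3.4] Å from
OD1, every ligand atom stays ≥ 4.5 Å (cutoff + 1) from the polar atoms
of non-contacted target residues, and placement is retried (up to 50
draws) before failing.  Detection therefore recovers the planted state
exactly, which is the pipeline's core testable property.  Per-condition
seeds are derived from the root seed by hashing the condition key, so
any design cell is reproducible in isolation and equal seeds give
byte-identical output.

Default planted statistics encode the qualitative pattern of the study
being emulated: pocket-constrained marginals 0.30 / 0.55 / 0.25 / 0.05
at 2.50 / 3.32 / 5.42 / 6.61, scaled per ligand (PEA 0.4, TYM 0.8,
PUT/CAD 1.0, GABA 0.6); joints of 0.20 (0.15 for tyramine) only at
{2.50, 3.32} for putrescine/cadaverine on both receptors and
additionally {3.32, 5.42} on TAAR6 (tyramine included); all other
pairs, all triplets, and all β-phenylethylamine/GABA joints are zero.
The unconstrained control plants weak marginals (0.08 / 0.18 / 0.02)
and a 0.05 joint only in a model subset (3 and 2 of 5 models on TAAR1
for putrescine/cadaverine; 1 of 5 on TAAR6), mirroring the reported
model-dependence of unconstrained docking.  Joint magnitudes where the
source reports only "observed/not observed" were chosen once as
plausible docking-ensemble frequencies and kept.

What the generator does **not** emulate: docking energetics and pose
diversity, competing non-Asp polar contacts (serines, asparagines,
tryptophans of the real pocket), receptor flexibility, and any
dependence between poses of one run.  Passing tests therefore
demonstrate that the analysis recovers whatever contact statistics the
poses contain — not that real Galaxy7TM output has those statistics.

## Sequence analyses

Percent identity reproduces the pairwise-blastp convention:
Smith–Waterman local alignment under BLOSUM62 with gap open 11 /
extend 1, identity = identical columns over alignment columns (gaps
included), rounded to integer percent.  Compositional score adjustment
is not reimplemented, so agreement with NCBI is expected to ±1 point.
Because co-optimal alignments can differ in identity count, the two
sequences are put in a canonical order before aligning, making the
function exactly symmetric.  Fingerprint analysis classifies each
column of equal-length motif segments as universal / subset:group /
variable, and a conserved-block scanner reports maximal gap-free MSA
windows of length ≥ `window` with ≥ `min_universal` universal columns
(a deliberate simplification of database fingerprint scanning, which
is out of scope).  MSA construction itself is out of scope; aligned
FASTA is accepted as input.

## Numerical and interface choices

- PDB v3.3 fixed columns, single-model files; altLoc other than
  blank/'A' dropped; ligand routing by residue-name allowlist (PEA,
  TYM, PUT, CAD, ABU by default) rather than record type, because
  docking programs vary; element from columns 77–78 with fallback to
  the first alphabetic character of the atom name.  Author residue
  numbering is used verbatim.
- Occupancy fractions are kept as exact rationals; percent displays
  are rounded to 1 decimal in per-cell tables and to integer percent
  in the whole-receptor frequency table (whose denominator is all
  poses of the receptor, not bonds).
- Replicates are pooled before fractions are computed; pooling equals
  the pose-count-weighted mean of replicate-wise fractions, which the
  suite asserts.
- `kabsch_superpose` requires N ≥ 3 matched points and returns a proper
  rotation always; RMSD on rigid-motion copies is exact to ~1e-14 Å.

## Problem sizes

The test suite and the acceptance script run the full 7500-pose design
in memory (a few seconds), use 600 poses per condition for parameter
recovery, 1000 randomised poses for the detector-vs-oracle comparison,
and 100 Monte-Carlo repeats at N = 300 points for the noise-RMSD
check.

## Known limitations

- The printed sequence-identity values can only be verified against
  the real UniProt sequences, which are fetched by the user (see
  README); everything else in the sequence module is exercised on
  synthetic and packaged fixture data.
- Site calling is a presence rule over models, not a statistical test;
  with 30–60 poses per model, planted joints below ~0.05 would make
  the all-models rule unstable.
- The RMSD values between jittered scaffold models characterise the
  generator, not any real receptor model set.
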