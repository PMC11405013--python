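# Methods

`ppihotspots` predicts protein–protein-interaction (PPI) hot-spot residues —
residues whose mutation substantially impairs a binding interaction — from
the *unbound* structure of the target protein. It combines four per-residue
features with a stacked ensemble classifier, and additionally provides two
geometric callers and the standard evaluation arithmetic used to benchmark
such predictors. This note records the model, the choices behind every
tunable, and the limits of what the synthetic test battery demonstrates.

## The prediction model

Each residue *i* of a single selected chain is described by four features:

* **k_C** — conservation grade on a 1..9 scale (9 = most conserved),
  derived from a multiple alignment of homologs;
* **aa** — amino-acid type, one-hot encoded for the learners;
* **SASA_i** — solvent-accessible surface area in Å², probe radius 1.4 Å;
* **ΔG_i^gas** — gas-phase molecular-mechanics energy in kcal/mol relative
  to an extended, non-interacting reference state,
  E_i^gas = E_i^int + E_i^vdW + E_i^ele.

A stacked ensemble maps the four features to a hot-spot probability; a
residue is called a hot spot when that probability is strictly greater
than 0.5.

The scientific rationale: hot spots tend to be conserved, and their
contribution to binding free energy shows up in the unbound structure either
as local energetic frustration (residues poised to form cross-interface
contacts are unstable without the partner) or as unusually stable scaffold
residues. The gas-phase energy term is what lets the model see hot spots
that never touch the partner protein directly.

## Conservation grades

Pipeline: homolog hits → near-duplicate removal (greedy clustering at ≥95%
pairwise identity, first representative kept) → coverage/identity filtering
(keep hits covering >60% of the target; drop identity ≤35% or ≥95%; among
survivors, when two hits' target intervals overlap by more than 10% of the
target length the shorter hit is rejected — this step's definition is
ambiguous in common practice, so it can be disabled) → cap at the top 300
hits (by search score, then identity, then input order) → target-anchored
alignment → per-column rate → grade.

Alignments are target-anchored: each hit is globally aligned to the target
(BLOSUM62, gap open −11, extend −1, via Biopython) and stacked on target
columns; insertions relative to the target are dropped, so column *p* always
means target position *p*. Prebuilt FASTA/A3M alignments are accepted
unchanged.

The default rate estimator is a sequence-weighted column heterogeneity:
Henikoff position-based weights, then the weighted Shannon entropy of the
20-letter distribution in each column, gaps excluded (0 for an invariant
column, ln 20 ≈ 3.0 in the uniform limit; an all-gap column receives the
maximum observed rate, with a log message). This is a deliberate proxy — an
empirical-Bayes phylogenetic rate program is the field's reference method,
and its per-position output can be substituted through the TSV rate adapter
without touching the rest of the pipeline. The proxy preserves the two
properties the classifier consumes: determinism and anti-monotone grades.

Grading: rates are z-scored over positions and binned into nine equal-width
bins spanning [−2.25, +2.25] (clamped); the lowest z maps to grade 9. A
zero-variance rate vector degenerates to grade 5 everywhere. The exact
partition used by conservation-grade servers is not published; equal-width
z bins are our declared convention.

## Gas-phase energy

Parameters are a heavy-atom united set shipped with the package
(`data/forcefield.tsv`): per-(residue, atom) partial charges with hydrogen
charges summed onto the bonded heavy atom, summing to the formal charge of
each residue type, and element-level Lennard-Jones constants (r_min/2, ε in
the Amber style). Combination rules: arithmetic r_min, geometric ε; Coulomb
constant 332.0636 kcal·Å/(mol·e²). This table is self-contained and
reproducible with zero external tools; it is *not* a published all-atom
force field, and an adapter ingests externally computed per-residue energy
tables for users who have them.

Exclusions follow molecular-mechanics convention on the heavy-atom bond
graph (residue topology plus peptide bonds, detected for consecutive
residues with C–N ≤ 1.9 Å): path distance 1–2 excluded, distance 3 scaled
by 1/2.0 (vdW) and 1/1.2 (electrostatics).

Decomposition: every inter-residue pair term is split half/half between the
two residues, so the per-residue ledger sums exactly to the total
inter-residue nonbonded energy. E_i^int is the intra-residue nonbonded
energy (1-4 and beyond) minus the same quantity evaluated on the residue's
extended template. Torsional terms are omitted: no transferable torsion set
exists for the united representation, and the intra-residue nonbonded terms
already vary with conformation while bond/angle terms cancel for fixed
covalent geometry. A lone residue posed exactly at its template scores zero
in every component — this self-consistency is asserted in the tests.

The extended templates are built deterministically by a natural-extension
(NeRF) tree walk from an internal-coordinate table (extended backbone,
anti side-chain rotamers, approximately planar rings) and cached per residue
type. The template defines the zero of the ledger; no claim is made that it
matches any particular external decomposition protocol.

Residues with missing heavy atoms are flagged, logged, and excluded from
the feature table (their partial energies would not be comparable). An
optional repulsive-only clash-relief step (capped steepest descent on the
r⁻¹² term, default off) is available for poorly refined inputs; the polar
solvation term of full MM-PBSA-style decompositions is out of scope, and the
nonpolar term is available only as the γ·SASA surrogate
(γ = 0.00542 kcal/mol/Å²) — neither enters the four-feature model.

## Solvent accessibility and contacts

SASA uses the Shrake–Rupley rolling-probe construction with a deterministic
golden-spiral lattice, 960 points per heavy atom by default, probe 1.4 Å,
Bondi vdW radii. The fixed world-frame lattice makes results reproducible
bit-for-bit at the cost of a small orientation dependence (≤0.5% under
rigid motion at the default density; measured ≈0.3% on a hexapeptide).

Contact predicates, used by the interface classifier and the probe caller:

* vdW contact: some heavy-atom pair within r_i + r_j + 0.5 Å (inclusive).
* hydrogen bond (heavy-atom criterion, usable without hydrogens):
  donor–acceptor ≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 120°, with
  per-residue donor/acceptor tables.
* interface residue: ≥1 atom within 5 Å (inclusive) of any partner atom.

The upstream literature defers the exact hydrogen-bond and vdW thresholds
to citations we do not reproduce; the values above are declared,
configurable defaults, not claims of equivalence.

## Stacked ensemble

The classifier re-implements the mechanics of AutoML tabular stacking over
a six-learner registry (gradient-boosted trees, random forest, extremely
randomized trees, k-nearest neighbors, a shallow neural network, logistic
regression — all scikit-learn implementations; distance- and
gradient-based learners are wrapped with standardization). Per layer, each
learner is trained with repeated stratified k-fold bagging; its out-of-fold
probabilities (averaged over repeats) join the original features as inputs
to the next layer. The output layer runs greedy forward ensemble selection
with replacement, maximizing F1 of calls at the 0.5 threshold on the
out-of-fold predictions; selection counts become normalized ensemble
weights, so the selected ensemble never validates below the best single
stacker. Defaults: 2 layers, k = 5, 1–2 repeats, seed 0. `k_folds=1` is a
degenerate no-bagging mode in which a one-layer, one-learner stack reduces
exactly to that learner — useful for testing and fast baselines.

Probabilities are raw weighted averages (no isotonic/Platt calibration);
class imbalance is left untreated because the intended labeled tables are
near-balanced (≈45% positives). Cross-validation is protein-grouped by
default so folds never split a protein. Permutation importance shuffles one
feature column at a time and reports the mean F1 drop over seeded repeats.

Determinism: one master seed derives every fold shuffle and learner seed;
two fits with the same seed serialize to byte-identical archives. Model
archives embed a schema hash of the feature columns and dtypes; prediction
and loading refuse mismatched schemas.

## Geometric callers and evaluation

The probe-consensus caller ingests probe clusters (MODEL-delimited PDB or a
serial→cluster sidecar), groups cluster centroids into consensus sites by
single-linkage at 4 Å (our declared convention; configurable), picks the
site with the most member clusters (ties break toward the site containing
the smallest cluster id), and returns all residues in vdW contact with its
probes. The interface-mode caller returns the interface residues of a
modeled complex. The union combination is a set union, which provably never
lowers sensitivity and never raises specificity relative to either input.

Metrics follow the standard quartet (sensitivity, precision, F1,
specificity) computed from TP/FP/TN/FN at full precision and display-rounded
half-up to two decimals. Precision with zero predicted positives raises an
explicit error by default and can be coerced to 0 with a warning for
degenerate folds. Hot-spot predictions outside the labeled universe are an
error rather than silently counted.

## Synthetic data: what it does and does not show

The generator produces three kinds of fixtures. Idealized structures:
helix/strand backbones (N, CA, C, O, CB) from canonical dihedrals with a
0.01 Å seeded jitter — valid PDB, correct Cα spacing, no real side chains.
Alignments: rows drawn i.i.d. per column with a controlled substitution
probability. Labeled tables: k_C uniform on 1..9, SASA from a gamma(2, 40)
truncated at 300 Å², ΔG^gas normal(0, 5 kcal/mol), amino acids uniform, and
labels Bernoulli under
logit P = β₀ + β₁·z(k_C) + β₂·z(SASA) + β₃·z(ΔG^gas) + offset(aa) + ε.
Defaults (β₀ = −0.2; β = 1.0, 0.6, 0.4; offsets W +0.8, Y +0.6, R +0.5;
ε sd 0.5; 60 proteins × 40 residues) emulate the shape of real curated
benchmarks: ~45% prevalence in the labeled table, conservation strongest,
then residue type (aromatic/arginine enrichment), surface area, energy. The
problem sizes are chosen so the whole battery runs on a laptop core in
minutes.

Passing the synthetic battery demonstrates mechanical correctness
(oracle-verified geometry and energetics, deterministic pipelines, signal
recovery when the generative model matches the classifier's features). It
does *not* demonstrate accuracy on real proteins: real features are
correlated, real conservation is phylogenetic rather than i.i.d., and real
hot-spot labels do not follow a logistic law in these four features.

## Numerical choices and degenerate inputs

Altlocs collapse to the highest-occupancy conformer (tie: alphabetically
first). Multi-model entries use the first model. MSE and common PTM residue
codes map to their parents; unknown residues are skipped with a warning.
Probability exactly 0.5 is a non-hot-spot (strict threshold). Zero-variance
rate vectors grade 5; all-gap columns take the maximum observed rate;
empty prediction sets evaluate with TP = FP = 0. Coordinates are PDB
numbering everywhere user-facing; no UniProt renumbering is attempted
(an offset table can be applied by the caller).

## Known limitations

* The energy model is a coarse united-atom approximation; absolute energies
  are not comparable to all-atom force-field output (the adapter exists for
  exactly that reason).
* The entropy-based rate proxy ignores phylogeny; deep, redundant
  alignments are handled only through sequence weighting.
* The probe-consensus caller depends on externally generated probe
  clusters; the package does not dock probes.
* No structure preparation (protonation, missing-atom rebuilding) beyond
  altloc collapsing and optional clash relief.
* mmCIF input, biological assemblies and antibody-specific handling are out
  of scope.
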