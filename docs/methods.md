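# Methods

This note documents the models, conventions and numerical choices behind
`fvbuild`, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Numbering and regions

Queries are numbered by global alignment (BLOSUM62, affine gaps) against one
curated reference profile per chain type (kappa, lambda, heavy); kappa vs
lambda is chosen by profile score unless overridden. Aligned framework
columns inherit scheme labels directly; each CDR segment is numbered by its
own rule: loops at or below the scheme's base length fill positions from
both ends of the CDR (deletions fall in the middle), longer loops carry
insertion codes A, B, C… at the CDR's anchor label. This makes numbering
deterministic and idempotent, and framework labels independent of loop
length.

Scheme tables (CDR bounds, label maps, anchors) are data files under
`fvbuild/data/schemes/`. Conventions pinned there:

- Chothia: L1 24–34 (11 base), L2 50–52 (3), L3 89–97 (9); H1 26–32 (7,
  loops of length 8–9 put codes at H31 — the 31/31A convention), H2 52–55
  (4), H3 95–102.
- Kabat: L2 extends to 7 residues; H1 31–35, H2 50–58.
- Honegger: L2 spans 12 residues.
- IMGT/Honegger label maps are monotone gapped approximations of the
  published coordinate systems, adequate for region bookkeeping at this
  scale; they are not a substitute for the official renumbering services.

A sequence is rejected as "not an antibody domain" below 30% identity to
every profile, on non-standard characters, or outside 90–150 residues.

Structures are indexed by Chothia positions throughout; other schemes act as
*views* (region membership is decided by renumbering the sequence, then
mapped back onto the Chothia-indexed residues), so loop definitions can be
switched without renumbering coordinates.

## Canonical classes

Canonical classes are data (`fvbuild/data/canonical_classes.csv`): class,
chain type, CDR, loop length, and (position : allowed residues) constraints
in Chothia coordinates. Constraints may sit in the framework — kL2:1
requires Ile/Val 48 and Gly 64; kL1:2A vs 2B split on Ile vs Leu at position
2; the H2 classes split on framework position 71. Assignment returns the
unique satisfied class, "none" when nothing matches, and raises a
configuration error when definitions overlap. Some shipped classes are
deliberately restrictive; the table is meant to be edited.

## Template scoring

Identity and similarity are computed over scheme-aligned positions present
in both sequences (CDRs excluded unless asked): identity = % identical,
similarity = % with BLOSUM62 > 0. The positive-BLOSUM62 convention is a
choice — published similarity percentages from other tools may differ
slightly under other conventions. Hit ordering is similarity, then identity,
then resolution (best first, absent last), then template id. The Top5
window rule retains hits within 10 percentage points of the best similarity,
boundary inclusive; the retained set is always a non-empty prefix of the
ranking.

## Framework building

An external comparative-modelling engine is replaced by an in-repo
restrained minimizer:

- Restraint graph: atom pairs (over N, CA, C, O, CB) within 8 Å in any
  template, at residue separation ≥ 2 (inter-chain pairs always qualify).
- Each template contributes `-w · exp(-(d - d_t)² / 2σ²)` per pair, σ = 1 Å;
  weights come from local sequence similarity in a ±2-residue window and are
  normalised across templates per pair. With several templates the wells are
  additive — conflicting templates cannot produce an error, only a
  compromise minimum nearer the better-matching template.
- A harmonic covalent-geometry term (intra-residue and peptide-link
  distances, k = 50 Å⁻², equilibria from the starting structure) keeps
  bonding intact where restraints are sparse.
- Minimization: L-BFGS with analytic gradients from the best template's
  coordinates threaded with the target sequence (substituted side chains are
  represented by an ideal-geometry CB; the model is backbone + CB
  throughout). `n` conformers come from seeded 0.2 Å Gaussian perturbations
  of the start; the kept model minimises restraint energy + 10 per steric
  clash (< 2.5 Å, non-bonded) + 2 per non-planar peptide ω (> 30° from
  cis/trans), with the model id as deterministic tie-break.
- Chimeric builds orient the threaded VL and VH donors by Kabsch
  superposition of shared framework backbone positions onto the interface
  template's domains (error if fewer than 20 shared positions), then
  restrain against the assembled chimera.
- Template positions absent for a target residue are bridged by linear
  interpolation between placed neighbours and flagged; such residues carry
  no template restraints and rely on the covalent term.

## CDR grafting

Loop candidates must match the target loop length exactly under the active
scheme. Ranking is lexicographic by default: loop+stem BLOSUM62 score (stems
= 3 residues each side), then the summed score of the template's other two
same-domain CDRs, then resolution, then id. Because worked cases exist in
which the cross-loop signal overrides the loop score, a `blended` mode
(loop + cross-loop combined into one primary key) is available; the tier
order is genuinely ambiguous and both behaviours are tested.

Grafting superposes each candidate's stems onto the framework stems (backbone
atoms, residues paired outward from the loop; stem RMSD above 1.5 Å logs an
"incompatible anchors" warning but still grafts), then rebuilds the loop by
the same multi-template restraint machinery restricted to loop atoms with
everything else frozen — framework coordinates are bitwise unchanged, by
construction and by test. Peptide ω angles that drift more than 30° from the
top template (e.g. a cis-proline lost in minimization) are logged. An
optional anomaly filter clusters the generated loop conformers
(single-linkage, 1 Å) and discards clusters holding < 10% of models; it is
off by default.

Defaults: 3 loop templates (5 recommended together with 10 loop models — the
best-overall validation profile), 10 loop models, canonical filtering on
(Chothia only; with automatic fallback to unfiltered when no template of the
target's class exists).

## Assessment

- β-sheet core: a fixed, configurable list of conserved Chothia framework
  positions per domain (37 light, 42 heavy) — `assess.CORE_POSITIONS`.
  Superposition is least-squares over backbone N, CA, C of shared core
  positions, computed once per pair and never refit per region.
- Region RMSDs are over carbonyl C and O atoms at scheme-matched positions;
  regions incomplete in either structure are flagged and excluded from
  summaries rather than imputed.
- Tilt: per-domain orthonormal frames from the principal axes of the core
  coordinates, with covariant sign fixing (chain-direction and
  first-residue references), so frames rotate rigidly with the domain; the
  reported quantity is the rotation angle between the two structures'
  VL→VH relative orientations. This construction is a documented surrogate
  for the assessment-protocol formula, pinned in code so values are
  reproducible within the package; absolute tilt values from other tools may
  differ by a method-dependent offset — deviations are the comparable
  quantity, and planted fixture rotations are recovered exactly.
- Quartiles use linear interpolation; Tukey whiskers are 1.5×IQR beyond the
  quartiles clipped to the data range; outliers lie beyond the whiskers.
  The paired t-test returns p = 1 for identical samples and raises on a
  constant non-zero shift (zero difference variance) instead of reporting
  p = 0.

## Synthetic fixtures

`fvbuild.synth` builds idealized Fv scaffolds: framework sequences are the
reference profiles themselves, loops come from a catalog keyed by (label,
length), backbones are generated from internal coordinates (meander-sheet
framework torsions, per-loop torsion sets) with standard bond lengths and
angles, and VH is placed by a fixed rigid transform. Perturbations plant
known ground truth: dissimilar substitutions (identity arithmetic is exact),
chain-smoothed Gaussian coordinate noise (window 9, exact per-atom marginal
σ, covalent geometry preserved), endpoint-anchored loop-conformer
displacement fields, and VH rotations about a seeded axis. The generator
refuses specs whose planted loop lengths do not survive numbering, so the
ground truth can never silently drift.

What the fixtures do **not** emulate: real β-sandwich packing and side-chain
chemistry, crystallographic artefacts (lattice contacts, non-planar
peptides, alternate conformers), genuine canonical-conformation/sequence
coupling, and realistic H3 conformational diversity. Passing tests therefore
demonstrate that the pipeline's contracts hold (correct selection, exact
rule evaluation, framework-intact grafting, planted-parameter recovery) —
not that predictions of real antibodies reach any particular accuracy.

## Validation campaigns and problem sizes

`fvbuild.validation` drives the desk-scale campaigns used by the test suite
and `scripts/acceptance.py`: single-target full-pipeline self-recovery
(three-entry database, decoys outside the similarity window and without
length-matched loops), a six-angle 3–15° rotation sweep, 20 randomized
five-entry databases for search-order recovery, 1000 random vectors/sets for
the window-filter and loop-ranking oracles, 100 random samples for the
statistics oracles, 50 grafts for the framework-intact contract, and a
20-target Top5-vs-Single comparison with five noisy (σ = 0.6 Å) template
copies per target. These sizes keep the whole campaign around a minute on
one CPU while leaving the comparisons far from their decision boundaries;
the Top5 advantage on that campaign (~0.19 Å mean framework RMSD, paired
p ≪ 0.001) is the expected error-averaging of independent template noise.

## Known limitations

- Backbone + CB only; no rotamer-level side-chain model, no physics-based
  refinement, no explicit solvent.
- Template-based H3 only: with no length-matched H3 template the loop is
  left at the framework conformation and flagged.
- The build score is a surrogate ranking, not a transferable energy;
  absolute values are not comparable across targets or to other tools.
- IMGT/Honegger label maps are approximations (see above); Chothia output
  numbering is the supported interchange convention.
- Redundancy pruning is O(n²) pairwise alignment — fine for curated
  databases of hundreds, not for PDB-scale crawls.
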