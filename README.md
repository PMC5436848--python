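# fvbuild

Automated template-based prediction of antibody Fv structures, with the
assessment machinery used in blind antibody-modelling assessments, and a
synthetic-fixture generator that makes the whole pipeline testable offline.

Antibody engineers routinely need three-dimensional models of the variable
fragment (Fv = VL + VH) from sequence alone — for stability, developability
and docking work. Because antibody frameworks are highly conserved and five
of the six hypervariable loops (CDRs) fall into discrete canonical
conformational classes, specialised homology modelling beats generalist
methods: pick framework templates from a curated database of antibody
structures, build the framework, then graft length-matched CDR loop
templates. `fvbuild` implements that pipeline as a library plus a CLI.

## Method

Prediction runs in three stages, with no manual intervention:

1. **Framework template selection.** The query chains are numbered under a
   standard scheme (Chothia, IMGT, Kabat or Honegger; shipped as data
   tables) by alignment to curated reference profiles. Database templates
   are scored at scheme-aligned positions: identity = % identical residues,
   similarity = % positions with positive BLOSUM62 score, CDRs excluded by
   default. Ranked hits are produced for the whole Fv and for each chain.
2. **Framework model construction**, by one of three strategies:
   - *Single*: one whole-Fv template, threaded with the target sequence;
   - *Chimeric*: separate VL and VH donor templates, oriented by rigidly
     superposing each domain onto a third whole-Fv interface template;
   - *Top5*: up to five templates simultaneously (templates more than 10
     similarity points below the best are rejected). Each template
     contributes an additive Gaussian distance well per restrained atom
     pair, weighted by local sequence similarity in a sliding window;
     coordinates minimise the total restraint energy (L-BFGS) from the best
     template's threaded coordinates. Candidate conformers from seeded
     perturbation are ranked by restraint energy + steric-clash +
     peptide-torsion penalties.
3. **CDR refinement.** For each loop, database templates with the *identical
   loop length* are collected (optionally restricted to the target's Chothia
   canonical class when such templates exist), ranked by BLOSUM62 score of
   the loop plus stem residues, then by a cross-loop bonus (templates whose
   other two same-domain CDRs also match well), then by crystallographic
   resolution. The retained templates drive a multi-template restrained
   rebuild of the loop with stems anchored on the framework; framework
   atoms are never moved. Loops with no length-matched template are left at
   the framework-model conformation and flagged.

**Assessment** mirrors blind-assessment practice: each predicted/experimental
pair is superposed once over a fixed β-sheet-core set of conserved framework
positions; per-region RMSDs are computed over backbone carbonyl (C, O) atoms
(sensitive to peptide flips that Cα RMSDs hide); the VL–VH tilt-angle
deviation is the angle between the two structures' relative domain
orientations from principal-axes frames. Summary tooling includes Tukey box
statistics, paired t-tests, similarity-binned tables and length×similarity
heat-map aggregation.

Everything is deterministic under a run seed, and batch runs derive a
per-target seed from (run seed, target id).

## Worked example

The fixture generator builds idealized Fv scaffolds and perturbed template
databases with known ground truth, so the full pipeline runs without any
downloads:

```python
import fvbuild as fb
from fvbuild import synth

# Template database: three perturbed copies of a base antibody, with known
# numbers of framework substitutions and 0.4 A coordinate noise.
spec = synth.ScaffoldSpec(name="TGT")
perts = [
    ("T0_LH", synth.PerturbationSpec(framework_noise_sigma=0.4, seed=1), "human", 1.8),
    ("T1_LH", synth.PerturbationSpec(substitutions=[("light", 9, "W"), ("heavy", 9, "W")],
                                     framework_noise_sigma=0.4, seed=2), "human", 2.0),
    ("T2_LH", synth.PerturbationSpec(substitutions=[("light", p, "W") for p in (5, 9, 13, 17)]
                                     + [("heavy", p, "W") for p in (5, 9, 13, 17)],
                                     framework_noise_sigma=0.4, seed=3), "mouse", 2.4),
]
db, truth = synth.make_synthetic_database(spec, perts)

target, _ = synth.make_synthetic_fv(spec)
config = fb.RunConfig(n_framework_models=2, n_cdr_models=2, seed=1)
res = fb.predict_structure(target.light.sequence(), target.heavy.sequence(),
                           db, config, target_id="TGT")
print("status:", res.status)
print("framework templates:", res.model.framework_templates)

report = fb.assess_pair(res.model.structure, target)
for region in ("FR", "L1", "L2", "L3", "H1", "H2", "H3", "FV"):
    print(f"{region:3s} carbonyl RMSD: {report.region_rmsd[region]:.2f} A")
print(f"tilt deviation: {report.tilt_deviation:.1f} deg")
```

which prints:

```
status: success
framework templates: ['T0_LH', 'T1_LH', 'T2_LH']
FR  carbonyl RMSD: 0.66 A
L1  carbonyl RMSD: 0.41 A
L2  carbonyl RMSD: 0.58 A
L3  carbonyl RMSD: 0.41 A
H1  carbonyl RMSD: 0.93 A
H2  carbonyl RMSD: 0.90 A
H3  carbonyl RMSD: 0.29 A
FV  carbonyl RMSD: 0.65 A
tilt deviation: 4.1 deg
```

All three templates fall within the 10-point similarity window, so the Top5
build restrains against all of them; the sub-Angstrom region RMSDs reflect
the 0.4 Å noise planted in the templates — the model averages template errors
rather than inheriting one copy's noise. The 4.1° tilt deviation is the
residual VL–VH orientation error under that noise.

The same flow is available from the shell:

```
fvbuild build-db templates/*.pdb --out mydb
fvbuild predict input.fasta --db mydb --out predictions --cdr-templates 5
fvbuild assess predictions/TGT.pdb xray/TGT.pdb
```

## Scope

Fv only (no Fab constant domains), template-based only (no ab-initio H3
modelling), backbone + CB resolution. The canonical-class table and the
numbering scheme tables are editable data files, not code.
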