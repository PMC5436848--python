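"""Framework-builder tests: threading, restrained minimization, the three
build strategies and model ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from fvbuild import geometry as geom
from fvbuild import synth
from fvbuild.build import (AtomTable, BuildError, FvModel, RestraintSystem,
                           build_chimeric_model, build_restraints,
                           build_single_model, build_top5_model, count_clashes,
                           rank_models, WELL_SIGMA)
from fvbuild.db import ingest_structure
from fvbuild.assess import assess_pair, superpose_core, region_carbonyl_rmsd


def fr_carbonyl_rmsd(model, reference):
    sup = superpose_core(model.structure, reference)
    val, _ = region_carbonyl_rmsd(model.structure, reference, sup, "FR")
    return val


def test_self_template_recovers_framework_below_point1(base_fv, base_numbered,
                                                       self_record):
    model = build_single_model(base_numbered, self_record, n_models=1, seed=0)[0]
    assert fr_carbonyl_rmsd(model, base_fv) <= 0.1


def test_fixed_seed_reproduces_bitwise(base_numbered, self_record):
    a = build_single_model(base_numbered, self_record, n_models=3, seed=42)
    b = build_single_model(base_numbered, self_record, n_models=3, seed=42)
    for x, y in zip(a, b):
        assert np.array_equal(x.structure.all_coords(), y.structure.all_coords())
    c = build_single_model(base_numbered, self_record, n_models=1, seed=43)[0]
    assert not np.array_equal(a[0].structure.all_coords(),
                              c.structure.all_coords())


def test_output_sequence_equals_target_even_with_substituted_template(
        base_scaffold, self_record):
    base, numbered = base_scaffold
    mutated, renumbered = synth.perturb_structure(
        base, numbered, synth.PerturbationSpec(
            substitutions=[("light", 10, "W"), ("heavy", 30, "W")], seed=1))
    model = build_single_model(renumbered, self_record, n_models=1, seed=0)[0]
    assert model.structure.light.sequence() == mutated.light.sequence()
    assert model.structure.heavy.sequence() == mutated.heavy.sequence()


def test_rigid_motion_of_template_moves_model_rigidly(base_fv, base_numbered):
    R = geom.rotation_about_axis(np.array([1.0, -2.0, 0.5]), 25.0)
    t = np.array([4.0, -7.0, 2.0])
    moved = base_fv.transform(R, t)
    rec0 = ingest_structure(base_fv).records[0]
    rec1 = ingest_structure(moved).records[0]
    m0 = build_single_model(base_numbered, rec0, n_models=1, seed=5)[0]
    m1 = build_single_model(base_numbered, rec1, n_models=1, seed=5)[0]
    back = geom.apply_rigid(m1.structure.all_coords(), R.T, -R.T @ t)
    assert geom.rmsd(back, m0.structure.all_coords()) < 0.05


def test_chimeric_with_one_template_matches_single_build(base_numbered,
                                                         self_record, base_fv):
    single = build_single_model(base_numbered, self_record, n_models=1, seed=3)[0]
    chimera = build_chimeric_model(base_numbered, self_record, self_record,
                                   self_record, n_models=1, seed=3)[0]
    sup = superpose_core(chimera.structure, single.structure)
    val, _ = region_carbonyl_rmsd(chimera.structure, single.structure, sup, "FV")
    assert val < 0.1


def test_chimeric_orientation_comes_from_interface_template(base_scaffold):
    base, numbered = base_scaffold
    donors = ingest_structure(base).records[0]
    rotated, _ = synth.perturb_structure(
        base, numbered, synth.PerturbationSpec(domain_rotation=10.0, seed=7))
    interface = ingest_structure(rotated).records[0]
    interface.template_id = "IFACE_LH"
    model = build_chimeric_model(numbered, donors, donors, interface,
                                 n_models=1, seed=0)[0]
    from fvbuild.assess import tilt_angle_deviation
    assert tilt_angle_deviation(model.structure, rotated) < 1.0
    assert abs(tilt_angle_deviation(model.structure, base) - 10.0) < 1.0


def test_chimeric_domains_stay_closest_to_their_own_donors(base_scaffold):
    base, numbered = base_scaffold
    donor_a = ingest_structure(base).records[0]
    shifted, _ = synth.perturb_structure(
        base, numbered, synth.PerturbationSpec(framework_noise_sigma=1.0, seed=9))
    donor_b = ingest_structure(shifted).records[0]
    donor_b.template_id = "DONORB_LH"
    model = build_chimeric_model(numbered, donor_a, donor_b, donor_a,
                                 n_models=1, seed=0)[0]

    def domain_rmsd(chain_model, chain_ref):
        keys = [r.key for r in chain_ref.residues]
        P = chain_model.coords(("N", "CA", "C"), keys=keys)
        Q = chain_ref.coords(("N", "CA", "C"), keys=keys)
        return geom.kabsch(P, Q)[2]

    # light came from donor A, heavy from donor B
    assert domain_rmsd(model.structure.light, donor_a.structure.light) < \
        domain_rmsd(model.structure.light, donor_b.structure.light)
    assert domain_rmsd(model.structure.heavy, donor_b.structure.heavy) < \
        domain_rmsd(model.structure.heavy, donor_a.structure.heavy)


def test_five_identical_templates_reduce_to_single(base_numbered, self_record):
    t5 = build_top5_model(base_numbered, [self_record] * 5, n_models=1, seed=1)[0]
    s1 = build_single_model(base_numbered, self_record, n_models=1, seed=1)[0]
    assert geom.rmsd(t5.structure.all_coords(), s1.structure.all_coords()) < 0.05


def test_top5_provenance_lists_exactly_the_templates_used(base_numbered,
                                                          graded_db):
    db, _ = graded_db
    recs = [db.get(t) for t in ("T0_LH", "T1_LH", "T2_LH")]
    model = build_top5_model(base_numbered, recs, n_models=1, seed=0)[0]
    assert model.framework_templates == ["T0_LH", "T1_LH", "T2_LH"]
    assert model.per_region_provenance["FR"] == ["T0_LH", "T1_LH", "T2_LH"]


def test_top5_rejects_bad_template_counts(base_numbered, self_record):
    with pytest.raises(BuildError):
        build_top5_model(base_numbered, [], n_models=1, seed=0)
    with pytest.raises(BuildError):
        build_top5_model(base_numbered, [self_record] * 6, n_models=1, seed=0)


def test_two_well_minimum_matches_closed_form_oracle():
    """An atom pair restrained by two Gaussian wells of unequal weight settles
    between the wells, nearer the higher-weighted one, at exactly the 1-D
    closed-form minimum."""
    d1, d2, w1, w2 = 5.0, 6.4, 0.7, 0.3
    table = AtomTable(keys=[("light", (1, ""), "CA"), ("light", (3, ""), "CA")],
                      res_ordinal=np.array([0, 2]), chain_code=np.array([0, 0]))
    system = RestraintSystem(
        table,
        well_d=np.array([[d1, d2]]), well_w=np.array([[w1, w2]]),
        pairs=np.array([[0, 1]]), bonds=np.zeros((0, 2), dtype=int),
        bond_d0=np.zeros(0), sigma=WELL_SIGMA)
    start = np.array([[0.0, 0.0, 0.0], [5.6, 0.0, 0.0]])
    final, _ = system.minimize(start, maxiter=500)
    d_final = np.linalg.norm(final[0] - final[1])

    def energy_1d(d):
        return -(w1 * np.exp(-(d - d1) ** 2 / (2 * WELL_SIGMA ** 2))
                 + w2 * np.exp(-(d - d2) ** 2 / (2 * WELL_SIGMA ** 2)))

    oracle = minimize_scalar(energy_1d, bounds=(d1 - 1, d2 + 1), method="bounded").x
    assert d_final == pytest.approx(oracle, abs=1e-3)
    assert d1 < d_final < d2
    assert abs(d_final - d1) < abs(d_final - d2)   # nearer the heavier well


def test_rank_models_prefers_clean_model_over_planted_clash(base_numbered,
                                                            self_record):
    clean = build_single_model(base_numbered, self_record, n_models=1, seed=0)[0]
    clashed = FvModel(
        structure=clean.structure.copy(), target_numbered=base_numbered,
        build_method="single", framework_templates=clean.framework_templates,
        restraint_energy=clean.restraint_energy, model_id="m1")
    # plant a 1 A backbone clash: drop one CA onto a residue two positions away
    res = clashed.structure.light.residues
    res[10].atoms["CA"] = res[12].atoms["CA"] + np.array([1.0, 0.0, 0.0])
    assert count_clashes(clashed.structure) > count_clashes(clean.structure)
    assert rank_models([clean, clashed]) is clean
    assert rank_models([clashed, clean]) is clean


def test_rank_models_tiebreak_and_single_model(base_numbered, self_record):
    m = build_single_model(base_numbered, self_record, n_models=1, seed=0)[0]
    assert rank_models([m]) is m
    twin = FvModel(structure=m.structure.copy(), target_numbered=base_numbered,
                   build_method="single", framework_templates=m.framework_templates,
                   restraint_energy=m.restraint_energy, model_id="m9")
    assert rank_models([twin, m]) is m     # lexicographically first id wins


def test_template_missing_positions_triggers_gap_fallback_warning(base_scaffold,
                                                                  self_record):
    base, _ = base_scaffold
    long_spec = synth.ScaffoldSpec(name="LONGH3",
                                   cdr_lengths={**synth.BASE_CDR_LENGTHS, "H3": 16})
    _, long_numbered = synth.make_synthetic_fv(long_spec)
    model = build_single_model(long_numbered, self_record, n_models=1, seed=0)[0]
    assert any("bridged by interpolation" in w for w in model.warnings)
    assert model.structure.heavy.sequence() == long_numbered["heavy"].sequence
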