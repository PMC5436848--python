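"""Assessment tests: core superposition, carbonyl RMSD sensitivity, tilt
deviation, and the summary statistics."""

import numpy as np
import pytest
import scipy.stats as sps

from fvbuild import geometry as geom
from fvbuild import synth
from fvbuild.assess import (AssessmentError, assess_pair, paired_t_test,
                            read_results_table, region_carbonyl_rmsd,
                            results_row, similarity_binned_stats,
                            superpose_core, tilt_angle_deviation,
                            length_similarity_heatmap, tukey_box_stats,
                            write_results_table, REGIONS)


def test_identical_structures_score_zero_everywhere(base_fv):
    result = assess_pair(base_fv, base_fv)
    assert all(v < 1e-8 for v in result.region_rmsd.values())
    assert result.tilt_deviation < 1e-4


def test_rigidly_moved_copy_superposes_exactly(base_fv):
    R = geom.rotation_about_axis(np.array([0.3, 1.0, -0.2]), 48.0)
    moved = base_fv.transform(R, np.array([10.0, -4.0, 2.0]))
    sup = superpose_core(base_fv, moved)
    assert sup.core_rmsd < 1e-6
    # the recovered transform inverts the applied rotation
    assert np.allclose(sup.rotation, R, atol=1e-6)


def test_planted_noise_gives_rmsd_near_noise_model_expectation(base_scaffold):
    """Per-coordinate sigma=0.5 noise: expected post-fit RMSD is close to
    sqrt(3)*sigma (the rigid fit absorbs only a few degrees of freedom)."""
    base, numbered = base_scaffold
    sigma = 0.5
    vals = []
    for seed in range(5):
        noisy, _ = synth.perturb_structure(
            base, numbered, synth.PerturbationSpec(framework_noise_sigma=sigma,
                                                   seed=seed))
        vals.append(superpose_core(base, noisy).core_rmsd)
    expected = np.sqrt(3) * sigma
    assert 0.5 * expected < np.mean(vals) < 1.2 * expected


def test_carbonyl_rmsd_detects_a_peptide_flip_that_calpha_rmsd_misses(
        base_fv, base_numbered):
    flipped = base_fv.copy()
    keys = [r.key for r in base_numbered["light"].residues if r.region == "CDR1"]
    idx = flipped.light.index()
    order = [r.key for r in base_numbered["light"].residues]
    i = order.index(keys[3])
    a = idx[order[i]]
    b = idx[order[i + 1]]
    axis = b.atoms["CA"] - a.atoms["CA"]
    R = geom.rotation_about_axis(axis, 180.0)
    for atom in ("C", "O"):
        a.atoms[atom] = R @ (a.atoms[atom] - a.atoms["CA"]) + a.atoms["CA"]
    sup = superpose_core(flipped, base_fv)
    loop_rmsd, _ = region_carbonyl_rmsd(flipped, base_fv, sup, "L1")
    ca_p = flipped.light.coords(("CA",), keys=keys)
    ca_q = base_fv.light.coords(("CA",), keys=keys)
    ca_rmsd = geom.rmsd(geom.apply_rigid(ca_p, sup.rotation, sup.translation), ca_q)
    assert ca_rmsd < 0.05
    assert loop_rmsd > 0.5


@pytest.mark.parametrize("angle", [3.0, 7.0, 15.0])
def test_planted_domain_rotation_recovered_within_half_degree(base_scaffold,
                                                              angle):
    base, numbered = base_scaffold
    rotated, _ = synth.perturb_structure(
        base, numbered, synth.PerturbationSpec(domain_rotation=angle, seed=13))
    assert tilt_angle_deviation(base, rotated) == pytest.approx(angle, abs=0.5)


def test_tilt_invariant_under_independent_rigid_motions(base_scaffold):
    base, numbered = base_scaffold
    rotated, _ = synth.perturb_structure(
        base, numbered, synth.PerturbationSpec(domain_rotation=7.0, seed=3))
    a = base.transform(geom.rotation_about_axis(np.array([1.0, 0, 0]), 30.0),
                       np.array([5.0, 5.0, 5.0]))
    b = rotated.transform(geom.rotation_about_axis(np.array([0, 1.0, 1.0]), -70.0),
                          np.array([-3.0, 8.0, 0.0]))
    assert tilt_angle_deviation(a, b) == pytest.approx(7.0, abs=0.5)


def test_too_few_core_positions_errors(base_fv):
    truncated = base_fv.copy()
    truncated.light.residues = truncated.light.residues[:10]
    truncated.heavy.residues = truncated.heavy.residues[:10]
    with pytest.raises(AssessmentError):
        superpose_core(base_fv, truncated)


def test_degenerate_axes_error():
    line = np.column_stack([np.linspace(0, 30, 40),
                            np.zeros(40), np.zeros(40)])
    with pytest.raises(ValueError):
        geom.domain_frame(line)


def test_rmsd_is_a_metric_on_fixture_coordinate_sets():
    rng = np.random.default_rng(7)
    a, b, c = (rng.normal(size=(30, 3)) for _ in range(3))
    assert geom.rmsd(a, a) == 0.0
    assert geom.rmsd(a, b) == pytest.approx(geom.rmsd(b, a))
    assert geom.rmsd(a, c) <= geom.rmsd(a, b) + geom.rmsd(b, c) + 1e-12


def test_tukey_constant_and_single_value_collapse():
    for vals in ([4.0] * 6, [4.0]):
        bs = tukey_box_stats(vals)
        assert bs.q1 == bs.median == bs.q3 == bs.mean == 4.0
        assert bs.outliers == []
        assert bs.whisker_low == bs.whisker_high == 4.0


def test_tukey_flags_the_planted_outlier():
    bs = tukey_box_stats([1, 2, 3, 4, 5, 6, 7, 100])
    # oracle: quartiles by linear interpolation on the 8 sorted values
    v = np.array([1, 2, 3, 4, 5, 6, 7, 100], dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    assert bs.q1 == pytest.approx(q1)
    assert bs.q3 == pytest.approx(q3)
    assert bs.outliers == [100.0]
    assert bs.whisker_high == 7.0


def test_tukey_empty_errors():
    with pytest.raises(AssessmentError):
        tukey_box_stats([])


def test_paired_t_identical_gives_p_one_and_shift_errors():
    assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
    with pytest.raises(AssessmentError):
        paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])   # constant shift


def test_paired_t_two_pairs_matches_closed_form():
    # differences {1, 3}: mean 2, sd sqrt(2), t = 2 with 1 degree of freedom
    p = paired_t_test([2.0, 4.0], [1.0, 1.0])
    assert p == pytest.approx(2 * (1 - sps.t.cdf(2.0, df=1)), abs=1e-12)


def test_paired_t_power_under_planted_shift():
    """delta=1, sigma=1, n=100: essentially every replicate is significant."""
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(100):
        a = rng.normal(size=100)
        b = a + 1.0 + rng.normal(scale=1.0, size=100)
        if paired_t_test(b, a) < 1e-3:
            hits += 1
    assert hits >= 99


def test_results_table_round_trip_and_summaries(base_fv, base_scaffold, tmp_path):
    base, numbered = base_scaffold
    rows = []
    rng = np.random.default_rng(3)
    for i in range(12):
        sim = float(rng.uniform(70, 100))
        res = assess_pair(base, base)
        for region in res.region_rmsd:
            res.region_rmsd[region] = float(rng.uniform(0, 3))
        rows.append(results_row(f"T{i}", "top5", res, sim, ["X_LH"]))
    path = tmp_path / "results.tsv"
    write_results_table(rows, path)
    table = read_results_table(path)
    assert len(table) == 12
    stats = similarity_binned_stats(table, metric="FR", threshold=85.0)
    lo = table[table.fw_similarity < 85.0].FR
    assert stats[stats.bin == "<85%"]["mean"].iloc[0] == pytest.approx(lo.mean())
    assert stats[stats.bin == "<85%"]["number"].iloc[0] == len(lo)
    # heat-map aggregation equals a direct groupby oracle
    table["h3_len"] = rng.integers(5, 18, size=len(table))
    hm = length_similarity_heatmap(table, "h3_len", "fw_similarity", "H3")
    cell = table[(table.h3_len == table.h3_len.iloc[0])
                 & (table.fw_similarity >= 85) & (table.fw_similarity < 95)]
    if len(cell):
        col = [c for c in hm.columns if c.left == 85][0]
        assert hm.loc[table.h3_len.iloc[0], col] == pytest.approx(cell.H3.mean())
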