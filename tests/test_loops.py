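"""CDR-refinement tests: template finding, ranking, and grafting contracts."""

import numpy as np
import pytest

from fvbuild import geometry as geom
from fvbuild import synth
from fvbuild.build import build_single_model
from fvbuild.db import TemplateDatabase, ingest_structure
from fvbuild.loops import (LoopError, LoopTemplate, find_loop_templates,
                           graft_and_model_loop, rank_loop_templates,
                           refine_all_cdrs)
from fvbuild.numbering import extract_cdrs


def target_cdrs_of(numbered):
    out = {}
    for role in ("light", "heavy"):
        for c in extract_cdrs(numbered[role]):
            out[c.label] = c
    return out


@pytest.fixture(scope="module")
def framework(base_numbered, self_record):
    return build_single_model(base_numbered, self_record, n_models=1, seed=1)[0]


def test_length_mismatch_gives_no_loop_template_signal(base_numbered, self_db):
    cdrs = target_cdrs_of(base_numbered)
    odd = synth.ScaffoldSpec(cdr_lengths={**synth.BASE_CDR_LENGTHS, "L3": 8})
    _, odd_numbered = synth.make_synthetic_fv(odd)
    odd_l3 = target_cdrs_of(odd_numbered)["L3"]
    assert find_loop_templates(odd_l3, self_db) == []
    assert find_loop_templates(cdrs["L3"], self_db) != []


def test_canonical_filter_restricts_and_falls_back(base_scaffold):
    base, numbered = base_scaffold
    # two templates: one with the target's H2 class (H2:3 via Arg71), one
    # switched to H2:2 by substituting framework position 71
    rec_match = ingest_structure(base).records[0]
    rec_match.template_id = "MATCH_LH"
    other, _ = synth.perturb_structure(
        base, numbered, synth.PerturbationSpec(substitutions=[("heavy", 71, "A")]))
    rec_other = ingest_structure(other).records[0]
    rec_other.template_id = "OTHER_LH"
    assert rec_match.canonical["H2"] == "H2:3"
    assert rec_other.canonical["H2"] == "H2:2"
    db = TemplateDatabase()
    db.add(rec_match)
    db.add(rec_other)
    h2 = target_cdrs_of(numbered)["H2"]
    filtered = find_loop_templates(h2, db, canonical_filter=True,
                                   target_class="H2:3")
    assert [t.template_id for t in filtered] == ["MATCH_LH"]
    unfiltered = find_loop_templates(h2, db, canonical_filter=False)
    assert len(unfiltered) == 2
    # fallback: no template of the target's class -> equals unfiltered result
    db2 = TemplateDatabase()
    db2.add(rec_other)
    fallback = find_loop_templates(h2, db2, canonical_filter=True,
                                   target_class="H2:3")
    assert [t.template_id for t in fallback] == ["OTHER_LH"]
    # canonical filtering never increases the candidate set
    assert len(filtered) <= len(unfiltered)


def make_candidate(tid, loop_score, cross=0.0, res=2.0):
    return LoopTemplate(template_id=tid, cdr_label="L1", loop_sequence="X",
                        canonical_class="none", loop_score=loop_score,
                        cross_loop_score=cross, resolution=res)


def test_single_candidate_ranks_first_regardless_of_score():
    r = rank_loop_templates([make_candidate("A", -99.0)], n_templates=3)
    assert [t.template_id for t in r.templates] == ["A"]


def test_equal_scores_resolve_by_resolution():
    a = make_candidate("A", 9.0, res=2.8)
    b = make_candidate("B", 9.0, res=1.5)
    r = rank_loop_templates([a, b], n_templates=2)
    assert [t.template_id for t in r.templates] == ["B", "A"]


def test_planted_score_set_matches_brute_force_sort():
    cands = [make_candidate("A", 12.0, res=2.2),
             make_candidate("B", 9.0, res=1.9),
             make_candidate("C", 9.0, res=2.0),
             make_candidate("D", 9.0, res=2.5)]
    r = rank_loop_templates(cands, n_templates=4)
    oracle = sorted(cands, key=lambda c: (-c.loop_score, -c.cross_loop_score,
                                          c.resolution, c.template_id))
    assert [t.template_id for t in r.templates] == [t.template_id for t in oracle]


def test_ranking_against_exhaustive_sort_on_random_sets():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(1, 8))
        cands = [make_candidate(f"T{i}", float(rng.integers(-5, 15)),
                                cross=float(rng.integers(0, 10)),
                                res=float(rng.choice([1.5, 2.0, 2.5, None][:3])))
                 for i in range(n)]
        for mode in ("tiered", "blended"):
            got = rank_loop_templates(cands, n_templates=n, ranking_mode=mode)
            oracle = sorted(cands, key=lambda c: c.sort_key(mode))
            assert [t.template_id for t in got.templates] == \
                [t.template_id for t in oracle]


def test_cross_loop_bonus_can_override_only_in_blended_mode():
    x = make_candidate("X", 10.0, cross=0.0)
    y = make_candidate("Y", 9.0, cross=5.0)
    tiered = rank_loop_templates([x, y], ranking_mode="tiered")
    blended = rank_loop_templates([x, y], ranking_mode="blended")
    assert tiered.templates[0].template_id == "X"
    assert blended.templates[0].template_id == "Y"


def test_self_graft_recovers_native_loop_and_keeps_framework_bitwise(
        framework, base_fv, base_numbered, self_db):
    before = framework.structure.all_coords()
    model, report = refine_all_cdrs(framework, self_db, n_loop_models=2, seed=5)
    assert report.flags == {}
    for label in ("L1", "L2", "L3", "H1", "H2", "H3"):
        role = "heavy" if label.startswith("H") else "light"
        keys = [r.key for r in base_numbered[role].residues
                if r.region == f"CDR{label[-1]}"]
        P = model.structure.chain(role).coords(("C", "O"), keys=keys)
        Q = base_fv.chain(role).coords(("C", "O"), keys=keys)
        assert geom.rmsd(P, Q) <= 0.1, label
    # framework atoms bitwise identical
    loop_keys = set()
    for role in ("light", "heavy"):
        for r in base_numbered[role].residues:
            if not r.region.startswith("FR"):
                loop_keys.add((role, r.key))
    from fvbuild.build import AtomTable
    table = AtomTable.from_structure(framework.structure)
    is_loop = np.array([(r, k) in loop_keys for (r, k, a) in table.keys])
    after = model.structure.all_coords()
    assert np.array_equal(before[~is_loop], after[~is_loop])


def test_refining_a_subset_leaves_other_loops_untouched(framework, self_db):
    model, report = refine_all_cdrs(framework, self_db, loops=("H3",),
                                    n_loop_models=1, seed=2)
    assert set(report.provenance) == {"H3"}
    numbered = framework.target_numbered
    for label in ("L1", "L2", "L3", "H1", "H2"):
        role = "heavy" if label.startswith("H") else "light"
        keys = [r.key for r in numbered[role].residues
                if r.region == f"CDR{label[-1]}"]
        P = model.structure.chain(role).coords(("N", "CA", "C", "O"), keys=keys)
        Q = framework.structure.chain(role).coords(("N", "CA", "C", "O"), keys=keys)
        assert np.array_equal(P, Q), label


def test_missing_loop_template_flags_loop_and_keeps_framework_coords(
        self_record):
    # target with an H3 length absent from the database
    spec = synth.ScaffoldSpec(name="ODD",
                              cdr_lengths={**synth.BASE_CDR_LENGTHS, "H3": 10})
    _, numbered = synth.make_synthetic_fv(spec)
    db = TemplateDatabase()
    db.add(self_record)
    fw = build_single_model(numbered, self_record, n_models=1, seed=0)[0]
    model, report = refine_all_cdrs(fw, db, n_loop_models=1, seed=0)
    assert report.flags == {"H3": "no loop template"}
    assert set(report.provenance) == {"L1", "L2", "L3", "H1", "H2"}
    role_keys = [r.key for r in numbered["heavy"].residues if r.region == "CDR3"]
    P = model.structure.heavy.coords(("N", "CA", "C"), keys=role_keys)
    Q = fw.structure.heavy.coords(("N", "CA", "C"), keys=role_keys)
    assert np.array_equal(P, Q)


def test_two_template_conformer_basin_beats_single_template(base_scaffold):
    """With two templates in loop conformer A and one in conformer B (equal
    sequences, hence equal scores), the grafted loop lands in A's basin — the
    restraint energy at A is lower than at B."""
    base, numbered = base_scaffold
    recs = []
    for tid, conf in (("A1_LH", 1), ("A2_LH", 1), ("B1_LH", 2)):
        fv, _ = synth.make_synthetic_fv(
            synth.ScaffoldSpec(name=tid.split("_")[0], conformers={"L1": conf}))
        rec = ingest_structure(fv).records[0]
        rec.template_id = tid
        rec.resolution = 2.0
        recs.append(rec)
    db = TemplateDatabase()
    for r in recs:
        db.add(r)
    self_rec = ingest_structure(base).records[0]
    fw = build_single_model(numbered, self_rec, n_models=1, seed=0)[0]
    cdrs = target_cdrs_of(numbered)
    cands = find_loop_templates(cdrs["L1"], db, canonical_filter=False)
    ranking = rank_loop_templates(cands, n_templates=3)
    model = graft_and_model_loop(fw, cdrs["L1"], ranking, n_loop_models=2, seed=3)
    keys = cdrs["L1"].positions
    got = model.structure.light.coords(("N", "CA", "C"), keys=keys)
    conf_a = recs[0].structure.light.coords(("N", "CA", "C"), keys=keys)
    conf_b = recs[2].structure.light.coords(("N", "CA", "C"), keys=keys)
    assert geom.rmsd(got, conf_a) < geom.rmsd(got, conf_b)


def test_incompatible_stem_anchors_warn_but_still_graft(framework, base_fv,
                                                        base_numbered):
    cdrs = target_cdrs_of(base_numbered)
    l1 = cdrs["L1"]
    rec = ingest_structure(base_fv).records[0]
    rec.template_id = "WRECK_LH"
    # wreck the stems of the ingested record so anchor superposition is poor
    idx = rec.structure.light.index()
    order = [r.key for r in base_numbered["light"].residues]
    i0 = order.index(l1.positions[0])
    for off, sign in ((-1, 1), (-2, -1), (-3, 1)):
        res = idx[order[i0 + off]]
        for a in res.atoms:
            res.atoms[a] = res.atoms[a] + sign * np.array([0.0, 0.0, 3.0])
    db = TemplateDatabase()
    db.add(rec)
    cands = find_loop_templates(l1, db, canonical_filter=False)
    ranking = rank_loop_templates(cands, n_templates=1)
    model = graft_and_model_loop(framework, l1, ranking, n_loop_models=1, seed=0)
    assert any("incompatible anchors" in w for w in model.warnings)
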