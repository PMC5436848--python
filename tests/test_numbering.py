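"""Numbering-engine tests: position assignment, insertion codes, region
partitions and scheme differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fvbuild.numbering import (NotAntibodyError, NumberingError,
                               REFERENCE_PROFILES, extract_cdrs,
                               extract_cdrs_as, framework_mask, get_scheme,
                               number_chain, numbering_report)

KAPPA = REFERENCE_PROFILES["kappa"]
HEAVY = REFERENCE_PROFILES["heavy"]


def test_canonical_length_kappa_chain_numbers_1_to_107_without_insertions():
    chain = number_chain(KAPPA, "light", "chothia")
    assert chain.chain_type == "kappa"
    assert [r.scheme_position for r in chain.residues] == list(range(1, 108))
    assert all(r.insertion_code == "" for r in chain.residues)


def test_insertion_inside_l1_adds_one_insertion_code_at_anchor_only():
    longer = KAPPA[:28] + "G" + KAPPA[28:]
    base = number_chain(KAPPA, "light", "chothia")
    chain = number_chain(longer, "light", "chothia")
    fr = lambda c: [(r.scheme_position, r.insertion_code)
                    for r in c.residues if r.region.startswith("FR")]
    assert fr(base) == fr(chain)
    extra = [r for r in chain.residues if r.insertion_code]
    assert len(extra) == 1
    anchor = get_scheme("chothia", "kappa").region_of("CDR1").anchor
    assert extra[0].scheme_position == anchor


def test_long_h3_uses_insertion_codes_at_h3_anchor():
    # 8 extra residues inside H3 -> loop length 16 with codes at the anchor
    seq = HEAVY[:98] + "GTTGWGWL" + HEAVY[98:]
    chain = number_chain(seq, "heavy", "chothia")
    loop = [r for r in chain.residues if r.region == "CDR3"]
    assert len(loop) == 16
    anchor = get_scheme("chothia", "heavy").region_of("CDR3").anchor
    coded = [r for r in loop if r.insertion_code]
    assert len(coded) == 8
    assert all(r.scheme_position == anchor for r in coded)


def test_numbering_is_idempotent():
    for seq, role in ((KAPPA, "light"), (HEAVY, "heavy")):
        a = number_chain(seq, role, "chothia")
        b = number_chain(a.sequence, role, "chothia")
        assert [r.key for r in a.residues] == [r.key for r in b.residues]
        assert [r.region for r in a.residues] == [r.region for r in b.residues]


@pytest.mark.parametrize("scheme", ["chothia", "imgt", "kabat", "honegger"])
@pytest.mark.parametrize("seq,role", [(KAPPA, "light"), (HEAVY, "heavy"),
                                      (REFERENCE_PROFILES["lambda"], "light")])
def test_regions_partition_the_chain_in_order(scheme, seq, role):
    chain = number_chain(seq, role, scheme)
    regions = [r.region for r in chain.residues]
    order = ["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"]
    seen = [regions[0]]
    for r in regions[1:]:
        if r != seen[-1]:
            seen.append(r)
    assert seen == order
    # partition identity: concatenating regions reproduces the sequence
    joined = "".join(
        "".join(res.amino_acid for res in chain.residues if res.region == reg)
        for reg in order)
    assert joined == seq


def test_cdr_extraction_returns_exact_substrings_and_stems():
    chain = number_chain(KAPPA, "light", "chothia")
    cdrs = {c.label: c for c in extract_cdrs(chain, stem_width=3)}
    assert cdrs["L1"].loop_sequence == KAPPA[23:34]
    assert cdrs["L2"].loop_sequence == KAPPA[49:52]
    assert cdrs["L2"].loop_length == 3
    assert cdrs["L2"].stem_before == KAPPA[46:49]
    assert cdrs["L2"].stem_after == KAPPA[52:55]
    assert not any(c.incomplete for c in cdrs.values())


def test_scheme_loop_lengths_match_the_documented_conventions():
    # Chothia L2 = 3, Kabat L2 = 7, Honegger L2 = 12; Chothia H1 = 7, H2 = 4
    light = {s: {c.label: c.loop_length
                 for c in extract_cdrs(number_chain(KAPPA, "light", s))}
             for s in ("chothia", "kabat", "honegger")}
    assert light["chothia"]["L2"] == 3
    assert light["kabat"]["L2"] == 7
    assert light["honegger"]["L2"] == 12
    heavy = {c.label: c.loop_length
             for c in extract_cdrs(number_chain(HEAVY, "heavy", "chothia"))}
    assert heavy["H1"] == 7
    assert heavy["H2"] == 4


def test_framework_mask_complements_cdrs():
    chain = number_chain(KAPPA, "light", "chothia")
    mask = framework_mask(chain)
    cdr_len = sum(c.loop_length for c in extract_cdrs(chain))
    assert mask.sum() == len(chain.residues) - cdr_len
    in_cdr = np.array([not r.region.startswith("FR") for r in chain.residues])
    assert not np.any(mask & in_cdr)


def test_chothia_and_kabat_masks_differ_at_h1_boundary():
    a = framework_mask(number_chain(HEAVY, "heavy", "chothia"))
    b = framework_mask(number_chain(HEAVY, "heavy", "kabat"))
    diff = np.where(a != b)[0]
    assert len(diff) > 0
    # the Chothia H1 region starts earlier than Kabat's
    chothia_cdr1 = [i for i, r in enumerate(number_chain(HEAVY, "heavy", "chothia").residues)
                    if r.region == "CDR1"]
    assert set(diff) & set(chothia_cdr1)


def test_extract_cdrs_as_reports_positions_in_native_numbering():
    chain = number_chain(KAPPA, "light", "chothia")
    kabat_view = {c.label: c for c in extract_cdrs_as(chain, "kabat")}
    own = chain.position_map()
    assert all(k in own for k in kabat_view["L2"].positions)
    assert kabat_view["L2"].loop_length == 7
    chothia_view = {c.label: c for c in extract_cdrs_as(chain, "chothia")}
    assert chothia_view["L2"].loop_length == 3


def test_input_errors():
    with pytest.raises(NumberingError):
        number_chain(KAPPA.replace("Q", "X", 1), "light", "chothia")
    with pytest.raises(NumberingError):
        number_chain("ACDEFGHIKL", "light", "chothia")   # far too short
    with pytest.raises(NotAntibodyError):
        number_chain("AGAGAGAGAG" * 10, "light", "chothia")


def test_numbering_report_lists_every_residue():
    chain = number_chain(KAPPA, "light", "chothia")
    text = numbering_report(chain)
    assert len(text.strip().splitlines()) == len(chain.residues) + 1


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_point_mutated_profiles_keep_partition_and_idempotence(data):
    """Random single/double framework mutations must not disturb numbering."""
    seq = list(KAPPA)
    n_mut = data.draw(st.integers(1, 3))
    for _ in range(n_mut):
        pos = data.draw(st.integers(0, len(seq) - 1))
        seq[pos] = data.draw(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    mutated = "".join(seq)
    chain = number_chain(mutated, "light", "chothia", chain_type="kappa")
    assert "".join(r.amino_acid for r in chain.residues) == mutated
    again = number_chain(mutated, "light", "chothia", chain_type="kappa")
    assert [r.key for r in chain.residues] == [r.key for r in again.residues]
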