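"""Shared fixtures: one default synthetic Fv scaffold and small databases
derived from it.  Session-scoped because fixture construction (numbering +
internal-coordinate building) is reused by many tests; tests that mutate
structures must copy them first.
"""

import numpy as np
import pytest

from fvbuild import synth
from fvbuild.db import TemplateDatabase, ingest_structure


@pytest.fixture(scope="session")
def base_scaffold():
    fv, numbered = synth.make_synthetic_fv(synth.ScaffoldSpec(name="BASE"))
    return fv, numbered


@pytest.fixture(scope="session")
def base_fv(base_scaffold):
    return base_scaffold[0]


@pytest.fixture(scope="session")
def base_numbered(base_scaffold):
    return base_scaffold[1]


@pytest.fixture(scope="session")
def self_record(base_fv):
    """The base scaffold ingested as its own template."""
    rec = ingest_structure(base_fv).records[0]
    rec.template_id = "BASE_LH"
    rec.resolution = 1.8
    rec.organism = "human"
    rec.structure.meta["id"] = "BASE_LH"
    return rec


@pytest.fixture(scope="session")
def self_db(self_record):
    db = TemplateDatabase()
    db.add(self_record)
    return db


def framework_substitutions(n_light: int, n_heavy: int, start: int = 5, step: int = 2):
    """Dissimilar (BLOSUM62-negative vs the reference) framework substitutions
    at safe positions (avoiding canonical-constraint sites 2/48/64/71), so that
    planted identity order and similarity order coincide."""
    from fvbuild.numbering import REFERENCE_PROFILES
    cdr = {"light": set(range(24, 35)) | set(range(50, 53)) | set(range(89, 98)),
           "heavy": set(range(26, 33)) | set(range(52, 56)) | set(range(95, 103))}
    subs = []
    for role, n_sub, ref in (("light", n_light, REFERENCE_PROFILES["kappa"]),
                             ("heavy", n_heavy, REFERENCE_PROFILES["heavy"])):
        avoid = {2, 48, 64, 71} | cdr[role]
        pos, count = start, 0
        while count < n_sub:
            if pos not in avoid:
                old = ref[pos - 1]
                new = "W" if old not in "WFY" else "D"
                subs.append((role, pos, new))
                count += 1
            pos += step
    return subs


@pytest.fixture(scope="session")
def graded_db(base_scaffold):
    """Six perturbed copies with planted, strictly ordered identities."""
    _, numbered = base_scaffold
    perts = []
    for k, n_sub in enumerate((0, 2, 4, 6, 8, 10)):
        spec = synth.PerturbationSpec(
            substitutions=framework_substitutions(n_sub, n_sub, start=5 + k),
            seed=100 + k)
        perts.append((f"T{k}_LH", spec, "human" if k % 2 == 0 else "mouse",
                      1.5 + 0.3 * k))
    db, truth = synth.make_synthetic_database(
        synth.ScaffoldSpec(name="BASE"), perts)
    return db, truth
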