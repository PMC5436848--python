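"""Synthetic Fv fixtures with planted ground truth.

Generates idealized two-domain Fv-like structures (backbone + CB built from
internal coordinates with standard bond lengths and angles), perturbed copies
with known substitution counts, coordinate noise, loop-conformer swaps and
inter-domain rotations, and whole template databases whose ranking-relevant
properties (pairwise identity, canonical classes, resolutions, organisms) are
known by construction.

The fixtures validate contracts, not biology: framework sequences are the
numbering reference profiles, CDR conformers come from a small internal
library of torsion/deformation sets, and the planted ground truth is what the
production operations are tested against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geom
from .db import (TemplateDatabase, ingest_structure, load_canonical_definitions)
from .numbering import (NumberedChain, get_scheme, number_chain,
                        REFERENCE_PROFILES)
from .structure import ChainStructure, FvStructure, Residue, ALL_ATOMS

CDR_LABELS = ("L1", "L2", "L3", "H1", "H2", "H3")

# Base (reference-profile) loop lengths under the Chothia tables.
BASE_CDR_LENGTHS = {"L1": 11, "L2": 3, "L3": 9, "H1": 7, "H2": 4, "H3": 8}

# Loop sequences keyed by (label, length[, class tag]); generic pools used when
# a key is absent.  Sequences for planted canonical classes satisfy the loop-
# position constraints of the shipped canonical table (framework-position
# constraints are satisfied by the reference profiles themselves).
_LOOP_SEQS = {
    ("L1", 11): "RASQSISSYLN",     # kL1:1 for kappa frameworks (29:I, 33:L)
    ("L1", 7): "SQSVSSA",
    ("L1", 9): "SESVDSYGN",
    ("L1", 12): "SQSLLHSNGYNY",
    ("L2", 3): "AAS",
    ("L2", 7): "AASSLQS",
    ("L3", 9): "QQSYSTPLT",        # kL3:1 (90:Q, 95:P)
    ("L3", 8): "QQYNSYST",
    ("H1", 7): "GFTFSSY",          # H1:1 (26:G)
    ("H1", 8): "GFSFTNNY",
    ("H1", 9): "GGSISSGDY",
    ("H2", 4): "SGSG",
    ("H2", 3): "SGG",
    ("H2", 6): "SNGGSY",
    ("H3", 8): "ARDRGFDY",
    ("H3", 10): "ARDRGGYFDY",
    ("H3", 16): "GTTGWGWLGKPIGAFA",
}
_POOL = "SGNYRATDVQ"


def loop_sequence(label: str, length: int) -> str:
    seq = _LOOP_SEQS.get((label, length))
    if seq is None:
        seq = "".join(_POOL[(i * 3 + length) % len(_POOL)] for i in range(length))
    return seq


@dataclass
class ScaffoldSpec:
    """Recipe for one synthetic Fv: light-chain isotype, per-loop lengths and
    conformer ids, and the run seed."""
    light_type: str = "kappa"                       # kappa | lambda
    cdr_lengths: dict[str, int] = field(default_factory=lambda: dict(BASE_CDR_LENGTHS))
    conformers: dict[str, int] = field(default_factory=dict)   # label -> conformer id
    loop_sequences: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    name: str = "SYN1"

    def __post_init__(self):
        if self.light_type not in ("kappa", "lambda"):
            raise ValueError("light_type must be kappa or lambda")
        for lab, n in self.cdr_lengths.items():
            if lab not in CDR_LABELS or n < 1:
                raise ValueError(f"bad CDR length spec {lab}={n}")


@dataclass
class PerturbationSpec:
    """Planted edits for a perturbed copy: framework coordinate noise, loop
    conformer swaps, an inter-domain rotation, and point substitutions."""
    framework_noise_sigma: float = 0.0              # Angstrom
    loop_conformers: dict[str, int] = field(default_factory=dict)
    domain_rotation: float = 0.0                    # degrees, applied to VH
    substitutions: list[tuple[str, int, str]] = field(default_factory=list)
    # (chain_role, chothia position, new residue)
    seed: int = 0

    def __post_init__(self):
        if self.framework_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _stable_rng(*key) -> np.random.Generator:
    """Deterministic RNG from a string key (stable across processes)."""
    token = "|".join(str(k) for k in key)
    return np.random.default_rng(zlib.crc32(token.encode()) & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# torsion scaffolds

_STRAND = (-120.0, 135.0)
_TURN = [(-60.0, -30.0), (-90.0, 0.0), (-70.0, -20.0), (55.0, 45.0)]


def _framework_torsions(n: int) -> list[tuple[float, float, float]]:
    """Meander sheet: strands of 8 alternating with 4-residue turns."""
    out = []
    period = 12
    for i in range(n):
        k = i % period
        if k < 8:
            phi, psi = _STRAND
        else:
            phi, psi = _TURN[k - 8]
        out.append((phi, psi, 180.0))
    return out


def _loop_torsions(label: str, length: int) -> list[tuple[float, float, float]]:
    rng = _stable_rng("loop-torsions", label, length)
    out = []
    for _ in range(length):
        phi = float(rng.uniform(-150, -50))
        psi = float(rng.uniform(-60, 160))
        out.append((phi, psi, 180.0))
    return out


def _loop_bump(label: str, length: int, conformer: int,
               n_atoms: int) -> np.ndarray:
    """Endpoint-anchored smooth displacement field distinguishing conformers.

    Conformer 0 is the torsion-built base; conformer k displaces loop atoms by
    a half-sine bump (zero at both stems) along a conformer-specific direction.
    """
    if conformer == 0:
        return np.zeros((n_atoms, 3))
    rng = _stable_rng("loop-conformer", label, length, conformer)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    amplitude = 1.2 + 0.3 * ((conformer - 1) % 3)
    s = np.sin(np.pi * (np.arange(n_atoms) + 1) / (n_atoms + 1))
    return amplitude * s[:, None] * direction[None, :]


# ---------------------------------------------------------------------------
# structure assembly

# Rigid placement of the heavy domain relative to the light domain.
_VH_ROTATION = geom.rotation_about_axis(np.array([0.0, 1.0, 0.0]), 50.0)
_VH_TRANSLATION = np.array([52.0, 8.0, 6.0])


def _chain_sequence(spec: ScaffoldSpec, role: str) -> tuple[str, str]:
    """(sequence, chain_type) with consensus framework + spec'd loops."""
    chain_type = "heavy" if role == "heavy" else spec.light_type
    ref = REFERENCE_PROFILES[chain_type]
    scheme = get_scheme("chothia", chain_type)
    prefix = "H" if role == "heavy" else "L"
    parts = []
    for region in scheme.regions:
        seg = ref[region.start - 1:region.end]
        if region.region.startswith("CDR"):
            lab = f"{prefix}{region.region[-1]}"
            n = spec.cdr_lengths.get(lab, len(seg))
            seg = spec.loop_sequences.get(lab, loop_sequence(lab, n))
            if len(seg) != n:
                raise ValueError(f"loop sequence for {lab} must have length {n}")
        parts.append(seg)
    return "".join(parts), chain_type


def _build_chain(spec: ScaffoldSpec, role: str) -> tuple[ChainStructure, NumberedChain]:
    seq, chain_type = _chain_sequence(spec, role)
    nc = number_chain(seq, "light" if role != "heavy" else "heavy", "chothia",
                      chain_type=chain_type)
    prefix = "H" if role == "heavy" else "L"
    # planted loop lengths must survive numbering (a loop sequence that
    # aliases into the framework would silently change the ground truth)
    for region_name, tag in (("CDR1", "1"), ("CDR2", "2"), ("CDR3", "3")):
        lab = f"{prefix}{tag}"
        want = spec.cdr_lengths.get(lab, BASE_CDR_LENGTHS[lab])
        got = sum(1 for r in nc.residues if r.region == region_name)
        if got != want:
            raise ValueError(
                f"planted {lab} length {want} not preserved by numbering "
                f"(got {got}); choose a different loop sequence")
    torsions: list[tuple[float, float, float]] = []
    fw_count = 0
    i = 0
    while i < len(nc.residues):
        r = nc.residues[i]
        if r.region.startswith("FR"):
            torsions.append(_framework_torsions(len(seq))[fw_count])
            fw_count += 1
            i += 1
        else:
            lab = f"{prefix}{r.region[-1]}"
            n = sum(1 for x in nc.residues if x.region == r.region)
            torsions.extend(_loop_torsions(lab, n))
            i += n
    gly = [aa == "G" for aa in seq]
    atoms = geom.build_backbone(torsions, gly)
    chain = ChainStructure(role, prefix, [
        Residue(nr.scheme_position, nr.insertion_code, nr.amino_acid, at)
        for nr, at in zip(nc.residues, atoms)])
    # apply conformer bumps to loops
    for lab, conf in spec.conformers.items():
        if not lab.startswith(prefix):
            continue
        _apply_conformer(chain, nc, lab, 0, conf)
    return chain, nc


def _loop_atom_slots(chain: ChainStructure, nc: NumberedChain, label: str):
    region = f"CDR{label[-1]}"
    keys = [r.key for r in nc.residues if r.region == region]
    idx = chain.index()
    slots = []
    for k in keys:
        res = idx[k]
        for a in ALL_ATOMS:
            if a in res.atoms:
                slots.append((res, a))
    return slots


def _apply_conformer(chain: ChainStructure, nc: NumberedChain, label: str,
                     old: int, new: int) -> None:
    slots = _loop_atom_slots(chain, nc, label)
    n = len(slots)
    length = sum(1 for r in nc.residues if r.region == f"CDR{label[-1]}")
    delta = (_loop_bump(label, length, new, n) - _loop_bump(label, length, old, n))
    for (res, a), d in zip(slots, delta):
        res.atoms[a] = res.atoms[a] + d


def make_synthetic_fv(spec: ScaffoldSpec) -> tuple[FvStructure, dict[str, NumberedChain]]:
    """Build an idealized Fv structure and its numbered chains.

    Deterministic for a fixed spec; two calls with the same seed produce
    bit-identical coordinates.
    """
    light, nc_l = _build_chain(spec, "light")
    heavy, nc_h = _build_chain(spec, "heavy")
    for r in heavy.residues:
        for a in r.atoms:
            r.atoms[a] = _VH_ROTATION @ r.atoms[a] + _VH_TRANSLATION
    fv = FvStructure(light, heavy, {
        "id": spec.name,
        "conformers": {lab: spec.conformers.get(lab, 0) for lab in CDR_LABELS},
        "spec_seed": spec.seed,
    })
    return fv, {"light": nc_l, "heavy": nc_h}


def perturb_structure(fv: FvStructure, numbered: dict[str, NumberedChain],
                      spec: PerturbationSpec) -> tuple[FvStructure, dict[str, NumberedChain]]:
    """Apply planted substitutions, Gaussian noise, loop conformer swaps and an
    inter-domain rotation; the applied ground truth is recorded in metadata."""
    out = fv.copy()
    numbered = dict(numbered)
    # substitutions (sequence-level; CB kept/dropped for Gly by ideal geometry)
    for role, pos, new_aa in spec.substitutions:
        chain = out.chain(role)
        res = chain.index().get((pos, ""))
        if res is None:
            raise ValueError(f"substitution position {pos} not present in {role} chain")
        res.aa = new_aa
        if new_aa == "G":
            res.atoms.pop("CB", None)
        elif "CB" not in res.atoms:
            res.atoms["CB"] = geom.ideal_cb(res.atoms["N"], res.atoms["CA"], res.atoms["C"])
    if spec.substitutions:
        for role in ("light", "heavy"):
            seq = out.chain(role).sequence()
            numbered[role] = number_chain(
                seq, "light" if role == "light" else "heavy", "chothia",
                chain_type=numbered[role].chain_type)
    # loop conformer swaps
    conformers = dict(out.meta.get("conformers", {}))
    for lab, conf in spec.loop_conformers.items():
        role = "heavy" if lab.startswith("H") else "light"
        _apply_conformer(out.chain(role), numbered[role], lab,
                         conformers.get(lab, 0), conf)
        conformers[lab] = conf
    # coordinate noise: chain-smoothed (window 9) so covalent geometry stays
    # intact, rescaled so the per-atom per-coordinate std equals sigma
    if spec.framework_noise_sigma > 0:
        rng = _stable_rng("noise", spec.seed)
        window = 9
        for chain in out.chains():
            n = len(chain.residues)
            raw = rng.normal(size=(n + window - 1, 3))
            kernel = np.ones(window) / window
            smooth = np.stack([np.convolve(raw[:, k], kernel, mode="valid")
                               for k in range(3)], axis=1)
            smooth *= spec.framework_noise_sigma * np.sqrt(window)
            for r, d in zip(chain.residues, smooth):
                for a in r.atoms:
                    r.atoms[a] = r.atoms[a] + d
    # inter-domain rotation of VH about an axis through the interface
    if spec.domain_rotation != 0.0:
        rng = _stable_rng("domain-axis", spec.seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = geom.rotation_about_axis(axis, spec.domain_rotation)
        center = out.heavy.coords().mean(axis=0)
        for r in out.heavy.residues:
            for a in r.atoms:
                r.atoms[a] = R @ (r.atoms[a] - center) + center
    out.meta["conformers"] = conformers
    out.meta["perturbation"] = {
        "noise_sigma": spec.framework_noise_sigma,
        "domain_rotation": spec.domain_rotation,
        "n_substitutions": len(spec.substitutions),
        "seed": spec.seed,
    }
    return out, numbered


# ---------------------------------------------------------------------------
# synthetic databases

def make_synthetic_database(
        base_spec: ScaffoldSpec,
        perturbations: list[tuple[str, PerturbationSpec, str, float]],
        definitions=None) -> tuple[TemplateDatabase, pd.DataFrame]:
    """Database of perturbed copies of a base scaffold with known ground truth.

    ``perturbations`` is a list of (template_id, PerturbationSpec, organism,
    resolution).  Returns the database plus a ground-truth table with one row
    per entry (substitution count, identity to base over all positions, noise
    sigma, rotation, organism, resolution).
    """
    if definitions is None:
        definitions = load_canonical_definitions()
    base, numbered = make_synthetic_fv(base_spec)
    n_total = sum(len(c.residues) for c in base.chains())
    db = TemplateDatabase()
    rows = []
    for tid, pspec, organism, resolution in perturbations:
        fv, _ = perturb_structure(base, numbered, pspec)
        fv.meta.update({"id": tid, "organism": organism, "resolution": resolution})
        result = ingest_structure(fv, organism=organism, resolution=resolution,
                                  definitions=definitions, accession=tid.split("_")[0])
        if not result.records:
            raise RuntimeError(f"fixture {tid} rejected: {result.rejected}")
        rec = result.records[0]
        rec.template_id = tid
        rec.structure.meta["id"] = tid
        db.add(rec)
        n_sub = len(pspec.substitutions)
        rows.append({
            "template_id": tid,
            "n_substitutions": n_sub,
            "identity_pct": 100.0 * (n_total - n_sub) / n_total,
            "noise_sigma": pspec.framework_noise_sigma,
            "domain_rotation": pspec.domain_rotation,
            "organism": organism,
            "resolution": resolution,
        })
    return db, pd.DataFrame(rows)


def combine_databases(*dbts: tuple[TemplateDatabase, pd.DataFrame]
                      ) -> tuple[TemplateDatabase, pd.DataFrame]:
    """Merge synthetic databases built from different base scaffolds."""
    db = TemplateDatabase()
    frames = []
    for d, truth in dbts:
        for rec in d:
            db.add(rec)
        frames.append(truth)
    return db, pd.concat(frames, ignore_index=True)


def manifest_text(truth: pd.DataFrame) -> str:
    """Fixture manifest (spec + ground truth) as delimited text."""
    return truth.to_csv(sep="\t", index=False)
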