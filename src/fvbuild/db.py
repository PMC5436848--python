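"""Antibody template database: ingest Fv structures, assign canonical classes,
prune redundancy, and serve indexed queries for framework and loop searches.

A database is serialized as a directory of PDB coordinate files plus one
delimited metadata table and a manifest, so it is diffable and updatable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .numbering import (CdrRegion, NumberedChain, extract_cdrs, number_chain,
                        NumberingError)
from .structure import (ChainStructure, FvStructure, Residue, read_pdb_chains,
                        write_pdb)

DB_SCHEMA_VERSION = "1"


class CanonicalConfigError(ValueError):
    """Overlapping canonical definitions: more than one class matches a loop."""


class IngestError(ValueError):
    pass


@dataclass(frozen=True)
class CanonicalDefinition:
    class_label: str       # e.g. "kL2:1"
    chain_type: str        # kappa | lambda | heavy
    cdr_label: str         # L1..L3 / H1..H3
    loop_length: int
    # (chothia position, allowed one-letter residues); positions may be in the
    # loop or the framework
    position_constraints: tuple[tuple[int, str], ...]

    def __post_init__(self):
        if self.loop_length < 1:
            raise ValueError("loop_length must be >= 1")


def load_canonical_definitions(path: str | Path | None = None) -> list[CanonicalDefinition]:
    """Load canonical-class definitions from a delimited file (shipped default
    table when no path is given)."""
    if path is None:
        text = resources.files("fvbuild.data").joinpath("canonical_classes.csv").read_text()
    else:
        text = Path(path).read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    out = []
    for rec in csv.DictReader(rows):
        constraints = []
        if rec["constraints"]:
            for item in rec["constraints"].split(";"):
                pos, allowed = item.split(":")
                constraints.append((int(pos), allowed))
        out.append(CanonicalDefinition(
            class_label=rec["class_label"],
            chain_type=rec["chain_type"],
            cdr_label=rec["cdr_label"],
            loop_length=int(rec["loop_length"]),
            position_constraints=tuple(constraints),
        ))
    return out


def assign_canonical_class(region: CdrRegion, chain: NumberedChain,
                           definitions: list[CanonicalDefinition]) -> str:
    """Return the unique canonical class whose length and position constraints
    are all satisfied, or "none"."""
    matches = []
    for d in definitions:
        if d.cdr_label != region.label or d.chain_type != chain.chain_type:
            continue
        if d.loop_length != region.loop_length:
            continue
        ok = True
        for pos, allowed in d.position_constraints:
            res = chain.residue_at(pos)
            if res is None or res.amino_acid not in allowed:
                ok = False
                break
        if ok:
            matches.append(d.class_label)
    if len(matches) > 1:
        raise CanonicalConfigError(
            f"canonical definitions overlap for {region.label}: {matches}")
    return matches[0] if matches else "none"


@dataclass
class TemplateRecord:
    template_id: str
    structure: FvStructure                    # residue ids = Chothia positions
    numbered: dict[str, NumberedChain]        # role -> NumberedChain
    cdrs: dict[str, CdrRegion]                # L1..H3 -> CdrRegion
    canonical: dict[str, str]                 # L1..H3 -> class label or "none"
    organism: str = "unknown"
    resolution: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    @property
    def light_isotype(self) -> str:
        return self.numbered["light"].chain_type

    def fv_sequence(self) -> str:
        return self.numbered["light"].sequence + self.numbered["heavy"].sequence

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.structure.chains())


# ---------------------------------------------------------------------------
# ingest

_CHAIN_BREAK_CN = 3.2  # Angstrom; larger C->N step means missing residues


def _completeness_check(residues: list[Residue]) -> tuple[list[str], str | None]:
    """Return (flags, fatal_reason).  Missing backbone atoms at the termini are
    flagged; missing backbone or chain breaks inside the domain are fatal."""
    flags = []
    n = len(residues)
    for i, r in enumerate(residues):
        if not r.has_backbone():
            if i < 3 or i >= n - 3:
                flags.append(f"incomplete terminal residue {r.position}{r.icode}")
            else:
                return flags, f"missing residues: backbone incomplete at {r.position}{r.icode}"
    for a, b in zip(residues, residues[1:]):
        if "C" in a.atoms and "N" in b.atoms:
            if np.linalg.norm(b.atoms["N"] - a.atoms["C"]) > _CHAIN_BREAK_CN:
                return flags, (f"missing residues: chain break between "
                               f"{a.position}{a.icode} and {b.position}{b.icode}")
    return flags, None


def _renumber_to_chothia(residues: list[Residue], nc: NumberedChain,
                         role: str, chain_id: str) -> ChainStructure:
    out = []
    for res, num in zip(residues, nc.residues):
        out.append(Residue(num.scheme_position, num.insertion_code, res.aa,
                           {k: v.copy() for k, v in res.atoms.items()}))
    return ChainStructure(role, chain_id, out)


@dataclass
class IngestResult:
    records: list[TemplateRecord]
    rejected: list[tuple[str, str]]           # (chain pair, reason)


def ingest_structure(source, chain_assignments: list[tuple[str, str]] | None = None,
                     organism: str = "unknown", resolution: float | None = None,
                     definitions: list[CanonicalDefinition] | None = None,
                     accession: str | None = None) -> IngestResult:
    """Build TemplateRecords from a PDB file (or an FvStructure).

    Chains are classified as heavy/light by profile alignment and paired in
    file order unless explicit (light_id, heavy_id) assignments are given.
    Structures with missing residues inside either variable domain are
    rejected with a reason.
    """
    if definitions is None:
        definitions = load_canonical_definitions()
    if isinstance(source, FvStructure):
        chains = {c.chain_id: c.residues for c in source.chains()}
        accession = accession or source.meta.get("id", "FV")
        organism = source.meta.get("organism", organism)
        resolution = source.meta.get("resolution", resolution)
    else:
        chains = read_pdb_chains(source)
        accession = accession or Path(str(source)).stem.upper()
    if not chains:
        raise IngestError(f"no protein chains parsed from {source}")

    classified: list[tuple[str, str, NumberedChain, list[Residue]]] = []
    for cid, residues in chains.items():
        seq = "".join(r.aa for r in residues)
        try:
            nc_h = number_chain(seq, "heavy", "chothia")
        except NumberingError:
            nc_h = None
        try:
            nc_l = number_chain(seq, "light", "chothia")
        except NumberingError:
            nc_l = None
        if nc_h is None and nc_l is None:
            continue
        if nc_l is None:
            role, nc = "heavy", nc_h
        elif nc_h is None:
            role, nc = "light", nc_l
        else:
            from .numbering import REFERENCE_PROFILES
            al = _aligner()
            s_h = al.score(REFERENCE_PROFILES["heavy"], seq)
            s_l = al.score(REFERENCE_PROFILES[nc_l.chain_type], seq)
            role, nc = ("heavy", nc_h) if s_h >= s_l else ("light", nc_l)
        classified.append((cid, role, nc, residues))

    if chain_assignments is None:
        pairs = []
        lights = [c for c in classified if c[1] == "light"]
        heavies = [c for c in classified if c[1] == "heavy"]
        for l, h in zip(lights, heavies):
            pairs.append((l, h))
    else:
        by_id = {c[0]: c for c in classified}
        pairs = []
        for lid, hid in chain_assignments:
            if lid not in by_id or hid not in by_id:
                raise IngestError(f"assigned chains {lid}/{hid} not found or not antibody domains")
            pairs.append((by_id[lid], by_id[hid]))

    if not pairs:
        raise IngestError(f"no antibody Fv domain found in {source}")

    records, rejected = [], []
    for (lid, _, nc_l, res_l), (hid, _, nc_h, res_h) in pairs:
        pair_name = f"{accession}_{lid}{hid}" if len(pairs) > 1 or lid != "L" else f"{accession}_{lid}{hid}"
        flags: list[str] = []
        fatal = None
        for residues, role in ((res_l, "light"), (res_h, "heavy")):
            f, fat = _completeness_check(residues)
            flags.extend(f)
            if fat:
                fatal = fatal or fat
        if fatal:
            rejected.append((pair_name, fatal))
            continue
        light = _renumber_to_chothia(res_l, nc_l, "light", "L")
        heavy = _renumber_to_chothia(res_h, nc_h, "heavy", "H")
        fv = FvStructure(light, heavy, {"id": pair_name, "organism": organism,
                                        "resolution": resolution})
        cdrs: dict[str, CdrRegion] = {}
        canonical: dict[str, str] = {}
        for nc in (nc_l, nc_h):
            for region in extract_cdrs(nc):
                cdrs[region.label] = region
                canonical[region.label] = assign_canonical_class(region, nc, definitions)
        records.append(TemplateRecord(
            template_id=pair_name,
            structure=fv,
            numbered={"light": nc_l, "heavy": nc_h},
            cdrs=cdrs,
            canonical=canonical,
            organism=organism,
            resolution=resolution,
            flags=flags,
        ))
    return IngestResult(records, rejected)


# ---------------------------------------------------------------------------
# database

@dataclass
class TemplateDatabase:
    records: dict[str, TemplateRecord] = field(default_factory=dict)

    def add(self, record: TemplateRecord) -> None:
        if record.template_id in self.records:
            raise ValueError(f"duplicate template_id {record.template_id}")
        self.records[record.template_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def get(self, template_id: str) -> TemplateRecord:
        return self.records[template_id]

    def ids(self) -> list[str]:
        return sorted(self.records)

    def filter(self, organism: str | None = None,
               light_isotype: str | None = None) -> "TemplateDatabase":
        out = TemplateDatabase()
        for r in self:
            if organism is not None and r.organism != organism:
                continue
            if light_isotype is not None and r.light_isotype != light_isotype:
                continue
            out.add(r)
        return out

    def loops(self, cdr_label: str, loop_length: int,
              canonical_class: str | None = None) -> list[TemplateRecord]:
        """Records whose named CDR has the given length (and class, if asked)."""
        out = []
        for r in sorted(self, key=lambda r: r.template_id):
            region = r.cdrs.get(cdr_label)
            if region is None or region.loop_length != loop_length or region.incomplete:
                continue
            if canonical_class is not None and r.canonical.get(cdr_label) != canonical_class:
                continue
            out.append(r)
        return out

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in sorted(self, key=lambda r: r.template_id):
            write_pdb(r.structure, directory / f"{r.template_id}.pdb")
            rows.append({
                "template_id": r.template_id,
                "organism": r.organism,
                "resolution": "" if r.resolution is None else f"{r.resolution:g}",
                "light_isotype": r.light_isotype,
                "canonical": ";".join(f"{k}={v}" for k, v in sorted(r.canonical.items())),
                "flags": ";".join(r.flags),
            })
        with open(directory / "metadata.tsv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else
                               ["template_id"], delimiter="\t")
            w.writeheader()
            w.writerows(rows)
        manifest = {"schema_version": DB_SCHEMA_VERSION, "n_records": len(self)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path,
             definitions: list[CanonicalDefinition] | None = None) -> "TemplateDatabase":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("schema_version") != DB_SCHEMA_VERSION:
            raise ValueError("unsupported database schema version")
        db = cls()
        with open(directory / "metadata.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                res = float(row["resolution"]) if row["resolution"] else None
                result = ingest_structure(
                    directory / f"{row['template_id']}.pdb",
                    organism=row["organism"], resolution=res,
                    definitions=definitions, accession=row["template_id"].split("_")[0])
                if not result.records:
                    raise ValueError(f"failed to reload {row['template_id']}: {result.rejected}")
                rec = result.records[0]
                rec.template_id = row["template_id"]
                rec.structure.meta["id"] = row["template_id"]
                db.add(rec)
        return db


# ---------------------------------------------------------------------------
# redundancy pruning

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.end_insertion_score = -1.0
    al.end_deletion_score = -1.0
    return al


def pair_identity(a: TemplateRecord, b: TemplateRecord) -> float:
    """Whole-Fv percent sequence identity by per-chain global alignment."""
    al = _aligner()
    matches = 0
    denom = 0
    for role in ("light", "heavy"):
        sa = a.numbered[role].sequence
        sb = b.numbered[role].sequence
        aln = al.align(sa, sb)[0]
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            matches += sum(1 for k in range(t1 - t0) if sa[t0 + k] == sb[q0 + k])
        denom += max(len(sa), len(sb))
    return 100.0 * matches / denom


def prune_redundant(records: list[TemplateRecord],
                    identity_threshold: float = 95.0) -> TemplateDatabase:
    """Prune to the given identity: single-linkage clusters of pairs whose
    identity exceeds the threshold, keeping per cluster the representative with
    the most complete termini (residue count), then best resolution, then id.
    """
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pair_identity(records[i], records[j]) > identity_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[TemplateRecord]] = {}
    for i, r in enumerate(records):
        clusters.setdefault(find(i), []).append(r)

    db = TemplateDatabase()
    for members in clusters.values():
        rep = min(members, key=lambda r: (
            -r.n_residues(),
            r.resolution if r.resolution is not None else float("inf"),
            r.template_id))
        db.add(rep)
    return db
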