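"""Antibody variable-domain numbering and region extraction.

Supports the Chothia, IMGT, Kabat and Honegger schemes via shipped
scheme-definition tables.  The numbering engine aligns the query against a
curated per-chain-type reference profile (global alignment, BLOSUM62) and maps
aligned columns onto scheme positions; loop-length variation is absorbed by
insertion codes at each CDR's anchor position, and shorter-than-base loops are
numbered by filling positions from both ends of the CDR.

The engine is deterministic for a fixed reference-profile set and is shared by
kappa and lambda light chains (the chain type is inferred from the profile
score unless given explicitly).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

SCHEMES = ("chothia", "imgt", "kabat", "honegger")
CHAIN_TYPES = ("heavy", "kappa", "lambda")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_INSERTION_CODES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


class NumberingError(ValueError):
    """Input or alignment problem while numbering a chain."""


class NotAntibodyError(NumberingError):
    """Sequence cannot be aligned to any variable-domain reference profile."""


@dataclass(frozen=True)
class SchemeRegion:
    region: str            # FR1..FR4, CDR1..CDR3
    start: int             # base index into the reference profile, 1-based
    end: int
    label_start: int       # scheme label of the first position in the region
    anchor: int | None     # scheme label where insertion codes accumulate

    def labels(self) -> list[int]:
        n = self.end - self.start + 1
        return list(range(self.label_start, self.label_start + n))


@dataclass(frozen=True)
class SchemeDefinition:
    scheme_name: str
    chain_type: str        # heavy | kappa | lambda
    regions: tuple[SchemeRegion, ...]

    def __post_init__(self):
        names = [r.region for r in self.regions]
        if names != list(REGION_ORDER):
            raise ValueError(f"scheme regions must be {REGION_ORDER}, got {names}")
        for a, b in zip(self.regions, self.regions[1:]):
            if b.start != a.end + 1 or b.label_start <= a.label_start + (a.end - a.start):
                raise ValueError("scheme regions must tile the profile with monotone labels")

    @property
    def n_base_positions(self) -> int:
        return self.regions[-1].end

    def region_of(self, region_name: str) -> SchemeRegion:
        for r in self.regions:
            if r.region == region_name:
                return r
        raise KeyError(region_name)

    def cdr_labels(self) -> list[str]:
        prefix = "H" if self.chain_type == "heavy" else "L"
        return [f"{prefix}{i}" for i in (1, 2, 3)]


@dataclass(frozen=True)
class NumberedResidue:
    amino_acid: str
    scheme_position: int
    insertion_code: str    # "" or a single letter
    region: str            # FR1..FR4, CDR1..CDR3

    @property
    def key(self) -> tuple[int, str]:
        return (self.scheme_position, self.insertion_code)

    def label(self) -> str:
        return f"{self.scheme_position}{self.insertion_code}"


@dataclass
class NumberedChain:
    chain_role: str        # heavy | light
    sequence: str
    residues: list[NumberedResidue]
    scheme: SchemeDefinition

    def __post_init__(self):
        if "".join(r.amino_acid for r in self.residues) != self.sequence:
            raise ValueError("residue amino acids must concatenate to the sequence")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys) or keys != sorted(keys):
            raise ValueError("scheme positions must be unique and monotonically ordered")

    @property
    def chain_type(self) -> str:
        return self.scheme.chain_type

    def position_map(self) -> dict[tuple[int, str], int]:
        """(scheme_position, insertion_code) -> residue index."""
        return {r.key: i for i, r in enumerate(self.residues)}

    def residue_at(self, position: int, icode: str = "") -> NumberedResidue | None:
        idx = self.position_map().get((position, icode))
        return None if idx is None else self.residues[idx]

    def region_indices(self, region: str) -> list[int]:
        return [i for i, r in enumerate(self.residues) if r.region == region]


@dataclass
class CdrRegion:
    label: str             # L1..L3 / H1..H3
    loop_sequence: str
    loop_length: int
    stem_before: str
    stem_after: str
    incomplete: bool = False
    positions: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.loop_length != len(self.loop_sequence):
            raise ValueError("loop_length must equal len(loop_sequence)")


# ---------------------------------------------------------------------------
# shipped data

def _data_text(name: str) -> str:
    return resources.files("fvbuild.data").joinpath(name).read_text()


def _load_scheme(scheme_name: str, chain_type: str) -> SchemeDefinition:
    fname = f"schemes/{scheme_name}_{'heavy' if chain_type == 'heavy' else 'light'}.csv"
    rows = []
    for line in _data_text(fname).splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line)
    reader = csv.DictReader(rows)
    regions = tuple(
        SchemeRegion(
            region=r["region"],
            start=int(r["start"]),
            end=int(r["end"]),
            label_start=int(r["label_start"]),
            anchor=int(r["anchor"]) if r["anchor"] else None,
        )
        for r in reader
    )
    return SchemeDefinition(scheme_name, chain_type, regions)


_SCHEME_CACHE: dict[tuple[str, str], SchemeDefinition] = {}


def get_scheme(scheme_name: str, chain_type: str) -> SchemeDefinition:
    scheme_name = scheme_name.lower()
    if scheme_name not in SCHEMES:
        raise NumberingError(f"unknown scheme {scheme_name!r}; expected one of {SCHEMES}")
    if chain_type not in CHAIN_TYPES:
        raise NumberingError(f"unknown chain type {chain_type!r}")
    key = (scheme_name, chain_type)
    if key not in _SCHEME_CACHE:
        _SCHEME_CACHE[key] = _load_scheme(*key)
    return _SCHEME_CACHE[key]


def _load_references() -> dict[str, str]:
    refs: dict[str, str] = {}
    name = None
    for line in _data_text("references.fasta").splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            refs[name] = ""
        elif name:
            refs[name] += line.strip()
    return refs


REFERENCE_PROFILES = _load_references()
BLOSUM62 = substitution_matrices.load("BLOSUM62")

# Minimum fraction of reference positions matched identically for a sequence
# to be accepted as an antibody variable domain.
IDENTITY_FLOOR = 0.30


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = BLOSUM62
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.end_insertion_score = -1.0
    al.end_deletion_score = -1.0
    return al


def _align_to_reference(sequence: str, reference: str) -> tuple[list[int | None], float]:
    """Return per-query-residue reference indices (0-based, None = insertion)
    and the fraction of reference positions matched identically."""
    aln = _aligner().align(reference, sequence)[0]
    slot: list[int | None] = [None] * len(sequence)
    n_ident = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            slot[q0 + k] = t0 + k
            if reference[t0 + k] == sequence[q0 + k]:
                n_ident += 1
    return slot, n_ident / len(reference)


def classify_chain_role(sequence: str) -> str | None:
    """Classify a sequence as a light or heavy variable domain by profile
    score; None when it does not number as either."""
    al = _aligner()
    best_role, best_score = None, None
    for role, types in (("light", ("kappa", "lambda")), ("heavy", ("heavy",))):
        try:
            number_chain(sequence, role, "chothia")
        except NumberingError:
            continue
        score = max(al.score(REFERENCE_PROFILES[t], sequence) for t in types)
        if best_score is None or score > best_score:
            best_role, best_score = role, score
    return best_role


def infer_chain_type(sequence: str, chain_role: str) -> str:
    """Pick the reference profile (kappa vs lambda for light chains) by score."""
    if chain_role == "heavy":
        return "heavy"
    al = _aligner()
    scores = {ct: al.score(REFERENCE_PROFILES[ct], sequence) for ct in ("kappa", "lambda")}
    return max(scores, key=lambda ct: (scores[ct], ct))


def _fill_cdr_positions(region: SchemeRegion, n: int) -> list[tuple[int, str]]:
    """Scheme labels for a CDR of length n: both-ends fill when short, anchor
    insertion codes when long."""
    labels = region.labels()
    b = len(labels)
    if n <= b:
        left = math.ceil(n / 2)
        right = n - left
        chosen = labels[:left] + (labels[b - right:] if right else [])
        return [(p, "") for p in chosen]
    anchor = region.anchor if region.anchor is not None else labels[b // 2]
    extra = n - b
    if extra > len(_INSERTION_CODES):
        raise NumberingError(f"CDR of length {n} exceeds insertion-code capacity")
    out: list[tuple[int, str]] = []
    for p in labels:
        out.append((p, ""))
        if p == anchor:
            out.extend((anchor, _INSERTION_CODES[k]) for k in range(extra))
    return out


def number_chain(sequence: str, chain_role: str, scheme: str,
                 chain_type: str | None = None) -> NumberedChain:
    """Assign scheme positions and region labels to a variable-domain sequence.

    ``chain_role`` is "heavy" or "light"; for light chains the kappa/lambda
    profile is chosen by alignment score unless ``chain_type`` is given.
    """
    sequence = sequence.strip().upper()
    if chain_role not in ("heavy", "light"):
        raise NumberingError(f"chain_role must be 'heavy' or 'light', got {chain_role!r}")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise NumberingError(f"non-standard characters in sequence: {sorted(bad)}")
    if not 90 <= len(sequence) <= 150:
        raise NumberingError(
            f"sequence length {len(sequence)} outside the plausible variable-domain "
            "range 90-150")
    if chain_type is None:
        chain_type = infer_chain_type(sequence, chain_role)
    elif chain_role == "heavy" and chain_type != "heavy":
        raise NumberingError("heavy chains must use the heavy profile")
    scheme_def = get_scheme(scheme, chain_type)
    reference = REFERENCE_PROFILES[chain_type]
    slot, ident = _align_to_reference(sequence, reference)
    if ident < IDENTITY_FLOOR:
        raise NotAntibodyError(
            f"sequence matches only {ident:.0%} of the {chain_type} variable-domain "
            "profile; not an antibody domain")

    residues: list[NumberedResidue] = []
    cursor = 0
    n = len(sequence)

    def next_aligned(i: int) -> int | None:
        for j in range(i, n):
            if slot[j] is not None:
                return slot[j]
        return None

    for region in scheme_def.regions:
        r_lo, r_hi = region.start - 1, region.end - 1  # 0-based profile range
        if region.region.startswith("CDR"):
            seg_start = cursor
            while cursor < n:
                s = slot[cursor]
                if s is None:
                    na = next_aligned(cursor)
                    if na is not None and na > r_hi:
                        break
                elif s > r_hi:
                    break
                cursor += 1
            seg = sequence[seg_start:cursor]
            for aa, (pos, icode) in zip(seg, _fill_cdr_positions(region, len(seg))):
                residues.append(NumberedResidue(aa, pos, icode, region.region))
        else:
            last_pos: int | None = None
            while cursor < n:
                s = slot[cursor]
                if s is None:
                    na = next_aligned(cursor)
                    if na is not None and na > r_hi:
                        break
                    if last_pos is None:
                        cursor += 1  # leading unalignable overhang: skip
                        continue
                    # framework insertion: insertion code on the previous label
                    prev = residues[-1]
                    nxt = _INSERTION_CODES[
                        _INSERTION_CODES.index(prev.insertion_code) + 1
                        if prev.insertion_code else 0]
                    residues.append(NumberedResidue(sequence[cursor], prev.scheme_position,
                                                    nxt, region.region))
                elif s > r_hi:
                    break
                else:
                    last_pos = region.label_start + (s - r_lo)
                    residues.append(NumberedResidue(sequence[cursor], last_pos, "",
                                                    region.region))
                cursor += 1
    if cursor != n:
        # trailing residues past FR4: attach as insertions on the final label
        for j in range(cursor, n):
            prev = residues[-1]
            nxt = _INSERTION_CODES[
                _INSERTION_CODES.index(prev.insertion_code) + 1 if prev.insertion_code else 0]
            residues.append(NumberedResidue(sequence[j], prev.scheme_position, nxt, "FR4"))
    if len(residues) != len(sequence):
        raise NotAntibodyError(
            "sequence has unalignable overhangs against the "
            f"{chain_type} variable-domain profile")
    return NumberedChain(chain_role, sequence, residues, scheme_def)


def extract_cdrs(chain: NumberedChain, stem_width: int = 3) -> list[CdrRegion]:
    """Extract the three CDRs of a numbered chain with flanking stem residues.

    A CDR is flagged incomplete when the chain is truncated around it (no
    framework residues on one side), rather than being silently shortened.
    """
    cdrs: list[CdrRegion] = []
    labels = chain.scheme.cdr_labels()
    for k, region_name in enumerate(("CDR1", "CDR2", "CDR3")):
        idx = chain.region_indices(region_name)
        before_name = REGION_ORDER[REGION_ORDER.index(region_name) - 1]
        after_name = REGION_ORDER[REGION_ORDER.index(region_name) + 1]
        before = chain.region_indices(before_name)
        after = chain.region_indices(after_name)
        seq = "".join(chain.residues[i].amino_acid for i in idx)
        stem_b = "".join(chain.residues[i].amino_acid for i in before[-stem_width:])
        stem_a = "".join(chain.residues[i].amino_acid for i in after[:stem_width])
        incomplete = (len(before) == 0) or (len(after) == 0)
        cdrs.append(CdrRegion(
            label=labels[k],
            loop_sequence=seq,
            loop_length=len(seq),
            stem_before=stem_b,
            stem_after=stem_a,
            incomplete=incomplete,
            positions=[chain.residues[i].key for i in idx],
        ))
    return cdrs


def extract_cdrs_as(chain: NumberedChain, scheme_name: str,
                    stem_width: int = 3) -> list[CdrRegion]:
    """Extract CDRs under a (possibly different) scheme, reporting residue
    positions in the chain's *own* numbering.

    The chain sequence is renumbered under ``scheme_name`` to decide region
    membership; the returned ``positions`` are the keys of the same residues
    in the original chain, so structures indexed under one scheme can be
    sliced by another scheme's loop definitions.
    """
    if scheme_name == chain.scheme.scheme_name:
        return extract_cdrs(chain, stem_width)
    renum = number_chain(chain.sequence, chain.chain_role, scheme_name,
                         chain_type=chain.chain_type)
    own_keys = [r.key for r in chain.residues]
    out = []
    labels = chain.scheme.cdr_labels()
    for k, region_name in enumerate(("CDR1", "CDR2", "CDR3")):
        idx = [i for i, r in enumerate(renum.residues) if r.region == region_name]
        seq = "".join(renum.residues[i].amino_acid for i in idx)
        lo = idx[0] if idx else 0
        hi = idx[-1] if idx else -1
        stem_b = chain.sequence[max(0, lo - stem_width):lo]
        stem_a = chain.sequence[hi + 1:hi + 1 + stem_width]
        out.append(CdrRegion(
            label=labels[k],
            loop_sequence=seq,
            loop_length=len(seq),
            stem_before=stem_b,
            stem_after=stem_a,
            incomplete=len(idx) == 0,
            positions=[own_keys[i] for i in idx],
        ))
    return out


def framework_mask(chain: NumberedChain) -> np.ndarray:
    """Boolean mask over residues, true exactly on FR1-FR4."""
    return np.array([r.region.startswith("FR") for r in chain.residues], dtype=bool)


def numbering_report(chain: NumberedChain) -> str:
    """Delimited-text numbering report: position, insertion code, region, residue."""
    lines = ["position\ticode\tregion\tamino_acid"]
    for r in chain.residues:
        lines.append(f"{r.scheme_position}\t{r.insertion_code or '-'}\t{r.region}\t{r.amino_acid}")
    return "\n".join(lines) + "\n"
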