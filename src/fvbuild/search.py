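"""Framework template search: scheme-position alignment scoring, ranked hits
for the Fv / light / heavy scopes, and the Top5 similarity-window rule.

Sequence correspondence comes from scheme numbering (both query and template
carry scheme positions), which for antibody variable domains reproduces the
column matching a profile HMM would give, deterministically.  Identity is the
percentage of compared positions with equal residues; similarity is the
percentage with a positive BLOSUM62 score — reported percentages depend on
this convention, which is therefore pinned here.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

from .db import TemplateDatabase, TemplateRecord
from .numbering import NumberedChain

BLOSUM62 = substitution_matrices.load("BLOSUM62")

SCOPES = ("fv", "light", "heavy", "cdr_loop")


class SearchError(ValueError):
    pass


class NoTemplatesError(SearchError):
    """Empty result after filtering (e.g. organism filter leaves nothing)."""


@dataclass(frozen=True)
class AlignmentScore:
    similarity: float       # percent
    identity: float         # percent
    aligned_length: int
    region_scope: str       # fv | light | heavy | cdr_loop

    def __post_init__(self):
        if not (0.0 <= self.identity <= self.similarity <= 100.0):
            raise ValueError("scores must satisfy 0 <= identity <= similarity <= 100")


@dataclass(frozen=True)
class TemplateHit:
    template_id: str
    score: AlignmentScore
    organism: str
    resolution: float | None

    @property
    def similarity(self) -> float:
        return self.score.similarity

    @property
    def identity(self) -> float:
        return self.score.identity


@dataclass
class SearchOptions:
    include_cdrs: bool = False
    organism_filter: str | None = None
    top_n: int = 5
    similarity_window: float = 10.0   # percentage points

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.similarity_window < 0:
            raise ValueError("similarity window must be >= 0")


def _compare_positions(q: NumberedChain, t: NumberedChain,
                       mask_cdrs: bool, cdr_label: str | None = None):
    """Yield (query_aa, template_aa) over shared scheme positions."""
    tmap = {r.key: r for r in t.residues}
    for r in q.residues:
        if cdr_label is not None:
            if r.region != f"CDR{cdr_label[-1]}":
                continue
        elif mask_cdrs and not r.region.startswith("FR"):
            continue
        other = tmap.get(r.key)
        if other is None:
            continue
        if cdr_label is not None and other.region != r.region:
            continue
        yield r.amino_acid, other.amino_acid


def pair_score(query: dict[str, NumberedChain], template: TemplateRecord,
               scope: str = "fv", mask_cdrs: bool = True,
               cdr_label: str | None = None) -> AlignmentScore:
    """Identity/similarity of a query against one template over a scope.

    ``query`` maps chain roles to numbered chains; scope "light"/"heavy" uses
    one chain, "fv" both, "cdr_loop" the single CDR named by ``cdr_label``.
    """
    if scope not in SCOPES:
        raise SearchError(f"unknown scope {scope!r}")
    roles = {"fv": ("light", "heavy"), "light": ("light",), "heavy": ("heavy",)}
    if scope == "cdr_loop":
        if cdr_label is None:
            raise SearchError("cdr_loop scope requires cdr_label")
        roles_used = ("heavy",) if cdr_label.startswith("H") else ("light",)
    else:
        roles_used = roles[scope]
    n = ident = simil = 0
    for role in roles_used:
        qc = query[role]
        tc = template.numbered[role]
        for qa, ta in _compare_positions(qc, tc, mask_cdrs,
                                         cdr_label if scope == "cdr_loop" else None):
            n += 1
            if qa == ta:
                ident += 1
            if BLOSUM62[qa, ta] > 0:
                simil += 1
    if n == 0:
        raise SearchError("no shared scheme positions between query and template")
    return AlignmentScore(100.0 * simil / n, 100.0 * ident / n, n,
                          scope)


def _hit_sort_key(h: TemplateHit):
    # similarity desc, identity desc, resolution asc (better first, missing
    # last), template_id lexicographic
    res = h.resolution if h.resolution is not None else float("inf")
    return (-h.similarity, -h.identity, res, h.template_id)


def search_framework_templates(query: dict[str, NumberedChain], db: TemplateDatabase,
                               options: SearchOptions | None = None
                               ) -> dict[str, list[TemplateHit]]:
    """Ranked framework template hits for the fv, light and heavy scopes."""
    options = options or SearchOptions()
    if options.organism_filter is not None:
        db = db.filter(organism=options.organism_filter)
    if len(db) == 0:
        raise NoTemplatesError(
            "no templates" + (f" from organism {options.organism_filter!r}"
                              if options.organism_filter else " in database"))
    out: dict[str, list[TemplateHit]] = {}
    for scope in ("fv", "light", "heavy"):
        hits = []
        for rec in db:
            score = pair_score(query, rec, scope=scope,
                               mask_cdrs=not options.include_cdrs)
            hits.append(TemplateHit(rec.template_id, score, rec.organism,
                                    rec.resolution))
        hits.sort(key=_hit_sort_key)
        out[scope] = hits[:options.top_n]
    return out


def top5_window_filter(hits: list[TemplateHit],
                       window: float = 10.0) -> list[TemplateHit]:
    """Retain hits whose similarity is within ``window`` percentage points of
    the best (boundary inclusive); the best hit is always retained."""
    if not hits:
        raise SearchError("window filter requires at least one hit")
    best = hits[0].similarity
    if any(h.similarity > best + 1e-9 for h in hits):
        raise SearchError("hits must be sorted by similarity descending")
    return [h for h in hits if best - h.similarity <= window + 1e-9]


def search_report(results: dict[str, list[TemplateHit]]) -> str:
    """Delimited-text search report."""
    lines = ["scope\trank\ttemplate_id\tsimilarity\tidentity\tresolution\torganism"]
    for scope in ("fv", "light", "heavy"):
        for i, h in enumerate(results.get(scope, []), start=1):
            res = "" if h.resolution is None else f"{h.resolution:.2f}"
            lines.append(f"{scope}\t{i}\t{h.template_id}\t{h.similarity:.1f}\t"
                         f"{h.identity:.1f}\t{res}\t{h.organism}")
    return "\n".join(lines) + "\n"
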