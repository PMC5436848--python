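"""CDR loop refinement: length-matched template selection with optional
canonical filtering, multi-criteria ranking, and restrained loop grafting that
leaves the framework untouched.

Loop templates must have identical loop length to the target CDR under the
chosen numbering scheme.  Ranking uses a BLOSUM62 score of the loop plus its
stem residues, a secondary bonus for templates whose other two same-domain
CDRs also score well against the target (loop conformations in a domain can
be interdependent), and finally crystallographic resolution.  Whether the
cross-loop bonus is a strict secondary tier or is blended into the primary
score is configurable (``ranking_mode``), since worked cases exist where
cross-loop scores override the loop score itself.

Canonical filtering applies under the Chothia scheme (canonical classes are
Chothia constructs); other schemes select purely by loop length and score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geom
from .build import (AtomTable, FvModel, build_restraints, CONFORMER_SIGMA)
from .db import (CanonicalDefinition, TemplateDatabase, TemplateRecord,
                 assign_canonical_class, load_canonical_definitions)
from .numbering import CdrRegion, NumberedChain, extract_cdrs_as
from .search import BLOSUM62
from .structure import ALL_ATOMS, FvStructure

STEM_WIDTH = 3                 # residues each side used for scoring + anchoring
STEM_RMSD_WARN = 1.5           # A; stem superposition above this is flagged
OMEGA_LOG_TOLERANCE = 30.0     # degrees; omega drift from template is logged
MINOR_CLUSTER_FRACTION = 0.10  # anomaly filter threshold
CDR_ORDER = ("L1", "L2", "L3", "H1", "H2", "H3")


class LoopError(ValueError):
    pass


@dataclass
class LoopTemplate:
    template_id: str
    cdr_label: str
    loop_sequence: str
    canonical_class: str
    loop_score: float                      # BLOSUM62 over loop + stems
    cross_loop_score: float                # sum over the other two domain CDRs
    resolution: float | None
    record: TemplateRecord | None = None
    region: CdrRegion | None = None        # the template's own CDR view

    def sort_key(self, mode: str):
        res = self.resolution if self.resolution is not None else float("inf")
        if mode == "tiered":
            return (-self.loop_score, -self.cross_loop_score, res, self.template_id)
        if mode == "blended":
            return (-(self.loop_score + self.cross_loop_score), res, self.template_id)
        raise LoopError(f"unknown ranking mode {mode!r}")


@dataclass
class LoopRanking:
    templates: list[LoopTemplate]
    n_templates_used: int
    filtering_mode: str                    # canonical | unfiltered

    def __post_init__(self):
        if self.n_templates_used < 1:
            raise LoopError("n_templates_used must be >= 1")


def _blosum_score(a: str, b: str) -> float:
    return float(sum(BLOSUM62[x, y] for x, y in zip(a, b)))


def _loop_plus_stem_score(target: CdrRegion, cand: CdrRegion) -> float:
    s = _blosum_score(target.loop_sequence, cand.loop_sequence)
    # stems aligned from the loop outward
    s += _blosum_score(target.stem_before[::-1], cand.stem_before[::-1])
    s += _blosum_score(target.stem_after, cand.stem_after)
    return s


def record_cdr_view(record: TemplateRecord, scheme: str) -> dict[str, CdrRegion]:
    """The record's CDRs under a given scheme (cached; Chothia is the stored
    default view)."""
    if scheme == "chothia":
        return record.cdrs
    cache = getattr(record, "_scheme_cdrs", None)
    if cache is None:
        cache = {}
        record._scheme_cdrs = cache
    if scheme not in cache:
        view: dict[str, CdrRegion] = {}
        for role in ("light", "heavy"):
            for region in extract_cdrs_as(record.numbered[role], scheme, STEM_WIDTH):
                view[region.label] = region
        cache[scheme] = view
    return cache[scheme]


def _cross_loop_score(target_cdrs: dict[str, CdrRegion],
                      cand_cdrs: dict[str, CdrRegion], label: str) -> float:
    """Score of the template's other two same-domain CDRs against the target,
    paired position-by-position from the loop start."""
    domain = label[0]
    total = 0.0
    for other in CDR_ORDER:
        if other == label or other[0] != domain:
            continue
        t = target_cdrs.get(other)
        c = cand_cdrs.get(other)
        if t is None or c is None:
            continue
        total += _blosum_score(t.loop_sequence, c.loop_sequence)
    return total


def find_loop_templates(target_cdr: CdrRegion, db: TemplateDatabase,
                        canonical_filter: bool = True,
                        target_class: str = "none",
                        target_cdrs: dict[str, CdrRegion] | None = None,
                        scheme: str = "chothia") -> list[LoopTemplate]:
    """All database loops with the target's exact length; when canonical
    filtering is on (Chothia only) and templates of the target's class exist,
    restrict to that class ("if available" — otherwise fall back to
    unfiltered).

    Returns an empty list when no length-matched template exists (the "no loop
    template" signal; callers must flag the loop unmodeled).
    """
    label = target_cdr.label
    matched: list[tuple[TemplateRecord, CdrRegion]] = []
    for rec in sorted(db, key=lambda r: r.template_id):
        view = record_cdr_view(rec, scheme)
        cand = view.get(label)
        if cand is None or cand.incomplete or cand.loop_length != target_cdr.loop_length:
            continue
        matched.append((rec, cand))
    if canonical_filter and scheme == "chothia" and target_class != "none":
        filtered = [(r, c) for r, c in matched
                    if r.canonical.get(label) == target_class]
        if filtered:
            matched = filtered
    target_cdrs = target_cdrs or {}
    out = []
    for rec, cand in matched:
        out.append(LoopTemplate(
            template_id=rec.template_id,
            cdr_label=label,
            loop_sequence=cand.loop_sequence,
            canonical_class=rec.canonical.get(label, "none"),
            loop_score=_loop_plus_stem_score(target_cdr, cand),
            cross_loop_score=_cross_loop_score(target_cdrs,
                                               record_cdr_view(rec, scheme), label),
            resolution=rec.resolution,
            record=rec,
            region=cand,
        ))
    return out


def rank_loop_templates(candidates: list[LoopTemplate], n_templates: int = 3,
                        ranking_mode: str = "tiered",
                        filtering_mode: str = "canonical") -> LoopRanking:
    """Sort candidates by (loop+stem score, cross-loop bonus, resolution, id)
    and retain the top ``n_templates``."""
    if not candidates:
        raise LoopError("rank_loop_templates requires at least one candidate")
    ordered = sorted(candidates, key=lambda c: c.sort_key(ranking_mode))
    return LoopRanking(ordered[:n_templates], n_templates, filtering_mode)


# ---------------------------------------------------------------------------
# grafting

def _stem_keys(nc: NumberedChain, loop_positions, stem_width: int):
    order = [r.key for r in nc.residues]
    i0 = order.index(loop_positions[0])
    i1 = order.index(loop_positions[-1])
    before = order[max(0, i0 - stem_width):i0]
    after = order[i1 + 1:i1 + 1 + stem_width]
    return before, after


def _transformed_loop_record(framework: FvStructure, target: dict[str, NumberedChain],
                             lt: LoopTemplate, role: str,
                             target_loop_keys, target_before, target_after,
                             ) -> tuple[TemplateRecord, float]:
    """Virtual template: the framework structure with the candidate's loop
    superposed onto the framework stems (Kabsch over paired stem backbone
    atoms, residues paired positionally from the loop outward)."""
    rec = lt.record
    tmpl_chain = rec.structure.chain(role)
    fw_chain = framework.chain(role)
    t_idx = tmpl_chain.index()
    f_idx = fw_chain.index()
    tmpl_before, tmpl_after = _stem_keys(rec.numbered[role], lt.region.positions,
                                         len(target_before) or STEM_WIDTH)
    # pair stems outward from the loop
    nb = min(len(target_before), len(tmpl_before))
    na = min(len(target_after), len(tmpl_after))
    stem_pairs = (list(zip(target_before[::-1][:nb], tmpl_before[::-1][:nb]))
                  + list(zip(target_after[:na], tmpl_after[:na])))
    P_rows, Q_rows = [], []
    for fk, tk in stem_pairs:
        fr, tr = f_idx.get(fk), t_idx.get(tk)
        if fr is None or tr is None:
            continue
        for a in ("N", "CA", "C"):
            if a in fr.atoms and a in tr.atoms:
                Q_rows.append(fr.atoms[a])
                P_rows.append(tr.atoms[a])
    if len(P_rows) < 6:
        raise LoopError(f"too few shared stem atoms for {lt.template_id}")
    R, t, stem_rmsd = geom.kabsch(np.array(P_rows), np.array(Q_rows))
    virtual = framework.copy()
    v_idx = virtual.chain(role).index()
    for fk, tk in zip(target_loop_keys, lt.region.positions):
        src = t_idx.get(tk)
        dst = v_idx.get(fk)
        if src is None or dst is None:
            continue
        for a in ("N", "CA", "C", "O", "CB"):
            if a in src.atoms:
                dst.atoms[a] = R @ src.atoms[a] + t
        if dst.aa == "G":
            dst.atoms.pop("CB", None)
        elif "CB" not in dst.atoms and dst.has_backbone():
            dst.atoms["CB"] = geom.ideal_cb(dst.atoms["N"], dst.atoms["CA"],
                                            dst.atoms["C"])
    record = TemplateRecord(
        template_id=f"__loop_{lt.template_id}__", structure=virtual,
        numbered=target, cdrs={}, canonical={}, organism="synthetic",
        resolution=lt.resolution)
    return record, stem_rmsd


def _loop_omegas(fv: FvStructure, role: str, loop_keys) -> list[float]:
    residues = fv.chain(role).residues
    pos = {r.key: i for i, r in enumerate(residues)}
    out = []
    for k in loop_keys:
        i = pos.get(k)
        if i is None or i + 1 >= len(residues):
            continue
        a, b = residues[i], residues[i + 1]
        if all(n in a.atoms for n in ("CA", "C")) and all(n in b.atoms for n in ("N", "CA")):
            out.append(geom.dihedral(a.atoms["CA"], a.atoms["C"],
                                     b.atoms["N"], b.atoms["CA"]))
    return out


def _cluster_loops(loop_coord_sets: list[np.ndarray], cutoff: float = 1.0) -> list[int]:
    """Single-linkage cluster labels on loop-coordinate RMSD."""
    n = len(loop_coord_sets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if geom.rmsd(loop_coord_sets[i], loop_coord_sets[j]) < cutoff:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def graft_and_model_loop(framework: FvModel, target_cdr: CdrRegion,
                         ranking: LoopRanking,
                         n_loop_models: int = 10, seed: int = 0,
                         stem_width: int = STEM_WIDTH,
                         anomaly_filter: bool = False) -> FvModel:
    """Rebuild one CDR loop from the ranked templates with multi-template
    restraints restricted to loop atoms; framework coordinates (everything
    outside the loop) are bitwise unchanged."""
    if not ranking.templates:
        raise LoopError("graft requires a non-empty ranking")
    label = target_cdr.label
    role = "heavy" if label.startswith("H") else "light"
    target = framework.target_numbered
    loop_keys = list(target_cdr.positions)
    before, after = _stem_keys(target[role], loop_keys, stem_width)

    virtuals = []
    warnings = list(framework.warnings)
    for lt in ranking.templates:
        rec, stem_rmsd = _transformed_loop_record(
            framework.structure, target, lt, role, loop_keys, before, after)
        if stem_rmsd > STEM_RMSD_WARN:
            warnings.append(
                f"incompatible anchors: {label} template {lt.template_id} stem "
                f"RMSD {stem_rmsd:.2f} A")
        virtuals.append(rec)

    # start from the top template's transformed loop
    start = virtuals[0].structure.copy()
    system, table = build_restraints(start, target, virtuals)
    loop_set = {(role, k) for k in loop_keys}
    atom_is_loop = np.array([(r, k) in loop_set for (r, k, _a) in table.keys])
    # keep only restraints touching the loop; freeze everything else
    touching = atom_is_loop[system.pairs[:, 0]] | atom_is_loop[system.pairs[:, 1]]
    system.pairs = system.pairs[touching]
    system.well_d = system.well_d[touching]
    system.well_w = system.well_w[touching]
    bond_touch = atom_is_loop[system.bonds[:, 0]] | atom_is_loop[system.bonds[:, 1]]
    system.bonds = system.bonds[bond_touch]
    system.bond_d0 = system.bond_d0[bond_touch]

    rng = np.random.default_rng(seed)
    coords0 = start.all_coords(ALL_ATOMS)
    candidates: list[tuple[float, int, np.ndarray]] = []
    for m in range(n_loop_models):
        x0 = coords0.copy()
        x0[atom_is_loop] += rng.normal(scale=CONFORMER_SIGMA,
                                       size=(int(atom_is_loop.sum()), 3))
        xmin, e = system.minimize(x0, free_mask=atom_is_loop)
        candidates.append((e, m, xmin))

    if anomaly_filter and len(candidates) > 1:
        sets = [x[atom_is_loop] for _, _, x in candidates]
        labels = _cluster_loops(sets)
        counts = {c: labels.count(c) for c in set(labels)}
        keep = [i for i, c in enumerate(labels)
                if counts[c] / len(labels) >= MINOR_CLUSTER_FRACTION]
        if keep:
            candidates = [candidates[i] for i in keep]

    e_best, m_best, x_best = min(candidates, key=lambda c: (c[0], c[1]))
    out = framework.structure.copy()
    out_coords = out.all_coords(ALL_ATOMS)
    out_coords[atom_is_loop] = x_best[atom_is_loop]
    out.set_all_coords(out_coords, ALL_ATOMS)

    # log peptide-plane (omega) drift from the top template, cis/trans checks
    om_model = _loop_omegas(out, role, loop_keys)
    om_tmpl = _loop_omegas(virtuals[0].structure, role, loop_keys)
    for k, (a, b) in enumerate(zip(om_model, om_tmpl)):
        dev = abs(((a - b) + 180.0) % 360.0 - 180.0)
        if dev > OMEGA_LOG_TOLERANCE:
            warnings.append(
                f"{label} omega drift {dev:.0f} deg from template at loop "
                f"position {k}")

    prov = dict(framework.per_region_provenance)
    prov[label] = [lt.template_id for lt in ranking.templates]
    return FvModel(
        structure=out, target_numbered=target,
        build_method=framework.build_method,
        framework_templates=framework.framework_templates,
        per_region_provenance=prov,
        restraint_energy=e_best,
        model_id=f"{framework.model_id}_{label.lower()}{m_best}",
        warnings=warnings)


@dataclass
class RefinementReport:
    provenance: dict[str, list[str]] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    canonical: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["loop\ttemplates\tcanonical\tloop_score\tflag"]
        for lab in CDR_ORDER:
            if lab not in self.provenance and lab not in self.flags:
                continue
            lines.append("\t".join([
                lab,
                ",".join(self.provenance.get(lab, [])) or "-",
                self.canonical.get(lab, "none"),
                f"{self.scores.get(lab, float('nan')):.1f}",
                self.flags.get(lab, "ok"),
            ]))
        return "\n".join(lines) + "\n"


def refine_all_cdrs(framework: FvModel, db: TemplateDatabase,
                    loops: tuple[str, ...] = CDR_ORDER,
                    canonical_filter: bool = True,
                    n_templates: int = 3, n_loop_models: int = 10,
                    ranking_mode: str = "tiered", seed: int = 0,
                    scheme: str = "chothia",
                    definitions: list[CanonicalDefinition] | None = None,
                    anomaly_filter: bool = False) -> tuple[FvModel, RefinementReport]:
    """Refine the selected CDR loops in canonical order; loops without any
    length-matched template keep their framework-model coordinates and are
    flagged (such predictions are to be viewed with scepticism)."""
    if definitions is None:
        definitions = load_canonical_definitions()
    target = framework.target_numbered
    target_cdrs: dict[str, CdrRegion] = {}
    target_classes: dict[str, str] = {}
    for role in ("light", "heavy"):
        for region in extract_cdrs_as(target[role], scheme, STEM_WIDTH):
            target_cdrs[region.label] = region
            if scheme == "chothia":
                target_classes[region.label] = assign_canonical_class(
                    region, target[role], definitions)
            else:
                target_classes[region.label] = "none"

    model = framework
    report = RefinementReport()
    for i, label in enumerate(CDR_ORDER):
        if label not in loops:
            continue
        cdr = target_cdrs[label]
        report.canonical[label] = target_classes[label]
        candidates = find_loop_templates(
            cdr, db, canonical_filter=canonical_filter,
            target_class=target_classes[label], target_cdrs=target_cdrs,
            scheme=scheme)
        if not candidates:
            report.flags[label] = "no loop template"
            continue
        ranking = rank_loop_templates(
            candidates, n_templates=n_templates, ranking_mode=ranking_mode,
            filtering_mode="canonical" if canonical_filter else "unfiltered")
        model = graft_and_model_loop(model, cdr, ranking,
                                     n_loop_models=n_loop_models,
                                     seed=seed + 101 * i,
                                     anomaly_filter=anomaly_filter)
        report.provenance[label] = model.per_region_provenance[label]
        report.scores[label] = ranking.templates[0].loop_score
    return model, report
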