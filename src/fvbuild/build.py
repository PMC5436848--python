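"""Framework model construction: Single, Chimeric and Top5 strategies.

The builder replaces an external comparative-modelling engine with an in-repo
restrained minimizer: every template contributes an additive Gaussian distance
well for each restrained atom pair (well centred at the template's distance,
contribution weighted by local sequence similarity in a sliding window), and
model coordinates are obtained by quasi-Newton minimization of the total
restraint energy plus a light covalent-geometry term, starting from the
highest-similarity template threaded with the target sequence.  Candidate
conformers are generated by seeded perturbation of the starting coordinates
and ranked by restraint energy plus steric-clash and peptide-torsion
penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from . import geometry as geom
from .db import TemplateRecord
from .numbering import NumberedChain
from .search import BLOSUM62
from .structure import ALL_ATOMS, ChainStructure, FvStructure, Residue

# Restraint-graph and energy parameters.
RESTRAINT_CUTOFF = 8.0        # A; pair restrained if within cutoff in any template
MIN_SEQ_SEPARATION = 2        # residues; intra-chain pairs closer are bonded terms
WELL_SIGMA = 1.0              # A; width of each Gaussian well
BOND_K = 50.0                 # 1/A^2; covalent-geometry harmonic constant
CONFORMER_SIGMA = 0.2         # A; seeded perturbation of starting coordinates
SIMILARITY_WINDOW = 5         # scheme positions; local-similarity weighting window
CLASH_DISTANCE = 2.5          # A
CLASH_PENALTY = 10.0
OMEGA_PENALTY = 2.0
MIN_SHARED_CORE = 20          # positions needed for a domain superposition


class BuildError(ValueError):
    pass


@dataclass
class FvModel:
    """A predicted Fv structure with its provenance."""
    structure: FvStructure
    target_numbered: dict[str, NumberedChain]
    build_method: str                       # single | chimeric | top5
    framework_templates: list[str]
    per_region_provenance: dict[str, list[str]] = field(default_factory=dict)
    restraint_energy: float | None = None
    model_id: str = "m0"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        for role in ("light", "heavy"):
            if self.structure.chain(role).sequence() != self.target_numbered[role].sequence:
                raise BuildError(f"model {role} sequence differs from target")


# ---------------------------------------------------------------------------
# threading

def thread_template(target: dict[str, NumberedChain], template: TemplateRecord,
                    roles: tuple[str, ...] = ("light", "heavy")
                    ) -> tuple[FvStructure, list[str]]:
    """Copy template backbone onto the target sequence at scheme-aligned
    positions; missing positions are bridged by interpolation (with a warning)
    and substituted CB atoms are rebuilt by ideal geometry."""
    warnings: list[str] = []
    chains: dict[str, ChainStructure] = {}
    for role in roles:
        nc = target[role]
        tmpl_chain = template.structure.chain(role)
        tmpl_idx = tmpl_chain.index()
        residues: list[Residue] = []
        missing: list[int] = []
        for num in nc.residues:
            src = tmpl_idx.get(num.key)
            atoms: dict[str, np.ndarray] = {}
            if src is not None and src.has_backbone():
                for a in ("N", "CA", "C", "O"):
                    atoms[a] = src.atoms[a].copy()
                if num.amino_acid != "G":
                    if src.aa == num.amino_acid and "CB" in src.atoms:
                        atoms["CB"] = src.atoms["CB"].copy()
                    else:
                        atoms["CB"] = geom.ideal_cb(atoms["N"], atoms["CA"], atoms["C"])
            else:
                missing.append(len(residues))
            residues.append(Residue(num.scheme_position, num.insertion_code,
                                    num.amino_acid, atoms))
        if missing:
            warnings.append(
                f"{role} chain: {len(missing)} positions absent from template "
                f"{template.template_id}; bridged by interpolation")
            _bridge_missing(residues, missing)
        chains[role] = ChainStructure(role, "L" if role == "light" else "H", residues)
    fv = FvStructure(chains["light"], chains["heavy"],
                     {"id": f"model_on_{template.template_id}"})
    return fv, warnings


def _bridge_missing(residues: list[Residue], missing: list[int]) -> None:
    """Fill residues with no template coordinates by interpolating between the
    nearest placed neighbours (or extrapolating at the termini)."""
    placed = [i for i in range(len(residues)) if residues[i].atoms]
    if not placed:
        raise BuildError("template covers no target positions")
    for i in missing:
        prv = max((p for p in placed if p < i), default=None)
        nxt = min((p for p in placed if p > i), default=None)
        if prv is None:
            ref, shift = residues[nxt], (i - nxt) * np.array([3.6, 0.0, 0.0])
        elif nxt is None:
            ref, shift = residues[prv], (i - prv) * np.array([3.6, 0.0, 0.0])
        else:
            t = (i - prv) / (nxt - prv)
            a, b = residues[prv], residues[nxt]
            for name in ("N", "CA", "C", "O"):
                residues[i].atoms[name] = (1 - t) * a.atoms[name] + t * b.atoms[name]
            if residues[i].aa != "G":
                residues[i].atoms["CB"] = geom.ideal_cb(
                    residues[i].atoms["N"], residues[i].atoms["CA"], residues[i].atoms["C"])
            continue
        for name in ("N", "CA", "C", "O"):
            residues[i].atoms[name] = ref.atoms[name] + shift
        if residues[i].aa != "G":
            residues[i].atoms["CB"] = geom.ideal_cb(
                residues[i].atoms["N"], residues[i].atoms["CA"], residues[i].atoms["C"])


# ---------------------------------------------------------------------------
# atom tables and restraint systems

@dataclass
class AtomTable:
    """Flat atom indexing of an FvStructure: per-atom residue key, chain role
    and a global residue ordinal used for sequence separation."""
    keys: list[tuple[str, tuple[int, str], str]]      # (role, residue key, atom)
    res_ordinal: np.ndarray
    chain_code: np.ndarray                            # 0 = light, 1 = heavy

    @classmethod
    def from_structure(cls, fv: FvStructure) -> "AtomTable":
        keys, ords, codes = [], [], []
        ordinal = 0
        for code, chain in enumerate(fv.chains()):
            for res in chain.residues:
                for a in ALL_ATOMS:
                    if a in res.atoms:
                        keys.append((chain.role, res.key, a))
                        ords.append(ordinal)
                        codes.append(code)
                ordinal += 1
        return cls(keys, np.array(ords), np.array(codes))

    def coords_of(self, fv: FvStructure) -> np.ndarray:
        return fv.all_coords(ALL_ATOMS)


def _local_similarity(nc: NumberedChain, template_chain: NumberedChain,
                      window: int = SIMILARITY_WINDOW) -> np.ndarray:
    """Per-residue local similarity of target vs template: fraction of
    positions in a +/-window residue window with positive BLOSUM62 score
    (template-absent positions count as non-positive)."""
    tmap = {r.key: r.amino_acid for r in template_chain.residues}
    n = len(nc.residues)
    pos = np.zeros(n)
    for i, r in enumerate(nc.residues):
        other = tmap.get(r.key)
        if other is not None and BLOSUM62[r.amino_acid, other] > 0:
            pos[i] = 1.0
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = pos[lo:hi].mean()
    return out


class RestraintSystem:
    """Additive Gaussian-well distance restraints plus covalent-geometry
    harmonics, with analytic gradients and an optional frozen-atom mask."""

    def __init__(self, table: AtomTable, well_d: np.ndarray, well_w: np.ndarray,
                 pairs: np.ndarray, bonds: np.ndarray, bond_d0: np.ndarray,
                 sigma: float = WELL_SIGMA):
        self.table = table
        self.pairs = pairs            # (n_pairs, 2) atom indices
        self.well_d = well_d          # (n_pairs, n_templates), nan = absent
        self.well_w = well_w          # weights, rows normalized, 0 where absent
        self.bonds = bonds            # (n_bonds, 2)
        self.bond_d0 = bond_d0
        self.sigma = sigma

    def energy_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        g = np.zeros_like(coords)
        e = 0.0
        if len(self.pairs):
            vi = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
            d = np.linalg.norm(vi, axis=1)
            dd = d[:, None] - self.well_d                      # nan-safe below
            z = np.where(np.isnan(dd), 0.0, dd)
            gauss = self.well_w * np.exp(-z * z / (2 * self.sigma ** 2))
            gauss = np.where(np.isnan(dd), 0.0, gauss)
            e -= float(gauss.sum())
            dEdd = (gauss * z).sum(axis=1) / self.sigma ** 2
            unit = vi / np.maximum(d, 1e-9)[:, None]
            f = dEdd[:, None] * unit
            np.add.at(g, self.pairs[:, 0], f)
            np.add.at(g, self.pairs[:, 1], -f)
        if len(self.bonds):
            vb = coords[self.bonds[:, 0]] - coords[self.bonds[:, 1]]
            db = np.linalg.norm(vb, axis=1)
            diff = db - self.bond_d0
            e += float(BOND_K * (diff ** 2).sum())
            fb = (2 * BOND_K * diff / np.maximum(db, 1e-9))[:, None] * vb
            np.add.at(g, self.bonds[:, 0], fb)
            np.add.at(g, self.bonds[:, 1], -fb)
        return e, g

    def minimize(self, coords: np.ndarray, free_mask: np.ndarray | None = None,
                 maxiter: int = 300) -> tuple[np.ndarray, float]:
        coords = coords.copy()
        if free_mask is None:
            free_mask = np.ones(len(coords), dtype=bool)
        free_idx = np.where(free_mask)[0]

        def fun(x):
            coords[free_idx] = x.reshape(-1, 3)
            e, g = self.energy_grad(coords)
            return e, g[free_idx].ravel()

        res = _scipy_minimize(fun, coords[free_idx].ravel(), jac=True,
                              method="L-BFGS-B",
                              options={"maxiter": maxiter, "ftol": 1e-12,
                                       "gtol": 1e-8})
        coords[free_idx] = res.x.reshape(-1, 3)
        e, _ = self.energy_grad(coords)
        return coords, float(e)


def _template_coords(table: AtomTable, target: dict[str, NumberedChain],
                     template: TemplateRecord) -> np.ndarray:
    """Template coordinates at the table's scheme-aligned atom slots (nan
    where the template lacks the position/atom)."""
    out = np.full((len(table.keys), 3), np.nan)
    for role in ("light", "heavy"):
        idx = template.structure.chain(role).index()
        for i, (r, key, a) in enumerate(table.keys):
            if r != role:
                continue
            res = idx.get(key)
            if res is not None and a in res.atoms:
                out[i] = res.atoms[a]
    return out


def _bond_pairs(table: AtomTable, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covalent-geometry pairs (intra-residue and peptide-link distances) with
    equilibrium values taken from the reference coordinates."""
    by_res: dict[tuple[int, int], dict[str, int]] = {}
    for i, (role, key, a) in enumerate(table.keys):
        rid = (table.chain_code[i], table.res_ordinal[i])
        by_res.setdefault(rid, {})[a] = i
    pairs = []
    ordered = sorted(by_res)
    for rid in ordered:
        atoms = by_res[rid]
        names = [n for n in ALL_ATOMS if n in atoms]
        for x in range(len(names)):
            for y in range(x + 1, len(names)):
                pairs.append((atoms[names[x]], atoms[names[y]]))
        nxt = (rid[0], rid[1] + 1)
        if nxt in by_res:
            nxt_atoms = by_res[nxt]
            for a, b in (("C", "N"), ("CA", "N"), ("C", "CA"), ("O", "N")):
                if a in atoms and b in nxt_atoms:
                    pairs.append((atoms[a], nxt_atoms[b]))
    bonds = np.array(pairs, dtype=int)
    d0 = np.linalg.norm(reference[bonds[:, 0]] - reference[bonds[:, 1]], axis=1)
    return bonds, d0


def build_restraints(start: FvStructure, target: dict[str, NumberedChain],
                     templates: list[TemplateRecord],
                     cutoff: float = RESTRAINT_CUTOFF) -> tuple[RestraintSystem, AtomTable]:
    """Restraint system over the starting structure's atoms from one or more
    templates: a pair is restrained when within ``cutoff`` in any template and
    at sequence separation >= 2 (inter-chain pairs always qualify)."""
    table = AtomTable.from_structure(start)
    tcoords = [_template_coords(table, target, t) for t in templates]
    # candidate pairs: within cutoff in any template
    pair_set: set[tuple[int, int]] = set()
    for tc in tcoords:
        valid = ~np.isnan(tc[:, 0])
        idx = np.where(valid)[0]
        tree = cKDTree(tc[idx])
        for a, b in tree.query_pairs(cutoff):
            i, j = int(idx[a]), int(idx[b])
            same_chain = table.chain_code[i] == table.chain_code[j]
            if same_chain and abs(int(table.res_ordinal[i]) - int(table.res_ordinal[j])) < MIN_SEQ_SEPARATION:
                continue
            pair_set.add((min(i, j), max(i, j)))
    pairs = np.array(sorted(pair_set), dtype=int).reshape(-1, 2)
    n_pairs, n_t = len(pairs), len(templates)
    well_d = np.full((n_pairs, n_t), np.nan)
    well_w = np.zeros((n_pairs, n_t))
    # per-template local similarity per residue ordinal
    sim: list[np.ndarray] = []
    for t in templates:
        per_role = {role: _local_similarity(target[role], t.numbered[role])
                    for role in ("light", "heavy")}
        flat = np.concatenate([per_role["light"], per_role["heavy"]])
        sim.append(flat)
    for k, tc in enumerate(tcoords):
        if n_pairs == 0:
            break
        di = tc[pairs[:, 0]]
        dj = tc[pairs[:, 1]]
        d = np.linalg.norm(di - dj, axis=1)
        ok = ~np.isnan(d)
        well_d[ok, k] = d[ok]
        w = (sim[k][table.res_ordinal[pairs[:, 0]]] +
             sim[k][table.res_ordinal[pairs[:, 1]]]) / 2.0
        well_w[ok, k] = w[ok]
    # normalize weights across templates per pair
    tot = well_w.sum(axis=1, keepdims=True)
    has = tot[:, 0] > 0
    well_w[has] /= tot[has]
    absent = np.isnan(well_d)
    some = (~absent).any(axis=1) & ~has
    if some.any():   # all-zero similarity: fall back to equal weights
        eq = (~absent[some]).astype(float)
        well_w[some] = eq / eq.sum(axis=1, keepdims=True)
    start_coords = table.coords_of(start)
    bonds, d0 = _bond_pairs(table, start_coords)
    return RestraintSystem(table, well_d, well_w, pairs, bonds, d0), table


# ---------------------------------------------------------------------------
# model quality

def count_clashes(fv: FvStructure) -> int:
    """Non-bonded atom pairs (sequence separation >= 2 or inter-chain) closer
    than the clash distance."""
    table = AtomTable.from_structure(fv)
    coords = table.coords_of(fv)
    tree = cKDTree(coords)
    n = 0
    for a, b in tree.query_pairs(CLASH_DISTANCE):
        same = table.chain_code[a] == table.chain_code[b]
        if same and abs(int(table.res_ordinal[a]) - int(table.res_ordinal[b])) < MIN_SEQ_SEPARATION:
            continue
        n += 1
    return n


def omega_outliers(fv: FvStructure, tolerance: float = 30.0) -> int:
    """Peptide omega torsions further than ``tolerance`` degrees from planar
    (trans 180 or cis 0)."""
    n = 0
    for chain in fv.chains():
        for a, b in zip(chain.residues, chain.residues[1:]):
            try:
                om = geom.dihedral(a.atoms["CA"], a.atoms["C"], b.atoms["N"], b.atoms["CA"])
            except KeyError:
                continue
            dev = min(abs(abs(om) - 180.0), abs(om))
            if dev > tolerance:
                n += 1
    return n


def model_score(model: FvModel) -> float:
    """Build score: restraint energy plus clash and torsion penalties."""
    e = model.restraint_energy if model.restraint_energy is not None else 0.0
    return (e + CLASH_PENALTY * count_clashes(model.structure)
            + OMEGA_PENALTY * omega_outliers(model.structure))


def rank_models(models: list[FvModel]) -> FvModel:
    """Best model by build score, deterministic with model_id tiebreak."""
    if not models:
        raise BuildError("rank_models requires at least one model")
    return min(models, key=lambda m: (model_score(m), m.model_id))


# ---------------------------------------------------------------------------
# build strategies

def _generate_conformers(start: FvStructure, system: RestraintSystem,
                         target: dict[str, NumberedChain], method: str,
                         templates: list[str], provenance: dict[str, list[str]],
                         n_models: int, seed: int,
                         warnings: list[str]) -> list[FvModel]:
    rng = np.random.default_rng(seed)
    coords0 = start.all_coords(ALL_ATOMS)
    out = []
    for m in range(n_models):
        x0 = coords0 + rng.normal(scale=CONFORMER_SIGMA, size=coords0.shape)
        xmin, e = system.minimize(x0)
        fv = start.copy()
        fv.set_all_coords(xmin, ALL_ATOMS)
        out.append(FvModel(
            structure=fv, target_numbered=target, build_method=method,
            framework_templates=list(templates),
            per_region_provenance=dict(provenance),
            restraint_energy=e, model_id=f"m{m}", warnings=list(warnings)))
    return out


def build_single_model(target: dict[str, NumberedChain], template: TemplateRecord,
                       n_models: int = 1, seed: int = 0) -> list[FvModel]:
    """Model from a single whole-Fv framework template."""
    start, warnings = thread_template(target, template)
    system, _ = build_restraints(start, target, [template])
    prov = {r: [template.template_id] for r in ("FR", "L1", "L2", "L3", "H1", "H2", "H3")}
    return _generate_conformers(start, system, target, "single",
                                [template.template_id], prov, n_models, seed, warnings)


def _superpose_domain(mobile: ChainStructure, onto: ChainStructure,
                      numbered: NumberedChain, role: str) -> ChainStructure:
    """Rigidly superpose a threaded domain onto the matching domain of the
    interface template via shared framework backbone positions."""
    fr_keys = [r.key for r in numbered.residues if r.region.startswith("FR")]
    onto_idx = onto.index()
    mob_idx = mobile.index()
    shared = [k for k in fr_keys if k in onto_idx and k in mob_idx
              and onto_idx[k].has_backbone() and mob_idx[k].has_backbone()]
    if len(shared) < MIN_SHARED_CORE:
        raise BuildError(
            f"superposition failure: only {len(shared)} shared framework "
            f"positions for the {role} domain")
    P = mobile.coords(("N", "CA", "C"), keys=shared)
    Q = onto.coords(("N", "CA", "C"), keys=shared)
    R, t, _ = geom.kabsch(P, Q)
    moved = mobile.copy()
    for res in moved.residues:
        for a in res.atoms:
            res.atoms[a] = R @ res.atoms[a] + t
    return moved


def build_chimeric_model(target: dict[str, NumberedChain],
                         light_template: TemplateRecord,
                         heavy_template: TemplateRecord,
                         interface_template: TemplateRecord,
                         n_models: int = 1, seed: int = 0) -> list[FvModel]:
    """Model from separate light and heavy donors oriented by a whole-Fv
    interface template."""
    warnings: list[str] = []
    lt, w1 = thread_template(target, light_template, roles=("light", "heavy"))
    ht, w2 = thread_template(target, heavy_template, roles=("light", "heavy"))
    warnings += w1 + w2
    light = _superpose_domain(lt.light, interface_template.structure.light,
                              target["light"], "light")
    heavy = _superpose_domain(ht.heavy, interface_template.structure.heavy,
                              target["heavy"], "heavy")
    start = FvStructure(light, heavy, {"id": "chimeric_start"})
    # restraints from the assembled chimera itself (distances of the start)
    chimera = TemplateRecord(
        template_id="__chimera__", structure=start.copy(),
        numbered=target, cdrs={}, canonical={},
        organism="synthetic", resolution=None)
    system, _ = build_restraints(start, target, [chimera])
    prov = {"FR": [light_template.template_id, heavy_template.template_id,
                   interface_template.template_id]}
    return _generate_conformers(
        start, system, target, "chimeric",
        [light_template.template_id, heavy_template.template_id,
         interface_template.template_id], prov, n_models, seed, warnings)


def build_top5_model(target: dict[str, NumberedChain],
                     templates: list[TemplateRecord],
                     n_models: int = 1, seed: int = 0) -> list[FvModel]:
    """Model from up to five framework templates simultaneously with additive
    per-template distance wells weighted by local sequence similarity."""
    if not templates:
        raise BuildError("top5 build requires at least one template")
    if len(templates) > 5:
        raise BuildError("top5 build accepts at most five templates")
    start, warnings = thread_template(target, templates[0])
    system, _ = build_restraints(start, target, templates)
    ids = [t.template_id for t in templates]
    prov = {r: list(ids) for r in ("FR", "L1", "L2", "L3", "H1", "H2", "H3")}
    return _generate_conformers(start, system, target, "top5", ids, prov,
                                n_models, seed, warnings)
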