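"""Desk-scale validation campaigns on synthetic fixtures with planted ground
truth.

The full-size validation of this kind of pipeline compares predictions against
deposited crystal structures; at desk scale the same machinery is exercised
against the fixture generator instead, where the truth (self templates,
planted rotations, planted identity orderings, noise levels) is known exactly.
Every function here recomputes its quantity from scratch by running the
production code paths.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .assess import (assess_pair, paired_t_test, superpose_core,
                     region_carbonyl_rmsd, tilt_angle_deviation,
                     tukey_box_stats)
from .build import build_single_model, build_top5_model, rank_models
from .db import TemplateDatabase, ingest_structure
from .loops import CDR_ORDER, find_loop_templates, graft_and_model_loop, \
    rank_loop_templates, LoopTemplate
from .numbering import extract_cdrs
from .pipeline import RunConfig, predict_structure
from .search import (AlignmentScore, SearchOptions, TemplateHit,
                     search_framework_templates, top5_window_filter)

# Framework positions safe for dissimilar substitutions: outside every CDR and
# away from canonical-constraint sites (2, 48, 64, 71).
_CDR_POSITIONS = {
    "light": set(range(24, 35)) | set(range(50, 53)) | set(range(89, 98)),
    "heavy": set(range(26, 33)) | set(range(52, 56)) | set(range(95, 103)),
}
_PROTECTED = {2, 48, 64, 71}


def _fw_positions(role: str, n_base: int) -> list[int]:
    return [p for p in range(3, n_base + 1)
            if p not in _CDR_POSITIONS[role] and p not in _PROTECTED]


def dissimilar_substitutions(rng: np.random.Generator, n_light: int,
                             n_heavy: int) -> list[tuple[str, int, str]]:
    """Random framework substitutions that are BLOSUM62-dissimilar to the
    reference residue, so similarity ranking follows substitution count."""
    from .numbering import REFERENCE_PROFILES
    subs = []
    for role, n_sub, ref, n_base in (("light", n_light,
                                      REFERENCE_PROFILES["kappa"], 107),
                                     ("heavy", n_heavy,
                                      REFERENCE_PROFILES["heavy"], 113)):
        pool = _fw_positions(role, n_base)
        picks = rng.choice(len(pool), size=n_sub, replace=False)
        for i in picks:
            pos = pool[int(i)]
            old = ref[pos - 1]
            subs.append((role, pos, "W" if old not in "WFY" else "D"))
    return subs


# ---------------------------------------------------------------------------
# self-recovery through the full pipeline

def self_recovery_metrics(seed: int, n_models: int = 2) -> dict[str, float]:
    """Predict a fixture target whose own structure is the only
    within-window entry of the database; report framework and worst-loop
    carbonyl RMSD against the deposited fixture coordinates."""
    base_spec = synth.ScaffoldSpec(name="TGT", seed=seed)
    base, numbered = synth.make_synthetic_fv(base_spec)
    rng = np.random.default_rng(seed)

    db = TemplateDatabase()
    self_rec = ingest_structure(base, organism="human", resolution=1.8).records[0]
    self_rec.template_id = "TGT_LH"
    db.add(self_rec)
    # decoys: >10 similarity points away and with unmatched loop lengths
    decoy_lengths = {"L1": 7, "L2": 2, "L3": 8, "H1": 8, "H2": 3, "H3": 10}
    for k in range(2):
        decoy_fv, decoy_nc = synth.make_synthetic_fv(
            synth.ScaffoldSpec(name=f"DEC{k}", cdr_lengths=decoy_lengths,
                               seed=seed + k + 1))
        far, _ = synth.perturb_structure(
            decoy_fv, decoy_nc,
            synth.PerturbationSpec(
                substitutions=dissimilar_substitutions(rng, 14, 14),
                framework_noise_sigma=0.3, seed=seed + 10 + k))
        rec = ingest_structure(far, organism="human",
                               resolution=2.5 + 0.1 * k).records[0]
        rec.template_id = f"DEC{k}_LH"
        db.add(rec)

    cfg = RunConfig(n_framework_models=n_models, n_cdr_models=n_models,
                    seed=seed)
    res = predict_structure(base.light.sequence(), base.heavy.sequence(), db,
                            cfg, target_id="TGT")
    assert res.status == "success", res.message
    result = assess_pair(res.model.structure, base)
    loops = [result.region_rmsd[lab] for lab in CDR_ORDER]
    return {
        "fr_rmsd": result.region_rmsd["FR"],
        "max_loop_rmsd": max(loops),
        "fv_rmsd": result.region_rmsd["FV"],
        "tilt": result.tilt_deviation,
        "framework_templates": res.model.framework_templates,
    }


# ---------------------------------------------------------------------------
# planted-rotation recovery

def rotation_recovery_errors(seed: int,
                             angles=(3.0, 5.0, 7.0, 9.0, 12.0, 15.0)
                             ) -> list[float]:
    base, numbered = synth.make_synthetic_fv(synth.ScaffoldSpec(seed=seed))
    errors = []
    for k, angle in enumerate(angles):
        rotated, _ = synth.perturb_structure(
            base, numbered,
            synth.PerturbationSpec(domain_rotation=float(angle), seed=seed + k))
        errors.append(abs(tilt_angle_deviation(base, rotated) - angle))
    return errors


# ---------------------------------------------------------------------------
# planted-identity search recovery

def search_rank_recovery(seed: int, n_databases: int = 20,
                         n_entries: int = 5) -> float:
    """Fraction of randomized databases for which the framework-search ranking
    equals the planted substitution-count order."""
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_databases):
        counts = sorted(rng.choice(np.arange(0, 16), size=n_entries,
                                   replace=False))
        spec = synth.ScaffoldSpec(name="BASE", seed=seed)
        perts = []
        for k, c in enumerate(counts):
            subs = dissimilar_substitutions(rng, int(c), int(c))
            perts.append((f"T{k}_LH",
                          synth.PerturbationSpec(substitutions=subs,
                                                 seed=seed + 31 * rep + k),
                          "human", 2.0))
        db, truth = synth.make_synthetic_database(spec, perts)
        base, numbered = synth.make_synthetic_fv(spec)
        ranked = search_framework_templates(
            numbered, db, SearchOptions(top_n=n_entries))["fv"]
        got = [h.template_id for h in ranked]
        want = list(truth.sort_values("n_substitutions").template_id)
        hits += int(got == want)
    return hits / n_databases


# ---------------------------------------------------------------------------
# rule oracles

def window_rule_agreement(seed: int, n_vectors: int = 1000) -> float:
    """Agreement of the Top5 similarity-window filter with direct rule
    evaluation on random similarity vectors."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 9))
        sims = np.sort(rng.uniform(40, 100, size=n))[::-1]
        window = float(rng.uniform(0, 25))
        hits = [TemplateHit(f"T{i}", AlignmentScore(float(s), float(s), 100, "fv"),
                            "x", 2.0) for i, s in enumerate(sims)]
        kept = [h.template_id for h in top5_window_filter(hits, window)]
        oracle = [h.template_id for h in hits
                  if sims[0] - h.similarity <= window + 1e-9]
        ok += int(kept == oracle)
    return ok / n_vectors


def loop_ranking_agreement(seed: int, n_sets: int = 1000) -> float:
    """Agreement of loop-template ranking with an exhaustive sort oracle on
    random candidate sets."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_sets):
        n = int(rng.integers(1, 9))
        cands = [
            LoopTemplate(template_id=f"T{i}", cdr_label="L1", loop_sequence="X",
                         canonical_class="none",
                         loop_score=float(rng.integers(-10, 20)),
                         cross_loop_score=float(rng.integers(0, 12)),
                         resolution=float(rng.choice([1.2, 1.8, 2.4, 3.0])))
            for i in range(n)]
        mode = "tiered" if rng.integers(2) else "blended"
        got = [t.template_id
               for t in rank_loop_templates(cands, n_templates=n,
                                            ranking_mode=mode).templates]
        oracle = [t.template_id for t in sorted(cands,
                                                key=lambda c: c.sort_key(mode))]
        ok += int(got == oracle)
    return ok / n_sets


def _tukey_oracle(values):
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(q):   # linear interpolation, independent implementation
        h = q * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    lo_b, hi_b = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [x for x in v if lo_b <= x <= hi_b]
    outliers = [x for x in v if x < lo_b or x > hi_b]
    return q1, med, q3, min(inside), max(inside), outliers


def stats_oracle_agreement(seed: int, n_samples: int = 100) -> float:
    """Agreement of Tukey box statistics and the paired t-test with
    closed-form / hand-computed oracles on random samples."""
    import scipy.stats as sps
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_samples):
        n = int(rng.integers(3, 40))
        vals = rng.normal(size=n) * rng.uniform(0.5, 3) + rng.uniform(-2, 2)
        if rng.integers(4) == 0:       # plant a gross outlier sometimes
            vals[0] += 50.0
        bs = tukey_box_stats(vals)
        q1, med, q3, wlo, whi, outl = _tukey_oracle(vals)
        good = (np.isclose(bs.q1, q1) and np.isclose(bs.median, med)
                and np.isclose(bs.q3, q3) and np.isclose(bs.whisker_low, wlo)
                and np.isclose(bs.whisker_high, whi)
                and np.allclose(bs.outliers, outl))
        a = rng.normal(size=n)
        b = a + rng.normal(scale=1.0, size=n) + rng.uniform(-1, 1)
        d = b - a
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p_oracle = 2 * sps.t.sf(abs(t), n - 1)
        good = good and np.isclose(paired_t_test(b, a), p_oracle)
        ok += int(good)
    return ok / n_samples


# ---------------------------------------------------------------------------
# grafting never perturbs the framework

def graft_framework_displacement(seed: int, n_grafts: int = 50) -> float:
    """Maximum framework-atom displacement over repeated grafts (bitwise-zero
    by contract)."""
    base, numbered = synth.make_synthetic_fv(synth.ScaffoldSpec(seed=seed))
    rec = ingest_structure(base, resolution=1.8).records[0]
    rec.template_id = "SELF_LH"
    db = TemplateDatabase()
    db.add(rec)
    framework = build_single_model(numbered, rec, n_models=1, seed=seed)[0]
    target_cdrs = {}
    for role in ("light", "heavy"):
        for c in extract_cdrs(numbered[role]):
            target_cdrs[c.label] = c
    loop_atom_keys = {(("heavy" if lab.startswith("H") else "light"), key)
                      for lab, c in target_cdrs.items() for key in c.positions}
    from .build import AtomTable
    table = AtomTable.from_structure(framework.structure)
    fw_mask = np.array([(r, k) not in loop_atom_keys
                        for (r, k, _a) in table.keys])
    before = framework.structure.all_coords()[fw_mask]
    worst = 0.0
    for g in range(n_grafts):
        label = CDR_ORDER[g % 6]
        cands = find_loop_templates(target_cdrs[label], db,
                                    canonical_filter=False,
                                    target_cdrs=target_cdrs)
        ranking = rank_loop_templates(cands, n_templates=3)
        model = graft_and_model_loop(framework, target_cdrs[label], ranking,
                                     n_loop_models=1, seed=seed + g)
        after = model.structure.all_coords()[fw_mask]
        disp = 0.0 if np.array_equal(before, after) else float(
            np.abs(after - before).max())
        worst = max(worst, disp)
    return worst


# ---------------------------------------------------------------------------
# scaled-down method comparison (Top5 vs Single)

def method_comparison_campaign(seed: int, n_targets: int = 20,
                               noise_sigma: float = 0.6
                               ) -> dict[str, object]:
    """Framework accuracy of Top5 vs Single on targets whose databases hold
    five noisy copies of the truth: the multi-template build averages
    independent template errors and should beat the best single template."""
    rng = np.random.default_rng(seed)
    singles, top5s = [], []
    for t in range(n_targets):
        spec = synth.ScaffoldSpec(name=f"C{t}", seed=seed + t)
        base, numbered = synth.make_synthetic_fv(spec)
        perts = []
        for k in range(5):
            subs = dissimilar_substitutions(rng, k, k)   # similarity spread
            perts.append((f"C{t}T{k}_LH",
                          synth.PerturbationSpec(
                              substitutions=subs,
                              framework_noise_sigma=noise_sigma,
                              seed=seed + 977 * t + k),
                          "human", 1.8 + 0.2 * k))
        db, _ = synth.make_synthetic_database(spec, perts)
        hits = search_framework_templates(numbered, db)["fv"]
        retained = top5_window_filter(hits, 10.0)
        records = [db.get(h.template_id) for h in retained]

        single = rank_models(build_single_model(numbered, records[0],
                                                n_models=1, seed=seed + t))
        multi = rank_models(build_top5_model(numbered, records,
                                             n_models=1, seed=seed + t))
        for model, sink in ((single, singles), (multi, top5s)):
            sup = superpose_core(model.structure, base)
            val, _flag = region_carbonyl_rmsd(model.structure, base, sup, "FR")
            sink.append(val)
    return {
        "single_fr_rmsds": singles,
        "top5_fr_rmsds": top5s,
        "single_mean": float(np.mean(singles)),
        "top5_mean": float(np.mean(top5s)),
        "n_targets": n_targets,
        "p_value": paired_t_test(singles, top5s),
    }
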