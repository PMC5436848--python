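"""Model assessment in the AMA-II style: β-sheet-core superposition, per-region
peptide-carbonyl RMSD, VL–VH tilt-angle deviation, and summary statistics.

Predicted/experimental pairs are superposed once over backbone atoms of a
fixed, configurable set of conserved Chothia framework positions (the β-sheet
core); per-region RMSDs are then computed over the C and O atoms of the
region's residues at scheme-matched positions without refitting.  Carbonyl
atoms are used because they expose peptide-plane flips that Cα-only RMSDs
hide.  The tilt angle is the relative VL→VH orientation from principal-axes
domain frames; the reported quantity is the *deviation* between the two
structures' relative orientations, which is invariant to independent global
rigid motions of either structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import geometry as geom
from .numbering import get_scheme
from .structure import ChainStructure, FvStructure

# Conserved beta-sheet framework core, Chothia positions per domain.
CORE_POSITIONS = {
    "light": [3, 4, 5, 6, 7, 18, 19, 20, 21, 22, 35, 36, 37, 38, 44, 45, 46,
              47, 48, 61, 62, 63, 70, 71, 72, 73, 74, 84, 85, 86, 87, 88,
              98, 99, 100, 101, 102],
    "heavy": [3, 4, 5, 6, 7, 18, 19, 20, 21, 22, 34, 35, 36, 37, 38, 45, 46,
              47, 48, 49, 57, 58, 68, 69, 70, 71, 72, 78, 79, 80, 81, 82,
              90, 91, 92, 93, 94, 103, 104, 105, 106, 107],
}
MIN_CORE_POSITIONS = 20

REGIONS = ("FR", "L1", "L2", "L3", "H1", "H2", "H3", "FV")


class AssessmentError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    core_positions_used: list[tuple[str, int]]
    core_rmsd: float

    def __post_init__(self):
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise AssessmentError("superposition must be a proper rotation")


@dataclass
class AssessmentResult:
    region_rmsd: dict[str, float]
    tilt_deviation: float
    scheme_used_for_cdrs: str = "chothia"
    flags: dict[str, str] = field(default_factory=dict)


def _region_of(role: str, position: int) -> str:
    """Chothia region label of a scheme position (kappa/lambda share bounds)."""
    scheme = get_scheme("chothia", "heavy" if role == "heavy" else "kappa")
    prefix = "H" if role == "heavy" else "L"
    for r in scheme.regions:
        lo = r.label_start
        hi = r.label_start + (r.end - r.start)
        if lo <= position <= hi:
            if r.region.startswith("CDR"):
                return f"{prefix}{r.region[-1]}"
            return "FR"
    return "FR"   # labels past FR4 end (C-terminal insertions)


def _shared_keys(a: ChainStructure, b: ChainStructure, atoms=("N", "CA", "C")):
    ia, ib = a.index(), b.index()
    out = []
    for k in sorted(set(ia) & set(ib)):
        if all(at in ia[k].atoms for at in atoms) and all(at in ib[k].atoms for at in atoms):
            out.append(k)
    return out


def superpose_core(predicted: FvStructure, experimental: FvStructure,
                   core_positions: dict[str, list[int]] | None = None
                   ) -> SuperpositionResult:
    """Least-squares rigid superposition of the predicted structure onto the
    experimental one over backbone atoms of the shared β-sheet core."""
    core_positions = core_positions or CORE_POSITIONS
    used: list[tuple[str, int]] = []
    P_rows, Q_rows = [], []
    for role in ("light", "heavy"):
        cp = predicted.chain(role)
        ce = experimental.chain(role)
        wanted = {(p, "") for p in core_positions[role]}
        keys = [k for k in _shared_keys(cp, ce) if k in wanted]
        used.extend((role, k[0]) for k in keys)
        P_rows.append(cp.coords(("N", "CA", "C"), keys=keys))
        Q_rows.append(ce.coords(("N", "CA", "C"), keys=keys))
    if len(used) < MIN_CORE_POSITIONS:
        raise AssessmentError(
            f"only {len(used)} shared core positions; need >= {MIN_CORE_POSITIONS}")
    P = np.vstack(P_rows)
    Q = np.vstack(Q_rows)
    R, t, rms = geom.kabsch(P, Q)
    return SuperpositionResult(R, t, used, rms)


def region_carbonyl_rmsd(predicted: FvStructure, experimental: FvStructure,
                         superposition: SuperpositionResult,
                         region: str) -> tuple[float, str | None]:
    """Carbonyl (C, O) RMSD of one region under the core superposition (never
    refit per region).  Returns (rmsd, flag); the flag marks regions that are
    incomplete in either structure, for exclusion from summaries."""
    if region not in REGIONS:
        raise AssessmentError(f"unknown region {region!r}")
    P_rows, Q_rows = [], []
    flag = None
    for role in ("light", "heavy"):
        cp = predicted.chain(role)
        ce = experimental.chain(role)
        ip, ie = cp.index(), ce.index()
        all_keys = sorted(set(ip) | set(ie))

        def in_region(key):
            reg = _region_of(role, key[0])
            if region == "FV":
                return True
            if region == "FR":
                return reg == "FR"
            return reg == region

        wanted = [k for k in all_keys if in_region(k)]
        for k in wanted:
            a, b = ip.get(k), ie.get(k)
            if a is None or b is None or "C" not in a.atoms or "C" not in b.atoms \
                    or "O" not in a.atoms or "O" not in b.atoms:
                flag = f"{region} incomplete at {role} {k[0]}{k[1]}"
                continue
            P_rows.append(a.atoms["C"]); Q_rows.append(b.atoms["C"])
            P_rows.append(a.atoms["O"]); Q_rows.append(b.atoms["O"])
    if not P_rows:
        raise AssessmentError(f"region {region} empty in the pair")
    P = geom.apply_rigid(np.array(P_rows), superposition.rotation,
                         superposition.translation)
    return geom.rmsd(P, np.array(Q_rows)), flag


def _relative_orientation(fv: FvStructure,
                          core_positions: dict[str, list[int]]) -> np.ndarray:
    frames = {}
    for role in ("light", "heavy"):
        chain = fv.chain(role)
        idx = chain.index()
        keys = [(p, "") for p in core_positions[role] if (p, "") in idx]
        coords = chain.coords(("N", "CA", "C"), keys=keys)
        if len(coords) < 3 * MIN_CORE_POSITIONS // 2:
            raise AssessmentError(f"too few core positions in {role} domain")
        frames[role] = geom.domain_frame(coords)
    return frames["light"].T @ frames["heavy"]


def tilt_angle_deviation(predicted: FvStructure, experimental: FvStructure,
                         core_positions: dict[str, list[int]] | None = None
                         ) -> float:
    """Deviation (degrees) between the two structures' VL→VH relative
    orientations; 0 for identical structures, invariant to global rigid
    motions of either member of the pair."""
    core_positions = core_positions or CORE_POSITIONS
    Rp = _relative_orientation(predicted, core_positions)
    Re = _relative_orientation(experimental, core_positions)
    return geom.rotation_angle(Rp @ Re.T)


def assess_pair(predicted: FvStructure, experimental: FvStructure,
                core_positions: dict[str, list[int]] | None = None
                ) -> AssessmentResult:
    """Full per-pair assessment: core superposition, per-region carbonyl
    RMSDs and tilt deviation."""
    sup = superpose_core(predicted, experimental, core_positions)
    rmsds: dict[str, float] = {}
    flags: dict[str, str] = {}
    for region in REGIONS:
        try:
            val, flag = region_carbonyl_rmsd(predicted, experimental, sup, region)
        except AssessmentError:
            flags[region] = "region missing"
            continue
        rmsds[region] = val
        if flag:
            flags[region] = flag
    tilt = tilt_angle_deviation(predicted, experimental, core_positions)
    return AssessmentResult(rmsds, tilt, "chothia", flags)


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class BoxStats:
    q1: float
    median: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def tukey_box_stats(values) -> BoxStats:
    """Tukey box-plot statistics: quartiles by linear interpolation, whiskers
    at 1.5×IQR beyond the quartiles clipped to the data range, and outliers
    beyond the whiskers."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise AssessmentError("tukey_box_stats requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_bound = q1 - 1.5 * iqr
    hi_bound = q3 + 1.5 * iqr
    inside = v[(v >= lo_bound) & (v <= hi_bound)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = sorted(float(x) for x in v[(v < lo_bound) | (v > hi_bound)])
    return BoxStats(float(q1), float(med), float(q3), float(v.mean()),
                    whisker_low, whisker_high, outliers)


def paired_t_test(values_a, values_b) -> float:
    """Two-sided paired t-test p-value.  Identical samples give p = 1; a
    constant non-zero shift (zero difference variance) is an error rather
    than p = 0."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise AssessmentError("paired test needs equal-length samples, n >= 2")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 1.0
        raise AssessmentError("zero variance of paired differences")
    return float(sps.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# per-target results tables

RESULTS_COLUMNS = ["target", "method", "FR", "L1", "L2", "L3", "H1", "H2", "H3",
                   "FV", "tilt", "fw_similarity", "templates"]


def results_row(target: str, method: str, result: AssessmentResult,
                fw_similarity: float, templates: list[str]) -> dict:
    row = {"target": target, "method": method,
           "tilt": result.tilt_deviation,
           "fw_similarity": fw_similarity,
           "templates": ",".join(templates)}
    for region in REGIONS:
        row[region] = result.region_rmsd.get(region, np.nan)
    return row


def write_results_table(rows: list[dict], path: str) -> None:
    pd.DataFrame(rows, columns=RESULTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def similarity_binned_stats(table: pd.DataFrame, metric: str = "FR",
                            threshold: float = 85.0) -> pd.DataFrame:
    """Mean/median/75th-percentile of a metric for targets with best-template
    similarity below vs above a threshold."""
    out = []
    for name, sub in (("<%g%%" % threshold, table[table.fw_similarity < threshold]),
                      (">%g%%" % threshold, table[table.fw_similarity >= threshold])):
        vals = sub[metric].dropna()
        if len(vals) == 0:
            continue
        out.append({
            "bin": name, "number": len(vals), "mean": vals.mean(),
            "median": vals.median(), "p75": vals.quantile(0.75),
        })
    return pd.DataFrame(out)


def length_similarity_heatmap(table: pd.DataFrame, length_col: str,
                              similarity_col: str, metric: str,
                              sim_bins=(0, 50, 70, 85, 95, 100.0001)
                              ) -> pd.DataFrame:
    """Mean metric in loop-length × similarity-bin cells (heat-map input)."""
    t = table.copy()
    t["_simbin"] = pd.cut(t[similarity_col], bins=list(sim_bins), right=False)
    return t.pivot_table(index=length_col, columns="_simbin", values=metric,
                         aggfunc="mean", observed=True)
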