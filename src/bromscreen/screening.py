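"""Targeted compound identification and untargeted bromine-compound discovery.

Targeted screening follows the accurate-mass workflow for suspect
contaminants in full-scan HRMS: a compound is confirmed only when its
quantifier isotopologue elutes at the expected retention time with
adequate S/N, the qualifier isotopologue co-elutes, the qualifier/quantifier
area ratio agrees with the predicted isotope envelope, and the observed
m/z is within the ppm gate (default 5 ppm). Every failed criterion is
recorded, so rejections are auditable.

Untargeted discovery exploits two properties of polybrominated ions: the
near-2 Da (1.99795 Da) spacing of the ⁷⁹Br/⁸¹Br isotopologues and the
near-binomial envelope shape, plus the systematic decrease of the mass
defect as ⁸¹Br count rises. Candidate elemental compositions for unknowns
come from bounded exhaustive formula decomposition under a ppm tolerance
with an RDBE plausibility filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (AtomicMassTable, IonSpecies, MolecularFormula,
                   ion_mz, parse_formula, ppm_error)
from .isotopes import (BR_SPACING_DA, IsotopeEnvelope, binomial_br_envelope,
                       fine_structure_envelope, envelope_match_score)
from .spectra import CentroidRun, extract_eic, integrate_peak

__all__ = [
    "TargetCompound",
    "DetectionResult",
    "UnknownBrHit",
    "identify_target",
    "discover_br_unknowns",
    "decompose_formula",
    "bioaccumulation_flag",
]


@dataclass(frozen=True)
class TargetCompound:
    """Screening definition of one analyte.

    quantifier_mz / qualifier_mz are theoretical isotopologue m/z values;
    both must belong to the compound's predicted envelope.
    """

    name: str
    neutral_formula: MolecularFormula
    adduct: str
    quantifier_mz: float
    qualifier_mz: float
    expected_rt: float  # minutes
    n_br: int

    def __post_init__(self):
        if self.quantifier_mz == self.qualifier_mz:
            raise ValueError("quantifier and qualifier ions must differ")

    @property
    def ion(self) -> IonSpecies:
        return IonSpecies(self.neutral_formula, self.adduct)

    def predicted_envelope(self, table: AtomicMassTable | None = None,
                           resolution: float = 60000.0) -> IsotopeEnvelope:
        env = fine_structure_envelope(self.ion, table, resolution=resolution)
        # both diagnostic ions must sit on predicted envelope peaks
        env.rel_abundance_at(self.quantifier_mz)
        env.rel_abundance_at(self.qualifier_mz)
        return env


@dataclass
class DetectionResult:
    compound: str
    detected: bool
    apex_rt: float | None = None
    quantifier_area: float = 0.0
    qualifier_area: float = 0.0
    ion_ratio: float | None = None  # qualifier / quantifier
    envelope_score: float | None = None
    mass_error_ppm: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class UnknownBrHit:
    apex_rt: float
    cluster: list[tuple[float, float]]  # observed (m/z, intensity)
    inferred_n_br: int
    candidate_formulas: list[tuple[MolecularFormula, float, float]]  # (formula, ppm, RDBE)

    @property
    def monoisotopic_mz(self) -> float:
        return self.cluster[0][0]


def identify_target(run: CentroidRun, target: TargetCompound,
                    mz_tol_ppm: float = 5.0, rt_tol: float = 0.10,
                    ratio_tol: float = 0.20,
                    table: AtomicMassTable | None = None) -> DetectionResult:
    """Apply the full identification rule to one target in one run.

    Criteria (all must pass; failures are listed in ``flags``):

    * quantifier EIC peak at ``expected_rt ± rt_tol`` with S/N ≥ 3;
    * qualifier peak co-eluting within ``rt_tol / 2`` of the quantifier apex;
    * observed qualifier/quantifier area ratio within ``ratio_tol``
      (relative) of the envelope-predicted abundance ratio;
    * observed quantifier m/z within ``mz_tol_ppm`` of theory.
    """
    for name, val in (("mz_tol_ppm", mz_tol_ppm), ("rt_tol", rt_tol),
                      ("ratio_tol", ratio_tol)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    result = DetectionResult(compound=target.name, detected=False)
    flags = result.flags

    quant_eic = extract_eic(run, target.quantifier_mz, mz_tol_ppm)
    quant_peak = integrate_peak(quant_eic, target.expected_rt, rt_tol)
    if quant_peak is None:
        flags.append("no quantifier peak")
        return result
    result.apex_rt = quant_peak.apex_rt
    result.quantifier_area = quant_peak.area

    qual_eic = extract_eic(run, target.qualifier_mz, mz_tol_ppm)
    qual_peak = integrate_peak(qual_eic, quant_peak.apex_rt, rt_tol / 2.0)
    if qual_peak is None:
        flags.append("qualifier co-elution")
    else:
        result.qualifier_area = qual_peak.area
        result.ion_ratio = qual_peak.area / quant_peak.area
        env = target.predicted_envelope(table)
        expected_ratio = (env.rel_abundance_at(target.qualifier_mz)
                          / env.rel_abundance_at(target.quantifier_mz))
        if abs(result.ion_ratio - expected_ratio) > ratio_tol * expected_ratio:
            flags.append("ion ratio")
        result.envelope_score = _apex_envelope_score(
            run, quant_peak.apex_rt, env, mz_tol_ppm)

    obs_mz = _observed_mz(run, quant_peak.apex_rt, target.quantifier_mz, mz_tol_ppm)
    if obs_mz is None:
        flags.append("no quantifier centroid at apex")
    else:
        result.mass_error_ppm = ppm_error(obs_mz, target.quantifier_mz)
        if result.mass_error_ppm > mz_tol_ppm:
            flags.append("mass error")

    result.detected = not flags
    return result


def _apex_scan(run: CentroidRun, rt: float):
    return run.scans[int(np.argmin(np.abs(run.rts - rt)))]


def _observed_mz(run: CentroidRun, apex_rt: float, center: float,
                 tol_ppm: float) -> float | None:
    """Intensity-weighted observed m/z in the apex scan's ppm window."""
    scan = _apex_scan(run, apex_rt)
    half = center * tol_ppm * 1e-6
    sel = (scan.mz >= center - half) & (scan.mz <= center + half)
    if not sel.any():
        return None
    w = scan.intensity[sel]
    if w.sum() == 0:
        return float(scan.mz[sel].mean())
    return float(np.average(scan.mz[sel], weights=w))


def _apex_envelope_score(run: CentroidRun, apex_rt: float,
                         env: IsotopeEnvelope, tol_ppm: float) -> float | None:
    scan = _apex_scan(run, apex_rt)
    lo = env.mz[0] * (1 - 2 * tol_ppm * 1e-6)
    hi = env.mz[-1] * (1 + 2 * tol_ppm * 1e-6)
    sel = (scan.mz >= lo) & (scan.mz <= hi) & (scan.intensity > 0)
    if not sel.any():
        return None
    observed = list(zip(scan.mz[sel], scan.intensity[sel]))
    score, _ = envelope_match_score(observed, env, tol_ppm)
    return score


# ---------------------------------------------------------------------------
# Untargeted discovery

def discover_br_unknowns(run: CentroidRun, min_n_br: int = 1,
                         spacing_tol_da: float = 0.005,
                         intensity_floor: float = 0.0,
                         mass_defect_filter: bool = False,
                         decomposition_bounds: dict[str, int] | None = None,
                         tol_ppm: float = 5.0,
                         min_scans: int = 3,
                         table: AtomicMassTable | None = None) -> list[UnknownBrHit]:
    """Scan-by-scan search for isotopologue clusters of brominated unknowns.

    Within each scan, peaks above *intensity_floor* are chained when
    consecutive m/z spacings fall within ``Δ(⁸¹Br−⁷⁹Br) ± spacing_tol_da``.
    The bromine count of a chain is the best least-squares fit of its
    normalized intensities to natural-abundance binomial envelopes over
    candidate n_br in ``[cluster_size − 1, cluster_size + 1]`` (tolerating
    one missing edge peak). A chromatographic compound persists across
    adjacent scans, so clusters seen in fewer than *min_scans* scans are
    rejected as baseline coincidences. Hits are deduplicated across
    adjacent scans by RT/m-z proximity, keeping the most intense
    occurrence, and each hit's monoisotopic peak is decomposed into
    candidate formulas.

    ``mass_defect_filter`` optionally applies the coarse heuristic that the
    fractional mass must decrease across the chain as the ⁸¹Br count rises;
    it is a pre-filter, never a hard identification gate.
    """
    if min_n_br < 1:
        raise ValueError("min_n_br must be >= 1")
    table = table or AtomicMassTable.default()
    p81 = table.isotope("81Br").abundance
    raw: list[tuple[float, list[tuple[float, float]], int]] = []
    for scan in run.scans:
        order = np.argsort(scan.mz)
        mz, inten = scan.mz[order], scan.intensity[order]
        keep = inten > intensity_floor
        mz, inten = mz[keep], inten[keep]
        for cluster in _chain_clusters(mz, inten, spacing_tol_da):
            cluster = _trim_cluster(cluster)
            if len(cluster) < min_n_br + 1:
                continue
            if mass_defect_filter and not _mass_defect_decreases(cluster):
                continue
            n_br = _fit_n_br(cluster, p81, min_n_br)
            if n_br is None or n_br < min_n_br:
                continue
            raw.append((scan.rt, cluster, n_br))
    hits = _dedupe_hits(raw, rt_window=0.1, mz_window=0.05,
                        min_scans=min_scans)
    out = []
    for rt, cluster, n_br in hits:
        cands = []
        if decomposition_bounds:
            cands = decompose_formula(cluster[0][0], charge=-1, tol_ppm=tol_ppm,
                                      bounds=decomposition_bounds, table=table)
        out.append(UnknownBrHit(apex_rt=rt, cluster=cluster,
                                inferred_n_br=n_br, candidate_formulas=cands))
    return sorted(out, key=lambda h: h.apex_rt)


def _chain_clusters(mz: np.ndarray, inten: np.ndarray, tol: float):
    """Chain peaks at successive Δ(⁸¹Br−⁷⁹Br) spacings.

    The next link need not be the next centroid: ¹³C satellites sit between
    Br isotopologues in fine-structure spectra, so each step searches the
    Δ ± tol window and takes its most intense peak. Chains start only at
    peaks with no Δ-spaced predecessor, and chains that shadow a ≥2×
    stronger chain one carbon-isotope unit below (its satellite series)
    are dropped.
    """
    n = mz.size
    chains = []
    for i in range(n):
        if np.any(np.abs((mz[i] - mz[:i]) - BR_SPACING_DA) <= tol):
            continue  # has a predecessor; not a chain start
        chain = [i]
        cur = i
        while True:
            cand = np.flatnonzero(np.abs((mz - mz[cur]) - BR_SPACING_DA) <= tol)
            if cand.size == 0:
                break
            cur = int(cand[np.argmax(inten[cand])])
            chain.append(cur)
        if len(chain) >= 2:
            chains.append(chain)
    # suppress carbon-satellite shadows of stronger chains
    kept = []
    for c in chains:
        base, top = mz[c[0]], inten[c].max()
        shadow = any(0.99 <= base - mz[o[0]] <= 1.01 and inten[o].max() >= 2 * top
                     for o in chains if o is not c)
        if not shadow:
            kept.append([(float(mz[k]), float(inten[k])) for k in c])
    return kept


def _mass_defect_decreases(cluster) -> bool:
    defects = [m - round(m) for m, _ in cluster]
    return all(b < a for a, b in zip(defects, defects[1:]))


def _trim_cluster(cluster, floor_frac: float = 0.02):
    """Strip contiguous edge peaks below *floor_frac* of the cluster max.

    In fine-structure spectra the merged ³⁴S/¹³C₂/¹⁸O satellite one Br
    spacing beyond the last true isotopologue (≈ +1.9987 Da, ~1% relative)
    would otherwise masquerade as an extra bromine.
    """
    top = max(i for _, i in cluster)
    lo, hi = 0, len(cluster)
    while lo < hi and cluster[lo][1] < floor_frac * top:
        lo += 1
    while hi > lo and cluster[hi - 1][1] < floor_frac * top:
        hi -= 1
    return cluster[lo:hi]


def _fit_n_br(cluster, p81: float, min_n_br: int) -> int | None:
    """Least-squares fit of normalized cluster intensities to binomial
    envelopes; candidates bracket the observed cluster size by one."""
    cluster = _trim_cluster(cluster)
    if len(cluster) < 2:
        return None
    obs = np.array([i for _, i in cluster], dtype=float)
    obs = obs / obs.max()
    size = len(cluster)
    best_n, best_sse = None, np.inf
    for n in range(max(min_n_br, size - 1), size + 2):
        env = binomial_br_envelope(n, base_mz=100.0, p81=p81)
        theo = env.rel_abundance
        # slide the observed window over the n+1 theoretical peaks
        for off in range(len(theo) - size + 1):
            seg = theo[off:off + size]
            sse = float(np.sum((obs - seg / seg.max()) ** 2))
            if sse < best_sse:
                best_sse, best_n = sse, n
    if best_n is None:
        return None
    # a genuine Br cluster fits its envelope closely; reject poor fits
    if best_sse / len(cluster) > 0.05:
        return None
    return best_n


def _dedupe_hits(raw, rt_window: float, mz_window: float, min_scans: int = 1):
    """Collapse scan-level cluster hits to one hit per eluting compound.

    Hits are first grouped by (base m/z, RT) proximity; groups seen in
    fewer than *min_scans* scans are discarded, the rest keep their most
    intense occurrence (the apex scan). A weaker surviving hit that
    co-elutes near a stronger one at a nearby base m/z (≤ 4.5 Da: a
    floor-truncated or satellite variant of the same envelope, seen in
    the peak's tail scans) is then suppressed.
    """
    groups: list[list[tuple[float, list, int]]] = []
    for rt, cluster, n_br in sorted(raw, key=lambda x: x[0]):
        base = cluster[0][0]
        for g in groups:
            g_rt, g_cluster, _ = g[-1]
            if abs(rt - g_rt) <= rt_window and abs(base - g_cluster[0][0]) <= mz_window:
                g.append((rt, cluster, n_br))
                break
        else:
            groups.append([(rt, cluster, n_br)])
    apexes = [max(g, key=lambda x: max(i for _, i in x[1]))
              for g in groups if len(g) >= min_scans]
    apexes.sort(key=lambda x: -max(i for _, i in x[1]))
    kept: list[tuple[float, list, int]] = []
    for rt, cluster, n_br in apexes:
        base = cluster[0][0]
        shadowed = any(abs(rt - krt) <= 3 * rt_window
                       and abs(base - kc[0][0]) <= 4.5
                       for krt, kc, _ in kept)
        if not shadowed:
            kept.append((rt, cluster, n_br))
    return kept


# ---------------------------------------------------------------------------
# Formula decomposition

#: Default element bounds for unknown decomposition.
DEFAULT_BOUNDS = {"C": 20, "H": 20, "N": 2, "O": 6, "S": 2, "Br": 8}


def rdbe(formula: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents: C − (H + Br + Cl)/2 + N/2 + 1."""
    return (formula["C"] - (formula["H"] + formula["Br"] + formula["Cl"]) / 2.0
            + formula["N"] / 2.0 + 1.0)


def decompose_formula(mz: float, charge: int = -1, tol_ppm: float = 5.0,
                      bounds: dict[str, int] | None = None,
                      rdbe_min: float = 0.0,
                      table: AtomicMassTable | None = None
                      ) -> list[tuple[MolecularFormula, float, float]]:
    """Exhaustive elemental composition search for an observed ion m/z.

    The composition is that of the *ion* (e.g. [C6H2OBr3]− lists the anion's
    atoms); the neutral for the RDBE filter is formed by adding |charge|
    hydrogens for anions (deprotonation convention) and removing them for
    cations. Returns ``(formula, ppm_error, rdbe)`` tuples ranked by
    absolute ppm error.

    The search iterates all non-hydrogen count combinations within *bounds*
    and solves for the hydrogen count directly from the mass residual, so
    it is exact over the stated bounds without enumerating H.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be non-negative")
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    if not bounds or all(v <= 0 for v in bounds.values()):
        raise ValueError("element bounds must allow at least one atom")
    table = table or AtomicMassTable.default()
    z = abs(charge)
    target = mz * z - (z if charge < 0 else -z) * table.electron_mass_da
    tol_da = mz * tol_ppm * 1e-6 * z
    m = {el: table.principal(el).mass_da for el in bounds}
    h_max = bounds.get("H", 0)
    heavy = [el for el in ("C", "N", "O", "S", "Br", "Cl", "P") if el in bounds]
    results = []

    def recurse(i: int, counts: dict[str, int], mass: float):
        if mass > target + tol_da:
            return
        if i == len(heavy):
            # solve for H
            resid = target - mass
            n_h = int(round(resid / m["H"])) if "H" in m else 0
            for h in {n_h, n_h - 1, n_h + 1}:
                if h < 0 or h > h_max:
                    continue
                total = mass + h * m.get("H", 0.0)
                if abs(total - target) > tol_da:
                    continue
                cand = {**counts}
                if h:
                    cand["H"] = h
                cand = {k: v for k, v in cand.items() if v > 0}
                if not cand:
                    continue
                formula = MolecularFormula(cand)
                neutral = formula.add("H", z if charge < 0 else -z)
                r = rdbe(neutral)
                if r < rdbe_min:
                    continue
                err = ppm_error(total / z, target / z)
                results.append((formula, err, r))
            return
        el = heavy[i]
        for n in range(bounds[el] + 1):
            new_mass = mass + n * m[el]
            if new_mass > target + tol_da:
                break
            recurse(i + 1, {**counts, el: n} if n else counts, new_mass)

    recurse(0, {}, 0.0)
    results.sort(key=lambda x: x[1])
    return results


def bioaccumulation_flag(log_kow: float, bcf: float) -> bool:
    """Conventional persistence screen: bioaccumulative ⟺ log Kow > 5 and
    BCF > 5000 (strict inequalities). Property values are inputs, typically
    from structure-based estimation software."""
    if not (np.isfinite(log_kow) and np.isfinite(bcf)):
        raise ValueError("log_kow and bcf must be finite")
    return bool(log_kow > 5.0 and bcf > 5000.0)
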