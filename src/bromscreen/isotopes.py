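"""Bromine isotopologue envelopes: binomial approximation and fine structure.

Bromine's two isotopes (⁷⁹Br/⁸¹Br, almost exactly 1:1 in nature) give
polybrominated ions their diagnostic envelopes — 1:4:6:4:1 for four
bromines, 1:6:15:20:15:6:1 for six — spaced by ~1.99795 Da. The binomial
model treats Br as the only polyisotopic element; the fine-structure model
expands every element's isotopes and then merges centroids the instrument
cannot resolve, which at Orbitrap-class resolving power collapses the
¹³C/³⁴S satellites into the Br isotopologue peaks and recovers the
integer-ratio patterns reported for these compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import binom

from .chem import AtomicMassTable, IonSpecies

__all__ = [
    "BR_SPACING_DA",
    "IsotopeEnvelope",
    "binomial_br_envelope",
    "fine_structure_envelope",
    "envelope_match_score",
]


def _br_spacing(table: AtomicMassTable) -> float:
    return table.isotope("81Br").mass_da - table.isotope("79Br").mass_da


#: m(⁸¹Br) − m(⁷⁹Br) under the pinned table, ≈ 1.99795 Da.
BR_SPACING_DA = _br_spacing(AtomicMassTable.default())


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Centroided isotopologue peaks, abundances relative to the tallest (=1).

    ``provenance`` records which model produced the envelope
    (``"binomial_Br"`` or ``"fine_structure"``); ``resolution_fwhm`` the
    resolving power used for centroid merging (0 = no merging).
    """

    peaks: tuple[tuple[float, float], ...]
    provenance: str
    resolution_fwhm: float = 0.0

    def __post_init__(self):
        if not self.peaks:
            raise ValueError("envelope must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if sorted(mzs) != mzs:
            raise ValueError("envelope peaks must be sorted by m/z")
        abund = [p[1] for p in self.peaks]
        if not np.isclose(max(abund), 1.0):
            raise ValueError("maximum relative abundance must be 1.0")
        if min(abund) <= 0:
            raise ValueError("relative abundances must be positive")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def rel_abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def nearest_integer_pattern(self) -> tuple[int, ...]:
        """The paper-style integer ratio string, e.g. (1, 4, 6, 4, 1).

        Abundances are rescaled so the smallest peak maps to 1 before
        rounding; a pure binomial p=0.5 envelope maps onto Pascal-triangle
        integers exactly.
        """
        a = self.rel_abundance
        return tuple(int(round(x)) for x in a / a.min())

    def rel_abundance_at(self, mz: float, tol_ppm: float = 5.0) -> float:
        """Relative abundance of the envelope peak nearest *mz* within tolerance."""
        mzs = self.mz
        i = int(np.argmin(np.abs(mzs - mz)))
        if abs(mzs[i] - mz) / mz * 1e6 > tol_ppm:
            raise ValueError(f"no envelope peak within {tol_ppm} ppm of {mz}")
        return float(self.rel_abundance[i])


def binomial_br_envelope(n_br: int, base_mz: float, p81: float = 0.4931,
                         table: AtomicMassTable | None = None) -> IsotopeEnvelope:
    """Envelope of an ion with *n_br* bromines, Br the only polyisotopic element.

    Peak k (k ⁸¹Br atoms) sits at ``base_mz + k·Δ`` with abundance
    ∝ C(n_br, k)·p81^k·(1−p81)^(n_br−k). With p81 = 0.5 the ratios are the
    binomial coefficients exactly — the 1:4:6:4:1-style patterns.
    """
    if n_br < 0:
        raise ValueError("n_br must be non-negative")
    if not 0.0 <= p81 <= 1.0:
        raise ValueError("p81 must lie in [0, 1]")
    table = table or AtomicMassTable.default()
    delta = _br_spacing(table)
    k = np.arange(n_br + 1)
    if p81 == 0.5:
        # exact Pascal coefficients, immune to pmf round-off
        w = np.array([float(comb(n_br, int(i))) for i in k])
    else:
        w = binom.pmf(k, n_br, p81)
    keep = w > 0
    k, w = k[keep], w[keep]
    w = w / w.max()
    peaks = tuple((float(base_mz + ki * delta), float(wi)) for ki, wi in zip(k, w))
    return IsotopeEnvelope(peaks, provenance="binomial_Br")


def _atom_distribution(element: str, table: AtomicMassTable):
    return [(iso.mass_da, iso.abundance) for iso in table.isotopes(element)]


def _convolve(dist_a, dist_b, prune: float):
    out: dict[float, float] = {}
    for ma, pa in dist_a:
        for mb, pb in dist_b:
            p = pa * pb
            if p < prune:
                continue
            m = ma + mb
            out[m] = out.get(m, 0.0) + p
    return sorted(out.items())


def _merge_centroids(dist, resolution: float):
    """Merge centroids closer than the FWHM at their m/z (Gaussian model,
    FWHM = m/z / resolving_power) by abundance-weighted mean."""
    merged = []
    cur_m, cur_p = dist[0]
    for m, p in dist[1:]:
        fwhm = cur_m / resolution
        if m - cur_m <= fwhm:
            tot = cur_p + p
            cur_m = (cur_m * cur_p + m * p) / tot
            cur_p = tot
        else:
            merged.append((cur_m, cur_p))
            cur_m, cur_p = m, p
    merged.append((cur_m, cur_p))
    return merged


def fine_structure_envelope(ion: IonSpecies, table: AtomicMassTable | None = None,
                            prune: float = 1e-4,
                            resolution: float = 60000.0) -> IsotopeEnvelope:
    """Full multinomial isotope expansion of *ion*, merged to instrument resolution.

    Convolves each element's single-atom isotope distribution into the ion's
    composition (pruning combinations below *prune* relative probability),
    merges centroids closer than the FWHM at that m/z, and renormalizes to
    max = 1. Any explicit heavy-isotope substitutions on *ion* are ignored:
    the envelope covers all isotopologues at natural abundance.
    """
    if not 0.0 < prune < 1.0:
        raise ValueError("prune must lie in (0, 1)")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    table = table or AtomicMassTable.default()
    formula = ion.ion_formula
    # absolute prune relative to the most probable path would need the max
    # up front; prune on running product instead, conservatively scaled
    dist = [(0.0, 1.0)]
    for el, n in formula.element_counts.items():
        atom = _atom_distribution(el, table)
        for _ in range(n):
            dist = _convolve(dist, atom, prune * 1e-3)
    z = abs(ion.charge)
    e = table.electron_mass_da * (z if ion.charge < 0 else -z)
    dist = sorted(((m + e) / z, p) for m, p in dist)
    dist = _merge_centroids(dist, resolution)
    pmax = max(p for _, p in dist)
    peaks = tuple((float(m), float(p / pmax)) for m, p in dist if p / pmax >= prune)
    return IsotopeEnvelope(peaks, provenance="fine_structure",
                           resolution_fwhm=resolution)


def envelope_match_score(observed: list[tuple[float, float]],
                         predicted: IsotopeEnvelope,
                         mz_tol_ppm: float = 5.0) -> tuple[float, list[dict]]:
    """Compare an observed peak cluster to a predicted envelope.

    Each predicted peak is greedily paired with the nearest unused observed
    peak within *mz_tol_ppm*. Matched observed intensities are renormalized
    to their own maximum; the score is ``1 − mean(|obs − pred| / pred)``
    over matched peaks, clipped to [0, 1], and 0 when fewer than two
    predicted peaks find a partner. Returns ``(score, deviations)`` where
    deviations holds per-peak m/z and abundance residuals.
    """
    if mz_tol_ppm <= 0:
        raise ValueError("mz_tol_ppm must be positive")
    if not observed:
        raise ValueError("observed peak list is empty")
    obs = sorted(observed)
    used = [False] * len(obs)
    pairs = []  # (pred_mz, pred_ab, obs_mz, obs_intensity)
    order = np.argsort(-predicted.rel_abundance)  # most intense first
    for i in order:
        pmz = predicted.mz[i]
        best, best_d = None, None
        for j, (omz, _oint) in enumerate(obs):
            if used[j]:
                continue
            d = abs(omz - pmz)
            if d / pmz * 1e6 <= mz_tol_ppm and (best is None or d < best_d):
                best, best_d = j, d
        if best is not None:
            used[best] = True
            pairs.append((pmz, predicted.rel_abundance[i], obs[best][0], obs[best][1]))
    if len(pairs) < 2:
        return 0.0, []
    omax = max(p[3] for p in pairs)
    deviations = []
    rel_dev = []
    for pmz, pab, omz, oint in sorted(pairs):
        orel = oint / omax
        rel_dev.append(abs(orel - pab) / pab)
        deviations.append({"predicted_mz": pmz, "observed_mz": omz,
                           "mz_delta_ppm": (omz - pmz) / pmz * 1e6,
                           "predicted_ab": pab, "observed_ab": orel})
    score = float(np.clip(1.0 - np.mean(rel_dev), 0.0, 1.0))
    return score, deviations
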