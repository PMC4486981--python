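"""Targeted identification, untargeted Br discovery and formula decomposition."""

import itertools

import numpy as np
import pytest

from bromscreen.chem import AtomicMassTable, ion_mz, parse_formula
from bromscreen.isotopes import BR_SPACING_DA, binomial_br_envelope
from bromscreen.screening import (DEFAULT_BOUNDS, bioaccumulation_flag,
                                  decompose_formula, discover_br_unknowns,
                                  identify_target, rdbe)
from bromscreen.simulate import make_run
from bromscreen.spectra import CentroidRun, RunMetadata, Scan

from conftest import deprotonated


def run_from_trace(peaks_by_mz, rt0=3.0, sigma=0.05, span=6.0, dt=0.01):
    """Build a run with Gaussian traces at given (m/z -> amplitude)."""
    scans = []
    for t in np.arange(0.0, span, dt):
        profile = np.exp(-0.5 * ((t - rt0) / sigma) ** 2)
        mzs, intens = [], []
        for mz, amp in sorted(peaks_by_mz.items()):
            inten = amp * profile
            if inten >= 1.0:
                mzs.append(mz)
                intens.append(inten)
        scans.append(Scan(float(t), np.array(mzs), np.array(intens)))
    return CentroidRun(scans, RunMetadata(sample_id="fixture"))


class TestIdentifyTarget:
    def test_detects_all_analytes_at_expected_rts(self, standard_run, targets):
        expected_rt = {"TBBPS-MAE": 4.20, "TBBPS-MBAE": 4.56,
                       "TBBPS-MDBPE": 4.80}
        for target in targets:
            res = identify_target(standard_run, target)
            assert res.detected, res.flags
            assert res.apex_rt == pytest.approx(expected_rt[target.name],
                                                abs=0.02)
            assert res.mass_error_ppm <= 5.0
            assert res.envelope_score > 0.8

    def test_low_level_detection(self, targets):
        """The Br6 derivative is confirmed down to the low ng/mL range."""
        run = make_run({"TBBPS-MDBPE": 2.0}, seed=21)
        res = identify_target(run, targets[2])
        assert res.detected
        assert res.apex_rt == pytest.approx(4.80, abs=0.02)

    def test_blank_not_detected(self, blank_run, targets):
        for target in targets:
            res = identify_target(blank_run, target)
            assert not res.detected
            assert res.flags == ["no quantifier peak"]

    def test_missing_qualifier_flagged(self, targets):
        target = targets[0]
        run = run_from_trace({target.quantifier_mz: 1e5}, rt0=target.expected_rt)
        res = identify_target(run, target)
        assert not res.detected
        assert "qualifier co-elution" in res.flags

    def test_wrong_ion_ratio_flagged(self, targets):
        target = targets[0]
        run = run_from_trace({target.quantifier_mz: 1e5,
                              target.qualifier_mz: 1e4},  # ~0.1, far from 0.67
                             rt0=target.expected_rt)
        res = identify_target(run, target)
        assert not res.detected
        assert "ion ratio" in res.flags

    def test_relaxing_tolerances_preserves_detection(self, standard_run, targets):
        for target in targets:
            tight = identify_target(standard_run, target, 5.0, 0.10, 0.20)
            loose = identify_target(standard_run, target, 10.0, 0.20, 0.40)
            if tight.detected:
                assert loose.detected

    def test_bad_tolerances_rejected(self, standard_run, targets):
        with pytest.raises(ValueError):
            identify_target(standard_run, targets[0], mz_tol_ppm=0)


class TestDiscoverBrUnknowns:
    def test_triplet_infers_two_bromines(self):
        base = 293.84105
        traces = {base + k * BR_SPACING_DA: amp
                  for k, amp in zip(range(3), (5e4, 1e5, 5e4))}
        run = run_from_trace(traces, rt0=2.0)
        hits = discover_br_unknowns(run, min_n_br=1)
        assert len(hits) == 1
        assert hits[0].inferred_n_br == 2
        assert hits[0].apex_rt == pytest.approx(2.0, abs=0.02)

    def test_quintet_infers_four_bromines(self):
        base = 560.66511  # monoisotopic of deprotonated tetrabromobisphenol-S
        amps = np.array([1, 4, 6, 4, 1]) * 2e4
        traces = {base + k * BR_SPACING_DA: a for k, a in enumerate(amps)}
        run = run_from_trace(traces, rt0=2.64)
        hits = discover_br_unknowns(run, min_n_br=2,
                                    decomposition_bounds=DEFAULT_BOUNDS)
        assert len(hits) == 1
        assert hits[0].inferred_n_br == 4
        formulas = [str(f) for f, _, _ in hits[0].candidate_formulas]
        assert "C12H5Br4O4S" in formulas

    def test_nonhalogenated_spectrum_is_empty(self):
        # isotope spacing ~1 Da (carbon-like), not the Br doublet spacing
        traces = {400.0: 1e5, 401.003: 2e4, 402.006: 5e3}
        run = run_from_trace(traces, rt0=3.0)
        assert discover_br_unknowns(run, min_n_br=1) == []

    def test_simulated_unknown_spikes_recovered(self):
        run = make_run({"TBBPS": 5.0, "tribromophenol": 5.0, "DBNP": 5.0},
                       seed=11)
        hits = discover_br_unknowns(run, min_n_br=1, intensity_floor=100.0,
                                    decomposition_bounds=DEFAULT_BOUNDS)
        by_n = {h.inferred_n_br: h for h in hits}
        assert set(by_n) == {2, 3, 4}
        best = {n: str(by_n[n].candidate_formulas[0][0]) for n in by_n}
        assert best[2] == "C6H2Br2NO3"
        assert best[3] == "C6H2Br3O"
        assert best[4] == "C12H5Br4O4S"

    def test_recovery_rate_and_false_positives(self):
        """Br2-Br6 clusters at high S/N are recovered in essentially every
        simulated run; halogen-free runs yield nothing."""
        names = ["DBNP", "tribromophenol", "TBBPS", "TBBPS-MBAE",
                 "TBBPS-MDBPE"]
        injected = found = 0
        for seed in range(8):
            run = make_run({n: 5.0 for n in names}, seed=200 + seed)
            hits = discover_br_unknowns(run, min_n_br=2, intensity_floor=100.0)
            injected += len(names)
            expected_n = {2, 3, 4, 5, 6}
            found += len(expected_n & {h.inferred_n_br for h in hits})
        assert found / injected >= 0.95
        for seed in range(8):
            blank = make_run({}, seed=300 + seed)
            assert discover_br_unknowns(blank, min_n_br=1) == []

    def test_fig4_style_window_contains_predicted_isotopologue(self, table):
        """The two-81Br isotopologue of deprotonated tetrabromobisphenol-S
        falls inside the reported untargeted EIC window."""
        mz = ion_mz(deprotonated("C12H6Br4O4S", k81=2), table)
        assert 564.65784 <= mz <= 564.66348

    def test_bad_min_n_br(self, blank_run):
        with pytest.raises(ValueError):
            discover_br_unknowns(blank_run, min_n_br=0)


def oracle_decompose(mz, tol_ppm, bounds, rdbe_min, table):
    """Independent brute force: enumerate every composition in bounds."""
    target = mz - table.electron_mass_da  # anion: observed mass includes e-
    masses = {el: table.principal(el).mass_da for el in bounds}
    hits = []
    ranges = [range(bounds[el] + 1) for el in bounds]
    for combo in itertools.product(*ranges):
        counts = {el: n for el, n in zip(bounds, combo) if n}
        if not counts:
            continue
        total = sum(masses[el] * n for el, n in counts.items())
        if abs(total - target) / mz * 1e6 > tol_ppm:
            continue
        neutral = dict(counts)
        neutral["H"] = neutral.get("H", 0) + 1
        r = (neutral.get("C", 0) - (neutral.get("H", 0) + neutral.get("Br", 0)
                                    + neutral.get("Cl", 0)) / 2.0
             + neutral.get("N", 0) / 2.0 + 1.0)
        if r >= rdbe_min:
            hits.append(frozenset(counts.items()))
    return set(hits)


class TestDecomposeFormula:
    @pytest.mark.parametrize("mz,expected", [
        (326.76612, "C6H2Br3O"),      # tribromophenolate-type anion
        (600.69605, "C15H9Br4O4S"),   # monoisotopic deprotonated MAE
        (293.84069, "C6H2Br2NO3"),    # dibromo-nitrophenolate-type anion
    ])
    def test_recovers_reported_assignments(self, mz, expected):
        hits = decompose_formula(mz, charge=-1, tol_ppm=5.0,
                                 bounds=DEFAULT_BOUNDS)
        assert expected in [str(f) for f, _, _ in hits]

    def test_zero_tolerance_on_inexact_mass_is_empty(self):
        assert decompose_formula(326.76600, tol_ppm=0.0,
                                 bounds=DEFAULT_BOUNDS) == []

    def test_ranked_by_ppm_error(self):
        hits = decompose_formula(600.69605, tol_ppm=10.0, bounds=DEFAULT_BOUNDS)
        errs = [e for _, e, _ in hits]
        assert errs == sorted(errs)

    def test_agrees_with_exhaustive_oracle(self, table):
        bounds = {"C": 20, "H": 20, "N": 2, "O": 6, "S": 2, "Br": 8}
        rng = np.random.default_rng(99)
        for mz in rng.uniform(120.0, 700.0, 20):
            got = {frozenset(f.element_counts.items())
                   for f, _, _ in decompose_formula(mz, tol_ppm=5.0,
                                                    bounds=bounds)}
            assert got == oracle_decompose(mz, 5.0, bounds, 0.0, table), mz

    def test_rdbe_neutral_convention(self):
        # deprotonated tribromophenol: neutral C6H3Br3O has RDBE 4
        assert rdbe(parse_formula("C6H3Br3O")) == 4.0

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError):
            decompose_formula(300.0, bounds={})


class TestBioaccumulationFlag:
    @pytest.mark.parametrize("log_kow,bcf,expected", [
        (7.01, 13200, True),   # strongly partitioning, high BCF
        (5.21, 1266, False),   # lipophilic but low BCF
        (5.0, 5000, False),    # boundary: strict inequalities
        (7.36, 8829, True),
    ])
    def test_rule(self, log_kow, bcf, expected):
        assert bioaccumulation_flag(log_kow, bcf) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bioaccumulation_flag(float("nan"), 100.0)
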