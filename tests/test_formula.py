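"""Tests for formula assignment, AI_mod, classification, and spectra utilities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import exhaustive_enumerate
from sipdom.errors import CalibrationError, EmptySampleError
from sipdom.formula import (
    COMPOUND_CLASSES,
    DEFAULT_RANGES,
    PROTON_MASS,
    AssignedPeak,
    DomSample,
    ElementRanges,
    MolecularFormula,
    Peak,
    ai_mod,
    apply_detection_limit,
    assign_peak,
    assign_peaks,
    classify_formula,
    enumerate_formulas,
    internal_calibrate,
    neutral_mass,
    normalize_intensities,
    weighted_ratios,
)

GLUCOSE = MolecularFormula(c=6, h=12, o=6)
BENZENE = MolecularFormula(c=6, h=6)


def valid_formulas(max_c=60):
    """Hypothesis strategy over chemically valid CHNOSP formulas."""
    def build(c, hc, oc, n, s, p):
        h = int(round(hc * c))
        if (h % 2) != ((n + p) % 2):
            h += 1
        h = max(h, 1)
        h = min(h, 2 * c + 2 + n, 250)
        if (h % 2) != ((n + p) % 2):
            h -= 1
        if h < 1 or 2 + 2 * c - h + n + p < 0:
            h = (n + p) % 2 + 2  # minimal valid H with right parity
        o = min(int(round(oc * c)), 100)
        return MolecularFormula(c=c, h=h, o=o, n=n, s=s, p=p)

    return st.builds(
        build,
        c=st.integers(min_value=1, max_value=max_c),
        hc=st.floats(min_value=0.0, max_value=2.5),
        oc=st.floats(min_value=0.0, max_value=1.5),
        n=st.integers(min_value=0, max_value=4),
        s=st.integers(min_value=0, max_value=2),
        p=st.integers(min_value=0, max_value=1),
    )


class TestNeutralMass:
    def test_proton_addition(self):
        assert neutral_mass(100.0) == pytest.approx(101.00727646, abs=1e-9)

    def test_inverse_identity_for_known_formula(self):
        m = MolecularFormula(c=15, h=22, o=8).monoisotopic_mass
        assert neutral_mass(m - PROTON_MASS) == pytest.approx(m, abs=1e-12)

    def test_palmitic_acid(self):
        palmitic = MolecularFormula(c=16, h=32, o=2)
        assert palmitic.monoisotopic_mass == pytest.approx(256.24023, abs=1e-5)
        mz = palmitic.monoisotopic_mass - PROTON_MASS
        assert neutral_mass(mz) == pytest.approx(256.24023, abs=1e-5)

    def test_unsupported_mode(self):
        with pytest.raises(ValueError):
            neutral_mass(100.0, charge_mode="positive")


class TestEnumerateFormulas:
    def test_unique_candidate_at_tight_tolerance(self):
        target = MolecularFormula(c=15, h=22, o=8).monoisotopic_mass
        assert target == pytest.approx(330.13147, abs=1e-5)
        candidates = enumerate_formulas(target, tol_ppm=0.5)
        assert len(candidates) == 1
        assert candidates[0][0] == MolecularFormula(c=15, h=22, o=8)
        assert abs(candidates[0][1]) < 1e-6

    def test_mass_below_constraint_space_is_empty(self):
        assert enumerate_formulas(10.0, tol_ppm=5.0) == []

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            enumerate_formulas(330.0, tol_ppm=0.0)

    @pytest.mark.parametrize(
        "truth",
        [
            MolecularFormula(c=20, h=24, o=10),
            MolecularFormula(c=10, h=17, o=3, n=1),
            MolecularFormula(c=27, h=34, o=9, s=1),
            MolecularFormula(c=12, h=19, o=6, p=1),
        ],
    )
    def test_agrees_with_exhaustive_oracle_at_5ppm(self, truth):
        target = truth.monoisotopic_mass
        got = enumerate_formulas(target, tol_ppm=5.0)
        oracle = exhaustive_enumerate(target, tol_ppm=5.0)
        assert len(got) == len(oracle)
        assert {(f.c, f.h, f.o, f.n, f.s, f.p) for f, _ in got} == set(oracle)
        assert got[0][0] == truth  # zero-error truth is the best candidate

    def test_candidates_sorted_by_absolute_error(self):
        target = MolecularFormula(c=20, h=24, o=10).monoisotopic_mass
        got = enumerate_formulas(target, tol_ppm=50.0)
        errors = [abs(e) for _, e in got]
        assert errors == sorted(errors)

    def test_every_candidate_respects_chemical_filters(self):
        target = MolecularFormula(c=25, h=30, o=8, n=2).monoisotopic_mass
        for f, err in enumerate_formulas(target, tol_ppm=20.0):
            assert f.h <= 2 * f.c + 2 + f.n
            assert f.dbe >= 0 and float(f.dbe).is_integer()
            assert abs(err) <= 20.0

    def test_min_oxygen_switch(self):
        target = BENZENE.monoisotopic_mass
        with_o = enumerate_formulas(target, tol_ppm=0.5, constraints=DEFAULT_RANGES)
        without = enumerate_formulas(
            target, tol_ppm=0.5, constraints=DEFAULT_RANGES.with_min_oxygen(0)
        )
        assert BENZENE not in [f for f, _ in with_o]
        assert BENZENE in [f for f, _ in without]


class TestAssignPeak:
    def test_ambiguity_flag(self):
        target = MolecularFormula(c=20, h=24, o=10).monoisotopic_mass
        peak = Peak(mz=target - PROTON_MASS, intensity=1.0)
        ap = assign_peak(peak, tol_ppm=50.0)
        assert ap.best == MolecularFormula(c=20, h=24, o=10)
        assert ap.ambiguous == (len(ap.candidates) >= 2)

    def test_unassignable_peak_has_empty_candidates(self):
        ap = assign_peak(Peak(mz=10.0, intensity=1.0), tol_ppm=0.1)
        assert ap.best is None and ap.candidates == ()


class TestAiMod:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            (BENZENE, 2.0 / 3.0),
            (GLUCOSE, 0.0),  # negative numerator clamps to zero
            (MolecularFormula(c=1, h=4), 0.0),  # numerator exactly zero
        ],
    )
    def test_reference_values(self, formula, expected):
        assert ai_mod(formula) == pytest.approx(expected, abs=1e-9)

    @given(valid_formulas())
    def test_never_negative(self, formula):
        assert ai_mod(formula) >= 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            (BENZENE, "Aromatics O-poor"),
            (MolecularFormula(c=10, h=6, o=8), "Aromatics O-rich"),
            (MolecularFormula(c=10, h=12, o=4), "Highly unsaturated O-poor"),
            (MolecularFormula(c=10, h=10, o=7), "Highly unsaturated O-rich"),
            (MolecularFormula(c=10, h=18, o=3), "Unsaturated O-poor"),
            (GLUCOSE, "Unsaturated O-rich"),
            (MolecularFormula(c=10, h=17, o=3, n=1), "Unsaturated with N"),
            (MolecularFormula(c=5, h=12, o=2), "Saturated O-poor"),
            (MolecularFormula(c=4, h=12, o=3, n=2), "Saturated O-rich"),
        ],
    )
    def test_reference_assignments(self, formula, expected):
        assert classify_formula(formula) == expected

    def test_nitrogen_takes_priority_in_unsaturated_band(self):
        f = MolecularFormula(c=10, h=17, o=6, n=1)  # H/C 1.7, O/C 0.6, N > 0
        assert classify_formula(f) == "Unsaturated with N"

    def test_boundary_ai_mod_routes_non_aromatic(self):
        # AI_mod exactly 0.5: numerator (1 + c − h/2) vs denominator c.
        f = MolecularFormula(c=10, h=12)  # AI_mod = (1+10−6)/10 = 0.5, H/C = 1.2
        assert ai_mod(f) == pytest.approx(0.5)
        assert classify_formula(f) == "Highly unsaturated O-poor"

    @given(valid_formulas())
    def test_partition_every_formula_gets_exactly_one_class(self, formula):
        assert classify_formula(formula) in COMPOUND_CLASSES


class TestNormalizationAndRatios:
    def _sample(self, formulas, intensities):
        assigned = [
            AssignedPeak(
                peak=Peak(mz=f.monoisotopic_mass - PROTON_MASS, intensity=i),
                best=f, error_ppm=0.0, candidates=((f, 0.0),), ambiguous=False,
            )
            for f, i in zip(formulas, intensities)
        ]
        return DomSample(sample_id="s", assigned=assigned)

    def test_rel_intensities(self):
        formulas = [GLUCOSE, BENZENE, MolecularFormula(c=10, h=18, o=3)]
        sample = normalize_intensities(self._sample(formulas, [1.0, 1.0, 2.0]))
        assert sorted(sample.rel_intensity.values()) == pytest.approx([0.25, 0.25, 0.5])
        assert sum(sample.rel_intensity.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_formula(self):
        sample = normalize_intensities(self._sample([GLUCOSE], [42.0]))
        assert list(sample.rel_intensity.values()) == [1.0]

    def test_idempotent(self):
        formulas = [GLUCOSE, BENZENE]
        s1 = normalize_intensities(self._sample(formulas, [3.0, 1.0]))
        s2 = normalize_intensities(s1)
        assert s1.rel_intensity == s2.rel_intensity

    def test_duplicate_formula_kept_once(self):
        sample = normalize_intensities(self._sample([GLUCOSE, GLUCOSE], [1.0, 3.0]))
        assert len(sample.rel_intensity) == 1

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            normalize_intensities(DomSample(sample_id="s", assigned=[]))

    def test_weighted_ratios_single_formula(self):
        sample = normalize_intensities(self._sample([GLUCOSE], [1.0]))
        ratios = weighted_ratios(sample)
        assert ratios["H/C"] == pytest.approx(2.0)
        assert ratios["O/C"] == pytest.approx(1.0)
        assert ratios["N/C"] == 0.0

    def test_weighted_ratios_midpoint(self):
        f1 = MolecularFormula(c=10, h=20, o=2)  # O/C 0.2
        f2 = MolecularFormula(c=10, h=20, o=6)  # O/C 0.6
        sample = normalize_intensities(self._sample([f1, f2], [5.0, 5.0]))
        assert weighted_ratios(sample)["O/C"] == pytest.approx(0.4)

    def test_weighted_ratios_glucose_benzene(self):
        sample = normalize_intensities(self._sample([GLUCOSE, BENZENE], [3.0, 1.0]))
        assert weighted_ratios(sample)["H/C"] == pytest.approx(0.75 * 2.0 + 0.25 * 1.0)

    @given(
        st.lists(
            st.tuples(valid_formulas(), st.floats(min_value=0.1, max_value=100.0)),
            min_size=1, max_size=8,
        )
    )
    def test_convexity_of_weighted_ratios(self, pairs):
        formulas = list({f for f, _ in pairs})
        intensities = [w for _, w in pairs][: len(formulas)]
        sample = normalize_intensities(self._sample(formulas, intensities))
        ratios = weighted_ratios(sample)
        for key, attr in [("H/C", "hc"), ("O/C", "oc"), ("N/C", "nc")]:
            per = [getattr(f, attr) for f in sample.rel_intensity]
            assert min(per) - 1e-12 <= ratios[key] <= max(per) + 1e-12


class TestInternalCalibration:
    def _spectrum(self, calibrants, offset_ppm=0.0, rng=None):
        peaks = []
        for f in calibrants:
            mz = (f.monoisotopic_mass - PROTON_MASS) * (1.0 + offset_ppm * 1e-6)
            peaks.append(Peak(mz=mz, intensity=100.0))
        return peaks

    CALIBRANTS = [
        MolecularFormula(c=10, h=12, o=5),
        MolecularFormula(c=14, h=18, o=6),
        MolecularFormula(c=17, h=22, o=8),
        MolecularFormula(c=20, h=26, o=9),
        MolecularFormula(c=24, h=30, o=11),
        MolecularFormula(c=27, h=36, o=12),
    ]

    def test_exact_calibrants_give_identity(self):
        peaks = self._spectrum(self.CALIBRANTS)
        corrected, diag = internal_calibrate(peaks, self.CALIBRANTS)
        assert diag["n_matched"] == len(self.CALIBRANTS)
        assert abs(diag["slope"]) < 1e-12 and abs(diag["intercept"]) < 1e-12
        for p0, p1 in zip(peaks, corrected):
            assert p1.mz == pytest.approx(p0.mz, rel=1e-12)
            assert p1.calibrated

    def test_uniform_offset_removed(self):
        peaks = self._spectrum(self.CALIBRANTS, offset_ppm=2.0)
        corrected, diag = internal_calibrate(peaks, self.CALIBRANTS)
        assert diag["post_rms_ppm"] < 0.05
        for f, p in zip(self.CALIBRANTS, corrected):
            true_mz = f.monoisotopic_mass - PROTON_MASS
            assert abs(p.mz - true_mz) / true_mz * 1e6 < 0.05

    def test_too_few_matches_raise(self):
        peaks = self._spectrum(self.CALIBRANTS[:3])
        with pytest.raises(CalibrationError):
            internal_calibrate(peaks, self.CALIBRANTS[:3])

    def test_non_strict_passes_through_with_warning(self):
        peaks = self._spectrum(self.CALIBRANTS[:3])
        with pytest.warns(UserWarning):
            out, diag = internal_calibrate(peaks, self.CALIBRANTS[:3], strict=False)
        assert [p.mz for p in out] == [p.mz for p in peaks]
        assert not diag["calibrated"]

    def test_calibration_never_increases_calibrant_rms(self, rng):
        for _ in range(10):
            peaks = []
            for f in self.CALIBRANTS:
                err = rng.normal(1.0, 0.3) * 1e-6  # ~1 ppm with scatter
                mz = (f.monoisotopic_mass - PROTON_MASS) * (1.0 + err)
                peaks.append(Peak(mz=mz, intensity=10.0))
            _, diag = internal_calibrate(peaks, self.CALIBRANTS)
            assert diag["post_rms_ppm"] <= diag["pre_rms_ppm"] + 1e-12


class TestDetectionLimit:
    def test_zero_threshold_retains_all(self):
        peaks = [Peak(100.0, 1.0), Peak(200.0, 50.0)]
        assert apply_detection_limit(peaks, 0.0) == peaks

    def test_relative_cut(self):
        peaks = [Peak(100.0, 100.0), Peak(200.0, 5.0), Peak(300.0, 1.0)]
        kept = apply_detection_limit(peaks, 0.02)
        assert [p.intensity for p in kept] == [100.0, 5.0]

    def test_idempotent(self):
        peaks = [Peak(100.0, 100.0), Peak(200.0, 5.0), Peak(300.0, 1.0)]
        once = apply_detection_limit(peaks, 0.02)
        assert apply_detection_limit(once, 0.02) == once

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            apply_detection_limit([], 1.0)
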