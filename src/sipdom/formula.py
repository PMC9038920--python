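"""Molecular-formula assignment and classification for FT-ICR-MS DOM spectra.

Ultra-high-resolution mass spectrometry of dissolved organic matter (DOM)
yields peak lists of m/z and intensity.  In negative electrospray mode each
peak is treated as a singly charged deprotonated ion [M−H]⁻, so the neutral
monoisotopic mass is m/z plus one proton mass.  A neutral mass is decomposed
into integer CHNOSP element counts within the constraint space
C₁₋₁₀₀ H₁₋₂₅₀ O₁₋₁₀₀ N₀₋₄ S₀₋₂ P₀₋₁ and a ppm mass tolerance, subject to
standard chemical filters: H ≤ 2C + 2 + N and an integer, non-negative
double-bond-equivalent count (the nitrogen rule).

Assigned formulas are summarized by molar ratios (H/C, O/C, N/C, S/C, P/C),
the modified aromaticity index AI_mod (oxygen half-weighted), and a
partition into nine van Krevelen compound classes ranging from O-poor
aromatics to O-rich saturated compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, EmptySampleError

# Exact masses of the lightest stable isotopes (Da).
MASS_C = 12.0
MASS_H = 1.00782503
MASS_O = 15.99491462
MASS_N = 14.00307401
MASS_S = 31.97207069
MASS_P = 30.97376151
#: Mass of a proton; [M−H]⁻ ions satisfy M = m/z + this value.
PROTON_MASS = 1.00727646

#: m/z acquisition window of the broadband spectra (Da).
ACQUISITION_WINDOW = (95.0, 1000.0)


@dataclass(frozen=True)
class ElementRanges:
    """Inclusive element-count bounds defining the assignment search space."""

    c: tuple[int, int] = (1, 100)
    h: tuple[int, int] = (1, 250)
    o: tuple[int, int] = (1, 100)
    n: tuple[int, int] = (0, 4)
    s: tuple[int, int] = (0, 2)
    p: tuple[int, int] = (0, 1)

    def with_min_oxygen(self, min_oxygen: int) -> "ElementRanges":
        return ElementRanges(
            c=self.c, h=self.h, o=(min_oxygen, self.o[1]), n=self.n, s=self.s, p=self.p
        )


DEFAULT_RANGES = ElementRanges()

#: The nine van Krevelen compound classes, in rule order.
COMPOUND_CLASSES = (
    "Aromatics O-poor",
    "Aromatics O-rich",
    "Highly unsaturated O-poor",
    "Highly unsaturated O-rich",
    "Unsaturated O-poor",
    "Unsaturated O-rich",
    "Unsaturated with N",
    "Saturated O-poor",
    "Saturated O-rich",
)


@dataclass(frozen=True)
class MolecularFormula:
    """A CHNOSP molecular formula with derived descriptors."""

    c: int
    h: int
    o: int = 0
    n: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        if self.c < 1 or self.h < 0:
            raise ValueError(f"invalid element counts in {self!r}")
        if min(self.o, self.n, self.s, self.p) < 0:
            raise ValueError(f"negative element count in {self!r}")

    @property
    def monoisotopic_mass(self) -> float:
        return (
            self.c * MASS_C
            + self.h * MASS_H
            + self.o * MASS_O
            + self.n * MASS_N
            + self.s * MASS_S
            + self.p * MASS_P
        )

    @property
    def hc(self) -> float:
        return self.h / self.c

    @property
    def oc(self) -> float:
        return self.o / self.c

    @property
    def nc(self) -> float:
        return self.n / self.c

    @property
    def sc(self) -> float:
        return self.s / self.c

    @property
    def pc(self) -> float:
        return self.p / self.c

    @property
    def dbe(self) -> float:
        """Double-bond equivalents, 1 + C − H/2 + N/2 + P/2 (trivalent N and P)."""
        return 1.0 + self.c - self.h / 2.0 + self.n / 2.0 + self.p / 2.0

    @property
    def ai_mod(self) -> float:
        return ai_mod(self)

    @property
    def compound_class(self) -> str:
        return classify_formula(self)

    def __str__(self) -> str:
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("O", self.o),
                           ("N", self.n), ("S", self.s), ("P", self.p)):
            if count:
                parts.append(f"{sym}{count}" if count > 1 else sym)
        return "".join(parts)


@dataclass(frozen=True)
class Peak:
    """One spectral peak (m/z in Da, intensity in arbitrary units)."""

    mz: float
    intensity: float
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError(f"peak at m/z {self.mz}: non-positive intensity")

    @property
    def in_window(self) -> bool:
        return ACQUISITION_WINDOW[0] <= self.mz <= ACQUISITION_WINDOW[1]


@dataclass(frozen=True)
class AssignedPeak:
    """A peak with its best formula candidate and the full candidate list."""

    peak: Peak
    best: MolecularFormula | None
    error_ppm: float | None
    candidates: tuple[tuple[MolecularFormula, float], ...]
    ambiguous: bool


def neutral_mass(mz: float, charge_mode: str = "negative") -> float:
    """Neutral monoisotopic mass of a singly charged deprotonated ion."""
    if charge_mode != "negative":
        raise ValueError(f"unsupported charge mode {charge_mode!r}; only negative [M−H]⁻")
    return mz + PROTON_MASS


@lru_cache(maxsize=8)
def _skeleton_grid(ranges: ElementRanges) -> tuple[np.ndarray, ...]:
    """Pre-computed (c, o, n, s, p) grid and its H-free mass, cached per ranges."""
    c = np.arange(ranges.c[0], ranges.c[1] + 1)
    o = np.arange(ranges.o[0], ranges.o[1] + 1)
    n = np.arange(ranges.n[0], ranges.n[1] + 1)
    s = np.arange(ranges.s[0], ranges.s[1] + 1)
    p = np.arange(ranges.p[0], ranges.p[1] + 1)
    C, O, N, S, P = np.meshgrid(c, o, n, s, p, indexing="ij")
    C, O, N, S, P = (a.ravel() for a in (C, O, N, S, P))
    skel = C * MASS_C + O * MASS_O + N * MASS_N + S * MASS_S + P * MASS_P
    order = np.argsort(skel)
    return C[order], O[order], N[order], S[order], P[order], skel[order]


def enumerate_formulas(
    target_mass: float,
    tol_ppm: float = 0.5,
    constraints: ElementRanges = DEFAULT_RANGES,
) -> list[tuple[MolecularFormula, float]]:
    """All formulas within ``tol_ppm`` of a neutral mass, sorted by |error|.

    Candidates satisfy the element ranges, H ≤ 2C + 2 + N, and an integer
    DBE ≥ 0 (which enforces the nitrogen rule, H ≡ N + P mod 2).  Returns
    ``(formula, signed error in ppm)`` pairs; the list may be empty.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    C, O, N, S, P, skel = _skeleton_grid(constraints)
    tol_da = tol_ppm * 1e-6 * target_mass
    # Restrict to skeletons that leave room for at least h_min hydrogens.
    h_min, h_max = constraints.h
    lo = np.searchsorted(skel, target_mass - tol_da - h_max * MASS_H)
    hi = np.searchsorted(skel, target_mass + tol_da - h_min * MASS_H, side="right")
    if lo >= hi:
        return []
    sl = slice(lo, hi)
    rem = target_mass - skel[sl]
    # Within a sub-ppm window only the nearest integer H count can match.
    h = np.rint(rem / MASS_H).astype(int)
    mass = skel[sl] + h * MASS_H
    err_da = mass - target_mass
    ok = (
        (np.abs(err_da) <= tol_da)
        & (h >= h_min)
        & (h <= h_max)
        & (h <= 2 * C[sl] + 2 + N[sl])
        & ((h % 2) == ((N[sl] + P[sl]) % 2))  # integer DBE (nitrogen rule)
        & (2.0 + 2.0 * C[sl] - h + N[sl] + P[sl] >= 0)  # DBE >= 0
    )
    idx = np.nonzero(ok)[0]
    out = []
    for i in idx:
        f = MolecularFormula(
            c=int(C[sl][i]), h=int(h[i]), o=int(O[sl][i]),
            n=int(N[sl][i]), s=int(S[sl][i]), p=int(P[sl][i]),
        )
        out.append((f, float(err_da[i] / target_mass * 1e6)))
    out.sort(key=lambda pair: (abs(pair[1]), str(pair[0])))
    return out


def assign_peak(
    peak: Peak,
    tol_ppm: float = 0.5,
    constraints: ElementRanges = DEFAULT_RANGES,
) -> AssignedPeak:
    """Assign the best-fitting formula to one peak (negative mode, [M−H]⁻)."""
    candidates = enumerate_formulas(neutral_mass(peak.mz), tol_ppm, constraints)
    if not candidates:
        return AssignedPeak(peak=peak, best=None, error_ppm=None, candidates=(), ambiguous=False)
    best, err = candidates[0]
    return AssignedPeak(
        peak=peak,
        best=best,
        error_ppm=err,
        candidates=tuple(candidates),
        ambiguous=len(candidates) >= 2,
    )


def assign_peaks(
    peaks: Iterable[Peak],
    tol_ppm: float = 0.5,
    min_oxygen: int = 1,
    constraints: ElementRanges = DEFAULT_RANGES,
) -> list[AssignedPeak]:
    """Assign formulas to a peak list; ``min_oxygen`` tightens the O range."""
    ranges = constraints.with_min_oxygen(min_oxygen)
    return [assign_peak(p, tol_ppm, ranges) for p in peaks]


def ai_mod(formula: MolecularFormula) -> float:
    """Modified aromaticity index with half-weighted oxygen.

    AI_mod = (1 + C − O/2 − S − (H + N + P)/2) / (C − O/2 − S − N − P);
    defined as 0 whenever the numerator is negative or the denominator is
    not positive (fully saturated / oxygen-rich formulas).
    """
    num = 1.0 + formula.c - 0.5 * formula.o - formula.s - 0.5 * (
        formula.h + formula.n + formula.p
    )
    den = formula.c - 0.5 * formula.o - formula.s - formula.n - formula.p
    if num < 0 or den <= 0:
        return 0.0
    return num / den


def classify_formula(formula: MolecularFormula) -> str:
    """Assign exactly one of the nine van Krevelen compound classes.

    Decision order: aromaticity first (AI_mod > 0.5, split by O/C at 0.5),
    then H/C < 1.5 (highly unsaturated, split by O/C), then 1.5 ≤ H/C ≤ 2
    with N present (unsaturated with N), then 1.5 ≤ H/C ≤ 2 (unsaturated,
    split by O/C), finally H/C > 2 (saturated, split by O/C).  The
    boundary AI_mod = 0.5 routes to the non-aromatic branch.
    """
    hc, oc = formula.hc, formula.oc
    if ai_mod(formula) > 0.5:
        return COMPOUND_CLASSES[0] if oc <= 0.5 else COMPOUND_CLASSES[1]
    if hc < 1.5:
        return COMPOUND_CLASSES[2] if oc <= 0.5 else COMPOUND_CLASSES[3]
    if hc <= 2.0:
        if formula.n > 0:
            return COMPOUND_CLASSES[6]
        return COMPOUND_CLASSES[4] if oc <= 0.5 else COMPOUND_CLASSES[5]
    return COMPOUND_CLASSES[7] if oc <= 0.5 else COMPOUND_CLASSES[8]


@dataclass
class DomSample:
    """A calibrated, assigned DOM sample with per-formula relative intensities."""

    sample_id: str
    assigned: list[AssignedPeak]
    habitat: str | None = None
    rel_intensity: dict[MolecularFormula, float] = field(default_factory=dict)

    @property
    def formulas(self) -> list[MolecularFormula]:
        return list(self.rel_intensity)


def normalize_intensities(sample: DomSample, drop_ambiguous: bool = False) -> DomSample:
    """Populate per-formula relative intensities summing to one.

    Each formula appears at most once per sample; if several peaks map to
    the same formula the most intense peak is kept.  Unassigned peaks are
    excluded from the normalization.
    """
    intensity: dict[MolecularFormula, float] = {}
    for ap in sample.assigned:
        if ap.best is None or (drop_ambiguous and ap.ambiguous):
            continue
        prev = intensity.get(ap.best, 0.0)
        intensity[ap.best] = max(prev, ap.peak.intensity)
    total = sum(intensity.values())
    if total <= 0:
        raise EmptySampleError(f"sample {sample.sample_id}: no assigned formulas to normalize")
    sample.rel_intensity = {f: v / total for f, v in intensity.items()}
    return sample


def weighted_ratios(sample: DomSample) -> dict[str, float]:
    """Intensity-weighted averages of the per-formula molar ratios.

    Each ratio is the relative-intensity-weighted mean of per-formula
    ratios (not a ratio of weighted sums).
    """
    if not sample.rel_intensity:
        raise EmptySampleError(f"sample {sample.sample_id}: normalize before weighting")
    out = {"H/C": 0.0, "O/C": 0.0, "N/C": 0.0, "S/C": 0.0, "P/C": 0.0}
    for f, w in sample.rel_intensity.items():
        out["H/C"] += w * f.hc
        out["O/C"] += w * f.oc
        out["N/C"] += w * f.nc
        out["S/C"] += w * f.sc
        out["P/C"] += w * f.pc
    return out


def internal_calibrate(
    peaks: Sequence[Peak],
    calibrants: Sequence[MolecularFormula],
    match_window_ppm: float = 3.0,
    min_matches: int = 5,
    strict: bool = True,
) -> tuple[list[Peak], dict]:
    """Internally calibrate a spectrum against known DOM formulas.

    Calibrant [M−H]⁻ m/z values are matched to the nearest observed peak
    within ``match_window_ppm``; a linear model of relative mass error
    versus m/z is fitted to the matches and divided out of every peak.
    Raises :class:`~sipdom.errors.CalibrationError` with fewer than
    ``min_matches`` matches (or warns and passes peaks through unchanged
    when ``strict`` is false).  Diagnostics report the matched count and
    the calibrant RMS error in ppm before and after correction.
    """
    mz_obs = np.array([p.mz for p in peaks])
    matches: list[tuple[float, float]] = []  # (observed, theoretical)
    for cal in calibrants:
        theo = cal.monoisotopic_mass - PROTON_MASS
        if len(mz_obs) == 0:
            break
        i = int(np.argmin(np.abs(mz_obs - theo)))
        if abs(mz_obs[i] - theo) / theo * 1e6 <= match_window_ppm:
            matches.append((float(mz_obs[i]), theo))
    if len(matches) < min_matches:
        msg = f"only {len(matches)} calibrants matched (need ≥ {min_matches})"
        if strict:
            raise CalibrationError(msg)
        warnings.warn(f"calibration failed: {msg}; peaks passed through uncalibrated",
                      stacklevel=2)
        return list(peaks), {"n_matched": len(matches), "calibrated": False}
    obs = np.array([m[0] for m in matches])
    theo = np.array([m[1] for m in matches])
    rel_err = (obs - theo) / theo
    coeffs = np.polyfit(obs, rel_err, deg=1)
    model = np.poly1d(coeffs)
    corrected = [
        Peak(mz=p.mz / (1.0 + float(model(p.mz))), intensity=p.intensity, calibrated=True)
        for p in peaks
    ]
    pre_rms = float(np.sqrt(np.mean((rel_err * 1e6) ** 2)))
    post_rel = (obs / (1.0 + model(obs)) - theo) / theo
    post_rms = float(np.sqrt(np.mean((post_rel * 1e6) ** 2)))
    diagnostics = {
        "n_matched": len(matches),
        "calibrated": True,
        "slope": float(coeffs[0]),
        "intercept": float(coeffs[1]),
        "pre_rms_ppm": pre_rms,
        "post_rms_ppm": post_rms,
    }
    return corrected, diagnostics


def apply_detection_limit(peaks: Sequence[Peak], rel_threshold: float) -> list[Peak]:
    """Drop peaks below ``rel_threshold`` × the base-peak intensity."""
    if not (0.0 <= rel_threshold < 1.0):
        raise ValueError(f"rel_threshold {rel_threshold} outside [0, 1)")
    if not peaks:
        return []
    cutoff = rel_threshold * max(p.intensity for p in peaks)
    return [p for p in peaks if p.intensity >= cutoff]


def build_dom_sample(
    sample_id: str,
    peaks: Sequence[Peak],
    tol_ppm: float = 0.5,
    min_oxygen: int = 1,
    calibrants: Sequence[MolecularFormula] | None = None,
    detection_rel: float = 0.0,
    habitat: str | None = None,
    drop_ambiguous: bool = False,
) -> DomSample:
    """Full per-sample chain: calibrate → detection limit → assign → normalize."""
    working = list(peaks)
    if calibrants:
        working, _ = internal_calibrate(working, calibrants, strict=False)
    if detection_rel > 0:
        working = apply_detection_limit(working, detection_rel)
    assigned = assign_peaks(working, tol_ppm=tol_ppm, min_oxygen=min_oxygen)
    sample = DomSample(sample_id=sample_id, assigned=assigned, habitat=habitat)
    return normalize_intensities(sample, drop_ambiguous=drop_ambiguous)
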