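"""Excess atom fraction (EAF) estimation for ¹³C DNA stable-isotope probing.

DNA banding in a CsCl density gradient equilibrates at a buoyant density set
by its GC content and its heavy-isotope content.  Quantitative SIP compares
the copy-weighted mean buoyant density of a marker gene (e.g. fungal 18S or
prokaryotic 16S rRNA genes, quantified by qPCR across gradient fractions)
between a ¹³C-labeled incubation and an unlabeled control.  The density
shift is converted, through the GC-dependent molecular weight of the DNA,
into the excess atom fraction of ¹³C — the fraction of carbon atoms in the
marker that are ¹³C beyond the natural abundance of 0.01111233.

Two linear GC–density calibrations are exposed:

* ``"hungate"`` — the calibration used inside the qSIP equation chain
  (density = 1.646057 + 0.083506·GC).
* ``"schildkraut"`` — the classic relation density = 1.660 + 0.098·GC,
  which predicts e.g. 1.69 g/mL for a 31.5% GC genome.

The two calibrations differ by construction; each is the exact inverse of
its own forward form, and the EAF pipeline selects one via the
``calibration`` switch (default ``"hungate"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateChemistryError,
    ImplausibleDensityError,
    InvalidProfileError,
    PairingError,
)

#: Natural abundance of ¹³C; EAF saturates at 1 minus this value.
NATURAL_13C_ABUNDANCE = 0.01111233

# GC -> unlabeled buoyant density, qSIP equation-chain calibration.
HUNGATE_INTERCEPT = 1.646057
HUNGATE_SLOPE = 0.083506

# GC -> buoyant density, classic CsCl relation.
SCHILDKRAUT_INTERCEPT = 1.660
SCHILDKRAUT_SLOPE = 0.098

_CALIBRATIONS = {
    "hungate": (HUNGATE_INTERCEPT, HUNGATE_SLOPE),
    "schildkraut": (SCHILDKRAUT_INTERCEPT, SCHILDKRAUT_SLOPE),
}

# Mean molecular weight per nucleotide of unlabeled DNA as a function of GC.
M_LIGHT_INTERCEPT = 307.691
M_LIGHT_SLOPE = 0.496

# Maximum ¹³C mass gain per nucleotide as a function of GC.
M_HEAVY_GAIN_INTERCEPT = 9.974564
M_HEAVY_GAIN_SLOPE = -0.4987282

#: Buoyant densities outside this window are physically implausible for DNA in CsCl.
DENSITY_WINDOW = (1.60, 1.85)


def _check_calibration(calibration: str) -> tuple[float, float]:
    try:
        return _CALIBRATIONS[calibration]
    except KeyError:
        raise ValueError(
            f"unknown calibration {calibration!r}; expected one of {sorted(_CALIBRATIONS)}"
        ) from None


@dataclass(frozen=True)
class GradientFraction:
    """One fraction of a CsCl gradient: measured density and qPCR copy number."""

    fraction_index: int
    density: float
    copies: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if not (DENSITY_WINDOW[0] <= self.density <= DENSITY_WINDOW[1]):
            raise ValueError(
                f"fraction {self.fraction_index}: density {self.density} g/mL outside "
                f"{DENSITY_WINDOW}"
            )
        if self.copies < 0:
            raise ValueError(f"fraction {self.fraction_index}: negative copies {self.copies}")

    @property
    def effective_copies(self) -> float:
        """Copies contributing to the weighted mean; zero when below detection."""
        return 0.0 if self.below_detection else self.copies


@dataclass(frozen=True)
class GradientProfile:
    """An ordered qPCR-over-density curve for one incubation and marker."""

    sample_id: str
    marker: str
    label: str  # "labeled" or "unlabeled"
    fractions: tuple[GradientFraction, ...]
    replicate_id: str | None = None
    isotope: str = "13C"

    def __post_init__(self) -> None:
        fractions = tuple(self.fractions)
        object.__setattr__(self, "fractions", fractions)
        if self.label not in ("labeled", "unlabeled"):
            raise ValueError(f"label must be 'labeled' or 'unlabeled', got {self.label!r}")
        indices = [f.fraction_index for f in fractions]
        if len(set(indices)) != len(indices):
            raise ValueError(f"profile {self.sample_id}: duplicate fraction indices")
        ordered = [f.density for f in sorted(fractions, key=lambda f: f.fraction_index)]
        diffs = np.diff(ordered)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError(
                f"profile {self.sample_id}: densities not strictly monotone over fraction index"
            )

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions])

    @property
    def copies(self) -> np.ndarray:
        return np.array([f.effective_copies for f in self.fractions])


@dataclass(frozen=True)
class StandardCurve:
    """A qPCR standard curve: Cq = slope·log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def is_valid(self) -> bool:
        if self.slope >= 0:
            return False
        return 0.90 <= self.efficiency <= 1.10 and self.r_squared > 0.9


def quantify_from_cq(
    cq: float, curve: StandardCurve, detection_cq: float = 35.0
) -> tuple[float, bool]:
    """Convert a cycle-threshold value to copies via a standard curve.

    Returns ``(copies, below_detection)``; Cq at or beyond the no-template
    control threshold (default 35 cycles) is flagged below detection.
    """
    if not curve.is_valid:
        raise ValueError(
            f"standard curve rejected: slope={curve.slope}, "
            f"efficiency={curve.efficiency if curve.slope < 0 else float('nan'):.3f}, "
            f"r_squared={curve.r_squared}"
        )
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return copies, cq >= detection_cq


def weighted_average_density(profile: GradientProfile, min_positive: int = 3) -> float:
    """Copy-weighted mean buoyant density W = Σ ρᵢ·yᵢ / Σ yᵢ of a profile.

    Requires at least ``min_positive`` fractions with detectable copies so
    that a single noisy fraction cannot masquerade as a band position.
    """
    copies = profile.copies
    positive = int(np.count_nonzero(copies > 0))
    if positive == 0:
        raise InvalidProfileError(f"profile {profile.sample_id}: all copies are zero")
    if positive < min_positive:
        raise InvalidProfileError(
            f"profile {profile.sample_id}: only {positive} quantified fractions "
            f"(need ≥ {min_positive})"
        )
    return float(np.dot(profile.densities, copies) / copies.sum())


def density_from_gc(gc: float, calibration: str = "schildkraut") -> float:
    """Predict the CsCl buoyant density of unlabeled DNA from its GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    intercept, slope = _check_calibration(calibration)
    return intercept + slope * gc


def gc_from_density(
    w_light: float, calibration: str = "hungate", tolerance: float = 0.05
) -> float:
    """Infer GC fraction from the unlabeled weighted mean density.

    Values implying GC slightly outside [0, 1] (within ``tolerance``) are
    clamped with a warning; anything further out raises
    :class:`~sipdom.errors.ImplausibleDensityError`.
    """
    intercept, slope = _check_calibration(calibration)
    gc = (w_light - intercept) / slope
    if not (-tolerance <= gc <= 1.0 + tolerance):
        raise ImplausibleDensityError(
            f"density {w_light} g/mL implies GC {gc:.3f}, outside "
            f"[-{tolerance}, 1+{tolerance}]"
        )
    if gc < 0.0 or gc > 1.0:
        clamped = min(max(gc, 0.0), 1.0)
        if abs(gc - clamped) < 1e-9:  # floating-point noise, not measurement noise
            return clamped
        warnings.warn(
            f"GC {gc:.4f} inferred from density {w_light} clamped to {clamped}",
            stacklevel=2,
        )
        return clamped
    return gc


def light_molecular_weight(gc: float) -> float:
    """Mean molecular weight per nucleotide (g/mol) of unlabeled DNA."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    return M_LIGHT_SLOPE * gc + M_LIGHT_INTERCEPT


def labeled_molecular_weight(w_lab: float, w_light: float, m_light: float) -> float:
    """Molecular weight of the labeled DNA inferred from the density shift.

    M_lab = (ΔW / W_light + 1) · M_light, i.e. the relative density gain
    maps one-to-one onto a relative mass gain.
    """
    if w_light <= 0:
        raise ValueError("unlabeled weighted density must be positive")
    return ((w_lab - w_light) / w_light + 1.0) * m_light


def max_heavy_molecular_weight(gc: float, m_light: float) -> float:
    """Molecular weight at full ¹³C substitution of every carbon atom."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    return m_light + (M_HEAVY_GAIN_SLOPE * gc + M_HEAVY_GAIN_INTERCEPT)


def excess_atom_fraction(m_lab: float, m_light: float, m_heavymax: float) -> float:
    """Excess atom fraction of ¹³C from the molecular-weight triplet.

    EAF = (M_lab − M_light)/(M_heavymax − M_light) × (1 − 0.01111233).
    Zero when the labeled and light weights coincide; saturates at
    1 − 0.01111233 when every carbon is ¹³C.  Small negative values are
    possible with noisy gradients and are returned unclipped.
    """
    if m_heavymax <= m_light:
        raise DegenerateChemistryError(
            f"M_heavymax ({m_heavymax}) must exceed M_light ({m_light})"
        )
    return (m_lab - m_light) / (m_heavymax - m_light) * (1.0 - NATURAL_13C_ABUNDANCE)


@dataclass(frozen=True)
class PairEaf:
    """The full equation chain for one labeled/unlabeled profile pair."""

    labeled_id: str
    unlabeled_id: str
    w_light: float
    w_lab: float
    gc: float
    m_light: float
    m_lab: float
    m_heavymax: float
    eaf: float

    @property
    def dw(self) -> float:
        return self.w_lab - self.w_light

    @property
    def atom_percent(self) -> float:
        """EAF expressed as atom % (×100), matching 'atm%' reporting."""
        return self.eaf * 100.0


@dataclass(frozen=True)
class EafResult:
    """Per-pair EAF values with summary statistics across replicate pairs."""

    pairs: tuple[PairEaf, ...]
    calibration: str
    ci: tuple[float, float] | None = None

    @property
    def eaf_values(self) -> np.ndarray:
        return np.array([p.eaf for p in self.pairs])

    @property
    def mean_eaf(self) -> float:
        return float(self.eaf_values.mean())

    @property
    def sd_eaf(self) -> float:
        values = self.eaf_values
        return float(values.std(ddof=1)) if len(values) > 1 else 0.0

    @property
    def mean_eaf_clipped(self) -> float:
        """Summary with negative per-pair values clipped to zero."""
        return float(np.clip(self.eaf_values, 0.0, None).mean())

    @property
    def mean_atom_percent(self) -> float:
        return self.mean_eaf * 100.0


def eaf_single_pair(
    w_lab: float,
    w_light: float,
    calibration: str = "hungate",
    labeled_id: str = "labeled",
    unlabeled_id: str = "unlabeled",
) -> PairEaf:
    """Run the density → GC → molecular weight → EAF chain for one pair."""
    gc = gc_from_density(w_light, calibration=calibration)
    m_light = light_molecular_weight(gc)
    m_lab = labeled_molecular_weight(w_lab, w_light, m_light)
    m_heavymax = max_heavy_molecular_weight(gc, m_light)
    eaf = excess_atom_fraction(m_lab, m_light, m_heavymax)
    return PairEaf(
        labeled_id=labeled_id,
        unlabeled_id=unlabeled_id,
        w_light=w_light,
        w_lab=w_lab,
        gc=gc,
        m_light=m_light,
        m_lab=m_lab,
        m_heavymax=m_heavymax,
        eaf=eaf,
    )


def _as_profiles(profiles) -> list[GradientProfile]:
    if isinstance(profiles, GradientProfile):
        return [profiles]
    return list(profiles)


def eaf_from_profiles(
    labeled,
    unlabeled,
    pairing: str = "replicate",
    calibration: str = "hungate",
    bootstrap: int = 0,
    seed: int | None = None,
    min_positive: int = 3,
) -> EafResult:
    """Estimate EAF from labeled and unlabeled gradient profiles.

    Parameters
    ----------
    labeled, unlabeled
        A :class:`GradientProfile` or sequence thereof; all profiles must
        share marker and isotope.
    pairing
        ``"replicate"`` pairs profiles one-to-one by ``replicate_id``;
        ``"mean-control"`` compares every labeled profile against the mean
        weighted density of all unlabeled controls.
    bootstrap
        If > 0, a seeded bootstrap over replicate pairs with this many
        resamples; the 2.5–97.5 percentile interval of the mean EAF is
        attached to the result.
    """
    labeled_list = _as_profiles(labeled)
    unlabeled_list = _as_profiles(unlabeled)
    if not labeled_list or not unlabeled_list:
        raise PairingError("need at least one labeled and one unlabeled profile")
    markers = {p.marker for p in labeled_list + unlabeled_list}
    isotopes = {p.isotope for p in labeled_list + unlabeled_list}
    if len(markers) > 1:
        raise PairingError(f"marker mismatch across profiles: {sorted(markers)}")
    if len(isotopes) > 1:
        raise PairingError(f"isotope mismatch across profiles: {sorted(isotopes)}")
    for p in labeled_list:
        if p.label != "labeled":
            raise PairingError(f"profile {p.sample_id} passed as labeled has label {p.label!r}")
    for p in unlabeled_list:
        if p.label != "unlabeled":
            raise PairingError(
                f"profile {p.sample_id} passed as unlabeled has label {p.label!r}"
            )

    pairs: list[PairEaf] = []
    if pairing == "replicate":
        lab_by_rep = {p.replicate_id: p for p in labeled_list}
        unlab_by_rep = {p.replicate_id: p for p in unlabeled_list}
        if len(lab_by_rep) != len(labeled_list) or len(unlab_by_rep) != len(unlabeled_list):
            raise PairingError("duplicate replicate_id within labeled or unlabeled set")
        if set(lab_by_rep) != set(unlab_by_rep):
            raise PairingError(
                f"replicate ids differ: labeled {sorted(map(str, lab_by_rep))} vs "
                f"unlabeled {sorted(map(str, unlab_by_rep))}"
            )
        for rep in sorted(lab_by_rep, key=str):
            lab, unlab = lab_by_rep[rep], unlab_by_rep[rep]
            w_light = weighted_average_density(unlab, min_positive=min_positive)
            w_lab = weighted_average_density(lab, min_positive=min_positive)
            pairs.append(
                eaf_single_pair(
                    w_lab,
                    w_light,
                    calibration=calibration,
                    labeled_id=lab.sample_id,
                    unlabeled_id=unlab.sample_id,
                )
            )
    elif pairing == "mean-control":
        w_light = float(
            np.mean(
                [weighted_average_density(p, min_positive=min_positive) for p in unlabeled_list]
            )
        )
        control_id = "+".join(p.sample_id for p in unlabeled_list)
        for lab in labeled_list:
            w_lab = weighted_average_density(lab, min_positive=min_positive)
            pairs.append(
                eaf_single_pair(
                    w_lab,
                    w_light,
                    calibration=calibration,
                    labeled_id=lab.sample_id,
                    unlabeled_id=control_id,
                )
            )
    else:
        raise ValueError(f"unknown pairing scheme {pairing!r}")

    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        values = np.array([p.eaf for p in pairs])
        means = np.array(
            [
                values[rng.integers(0, len(values), size=len(values))].mean()
                for _ in range(bootstrap)
            ]
        )
        ci = (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))

    return EafResult(pairs=tuple(pairs), calibration=calibration, ci=ci)
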