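"""Ground-truthed synthetic data for the qSIP and DOM pipelines.

Every generator is a pure function of a configuration plus a seed, and
returns a :class:`SyntheticTruth` record alongside the simulated dataset so
that estimator round-trips can be scored against known parameters.

Gradient pairs are simulated by inverting the EAF equation chain: the
unlabeled band centre follows from the taxon's GC content via the selected
GC–density calibration, the labeled band centre from the true EAF via the
molecular-weight chain, and copies per fraction are the integral of a
Gaussian band over each fraction's density interval (the standard
isoconcentration approximation), scaled to a total copy number, then
multiplied by lognormal qPCR noise and truncated at a detection floor.

Peak lists are built from CHNOSP formulas sampled inside the assignment
constraint space, converted to [M−H]⁻ m/z with Normal ppm-scale mass error
and lognormal intensities, plus formula-free noise peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigError
from .formula import (
    DEFAULT_RANGES,
    PROTON_MASS,
    ElementRanges,
    MolecularFormula,
    Peak,
    classify_formula,
)
from .qsip import (
    NATURAL_13C_ABUNDANCE,
    GradientFraction,
    GradientProfile,
    density_from_gc,
    light_molecular_weight,
    max_heavy_molecular_weight,
)
from .domstats import SampleMatrix


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters serialized alongside each simulated dataset."""

    seed: int | None
    true_eaf: float | None = None
    taxon_gc: float | None = None
    band_center_unlabeled: float | None = None
    band_center_labeled: float | None = None
    formulas: tuple[MolecularFormula | None, ...] | None = None
    group_labels: tuple[str, ...] | None = None
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GradientSimConfig:
    """Geometry, band, and noise parameters for a simulated gradient pair.

    Defaults mirror the experimental setup: 15 fractions spanning the
    1.66–1.78 g/mL working range of a CsCl gradient started at 1.70 g/mL,
    a 0.006 g/mL Gaussian band width, and 20% CV multiplicative qPCR noise.
    """

    taxon_gc: float
    true_eaf: float = 0.0
    n_fractions: int = 15
    density_min: float = 1.66
    density_max: float = 1.78
    band_sd: float = 0.006
    total_copies: float = 1e6
    qpcr_cv: float = 0.20
    detection_floor: float = 0.0
    calibration: str = "hungate"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_fractions < 5:
            raise ConfigError("need at least 5 fractions")
        if self.band_sd <= 0:
            raise ConfigError("band_sd must be positive")
        if not (0.0 <= self.true_eaf <= 1.0 - NATURAL_13C_ABUNDANCE):
            raise ConfigError(
                f"true_eaf {self.true_eaf} outside [0, {1.0 - NATURAL_13C_ABUNDANCE:.8f}]"
            )
        if self.density_min >= self.density_max:
            raise ConfigError("density_min must be below density_max")


def band_centers(config: GradientSimConfig) -> tuple[float, float]:
    """Unlabeled and labeled band-centre densities implied by the config."""
    rho0 = density_from_gc(config.taxon_gc, calibration=config.calibration)
    m_light = light_molecular_weight(config.taxon_gc)
    m_heavymax = max_heavy_molecular_weight(config.taxon_gc, m_light)
    m_lab = m_light + config.true_eaf / (1.0 - NATURAL_13C_ABUNDANCE) * (
        m_heavymax - m_light
    )
    rho_lab = rho0 * m_lab / m_light
    return rho0, rho_lab


def _band_profile(
    center: float,
    config: GradientSimConfig,
    rng: np.random.Generator,
    sample_id: str,
    label: str,
    replicate_id: str | None,
) -> GradientProfile:
    centers = np.linspace(config.density_min, config.density_max, config.n_fractions)
    step = centers[1] - centers[0]
    edges = np.concatenate([[centers[0] - step / 2], centers[:-1] + step / 2,
                            [centers[-1] + step / 2]])
    mass = np.diff(norm.cdf(edges, loc=center, scale=config.band_sd))
    total = mass.sum()
    if total <= 0:
        raise ConfigError(f"band at {center} g/mL carries no mass inside the density span")
    copies = mass / total * config.total_copies
    if config.qpcr_cv > 0:
        sigma = np.sqrt(np.log1p(config.qpcr_cv ** 2))
        copies = copies * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=copies.shape)
    fractions = []
    for i, (rho, y) in enumerate(zip(centers, copies), start=1):
        below = y < config.detection_floor
        fractions.append(
            GradientFraction(
                fraction_index=i,
                density=float(rho),
                copies=0.0 if below else float(y),
                below_detection=bool(below),
            )
        )
    return GradientProfile(
        sample_id=sample_id,
        marker="18S",
        label=label,
        fractions=tuple(fractions),
        replicate_id=replicate_id,
    )


def simulate_gradient_pair(
    config: GradientSimConfig, replicate_id: str | None = None
) -> tuple[GradientProfile, GradientProfile, SyntheticTruth]:
    """Simulate a labeled/unlabeled gradient pair with known true EAF."""
    rho0, rho_lab = band_centers(config)
    for name, center in (("unlabeled", rho0), ("labeled", rho_lab)):
        if not (config.density_min <= center <= config.density_max):
            raise ConfigError(
                f"{name} band centre {center:.4f} g/mL outside density span "
                f"[{config.density_min}, {config.density_max}]"
            )
    rng = np.random.default_rng(config.seed)
    unlabeled = _band_profile(rho0, config, rng, "sim-unlabeled", "unlabeled", replicate_id)
    labeled = _band_profile(rho_lab, config, rng, "sim-labeled", "labeled", replicate_id)
    truth = SyntheticTruth(
        seed=config.seed,
        true_eaf=config.true_eaf,
        taxon_gc=config.taxon_gc,
        band_center_unlabeled=rho0,
        band_center_labeled=rho_lab,
        extras={"calibration": config.calibration},
    )
    return labeled, unlabeled, truth


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Composition and noise parameters for a simulated FT-ICR-MS peak list.

    Defaults approximate a marine-DOM spectrum: ~2500 formulas per sample
    (the per-sample assignment counts of the study), H/C mostly 0.3–2.2 and
    O/C up to 1.0, m/z acquisition window 95–1000 Da, sub-ppm mass error,
    and lognormal intensities.
    """

    n_formulas: int = 2500
    constraints: ElementRanges = DEFAULT_RANGES
    hc_range: tuple[float, float] = (0.3, 2.2)
    oc_range: tuple[float, float] = (0.05, 1.0)
    mz_min: float = 95.0
    mz_max: float = 1000.0
    ppm_sd: float = 0.2
    intensity_meanlog: float = 0.0
    intensity_sdlog: float = 1.0
    n_noise_peaks: int = 0
    p_n: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    p_s: tuple[float, ...] = (0.85, 0.12, 0.03)
    p_p: tuple[float, ...] = (0.92, 0.08)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_formulas < 1:
            raise ConfigError("n_formulas must be positive")
        if not (self.mz_min < self.mz_max):
            raise ConfigError("empty m/z window")
        if self.hc_range[0] >= self.hc_range[1] or self.oc_range[0] >= self.oc_range[1]:
            raise ConfigError("degenerate H/C or O/C sampling range")


def _valid_formula(f: MolecularFormula, ranges: ElementRanges) -> bool:
    checks = (
        ranges.c[0] <= f.c <= ranges.c[1],
        ranges.h[0] <= f.h <= ranges.h[1],
        ranges.o[0] <= f.o <= ranges.o[1],
        ranges.n[0] <= f.n <= ranges.n[1],
        ranges.s[0] <= f.s <= ranges.s[1],
        ranges.p[0] <= f.p <= ranges.p[1],
        f.h <= 2 * f.c + 2 + f.n,
        (f.h % 2) == ((f.n + f.p) % 2),
        f.dbe >= 0,
    )
    return all(checks)


def sample_formula(
    rng: np.random.Generator, config: SpectrumSimConfig, max_tries: int = 1000
) -> MolecularFormula:
    """Draw one chemically valid formula with realistic H/C and O/C ratios."""
    ranges = config.constraints
    for _ in range(max_tries):
        c = int(rng.integers(max(ranges.c[0], 4), min(ranges.c[1], 60) + 1))
        n = int(rng.choice(len(config.p_n), p=config.p_n)) + ranges.n[0]
        s = int(rng.choice(len(config.p_s), p=config.p_s)) + ranges.s[0]
        p = int(rng.choice(len(config.p_p), p=config.p_p)) + ranges.p[0]
        h = int(round(rng.uniform(*config.hc_range) * c))
        # Nitrogen rule: flip parity downward if needed.
        if (h % 2) != ((n + p) % 2):
            h -= 1
        o = int(round(rng.uniform(*config.oc_range) * c))
        o = max(o, ranges.o[0])
        if h < max(ranges.h[0], 1):
            continue
        f = MolecularFormula(c=c, h=h, o=o, n=n, s=s, p=p)
        mz = f.monoisotopic_mass - PROTON_MASS
        if _valid_formula(f, ranges) and config.mz_min <= mz <= config.mz_max:
            return f
    raise ConfigError("could not sample a valid formula; constraint ranges infeasible")


def sample_constraint_space(
    n: int,
    rng: np.random.Generator,
    mass_max: float = 500.0,
    constraints: ElementRanges = DEFAULT_RANGES,
) -> list[MolecularFormula]:
    """Uniform draws of valid formulas from the constraint space, mass-capped.

    Element counts are drawn uniformly over their ranges and rejected until
    they satisfy the chemical filters and the mass ceiling; used for
    enumeration round-trip and classification-partition checks.
    """
    out: list[MolecularFormula] = []
    r = constraints
    while len(out) < n:
        c = int(rng.integers(r.c[0], r.c[1] + 1))
        h = int(rng.integers(r.h[0], r.h[1] + 1))
        o = int(rng.integers(r.o[0], r.o[1] + 1))
        nn = int(rng.integers(r.n[0], r.n[1] + 1))
        s = int(rng.integers(r.s[0], r.s[1] + 1))
        p = int(rng.integers(r.p[0], r.p[1] + 1))
        f = MolecularFormula(c=c, h=h, o=o, n=nn, s=s, p=p)
        if _valid_formula(f, r) and f.monoisotopic_mass <= mass_max:
            out.append(f)
    return out


def simulate_peak_list(config: SpectrumSimConfig):
    """Simulate one peak list: truth peaks from known formulas plus noise.

    Returns ``(peaks, truth)`` where ``truth.formulas`` aligns with the
    m/z-sorted peak list (``None`` marks noise peaks).
    """
    rng = np.random.default_rng(config.seed)
    formulas: list[MolecularFormula] = []
    seen: set[MolecularFormula] = set()
    guard = 0
    while len(formulas) < config.n_formulas:
        f = sample_formula(rng, config)
        guard += 1
        if f not in seen:
            seen.add(f)
            formulas.append(f)
        if guard > 50 * config.n_formulas:
            raise ConfigError("formula sampling stalled; constraint ranges too tight")
    records: list[tuple[float, float, MolecularFormula | None]] = []
    for f in formulas:
        mz_true = f.monoisotopic_mass - PROTON_MASS
        eps = rng.normal(0.0, config.ppm_sd * 1e-6) if config.ppm_sd > 0 else 0.0
        mz = mz_true * (1.0 + eps)
        intensity = rng.lognormal(config.intensity_meanlog, config.intensity_sdlog)
        records.append((mz, intensity, f))
    for _ in range(config.n_noise_peaks):
        mz = rng.uniform(config.mz_min, config.mz_max)
        intensity = rng.lognormal(config.intensity_meanlog - 1.0, config.intensity_sdlog)
        records.append((mz, intensity, None))
    records.sort(key=lambda r: r[0])
    peaks = [Peak(mz=mz, intensity=inten) for mz, inten, _ in records]
    truth = SyntheticTruth(
        seed=config.seed,
        formulas=tuple(f for _, _, f in records),
        extras={"n_noise_peaks": config.n_noise_peaks, "ppm_sd": config.ppm_sd},
    )
    return peaks, truth


def simulate_dom_groups(
    n_per_group: int,
    groups: Mapping[str, Mapping[str, float]],
    seed: int | None = None,
    n_formulas: int = 300,
    sample_cv: float = 0.15,
    library_config: SpectrumSimConfig | None = None,
) -> tuple[SampleMatrix, SyntheticTruth]:
    """Simulate grouped DOM samples with class-level intensity shifts.

    A shared formula library with lognormal baseline intensities is drawn
    once; each group multiplies the intensities of formulas in the classes
    named in its effect map (e.g. ``{"sediment": {"Unsaturated with N": 3.0}}``),
    then per-sample lognormal noise is applied and rows are normalized.
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    if n_per_group < 2:
        raise ConfigError("need at least two samples per group")
    rng = np.random.default_rng(seed)
    cfg = library_config or SpectrumSimConfig(
        n_formulas=n_formulas, seed=None, ppm_sd=0.0
    )
    library: list[MolecularFormula] = []
    seen: set[MolecularFormula] = set()
    while len(library) < n_formulas:
        f = sample_formula(rng, cfg)
        if f not in seen:
            seen.add(f)
            library.append(f)
    classes = [classify_formula(f) for f in library]
    baseline = rng.lognormal(0.0, 1.0, size=n_formulas)
    if np.count_nonzero(baseline) <= 1:
        raise ConfigError("degenerate composition: all mass on one formula")
    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    sigma = np.sqrt(np.log1p(sample_cv ** 2)) if sample_cv > 0 else 0.0
    for gname in groups:
        effects = groups[gname]
        mult = np.array([float(effects.get(cls, 1.0)) for cls in classes])
        for i in range(n_per_group):
            noise = (
                rng.lognormal(-sigma ** 2 / 2, sigma, size=n_formulas)
                if sigma > 0
                else np.ones(n_formulas)
            )
            intensity = baseline * mult * noise
            rows.append(intensity / intensity.sum())
            sample_ids.append(f"{gname}-{i + 1}")
            labels.append(gname)
    matrix = SampleMatrix(
        sample_ids=sample_ids,
        formula_keys=[str(f) for f in library],
        values=np.vstack(rows),
    )
    truth = SyntheticTruth(
        seed=seed,
        group_labels=tuple(labels),
        extras={"effects": {g: dict(e) for g, e in groups.items()},
                "classes": classes},
    )
    return matrix, truth
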