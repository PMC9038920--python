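"""Sample-level DOM comparisons: Bray–Curtis, PCoA, and habitat grouping.

Samples are compared on the relative signal intensities of their assigned
molecular formulas.  Bray–Curtis dissimilarity BC(j,k) = Σ|xⱼ−xₖ| / Σ(xⱼ+xₖ)
is computed on the sample × formula matrix (formulas absent from a sample
contribute zero; no imputation), and principal coordinates analysis embeds
the resulting dissimilarity matrix via Gower double-centering and
eigendecomposition.  Habitat categories follow depth, dissolved-oxygen and
redox rules for a redox-stratified upwelling system: surface ocean,
oxycline, oxygen minimum zone (OMZ), suboxic core top, and sulfidic
subseafloor sediments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnclassifiableHabitatError
from .formula import DomSample, MolecularFormula

HABITATS = ("surface", "oxycline", "OMZ", "core_top", "subseafloor")


@dataclass
class SampleMatrix:
    """Relative-intensity matrix, samples × formulas, rows summing to one."""

    sample_ids: list[str]
    formula_keys: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.formula_keys)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.formula_keys)} formulas"
            )
        if np.any(self.values < 0):
            raise ValueError("relative intensities must be non-negative")

    @classmethod
    def from_samples(cls, samples: Sequence[DomSample]) -> "SampleMatrix":
        """Union the formulas of normalized samples into one matrix."""
        keys: list[str] = []
        seen: dict[str, int] = {}
        per_sample: list[dict[str, float]] = []
        for s in samples:
            row = {str(f): v for f, v in s.rel_intensity.items()}
            per_sample.append(row)
            for k in row:
                if k not in seen:
                    seen[k] = len(keys)
                    keys.append(k)
        values = np.zeros((len(samples), len(keys)))
        for i, row in enumerate(per_sample):
            for k, v in row.items():
                values[i, seen[k]] = v
        return cls([s.sample_id for s in samples], keys, values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.formula_keys)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal, entries in [0, 1]."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"dissimilarity matrix shape {self.d.shape} for {n} labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")

    def percent(self) -> np.ndarray:
        """Percent-scale view (×100) of the dissimilarities."""
        return self.d * 100.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class Ordination:
    """PCoA result: coordinates on axes of positive eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray  # n_samples × n_positive_axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def bray_curtis(matrix: SampleMatrix) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis dissimilarity between the rows of a sample matrix."""
    x = matrix.values
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    row_sums = x.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = [matrix.sample_ids[i] for i in np.nonzero(row_sums <= 0)[0]]
        raise ValueError(f"all-zero rows make Bray–Curtis undefined: {bad}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            num = np.abs(x[j] - x[k]).sum()
            den = (x[j] + x[k]).sum()
            d[j, k] = d[k, j] = num / den
    return DissimilarityMatrix(labels=list(matrix.sample_ids), d=d)


def pcoa(dm: DissimilarityMatrix, eig_tol: float = 1e-10) -> Ordination:
    """Principal coordinates analysis by Gower double-centering.

    B = −½·J·D²·J with J = I − 11ᵀ/n is eigendecomposed; coordinates are
    eigenvectors scaled by √λ for eigenvalues above ``eig_tol`` relative to
    the largest.  Negative eigenvalues (non-Euclidean dissimilarities) are
    reported in ``eigenvalues`` but yield no coordinates, and the explained
    proportions are taken over the positive eigenvalues only.
    """
    d = dm.d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0) if len(eigvals) else 1.0
    positive = eigvals > eig_tol * scale
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return Ordination(
        sample_ids=list(dm.labels),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# Water-column depth windows (m) with their characteristic O2 bands (µM).
_WATER_RULES = {
    "surface": ((5.0, 10.0), (110.0, 160.0)),
    "oxycline": ((50.0, 95.0), (40.0, 110.0)),
    "OMZ": ((95.0, 125.0), (0.0, 60.0)),
}


def assign_habitat(
    depth: float,
    o2: float | None = None,
    matrix_type: str = "water",
    redox: str | None = None,
) -> str:
    """Classify a sample into one of the five biogeochemical habitats.

    Water samples (depth in m, O₂ in µM) are classified by depth window —
    surface 5–10 m, oxycline 50–95 m, OMZ 95–125 m — with depth taking
    precedence where windows meet (95 m is assigned to the OMZ).  Sediment
    samples (depth in cmbsf) are classified by redox state: suboxic pore
    water is core top, sulfidic is subseafloor.  Metadata outside every
    rule raises :class:`~sipdom.errors.UnclassifiableHabitatError`.
    """
    if matrix_type == "water":
        if o2 is None:
            raise ValueError("water samples require a dissolved-O2 value")
        hits = [
            name
            for name, ((dlo, dhi), _) in _WATER_RULES.items()
            if dlo <= depth <= dhi
        ]
        if not hits:
            raise UnclassifiableHabitatError(
                f"water sample at {depth} m matches no depth window"
            )
        if len(hits) > 1:
            # Windows meet only at 95 m; the boundary belongs to the OMZ.
            return "OMZ" if "OMZ" in hits else hits[0]
        return hits[0]
    if matrix_type == "sediment":
        if redox == "suboxic":
            return "core_top"
        if redox == "sulfidic":
            return "subseafloor"
        raise UnclassifiableHabitatError(
            f"sediment sample at {depth} cmbsf with redox {redox!r} is unclassifiable"
        )
    raise ValueError(f"matrix_type must be 'water' or 'sediment', got {matrix_type!r}")
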