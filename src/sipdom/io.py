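"""Delimited-text readers and writers, run configuration, and provenance.

All exchange formats are comma-separated UTF-8 text with a header row and
"." as the decimal mark.  Densities are written to 4 decimal places, EAF
values to 4, and ppm errors to 3.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ParseError
from .formula import AssignedPeak, MolecularFormula, Peak
from .domstats import DissimilarityMatrix, Ordination, SampleMatrix
from .qsip import EafResult, GradientFraction, GradientProfile

logger = logging.getLogger("sipdom")

FRACTION_COLUMNS = [
    "sample_id",
    "replicate_id",
    "marker",
    "label",
    "fraction_index",
    "density_g_ml",
    "copies",
    "below_detection",
]


def read_fraction_table(path) -> list[GradientProfile]:
    """Read gradient profiles from a fraction table.

    Rows are grouped into one profile per (sample_id, marker, label,
    replicate_id); fractions are sorted by index.  Schema violations raise
    :class:`~sipdom.errors.ParseError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in FRACTION_COLUMNS if c not in df.columns and c != "below_detection"]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "below_detection" not in df.columns:
        df["below_detection"] = False
    profiles: list[GradientProfile] = []
    keys = ["sample_id", "marker", "label", "replicate_id"]
    df["replicate_id"] = df["replicate_id"].astype("string")
    for (sample_id, marker, label, replicate_id), group in df.groupby(keys, dropna=False):
        fractions = []
        seen_idx: set[int] = set()
        for row in group.itertuples():
            rownum = row.Index + 2  # header is line 1
            try:
                idx = int(row.fraction_index)
                density = float(row.density_g_ml)
                copies = float(row.copies)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path} row {rownum}: non-numeric field ({exc})") from None
            if copies < 0:
                raise ParseError(f"{path} row {rownum}: negative copies {copies}")
            if idx in seen_idx:
                raise ParseError(
                    f"{path} row {rownum}: duplicate fraction index {idx} in profile "
                    f"{sample_id}/{marker}/{label}"
                )
            seen_idx.add(idx)
            below = bool(row.below_detection) if not pd.isna(row.below_detection) else False
            try:
                fractions.append(
                    GradientFraction(
                        fraction_index=idx,
                        density=density,
                        copies=copies,
                        below_detection=below,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path} row {rownum}: {exc}") from None
        fractions.sort(key=lambda f: f.fraction_index)
        rep = None if pd.isna(replicate_id) else str(replicate_id)
        try:
            profiles.append(
                GradientProfile(
                    sample_id=str(sample_id),
                    marker=str(marker),
                    label=str(label),
                    fractions=tuple(fractions),
                    replicate_id=rep,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: profile {sample_id}/{marker}/{label}: {exc}") from None
    return profiles


def write_fraction_table(profiles: Sequence[GradientProfile], path) -> None:
    rows = []
    for p in profiles:
        for f in p.fractions:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "replicate_id": p.replicate_id if p.replicate_id is not None else "",
                    "marker": p.marker,
                    "label": p.label,
                    "fraction_index": f.fraction_index,
                    "density_g_ml": f"{f.density:.4f}",
                    "copies": repr(f.copies),
                    "below_detection": f.below_detection,
                }
            )
    pd.DataFrame(rows, columns=FRACTION_COLUMNS).to_csv(path, index=False)


def read_peak_list(path) -> list[Peak]:
    """Read a two-column (mz, intensity) peak list, ordered by m/z.

    Peaks outside the 95–1000 Da acquisition window are retained but
    logged; an empty file yields an empty list with a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty peak list", path)
        return []
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (mz, intensity)")
    df = df.iloc[:, :2]
    df.columns = ["mz", "intensity"]
    peaks = []
    for row in df.itertuples():
        rownum = row.Index + 2
        try:
            mz = float(row.mz)
            intensity = float(row.intensity)
        except (TypeError, ValueError):
            raise ParseError(f"{path} row {rownum}: non-numeric value") from None
        try:
            peak = Peak(mz=mz, intensity=intensity)
        except ValueError as exc:
            raise ParseError(f"{path} row {rownum}: {exc}") from None
        if not peak.in_window:
            logger.warning("%s row %d: m/z %.5f outside acquisition window", path, rownum, mz)
        peaks.append(peak)
    peaks.sort(key=lambda p: p.mz)
    return peaks


def write_peak_list(peaks: Sequence[Peak], path) -> None:
    pd.DataFrame(
        {"mz": [f"{p.mz:.6f}" for p in peaks], "intensity": [repr(p.intensity) for p in peaks]}
    ).to_csv(path, index=False)


def read_calibrant_list(path) -> list[MolecularFormula]:
    """Read a calibrant table with element-count columns c,h,o,n,s,p."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("c", "h"):
        if needed not in cols:
            raise ParseError(f"{path}: missing element column {needed!r}")
    out = []
    for row in df.itertuples(index=False):
        d = {k: int(getattr(row, cols[k])) if k in cols else 0 for k in "chonsp"}
        out.append(MolecularFormula(**d))
    return out


def write_eaf_table(result: EafResult, path) -> None:
    """One row per labeled/unlabeled pair, plus a summary row."""
    rows = []
    for p in result.pairs:
        rows.append(
            {
                "labeled_id": p.labeled_id,
                "unlabeled_id": p.unlabeled_id,
                "W_light_g_ml": f"{p.w_light:.4f}",
                "W_lab_g_ml": f"{p.w_lab:.4f}",
                "dW_g_ml": f"{p.dw:.4f}",
                "GC": f"{p.gc:.4f}",
                "M_light": f"{p.m_light:.4f}",
                "M_lab": f"{p.m_lab:.4f}",
                "M_heavymax": f"{p.m_heavymax:.4f}",
                "EAF": f"{p.eaf:.4f}",
                "atom_percent": f"{p.atom_percent:.2f}",
            }
        )
    summary = {
        "labeled_id": "summary",
        "unlabeled_id": result.calibration,
        "W_light_g_ml": "",
        "W_lab_g_ml": "",
        "dW_g_ml": "",
        "GC": "",
        "M_light": "",
        "M_lab": "",
        "M_heavymax": "",
        "EAF": f"{result.mean_eaf_clipped:.4f}",
        "atom_percent": f"{result.mean_eaf_clipped * 100.0:.2f}",
    }
    rows.append(summary)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_assignments(assigned: Sequence[AssignedPeak], path) -> None:
    """Assignment table: mz, intensity, element counts, error, class."""
    rows = []
    for ap in assigned:
        f = ap.best
        rows.append(
            {
                "mz": f"{ap.peak.mz:.6f}",
                "intensity": repr(ap.peak.intensity),
                "c": f.c if f else "",
                "h": f.h if f else "",
                "o": f.o if f else "",
                "n": f.n if f else "",
                "s": f.s if f else "",
                "p": f.p if f else "",
                "error_ppm": f"{ap.error_ppm:.3f}" if ap.error_ppm is not None else "",
                "ai_mod": f"{f.ai_mod:.4f}" if f else "",
                "compound_class": f.compound_class if f else "",
                "ambiguous": ap.ambiguous,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sample_matrix(matrix: SampleMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, index_label="sample_id")


def read_sample_matrix(path) -> SampleMatrix:
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix entry ({exc})") from None
    return SampleMatrix(
        sample_ids=[str(i) for i in df.index],
        formula_keys=[str(c) for c in df.columns],
        values=values,
    )


def write_dissimilarity_matrix(dm: DissimilarityMatrix, path, percent: bool = False) -> None:
    values = dm.percent() if percent else dm.d
    pd.DataFrame(values, index=dm.labels, columns=dm.labels).to_csv(
        path, index_label="sample_id", float_format="%.6f"
    )


def write_ordination(ordination: Ordination, coords_path, eigen_path) -> None:
    """Long-format coordinates plus an eigenvalue table."""
    rows = []
    for i, sid in enumerate(ordination.sample_ids):
        for axis in range(ordination.coordinates.shape[1]):
            rows.append(
                {
                    "sample_id": sid,
                    "axis": axis + 1,
                    "coordinate": f"{ordination.coordinates[i, axis]:.6f}",
                }
            )
    pd.DataFrame(rows, columns=["sample_id", "axis", "coordinate"]).to_csv(
        coords_path, index=False
    )
    n_pos = len(ordination.proportion_explained)
    eig_rows = []
    for i, ev in enumerate(ordination.eigenvalues):
        eig_rows.append(
            {
                "axis": i + 1,
                "eigenvalue": f"{ev:.6g}",
                "proportion_explained": (
                    f"{ordination.proportion_explained[i]:.6f}" if i < n_pos else ""
                ),
            }
        )
    pd.DataFrame(eig_rows).to_csv(eigen_path, index=False)


def write_truth(truth, path) -> None:
    """Serialize a SyntheticTruth record as JSON next to its dataset."""
    d = dataclasses.asdict(truth)
    if d.get("formulas") is not None:
        d["formulas"] = [str(f) if f is not None else "" for f in truth.formulas]
    Path(path).write_text(json.dumps(d, indent=2, default=str))


_RUNCONFIG_KEYS = {
    "mode",
    "fractions",
    "peaks",
    "calibrants",
    "pairing",
    "calibration",
    "tol_ppm",
    "min_oxygen",
    "detection_rel",
    "bootstrap",
    "seed",
    "out_dir",
    "percent_scale",
    "log_level",
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    mode: str  # "qsip" or "dom"
    out_dir: str
    fractions: str | None = None
    peaks: list[str] = dataclasses.field(default_factory=list)
    calibrants: str | None = None
    pairing: str = "replicate"
    calibration: str = "hungate"
    tol_ppm: float = 0.5
    min_oxygen: int = 1
    detection_rel: float = 0.0
    bootstrap: int = 0
    seed: int | None = None
    percent_scale: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "mode" not in raw or "out_dir" not in raw:
            raise ConfigError(f"{path}: config requires 'mode' and 'out_dir'")
        if raw["mode"] not in ("qsip", "dom"):
            raise ConfigError(f"{path}: mode must be 'qsip' or 'dom'")
        if isinstance(raw.get("peaks"), str):
            raw["peaks"] = [raw["peaks"]]
        return cls(**raw)

    def write_provenance(self) -> None:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        record = {"package": "sipdom", "version": __version__, "seed": self.seed,
                  "config": dataclasses.asdict(self)}
        (out / "provenance.json").write_text(json.dumps(record, indent=2))
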