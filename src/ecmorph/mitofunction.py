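"""Mitochondrial-function readouts: mito-stress-test OCR metrics and the
superoxide / membrane-potential ratio.

The extracellular-flux (Seahorse) mito stress test measures the oxygen
consumption rate (OCR) of a cell monolayer through a sequence of injections:
glucose (substrate), oligomycin (ATP-synthase inhibitor), FCCP (uncoupler)
and rotenone/antimycin A (complex I/III inhibitors). The standard derived
metrics are

    non_mito   = mean OCR after rotenone/antimycin A
    basal      = last OCR of the glucose phase - non_mito
    atp_linked = last OCR of the glucose phase - min OCR under oligomycin
    maximal    = max OCR under FCCP - non_mito
    spare      = maximal - basal

all in pmol O2/min, and additionally normalised per 1000 seeded cells.
Measurements from a pre-glucose baseline phase, when present, are carried
but ignored by the metrics: the glucose phase is the working basal state.

Mitochondrial superoxide (MitoSOX) signal is reported as a ratio to the
membrane-potential-dependent MitoTracker Red signal, making the readout
insensitive to mitochondrial mass/uptake differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .clinical_stats import TestResult, mann_whitney_u
from .profiles import bh_adjust

PHASE_ORDER = ("baseline", "glucose", "oligomycin", "fccp", "rot_aa")
REQUIRED_PHASES = ("glucose", "oligomycin", "fccp", "rot_aa")


@dataclass
class OCRTrace:
    """Ordered OCR measurements for one well of a mito stress assay.

    ``measurements`` columns: ``time_min`` (float), ``phase`` (one of
    :data:`PHASE_ORDER`), ``ocr`` (pmol O2/min); an optional ``ecar``
    column is carried through untouched. ``cell_count`` is the number of
    cells in the well, used for normalisation.
    """

    measurements: pd.DataFrame
    well_id: str = "A01"
    cell_count: int = 1

    def __post_init__(self) -> None:
        m = self.measurements
        for col in ("time_min", "phase", "ocr"):
            if col not in m.columns:
                raise ValueError(f"measurements lack column {col!r}")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")
        if not np.isfinite(m["ocr"]).all():
            raise ValueError("non-finite OCR values")
        phases = [p for p in m["phase"] if p is not None]
        order = {p: i for i, p in enumerate(PHASE_ORDER)}
        unknown = set(phases) - set(PHASE_ORDER)
        if unknown:
            raise ValueError(f"unknown phases {sorted(unknown)}")
        idx = [order[p] for p in phases]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("phases out of injection order")

    def phase_values(self, phase: str) -> np.ndarray:
        sel = self.measurements.loc[self.measurements["phase"] == phase, "ocr"]
        return sel.to_numpy(dtype=float)


@dataclass
class MitoMetrics:
    """Derived respiration metrics, raw and per-1000-cells."""

    non_mito: float
    basal: float
    atp_linked: float
    maximal: float
    spare: float
    cell_count: int
    well_id: str = ""
    warnings: list = field(default_factory=list)

    _RAW = ("non_mito", "basal", "atp_linked", "maximal", "spare")

    @property
    def per_1000(self) -> dict[str, float]:
        return {
            k: getattr(self, k) / self.cell_count * 1000.0 for k in self._RAW
        }

    def to_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self._RAW}
        d.update({f"{k}_per_1000": v for k, v in self.per_1000.items()})
        d["cell_count"] = self.cell_count
        d["well_id"] = self.well_id
        return d


def mito_stress_metrics(trace: OCRTrace) -> MitoMetrics:
    """Compute the mito-stress-test metrics for one OCR trace.

    Raises ``ValueError`` if any injection phase is missing. Negative
    derived metrics are biologically implausible but numerically possible
    under noise; they are emitted with a warning flag rather than clipped.
    """
    for phase in REQUIRED_PHASES:
        if len(trace.phase_values(phase)) == 0:
            raise ValueError(f"phase {phase!r} missing from trace {trace.well_id}")
    glucose = trace.phase_values("glucose")
    non_mito = float(np.mean(trace.phase_values("rot_aa")))
    basal = float(glucose[-1] - non_mito)
    atp_linked = float(glucose[-1] - np.min(trace.phase_values("oligomycin")))
    maximal = float(np.max(trace.phase_values("fccp")) - non_mito)
    spare = maximal - basal
    metrics = MitoMetrics(
        non_mito=non_mito,
        basal=basal,
        atp_linked=atp_linked,
        maximal=maximal,
        spare=spare,
        cell_count=trace.cell_count,
        well_id=trace.well_id,
    )
    for name in ("basal", "atp_linked", "maximal", "spare"):
        if getattr(metrics, name) < 0:
            metrics.warnings.append(f"negative {name}")
    return metrics


def metrics_table(traces) -> pd.DataFrame:
    """Apply :func:`mito_stress_metrics` to many traces; one row per well."""
    return pd.DataFrame([mito_stress_metrics(t).to_dict() for t in traces])


def mitosox_normalise(
    mitosox: pd.Series | np.ndarray, mtred: pd.Series | np.ndarray
) -> tuple[np.ndarray, int]:
    """Superoxide signal normalised to membrane potential.

    Returns the per-record ``mitosox / mtred`` ratio and the number of
    records excluded because their MitoTracker Red signal was non-positive
    (excluded ratios are returned as NaN so the caller keeps alignment).
    """
    sox = np.asarray(mitosox, dtype=float)
    red = np.asarray(mtred, dtype=float)
    if sox.shape != red.shape:
        raise ValueError("mitosox and mtred must align")
    ok = red > 0
    ratio = np.full(sox.shape, np.nan)
    ratio[ok] = sox[ok] / red[ok]
    return ratio, int((~ok).sum())


def mitosox_group_medians(
    df: pd.DataFrame,
    group_col: str = "group",
    sox_col: str = "mitosox",
    red_col: str = "mtred",
) -> pd.Series:
    """Median normalised superoxide signal per group."""
    ratio, _ = mitosox_normalise(df[sox_col], df[red_col])
    return pd.Series(ratio, index=df.index).groupby(df[group_col]).median()


def compare_groups(
    metrics: pd.DataFrame,
    value_cols,
    group_col: str = "group",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of metrics between groups.

    One row per (metric, group pair); Benjamini-Hochberg q-values are
    computed across all rows.
    """
    groups = list(pd.unique(metrics[group_col]))
    rows = []
    for col in value_cols:
        for ga, gb in combinations(groups, 2):
            a = metrics.loc[metrics[group_col] == ga, col].dropna()
            b = metrics.loc[metrics[group_col] == gb, col].dropna()
            res: TestResult = mann_whitney_u(a, b)
            rows.append(
                {
                    "metric": col,
                    "group_a": ga,
                    "group_b": gb,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_a": len(a),
                    "n_b": len(b),
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
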