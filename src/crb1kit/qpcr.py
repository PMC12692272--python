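"""Efficiency-corrected relative qPCR quantification of CRB1 isoforms.

Relative quantities follow the efficiency-corrected ratio model
(Pfaffl): ratio = E_target^dCq(target) / E_ref^dCq(ref), with each primer
pair's amplification efficiency E (fold per cycle, ideally 2) estimated
from a standard dilution series as E = 10^(-1/slope) of the Cq vs
log10(input) regression.  Isoform shares within one sample are the
efficiency-corrected quantities of the A/B/C amplicons relative to the
total-CRB1 amplicon, normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import DomainError

#: efficiency must exceed 1 (some amplification) and stay near perfect doubling
MIN_EFFICIENCY = 1.0
MAX_EFFICIENCY = 2.2
#: Cq at/above this cutoff is treated as "not detected" (quantity 0)
DEFAULT_CQ_CUTOFF = 40.0

ISOFORM_TARGETS = ("CRB1_A", "CRB1_B", "CRB1_C")
TOTAL_TARGET = "CRB1_total"


class QpcrError(ValueError):
    """Raised for invalid qPCR measurements or tables."""


@dataclass(frozen=True)
class QpcrMeasurement:
    """One quantification cycle with its primer pair's amplification efficiency."""

    sample_id: str
    target_id: str
    cq: float
    efficiency: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cq) or self.cq <= 0:
            raise QpcrError(f"Cq must be finite and positive, got {self.cq}")
        _check_efficiency(self.efficiency)


@dataclass(frozen=True)
class DilutionSeries:
    """Standard curve for one primer pair: (log10 input, Cq) pairs."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise QpcrError(f"a dilution series needs >= 3 points, got {len(self.points)}")
        amounts = [a for a, _ in self.points]
        if not all(b < a for a, b in zip(amounts, amounts[1:])):
            raise QpcrError("input amounts must be strictly decreasing")


def _check_efficiency(e: float) -> None:
    if not (MIN_EFFICIENCY < e <= MAX_EFFICIENCY):
        raise QpcrError(
            f"amplification efficiency {e} outside ({MIN_EFFICIENCY}, {MAX_EFFICIENCY}]"
        )


def fit_efficiency(series: DilutionSeries) -> float:
    """Estimate amplification efficiency from a standard curve.

    Least-squares slope ``b`` of Cq against log10(relative input); the
    per-cycle fold amplification is ``E = 10^(-1/b)``.  A slope of
    -log2(10) ~ -3.32 corresponds to perfect doubling (E = 2).
    """
    x = np.array([a for a, _ in series.points], dtype=float)
    y = np.array([c for _, c in series.points], dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    if slope >= 0:
        raise QpcrError(f"non-negative standard-curve slope {slope:.4g}")
    return float(10.0 ** (-1.0 / slope))


def pfaffl_ratio(
    target: tuple[float, float, float], reference: tuple[float, float, float]
) -> float:
    """Efficiency-corrected expression ratio of sample vs control.

    Both arguments are ``(E, Cq_control, Cq_sample)`` triples; the ratio is
    ``E_t^(Cq_control,t - Cq_sample,t) / E_r^(Cq_control,r - Cq_sample,r)``.
    """
    e_t, cq_control_t, cq_sample_t = target
    e_r, cq_control_r, cq_sample_r = reference
    _check_efficiency(e_t)
    _check_efficiency(e_r)
    for cq in (cq_control_t, cq_sample_t, cq_control_r, cq_sample_r):
        if not np.isfinite(cq):
            raise QpcrError(f"non-finite Cq {cq}")
    return float(
        e_t ** (cq_control_t - cq_sample_t) / e_r ** (cq_control_r - cq_sample_r)
    )


def isoform_shares(
    measurements: Mapping[str, tuple[float, float]],
    total: Optional[tuple[float, float]] = None,
    cq_cutoff: float = DEFAULT_CQ_CUTOFF,
) -> dict[str, float]:
    """Isoform expression shares within one sample.

    ``measurements`` maps isoform target ids (CRB1_A/B/C, or bare A/B/C) to
    ``(E, Cq)``; ``total`` is the optional total-CRB1 ``(E, Cq)`` anchor.
    Each isoform's efficiency-corrected quantity is
    ``Q_i = E_i^(Cq_anchor - Cq_i)`` and shares are ``Q_i / sum_j Q_j``
    (the anchor cancels under normalization, so shares are invariant to a
    constant Cq shift and to the choice of anchor).  Targets at/above the
    detection cutoff get quantity 0.
    """
    keys = {k.replace("CRB1_", ""): k for k in measurements}
    missing = [iso for iso in "ABC" if iso not in keys]
    if missing:
        raise QpcrError(f"missing isoform measurement(s): {missing}")
    cq_anchor = total[1] if total is not None else min(
        cq for _, cq in measurements.values()
    )
    quantities = {}
    for iso in "ABC":
        e, cq = measurements[keys[iso]]
        _check_efficiency(e)
        if not np.isfinite(cq):
            raise QpcrError(f"non-finite Cq for isoform {iso}")
        quantities[iso] = 0.0 if cq >= cq_cutoff else float(e ** (cq_anchor - cq))
    denom = sum(quantities.values())
    if denom == 0:
        raise QpcrError("no isoform detected below the Cq cutoff")
    return {iso: q / denom for iso, q in quantities.items()}


def shares_from_table(
    table, cq_cutoff: float = DEFAULT_CQ_CUTOFF
) -> pd.DataFrame:
    """Compute per-sample isoform shares from a long-format measurement table.

    Expects columns ``sample_id, target_id, Cq, efficiency``; technical
    replicates (repeated sample/target rows) are averaged on the Cq scale
    before ratio computation.  Returns one row per sample with the A/B/C
    shares.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t")
    required = {"sample_id", "target_id", "Cq", "efficiency"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"measurement table lacks columns {sorted(missing)}")

    rows = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        collapsed = group.groupby("target_id").agg(
            Cq=("Cq", "mean"), efficiency=("efficiency", "first")
        )
        meas = {
            t: (float(r["efficiency"]), float(r["Cq"]))
            for t, r in collapsed.iterrows()
            if t in ISOFORM_TARGETS or t in ("A", "B", "C")
        }
        total = None
        if TOTAL_TARGET in collapsed.index:
            r = collapsed.loc[TOTAL_TARGET]
            total = (float(r["efficiency"]), float(r["Cq"]))
        shares = isoform_shares(meas, total=total, cq_cutoff=cq_cutoff)
        rows.append({"sample_id": sample_id, **{f"share_{k}": v for k, v in shares.items()}})
    return pd.DataFrame(rows)
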