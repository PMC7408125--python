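"""Chromatographic peak integration and reference-relative abundances.

Production levels are semi-quantitative: the integrated area of a
compound's extracted-ion-chromatogram (EIC) peak, expressed as a
percentage of the area measured for a designated reference strain (the
reference is fixed to 100% for every compound it produces).  When the
reference strain does not produce a compound no denominator exists; those
cells keep their absolute areas and carry a ``reference-nonproducer``
flag rather than a fabricated percentage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spectra import EICTrace

__all__ = ["StrainCompoundMatrix", "RAMatrix", "extract_eic", "integrate_peak",
           "detect_window", "relative_abundance", "best_producer"]

log = logging.getLogger(__name__)

REFERENCE_NONPRODUCER = "reference-nonproducer"


@dataclass
class StrainCompoundMatrix:
    """Strains (rows) by compounds (columns) abundance table with a reference strain."""

    values: pd.DataFrame
    reference_strain: str

    def __post_init__(self) -> None:
        if self.reference_strain not in self.values.index:
            raise ValueError(f"reference strain {self.reference_strain!r} not in matrix")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RAMatrix:
    """Relative abundances in percent, plus per-cell flags.

    ``flags`` has the same shape as ``values``; empty string means a plain
    percentage, ``reference-nonproducer`` marks cells that hold absolute
    areas because the reference strain lacks the compound.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    reference_strain: str


def extract_eic(traces: Sequence[EICTrace], target_mz: float, tol_da: float = 0.01) -> EICTrace:
    """Sum the channels within ``tol_da`` of *target_mz* on their shared RT grid."""
    if not traces:
        raise ValueError("no traces supplied")
    grid = traces[0].rt
    for t in traces[1:]:
        if t.rt.shape != grid.shape or not np.allclose(t.rt, grid):
            raise ValueError("traces must share one retention-time grid")
    selected = [t for t in traces if abs(t.target_mz - target_mz) <= tol_da]
    if not selected:
        warnings.warn(f"no channel within {tol_da} Da of m/z {target_mz}; returning zeros",
                      stacklevel=2)
        return EICTrace(rt=grid.copy(), intensity=np.zeros_like(grid),
                        target_mz=target_mz, tol_da=tol_da)
    total = np.sum([t.intensity for t in selected], axis=0)
    return EICTrace(rt=grid.copy(), intensity=total, target_mz=target_mz, tol_da=tol_da)


def integrate_peak(t: EICTrace, rt_window: tuple[float, float]) -> float:
    """Trapezoidal area of the baseline-subtracted trace inside *rt_window*.

    The baseline is the median intensity outside the window (0 when the
    window covers the whole trace); negative areas are clipped to 0 with a
    warning.
    """
    lo, hi = rt_window
    if hi <= lo:
        raise ValueError("empty integration window")
    mask = (t.rt >= lo) & (t.rt <= hi)
    if not mask.any():
        raise ValueError("integration window outside the retention-time grid")
    baseline = float(np.median(t.intensity[~mask])) if (~mask).any() else 0.0
    area = float(np.trapezoid(t.intensity[mask] - baseline, t.rt[mask]))
    if area < 0:
        warnings.warn("negative integrated area clipped to 0", stacklevel=2)
        area = 0.0
    return area


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def detect_window(t: EICTrace, n_sigma: float = 3.0) -> tuple[float, float]:
    """Apex ± n_sigma window from a local Gaussian fit around the trace maximum."""
    if t.rt.size < 5:
        raise ValueError("trace too short for peak detection")
    apex = int(np.argmax(t.intensity))
    lo = max(apex - 25, 0)
    hi = min(apex + 26, t.rt.size)
    x, y = t.rt[lo:hi], t.intensity[lo:hi]
    dt = float(np.median(np.diff(t.rt)))
    try:
        popt, _ = curve_fit(
            _gaussian, x, y,
            p0=[float(y.max()), float(t.rt[apex]), 3 * dt],
            maxfev=2000,
        )
        mu, sigma = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        mu, sigma = float(t.rt[apex]), 3 * dt
    sigma = max(sigma, dt)
    return mu - n_sigma * sigma, mu + n_sigma * sigma


def relative_abundance(m: StrainCompoundMatrix) -> RAMatrix:
    """Express abundances as percent of the reference strain, per compound."""
    ref = m.values.loc[m.reference_strain]
    values = m.values.copy().astype(float)
    flags = pd.DataFrame("", index=m.values.index, columns=m.values.columns)
    for c in m.values.columns:
        denom = ref[c]
        if denom > 0:
            values[c] = 100.0 * m.values[c] / denom
        else:
            # no denominator: keep absolute areas, flag producing strains
            producers = m.values[c] > 0
            flags.loc[producers, c] = REFERENCE_NONPRODUCER
            if producers.any():
                log.info("compound %s absent from reference %s: %d strains flagged",
                         c, m.reference_strain, int(producers.sum()))
    return RAMatrix(values=values, flags=flags, reference_strain=m.reference_strain)


def best_producer(ra: RAMatrix | StrainCompoundMatrix) -> pd.DataFrame:
    """Per-compound best-producing strain.

    Returns a frame indexed by compound with columns ``strain`` (the argmax,
    lexicographically smallest on ties, or ``"none"`` for an all-zero
    compound) and ``tie`` (bool).
    """
    values = ra.values
    out = []
    for c in values.columns:
        col = values[c]
        top = col.max()
        if top <= 0:
            out.append({"compound": c, "strain": "none", "tie": False})
            continue
        winners = sorted(col.index[col == top])
        out.append({"compound": c, "strain": winners[0], "tie": len(winners) > 1})
    return pd.DataFrame(out).set_index("compound")
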