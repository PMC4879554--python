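"""Auxiliary radiobiology/expression quantifications.

``fit_d0`` estimates the mean lethal dose D0 of the single-hit survival
model SF(D) = exp(-D/D0) from a clonogenic survival curve; by
construction SF(D0) = 1/e ~ 36.8%, i.e. "the dose at which 37% of cells
survive".  ``ddct_fold_change`` is the standard 2^-ddCt relative qPCR
quantification against a reference gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SurvivalCurve", "CtRecord", "fit_d0", "survival_at", "ddct_fold_change"]


@dataclass
class SurvivalCurve:
    """Clonogenic survival: dose (Gy) vs surviving fraction, SF(0) = 1."""

    doses: np.ndarray
    surviving_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)
        d, sf = self.doses, self.surviving_fraction
        if d.size < 2 or d.shape != sf.shape:
            raise ValueError("need >= 2 (dose, SF) pairs of equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if d[0] != 0:
            raise ValueError("curve must include dose 0 (plating control)")
        if np.any(sf <= 0):
            raise ValueError("surviving fractions must be positive (log fit undefined at 0)")
        if abs(sf[0] - 1.0) > 1e-9:
            raise ValueError("SF at dose 0 must be 1")


@dataclass
class CtRecord:
    """qPCR threshold cycles for target and reference genes in test/control samples."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        vals = (self.ct_target_test, self.ct_ref_test, self.ct_target_ctrl, self.ct_ref_ctrl)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all Ct values must be finite")


def fit_d0(curve: SurvivalCurve) -> float:
    """Least-squares D0 of the single-hit model SF = exp(-D/D0).

    The fit is linear on the log scale through the origin:
    ln SF = -D/D0, so slope = sum(D ln SF)/sum(D^2) and D0 = -1/slope.
    Scale-covariant: scaling all doses by k scales D0 by k exactly.
    """
    d = curve.doses[curve.doses > 0]
    sf = curve.surviving_fraction[curve.doses > 0]
    if d.size < 2:
        raise ValueError("need >= 2 positive-dose points")
    log_sf = np.log(sf)
    if np.any(sf > 1) and not np.all(np.diff(curve.surviving_fraction) < 0):
        warnings.warn("surviving fraction exceeds 1 without a decreasing trend", stacklevel=2)
    slope = float(np.sum(d * log_sf) / np.sum(d * d))
    if slope >= 0:
        raise ValueError("fitted slope is non-negative: survival does not decay with dose")
    return -1.0 / slope


def survival_at(d0: float, dose: float) -> float:
    """Single-hit surviving fraction exp(-dose/d0)."""
    if d0 <= 0:
        raise ValueError("D0 must be positive")
    return float(np.exp(-dose / d0))


def ddct_fold_change(rec: CtRecord) -> float:
    """Relative expression fold change 2^-ddCt.

    ddCt = (Ct_target - Ct_ref)_test - (Ct_target - Ct_ref)_control.
    A target amplifying one cycle earlier in the test sample (refs equal)
    therefore gives a 2-fold change.
    """
    ddct = (rec.ct_target_test - rec.ct_ref_test) - (rec.ct_target_ctrl - rec.ct_ref_ctrl)
    return float(2.0 ** (-ddct))
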