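"""Mean spectra, difference spectra, peak detection and band annotation.

This is the biochemical-interpretation path: per-group mean spectra are
computed from background-subtracted, *non*-derivatized spectra, then
baseline-corrected with a fifth-order polynomial, Savitzky-Golay
smoothed (window 3) and vector-normalized.  Difference spectra between
group means carry signed peaks whose positions are matched against a
table of literature band assignments (DNA, protein and lipid modes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import (
    PreprocessConfig,
    baseline_correct,
    interpolate_region,
    sg_smooth,
    subtract_background,
    vector_normalize,
)
from .spectra_io import Spectrum, SpectrumSet, SpectrumValidationError

__all__ = [
    "Band",
    "BandTable",
    "MeanSpectrum",
    "default_band_table",
    "group_mean_spectrum",
    "difference_spectrum",
    "detect_peaks",
    "annotate_bands",
    "integrated_band_area",
]


@dataclass(frozen=True)
class Band:
    """One literature band: centre, matching half-window, assignment, class link."""

    center: float          # cm^-1
    window: float          # +- cm^-1 accepted for a match
    assignment: str
    class_association: str  # parent | recurrent | non_responder | responder | shared

    def __post_init__(self) -> None:
        if self.center <= 0 or self.window <= 0:
            raise ValueError("band centre and window must be positive")


@dataclass
class BandTable:
    """Wavenumber -> biochemical assignment map."""

    bands: list[Band]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "center": float(b.center),
                    "window": float(b.window),
                    "assignment": b.assignment,
                    "class_association": b.class_association,
                }
                for b in self.bands
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BandTable":
        df = pd.read_csv(path)
        return cls(
            [
                Band(
                    center=float(r.center),
                    window=float(r.window),
                    assignment=str(r.assignment),
                    class_association=str(r.class_association),
                )
                for r in df.itertuples(index=False)
            ]
        )


_DEFAULT_WINDOW = 8.0  # covers reported intra-band drift (e.g. 1447 vs 1450)

_DEFAULT_BANDS: list[tuple[float, float, str, str]] = [
    (1008, _DEFAULT_WINDOW, "phenylalanine ring breathing", "parent"),
    (1095, _DEFAULT_WINDOW, "DNA backbone (PO2- stretch)", "parent"),
    (1260, _DEFAULT_WINDOW, "amide III", "shared"),
    (1272, _DEFAULT_WINDOW, "lipid =CH bend / amide III", "recurrent"),
    (1305, _DEFAULT_WINDOW, "lipid CH2 twist", "recurrent"),
    (1313, _DEFAULT_WINDOW, "lipid/collagen CH3CH2 twist", "non_responder"),
    (1320, _DEFAULT_WINDOW, "DNA bases / amide III / lipid CH2 deformation", "non_responder"),
    (1340, _DEFAULT_WINDOW, "total nucleic acid content", "parent"),
    (1367, _DEFAULT_WINDOW, "phospholipid", "non_responder"),
    (1447, _DEFAULT_WINDOW, "CH2 bending (protein/lipid)", "shared"),
    (1485, _DEFAULT_WINDOW, "G and A bases of DNA", "non_responder"),
    (1560, _DEFAULT_WINDOW, "tryptophan", "parent"),
    (1579, _DEFAULT_WINDOW, "DNA and heme", "non_responder"),
    (1610, _DEFAULT_WINDOW, "cytosine base", "parent"),
    (1660, _DEFAULT_WINDOW, "amide I", "shared"),
    (1660, _DEFAULT_WINDOW, "ceramide backbone", "recurrent"),
    (1673, _DEFAULT_WINDOW, "ceramide shoulder", "recurrent"),
    (1725, _DEFAULT_WINDOW, "lipid C=O ester", "recurrent"),
    (1746, _DEFAULT_WINDOW, "lipid C=O ester (triglyceride)", "recurrent"),
    (1750, _DEFAULT_WINDOW, "lipid C=O (tissue)", "non_responder"),
    (2850, 15.0, "lipid CH2 symmetric stretch", "recurrent"),
    (2880, 15.0, "lipid CH2 asymmetric stretch", "recurrent"),
    (2900, 15.0, "protein CH3 stretch", "parent"),
]


def default_band_table() -> BandTable:
    """The packaged band-assignment table (literature Raman bands of cells/tissues)."""
    return BandTable([Band(*row) for row in _DEFAULT_BANDS])


@dataclass
class MeanSpectrum:
    """Per-group mean spectrum plus provenance."""

    spectrum: Spectrum
    n_averaged: int
    group: str

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectrum.wavenumbers

    @property
    def intensities(self) -> np.ndarray:
        return self.spectrum.intensities


def group_mean_spectrum(
    sset: SpectrumSet, group: str, cfg: PreprocessConfig | None = None
) -> MeanSpectrum:
    """Mean spectrum of one group on the mean-spectrum preprocessing path.

    Per spectrum: optional background subtraction and region
    interpolation; the (non-derivatized) spectra are then averaged
    pointwise, baseline-corrected (order ``cfg.baseline_poly_order``),
    SG-smoothed (window ``cfg.sg_window``) and vector-normalized.
    """
    cfg = cfg or PreprocessConfig()
    members = [s for s in sset.spectra if s.group == group]
    if not members:
        raise SpectrumValidationError(f"group {group!r} is empty")
    stack = []
    for s in members:
        if cfg.background is not None:
            s = subtract_background(s, cfg.background)
        s = interpolate_region(s, cfg.region, cfg.interp_step)
        stack.append(s)
    axis = stack[0].wavenumbers
    mean = Spectrum(
        axis,
        np.mean([s.intensities for s in stack], axis=0),
        meta={"group": group, "region": cfg.region, "spectrum_id": f"mean_{group}"},
    )
    mean = baseline_correct(mean, cfg.baseline_poly_order)
    mean = sg_smooth(mean, cfg.sg_window, cfg.sg_polyorder)
    mean = vector_normalize(mean)
    return MeanSpectrum(spectrum=mean, n_averaged=len(members), group=group)


def difference_spectrum(a: MeanSpectrum, b: MeanSpectrum) -> Spectrum:
    """Signed pointwise difference a - b (e.g. recurrent minus parent)."""
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.allclose(
        a.wavenumbers, b.wavenumbers
    ):
        raise SpectrumValidationError("difference spectrum requires identical axes")
    return Spectrum(
        a.wavenumbers,
        a.intensities - b.intensities,
        meta={
            "spectrum_id": f"diff_{a.group}_minus_{b.group}",
            "group": f"{a.group}-{b.group}",
            "operands": f"{a.group} - {b.group}",
        },
    )


def detect_peaks(spectrum: Spectrum, min_prominence: float | None = None) -> list[dict]:
    """Local extrema (both signs) above a prominence threshold.

    The default threshold is 3x the median absolute deviation of the
    intensities — scale-free, so it works on normalized difference
    spectra.  Each peak is reported as
    ``{"position": cm^-1, "height": signed value, "sign": +1/-1}``.
    """
    y = spectrum.intensities
    if min_prominence is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        min_prominence = 3.0 * mad if mad > 0 else np.finfo(float).tiny
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    peaks: list[dict] = []
    for sign, yy in ((1, y), (-1, -y)):
        idx, _ = find_peaks(yy, prominence=min_prominence)
        for i in idx:
            peaks.append(
                {
                    "position": float(spectrum.wavenumbers[i]),
                    "height": float(y[i]),
                    "sign": sign,
                }
            )
    peaks.sort(key=lambda p: p["position"])
    return peaks


def annotate_bands(peaks: list[dict], table: BandTable | None = None) -> list[dict]:
    """Attach literature assignments to detected peaks.

    A peak matches every band with |center - position| <= window
    (one-to-many is deliberate: 1660 cm^-1 reports both amide I and
    ceramide).  Peaks with no match are labelled ``unassigned``.  The
    result is independent of the input peak order.
    """
    table = table or default_band_table()
    annotated = []
    for p in peaks:
        matches = [
            b for b in table.bands if abs(b.center - p["position"]) <= b.window
        ]
        matches.sort(key=lambda b: (abs(b.center - p["position"]), b.center))
        q = dict(p)
        q["assignments"] = [b.assignment for b in matches] or ["unassigned"]
        q["class_associations"] = [b.class_association for b in matches] or []
        annotated.append(q)
    return annotated


def integrated_band_area(spectrum: Spectrum, lo: float = 2840.0, hi: float = 2880.0) -> float:
    """Trapezoidal area in [lo, hi] cm^-1 (default: the lipid CH2 stretch window)."""
    w = spectrum.wavenumbers
    mask = (w >= lo) & (w <= hi)
    if mask.sum() < 2:
        raise SpectrumValidationError(f"fewer than 2 points in [{lo:g}, {hi:g}] cm^-1")
    return float(np.trapezoid(spectrum.intensities[mask], w[mask]))
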