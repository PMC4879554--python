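"""Synthetic Raman spectra, survival curves and Ct tables.

Spectra are sums of Lorentzian bands at literature positions for
cellular DNA, protein and lipid vibrational modes, on top of a smooth
polynomial fluorescence baseline, with per-spectrum band-amplitude
variation, per-batch multiplicative intensity scaling (lognormal) and
additive Gaussian detector noise:

    I(nu) = batch_factor * [ sum_i a_i * L(nu; c_i, w_i) + baseline(nu) ] + eps(nu)

where L is a unit-height Lorentzian with half-width-at-half-maximum w_i.
Class profiles differ by which bands are elevated: "recurrent" cells
carry elevated lipid bands (1272, 1305, 1447, 1660/1673, 1725, 1746 and
the 2840-2880 cm^-1 CH2 stretches), "parent" cells elevated DNA/protein
bands (1008, 1095, 1340, 1560, 1610, ~2900), and "non_responder" tissue
elevated 1313/1320/1340/1367/1485/1579/1750.  Every generator is a pure
function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assays import SurvivalCurve
from .spectra_io import REGIONS, Manifest, Spectrum, SpectrumSet

__all__ = [
    "SimBand",
    "ClassBandProfile",
    "SimConfig",
    "class_profile",
    "simulate_spectrum",
    "simulate_cell_study",
    "simulate_tissue_study",
    "simulate_two_class_study",
    "simulate_survival",
]

#: Margin (cm^-1) by which the native simulated axis exceeds the analysis
#: region on both sides, so interpolation never runs off support.
AXIS_MARGIN = 30.0

#: Default elevation of class-associated band amplitudes over the shared
#: backbone (arbitrary units, backbone amplitudes are 0.2-1.0).
CLASS_DELTA = 0.25


@dataclass(frozen=True)
class SimBand:
    center: float       # cm^-1
    hwhm: float         # Lorentzian half width at half maximum, cm^-1
    amplitude: float    # mean peak height, a.u.
    cv: float = 0.03    # per-spectrum coefficient of variation of the amplitude

    def __post_init__(self) -> None:
        if not (3.0 <= self.hwhm <= 40.0):
            raise ValueError(f"band width {self.hwhm} outside [3, 40] cm^-1")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


@dataclass(frozen=True)
class ClassBandProfile:
    label: str
    bands: tuple[SimBand, ...]

    @property
    def max_amplitude(self) -> float:
        return max(b.amplitude for b in self.bands)

    def shifted(self, jitter: dict[float, float]) -> "ClassBandProfile":
        """Profile with band centres shifted by ``jitter[center]`` (cm^-1)."""
        return ClassBandProfile(
            self.label,
            tuple(
                replace(b, center=b.center + jitter.get(b.center, 0.0))
                for b in self.bands
            ),
        )

    def elevated(self, centers: dict[float, float]) -> "ClassBandProfile":
        """Profile with band amplitudes raised by ``centers[center]``."""
        return ClassBandProfile(
            self.label,
            tuple(
                replace(b, amplitude=b.amplitude + centers.get(b.center, 0.0))
                for b in self.bands
            ),
        )


# Shared cellular backbone, fingerprint region (center, hwhm, amplitude).
_FP_SHARED = [
    (1008, 3.5, 0.55), (1095, 7, 0.35), (1260, 9, 0.50), (1272, 7, 0.30),
    (1305, 7, 0.40), (1340, 8, 0.45), (1447, 8, 0.80), (1485, 7, 0.25),
    (1560, 7, 0.25), (1610, 7, 0.30), (1660, 9, 0.90), (1725, 7, 0.20),
    (1746, 7, 0.25),
]
# Shared C-H stretch backbone, high-wavenumber region.
_HW_SHARED = [(2850, 12, 0.70), (2880, 12, 0.60), (2900, 12, 0.85), (2930, 14, 1.00)]

_PARENT_UP = {1008: CLASS_DELTA, 1095: CLASS_DELTA, 1340: CLASS_DELTA,
              1560: CLASS_DELTA, 1610: CLASS_DELTA, 2900: CLASS_DELTA}
_RECURRENT_UP = {1272: CLASS_DELTA, 1305: CLASS_DELTA, 1447: CLASS_DELTA,
                 1660: CLASS_DELTA, 1725: CLASS_DELTA, 1746: CLASS_DELTA,
                 2850: CLASS_DELTA, 2880: CLASS_DELTA}
_RECURRENT_EXTRA = [(1673, 6, 0.20)]  # ceramide shoulder, recurrent cells only

# Tissue backbone (1200-1800 cm^-1 study).
_TISSUE_SHARED = [
    (1260, 9, 0.50), (1305, 7, 0.35), (1340, 8, 0.45), (1447, 8, 0.80),
    (1485, 7, 0.25), (1560, 7, 0.25), (1579, 6, 0.20), (1610, 7, 0.30),
    (1660, 9, 0.90), (1750, 7, 0.20),
]
_NONRESP_UP = {1340: CLASS_DELTA, 1485: CLASS_DELTA, 1579: CLASS_DELTA,
               1750: CLASS_DELTA}
_NONRESP_EXTRA = [(1313, 6, 0.25), (1320, 6, 0.25), (1367, 6, 0.25)]


def _bands(rows, cv: float = 0.03) -> tuple[SimBand, ...]:
    return tuple(SimBand(c, w, a, cv) for c, w, a in rows)


def class_profile(label: str, cv: float = 0.03) -> ClassBandProfile:
    """Packaged class presets: parent, recurrent, sf268_recurrent,
    responder, non_responder.

    ``sf268_recurrent`` inverts the DNA/protein shift of the standard
    recurrent preset (slightly higher DNA, lower protein than its
    parent), mimicking the one atypical cell line.
    """
    shared = _bands(_FP_SHARED + _HW_SHARED, cv)
    if label == "parent":
        return ClassBandProfile("parent", shared).elevated(_PARENT_UP)
    if label == "recurrent":
        prof = ClassBandProfile("recurrent", shared + _bands(_RECURRENT_EXTRA, cv))
        return prof.elevated(_RECURRENT_UP)
    if label == "sf268_recurrent":
        prof = ClassBandProfile("sf268_recurrent", shared)
        return prof.elevated(
            {1095: 1.3 * CLASS_DELTA, 1340: 1.3 * CLASS_DELTA, 1610: 1.3 * CLASS_DELTA,
             1008: -0.4 * CLASS_DELTA, 1560: -0.4 * CLASS_DELTA, 1660: -0.15 * CLASS_DELTA}
        )
    tissue = _bands(_TISSUE_SHARED, cv)
    if label == "responder":
        return ClassBandProfile("responder", tissue)
    if label == "non_responder":
        prof = ClassBandProfile("non_responder", tissue + _bands(_NONRESP_EXTRA, cv))
        return prof.elevated(_NONRESP_UP)
    raise ValueError(f"unknown class profile {label!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    ``noise_sd`` is the additive Gaussian SD as a fraction of the
    largest mean band amplitude in the study; ``batch_scale_sd`` the
    lognormal SD of the per-batch multiplicative intensity factor.
    """

    n_spectra_per_group: int = 30
    region: str = "fingerprint"
    step: float = 1.0
    baseline_coeffs: tuple[float, ...] = (2.0, 3.0, -2.0, 0.5)
    noise_sd: float = 0.05
    noise_corr_len: float = 7.0     # Gaussian sigma (cm^-1) of correlated nuisance; 0 = white
    batch_scale_sd: float = 0.1
    n_batches: int = 3
    overlap_fraction: float = 0.1   # tissue study: mixed-profile fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra_per_group < 2:
            raise ValueError("need at least 2 spectra per group")
        if self.noise_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("noise and batch SDs must be >= 0")
        if len(self.baseline_coeffs) > 6:
            raise ValueError("baseline polynomial degree must be <= 5")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")


def _native_axis(cfg: SimConfig) -> np.ndarray:
    lo, hi = REGIONS[cfg.region]
    lo, hi = lo - AXIS_MARGIN, hi + AXIS_MARGIN
    n = int(round((hi - lo) / cfg.step))
    return lo + cfg.step * np.arange(n + 1)


def _baseline(axis: np.ndarray, cfg: SimConfig) -> np.ndarray:
    # Polynomial in the scaled coordinate x in [0, 1] over the region, so
    # coefficients mean the same thing in every region.
    lo, hi = REGIONS[cfg.region]
    x = (axis - lo) / (hi - lo)
    return np.polynomial.polynomial.polyval(x, np.asarray(cfg.baseline_coeffs))


def _noise(rng: np.random.Generator, n: int, sd: float, corr_len_pts: float) -> np.ndarray:
    """Additive detector noise with per-channel SD ``sd``.

    Adjacent channels are correlated through the spectrograph line-spread
    function, modelled as a Gaussian kernel of sigma ``corr_len_pts``
    (in grid points).  The kernel is l2-normalized so the marginal
    per-channel SD stays ``sd`` regardless of the correlation length.
    """
    white = rng.normal(0.0, 1.0, n)
    if corr_len_pts <= 0 or sd == 0:
        return sd * white
    half = int(np.ceil(4 * corr_len_pts))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / corr_len_pts) ** 2)
    kernel /= np.linalg.norm(kernel)
    return sd * np.convolve(white, kernel, mode="same")


def _lorentzians(axis: np.ndarray, centers, hwhms, amps) -> np.ndarray:
    out = np.zeros_like(axis)
    for c, w, a in zip(centers, hwhms, amps):
        out += a * w * w / ((axis - c) ** 2 + w * w)
    return out


def simulate_spectrum(
    profile: ClassBandProfile,
    cfg: SimConfig,
    rng: np.random.Generator,
    batch_factor: float = 1.0,
    noise_abs: float | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Draw one spectrum from a class profile.

    Band amplitudes are drawn per spectrum from Normal(mean, cv*mean)
    clipped at zero; noise is additive Gaussian with absolute SD
    ``noise_abs`` (default ``cfg.noise_sd * profile.max_amplitude``).
    Bands outside the simulated region contribute their (negligible)
    Lorentzian tails only.
    """
    axis = _native_axis(cfg)
    lo, hi = axis[0], axis[-1]
    in_region = [b for b in profile.bands if lo - 100 <= b.center <= hi + 100]
    if not in_region:
        import warnings

        warnings.warn(
            f"profile {profile.label!r} has no bands in region {cfg.region}; "
            "baseline + noise only",
            stacklevel=2,
        )
    amps = np.array(
        [max(0.0, rng.normal(b.amplitude, b.cv * b.amplitude)) for b in in_region]
    )
    signal = _lorentzians(
        axis, [b.center for b in in_region], [b.hwhm for b in in_region], amps
    )
    if noise_abs is None:
        noise_abs = cfg.noise_sd * profile.max_amplitude
    eps = _noise(rng, axis.size, noise_abs, cfg.noise_corr_len / cfg.step)
    y = batch_factor * (signal + _baseline(axis, cfg)) + eps
    m = {"group": profile.label, "region": cfg.region}
    if meta:
        m.update(meta)
    return Spectrum(axis, y, meta=m)


def _simulate_groups(
    group_profiles: dict[str, ClassBandProfile],
    cfg: SimConfig,
    rng: np.random.Generator,
    noise_abs: float,
    mixed_profile: ClassBandProfile | None = None,
) -> tuple[SpectrumSet, Manifest]:
    spectra: list[Spectrum] = []
    rows = []
    for group, profile in group_profiles.items():
        batch_factors = np.exp(rng.normal(0.0, cfg.batch_scale_sd, cfg.n_batches))
        n_mixed = int(round(cfg.overlap_fraction * cfg.n_spectra_per_group)) if mixed_profile else 0
        for i in range(cfg.n_spectra_per_group):
            batch = i % cfg.n_batches
            prof = mixed_profile if i < n_mixed else profile
            sid = f"{group}_{i:03d}"
            s = simulate_spectrum(
                prof, cfg, rng, batch_factor=float(batch_factors[batch]),
                noise_abs=noise_abs,
                meta={
                    "spectrum_id": sid, "sample_id": group,
                    "group": group, "batch": f"b{batch}", "seed": str(cfg.seed),
                },
            )
            spectra.append(s)
            rows.append(
                {"path": f"{sid}.txt", "spectrum_id": sid, "sample_id": group,
                 "group": group, "batch": f"b{batch}"}
            )
    return SpectrumSet(spectra), Manifest(pd.DataFrame(rows))


def _group_jitter(profile: ClassBandProfile, rng: np.random.Generator,
                  max_shift: float = 0.8) -> ClassBandProfile:
    """Sample-specific band-centre jitter (<= max_shift cm^-1), one draw per group."""
    jitter = {b.center: float(rng.uniform(-max_shift, max_shift)) for b in profile.bands}
    return profile.shifted(jitter)


def simulate_cell_study(cfg: SimConfig | None = None) -> tuple[SpectrumSet, Manifest]:
    """The 8-group cell-pellet design: {PS1, PS2, SF268, U87MG} x {P, R}.

    Each group gets its class preset plus its own small band-centre
    jitter, mimicking inter-sample variation; SF268 R uses the preset
    with the inverted DNA/protein shift.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    parent = class_profile("parent")
    recurrent = class_profile("recurrent")
    sf268_r = class_profile("sf268_recurrent")
    samples = ["PS1", "PS2", "SF268", "U87MG"]
    profiles: dict[str, ClassBandProfile] = {}
    for sample in samples:
        profiles[f"{sample}_P"] = _group_jitter(parent, rng)
        base = sf268_r if sample == "SF268" else recurrent
        profiles[f"{sample}_R"] = _group_jitter(base, rng)
    noise_abs = cfg.noise_sd * max(p.max_amplitude for p in profiles.values())
    return _simulate_groups(profiles, cfg, rng, noise_abs)


def simulate_tissue_study(cfg: SimConfig | None = None) -> tuple[SpectrumSet, Manifest]:
    """The responder / non-responder tissue design on 1200-1800 cm^-1.

    A configurable fraction of each group (default 10%) is drawn from a
    50/50 mixed profile, mimicking the clonal-cell overlap between
    outcome groups.
    """
    cfg = cfg or SimConfig(region="tissue", n_spectra_per_group=45)
    if cfg.region != "tissue":
        cfg = replace(cfg, region="tissue")
    rng = np.random.default_rng(cfg.seed)
    responder = class_profile("responder")
    non_responder = class_profile("non_responder")
    # 50/50 mixture: a band absent from one class averages with zero.
    amp_r = {(b.center, b.hwhm): b.amplitude for b in responder.bands}
    amp_n = {(b.center, b.hwhm): b.amplitude for b in non_responder.bands}
    mixed = ClassBandProfile(
        "mixed",
        tuple(
            SimBand(c, w, 0.5 * (amp_r.get((c, w), 0.0) + amp_n.get((c, w), 0.0)),
                    responder.bands[0].cv)
            for (c, w) in sorted(set(amp_r) | set(amp_n))
        ),
    )
    profiles = {"responder": responder, "non_responder": non_responder}
    noise_abs = cfg.noise_sd * max(p.max_amplitude for p in profiles.values())
    return _simulate_groups(profiles, cfg, rng, noise_abs, mixed_profile=mixed)


def simulate_two_class_study(
    cfg: SimConfig | None = None,
    delta_in_noise_units: float = 4.0,
    band_center: float = 1008.0,
) -> tuple[SpectrumSet, Manifest]:
    """Controlled two-class experiment: classes differ in one band only.

    Class "B" has the amplitude of the band at ``band_center`` raised by
    ``delta_in_noise_units`` times the absolute noise SD over class "A";
    everything else (backbone, baseline, batches) is identical.  Used
    for parameter-recovery and permutation-null checks.
    """
    cfg = cfg or SimConfig()
    base = ClassBandProfile("A", _bands(_FP_SHARED + _HW_SHARED, 0.03))
    noise_abs = cfg.noise_sd * base.max_amplitude
    delta = delta_in_noise_units * noise_abs
    shifted = ClassBandProfile("B", base.bands).elevated({band_center: delta})
    rng = np.random.default_rng(cfg.seed)
    return _simulate_groups({"A": base, "B": shifted}, cfg, rng, noise_abs)


def simulate_survival(
    true_d0: float,
    doses=(0.0, 2.0, 4.0, 6.0, 8.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SurvivalCurve:
    """Single-hit survival curve SF = exp(-D/D0) with lognormal noise; SF(0) = 1."""
    if true_d0 <= 0:
        raise ValueError("true_d0 must be positive")
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    sf = np.exp(-doses / true_d0) * np.exp(rng.normal(0.0, noise_sd, doses.size))
    sf[doses == 0] = 1.0
    return SurvivalCurve(doses=doses, surviving_fraction=sf)
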