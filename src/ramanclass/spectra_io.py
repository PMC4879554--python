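"""Reading, writing and validation of Raman spectra and study manifests.

A spectrum is stored on disk as plain two-column delimited text
(wavenumber in cm^-1, intensity in arbitrary units).  Lines starting
with ``#`` are comments; ``#key: value`` lines carry metadata
(spectrum_id, sample_id, group, batch, region).  A manifest is a CSV
table with columns ``path,spectrum_id,sample_id,group,batch`` that
binds individual spectrum files into a labelled study.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "Manifest",
    "SpectrumParseError",
    "SpectrumValidationError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "load_set",
    "write_study",
]

#: Recognised spectral regions and their bounds in cm^-1.
REGIONS: dict[str, tuple[float, float]] = {
    "fingerprint": (700.0, 1800.0),
    "high_wavenumber": (2800.0, 3100.0),
    "tissue": (1200.0, 1800.0),
}

MIN_SPECTRUM_LENGTH = 8

_META_KEYS = ("spectrum_id", "sample_id", "group", "batch", "region")


class SpectrumParseError(ValueError):
    """A spectrum file contains a line that cannot be parsed."""


class SpectrumValidationError(ValueError):
    """A spectrum or spectrum set violates a structural invariant."""


@dataclass
class Spectrum:
    """One Raman acquisition: wavenumber axis, intensities, provenance.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly increasing Raman shifts in cm^-1, all finite and positive.
    intensities : ndarray
        Scattered intensity in arbitrary units, same length as the axis.
    meta : dict
        Free-form provenance; recognised keys are ``spectrum_id``,
        ``sample_id``, ``group``, ``batch`` and ``region``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        w, y = self.wavenumbers, self.intensities
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise SpectrumValidationError(
                f"axis and intensities must be 1-D and equal length, got {w.shape} vs {y.shape}"
            )
        if w.size < MIN_SPECTRUM_LENGTH:
            raise SpectrumValidationError(
                f"spectrum has {w.size} points; at least {MIN_SPECTRUM_LENGTH} required"
            )
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise SpectrumValidationError("wavenumbers must be finite and positive")
        if not np.all(np.isfinite(y)):
            raise SpectrumValidationError("intensities must be finite")
        dw = np.diff(w)
        if np.any(dw == 0):
            dup = w[:-1][dw == 0][0]
            raise SpectrumValidationError(f"duplicate wavenumber {dup:g} cm^-1")
        if np.any(dw < 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def spectrum_id(self) -> str:
        return str(self.meta.get("spectrum_id", ""))

    @property
    def group(self) -> str:
        return str(self.meta.get("group", ""))

    def copy_with(self, *, wavenumbers=None, intensities=None, **meta_updates) -> "Spectrum":
        """Return a new Spectrum with replaced data and/or updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=self.intensities if intensities is None else intensities,
            meta=meta,
        )


@dataclass
class SpectrumSet:
    """A labelled collection of spectra — the unit of training/validation."""

    spectra: list[Spectrum]
    common_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.common_axis is not None:
            self.common_axis = np.asarray(self.common_axis, dtype=float)
            for s in self.spectra:
                if s.wavenumbers.shape != self.common_axis.shape or not np.allclose(
                    s.wavenumbers, self.common_axis
                ):
                    raise SpectrumValidationError(
                        f"spectrum {s.spectrum_id!r} is not on the declared common axis"
                    )
        for s in self.spectra:
            if not s.group:
                raise SpectrumValidationError(
                    f"spectrum {s.spectrum_id!r} has no group label"
                )

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.group, None)
        return list(seen)

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.spectra]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.spectra:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        return sizes

    def subset(self, indices) -> "SpectrumSet":
        return SpectrumSet([self.spectra[i] for i in indices], common_axis=self.common_axis)

    def select_groups(self, groups) -> "SpectrumSet":
        keep = set(groups)
        return SpectrumSet(
            [s for s in self.spectra if s.group in keep], common_axis=self.common_axis
        )

    def matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) array (common axis required)."""
        if self.common_axis is None:
            raise SpectrumValidationError("SpectrumSet has no common axis; preprocess first")
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class Manifest:
    """Table binding spectrum files to study labels.

    Columns: path, spectrum_id, sample_id, group, batch.
    """

    table: pd.DataFrame

    COLUMNS = ("path", "spectrum_id", "sample_id", "group", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise SpectrumValidationError(f"manifest missing columns: {missing}")
        if len(self.table) == 0:
            raise SpectrumValidationError("manifest is empty")
        ids = self.table["spectrum_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SpectrumValidationError(f"duplicate spectrum_id in manifest: {dup!r}")

    def __len__(self) -> int:
        return len(self.table)


_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    # Instrument exports vary between comma- and whitespace-delimited text.
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_spectrum(path: str | os.PathLike) -> Spectrum:
    """Read a two-column text spectrum, returning it sorted by ascending wavenumber.

    ``#key: value`` header lines populate metadata.  Raises
    :class:`SpectrumParseError` naming the offending line on non-numeric
    rows, and :class:`SpectrumValidationError` on duplicate wavenumbers.
    """
    meta: dict = {}
    w: list[float] = []
    y: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            fields = _split_row(line)
            if len(fields) < 2:
                raise SpectrumParseError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            a, b = fields[0], fields[1]
            if not _NUM_RE.match(a) or not _NUM_RE.match(b):
                raise SpectrumParseError(f"{path}: line {lineno}: non-numeric row {line!r}")
            w.append(float(a))
            y.append(float(b))
    w_arr = np.asarray(w)
    y_arr = np.asarray(y)
    order = np.argsort(w_arr, kind="stable")
    return Spectrum(w_arr[order], y_arr[order], meta=meta)


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column text with ``#key: value`` metadata header.

    Values are written with ``repr`` precision so a write→read round trip
    reproduces the spectrum exactly.
    """
    buf = io.StringIO()
    for key in _META_KEYS:
        if key in spectrum.meta:
            buf.write(f"# {key}: {spectrum.meta[key]}\n")
    buf.write("# wavenumber_cm-1 intensity_au\n")
    for wi, yi in zip(spectrum.wavenumbers, spectrum.intensities):
        buf.write(f"{float(wi)!r} {float(yi)!r}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_manifest(path: str | os.PathLike) -> Manifest:
    """Read a study manifest CSV."""
    table = pd.read_csv(path, dtype=str).fillna("")
    return Manifest(table)


def load_set(manifest: Manifest, base_dir: str | os.PathLike | None = None) -> SpectrumSet:
    """Load every spectrum listed in a manifest into a SpectrumSet.

    Paths are resolved relative to ``base_dir`` when given.  Group labels
    come from the manifest (overriding any file header).  Raises
    ``FileNotFoundError`` naming the first unresolvable path.
    """
    spectra: list[Spectrum] = []
    for row in manifest.table.itertuples(index=False):
        p = row.path
        if base_dir is not None:
            p = os.path.join(base_dir, p)
        if not os.path.exists(p):
            raise FileNotFoundError(f"manifest references missing spectrum file: {p}")
        s = read_spectrum(p)
        spectra.append(
            s.copy_with(
                spectrum_id=str(row.spectrum_id),
                sample_id=str(row.sample_id),
                group=str(row.group),
                batch=str(row.batch),
            )
        )
    sset = SpectrumSet(spectra)
    for g, n in sset.group_sizes().items():
        if n == 0:  # unreachable by construction; kept for the invariant
            raise SpectrumValidationError(f"group {g!r} is empty after load")
    return sset


def write_study(sset: SpectrumSet, out_dir: str | os.PathLike) -> Manifest:
    """Write every spectrum of a set plus a ``manifest.csv`` into a directory.

    Returns the manifest (paths relative to ``out_dir``).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, s in enumerate(sset.spectra):
        sid = s.meta.get("spectrum_id") or f"s{i:04d}"
        fname = f"{sid}.txt"
        write_spectrum(s, os.path.join(out_dir, fname))
        rows.append(
            {
                "path": fname,
                "spectrum_id": sid,
                "sample_id": s.meta.get("sample_id", ""),
                "group": s.group,
                "batch": s.meta.get("batch", ""),
            }
        )
    manifest = Manifest(pd.DataFrame(rows))
    manifest.table.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
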