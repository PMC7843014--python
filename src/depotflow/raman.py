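"""Raman spectral unmixing: spectra -> relative ethanol concentration.

The surface-Raman assay observes a mixture of two known pure-component
spectra (ethanol and tumor tissue).  Each measured spectrum is decomposed
by non-negative linear least squares against the two references, and the
ethanol weight fraction ``w_e / (w_e + w_t)`` is reported as the relative
ethanol concentration at the tumor surface.  A time series of such
fractions is the observable the transport model is fitted to.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import (
    GridMismatchError,
    IllConditionedBasisError,
    InvalidArgumentError,
    UndefinedFractionError,
)

#: Condition number above which a two-column basis is treated as collinear.
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class RamanSpectrum:
    """A single spectrum on a strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise InvalidArgumentError("wavenumbers and intensities must be 1-D and equal length")
        if wn.size < 2 or not np.all(np.diff(wn) > 0):
            raise InvalidArgumentError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)


@dataclass(frozen=True)
class SpectralBasis:
    """Pure-component reference spectra (ethanol, tissue) on a shared grid."""

    wavenumbers: np.ndarray
    ethanol_ref: np.ndarray
    tissue_ref: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        e = np.asarray(self.ethanol_ref, dtype=float)
        t = np.asarray(self.tissue_ref, dtype=float)
        if not (wn.shape == e.shape == t.shape) or wn.ndim != 1:
            raise InvalidArgumentError("basis vectors must be 1-D and match the grid length")
        if not np.all(np.diff(wn) > 0):
            raise InvalidArgumentError("wavenumber grid must be strictly increasing")
        if np.any(e < 0) or np.any(t < 0):
            raise InvalidArgumentError("reference spectra must be non-negative")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "ethanol_ref", e)
        object.__setattr__(self, "tissue_ref", t)

    @property
    def matrix(self) -> np.ndarray:
        """The (n_channels, 2) design matrix [ethanol_ref | tissue_ref]."""
        return np.column_stack([self.ethanol_ref, self.tissue_ref])

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass(frozen=True)
class ConcentrationSeries:
    """Relative ethanol concentration at the tumor surface versus time.

    ``c`` is clipped to [0, 1]; ``c_raw`` keeps the unclipped fit values;
    ``residuals`` keeps the per-point unmixing residual norm when the series
    came from spectra (otherwise zeros).
    """

    times: np.ndarray
    c: np.ndarray
    c_raw: np.ndarray | None = None
    residuals: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if t.ndim != 1 or t.size != c.size:
            raise InvalidArgumentError("times and c must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        raw = self.c_raw if self.c_raw is not None else c.copy()
        raw = np.asarray(raw, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "c_raw", raw)
        object.__setattr__(self, "c", np.clip(c, 0.0, 1.0))
        if self.residuals is not None:
            object.__setattr__(self, "residuals", np.asarray(self.residuals, dtype=float))

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        res = self.residuals if self.residuals is not None else np.zeros_like(self.c)
        return pd.DataFrame({"time_s": self.times, "c_rel": self.c, "residual": res})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            c=df["c_rel"].to_numpy(),
            residuals=df["residual"].to_numpy() if "residual" in df else None,
        )


def fit_components(measured: RamanSpectrum, basis: SpectralBasis):
    """Non-negative least-squares decomposition of one spectrum.

    Returns ``(w_ethanol, w_tissue, residual_norm)`` minimizing
    ``||measured - w_e*ethanol_ref - w_t*tissue_ref||_2`` with both weights
    >= 0.  The constrained solution equals the unconstrained normal-equations
    solution whenever the latter is already feasible.
    """
    if measured.wavenumbers.size != basis.wavenumbers.size or not np.allclose(
        measured.wavenumbers, basis.wavenumbers, rtol=0, atol=1e-9
    ):
        raise GridMismatchError("measured spectrum and basis are on different wavenumber grids")
    if basis.condition_number() > _COND_LIMIT:
        raise IllConditionedBasisError(
            f"basis condition number exceeds {_COND_LIMIT:g}; references are collinear"
        )
    w, rnorm = nnls(basis.matrix, measured.intensities)
    return float(w[0]), float(w[1]), float(rnorm)


def relative_concentration(w_ethanol: float, w_tissue: float) -> float:
    """Ethanol weight fraction ``w_e / (w_e + w_t)``, clipped to [0, 1]."""
    if w_ethanol < 0 or w_tissue < 0:
        raise InvalidArgumentError("component weights must be non-negative")
    total = w_ethanol + w_tissue
    if total == 0:
        raise UndefinedFractionError("both component weights are zero")
    return float(np.clip(w_ethanol / total, 0.0, 1.0))


def build_series(manifest, basis: SpectralBasis, normalization: str = "fraction") -> ConcentrationSeries:
    """Unmix a timed sequence of spectra into a ConcentrationSeries.

    Parameters
    ----------
    manifest
        Iterable of ``(time_s, RamanSpectrum)`` pairs in any order, or a
        path to a manifest CSV with columns ``time_s, spectrum_file`` whose
        files are two-column CSVs (wavenumber, intensity) resolved relative
        to the manifest's directory.
    normalization
        ``"fraction"`` (default): c = w_e / (w_e + w_t).
        ``"ethanol_weight"``: c = w_e alone, assuming the references are
        scaled so a pure-ethanol spectrum fits with weight 1.
    """
    if normalization not in ("fraction", "ethanol_weight"):
        raise InvalidArgumentError(f"unknown normalization {normalization!r}")
    if isinstance(manifest, (str, os.PathLike)):
        manifest = list(_iter_manifest(manifest))
    pairs = sorted(manifest, key=lambda p: p[0])
    if len(pairs) < 3:
        raise InvalidArgumentError("a concentration series needs at least 3 time points")
    times, cs, resids = [], [], []
    for t, spec in pairs:
        w_e, w_t, rnorm = fit_components(spec, basis)
        if normalization == "fraction":
            c = relative_concentration(w_e, w_t)
        else:
            c = w_e
        times.append(float(t))
        cs.append(c)
        resids.append(rnorm)
    return ConcentrationSeries(
        times=np.array(times),
        c=np.array(cs),
        c_raw=np.array(cs),
        residuals=np.array(resids),
    )


def _iter_manifest(path):
    base = os.path.dirname(os.fspath(path))
    df = pd.read_csv(path)
    for _, row in df.iterrows():
        fn = os.path.join(base, str(row["spectrum_file"]))
        try:
            sdf = pd.read_csv(fn)
        except (OSError, pd.errors.ParserError) as exc:
            raise IOError(f"could not read spectrum file {fn!r}") from exc
        yield float(row["time_s"]), RamanSpectrum(
            wavenumbers=sdf.iloc[:, 0].to_numpy(), intensities=sdf.iloc[:, 1].to_numpy()
        )
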