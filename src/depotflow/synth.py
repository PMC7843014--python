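"""Synthetic inputs for every stage of the pipeline.

Each generator emulates the statistical structure its consumer assumes:

* pseudo-Raman reference spectra (sums of Gaussian peaks) and timed linear
  ethanol/tissue mixtures whose mixing fraction follows the transport
  forward model;
* fluorescence-like injection images -- a supra-threshold disk with
  optional finger-like leakage lobes;
* serial-section area profiles of a spherical necrotic core;
* exponential-growth tumor cohorts on a three-measurements-per-week caliper
  schedule, with lognormal measurement noise;
* Bernoulli adverse-event tables.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .morpho import IntensityImage
from .raman import RamanSpectrum, SpectralBasis
from .transport import TransportParams, simulate_surface_concentration
from .volumetrics import SectionProfile

#: Default caliper schedule: Mon/Wed/Fri for five weeks.
DEFAULT_SCHEDULE_DAYS = tuple(
    d for week in range(5) for d in (7 * week, 7 * week + 2, 7 * week + 4)
)


@dataclass(frozen=True)
class SyntheticTruth:
    """The generating truth behind a synthetic Raman acquisition."""

    params: TransportParams
    noise_sd: float = 0.0
    seed: int = 0
    schedule: np.ndarray = field(default_factory=lambda: np.arange(0.0, 1801.0, 10.0))

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.ndim != 1 or sched[0] != 0 or not np.all(np.diff(sched) > 0):
            raise InvalidArgumentError("schedule must start at 0 and be strictly increasing")
        object.__setattr__(self, "schedule", sched)


def _gaussian_peaks(grid, centers, widths, heights):
    out = np.zeros_like(grid)
    for c, w, h in zip(centers, widths, heights):
        out += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return out


def gen_basis_spectra(n_channels: int, seed: int) -> SpectralBasis:
    """Two smooth, non-negative, linearly independent pseudo-spectra.

    The peaks are synthetic Gaussians at seeded but disjoint band centers,
    not literature ethanol Raman bands: only the linear-mixture structure
    matters downstream.
    """
    if n_channels < 16:
        raise InvalidArgumentError("need at least 16 spectral channels")
    rng = np.random.default_rng(seed)
    wn = np.linspace(800.0, 1800.0, int(n_channels))
    span = wn[-1] - wn[0]
    # interleave band centers so neither spectrum is a multiple of the other
    slots = np.linspace(wn[0] + 0.05 * span, wn[-1] - 0.05 * span, 8)
    jitter = rng.uniform(-0.03, 0.03, 8) * span
    centers = slots + jitter
    widths = rng.uniform(0.015, 0.05, 8) * span
    heights = rng.uniform(0.5, 1.0, 8)
    ethanol = _gaussian_peaks(wn, centers[0::2], widths[0::2], heights[0::2])
    tissue = _gaussian_peaks(wn, centers[1::2], widths[1::2], heights[1::2])
    basis = SpectralBasis(wavenumbers=wn, ethanol_ref=ethanol, tissue_ref=tissue)
    assert basis.condition_number() < 1e6
    return basis


def gen_raman_timeseries(truth: SyntheticTruth, basis: SpectralBasis,
                         n_grid: int = 60, n_steps: int = 400):
    """Timed spectra: c(t)*ethanol + (1-c(t))*tissue + Gaussian noise.

    The mixing fraction c(t) is the transport forward model's surface
    concentration on the truth's schedule.  Returns a list of
    ``(time_s, RamanSpectrum)`` pairs.
    """
    series = simulate_surface_concentration(
        truth.params, truth.schedule, n_grid=n_grid, n_steps=n_steps
    )
    rng = np.random.default_rng(truth.seed)
    out = []
    for t, c in zip(series.times, series.c):
        intens = c * basis.ethanol_ref + (1.0 - c) * basis.tissue_ref
        if truth.noise_sd > 0:
            intens = intens + rng.normal(0.0, truth.noise_sd, intens.size)
        out.append((float(t), RamanSpectrum(wavenumbers=basis.wavenumbers, intensities=intens)))
    return out


def gen_injection_image(
    side_px: int = 256,
    disk_radius_px: int = 60,
    n_lobes: int = 0,
    lobe_gain: float = 1.0,
    scale_mm_per_px: float = 0.1,
    seed: int = 0,
    threshold: float = 1000.0,
) -> IntensityImage:
    """A synthetic fluorescence image of an injection zone.

    A bright central disk (intensity 2x ``threshold``) with ``n_lobes``
    finger-like protrusions of length ``lobe_gain * disk_radius`` emulating
    leakage; the background sits well below threshold with mild seeded
    noise.  ``n_lobes=0`` is the compact (pure disk) case.
    """
    r = int(disk_radius_px)
    side = int(side_px)
    if side < 16:
        raise InvalidArgumentError("image side must be at least 16 px")
    if not 0 < r < side / 2:
        raise InvalidArgumentError("disk radius must fit inside the frame")
    if n_lobes < 0 or lobe_gain < 0:
        raise InvalidArgumentError("n_lobes and lobe_gain must be non-negative")
    lobe_len = lobe_gain * r
    if n_lobes > 0 and r + lobe_len >= side / 2:
        raise InvalidArgumentError("lobes do not fit inside the frame")
    cy = cx = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    rad = np.hypot(dy, dx)
    shape = rad <= r
    if n_lobes > 0 and lobe_len > 0:
        ang = np.arctan2(dy, dx)
        width = max(2.0, r / 5.0)
        for k in range(int(n_lobes)):
            theta = 2.0 * np.pi * k / n_lobes
            # signed distance from the finger's axis
            along = dx * np.cos(theta) + dy * np.sin(theta)
            across = -dx * np.sin(theta) + dy * np.cos(theta)
            finger = (along >= 0) & (along <= r + lobe_len) & (np.abs(across) <= width / 2)
            shape |= finger
        del ang
    rng = np.random.default_rng(seed)
    img = rng.uniform(0.0, 0.2 * threshold, (side, side))
    img[shape] = 2.0 * threshold
    return IntensityImage(pixels=img, scale_mm_per_px=scale_mm_per_px)


def gen_section_profile(
    sphere_radius: float,
    dx: float,
    offset: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SectionProfile:
    """Serial-section areas of a spherical necrotic core.

    ``A(x) = pi (r^2 - x^2)`` for |x| < r, else 0, on a grid of spacing
    ``dx`` shifted by ``offset`` (0 = one section exactly through the
    center).  Optional Gaussian area noise (clipped at 0) with the given
    seed emulates ROI-tracing variability.
    """
    if sphere_radius <= 0 or dx <= 0:
        raise InvalidArgumentError("sphere_radius and dx must be positive")
    r = float(sphere_radius)
    n_half = int(np.ceil((r - offset) / dx)) + 1
    n_low = int(np.ceil((r + offset) / dx)) + 1
    pos = offset + dx * np.arange(-n_low, n_half + 1)
    areas = np.pi * np.clip(r**2 - pos**2, 0.0, None)
    areas[np.abs(pos) >= r] = 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        areas = np.clip(areas + rng.normal(0.0, noise_sd, areas.size), 0.0, None)
    return SectionProfile(positions=pos, areas=areas)


def gen_cohort(
    n_per_arm: dict,
    v0: float = 50.0,
    growth_rates: dict | None = None,
    meas_noise_cv: float = 0.1,
    schedule_days=DEFAULT_SCHEDULE_DAYS,
    max_day: float = 35.0,
    seed: int = 0,
) -> pd.DataFrame:
    """An exponential-growth tumor cohort measured three times per week.

    ``V(t) = v0 * exp(k_arm * t) * lognoise`` with lognormal measurement
    noise of coefficient of variation ``meas_noise_cv``.  Volumes are
    converted to caliper width/length assuming W = L (V = W^3 / 2).
    Returns the long cohort table (animal_id, arm, day, width_mm,
    length_mm, dead_flag) consumed by :mod:`depotflow.cohort`.
    """
    if v0 <= 0:
        raise InvalidArgumentError("v0 must be positive")
    if growth_rates is None:
        growth_rates = {arm: 0.14 for arm in n_per_arm}
    days = np.asarray([d for d in schedule_days if d <= max_day], dtype=float)
    if days.size < 2 or not np.all(np.diff(days) > 0):
        raise InvalidArgumentError("schedule must be increasing with >= 2 days <= max_day")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(meas_noise_cv**2))  # lognormal sd for the given CV
    rows = []
    for arm, n in n_per_arm.items():
        k = float(growth_rates[arm])
        for i in range(int(n)):
            aid = f"{arm}-{i:02d}"
            for d in days:
                v = v0 * np.exp(k * d)
                if sigma > 0:
                    v *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                w = (2.0 * v) ** (1.0 / 3.0)
                rows.append(
                    {"animal_id": aid, "arm": arm, "day": d,
                     "width_mm": w, "length_mm": w, "dead_flag": False}
                )
    return pd.DataFrame(rows)


def gen_event_table(p_per_group: dict, n_per_group: dict, seed: int = 0):
    """Bernoulli adverse-event counts per group.

    Returns an :class:`depotflow.cohort.EventTable`.
    """
    from .cohort import EventTable

    rng = np.random.default_rng(seed)
    groups, events, totals = [], [], []
    for g, p in p_per_group.items():
        if not 0 <= p <= 1:
            raise InvalidArgumentError("event probabilities must lie in [0, 1]")
        n = int(n_per_group[g])
        groups.append(g)
        events.append(int(rng.binomial(n, p)))
        totals.append(n)
    return EventTable(groups=tuple(groups), events=tuple(events), totals=tuple(totals))


# ---------------------------------------------------------------------------
# writers (external interfaces)
# ---------------------------------------------------------------------------


def write_spectra(directory, timed_spectra) -> str:
    """Write spectrum CSVs plus a ``manifest.csv`` (time_s, spectrum_file)."""
    import os

    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, (t, spec) in enumerate(timed_spectra):
        fn = f"spectrum_{i:04d}.csv"
        pd.DataFrame({"wavenumber": spec.wavenumbers, "intensity": spec.intensities}).to_csv(
            os.path.join(directory, fn), index=False
        )
        rows.append({"time_s": t, "spectrum_file": fn})
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_image(path, image: IntensityImage) -> None:
    """Write a 16-bit TIFF plus a JSON sidecar with the physical scale."""
    import tifffile

    px = np.asarray(image.pixels, dtype=float)
    top = px.max() if px.max() > 0 else 1.0
    tifffile.imwrite(path, (px / top * 65535).astype(np.uint16))
    with open(str(path) + ".json", "w") as fh:
        json.dump({"mm_per_px": image.scale_mm_per_px, "signal_channel": image.channel,
                   "intensity_scale": top / 65535.0}, fh)


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def write_event_csv(path, table) -> None:
    table.to_frame().to_csv(path, index=False)
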