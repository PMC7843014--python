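"""Two-compartment Fickian transport model of the surface-Raman assay.

The assay stacks a well of neat ethanol (height ``h_E``, diffusivity
``D_E``) under a slab of tumor tissue (height ``h_T``, diffusivity
``D_T``), separated by a membrane permeable to ethanol.  Ethanol diffuses
upward; a confocal Raman probe reads the relative ethanol concentration at
the top tumor surface, where a first-order loss term ``K_EV`` accounts for
evaporation.  This module solves the coupled 1-D diffusion problem

    dc/dt = D d2c/dx2         on [0, h_E] u [h_E, h_E + h_T]

with zero flux at the bottom (x = 0), partition jump ``c_T = Phi_ET * c_E``
plus flux continuity at the interface, and either a Robin evaporation
condition ``-D_T dc/dx = K_EV c`` at the top surface (default) or, as a
configurable variant, a volumetric sink ``-K_EV c`` in the tumor.  Inverting
the model against a measured concentration series estimates ``D_T`` (the
effective diffusion coefficient of ethanol in tumor) and ``K_EV``.

Numerics: finite volumes on the partition-weighted variable ``a`` (equal to
``c`` in the ethanol compartment and ``c / Phi_ET`` in the tumor, so that
``a`` is continuous at the interface), with faces clustered at the interface
and at the tumor surface, and backward-Euler stepping on geometric
dt-doubling blocks.  The scheme is unconditionally stable and conserves
mass exactly (up to linear-solver roundoff) when ``K_EV = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded
from scipy.optimize import least_squares
from scipy.special import erfc

from .errors import (
    DiagnosticUnavailableError,
    FitFailureError,
    InvalidArgumentError,
    NonIdentifiableError,
    NumericalResolutionError,
)
from .raman import ConcentrationSeries

#: Default fit bounds (cm^2/s and cm/s).
DEFAULT_BOUNDS = {"D_T": (1e-8, 1e-4), "K_EV": (0.0, 1e-2)}


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of the two-compartment assay.

    Units: diffusivities cm^2/s; heights cm; ``K_EV`` cm/s when applied as a
    surface mass-transfer (Robin) coefficient, 1/s in the volumetric-sink
    variant; ``Phi_ET`` dimensionless.
    """

    D_T: float
    K_EV: float = 0.0
    h_T: float = 0.5
    D_E: float = 1e-5
    Phi_ET: float = 1.0
    h_E: float = 1.5

    def __post_init__(self):
        if not (self.D_T > 0 and self.D_E > 0):
            raise InvalidArgumentError("diffusion coefficients must be positive")
        if self.K_EV < 0:
            raise InvalidArgumentError("K_EV must be non-negative")
        if not (0 < self.Phi_ET <= 10):
            raise InvalidArgumentError("Phi_ET must lie in (0, 10]")
        if not (self.h_E > 0 and self.h_T > 0):
            raise InvalidArgumentError("compartment heights must be positive")

    def equilibrium_surface_concentration(self) -> float:
        """Closed-form plateau for K_EV = 0 (mass conservation).

        The initial ethanol mass ``h_E`` redistributes over a total capacity
        ``h_E + Phi_ET * h_T``; the tumor-side concentration is ``Phi_ET``
        times the shared weighted variable.
        """
        return self.Phi_ET * self.h_E / (self.h_E + self.Phi_ET * self.h_T)


@dataclass(frozen=True)
class TransportFit:
    """Result of fitting (D_T, K_EV) to an observed concentration series."""

    params_hat: TransportParams
    sse: float
    n_iter: int
    converged: bool
    ci_halfwidths: dict | None = None
    kev_mode: str = "surface"
    start_diagnostics: list = field(default_factory=list, compare=False)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _mesh(p: TransportParams, n_grid: int):
    """Cell widths / capacities / conductivities on the stacked domain.

    ``n_grid`` cells per compartment.  Ethanol faces follow a sine grading
    (clustered at the interface); tumor faces follow a cosine grading
    (clustered at both the interface and the top surface, where the Robin
    condition and the observation live).
    """
    n = int(n_grid)
    j = np.arange(n + 1)
    faces_e = p.h_E * np.sin(0.5 * np.pi * j / n)
    faces_t = p.h_E + 0.5 * p.h_T * (1.0 - np.cos(np.pi * j / n))
    faces = np.concatenate([faces_e, faces_t[1:]])
    widths = np.diff(faces)
    in_tumor = np.arange(widths.size) >= n
    beta = np.where(in_tumor, p.Phi_ET, 1.0)  # capacity: c = beta * a
    cond = np.where(in_tumor, p.D_T * p.Phi_ET, p.D_E)
    return widths, beta, cond, in_tumor


def _time_grid(t_max: float, n_steps: int, n_blocks: int = 12):
    """Geometric dt-doubling grid: fine early steps, coarse late ones."""
    m = max(2, int(n_steps) // n_blocks)
    dt0 = t_max / (m * (2.0**n_blocks - 1.0))
    ts = [0.0]
    dt = dt0
    for _ in range(n_blocks):
        for _ in range(m):
            ts.append(ts[-1] + dt)
        dt *= 2.0
    ts = np.array(ts)
    ts[-1] = t_max  # guard roundoff
    return ts


def _solve(p: TransportParams, t_max: float, n_grid: int, n_steps: int, kev_mode: str):
    """March the FV system; returns (step times, surface c, field a, widths, beta)."""
    widths, beta, cond, in_tumor = _mesh(p, n_grid)
    n = widths.size
    # face conductances (harmonic; interior faces only)
    g = 1.0 / (0.5 * widths[:-1] / cond[:-1] + 0.5 * widths[1:] / cond[1:])

    # surface observation / Robin coupling factor:
    # a_face = a_N / (1 + K_EV * w_N / (2 D_T)) in surface mode
    if kev_mode == "surface":
        robin_denom = 1.0 + p.K_EV * widths[-1] / (2.0 * p.D_T)
        gamma = p.K_EV * p.Phi_ET / robin_denom  # outflux = gamma * a_N
        sink = np.zeros(n)
    elif kev_mode == "volumetric":
        robin_denom = 1.0
        gamma = 0.0
        sink = np.where(in_tumor, p.K_EV * p.Phi_ET * widths, 0.0)
    else:
        raise InvalidArgumentError(f"unknown kev_mode {kev_mode!r}")

    a = np.where(in_tumor, 0.0, 1.0)  # initial: c=1 in ethanol, 0 in tumor
    times = _time_grid(t_max, n_steps)
    surface = np.empty(times.size)
    surface[0] = p.Phi_ET * a[-1] / robin_denom

    stiff_diag = np.zeros(n)
    stiff_diag[:-1] += g
    stiff_diag[1:] += g
    stiff_diag += sink
    stiff_diag[-1] += gamma
    mass = beta * widths

    ab = np.empty((2, n))
    chol = None
    prev_dt = -1.0
    store = np.empty((times.size, n))
    store[0] = a
    for k in range(1, times.size):
        dt = times[k] - times[k - 1]
        if not np.isclose(dt, prev_dt):
            ab[1, :] = mass / dt + stiff_diag
            ab[0, 0] = 0.0
            ab[0, 1:] = -g
            try:
                chol = cholesky_banded(ab, lower=False)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise NumericalResolutionError(
                    "banded Cholesky failed; refine the grid or time step"
                ) from exc
            prev_dt = dt
        a = cho_solve_banded((chol, False), mass / dt * a)
        if not np.all(np.isfinite(a)):
            raise NumericalResolutionError("non-finite solution; refine the grid")
        store[k] = a
        surface[k] = p.Phi_ET * a[-1] / robin_denom
    return times, surface, store, widths, beta


def simulate_surface_concentration(
    params: TransportParams,
    times,
    n_grid: int = 60,
    n_steps: int = 400,
    kev_mode: str = "surface",
) -> ConcentrationSeries:
    """Forward-simulate the relative surface concentration at given times.

    ``times`` must start at 0 and be strictly increasing; ``n_grid`` is the
    number of cells per compartment (>= 50).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1 or t[0] != 0 or (t.size > 1 and not np.all(np.diff(t) > 0)):
        raise InvalidArgumentError("times must start at 0 and be strictly increasing")
    if n_grid < 50:
        raise InvalidArgumentError("n_grid must be at least 50 cells per compartment")
    if t[-1] == 0:
        return ConcentrationSeries(times=t, c=np.zeros_like(t))
    step_t, surf, _, _, _ = _solve(params, float(t[-1]), n_grid, n_steps, kev_mode)
    c = np.interp(t, step_t, surf)
    c[t == 0] = 0.0
    return ConcentrationSeries(times=t, c=c, c_raw=c.copy())


def simulate_profile(
    params: TransportParams,
    times,
    n_grid: int = 60,
    n_steps: int = 400,
    kev_mode: str = "surface",
):
    """Full concentration field c(x, t) for diagnostics and verification.

    Returns ``(x_centers, c)`` with ``c`` of shape (len(times), n_cells),
    already on the physical concentration scale (partition jump applied).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t[0] != 0 or not np.all(np.diff(t) > 0):
        raise InvalidArgumentError("times must start at 0 and be strictly increasing")
    step_t, _, store, widths, beta = _solve(params, float(t[-1]), n_grid, n_steps, kev_mode)
    x = np.concatenate([[0.0], np.cumsum(widths)])
    centers = 0.5 * (x[:-1] + x[1:])
    field_at = np.empty((t.size, centers.size))
    for i in range(centers.size):
        field_at[:, i] = np.interp(t, step_t, store[:, i])
    return centers, field_at * beta[None, :]


def total_mass(params: TransportParams, a_field_c: np.ndarray, n_grid: int = 60) -> np.ndarray:
    """Partition-weighted mass integral of a c-field from simulate_profile."""
    widths, beta, _, _ = _mesh(params, n_grid)
    return (a_field_c / beta[None, :] * (beta * widths)[None, :]).sum(axis=1)


def semi_infinite_oracle(params: TransportParams, depth, t, reflected: bool = False):
    """Closed-form two-medium contact solution (early-time reference).

    Two semi-infinite media meet at the interface: ethanol (c=1) below,
    tumor (c=0) above, partition ``Phi``.  At depth ``z`` into the tumor,

        c(z, t) = B * erfc( z / (2 sqrt(D_T t)) ),
        B = Phi * sqrt(D_E) / (sqrt(D_E) + Phi * sqrt(D_T)).

    With ``reflected=True`` a single image term about the insulated top
    surface is added (doubling the value at z = h_T), valid while the
    reflected front has not re-reached the interface.
    """
    z = np.asarray(depth, dtype=float)
    t = np.asarray(t, dtype=float)
    b = (
        params.Phi_ET
        * np.sqrt(params.D_E)
        / (np.sqrt(params.D_E) + params.Phi_ET * np.sqrt(params.D_T))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = z / (2.0 * np.sqrt(params.D_T * t))
        out = b * erfc(arg)
        if reflected:
            out = out + b * erfc((2.0 * params.h_T - z) / (2.0 * np.sqrt(params.D_T * t)))
    return np.where(t > 0, out, 0.0)


# ---------------------------------------------------------------------------
# inverse problem
# ---------------------------------------------------------------------------


def fit_transport(
    observed: ConcentrationSeries,
    fixed: TransportParams,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
    n_grid: int = 60,
    n_steps: int = 400,
    kev_mode: str = "surface",
) -> TransportFit:
    """Estimate (D_T, K_EV) by bounded nonlinear least squares.

    ``fixed`` supplies the known assay geometry (D_E, Phi_ET, h_E, h_T);
    its D_T / K_EV entries are ignored.  D_T is optimized in log10 space.
    ``n_starts`` log-uniform multi-starts guard against local minima; the
    best local optimum by SSE is returned.
    """
    if len(observed) < 10:
        raise InvalidArgumentError("need at least 10 observed points spanning a rise")
    if float(np.max(observed.c)) < 1e-6:
        raise NonIdentifiableError("observed series is flat at zero; D_T is not identifiable")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    (dt_lo, dt_hi), (kev_lo, kev_hi) = b["D_T"], b["K_EV"]
    log_lo, log_hi = np.log10(dt_lo), np.log10(dt_hi)
    t_obs, c_obs = observed.times, observed.c

    def residuals(x):
        p = replace(fixed, D_T=10.0 ** x[0], K_EV=x[1])
        sim = simulate_surface_concentration(p, t_obs, n_grid=n_grid, n_steps=n_steps, kev_mode=kev_mode)
        return sim.c - c_obs

    rng = np.random.default_rng(seed)
    starts = [(0.5 * (log_lo + log_hi), max(kev_lo, min(kev_hi, 1e-5)))]
    while len(starts) < n_starts:
        starts.append(
            (
                rng.uniform(log_lo, log_hi),
                float(np.clip(10.0 ** rng.uniform(-7, np.log10(max(kev_hi, 1e-7))), kev_lo, kev_hi)),
            )
        )

    best = None
    diagnostics = []
    for x0 in starts[:n_starts]:
        try:
            res = least_squares(
                residuals,
                x0=np.array(x0),
                bounds=([log_lo, kev_lo], [log_hi, kev_hi]),
                gtol=1e-10,
                xtol=1e-12,
                ftol=1e-12,
                x_scale=[1.0, max(0.1 * (kev_hi - kev_lo), 1e-6)],
            )
        except (NumericalResolutionError, np.linalg.LinAlgError) as exc:
            diagnostics.append({"x0": x0, "error": str(exc)})
            continue
        diagnostics.append({"x0": x0, "sse": float(res.cost * 2), "status": res.status})
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("all optimizer starts failed", diagnostics)

    params_hat = replace(fixed, D_T=10.0 ** best.x[0], K_EV=float(best.x[1]))
    sse = float(2 * best.cost)
    ci = _curvature_ci(best, params_hat, len(observed))
    return TransportFit(
        params_hat=params_hat,
        sse=sse,
        n_iter=int(best.nfev),
        converged=bool(best.status > 0),
        ci_halfwidths=ci,
        kev_mode=kev_mode,
        start_diagnostics=diagnostics,
    )


def _curvature_ci(res, params_hat: TransportParams, n_obs: int):
    """95% half-widths from the local Gauss-Newton curvature (delta method)."""
    dof = n_obs - res.x.size
    if dof <= 0:
        return None
    s2 = 2 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None
    hw = 1.96 * np.sqrt(np.clip(np.diag(cov), 0, None))
    return {
        "D_T": float(np.log(10.0) * params_hat.D_T * hw[0]),  # log10 -> natural scale
        "K_EV": float(hw[1]),
    }


def time_to_half_plateau(series: ConcentrationSeries) -> float:
    """First time c crosses half its final observed value (linear interp).

    A simple identifiability diagnostic: larger D_T shifts it earlier.
    """
    c = series.c
    t = series.times
    if float(np.max(c)) <= 0.05:
        raise DiagnosticUnavailableError("series never rises above 0.05; no plateau to halve")
    half = 0.5 * c[-1]
    above = np.nonzero(c >= half)[0]
    if above.size == 0:
        raise DiagnosticUnavailableError("series never crosses half its final value")
    i = int(above[0])
    if i == 0:
        return float(t[0])
    frac = (half - c[i - 1]) / (c[i] - c[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def rise_schedule(params: TransportParams, n_points: int = 120, plateau_fraction: float = 0.9,
                  n_grid: int = 60, n_steps: int = 400) -> np.ndarray:
    """A measurement schedule spanning the concentration rise.

    Doubles the horizon until the simulated surface concentration either
    reaches ``plateau_fraction`` of the K_EV=0 equilibrium value or has
    peaked inside the window (with evaporation the curve rises then decays
    and never attains the conservative plateau), then returns a uniform
    grid of ``n_points`` samples over that horizon.  This is how the
    synthetic assay chooses its acquisition duration: the fit is only
    identifiable if the observations span the rise.
    """
    target = plateau_fraction * params.equilibrium_surface_concentration()
    t_max = 0.1 * params.h_T**2 / params.D_T
    for _ in range(25):
        sim = simulate_surface_concentration(
            params, np.linspace(0, t_max, 50), n_grid=n_grid, n_steps=n_steps
        )
        if sim.c[-1] >= target or (
            np.max(sim.c) > 0.05 and np.argmax(sim.c) < 0.6 * sim.c.size
        ):
            break
        t_max *= 2.0
    return np.linspace(0.0, t_max, int(n_points))
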