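"""Stochastic reaction-diffusion simulators for LALI (local activation,
long-range inhibition) spot patterns.

Two models are provided:

* a **linear Turing model** on a periodic lattice, updated by explicit
  finite differences for a fixed number of steps,

      du/dt = f_u*u - f_v*v + D * lap(u)
      dv/dt = g_u*u - g_v*v +     lap(v)

  with random initial concentrations u, v ~ Uniform(0, 1) per cell; and

* the **FitzHugh-Nagumo (FHN) model** on a square domain with no-flux
  boundaries, integrated by the method of lines over a fixed time window,

      du/dt = -(u - R)(u^2 - 1) - rho*(v - u) + D * lap(u)
      dv/dt = -(v - u)                        +     lap(v)

  started from the homogeneous steady state u = v = -1 perturbed by
  spatially uncorrelated uniform noise.

In both models developmental noise enters solely through the random
initial conditions; everything else is deterministic, so a (parameter
set, seed) pair reproduces a simulation exactly.  The final fields are
intentionally *not* steady states: integration stops at a fixed step
count / end time, capturing the pattern at an intermediate stage.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn

from .morphometrics import BinaryPattern

__all__ = [
    "LinearTuringParams",
    "FHNParams",
    "MorphogenField",
    "simulate_linear",
    "simulate_fhn",
    "fhn_homogeneous_steady_states",
    "linear_growth_rates",
    "binarize_field",
    "save_field",
    "load_field",
]


class SimulationError(RuntimeError):
    """Raised when a simulation produces non-finite values."""


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearTuringParams:
    """Parameters of the linear Turing model.

    The kinetic constants are rates: ``f_u`` (activator self-upregulation),
    ``f_v`` (down-regulation of activator by inhibitor), ``g_u``
    (upregulation of inhibitor by activator), ``g_v`` (inhibitor
    self-down-regulation).  ``D`` is the activator:inhibitor diffusion
    ratio; the inhibitor diffusion coefficient is 1 in lattice units.

    Construction validates the diffusion-driven-instability (Turing)
    conditions and the explicit-scheme stability bound
    ``dt <= dx**2 / (4 * max(D, 1))``.
    """

    f_u: float = 0.811
    f_v: float = 1.0
    g_u: float = 1.0
    g_v: float = 1.0
    D: float = 0.25
    grid_n: int = 200
    dx: float = 1.0
    dt: float = 0.05
    n_steps: int = 200_000
    boundary: str = "periodic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.boundary != "periodic":
            raise ValueError("linear model supports periodic boundaries only")
        if not (0 < self.D < 1):
            raise ValueError(f"D must lie in (0, 1): got {self.D}")
        if self.grid_n < 8:
            raise ValueError("grid_n must be >= 8")
        tr = self.f_u - self.g_v
        det = self.f_v * self.g_u - self.f_u * self.g_v
        crit = self.f_u - self.D * self.g_v
        if not (tr < 0 and det > 0 and crit > 0 and crit**2 > 4 * self.D * det):
            raise ValueError(
                "Turing conditions violated: need f_u - g_v < 0, "
                "f_v*g_u - f_u*g_v > 0, f_u - D*g_v > 0 and "
                "(f_u - D*g_v)**2 > 4*D*(f_v*g_u - f_u*g_v); "
                f"got f_u={self.f_u}, f_v={self.f_v}, g_u={self.g_u}, "
                f"g_v={self.g_v}, D={self.D}"
            )
        dt_max = self.dx**2 / (4.0 * max(self.D, 1.0))
        if self.dt > dt_max:
            raise ValueError(
                f"dt={self.dt} violates the explicit-scheme stability bound "
                f"dt <= dx^2/(4*max(D,1)) = {dt_max:g}"
            )


@dataclass(frozen=True)
class FHNParams:
    """Parameters of the FitzHugh-Nagumo model.

    ``R`` is the reference activator concentration (it is also the
    intermediate homogeneous steady state), ``rho`` the relative
    production rate of activator versus inhibitor, ``D`` the diffusion
    ratio, ``L`` the physical side length of the square domain and
    ``perturb_amp`` the half-width of the uniform perturbation applied
    to the u = v = -1 steady state at each grid point.
    """

    R: float = 0.047
    rho: float = 2.63
    D: float = 0.0194
    L: float = 20.0
    grid_n: int = 200
    t_end: float = 20.0
    perturb_amp: float = 0.25
    perturb_target: str = "both"  # "both" or "u"
    boundary: str = "no-flux"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.boundary != "no-flux":
            raise ValueError("FHN model supports no-flux boundaries only")
        if self.grid_n < 8:
            raise ValueError("grid_n must be >= 8")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.perturb_amp < 0:
            raise ValueError("perturb_amp must be >= 0")
        if self.perturb_target not in ("both", "u"):
            raise ValueError("perturb_target must be 'both' or 'u'")

    @property
    def dx(self) -> float:
        return self.L / self.grid_n


@dataclass
class MorphogenField:
    """Activator/inhibitor lattices produced by a simulator run.

    For the linear model, whose unstable modes grow without bound, the
    stored fields may be rescaled by a common positive factor to keep
    them representable; ``log_amplitude`` records the natural log of the
    discarded factor (0.0 when no rescaling occurred).  All downstream
    pattern measures are invariant under positive rescaling.
    """

    u: np.ndarray
    v: np.ndarray
    dx: float
    t_final: float
    model_tag: str  # "linear" | "fhn"
    params: LinearTuringParams | FHNParams
    log_amplitude: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2-D arrays of identical shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise SimulationError("non-finite values in morphogen field")


# --------------------------------------------------------------------------
# linear Turing model
# --------------------------------------------------------------------------

def _periodic_laplacian_eigenvalues(n: int, dx: float) -> np.ndarray:
    """Eigenvalues of the periodic 5-point Laplacian on an n x n lattice."""
    theta = 2.0 * np.pi * np.fft.fftfreq(n)
    lam1 = (2.0 * np.cos(theta) - 2.0) / dx**2
    return lam1[:, None] + lam1[None, :]


def _per_mode_update_matrices(p: LinearTuringParams) -> np.ndarray:
    """Per-Fourier-mode one-step update matrix A(k) = I + dt*J(k), shape (n, n, 4)."""
    lam = _periodic_laplacian_eigenvalues(p.grid_n, p.dx)
    a = 1.0 + p.dt * (p.f_u + p.D * lam)
    b = np.full_like(lam, -p.dt * p.f_v)
    c = np.full_like(lam, p.dt * p.g_u)
    d = 1.0 + p.dt * (-p.g_v + lam)
    return np.stack([a, b, c, d], axis=-1)


def _matmul22(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            x[..., 0] * y[..., 0] + x[..., 1] * y[..., 2],
            x[..., 0] * y[..., 1] + x[..., 1] * y[..., 3],
            x[..., 2] * y[..., 0] + x[..., 3] * y[..., 2],
            x[..., 2] * y[..., 1] + x[..., 3] * y[..., 3],
        ],
        axis=-1,
    )


def _matpow22_scaled(a: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """A**n by binary exponentiation with overflow-safe global rescaling.

    Returns (P, log_scale) such that the true power is P * exp(log_scale).
    """
    result = np.zeros_like(a)
    result[..., 0] = 1.0
    result[..., 3] = 1.0
    log_r, log_a = 0.0, 0.0
    while n:
        if n & 1:
            result = _matmul22(result, a)
            log_r += log_a
            m = np.abs(result).max()
            result /= m
            log_r += np.log(m)
        n >>= 1
        if n:
            a = _matmul22(a, a)
            log_a *= 2.0
            m = np.abs(a).max()
            a /= m
            log_a += np.log(m)
    return result, log_r


_EULER_RENORM = 1e100


def simulate_linear(
    params: LinearTuringParams,
    *,
    u0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    method: str = "spectral",
) -> MorphogenField:
    """Run the linear Turing model for exactly ``params.n_steps`` updates.

    Initial conditions default to i.i.d. Uniform(0, 1) per cell for both
    morphogens (the developmental-noise model); pass ``u0``/``v0`` to
    override them deterministically.

    Two equivalent integration paths are provided.  ``method="euler"``
    performs the literal forward-Euler lattice iteration with the 5-point
    periodic Laplacian.  ``method="spectral"`` (default) applies the
    identical linear update in Fourier space, raising each mode's 2x2
    one-step matrix to the n_steps-th power by binary exponentiation;
    because the scheme is linear the two agree to roundoff while the
    spectral path costs O(n^2 log n) regardless of step count.  Growing
    fields are rescaled by a common factor recorded in
    ``MorphogenField.log_amplitude``.
    """
    n = params.grid_n
    rng = np.random.default_rng(params.seed)
    if u0 is None:
        u0 = rng.uniform(0.0, 1.0, (n, n))
    if v0 is None:
        v0 = rng.uniform(0.0, 1.0, (n, n))
    u0 = np.asarray(u0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if u0.shape != (n, n) or v0.shape != (n, n):
        raise ValueError(f"initial conditions must have shape ({n}, {n})")

    if method == "spectral":
        u, v, log_amp = _simulate_linear_spectral(params, u0, v0)
    elif method == "euler":
        u, v, log_amp = _simulate_linear_euler(params, u0, v0)
    else:
        raise ValueError(f"unknown method {method!r}")

    return MorphogenField(
        u=u,
        v=v,
        dx=params.dx,
        t_final=params.n_steps * params.dt,
        model_tag="linear",
        params=params,
        log_amplitude=log_amp,
    )


def _simulate_linear_spectral(
    p: LinearTuringParams, u0: np.ndarray, v0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    prop, log_scale = _linear_propagator(p)
    uf = np.fft.fft2(u0)
    vf = np.fft.fft2(v0)
    u = np.fft.ifft2(prop[..., 0] * uf + prop[..., 1] * vf).real
    v = np.fft.ifft2(prop[..., 2] * uf + prop[..., 3] * vf).real
    # fold the scale back in when it is representable so that small runs
    # return unscaled fields (as the literal Euler iteration would)
    if abs(log_scale) < 300.0:
        s = np.exp(log_scale)
        u *= s
        v *= s
        log_scale = 0.0
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise SimulationError(
            f"non-finite field after {p.n_steps} steps "
            f"(dt={p.dt}, stability bound {p.dx**2 / (4 * max(p.D, 1)):g})"
        )
    return u, v, log_scale


_PROPAGATOR_CACHE: dict[tuple, tuple[np.ndarray, float]] = {}


def _linear_propagator(p: LinearTuringParams) -> tuple[np.ndarray, float]:
    key = (p.grid_n, p.dx, p.dt, p.n_steps, p.f_u, p.f_v, p.g_u, p.g_v, p.D)
    hit = _PROPAGATOR_CACHE.get(key)
    if hit is None:
        if len(_PROPAGATOR_CACHE) > 64:
            _PROPAGATOR_CACHE.clear()
        hit = _matpow22_scaled(_per_mode_update_matrices(p), p.n_steps)
        _PROPAGATOR_CACHE[key] = hit
    return hit


def _simulate_linear_euler(
    p: LinearTuringParams, u0: np.ndarray, v0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    u, v = u0.copy(), v0.copy()
    inv_dx2 = 1.0 / p.dx**2

    def lap(f: np.ndarray) -> np.ndarray:
        return (
            np.roll(f, 1, 0) + np.roll(f, -1, 0) + np.roll(f, 1, 1) + np.roll(f, -1, 1) - 4.0 * f
        ) * inv_dx2

    log_amp = 0.0
    for step in range(p.n_steps):
        u, v = (
            u + p.dt * (p.f_u * u - p.f_v * v + p.D * lap(u)),
            v + p.dt * (p.g_u * u - p.g_v * v + lap(v)),
        )
        m = max(np.abs(u).max(), np.abs(v).max())
        if not np.isfinite(m):
            raise SimulationError(
                f"non-finite field at step {step + 1} "
                f"(dt={p.dt}, stability bound {p.dx**2 / (4 * max(p.D, 1)):g})"
            )
        if m > _EULER_RENORM:
            u /= m
            v /= m
            log_amp += np.log(m)
    return u, v, log_amp


def linear_growth_rates(params: LinearTuringParams, k_squared: float) -> np.ndarray:
    """Dispersion relation of the linear model.

    Returns the two (possibly complex) eigenvalues of the per-mode
    Jacobian ``[[f_u - D*k^2, -f_v], [g_u, -g_v - k^2]]``.  The band of
    k^2 with positive real part locates the diffusion-driven instability
    and 2*pi/k_max predicts the emerging pattern wavelength.
    """
    if k_squared < 0:
        raise ValueError("k_squared must be >= 0")
    jac = np.array(
        [
            [params.f_u - params.D * k_squared, -params.f_v],
            [params.g_u, -params.g_v - k_squared],
        ]
    )
    return np.linalg.eigvals(jac)


def fastest_growing_wavenumber(params: LinearTuringParams, k_max: float = 10.0) -> float:
    """k (not k^2) maximizing the real part of the dispersion relation."""
    k2 = np.linspace(0.0, k_max**2, 4001)
    tr = (params.f_u - params.D * k2) + (-params.g_v - k2)
    det = (params.f_u - params.D * k2) * (-params.g_v - k2) + params.f_v * params.g_u
    sigma = (tr / 2.0 + np.sqrt(np.asarray(tr**2 / 4.0 - det, dtype=complex))).real
    return float(np.sqrt(k2[np.argmax(sigma)]))


# --------------------------------------------------------------------------
# FitzHugh-Nagumo model
# --------------------------------------------------------------------------

def fhn_homogeneous_steady_states(R: float, rho: float = 0.0) -> np.ndarray:
    """Homogeneous steady states of the FHN kinetics.

    With u = v the inhibitor equation is satisfied identically and the
    activator equation reduces to (u - R)(u^2 - 1) = 0; the roots of that
    cubic are computed numerically and returned sorted ascending.  ``rho``
    is accepted for interface symmetry but drops out at u = v.
    """
    roots = np.roots([1.0, -R, -1.0, R])
    roots = np.sort(roots.real[np.abs(roots.imag) < 1e-9])
    return roots


def _neumann_laplacian_eigenvalues(n: int, dx: float) -> np.ndarray:
    """Eigenvalues of the no-flux (mirrored) 5-point Laplacian under DCT-II."""
    lam1 = 2.0 * (np.cos(np.pi * np.arange(n) / n) - 1.0) / dx**2
    return lam1[:, None] + lam1[None, :]


def simulate_fhn(
    params: FHNParams,
    *,
    u0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    dt: float = 0.02,
) -> MorphogenField:
    """Integrate the FHN model to ``t_end`` by the method of lines.

    The spatial discretization is the 5-point Laplacian with no-flux
    (mirrored ghost cell) boundaries.  Time stepping uses Strang
    splitting: the stiff diffusion terms are advanced exactly in the
    cosine (DCT-II) basis, which diagonalizes the Neumann Laplacian,
    and the pointwise reaction terms by Heun's method with step ``dt``.
    The splitting keeps the cost independent of the diffusion stiffness,
    which matters because Monte-Carlo phenotype clouds need thousands of
    runs.  Homogeneous steady states are exact fixed points of the
    scheme.

    Initial conditions default to the steady state u = v = -1 perturbed
    by i.i.d. Uniform(-perturb_amp, +perturb_amp) noise at every grid
    point (applied to both fields, or to u only per ``perturb_target``).
    """
    n = params.grid_n
    rng = np.random.default_rng(params.seed)
    if u0 is None:
        u0 = -1.0 + params.perturb_amp * rng.uniform(-1.0, 1.0, (n, n))
    if v0 is None:
        if params.perturb_target == "both":
            v0 = -1.0 + params.perturb_amp * rng.uniform(-1.0, 1.0, (n, n))
        else:
            v0 = np.full((n, n), -1.0)
    u = np.asarray(u0, dtype=float).copy()
    v = np.asarray(v0, dtype=float).copy()
    if u.shape != (n, n) or v.shape != (n, n):
        raise ValueError(f"initial conditions must have shape ({n}, {n})")

    n_steps = max(1, int(np.ceil(params.t_end / dt)))
    dt = params.t_end / n_steps
    lam = _neumann_laplacian_eigenvalues(n, params.dx)
    e_u = np.exp(params.D * lam * dt / 2.0)
    e_v = np.exp(lam * dt / 2.0)
    R, rho = params.R, params.rho

    def diffuse(f: np.ndarray, e: np.ndarray) -> np.ndarray:
        return idctn(dctn(f, norm="ortho") * e, norm="ortho")

    for step in range(n_steps):
        u = diffuse(u, e_u)
        v = diffuse(v, e_v)
        # Heun step on the reaction terms
        fu1 = -(u - R) * (u * u - 1.0) - rho * (v - u)
        fv1 = -(v - u)
        up = u + dt * fu1
        vp = v + dt * fv1
        fu2 = -(up - R) * (up * up - 1.0) - rho * (vp - up)
        fv2 = -(vp - up)
        u = u + dt * (fu1 + fu2) / 2.0
        v = v + dt * (fv1 + fv2) / 2.0
        u = diffuse(u, e_u)
        v = diffuse(v, e_v)
        if step % 50 == 49 and not np.isfinite(u).all():
            raise SimulationError(
                f"non-finite FHN state at t = {(step + 1) * dt:g}"
            )

    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise SimulationError(f"non-finite FHN state at t = {params.t_end:g}")
    return MorphogenField(
        u=u,
        v=v,
        dx=params.dx,
        t_final=params.t_end,
        model_tag="fhn",
        params=params,
    )


# --------------------------------------------------------------------------
# binarization
# --------------------------------------------------------------------------

def binarize_field(
    field: MorphogenField, T_rel: float, *, shift: str | None = None
) -> BinaryPattern:
    """Threshold the activator field into a pigmented/background pattern.

    A pixel is pigmented iff ``s >= T_rel * mean(s)`` where ``s`` is the
    activator after a model-specific positive shift chosen so that the
    relative threshold is meaningful:

    * ``"plus1"`` (FHN default): s = u + 1, mapping the background
      steady state u = -1 to 0;
    * ``"min"`` (linear default): s = u - min(u).  The linear kinetics
      damp the uniform mode while patterned modes grow, so at the
      measurement time the raw field oscillates about zero and its mean
      carries no information; anchoring the shift at the field minimum
      makes T_rel > 1 select the upper part of the morphogen range and
      produce minority-pigmented spot patterns.
    * ``"none"``: threshold the raw activator.
    """
    if T_rel <= 0:
        raise ValueError("T_rel must be positive")
    if shift is None:
        shift = "plus1" if field.model_tag == "fhn" else "min"
    u = field.u
    if shift == "none":
        s = u
    elif shift == "plus1":
        s = u + 1.0
    elif shift == "min":
        s = u - u.min()
    else:
        raise ValueError(f"unknown shift {shift!r}")
    mean = float(s.mean())
    if mean <= 0:
        raise ValueError(
            f"mean of shifted activator is {mean:g} <= 0; relative threshold undefined"
        )
    mask = s >= T_rel * mean
    return BinaryPattern(mask=mask)


# --------------------------------------------------------------------------
# field archive
# --------------------------------------------------------------------------

def save_field(field: MorphogenField, path) -> None:
    """Archive a field with its full parameter record (compressed npz)."""
    rec = dataclasses.asdict(field.params)
    # seeds may be SeedSequence objects; archive only primitive values
    rec = {k: (v if isinstance(v, (int, float, str, bool, type(None))) else None)
           for k, v in rec.items()}
    keys = list(rec)
    vals = [repr(rec[k]) for k in keys]
    np.savez_compressed(
        path,
        u=field.u,
        v=field.v,
        dx=field.dx,
        t_final=field.t_final,
        model_tag=field.model_tag,
        log_amplitude=field.log_amplitude,
        param_keys=np.array(keys),
        param_vals=np.array(vals),
    )


def load_field(path) -> MorphogenField:
    with np.load(path, allow_pickle=False) as z:
        rec = {
            k: eval(v, {"__builtins__": {}}, {})  # reprs of numbers/strings/None only
            for k, v in zip(z["param_keys"], z["param_vals"])
        }
        tag = str(z["model_tag"])
        params = LinearTuringParams(**rec) if tag == "linear" else FHNParams(**rec)
        return MorphogenField(
            u=z["u"],
            v=z["v"],
            dx=float(z["dx"]),
            t_final=float(z["t_final"]),
            model_tag=tag,
            params=params,
            log_amplitude=float(z["log_amplitude"]),
        )
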