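"""Fluid-like non-parametric registration of consecutive frames.

The model finds a dense displacement field ``u`` mapping a deformable
source image S onto a fixed template T in an Eulerian frame, i.e. it
minimises the sum-of-squares matching energy

    E_match(u) = 1/2 * sum_x (S(x - u(x)) - T(x))**2

together with a curvature regulariser applied to the *velocity* field
``v = du/dt`` rather than to ``u`` itself — this is what makes the model
fluid-like and lets it absorb large inter-frame deformations.  In the
over-damped limit with position-independent damping ``gamma`` and a
viscosity weight ``eta`` the flow reduces to solving, at every pseudo-time,

    (gamma + eta * Lap**2) v = f(x, u),
    f(x, u) = -(S(x - u(x)) - T(x)) * grad(S)|_{x - u(x)},

and integrating du/dt = v with a step-size-controlled Runge–Kutta pair
until the relative SSD change per accepted step falls below a threshold.
The biharmonic operator is diagonalised with a type-II cosine transform
(Neumann boundaries — microscopy frames are not periodic), so each
velocity solve is a pair of fast transforms per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "warp_image",
    "ssd_residual",
    "force_field",
    "solve_velocity",
    "register_pair",
]


@dataclass
class RegistrationParams:
    """Tunables of the variational fluid registration.

    alpha
        Weight of the curvature regularity term relative to the matching
        term.  In the over-damped flow it plays the role of the viscosity
        weight, so ``eta_viscosity`` defaults to ``alpha``.  Colony motion
        between consecutive frames is smooth, so a fairly stiff default
        (10) recovers it far more accurately than a weak one: the SSD term
        alone leaves the field unconstrained wherever the texture gradient
        is weak.
    gamma_damping
        Position-independent damping coefficient; larger values slow the
        flow but guarantee convergence once the images match.
    rk_rel_tol
        Relative local-error tolerance of the embedded Runge-Kutta 4(5)
        integrator.
    convergence_rel_change
        Relative SSD decrease per accepted step below which the flow is
        declared converged.
    pre_smooth_sigma
        Gaussian pre-smoothing of both inputs (pixels); 0 disables it.
        Raw phase-contrast SSD forces are noise-dominated without it.
    """

    alpha: float = 10.0
    gamma_damping: float = 0.1
    eta_viscosity: float | None = None
    rk_rel_tol: float = 1e-3
    max_pseudo_time: float = 1e6
    convergence_rel_change: float = 1e-4
    max_steps: int = 500
    pre_smooth_sigma: float = 1.0
    advection: bool = False

    def __post_init__(self) -> None:
        if self.eta_viscosity is None:
            self.eta_viscosity = self.alpha
        for name in ("alpha", "gamma_damping", "eta_viscosity", "rk_rel_tol",
                     "max_pseudo_time", "convergence_rel_change"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.pre_smooth_sigma < 0:
            raise ValueError("pre_smooth_sigma must be >= 0")


@dataclass
class RegistrationResult:
    field: np.ndarray  # (2, H, W) displacement, pixel units
    residual_history: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = False
    steps_taken: int = 0
    min_jacobian: float = 1.0


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _sample_coords(u: np.ndarray) -> np.ndarray:
    h, w = u.shape[1:]
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.stack([rr - u[0], cc - u[1]])


def warp_image(
    S: np.ndarray,
    u: np.ndarray,
    interpolation: Literal["linear", "nearest"] = "linear",
) -> np.ndarray:
    """Sample S at x - u(x) (Eulerian warp), edge-clamped outside the domain."""
    S = np.asarray(S, dtype=np.float64)
    if u.shape != (2, *S.shape):
        raise ValueError(f"field shape {u.shape} does not match image {S.shape}")
    order = 1 if interpolation == "linear" else 0
    return ndimage.map_coordinates(S, _sample_coords(u), order=order, mode="nearest")


def ssd_residual(S: np.ndarray, T: np.ndarray, u: np.ndarray) -> float:
    """Matching energy 1/2 * sum (S(x-u) - T)^2."""
    _check_pair(S, T)
    diff = warp_image(S, u) - np.asarray(T, dtype=np.float64)
    return 0.5 * float(np.sum(diff * diff))


def _gradient(img: np.ndarray) -> np.ndarray:
    """Central differences, one-sided at borders; returns (2, H, W)."""
    gr, gc = np.gradient(img)
    return np.stack([gr, gc])


def force_field(S: np.ndarray, T: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Body force of the SSD matching term in the Eulerian frame.

    f(x, u) = (S(x-u(x)) - T(x)) * grad(S)|_{x-u(x)} — the negative
    variational gradient of the matching energy under the ``S(x-u)``
    sampling convention, so the over-damped flow along f descends the
    SSD.  The gradient of the warped source stands in for grad(S)
    evaluated at the pulled-back point.
    """
    _check_pair(S, T)
    Sw = warp_image(S, u)
    grad = _gradient(Sw)
    return (Sw - np.asarray(T, dtype=np.float64))[None] * grad


def _laplacian_symbol(shape: tuple[int, int]) -> np.ndarray:
    """Eigenvalues of the 5-point Laplacian under the DCT-II (Neumann) basis."""
    h, w = shape
    lr = 2.0 * np.cos(np.pi * np.arange(h) / h) - 2.0
    lc = 2.0 * np.cos(np.pi * np.arange(w) / w) - 2.0
    return lr[:, None] + lc[None, :]


def solve_velocity(f: np.ndarray, gamma_damping: float, eta_viscosity: float) -> np.ndarray:
    """Solve (gamma + eta * Lap^2) v = f componentwise via DCT diagonalisation.

    The discrete biharmonic is the square of the Neumann 5-point Laplacian,
    so in the cosine-transform domain the operator is the scalar
    gamma + eta * lambda^2 per mode — one forward/inverse transform pair
    per vector component ("fast Poisson" structure).
    """
    if gamma_damping <= 0 or eta_viscosity <= 0:
        raise ValueError("gamma_damping and eta_viscosity must be positive")
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3 or f.shape[0] != 2:
        raise ValueError("force must have shape (2, H, W)")
    if not np.all(np.isfinite(f)):
        raise ValueError("force field contains non-finite values")
    lam = _laplacian_symbol(f.shape[1:])
    denom = gamma_damping + eta_viscosity * lam * lam
    out = np.empty_like(f)
    for k in range(2):
        fh = dctn(f[k], type=2, norm="ortho")
        out[k] = idctn(fh / denom, type=2, norm="ortho")
    return out


def _velocity(S: np.ndarray, T: np.ndarray, u: np.ndarray, p: RegistrationParams) -> np.ndarray:
    v = solve_velocity(force_field(S, T, u), p.gamma_damping, p.eta_viscosity)
    if p.advection:
        # classical fluid transport du/dt = v - (grad u) v
        adv = np.empty_like(v)
        for k in range(2):
            gr, gc = np.gradient(u[k])
            adv[k] = gr * v[0] + gc * v[1]
        v = v - adv
    return v


# Cash–Karp embedded Runge–Kutta 4(5) tableau.
_CK_A = (
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (3 / 10, -9 / 10, 6 / 5),
    (-11 / 54, 5 / 2, -70 / 27, 35 / 27),
    (1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096),
)
_CK_B5 = (37 / 378, 0.0, 250 / 621, 125 / 594, 0.0, 512 / 1771)
_CK_B4 = (2825 / 27648, 0.0, 18575 / 48384, 13525 / 55296, 277 / 14336, 1 / 4)


def _min_jacobian(u: np.ndarray) -> float:
    """min det(grad(x - u)) — diagnostic for folding of the deformation."""
    a = 1.0 - np.gradient(u[0], axis=0)
    b = -np.gradient(u[0], axis=1)
    c = -np.gradient(u[1], axis=0)
    d = 1.0 - np.gradient(u[1], axis=1)
    return float(np.min(a * d - b * c))


def register_pair(
    S: np.ndarray,
    T: np.ndarray,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Estimate the displacement field mapping S onto T.

    Integrates du/dt = v(u) with an adaptive Cash–Karp 4(5) pair; a step is
    accepted when the embedded error estimate passes the relative tolerance
    and the SSD does not increase (the damped flow is descent-like, so an
    SSD increase signals an overlong step).
    """
    p = params or RegistrationParams()
    S = np.asarray(S, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    _check_pair(S, T)
    if p.pre_smooth_sigma > 0:
        S = ndimage.gaussian_filter(S, p.pre_smooth_sigma)
        T = ndimage.gaussian_filter(T, p.pre_smooth_sigma)

    u = np.zeros((2, *S.shape))
    t = 0.0
    res = ssd_residual(S, T, u)
    history = [(t, res)]
    converged = res == 0.0
    steps = 0
    # scale the initial pseudo-time step so the first displacement
    # increment is about half a pixel — the damped velocity sets the
    # natural time unit of the flow
    dt = 0.1
    if not converged:
        v0 = _velocity(S, T, u, p)
        vmax = float(np.max(np.abs(v0)))
        if vmax > 0:
            dt = 0.5 / vmax

    while not converged and steps < p.max_steps and t < p.max_pseudo_time:
        ks = []
        for stage in range(6):
            uu = u
            for a, k in zip(_CK_A[stage], ks):
                uu = uu + dt * a * k
            ks.append(_velocity(S, T, uu, p))
        u5 = u + dt * sum(b * k for b, k in zip(_CK_B5, ks))
        u4 = u + dt * sum(b * k for b, k in zip(_CK_B4, ks))
        if not np.all(np.isfinite(u5)):
            raise FloatingPointError(
                f"registration diverged (non-finite field at pseudo-time {t:.4g})"
            )
        err = float(np.max(np.abs(u5 - u4)))
        tol = p.rk_rel_tol * max(1.0, float(np.max(np.abs(u5))))
        new_res = ssd_residual(S, T, u5)
        if err <= tol and new_res <= res * (1.0 + 1e-12):
            steps += 1
            t += dt
            rel_change = (res - new_res) / max(res, 1e-30)
            u, res = u5, new_res
            history.append((t, res))
            if rel_change < p.convergence_rel_change:
                converged = True
            dt = dt * min(2.0, 0.9 * (tol / max(err, 1e-300)) ** 0.2)
        else:
            dt *= 0.5
            if dt < 1e-12:
                break

    result = RegistrationResult(
        field=u,
        residual_history=history,
        converged=converged,
        steps_taken=steps,
        min_jacobian=_min_jacobian(u),
    )
    if result.min_jacobian < 0.1:
        import logging

        logging.getLogger(__name__).warning(
            "deformation close to folding: min Jacobian %.3f", result.min_jacobian
        )
    return result
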