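"""Fully implicit time integration of the stiff coupled dynamics.

The Swift-Hohenberg operator makes the dynamics stiff, so time stepping uses
a Crank-Nicolson discretization

    F(u_{n+1}) = u_{n+1} − u_n − (dt/2) [N(u_{n+1}) + N(u_n)] = 0

solved at every step by an inexact Newton method: the Newton correction is
obtained from a matrix-free GMRES iteration (the Jacobian action is
approximated by finite differences), preconditioned by the inverse of the
Fourier-diagonal linear part with a small shift, and globalized with a
backtracking line search on g(s) = ½‖F(u + s δu)‖². Step size is controlled
by step doubling (one full step against two half steps), which lets dt grow
by orders of magnitude as the dynamics approaches an attractor. Snapshots
are emitted on an exponentially spaced schedule.

State vectors are the stacked real representation (Re z, Im z, o_1..o_m) of
:mod:`mapcrystal.model`; all norms are RMS over every real degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft

from .grid import GridSpec, KC_Z
from .model import (FieldState, ModelSpec, linear_spectrum, pack, rhs_stacked,
                    total_energy, unpack)

_MACHEPS = np.finfo(float).eps


def _rms(u: np.ndarray) -> float:
    return float(np.sqrt(np.mean(u * u)))


# ---------------------------------------------------------------------------
# configuration and output containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegratorConfig:
    """Tolerances and controls of the implicit integrator.

    Times are absolute (multiply by r_z to convert to units of τ = 1/r_z).
    """

    t_end: float
    dt0: float = 0.5
    newton_tol: float = 1e-8          # RMS residual for Newton convergence
    newton_max: int = 12
    gmres_dim: int = 30               # Krylov subspace dimensionality
    gmres_tol: float = 1e-4           # relative residual per Newton step
    gmres_restarts: int = 2
    precond_shift: float = 0.01
    step_rtol: float = 1e-4           # step-doubling local error tolerance
    grow: float = 1.5
    shrink: float = 0.5
    safety: float = 0.9
    dt_min: float = 1e-10
    frame_count: int = 150
    frame_t0: float | None = None     # default 0.1 τ, set at run time
    stationary_rms: float = 1e-6      # ‖rhs‖ threshold for stationarity
    store_energy: bool = True

    def __post_init__(self) -> None:
        for name in ("newton_tol", "gmres_tol", "precond_shift", "step_rtol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gmres_dim < 1:
            raise ValueError("gmres_dim must be ≥ 1")
        if self.frame_count < 2:
            raise ValueError("need at least 2 frames")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


@dataclass
class FrameSet:
    """Trajectory snapshots with per-frame diagnostics.

    ``frames[0]`` is the initial condition at t = 0; later frames follow the
    exponential schedule t_j = t_0 (t_f/t_0)^{j/(J−1)}. ``diagnostics`` holds
    one dict per frame (power per field, energy, step statistics).
    """

    frames: list[FieldState]
    model: ModelSpec
    config: IntegratorConfig
    seed: int | None = None
    diagnostics: list[dict] = dc_field(default_factory=list)
    stationary_at: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, j: int) -> FieldState:
        return self.frames[j]


def frame_schedule(t0: float, t_end: float, count: int) -> np.ndarray:
    """t = 0 followed by count−1 exponentially spaced times from t0 to t_end."""
    if not 0 < t0 < t_end:
        raise ValueError("need 0 < t0 < t_end")
    return np.concatenate([[0.0], np.geomspace(t0, t_end, count - 1)])


# ---------------------------------------------------------------------------
# Crank-Nicolson residual and Jacobian action
# ---------------------------------------------------------------------------

def cn_residual(u_next: np.ndarray, u_curr: np.ndarray, dt: float,
                model: ModelSpec, n_curr: np.ndarray | None = None) -> np.ndarray:
    """F(u_{n+1}) = u_{n+1} − u_n − (dt/2)[N(u_{n+1}) + N(u_n)].

    ``n_curr`` may pass a precomputed N(u_n) to avoid recomputation.
    """
    if n_curr is None:
        n_curr = rhs_stacked(u_curr, model)
    return u_next - u_curr - 0.5 * dt * (rhs_stacked(u_next, model) + n_curr)


def jvp(residual_fn: Callable[[np.ndarray], np.ndarray], u: np.ndarray,
        v: np.ndarray, f0: np.ndarray | None = None,
        eps: float | None = None) -> np.ndarray:
    """Finite-difference directional derivative [F(u + εv) − F(u)]/ε.

    By default ε = √(machine epsilon)·(1 + ‖u‖)/‖v‖, the standard
    matrix-free Newton-Krylov heuristic; ``eps`` overrides it.
    """
    vnorm = float(np.linalg.norm(v.ravel()))
    if vnorm == 0.0:
        raise ValueError("jvp direction vector must be nonzero")
    if f0 is None:
        f0 = residual_fn(u)
    if eps is None:
        eps = np.sqrt(_MACHEPS) * (1.0 + float(np.linalg.norm(u.ravel()))) / vnorm
    return (residual_fn(u + eps * v) - f0) / eps


# ---------------------------------------------------------------------------
# GMRES (restarted, Arnoldi + Hessenberg least squares)
# ---------------------------------------------------------------------------

def gmres(apply_A: Callable[[np.ndarray], np.ndarray], b: np.ndarray,
          x0: np.ndarray | None = None, m: int = 30, tol: float = 1e-6,
          restarts: int = 1):
    """Restarted GMRES on 1-D real vectors.

    The Krylov basis is built with a modified Gram-Schmidt Arnoldi process;
    the correction minimizes the residual through the small Hessenberg least
    squares problem. Returns ``(x, history)`` where ``history`` is the list
    of residual norms (including the initial one); breakdown (a happy or
    lucky one) returns early with the current iterate.
    """
    b = np.asarray(b, dtype=float).ravel()
    n = b.size
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return x * 0.0, [0.0]
    history: list[float] = []
    for _ in range(max(1, restarts)):
        r = b - apply_A(x).ravel() if np.any(x) else b.copy()
        beta = np.linalg.norm(r)
        if not history:
            history.append(float(beta))
        if beta <= tol * bnorm:
            break
        V = np.empty((m + 1, n))
        H = np.zeros((m + 1, m))
        V[0] = r / beta
        k_used = 0
        for k in range(m):
            w = apply_A(V[k]).ravel()
            for i in range(k + 1):          # modified Gram-Schmidt
                H[i, k] = np.dot(w, V[i])
                w = w - H[i, k] * V[i]
            H[k + 1, k] = np.linalg.norm(w)
            k_used = k + 1
            if H[k + 1, k] < 1e-14 * beta or H[k + 1, k] == 0.0:
                break                        # breakdown: subspace is invariant
            V[k + 1] = w / H[k + 1, k]
            # residual of the least-squares problem so far
            e1 = np.zeros(k + 2)
            e1[0] = beta
            ylsq, res, *_ = np.linalg.lstsq(H[:k + 2, :k + 1], e1, rcond=None)
            rnorm = float(np.linalg.norm(e1 - H[:k + 2, :k + 1] @ ylsq))
            history.append(rnorm)
            if rnorm <= tol * bnorm:
                break
        e1 = np.zeros(k_used + 1)
        e1[0] = beta
        y, *_ = np.linalg.lstsq(H[:k_used + 1, :k_used], e1, rcond=None)
        x = x + V[:k_used].T @ y
        if history[-1] <= tol * bnorm:
            break
    return x, history


# ---------------------------------------------------------------------------
# preconditioner
# ---------------------------------------------------------------------------

def make_preconditioner(model: ModelSpec, dt: float, shift: float = 0.01,
                        grid: GridSpec | None = None,
                        amp_shift: Sequence[float] | None = None):
    """Inverse of the CN linear part in Fourier space with a small shift.

    Per field f and mode k the diagonal is [(1 − (dt/2) λ_f(k)/c_f) + η]⁻¹,
    which approximates the inverse Newton matrix and avoids singularities at
    marginally stable modes. Returns a callable acting on stacked states.

    ``amp_shift`` optionally subtracts a damping term from each field's
    spectrum (one scalar or (ny, nx) array per field: z, o_1, ..); the
    Newton solver passes a mean-field estimate of the Jacobian of the cubic
    nonlinearity and of the gradient couplings, which captures the dominant
    saturated-state stiffness that the bare linear operator misses once
    dt·λ_max ≫ 1.
    """
    if shift <= 0:
        raise ValueError("preconditioner shift must be positive")
    grid = grid or model.grid
    k2 = grid.k2()
    if amp_shift is None:
        amp_shift = [0.0] * (1 + len(model.fields))
    lams = [linear_spectrum(k2, model.r_z, KC_Z) - amp_shift[0]]   # Re z
    lams.append(lams[0])                                           # Im z
    for fs, a in zip(model.fields, amp_shift[1:]):
        lams.append((linear_spectrum(k2, fs.r, fs.kc) - a) / fs.c)
    diag = np.stack([1.0 / (1.0 - 0.5 * dt * lam + shift) for lam in lams])

    def apply_M(v: np.ndarray) -> np.ndarray:
        v = v.reshape(diag.shape)
        return sfft.ifft2(diag * sfft.fft2(v, axes=(-2, -1)),
                          axes=(-2, -1)).real

    return apply_M


# ---------------------------------------------------------------------------
# Newton solve of one CN step
# ---------------------------------------------------------------------------

class StepFailure(RuntimeError):
    """Newton failed to converge for the attempted step size."""


def _jacobian_shifts(u: np.ndarray, model: ModelSpec) -> list:
    """Mean-field damping estimates fed to the preconditioner.

    Per field: the spatially averaged Jacobian of the cubic nonlinearity
    (2⟨|z|²⟩, 3⟨o²⟩) plus, for gradient couplings, the Fourier-diagonal
    quadratic form s·p(2p−1)·⟨|S|^{2p−2} ∂_α b ∂_β b⟩ k_α k_β that
    approximates the coupling's stiffness on the coupled partner. Only used
    for preconditioning, so the estimate needs to be of the right magnitude,
    not exact.
    """
    grid = model.grid
    shifts: list = [2.0 * float(np.mean(u[0] ** 2 + u[1] ** 2))]
    shifts += [3.0 * float(np.mean(u[2 + i] ** 2))
               for i in range(len(model.fields))]
    grad_cps = [cp for cp in model.couplings
                if cp.kind.startswith("gradient") and cp.strength > 0]
    if not grad_cps:
        return shifts
    kx, ky = grid.wavenumbers()
    state = unpack(u)
    grads: dict = {}

    def grad(idx):
        if idx not in grads:
            f = state.z if idx == 0 else state.os[idx - 1]
            grads[idx] = grid.gradient(f)
        return grads[idx]

    def quad_form(w, gx, gy, factor):
        cxx = float(np.mean(w * np.abs(gx) ** 2))
        cyy = float(np.mean(w * np.abs(gy) ** 2))
        cxy = float(np.mean(w * (gx * np.conj(gy)).real))
        return factor * (cxx * kx**2 + 2 * cxy * kx * ky + cyy * ky**2)

    for cp in grad_cps:
        p = 1 if cp.kind == "gradient2" else 2
        a, b = cp.pair
        ax, ay = grad(a)
        bx, by = grad(b)
        s = ax * bx + ay * by
        w = np.abs(s) ** (2 * p - 2)
        fac = cp.strength * p * (2 * p - 1)
        shifts[a] = shifts[a] + quad_form(w, bx, by, fac * (1 if a == 0 else 2))
        shifts[b] = shifts[b] + quad_form(w, ax, ay, fac * 2)
    return shifts


def newton_step(u_guess: np.ndarray, u_curr: np.ndarray, dt: float,
                model: ModelSpec, config: IntegratorConfig,
                n_curr: np.ndarray | None = None):
    """Solve the CN difference equation by inexact Newton with line search.

    Returns ``(u_next, info)`` where info records iteration counts and the
    smallest accepted line-search parameter. Raises :class:`StepFailure`
    when ``newton_max`` iterations do not reach ``newton_tol`` (the caller
    then rejects the step and reduces dt).
    """
    if n_curr is None:
        n_curr = rhs_stacked(u_curr, model)
    shape = u_guess.shape

    def residual(v: np.ndarray) -> np.ndarray:
        return cn_residual(v.reshape(shape), u_curr, dt, model, n_curr)

    apply_M = make_preconditioner(model, dt, config.precond_shift,
                                  amp_shift=_jacobian_shifts(u_curr, model))
    u = u_guess.copy()
    F = residual(u)
    info = {"newton_iters": 0, "gmres_iters": 0, "min_step": 1.0,
            "residual": _rms(F), "residuals": [_rms(F)]}
    for it in range(config.newton_max):
        if _rms(F) < config.newton_tol:
            return u, info
        F_flat = F.ravel()

        def apply_A(v: np.ndarray) -> np.ndarray:
            Jv = jvp(lambda w: residual(w).reshape(shape), u, v.reshape(shape),
                     f0=F)
            return apply_M(Jv).ravel()

        b = apply_M(F).ravel()
        delta, hist = gmres(apply_A, -b, m=config.gmres_dim,
                            tol=config.gmres_tol,
                            restarts=config.gmres_restarts)
        info["gmres_iters"] += len(hist) - 1
        delta = delta.reshape(shape)
        # backtracking line search: require plain decrease of g = ½‖F‖²
        g0 = 0.5 * float(np.sum(F_flat * F_flat))
        s = 1.0
        for _ in range(25):
            u_try = u + s * delta
            F_try = residual(u_try)
            g = 0.5 * float(np.vdot(F_try.ravel(), F_try.ravel()).real)
            if g < g0:
                break
            s *= 0.5
        else:
            raise StepFailure(
                f"line search stalled at Newton iteration {it} (dt={dt:g})")
        info["min_step"] = min(info["min_step"], s)
        u, F = u_try, F_try
        info["newton_iters"] = it + 1
        info["residual"] = _rms(F)
        info["residuals"].append(_rms(F))
    if _rms(F) < config.newton_tol:
        return u, info
    raise StepFailure(
        f"Newton did not converge in {config.newton_max} iterations "
        f"(residual {_rms(F):.3e}, dt={dt:g})")


def cn_step(u: np.ndarray, dt: float, model: ModelSpec,
            config: IntegratorConfig, n_curr: np.ndarray | None = None):
    """One Crank-Nicolson step from u with step size dt.

    The Newton iteration starts from the explicit-Euler predictor
    u + dt·N(u), whose CN residual is already O(dt²).
    """
    if n_curr is None:
        n_curr = rhs_stacked(u, model)
    guess = u + dt * n_curr
    return newton_step(guess, u, dt, model, config, n_curr=n_curr)


# ---------------------------------------------------------------------------
# adaptive driver
# ---------------------------------------------------------------------------

def adaptive_integrate(ic: FieldState, model: ModelSpec,
                       config: IntegratorConfig, seed: int | None = None,
                       progress: Callable[[dict], None] | None = None) -> FrameSet:
    """Integrate the coupled dynamics from ``ic`` to ``config.t_end``.

    Step-doubling local error control: each accepted step compares one full
    CN step against two half steps and requires the RMS difference to stay
    below ``step_rtol`` (relative to the field scale); the two-half-step
    solution is kept. Snapshots are stored at the exponential frame schedule
    (frame 0 is the initial condition). When the RMS of the rhs stays below
    ``stationary_rms`` for one intrinsic timescale τ the state is declared
    stationary and the remaining scheduled frames repeat it at their nominal
    times.
    """
    grid = model.grid
    if grid is None:
        raise ValueError("model must carry a grid")
    if ic.z.shape != grid.shape:
        raise ValueError("initial condition is not on the model grid")
    tau = model.tau
    t0 = config.frame_t0 if config.frame_t0 is not None else 0.1 * tau
    schedule = frame_schedule(t0, config.t_end, config.frame_count)

    u = pack(ic)
    t = 0.0
    dt = config.dt0

    def diagnostics(u, t, extra=None):
        st = unpack(u, t)
        d = {"t": t, "power_z": float(np.mean(np.abs(st.z) ** 2))}
        for i, o in enumerate(st.os):
            d[f"power_o{i + 1}"] = float(np.mean(o**2))
        if config.store_energy:
            d["energy"] = total_energy(st, model, grid)
        if extra:
            d.update(extra)
        return d

    frames = [FieldState(0.0, ic.z.copy(), tuple(o.copy() for o in ic.os))]
    diags = [diagnostics(u, 0.0)]
    fs = FrameSet(frames, model, config, seed=seed, diagnostics=diags)

    next_idx = 1
    stat_since: float | None = None
    n_u = rhs_stacked(u, model)
    scale_floor = 1.0

    while next_idx < len(schedule):
        target = schedule[next_idx]
        # stationarity: sustained small rhs for one τ
        if _rms(n_u) < config.stationary_rms:
            if stat_since is None:
                stat_since = t
            if t - stat_since >= tau:
                fs.stationary_at = stat_since
                for j in range(next_idx, len(schedule)):
                    frames.append(FieldState(schedule[j], (u[0] + 1j * u[1]).copy(),
                                             tuple(u[2:].copy())))
                    diags.append(diagnostics(u, schedule[j],
                                             {"stationary": True}))
                return fs
        else:
            stat_since = None

        dt_try = min(dt, target - t)
        accepted = False
        while not accepted:
            if dt_try < config.dt_min:
                raise RuntimeError(
                    f"step size underflow at t={t:g} (dt={dt_try:g}); "
                    f"last rhs RMS {_rms(n_u):.3e}")
            try:
                u_full, info1 = cn_step(u, dt_try, model, config, n_curr=n_u)
                u_half, info2 = cn_step(u, 0.5 * dt_try, model, config,
                                        n_curr=n_u)
                u_two, info3 = cn_step(u_half, 0.5 * dt_try, model, config)
            except StepFailure:
                dt_try *= config.shrink
                continue
            scale = scale_floor + _rms(u_two)
            err = _rms(u_full - u_two) / scale
            if err <= config.step_rtol:
                accepted = True
            else:
                dt_try *= max(config.shrink,
                              config.safety * (config.step_rtol / err) ** (1 / 3))
        t = t + dt_try
        u = u_two
        n_u = rhs_stacked(u, model)
        if err > 0:
            factor = config.safety * (config.step_rtol / err) ** (1 / 3)
        else:
            factor = config.grow
        dt = dt_try * float(np.clip(factor, config.shrink, config.grow))
        if progress is not None:
            progress({"t": t, "dt": dt_try, "err": err,
                      "newton": info1["newton_iters"],
                      "gmres": info1["gmres_iters"],
                      "rhs_rms": _rms(n_u)})
        if t >= target - 1e-12 * max(1.0, target):
            frames.append(unpack(u.copy(), t))
            diags.append(diagnostics(u, t, {
                "dt": dt_try, "err": err,
                "newton_iters": info1["newton_iters"] + info2["newton_iters"]
                + info3["newton_iters"],
                "gmres_iters": info1["gmres_iters"] + info2["gmres_iters"]
                + info3["gmres_iters"],
                "rhs_rms": _rms(n_u)}))
            next_idx += 1
    return fs
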