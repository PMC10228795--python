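"""Time integration to steady state, plus an independent Newton oracle."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .model import (
    DimensionlessParameters,
    ModelConfiguration,
    SpeciesState,
    make_packed_rhs,
)

__all__ = ["SteadyStateField", "NewtonResult", "integrate_to_steady_state", "steady_state_by_rootfinding"]

# interleaved packing couples compartment i to i +/- 1 of the same species,
# i.e. entries 4 apart -> banded Jacobian for LSODA
_BANDWIDTH = 4


@dataclass
class SteadyStateField:
    """Endpoint of an integration run with convergence metadata."""

    state: SpeciesState
    converged: bool
    final_time: float
    residual: float
    tolerance: float
    min_value: float  #: most negative entry seen at any recorded frame
    message: str = ""
    kymograph_times: np.ndarray | None = None
    kymograph: np.ndarray | None = None  #: (T, 4, N), first frame = initial state


def _frame_times(horizon: float, n_frames: int, t_min: float = 1e-3) -> np.ndarray:
    return np.geomspace(t_min, horizon, n_frames)


def integrate_to_steady_state(
    q: DimensionlessParameters,
    cfg: ModelConfiguration,
    initial: SpeciesState | None = None,
    keep_kymograph: bool = False,
    n_frames: int = 100,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    mxstep: int = 100_000,
) -> SteadyStateField:
    """Integrate the 4 x N system until max|du/dt| < cfg.tolerance.

    LSODA (stiff-capable, banded finite-difference Jacobian) advances the
    state through log-spaced checkpoints up to ``cfg.horizon``; the residual
    is tested at each checkpoint so converged runs stop early.  Solver
    failures are reported via ``converged=False`` and ``message``, never
    raised, so parameter-space scans survive pathological draws.
    """
    if initial is None:
        initial = SpeciesState.from_config(cfg)
    if initial.n_compartments != cfg.n_compartments:
        raise ValueError("initial state and configuration disagree on compartment count")

    f = make_packed_rhs(q, cfg)
    y = initial.pack()

    t_min = min(1e-3, cfg.horizon / 10.0)
    times = _frame_times(cfg.horizon, n_frames if keep_kymograph else 25, t_min)
    # checkpoints where convergence is tested: one per decade
    n_decades = max(int(round(np.log10(cfg.horizon / t_min))), 1)
    checkpoints = np.geomspace(t_min, cfg.horizon, n_decades + 1)

    frames = [y.copy()] if keep_kymograph else None
    frame_times = [0.0] if keep_kymograph else None
    min_value = float(np.min(y))
    t_now = 0.0
    converged = False
    message = "horizon reached"
    residual = float(np.max(np.abs(f(y))))

    for t_next in checkpoints:
        if t_next <= t_now:
            continue
        seg = times[(times > t_now) & (times <= t_next)]
        t_seg = np.concatenate([[t_now], seg])
        if t_seg[-1] < t_next:
            t_seg = np.append(t_seg, t_next)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol, info = odeint(
                f, y, t_seg,
                ml=_BANDWIDTH, mu=_BANDWIDTH,
                rtol=rtol, atol=atol, mxstep=mxstep,
                full_output=True,
            )
        ok = info["message"] == "Integration successful."
        min_value = min(min_value, float(np.min(sol[1:] if ok else sol[1:2])))
        if frames is not None:
            good = sol[1:] if ok else []
            for tv, row in zip(t_seg[1:], good):
                frames.append(row.copy())
                frame_times.append(float(tv))
        if not ok:
            residual = float(np.max(np.abs(f(y))))
            message = f"solver failure at t={t_now:g}: {info['message']}"
            break
        y = sol[-1]
        t_now = float(t_seg[-1])
        residual = float(np.max(np.abs(f(y))))
        if not np.isfinite(residual):
            message = f"non-finite residual at t={t_now:g}"
            break
        if residual < cfg.tolerance:
            converged = True
            message = "converged"
            break

    final = SpeciesState.unpack(y)
    kymo = kymo_t = None
    if frames is not None:
        # last frame must equal the returned state
        if frame_times[-1] != t_now:
            frames.append(y.copy())
            frame_times.append(t_now)
        kymo = np.stack([fr.reshape(-1, 4).T for fr in frames])
        kymo_t = np.asarray(frame_times)
    return SteadyStateField(
        state=final,
        converged=converged,
        final_time=t_now,
        residual=residual,
        tolerance=cfg.tolerance,
        min_value=min_value,
        message=message,
        kymograph_times=kymo_t,
        kymograph=kymo,
    )


# ---------------------------------------------------------------------------
# Newton oracle
# ---------------------------------------------------------------------------


@dataclass
class NewtonResult:
    state: SpeciesState
    converged: bool
    residual: float
    n_iter: int
    message: str = ""


def _fd_jacobian(f, y: np.ndarray, fy: np.ndarray) -> np.ndarray:
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-7 * max(abs(y[j]), 1.0)
        yp = y.copy()
        yp[j] += h
        J[:, j] = (f(yp) - fy) / h
    return J


def steady_state_by_rootfinding(
    q: DimensionlessParameters,
    cfg: ModelConfiguration,
    initial_guess: SpeciesState,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> NewtonResult:
    """Damped Newton iteration on RHS = 0; independent of the integrator.

    Uses a dense finite-difference Jacobian and a backtracking line search
    on the residual max-norm.  Returns a root (residual <= tol relative to
    the state scale: the finite-difference noise floor grows with the state
    magnitude, so for states of order 1 this is the absolute tolerance) or
    reports non-convergence; a singular Jacobian is reported, not raised.
    """
    if np.any(initial_guess.stack() < 0):
        raise ValueError("initial guess must be non-negative")
    f = make_packed_rhs(q, cfg)
    y = initial_guess.pack()
    fy = f(y)
    res = float(np.max(np.abs(fy)))

    def scaled_tol() -> float:
        return tol * max(1.0, float(np.max(np.abs(y))))

    for it in range(1, max_iter + 1):
        if res <= tol:
            return NewtonResult(SpeciesState.unpack(y), True, res, it - 1, "converged")
        J = _fd_jacobian(f, y, fy)
        try:
            step = np.linalg.solve(J, -fy)
        except np.linalg.LinAlgError:
            return NewtonResult(SpeciesState.unpack(y), False, res, it - 1, "singular Jacobian")
        lam = 1.0
        while lam >= 1e-6:
            y_new = np.maximum(y + lam * step, 0.0)
            fy_new = f(y_new)
            res_new = float(np.max(np.abs(fy_new)))
            if np.isfinite(res_new) and res_new < res:
                break
            lam *= 0.5
        else:
            ok = res <= scaled_tol()
            return NewtonResult(SpeciesState.unpack(y), ok, res, it,
                                "converged" if ok else "line search stalled")
        y, fy, res = y_new, fy_new, res_new
    converged = res <= scaled_tol()
    return NewtonResult(
        SpeciesState.unpack(y), converged, res, max_iter,
        "converged" if converged else "max iterations",
    )
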