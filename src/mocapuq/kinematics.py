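"""Constrained inverse kinematics and coordinate-trajectory processing.

IK poses the model at each frame by bounded weighted nonlinear least
squares on marker distances, warm-started from the previous frame.  The
processing chain for kinetics follows standard gait practice: unwrap
rotational coordinates, zero-phase low-pass filter, differentiate with
central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy.optimize import least_squares

from .errors import ConvergenceError, DomainError, UnderdeterminedError
from .model import LinkSegmentModel, compute_state, marker_jacobian

DEFAULT_CUTOFF_HZ = 6.0  # low-pass cutoff for gait kinematics


@dataclass(frozen=True)
class MarkerTrajectories:
    """Time series of ground-frame marker positions (TRC semantics).

    ``positions`` has shape (n_frames, n_markers, 3) in meters; ``mask``
    flags valid samples (False where a marker dropped out).
    """

    times: np.ndarray
    rate: float
    names: tuple[str, ...]
    positions: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).reshape(-1)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (t.shape[0], len(self.names), 3):
            raise DomainError(
                f"positions shape {pos.shape} inconsistent with "
                f"{t.shape[0]} frames x {len(self.names)} markers"
            )
        if t.shape[0] > 1:
            dt = np.diff(t)
            if not (dt > 0).all():
                raise DomainError("times must be strictly increasing")
            med = float(np.median(dt))
            if abs(1.0 / med - self.rate) > 0.01 * self.rate:
                raise DomainError(
                    f"rate {self.rate} Hz inconsistent with median step {med:g} s"
                )
        mask = self.mask
        if mask is None:
            mask = np.isfinite(pos).all(axis=2)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != pos.shape[:2]:
                raise DomainError("mask shape mismatch")
            mask = mask & np.isfinite(pos).all(axis=2)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def frame(self, i: int) -> dict[str, np.ndarray]:
        """Valid marker observations at frame ``i`` as a name -> xyz map."""
        return {
            n: self.positions[i, m]
            for m, n in enumerate(self.names)
            if self.mask[i, m]
        }


@dataclass(frozen=True)
class IKSolution:
    """Per-frame generalized coordinates with marker fit diagnostics."""

    times: np.ndarray
    coordinate_names: tuple[str, ...]
    coordinates: np.ndarray  # (n_frames, n_q)
    per_marker_error: Mapping[str, np.ndarray]  # name -> (n_frames,), m
    rmse_per_frame: np.ndarray
    flagged_frames: tuple[int, ...] = ()


@dataclass(frozen=True)
class CoordinateDerivatives:
    velocities: np.ndarray
    accelerations: np.ndarray


def _usable(model, observed, weights):
    c = model.compiled
    name_to_idx = {n: i for i, n in enumerate(c.marker_names)}
    idx, obs, w = [], [], []
    for name, pos in observed.items():
        if name not in name_to_idx:
            continue
        pos = np.asarray(pos, dtype=float).reshape(3)
        if not np.isfinite(pos).all():
            continue
        wt = weights.get(name, 1.0)
        if wt < 0:
            raise DomainError(f"marker {name!r}: negative weight")
        if wt == 0:
            continue
        idx.append(name_to_idx[name])
        obs.append(pos)
        w.append(wt)
    return np.array(idx, dtype=int), np.array(obs).reshape(-1, 3), np.array(w)


def _check_not_collinear(points: np.ndarray) -> None:
    if len(points) < 3:
        raise UnderdeterminedError(
            f"need at least 3 usable markers, got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-9):
        raise UnderdeterminedError("usable markers are collinear")


def solve_ik_frame(
    model: LinkSegmentModel,
    observed: Mapping[str, Sequence[float]],
    weights: Mapping[str, float] | None = None,
    initial_guess: np.ndarray | None = None,
    *,
    max_iter: int = 200,
) -> tuple[np.ndarray, dict[str, float]]:
    """Pose the model against one frame of marker observations.

    Minimizes sum_i w_i ||m_i(q) - o_i||^2 subject to coordinate bounds.
    Returns the optimal coordinates and the per-marker distances at the
    optimum.
    """
    c = model.compiled
    if weights is None:
        weights = model.default_weights()
    idx, obs, w = _usable(model, observed, weights)
    _check_not_collinear(obs)
    sqw = np.repeat(np.sqrt(w), 3)
    if initial_guess is None:
        x0 = model.neutral_pose()
    else:
        x0 = model.check_q(initial_guess)
    lo, hi = c.lower, c.upper
    x0 = np.clip(x0, lo, hi)

    cache: dict[bytes, object] = {}

    def _state(x):
        key = x.tobytes()
        st = cache.get(key)
        if st is None:
            cache.clear()
            st = compute_state(model, x, validate=False)
            cache[key] = st
        return st

    def fun(x):
        st = _state(x)
        return sqw * (st.marker_positions[idx] - obs).ravel()

    def jac(x):
        st = _state(x)
        return sqw[:, None] * marker_jacobian(model, st, idx)

    res = least_squares(
        fun, x0, jac=jac, bounds=(lo, hi), method="trf",
        ftol=None, xtol=1e-12, gtol=1e-10, max_nfev=max_iter,
    )
    if res.status == 0:
        raise ConvergenceError(
            f"IK did not converge within {max_iter} iterations "
            f"(final residual {np.linalg.norm(res.fun):.3e})",
            final_residual=float(np.linalg.norm(res.fun)),
        )
    st = compute_state(model, res.x, validate=False)
    dists = np.linalg.norm(st.marker_positions[idx] - obs, axis=1)
    errors = {c.marker_names[i]: float(d) for i, d in zip(idx, dists)}
    return res.x, errors


def gauss_newton_pose(
    model: LinkSegmentModel,
    observed: Mapping[str, Sequence[float]],
    weights: Mapping[str, float] | None = None,
    initial_guess: np.ndarray | None = None,
    *,
    max_iter: int = 60,
    step_tol: float = 1e-10,
) -> np.ndarray:
    """Lightweight damped Gauss-Newton pose solve (same objective as
    :func:`solve_ik_frame`).

    Intended for the high-volume single-frame pose checks of the scaling
    rejection sampler, where the solve starts near the optimum and the
    bounds are inactive; the trust-region solver remains the reference
    path for trajectory IK.  Bounds are enforced by clamping.
    """
    c = model.compiled
    if weights is None:
        weights = model.default_weights()
    idx, obs, w = _usable(model, observed, weights)
    _check_not_collinear(obs)
    sqw = np.repeat(np.sqrt(w), 3)
    x = model.neutral_pose() if initial_guess is None else np.asarray(
        initial_guess, dtype=float
    ).copy()
    x = np.clip(x, c.lower, c.upper)
    lam = 1e-10
    for _ in range(max_iter):
        st = compute_state(model, x, validate=False)
        r = sqw * (st.marker_positions[idx] - obs).ravel()
        J = sqw[:, None] * marker_jacobian(model, st, idx)
        A = J.T @ J
        A[np.diag_indices_from(A)] += lam * (1.0 + A.diagonal())
        dx = np.linalg.solve(A, -(J.T @ r))
        x_new = np.clip(x + dx, c.lower, c.upper)
        step = np.linalg.norm(x_new - x)
        x = x_new
        if step < step_tol:
            break
    return x


def solve_ik(
    model: LinkSegmentModel,
    trajectories: MarkerTrajectories,
    weights: Mapping[str, float] | None = None,
    initial_guess: np.ndarray | None = None,
) -> IKSolution:
    """Solve IK over a whole trial with per-frame warm starting.

    Frame 0 starts from the model's neutral pose (or ``initial_guess``);
    each later frame starts from the previous solution, so the solve is
    deterministic given its inputs.  Frames with fewer than three usable
    markers are flagged and filled by linear interpolation in the
    coordinate domain.
    """
    c = model.compiled
    if weights is None:
        weights = model.default_weights()
    T = trajectories.n_frames
    n_q = c.n_q
    coords = np.full((T, n_q), np.nan)
    per_err = {n: np.full(T, np.nan) for n in trajectories.names if n in c.marker_names}
    rmse = np.full(T, np.nan)
    flagged = []
    guess = model.neutral_pose() if initial_guess is None else np.asarray(initial_guess, float)
    for t in range(T):
        observed = trajectories.frame(t)
        try:
            q, errors = solve_ik_frame(model, observed, weights, guess)
        except UnderdeterminedError:
            flagged.append(t)
            continue
        except ConvergenceError as exc:
            raise ConvergenceError(f"frame {t}: {exc}", exc.final_residual) from exc
        coords[t] = q
        guess = q
        for n, e in errors.items():
            per_err[n][t] = e
        vals = np.array(list(errors.values()))
        rmse[t] = np.sqrt(np.mean(vals**2))
    if len(flagged) == T:
        raise UnderdeterminedError("no frame has 3 usable markers")
    if flagged:
        good = np.setdiff1d(np.arange(T), flagged)
        for k in range(n_q):
            coords[flagged, k] = np.interp(
                trajectories.times[flagged], trajectories.times[good], coords[good, k]
            )
    return IKSolution(
        times=trajectories.times.copy(),
        coordinate_names=c.names,
        coordinates=coords,
        per_marker_error=per_err,
        rmse_per_frame=rmse,
        flagged_frames=tuple(flagged),
    )


def marker_position_trajectory(model: LinkSegmentModel, coordinates) -> np.ndarray:
    """Ground-frame marker positions (n_frames, n_markers, 3) for a
    coordinate trajectory."""
    coordinates = np.atleast_2d(np.asarray(coordinates, dtype=float))
    out = np.empty((coordinates.shape[0], len(model.marker_names), 3))
    for t, q in enumerate(coordinates):
        out[t] = compute_state(model, q, validate=False).marker_positions
    return out


def lowpass_filter(values, rate: float, cutoff: float = DEFAULT_CUTOFF_HZ, *,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    ``order`` is the one-pass order; the effective order doubles with the
    backward pass.  DC gain is exactly 1.
    """
    if cutoff >= rate / 2:
        raise DomainError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {rate / 2} Hz"
        )
    values = np.asarray(values, dtype=float)
    sos = _signal.butter(order, cutoff, fs=rate, output="sos")
    return _signal.sosfiltfilt(sos, values, axis=0)


def differentiate(values, times) -> CoordinateDerivatives:
    """First and second time derivatives by central differences.

    Interior points use second-order central differences; the first and
    last frames use one-sided differences.  Accelerations are obtained by
    differentiating the velocities the same way.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float).reshape(-1)
    if times.shape[0] < 3:
        raise DomainError("need at least 3 frames to differentiate")
    dt = np.diff(times)
    if dt.max() - dt.min() > 0.01 * np.median(dt):
        raise DomainError("time steps must be uniform to within 1%")
    vel = np.gradient(values, times, axis=0)
    acc = np.gradient(vel, times, axis=0)
    return CoordinateDerivatives(velocities=vel, accelerations=acc)


def process_coordinates(
    model: LinkSegmentModel,
    solution: IKSolution,
    *,
    cutoff: float = DEFAULT_CUTOFF_HZ,
) -> tuple[np.ndarray, CoordinateDerivatives]:
    """Unwrap, filter, and differentiate an IK coordinate trajectory.

    Rotational coordinates are unwrapped across frames before filtering to
    avoid 2-pi jumps.  Returns the filtered coordinates and their
    derivatives on the solution's time base.
    """
    coords = solution.coordinates.copy()
    rot = model.rotational_mask
    coords[:, rot] = np.unwrap(coords[:, rot], axis=0)
    rate = 1.0 / float(np.median(np.diff(solution.times)))
    filtered = lowpass_filter(coords, rate, cutoff)
    derivs = differentiate(filtered, solution.times)
    return filtered, derivs
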