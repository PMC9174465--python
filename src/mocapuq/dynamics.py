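"""Inverse dynamics of the link-segment model and joint powers.

Net generalized forces are computed by a recursive Newton-Euler pass over
the segment tree: an outward sweep propagates angular/linear velocities
and accelerations from the free base to the leaves; an inward sweep
accumulates the wrench transmitted across each joint from segment inertia,
gravity, and applied external loads, and projects it onto the joint's
coordinate axes.  The free base cannot be actuated, so the generalized
forces of its six coordinates form the residual wrench; it is returned
alongside the joint moments rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .model import KinematicState, LinkSegmentModel, compute_state

GRAVITY = np.array([0.0, -9.80665, 0.0])  # y-up lab frame, m/s^2
COP_FORCE_THRESHOLD_N = 10.0  # below this, center of pressure is meaningless


@dataclass(frozen=True)
class LoadChannel:
    """One external load: a force applied at a moving ground-frame point,
    plus a free moment, acting on a named segment."""

    segment: str
    force: np.ndarray  # (T, 3) N
    point: np.ndarray  # (T, 3) m, ground frame
    moment: np.ndarray  # (T, 3) N*m free moment

    def __post_init__(self):
        for name in ("force", "point", "moment"):
            a = np.asarray(getattr(self, name), dtype=float)
            a = np.atleast_2d(a)
            object.__setattr__(self, name, a)


@dataclass(frozen=True)
class ExternalLoads:
    """A set of measured external load channels on a common time base."""

    times: np.ndarray
    channels: tuple[LoadChannel, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).reshape(-1)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "channels", tuple(self.channels))
        for ch in self.channels:
            if ch.force.shape != (t.shape[0], 3):
                raise DomainError(
                    f"load on {ch.segment!r}: expected shape ({t.shape[0]}, 3)"
                )

    def resample(self, times, *, cop_threshold: float = COP_FORCE_THRESHOLD_N
                 ) -> "ExternalLoads":
        """Linear interpolation onto a new time base.

        Where the force magnitude falls below ``cop_threshold`` the center
        of pressure is zeroed: at near-zero load the measured CoP is pure
        noise and would otherwise inject large spurious moments.
        """
        times = np.asarray(times, dtype=float).reshape(-1)
        new_channels = []
        for ch in self.channels:
            f = _interp_cols(times, self.times, ch.force)
            p = _interp_cols(times, self.times, ch.point)
            m = _interp_cols(times, self.times, ch.moment)
            weak = np.linalg.norm(f, axis=1) < cop_threshold
            p[weak] = 0.0
            new_channels.append(LoadChannel(ch.segment, f, p, m))
        return ExternalLoads(times=times, channels=tuple(new_channels))


def _interp_cols(tq, t, a):
    out = np.empty((tq.shape[0], a.shape[1]))
    for j in range(a.shape[1]):
        out[:, j] = np.interp(tq, t, a[:, j])
    return out


@dataclass(frozen=True)
class JointMoments:
    """Generalized forces per coordinate (N*m rotational, N translational),
    plus the unactuated free-base residual (the base coordinates' entries)."""

    times: np.ndarray
    coordinate_names: tuple[str, ...]
    moments: np.ndarray  # (T, n_q)
    base_coordinates: tuple[str, ...] = ()

    def residual(self) -> np.ndarray:
        """Generalized forces of the free-base coordinates, (T, n_base)."""
        idx = [self.coordinate_names.index(n) for n in self.base_coordinates]
        return self.moments[:, idx]


@dataclass(frozen=True)
class JointPowers:
    times: np.ndarray
    coordinate_names: tuple[str, ...]
    powers: np.ndarray  # (T, n_q) W


@dataclass
class BodyMotion:
    """Ground-frame rigid-body motion of every segment at one instant."""

    omega: np.ndarray  # (n_seg, 3) rad/s
    alpha: np.ndarray  # (n_seg, 3) rad/s^2
    v_origin: np.ndarray  # (n_seg, 3) m/s (segment origin = joint center)
    a_origin: np.ndarray  # (n_seg, 3) m/s^2
    v_com: np.ndarray
    a_com: np.ndarray
    r_com: np.ndarray  # ground-frame com positions


def compute_body_motion(
    model: LinkSegmentModel, state: KinematicState, qdot, qddot
) -> BodyMotion:
    """Propagate velocities/accelerations outward through the tree."""
    c = model.compiled
    qdot = np.asarray(qdot, dtype=float).reshape(c.n_q)
    qddot = np.asarray(qddot, dtype=float).reshape(c.n_q)
    S = c.n_seg
    omega = np.zeros((S, 3))
    alpha = np.zeros((S, 3))
    v = np.zeros((S, 3))
    a = np.zeros((S, 3))
    v_com = np.zeros((S, 3))
    a_com = np.zeros((S, 3))
    r_com = np.zeros((S, 3))
    for i in range(S):
        pi = c.parent_idx[i]
        if pi < 0:
            Rp = np.eye(3)
            wp = np.zeros(3)
            ap_ang = np.zeros(3)
            vp = np.zeros(3)
            ap = np.zeros(3)
            pp = np.zeros(3)
        else:
            Rp = state.R[pi]
            wp = omega[pi]
            ap_ang = alpha[pi]
            vp = v[pi]
            ap = a[pi]
            pp = state.p[pi]
        off = c.offsets[i]
        nt = c.n_trans[i]
        rc = state.p[i] - pp  # ground-frame parent-origin -> joint-center
        tdot_g = np.zeros(3)
        tddot_g = np.zeros(3)
        if nt:
            tdot_g = Rp @ qdot[off : off + nt]
            tddot_g = Rp @ qddot[off : off + nt]
        v[i] = vp + np.cross(wp, rc) + tdot_g
        a[i] = (
            ap
            + np.cross(ap_ang, rc)
            + np.cross(wp, np.cross(wp, rc))
            + 2.0 * np.cross(wp, tdot_g)
            + tddot_g
        )
        w = wp.copy()
        al = ap_ang.copy()
        for k in range(len(c.joint_axes[i])):
            kq = off + nt + k
            ag = state.coord_axis[kq]
            al = al + ag * qddot[kq] + np.cross(w, ag) * qdot[kq]
            w = w + ag * qdot[kq]
        omega[i] = w
        alpha[i] = al
        rcom = state.R[i] @ c.com[i]
        r_com[i] = state.p[i] + rcom
        v_com[i] = v[i] + np.cross(w, rcom)
        a_com[i] = a[i] + np.cross(al, rcom) + np.cross(w, np.cross(w, rcom))
    return BodyMotion(omega=omega, alpha=alpha, v_origin=v, a_origin=a,
                      v_com=v_com, a_com=a_com, r_com=r_com)


def _id_frame(model, state, motion, ext_forces, ext_points, ext_moments, gravity):
    """Inward Newton-Euler pass; returns generalized forces (n_q,)."""
    c = model.compiled
    S = c.n_seg
    f = np.zeros((S, 3))  # wrench transmitted from parent, about joint center
    n = np.zeros((S, 3))
    gen = np.zeros(c.n_q)
    for i in range(S - 1, -1, -1):
        Ig = state.R[i] @ c.inertia[i] @ state.R[i].T
        m = c.mass[i]
        inertial_f = m * (motion.a_com[i] - gravity)
        fi = inertial_f.copy()
        ni = (
            Ig @ motion.alpha[i]
            + np.cross(motion.omega[i], Ig @ motion.omega[i])
            + np.cross(motion.r_com[i] - state.p[i], inertial_f)
        )
        for fe, pe, me in zip(ext_forces[i], ext_points[i], ext_moments[i]):
            fi -= fe
            ni -= me + np.cross(pe - state.p[i], fe)
        for j in range(i + 1, S):
            if c.parent_idx[j] == i:
                fi += f[j]
                ni += n[j] + np.cross(state.p[j] - state.p[i], f[j])
        f[i] = fi
        n[i] = ni
        off = c.offsets[i]
        nt = c.n_trans[i]
        for k in range(nt):
            gen[off + k] = state.coord_axis[off + k] @ fi
        for k in range(len(c.joint_axes[i])):
            kq = off + nt + k
            gen[kq] = state.coord_axis[kq] @ ni
    return gen


def inverse_dynamics(
    model: LinkSegmentModel,
    q,
    qdot,
    qddot,
    loads: ExternalLoads | None = None,
    gravity: Sequence[float] = GRAVITY,
    times=None,
) -> JointMoments:
    """Net generalized forces reproducing the prescribed motion.

    ``q``, ``qdot``, ``qddot`` are (T, n_q) trajectories (or single
    frames).  ``loads`` must already be on the same time base (use
    :meth:`ExternalLoads.resample`).  The free-base coordinates' entries
    are the residual wrench components required at the unactuated base.
    """
    c = model.compiled
    q = np.atleast_2d(np.asarray(q, dtype=float))
    qdot = np.atleast_2d(np.asarray(qdot, dtype=float))
    qddot = np.atleast_2d(np.asarray(qddot, dtype=float))
    if not (q.shape == qdot.shape == qddot.shape) or q.shape[1] != c.n_q:
        raise DomainError(
            f"q/qdot/qddot must all be (T, {c.n_q}); got "
            f"{q.shape}, {qdot.shape}, {qddot.shape}"
        )
    T = q.shape[0]
    gravity = np.asarray(gravity, dtype=float).reshape(3)
    if loads is not None:
        if loads.times.shape[0] != T:
            raise DomainError(
                f"loads have {loads.times.shape[0]} frames, kinematics {T}; "
                "resample first"
            )
        for ch in loads.channels:
            if ch.segment not in c.seg_index:
                raise DomainError(f"external load on unknown segment {ch.segment!r}")
    out = np.empty((T, c.n_q))
    empty = [[] for _ in range(c.n_seg)]
    for t in range(T):
        state = compute_state(model, q[t], validate=False)
        motion = compute_body_motion(model, state, qdot[t], qddot[t])
        if loads is None:
            ef = em = ep = empty
        else:
            ef = [[] for _ in range(c.n_seg)]
            ep = [[] for _ in range(c.n_seg)]
            em = [[] for _ in range(c.n_seg)]
            for ch in loads.channels:
                si = c.seg_index[ch.segment]
                ef[si].append(ch.force[t])
                ep[si].append(ch.point[t])
                em[si].append(ch.moment[t])
        out[t] = _id_frame(model, state, motion, ef, ep, em, gravity)
    base = model.segments[0].joint.coordinate_names
    if times is None:
        times = np.arange(T, dtype=float)
    return JointMoments(
        times=np.asarray(times, dtype=float).reshape(-1),
        coordinate_names=c.names,
        moments=out,
        base_coordinates=tuple(base),
    )


def joint_powers(moments: JointMoments, velocities) -> JointPowers:
    """Instantaneous joint powers: elementwise moment x coordinate velocity."""
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    if velocities.shape != moments.moments.shape:
        raise DomainError(
            f"velocities shape {velocities.shape} does not match moments "
            f"{moments.moments.shape}"
        )
    return JointPowers(
        times=moments.times,
        coordinate_names=moments.coordinate_names,
        powers=moments.moments * velocities,
    )


def mechanical_energy(model: LinkSegmentModel, q, qdot,
                      gravity: Sequence[float] = GRAVITY) -> float:
    """Total kinetic plus gravitational potential energy at one instant."""
    c = model.compiled
    state = compute_state(model, q, validate=False)
    motion = compute_body_motion(model, state, qdot, np.zeros(c.n_q))
    gravity = np.asarray(gravity, dtype=float).reshape(3)
    E = 0.0
    for i in range(c.n_seg):
        Ig = state.R[i] @ c.inertia[i] @ state.R[i].T
        E += 0.5 * c.mass[i] * motion.v_com[i] @ motion.v_com[i]
        E += 0.5 * motion.omega[i] @ Ig @ motion.omega[i]
        E -= c.mass[i] * gravity @ motion.r_com[i]
    return float(E)
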