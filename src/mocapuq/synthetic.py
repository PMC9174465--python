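"""Synthetic gait fixture: a lower-body model plus dynamically consistent
marker and ground-reaction data with full ground truth.

The generator prescribes smooth periodic joint-angle curves (sums of a few
harmonics with gait-plausible amplitudes), produces marker trajectories by
forward kinematics, and computes the external wrench that whole-body
dynamics requires at every instant.  That wrench is assigned to the feet
with a smooth double-support transition weight, as a force at a
center-of-pressure under each foot plus a free moment.  Because the loads
are constructed from the same equations of motion the inverse-dynamics
pass solves, the generate -> IK -> ID triangle closes on the stored ground
truth exactly (up to round-off) at zero marker noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    GRAVITY,
    ExternalLoads,
    JointMoments,
    LoadChannel,
    compute_body_motion,
    inverse_dynamics,
)
from .errors import DomainError
from .events import GaitEvents, detect_gait_events
from .kinematics import MarkerTrajectories
from .model import JointSpec, LinkSegmentModel, MarkerRegistration, Segment, compute_state

SUBJECT_MASS_KG = 83.5  # fixture total mass

# Winter-style body-segment mass fractions; the pelvis segment stands in
# for pelvis + head-arms-trunk so the total is the subject mass.
_THIGH_FRAC = 0.100
_SHANK_FRAC = 0.0465
_FOOT_FRAC = 0.0145


def _diag(x, y, z):
    return ((x, 0.0, 0.0), (0.0, y, 0.0), (0.0, 0.0, z))


def default_gait_model(name: str = "lowerbody") -> LinkSegmentModel:
    """Two-legged lower-body model: free pelvis, ball hips, pin knees and
    ankles; 14 markers; segment masses summing to 83.5 kg.

    Conventions (right-handed, x forward, y up, z right): hip flexion and
    ankle dorsiflexion are positive rotations about +z; knee flexion is
    positive about -z (so flexion angles are positive numbers).
    """
    m_thigh = _THIGH_FRAC * SUBJECT_MASS_KG
    m_shank = _SHANK_FRAC * SUBJECT_MASS_KG
    m_foot = _FOOT_FRAC * SUBJECT_MASS_KG
    m_pelvis = SUBJECT_MASS_KG - 2 * (m_thigh + m_shank + m_foot)

    segments = [
        Segment(
            name="pelvis",
            parent=None,
            joint=JointSpec(
                type="free",
                axes=((0.0, 0.0, 1.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
                coordinate_names=(
                    "pelvis_tx", "pelvis_ty", "pelvis_tz",
                    "pelvis_tilt", "pelvis_list", "pelvis_rotation",
                ),
            ),
            location_in_parent=(0.0, 0.95, 0.0),
            mass=m_pelvis,
            com=(0.0, 0.25, 0.0),
            inertia=_diag(2.8, 1.2, 2.5),
            length_axis=(0.0, 1.0, 0.0),
        ),
    ]
    for side, sz in (("r", 1.0), ("l", -1.0)):
        segments += [
            Segment(
                name=f"thigh_{side}",
                parent="pelvis",
                joint=JointSpec(
                    type="ball",
                    axes=((0.0, 0.0, 1.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
                    coordinate_names=(
                        f"hip_flexion_{side}",
                        f"hip_adduction_{side}",
                        f"hip_rotation_{side}",
                    ),
                ),
                location_in_parent=(0.0, -0.07, 0.09 * sz),
                mass=m_thigh,
                com=(0.0, -0.17, 0.0),
                inertia=_diag(0.13, 0.03, 0.13),
            ),
            Segment(
                name=f"shank_{side}",
                parent=f"thigh_{side}",
                joint=JointSpec(
                    type="pin",
                    axes=((0.0, 0.0, -1.0),),
                    coordinate_names=(f"knee_flexion_{side}",),
                ),
                location_in_parent=(0.0, -0.42, 0.0),
                mass=m_shank,
                com=(0.0, -0.18, 0.0),
                inertia=_diag(0.05, 0.007, 0.05),
            ),
            Segment(
                name=f"foot_{side}",
                parent=f"shank_{side}",
                joint=JointSpec(
                    type="pin",
                    axes=((0.0, 0.0, 1.0),),
                    coordinate_names=(f"ankle_angle_{side}",),
                ),
                location_in_parent=(0.0, -0.42, 0.0),
                mass=m_foot,
                com=(0.06, -0.04, 0.0),
                inertia=_diag(0.002, 0.006, 0.006),
                length_axis=(1.0, 0.0, 0.0),
            ),
        ]

    markers = [
        MarkerRegistration("RASI", "pelvis", (0.10, 0.02, 0.12)),
        MarkerRegistration("LASI", "pelvis", (0.10, 0.02, -0.12)),
        MarkerRegistration("RPSI", "pelvis", (-0.12, 0.03, 0.05)),
        MarkerRegistration("LPSI", "pelvis", (-0.12, 0.03, -0.05)),
    ]
    for side, S, sz in (("r", "R", 1.0), ("l", "L", -1.0)):
        markers += [
            MarkerRegistration(f"{S}THI", f"thigh_{side}", (0.04, -0.20, 0.06 * sz)),
            MarkerRegistration(f"{S}KNE", f"thigh_{side}", (0.0, -0.40, 0.06 * sz)),
            MarkerRegistration(f"{S}TIB", f"shank_{side}", (0.03, -0.18, 0.05 * sz)),
            MarkerRegistration(f"{S}ANK", f"shank_{side}", (0.0, -0.40, 0.05 * sz)),
            MarkerRegistration(f"{S}TOE", f"foot_{side}", (0.15, -0.06, 0.01 * sz)),
        ]
    return LinkSegmentModel(name=name, segments=tuple(segments), markers=tuple(markers))


# ---------------------------------------------------------------------------
# Prescribed joint-angle curves


@dataclass(frozen=True)
class HarmonicCurve:
    """offset + slope*t + sum_j A_j sin(2*pi*k_j*(t/T + shift) + phi_j)."""

    offset: float = 0.0
    slope: float = 0.0
    terms: tuple[tuple[float, int, float], ...] = ()  # (amplitude, k, phase)

    def evaluate(self, t, period: float, shift: float = 0.0):
        t = np.asarray(t, dtype=float)
        w0 = 2.0 * np.pi / period
        q = self.offset + self.slope * t
        dq = np.full_like(t, self.slope)
        ddq = np.zeros_like(t)
        for A, k, phi in self.terms:
            arg = k * w0 * t + 2.0 * np.pi * k * shift + phi
            q = q + A * np.sin(arg)
            dq = dq + A * k * w0 * np.cos(arg)
            ddq = ddq - A * (k * w0) ** 2 * np.sin(arg)
        return q, dq, ddq


def _deg(x):
    return float(np.deg2rad(x))


def default_gait_curves(forward_speed: float = 1.2) -> dict[str, HarmonicCurve]:
    """Gait-plausible curves for the default model (right heel strike at
    t = 0; the left leg runs the same curves half a cycle out of phase)."""
    half = np.pi
    curves = {
        "pelvis_tx": HarmonicCurve(slope=forward_speed,
                                   terms=((0.015, 2, 0.0),)),
        "pelvis_ty": HarmonicCurve(terms=((0.012, 2, 0.5),)),
        "pelvis_tz": HarmonicCurve(terms=((0.010, 1, 0.0),)),
        "pelvis_tilt": HarmonicCurve(offset=_deg(2), terms=((_deg(2), 2, 0.0),)),
        "pelvis_list": HarmonicCurve(terms=((_deg(2), 1, 0.3),)),
        "pelvis_rotation": HarmonicCurve(terms=((_deg(5), 1, 0.0),)),
    }
    for side, shift in (("r", 0.0), ("l", 0.5)):
        ph = 2.0 * np.pi * shift

        def sideterms(terms):
            return tuple((A, k, phi + k * ph) for A, k, phi in terms)

        curves[f"hip_flexion_{side}"] = HarmonicCurve(
            offset=_deg(10), terms=sideterms(((_deg(20), 1, half / 2),)))
        curves[f"hip_adduction_{side}"] = HarmonicCurve(
            terms=sideterms(((_deg(4), 1, 0.3),)))
        curves[f"hip_rotation_{side}"] = HarmonicCurve(
            terms=sideterms(((_deg(3), 1, 1.0),)))
        curves[f"knee_flexion_{side}"] = HarmonicCurve(
            offset=_deg(25),
            terms=sideterms(((-_deg(20), 1, 0.7),)))
        curves[f"ankle_angle_{side}"] = HarmonicCurve(
            offset=_deg(-5),
            terms=sideterms(((-_deg(12), 1, -2.0 * np.pi * 0.3),
                             (_deg(3), 2, 0.8),)))
    return curves


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def stance_weight(phase, *, stance_end: float = 0.62, double_support: float = 0.12):
    """Fraction of the total external wrench borne by the right foot as a
    function of gait-cycle phase (right heel strike at 0); the left foot
    carries the complement 1 - w."""
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    w = np.where(
        phi < double_support,
        _smoothstep(phi / double_support),
        np.where(
            phi < stance_end - double_support,
            1.0,
            np.where(
                phi < stance_end,
                1.0 - _smoothstep((phi - (stance_end - double_support)) / double_support),
                0.0,
            ),
        ),
    )
    return w


@dataclass(frozen=True)
class GaitParams:
    """Conditions for the synthetic trial.

    One gait cycle of 1.0 s sampled at 100 Hz, walking forward at 1.2 m/s,
    noise-free markers by default.
    """

    cycle_duration: float = 1.0
    rate: float = 100.0
    forward_speed: float = 1.2
    marker_noise_sd: float = 0.0
    n_cycles: float = 1.0


@dataclass
class SyntheticTrial:
    model: LinkSegmentModel
    params: GaitParams
    times: np.ndarray
    coordinate_names: tuple[str, ...]
    true_q: np.ndarray
    true_qdot: np.ndarray
    true_qddot: np.ndarray
    trajectories: MarkerTrajectories
    loads: ExternalLoads
    true_moments: JointMoments
    events: GaitEvents
    seed: int = 0


def generate_trial(
    model: LinkSegmentModel | None = None,
    params: GaitParams | None = None,
    seed: int = 0,
) -> SyntheticTrial:
    """Generate one synthetic walking trial with full ground truth."""
    if model is None:
        model = default_gait_model()
    if params is None:
        params = GaitParams()
    if params.rate < 50.0:
        raise DomainError(f"rate {params.rate} Hz too low; need >= 50 Hz")
    c = model.compiled
    curves = default_gait_curves(params.forward_speed)
    missing = [n for n in c.names if n not in curves]
    if missing:
        raise DomainError(f"no gait curve for coordinates {missing}")
    n_frames = int(round(params.n_cycles * params.cycle_duration * params.rate))
    times = np.arange(n_frames) / params.rate
    q = np.empty((n_frames, c.n_q))
    qdot = np.empty_like(q)
    qddot = np.empty_like(q)
    for k, name in enumerate(c.names):
        qk, dqk, ddqk = curves[name].evaluate(times, params.cycle_duration)
        q[:, k], qdot[:, k], qddot[:, k] = qk, dqk, ddqk
    for t in range(n_frames):
        model.check_q(q[t])  # amplitudes must respect coordinate bounds

    # markers by forward kinematics (+ optional isotropic Gaussian noise)
    rng = np.random.default_rng(seed)
    mpos = np.empty((n_frames, len(c.marker_names), 3))
    states = []
    for t in range(n_frames):
        st = compute_state(model, q[t], validate=False)
        states.append(st)
        mpos[t] = st.marker_positions
    if params.marker_noise_sd > 0:
        mpos = mpos + rng.normal(0.0, params.marker_noise_sd, mpos.shape)
    trajectories = MarkerTrajectories(
        times=times, rate=params.rate, names=c.marker_names, positions=mpos
    )

    # external loads: whole-body required wrench split between the feet
    phase = times / params.cycle_duration
    w_r = stance_weight(phase)
    w_l = 1.0 - w_r
    feet = {"foot_r": w_r, "foot_l": w_l}
    foot_point_local = np.array([0.06, -0.05, 0.0])  # mid-foot, segment frame
    forces = {k: np.zeros((n_frames, 3)) for k in feet}
    points = {k: np.zeros((n_frames, 3)) for k in feet}
    moments = {k: np.zeros((n_frames, 3)) for k in feet}
    for t in range(n_frames):
        st = states[t]
        motion = compute_body_motion(model, st, qdot[t], qddot[t])
        inertial = c.mass[:, None] * (motion.a_com - GRAVITY)
        F_total = inertial.sum(axis=0)
        M_O = np.zeros(3)
        for i in range(c.n_seg):
            Ig = st.R[i] @ c.inertia[i] @ st.R[i].T
            M_O += (
                Ig @ motion.alpha[i]
                + np.cross(motion.omega[i], Ig @ motion.omega[i])
                + np.cross(motion.r_com[i], inertial[i])
            )
        cop = {}
        for foot in feet:
            si = c.seg_index[foot]
            pg = st.p[si] + st.R[si] @ foot_point_local
            cop[foot] = np.array([pg[0], 0.0, pg[2]])  # project onto floor
        M_res = M_O - sum(
            np.cross(cop[foot], feet[foot][t] * F_total) for foot in feet
        )
        for foot, w in feet.items():
            forces[foot][t] = w[t] * F_total
            points[foot][t] = cop[foot]
            moments[foot][t] = w[t] * M_res
    loads = ExternalLoads(
        times=times,
        channels=tuple(
            LoadChannel(foot, forces[foot], points[foot], moments[foot])
            for foot in feet
        ),
    )
    true_moments = inverse_dynamics(model, q, qdot, qddot, loads, times=times)
    ev = detect_gait_events(times, forces["foot_r"][:, 1])
    return SyntheticTrial(
        model=model,
        params=params,
        times=times,
        coordinate_names=c.names,
        true_q=q,
        true_qdot=qdot,
        true_qddot=qddot,
        trajectories=trajectories,
        loads=loads,
        true_moments=true_moments,
        events=ev,
        seed=seed,
    )
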