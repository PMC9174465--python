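"""Rigid link-segment skeletal model: segments, joints, markers, scaling.

The model is a tree of rigid segments connected by low-degree-of-freedom
joints (free, ball, universal, pin).  Each segment carries mass properties
and a set of registered markers expressed in its local frame.  Frames are
right-handed with x forward, y up, z lateral (right); rotational joint
coordinates are intrinsic rotations about ordered axes expressed in the
parent frame.

Generalized coordinates are concatenated joint coordinates in segment
(topological) order.  For a free joint the ordering is three translations
along the parent axes followed by the rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import DomainError, ModelError

JOINT_DOF = {"free": 6, "ball": 3, "universal": 2, "pin": 1}
_DEFAULT_ROT_BOUND = np.pi
_DEFAULT_TRANS_BOUND = 10.0  # m; generous box for free-joint translations


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues' formula)."""
    x, y, z = axis
    c = np.cos(angle)
    s = np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


@dataclass(frozen=True)
class JointSpec:
    """Joint connecting a segment to its parent.

    ``axes`` are the rotation axes (unit vectors, parent frame), applied as
    intrinsic successive rotations in order.  A free joint additionally has
    three translational coordinates (along the parent x, y, z axes) that
    precede the rotations in the coordinate ordering.
    """

    type: str
    axes: tuple[tuple[float, float, float], ...]
    coordinate_names: tuple[str, ...]
    coordinate_bounds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.type not in JOINT_DOF:
            raise ModelError(f"unknown joint type {self.type!r}")
        n_rot = {"free": 3, "ball": 3, "universal": 2, "pin": 1}[self.type]
        axes = tuple(tuple(float(c) for c in a) for a in self.axes)
        if len(axes) != n_rot:
            raise ModelError(
                f"joint type {self.type!r} needs {n_rot} axes, got {len(axes)}"
            )
        for a in axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise ModelError(f"joint axis {a} is not unit-norm")
        object.__setattr__(self, "axes", axes)
        if len(self.coordinate_names) != self.dof:
            raise ModelError(
                f"{self.type} joint needs {self.dof} coordinate names, "
                f"got {len(self.coordinate_names)}"
            )
        bounds = self.coordinate_bounds
        if not bounds:
            bounds = tuple(self._default_bounds())
        bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        if len(bounds) != self.dof:
            raise ModelError("coordinate_bounds length mismatch")
        for name, (lo, hi) in zip(self.coordinate_names, bounds):
            if not lo < hi:
                raise ModelError(f"coordinate {name!r}: bounds min must be < max")
        object.__setattr__(self, "coordinate_bounds", bounds)

    def _default_bounds(self):
        for kind in self.coordinate_kinds:
            b = _DEFAULT_TRANS_BOUND if kind == "trans" else _DEFAULT_ROT_BOUND
            yield (-b, b)

    @property
    def dof(self) -> int:
        return JOINT_DOF[self.type]

    @property
    def n_translations(self) -> int:
        return 3 if self.type == "free" else 0

    @property
    def coordinate_kinds(self) -> tuple[str, ...]:
        return ("trans",) * self.n_translations + ("rot",) * len(self.axes)


@dataclass(frozen=True)
class Segment:
    """Rigid body segment: joint to parent, mass properties, scaling axis."""

    name: str
    parent: str | None
    joint: JointSpec
    location_in_parent: tuple[float, float, float]
    mass: float
    com: tuple[float, float, float]
    inertia: tuple[tuple[float, float, float], ...]
    length_axis: tuple[float, float, float] = (0.0, -1.0, 0.0)

    def __post_init__(self):
        object.__setattr__(
            self, "location_in_parent", tuple(map(float, self.location_in_parent))
        )
        object.__setattr__(self, "com", tuple(map(float, self.com)))
        object.__setattr__(self, "mass", float(self.mass))
        I = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        if self.mass < 0:
            raise ModelError(f"segment {self.name!r}: mass must be >= 0")
        if not np.allclose(I, I.T, atol=1e-12):
            raise ModelError(f"segment {self.name!r}: inertia must be symmetric")
        if np.linalg.eigvalsh(I).min() < -1e-12:
            raise ModelError(
                f"segment {self.name!r}: inertia must be positive semidefinite"
            )
        object.__setattr__(self, "inertia", tuple(map(tuple, I.tolist())))
        la = _as_vec3(self.length_axis)
        n = np.linalg.norm(la)
        if n == 0:
            raise ModelError(f"segment {self.name!r}: zero length_axis")
        object.__setattr__(self, "length_axis", tuple((la / n).tolist()))

    @property
    def inertia_matrix(self) -> np.ndarray:
        return np.asarray(self.inertia, dtype=float)


@dataclass(frozen=True)
class MarkerRegistration:
    """A named marker fixed at a local position in a segment's frame."""

    name: str
    segment: str
    local_position: tuple[float, float, float]
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "local_position", tuple(map(float, self.local_position))
        )
        if self.weight < 0:
            raise ModelError(f"marker {self.name!r}: weight must be >= 0")


class _Compiled:
    """Flat array view of a model for fast kinematics (built lazily)."""

    def __init__(self, model: "LinkSegmentModel"):
        segs = model.segments
        self.n_seg = len(segs)
        self.seg_index = {s.name: i for i, s in enumerate(segs)}
        self.parent_idx = np.array(
            [-1 if s.parent is None else self.seg_index[s.parent] for s in segs]
        )
        self.loc = np.array([s.location_in_parent for s in segs])
        self.mass = np.array([s.mass for s in segs])
        self.com = np.array([s.com for s in segs])
        self.inertia = np.array([s.inertia for s in segs])
        # coordinate layout
        offsets, kinds, axes, names, lo, hi, coord_seg = [], [], [], [], [], [], []
        off = 0
        for i, s in enumerate(segs):
            offsets.append(off)
            j = s.joint
            for k, (kind, name, (blo, bhi)) in enumerate(
                zip(j.coordinate_kinds, j.coordinate_names, j.coordinate_bounds)
            ):
                kinds.append(kind)
                names.append(name)
                lo.append(blo)
                hi.append(bhi)
                coord_seg.append(i)
            for a in j.axes:
                axes.append(a)
            off += j.dof
        self.n_q = off
        self.offsets = np.array(offsets, dtype=int)
        self.kinds = tuple(kinds)
        self.is_rot = np.array([k == "rot" for k in kinds])
        self.names = tuple(names)
        self.lower = np.array(lo)
        self.upper = np.array(hi)
        self.coord_seg = np.array(coord_seg, dtype=int)
        self.joint_axes = [np.array(s.joint.axes) for s in segs]
        self.n_trans = np.array([s.joint.n_translations for s in segs])
        # markers
        self.marker_names = tuple(m.name for m in model.markers)
        self.marker_seg = np.array(
            [self.seg_index[m.segment] for m in model.markers], dtype=int
        )
        self.marker_local = np.array(
            [m.local_position for m in model.markers]
        ).reshape(-1, 3)
        self.marker_weight = np.array([m.weight for m in model.markers])
        # ancestry: affected[k, m] = coordinate k moves marker m
        anc = np.zeros((self.n_seg, self.n_seg), dtype=bool)
        for i in range(self.n_seg):
            j = i
            while j >= 0:
                anc[j, i] = True
                j = self.parent_idx[j]
        self.affects = anc[self.coord_seg][:, self.marker_seg]  # (n_q, n_markers)
        self.seg_affects = anc  # (n_seg ancestor, n_seg)


@dataclass(frozen=True)
class LinkSegmentModel:
    """A tree of segments with registered markers.

    Segments must be listed with every parent before its children; exactly
    one segment is the root (``parent is None``).
    """

    name: str
    segments: tuple[Segment, ...]
    markers: tuple[MarkerRegistration, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "markers", tuple(self.markers))
        seen: dict[str, int] = {}
        roots = 0
        for s in self.segments:
            if s.name in seen:
                raise ModelError(f"duplicate segment name {s.name!r}")
            if s.parent is None:
                roots += 1
            elif s.parent not in seen:
                raise ModelError(
                    f"segment {s.name!r}: parent {s.parent!r} not defined before it"
                )
            seen[s.name] = 1
        if roots != 1:
            raise ModelError(f"model must have exactly one root segment, got {roots}")
        mnames = set()
        for m in self.markers:
            if m.name in mnames:
                raise ModelError(f"duplicate marker name {m.name!r}")
            mnames.add(m.name)
            if m.segment not in seen:
                raise ModelError(
                    f"marker {m.name!r}: unknown segment {m.segment!r}"
                )
        cnames = [n for s in self.segments for n in s.joint.coordinate_names]
        if len(cnames) != len(set(cnames)):
            raise ModelError("coordinate names must be unique across joints")
        object.__setattr__(self, "_cache", {})

    # -- compiled view -------------------------------------------------
    @property
    def compiled(self) -> _Compiled:
        c = self._cache.get("compiled")
        if c is None:
            c = _Compiled(self)
            self._cache["compiled"] = c
        return c

    @property
    def coordinate_names(self) -> tuple[str, ...]:
        return self.compiled.names

    @property
    def n_coordinates(self) -> int:
        return self.compiled.n_q

    @property
    def coordinate_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.compiled
        return c.lower.copy(), c.upper.copy()

    @property
    def rotational_mask(self) -> np.ndarray:
        """Boolean mask over coordinates; True for rotational coordinates."""
        return self.compiled.is_rot.copy()

    @property
    def marker_names(self) -> tuple[str, ...]:
        return self.compiled.marker_names

    @property
    def total_mass(self) -> float:
        return float(self.compiled.mass.sum())

    def marker(self, name: str) -> MarkerRegistration:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def neutral_pose(self) -> np.ndarray:
        """All-zero coordinate vector clipped into bounds."""
        c = self.compiled
        return np.clip(np.zeros(c.n_q), c.lower, c.upper)

    def default_weights(self) -> dict[str, float]:
        return {m.name: m.weight for m in self.markers}

    def check_q(self, q, *, tol: float = 1e-9) -> np.ndarray:
        c = self.compiled
        q = np.asarray(q, dtype=float).reshape(-1)
        if q.shape[0] != c.n_q:
            raise DomainError(
                f"expected {c.n_q} coordinates, got {q.shape[0]}"
            )
        bad = (q < c.lower - tol) | (q > c.upper + tol)
        if bad.any():
            k = int(np.argmax(bad))
            raise DomainError(
                f"coordinate {c.names[k]!r} = {q[k]:g} outside bounds "
                f"[{c.lower[k]:g}, {c.upper[k]:g}]"
            )
        return q

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "joint": {
                        "type": s.joint.type,
                        "axes": [list(a) for a in s.joint.axes],
                        "coordinate_names": list(s.joint.coordinate_names),
                        "coordinate_bounds": [list(b) for b in s.joint.coordinate_bounds],
                    },
                    "location_in_parent": list(s.location_in_parent),
                    "mass": s.mass,
                    "com": list(s.com),
                    "inertia": [list(r) for r in s.inertia],
                    "length_axis": list(s.length_axis),
                }
                for s in self.segments
            ],
            "markers": [
                {
                    "name": m.name,
                    "segment": m.segment,
                    "local_position": list(m.local_position),
                    "weight": m.weight,
                }
                for m in self.markers
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinkSegmentModel":
        segments = tuple(
            Segment(
                name=sd["name"],
                parent=sd.get("parent"),
                joint=JointSpec(
                    type=sd["joint"]["type"],
                    axes=tuple(tuple(a) for a in sd["joint"]["axes"]),
                    coordinate_names=tuple(sd["joint"]["coordinate_names"]),
                    coordinate_bounds=tuple(
                        tuple(b) for b in sd["joint"].get("coordinate_bounds", ())
                    ),
                ),
                location_in_parent=tuple(sd["location_in_parent"]),
                mass=sd["mass"],
                com=tuple(sd["com"]),
                inertia=tuple(tuple(r) for r in sd["inertia"]),
                length_axis=tuple(sd.get("length_axis", (0.0, -1.0, 0.0))),
            )
            for sd in d["segments"]
        )
        markers = tuple(
            MarkerRegistration(
                name=md["name"],
                segment=md["segment"],
                local_position=tuple(md["local_position"]),
                weight=md.get("weight", 1.0),
            )
            for md in d.get("markers", [])
        )
        return cls(name=d.get("name", "model"), segments=segments, markers=markers)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "LinkSegmentModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class KinematicState:
    """Pose of every segment plus per-coordinate geometric data.

    ``coord_axis`` holds the ground-frame instantaneous axis of each
    coordinate (rotation axis or translation direction); ``coord_origin``
    the ground-frame joint center the coordinate rotates about (undefined,
    zeros, for translational coordinates).
    """

    q: np.ndarray
    R: np.ndarray  # (n_seg, 3, 3) segment-to-ground rotations
    p: np.ndarray  # (n_seg, 3) segment origins (joint centers) in ground
    coord_axis: np.ndarray  # (n_q, 3)
    coord_origin: np.ndarray  # (n_q, 3)
    marker_positions: np.ndarray  # (n_markers, 3)


def compute_state(model: LinkSegmentModel, q, *, validate: bool = True) -> KinematicState:
    """Pose the model at coordinates ``q`` (forward kinematics)."""
    c = model.compiled
    if validate:
        q = model.check_q(q)
    else:
        q = np.asarray(q, dtype=float).reshape(-1)
    R = np.empty((c.n_seg, 3, 3))
    p = np.empty((c.n_seg, 3))
    axis = np.zeros((c.n_q, 3))
    origin = np.zeros((c.n_q, 3))
    for i in range(c.n_seg):
        pi = c.parent_idx[i]
        if pi < 0:
            Rp = np.eye(3)
            pp = np.zeros(3)
        else:
            Rp = R[pi]
            pp = p[pi]
        off = c.offsets[i]
        nt = c.n_trans[i]
        loc = c.loc[i]
        if nt:
            loc = loc + q[off : off + nt]
            axis[off : off + nt] = Rp.T[:nt]  # columns of Rp: parent axes in ground
        pos = pp + Rp @ loc
        p[i] = pos
        Rj = Rp
        for k in range(len(c.joint_axes[i])):
            kq = off + nt + k
            a = c.joint_axes[i][k]
            ag = Rj @ a
            axis[kq] = ag
            origin[kq] = pos
            Rj = Rj @ _rodrigues(a, q[kq])
        R[i] = Rj
    mpos = p[c.marker_seg] + np.einsum(
        "mij,mj->mi", R[c.marker_seg], c.marker_local
    )
    return KinematicState(q=q, R=R, p=p, coord_axis=axis, coord_origin=origin,
                          marker_positions=mpos)


def forward_kinematics(model: LinkSegmentModel, q) -> dict[str, np.ndarray]:
    """Ground-frame positions of every registered marker at pose ``q``."""
    st = compute_state(model, q)
    return {n: st.marker_positions[i].copy()
            for i, n in enumerate(model.marker_names)}


def marker_jacobian(
    model: LinkSegmentModel,
    state: KinematicState,
    marker_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Geometric Jacobian d(marker positions)/dq, shape (3*M, n_q).

    Rows are grouped per marker (x, y, z).  ``marker_idx`` selects a subset
    of the model's markers (default: all, in model order).
    """
    c = model.compiled
    if marker_idx is None:
        marker_idx = np.arange(len(c.marker_names))
    mpos = state.marker_positions[marker_idx]  # (M, 3)
    M = len(marker_idx)
    # (n_q, M, 3) displacement from each coordinate's origin to each marker
    diff = mpos[None, :, :] - state.coord_origin[:, None, :]
    J = np.cross(state.coord_axis[:, None, :], diff)
    J[~c.is_rot] = state.coord_axis[~c.is_rot][:, None, :]
    J *= c.affects[:, marker_idx][:, :, None]
    return J.transpose(1, 2, 0).reshape(3 * M, c.n_q)


# ---------------------------------------------------------------------------
# Scaling


@dataclass(frozen=True)
class ScaleFactorSet:
    """Per-segment, per-axis dimensionless scale factors."""

    factors: Mapping[str, tuple[float, float, float]]

    def __post_init__(self):
        f = {k: tuple(map(float, _as_vec3(v))) for k, v in dict(self.factors).items()}
        for name, v in f.items():
            if min(v) <= 0:
                raise DomainError(
                    f"scale factors for segment {name!r} must be strictly positive"
                )
        object.__setattr__(self, "factors", f)

    @classmethod
    def isotropic(cls, factors: Mapping[str, float]) -> "ScaleFactorSet":
        return cls({k: (float(v),) * 3 for k, v in factors.items()})

    def get(self, segment: str) -> np.ndarray:
        return np.asarray(self.factors.get(segment, (1.0, 1.0, 1.0)))

    def compose(self, other: "ScaleFactorSet") -> "ScaleFactorSet":
        names = set(self.factors) | set(other.factors)
        return ScaleFactorSet(
            {n: tuple(self.get(n) * other.get(n)) for n in names}
        )


def scale_model(
    model: LinkSegmentModel,
    factors: ScaleFactorSet,
    *,
    preserve_mass_properties: bool = False,
) -> LinkSegmentModel:
    """Scale segment dimensions (and, by default, mass properties).

    Each segment's joint-center offset in its parent is scaled by the
    *parent's* factors; its center of mass and marker local positions are
    scaled by its *own* factors (markers ride with the segment's anatomical
    frame, so their ground positions change with segment dimensions).
    Unless ``preserve_mass_properties`` is set, mass scales with the volume
    (product of the three factors) and each inertia component I_ab with
    volume * f_a * f_b (mass x length^2 similarity).
    """
    new_segments = []
    for s in model.segments:
        own = factors.get(s.name)
        parent_f = factors.get(s.parent) if s.parent is not None else np.ones(3)
        loc = np.asarray(s.location_in_parent) * parent_f
        com = np.asarray(s.com) * own
        if preserve_mass_properties:
            mass = s.mass
            inertia = s.inertia_matrix
        else:
            vol = float(np.prod(own))
            mass = s.mass * vol
            inertia = s.inertia_matrix * vol * np.outer(own, own)
        new_segments.append(
            replace(
                s,
                location_in_parent=tuple(loc),
                com=tuple(com),
                mass=mass,
                inertia=tuple(map(tuple, inertia.tolist())),
            )
        )
    new_markers = []
    for m in model.markers:
        own = factors.get(m.segment)
        new_markers.append(
            replace(m, local_position=tuple(np.asarray(m.local_position) * own))
        )
    return LinkSegmentModel(
        name=model.name, segments=tuple(new_segments), markers=tuple(new_markers)
    )
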