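"""Monte Carlo uncertainty propagation for marker-based inverse analyses.

Model calibration is uncertain in two ways this module samples:

* **marker registration** — each marker's location in its segment frame is
  known only to within a distance *e*; perturbations are drawn uniformly
  in the ball of radius *e* (cube sampling with rejection);
* **segment scaling** — segment dimensions are known only through
  marker-driven scaling; candidate per-segment scale factors are drawn
  uniformly on an interval and accepted only if, after re-posing the
  scaled model by IK against the original model's calibration-pose marker
  positions, every marker lies within *e* of its original counterpart.

An ensemble of N equally plausible models is generated per uncertainty
level (levels can be analyzed cumulatively, augmenting lower levels), and
every model is run through the identical IK -> filter -> differentiate ->
inverse dynamics -> joint power pipeline with the same experimental
inputs.  The spread of the resulting trajectories and of nine peak gait
metrics quantifies the output uncertainty; minimum stance knee flexion is
additionally mapped onto crouch-gait severity categories to expose
classification ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import ExternalLoads, JointMoments, JointPowers, GRAVITY, \
    inverse_dynamics, joint_powers
from .errors import DomainError, MocapUQError, RejectionCapError
from .events import GaitEvents, detect_gait_events
from .kinematics import (
    DEFAULT_CUTOFF_HZ,
    IKSolution,
    MarkerTrajectories,
    gauss_newton_pose,
    marker_position_trajectory,
    process_coordinates,
    solve_ik,
    solve_ik_frame,
)
from .model import LinkSegmentModel, ScaleFactorSet, compute_state, scale_model

STRATEGIES = ("marker_registration", "segment_scaling")


@dataclass(frozen=True)
class UncertaintyConfig:
    """Study configuration for one uncertainty-propagation run."""

    strategy: str
    levels_e: tuple[float, ...] = (0.005, 0.010, 0.015, 0.020)  # m
    N: int = 100
    scale_interval: tuple[float, float] = (0.90, 1.10)
    seed: int = 0
    rejection_cap: int = 200_000
    augment_previous: bool = True
    isotropic_scaling: bool = True

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise DomainError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        levels = tuple(float(e) for e in self.levels_e)
        if not levels or min(levels) <= 0:
            raise DomainError("uncertainty levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise DomainError("uncertainty levels must be strictly increasing")
        object.__setattr__(self, "levels_e", levels)
        if self.N < 1:
            raise DomainError("N must be >= 1")
        lo, hi = self.scale_interval
        if not (0 < lo < hi):
            raise DomainError("scale interval must satisfy 0 < lo < hi")
        object.__setattr__(self, "scale_interval", (float(lo), float(hi)))


# ---------------------------------------------------------------------------
# Samplers


def sample_in_ball(e: float, rng: np.random.Generator, *,
                   rejection_cap: int = 1000) -> np.ndarray:
    """One point uniform in the closed ball of radius ``e``.

    Draws uniform in the cube [-e, e]^3 and rejects points outside the
    ball, so every point in the ball is equally probable.
    """
    if e < 0:
        raise DomainError("radius e must be >= 0")
    if e == 0:
        return np.zeros(3)
    for _ in range(rejection_cap):
        x = rng.uniform(-e, e, 3)
        if x @ x <= e * e:
            return x
    raise RejectionCapError(  # pragma: no cover - acceptance prob ~0.52
        f"ball sampler exceeded {rejection_cap} draws"
    )


def perturb_markers(
    model: LinkSegmentModel,
    e: float,
    rng: np.random.Generator,
    *,
    per_marker_e: Mapping[str, float] | None = None,
    rejection_cap: int = 1000,
) -> LinkSegmentModel:
    """Independently offset every marker's local position uniformly within
    the ball of radius ``e`` (or a per-marker radius).  All other model
    fields are untouched."""
    new_markers = []
    for m in model.markers:
        em = per_marker_e.get(m.name, e) if per_marker_e else e
        off = sample_in_ball(em, rng, rejection_cap=rejection_cap)
        new_markers.append(
            replace(m, local_position=tuple(np.asarray(m.local_position) + off))
        )
    return LinkSegmentModel(
        name=model.name, segments=model.segments, markers=tuple(new_markers)
    )


def _same_segment_pairs(model: LinkSegmentModel):
    """(segment index, local delta vector, unscaled distance) for every
    pair of markers sharing a segment.  Same-segment marker distances are
    pose-invariant, so they bound the achievable IK fit from below."""
    c = model.compiled
    pairs = []
    for si in range(c.n_seg):
        idx = np.nonzero(c.marker_seg == si)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                delta = c.marker_local[idx[a]] - c.marker_local[idx[b]]
                pairs.append((si, delta, float(np.linalg.norm(delta))))
    return pairs


def sample_scaled_model(
    model: LinkSegmentModel,
    e: float,
    scale_interval: tuple[float, float],
    calibration_pose: np.ndarray,
    rng: np.random.Generator,
    *,
    isotropic: bool = True,
    weights: Mapping[str, float] | None = None,
    rejection_cap: int = 200_000,
) -> tuple[LinkSegmentModel, ScaleFactorSet]:
    """Rejection-sample an equally plausible scaled model.

    Each candidate draws per-segment scale factors uniformly on
    ``scale_interval`` (one scalar per segment when ``isotropic``, else a
    per-axis triplet), scales the model, re-poses it by IK against the
    original model's calibration-pose marker positions, and is accepted
    iff every marker then lies within ``e`` of its original counterpart.

    The first accepted candidate in draw order is returned, so results
    are reproducible from the generator state.  Candidates whose
    same-segment marker distances already certify a fit worse than ``e``
    (those distances are pose-invariant: if a scaled pair distance
    differs from the original by more than 2e, no pose can bring both
    markers within e) are rejected without the IK solve; this prunes
    draws but cannot change which candidate is accepted.
    """
    if e <= 0:
        raise DomainError("e must be > 0 for scale sampling")
    lo, hi = scale_interval
    if not (0 < lo < hi):
        raise DomainError("scale interval must satisfy 0 < lo < hi")
    calibration_pose = model.check_q(calibration_pose)
    ref = compute_state(model, calibration_pose).marker_positions
    observed = {n: ref[i] for i, n in enumerate(model.marker_names)}
    seg_names = [s.name for s in model.segments]
    S = len(seg_names)
    pairs = _same_segment_pairs(model)
    batch = 512
    drawn = 0
    while drawn < rejection_cap:
        nb = min(batch, rejection_cap - drawn)
        drawn += nb
        if isotropic:
            fac = rng.uniform(lo, hi, (nb, S))
        else:
            fac = rng.uniform(lo, hi, (nb, S, 3))
        feasible = np.ones(nb, dtype=bool)
        for si, delta, d0 in pairs:
            if isotropic:
                d = fac[:, si] * d0
            else:
                d = np.linalg.norm(fac[:, si, :] * delta, axis=1)
            feasible &= np.abs(d - d0) <= 2.0 * e
        for b in np.nonzero(feasible)[0]:
            if isotropic:
                factors = ScaleFactorSet.isotropic(dict(zip(seg_names, fac[b])))
            else:
                factors = ScaleFactorSet(
                    {n: tuple(v) for n, v in zip(seg_names, fac[b])}
                )
            candidate = scale_model(model, factors)
            try:
                q = gauss_newton_pose(candidate, observed, weights, calibration_pose)
            except MocapUQError:
                continue
            pos = compute_state(candidate, q, validate=False).marker_positions
            dist = np.linalg.norm(pos - ref, axis=1)
            if dist.max() <= e:
                return candidate, factors
    raise RejectionCapError(
        f"no scaled model accepted in {rejection_cap} draws at e = {e:g} m; "
        f"increase e or narrow the scale interval {scale_interval}"
    )


# ---------------------------------------------------------------------------
# Ensembles


@dataclass(frozen=True)
class EnsembleMember:
    model: LinkSegmentModel
    strategy: str
    level_e: float
    level_index: int
    draw_index: int
    scale_factors: ScaleFactorSet | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.level_index, self.draw_index)


@dataclass(frozen=True)
class ModelEnsemble:
    """Per-level sets of perturbed models with provenance.

    ``members_per_level[i]`` holds the N fresh models drawn at level i;
    when ``augment_previous`` is set, the analysis set at level i is the
    union of all sets up to i (the nested "augmentation" reading), so each
    level's analysis set contains every lower level's models by
    construction.
    """

    strategy: str
    levels_e: tuple[float, ...]
    seed: int
    members_per_level: tuple[tuple[EnsembleMember, ...], ...]
    augment_previous: bool = True

    def analysis_members(self, level_index: int) -> tuple[EnsembleMember, ...]:
        if self.augment_previous:
            out: list[EnsembleMember] = []
            for lvl in self.members_per_level[: level_index + 1]:
                out.extend(lvl)
            return tuple(out)
        return self.members_per_level[level_index]

    @property
    def all_members(self) -> tuple[EnsembleMember, ...]:
        return tuple(m for lvl in self.members_per_level for m in lvl)


def _member_rng(seed: int, level_index: int, draw_index: int) -> np.random.Generator:
    # independent, order-insensitive substream per (level, draw)
    return np.random.default_rng([seed, level_index, draw_index])


def build_ensemble(
    model: LinkSegmentModel,
    config: UncertaintyConfig,
    *,
    calibration_pose: np.ndarray | None = None,
    weights: Mapping[str, float] | None = None,
) -> ModelEnsemble:
    """Generate N fresh models at every uncertainty level.

    Fully reproducible from ``config.seed``: each (level, draw) pair gets
    its own random substream, so members are independent of generation
    order."""
    if calibration_pose is None:
        calibration_pose = model.neutral_pose()
    levels = []
    for li, e in enumerate(config.levels_e):
        members = []
        for d in range(config.N):
            rng = _member_rng(config.seed, li, d)
            if config.strategy == "marker_registration":
                m = perturb_markers(model, e, rng)
                sf = None
            else:
                m, sf = sample_scaled_model(
                    model, e, config.scale_interval, calibration_pose, rng,
                    isotropic=config.isotropic_scaling, weights=weights,
                    rejection_cap=config.rejection_cap,
                )
            members.append(
                EnsembleMember(
                    model=m, strategy=config.strategy, level_e=e,
                    level_index=li, draw_index=d, scale_factors=sf,
                )
            )
        levels.append(tuple(members))
    return ModelEnsemble(
        strategy=config.strategy,
        levels_e=config.levels_e,
        seed=config.seed,
        members_per_level=tuple(levels),
        augment_previous=config.augment_previous,
    )


# ---------------------------------------------------------------------------
# Peak gait metrics


@dataclass(frozen=True)
class PeakConfig:
    """Which coordinates carry the hip/knee/ankle angles of the analyzed
    leg, with flexion (hip, knee) and dorsiflexion (ankle) positive."""

    hip_flexion: str = "hip_flexion_r"
    knee_flexion: str = "knee_flexion_r"
    ankle_dorsiflexion: str = "ankle_angle_r"
    stance_load_segment: str = "foot_r"


DEFAULT_PEAK_CONFIG = PeakConfig()

METRIC_NAMES = (
    "peak_hip_extension_angle",
    "min_knee_flexion_angle_stance",
    "peak_ankle_plantarflexion_angle",
    "peak_hip_flexion_moment",
    "peak_knee_flexion_moment_stance",
    "peak_ankle_plantarflexion_moment",
    "peak_hip_power_pushoff",
    "min_knee_power_stance",
    "peak_ankle_power_pushoff",
)


@dataclass(frozen=True)
class PeakMetrics:
    """The nine scalar gait outcomes (angles deg, moments N*m, powers W)."""

    peak_hip_extension_angle: float
    min_knee_flexion_angle_stance: float
    peak_ankle_plantarflexion_angle: float
    peak_hip_flexion_moment: float
    peak_knee_flexion_moment_stance: float
    peak_ankle_plantarflexion_moment: float
    peak_hip_power_pushoff: float
    min_knee_power_stance: float
    peak_ankle_power_pushoff: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _window(mask, metric):
    if not mask.any():
        raise DomainError(f"empty window for metric {metric!r}")
    return mask


def extract_peaks(
    coordinates,
    moments,
    powers,
    events: GaitEvents,
    coordinate_names: Sequence[str],
    config: PeakConfig = DEFAULT_PEAK_CONFIG,
) -> PeakMetrics:
    """Extract the nine peak gait metrics from one model's trajectories.

    ``coordinates`` are in radians; angle metrics are reported in degrees.
    Stance-restricted metrics search only within stance; push-off metrics
    only within the push-off window; the remaining peaks span the trial.
    """
    coordinates = np.atleast_2d(np.asarray(coordinates, float))
    moments = np.atleast_2d(np.asarray(moments, float))
    powers = np.atleast_2d(np.asarray(powers, float))
    names = list(coordinate_names)
    ih = names.index(config.hip_flexion)
    ik_ = names.index(config.knee_flexion)
    ia = names.index(config.ankle_dorsiflexion)
    hip_deg = np.rad2deg(coordinates[:, ih])
    knee_deg = np.rad2deg(coordinates[:, ik_])
    ankle_deg = np.rad2deg(coordinates[:, ia])
    stance = _window(events.stance, "stance metrics")
    pushoff = _window(events.pushoff, "push-off metrics")
    return PeakMetrics(
        peak_hip_extension_angle=float(np.max(-hip_deg)),
        min_knee_flexion_angle_stance=float(np.min(knee_deg[stance])),
        peak_ankle_plantarflexion_angle=float(np.max(-ankle_deg)),
        peak_hip_flexion_moment=float(np.max(moments[:, ih])),
        peak_knee_flexion_moment_stance=float(np.max(moments[stance, ik_])),
        peak_ankle_plantarflexion_moment=float(np.max(-moments[:, ia])),
        peak_hip_power_pushoff=float(np.max(powers[pushoff, ih])),
        min_knee_power_stance=float(np.min(powers[stance, ik_])),
        peak_ankle_power_pushoff=float(np.max(powers[pushoff, ia])),
    )


def metric_ranges(
    peaks: Iterable[PeakMetrics],
) -> dict[str, tuple[float, float]]:
    """Min/max of each peak metric across a set of equally plausible
    models."""
    peaks = list(peaks)
    if not peaks:
        raise DomainError("need at least one model to collect ranges")
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(p, name) for p in peaks]
        out[name] = (min(vals), max(vals))
    return out


# ---------------------------------------------------------------------------
# Crouch-gait classification

CROUCH_BOUNDARIES_DEG = (15.0, 30.0, 50.0)
CROUCH_CATEGORIES = (
    "typically developing",
    "mild crouch",
    "moderate crouch",
    "severe crouch",
)


def classify_crouch(min_knee_flexion_stance: float) -> str:
    """Crouch-gait severity from minimum stance knee flexion (degrees).

    Below 15 deg: typically developing; 15-30: mild; 30-50: moderate;
    above 50: severe.  A boundary value belongs to the higher-severity
    class (15 -> mild, 30 -> moderate, 50 -> severe).
    """
    a = float(min_knee_flexion_stance)
    if not math.isfinite(a):
        raise DomainError("knee flexion angle must be finite")
    for bound, cat in zip(CROUCH_BOUNDARIES_DEG, CROUCH_CATEGORIES):
        if a < bound:
            return cat
    return CROUCH_CATEGORIES[-1]


@dataclass(frozen=True)
class ClassificationRange:
    """Angle range across an ensemble and every severity category the
    closed range intersects."""

    angle_range: tuple[float, float]
    categories: tuple[str, ...]
    ambiguous: bool


def classification_range(min_knee_flexion_angles: Iterable[float]) -> ClassificationRange:
    """Categories compatible with an ensemble of equally plausible minimum
    stance knee-flexion angles; flagged ambiguous when the range straddles
    a category boundary."""
    angles = [float(a) for a in min_knee_flexion_angles]
    if not angles:
        raise DomainError("need at least one angle")
    lo, hi = min(angles), max(angles)
    edges = (-math.inf,) + CROUCH_BOUNDARIES_DEG + (math.inf,)
    cats = []
    for i, cat in enumerate(CROUCH_CATEGORIES):
        a, b = edges[i], edges[i + 1]
        # category interval is [a, b); closed range [lo, hi] intersects it
        if lo < b and hi >= a:
            cats.append(cat)
    return ClassificationRange(
        angle_range=(lo, hi), categories=tuple(cats), ambiguous=len(cats) > 1
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineResult:
    """Everything the processing pipeline computes for one model."""

    model: LinkSegmentModel
    ik: IKSolution
    coordinates_filtered: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    moments: JointMoments
    powers: JointPowers
    peaks: PeakMetrics


@dataclass(frozen=True)
class ModelFailure:
    index: int
    provenance: tuple[int, int] | None
    error: str


def run_single_model(
    model: LinkSegmentModel,
    trajectories: MarkerTrajectories,
    loads: ExternalLoads,
    events: GaitEvents,
    *,
    weights: Mapping[str, float] | None = None,
    peak_config: PeakConfig = DEFAULT_PEAK_CONFIG,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    gravity=GRAVITY,
) -> PipelineResult:
    """IK -> filter -> differentiate -> inverse dynamics -> powers -> peaks
    for one model against fixed experimental inputs."""
    ik = solve_ik(model, trajectories, weights)
    filtered, derivs = process_coordinates(model, ik, cutoff=cutoff)
    loads_rs = loads.resample(ik.times)
    moments = inverse_dynamics(
        model, filtered, derivs.velocities, derivs.accelerations,
        loads_rs, gravity, times=ik.times,
    )
    powers = joint_powers(moments, derivs.velocities)
    peaks = extract_peaks(
        filtered, moments.moments, powers.powers, events,
        ik.coordinate_names, peak_config,
    )
    return PipelineResult(
        model=model, ik=ik, coordinates_filtered=filtered,
        velocities=derivs.velocities, accelerations=derivs.accelerations,
        moments=moments, powers=powers, peaks=peaks,
    )


def run_pipeline(
    members: Sequence[EnsembleMember | LinkSegmentModel],
    trajectories: MarkerTrajectories,
    loads: ExternalLoads,
    events: GaitEvents | None = None,
    *,
    weights: Mapping[str, float] | None = None,
    peak_config: PeakConfig = DEFAULT_PEAK_CONFIG,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    gravity=GRAVITY,
) -> tuple[dict[int, PipelineResult], list[ModelFailure]]:
    """Run the identical pipeline over every ensemble member.

    All members see the same marker data, weights, and external loads.
    Per-model failures are recorded with provenance and the run continues.
    Returns results keyed by position in ``members`` plus the failures.
    """
    if events is None:
        events = _default_events(loads, peak_config)
    results: dict[int, PipelineResult] = {}
    failures: list[ModelFailure] = []
    for i, member in enumerate(members):
        model = member.model if isinstance(member, EnsembleMember) else member
        try:
            results[i] = run_single_model(
                model, trajectories, loads, events, weights=weights,
                peak_config=peak_config, cutoff=cutoff, gravity=gravity,
            )
        except MocapUQError as exc:
            prov = member.key if isinstance(member, EnsembleMember) else None
            failures.append(ModelFailure(index=i, provenance=prov, error=str(exc)))
    return results, failures


def _default_events(loads: ExternalLoads, peak_config: PeakConfig) -> GaitEvents:
    for ch in loads.channels:
        if ch.segment == peak_config.stance_load_segment:
            return detect_gait_events(loads.times, ch.force[:, 1])
    raise DomainError(
        f"no load channel on segment {peak_config.stance_load_segment!r} "
        "to detect gait events from; pass events explicitly"
    )


def marker_error_metrics(
    models: Sequence[LinkSegmentModel],
    solutions: Sequence[IKSolution],
    reference_positions: np.ndarray,
    marker_names: Sequence[str],
    tracked: Sequence[str] | None = None,
) -> tuple[float, float]:
    """The two scalar marker-error summaries of an ensemble.

    Errors are distances between each perturbed model's markers (posed by
    its own IK solution) and the *original model's* markers (posed by the
    original solution) — not the experimental markers.  Returns
    ``(rmse_avg_frames_max_models, max_error_all)``: the per-model RMSE
    across tracked markers at each frame, averaged over frames, maximized
    over models; and the maximum single-marker error over all markers,
    frames, and models.
    """
    if len(models) == 0:
        raise DomainError("empty ensemble")
    if len(models) != len(solutions):
        raise DomainError("one IK solution required per model")
    marker_names = list(marker_names)
    if tracked is None:
        tracked = marker_names  # lower-body fixture: all markers qualify
    tidx = np.array([marker_names.index(n) for n in tracked])
    ref = np.asarray(reference_positions, dtype=float)
    rmse_models = []
    max_all = 0.0
    for model, sol in zip(models, solutions):
        pos = marker_position_trajectory(model, sol.coordinates)
        err = np.linalg.norm(pos - ref, axis=2)  # (T, M)
        rmse_t = np.sqrt(np.mean(err[:, tidx] ** 2, axis=1))
        rmse_models.append(float(np.mean(rmse_t)))
        max_all = max(max_all, float(err[:, tidx].max()))
    return max(rmse_models), max_all


# ---------------------------------------------------------------------------
# Top-level study driver


@dataclass(frozen=True)
class LevelSummary:
    level_e: float
    n_models: int
    rmse_avg_frames_max_models: float
    max_marker_error: float
    ranges: Mapping[str, tuple[float, float]]
    classification: ClassificationRange


@dataclass(frozen=True)
class UncertaintyReport:
    """Per-level marker-error metrics and peak-metric ranges for one
    strategy."""

    strategy: str
    seed: int
    levels: tuple[LevelSummary, ...]
    baseline_peaks: PeakMetrics
    failures: tuple[ModelFailure, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            row = {
                "uncertainty_cm": lv.level_e * 100.0,
                "n_models": lv.n_models,
                "rmse_avg_frames_max_models_cm": lv.rmse_avg_frames_max_models * 100.0,
                "max_marker_error_cm": lv.max_marker_error * 100.0,
            }
            for name, (lo, hi) in lv.ranges.items():
                row[f"{name}_min"] = lo
                row[f"{name}_max"] = hi
            row["crouch_categories"] = "|".join(lv.classification.categories)
            rows.append(row)
        return pd.DataFrame(rows)


def analyze_uncertainty(
    model: LinkSegmentModel,
    trajectories: MarkerTrajectories,
    loads: ExternalLoads,
    config: UncertaintyConfig,
    *,
    weights: Mapping[str, float] | None = None,
    events: GaitEvents | None = None,
    peak_config: PeakConfig = DEFAULT_PEAK_CONFIG,
    calibration_pose: np.ndarray | None = None,
    tracked_markers: Sequence[str] | None = None,
) -> UncertaintyReport:
    """Full uncertainty-propagation study against one trial.

    Runs the baseline pipeline on the unperturbed model, builds the
    ensemble, runs every member through the identical pipeline, and
    summarizes marker-error metrics, nine peak-metric ranges, and crouch
    classification per uncertainty level.
    """
    if events is None:
        events = _default_events(loads, peak_config)
    baseline = run_single_model(
        model, trajectories, loads, events,
        weights=weights, peak_config=peak_config,
    )
    ref_positions = marker_position_trajectory(model, baseline.ik.coordinates)
    ensemble = build_ensemble(
        model, config, calibration_pose=calibration_pose, weights=weights
    )
    member_list = list(ensemble.all_members)
    results, failures = run_pipeline(
        member_list, trajectories, loads, events,
        weights=weights, peak_config=peak_config,
    )
    by_key = {
        member_list[i].key: res for i, res in results.items()
    }
    levels = []
    for li, e in enumerate(config.levels_e):
        members = ensemble.analysis_members(li)
        level_results = [by_key[m.key] for m in members if m.key in by_key]
        if not level_results:
            raise MocapUQError(f"every model failed at level e = {e:g} m")
        rmse_max, err_max = marker_error_metrics(
            [r.model for r in level_results],
            [r.ik for r in level_results],
            ref_positions,
            model.marker_names,
            tracked_markers,
        )
        peaks = [r.peaks for r in level_results]
        ranges = metric_ranges(peaks)
        cls = classification_range(
            [p.min_knee_flexion_angle_stance for p in peaks]
        )
        levels.append(
            LevelSummary(
                level_e=e,
                n_models=len(level_results),
                rmse_avg_frames_max_models=rmse_max,
                max_marker_error=err_max,
                ranges=ranges,
                classification=cls,
            )
        )
    return UncertaintyReport(
        strategy=config.strategy,
        seed=config.seed,
        levels=tuple(levels),
        baseline_peaks=baseline.peaks,
        failures=tuple(failures),
    )
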