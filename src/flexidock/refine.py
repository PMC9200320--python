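"""Refinement stage: greedy quench with fine rigid moves, optional jump
minimization, and interface-score ranking.

The all-atom refinement of the original protocol (rotamer packing plus a
full-atom force field) is out of scope here; this stage keeps its
contracted roles — clash relief and re-ranking — using the coarse
refinement score (Lennard-Jones + torsion statistics) with the stated fine
move magnitudes (0.1 A translations, 3 degree rotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from .geom import RigidTransform, random_axis
from .remc import CandidateRecord
from .sample import MobileSelection, MoveSchedule, backbone_move, NoMobileFragmentsError
from .score import LJParams, ScoreWeights, TorsionParams, ScoreBreakdown, interface_score, muds, refinement_score
from .structmodel import CoarsePose


@dataclass(frozen=True)
class RefineConfig:
    trans_sigma: float = 0.1  # angstrom
    rot_sigma: float = 3.0  # degrees
    n_quench_trials: int = 300
    minimize: bool = True
    p_backrub: float = 0.0  # optional small backbone quench moves
    backrub_max_angle: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.trans_sigma <= 0 or self.rot_sigma <= 0:
            raise ValueError("sigmas must be positive")


def _fine_rigid(pose: CoarsePose, cfg: RefineConfig, rng: np.random.Generator) -> CoarsePose:
    t = rng.normal(0.0, cfg.trans_sigma, size=3)
    axis = random_axis(rng)
    angle = np.radians(rng.normal(0.0, cfg.rot_sigma))
    center = pose.ligand_centroid()
    move = RigidTransform.from_translation(t).compose(
        RigidTransform.from_rotvec(angle * axis, center=center)
    )
    return pose.with_jump(move.compose(pose.jump))


def _jump_minimize(pose: CoarsePose, score_fn, n_sweeps: int = 2) -> CoarsePose:
    """Coordinate descent over the 6 jump parameters with bounded line searches."""
    center = pose.ligand_centroid()
    axes = np.eye(3)

    def apply_param(p: CoarsePose, kind: str, k: int, v: float) -> CoarsePose:
        if kind == "t":
            move = RigidTransform.from_translation(v * axes[k])
        else:
            move = RigidTransform.from_rotvec(np.radians(v) * axes[k], center=center)
        return p.with_jump(move.compose(p.jump))

    cur = pose
    cur_score = score_fn(cur)
    for _ in range(n_sweeps):
        for kind, bound in (("t", 0.5), ("r", 5.0)):
            for k in range(3):
                res = minimize_scalar(
                    lambda v: score_fn(apply_param(cur, kind, k, v)),
                    bounds=(-bound, bound),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
                if res.fun < cur_score:
                    cur = apply_param(cur, kind, k, float(res.x))
                    cur_score = float(res.fun)
    return cur


def refine(
    candidate: CandidateRecord | CoarsePose,
    config: RefineConfig | None = None,
    weights: ScoreWeights | None = None,
    selection: MobileSelection | None = None,
    lj_params: LJParams | None = None,
    torsion_params: TorsionParams | None = None,
    trace: list | None = None,
) -> tuple[CoarsePose, float, ScoreBreakdown]:
    """Zero-temperature quench of one candidate.

    Proposes fine rigid moves (and, if configured, small backrubs on the
    mobile fragments) and accepts only score decreases, then optionally
    runs a coordinate-descent minimization of the six jump parameters.
    Deterministic for a fixed config seed; the returned refinement score
    never exceeds the input's.  Pass ``trace`` to collect the accepted
    score sequence.
    """
    config = config or RefineConfig()
    weights = weights or ScoreWeights()
    pose = candidate.state if isinstance(candidate, CandidateRecord) else candidate
    rng = np.random.default_rng(config.seed)

    def score_fn(p: CoarsePose) -> float:
        return refinement_score(p, weights, lj_params, torsion_params)

    cur = pose
    cur_score = score_fn(cur)
    if trace is not None:
        trace.append(cur_score)
    brub_schedule = MoveSchedule(backrub_max_angle=config.backrub_max_angle)
    for _ in range(config.n_quench_trials):
        if config.p_backrub > 0 and selection is not None and rng.uniform() < config.p_backrub:
            try:
                prop = backbone_move(cur, selection, brub_schedule, rng)
            except NoMobileFragmentsError:
                prop = _fine_rigid(cur, config, rng)
        else:
            prop = _fine_rigid(cur, config, rng)
        s = score_fn(prop)
        if s < cur_score:
            cur, cur_score = prop, s
            if trace is not None:
                trace.append(cur_score)

    if config.minimize:
        cur = _jump_minimize(cur, score_fn)
        cur_score = score_fn(cur)
        if trace is not None:
            trace.append(cur_score)

    iface = interface_score(cur, weights, lj_params, torsion_params)
    breakdown = muds(cur, weights, None, lj_params, torsion_params)
    return cur, iface, breakdown


@dataclass(frozen=True)
class RankedCandidate:
    pose: CoarsePose
    interface_score: float
    serial: int
    breakdown: ScoreBreakdown | None = None


def rank_candidates(refined: list[RankedCandidate]) -> list[RankedCandidate]:
    """Ascending by interface score; ties broken by serial (stable)."""
    if not refined:
        raise ValueError("no candidates to rank")
    return sorted(refined, key=lambda c: (c.interface_score, c.serial))
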