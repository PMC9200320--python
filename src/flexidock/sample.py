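"""Mobile-residue selection, Monte Carlo move set, and pose initializers.

Residue selections come in five modes: interface patches at 5.5 or 8 A
(recomputed on demand as the pose changes), either patch augmented with all
loop residues of the unbound monomers, or a user-directed list.  Selected
residues are grouped into contiguous fragments whose terminal residues act
as backrub pivots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .geom import RigidTransform, backrub_rotate, random_axis, random_rotation
from .structmodel import CoarsePose, Residue, assign_secstruct

SELECTION_MODES = ("interface_5.5", "interface_8", "interface_5.5_plus_loops",
                   "interface_8_plus_loops", "directed")

_MODE_CUTOFF = {
    "interface_5.5": 5.5,
    "interface_8": 8.0,
    "interface_5.5_plus_loops": 5.5,
    "interface_8_plus_loops": 8.0,
}


@dataclass(frozen=True)
class Fragment:
    """Contiguous mobile segment on one partner; ends are the backrub pivots."""

    partner: str  # "receptor" | "ligand"
    start: int  # dense index into the partner residue list (pivot_first)
    end: int  # dense index (pivot_last, inclusive)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MobileSelection:
    mode: str
    residues: frozenset  # of (chain_id, seq_id)
    fragments: tuple[Fragment, ...]

    def __post_init__(self):
        if self.mode not in SELECTION_MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}")


@dataclass(frozen=True)
class MoveSchedule:
    """Move-set parameters; magnitudes are unstated upstream and config-exposed."""

    p_rigid: float = 0.5
    rigid_trans_sigma: float = 0.7  # angstrom, per axis
    rigid_rot_sigma: float = 5.0  # degrees
    backrub_max_angle: float = 20.0  # degrees

    def __post_init__(self):
        if not 0.0 <= self.p_rigid <= 1.0:
            raise ValueError("p_rigid must be in [0, 1]")
        if min(self.rigid_trans_sigma, self.rigid_rot_sigma, self.backrub_max_angle) < 0:
            raise ValueError("move magnitudes must be non-negative")


class NoMobileFragmentsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# selection


def select_interface(pose: CoarsePose, cutoff: float) -> set[tuple[str, int]]:
    """Residues of either partner with any coarse atom within ``cutoff`` of the
    other partner's coarse atoms."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = pose.receptor
    lig = pose.ligand
    rec_coords = [r.coarse_coords() for r in rec]
    lig_coords = [r.coarse_coords() for r in lig]
    a = np.vstack(rec_coords)
    b = np.vstack(lig_coords)
    a_idx = np.repeat(np.arange(len(rec)), [len(c) for c in rec_coords])
    b_idx = np.repeat(np.arange(len(lig)), [len(c) for c in lig_coords])
    d = cdist(a, b)
    close = d <= cutoff
    out: set[tuple[str, int]] = set()
    if close.any():
        for i in np.unique(a_idx[np.where(close.any(axis=1))[0]]):
            out.add(rec[i].key)
        for j in np.unique(b_idx[np.where(close.any(axis=0))[0]]):
            out.add(lig[j].key)
    return out


def loop_residues(residues) -> set[tuple[str, int]]:
    """Keys of residues labeled L by the dihedral-box secondary structure."""
    residues = list(residues)
    labels = assign_secstruct(residues)
    return {res.key for res, lab in zip(residues, labels) if lab == "L"}


def add_loop_residues(selection: set, labels_or_residues) -> set:
    """Union of a selection with all loop residues.

    Accepts either a residue list (labels computed here) or a pre-zipped
    iterable of (residue, label).
    """
    items = list(labels_or_residues)
    if not items:
        return set(selection)
    if isinstance(items[0], tuple):
        return set(selection) | {res.key for res, lab in items if lab == "L"}
    return set(selection) | loop_residues(items)


def contiguous_fragments(
    residues, selected: set[tuple[str, int]], partner: str, min_len: int = 3
) -> list[Fragment]:
    """Maximal runs of consecutive selected seq_ids within one partner.

    Runs shorter than ``min_len`` are dropped; fragment ends are the pivots.
    Fragments never span chains or numbering gaps.
    """
    residues = list(residues)
    frags: list[Fragment] = []
    i = 0
    n = len(residues)
    while i < n:
        if residues[i].key not in selected:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and residues[j + 1].key in selected
            and residues[j + 1].chain_id == residues[j].chain_id
            and residues[j + 1].seq_id == residues[j].seq_id + 1
        ):
            j += 1
        if j - i + 1 >= min_len:
            frags.append(Fragment(partner, i, j))
        i = j + 1
    return frags


def build_selection(
    pose: CoarsePose,
    mode: str,
    directed: set[tuple[str, int]] | None = None,
    min_fragment_len: int = 3,
) -> MobileSelection:
    """Assemble the mobile selection for the current pose."""
    if mode == "directed":
        if not directed:
            raise ValueError("directed mode requires a non-empty residue list")
        keys = set(directed)
    else:
        keys = select_interface(pose, _MODE_CUTOFF[mode])
        if mode.endswith("_plus_loops"):
            keys |= loop_residues(pose.receptor)
            keys |= loop_residues(pose.ligand)
    frags = contiguous_fragments(pose.receptor, keys, "receptor", min_fragment_len)
    frags += contiguous_fragments(pose.ligand_local, keys, "ligand", min_fragment_len)
    return MobileSelection(mode=mode, residues=frozenset(keys), fragments=tuple(frags))


def parse_mobile_list(text: str) -> set[tuple[str, int]]:
    """Parse a directed mobile-residue list: lines of ``chain:seq`` or
    ``chain:start-end``; '#' starts a comment."""
    keys: set[tuple[str, int]] = set()
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        chain, _, spec = line.partition(":")
        if not chain or not spec:
            raise ValueError(f"malformed mobile-residue line: {raw!r}")
        if "-" in spec:
            lo, hi = spec.split("-", 1)
            for s in range(int(lo), int(hi) + 1):
                keys.add((chain, s))
        else:
            keys.add((chain, int(spec)))
    return keys


# ---------------------------------------------------------------------------
# move proposals (all symmetric, as Metropolis requires)


def rigid_move(pose: CoarsePose, schedule: MoveSchedule, rng: np.random.Generator) -> CoarsePose:
    """Gaussian rigid-body perturbation of the ligand jump.

    Translation ~ N(0, sigma) per axis; rotation about a uniform random axis
    through the ligand centroid with angle ~ N(0, rot_sigma).  The proposal
    density is symmetric (Gaussian magnitudes, uniform axis).
    """
    t = rng.normal(0.0, schedule.rigid_trans_sigma, size=3)
    axis = random_axis(rng)
    angle = np.radians(rng.normal(0.0, schedule.rigid_rot_sigma))
    center = pose.ligand_centroid()
    rot = RigidTransform.from_rotvec(angle * axis, center=center)
    move = RigidTransform.from_translation(t).compose(rot)
    return pose.with_jump(move.compose(pose.jump))


def backbone_move(
    pose: CoarsePose,
    selection: MobileSelection,
    schedule: MoveSchedule,
    rng: np.random.Generator,
) -> CoarsePose:
    """Backrub one uniformly chosen mobile fragment by a uniform random angle."""
    if not selection.fragments:
        raise NoMobileFragmentsError("no mobile fragments")
    frag = selection.fragments[rng.integers(len(selection.fragments))]
    angle = rng.uniform(-schedule.backrub_max_angle, schedule.backrub_max_angle)
    if frag.partner == "receptor":
        new_rec = backrub_rotate(list(pose.receptor), frag.start, frag.end, angle)
        return pose.with_receptor(new_rec)
    new_lig = backrub_rotate(list(pose.ligand_local), frag.start, frag.end, angle)
    return pose.with_ligand_local(new_lig)


def propose_move(
    pose: CoarsePose,
    selection: MobileSelection,
    schedule: MoveSchedule,
    rng: np.random.Generator,
) -> CoarsePose:
    """One MC trial move: rigid with probability p_rigid, else backbone.

    Falls back to a rigid move when no mobile fragments exist.
    """
    if rng.uniform() < schedule.p_rigid or not selection.fragments:
        return rigid_move(pose, schedule, rng)
    return backbone_move(pose, selection, schedule, rng)


# ---------------------------------------------------------------------------
# initial pose generation


class UndefinedSeparationAxisError(ValueError):
    pass


def slide_into_contact(
    pose: CoarsePose,
    contact_lo: float = 3.5,
    contact_hi: float = 4.5,
    step: float = 0.25,
    max_travel: float = 200.0,
) -> CoarsePose:
    """Translate the ligand along the centroid axis until the closest
    inter-chain coarse-atom distance first falls inside [contact_lo,
    contact_hi]; backs off one step on overshoot."""

    def min_dist(p: CoarsePose) -> float:
        a = np.vstack([r.coarse_coords() for r in p.receptor])
        b = np.vstack([r.coarse_coords() for r in p.ligand])
        return float(cdist(a, b).min())

    d0 = min_dist(pose)
    if contact_lo <= d0 <= contact_hi:
        return pose
    axis = pose.receptor_centroid() - pose.ligand_centroid()
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise UndefinedSeparationAxisError("undefined separation axis")
    axis = axis / norm
    direction = 1.0 if d0 > contact_hi else -1.0
    travelled = 0.0
    cur = pose
    prev = pose
    while travelled <= max_travel:
        prev = cur
        cur = cur.with_jump(
            RigidTransform.from_translation(direction * step * axis).compose(cur.jump)
        )
        travelled += step
        d = min_dist(cur)
        if contact_lo <= d <= contact_hi:
            return cur
        if direction > 0 and d < contact_lo:
            return prev  # back off one step on overshoot
        if direction < 0 and d > contact_hi:
            return prev
    raise RuntimeError("no contact achievable within travel limit")


def init_global(
    receptor: list[Residue], ligand: list[Residue], rng: np.random.Generator
) -> CoarsePose:
    """Blind global-docking start: both partners uniformly re-oriented about
    their centroids, ligand placed at a uniform random direction, then slid
    into contact."""
    rc = np.mean([r.CA for r in receptor], axis=0)
    lc = np.mean([r.CA for r in ligand], axis=0)
    Rr = random_rotation(rng)
    Rl = random_rotation(rng)
    receptor = [r.transformed(RigidTransform(Rr, rc - Rr @ rc)) for r in receptor]
    ligand = [r.transformed(RigidTransform(Rl, lc - Rl @ lc)) for r in ligand]

    def radius(res_list, c):
        coords = np.vstack([r.coarse_coords() for r in res_list])
        return float(np.linalg.norm(coords - c, axis=1).max())

    r_rec = radius(receptor, rc)
    r_lig = radius(ligand, lc)
    direction = random_axis(rng)
    target = rc + (r_rec + r_lig + 5.0) * direction
    shift = target - lc
    ligand = [r.transformed(RigidTransform.from_translation(shift)) for r in ligand]
    return slide_into_contact(CoarsePose(receptor, ligand))


def init_local(
    receptor: list[Residue],
    ligand: list[Residue],
    bound_reference: CoarsePose | None = None,
    rng: np.random.Generator | None = None,
    perturb: bool = True,
    separation: float = 15.0,
    rotation_deg: float = 45.0,
    perturb_trans_sigma: float = 1.0,
    perturb_rot_sigma_deg: float = 1.0,
) -> CoarsePose:
    """Local-docking start: ligand moved ``separation`` angstrom farther along
    the receptor-to-ligand centroid axis and rotated ``rotation_deg`` about
    that axis (through its centroid); optional Gaussian 1 A / 1 deg
    perturbation differentiates trajectories.

    If ``bound_reference`` is given, the monomers are first superposed onto
    their counterparts in the reference complex (backbone CA Kabsch).
    """
    from .geom import kabsch

    if bound_reference is not None:
        Tr, _ = kabsch(
            np.array([r.CA for r in receptor]),
            np.array([r.CA for r in bound_reference.receptor]),
        )
        receptor = [r.transformed(Tr) for r in receptor]
        Tl, _ = kabsch(
            np.array([r.CA for r in ligand]),
            np.array([r.CA for r in bound_reference.ligand]),
        )
        ligand = [r.transformed(Tl) for r in ligand]

    rc = np.mean([r.CA for r in receptor], axis=0)
    lc = np.mean([r.CA for r in ligand], axis=0)
    axis = lc - rc
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise UndefinedSeparationAxisError("undefined separation axis")
    axis = axis / norm

    pose = CoarsePose(receptor, ligand)
    sep = RigidTransform.from_translation(separation * axis)
    lc_after = lc + separation * axis
    spin = RigidTransform.from_rotvec(np.radians(rotation_deg) * axis, center=lc_after)
    jump = spin.compose(sep)
    if perturb:
        if rng is None:
            raise ValueError("perturb=True requires an rng")
        t = rng.normal(0.0, perturb_trans_sigma, size=3)
        p_axis = random_axis(rng)
        p_angle = np.radians(rng.normal(0.0, perturb_rot_sigma_deg))
        wiggle = RigidTransform.from_translation(t).compose(
            RigidTransform.from_rotvec(p_angle * p_axis, center=lc_after)
        )
        jump = wiggle.compose(jump)
    return pose.with_jump(jump.compose(pose.jump))
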