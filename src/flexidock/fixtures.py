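"""Synthetic structures and decoy sets for offline testing.

Chains are grown by internal-coordinate extension (NeRF) with ideal bond
lengths and angles, so dihedral extraction on the result is an exact
cross-check of the requested phi/psi/omega values.  Toy complexes emulate
unbound-to-bound conformational change by backrubbing a designated loop,
which makes the unbound/bound backbone deviation controllable and known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geom import RigidTransform, backrub_rotate, kabsch
from .structmodel import CoarsePose, Residue, virtual_cb

# ideal backbone internal coordinates (angstrom / degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.1

HELIX_PHI, HELIX_PSI = -57.0, -47.0
# outside both the helix and strand dihedral boxes -> labeled loop
LOOP_PHI, LOOP_PSI = (-150.0, 40.0)


def place_atom(a, b, c, length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position atom D given A-B-C, |C-D|, angle(B,C,D), dihedral(A,B,C,D)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(theta),
            length * np.sin(theta) * np.cos(chi),
            -length * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_chain(
    dihedrals: list[tuple[float, float]],
    chain_id: str = "A",
    sequence: str | None = None,
    omega: float = 180.0,
    start_seq_id: int = 1,
) -> list[Residue]:
    """Build a chain with the given per-residue (phi, psi) by NeRF extension.

    phi of the first residue and psi of the last are geometrically undefined
    at termini but are still consumed to place the final carbonyl.
    """
    n_res = len(dihedrals)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    sequence = sequence or "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match dihedral list")

    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res

    # seed residue 0 in a canonical orientation
    N[0] = np.zeros(3)
    CA[0] = np.array([B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])

    for i in range(1, n_res):
        psi_prev = dihedrals[i - 1][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, omega)
        phi_i = dihedrals[i][0]
        C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi_i)

    residues = []
    for i in range(n_res):
        psi_i = dihedrals[i][1]
        # carbonyl O: anti to the next N, i.e. torsion psi+180 about N-CA-C
        O = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi_i + 180.0)
        aa = sequence[i]
        cb = virtual_cb(N[i], CA[i], C[i])
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_id=start_seq_id + i,
                aa=aa,
                N=N[i],
                CA=CA[i],
                C=C[i],
                O=O,
                CB=cb,
                centroid=CA[i].copy() if aa == "G" else cb.copy(),
                cb_is_virtual=(aa == "G"),
            )
        )
    return residues


def make_helix(n_res: int, sequence: str | None = None, chain_id: str = "A") -> list[Residue]:
    """Ideal alpha helix (phi -57, psi -47, omega 180)."""
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    return make_chain([(HELIX_PHI, HELIX_PSI)] * n_res, chain_id=chain_id, sequence=sequence)


def make_helix_loop(
    helix_len: int,
    loop_len: int,
    chain_id: str = "A",
    sequence: str | None = None,
) -> tuple[list[Residue], list[int]]:
    """Helix with a C-terminal loop tail; returns (residues, loop index list)."""
    dihedrals = [(HELIX_PHI, HELIX_PSI)] * helix_len + [(LOOP_PHI, LOOP_PSI)] * loop_len
    res = make_chain(dihedrals, chain_id=chain_id, sequence=sequence)
    return res, list(range(helix_len, helix_len + loop_len))


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a synthetic two-chain docking fixture."""

    receptor_helix_len: int = 14
    receptor_loop_len: int = 5
    ligand_len: int = 10
    backrub_angle: float = 0.0  # applied to the receptor loop to make the unbound form
    contact_gap: tuple[float, float] = (4.0, 4.45)  # closest inter-chain atom distance window
    seed: int = 0


def _min_interchain_distance(rec: list[Residue], lig: list[Residue]) -> float:
    from scipy.spatial.distance import cdist

    a = np.vstack([r.coarse_coords() for r in rec])
    b = np.vstack([r.coarse_coords() for r in lig])
    return float(cdist(a, b).min())


def make_toy_complex(spec: ToyComplexSpec) -> tuple[list[Residue], list[Residue], CoarsePose]:
    """Build (unbound receptor, unbound ligand, bound complex).

    The bound complex is a receptor helix (with loop tail) packed against a
    ligand helix at van der Waals contact.  The unbound receptor differs
    from its bound form by a backrub of the loop by ``spec.backrub_angle``
    degrees, so the unbound-to-bound deviation is controlled exactly.
    """
    receptor, loop_idx = make_helix_loop(
        spec.receptor_helix_len, spec.receptor_loop_len, chain_id="A"
    )
    ligand = make_helix(spec.ligand_len, chain_id="B")
    ligand = [r.replace(seq_id=r.seq_id) for r in ligand]

    # orient ligand helix axis roughly parallel to the receptor helix and
    # offset it sideways, then close the gap to the contact window
    rec_ca = np.array([r.CA for r in receptor[: spec.receptor_helix_len]])
    axis = rec_ca[-1] - rec_ca[0]
    axis /= np.linalg.norm(axis)
    lig_ca = np.array([r.CA for r in ligand])
    lig_axis = lig_ca[-1] - lig_ca[0]
    lig_axis /= np.linalg.norm(lig_axis)
    # rotate ligand so its axis aligns with the receptor axis
    v = np.cross(lig_axis, axis)
    s = np.linalg.norm(v)
    if s > 1e-9:
        angle = np.arctan2(s, float(lig_axis @ axis))
        T_align = RigidTransform.from_rotvec(angle * v / s, center=lig_ca.mean(axis=0))
        ligand = [r.transformed(T_align) for r in ligand]

    # sideways offset: perpendicular to the helix axis and pointing away from
    # the loop tail, so the ligand docks against the helix face
    helix_center = rec_ca.mean(axis=0)
    loop_center = np.mean([receptor[i].CA for i in loop_idx], axis=0)
    away = helix_center - loop_center
    perp = away - (away @ axis) * axis
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    target = helix_center + 20.0 * perp
    shift = target - np.mean([r.CA for r in ligand], axis=0)
    ligand = [r.transformed(RigidTransform.from_translation(shift)) for r in ligand]

    # bisection on the approach distance to land in the contact window
    lo_gap, hi_gap = spec.contact_gap
    lo, hi = 0.0, 25.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        moved = [r.transformed(RigidTransform.from_translation(-mid * perp)) for r in ligand]
        d = _min_interchain_distance(receptor, moved)
        if d > hi_gap:
            lo = mid
        elif d < lo_gap:
            hi = mid
        else:
            ligand = moved
            break
    else:
        raise RuntimeError("could not place ligand in contact window")

    bound = CoarsePose(receptor, ligand)

    # unbound monomers: backrub the receptor loop to emulate induced fit
    if spec.backrub_angle != 0.0 and spec.receptor_loop_len >= 3:
        pivot_first = loop_idx[0] - 1  # last helix residue anchors the loop
        pivot_last = loop_idx[-1]
        unbound_receptor = backrub_rotate(receptor, pivot_first, pivot_last, spec.backrub_angle)
    else:
        unbound_receptor = list(receptor)
    unbound_ligand = list(ligand)
    return unbound_receptor, unbound_ligand, bound


@dataclass(frozen=True)
class DecoyRow:
    serial: int
    score: float
    near_native: bool


def make_decoy_set(
    n: int, near_native_fraction: float, score_signal: float, seed: int = 0
) -> list[DecoyRow]:
    """Synthetic scored/flagged candidates with tunable flag-score association.

    ``score_signal`` 0 makes scores independent of the near-native flag;
    1 makes every near-native candidate score below every other.
    """
    if n < 5:
        raise ValueError("need at least 5 candidates")
    if not 0.0 <= near_native_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not 0.0 <= score_signal <= 1.0:
        raise ValueError("score_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_near = int(round(near_native_fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_near, replace=False)] = True
    u = rng.uniform(0.0, 1.0, size=n)
    scores = u - 2.0 * score_signal * flags
    return [DecoyRow(i, float(scores[i]), bool(flags[i])) for i in range(n)]


def funnel_energy_factory(
    native_pose: CoarsePose,
    width: float = 4.0,
    depth: float = 25.0,
    clash_weight: float = 1.0,
    clash_dist: float = 3.5,
    tether: float = 0.3,
):
    """Smooth funnel energy with its global minimum at the native pose.

    energy = depth * (1 - exp(-lrmsd^2 / width^2)) + tether * lrmsd
             + soft CA clash penalty.
    The lrmsd here is the ligand backbone RMSD after receptor-CA
    superposition, mirroring the evaluation metric.  The linear tether keeps
    the landscape strictly monotone in lrmsd beyond the funnel width so hot
    replicas cannot diffuse away on a plateau.  Usable wherever the
    composite docking score is.
    """
    native_rec_ca = np.array([r.CA for r in native_pose.receptor])
    native_lig_bb = np.vstack([r.backbone_coords() for r in native_pose.ligand])

    # poses share residue tuples copy-on-write, so derived arrays and the
    # receptor superposition can be cached per tuple identity
    rec_cache: dict = {}
    lig_cache: dict = {}

    def _receptor_data(pose: CoarsePose):
        key = id(pose.receptor)
        hit = rec_cache.get(key)
        if hit is None or hit[0] is not pose.receptor:
            if len(rec_cache) > 512:
                rec_cache.clear()
            rec_ca = np.array([r.CA for r in pose.receptor])
            T, _ = kabsch(rec_ca, native_rec_ca)
            rec_cache[key] = hit = (pose.receptor, rec_ca, T)
        return hit[1], hit[2]

    def _ligand_local_bb(pose: CoarsePose):
        key = id(pose.ligand_local)
        hit = lig_cache.get(key)
        if hit is None or hit[0] is not pose.ligand_local:
            if len(lig_cache) > 512:
                lig_cache.clear()
            arr = np.vstack([r.backbone_coords() for r in pose.ligand_local])
            lig_cache[key] = hit = (pose.ligand_local, arr)
        return hit[1]

    def energy(pose: CoarsePose) -> float:
        rec_ca, T = _receptor_data(pose)
        lig_bb = pose.jump.apply(_ligand_local_bb(pose))
        moved = T.apply(lig_bb)
        lrmsd2 = float(np.mean(np.sum((moved - native_lig_bb) ** 2, axis=1)))
        e = depth * (1.0 - np.exp(-lrmsd2 / width**2)) + tether * math.sqrt(lrmsd2)
        # soft clash: quadratic penalty on CA pairs inside clash_dist
        lig_ca = lig_bb[1::4]
        d2 = np.sum((rec_ca[:, None, :] - lig_ca[None, :, :]) ** 2, axis=-1)
        close = d2 < clash_dist**2
        if close.any():
            overlap = clash_dist - np.sqrt(d2[close])
            e += clash_weight * float(np.sum(overlap**2))
        return float(e)

    return energy
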