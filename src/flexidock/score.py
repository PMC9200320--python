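"""Low-resolution composite docking energy and its per-term breakdown.

The total is a weighted sum of an inter-chain residue-pair-transform term,
split Lennard-Jones clash/attraction terms over the coarse atoms, and
knowledge-based backbone torsion statistics (phi/psi propensity, omega
planarity, amino-acid-given-torsion propensity).

The pair-transform term ships three ways: exact binned-lookup machinery
(:class:`PairTransformTable`), a builder that trains a table on any set of
complexes, and a smooth analytic surrogate well used as the no-download
default.  The torsion surfaces are analytic mixtures of periodic bumps per
residue class (general / glycine / proline / pre-proline), normalized on a
grid so densities integrate to one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .geom import PairTransform, pair_transform, random_rotation, RigidTransform
from .structmodel import CoarsePose, Residue, backbone_dihedrals

# ---------------------------------------------------------------------------
# weights and breakdown


@dataclass(frozen=True)
class ScoreWeights:
    """Dimensionless multipliers of the composite energy terms.

    Defaults follow the reduced (0.1x) weighting of the non-pair-transform
    terms; all are config-exposed.
    """

    w_motif: float = 1.0
    w_lj_rep: float = 0.1
    w_lj_attr: float = 0.1
    w_rama: float = 0.1
    w_omega: float = 0.1
    w_aa_propensity: float = 0.1


@dataclass(frozen=True)
class ScoreBreakdown:
    e_motif: float
    e_lj_rep: float
    e_lj_attr: float
    e_rama: float
    e_omega: float
    e_aa_propensity: float
    total: float

    def terms(self) -> dict[str, float]:
        return {
            "e_motif": self.e_motif,
            "e_lj_rep": self.e_lj_rep,
            "e_lj_attr": self.e_lj_attr,
            "e_rama": self.e_rama,
            "e_omega": self.e_omega,
            "e_aa_propensity": self.e_aa_propensity,
        }


# ---------------------------------------------------------------------------
# Lennard-Jones clash / attraction over coarse atoms


@dataclass(frozen=True)
class LJParams:
    epsilon: float = 0.2
    # per-atom-type r_min/2 style radii; pair r_min is the sum
    radii: dict = field(
        default_factory=lambda: {
            "N": 1.55, "CA": 1.85, "C": 1.70, "O": 1.45, "CB": 1.90, "centroid": 2.10,
        }
    )
    cutoff: float = 8.0
    cap_frac: float = 0.6  # below cap_frac * r_min the repulsion continues linearly
    min_seq_sep: int = 5  # intra-chain pairs need |i - j| > 4


_ATOM_ORDER = ("N", "CA", "C", "O", "CB", "centroid")


def _atom_arrays(groups: list[list[Residue]], params: LJParams):
    """Flatten residue groups to coords / radii / group index / residue serial."""
    coords, radii, gidx, ridx = [], [], [], []
    serial = 0
    for g, residues in enumerate(groups):
        for res in residues:
            for name in _ATOM_ORDER:
                v = getattr(res, name)
                if v is None:
                    continue
                if name == "centroid" and res.aa == "G":
                    continue  # glycine centroid duplicates CA
                coords.append(v)
                radii.append(params.radii[name])
                gidx.append(g)
                ridx.append(serial)
            serial += 1
    return (
        np.asarray(coords, float),
        np.asarray(radii, float),
        np.asarray(gidx, int),
        np.asarray(ridx, int),
    )


def _lj_split(d: np.ndarray, rmin: np.ndarray, params: LJParams):
    """Vectorized 6-12 LJ split into a non-negative repulsive part (shifted so
    it is zero at r_min, linearly extended below cap_frac*r_min) and a
    non-positive attractive part for r_min <= r < cutoff."""
    eps = params.epsilon
    rep = np.zeros_like(d)
    attr = np.zeros_like(d)

    below = d < rmin
    cap = params.cap_frac * rmin
    mid = below & (d >= cap)
    x = rmin[mid] / d[mid]
    rep[mid] = eps * (x**12 - 2.0 * x**6 + 1.0)

    low = d < cap
    if low.any():
        xc = 1.0 / params.cap_frac
        e_cap = eps * (xc**12 - 2.0 * xc**6 + 1.0)
        # slope of the LJ at the cap point (positive going inward)
        slope = eps * 12.0 * (xc**12 - xc**6) / cap[low]
        rep[low] = e_cap + slope * (cap[low] - d[low])

    mask_attr = (d >= rmin) & (d < params.cutoff)
    x = rmin[mask_attr] / d[mask_attr]
    attr[mask_attr] = eps * (x**12 - 2.0 * x**6)
    return rep, attr


def lj_terms(
    pose_or_groups, params: LJParams | None = None
) -> tuple[float, float]:
    """(e_rep, e_attr) summed over inter-chain pairs and intra-chain pairs
    separated by more than 4 residues, over the coarse atoms."""
    params = params or LJParams()
    if isinstance(pose_or_groups, CoarsePose):
        groups = [list(pose_or_groups.receptor), list(pose_or_groups.ligand)]
    else:
        groups = [list(g) for g in pose_or_groups]
    coords, radii, gidx, ridx = _atom_arrays(groups, params)
    n = len(coords)
    if n < 2:
        return 0.0, 0.0
    d = cdist(coords, coords)
    rmin = radii[:, None] + radii[None, :]
    same_group = gidx[:, None] == gidx[None, :]
    seq_sep = np.abs(ridx[:, None] - ridx[None, :])
    pair_ok = (~same_group) | (seq_sep >= params.min_seq_sep)
    iu = np.triu_indices(n, k=1)
    sel = pair_ok[iu] & (d[iu] < params.cutoff)
    dv = d[iu][sel]
    rv = rmin[iu][sel]
    if dv.size == 0:
        return 0.0, 0.0
    rep, attr = _lj_split(dv, rv, params)
    return float(rep.sum()), float(attr.sum())


# ---------------------------------------------------------------------------
# backbone torsion statistics (analytic surrogate surfaces)


@dataclass(frozen=True)
class TorsionParams:
    omega_k: float = 2.0  # per squared radian of deviation from planarity
    kappa: float = 8.0  # concentration of the phi/psi bumps
    floor: float = 1e-4  # uniform floor density mixed into every surface


# (weight, phi0, psi0) basins per residue class, degrees
_RAMA_BASINS: dict[str, list[tuple[float, float, float]]] = {
    "general": [
        (0.40, -63.0, -43.0),
        (0.35, -120.0, 130.0),
        (0.15, -90.0, 120.0),
        (0.10, 60.0, 45.0),
    ],
    "glycine": [
        (0.25, -63.0, -43.0),
        (0.25, 63.0, 43.0),
        (0.25, -120.0, 130.0),
        (0.25, 80.0, -170.0),
    ],
    "proline": [
        (0.50, -63.0, -35.0),
        (0.50, -65.0, 150.0),
    ],
    "prepro": [
        (0.35, -63.0, -43.0),
        (0.40, -120.0, 130.0),
        (0.25, -130.0, 75.0),
    ],
}

_CLASS_OF_AA = {"G": "glycine", "P": "proline"}


def rama_class(aa: str, next_aa: str | None = None) -> str:
    """Residue class for the torsion surface; pre-proline context wins."""
    if next_aa == "P" and aa not in ("G", "P"):
        return "prepro"
    return _CLASS_OF_AA.get(aa, "general")


class _RamaSurface:
    """Normalized mixture-of-periodic-bumps density over (phi, psi)."""

    def __init__(self, params: TorsionParams):
        self.params = params
        self._norm: dict[str, float] = {}
        grid = np.arange(-177.5, 180.0, 5.0)
        pp, ss = np.meshgrid(grid, grid, indexing="ij")
        cell = np.radians(5.0) ** 2
        for cls in _RAMA_BASINS:
            dens = self._raw(cls, pp, ss)
            self._norm[cls] = float(np.sum(dens) * cell)

    def _raw(self, cls: str, phi, psi):
        k = self.params.kappa
        phi_r, psi_r = np.radians(phi), np.radians(psi)
        dens = np.full_like(np.asarray(phi_r, float), self.params.floor)
        for w, p0, s0 in _RAMA_BASINS[cls]:
            dens = dens + w * np.exp(
                k * (np.cos(phi_r - math.radians(p0)) - 1.0)
                + k * (np.cos(psi_r - math.radians(s0)) - 1.0)
            )
        return dens

    def density(self, cls: str, phi: float, psi: float) -> float:
        return float(self._raw(cls, phi, psi) / self._norm[cls])

    def peak(self, cls: str) -> tuple[float, float, float]:
        """(phi, psi, density) at the dominant basin center."""
        w, p0, s0 = max(_RAMA_BASINS[cls], key=lambda b: b[0])
        return p0, s0, self.density(cls, p0, s0)


_SURFACE_CACHE: dict[TorsionParams, _RamaSurface] = {}


def rama_surface(params: TorsionParams | None = None) -> _RamaSurface:
    params = params or TorsionParams()
    if params not in _SURFACE_CACHE:
        _SURFACE_CACHE[params] = _RamaSurface(params)
    return _SURFACE_CACHE[params]


def torsion_stats(
    residues, params: TorsionParams | None = None
) -> tuple[float, float, float]:
    """(e_rama, e_omega, e_aa_propensity); undefined dihedrals contribute 0."""
    params = params or TorsionParams()
    surf = rama_surface(params)
    residues = list(residues)
    if len(residues) < 2:
        return 0.0, 0.0, 0.0
    dihedrals = backbone_dihedrals(residues)
    e_rama = e_omega = e_aa = 0.0
    classes = list(_RAMA_BASINS)
    for i, (res, rec) in enumerate(zip(residues, dihedrals)):
        nxt = residues[i + 1].aa if i + 1 < len(residues) else None
        cls = rama_class(res.aa, nxt)
        if rec.phi is not None and rec.psi is not None:
            e_rama += -math.log(surf.density(cls, rec.phi, rec.psi))
            # p(aa-class | phi, psi) with a uniform class prior
            dens = {c: surf.density(c, rec.phi, rec.psi) for c in classes}
            e_aa += -math.log(dens[cls] / sum(dens.values()))
        if rec.omega is not None:
            om = math.radians(rec.omega)
            d_trans = math.atan2(math.sin(om - math.pi), math.cos(om - math.pi))
            d_cis = math.atan2(math.sin(om), math.cos(om))
            e_omega += params.omega_k * min(d_trans**2, d_cis**2)
    return e_rama, e_omega, e_aa


# ---------------------------------------------------------------------------
# residue-pair-transform scoring


class PairScoreBase:
    """Interface shared by the trained table and the analytic surrogate."""

    max_ca_dist: float

    def score_pair(self, pt: PairTransform, aa_a: str, aa_b: str) -> float:
        raise NotImplementedError


@dataclass
class PairTableSpec:
    """Binning of the 6-D transform space (config-exposed, non-canonical)."""

    max_ca_dist: float = 10.0
    trans_bin: float = 1.0  # angstrom per translation bin, range +/- max_ca_dist
    rot_bin_deg: float = 30.0  # degrees per rotation-vector-component bin
    pseudocount: float = 1.0


class PairTransformTable(PairScoreBase):
    """Sparse binned 6-D score: value per (aa-pair-class, bin tuple).

    Out-of-range transforms and unseen bins score 0 (no interaction).
    """

    def __init__(self, spec: PairTableSpec, scores: dict | None = None, meta: dict | None = None):
        self.spec = spec
        self.max_ca_dist = spec.max_ca_dist
        self.scores: dict[tuple, float] = scores or {}
        self.meta = meta or {}

    def _bin(self, pt: PairTransform) -> tuple | None:
        s = self.spec
        if pt.distance > s.max_ca_dist:
            return None
        tb = tuple(int(math.floor(v / s.trans_bin)) for v in pt.translation)
        rb = tuple(int(math.floor(math.degrees(v) / s.rot_bin_deg)) for v in pt.rotation)
        return tb + rb

    def key(self, pt: PairTransform, aa_a: str, aa_b: str) -> tuple | None:
        b = self._bin(pt)
        if b is None:
            return None
        return (aa_a, aa_b) + b

    def score_pair(self, pt: PairTransform, aa_a: str, aa_b: str) -> float:
        k = self.key(pt, aa_a, aa_b)
        if k is None:
            return 0.0
        return self.scores.get(k, 0.0)

    # -- serialization (pure JSON container) --
    def to_json(self) -> str:
        payload = {
            "spec": {
                "max_ca_dist": self.spec.max_ca_dist,
                "trans_bin": self.spec.trans_bin,
                "rot_bin_deg": self.spec.rot_bin_deg,
                "pseudocount": self.spec.pseudocount,
            },
            "meta": self.meta,
            "scores": [[list(k[:2]) + list(k[2:]), v] for k, v in self.scores.items()],
        }
        return json.dumps(payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "PairTransformTable":
        try:
            payload = json.loads(text)
            spec = PairTableSpec(**payload["spec"])
            scores = {}
            for k, v in payload["scores"]:
                scores[(k[0], k[1]) + tuple(int(x) for x in k[2:])] = float(v)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed pair-transform table: {exc}") from exc
        return cls(spec, scores, payload.get("meta", {}))

    @classmethod
    def load(cls, path: str | Path) -> "PairTransformTable":
        return cls.from_json(Path(path).read_text())


class SurrogatePairScore(PairScoreBase):
    """Smooth analytic orientation/distance well; the no-download default.

    A Gaussian well centred at a typical contact distance, modulated by the
    relative-rotation magnitude.  Rigid-motion invariant by construction
    (it only sees the pair transform).
    """

    def __init__(
        self,
        depth: float = 1.0,
        d0: float = 6.0,
        sigma: float = 2.0,
        max_ca_dist: float = 10.0,
    ):
        self.depth = depth
        self.d0 = d0
        self.sigma = sigma
        self.max_ca_dist = max_ca_dist

    def score_pair(self, pt: PairTransform, aa_a: str, aa_b: str) -> float:
        d = pt.distance
        if d > self.max_ca_dist:
            return 0.0
        radial = math.exp(-((d - self.d0) ** 2) / (2.0 * self.sigma**2))
        angular = 0.5 * (1.0 + math.cos(pt.angle))
        return -self.depth * radial * (0.25 + 0.75 * angular)


def _interacting_pairs(pose: CoarsePose, max_ca_dist: float):
    rec = pose.receptor
    lig = pose.ligand
    ca_r = np.array([r.CA for r in rec])
    ca_l = np.array([r.CA for r in lig])
    d = cdist(ca_r, ca_l)
    for i, j in zip(*np.where(d <= max_ca_dist)):
        yield rec[i], lig[j]


def pair_transform_score(pose: CoarsePose, table: PairScoreBase) -> float:
    """Inter-chain pair-transform score over CA-CA contacts within table range."""
    total = 0.0
    for ra, rb in _interacting_pairs(pose, table.max_ca_dist):
        total += table.score_pair(pair_transform(ra, rb), ra.aa, rb.aa)
    return float(total)


class NoContactsError(ValueError):
    pass


def build_pair_table(
    complexes: list[CoarsePose],
    spec: PairTableSpec | None = None,
    pseudocount: float | None = None,
    n_background: int = 30,
    seed: int = 0,
) -> PairTransformTable:
    """Train a binned pair-transform table on a set of complexes.

    Bin scores are ``-log[(count + pc) / (expected + pc)]`` where the
    expected counts come from a shuffled-orientation background: the ligand
    of each training complex is rigidly re-oriented at random (rotation
    about its centroid) ``n_background`` times and contacts are re-counted,
    then rescaled to match the observed total.
    """
    spec = spec or PairTableSpec()
    pc = spec.pseudocount if pseudocount is None else pseudocount
    rng = np.random.default_rng(seed)
    table = PairTransformTable(spec)

    counts: dict[tuple, float] = {}
    bg: dict[tuple, float] = {}
    n_obs = 0
    n_bg = 0
    for pose in complexes:
        for ra, rb in _interacting_pairs(pose, spec.max_ca_dist):
            k = table.key(pair_transform(ra, rb), ra.aa, rb.aa)
            if k is not None:
                counts[k] = counts.get(k, 0.0) + 1.0
                n_obs += 1
        for _ in range(n_background):
            c = pose.ligand_centroid()
            R = random_rotation(rng)
            T = RigidTransform(R, c - R @ c)
            shuffled = pose.with_jump(T.compose(pose.jump))
            for ra, rb in _interacting_pairs(shuffled, spec.max_ca_dist):
                k = table.key(pair_transform(ra, rb), ra.aa, rb.aa)
                if k is not None:
                    bg[k] = bg.get(k, 0.0) + 1.0
                    n_bg += 1
    if n_obs == 0:
        raise NoContactsError("no inter-chain contacts in training set")
    scale = n_obs / n_bg if n_bg else 1.0
    scores = {}
    for k in set(counts) | set(bg):
        expected = bg.get(k, 0.0) * scale
        scores[k] = -math.log((counts.get(k, 0.0) + pc) / (expected + pc))
    table.scores = scores
    table.meta = {"n_complexes": len(complexes), "n_observed_pairs": n_obs}
    return table


# ---------------------------------------------------------------------------
# composite score


def muds(
    pose: CoarsePose,
    weights: ScoreWeights | None = None,
    table: PairScoreBase | None = None,
    lj_params: LJParams | None = None,
    torsion_params: TorsionParams | None = None,
) -> ScoreBreakdown:
    """Composite low-resolution energy with per-term breakdown."""
    weights = weights or ScoreWeights()
    table = table or SurrogatePairScore()
    e_motif = pair_transform_score(pose, table) if weights.w_motif != 0.0 else 0.0
    e_rep, e_attr = lj_terms(pose, lj_params)
    t_rec = torsion_stats(pose.receptor, torsion_params)
    t_lig = torsion_stats(pose.ligand, torsion_params)
    e_rama = t_rec[0] + t_lig[0]
    e_omega = t_rec[1] + t_lig[1]
    e_aa = t_rec[2] + t_lig[2]
    total = (
        weights.w_motif * e_motif
        + weights.w_lj_rep * e_rep
        + weights.w_lj_attr * e_attr
        + weights.w_rama * e_rama
        + weights.w_omega * e_omega
        + weights.w_aa_propensity * e_aa
    )
    return ScoreBreakdown(e_motif, e_rep, e_attr, e_rama, e_omega, e_aa, total)


def _rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    """Rotation vector (radians) from a proper rotation matrix (fast path)."""
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    cos_t = max(-1.0, min(1.0, (tr - 1.0) / 2.0))
    theta = math.acos(cos_t)
    if theta < 1e-8:
        return np.zeros(3)
    if theta > math.pi - 1e-6:
        # near 180 deg: axis from the symmetric part
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.maximum(np.diag(A), 0.0))
        # fix signs using off-diagonals
        if axis[0] > 0:
            axis[1] = math.copysign(axis[1], A[0, 1])
            axis[2] = math.copysign(axis[2], A[0, 2])
        elif axis[1] > 0:
            axis[2] = math.copysign(axis[2], A[1, 2])
        n = np.linalg.norm(axis)
        return theta * axis / n if n > 0 else np.zeros(3)
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return theta * axis / (2.0 * math.sin(theta))


class MudsEnergy:
    """Cached composite-score evaluator for the Monte Carlo hot path.

    Poses share residue tuples copy-on-write, so all intra-partner terms
    (torsion statistics, intra-chain LJ) and per-residue frames are cached
    per partner tuple; only the inter-chain LJ and pair-transform terms are
    recomputed per call.  The ligand is handled in its local frame with the
    jump applied to flat coordinate arrays, so rigid-body moves never touch
    residue objects.  Totals agree with :func:`muds` to float precision.
    """

    def __init__(
        self,
        weights: ScoreWeights | None = None,
        table: PairScoreBase | None = None,
        lj_params: LJParams | None = None,
        torsion_params: TorsionParams | None = None,
    ):
        self.weights = weights or ScoreWeights()
        self.table = table or SurrogatePairScore()
        self.lj_params = lj_params or LJParams()
        self.torsion_params = torsion_params or TorsionParams()
        self._cache: dict[int, tuple] = {}

    def _static(self, residues: tuple):
        key = id(residues)
        hit = self._cache.get(key)
        if hit is not None and hit[0] is residues:
            return hit[1]
        if len(self._cache) > 256:
            self._cache.clear()
        params = self.lj_params
        coords, radii, _, ridx = _atom_arrays([list(residues)], params)
        rep, attr = lj_terms([list(residues)], params)
        tors = torsion_stats(residues, self.torsion_params)
        ca = np.array([r.CA for r in residues])
        from .geom import residue_frame

        frames = []
        for r in residues:
            f = residue_frame(r)
            frames.append((f.rotation, f.translation))
        aas = [r.aa for r in residues]
        data = {
            "coords": coords, "radii": radii, "ridx": ridx,
            "lj_intra": (rep, attr), "tors": tors, "ca": ca,
            "frames": frames, "aa": aas,
        }
        self._cache[key] = (residues, data)
        return data

    def _inter_lj(self, a: dict, b_coords: np.ndarray, b_radii: np.ndarray):
        params = self.lj_params
        d = cdist(a["coords"], b_coords)
        rmin = a["radii"][:, None] + b_radii[None, :]
        sel = d < params.cutoff
        if not sel.any():
            return 0.0, 0.0
        rep, attr = _lj_split(d[sel], rmin[sel], params)
        return float(rep.sum()), float(attr.sum())

    def breakdown(self, pose: CoarsePose) -> ScoreBreakdown:
        w = self.weights
        rec = self._static(pose.receptor)
        lig = self._static(pose.ligand_local)
        R = pose.jump.rotation
        t = pose.jump.translation

        lig_coords = lig["coords"] @ R.T + t
        rep_i, attr_i = self._inter_lj(rec, lig_coords, lig["radii"])
        e_rep = rec["lj_intra"][0] + lig["lj_intra"][0] + rep_i
        e_attr = rec["lj_intra"][1] + lig["lj_intra"][1] + attr_i
        e_rama = rec["tors"][0] + lig["tors"][0]
        e_omega = rec["tors"][1] + lig["tors"][1]
        e_aa = rec["tors"][2] + lig["tors"][2]

        e_motif = 0.0
        if w.w_motif != 0.0:
            ca_lig = lig["ca"] @ R.T + t
            d = cdist(rec["ca"], ca_lig)
            rng_max = self.table.max_ca_dist
            for i, j in zip(*np.where(d <= rng_max)):
                Ra, ta = rec["frames"][i]
                Rb, tb = lig["frames"][j]
                # global frame of ligand residue j: jump o local frame
                Rbg = R @ Rb
                tbg = R @ tb + t
                rel_rot = Ra.T @ Rbg
                rel_t = Ra.T @ (tbg - ta)
                pt = PairTransform(rel_t, _rotvec_from_matrix(rel_rot))
                e_motif += self.table.score_pair(pt, rec["aa"][i], lig["aa"][j])

        total = (
            w.w_motif * e_motif
            + w.w_lj_rep * e_rep
            + w.w_lj_attr * e_attr
            + w.w_rama * e_rama
            + w.w_omega * e_omega
            + w.w_aa_propensity * e_aa
        )
        return ScoreBreakdown(e_motif, e_rep, e_attr, e_rama, e_omega, e_aa, total)

    def __call__(self, pose: CoarsePose) -> float:
        return self.breakdown(pose).total


def refinement_score(
    pose_or_groups,
    weights: ScoreWeights | None = None,
    lj_params: LJParams | None = None,
    torsion_params: TorsionParams | None = None,
) -> float:
    """LJ + torsion terms only (no pair-transform term); used in refinement."""
    weights = weights or ScoreWeights()
    if isinstance(pose_or_groups, CoarsePose):
        groups = [list(pose_or_groups.receptor), list(pose_or_groups.ligand)]
    else:
        groups = [list(g) for g in pose_or_groups]
    e_rep, e_attr = lj_terms(groups, lj_params)
    e_rama = e_omega = e_aa = 0.0
    for g in groups:
        r, o, a = torsion_stats(g, torsion_params)
        e_rama += r
        e_omega += o
        e_aa += a
    return (
        weights.w_lj_rep * e_rep
        + weights.w_lj_attr * e_attr
        + weights.w_rama * e_rama
        + weights.w_omega * e_omega
        + weights.w_aa_propensity * e_aa
    )


def interface_score(
    pose: CoarsePose,
    weights: ScoreWeights | None = None,
    lj_params: LJParams | None = None,
    torsion_params: TorsionParams | None = None,
) -> float:
    """Binding-energy-like quantity: score(complex) - score(receptor) - score(ligand).

    Computed with the refinement score; intra-partner contributions cancel,
    so separated chains give ~0 and clashing poses give positive values.
    """
    e_ab = refinement_score(pose, weights, lj_params, torsion_params)
    e_a = refinement_score([list(pose.receptor)], weights, lj_params, torsion_params)
    e_b = refinement_score([list(pose.ligand)], weights, lj_params, torsion_params)
    return e_ab - e_a - e_b
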