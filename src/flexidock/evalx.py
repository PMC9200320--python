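"""Docking quality metrics, difficulty classes, enrichment, and bootstrap N5.

Implements the standard complex-prediction quality measures — fraction of
native contacts, interface/ligand/whole-complex RMSDs, the four-level
quality rank derived from them — plus the bootstrap expected-N5 success
statistic: resample the candidate set with replacement, count near-native
models among the five top-scoring, and average over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geom import kabsch
from .structmodel import CoarsePose, Residue

LOWRES_NEAR_NATIVE_CA_RMSD = 5.0  # angstrom


@dataclass(frozen=True)
class CapriThresholds:
    """Quality-rank boundaries (standard values, config-exposed)."""

    fnat_contact_cutoff: float = 5.0  # angstrom, any coarse-atom pair
    interface_cutoff: float = 10.0  # native-interface residue definition
    acceptable: tuple[float, float, float] = (0.1, 10.0, 4.0)  # fnat, lrmsd, irmsd
    medium: tuple[float, float, float] = (0.3, 5.0, 2.0)
    high: tuple[float, float, float] = (0.5, 1.0, 1.0)


@dataclass(frozen=True)
class DockMetrics:
    fnat: float
    irmsd: float
    lrmsd: float
    ca_rmsd: float
    capri_rank: int  # 0 incorrect, 1 acceptable, 2 medium, 3 high


class NoNativeInterfaceError(ValueError):
    pass


def _residue_map(residues) -> dict[tuple[str, int], Residue]:
    return {r.key: r for r in residues}


def _paired(pred_res, native_res) -> list[tuple[Residue, Residue]]:
    pm = _residue_map(pred_res)
    return [(pm[r.key], r) for r in native_res if r.key in pm]


def _contacts(pose: CoarsePose, cutoff: float) -> set[tuple]:
    rec, lig = pose.receptor, pose.ligand
    rc = [r.coarse_coords() for r in rec]
    lc = [r.coarse_coords() for r in lig]
    a = np.vstack(rc)
    b = np.vstack(lc)
    ai = np.repeat(np.arange(len(rec)), [len(c) for c in rc])
    bi = np.repeat(np.arange(len(lig)), [len(c) for c in lc])
    close = cdist(a, b) <= cutoff
    out = set()
    ii, jj = np.where(close)
    for i, j in zip(ai[ii], bi[jj]):
        out.add((rec[i].key, lig[j].key))
    return out


def fnat(pred: CoarsePose, native: CoarsePose, cutoff: float = 5.0) -> float:
    """Fraction of the native inter-chain residue contacts present in ``pred``."""
    native_contacts = _contacts(native, cutoff)
    if not native_contacts:
        raise NoNativeInterfaceError("no native interface")
    pred_contacts = _contacts(pred, cutoff)
    return len(native_contacts & pred_contacts) / len(native_contacts)


def _backbone_stack(pairs: list[tuple[Residue, Residue]]):
    pred = np.vstack([p.backbone_coords() for p, _ in pairs])
    nat = np.vstack([n.backbone_coords() for _, n in pairs])
    return pred, nat


def lrmsd(pred: CoarsePose, native: CoarsePose) -> float:
    """Ligand backbone RMSD after superposing the receptors (backbone Kabsch)."""
    rec_pairs = _paired(pred.receptor, native.receptor)
    lig_pairs = _paired(pred.ligand, native.ligand)
    if len(rec_pairs) < 3 or not lig_pairs:
        raise ValueError("insufficient residue correspondence")
    rp, rn = _backbone_stack(rec_pairs)
    T, _ = kabsch(rp, rn)
    lp, ln = _backbone_stack(lig_pairs)
    moved = T.apply(lp)
    return float(np.sqrt(np.mean(np.sum((moved - ln) ** 2, axis=1))))


def interface_residue_keys(native: CoarsePose, cutoff: float = 10.0) -> set[tuple[str, int]]:
    """Native-interface residues: any coarse atom within ``cutoff`` of the partner."""
    keys = set()
    for rk, lk in _contacts(native, cutoff):
        keys.add(rk)
        keys.add(lk)
    return keys


def irmsd(pred: CoarsePose, native: CoarsePose, interface_cutoff: float = 10.0) -> float:
    """Backbone RMSD over native-interface residues after superposing on them."""
    keys = interface_residue_keys(native, interface_cutoff)
    if not keys:
        raise NoNativeInterfaceError("no native interface")
    pairs = [
        pr
        for pr in _paired(pred.all_residues(), native.all_residues())
        if pr[1].key in keys
    ]
    if len(pairs) < 3:
        raise ValueError("insufficient residue correspondence at the interface")
    pp, nn = _backbone_stack(pairs)
    _, r = kabsch(pp, nn)
    return r


def ca_rmsd(pred: CoarsePose, native: CoarsePose) -> float:
    """Whole-complex CA RMSD after whole-complex superposition."""
    pairs = _paired(pred.all_residues(), native.all_residues())
    if len(pairs) < 3:
        raise ValueError("insufficient residue correspondence")
    pp = np.array([p.CA for p, _ in pairs])
    nn = np.array([n.CA for _, n in pairs])
    _, r = kabsch(pp, nn)
    return r


def capri_rank(
    fnat_v: float, lrmsd_v: float, irmsd_v: float, thresholds: CapriThresholds | None = None
) -> int:
    """Highest quality rank whose boundary conditions all hold (0 = incorrect)."""
    t = thresholds or CapriThresholds()
    rank = 0
    for level, (f_min, l_max, i_max) in enumerate(
        (t.acceptable, t.medium, t.high), start=1
    ):
        if fnat_v >= f_min and (lrmsd_v <= l_max or irmsd_v <= i_max):
            rank = level
    return rank


def dock_metrics(
    pred: CoarsePose, native: CoarsePose, thresholds: CapriThresholds | None = None
) -> DockMetrics:
    t = thresholds or CapriThresholds()
    f = fnat(pred, native, t.fnat_contact_cutoff)
    l = lrmsd(pred, native)
    i = irmsd(pred, native, t.interface_cutoff)
    c = ca_rmsd(pred, native)
    return DockMetrics(f, i, l, c, capri_rank(f, l, i, t))


def classify_difficulty(rmsd_bu: float) -> str:
    """Target difficulty from unbound-to-bound backbone deviation.

    rigid < 1.2 A; medium 1.2-2.2 A (2.2 inclusive); difficult > 2.2 A.
    """
    if rmsd_bu < 0:
        raise ValueError("RMSD must be non-negative")
    if rmsd_bu < 1.2:
        return "rigid"
    if rmsd_bu <= 2.2:
        return "medium"
    return "difficult"


def identify_mobile_residues(
    unbound, bound, threshold: float = 0.5
) -> set[tuple[str, int]]:
    """Residues whose backbone moves more than ``threshold`` between unbound
    and bound forms of one monomer, after whole-monomer backbone
    superposition.

    Accepts residue lists (one monomer each side).
    """
    pairs = _paired(list(unbound), list(bound))
    if len(pairs) < 3:
        raise ValueError("insufficient residue correspondence")
    up, bp = _backbone_stack(pairs)
    T, _ = kabsch(up, bp)
    moved = T.apply(up)
    out = set()
    for k, (p, n) in enumerate(pairs):
        a = moved[4 * k : 4 * k + 4]
        b = bp[4 * k : 4 * k + 4]
        res_rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
        if res_rmsd > threshold:
            out.add(n.key)
    return out


# ---------------------------------------------------------------------------
# success statistics


def enrichment(
    scores: list[float], quality_flags: list[bool], top_fraction: float = 0.10
) -> int:
    """Count of acceptable-or-better candidates among the lowest-scoring
    ceil(top_fraction * n)."""
    n = len(scores)
    if n < 10:
        raise ValueError("need at least 10 candidates")
    if len(quality_flags) != n:
        raise ValueError("scores and flags must align")
    k = int(np.ceil(top_fraction * n))
    order = np.argsort(np.asarray(scores), kind="stable")
    return int(sum(bool(quality_flags[i]) for i in order[:k]))


@dataclass(frozen=True)
class N5Result:
    samples: tuple[int, ...]
    expected: float
    success: bool  # expected >= 3


def n5_bootstrap(
    scores: list[float],
    near_native: list[bool],
    n_draw: int = 1000,
    n_rep: int = 1000,
    rng: np.random.Generator | None = None,
    serials: list[int] | None = None,
) -> N5Result:
    """Bootstrap expected-N5.

    Per replicate: draw ``n_draw`` candidates with replacement, take the five
    top-scoring (ascending score, serial tie-break, stable), count the
    near-native ones.  ``expected`` is the mean over ``n_rep`` replicates and
    success means expected >= 3.
    """
    n = len(scores)
    if n < 5:
        raise ValueError("need at least 5 candidates")
    if len(near_native) != n:
        raise ValueError("scores and flags must align")
    rng = rng or np.random.default_rng()
    serials = serials if serials is not None else list(range(n))
    scores_a = np.asarray(scores, float)
    serial_a = np.asarray(serials)
    flags_a = np.asarray(near_native, bool)
    # pre-rank candidates by (score, serial); the top 5 of a resample are the
    # 5 best-ranked entries of the drawn multiset (duplicates count)
    order = np.lexsort((serial_a, scores_a))
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(n)
    flags_by_rank = flags_a[order]

    samples = []
    for _ in range(n_rep):
        draw = rng.integers(0, n, size=n_draw)
        ranks = np.sort(rank_of[draw])[:5]
        samples.append(int(flags_by_rank[ranks].sum()))
    expected = float(np.mean(samples))
    return N5Result(tuple(samples), expected, expected >= 3.0)


def is_near_native_lowres(ca_rmsd_v: float, cutoff: float = LOWRES_NEAR_NATIVE_CA_RMSD) -> bool:
    """Low-resolution near-native call: whole-complex CA RMSD <= 5 A."""
    return ca_rmsd_v <= cutoff


def is_near_native_highres(rank: int) -> bool:
    """High-resolution near-native call: quality rank acceptable or better."""
    return rank >= 1
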