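import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import chisquare

from flexidock.fixtures import ToyComplexSpec, make_helix, make_helix_loop, make_toy_complex
from flexidock.geom import RigidTransform
from flexidock.sample import (
    Fragment,
    MobileSelection,
    MoveSchedule,
    NoMobileFragmentsError,
    UndefinedSeparationAxisError,
    add_loop_residues,
    backbone_move,
    build_selection,
    contiguous_fragments,
    init_global,
    init_local,
    parse_mobile_list,
    rigid_move,
    select_interface,
    slide_into_contact,
)
from flexidock.structmodel import CoarsePose, assign_secstruct


def brute_force_interface(pose, cutoff):
    """O(N^2) oracle: all-pairs coarse-atom scan."""
    out = set()
    for r in pose.receptor:
        for l in pose.ligand:
            if cdist(r.coarse_coords(), l.coarse_coords()).min() <= cutoff:
                out.add(r.key)
                out.add(l.key)
    return out


class TestSelectInterface:
    def test_matches_brute_force(self, bound_pose):
        for cutoff in (4.0, 5.5, 8.0, 12.0):
            assert select_interface(bound_pose, cutoff) == brute_force_interface(bound_pose, cutoff)

    def test_monotone_in_cutoff(self, bound_pose):
        assert select_interface(bound_pose, 5.5) <= select_interface(bound_pose, 8.0)

    def test_two_residue_toys(self):
        a = make_helix(4, chain_id="A")[:1]
        b = [make_helix(4, chain_id="B")[0].replace(chain_id="B")]
        # closest atoms ~4.0 apart
        b = [b[0].transformed(RigidTransform.from_translation([8.0, 0, 0]))]
        pose = CoarsePose(a, b)
        d = cdist(a[0].coarse_coords(), pose.ligand[0].coarse_coords()).min()
        sel_55 = select_interface(pose, 5.5)
        if d <= 5.5:
            assert len(sel_55) == 2
        sel_wide = select_interface(pose, d + 0.1)
        assert len(sel_wide) == 2
        sel_narrow = select_interface(pose, max(d - 0.1, 0.1))
        assert len(sel_narrow) == 0

    def test_separated_empty(self, bound_pose):
        far = bound_pose.with_jump(
            RigidTransform.from_translation([300.0, 0, 0]).compose(bound_pose.jump)
        )
        assert select_interface(far, 8.0) == set()


class TestLoops:
    def test_all_helix_unchanged(self, helix12):
        base = {("A", 3)}
        assert add_loop_residues(base, helix12[1:-1]) >= base
        labels = assign_secstruct(helix12)
        expected = base | {r.key for r, l in zip(helix12, labels) if l == "L"}
        assert add_loop_residues(base, helix12) == expected

    def test_hairpin_loop_added(self):
        chain, loop_idx = make_helix_loop(14, 5)
        labels = assign_secstruct(chain)
        sel = add_loop_residues(set(), chain)
        for i in loop_idx:
            assert chain[i].key in sel

    def test_all_loop_chain(self):
        from flexidock.fixtures import make_chain

        coil = make_chain([(-150.0, 40.0)] * 6)
        sel = add_loop_residues(set(), coil)
        assert sel == {r.key for r in coil}


class TestContiguousFragments:
    def _fake_chain(self, seq_ids, chain="A"):
        h = make_helix(max(seq_ids) + 2, chain_id=chain)
        return [h[i].replace(seq_id=s) for i, s in enumerate(seq_ids)]

    def test_definition(self):
        residues = self._fake_chain(list(range(1, 15)))
        selected = {("A", s) for s in (3, 4, 5, 9, 10, 11, 12)}
        frags = contiguous_fragments(residues, selected, "receptor")
        spans = [(residues[f.start].seq_id, residues[f.end].seq_id) for f in frags]
        assert spans == [(3, 5), (9, 12)]

    def test_below_min_len_dropped(self):
        residues = self._fake_chain(list(range(1, 10)))
        selected = {("A", 3), ("A", 4)}
        assert contiguous_fragments(residues, selected, "receptor") == []

    def test_never_cross_chains(self):
        a = self._fake_chain(list(range(1, 6)), "A")
        b = self._fake_chain(list(range(6, 11)), "B")
        residues = a + b
        selected = {r.key for r in residues}
        frags = contiguous_fragments(residues, selected, "receptor")
        # oracle: enumerate runs per chain
        for f in frags:
            chains = {residues[i].chain_id for i in range(f.start, f.end + 1)}
            assert len(chains) == 1
        assert len(frags) == 2

    def test_numbering_gap_breaks_run(self):
        residues = self._fake_chain([1, 2, 3, 7, 8, 9])
        selected = {r.key for r in residues}
        frags = contiguous_fragments(residues, selected, "receptor")
        assert len(frags) == 2


class TestRigidMove:
    def test_sigma_zero_limit(self, bound_pose, rng):
        sched = MoveSchedule(rigid_trans_sigma=1e-12, rigid_rot_sigma=1e-12)
        out = rigid_move(bound_pose, sched, rng)
        for a, b in zip(out.ligand, bound_pose.ligand):
            assert np.allclose(a.CA, b.CA, atol=1e-9)

    def test_receptor_unmoved(self, bound_pose, rng):
        out = rigid_move(bound_pose, MoveSchedule(), rng)
        assert out.receptor is bound_pose.receptor

    def test_deterministic(self, bound_pose):
        a = rigid_move(bound_pose, MoveSchedule(), np.random.default_rng(7))
        b = rigid_move(bound_pose, MoveSchedule(), np.random.default_rng(7))
        for ra, rb in zip(a.ligand, b.ligand):
            assert np.array_equal(ra.CA, rb.CA)

    def test_displacement_statistics(self, bound_pose):
        sched = MoveSchedule(rigid_trans_sigma=0.7, rigid_rot_sigma=1e-9)
        rng = np.random.default_rng(11)
        n = 10_000
        c0 = bound_pose.ligand_centroid()
        disp = np.array([
            np.linalg.norm(rigid_move(bound_pose, sched, rng).ligand_centroid() - c0)
            for _ in range(n)
        ])
        # |N(0, sigma I3)| has mean sigma*sqrt(8/pi) -- chi distribution k=3
        sigma = 0.7
        expected_mean = sigma * np.sqrt(8 / np.pi)
        var = sigma**2 * (3 - 8 / np.pi)
        se = np.sqrt(var / n)
        assert abs(disp.mean() - expected_mean) < 3 * se


class TestBackboneMove:
    def test_restricted_to_fragment(self, bound_pose):
        sel = build_selection(bound_pose, "interface_8")
        assert sel.fragments
        rng = np.random.default_rng(0)
        frag_keys = set()
        for f in sel.fragments:
            residues = bound_pose.receptor if f.partner == "receptor" else bound_pose.ligand_local
            frag_keys |= {residues[i].key for i in range(f.start, f.end + 1)}
        for _ in range(200):
            out = backbone_move(bound_pose, sel, MoveSchedule(), rng)
            for a, b in zip(out.receptor + out.ligand_local, bound_pose.receptor + bound_pose.ligand_local):
                if not np.allclose(a.CA, b.CA, atol=0):
                    assert a.key in frag_keys

    def test_zero_angle_identity(self, bound_pose):
        sel = build_selection(bound_pose, "interface_8")
        sched = MoveSchedule(backrub_max_angle=0.0)
        out = backbone_move(bound_pose, sel, sched, np.random.default_rng(1))
        for a, b in zip(out.receptor, bound_pose.receptor):
            assert np.allclose(a.coarse_coords(), b.coarse_coords(), atol=1e-12)

    def test_no_fragments_error(self, bound_pose):
        sel = MobileSelection("interface_8", frozenset(), ())
        with pytest.raises(NoMobileFragmentsError):
            backbone_move(bound_pose, sel, MoveSchedule(), np.random.default_rng(0))

    def test_directed_only_listed_move(self, toy_complex):
        ur, ul, bound = toy_complex
        directed = {("A", s) for s in range(15, 20)}  # the loop tail
        sel = build_selection(bound, "directed", directed=directed)
        rng = np.random.default_rng(5)
        for _ in range(100):
            out = backbone_move(bound, sel, MoveSchedule(), rng)
            for a, b in zip(out.receptor, bound.receptor):
                if not np.allclose(a.CA, b.CA, atol=0):
                    assert a.key in directed


class TestInitializers:
    def test_init_local_exact_offsets(self, toy_complex):
        ur, ul, bound = toy_complex
        pose = init_local(ur, ul, bound, perturb=False)
        # centroid separation increased by exactly 15
        rc = np.mean([r.CA for r in pose.receptor], axis=0)
        ref = init_local(ur, ul, bound, perturb=False, separation=0.0, rotation_deg=0.0)
        d_ref = np.linalg.norm(np.mean([r.CA for r in ref.ligand], axis=0) - rc)
        d_new = np.linalg.norm(np.mean([r.CA for r in pose.ligand], axis=0) - rc)
        assert d_new - d_ref == pytest.approx(15.0, abs=1e-8)
        # rotation angle exactly 45 degrees
        delta = pose.jump.compose(ref.jump.invert())
        assert delta.rotation_angle_deg() == pytest.approx(45.0, abs=1e-8)

    def test_init_local_reproducible(self, toy_complex):
        ur, ul, bound = toy_complex
        a = init_local(ur, ul, bound, np.random.default_rng(3), perturb=True)
        b = init_local(ur, ul, bound, np.random.default_rng(3), perturb=True)
        assert np.array_equal(a.jump.rotation, b.jump.rotation)
        assert np.array_equal(a.jump.translation, b.jump.translation)

    def test_init_local_perturbation_statistics(self, toy_complex):
        ur, ul, bound = toy_complex
        rng = np.random.default_rng(23)
        base = init_local(ur, ul, bound, perturb=False)
        n = 1000
        offsets = []
        for _ in range(n):
            p = init_local(ur, ul, bound, rng, perturb=True)
            offsets.append(np.linalg.norm(p.jump.translation - base.jump.translation))
        offsets = np.array(offsets)
        # pure translation part is Gaussian sigma=1 per axis, but the rotation
        # perturbation also shifts jump.translation; compare against sampled
        # norm mean loosely (3 SE of the chi-distribution)
        expected_mean = np.sqrt(8 / np.pi)
        se = np.sqrt((3 - 8 / np.pi) / n)
        assert abs(offsets.mean() - expected_mean) < max(3 * se, 0.25)

    def test_init_local_coincident_centroids(self, helix12):
        lig = [r.replace(chain_id="B") for r in helix12]
        with pytest.raises(UndefinedSeparationAxisError):
            init_local(helix12, lig, perturb=False)

    def test_init_global_contact(self, toy_complex, rng):
        ur, ul, _ = toy_complex
        pose = init_global(ur, ul, rng)
        a = np.vstack([r.coarse_coords() for r in pose.receptor])
        b = np.vstack([r.coarse_coords() for r in pose.ligand])
        dmin = cdist(a, b).min()
        assert dmin <= 4.5 + 0.26  # contact window plus one slide step
        assert dmin > 2.0  # no hard clash

    def test_init_global_direction_uniform(self, toy_complex):
        ur, ul, _ = toy_complex
        rng = np.random.default_rng(99)
        dirs = []
        for _ in range(1000):
            rc = np.mean([r.CA for r in ur], axis=0)
            pose = init_global(ur, ul, rng)
            v = pose.ligand_centroid() - pose.receptor_centroid()
            dirs.append(v / np.linalg.norm(v))
        z = np.array(dirs)[:, 2]
        # z-coordinate of a uniform direction is U(-1, 1): chi-square on 8 bins
        counts, _ = np.histogram(z, bins=8, range=(-1, 1))
        _, p = chisquare(counts)
        assert p > 0.001


class TestSlideIntoContact:
    def test_already_in_contact_unchanged(self, bound_pose):
        out = slide_into_contact(bound_pose)
        assert out is bound_pose

    def test_from_far_lands_in_window(self, bound_pose):
        far = bound_pose.with_jump(
            RigidTransform.from_translation(
                50.0 * (bound_pose.ligand_centroid() - bound_pose.receptor_centroid())
                / np.linalg.norm(bound_pose.ligand_centroid() - bound_pose.receptor_centroid())
            ).compose(bound_pose.jump)
        )
        out = slide_into_contact(far)
        a = np.vstack([r.coarse_coords() for r in out.receptor])
        b = np.vstack([r.coarse_coords() for r in out.ligand])
        d = cdist(a, b).min()
        assert 3.5 - 0.26 <= d <= 4.5 + 1e-9

    def test_matches_line_search_oracle(self, bound_pose):
        direction = bound_pose.ligand_centroid() - bound_pose.receptor_centroid()
        direction /= np.linalg.norm(direction)
        far = bound_pose.with_jump(
            RigidTransform.from_translation(30.0 * direction).compose(bound_pose.jump)
        )
        out = slide_into_contact(far, step=0.25)
        # oracle: brute-force scan of the same step grid
        a = np.vstack([r.coarse_coords() for r in far.receptor])
        b0 = np.vstack([r.coarse_coords() for r in far.ligand])
        axis = far.receptor_centroid() - far.ligand_centroid()
        axis /= np.linalg.norm(axis)
        best = None
        for k in range(1, 801):
            d = cdist(a, b0 + k * 0.25 * axis).min()
            if 3.5 <= d <= 4.5:
                best = k
                break
            if d < 3.5:
                best = k - 1
                break
        bsol = np.vstack([r.coarse_coords() for r in out.ligand])
        assert np.allclose(bsol, b0 + best * 0.25 * axis, atol=1e-8)


def test_parse_mobile_list():
    text = "A:5\nA:10-12  # a loop\nB:3\n\n# comment\n"
    assert parse_mobile_list(text) == {("A", 5), ("A", 10), ("A", 11), ("A", 12), ("B", 3)}
    with pytest.raises(ValueError):
        parse_mobile_list("nonsense")


def test_directed_requires_list(bound_pose):
    with pytest.raises(ValueError):
        build_selection(bound_pose, "directed")


def test_unknown_mode(bound_pose):
    with pytest.raises(ValueError):
        MobileSelection("bogus", frozenset(), ())
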