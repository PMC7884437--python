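from dataclasses import replace

import numpy as np
import pytest

from resmap import structmotif as sm
from resmap import synthetic_data as syn
from resmap.structure_model import ParameterizedStructure

AMINO = list(sm.THREE_TO_ONE)


def varied_helix(n=40, drop=(), seed_names=0):
    """Single-chain helix with a varied (non-degenerate) sequence."""
    members, _ = syn.make_motif_family(
        syn.SyntheticSpec(family_length=n, n_members=1, n_displaced=0, loop_span=(1, 1))
    )
    st = members[0]
    atoms = []
    for a in st.atoms:
        pos = a.residue_id[1]
        if pos in drop:
            continue
        atoms.append(replace(a, res_name=AMINO[(pos + seed_names) % 20], coords=a.coords.copy()))
    return ParameterizedStructure(atoms, st.provenance)


def transformed(st, R, t):
    atoms = [replace(a, coords=R @ a.coords + t) for a in st.atoms]
    return ParameterizedStructure(atoms, st.provenance + ":moved")


class TestAlignPair:
    def test_self_alignment(self):
        st = varied_helix()
        aln = sm.align_pair(st, st)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)
        assert aln.coverage == 1.0
        assert np.allclose(aln.rotation, np.eye(3), atol=1e-9)

    def test_recovers_applied_rigid_motion(self):
        st = varied_helix()
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = transformed(st, R, np.array([5.0, -2.0, 1.0]))
        aln = sm.align_pair(st, moved)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(aln.rotation @ R, np.eye(3), atol=1e-6)
        assert np.linalg.det(aln.rotation) == pytest.approx(1.0)

    def test_displaced_loop_leaves_core_tight(self):
        members, span = syn.make_motif_family(
            syn.SyntheticSpec(displacement=3.0, n_members=2, n_displaced=1)
        )
        aln = sm.align_pair(members[1], members[0])  # member 0 is displaced
        assert aln.rmsd > 0.0
        lo, hi = span
        corr = dict(aln.correspondence)
        _, rids_a, ca_a = sm._sequence_and_ca(members[1], None)
        _, rids_b, ca_b = sm._sequence_and_ca(members[0], None)
        ia = {r: i for i, r in enumerate(rids_a)}
        ib = {r: i for i, r in enumerate(rids_b)}
        for ra, rb in aln.correspondence:
            if lo <= ra[1] <= hi:
                continue
            d = np.linalg.norm(ca_a[ia[ra]] - aln.transform(ca_b[ib[rb]]))
            assert d < 0.1

    def test_too_short_chain_rejected(self):
        st = varied_helix(n=6)
        with pytest.raises(ValueError):
            sm.align_pair(st, st)

    def test_kabsch_beats_random_rotations(self):
        """Kabsch optimality oracle: no random rotation does better."""
        rng = np.random.default_rng(42)
        P = rng.normal(size=(30, 3)) * 5
        Q = P @ _random_rotation(rng).T + rng.normal(scale=0.3, size=(30, 3))
        _, _, best = sm.kabsch(P, Q)
        for _ in range(100):
            R = _random_rotation(rng)
            Qr = Q @ R.T
            t = P.mean(axis=0) - Qr.mean(axis=0)
            rmsd = np.sqrt(np.mean(np.sum((P - (Qr + t)) ** 2, axis=1)))
            assert best <= rmsd + 1e-12


def _random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestFamilies:
    def test_scaffold_copies_vs_unrelated_fold(self):
        same, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=0.0, n_members=5))
        # a heavily displaced variant acts as a structurally unrelated member
        odd, _ = syn.make_motif_family(
            syn.SyntheticSpec(displacement=15.0, loop_span=(5, 40), n_members=1, n_displaced=1)
        )
        fams = sm.classify_families(same + odd)
        assert fams == [[0, 1, 2, 3, 4], [5]]

    def test_identical_members_one_family(self):
        same, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=0.0, n_members=3))
        assert sm.classify_families(same) == [[0, 1, 2]]

    def test_zero_rmsd_threshold_splits_noisy_copies(self):
        rng = np.random.default_rng(0)
        base = varied_helix()
        noisy = []
        for _ in range(3):
            atoms = [replace(a, coords=a.coords + rng.normal(scale=0.2, size=3)) for a in base.atoms]
            noisy.append(ParameterizedStructure(atoms, "noisy"))
        fams = sm.classify_families(noisy, rmsd_max=0.0)
        assert fams == [[0], [1], [2]]

    def test_partition_invariant_to_input_order(self):
        same, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=0.0, n_members=3))
        odd, _ = syn.make_motif_family(
            syn.SyntheticSpec(displacement=15.0, loop_span=(5, 40), n_members=1, n_displaced=1)
        )
        members = same + odd
        f1 = sm.classify_families(members)
        perm = [3, 1, 0, 2]
        f2 = sm.classify_families([members[i] for i in perm])
        relabeled = sorted(sorted(perm.index(i) for i in fam) for fam in f1)
        assert sorted(f2) == relabeled


class TestDeviationProfile:
    def test_identical_members_zero_profile(self):
        members, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=0.0, n_members=3))
        fam = sm.build_family_alignment(members)
        prof = sm.deviation_profile(fam)
        assert np.nanmax(prof.max_deviation) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_loop_shows_in_profile(self):
        members, (lo, hi) = syn.make_motif_family(
            syn.SyntheticSpec(displacement=3.0, n_members=3, n_displaced=1)
        )
        fam = sm.build_family_alignment(members)
        prof = sm.deviation_profile(fam)
        in_span = [d for rid, d in zip(prof.ref_rids, prof.max_deviation) if lo < rid[1] < hi]
        out_span = [
            d for rid, d in zip(prof.ref_rids, prof.max_deviation)
            if rid[1] < lo - 2 or rid[1] > hi + 2
        ]
        assert max(in_span) == pytest.approx(3.0, abs=0.3)
        assert max(out_span) < 0.3

    def test_opposite_displacements_add(self):
        members, (lo, hi) = syn.make_motif_family(
            syn.SyntheticSpec(displacement=2.0, n_members=4, n_displaced=2,
                              displacement_mode="spread")
        )
        fam = sm.build_family_alignment(members, reference=3)
        prof = sm.deviation_profile(fam)
        in_span = [d for rid, d in zip(prof.ref_rids, prof.max_deviation) if lo < rid[1] < hi]
        assert max(in_span) == pytest.approx(4.0, abs=0.4)

    def test_family_of_one_rejected(self):
        members, _ = syn.make_motif_family(syn.SyntheticSpec(n_members=1, n_displaced=0))
        with pytest.raises(ValueError):
            sm.build_family_alignment(members)


class TestDetectMotifs:
    def test_flat_profile_no_motifs(self):
        members, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=0.0, n_members=3))
        prof = sm.deviation_profile(sm.build_family_alignment(members))
        assert sm.detect_motifs(prof) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_span_recovered_exactly(self, seed):
        spec = syn.SyntheticSpec(seed=seed, displacement=3.0, loop_span=(20, 30))
        members, span = syn.make_motif_family(spec)
        prof = sm.deviation_profile(sm.build_family_alignment(members))
        motifs = sm.detect_motifs(prof, threshold=1.5, min_pairs=1)
        assert [(m.start, m.end) for m in motifs] == [span]

    def test_subthreshold_displacement_no_motif(self):
        members, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=1.0))
        prof = sm.deviation_profile(sm.build_family_alignment(members))
        assert sm.detect_motifs(prof, threshold=1.5) == []

    def test_two_separated_spans_in_order(self):
        m1, s1 = syn.make_motif_family(syn.SyntheticSpec(displacement=3.0, loop_span=(8, 12)))
        m2, s2 = syn.make_motif_family(syn.SyntheticSpec(displacement=3.0, loop_span=(30, 34)))
        # combine: displace both spans in one family
        members, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=0.0))
        combined = []
        for a, b, c in zip(m1, m2, members):
            atoms = []
            for aa, ab, ac in zip(a.atoms, b.atoms, c.atoms):
                disp = (aa.coords - ac.coords) + (ab.coords - ac.coords)
                atoms.append(replace(ac, coords=ac.coords + disp))
            combined.append(ParameterizedStructure(atoms, "combined"))
        prof = sm.deviation_profile(sm.build_family_alignment(combined))
        motifs = sm.detect_motifs(prof, threshold=1.5)
        assert [(m.start, m.end) for m in motifs] == [s1, s2]

    def test_no_displaced_members_no_motif(self):
        members, _ = syn.make_motif_family(syn.SyntheticSpec(displacement=3.0, n_displaced=0))
        prof = sm.deviation_profile(sm.build_family_alignment(members))
        assert sm.detect_motifs(prof) == []


def test_family_fasta_is_gapped_alignment():
    ref = varied_helix()
    member = varied_helix(drop={10, 11})
    fam = sm.build_family_alignment([ref, member])
    fasta = sm.family_to_fasta(fam)
    rows = [l for l in fasta.splitlines() if not l.startswith(">")]
    assert len(rows) == 2
    assert len(rows[0]) == len(rows[1]) == fam.n_positions
    assert "-" not in rows[0] and rows[1].count("-") == 2


class TestMapToReference:
    def test_reference_maps_to_itself(self):
        members = [varied_helix(), varied_helix()]
        fam = sm.build_family_alignment(members)
        labels = sm.map_to_reference(fam)[0]
        for rid, label in labels.items():
            assert label == str(rid[1])

    def test_numbering_offset_and_prefix(self):
        members = [varied_helix(), varied_helix()]
        fam = sm.build_family_alignment(members)
        labels = sm.map_to_reference(fam, numbering_offset=19, prefix="Im7#")[0]
        assert labels[("A", 1, "")] == "Im7#20"

    def test_member_deletion_skips_reference_positions(self):
        ref = varied_helix()
        member = varied_helix(drop={10, 11})
        fam = sm.build_family_alignment([ref, member])
        labels = sm.map_to_reference(fam)[1]
        assigned = set(labels.values())
        assert "10" not in assigned and "11" not in assigned
        assert "9" in assigned and "12" in assigned

    def test_member_insertion_gets_insertion_labels(self):
        ref = varied_helix(drop={10, 11})  # reference lacks two positions
        member = varied_helix()
        fam = sm.build_family_alignment([ref, member])
        labels = sm.map_to_reference(fam)[1]
        ins = [v for v in labels.values() if v and v[-1].isalpha()]
        assert len(ins) == 2
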