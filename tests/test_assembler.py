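import numpy as np
import pytest
import gemmi

from pbscore import assembler, seqkit, structio, synthdata
from pbscore.assembler import AssemblyError, TrimerSpec

from oracles import quaternion_superpose_rmsd, naive_contact_pairs


@pytest.fixture(scope="module")
def asu():
    model, truth = synthdata.make_asu_fixture(seed=0)
    return model, truth


def chain_protein_seq(chain):
    return "".join(structio.AA3TO1[r.name] for r in chain.residues
                   if r.name in structio.AA3TO1)


class TestSymmetryOperators:
    def test_builtin_threefold_matches_gemmi_space_group_table(self):
        ours = {gemmi.Op(t).triplet() for t in assembler.P321_THREEFOLD}
        sg = gemmi.SpaceGroup("P 3 2 1")
        gemmi_rotations = {op.triplet() for op in sg.operations()
                           if np.linalg.det(np.array(op.rot)) > 0
                           and op.triplet().endswith("z")}
        assert ours <= gemmi_rotations and len(ours) == 3

    def test_group_closure_of_threefold(self):
        ops = assembler.threefold_operators()
        a, b = ops[1], ops[2]
        assert a.compose(b).is_identity()
        assert b.compose(a).is_identity()


class TestExpandTrimer:
    def test_identity_only_relabels(self, asu):
        model, _ = asu
        out = assembler.expand_trimer(
            model, [assembler.SymmetryOperator.from_triplet("x,y,z")])
        assert out.chain_ids == ["A", "B"]
        assert np.abs(out.coords() - model.coords()).max() < 1e-9

    def test_matches_synthetic_c3_fixture(self):
        chain = synthdata.make_random_chain(12, seed=4,
                                            center=np.array([9.0, 3.0, 2.0]))
        fixture = synthdata.make_c3_assembly(chain)
        asu1 = structio.StructureModel([fixture.chains[0].copy()],
                                       fixture.cell)
        out = assembler.expand_trimer(asu1)
        for cid in "ABC":
            assert np.abs(out.chain(cid).coords()
                          - fixture.chain(cid).coords()).max() < 1e-9

    def test_heterodimer_expansion_copies_mutually_superpose(self, asu):
        model, _ = asu
        out = assembler.expand_trimer(model)
        assert out.chain_ids == list("ABCDEF")
        # alpha-type copies at A/C/E, beta-type at B/D/F
        for pair_chains in (("A", "C"), ("A", "E")):
            a = out.chain(pair_chains[0]).coords()
            c = out.chain(pair_chains[1]).coords()
            _, rmsd = assembler.superpose(a, c)
            assert rmsd < 0.01

    def test_missing_cell_errors(self, asu):
        model, _ = asu
        bare = structio.StructureModel([c.copy() for c in model.chains])
        with pytest.raises(AssemblyError):
            assembler.expand_trimer(bare)


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        _, rmsd = assembler.superpose(pts, pts)
        assert rmsd < 1e-12

    def test_rotated_translated_copy_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, (50, 3))
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=np.random.RandomState(3))
        moved = pts @ rot.as_matrix().T + np.array([4.0, -2.0, 7.0])
        transform, rmsd = assembler.superpose(pts, moved)
        assert rmsd < 1e-9
        assert np.abs(transform.apply(pts) - moved).max() < 1e-8

    def test_noisy_copy_matches_quaternion_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-10, 10, (100, 3))
        noisy = pts + rng.normal(0, 0.5, pts.shape)
        _, rmsd = assembler.superpose(pts, noisy)
        assert rmsd == pytest.approx(
            quaternion_superpose_rmsd(pts, noisy), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(AssemblyError):
            assembler.superpose(line, line)
        with pytest.raises(AssemblyError):
            assembler.superpose(line[:2], line[:2])


class TestThreading:
    def test_threading_own_sequence_reproduces_chain(self, asu):
        model, _ = asu
        tmpl = model.chain("A")
        seq = seqkit.SequenceRecord("self", "protein",
                                    chain_protein_seq(tmpl))
        aln = seqkit.global_align(seq, seq)
        out, report = assembler.thread_subunit(tmpl, seq, aln)
        assert report.n_identical == report.n_modeled == len(seq)
        protein = [r for r in tmpl.residues if r.name in structio.AA3TO1]
        assert [r.name for r in out.residues] == [r.name for r in protein]
        got = np.array([a.pos for r in out.residues for a in r.atoms])
        want = np.array([a.pos for r in protein for a in r.atoms])
        assert np.abs(got - want).max() == 0.0

    def test_substitutions_truncated_to_cb_and_backbone_kept(self, asu):
        model, _ = asu
        tmpl = model.chain("A")
        seq = seqkit.SequenceRecord("t", "protein", chain_protein_seq(tmpl))
        hom, truth = synthdata.make_homolog(seq.residues, 0.5, 0, seed=8,
                                            rec_id="hom")
        aln = seqkit.global_align(seq, hom)
        out, report = assembler.thread_subunit(tmpl, hom, aln)
        assert report.n_modeled == len(hom)
        for res, letter in zip(out.residues, hom.residues):
            assert structio.AA3TO1[res.name] == letter
            names = {a.name for a in res.atoms}
            assert names <= {"N", "CA", "C", "O", "CB"} or \
                structio.AA3TO1[res.name] == letter
        # conserved cysteine position carried through (numbering 1-based)
        assert out.residues[11].seqnum == 12

    def test_insertion_residues_reported_unmodeled(self, asu):
        model, _ = asu
        tmpl = model.chain("A")
        seq = seqkit.SequenceRecord("t", "protein", chain_protein_seq(tmpl))
        hom, truth = synthdata.make_homolog(seq.residues, 0.6, 6, seed=9,
                                            rec_id="pb_like")
        aln = seqkit.global_align(seq, hom)
        out, report = assembler.thread_subunit(tmpl, hom, aln)
        assert len(report.unmodeled) == 6
        modeled_nums = {r.seqnum for r in out.residues}
        assert modeled_nums.isdisjoint(report.unmodeled)
        assert report.n_modeled + len(report.unmodeled) == len(hom)

    def test_mismatched_alignment_rejected(self, asu):
        model, _ = asu
        tmpl = model.chain("A")
        other = seqkit.SequenceRecord("x", "protein", "MSIITKSIVNAD")
        aln = seqkit.global_align(other, other)
        with pytest.raises(AssemblyError):
            assembler.thread_subunit(tmpl, other, aln)


@pytest.fixture(scope="module")
def built(asu):
    model, truth = asu
    base = assembler.expand_trimer(model)
    library = {}
    for kind, cid in (("alphaII", "A"), ("beta18", "B"), ("PB", "A")):
        tmpl = model.chain(cid)
        seq = seqkit.SequenceRecord(
            "t", "protein", chain_protein_seq(tmpl))
        hom, _ = synthdata.make_homolog(seq.residues, 0.6, 0,
                                        seed=ord(kind[0]), rec_id=kind)
        aln = seqkit.global_align(seq, hom)
        library[kind], _ = assembler.thread_subunit(tmpl, hom, aln)
    linker = synthdata.make_random_chain(6, seed=5, chain_id="G",
                                         spread=2.0)
    library["Lc"] = linker
    return base, library


class TestBuildTrimer:
    def test_apc_spec_is_identity(self, built):
        base, library = built
        out = assembler.build_trimer(base, TrimerSpec.for_variant("APC"),
                                     library)
        assert out.structure.chain_ids == list("ABCDEF")
        assert np.abs(out.structure.coords() - base.coords()).max() == 0.0

    def test_apc2_substitutes_slot_a_with_alphaII_and_linker_at_g(self, built):
        base, library = built
        out = assembler.build_trimer(base, TrimerSpec.for_variant("APC_2"),
                                     library)
        assert out.structure.chain_ids == list("ABCDEFG")
        # substituted chain has the homolog sequence, not the base one
        got = chain_protein_seq(out.structure.chain("A"))
        assert got == "".join(structio.AA3TO1[r.name]
                              for r in library["alphaII"].residues)
        # unsubstituted chains untouched
        for cid in "BCDEF":
            assert np.abs(out.structure.chain(cid).coords()
                          - base.chain(cid).coords()).max() == 0.0

    def test_apc3_substitutes_neighboring_heterodimers_no_linker(self, built):
        base, library = built
        out = assembler.build_trimer(base, TrimerSpec.for_variant("APC_3"),
                                     library)
        assert out.structure.chain_ids == list("ABCDEF")
        a_seq = chain_protein_seq(out.structure.chain("A"))
        f_seq = chain_protein_seq(out.structure.chain("F"))
        assert a_seq == "".join(structio.AA3TO1[r.name]
                                for r in library["PB"].residues)
        assert f_seq == "".join(structio.AA3TO1[r.name]
                                for r in library["beta18"].residues)

    def test_substituted_chain_superposes_on_displaced_slot(self, built):
        base, library = built
        out = assembler.build_trimer(base, TrimerSpec.for_variant("APC_2"),
                                     library)
        sub = out.structure.chain("A")
        displaced = base.chain("A")
        index = {(r.source_seqnum, a.name): a.pos for r in sub.residues
                 for a in r.atoms if a.name in ("N", "CA", "C")}
        pa, pb = [], []
        for r in displaced.residues:
            for a in r.atoms:
                if (r.seqnum, a.name) in index:
                    pa.append(index[(r.seqnum, a.name)])
                    pb.append(a.pos)
        rmsd = np.sqrt(np.mean(np.sum((np.array(pa) - np.array(pb)) ** 2,
                                      axis=1)))
        assert rmsd < 1e-9

    def test_missing_library_kind_errors(self, built):
        base, _ = built
        with pytest.raises(AssemblyError):
            assembler.build_trimer(base, TrimerSpec.for_variant("APC_2"), {})


class TestPlaceLinker:
    def test_template_equal_to_target_places_with_zero_rmsd(self, asu):
        model, _ = asu
        base = assembler.expand_trimer(model)
        template = base.copy()
        linker = synthdata.make_random_chain(6, seed=7, chain_id="O",
                                             spread=2.0)
        template.chains.append(linker)
        out, rmsd = assembler.place_linker(base, template, "O")
        assert rmsd < 1e-9
        assert np.abs(out.chain("G").coords() - linker.coords()).max() < 1e-9

    def test_axis_linker_stays_on_axis(self):
        chain = synthdata.make_random_chain(12, seed=8,
                                            center=np.array([10.0, 0.0, 0.0]))
        fixture = synthdata.make_c3_assembly(chain)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        target = fixture.copy()
        for ch in target.chains:
            for r in ch.residues:
                for a in r.atoms:
                    a.pos = rot.as_matrix() @ a.pos
        linker = synthdata.make_random_chain(6, seed=9, chain_id="O",
                                             spread=1.5)
        on_axis = linker.coords().mean(axis=0)
        shift = np.array([-on_axis[0], -on_axis[1], 0.0])
        for r in linker.residues:
            for a in r.atoms:
                a.pos = a.pos + shift     # centroid onto the z axis
        template = fixture.copy()
        template.chains.append(linker)
        out, _ = assembler.place_linker(target, template, "O")
        placed_centroid = out.chain("G").coords().mean(axis=0)
        axis_dir = rot.as_matrix() @ np.array([0.0, 0.0, 1.0])
        radial = placed_centroid - placed_centroid.dot(axis_dir) * axis_dir
        assert np.linalg.norm(radial) < 1e-6

    def test_equivariance_under_target_rotation(self, asu):
        model, _ = asu
        base = assembler.expand_trimer(model)
        template = base.copy()
        linker = synthdata.make_random_chain(6, seed=10, chain_id="O",
                                             spread=2.0)
        template.chains.append(linker)
        out1, _ = assembler.place_linker(base, template, "O")
        from scipy.spatial.transform import Rotation
        rmat = Rotation.from_euler("zyx", [15, -25, 40],
                                   degrees=True).as_matrix()
        rotated = base.copy()
        for ch in rotated.chains:
            for r in ch.residues:
                for a in r.atoms:
                    a.pos = rmat @ a.pos
        out2, _ = assembler.place_linker(rotated, template, "O")
        want = out1.chain("G").coords() @ rmat.T
        assert np.abs(out2.chain("G").coords() - want).max() < 1e-6

    def test_unmatched_chains_error(self, asu):
        model, _ = asu
        base = assembler.expand_trimer(model)
        template = structio.StructureModel(
            [synthdata.make_random_chain(6, seed=11, chain_id="Z")])
        template.chains.append(
            synthdata.make_random_chain(5, seed=12, chain_id="O"))
        with pytest.raises(AssemblyError):
            assembler.place_linker(base, template, "O")


class TestClashes:
    def test_well_separated_atoms_have_no_clashes(self):
        chain = synthdata.make_random_chain(5, seed=1)
        for i, r in enumerate(chain.residues):
            r.atoms[0].pos = np.array([10.0 * i, 0.0, 0.0])
        report = assembler.count_clashes(
            structio.StructureModel([chain]))
        assert report.count == 0

    def test_planted_overlap_detected(self):
        from pbscore.structio import Atom, Chain, Residue, StructureModel
        d = 0.5 * 2 * 1.87 * 0.7 * 0.99     # just under the scaled sum
        m = StructureModel([
            Chain("A", [Residue("ALA", 1, "", [
                Atom("CB", "C", np.zeros(3))])]),
            Chain("B", [Residue("ALA", 1, "", [
                Atom("CB", "C", np.array([d, 0.0, 0.0]))])]),
        ])
        assert assembler.count_clashes(m).count == 1

    def test_matches_naive_quadratic_scan(self):
        rng = np.random.default_rng(13)
        from pbscore.structio import Atom, Chain, Residue, StructureModel
        chains = []
        for cid in "AB":
            ch = Chain(cid)
            for i in range(40):
                ch.residues.append(Residue("ALA", i + 1, "", [
                    Atom("CB", "C", rng.uniform(0, 12, 3))]))
            chains.append(ch)
        m = StructureModel(chains)
        report = assembler.count_clashes(m)
        cutoff = 0.7 * 2 * 1.87
        got = {(a[:2] + (a[3],), b[:2] + (b[3],))
               for a, b, _ in report.pairs}
        atoms = [(ch.id, r.seqnum, a.name, a.pos)
                 for ch in chains for r in ch.residues for a in r.atoms]
        want = set()
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                ai, aj = atoms[i], atoms[j]
                if ai[:2] == aj[:2]:
                    continue
                if np.linalg.norm(ai[3] - aj[3]) < cutoff:
                    pair = tuple(sorted([ai[:3], aj[:3]]))
                    want.add(pair)
        assert {tuple(sorted(p)) for p in got} == want

    def test_greedy_relief_reduces_clashes_without_touching_backbone(self):
        asu, _ = synthdata.make_asu_fixture(seed=2)
        before = assembler.count_clashes(asu)
        relieved, removed = assembler.relieve_clashes(asu, max_rounds=5)
        after = assembler.count_clashes(relieved)
        assert removed <= 5
        assert after.count <= before.count
        for cid in "AB":
            for r0, r1 in zip(asu.chain(cid).residues,
                              relieved.chain(cid).residues):
                for name in ("N", "CA", "C", "O"):
                    a0, a1 = r0.atom(name), r1.atom(name)
                    if a0 is not None:
                        assert a1 is not None
                        assert np.all(a0.pos == a1.pos)
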