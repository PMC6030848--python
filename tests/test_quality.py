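"""Scoring: lDDT vs a brute-force oracle, Kabsch RMSD, QS-score, PMF, DisCo."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from protmod import fixtures, quality
from protmod import template_store as ts
from protmod.quality import LddtParams, kabsch_rmsd, lddt, qs_score
from protmod.structio import Assembly, Atom, Chain, Residue


# ---------------------------------------------------------------- lDDT


def lddt_oracle(model, reference, params):
    """Independent brute-force lDDT: explicit double loop over atoms."""
    def atoms_of(asm):
        out = {}
        for chain in asm.chains:
            for res in chain.residues:
                for a in res.atoms:
                    out[(chain.id, res.number, a.name)] = a.coord
        return out

    ref = atoms_of(reference)
    mod = atoms_of(model)
    keys = list(ref)
    fractions = []
    for t in params.thresholds:
        total = kept = 0
        for i, j in itertools.combinations(range(len(keys)), 2):
            ki, kj = keys[i], keys[j]
            if ki[:2] == kj[:2]:
                continue
            d_ref = np.linalg.norm(ref[ki] - ref[kj])
            if d_ref >= params.inclusion_radius:
                continue
            total += 1
            if ki in mod and kj in mod:
                d_mod = np.linalg.norm(mod[ki] - mod[kj])
                if abs(d_mod - d_ref) < t:
                    kept += 1
        fractions.append(kept / total)
    return 100.0 * float(np.mean(fractions))


def test_lddt_of_reference_with_itself_is_100(helix12):
    global_score, per_res = lddt(helix12, helix12)
    assert global_score == 100.0
    assert all(v == 100.0 for v in per_res.values())


def test_lddt_invariant_under_rigid_transform(helix12):
    moved = helix12.copy()
    rot = Rotation.from_euler("xyz", [31, -42, 53], degrees=True).as_matrix()
    shift = np.array([5.0, -3.0, 8.0])
    for chain in moved.chains:
        for res in chain.residues:
            for a in res.atoms:
                a.coord = rot @ a.coord + shift
    score, _ = lddt(moved, helix12)
    assert abs(score - 100.0) < 1e-9


def test_lddt_matches_bruteforce_oracle_on_random_toys():
    params = LddtParams()
    rng = np.random.default_rng(17)
    for trial in range(20):
        n = int(rng.integers(3, 11))
        ref = fixtures.make_helix(max(4, n))
        model = fixtures.perturb(ref, float(rng.uniform(0.05, 1.5)),
                                 seed=int(rng.integers(0, 2**31)))
        got, _ = lddt(model, ref, params)
        want = lddt_oracle(model, ref, params)
        assert got == pytest.approx(want, abs=1e-9)


def test_lddt_displaced_residue_thresholds():
    ref = fixtures.make_helix(6)
    model = ref.copy()
    # displace one CA by 1.5 Å: its pairs fail 0.5/1 but pass 2/4
    model.chains[0].residues[2].atom("CA").coord += np.array([1.5, 0.0, 0.0])
    got, per_res = lddt(model, ref)
    want = lddt_oracle(model, ref, LddtParams())
    assert got == pytest.approx(want, abs=1e-9)
    assert per_res[("A", 3)] < 100.0


def test_lddt_missing_model_atoms_are_not_preserved():
    ref = fixtures.make_helix(6)
    model = ref.copy()
    res = model.chains[0].residues[2]
    res.atoms = [a for a in res.atoms if a.name != "CB"]
    got, _ = lddt(model, ref)
    want = lddt_oracle(model, ref, LddtParams())
    assert got == pytest.approx(want, abs=1e-9)
    assert got < 100.0


def test_lddt_monotone_under_growing_noise(helix12):
    scores = [lddt(fixtures.perturb(helix12, s, seed=9), helix12)[0]
              for s in (0.1, 0.5, 1.0, 2.0)]
    assert all(b < a for a, b in zip(scores, scores[1:]))


def test_lddt_zero_reference_pairs_errors():
    tiny = Assembly(id="t", chains=[Chain(id="A", residues=[
        Residue(1, "GLY", atoms=[Atom("CA", "C", np.zeros(3))])])])
    with pytest.raises(ValueError):
        lddt(tiny, tiny)


# ---------------------------------------------------------------- Kabsch


def kabsch_oracle(a, b):
    """Brute-force optimal-rotation RMSD via multi-start optimisation."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a @ r.T - b) ** 2, axis=1))))

    best = np.inf
    rng = np.random.default_rng(3)
    for _ in range(24):
        res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_kabsch_identity_and_rigid_copy():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.4, 1.2]])
    assert kabsch_rmsd(pts, pts)[0] == pytest.approx(0.0, abs=1e-12)
    rot = Rotation.from_euler("zyx", [10, 60, -35], degrees=True).as_matrix()
    moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
    rmsd, r, t = kabsch_rmsd(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(r) == pytest.approx(1.0)


def test_kabsch_matches_bruteforce_oracle():
    rng = np.random.default_rng(5)
    for _ in range(3):
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        rmsd, _, _ = kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(kabsch_oracle(a, b), abs=1e-6)


def test_kabsch_never_worse_than_unsuperposed():
    rng = np.random.default_rng(6)
    a = rng.normal(size=(6, 3))
    b = rng.normal(size=(6, 3))
    raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    assert kabsch_rmsd(a, b)[0] <= raw + 1e-12


def test_kabsch_degenerate_inputs_error():
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_rmsd(line, line)


# ---------------------------------------------------------------- contacts / QS


def test_interface_contacts_match_planted_truth(dimer_with_truth):
    asm, truth = dimer_with_truth
    assert quality.interface_contacts(asm) == truth


def test_far_apart_chains_and_zero_cutoff_empty(dimer_with_truth):
    far, _ = fixtures.make_toy_dimer(10, 0, seed=3)
    assert quality.interface_contacts(far) == frozenset()
    assert quality.interface_contacts(dimer_with_truth[0], cutoff=0.0) == frozenset()


def contact_fixture(contacts_a, broken, added):
    """Two-chain assemblies realising prescribed contact sets.

    Residue slot i sits at z = 6*i; a contacting pair is 4 Å apart in x,
    a broken one 30 Å. `added` slots exist only with contacts in the model.
    """
    def build(pairs_close):
        a_res, b_res = [], []
        slots = sorted({n for n in contacts_a} | {n for n in added})
        for n in slots:
            z = 6.0 * n
            dx = 4.0 if n in pairs_close else 30.0
            a_res.append(Residue(n, "GLY", atoms=[
                Atom("CA", "C", np.array([0.0, 0.0, z]))]))
            b_res.append(Residue(n, "GLY", atoms=[
                Atom("CA", "C", np.array([dx, 0.0, z]))]))
        return Assembly(id="c", chains=[Chain("A", a_res), Chain("B", b_res)])

    reference = build(set(contacts_a))
    model = build((set(contacts_a) - set(broken)) | set(added))
    return model, reference


def test_qs_score_identity_and_disjoint():
    model, reference = contact_fixture(range(1, 6), broken=[], added=[])
    assert qs_score(model, reference, chain_mapping={"A": "A", "B": "B"}) == 1.0
    disjoint_model, _ = contact_fixture(range(1, 6), broken=range(1, 6), added=[])
    assert qs_score(disjoint_model, reference,
                    chain_mapping={"A": "A", "B": "B"}) == 0.0


def test_qs_score_jaccard_six_of_ten_plus_two():
    model, reference = contact_fixture(
        range(1, 11), broken=[7, 8, 9, 10], added=[11, 12])
    score = qs_score(model, reference, chain_mapping={"A": "A", "B": "B"})
    assert score == pytest.approx(6 / 12)


def test_qs_score_symmetric_under_swap():
    model, reference = contact_fixture(range(1, 11), broken=[3, 4], added=[12])
    ab = qs_score(model, reference)
    ba = qs_score(reference, model)
    assert ab == pytest.approx(ba)


def test_qs_score_weighted_variant_in_range(dimer_with_truth):
    asm, _ = dimer_with_truth
    moved = fixtures.perturb(asm, 2.0, scope="chain-rigid", seed=4, chain_id="B")
    w = qs_score(moved, asm, weighted=True)
    j = qs_score(moved, asm)
    assert 0.0 <= j <= 1.0 and 0.0 <= w <= 1.0


def test_qs_score_no_contacts_warns_zero():
    far, _ = fixtures.make_toy_dimer(10, 0, seed=3)
    assert qs_score(far, far) == 0.0


# ---------------------------------------------------------------- PMF / z-score


def manual_pmf_fixture():
    res = [
        Residue(1, "ALA", atoms=[Atom("CB", "C", np.array([0.0, 0.0, 0.0])),
                                 Atom("CA", "C", np.array([0.0, 1.5, 0.0]))]),
        Residue(2, "GLY", atoms=[Atom("CA", "C", np.array([5.0, 0.0, 0.0]))]),
        Residue(3, "ALA", atoms=[Atom("CB", "C", np.array([10.0, 0.0, 0.0])),
                                 Atom("CA", "C", np.array([10.0, 1.5, 0.0]))]),
    ]
    return Assembly(id="toy", chains=[Chain("A", res)])


def test_train_pmf_matches_manual_tally():
    pot = quality.train_pmf([manual_pmf_fixture()])
    # distances: ALA-GLY 5.0 (x2, bin 4), ALA-ALA 10.0 (bin 14)
    p4, p14 = 2 / 3, 1 / 3
    expect_ag = -math.log((2 + 1) / (2 * p4 + 1))
    expect_aa_14 = -math.log((1 + 1) / (1 * p14 + 1))
    assert pot.scores[("ALA", "GLY")][4] == pytest.approx(expect_ag)
    assert pot.scores[("ALA", "ALA")][14] == pytest.approx(expect_aa_14)
    # empty bin of the ALA-GLY profile: obs 0, expected 2*p14
    assert pot.scores[("ALA", "GLY")][14] == pytest.approx(
        -math.log(1 / (2 * p14 + 1)))


def test_pmf_single_pair_type_is_flat_zero():
    helix = fixtures.make_helix(10)  # all-ALA: one type pair
    pot = quality.train_pmf([helix])
    profile = pot.scores[("ALA", "ALA")]
    occupied = [k for k, v in enumerate(profile)
                if abs(v) > 1e-12]
    # wherever observations exist, obs == exp exactly (self-reference)
    helix_scores = pot.score_assembly(helix)
    assert helix_scores == pytest.approx(0.0, abs=0.3)


def test_pmf_symmetry():
    pot = quality.train_pmf(fixtures.make_scored_set(6, seed=2))
    assert pot.score("ALA", "LEU", 6.1) == pot.score("LEU", "ALA", 6.1)


def test_reference_member_scores_within_two_sigma():
    refs = fixtures.make_scored_set(12, seed=0)
    pot = quality.train_pmf(refs)
    stats = quality.build_ref_stats(refs, pot)
    for asm in refs[:4]:
        _, z = quality.qmean_global(asm, pot, stats)
        assert abs(z) <= 2.0


def test_native_beats_shuffled_decoys():
    refs = fixtures.make_scored_set(12, seed=0)
    pot = quality.train_pmf(refs)
    stats = quality.build_ref_stats(refs, pot)
    native = fixtures.make_scored_set(1, seed=99)[0]
    _, z_native = quality.qmean_global(native, pot, stats)
    for s in range(20):
        _, z_decoy = quality.qmean_global(
            fixtures.shuffle_decoy(native, seed=s), pot, stats)
        assert z_native > z_decoy


def test_qmean_norm_is_in_unit_interval():
    refs = fixtures.make_scored_set(8, seed=1)
    pot = quality.train_pmf(refs)
    stats = quality.build_ref_stats(refs, pot)
    for asm in refs:
        qn, _ = quality.qmean_global(asm, pot, stats)
        assert 0.0 <= qn <= 1.0


def test_too_short_model_errors():
    refs = fixtures.make_scored_set(6, seed=1)
    pot = quality.train_pmf(refs)
    with pytest.raises(ValueError):
        pot.score_assembly(Assembly(id="t", chains=[Chain("A", [
            Residue(1, "ALA", atoms=[Atom("CB", "C", np.zeros(3))])])]))


# ---------------------------------------------------------------- DisCo


def self_ensemble(asm):
    pair = ts.align_pair(asm.chains[0].sequence, asm.chains[0].sequence,
                         template_chain_ref="tpl.A")
    return [(asm, {"A": pair})]


def test_disco_self_consistent_ensemble_scores_one():
    tpl = fixtures.make_helix(15, sequence="ADKLVEGFRSTYWQA")
    scores = quality.disco_local(tpl, self_ensemble(tpl))
    assert len(scores) == 15
    assert all(v == pytest.approx(1.0) for v in scores.values())


def test_disco_displaced_residue_scores_strictly_lowest():
    tpl = fixtures.make_helix(15, sequence="ADKLVEGFRSTYWQA")
    model = tpl.copy()
    for a in model.chains[0].residues[7].atoms:
        a.coord = a.coord + np.array([10.0, 0.0, 0.0])
    scores = quality.disco_local(model, self_ensemble(tpl))
    displaced = scores[("A", 8)]
    assert all(displaced < v for k, v in scores.items() if k != ("A", 8))


def test_disco_wide_ensemble_is_more_tolerant():
    tpl = fixtures.make_helix(15, sequence="ADKLVEGFRSTYWQA")
    noisy = fixtures.perturb(tpl, 2.0, seed=12)
    model = fixtures.perturb(tpl, 0.8, seed=13)
    pair = ts.align_pair(tpl.chains[0].sequence, tpl.chains[0].sequence,
                         template_chain_ref="tpl.A")
    tight = quality.disco_local(model, [(tpl, {"A": pair})])
    wide = quality.disco_local(model, [(tpl, {"A": pair}), (noisy, {"A": pair})])
    assert np.mean(list(wide.values())) > np.mean(list(tight.values())) - 0.05


def test_disco_without_templates_errors():
    with pytest.raises(ValueError):
        quality.disco_local(fixtures.make_helix(6), [])
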