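"""Entropy, residue classification, PPI fingerprint, interface call, QSQE."""

import math

import numpy as np
import pytest

from protmod import fixtures
from protmod.interface_analysis import (
    MSA,
    ResidueClassLabels,
    classify_interface,
    classify_residues,
    column_entropy,
    compute_qsqe,
    fit_qsqe,
    ppi_fingerprint,
)
from protmod.structio import Assembly, Atom, Chain, Residue


def labels_from_truth(truth_cols, n_cols):
    return ResidueClassLabels(
        "A",
        {c + 1: ("interface" if c in set(truth_cols) else "surface")
         for c in range(n_cols)},
        5.0, 0.25)


# ---------------------------------------------------------------- entropy


def test_entropy_analytic_values():
    rows = [("t", "A" * 20)] + [(f"r{i}", aa * 20) for i, aa in
                                enumerate("ACDEFGHIKLMNPQRSTVWY")]
    msa = MSA(rows=rows)
    # column over all 21 rows: 2/21 A, 1/21 each for the 19 others
    conserved = MSA(rows=[("t", "AAA"), ("x", "AAA")])
    assert column_entropy(conserved, 0) == pytest.approx(0.0)

    uniform = MSA(rows=[(f"r{i}", aa) for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")])
    assert column_entropy(uniform, 0) == pytest.approx(math.log2(20))

    fifty = MSA(rows=[("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
    assert column_entropy(fifty, 0) == pytest.approx(1.0)


def test_entropy_excludes_gaps_and_flags_all_gap():
    msa = MSA(rows=[("a", "A-"), ("b", "A-"), ("c", "C-")])
    h = column_entropy(msa, 0)
    assert h == pytest.approx(-(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3))
    assert column_entropy(msa, 1) is None


def test_entropy_bounds_hold_on_random_columns():
    msa, _ = fixtures.synth_msa(target_len=40, n_rows=25, seed=21)
    for col in range(40):
        h = column_entropy(msa, col)
        assert 0.0 <= h <= math.log2(20) + 1e-12


# ---------------------------------------------------------------- classification


def test_isolated_chain_has_no_interface(helix12):
    labels = classify_residues(helix12, "A")
    assert labels.numbers("interface") == []
    counts = sum(len(labels.numbers(c)) for c in ("interface", "surface", "core"))
    assert counts == 12


def test_dimer_interface_matches_planted_contacts(dimer_with_truth):
    asm, truth = dimer_with_truth
    expected = sorted({p[1] for pair in truth for p in pair if p[0] == "A"})
    labels = classify_residues(asm, "A")
    assert labels.numbers("interface") == expected


def test_buried_residue_is_core():
    # a central residue caged by a shell of residues: rSASA ~ 0
    shell = []
    golden = np.pi * (3 - 5**0.5)
    for i in range(40):
        z = 1 - 2 * (i + 0.5) / 40
        r = (1 - z * z) ** 0.5
        theta = golden * i
        shell.append(5.5 * np.array([r * np.cos(theta), r * np.sin(theta), z]))
    residues = [Residue(1, "ALA", atoms=[Atom("CA", "C", np.zeros(3)),
                                         Atom("CB", "C", np.array([1.5, 0, 0]))])]
    for i, pos in enumerate(shell):
        residues.append(Residue(i + 2, "ALA", atoms=[Atom("CA", "C", pos)]))
    asm = Assembly(id="cage", chains=[Chain("A", residues)])
    labels = classify_residues(asm, "A")
    assert labels.labels[1] == "core"
    total = sum(len(labels.numbers(c)) for c in ("interface", "surface", "core"))
    assert total == len(residues)


def test_absent_chain_errors(helix12):
    with pytest.raises(KeyError):
        classify_residues(helix12, "Z")


# ---------------------------------------------------------------- fingerprint


def test_flat_conservation_gives_near_zero_ratio():
    # a large alignment keeps the sampling noise of the per-bin entropies
    # well below the 0.1 band expected from the symmetric construction
    msa, truth = fixtures.synth_msa(target_len=240, n_rows=169,
                                    conservation_delta=0.0, seed=31)
    curve = ppi_fingerprint(msa, labels_from_truth(
        [c for c, l in truth.items() if l == "interface"], len(msa.target)))
    populated = curve.populated()
    assert populated
    assert all(abs(curve.ratio[i]) < 0.1 for i in populated)


def test_planted_conservation_drives_remote_ratio_negative():
    msa, truth = fixtures.synth_msa(conservation_delta=2.0, seed=32)
    curve = ppi_fingerprint(msa, labels_from_truth(
        [c for c, l in truth.items() if l == "interface"], len(msa.target)))
    remote = [curve.ratio[i] for i in curve.populated()
              if curve.bin_edges[i + 1] <= 40.0]
    assert remote and all(r < 0 for r in remote)


def test_close_homologs_leave_remote_bins_empty_not_zero():
    msa, truth = fixtures.synth_msa(
        identity_ladder=(0.96, 0.97, 0.98), n_rows=31, seed=33)
    curve = ppi_fingerprint(msa, labels_from_truth(
        [c for c, l in truth.items() if l == "interface"], len(msa.target)))
    for i in range(len(curve.ratio)):
        if curve.bin_edges[i + 1] <= 90.0:
            assert curve.ratio[i] is None
            assert curve.n_sequences[i] < curve.min_seqs


def test_fingerprint_requires_interface_residues():
    msa, _ = fixtures.synth_msa(seed=34)
    all_surface = ResidueClassLabels(
        "A", {c + 1: "surface" for c in range(len(msa.target))}, 5.0, 0.25)
    with pytest.raises(ValueError, match="interface"):
        ppi_fingerprint(msa, all_surface)


def test_fingerprint_invariant_under_row_permutation():
    msa, truth = fixtures.synth_msa(conservation_delta=1.0, seed=35)
    labels = labels_from_truth(
        [c for c, l in truth.items() if l == "interface"], len(msa.target))
    curve = ppi_fingerprint(msa, labels)
    rng = np.random.default_rng(0)
    perm = [0] + (1 + rng.permutation(len(msa.rows) - 1)).tolist()
    shuffled = MSA(rows=[msa.rows[i] for i in perm])
    curve2 = ppi_fingerprint(shuffled, labels)
    assert curve.ratio == curve2.ratio


def test_classifier_labels_and_indeterminate():
    msa, truth = fixtures.synth_msa(conservation_delta=2.0, seed=36)
    iface = [c for c, l in truth.items() if l == "interface"]
    curve = ppi_fingerprint(msa, labels_from_truth(iface, len(msa.target)))
    label, conf = classify_interface(curve)
    assert label == "biological" and conf > 0.5

    flat, truth0 = fixtures.synth_msa(conservation_delta=0.0, seed=37)
    curve0 = ppi_fingerprint(flat, labels_from_truth(
        [c for c, l in truth0.items() if l == "interface"], len(flat.target)))
    assert classify_interface(curve0)[0] == "crystal-contact"

    near, trn = fixtures.synth_msa(identity_ladder=(0.55, 0.65, 0.75),
                                   conservation_delta=1.0, seed=38)
    curve_near = ppi_fingerprint(near, labels_from_truth(
        [c for c, l in trn.items() if l == "interface"], len(near.target)))
    assert classify_interface(curve_near)[0] == "indeterminate"


# ---------------------------------------------------------------- QSQE


def test_qsqe_at_zero_features_matches_logistic_intercept():
    assert compute_qsqe({}) == pytest.approx(1 / (1 + math.exp(2.0)), abs=1e-6)


def test_qsqe_monotone_in_interface_identity():
    base = {"mean_remote_r": -0.5, "contacts": 10, "interface_identity": 0.2,
            "coverage": 0.8}
    lo = compute_qsqe(base)
    hi = compute_qsqe({**base, "interface_identity": 0.9})
    assert hi >= lo


def test_qsqe_bounded_for_random_features():
    rng = np.random.default_rng(12)
    for _ in range(50):
        f = {"mean_remote_r": rng.normal(), "contacts": abs(rng.normal()) * 30,
             "interface_identity": rng.random(), "coverage": rng.random()}
        assert 0.0 <= compute_qsqe(f) <= 1.0


def test_qsqe_fit_recovers_separable_labels():
    rng = np.random.default_rng(13)
    rows, labels = [], []
    for _ in range(60):
        biological = rng.random() < 0.5
        rows.append({
            "mean_remote_r": rng.normal(-0.8 if biological else 0.0, 0.1),
            "contacts": float(rng.integers(5, 30)),
            "interface_identity": rng.random(),
            "coverage": rng.random(),
        })
        labels.append(int(biological))
    coeffs = fit_qsqe(rows, labels)
    correct = sum(
        (compute_qsqe(r, coeffs=coeffs) > 0.5) == bool(l)
        for r, l in zip(rows, labels))
    assert correct >= 55
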