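"""Template library annotation, GMQE surrogate, mapping and ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protmod import fixtures
from protmod import template_store as ts
from protmod.structio import Assembly


def entry_from(*assemblies, ids=None):
    return ts.build_library(list(assemblies), ids=ids)


def merge_chains(*assemblies) -> Assembly:
    chains = []
    for i, asm in enumerate(assemblies):
        chain = asm.copy().chains[0]
        chain.id = chr(ord("A") + i)
        chains.append(chain)
    return Assembly(id="complex", chains=chains)


def test_stoichiometry_strings():
    homo = merge_chains(fixtures.make_helix(8), fixtures.make_helix(8))
    hetero = merge_chains(fixtures.make_helix(8),
                          fixtures.make_helix(8, residue_name="SER"))
    trimer = merge_chains(fixtures.make_helix(8), fixtures.make_helix(8),
                          fixtures.make_helix(8, residue_name="SER"))
    assert entry_from(homo)[0].stoichiometry == "A2"
    assert entry_from(hetero)[0].stoichiometry == "A1B1"
    assert entry_from(trimer)[0].stoichiometry == "A2B1"


def test_gmqe_formula_endpoints_and_blend():
    perfect = ts.align_pair("MKVLF", "MKVLF")
    assert ts.compute_gmqe([perfect]) == pytest.approx(1.0)

    half = ts.AlignmentPair("t", "p", "MKVLMKVL", "MK--XXXX".replace("X", "A"),
                            score=0.0)
    # identity 0.5 over 6 aligned columns? construct directly instead:
    pair = ts.AlignmentPair("t", "p", "AAAACCCC", "AAGG----", score=0.0)
    assert pair.identity == pytest.approx(0.5)
    assert pair.coverage == pytest.approx(0.5)
    assert ts.compute_gmqe([pair]) == pytest.approx(0.5 * (0.2 + 0.4))

    assert ts.compute_gmqe([pair], qmean_norm=0.8) == pytest.approx(
        0.5 * 0.30 + 0.5 * 0.8)


def test_gmqe_clamped_to_unit_interval():
    perfect = ts.align_pair("MKVLF", "MKVLF")
    assert 0.0 <= ts.compute_gmqe([perfect], qmean_norm=1.0) <= 1.0


@settings(max_examples=60, deadline=None)
@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.2), st.floats(0, 0.2))
def test_gmqe_monotone_in_identity_and_coverage(ident, cov, d_ident, d_cov):
    def surrogate(i, c):
        pair = ts.AlignmentPair.__new__(ts.AlignmentPair)
        pair.identity, pair.coverage = i, c
        return ts.compute_gmqe([pair])

    base = surrogate(ident, cov)
    assert surrogate(min(1.0, ident + d_ident), cov) >= base - 1e-12
    assert surrogate(ident, min(1.0, cov + d_cov)) >= base - 1e-12


def test_homodimer_mapping_gives_a2_model():
    seq = "ADKLVEGF"
    dimer = merge_chains(fixtures.make_helix(8, sequence=seq),
                         fixtures.make_helix(8, sequence=seq))
    entry = entry_from(dimer)[0]
    mapping, _ = ts.infer_assembly_mapping({"t1": seq, "t2": seq}, entry)
    assert sorted(len(v) for v in mapping.pairs.values()) == [1, 1]
    assert mapping.stoichiometry == "A1B1" or mapping.stoichiometry == "A1B1"
    # two identical targets jointly claim both chains
    used = [c for v in mapping.pairs.values() for c in v]
    assert sorted(used) == ["A", "B"]


def test_heterodimer_mapping_is_bijective():
    x, y = "ADKLVEGF", "SSTTYYWW"
    hetero = merge_chains(fixtures.make_helix(8, sequence=x),
                          fixtures.make_helix(8, sequence=y))
    entry = entry_from(hetero)[0]
    mapping, _ = ts.infer_assembly_mapping({"tx": x, "ty": y}, entry)
    assert mapping.pairs["tx"] == ["A"]
    assert mapping.pairs["ty"] == ["B"]


def test_unrelated_target_raises_no_mapping():
    entry = entry_from(fixtures.make_helix(8, sequence="AAAAAAAA"))[0]
    with pytest.raises(ts.NoMappingError, match="tz"):
        ts.infer_assembly_mapping({"tz": "WWWWYYYY"}, entry)


def test_ranking_prefers_higher_identity():
    target = "ADKLVEGFRSTY"
    good = fixtures.make_helix(12, sequence=target)
    good.id = "good"
    poor = fixtures.make_helix(12, sequence="ADKAAAAARSTY")
    poor.id = "poor"
    hits = ts.rank_templates({"t": target}, entry_from(good, poor, ids=["good", "poor"]))
    assert [h.template.id for h in hits] == ["good", "poor"]
    assert hits[0].gmqe_pre > hits[1].gmqe_pre


def test_ranking_tie_broken_by_qsqe_then_id():
    target = "ADKLVEGFRSTY"
    t1 = fixtures.make_helix(12, sequence=target)
    t2 = fixtures.make_helix(12, sequence=target)
    lib = entry_from(t1, t2, ids=["tplB", "tplA"])
    hits = ts.rank_templates({"t": target}, lib,
                             qsqe_by_template={"tplA": 0.2, "tplB": 0.6})
    assert [h.template.id for h in hits] == ["tplB", "tplA"]
    # equal gmqe and qsqe -> lexicographic template id
    hits2 = ts.rank_templates({"t": target}, lib)
    assert [h.template.id for h in hits2] == ["tplA", "tplB"]


def test_ranking_output_order_independent_of_library_order():
    target = "ADKLVEGFRSTY"
    a = fixtures.make_helix(12, sequence=target)
    b = fixtures.make_helix(12, sequence="ADKLVEGFRSAA")
    lib1 = entry_from(a, b, ids=["a", "b"])
    lib2 = entry_from(b, a, ids=["b", "a"])
    ids1 = [h.template.id for h in ts.rank_templates({"t": target}, lib1)]
    ids2 = [h.template.id for h in ts.rank_templates({"t": target}, lib2)]
    assert ids1 == ids2


def test_irrelevant_library_yields_empty_hit_list():
    lib = entry_from(fixtures.make_helix(8, sequence="AAAAAAAA"))
    assert ts.rank_templates({"t": "WWWWYYYY"}, lib) == []


def test_hits_table_has_header_and_rows():
    target = "ADKLVEGFRSTY"
    lib = entry_from(fixtures.make_helix(12, sequence=target), ids=["tpl"])
    table = ts.hits_table(ts.rank_templates({"t": target}, lib))
    lines = table.strip().split("\n")
    assert lines[0].startswith("template_id\t")
    assert len(lines) == 2 and "tpl" in lines[1]
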