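import io

import pytest

from skimlbd import (
    ContingencyTable,
    Document,
    PairResult,
    SearchParams,
    build_index,
    prediction_score,
    run_query_plan,
    select_top_pairs,
    skim_closed,
    skim_open,
)
from skimlbd.engine import read_skim_tsv, write_skim_tsv
from skimlbd.simulate import emit_fixtures


def make_pair(x, y, p, n_both=5, n_y=10):
    table = ContingencyTable(n_both, 5, n_y - n_both, 100)
    return PairResult(x, y, table, p, frozenset(range(n_both)))


# ---------------------------------------------------------------------------
# Prediction score
# ---------------------------------------------------------------------------


def test_score_is_ratio_when_significant():
    assert prediction_score(make_pair("b", "c", 1e-20, n_both=10, n_y=10)) == 1.0
    assert prediction_score(make_pair("b", "c", 1e-12, n_both=8, n_y=100)) == pytest.approx(0.08)


def test_score_zero_when_not_significant():
    assert prediction_score(make_pair("b", "c", 0.5)) == 0.0
    # the gate is strict: p exactly at the threshold scores 0
    assert prediction_score(make_pair("b", "c", 1e-5)) == 0.0


# ---------------------------------------------------------------------------
# Stage-one filter: threshold then cap
# ---------------------------------------------------------------------------


def test_select_top_pairs_threshold_is_strict():
    pairs = [make_pair("a", "b1", 1e-5), make_pair("a", "b2", 9.99e-6)]
    kept = select_top_pairs(pairs, 1e-5, 300)
    assert [p.y_label for p in kept] == ["b2"]


def test_select_top_pairs_cap_keeps_smallest():
    pairs = [make_pair("a", f"b{i:02d}", 1e-8 * (i + 1)) for i in range(10)]
    kept = select_top_pairs(list(reversed(pairs)), 1e-5, 4)
    assert [p.y_label for p in kept] == ["b00", "b01", "b02", "b03"]


def test_select_top_pairs_deterministic_tie_break():
    pairs = [make_pair("a", label, 1e-8) for label in ["bz", "ba", "bm"]]
    kept = select_top_pairs(pairs, 1e-5, 2)
    assert [p.y_label for p in kept] == ["ba", "bm"]


# ---------------------------------------------------------------------------
# Open discovery
# ---------------------------------------------------------------------------


def test_skim_open_recovers_planted_chain(chain_fixture):
    hits = skim_open(
        chain_fixture["a"], chain_fixture["b_terms"], chain_fixture["c_terms"],
        chain_fixture["index"], SearchParams(),
    )
    assert hits, "expected hits from the planted chain"
    assert hits[0].c_label == "targetterm" and hits[0].b_label == "linkterm"
    assert hits[0].rank == 1
    assert [h.rank for h in hits] == list(range(1, len(hits) + 1))
    assert hits[0].ab.p_value < 1e-5


def test_skim_open_no_hit_violates_threshold(chain_fixture):
    hits = skim_open(
        chain_fixture["a"], chain_fixture["b_terms"], chain_fixture["c_terms"],
        chain_fixture["index"], SearchParams(),
    )
    assert all(h.ab.p_value < 1e-5 for h in hits)


def test_skim_open_unreachable_threshold_yields_empty(chain_fixture):
    hits = skim_open(
        chain_fixture["a"], chain_fixture["b_terms"], chain_fixture["c_terms"],
        chain_fixture["index"], SearchParams(ab_p_threshold=1e-300),
    )
    assert hits == []


def test_skim_open_requires_nonempty_lists(chain_fixture):
    with pytest.raises(ValueError):
        skim_open(chain_fixture["a"], [], chain_fixture["c_terms"], chain_fixture["index"])


def test_skim_open_suppresses_trivial_self_link():
    docs = [Document(i, "alpha beta", "beta gamma", 1990) for i in range(1, 40)]
    docs += [Document(i, "filler", "", 1990) for i in range(40, 400)]
    index = build_index(docs)
    hits = skim_open("alpha", ["beta"], ["beta", "gamma"], index, SearchParams())
    assert all(not (h.b_label == h.c_label) for h in hits)
    assert any(h.c_label == "gamma" for h in hits)


def test_skim_open_top_n_caps_output(chain_fixture):
    hits = skim_open(
        chain_fixture["a"], chain_fixture["b_terms"], chain_fixture["c_terms"],
        chain_fixture["index"], SearchParams(top_n=1),
    )
    assert len(hits) == 1 and hits[0].rank == 1


def test_skim_open_deterministic_output(chain_fixture, tmp_path):
    buffers = []
    for _ in range(2):
        hits = skim_open(
            chain_fixture["a"], chain_fixture["b_terms"], chain_fixture["c_terms"],
            chain_fixture["index"], SearchParams(),
        )
        buffer = io.StringIO()
        write_skim_tsv(hits, buffer)
        buffers.append(buffer.getvalue())
    assert buffers[0] == buffers[1]


# ---------------------------------------------------------------------------
# Closed discovery
# ---------------------------------------------------------------------------


@pytest.fixture()
def closed_index():
    # b1 links both ends; b2 co-occurs only with the A term
    docs = [Document(i, "aterm b1", "", 1990) for i in range(1, 31)]
    docs += [Document(i, "b1 cterm", "", 1990) for i in range(31, 61)]
    docs += [Document(i, "aterm b2", "", 1990) for i in range(61, 91)]
    docs += [Document(i, "filler", "", 1990) for i in range(91, 600)]
    return build_index(docs)


def test_skim_closed_reports_only_doubly_linked_b(closed_index):
    links = skim_closed("aterm", "cterm", ["b1", "b2"], closed_index, SearchParams())
    assert [ln.b_label for ln in links] == ["b1"]
    assert links[0].ab.p_value < 1e-5 and links[0].bc.p_value < 1e-5


def test_skim_closed_no_b_significant_on_both_sides(closed_index):
    assert skim_closed("aterm", "cterm", ["b2"], closed_index, SearchParams()) == []


def test_skim_closed_identical_a_and_c(closed_index):
    links = skim_closed("aterm", "aterm", ["b1", "b2"], closed_index, SearchParams())
    assert links
    for link in links:
        # the B-C table is the transpose of the A-B table
        assert link.bc.p_value == pytest.approx(link.ab.p_value, rel=1e-12)
        assert link.bc.table.n_both == link.ab.table.n_both


def test_open_closed_consistency(chain_fixture):
    """For a chain present in both modes, the A-B and B-C p-values agree
    bit-exactly."""
    params = SearchParams()
    hits = skim_open(
        chain_fixture["a"], chain_fixture["b_terms"], chain_fixture["c_terms"],
        chain_fixture["index"], params,
    )
    links = skim_closed(
        chain_fixture["a"], "targetterm", chain_fixture["b_terms"],
        chain_fixture["index"], params,
    )
    open_by_b = {h.b_label: h for h in hits if h.c_label == "targetterm"}
    assert links, "closed search should find the planted B"
    for link in links:
        hit = open_by_b[link.b_label]
        assert hit.ab.p_value == link.ab.p_value  # bit-identical
        assert hit.bc.p_value == link.bc.p_value


# ---------------------------------------------------------------------------
# Query plans and result files
# ---------------------------------------------------------------------------


def test_run_query_plan_open_mode(tmp_path, chain_fixture):
    paths = emit_fixtures(chain_fixture["docs"], chain_fixture["manifest"], tmp_path)
    out = tmp_path / "hits.tsv"
    plan = {
        "mode": "skim-open",
        "corpus": str(paths["jsonl"]),
        "a_terms": str(paths["a_terms"]),
        "b_terms": str(paths["b_terms"]),
        "c_terms": str(paths["c_terms"]),
        "output": str(out),
    }
    result = run_query_plan(plan)
    rows = read_skim_tsv(result)
    assert rows[0]["c_label"] == "targetterm" and rows[0]["rank"] == "1"


def test_run_query_plan_unknown_mode_fails_before_computation(tmp_path):
    with pytest.raises(ValueError, match="mode"):
        run_query_plan({"mode": "sideways", "output": str(tmp_path / "x.tsv")})


def test_run_query_plan_missing_file_fails_fast(tmp_path):
    plan = {
        "mode": "km",
        "corpus": str(tmp_path / "nope.jsonl"),
        "a_terms": str(tmp_path / "nope.tsv"),
        "b_terms": str(tmp_path / "nope.tsv"),
        "output": str(tmp_path / "out.tsv"),
    }
    with pytest.raises((FileNotFoundError, ValueError)):
        run_query_plan(plan)
    assert not (tmp_path / "out.tsv").exists()


def test_run_query_plan_top_n(tmp_path, chain_fixture):
    paths = emit_fixtures(chain_fixture["docs"], chain_fixture["manifest"], tmp_path)
    out = tmp_path / "hits.tsv"
    plan = {
        "mode": "skim-open",
        "corpus": str(paths["jsonl"]),
        "a_terms": str(paths["a_terms"]),
        "b_terms": str(paths["b_terms"]),
        "c_terms": str(paths["c_terms"]),
        "output": str(out),
        "top_n": 5,
    }
    rows = read_skim_tsv(run_query_plan(plan))
    assert len(rows) <= 5


def test_read_skim_tsv_rejects_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("# skimlbd skim-results v1\na_label\tc_label\nx\ty\n")
    with pytest.raises(ValueError, match="b_label"):
        read_skim_tsv(path)


def test_search_params_validation():
    with pytest.raises(ValueError):
        SearchParams(ab_p_threshold=0.0)
    with pytest.raises(ValueError):
        SearchParams(max_b_pairs=0)
    with pytest.raises(ValueError):
        SearchParams(association_measure="mutual-information")
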