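import math
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2 as chi2_dist, fisher_exact

from skimlbd import (
    ContingencyTable,
    Document,
    build_index,
    chi_square,
    contingency,
    fisher_one_sided,
    format_p,
    km_query,
    pair_result,
)
from skimlbd.stats import write_results_tsv


def exact_tail(table: ContingencyTable) -> Fraction:
    """Independent oracle: direct rational summation of the hypergeometric
    upper tail P(X >= a)."""
    a, n, nx, ny = table.n_both, table.n_total, table.n_x, table.n_y
    num = sum(math.comb(nx, k) * math.comb(n - nx, ny - k) for k in range(a, min(nx, ny) + 1))
    return Fraction(num, math.comb(n, ny))


small_tables = st.tuples(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
).map(lambda t: ContingencyTable(*t))


# ---------------------------------------------------------------------------
# Contingency tables from the index
# ---------------------------------------------------------------------------


@pytest.fixture()
def six_doc_index():
    # x hits docs {1,2,3}; y hits docs {3,4}; docs 5,6 contain neither
    docs = [
        Document(1, "xterm", "", 1990),
        Document(2, "xterm", "", 1990),
        Document(3, "xterm yterm", "", 1990),
        Document(4, "yterm", "", 1990),
        Document(5, "other", "", 1990),
        Document(6, "other", "", 1990),
    ]
    return build_index(docs)


def test_contingency_set_arithmetic(six_doc_index):
    table = contingency(six_doc_index, "xterm", "yterm")
    assert (table.n_both, table.n_x_only, table.n_y_only, table.n_neither) == (1, 2, 1, 2)
    assert table.n_total == 6


def test_contingency_disjoint_terms(six_doc_index):
    assert contingency(six_doc_index, "xterm", "other").n_both == 0


def test_contingency_identical_terms(six_doc_index):
    table = contingency(six_doc_index, "xterm", "xterm")
    assert table.n_both == table.n_x == table.n_y == 3
    assert table.n_x_only == table.n_y_only == 0


def test_pair_result_evidence_and_ratio(six_doc_index):
    res = pair_result(six_doc_index, "xterm", "yterm")
    assert res.pmid_evidence == {3}
    assert res.ratio == pytest.approx(1 / 2)  # n_both / n_y
    assert not res.absent


def test_pair_result_absent_term_flagged(six_doc_index):
    res = pair_result(six_doc_index, "xterm", "neverseen")
    assert res.absent and res.p_value == 1.0 and res.ratio == 0.0


def test_table_rejects_negative_counts():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# One-sided exact test
# ---------------------------------------------------------------------------


def test_fisher_hand_checkable_values():
    assert fisher_one_sided(ContingencyTable(0, 10, 10, 80)) == 1.0
    assert fisher_one_sided(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 6, rel=1e-12)
    table = ContingencyTable(5, 5, 5, 85)
    assert fisher_one_sided(table) == pytest.approx(float(exact_tail(table)), rel=1e-12)


@given(small_tables)
def test_fisher_matches_rational_oracle(table):
    expected = float(exact_tail(table)) if table.n_both > 0 else 1.0
    assert fisher_one_sided(table) == pytest.approx(expected, rel=1e-12)


@given(small_tables)
def test_fisher_matches_scipy_greater_tail(table):
    """Cross-check against an independent library implementation."""
    observed = [[table.n_both, table.n_x_only], [table.n_y_only, table.n_neither]]
    _odds, expected = fisher_exact(observed, alternative="greater")
    assert fisher_one_sided(table) == pytest.approx(expected, rel=1e-9)


@given(small_tables)
def test_fisher_bounds_and_symmetry(table):
    p = fisher_one_sided(table)
    assert 0.0 < p <= 1.0
    assert fisher_one_sided(table.transpose()) == pytest.approx(p, rel=1e-12)
    if table.n_both == 0:
        assert p == 1.0


@given(st.integers(2, 40), st.data())
def test_fisher_monotone_in_overlap(n, data):
    """With N and both margins fixed, p is non-increasing as the overlap
    count a grows."""
    nx = data.draw(st.integers(1, n - 1))
    ny = data.draw(st.integers(1, n - 1))
    k_min, k_max = max(0, nx + ny - n), min(nx, ny)
    previous = None
    for a in range(k_min, k_max + 1):
        table = ContingencyTable(a, nx - a, ny - a, n - nx - ny + a)
        p = fisher_one_sided(table)
        if previous is not None:
            assert p <= previous + 1e-15
        previous = p


def test_fisher_extreme_table_far_below_display_floor():
    # massive enrichment: p underflows past 2.2e-308 and displays as "0"
    table = ContingencyTable(500, 0, 0, 100000)
    p = fisher_one_sided(table)
    assert p < 2.2e-308
    assert format_p(p) == "0"


# ---------------------------------------------------------------------------
# Chi-square alternative
# ---------------------------------------------------------------------------


def test_chi_square_exact_independence():
    result = chi_square(ContingencyTable(25, 25, 25, 25))
    assert result.statistic == pytest.approx(0.0) and result.p_value == pytest.approx(1.0)
    assert not result.degenerate


def test_chi_square_hand_computed_statistic():
    # N=100, margins 25/75 each way, all four cells deviate by 13.75:
    # X^2 = 189.0625 * (1/6.25 + 2/18.75 + 1/56.25) = 53.7777...
    result = chi_square(ContingencyTable(20, 5, 5, 70))
    statistic = 189.0625 * (1 / 6.25 + 2 / 18.75 + 1 / 56.25)
    assert result.statistic == pytest.approx(statistic, rel=1e-12)
    assert result.p_value == pytest.approx(float(chi2_dist.sf(statistic, 1)), rel=1e-12)


def test_chi_square_zero_margin_is_degenerate():
    result = chi_square(ContingencyTable(0, 0, 5, 5))
    assert result.degenerate and result.p_value == 1.0


# ---------------------------------------------------------------------------
# Display convention
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    ("p", "display"),
    [
        (1e-310, "0"),
        (2.2e-309, "0"),
        (2.3e-33, "2e-33"),
        (6.4e-106, "6e-106"),
        (9.7e-8, "1e-7"),
        (0.17, "0.2"),
        (0.05, "0.05"),
        (1.0, "1"),
    ],
)
def test_format_p(p, display):
    assert format_p(p) == display


def test_format_p_rejects_out_of_range():
    with pytest.raises(ValueError):
        format_p(1.5)


# ---------------------------------------------------------------------------
# Single-stage query
# ---------------------------------------------------------------------------


def test_km_query_cardinality_and_order(six_doc_index):
    results = km_query(["xterm"], ["yterm", "other", "neverseen"], six_doc_index)
    assert len(results) == 3
    assert [r.p_value for r in results] == sorted(r.p_value for r in results)


def test_km_query_planted_pair_is_most_significant(chain_fixture):
    results = km_query(
        [chain_fixture["a"]], chain_fixture["b_terms"], chain_fixture["index"]
    )
    assert results[0].y_label == "linkterm"


def test_km_query_cutoff_excluding_everything(six_doc_index):
    results = km_query(["xterm"], ["yterm"], six_doc_index, cutoff_year=1500)
    assert all(r.p_value == 1.0 and r.table.n_total == 0 for r in results)


def test_km_query_requires_nonempty_lists(six_doc_index):
    with pytest.raises(ValueError):
        km_query([], ["yterm"], six_doc_index)


def test_results_tsv_schema(tmp_path, six_doc_index):
    path = tmp_path / "results.tsv"
    write_results_tsv(km_query(["xterm"], ["yterm"], six_doc_index), path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("# skimlbd pair-results v")
    header = lines[1].split("\t")
    assert header[:5] == ["x_label", "y_label", "n_x", "n_y", "n_both"]
    assert len(lines) == 3
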