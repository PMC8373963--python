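"""Quantitative web assembly, diversity and the weighted metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from aphidweb.webs import (
    QuantitativeWeb,
    build_web,
    community_summary,
    shannon_diversity,
    taxon_entropies,
    web_metrics,
)
from conftest import rec


# ---------------------------------------------------------------------------
# independent literal transcription of the weighted-metric definitions,
# coded with explicit loops; the oracle for the vectorized implementation


def oracle_metrics(b):
    b = np.asarray(b, dtype=float)
    rows, cols = b.shape
    btot = b.sum()

    def n_N(k):
        colsum = b[:, k].sum()
        if colsum == 0:
            return 0.0
        h = 0.0
        for i in range(rows):
            if b[i, k] > 0:
                p = b[i, k] / colsum
                h -= p * math.log2(p)
        return 2.0**h

    def n_P(i):
        rowsum = b[i, :].sum()
        if rowsum == 0:
            return 0.0
        h = 0.0
        for k in range(cols):
            if b[i, k] > 0:
                p = b[i, k] / rowsum
                h -= p * math.log2(p)
        return 2.0**h

    gq = sum((b[:, k].sum() / btot) * n_N(k) for k in range(cols))
    vq = sum((b[i, :].sum() / btot) * n_P(i) for i in range(rows))
    s = sum(1 for i in range(rows) if b[i, :].sum() > 0) + sum(
        1 for k in range(cols) if b[:, k].sum() > 0
    )
    cq = 0.5 * (gq + vq) / s
    return gq, vq, cq, s


def make_web(b):
    b = np.asarray(b, dtype=float)
    return QuantitativeWeb(
        lower_species=[f"P{i}" for i in range(b.shape[0])],
        upper_species=[f"H{k}" for k in range(b.shape[1])],
        b=b,
    )


# ---------------------------------------------------------------------------
# Shannon diversity and community summaries


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([10, 10], math.log(2)),
        ([7], 0.0),
        ([1, 2, 3], 1.0114042647073518),  # -sum(p ln p), p = 1/6, 2/6, 3/6
        ([2, 2, 2, 2], math.log(4)),
    ],
)
def test_shannon_examples(counts, expected):
    assert shannon_diversity(counts) == pytest.approx(expected, abs=1e-12)


def test_shannon_rejects_degenerate_input():
    with pytest.raises(ValueError):
        shannon_diversity([0, 0])
    with pytest.raises(ValueError):
        shannon_diversity([3, -1])


def test_community_summary_zero_counts_ignored():
    cs = community_summary([5, 0, 3])
    assert (cs.abundance, cs.richness) == (8, 2)
    assert cs.shannon == pytest.approx(-(5 / 8 * math.log(5 / 8) + 3 / 8 * math.log(3 / 8)))


def test_community_summary_single_species_has_zero_diversity():
    cs = community_summary([1])
    assert (cs.abundance, cs.richness, cs.shannon) == (1, 1, 0.0)


@given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=12).filter(lambda c: sum(c) > 0))
@settings(max_examples=200, derandomize=True)
def test_shannon_bounds_and_permutation_invariance(counts):
    h = shannon_diversity(counts)
    richness = sum(1 for c in counts if c > 0)
    assert 0.0 <= h <= math.log(richness) + 1e-12
    assert shannon_diversity(sorted(counts, reverse=True)) == pytest.approx(h)


# ---------------------------------------------------------------------------
# web assembly


def test_build_web_counts_links(small_records):
    web = build_web(small_records)
    assert web.lower_species == ["P1", "P2"]
    assert web.upper_species == ["H1", "H2"]
    assert web.b[0, 0] == 2 and web.b[1, 1] == 1
    assert web.total == 3
    assert web.diagnostics.n_links == 3


def test_build_web_without_hyperparasitoids_is_empty():
    records = [rec("A", 2014, f"m{i}", "P1") for i in range(5)]
    web = build_web(records)
    assert web.total == 0
    assert web.n_acting_species == 0


def test_build_web_orphan_hyper_excluded_and_logged():
    records = [
        rec("A", 2014, "m1", "P1", ["H1"]),
        rec("A", 2014, "m2", None, ["H1"]),  # hyperparasitoid with unknown resource
    ]
    web = build_web(records)
    assert web.total == 1
    assert web.diagnostics.n_orphan_hyper == 1
    assert web.diagnostics.orphan_sample_ids == ["m2"]


def test_build_web_total_matches_independent_tally(default_bundle):
    records = default_bundle.detections
    web = build_web(records)
    tally = sum(len(r.hyper_species) for r in records if r.primary_species is not None)
    assert web.total == tally


def test_build_web_site_year_scope(small_records):
    extra = [rec("B", 2015, "x1", "P1", ["H1"])]
    webs = build_web(small_records + extra, scope="site-year")
    assert set(webs) == {("A", 2014), ("B", 2015)}
    assert webs[("A", 2014)].total == 3
    assert webs[("B", 2015)].total == 1


# ---------------------------------------------------------------------------
# entropies and metrics


def test_taxon_entropies_column_examples():
    web = make_web([[2, 0], [1, 5]])
    eff = taxon_entropies(web)
    # column (2,1): H = -(2/3 log2 2/3 + 1/3 log2 1/3)
    h = -(2 / 3 * math.log2(2 / 3) + 1 / 3 * math.log2(1 / 3))
    assert eff["H_N"][0] == pytest.approx(h)
    assert eff["n_N"][0] == pytest.approx(2**h)
    # column (0,5): a single host species, entropy 0, one effective host
    assert eff["H_N"][1] == 0.0
    assert eff["n_N"][1] == 1.0


def test_taxon_entropies_zero_margin_gets_zero_effective_number():
    web = make_web([[1, 0], [1, 0]])
    eff = taxon_entropies(web)
    assert eff["n_N"][1] == 0.0


@pytest.mark.parametrize(
    "b, gq, vq, cq",
    [
        (np.eye(3), 1.0, 1.0, 1 / 6),  # perfect specialists
        (np.ones((2, 2)), 2.0, 2.0, 0.5),  # uniform web
        ([[2, 0], [1, 1]], 1.6674111811317325, 1.5, 0.39592639764146653),
    ],
)
def test_web_metrics_examples(b, gq, vq, cq):
    m = web_metrics(make_web(b))
    assert m.generality == pytest.approx(gq, abs=1e-10)
    assert m.vulnerability == pytest.approx(vq, abs=1e-10)
    assert m.connectance == pytest.approx(cq, abs=1e-10)


def test_web_metrics_empty_web_errors():
    with pytest.raises(ValueError):
        web_metrics(make_web(np.zeros((2, 2))))


def test_metrics_match_oracle_on_exhaustive_small_webs():
    """Vectorized metrics equal the literal-transcription oracle on every
    small web (all shapes up to 9 cells, entries in {0,1,2})."""
    checked = 0
    for rows in range(1, 5):
        for cols in range(1, 5):
            if rows * cols > 9:
                continue
            for flat in np.ndindex(*(3,) * (rows * cols)):
                b = np.array(flat, dtype=float).reshape(rows, cols)
                if b.sum() == 0:
                    continue
                m = web_metrics(make_web(b))
                gq, vq, cq, s = oracle_metrics(b)
                assert m.generality == pytest.approx(gq, abs=1e-12)
                assert m.vulnerability == pytest.approx(vq, abs=1e-12)
                assert m.connectance == pytest.approx(cq, abs=1e-12)
                assert m.n_acting_species == s
                checked += 1
    assert checked > 30000


web_matrices = arrays(
    np.int64,
    st.tuples(st.integers(1, 4), st.integers(1, 4)),
    elements=st.integers(0, 5),
).filter(lambda b: b.sum() > 0)


@given(web_matrices)
@settings(max_examples=300, derandomize=True)
def test_transpose_duality(b):
    """Swapping trophic levels swaps generality and vulnerability."""
    m = web_metrics(make_web(b))
    mt = web_metrics(make_web(b).transpose())
    assert m.generality == pytest.approx(mt.vulnerability, abs=1e-10)
    assert m.vulnerability == pytest.approx(mt.generality, abs=1e-10)
    assert m.connectance == pytest.approx(mt.connectance, abs=1e-10)


@given(web_matrices, st.integers(2, 7))
@settings(max_examples=200, derandomize=True)
def test_scale_invariance(b, factor):
    """Multiplying all counts by a constant leaves the metrics unchanged."""
    m1 = web_metrics(make_web(b))
    m2 = web_metrics(make_web(b * factor))
    assert m1.generality == pytest.approx(m2.generality, abs=1e-10)
    assert m1.vulnerability == pytest.approx(m2.vulnerability, abs=1e-10)
    assert m1.connectance == pytest.approx(m2.connectance, abs=1e-10)


@given(web_matrices)
@settings(max_examples=300, derandomize=True)
def test_metric_bounds(b):
    """1 <= Gq <= acting lower species; 1 <= Vq <= acting upper species."""
    m = web_metrics(make_web(b))
    lower_acting = int((b.sum(axis=1) > 0).sum())
    upper_acting = int((b.sum(axis=0) > 0).sum())
    assert 1.0 - 1e-10 <= m.generality <= lower_acting + 1e-10
    assert 1.0 - 1e-10 <= m.vulnerability <= upper_acting + 1e-10
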