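"""FPKM arithmetic, Fisher/hypergeometric exactness, BH, class summaries."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structrip.enrichment_stats import (
    MembershipError, bh_adjust, class_enrichment_summary, compute_fpkm,
    hypergeometric_overlap, quantify, top_abundant,
)
from structrip.enrichment_stats import test_enrichment as enrichment_test


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher: sum of probabilities of all tables with
    the same margins that are no more likely than the observed one."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hypergeom_upper_tail_oracle(k, n_total, n_a, n_b):
    """P[X >= k] for X ~ Hypergeom(N, |A|, |B|) by exact summation."""
    denom = comb(n_total, n_b)
    lo, hi = max(k, max(0, n_a + n_b - n_total)), min(n_a, n_b)
    return float(sum(
        Fraction(comb(n_a, x) * comb(n_total - n_a, n_b - x), denom)
        for x in range(lo, hi + 1)
    ))


def test_fpkm_closed_form():
    assert compute_fpkm(1000, 1000, 1_000_000) == pytest.approx(1000.0)
    assert compute_fpkm(0, 500, 1_000_000) == 0.0


@settings(derandomize=True, max_examples=50)
@given(
    count=st.integers(0, 10_000),
    length=st.integers(1, 50_000),
    total=st.integers(1, 10**7),
    k=st.integers(1, 1000),
)
def test_fpkm_invariant_under_joint_scaling(count, length, total, k):
    base = compute_fpkm(count, length, total)
    scaled = compute_fpkm(count * k, length, total * k)
    assert scaled == pytest.approx(base, rel=1e-12)


def test_fpkm_domain_errors():
    with pytest.raises(ValueError):
        compute_fpkm(1, 0, 100)
    with pytest.raises(ValueError):
        compute_fpkm(1, 100, 0)


def test_enrichment_empty_evidence():
    fc, p = enrichment_test(0, 0, 1000, 1000)
    assert fc == 1.0 and p == 1.0


def test_enrichment_matches_fisher_oracle():
    ip, inp, tot = 80, 10, 100_000
    _, p = enrichment_test(ip, inp, tot, tot)
    expected = fisher_two_sided_oracle(ip, tot - ip, inp, tot - inp)
    assert p == pytest.approx(expected, rel=1e-9)


def test_enrichment_symmetric_under_swap():
    fc, p = enrichment_test(30, 12, 5000, 4000, length=200)
    fc_sw, p_sw = enrichment_test(12, 30, 4000, 5000, length=200)
    assert p == pytest.approx(p_sw, rel=1e-12)
    assert fc * fc_sw == pytest.approx(1.0, rel=0.05)  # eps breaks exact inversion


def test_enrichment_count_exceeding_total_rejected():
    with pytest.raises(ValueError):
        enrichment_test(10, 2, 5, 100)


def test_hypergeometric_overlap_exact_and_boundaries():
    universe = set(range(20))
    a = set(range(10))
    b = set(range(1, 10)) | {15}
    res = hypergeometric_overlap(a, b, universe)
    assert res.n_overlap == 9
    assert res.p == pytest.approx(hypergeom_upper_tail_oracle(9, 20, 10, 10), rel=1e-12)
    # forced outcome
    full = hypergeometric_overlap(universe, universe, universe)
    assert full.n_overlap == 20 and full.p == pytest.approx(1.0)
    # disjoint sets: p ~ 1 without underflow
    disjoint = hypergeometric_overlap(set(range(5)), set(range(10, 15)), universe)
    assert 0.99 <= disjoint.p <= 1.0
    with pytest.raises(MembershipError):
        hypergeometric_overlap({99}, b, universe)


def test_bh_hand_oracle_and_properties():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_bh_order_equivariance_and_dominance(pvals, rnd):
    p = np.array(pvals)
    q = bh_adjust(p)
    assert (q >= p - 1e-12).all() and (q <= 1.0).all()
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    q_perm = bh_adjust(p[perm])
    np.testing.assert_allclose(q_perm, q[perm], atol=1e-15)


def test_bh_matches_statsmodels_oracle():
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(0)
    p = rng.uniform(size=200)
    expected = statsmodels.multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


def _toy_quants():
    return pd.DataFrame({
        "transcript_id": [f"T{i}" for i in range(6)],
        "class": ["snoRNA-H/ACA", "snoRNA-H/ACA", "snoRNA-C/D",
                  "scaRNA", "coding", "coding"],
        "box_type": ["H/ACA", "H/ACA", "C/D", "none", "none", "none"],
        "ip_fpkm": [5.0, 5.0, 3.0, 2.0, 10.0, 1.0],
        "input_fpkm": [2.0, 0.5, 2.0, 2.0, 10.0, 1.0],
        "expressed": [True, False, True, True, True, True],
        "enriched": [True, False, False, False, False, False],
    })


def test_top_abundant_tie_rule_and_bounds():
    q = _toy_quants()
    top, comp = top_abundant(q, n=3)
    assert list(top["transcript_id"]) == ["T4", "T0", "T1"]  # ties by id
    empty, _ = top_abundant(q, n=0)
    assert len(empty) == 0
    allq, _ = top_abundant(q, n=100)
    assert len(allq) == len(q)
    assert comp["count"].sum() == 3


def test_class_summary_fraction_and_na():
    summary = class_enrichment_summary(_toy_quants()).set_index("group")
    assert summary.loc["snoRNA-H/ACA", "n_expressed"] == 1
    assert summary.loc["snoRNA-H/ACA", "fraction"] == pytest.approx(1.0)
    # box-type rows partition the snoRNA total
    sno_total = summary.loc["snoRNA (all)", "n_expressed"]
    assert (summary.loc["snoRNA H/ACA", "n_expressed"]
            + summary.loc["snoRNA C/D", "n_expressed"]) == sno_total


def test_class_summary_49_of_174():
    q = pd.DataFrame({
        "transcript_id": [f"S{i}" for i in range(174)],
        "class": ["snoRNA-H/ACA"] * 174,
        "box_type": ["H/ACA"] * 174,
        "ip_fpkm": 1.0, "input_fpkm": 2.0,
        "expressed": True,
        "enriched": [True] * 49 + [False] * 125,
    })
    summary = class_enrichment_summary(q).set_index("group")
    assert summary.loc["snoRNA (all)", "fraction"] == pytest.approx(49 / 174)


def test_quantify_null_flags_within_alpha(bundle):
    """Global null: with the FC gate on top of p < 0.05, the flagged fraction
    stays at or below alpha."""
    rng = np.random.default_rng(7)
    tx = bundle.transcripts
    n = len(tx)
    ip = {f"IP_{r}": pd.Series(rng.poisson(60, n), index=tx["transcript_id"])
          for r in (1, 2)}
    inp = {f"Input_{r}": pd.Series(rng.poisson(60, n), index=tx["transcript_id"])
           for r in (1, 2)}
    q = quantify(ip, inp, tx)
    assert q["enriched"].mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
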