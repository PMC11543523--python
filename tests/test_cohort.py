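"""Patient categorization, rank statistics against enumeration oracles,
and the synthetic cohort generator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from papvr.cohort import (
    CohortValidationError,
    PatientRecord,
    categorize_model_variant,
    correlations,
    frame_to_records,
    generate_synthetic_cohort,
    kruskal_wallis,
    rank_sum_test,
    read_cohort_csv,
    records_to_frame,
    summarize_cohort,
    write_cohort_csv,
)


def _rec(**kw):
    base = dict(id="P1", age=40, sex="F", clinical_variant="SVC",
                n_territories=2, distance_to_ra_cm=3.0, qp_qs_invasive=1.5)
    base.update(kw)
    return PatientRecord(**base)


# -- categorization ----------------------------------------------------------

def test_categorization_rule():
    assert categorize_model_variant(_rec(clinical_variant="L", distance_to_ra_cm=None)) == "VC"
    assert categorize_model_variant(_rec(clinical_variant="SVC", distance_to_ra_cm=3.0)) == "VC"
    assert categorize_model_variant(_rec(clinical_variant="RA", distance_to_ra_cm=0.5)) == "RA"
    assert categorize_model_variant(_rec(clinical_variant="SVC", distance_to_ra_cm=2.0)) == "RA"


def test_missing_distance_handling():
    rec = _rec(clinical_variant="SVC", distance_to_ra_cm=None)
    with pytest.raises(CohortValidationError):
        categorize_model_variant(rec)
    assert categorize_model_variant(rec, permissive=True) == "VC"
    assert categorize_model_variant(
        _rec(clinical_variant="RA", distance_to_ra_cm=None), permissive=True
    ) == "RA"


def test_record_validation():
    with pytest.raises(CohortValidationError):
        _rec(qp_qs_invasive=None)  # no Qp/Qs estimation at all
    with pytest.raises(CohortValidationError):
        _rec(pvr_wu=3.5)  # exclusion criterion
    with pytest.raises(CohortValidationError):
        _rec(n_territories=4)
    with pytest.raises(CohortValidationError):
        _rec(clinical_variant="L")  # L with a distance recorded


# -- rank statistics vs enumeration oracles ---------------------------------

def _exact_ranksum_p(a, b):
    """Brute-force two-sided rank-sum p by enumerating all C(n, na) rank
    assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = len(a)
    w_obs = ranks[:na].sum()
    mu = na * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def test_rank_sum_exact_small_sample():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    stat, p = rank_sum_test(a, b)
    assert stat == 6.0  # ranks 1+2+3
    assert p == pytest.approx(0.1)  # 2 * 1/20
    assert p == pytest.approx(_exact_ranksum_p(a, b))


@pytest.mark.parametrize("a,b", [
    ([1.2, 3.4, 2.2, 5.0], [2.5, 4.1, 6.3]),
    ([0.1, 0.2], [0.3, 0.4, 0.5, 0.6]),
])
def test_rank_sum_matches_enumeration(a, b):
    _, p = rank_sum_test(a, b)
    assert p == pytest.approx(_exact_ranksum_p(np.array(a), np.array(b)))


def test_rank_sum_degenerate_and_invariance():
    _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p > 0.99
    _, p_id = rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0])
    assert p_id == 1.0
    # rank test is invariant under common strictly monotone transforms
    a, b = [1.0, 2.5, 3.0, 7.0], [2.0, 4.0, 5.5]
    _, p1 = rank_sum_test(a, b)
    _, p2 = rank_sum_test(np.exp(a), np.exp(b))
    assert p1 == pytest.approx(p2)


def test_kruskal_wallis_hand_enumeration():
    """Groups {1,2},{3,4},{5,6}: ranks are the values themselves, so
    H = 12/(n(n+1)) * sum(R_j^2/n_j) - 3(n+1) = 4.571428..."""
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    h_expected = 12.0 / (6 * 7) * (3.0**2 / 2 + 7.0**2 / 2 + 11.0**2 / 2) - 3 * 7
    stat, p_exact = kruskal_wallis(groups, method="exact")
    assert stat == pytest.approx(h_expected)
    # oracle: enumerate all 90 distinct assignments of 6 ranks into (2,2,2)
    ranks = np.arange(1.0, 7.0)
    count = total = 0
    for g1 in itertools.combinations(range(6), 2):
        rest = [i for i in range(6) if i not in g1]
        for g2 in itertools.combinations(rest, 2):
            g3 = [i for i in rest if i not in g2]
            r1, r2, r3 = ranks[list(g1)].sum(), ranks[list(g2)].sum(), ranks[list(g3)].sum()
            h = 12.0 / 42 * (r1**2 / 2 + r2**2 / 2 + r3**2 / 2) - 21
            total += 1
            if h >= h_expected - 1e-12:
                count += 1
    assert p_exact == pytest.approx(count / total)


def test_kruskal_wallis_two_group_consistency():
    a = [1.1, 2.3, 3.8, 4.2, 5.5, 6.1, 7.9]
    b = [2.8, 4.9, 6.6, 8.1, 9.3, 10.2, 11.0]
    _, p_rs = rank_sum_test(a, b)
    _, p_kw = kruskal_wallis([a, b], method="asymptotic")
    assert p_kw == pytest.approx(p_rs, abs=0.05)


def test_kruskal_wallis_null_calibration():
    """Under the null (one permuted pool) E[H] = k - 1."""
    rng = np.random.default_rng(42)
    pool = rng.normal(size=10)
    hs = []
    for _ in range(4000):
        rng.shuffle(pool)
        stat, _ = kruskal_wallis([pool[:4], pool[4:7], pool[7:]], method="asymptotic")
        hs.append(stat)
    assert np.mean(hs) == pytest.approx(2.0, rel=0.05)


def test_kruskal_wallis_guards():
    with pytest.raises(Exception):
        kruskal_wallis([[1.0, 2.0]])
    with pytest.raises(Exception):
        kruskal_wallis([list(range(8)), list(range(8))], method="exact")


def test_correlations():
    x = np.linspace(0.0, 2.0, 10)
    r = correlations(x, x)
    assert r.pearson_r == pytest.approx(1.0) and r.spearman_rho == pytest.approx(1.0)
    r = correlations(x, np.exp(x**2))
    assert r.spearman_rho == pytest.approx(1.0)
    assert r.pearson_r < 1.0
    r = correlations(x, -x)
    assert r.pearson_r == pytest.approx(-1.0) and r.spearman_rho == pytest.approx(-1.0)
    # complete-case handling and degenerate input
    r = correlations([1.0, None, 2.0, 3.0, 4.0], [2.0, 9.9, None, 6.0, 8.0])
    assert r.pearson_r == pytest.approx(1.0)
    assert correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]).pearson_r is None


# -- synthetic cohort --------------------------------------------------------

def test_synthetic_cohort_deterministic():
    a = records_to_frame(generate_synthetic_cohort(seed=17))
    b = records_to_frame(generate_synthetic_cohort(seed=17))
    assert a.equals(b)
    c = records_to_frame(generate_synthetic_cohort(seed=18))
    assert not a.equals(c)


def test_synthetic_cohort_structure():
    records = generate_synthetic_cohort(seed=0)
    df = records_to_frame(records)
    assert len(df) == 49
    assert (df["clinical_variant"] != "L").sum() == 36
    assert (df["clinical_variant"] == "L").sum() == 13
    groups = pd.Series([categorize_model_variant(r) for r in records])
    assert (groups == "RA").sum() == 19
    assert (groups == "VC").sum() == 30
    # catheterization subset at 2 territories: 13 VC vs 4 RA
    cath = df["qp_qs_invasive"].notna()
    t2 = cath & (df["n_territories"] == 2)
    assert ((groups == "VC") & t2).sum() == 13
    assert ((groups == "RA") & t2).sum() == 4
    # missingness pattern: 16 invasive-only / 20 both / 13 CMR-only
    cmr = df["qp_qs_cmr"].notna()
    assert int((cath & ~cmr).sum()) == 16
    assert int((cath & cmr).sum()) == 20
    assert int((~cath & cmr).sum()) == 13
    # inclusion criteria hold for every record (validated on construction)
    assert (df["pvr_wu"] <= 3.0).all()


def test_synthetic_median_matching():
    """Across seeds the per-stratum sample medians centre on the configured
    targets to within IQR width / sqrt(n)."""
    target = {(2, "RA"): 2.0, (3, "VC"): 1.7}
    iqr_w = {(2, "RA"): 0.2, (3, "VC"): 0.7}
    meds = {k: [] for k in target}
    ns = {k: [] for k in target}
    for seed in range(100):
        records = generate_synthetic_cohort(seed=seed)
        df = records_to_frame(records)
        df["g"] = [categorize_model_variant(r) for r in records]
        for (terr, grp) in target:
            vals = df[(df["n_territories"] == terr) & (df["g"] == grp)][
                "qp_qs_invasive"].dropna()
            meds[(terr, grp)].append(vals.median())
            ns[(terr, grp)].append(len(vals))
    for key, med_target in target.items():
        tol = iqr_w[key] / np.sqrt(np.mean(ns[key]))
        assert np.mean(meds[key]) == pytest.approx(med_target, abs=max(tol, 0.05)), key


def test_cmr_invasive_rank_correlation():
    """Dual-modality patients show the configured rank correlation (pooled
    over seeds to tame small-sample noise)."""
    rhos = []
    for seed in range(8):
        df = records_to_frame(generate_synthetic_cohort(seed=seed))
        both = df.dropna(subset=["qp_qs_invasive", "qp_qs_cmr"])
        r = correlations(both["qp_qs_invasive"], both["qp_qs_cmr"])
        rhos.append(r.spearman_rho)
    assert np.mean(rhos) == pytest.approx(0.75, abs=0.15)


def test_pipeline_closure_and_summary(tmp_path):
    records = generate_synthetic_cohort(seed=3)
    summary = summarize_cohort(records)
    assert summary.n == 49
    assert summary.counts["model_RA"] == 19
    assert set(summary.stratum_table["model_group"]) == {"RA", "VC"}
    assert {1, 2, 3} == set(summary.stratum_table["n_territories"])
    assert "ra_vs_vc_invasive" in summary.tests
    # median/IQR ordering invariant
    for _, row in summary.stratum_table.iterrows():
        if not np.isnan(row.get("invasive_median", np.nan)):
            assert row["invasive_q25"] <= row["invasive_median"] <= row["invasive_q75"]
    # CSV round trip
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    back = read_cohort_csv(path)
    assert records_to_frame(back).equals(records_to_frame(records))


def test_summarize_small_strata():
    records = [
        _rec(id="a", qp_qs_invasive=1.2, clinical_variant="L", distance_to_ra_cm=None),
        _rec(id="b", qp_qs_invasive=1.4, clinical_variant="L", distance_to_ra_cm=None),
        _rec(id="c", qp_qs_invasive=1.5, clinical_variant="L", distance_to_ra_cm=None),
        _rec(id="d", qp_qs_invasive=1.9, clinical_variant="RA", distance_to_ra_cm=0.0,
             n_territories=3),
    ]
    summary = summarize_cohort(records)
    t2 = summary.stratum_table
    vc2 = t2[(t2.n_territories == 2) & (t2.model_group == "VC")].iloc[0]
    assert vc2["invasive_median"] == pytest.approx(1.4)  # odd-length median
    ra3 = t2[(t2.n_territories == 3) & (t2.model_group == "RA")].iloc[0]
    assert ra3["invasive_median"] == pytest.approx(1.9)  # singleton stratum
    assert ra3["invasive_q25"] == ra3["invasive_q75"] == pytest.approx(1.9)
    # absent strata are not reported as zeros
    assert not ((t2.n_territories == 1)).any()
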