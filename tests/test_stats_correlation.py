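import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pulsekin import matrix_assembly as ma
from pulsekin import stats_correlation as sc


# --- Spearman building blocks ----------------------------------------------

def oracle_spearman(x, y):
    """Rank (average ties, via pandas) then Pearson by the explicit formula."""
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def test_spearman_matches_oracle_on_random_vectors():
    rng = np.random.default_rng(1234)
    for _ in range(1000):
        n = rng.integers(4, 30)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rng.random() < 0.3:  # inject ties
            x = np.round(x)
            y = np.round(y)
        rho, p, _ = sc.spearman(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)


def test_spearman_exact_small_n_agrees_with_enumeration():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [1.0, 3.0, 2.0, 5.0, 4.0]
    rho, p_exact, _ = sc.spearman(x, y, exact=True)
    # enumeration over 5! permutations is the oracle inside spearman(exact=True);
    # cross-check against scipy's exact p for small samples
    ref = sps.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic)
    assert 0.0 < p_exact < 1.0


@pytest.mark.parametrize(
    "n, expected",
    [(12, 0.576), (10, 0.632)],  # 0.632 = sqrt(t^2/(8+t^2)), t = t_{0.975,8}
)
def test_critical_rho_thresholds(n, expected):
    assert sc.critical_rho(n) == pytest.approx(expected, abs=1e-3)


def test_critical_rho_monotone_in_n_and_alpha():
    values = [sc.critical_rho(n) for n in range(5, 40)]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert sc.critical_rho(12, alpha=0.01) > sc.critical_rho(12, alpha=0.05)


def test_rho_at_critical_value_is_significant():
    rho = sc.critical_rho(12) + 1e-6
    assert sc.spearman_pvalue(rho, 12) < 0.05
    assert sc.spearman_pvalue(rho - 2e-6, 12) > 0.05


# --- BH --------------------------------------------------------------------

def oracle_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, pvals[idx] * m / rank)
        q[idx] = prev
    return q


def test_bh_worked_example():
    q = sc.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_matches_stepup_oracle_and_is_monotone(pvals):
    p = np.asarray(pvals)
    q = sc.bh_adjust(p)
    assert np.allclose(q, oracle_bh(p))
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_single_test_is_identity():
    assert sc.bh_adjust([0.037])[0] == pytest.approx(0.037)


# --- matrix-level correlations ---------------------------------------------

def _matrix(protein, kloss, mrna, samples):
    idx = [f"g{i}" for i in range(len(protein))]
    mk = lambda a: pd.DataFrame(a, index=idx, columns=samples, dtype=float)
    meta = pd.DataFrame(
        {"gene_id": idx, "class": "UQ", "representative": idx}, index=idx
    )
    return ma.OmicsMatrix(mk(protein), mk(kloss), mk(mrna), meta)


def test_absolute_correlation_monotone_layers_give_unit_rho():
    samples = ["S1", "S2"]
    vals = [[i, i + 0.5] for i in range(6)]
    squared = [[v**2 for v in row] for row in vals]  # monotone transform
    om = _matrix(vals, squared, vals, samples)
    rho, p, n = sc.absolute_correlation(om, "protein_kloss")
    assert rho == pytest.approx(1.0)
    assert n == 6


def test_absolute_correlation_reversed_ranks():
    samples = ["S1"]
    x = [[i] for i in range(5)]
    y = [[-i] for i in range(5)]
    om = _matrix(x, y, x, samples)
    rho, _, _ = sc.absolute_correlation(om, "protein_kloss")
    assert rho == pytest.approx(-1.0)


def test_absolute_correlation_hand_ranked_table():
    # 5 rows with a tie in y: hand-computed average-rank Spearman
    x = [[1.0], [2.0], [3.0], [4.0], [5.0]]
    y = [[10.0], [10.0], [30.0], [20.0], [50.0]]
    om = _matrix(x, y, x, ["S1"])
    rho, _, _ = sc.absolute_correlation(om, "protein_kloss")
    # ranks x = 1..5; ranks y = 1.5, 1.5, 4, 3, 5
    assert rho == pytest.approx(oracle_spearman([1, 2, 3, 4, 5], [10, 10, 30, 20, 50]))


def test_absolute_correlation_needs_three_rows():
    om = _matrix([[1.0], [2.0]], [[1.0], [2.0]], [[1.0], [2.0]], ["S1"])
    with pytest.raises(ValueError, match="3"):
        sc.absolute_correlation(om, "mRNA_kloss")


def test_relative_correlation_rank_identical_fold_changes():
    samples = ["A1", "A2", "B1", "B2"]
    cond = {s: s[0] for s in samples}
    rng = np.random.default_rng(0)
    base = rng.normal(size=(8, 1))
    fc = rng.normal(size=(8, 1))
    x = np.hstack([base + fc, base + fc, base, base])
    om = _matrix(x, x * 2.0, x, samples)  # layer fold changes rank-identical
    rho, _, _ = sc.relative_correlation(om, cond, "mRNA_kloss")
    assert rho == pytest.approx(1.0)


def test_relative_correlation_label_permutation_centers_at_zero():
    rng = np.random.default_rng(7)
    samples = ["A1", "A2", "B1", "B2"]
    cond = {s: s[0] for s in samples}
    x = rng.normal(size=(40, 4))
    rhos = []
    for _ in range(200):
        y = x[rng.permutation(40)]
        om = _matrix(x, y, x, samples)
        rhos.append(sc.relative_correlation(om, cond, "mRNA_kloss")[0])
    assert abs(np.mean(rhos)) < 0.05


def test_per_group_correlation_monotone_row():
    samples = [f"S{i}" for i in range(12)]
    x = [list(range(12))]
    om = _matrix(x, x, x, samples)
    res = sc.per_group_correlation(om, "mRNA_kloss")
    assert res["rho"].iloc[0] == pytest.approx(1.0)
    assert res["p"].iloc[0] < 1e-8
    assert res["n"].iloc[0] == 12


def test_per_group_correlation_constant_row_flagged():
    samples = [f"S{i}" for i in range(6)]
    x = [list(range(6))]
    const = [[1.0] * 6]
    om = _matrix(x, const, x, samples)
    res = sc.per_group_correlation(om, "mRNA_kloss")
    assert np.isnan(res["rho"].iloc[0])


def test_per_group_matches_scalar_spearman(small_pipeline):
    om = small_pipeline["omics"]
    res = sc.per_group_correlation(om, "mRNA_kloss")
    for gid in res.index[:20]:
        rho, p, n = sc.spearman(om.mrna.loc[gid], om.kloss.loc[gid])
        assert res.loc[gid, "rho"] == pytest.approx(rho, abs=1e-12)
        assert res.loc[gid, "p"] == pytest.approx(p, rel=1e-9)


# --- CV quintiles ----------------------------------------------------------

def test_cv_of_constant_profile_is_zero():
    samples = ["S1", "S2", "S3"]
    protein = [[5.0, 5.0, 5.0]] + [[i, i + 1, i + 2] for i in range(9)]
    om = _matrix(protein, protein, protein, samples)
    cors = pd.DataFrame(
        {"rho": np.linspace(-1, 1, 10), "p": 0.5, "n": 3},
        index=om.protein.index,
    )
    res = sc.cv_quintile_analysis(om, cors)
    assert res["per_group"].loc["g0", "cv"] == pytest.approx(0.0)


def test_ten_groups_make_quintiles_of_two():
    rng = np.random.default_rng(2)
    samples = ["S1", "S2", "S3", "S4"]
    protein = rng.normal(10, 1, size=(10, 4))
    om = _matrix(protein, protein, protein, samples)
    cors = pd.DataFrame(
        {"rho": np.linspace(-1, 1, 10), "p": 0.5, "n": 4},
        index=om.protein.index,
    )
    res = sc.cv_quintile_analysis(om, cors)
    assert (res["summary"]["size"] == 2).all()


def test_high_rho_groups_with_less_noise_have_lower_cv():
    rng = np.random.default_rng(9)
    samples = [f"S{i}" for i in range(10)]
    n = 100
    rho = np.linspace(-0.9, 0.9, n)
    noise_sd = np.where(rho > 0.5, 0.2, 0.4)  # top-correlation groups: half SD
    protein = 10.0 + rng.normal(0, 1, size=(n, 1)) + \
        rng.normal(0, noise_sd[:, None], size=(n, 10))
    om = _matrix(protein, protein, protein, samples)
    cors = pd.DataFrame({"rho": rho, "p": 0.5, "n": 10}, index=om.protein.index)
    res = sc.cv_quintile_analysis(om, cors)
    assert res["summary"].loc["Q5", "median"] < res["summary"].loc["Q1", "median"]
    assert res["kruskal_p"] < 0.01
    assert len(res["pairwise"]) == 10  # all quintile pairs


# --- differential tests ----------------------------------------------------

def test_differential_identical_groups_fc_zero():
    samples = ["A1", "A2", "A3", "B1", "B2", "B3"]
    cond = {s: s[0] for s in samples}
    rng = np.random.default_rng(4)
    half = rng.normal(size=(5, 3))
    values = pd.DataFrame(
        np.hstack([half, half]), columns=samples,
        index=[f"k{i}" for i in range(5)],
    )
    res = sc.differential_test(values, cond)
    assert np.allclose(res["log2_fc"], 0.0)


def test_differential_planted_shift_detected():
    rng = np.random.default_rng(8)
    samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
    cond = {s: s[0] for s in samples}
    null = rng.normal(0, 0.05, size=(30, 12))
    values = pd.DataFrame(null, columns=samples,
                          index=[f"k{i}" for i in range(30)])
    values.iloc[0, :6] += 1.0  # planted 2-fold shift
    res = sc.differential_test(values, cond)
    assert res["q"].iloc[0] < 0.01
    assert res["log2_fc"].iloc[0] == pytest.approx(1.0, abs=0.1)
    assert (res["q"] >= res["p"] - 1e-15).all()


def test_differential_zero_variance_flagged():
    samples = ["A1", "A2", "B1", "B2"]
    cond = {s: s[0] for s in samples}
    values = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], columns=samples, index=["k0"])
    res = sc.differential_test(values, cond)
    assert np.isnan(res["p"].iloc[0])
    assert bool(res["flagged_zero_variance"].iloc[0])


def _iso_values(entries):
    return pd.DataFrame(entries, columns=["gene_id", "group_id", "value"])


def test_isoform_identical_groups_not_called():
    entries = [("G1", g, v) for g in ("a", "b") for v in (1.0, 1.1, 0.9)]
    res = sc.isoform_differential(_iso_values(entries))
    assert not res.loc["G1", "called"]


def test_isoform_fc_gate_blocks_significant_but_small_difference():
    rng = np.random.default_rng(5)
    entries = [("G1", "a", v) for v in rng.normal(0.0, 0.01, 10)]
    entries += [("G1", "b", v) for v in rng.normal(0.30, 0.01, 10)]
    res = sc.isoform_differential(_iso_values(entries))
    assert res.loc["G1", "p"] < 0.001  # highly significant...
    assert not res.loc["G1", "called"]  # ...but below the 0.32 log2 FC gate


def test_isoform_planted_1p5_fold_split_called():
    rng = np.random.default_rng(6)
    entries = [("G1", "a", v) for v in rng.normal(0.0, 0.05, 8)]
    entries += [("G1", "b", v) for v in rng.normal(np.log2(1.5), 0.05, 8)]
    res = sc.isoform_differential(_iso_values(entries))
    assert bool(res.loc["G1", "called"])
    assert res.loc["G1", "test"] == "t_test"


def test_isoform_three_groups_uses_anova_tukey():
    rng = np.random.default_rng(7)
    entries = []
    for g, mu in (("a", 0.0), ("b", 0.0), ("c", 1.0)):
        entries += [("G1", g, v) for v in rng.normal(mu, 0.05, 6)]
    res = sc.isoform_differential(_iso_values(entries))
    assert res.loc["G1", "test"] == "anova_tukey"
    assert bool(res.loc["G1", "called"])


def test_isoform_singleton_group_excluded():
    entries = [("G1", "a", 1.0)] + [("G1", "b", v) for v in (1.0, 2.0)]
    res = sc.isoform_differential(_iso_values(entries))
    assert res.empty  # only one valid group remains -> gene skipped
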