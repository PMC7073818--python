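import numpy as np
import pandas as pd
import pytest

from pulsekin import sim, turnover
from pulsekin.turnover import RIAProfile, TurnoverConfig

from conftest import make_precursor_rows, precursor_frame

TIMES = [1.0, 4.5, 11.0]


def grid_search_k(times, rias, lo=1e-4, hi=5.0, n=200_001):
    """Independent oracle: dense grid search of the RIA least-squares fit."""
    ks = np.linspace(lo, hi, n)
    t = np.asarray(times)[:, None]
    y = np.asarray(rias)[:, None]
    rss = ((y - np.exp(-ks[None, :] * t)) ** 2).sum(axis=0)
    return float(ks[np.argmin(rss)])


def _profile(k, times=TIMES):
    return RIAProfile("S1", "ELVISLIVESK", 2, tuple((t, np.exp(-k * t)) for t in times))


@pytest.mark.parametrize("L, H, expected", [(100, 100, 0.5), (0, 50, 0.0), (30, 10, 0.75)])
def test_compute_ria(L, H, expected):
    assert turnover.compute_ria(L, H) == pytest.approx(expected)


def test_compute_ria_undefined_when_no_signal():
    assert np.isnan(turnover.compute_ria(0.0, 0.0))
    assert np.isnan(turnover.compute_ria(np.nan, np.nan))


def test_model_identities():
    assert turnover.ria_model(0.0, 0.7) == 1.0
    assert turnover.ria_model(1e4, 0.1) < 1e-6


@pytest.mark.parametrize("k_true", [0.02, 0.2, 0.6])
def test_noiseless_fit_recovers_k_and_matches_grid_oracle(k_true):
    profile = _profile(k_true)
    est = turnover.fit_kloss_ria(profile)
    assert est.k_loss == pytest.approx(k_true, abs=1e-6)
    oracle = grid_search_k(TIMES, [r for _, r in profile.points])
    assert est.k_loss == pytest.approx(oracle, abs=5e-5)  # oracle grid spacing


def test_noisy_fit_matches_grid_oracle():
    rng = np.random.default_rng(0)
    rias = np.exp(-0.15 * np.array(TIMES)) * rng.lognormal(0, 0.05, 3)
    profile = RIAProfile("S1", "ELVISLIVESK", 2, tuple(zip(TIMES, rias)))
    est = turnover.fit_kloss_ria(profile)
    assert est.k_loss == pytest.approx(grid_search_k(TIMES, rias), abs=5e-5)


def test_halflife_identity():
    est = turnover.fit_kloss_ria(_profile(np.log(2.0)))
    assert turnover.ria_model(1.0, est.k_loss) == pytest.approx(0.5, abs=1e-6)


def test_fitted_k_monotone_in_true_k():
    ks = [turnover.fit_kloss_ria(_profile(k)).k_loss for k in (0.05, 0.1, 0.2, 0.4)]
    assert ks == sorted(ks)


def test_scale_equivariance_of_ria_path():
    rows = make_precursor_rows("S1", "ELVISLIVESK", 0.2, 1000.0, TIMES)
    base = precursor_frame(rows)
    scaled = base.copy()
    scaled["intensity"] *= 37.5
    k1 = turnover.fit_kloss_ria_table(base)[0]["k_loss"].iloc[0]
    k2 = turnover.fit_kloss_ria_table(scaled)[0]["k_loss"].iloc[0]
    assert k1 == pytest.approx(k2, rel=1e-12)


# --- filters ---------------------------------------------------------------

def _points(entries):
    """entries: (peptide, time, ria)"""
    return pd.DataFrame(
        [("S1", p, 2, 1, t, r) for p, t, r in entries],
        columns=["sample", "peptide", "charge", "replicate", "time_h", "ria"],
    )


def test_single_time_point_excluded():
    pts = _points([("AAK", 1.0, 0.9)])
    kept, excl = turnover.filter_profiles(pts)
    assert kept.empty
    assert excl["reason"].tolist() == ["single_time_point"]


def test_non_increasing_labeling_excluded():
    pts = _points([("AAK", 1.0, 0.90), ("AAK", 4.5, 0.95), ("AAK", 11.0, 0.97)])
    kept, excl = turnover.filter_profiles(pts)
    assert kept.empty
    assert excl["reason"].tolist() == ["non_increasing_labeling"]


def test_decaying_profile_retained():
    pts = _points([("AAK", 1.0, 0.9), ("AAK", 11.0, 0.3)])
    kept, excl = turnover.filter_profiles(pts)
    assert len(kept) == 2 and excl.empty


def test_endpoint_rule_keeps_noisy_but_decaying_profile():
    pts = _points([("AAK", 1.0, 0.8), ("AAK", 4.5, 0.85), ("AAK", 11.0, 0.4)])
    kept, _ = turnover.filter_profiles(pts)
    assert len(kept) == 3
    kept_strict, excl = turnover.filter_profiles(
        pts, TurnoverConfig(strict_monotonic=True)
    )
    assert kept_strict.empty
    assert excl["reason"].tolist() == ["non_increasing_labeling"]


def test_t0_points_are_not_fit_data():
    rows = make_precursor_rows("S1", "ELVISLIVESK", 0.3, 1000.0, [0.0] + TIMES)
    points = turnover.build_ria_points(precursor_frame(rows))
    assert (points["time_h"] > 0).all()
    est, _ = turnover.fit_kloss_ria_table(precursor_frame(rows))
    assert est["n_points"].iloc[0] == 3
    assert est["k_loss"].iloc[0] == pytest.approx(0.3, abs=1e-6)


def test_replicates_contribute_separate_points():
    rows = make_precursor_rows("S1", "ELVISLIVESK", 0.3, 1000.0, TIMES, replicate=1)
    rows += make_precursor_rows("S1", "ELVISLIVESK", 0.3, 1000.0, TIMES, replicate=2)
    est, _ = turnover.fit_kloss_ria_table(precursor_frame(rows))
    assert est["n_points"].iloc[0] == 6


# --- aggregation -----------------------------------------------------------

def _estimates(entries):
    """entries: (sample, peptide, k, weight)"""
    return pd.DataFrame(
        [(s, p, 2, k, 3, 0.0, "RIA", w) for s, p, k, w in entries],
        columns=["sample", "peptide", "charge", "k_loss", "n_points", "rss",
                 "method", "weight"],
    )


def _make_assignment(peptide, gene="G1", tids=("G1.T1",)):
    from pulsekin.peptide_mapping import PeptideAssignment

    cls = "unique" if len(tids) == 1 else "shared"
    return PeptideAssignment(peptide, frozenset(tids), frozenset([gene]), cls)


def _make_group(peptides, gid="UQ:G1.T1"):
    from pulsekin.peptide_mapping import ASGroup

    return ASGroup(gid, "G1", frozenset(["G1.T1"]), "UQ", "G1.T1",
                   frozenset(peptides))


def test_precursor_to_peptide_weighted_mean():
    est = _estimates([("S1", "AAK", 0.1, 1.0), ("S1", "AAK", 0.3, 3.0)])
    est.loc[1, "charge"] = 3
    agg = turnover.aggregate_kloss(
        est, {"AAK": _make_assignment("AAK")}, [], samples=["S1"]
    )
    assert agg["peptide"].loc["AAK", "S1"] == pytest.approx(0.25)


def test_group_is_median_of_log2_peptide_rates():
    entries = [("S1", p, 2.0 ** v, 1.0) for p, v in
               [("AAK", -3.0), ("CCK", -2.0), ("DDK", -1.0)]]
    est = _estimates(entries)
    assignments = {p: _make_assignment(p) for p in ("AAK", "CCK", "DDK")}
    group = _make_group(["AAK", "CCK", "DDK"])
    agg = turnover.aggregate_kloss(est, assignments, [group], samples=["S1"])
    assert agg["group"].loc["UQ:G1.T1", "S1"] == pytest.approx(-2.0)


def test_mean_summary_configurable():
    entries = [("S1", p, 2.0 ** v, 1.0) for p, v in
               [("AAK", -3.0), ("CCK", -2.0), ("DDK", 0.0)]]
    est = _estimates(entries)
    assignments = {p: _make_assignment(p) for p in ("AAK", "CCK", "DDK")}
    group = _make_group(["AAK", "CCK", "DDK"])
    agg = turnover.aggregate_kloss(
        est, assignments, [group], TurnoverConfig(peptide_summary="mean"),
        samples=["S1"],
    )
    assert agg["group"].loc["UQ:G1.T1", "S1"] == pytest.approx(-5.0 / 3.0)


def test_peptide_missing_in_one_sample_dropped_from_cross_sample_matrix():
    est = _estimates(
        [("S1", "AAK", 0.1, 1.0), ("S2", "AAK", 0.1, 1.0), ("S1", "CCK", 0.2, 1.0)]
    )
    assignments = {p: _make_assignment(p) for p in ("AAK", "CCK")}
    agg = turnover.aggregate_kloss(est, assignments, [], samples=["S1", "S2"])
    assert "CCK" not in agg["peptide"].index
    assert agg["log"]["non_full_profile_peptides"] == 1


def test_single_peptide_group_omitted_and_logged():
    est = _estimates([("S1", "AAK", 0.1, 1.0)])
    assignments = {"AAK": _make_assignment("AAK")}
    group = _make_group(["AAK"])
    agg = turnover.aggregate_kloss(est, assignments, [group], samples=["S1"])
    assert agg["group"].empty
    assert agg["log"]["groups_below_min_peptides"] == 1


def test_multi_gene_peptides_removed():
    est = _estimates([("S1", "AAK", 0.1, 1.0)])
    from pulsekin.peptide_mapping import PeptideAssignment

    assignments = {
        "AAK": PeptideAssignment(
            "AAK", frozenset(["G1.T1", "G2.T1"]), frozenset(["G1", "G2"]),
            "multi_gene",
        )
    }
    agg = turnover.aggregate_kloss(est, assignments, [], samples=["S1"])
    assert agg["peptide"].empty
    assert agg["log"]["multi_gene_or_unmapped_precursors"] == 1


# --- NLI path --------------------------------------------------------------

def test_run_normalization_contract():
    # three runs with grand sums 100, 200, 400 -> median 200
    rows = []
    for rep, (t, total) in enumerate([(1.0, 100.0), (4.5, 200.0), (11.0, 400.0)]):
        rows.append(("S1", 1, t, "AAAAAAK", 2, "light", total * 0.6))
        rows.append(("S1", 1, t, "AAAAAAK", 2, "heavy", total * 0.4))
    normed = turnover.normalize_runs(precursor_frame(rows))
    sums = normed.groupby("time_h")["intensity"].sum()
    assert np.allclose(sums, 200.0)


def test_nli_noiseless_recovery():
    rows = []
    for t in TIMES:
        rows.append(("S1", 1, t, "AAAAAAK", 2, "light", 1000.0 * np.exp(-0.3 * t)))
        rows.append(("S1", 1, t, "AAAAAAK", 2, "heavy",
                     1000.0 * (1 - np.exp(-0.3 * t))))
    est, _ = turnover.fit_kloss_nli(precursor_frame(rows))
    assert est["k_loss"].iloc[0] == pytest.approx(0.3, abs=1e-6)
    assert est["method"].iloc[0] == "NLI"


def test_nli_agrees_with_ria_on_noiseless_steady_state():
    rng = np.random.default_rng(3)
    rows = []
    for i, k in enumerate(np.exp(rng.uniform(np.log(0.02), np.log(0.6), 50))):
        rows += make_precursor_rows("S1", f"PEPTIDE{i}K", k, 1000.0, TIMES)
    prec = precursor_frame(rows)
    ria = turnover.fit_kloss_ria_table(prec)[0].set_index("peptide")["k_loss"]
    nli = turnover.fit_kloss_nli(prec)[0].set_index("peptide")["k_loss"]
    assert np.max(np.abs(ria - nli.reindex(ria.index))) < 1e-4


# --- k_deg helper ----------------------------------------------------------

def test_kdeg_from_kloss():
    assert turnover.kdeg_from_kloss(0.5, 0.03) == pytest.approx(0.47)
    assert turnover.kdeg_from_kloss(0.2, 0.0) == 0.2


def test_kcd_from_doubling_time():
    assert turnover.kcd_from_doubling_time(23.1) == pytest.approx(0.03, abs=5e-4)
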