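"""Degradation-rate (k_loss) estimation from pulsed-SILAC quantities.

Under steady-state growth the pre-existing (light) fraction of a protein
decays exponentially: RIA(t) = RIA0 * exp(-k_loss * t) with RIA = L/(L+H)
and RIA0 fixed at 1 because no heavy label is present before the pulse.
k_loss lumps true degradation (k_deg) and dilution by cell division (k_cd):
k_loss = k_deg + k_cd.  log2 k_loss is the cross-sample degradation proxy.

Two estimation paths are provided:

* RIA: nonlinear least squares on the isotope ratio, intercept fixed at 1,
  t = 0 points excluded (the initial condition is an assumption, not data).
* NLI (normalized light intensity): runs are rescaled so every injection's
  grand total H+L signal matches the within-sample median, then the light
  channel alone is fitted as L(t) = L0 * exp(-k t) with L0 free.

Both paths share the profile filters (at least two usable time points;
labeling must increase over time, i.e. the light signal/ratio must fall
between the first and last observed time) and the same aggregation:
precursor -> peptide by intensity-weighted mean, peptide -> AS group by the
median (configurable mean) of log2 peptide rates, at least two peptides per
group, and peptides must be quantified in every sample ("full profiles")
before any cross-sample comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class TurnoverConfig:
    """Fitting and aggregation settings.

    ria0 is the assumed isotope ratio at t = 0 (1 unless overridden for
    diagnostic purposes).  k is optimized within ``k_bounds`` (per hour) on a
    log grid of ``grid_size`` points followed by ``refine_iters``
    golden-section steps.  ``peptide_summary`` selects the peptide -> group
    collapse (median or mean of log2 rates).  ``strict_monotonic`` switches
    the labeling filter from endpoint comparison to strict per-step decrease.
    ``k_cd`` optionally maps sample -> cell-division rate per hour.
    """

    ria0: float = 1.0
    k_bounds: tuple[float, float] = (1e-6, 100.0)
    grid_size: int = 96
    refine_iters: int = 70
    weighting: str = "intensity"  # or "uniform"
    peptide_summary: str = "median"  # or "mean"
    strict_monotonic: bool = False
    min_points: int = 2
    k_cd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.peptide_summary not in ("median", "mean"):
            raise ValueError("peptide_summary must be 'median' or 'mean'")
        if self.weighting not in ("intensity", "uniform"):
            raise ValueError("weighting must be 'intensity' or 'uniform'")
        if not (0 < self.k_bounds[0] < self.k_bounds[1]):
            raise ValueError("k_bounds must be positive and increasing")


@dataclass(frozen=True)
class RIAProfile:
    """One precursor's labeling time course within one sample."""

    sample_id: str
    peptide: str
    charge: int
    points: tuple[tuple[float, float], ...]  # (time_h, ria), times increasing


@dataclass(frozen=True)
class KlossEstimate:
    level: str  # precursor | peptide | group
    sample_id: str
    key: str
    k_loss: float
    n_points: int
    rss: float
    method: str  # RIA | NLI
    converged: bool = True
    weight: float = field(default=0.0)


def ria_model(t, k):
    """Model isotope ratio exp(-k t); equals 1 at t = 0 for any k."""
    return np.exp(-np.asarray(k, dtype=float) * np.asarray(t, dtype=float))


def compute_ria(L, H):
    """Relative isotopic abundance L / (L + H).

    Missing channels count as 0; the value is undefined (NaN) when L + H is
    0 or both channels are missing — such points are skipped by the caller.
    """
    Lv = np.nan_to_num(np.asarray(L, dtype=float))
    Hv = np.nan_to_num(np.asarray(H, dtype=float))
    total = Lv + Hv
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, Lv / np.where(total > 0, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def kdeg_from_kloss(k_loss: float, k_cd: float) -> float:
    """True degradation rate k_deg = k_loss - k_cd (may be negative when
    label recycling or division-rate error dominates; returned as-is)."""
    return k_loss - k_cd


def kcd_from_doubling_time(doubling_time_h: float) -> float:
    """Cell-division rate from culture doubling time: k_cd = ln2 / T_d."""
    if doubling_time_h <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / doubling_time_h


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def pivot_channels(precursors: pd.DataFrame) -> pd.DataFrame:
    """Long precursor table -> one row per (sample, peptide, charge,
    replicate, time_h) with L and H columns."""
    wide = precursors.pivot_table(
        index=["sample", "peptide", "charge", "replicate", "time_h"],
        columns="channel",
        values="intensity",
        aggfunc="first",
        dropna=False,
    ).reset_index()
    wide.columns.name = None
    for ch in ("light", "heavy"):
        if ch not in wide.columns:
            wide[ch] = np.nan
    return wide.rename(columns={"light": "L", "heavy": "H"})


def build_ria_points(precursors: pd.DataFrame) -> pd.DataFrame:
    """Per-point RIA table for the RIA fitting path.

    Only t > 0 points enter (RIA0 = 1 is an assumption replacing the t = 0
    observation); points with both channels missing are dropped.
    """
    wide = pivot_channels(precursors)
    wide = wide[wide["time_h"] > 0].copy()
    both_missing = wide["L"].isna() & wide["H"].isna()
    wide = wide[~both_missing].copy()
    wide["ria"] = compute_ria(wide["L"].to_numpy(), wide["H"].to_numpy())
    wide = wide[np.isfinite(wide["ria"])].copy()
    wide["weight_point"] = wide[["L", "H"]].fillna(0.0).sum(axis=1)
    return wide


PROFILE_KEY = ["sample", "peptide", "charge"]


def filter_profiles(
    points: pd.DataFrame,
    config: TurnoverConfig = TurnoverConfig(),
    value_col: str = "ria",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-profile inclusion filters.

    Profiles (one precursor in one sample) are dropped when they have fewer
    than ``config.min_points`` usable points (reason ``single_time_point``)
    or when the light signal/ratio does not fall from the first to the last
    observed time (reason ``non_increasing_labeling``; with
    ``strict_monotonic`` every consecutive per-time mean must fall).

    Returns (retained points, exclusion log with one row per dropped
    profile and its reason).
    """
    if points.empty:
        return points, pd.DataFrame(columns=PROFILE_KEY + ["reason"])

    per_time = (
        points.groupby(PROFILE_KEY + ["time_h"], sort=True)[value_col]
        .mean()
        .reset_index()
    )
    n_points = points.groupby(PROFILE_KEY, sort=False)[value_col].size()

    exclusions: list[tuple] = []
    few = n_points[n_points < config.min_points]
    for key in few.index:
        exclusions.append((*key, "single_time_point"))
    ok_keys = set(n_points[n_points >= config.min_points].index)

    per_time = per_time.sort_values(PROFILE_KEY + ["time_h"], kind="stable")
    grp = per_time.groupby(PROFILE_KEY, sort=False)[value_col]
    if config.strict_monotonic:
        decreasing = grp.apply(lambda v: bool(np.all(np.diff(v.to_numpy()) < 0)))
    else:
        decreasing = grp.last() < grp.first()
    for key in decreasing.index[~decreasing]:
        if key in ok_keys:
            exclusions.append((*key, "non_increasing_labeling"))
            ok_keys.discard(key)

    excl = pd.DataFrame(exclusions, columns=PROFILE_KEY + ["reason"])
    keep_idx = points.set_index(PROFILE_KEY).index.isin(ok_keys)
    return points[keep_idx].copy(), excl


# ---------------------------------------------------------------------------
# batched 1-D least-squares decay fitting
# ---------------------------------------------------------------------------

def _pad_profiles(points: pd.DataFrame, value_col: str):
    """Stack ragged profiles into padded (n_profiles, max_pts) arrays."""
    pts = points.sort_values(PROFILE_KEY + ["time_h", "replicate"], kind="stable")
    codes, keys = pd.factorize(
        pd.MultiIndex.from_frame(pts[PROFILE_KEY]), sort=False
    )
    pos = pts.groupby(codes, sort=False).cumcount().to_numpy()
    n = len(keys)
    width = int(pos.max()) + 1 if len(pos) else 1
    t = np.full((n, width), np.nan)
    y = np.full((n, width), np.nan)
    t[codes, pos] = pts["time_h"].to_numpy(dtype=float)
    y[codes, pos] = pts[value_col].to_numpy(dtype=float)
    mask = np.isfinite(y)
    t = np.nan_to_num(t)
    y = np.nan_to_num(y)
    return keys, t, y, mask


def _rss_ria(k: np.ndarray, t, y, mask, ria0: float) -> np.ndarray:
    pred = ria0 * np.exp(-k[:, None] * t)
    return np.sum(((y - pred) ** 2) * mask, axis=1)


def _rss_nli(k: np.ndarray, t, y, mask, _unused: float) -> np.ndarray:
    # profile out the free amplitude: L0*(k) = sum(y e) / sum(e^2)
    e = np.exp(-k[:, None] * t) * mask
    denom = np.sum(e * e, axis=1)
    denom = np.where(denom > 0, denom, 1.0)
    l0 = np.sum(y * e, axis=1) / denom
    pred = l0[:, None] * e
    return np.sum(((y - pred) ** 2) * mask, axis=1)


_RSS = {"RIA": _rss_ria, "NLI": _rss_nli}


def _fit_decay_batch(t, y, mask, method: str, config: TurnoverConfig):
    """Minimize the per-profile RSS over k in log space.

    A coarse log-spaced grid brackets the minimum; golden-section search
    refines it.  Returns (k, rss) arrays.
    """
    rss_fn = _RSS[method]
    lo, hi = config.k_bounds
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), config.grid_size))
    n = t.shape[0]
    rss_grid = np.empty((n, config.grid_size))
    for j, kj in enumerate(grid):
        rss_grid[:, j] = rss_fn(np.full(n, kj), t, y, mask, config.ria0)
    best = np.argmin(rss_grid, axis=1)
    a = np.log(grid[np.maximum(best - 1, 0)])
    b = np.log(grid[np.minimum(best + 1, config.grid_size - 1)])

    for _ in range(config.refine_iters):
        span = b - a
        c = b - _GOLDEN * span
        d = a + _GOLDEN * span
        fc = rss_fn(np.exp(c), t, y, mask, config.ria0)
        fd = rss_fn(np.exp(d), t, y, mask, config.ria0)
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)

    k = np.exp(0.5 * (a + b))
    rss = rss_fn(k, t, y, mask, config.ria0)
    return k, rss


def fit_precursor_kloss(
    points: pd.DataFrame,
    config: TurnoverConfig = TurnoverConfig(),
    method: str = "RIA",
    value_col: str = "ria",
) -> pd.DataFrame:
    """Fit k_loss for every filtered profile in a per-point table.

    Returns a DataFrame (sample, peptide, charge, k_loss, n_points, rss,
    weight, method); weight is the summed L+H signal over the profile and
    feeds the precursor -> peptide weighted average.
    """
    if points.empty:
        return pd.DataFrame(
            columns=PROFILE_KEY + ["k_loss", "n_points", "rss", "weight", "method"]
        )
    keys, t, y, mask = _pad_profiles(points, value_col)
    k, rss = _fit_decay_batch(t, y, mask, method, config)
    if "weight_point" in points.columns:
        weights = points.groupby(PROFILE_KEY, sort=False)["weight_point"].sum()
    else:
        weights = points.groupby(PROFILE_KEY, sort=False)[value_col].size().astype(float)
    out = pd.DataFrame(
        {
            "sample": keys.get_level_values(0),
            "peptide": keys.get_level_values(1),
            "charge": keys.get_level_values(2),
            "k_loss": k,
            "n_points": mask.sum(axis=1),
            "rss": rss,
            "method": method,
        }
    )
    out["weight"] = weights.reindex(
        pd.MultiIndex.from_frame(out[PROFILE_KEY])
    ).to_numpy()
    if config.weighting == "uniform":
        out["weight"] = 1.0
    return out


def fit_kloss_ria(
    profile: RIAProfile, config: TurnoverConfig = TurnoverConfig()
) -> KlossEstimate:
    """Fit one precursor profile by the RIA method (scalar convenience API)."""
    pts = pd.DataFrame(
        {
            "sample": profile.sample_id,
            "peptide": profile.peptide,
            "charge": profile.charge,
            "replicate": 1,
            "time_h": [t for t, _ in profile.points],
            "ria": [r for _, r in profile.points],
        }
    )
    fit = fit_precursor_kloss(pts, config, method="RIA")
    row = fit.iloc[0]
    return KlossEstimate(
        "precursor",
        profile.sample_id,
        f"{profile.peptide}/{profile.charge}",
        float(row["k_loss"]),
        int(row["n_points"]),
        float(row["rss"]),
        "RIA",
        weight=float(row["weight"]),
    )


# ---------------------------------------------------------------------------
# NLI path
# ---------------------------------------------------------------------------

def normalize_runs(precursors: pd.DataFrame) -> pd.DataFrame:
    """Rescale every injection (sample, replicate, time point) so its grand
    total H+L intensity equals the median grand total across that sample's
    injections."""
    df = precursors.copy()
    run_key = ["sample", "replicate", "time_h"]
    totals = df.groupby(run_key)["intensity"].sum(min_count=1)
    med = totals.groupby(level="sample").median()
    scale = (med.reindex(totals.index.get_level_values("sample")).to_numpy()
             / totals.to_numpy())
    scale_s = pd.Series(scale, index=totals.index, name="scale")
    df = df.merge(scale_s.reset_index(), on=run_key, how="left")
    df["intensity"] = df["intensity"] * df.pop("scale")
    return df


def build_nli_points(precursors: pd.DataFrame) -> pd.DataFrame:
    """Per-point normalized light intensity table (t = 0 included: with a
    free amplitude the t = 0 light signal is a genuine observation)."""
    normed = normalize_runs(precursors)
    wide = pivot_channels(normed)
    wide = wide[wide["L"].notna()].copy()
    wide["nli"] = wide["L"]
    wide["weight_point"] = wide[["L", "H"]].fillna(0.0).sum(axis=1)
    return wide


def fit_kloss_nli(
    precursors: pd.DataFrame, config: TurnoverConfig = TurnoverConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full NLI path: normalize, filter, fit.

    Returns (estimates, exclusion log)."""
    points = build_nli_points(precursors)
    kept, excl = filter_profiles(points, config, value_col="nli")
    return fit_precursor_kloss(kept, config, method="NLI", value_col="nli"), excl


def fit_kloss_ria_table(
    precursors: pd.DataFrame, config: TurnoverConfig = TurnoverConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full RIA path on a precursor table.

    Returns (estimates, exclusion log)."""
    points = build_ria_points(precursors)
    kept, excl = filter_profiles(points, config, value_col="ria")
    return fit_precursor_kloss(kept, config, method="RIA", value_col="ria"), excl


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_kloss(
    estimates: pd.DataFrame,
    assignments: dict,
    groups: list,
    config: TurnoverConfig = TurnoverConfig(),
    samples: list[str] | None = None,
) -> dict:
    """Precursor -> peptide -> AS-group aggregation of k_loss estimates.

    * multi-gene peptides are removed;
    * peptide k_loss per sample = intensity-weighted mean over charges;
    * only peptides with a k_loss in every sample (full profiles) survive;
    * group log2 k_loss per sample = median (or mean) of log2 peptide rates,
      requiring at least two member peptides.

    Returns dict with keys ``peptide`` (peptide x sample, linear k),
    ``group`` (group_id x sample, log2 k) and ``log`` (counts of records
    removed by each rule).
    """
    log: dict[str, int] = {}
    est = estimates.copy()
    multi = {p for p, a in assignments.items() if a.cls == "multi_gene"}
    known = set(assignments)
    n0 = len(est)
    est = est[est["peptide"].isin(known - multi)]
    log["multi_gene_or_unmapped_precursors"] = n0 - len(est)
    if samples is None:
        samples = sorted(estimates["sample"].unique())
    if est.empty:
        empty_pep = pd.DataFrame(columns=samples)
        empty_pep.index.name = "peptide"
        empty_grp = pd.DataFrame(columns=samples)
        empty_grp.index.name = "group_id"
        log["non_full_profile_peptides"] = 0
        log["groups_below_min_peptides"] = len(groups)
        return {"peptide": empty_pep, "group": empty_grp, "log": log}

    def wmean(sub: pd.DataFrame) -> float:
        w = sub["weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all() or w.sum() <= 0:
            w = np.ones(len(sub))
        return float(np.average(sub["k_loss"], weights=w))

    pep_long = (
        est.groupby(["sample", "peptide"], sort=False)[["k_loss", "weight"]]
        .apply(wmean)
        .rename("k_loss")
        .reset_index()
    )
    peptide_k = pep_long.pivot(index="peptide", columns="sample", values="k_loss")
    peptide_k = peptide_k.reindex(columns=samples)

    full = peptide_k.dropna(axis=0, how="any")
    log["non_full_profile_peptides"] = len(peptide_k) - len(full)
    peptide_k = full

    summary = np.median if config.peptide_summary == "median" else np.mean
    rows = {}
    n_small = 0
    for g in groups:
        members = sorted(set(g.peptides) & set(peptide_k.index))
        if len(members) < 2:
            n_small += 1
            continue
        vals = np.log2(peptide_k.loc[members].to_numpy(dtype=float))
        rows[g.group_id] = summary(vals, axis=0)
    log["groups_below_min_peptides"] = n_small
    group_log2k = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    group_log2k.index.name = "group_id"
    return {"peptide": peptide_k, "group": group_log2k, "log": log}
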