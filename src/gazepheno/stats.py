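"""Resampling statistics: bootstrap effect sizes, epoch sampling,
within-individual reliability, partial rank correlation, FDR and the
demographic / familiarity / severity tests.

Group effect sizes are Cohen's d with the pooled-SD denominator, oriented
TD - ASD (positive = TD higher), estimated by within-group bootstrap
resampling (default 10,000 iterations); the CI is the 2.5th/97.5th
percentile of the bootstrap distribution and the two-sided p-value is the
add-one-smoothed sign-crossing fraction.  Reliability is the Spearman
correlation of a per-participant feature across two non-overlapping randomly
placed epochs of the combined timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import FEATURES_8, GROUP_ASD, GROUP_TD, logger


# ---------------------------------------------------------------------------
# Cohen's d and bootstrap
# ---------------------------------------------------------------------------

def cohens_d(a, b) -> float:
    """(mean(a) - mean(b)) / pooled SD with the (n_a + n_b - 2) denominator."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
        / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class EffectSizeResult:
    feature: str
    d: float
    ci_low: float
    ci_high: float
    p: float
    n_iter: int
    epoch_minutes: object = "full"
    p_adj: float | None = None
    boot_distribution: np.ndarray | None = field(default=None, repr=False)


def _boot_d_matrix(a: np.ndarray, b: np.ndarray, n_iter: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized within-group bootstrap of Cohen's d (one value per row)."""
    na, nb = len(a), len(b)
    out = np.empty(n_iter)
    todo = np.arange(n_iter)
    while len(todo):
        sa = a[rng.integers(0, na, size=(len(todo), na))]
        sb = b[rng.integers(0, nb, size=(len(todo), nb))]
        va = sa.var(axis=1, ddof=1)
        vb = sb.var(axis=1, ddof=1)
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        ok = pooled > 0
        out[todo[ok]] = (sa.mean(axis=1) - sb.mean(axis=1))[ok] \
            / np.sqrt(pooled[ok])
        if (~ok).any():
            logger.info("redrawing %d degenerate bootstrap iterations",
                        int((~ok).sum()))
        todo = todo[~ok]
    return out


def _crossing_p(dist: np.ndarray) -> float:
    """Two-sided sign-crossing p with add-one smoothing."""
    n = len(dist)
    center = dist.mean()
    if center == 0:
        return 1.0
    other = int(np.sum(dist <= 0) if center > 0 else np.sum(dist >= 0))
    return min(1.0, 2.0 * (1 + other) / (n + 1))


def bootstrap_effect(a, b, n_iter: int = 10_000, seed: int = 0,
                     feature: str = "") -> EffectSizeResult:
    """Bootstrap Cohen's d (a - b orientation) with CI and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite values")
    rng = np.random.default_rng(seed)
    dist = _boot_d_matrix(a, b, n_iter, rng)
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return EffectSizeResult(feature=feature, d=float(dist.mean()),
                            ci_low=float(lo), ci_high=float(hi),
                            p=_crossing_p(dist), n_iter=n_iter,
                            boot_distribution=dist)


# ---------------------------------------------------------------------------
# Epoch sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochPair:
    start_a: float
    start_b: float
    duration_s: float

    def __post_init__(self) -> None:
        a0, a1 = self.start_a, self.start_a + self.duration_s
        b0, b1 = self.start_b, self.start_b + self.duration_s
        if max(a0, b0) < min(a1, b1):
            raise ValueError("epochs overlap")


def sample_epochs(total_duration_s: float, duration_s: float, k: int,
                  rng: np.random.Generator):
    """Draw one contiguous epoch start, or a non-overlapping pair.

    Starts are uniform over the feasible set; for ``k = 2`` the pair is
    uniform over the feasible non-overlapping region (by rejection).
    """
    if duration_s <= 0 or k not in (1, 2):
        raise ValueError("duration must be positive and k in {1, 2}")
    if k * duration_s > total_duration_s + 1e-9:
        raise ValueError(
            f"{k} epochs of {duration_s} s do not fit in "
            f"{total_duration_s} s")
    hi = total_duration_s - duration_s
    if k == 1:
        return float(rng.uniform(0.0, hi)) if hi > 0 else 0.0
    if total_duration_s - 2 * duration_s < 1e-9:
        pair = (0.0, duration_s)  # only tiling placement fits
        return EpochPair(pair[0], pair[1], duration_s)
    for _ in range(100_000):
        a = rng.uniform(0.0, hi)
        b = rng.uniform(0.0, hi)
        if abs(a - b) >= duration_s:
            return EpochPair(float(a), float(b), duration_s)
    raise RuntimeError("failed to draw non-overlapping epochs")


def _group_features(timeline, start, dur, feature_idx, idx):
    m = timeline.feature_matrix(start, dur)
    return m[idx][:, feature_idx]


def epoch_sampled_effect(timeline, feature: str, duration_s: float,
                         n_iter: int = 10_000, seed: int = 0,
                         bootstrap_participants: bool = True
                         ) -> EffectSizeResult:
    """Epoch-sampled bootstrap Cohen's d (TD - ASD) for one feature.

    Per iteration: a random contiguous epoch is drawn from the combined
    timeline, participants are resampled with replacement within each group,
    and Cohen's d of the feature within the epoch is computed.  Participants
    with an undefined feature in the epoch are dropped for that iteration.
    """
    rng = np.random.default_rng(seed)
    fi = list(FEATURES_8).index(feature)
    td = timeline.group_indices(GROUP_TD)
    asd = timeline.group_indices(GROUP_ASD)
    dist = np.empty(n_iter)
    for it in range(n_iter):
        start = sample_epochs(timeline.total_seconds, duration_s, 1, rng)
        m = timeline.feature_matrix(start, duration_s)[:, fi]
        i_td = td[rng.integers(0, len(td), len(td))] \
            if bootstrap_participants else td
        i_asd = asd[rng.integers(0, len(asd), len(asd))] \
            if bootstrap_participants else asd
        va = m[i_td]
        vb = m[i_asd]
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        if len(va) < 2 or len(vb) < 2:
            dist[it] = np.nan
            continue
        try:
            dist[it] = cohens_d(va, vb)
        except ValueError:
            dist[it] = np.nan
    dist = dist[np.isfinite(dist)]
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return EffectSizeResult(feature=feature, d=float(dist.mean()),
                            ci_low=float(lo), ci_high=float(hi),
                            p=_crossing_p(dist), n_iter=n_iter,
                            epoch_minutes=duration_s / 60.0,
                            boot_distribution=dist)


# ---------------------------------------------------------------------------
# Within-individual reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    feature: str
    group: str
    rho: float
    p: float
    epoch_minutes: float
    n_iter: int
    p_adj: float | None = None
    rho_distribution: np.ndarray | None = field(default=None, repr=False)


def reliability_sampled(timeline, feature: str, duration_s: float,
                        n_iter: int = 10_000, group: str = GROUP_TD,
                        seed: int = 0) -> ReliabilityResult:
    """Spearman reliability of a feature across non-overlapping epoch pairs.

    Per iteration a non-overlapping epoch pair is drawn, the feature is
    computed per participant in each epoch, and the participants' values are
    rank-correlated between the epochs.  Iterations where the feature is
    constant across participants are skipped (logged).
    """
    rng = np.random.default_rng(seed)
    fi = list(FEATURES_8).index(feature)
    idx = timeline.group_indices(group)
    if len(idx) < 3:
        raise ValueError("need >= 3 participants in the group")
    rhos = []
    skipped = 0
    for _ in range(n_iter):
        pair = sample_epochs(timeline.total_seconds, duration_s, 2, rng)
        xa = timeline.feature_matrix(pair.start_a, duration_s)[idx, fi]
        xb = timeline.feature_matrix(pair.start_b, duration_s)[idx, fi]
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 3 or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
            skipped += 1
            continue
        rhos.append(sps.spearmanr(xa[ok], xb[ok]).statistic)
    if skipped:
        logger.info("reliability_sampled: skipped %d degenerate iterations",
                    skipped)
    rhos = np.asarray(rhos)
    return ReliabilityResult(feature=feature, group=group,
                             rho=float(rhos.mean()), p=_crossing_p(rhos),
                             epoch_minutes=duration_s / 60.0,
                             n_iter=len(rhos), rho_distribution=rhos)


def reliability_group_difference(timeline, feature: str, duration_s: float,
                                 n_iter: int = 10_000, seed: int = 0) -> dict:
    """Bootstrap comparison of reliability between ASD and TD.

    Per iteration the same epoch pair is used for both groups; the
    distribution of rho_ASD - rho_TD gives a two-sided sign-crossing p.
    """
    rng = np.random.default_rng(seed)
    fi = list(FEATURES_8).index(feature)
    idx = {g: timeline.group_indices(g) for g in (GROUP_ASD, GROUP_TD)}
    diffs = []
    for _ in range(n_iter):
        pair = sample_epochs(timeline.total_seconds, duration_s, 2, rng)
        xa = timeline.feature_matrix(pair.start_a, duration_s)[:, fi]
        xb = timeline.feature_matrix(pair.start_b, duration_s)[:, fi]
        rho = {}
        for g, gi in idx.items():
            va, vb = xa[gi], xb[gi]
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3 or np.ptp(va[ok]) == 0 or np.ptp(vb[ok]) == 0:
                rho[g] = np.nan
            else:
                rho[g] = sps.spearmanr(va[ok], vb[ok]).statistic
        if np.isfinite(rho[GROUP_ASD]) and np.isfinite(rho[GROUP_TD]):
            diffs.append(rho[GROUP_ASD] - rho[GROUP_TD])
    diffs = np.asarray(diffs)
    return {"feature": feature, "mean_diff": float(diffs.mean()),
            "p": _crossing_p(diffs), "n_iter": len(diffs)}


# ---------------------------------------------------------------------------
# Partial rank correlation
# ---------------------------------------------------------------------------

def partial_rank_correlation(x, y, z, w) -> float:
    """Rank-residual partial correlation.

    All four variables are rank-transformed; rank(x) is regressed on rank(z)
    and rank(y) on rank(w); the Pearson correlation of the two residual
    vectors is returned (the data are already ranks, so Pearson on residuals
    is the rank-based partial correlation).
    """
    arrays = [np.asarray(v, dtype=float) for v in (x, y, z, w)]
    n = len(arrays[0])
    if any(len(v) != n for v in arrays) or n < 3:
        raise ValueError("x, y, z, w must share a length >= 3")
    rx, ry, rz, rw = (sps.rankdata(v) for v in arrays)

    def _residuals(v, cov):
        design = np.column_stack([np.ones_like(cov), cov])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ex = _residuals(rx, rz)
    ey = _residuals(ry, rw)
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        raise ValueError("zero-variance residuals; partial correlation "
                         "undefined")
    return float(np.corrcoef(ex, ey)[0, 1])


# ---------------------------------------------------------------------------
# FDR and demographic tests
# ---------------------------------------------------------------------------

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t(a, b) -> tuple[float, int]:
    """Unpaired two-tailed t statistic assuming equal variance, with df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), len(a) + len(b) - 2


def chi_square_independence(table) -> float:
    """Yates continuity-corrected chi-square for a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    return float(sps.chi2_contingency(t, correction=True).statistic)


def familiarity_split_tests(features, metas: dict, episode_id: str,
                            feature_names=FEATURES_8) -> list[dict]:
    """Familiar (> 5) vs unfamiliar (< 5) t tests per feature and stratum.

    ``features`` is a per-participant feature DataFrame for the episode with
    ``participant_id`` and ``group`` columns.  Participants with a missing
    rating or a rating of exactly 5 are excluded.  Tests run within ASD,
    within TD, and pooled; a stratum with < 2 members is skipped with a log.
    """
    df = features.copy()
    ratings = {pid: metas[pid].familiarity.get(episode_id)
               for pid in df["participant_id"]}
    df["rating"] = df["participant_id"].map(ratings)
    df = df[df["rating"].notna() & (df["rating"] != 5)]
    df["familiar"] = df["rating"] > 5
    results = []
    for stratum in (GROUP_ASD, GROUP_TD, "all"):
        sub = df if stratum == "all" else df[df["group"] == stratum]
        fam = sub[sub["familiar"]]
        unfam = sub[~sub["familiar"]]
        for feat in feature_names:
            a = fam[feat].dropna().to_numpy()
            b = unfam[feat].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                logger.info("familiarity test skipped (%s, %s): stratum too "
                            "small", stratum, feat)
                continue
            t, df_ = two_sample_t(a, b)
            p = 2 * sps.t.sf(abs(t), df_)
            results.append({"stratum": stratum, "feature": feat,
                            "episode_id": episode_id, "t": t, "df": df_,
                            "p": p, "n_familiar": len(a),
                            "n_unfamiliar": len(b)})
    return results


def severity_correlation(features, metas: dict,
                         feature_names=("pct_onscreen", "pct_face",
                                        "pct_eyes", "mean_heatmap_corr")
                         ) -> list[dict]:
    """Spearman correlation of gaze features with symptom severity (ASD).

    Participants with missing severity are dropped pairwise; p-values are
    uncorrected.  All-tied severity raises (correlation undefined).
    """
    df = features[features["group"] == GROUP_ASD].copy()
    df["severity"] = df["participant_id"].map(
        lambda pid: metas[pid].severity_css)
    df = df[df["severity"].notna()]
    if len(df) < 3:
        raise ValueError("need >= 3 ASD participants with severity")
    if np.ptp(df["severity"].to_numpy()) == 0:
        raise ValueError("severity all tied; correlation undefined")
    out = []
    for feat in feature_names:
        sub = df[[feat, "severity"]].dropna()
        res = sps.spearmanr(sub[feat], sub["severity"])
        out.append({"feature": feat, "rho": float(res.statistic),
                    "p": float(res.pvalue), "n": len(sub)})
    return out
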