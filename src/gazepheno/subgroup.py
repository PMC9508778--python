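"""Subgroup structure: supervised ASD-vs-TD classification and unsupervised
mixture clustering.

Classification uses Gaussian Naive Bayes on the four-feature gaze vector
(on-screen, face and eye looking time, mean reference-heatmap correlation)
with epoch-sampled cross-validation: per iteration a random 10-min epoch is
drawn, one third of each group is held out, and held-out accuracy is scored.
Chance is calibrated by an identical procedure with diagnosis labels
permuted once per iteration.

Clustering fits a variational Bayesian Gaussian mixture (initialized with 5
components; the weight-concentration prior empties unneeded ones) to the
per-window standardized feature matrix over a moving window, dissolves
clusters smaller than ``min_size`` into the nearest large cluster, and
reports per-participant assignment frequencies across windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

from .core import FEATURES_4, FEATURES_8, GROUP_ASD, GROUP_TD, logger
from .stats import sample_epochs

_FOUR = [list(FEATURES_8).index(f) for f in FEATURES_4]


# ---------------------------------------------------------------------------
# Gaussian Naive Bayes
# ---------------------------------------------------------------------------

def gnb_fit_predict(train_x, train_y, test_x):
    """Gaussian Naive Bayes: fit per-class feature Gaussians, predict.

    Class priors come from training frequencies; per-class per-feature
    variances get a small floor (1e-9 of the largest feature variance).
    Posterior ties go to the majority (first-listed on count ties) training
    class, logged.
    """
    X = np.asarray(train_x, dtype=float)
    y = np.asarray(train_y)
    T = np.atleast_2d(np.asarray(test_x, dtype=float))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain >= 2 classes")
    if np.any(counts < 2):
        raise ValueError("each class needs >= 2 training members")
    floor = 1e-9 * max(X.var(axis=0).max(), 1e-12)
    log_post = np.empty((len(T), len(classes)))
    for j, c in enumerate(classes):
        sub = X[y == c]
        mu = sub.mean(axis=0)
        var = sub.var(axis=0) + floor
        ll = -0.5 * (np.log(2 * np.pi * var) + (T - mu) ** 2 / var).sum(axis=1)
        log_post[:, j] = ll + np.log(counts[j] / len(y))
    best = log_post.max(axis=1, keepdims=True)
    tied = (np.isclose(log_post, best)).sum(axis=1) > 1
    pred_idx = log_post.argmax(axis=1)
    if tied.any():
        majority = int(np.argmax(counts))
        pred_idx[tied] = majority
        logger.info("gnb: %d posterior ties resolved to majority class",
                    int(tied.sum()))
    return classes[pred_idx]


@dataclass
class ClassifierResult:
    mean_accuracy: float
    sd_accuracy: float
    n_iter: int
    p: float | None = None
    chance_95: float | None = None
    participant_frequency: dict = field(default_factory=dict)
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def _cv_iterations(timeline, n_iter, seed, epoch_minutes, permute):
    rng = np.random.default_rng(seed)
    cols = _FOUR
    asd = timeline.group_indices(GROUP_ASD)
    td = timeline.group_indices(GROUP_TD)
    if len(asd) < 3 or len(td) < 3:
        raise ValueError("each group needs >= 3 participants")
    hold_asd = len(asd) // 3
    hold_td = len(td) // 3
    if hold_asd < 1 or hold_td < 1:
        raise ValueError("groups too small for one-third holdout")
    duration = min(epoch_minutes * 60.0, timeline.total_seconds)
    P = timeline.n_participants
    labels = np.asarray(timeline.groups)
    accs = np.empty(n_iter)
    held = np.zeros(P, dtype=np.int64)
    correct = np.zeros(P, dtype=np.int64)
    for it in range(n_iter):
        start = sample_epochs(timeline.total_seconds, duration, 1, rng)
        m = timeline.feature_matrix(start, duration)[:, cols]
        lab = labels[rng.permutation(P)] if permute else labels
        test_idx = np.concatenate([
            rng.choice(asd, hold_asd, replace=False),
            rng.choice(td, hold_td, replace=False)])
        train_mask = np.ones(P, dtype=bool)
        train_mask[test_idx] = False
        ok = np.all(np.isfinite(m), axis=1)
        tr = train_mask & ok
        te = test_idx[ok[test_idx]]
        if len(np.unique(lab[tr])) < 2 or len(te) == 0:
            accs[it] = np.nan
            continue
        pred = gnb_fit_predict(m[tr], lab[tr], m[te])
        hit = pred == lab[te]
        accs[it] = hit.mean()
        held[te] += 1
        correct[te] += hit
    return accs[np.isfinite(accs)], held, correct


def crossvalidated_classification(timeline, n_iter: int = 10_000,
                                  seed: int = 0,
                                  epoch_minutes: float = 10.0
                                  ) -> ClassifierResult:
    """Epoch-sampled cross-validated GNB classification of ASD vs TD.

    Reports mean +- SD held-out accuracy across iterations and each
    participant's correct-classification frequency (over the iterations in
    which they were held out).
    """
    accs, held, correct = _cv_iterations(timeline, n_iter, seed,
                                         epoch_minutes, permute=False)
    freq = {pid: (correct[i] / held[i] if held[i] else np.nan)
            for i, pid in enumerate(timeline.pids)}
    return ClassifierResult(mean_accuracy=float(accs.mean()),
                            sd_accuracy=float(accs.std(ddof=1)),
                            n_iter=len(accs), participant_frequency=freq)


def classification_null(timeline, observed_accuracy: float | None = None,
                        n_iter: int = 10_000, seed: int = 0,
                        epoch_minutes: float = 10.0):
    """Label-permutation null of the CV accuracy; 95th-percentile chance.

    Diagnosis labels are permuted across participants once per iteration
    before the train/test split, destroying any label-feature association
    while preserving class imbalance and the CV structure.
    """
    null, _, _ = _cv_iterations(timeline, n_iter, seed, epoch_minutes,
                                permute=True)
    chance_95 = float(np.percentile(null, 95))
    p = None
    if observed_accuracy is not None:
        p = (1 + int(np.sum(null >= observed_accuracy))) / (len(null) + 1)
    return null, chance_95, p


# ---------------------------------------------------------------------------
# Variational Bayesian Gaussian mixture clustering
# ---------------------------------------------------------------------------

_INIT_SCHEMES = ("kmeans", "k-means++", "random_from_data")


def _make_bgm(init_k: int, random_state: int,
              init_params: str = "kmeans") -> BayesianGaussianMixture:
    return BayesianGaussianMixture(
        n_components=init_k, covariance_type="tied",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1e-3, init_params=init_params,
        max_iter=1000, random_state=random_state)


def _fit_from_responsibilities(X: np.ndarray, init_k: int,
                               resp: np.ndarray,
                               random_state: int) -> BayesianGaussianMixture:
    """Fit a mixture whose EM starts from given hard responsibilities."""
    import types

    gmm = _make_bgm(init_k, random_state)

    def _init(self, X_, rs, **kw):  # noqa: ANN001 - sklearn private hook
        self._initialize(X_, resp)

    gmm._initialize_parameters = types.MethodType(_init, gmm)
    gmm.fit(X)
    return gmm


def fit_mixture_clusters(window_features: np.ndarray, init_k: int = 5,
                         seed: int = 0, n_restarts: int = 9) -> np.ndarray:
    """Fit a variational Bayesian Gaussian mixture; return raw assignments.

    The Dirichlet-process weight-concentration prior lets superfluous
    components empty out, so the number of populated clusters is learned
    from the data regardless of ``init_k``.  The optimizer is restarted from
    ``n_restarts`` random initializations (k-means / k-means++ / random data
    points) plus a deterministic ladder of k-means partitions with
    2..init_k clusters (padded with empty components); the solution with
    the highest variational lower bound wins.  Restarts that fail to
    converge are discarded (logged); all of them failing raises.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(window_features, dtype=float)
    if X.shape[0] < init_k:
        raise ValueError("need at least init_k participants")

    candidates = []
    for attempt in range(n_restarts):
        candidates.append(_make_bgm(
            init_k, seed * 131 + attempt,
            _INIT_SCHEMES[attempt % len(_INIT_SCHEMES)]))

    fitted = []
    failures = 0
    for gmm in candidates:
        gmm.fit(X)
        if gmm.converged_:
            fitted.append(gmm)
        else:
            failures += 1
    for m in range(2, init_k + 1):
        labels = KMeans(n_clusters=m, n_init=3,
                        random_state=seed).fit_predict(X)
        resp = np.zeros((len(X), init_k))
        resp[np.arange(len(X)), labels] = 1.0
        gmm = _fit_from_responsibilities(X, init_k, resp, seed)
        if gmm.converged_:
            fitted.append(gmm)
        else:
            failures += 1
    if failures:
        logger.info("mixture fit: %d restarts failed to converge", failures)
    if not fitted:
        raise RuntimeError("mixture fit failed to converge in every restart")
    best = max(fitted, key=lambda g: float(np.ravel(g.lower_bound_)[0]))
    return best.predict(X)


def merge_small_clusters(assignment: np.ndarray, features: np.ndarray,
                         min_size: int = 4) -> np.ndarray:
    """Dissolve clusters smaller than ``min_size`` into the nearest large one.

    Large-cluster means are computed before any reassignment; each member of
    a small cluster joins the large cluster with the nearest (Euclidean)
    mean, ties to the lowest cluster index (logged).
    """
    assignment = np.asarray(assignment).copy()
    X = np.asarray(features, dtype=float)
    labels, counts = np.unique(assignment, return_counts=True)
    large = labels[counts >= min_size]
    if len(large) == 0:
        raise ValueError("no cluster reaches min_size; cannot merge")
    small = labels[counts < min_size]
    if len(small) == 0:
        return assignment
    means = np.stack([X[assignment == c].mean(axis=0) for c in large])
    for c in small:
        for i in np.flatnonzero(assignment == c):
            dists = np.linalg.norm(means - X[i], axis=1)
            if (dists == dists.min()).sum() > 1:
                logger.info("merge tie for participant %d resolved to lowest "
                            "cluster index", i)
            assignment[i] = large[int(np.argmin(dists))]
    return assignment


@dataclass
class ClusterResult:
    window_assignments: np.ndarray      # (P, n_windows), -1 where undefined
    n_clusters_per_window: np.ndarray
    assignment_frequency: np.ndarray    # (P, n_final_clusters)
    cluster_ids: np.ndarray
    cluster_size_mean: np.ndarray
    cluster_size_sd: np.ndarray
    n_windows: int


def windowed_cluster_frequencies(timeline, window_minutes: float = 10.0,
                                 step_minutes: float = 1.0, seed: int = 0,
                                 init_k: int = 5,
                                 min_size: int = 4) -> ClusterResult:
    """Mixture clustering over a moving window with assignment frequencies.

    One standardized four-feature mixture fit per window position.  Cluster
    identities are matched across windows by nearest cluster-mean vectors:
    the window whose (post-merge) cluster count equals the modal count
    serves as the reference, and every window's clusters map — possibly
    many-to-one — onto the nearest reference mean, so a window that
    transiently splits a cluster still contributes to the same identities.
    With fewer than 3 windows the frequencies are unstable (warning).
    """
    window_s = window_minutes * 60.0
    step_s = step_minutes * 60.0
    total = timeline.total_seconds
    if window_s > total + 1e-9:
        raise ValueError("window exceeds the timeline")
    n_windows = int(np.floor((total - window_s) / step_s + 1e-9)) + 1
    if n_windows < 3:
        logger.warning("only %d windows; assignment frequencies unstable",
                       n_windows)
    P = timeline.n_participants
    raw_assign = np.full((P, n_windows), -1, dtype=np.int64)
    n_clusters = np.zeros(n_windows, dtype=np.int64)
    window_means: list[dict] = []
    for wi in range(n_windows):
        start = wi * step_s
        m = timeline.feature_matrix(start, window_s)[:, _FOUR]
        ok = np.all(np.isfinite(m), axis=1)
        X = m[ok]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd
        raw = fit_mixture_clusters(Xz, init_k=init_k, seed=seed + wi)
        n_clusters[wi] = len(np.unique(raw))
        merged = merge_small_clusters(raw, Xz, min_size=min_size)
        raw_assign[np.flatnonzero(ok), wi] = merged
        window_means.append({c: Xz[merged == c].mean(axis=0)
                             for c in np.unique(merged)})

    # Reference window: first window whose merged cluster count is modal.
    counts = np.array([len(wm) for wm in window_means])
    modal = np.bincount(counts).argmax()
    ref_wi = int(np.flatnonzero(counts == modal)[0])
    ref_ids = sorted(window_means[ref_wi])
    ref_matrix = np.stack([window_means[ref_wi][c] for c in ref_ids])
    relabel_ref = {c: i for i, c in enumerate(ref_ids)}

    assignments = np.full((P, n_windows), -1, dtype=np.int64)
    for wi in range(n_windows):
        if wi == ref_wi:
            mapping = relabel_ref
        else:
            mapping = {}
            for c, mean in window_means[wi].items():
                d = np.linalg.norm(ref_matrix - mean, axis=1)
                mapping[c] = int(np.argmin(d))
        col = raw_assign[:, wi]
        present = col >= 0
        assignments[present, wi] = [mapping[c] for c in col[present]]

    cluster_ids = np.unique(assignments[assignments >= 0])
    freq = np.zeros((P, len(cluster_ids)))
    for i in range(P):
        present = assignments[i] >= 0
        denom = max(int(present.sum()), 1)
        for j, c in enumerate(cluster_ids):
            freq[i, j] = np.sum(assignments[i][present] == c) / denom
    sizes = np.array([[np.sum(assignments[:, w] == c) for w in range(n_windows)]
                      for c in cluster_ids], dtype=float)
    return ClusterResult(
        window_assignments=assignments,
        n_clusters_per_window=n_clusters,
        assignment_frequency=freq,
        cluster_ids=cluster_ids,
        cluster_size_mean=sizes.mean(axis=1),
        cluster_size_sd=sizes.std(axis=1, ddof=1) if n_windows > 1
        else np.zeros(len(cluster_ids)),
        n_windows=n_windows)
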