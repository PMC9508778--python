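"""Gaze fingerprinting: nearest-neighbour identification of individuals
across epochs with a permutation null.

Each participant is an 8-dimensional gaze feature vector per epoch (or the
4-feature reduced set).  Features are standardized to zero mean and unit
variance across participants within each epoch; a participant's epoch-A
vector is identified as the owner of the nearest (L2) epoch-B vector, with
all participants — including themselves — as candidates.  Chance is
calibrated by shuffling the identities of the epoch-B vectors: the number of
chance matches behaves like the fixed points of a random permutation
(approximately Poisson with mean 1), putting the 95th-percentile chance
level at 3/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import FEATURES_4, FEATURES_8, logger
from .stats import sample_epochs


def standardize_features(m: np.ndarray, feature_names=None) -> np.ndarray:
    """Z-score each column across participants (population SD).

    A constant column makes the scale undefined and raises, naming the
    feature when names are supplied.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a (participants x features) matrix with >= 2 "
                         "rows")
    sd = m.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        name = feature_names[j] if feature_names is not None else f"column {j}"
        raise ValueError(f"constant feature {name}; cannot standardize")
    return (m - m.mean(axis=0)) / sd


@dataclass
class FingerprintResult:
    accuracy: float
    n_identified: int
    n_total: int
    n_perm: int = 0
    p: float | None = None
    null_95: float | None = None
    epoch_minutes: object = "full"
    feature_set: str = "8-feature"
    p_adj: float | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def identify_participants(epoch_a: np.ndarray, epoch_b: np.ndarray,
                          ids_a=None, ids_b=None):
    """Minimum-L2 identification of epoch-A vectors among epoch-B vectors.

    ``ids_a`` / ``ids_b`` carry participant identities (defaults: row
    index); with bootstrap-duplicated rows an identification succeeds iff
    the nearest epoch-B row belongs to any copy of the same original
    participant.  Distance ties resolve to the lowest row index (logged).
    """
    A = np.asarray(epoch_a, dtype=float)
    B = np.asarray(epoch_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("epoch matrices differ in shape")
    n = A.shape[0]
    ids_a = np.arange(n) if ids_a is None else np.asarray(ids_a)
    ids_b = np.arange(n) if ids_b is None else np.asarray(ids_b)
    d = cdist(A, B)
    nn = d.argmin(axis=1)
    ties = (d == d[np.arange(n), nn][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("identify_participants: %d distance ties broken by "
                    "lowest index", int(ties.sum()))
    predicted = ids_b[nn]
    correct = predicted == ids_a
    result = FingerprintResult(accuracy=float(correct.mean()),
                               n_identified=int(correct.sum()), n_total=n)
    return predicted, nn, result


def permutation_null(epoch_a: np.ndarray, epoch_b: np.ndarray,
                     n_perm: int = 10_000, seed: int = 0,
                     ids_a=None, ids_b=None) -> FingerprintResult:
    """Permutation test of identification accuracy.

    Per iteration the identities of the epoch-B vectors are shuffled by a
    uniform random permutation and accuracy is recomputed.  ``p`` is the
    add-one-smoothed fraction of null accuracies at or above the observed
    one; ``null_95`` is the null distribution's 95th percentile.
    """
    if n_perm < 100:
        logger.warning("permutation_null: n_perm=%d gives an unstable 95th "
                       "percentile", n_perm)
    n = len(epoch_a)
    ids_a = np.arange(n) if ids_a is None else np.asarray(ids_a)
    ids_b = np.arange(n) if ids_b is None else np.asarray(ids_b)
    _, nn, observed = identify_participants(epoch_a, epoch_b, ids_a, ids_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = np.mean(ids_b[perm[nn]] == ids_a)
    p = (1 + int(np.sum(null >= observed.accuracy))) / (n_perm + 1)
    return FingerprintResult(
        accuracy=observed.accuracy, n_identified=observed.n_identified,
        n_total=n, n_perm=n_perm, p=p,
        null_95=float(np.percentile(null, 95)), null_distribution=null)


def _feature_indices(feature_set: str) -> list[int]:
    names = FEATURES_8 if feature_set == "8-feature" else FEATURES_4
    return [list(FEATURES_8).index(f) for f in names]


def episode_fingerprint(timeline, group: str, feature_set: str = "8-feature",
                        n_perm: int = 10_000, seed: int = 0
                        ) -> FingerprintResult:
    """Fingerprint across the two full episodes for one group."""
    ep_a, ep_b = timeline.episode_ids[:2]
    idx = timeline.group_indices(group)
    cols = _feature_indices(feature_set)
    fa = _episode_features(timeline, ep_a)[idx][:, cols]
    fb = _episode_features(timeline, ep_b)[idx][:, cols]
    ok = np.all(np.isfinite(fa), axis=1) & np.all(np.isfinite(fb), axis=1)
    if ok.sum() < len(idx):
        logger.info("fingerprint: dropped %d participants with missing "
                    "features", int((~ok).sum()))
    res = permutation_null(standardize_features(fa[ok]),
                           standardize_features(fb[ok]),
                           n_perm=n_perm, seed=seed)
    res.feature_set = feature_set
    return res


def _episode_features(timeline, episode_id):
    if hasattr(timeline, "episode_frame_ranges"):
        f0, f1 = timeline.episode_frame_ranges[episode_id]
        fps = timeline.config.frame_rate_fps
        return timeline.feature_matrix(f0 / fps, (f1 - f0) / fps)
    return timeline.features[episode_id]


def sampled_fingerprint(timeline, duration_s: float, n_iter: int = 1000,
                        group: str = "TD", feature_set: str = "8-feature",
                        seed: int = 0,
                        bootstrap_participants: bool = True
                        ) -> FingerprintResult:
    """Epoch-sampled, participant-bootstrapped fingerprint accuracy.

    Per iteration: a non-overlapping epoch pair is drawn, group members are
    resampled with replacement, features are rebuilt per epoch and
    standardized, and identification runs epoch-A -> epoch-B; with
    duplicated participants a success is the nearest neighbour being any
    copy of the same original.  The permutation null collects one shuffled
    accuracy per iteration; ``p`` compares the mean observed accuracy
    against it.
    """
    if 2 * duration_s > timeline.total_seconds + 1e-9:
        raise ValueError("two epochs of this duration do not fit")
    rng = np.random.default_rng(seed)
    idx = timeline.group_indices(group)
    cols = _feature_indices(feature_set)
    accs = []
    nulls = []
    for _ in range(n_iter):
        pair = sample_epochs(timeline.total_seconds, duration_s, 2, rng)
        fa = timeline.feature_matrix(pair.start_a, duration_s)[idx][:, cols]
        fb = timeline.feature_matrix(pair.start_b, duration_s)[idx][:, cols]
        sel = np.arange(len(idx))
        if bootstrap_participants:
            sel = rng.integers(0, len(idx), len(idx))
        fa_s, fb_s, ids = fa[sel], fb[sel], sel
        ok = np.all(np.isfinite(fa_s), axis=1) \
            & np.all(np.isfinite(fb_s), axis=1)
        if ok.sum() < 3:
            continue
        fa_s, fb_s, ids = fa_s[ok], fb_s[ok], ids[ok]
        try:
            A = standardize_features(fa_s)
            B = standardize_features(fb_s)
        except ValueError:
            continue
        _, nn, res = identify_participants(A, B, ids, ids)
        accs.append(res.accuracy)
        perm = rng.permutation(len(ids))
        nulls.append(np.mean(ids[perm[nn]] == ids))
    accs = np.asarray(accs)
    nulls = np.asarray(nulls)
    mean_acc = float(accs.mean())
    p = (1 + int(np.sum(nulls >= mean_acc))) / (len(nulls) + 1)
    return FingerprintResult(
        accuracy=mean_acc,
        n_identified=int(round(mean_acc * len(idx))), n_total=len(idx),
        n_perm=len(nulls), p=p, null_95=float(np.percentile(nulls, 95)),
        epoch_minutes=duration_s / 60.0, feature_set=feature_set,
        null_distribution=nulls)
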