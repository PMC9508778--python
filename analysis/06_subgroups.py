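#!/usr/bin/env python
"""Subgroup structure: supervised diagnosis classification and unsupervised
mixture clustering.

A Gaussian Naive Bayes classifier on the four-feature gaze vector is
cross-validated over randomly sampled epochs with one-third holdout per
group and compared with a label-permutation null.  A variational Bayesian
Gaussian mixture over moving windows then looks for subgroups without using
diagnosis labels, with per-participant assignment frequencies.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS_DIR, SEED, default_config, load_timeline  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from gazepheno import gaze_io, subgroup as sg  # noqa: E402
from gazepheno.core import GROUP_ASD  # noqa: E402


def main() -> None:
    config = default_config()
    tl = load_timeline(config)

    cv = sg.crossvalidated_classification(tl, n_iter=1000, seed=SEED,
                                          epoch_minutes=2.5)
    null, chance_95, p = sg.classification_null(tl, cv.mean_accuracy,
                                                n_iter=1000, seed=SEED + 1,
                                                epoch_minutes=2.5)
    print(f"GNB classification accuracy {cv.mean_accuracy:.3f} "
          f"+- {cv.sd_accuracy:.3f} (mean +- SD over {cv.n_iter} CV "
          f"iterations)")
    print(f"chance level {chance_95:.3f} (95th percentile of permutation "
          f"null), p = {p:.3f}")
    freq = pd.DataFrame({
        "participant_id": tl.pids, "group": tl.groups,
        "correct_frequency": [cv.participant_frequency[p]
                              for p in tl.pids]})
    consistent = freq["correct_frequency"] > 0.75
    misclassified = freq["correct_frequency"] < 0.25
    print(f"{int(consistent.sum())} participants correctly classified "
          f">75% of the time; {int(misclassified.sum())} misclassified "
          f">75% of the time "
          f"({int((misclassified & (freq['group'] == GROUP_ASD)).sum())} "
          f"autistic)")

    cr = sg.windowed_cluster_frequencies(tl, window_minutes=4.0,
                                         step_minutes=0.5, seed=SEED + 2)
    counts = np.unique(cr.n_clusters_per_window, return_counts=True)
    print(f"\nmixture clustering over {cr.n_windows} windows; raw cluster "
          f"counts per window: "
          + ", ".join(f"{k}: {c}" for k, c in zip(*counts)))
    for j, cid in enumerate(cr.cluster_ids):
        members = cr.assignment_frequency[:, j] > 0.5
        n_asd = int(np.sum(members & (tl.groups == GROUP_ASD)))
        print(f"  cluster {cid}: {cr.cluster_size_mean[j]:.1f} "
              f"+- {cr.cluster_size_sd[j]:.1f} members per window "
              f"({n_asd} autistic among majority members)")
    maxfreq = cr.assignment_frequency.max(axis=1)
    print(f"{int((maxfreq > 0.75).sum())}/{tl.n_participants} participants "
          f"assigned to one cluster >75% of windows")

    freq.to_csv(RESULTS_DIR / "classification_frequencies.csv", index=False,
                float_format="%.4f")
    cluster_df = pd.DataFrame(
        cr.assignment_frequency,
        columns=[f"cluster_{c}" for c in cr.cluster_ids])
    cluster_df.insert(0, "participant_id", tl.pids)
    cluster_df.insert(1, "group", tl.groups)
    out = RESULTS_DIR / "cluster_frequencies.csv"
    cluster_df.to_csv(out, index=False, float_format="%.4f")
    gaze_io.write_manifest(RESULTS_DIR, "subgroups", config, SEED,
                           outputs=[out])


if __name__ == "__main__":
    main()
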