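#!/usr/bin/env python
"""Group effect sizes: bootstrap Cohen's d per feature, per episode, plus
an epoch-duration sweep on the combined timeline.

Cohen's d is oriented TD - ASD (positive = controls higher).  Full-episode
effects use 10,000 within-group bootstrap resamples; the sweep combines
epoch sampling with participant resampling at a smaller iteration count and
FDR-corrects p-values within each duration.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS_DIR, SEED, default_config, load_timeline  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from gazepheno import gaze_io, stats  # noqa: E402
from gazepheno.core import FEATURES_8, GROUP_ASD, GROUP_TD  # noqa: E402


def main() -> None:
    config = default_config()
    tl = load_timeline(config)
    td = tl.group_indices(GROUP_TD)
    asd = tl.group_indices(GROUP_ASD)

    rows = []
    for ep in tl.episode_ids:
        m = tl.episode_features(ep)[list(FEATURES_8)].to_numpy()
        results = []
        for j, feat in enumerate(FEATURES_8):
            res = stats.bootstrap_effect(m[td, j], m[asd, j],
                                         n_iter=config.n_boot,
                                         seed=SEED + j, feature=feat)
            results.append(res)
        adj = stats.fdr_adjust([r.p for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
            rows.append({"episode_id": ep, "feature": r.feature, "d": r.d,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "p": r.p, "p_adj": r.p_adj, "epoch": "full"})

    # epoch-duration sweep on the combined timeline
    for minutes in (4.0, 2.0, 1.0, 0.5):
        results = []
        for j, feat in enumerate(("pct_onscreen", "pct_face", "pct_eyes",
                                  "mean_heatmap_corr")):
            res = stats.epoch_sampled_effect(tl, feat, minutes * 60.0,
                                             n_iter=500, seed=SEED + j)
            results.append(res)
        adj = stats.fdr_adjust([r.p for r in results])
        for r, pa in zip(results, adj):
            rows.append({"episode_id": "combined", "feature": r.feature,
                         "d": r.d, "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "p": r.p, "p_adj": float(pa),
                         "epoch": f"{minutes:g} min"})

    df = pd.DataFrame(rows)
    out_csv = RESULTS_DIR / "effects.csv"
    df.to_csv(out_csv, index=False, float_format="%.4f")
    out_json = RESULTS_DIR / "effects.json"
    out_json.write_text(json.dumps(rows, indent=2, default=float))

    sig = df[(df["epoch"] == "full") & (df["p_adj"] < 0.05)]
    print(f"effect sizes -> {out_csv}")
    print(f"significant full-episode effects (FDR < 0.05): "
          f"{len(sig)}/{2 * len(FEATURES_8)}")
    show = df[df["feature"].isin(["pct_face", "pct_eyes",
                                  "mean_heatmap_corr"])]
    print(show.round(3).to_string(index=False))
    gaze_io.write_manifest(RESULTS_DIR, "effects", config, SEED,
                           outputs=[out_csv, out_json])


if __name__ == "__main__":
    main()
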