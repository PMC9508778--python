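#!/usr/bin/env python
"""Generate the synthetic study cohort and write it to results/cohort/.

The cohort has 30 ASD and 60 TD participants watching two 5-minute
shot-structured episodes.  Both groups contain an "atypical gaze" trait
component (ASD 50%, TD 25% prevalence): individuals are stable across
episodes, groups differ on average, and the atypical subgroup crosses
diagnostic lines.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORT_DIR, SEED, cohort_spec, default_config  # noqa: E402

import numpy as np  # noqa: E402

from gazepheno import synthetic as syn  # noqa: E402
from gazepheno.core import GROUP_ASD, GROUP_TD  # noqa: E402


def main() -> None:
    config = default_config()
    spec = cohort_spec()
    recordings, scenes, traits = syn.make_cohort(spec, config,
                                                 out_dir=COHORT_DIR)
    print(f"wrote {len(recordings)} recordings for "
          f"{spec.n_asd} ASD + {spec.n_td} TD participants "
          f"to {COHORT_DIR}")
    for ep, scene in scenes.items():
        print(f"  {ep}: {scene.n_frames} frames, "
              f"{len(scene.shots)} shots, "
              f"{100 * scene.fraction_frames_with_person():.1f}% of frames "
              f"with a person")
    for group in (GROUP_TD, GROUP_ASD):
        vals = [tv.p_face for pid, info in traits.items()
                if info["meta"].group == group
                for tv in info["episodes"].values()]
        print(f"  {group}: face-preference trait "
              f"{100 * np.mean(vals):.1f}% +- {100 * np.std(vals):.1f}%")
    n_atypical = sum(info["component"] for info in traits.values())
    print(f"  atypical-gaze component members: {n_atypical} of "
          f"{len(traits)} (seed {SEED})")


if __name__ == "__main__":
    main()
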