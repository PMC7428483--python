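"""Generate the color-name association stimuli for both learning conditions.

Writes one 40-trial session plan per condition (10 stratified-hue target
colors each, candidate windows on the 35-step saturation grid) under
results/stimuli/ and prints the worked example of the grid construction.
"""

from pathlib import Path

import numpy as np

from learnconn import stimuli

OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    grid = stimuli.build_saturation_grid(46)
    windows = stimuli.enumerate_candidate_windows(grid)
    print(f"saturation grid for S=46: {list(grid.values)}")
    print(f"candidate windows containing 46: {len(windows)}")
    for w in windows:
        print(f"  {list(w)}")

    rng = np.random.default_rng(seed)
    for condition in stimuli.CONDITIONS:
        colors = stimuli.sample_target_colors(stimuli.N_ASSOCIATIONS, rng)
        named = [(f"{condition}_color{i:02d}", c) for i, c in enumerate(colors)]
        plan = stimuli.build_session_plan(named, condition, rng, rng_seed=seed)
        path = OUT / f"session_{condition}.tsv"
        stimuli.write_plan(plan, path)
        slots = [t.target_slot for t in plan.trials]
        print(
            f"{condition}: {len(plan.trials)} trials -> {path.name}; "
            f"target slot counts {np.bincount(slots, minlength=5).tolist()}"
        )


if __name__ == "__main__":
    main()
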