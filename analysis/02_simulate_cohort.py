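"""Simulate a cohort and write it in the pipeline's on-disk formats.

Uses a half-scale parcellation (131 nodes) so the TSV output stays modest;
the full-scale statistics are computed in-memory by scripts/acceptance.py.
Output: results/cohort/ with one run TSV per subject x condition,
parcellation.tsv and scores.tsv.
"""

from pathlib import Path

from learnconn import synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 0) -> None:
    config = synthetic.SimulationConfig(seed=seed, volumes=120).scaled(0.5)
    cohort = synthetic.simulate_cohort(config)
    synthetic.write_cohort(cohort, OUT)
    print(
        f"wrote {len(cohort.series)} runs ({config.n_subjects} subjects x "
        f"{len(config.conditions)} conditions, {config.n_nodes} nodes, "
        f"{config.volumes} volumes at TR {config.tr_seconds:g} s) to {OUT}"
    )
    print(cohort.scores.describe().loc[["mean", "std"]].round(1).to_string())


if __name__ == "__main__":
    main()
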