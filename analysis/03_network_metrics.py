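"""Compute per-run connectivity statistics for the simulated cohort.

Reads results/cohort/ (written by 02), applies the preprocessing chain
(drop 5 volumes, 0.01 Hz high-pass) and the 25% proportional threshold, and
writes the tidy metrics table to results/metrics.tsv.
"""

from pathlib import Path

from learnconn import pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = pipeline.RunConfig(
        mode="roi-tsv",
        input_dir=str(ROOT / "cohort"),
        output_dir=str(ROOT),
    )
    report = pipeline.run_pipeline(config)
    m = report.metrics
    print(f"metrics for {len(m)} runs -> {ROOT / 'metrics.tsv'}")
    print(f"links per graph: {m['links'].unique().tolist()}")
    print(
        m.groupby("condition")[["within_DMN", "within_FPN", "between_DMN_FPN"]]
        .mean()
        .round(1)
        .to_string()
    )


if __name__ == "__main__":
    main()
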