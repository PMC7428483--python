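"""Group-level comparison of the three graph statistics across states.

Reads results/metrics.tsv and results/cohort/scores.tsv (written by 02/03)
and runs the nonparametric design: Friedman omnibus with Bonferroni-
corrected pairwise Wilcoxon tests per metric family, the errorless vs.
trial-and-error score contrast, and the brain-behavior Spearman correlation
of the difference scores.  Writes results/group_stats.tsv and
results/pattern.tsv and prints the relation table.
"""

from pathlib import Path

import pandas as pd

from learnconn import stats, synthetic

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metrics = pd.read_csv(ROOT / "metrics.tsv", sep="\t")
    scores = pd.read_csv(ROOT / "cohort" / "scores.tsv", sep="\t")

    families = {
        "learning": synthetic.LEARNING_FAMILY,
        "test": synthetic.TEST_FAMILY,
    }
    tables = {}
    for family, conditions in families.items():
        for metric in ("within_DMN", "within_FPN", "between_DMN_FPN"):
            tables[f"{family}:{metric}"] = stats.CohortTable.from_metrics(
                metrics, metric, conditions
            )
    pattern = stats.pattern_summary(tables)
    pattern.to_csv(ROOT / "pattern.tsv", sep="\t", index=False)
    print("relation table:")
    print(pattern[["metric", "pair", "p_corrected", "relation"]].to_string(index=False))

    score_res = stats.wilcoxon_signed_rank(
        scores["score_EL"].to_numpy(float), scores["score_TE"].to_numpy(float)
    )
    print(
        f"\nEL vs T&E scores: mean {scores['score_EL'].mean():.0f} vs "
        f"{scores['score_TE'].mean():.0f}, Wilcoxon p = {score_res.p_value:.3f}"
    )

    diffs, bb = stats.brain_behavior_analysis(metrics, scores)
    diffs.to_csv(ROOT / "behavior_diffs.tsv", sep="\t")
    print(
        f"brain-behavior coupling: Spearman rho = {bb.statistic:.3f}, "
        f"p = {bb.p_value:.3f} over {bb.n} subjects"
    )


if __name__ == "__main__":
    main()
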