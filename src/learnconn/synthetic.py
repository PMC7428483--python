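"""Block-covariance cohort simulator for the learning-network analysis.

The study data (43 subjects, five task states, 264-node parcellation) are
not public, so the pipeline is exercised on synthetic cohorts with the same
statistical skeleton: each run is a zero-mean multivariate normal time
series whose node-by-node correlation matrix has a block structure over the
DMN, FPN and remaining nodes.  A baseline correlation ``rho0`` couples all
node pairs; condition-dependent boosts raise the within-DMN, within-FPN and
DMN-x-FPN blocks; a per-subject effect perturbs the DMN-x-FPN block with
opposite sign in the two learning conditions, coupling each subject's
trial-and-error-minus-errorless connectivity difference to a behavioral
score difference with the planted rank correlation.

Gaussian state noise on the block boosts (fresh per subject and condition)
plays the role of spontaneous arousal/engagement fluctuations and provides
the between-subject spread of the graph metrics; an optional AR(1)
coefficient adds temporal smoothness.  No hemodynamic forward model is
attempted — the analysis consumes correlations, which the block structure
controls directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from learnconn.preprocess import Parcellation, RoiTimeSeriesMatrix, write_roi_tsv

CONDITIONS = ("rest", "EL-learn", "TE-learn", "EL-test", "TE-test")
LEARNING_FAMILY = ("rest", "EL-learn", "TE-learn")
TEST_FAMILY = ("rest", "EL-test", "TE-test")

# sign with which the per-subject effect enters the DMN x FPN block
SUBJECT_EFFECT_SIGN = {
    "rest": 0.0,
    "EL-learn": -0.5,
    "TE-learn": +0.5,
    "EL-test": 0.0,
    "TE-test": 0.0,
}


def _default_dmn_boost() -> dict[str, float]:
    return {"rest": 0.0, "EL-learn": 0.0, "TE-learn": 0.06, "EL-test": 0.0, "TE-test": 0.0}


def _default_fpn_boost() -> dict[str, float]:
    return {"rest": 0.0, "EL-learn": 0.12, "TE-learn": 0.12, "EL-test": 0.10, "TE-test": 0.10}


def _default_between_boost() -> dict[str, float]:
    return {"rest": 0.0, "EL-learn": 0.04, "TE-learn": 0.04, "EL-test": 0.0, "TE-test": 0.0}


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the study's design constants.

    Node counts (58 DMN, 25 FPN, 181 other = 264), the 10-minute run length
    at TR 3 s (200 volumes) and the cohort size (43) are the study's values.
    Correlation boosts are calibration constants chosen so that group
    contrasts at n = 43 reproduce the qualitative significance pattern of
    the learning and test families (see docs/methods.md); ``tau`` scales the
    per-subject DMN-x-FPN effect and ``slope_a``/``sigma_b`` turn it into a
    behavioral score difference with planted Spearman correlation ~0.32.
    """

    n_subjects: int = 43
    n_dmn: int = 58
    n_fpn: int = 25
    n_other: int = 181
    volumes: int = 200
    tr_seconds: float = 3.0
    rho0: float = 0.08
    dmn_boost: dict[str, float] = field(default_factory=_default_dmn_boost)
    fpn_boost: dict[str, float] = field(default_factory=_default_fpn_boost)
    between_boost: dict[str, float] = field(default_factory=_default_between_boost)
    tau: float = 0.03
    state_noise_sd: float = 0.03
    slope_a: float = 670.0
    sigma_b: float = 30.0
    score_mean: float = 190.0
    score_sd: float = 65.0
    phi: float = 0.0
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("at least 2 subjects required")
        for name in ("n_dmn", "n_fpn", "n_other"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.volumes < 10:
            raise ValueError("at least 10 volumes required")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must lie in [0, 1)")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return self.n_dmn + self.n_fpn + self.n_other

    def scaled(self, factor: float) -> "SimulationConfig":
        """Shrink the parcellation by ``factor`` (node counts only).

        Correlation-scale parameters are left untouched; degree-scale
        quantities shrink roughly proportionally with the node count.
        """
        if not 0 < factor <= 1:
            raise ValueError("factor must lie in (0, 1]")
        return replace(
            self,
            n_dmn=max(2, round(self.n_dmn * factor)),
            n_fpn=max(2, round(self.n_fpn * factor)),
            n_other=max(2, round(self.n_other * factor)),
        )


@dataclass
class SyntheticCohort:
    """Complete subject x condition design with scores and provenance."""

    config: SimulationConfig
    parcellation: Parcellation
    series: dict[tuple[str, str], RoiTimeSeriesMatrix]
    scores: pd.DataFrame  # columns: subject, score_EL, score_TE
    subject_effects: pd.Series

    @property
    def subjects(self) -> list[str]:
        return list(self.scores["subject"])


def make_parcellation(config: SimulationConfig) -> Parcellation:
    """Synthetic node table: labels DMN/FPN/other, coordinates on a 9 mm grid.

    Coordinates are placeholders (the simulator never uses geometry); they
    are spaced widely so ROI spheres would not overlap if extraction were
    exercised on matching volumes.
    """
    n = config.n_nodes
    side = int(np.ceil(n ** (1 / 3)))
    idx = np.arange(n)
    coords = np.stack(
        [idx % side, (idx // side) % side, idx // (side * side)], axis=1
    ) * 9.0
    labels = (
        ["DMN"] * config.n_dmn + ["FPN"] * config.n_fpn + ["other"] * config.n_other
    )
    table = pd.DataFrame(
        {
            "node_id": [f"n{j:03d}" for j in range(n)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network": labels,
        }
    )
    return Parcellation(table)


def make_covariance(
    config: SimulationConfig,
    condition: str,
    subject_effect: float = 0.0,
    state_noise: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Unit-diagonal block correlation matrix for one run.

    Off-block cells carry ``rho0``; the DMN and FPN diagonal blocks add
    their condition boosts; the DMN x FPN block adds the between boost, the
    signed subject effect, and state noise.  The result is repaired to
    positive definiteness by flooring eigenvalues at 1e-6 and re-normalizing
    the diagonal.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    noise = {"dmn": 0.0, "fpn": 0.0, "between": 0.0}
    if state_noise:
        noise.update(state_noise)
    n = config.n_nodes
    nd, nf = config.n_dmn, config.n_fpn
    sigma = np.full((n, n), config.rho0)
    dmn = slice(0, nd)
    fpn = slice(nd, nd + nf)
    sigma[dmn, dmn] += config.dmn_boost[condition] + noise["dmn"]
    sigma[fpn, fpn] += config.fpn_boost[condition] + noise["fpn"]
    between = (
        config.between_boost[condition]
        + SUBJECT_EFFECT_SIGN[condition] * subject_effect
        + noise["between"]
    )
    sigma[dmn, fpn] += between
    sigma[fpn, dmn] += between
    np.fill_diagonal(sigma, 1.0)
    if np.abs(sigma).max() > 5.0:
        raise ValueError("correlation parameters are unrepairably large")

    w, v = np.linalg.eigh(sigma)
    if w.min() < 1e-6:
        w = np.maximum(w, 1e-6)
        sigma = (v * w) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
        np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_subject(
    config: SimulationConfig,
    condition: str,
    subject_effect: float,
    rng: np.random.Generator,
    state_noise: Mapping[str, float] | None = None,
) -> RoiTimeSeriesMatrix:
    """One run: ``volumes`` draws from the block-covariance normal.

    With ``phi > 0`` the innovations follow a stationary AR(1) per node
    (scaled to keep unit marginal variance) before spatial mixing, so the
    target correlation matrix is unchanged.
    """
    sigma = make_covariance(config, condition, subject_effect, state_noise)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((config.volumes, config.n_nodes))
    if config.phi > 0:
        phi = config.phi
        scale = np.sqrt(1.0 - phi**2)
        out = np.empty_like(z)
        out[0] = z[0]
        for t in range(1, config.volumes):
            out[t] = phi * out[t - 1] + scale * z[t]
        z = out
    data = z @ chol.T
    return RoiTimeSeriesMatrix(data, config.tr_seconds)


def simulate_scores(
    config: SimulationConfig,
    subject_effects: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Behavioral scores coupled to the subject effects.

    The latent score difference is ``slope_a * effect + N(0, sigma_b)``;
    errorless and trial-and-error scores share a common ability term and
    split the difference, then round to multiples of 10 and clip to
    [0, 400] as the 40-trial scoring rule dictates.
    """
    n = len(subject_effects)
    latent_diff = config.slope_a * subject_effects + rng.normal(
        0.0, config.sigma_b, size=n
    )
    ability = rng.normal(config.score_mean, config.score_sd, size=n)
    raw_el = ability - latent_diff / 2.0
    raw_te = ability + latent_diff / 2.0
    to_score = lambda v: np.clip(np.round(v / 10.0) * 10.0, 0, 400).astype(int)
    return pd.DataFrame(
        {
            "subject": [f"sub{i:02d}" for i in range(n)],
            "score_EL": to_score(raw_el),
            "score_TE": to_score(raw_te),
        }
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full design: every subject simulated in every configured condition.

    All randomness flows from ``config.seed``; subject effects are drawn
    once per subject (SD ``tau``) and reused across conditions, entering
    the covariance with the condition-dependent sign.
    """
    rng = np.random.default_rng(config.seed)
    effects = rng.normal(0.0, config.tau, size=config.n_subjects)
    parc = make_parcellation(config)
    series: dict[tuple[str, str], RoiTimeSeriesMatrix] = {}
    for i in range(config.n_subjects):
        subject = f"sub{i:02d}"
        for condition in config.conditions:
            state_noise = {
                "dmn": rng.normal(0.0, config.state_noise_sd),
                "fpn": rng.normal(0.0, config.state_noise_sd),
                "between": rng.normal(0.0, config.state_noise_sd),
            }
            series[(subject, condition)] = simulate_subject(
                config, condition, effects[i], rng, state_noise
            )
    scores = simulate_scores(config, effects, rng)
    return SyntheticCohort(
        config=config,
        parcellation=parc,
        series=series,
        scores=scores,
        subject_effects=pd.Series(effects, index=scores["subject"].tolist()),
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort in the pipeline's file formats (TSV throughout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.parcellation.to_tsv(outdir / "parcellation.tsv")
    cohort.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    for (subject, condition), ts in cohort.series.items():
        write_roi_tsv(
            ts,
            outdir / f"{subject}_{condition}.tsv",
            subject=subject,
            condition=condition,
        )
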