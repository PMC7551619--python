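"""Simulated sensory panels with known ground truth.

The generator encodes the population structure the threshold analyses
assume, so estimator behavior can be checked against known latent
parameters:

* a *specific-anosmia* point mass: a fraction of subjects cannot detect
  the odorant at any concentration and answer forced-choice trials at
  the task's guessing rate;
* log-normal individual thresholds among the remaining subjects
  (log10 thresholds are Normal around the population median);
* a logistic detection function of log10 concentration per subject,
  centered at the subject's threshold (detection probability 0.5 at
  threshold), under a high-threshold guessing model — an undetected
  difference is answered correctly at chance;
* one-step *adaptation carryover*: after a trial in which the subject
  truly detected the odorant, the detection probability at the next
  (higher) concentration is multiplied by ``adaptation_carryover``,
  producing the run-of-correct-then-miss patterns that motivate the
  adaptation branch of the BET rule;
* preference segmentation: each detecting subject is a spike-liker or a
  spike-rejecter, and their probability of choosing the spiked sample
  moves away from 1/2 in proportion to their detection probability —
  polarization appears as soon as the odorant is perceptible.

All randomness flows through a single integer seed; a given config and
seed always reproduce the identical datasets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from threshpanel.core_data import (
    ConcentrationSeries,
    DiscriminationDataset,
    PreferenceDataset,
)
from threshpanel.errors import DomainError

#: Triangle-test ladder (ng/L), decade-spaced.
TRIANGLE_LADDER = (0.2, 2.0, 20.0, 200.0, 2000.0)
#: Paired-preference ladder (ng/L); note the non-uniform step pattern.
PREFERENCE_LADDER = (3.75, 7.5, 37.5, 75.0, 375.0, 750.0)


@dataclass(frozen=True)
class PanelSimConfig:
    """Population and task parameters for one simulated panel.

    Defaults describe a consumer panel for a peppery-aroma compound in
    red wine: roughly 40% specifically anosmic, responder thresholds
    log-normally spread about 100 ng/L with a 1.3-decade standard
    deviation (wide enough that an occasional panelist sits below the
    ladder floor), a moderately steep detection function, mild one-step
    adaptation, and a one-in-four minority that likes the added aroma.
    """

    n_panelists: int = 56
    series: ConcentrationSeries = field(
        default_factory=lambda: ConcentrationSeries(TRIANGLE_LADDER)
    )
    anosmic_fraction: float = 0.40
    threshold_median: float = 100.0
    threshold_log_sd: float = 1.3
    psychometric_slope: float = 2.0
    adaptation_carryover: float = 0.8
    preferer_fraction: float = 0.25
    chance_level: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("anosmic_fraction", "adaptation_carryover",
                     "preferer_fraction", "chance_level"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.threshold_median <= 0:
            raise DomainError("threshold_median must be positive")
        if self.psychometric_slope <= 0:
            raise DomainError("psychometric_slope must be positive")
        if self.n_panelists < 1:
            raise DomainError("n_panelists must be >= 1")

    def with_seed(self, seed: int) -> "PanelSimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SubjectProfile:
    """Latent state of one simulated panelist."""

    panelist: str
    anosmic: bool
    log10_threshold: float | None  # absent for anosmic subjects
    preference_direction: int | None  # +1 spike-liker, -1 spike-rejecter

    def __post_init__(self):
        if self.anosmic and (
            self.log10_threshold is not None or self.preference_direction is not None
        ):
            raise DomainError("anosmic subjects carry no threshold or preference")


def draw_subjects(config: PanelSimConfig) -> list[SubjectProfile]:
    """Sample the latent subject population for one panel."""
    rng = np.random.default_rng(config.seed)
    subjects = []
    width = max(len(str(config.n_panelists)), 3)
    for i in range(config.n_panelists):
        pid = f"S{i + 1:0{width}d}"
        if rng.random() < config.anosmic_fraction:
            subjects.append(SubjectProfile(pid, True, None, None))
        else:
            log_t = rng.normal(np.log10(config.threshold_median), config.threshold_log_sd)
            direction = 1 if rng.random() < config.preferer_fraction else -1
            subjects.append(SubjectProfile(pid, False, float(log_t), direction))
    return subjects


def detection_probability(
    subject: SubjectProfile, c: float, config: PanelSimConfig
) -> float:
    """Probability the subject truly detects the odorant at ``c`` ng/L.

    Logistic in log10 concentration with location at the subject's
    threshold; identically zero for anosmic subjects.
    """
    if c <= 0:
        raise DomainError(f"concentration must be positive, got {c}")
    if subject.anosmic:
        return 0.0
    z = config.psychometric_slope * (np.log10(c) - subject.log10_threshold)
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate_triangle(
    subjects: Sequence[SubjectProfile], config: PanelSimConfig, condition: str = ""
) -> DiscriminationDataset:
    """One ascending triangle test per subject per ladder level.

    A trial is answered correctly when the subject detects the spiked
    sample, or otherwise by guessing at ``chance_level``.  A detection at
    one level multiplies the detection probability at the next level by
    ``adaptation_carryover`` (no carryover beyond one step).
    """
    rng = np.random.default_rng(_stream_seed(config.seed, "triangle"))
    records = {}
    for subject in subjects:
        outcomes = []
        detected_prev = False
        for c in config.series.levels:
            p_det = detection_probability(subject, c, config)
            if detected_prev:
                p_det *= config.adaptation_carryover
            detected = rng.random() < p_det
            correct = detected or rng.random() < config.chance_level
            outcomes.append(correct)
            detected_prev = detected
        records[subject.panelist] = tuple(outcomes)
    return DiscriminationDataset(
        series=config.series, records=records, condition=condition
    )


def simulate_preference(
    subjects: Sequence[SubjectProfile], config: PanelSimConfig
) -> PreferenceDataset:
    """One ascending spiked-vs-blank 2AFC choice per subject per level.

    P(choose spike) = 1/2 + direction * detection/2: indistinguishable
    samples split 50/50, and the choice polarizes toward the subject's
    preference direction as detection becomes reliable.
    """
    rng = np.random.default_rng(_stream_seed(config.seed, "preference"))
    records = {}
    for subject in subjects:
        choices = []
        for c in config.series.levels:
            p_det = detection_probability(subject, c, config)
            direction = subject.preference_direction or 0
            p_spike = 0.5 + direction * 0.5 * p_det
            choices.append("spike" if rng.random() < p_spike else "blank")
        records[subject.panelist] = tuple(choices)
    return PreferenceDataset(series=config.series, records=records)


def _stream_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Independent, reproducible substream per simulation stage."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.SeedSequence(seed, spawn_key=(key,))


def population_detection_curve(
    subjects: Sequence[SubjectProfile], config: PanelSimConfig
):
    """Mean detection probability over given subjects, as a function of c.

    Used by recovery tests to locate the concentration where the
    chance-corrected group proportion correct crosses a criterion.
    """

    def mean_detection(c: float) -> float:
        return float(
            np.mean([detection_probability(s, c, config) for s in subjects])
        )

    return mean_detection
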