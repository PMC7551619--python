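"""Individual best-estimate thresholds under a modified ASTM E679 rule.

Each panelist answers one triangle test per ascending concentration.  The
best-estimate threshold (BET) is assigned by a three-branch decision rule:

1. **standard** — if the top-level answer is correct, the BET is the
   geometric mean of the lowest concentration from which every answer is
   correct and the level below it (one hypothetical step below the ladder
   when that run starts at the lowest level: *lowest-extrapolated*);
2. **adaptation** — otherwise, if the panelist answered at least three
   consecutive levels correctly before missing a higher one, the misses at
   nominally easier concentrations are attributed to sensory adaptation and
   the BET is the geometric mean of the run's starting concentration and
   the level below it (chance probability of such a run in a triangle task
   is (1/3)^3 ≈ 3.7%, so the run is taken as evidence of sensitivity);
3. **non-responder-imputed** — otherwise the panelist is classified
   anosmic and the BET is imputed as the geometric mean of the top
   concentration and the next hypothetical step above; the imputed value
   is used only for visualization, never in summary statistics.

Group summaries are geometric means of responder BETs (antilog of the mean
of log10 BETs); conditions are compared with a pooled-variance two-sample
t-test on the logged responder BETs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from threshpanel.core_data import ConcentrationSeries, DiscriminationDataset, extend_series
from threshpanel.errors import InsufficientDataError, IntegrityError

RULE_STANDARD = "standard"
RULE_LOWEST = "lowest-extrapolated"
RULE_ADAPTATION = "adaptation"
RULE_IMPUTED = "non-responder-imputed"


@dataclass(frozen=True)
class BETResult:
    panelist: str
    bet: float
    rule: str
    responder: bool


@dataclass(frozen=True)
class GroupBETSummary:
    n_total: int
    n_responders: int
    n_anosmic: int
    responder_fraction: float
    geometric_mean_bet: float | None
    sd_log_bet: float | None


@dataclass(frozen=True)
class LogBETComparison:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_a: int
    n_b: int


def _geomean(a: float, b: float) -> float:
    return math.sqrt(a * b)


def classify_and_estimate(
    outcomes: Sequence[bool],
    series: ConcentrationSeries,
    panelist: str = "",
) -> BETResult:
    """Apply the three-branch BET decision rule to one outcome vector.

    ``outcomes`` is ordered ascending by concentration (True = correct).
    The standard branch takes precedence; the adaptation branch is
    consulted only when the top-level answer is wrong.  When several runs
    of three or more correct answers qualify under the adaptation branch,
    the run starting at the lowest concentration is used.
    """
    outcomes = [bool(o) for o in outcomes]
    n = len(series)
    if len(outcomes) != n:
        raise IntegrityError(
            f"{len(outcomes)} outcomes for a {n}-level series"
        )
    levels = series.levels

    if outcomes[-1]:
        # Standard rule: lowest level from which every answer is correct.
        start = n - 1
        while start > 0 and outcomes[start - 1]:
            start -= 1
        below = levels[start - 1] if start > 0 else extend_series(series, "below")
        rule = RULE_STANDARD if start > 0 else RULE_LOWEST
        return BETResult(panelist, _geomean(levels[start], below), rule, True)

    # Adaptation rule: earliest run of >=3 consecutive correct answers.
    # The top-level answer is wrong here, so any such run is necessarily
    # followed by an incorrect answer at a higher concentration.
    run = 0
    for i, ok in enumerate(outcomes):
        run = run + 1 if ok else 0
        if run == 3:
            start = i - 2
            below = (
                levels[start - 1] if start > 0 else extend_series(series, "below")
            )
            return BETResult(
                panelist, _geomean(levels[start], below), RULE_ADAPTATION, True
            )

    imputed = _geomean(levels[-1], extend_series(series, "above"))
    return BETResult(panelist, imputed, RULE_IMPUTED, False)


def estimate_dataset(data: DiscriminationDataset) -> list[BETResult]:
    """BETs for every panelist in a discrimination dataset."""
    return [
        classify_and_estimate(outcomes, data.series, panelist=pid)
        for pid, outcomes in data.records.items()
    ]


def summarize_group(bets: Iterable[BETResult]) -> GroupBETSummary:
    """Group summary over responders; imputed BETs only counted.

    The geometric mean is the antilog of the arithmetic mean of the log10
    responder BETs.  ``sd_log_bet`` is the sample standard deviation of
    the log10 responder BETs.  With zero responders both are ``None``.
    """
    bets = list(bets)
    if not bets:
        raise InsufficientDataError("no BETs to summarize")
    responders = [b for b in bets if b.responder]
    n_total = len(bets)
    n_resp = len(responders)
    gm = sd = None
    if n_resp > 0:
        logs = np.log10([b.bet for b in responders])
        gm = float(10 ** logs.mean())
        sd = float(logs.std(ddof=1)) if n_resp > 1 else 0.0
    return GroupBETSummary(
        n_total=n_total,
        n_responders=n_resp,
        n_anosmic=n_total - n_resp,
        responder_fraction=n_resp / n_total,
        geometric_mean_bet=gm,
        sd_log_bet=sd,
    )


def compare_log_bets(
    group_a: Iterable[BETResult], group_b: Iterable[BETResult]
) -> LogBETComparison:
    """Pooled-variance two-sample t-test on log10 responder BETs.

    Imputed non-responders are excluded.  Student (pooled) rather than
    Welch, with df = n_a + n_b - 2.
    """
    log_a = np.log10([b.bet for b in group_a if b.responder])
    log_b = np.log10([b.bet for b in group_b if b.responder])
    if len(log_a) < 2 or len(log_b) < 2:
        raise InsufficientDataError(
            f"need >=2 responders per group, got {len(log_a)} and {len(log_b)}"
        )
    t, p = stats.ttest_ind(log_a, log_b, equal_var=True)
    return LogBETComparison(
        t_statistic=float(t),
        degrees_of_freedom=len(log_a) + len(log_b) - 2,
        p_value=float(p),
        n_a=len(log_a),
        n_b=len(log_b),
    )
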