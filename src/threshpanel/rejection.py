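"""Consumer rejection thresholds from ascending paired-preference data.

Panelists taste spiked/blank pairs at ascending spike concentrations and
state a preference (2AFC).  Because a single 2AFC response carries a 50%
guessing rate, responders are gated by *consistency*: a panelist whose
preference points the same way at all of the top ``k_top`` (default 3)
concentrations is a consistent responder — the chance probability of that
happening in one given direction is (1/2)^3 = 12.5%.  Consistent
preferers chose the spike all three times; consistent rejecters chose the
blank all three times; everyone else is a non-responder.

Within a segment of consistent responders, preference for the spike is
coded 1 and regressed on log10 concentration.  The concentration where
the fitted line crosses 0.25 is the group rejection threshold (the group
prefers the blank beyond it); a crossing of 0.75 from below would mark a
group preference threshold for the spike.  Crossings further than one
hypothetical ladder step outside the tested range are reported as
undefined rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
import statsmodels.api as sm

from threshpanel.core_data import ConcentrationSeries, PreferenceDataset, extend_series
from threshpanel.errors import DomainError, InsufficientDataError

STATUS_PREFERER = "consistent-preferer"
STATUS_REJECTER = "consistent-rejecter"
STATUS_NONRESPONDER = "non-responder"

REJECTION_CRITERION = 0.25
PREFERENCE_CRITERION = 0.75

#: Minimum segment size below which no threshold is computed for a
#: preferers-only fit; a handful of panelists cannot support a group line.
MIN_SEGMENT_FOR_THRESHOLD = 10


@dataclass(frozen=True)
class RejectionClassification:
    panelist: str
    status: str
    top_choices: tuple[str, ...]


@dataclass(frozen=True)
class RejectionFit:
    """OLS fit of spike=1/blank=0 codes on log10 concentration."""

    slope: float
    intercept: float
    rejection_threshold: float | None
    preference_threshold: float | None
    n_included: int
    segment: str
    flag: str = ""


def classify_consistency(
    choices,
    series: ConcentrationSeries,
    k_top: int = 3,
) -> RejectionClassification:
    """Classify one panelist by the direction of their top-k preferences."""
    if k_top < 1:
        raise DomainError(f"k_top must be >= 1, got {k_top}")
    if k_top > len(series):
        raise DomainError(f"k_top={k_top} exceeds {len(series)} ladder levels")
    top = tuple(choices[-k_top:])
    if all(c == "spike" for c in top):
        status = STATUS_PREFERER
    elif all(c == "blank" for c in top):
        status = STATUS_REJECTER
    else:
        status = STATUS_NONRESPONDER
    return RejectionClassification(panelist="", status=status, top_choices=top)


def chance_consistency_probability(k_top: int, directions: str = "one-sided") -> float:
    """Probability a pure guesser is classified consistent.

    ``one-sided`` is the probability of k_top identical choices in one
    given direction, (1/2)^k_top — 12.5% for k_top = 3; ``either`` sums
    the two disjoint directions, 2·(1/2)^k_top.
    """
    if k_top < 1:
        raise DomainError(f"k_top must be >= 1, got {k_top}")
    p = 0.5 ** k_top
    if directions == "one-sided":
        return p
    if directions == "either":
        return 2.0 * p
    raise DomainError(f"directions must be 'one-sided' or 'either', got {directions!r}")


def classify_dataset(
    data: PreferenceDataset, k_top: int = 3
) -> list[RejectionClassification]:
    return [
        RejectionClassification(
            panelist=pid,
            status=classify_consistency(choices, data.series, k_top).status,
            top_choices=tuple(choices[-k_top:]),
        )
        for pid, choices in data.records.items()
    ]


def _crossing(slope, intercept, criterion, series, from_below):
    """Concentration where the line crosses `criterion`, honoring the
    required approach direction and the one-step extrapolation guard."""
    if abs(slope) < 1e-9:  # flat line up to arithmetic dust
        return None
    if from_below and slope <= 0:
        return None
    if not from_below and slope >= 0:
        return None
    exponent = (criterion - intercept) / slope
    if abs(exponent) > 300:
        return None
    c = 10 ** exponent
    lo = extend_series(series, "below")
    hi = extend_series(series, "above")
    if not lo <= c <= hi:
        return None
    return c


def fit_rejection(
    data: PreferenceDataset,
    include: Collection[str] | None = None,
    segment: str = "all-consistent",
    rejection_criterion: float = REJECTION_CRITERION,
    preference_criterion: float = PREFERENCE_CRITERION,
) -> RejectionFit:
    """Fit the preference line for a segment and read off both thresholds.

    ``include`` selects panelist ids (defaults to every panelist in the
    dataset); ``segment`` is a label carried into the result.  The
    rejection threshold requires a falling line (slope < 0) crossing
    0.25; the preference threshold a rising line crossing 0.75.  Either
    is ``None`` when the geometry does not produce an in-guard crossing.
    """
    records = data.records
    if include is not None:
        include = set(include)
        records = {pid: v for pid, v in records.items() if pid in include}
    if len(records) < 2:
        raise InsufficientDataError(
            f"segment {segment!r} selects {len(records)} panelists; need >= 2"
        )

    logc = np.log10(data.series.levels)
    x = np.concatenate([logc for _ in records])
    y = np.concatenate(
        [np.asarray([1.0 if c == "spike" else 0.0 for c in v]) for v in records.values()]
    )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])

    fitted_ends = intercept + slope * np.array([logc[0], logc[-1]])
    flag = "" if np.all((fitted_ends >= 0) & (fitted_ends <= 1)) else "fit-out-of-range"

    return RejectionFit(
        slope=slope,
        intercept=intercept,
        rejection_threshold=_crossing(
            slope, intercept, rejection_criterion, data.series, from_below=False
        ),
        preference_threshold=_crossing(
            slope, intercept, preference_criterion, data.series, from_below=True
        ),
        n_included=len(records),
        segment=segment,
        flag=flag,
    )


def spike_proportions(data: PreferenceDataset, include=None) -> dict[float, float]:
    """Per-level proportion choosing the spike, for descriptive reporting."""
    records = data.records
    if include is not None:
        include = set(include)
        records = {pid: v for pid, v in records.items() if pid in include}
    if not records:
        raise InsufficientDataError("no panelists selected")
    mat = np.asarray(
        [[1.0 if c == "spike" else 0.0 for c in v] for v in records.values()]
    )
    return {
        float(conc): float(p) for conc, p in zip(data.series.levels, mat.mean(axis=0))
    }


def segment_report(data: PreferenceDataset, k_top: int = 3) -> dict:
    """Counts and per-segment fits for a full preference dataset.

    Fits the preference line for all consistent responders and for the
    consistent rejecters alone.  A small preferer segment (fewer than
    ``MIN_SEGMENT_FOR_THRESHOLD``) is reported descriptively — per-level
    spike proportions — without a fitted threshold.
    """
    classes = classify_dataset(data, k_top)
    preferers = [c.panelist for c in classes if c.status == STATUS_PREFERER]
    rejecters = [c.panelist for c in classes if c.status == STATUS_REJECTER]
    consistent = preferers + rejecters

    report: dict = {
        "n_total": len(classes),
        "n_consistent_preferers": len(preferers),
        "n_consistent_rejecters": len(rejecters),
        "n_non_responders": len(classes) - len(consistent),
        "classifications": classes,
        "fits": {},
        "preferers_descriptive": None,
    }
    if len(consistent) >= 2:
        report["fits"]["all-consistent"] = fit_rejection(
            data, include=consistent, segment="all-consistent"
        )
    if len(rejecters) >= 2:
        report["fits"]["rejecters-only"] = fit_rejection(
            data, include=rejecters, segment="rejecters-only"
        )
    if preferers:
        report["preferers_descriptive"] = spike_proportions(data, include=preferers)
        if len(preferers) >= MIN_SEGMENT_FOR_THRESHOLD:
            report["fits"]["preferers-only"] = fit_rejection(
                data, include=preferers, segment="preferers-only"
            )
    return report
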