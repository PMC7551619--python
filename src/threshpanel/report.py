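"""End-to-end study reports: BET summaries, graphical fits, histograms.

`run_study1` chains the per-panelist BET classification, the group
summaries, the responders-only graphical fits, and the between-condition
comparison on logged BETs into one JSON-ready report with a provenance
block, so a complete two-condition threshold study reduces to one call.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from typing import Iterable

from threshpanel import __version__ as _pkg_version
from threshpanel.bet_astm import (
    BETResult,
    compare_log_bets,
    estimate_dataset,
    summarize_group,
)
from threshpanel.core_data import ConcentrationSeries, DiscriminationDataset, extend_series
from threshpanel.errors import InsufficientDataError
from threshpanel.graphical_method import fit_graphical


def attainable_bets(series: ConcentrationSeries) -> list[float]:
    """Every BET value the decision rule can produce on this ladder.

    The geometric-mean midpoints of adjacent levels (shared by the
    standard and adaptation branches), the below-range extrapolated
    midpoint, and the imputed non-responder value above the range.
    """
    levels = (extend_series(series, "below"),) + series.levels + (
        extend_series(series, "above"),
    )
    return [math.sqrt(a * b) for a, b in zip(levels, levels[1:])]


def bet_histogram(
    bets: Iterable[BETResult], series: ConcentrationSeries
) -> dict[float, int]:
    """Counts of panelists per attainable BET value (imputed included).

    Imputed non-responder BETs appear here for visualization even though
    they are excluded from every summary statistic.
    """
    bets = list(bets)
    if not bets:
        raise InsufficientDataError("no BETs to bin")
    bins = attainable_bets(series)
    counts = {b: 0 for b in bins}
    for r in bets:
        key = min(bins, key=lambda b: abs(math.log10(b) - math.log10(r.bet)))
        counts[key] += 1
    return counts


def _dataset_hash(data: DiscriminationDataset) -> str:
    canon = json.dumps(
        {
            "levels": list(data.series.levels),
            "condition": data.condition,
            "records": {k: [int(v) for v in row] for k, row in sorted(data.records.items())},
        },
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if is_dataclass(obj):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return round(obj, 10)  # stable formatting across reruns
    return obj


def run_study1(
    data_a: DiscriminationDataset,
    data_b: DiscriminationDataset,
    criterion: float | None = None,
    confidence_level: float = 0.95,
) -> dict:
    """Full two-condition detection-threshold analysis.

    For each condition: per-panelist BETs, the group summary over
    responders, and the graphical fit restricted to the BET-classified
    responders.  Conditions are then compared with the pooled t-test on
    logged responder BETs.  Returns a JSON-ready dict; serializing the
    same inputs twice yields byte-identical output.
    """
    report: dict = {"conditions": {}, "provenance": {"package_version": _pkg_version}}
    per_condition_bets = []
    for label, data in (("a", data_a), ("b", data_b)):
        name = data.condition or label
        bets = estimate_dataset(data)
        per_condition_bets.append(bets)
        responders = [b.panelist for b in bets if b.responder]
        block = {
            "bets": [_jsonable(b) for b in bets],
            "summary": _jsonable(summarize_group(bets)),
            "histogram": {
                f"{k:.6g}": v for k, v in bet_histogram(bets, data.series).items()
            },
        }
        try:
            block["graphical"] = _jsonable(
                fit_graphical(
                    data,
                    include=responders,
                    criterion=criterion,
                    confidence_level=confidence_level,
                )
            )
        except InsufficientDataError as exc:
            block["graphical"] = {"error": f"{name}: {exc}"}
        report["conditions"][name] = block
        report["provenance"][f"input_hash_{label}"] = _dataset_hash(data)
    try:
        report["comparison"] = _jsonable(compare_log_bets(*per_condition_bets))
    except InsufficientDataError as exc:
        report["comparison"] = {"error": str(exc)}
    return report


def report_to_json(report: dict) -> str:
    """Deterministic serialization: sorted keys, stable float formatting."""
    return json.dumps(_jsonable(report), sort_keys=True, indent=2)
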