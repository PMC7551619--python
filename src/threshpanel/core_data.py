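"""Domain types and validated CSV I/O for ascending forced-choice panels.

Everything downstream operates on two dataset shapes built around a fixed
ascending concentration ladder: triangle-test discrimination outcomes
(correct/incorrect per level) and paired-preference 2AFC choices
(spike/blank per level).  Files are exchanged in long format — one row per
panelist × level — with configurable column names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from threshpanel.errors import DomainError, IntegrityError, SchemaError

#: Default long-format column names; override any subset via ``schema=``.
DEFAULT_SCHEMA: dict[str, str] = {
    "panelist": "panelist",
    "condition": "condition",
    "concentration": "concentration",
    "outcome": "outcome",
}

_CORRECT_TOKENS = {"1", "correct", "true", "c", "yes"}
_INCORRECT_TOKENS = {"0", "incorrect", "false", "w", "no"}
_SPIKE_TOKENS = {"spike", "spiked", "1", "true"}
_BLANK_TOKENS = {"blank", "unspiked", "0", "false"}


@dataclass(frozen=True)
class ConcentrationSeries:
    """An ascending ladder of spike concentrations in ng/L.

    The step ratios between the two extreme pairs of levels are exposed
    because the hypothetical one-step extensions (used by the lowest
    extrapolation and the non-responder imputation) follow the *local*
    spacing, which need not be uniform across the ladder.
    """

    levels: tuple[float, ...]

    def __init__(self, levels: Sequence[float]):
        levels = tuple(float(c) for c in levels)
        if len(levels) < 2:
            raise DomainError("a concentration series needs at least 2 levels")
        if any(c <= 0 for c in levels):
            raise DomainError(f"concentrations must be positive, got {levels}")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise DomainError(f"levels must be strictly increasing, got {levels}")
        object.__setattr__(self, "levels", levels)

    @property
    def step_ratio_low(self) -> float:
        """Ratio between the two lowest levels (> 1)."""
        return self.levels[1] / self.levels[0]

    @property
    def step_ratio_high(self) -> float:
        """Ratio between the two highest levels (> 1)."""
        return self.levels[-1] / self.levels[-2]

    def __len__(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class DiscriminationDataset:
    """Per-panelist ordered triangle-test outcomes aligned to a ladder.

    ``records`` maps panelist id to a tuple of booleans (True = correct),
    one entry per series level, ascending.
    """

    series: ConcentrationSeries
    records: Mapping[str, tuple[bool, ...]]
    condition: str = ""

    def __post_init__(self):
        n = len(self.series)
        for pid, outcomes in self.records.items():
            if len(outcomes) != n:
                raise IntegrityError(
                    f"panelist {pid!r}: {len(outcomes)} outcomes for {n} levels"
                )

    @property
    def n_panelists(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PreferenceDataset:
    """Per-panelist ordered 2AFC choices aligned to a ladder.

    ``records`` maps panelist id to a tuple of choice strings drawn from
    the two-valued alphabet ``{"spike", "blank"}``, ascending by level.
    """

    series: ConcentrationSeries
    records: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        n = len(self.series)
        for pid, choices in self.records.items():
            if len(choices) != n:
                raise IntegrityError(
                    f"panelist {pid!r}: {len(choices)} choices for {n} levels"
                )
            bad = [c for c in choices if c not in ("spike", "blank")]
            if bad:
                raise DomainError(
                    f"panelist {pid!r}: choices must be 'spike' or 'blank', got {bad[0]!r}"
                )

    @property
    def n_panelists(self) -> int:
        return len(self.records)


def extend_series(series: ConcentrationSeries, direction: str) -> float:
    """Next hypothetical ladder level one local step beyond the range.

    ``direction="below"`` divides the lowest level by the low step ratio;
    ``"above"`` multiplies the highest level by the high step ratio.  On
    the decade ladder 0.2–2000 ng/L this yields 0.02 and 20,000 ng/L.
    """
    if direction == "below":
        return series.levels[0] / series.step_ratio_low
    if direction == "above":
        return series.levels[-1] * series.step_ratio_high
    raise DomainError(f"direction must be 'below' or 'above', got {direction!r}")


def _resolve_schema(schema: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(cols)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        cols.update(schema)
    return cols


def _load_long(path, cols, required):
    path = Path(path)
    df = pd.read_csv(path)
    for key in required:
        if cols[key] not in df.columns:
            raise SchemaError(
                f"{path.name}: required column {cols[key]!r} (for {key!r}) not found"
            )
    conc = pd.to_numeric(df[cols["concentration"]], errors="coerce")
    if conc.isna().any() or (conc <= 0).any():
        raise DomainError(f"{path.name}: concentrations must be positive numbers")
    df = df.assign(_conc=conc)
    return df


def _collect_records(df, cols, parse_value):
    """Group rows by panelist, sort by concentration, validate completeness."""
    levels = sorted(df["_conc"].unique())
    records: dict[str, tuple] = {}
    for pid, sub in df.groupby(df[cols["panelist"]].astype(str), sort=True):
        sub = sub.sort_values("_conc")
        if sorted(sub["_conc"]) != levels or len(sub) != len(levels):
            raise IntegrityError(
                f"panelist {pid!r}: missing or duplicate concentration levels"
            )
        records[pid] = tuple(parse_value(v) for v in sub[cols["outcome"]])
    return ConcentrationSeries(levels), records


def _parse_outcome(value) -> bool:
    token = str(value).strip().lower()
    if token in _CORRECT_TOKENS:
        return True
    if token in _INCORRECT_TOKENS:
        return False
    raise DomainError(f"cannot parse discrimination outcome {value!r}")


def _parse_choice(value) -> str:
    token = str(value).strip().lower()
    if token in _SPIKE_TOKENS:
        return "spike"
    if token in _BLANK_TOKENS:
        return "blank"
    raise DomainError(f"cannot parse preference choice {value!r}")


def read_discrimination_csv(
    path, schema: Mapping[str, str] | None = None
) -> DiscriminationDataset:
    """Read a long-format triangle-test CSV into a validated dataset.

    Outcomes are parsed case-insensitively from 1/0, correct/incorrect or
    TRUE/FALSE encodings.  Rows may appear in any order; levels are
    aligned by sorted concentration.  A condition label is taken from the
    condition column when present and single-valued.
    """
    cols = _resolve_schema(schema)
    df = _load_long(path, cols, ("panelist", "concentration", "outcome"))
    condition = ""
    if cols["condition"] in df.columns:
        labels = df[cols["condition"]].astype(str).unique()
        if len(labels) == 1:
            condition = labels[0]
    series, records = _collect_records(df, cols, _parse_outcome)
    return DiscriminationDataset(series=series, records=records, condition=condition)


def read_preference_csv(
    path, schema: Mapping[str, str] | None = None
) -> PreferenceDataset:
    """Read a long-format paired-preference CSV into a validated dataset."""
    cols = _resolve_schema(schema)
    df = _load_long(path, cols, ("panelist", "concentration", "outcome"))
    series, records = _collect_records(df, cols, _parse_choice)
    return PreferenceDataset(series=series, records=records)


def write_discrimination_csv(
    dataset: DiscriminationDataset, path, schema: Mapping[str, str] | None = None
) -> None:
    """Write a discrimination dataset in long format (outcome as 1/0)."""
    cols = _resolve_schema(schema)
    rows = []
    for pid, outcomes in dataset.records.items():
        for conc, ok in zip(dataset.series.levels, outcomes):
            rows.append(
                {
                    cols["panelist"]: pid,
                    cols["condition"]: dataset.condition,
                    cols["concentration"]: conc,
                    cols["outcome"]: int(ok),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_preference_csv(
    dataset: PreferenceDataset, path, schema: Mapping[str, str] | None = None
) -> None:
    """Write a preference dataset in long format (choices as spike/blank)."""
    cols = _resolve_schema(schema)
    rows = []
    for pid, choices in dataset.records.items():
        for conc, choice in zip(dataset.series.levels, choices):
            rows.append(
                {
                    cols["panelist"]: pid,
                    cols["concentration"]: conc,
                    cols["outcome"]: choice,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
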