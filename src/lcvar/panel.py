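"""Long-format multi-person time-series panels.

Intensive longitudinal (EMA) data arrive as one row per person per
measurement occasion ("beep") within a day.  A VAR(p) model can only use a
time point whose p immediately preceding occasions were fully observed, so
a central task of this module is computing, for every row, whether it is
*predictable* under a given lag order — and hence each person's effective
number of time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LongPanel",
    "PredictabilityMask",
    "PanelValidationError",
    "read_long_panel",
    "make_panel",
    "predictability_mask",
    "center_within_person",
    "zero_variance_report",
]

#: canonical internal column names
ID, DAY, BEEP = "person_id", "day", "beep"


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class LongPanel:
    """Validated long-format panel, sorted by (person, day, beep).

    Parameters
    ----------
    data
        DataFrame with columns ``person_id``, ``day``, ``beep``, the outcome
        columns and any covariate columns.  Rows are sorted by
        (person_id, day, beep).
    outcomes
        Names of the m outcome columns.
    x_continuous, x_factor
        Names of continuous / categorical covariate columns used in the
        model.  Factor columns are expanded to treatment-coded dummies
        (first sorted level is the reference) by :meth:`covariate_matrix`.
    """

    data: pd.DataFrame
    outcomes: tuple[str, ...]
    x_continuous: tuple[str, ...] = ()
    x_factor: tuple[str, ...] = ()
    has_day: bool = True

    # -- derived --------------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.outcomes)

    @property
    def persons(self) -> np.ndarray:
        """Unique person ids in order of first appearance."""
        return self.data[ID].to_numpy()[
            np.sort(np.unique(self.data[ID].to_numpy(), return_index=True)[1])
        ]

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def person_codes(self) -> np.ndarray:
        """Integer code 0..N-1 per row, in order of first appearance."""
        lookup = {p: i for i, p in enumerate(self.persons)}
        return self.data[ID].map(lookup).to_numpy()

    def observed(self) -> np.ndarray:
        """Row is fully observed: no missing outcome or used covariate."""
        cols = list(self.outcomes) + list(self.x_continuous) + list(self.x_factor)
        return ~self.data[cols].isna().any(axis=1).to_numpy()

    def covariate_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(n_rows, q) float design for the covariates, with names.

        Factors are treatment-coded against the first sorted level.
        Missing covariate cells propagate as NaN (the row is then not
        fully observed and never enters a likelihood).
        """
        blocks: list[pd.DataFrame] = []
        for c in self.x_continuous:
            blocks.append(self.data[[c]].astype(float))
        for c in self.x_factor:
            levels = sorted(self.data[c].dropna().unique())
            dummies = pd.DataFrame(
                {f"{c}[{lv}]": (self.data[c] == lv).astype(float) for lv in levels[1:]}
            )
            dummies[self.data[c].isna().to_numpy()] = np.nan
            blocks.append(dummies)
        if not blocks:
            return np.empty((len(self.data), 0)), []
        X = pd.concat(blocks, axis=1)
        return X.to_numpy(float), list(X.columns)

    def outcome_matrix(self) -> np.ndarray:
        return self.data[list(self.outcomes)].to_numpy(float)


@dataclass(frozen=True)
class PredictabilityMask:
    """Per-row predictability under one lag order.

    ``predictable[r]`` is True iff row r and its ``lag`` immediately
    preceding occasions (consecutive beeps, same day when day breaks are
    honoured) are all fully observed.  ``counts`` maps each person to
    T_{i,p}, the effective number of time points.
    """

    lag: int
    predictable: np.ndarray
    counts: pd.Series = field(repr=False)

    @property
    def n_predictable(self) -> int:
        return int(self.predictable.sum())

    def summary(self) -> dict:
        total = len(self.predictable)
        n = self.n_predictable
        return {
            "lag": self.lag,
            "total_rows": total,
            "predictable_rows": n,
            "percent": 100.0 * n / total if total else 0.0,
            "per_person_counts": {str(k): int(v) for k, v in self.counts.items()},
        }


def make_panel(
    df: pd.DataFrame,
    outcomes: list[str] | tuple[str, ...],
    x_continuous: list[str] | tuple[str, ...] = (),
    x_factor: list[str] | tuple[str, ...] = (),
    has_day: bool = True,
) -> LongPanel:
    """Validate and sort a DataFrame already using canonical column names."""
    df = df.copy()
    if not has_day:
        df[DAY] = 1
    required = [ID, DAY, BEEP, *outcomes]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(f"missing required columns: {missing}")
    for c in outcomes:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise PanelValidationError(f"outcome column {c!r} is not numeric: {exc}")
    df[DAY] = df[DAY].astype(int)
    df[BEEP] = df[BEEP].astype(int)
    if (df[DAY] < 1).any() or (df[BEEP] < 1).any():
        raise PanelValidationError("day and beep indices must be >= 1")
    dup = df.duplicated(subset=[ID, DAY, BEEP], keep=False)
    if dup.any():
        triples = df.loc[dup, [ID, DAY, BEEP]].drop_duplicates().values.tolist()
        raise PanelValidationError(f"duplicate (person, day, beep) triples: {triples}")
    df = df.sort_values([ID, DAY, BEEP], kind="mergesort").reset_index(drop=True)
    return LongPanel(
        data=df,
        outcomes=tuple(outcomes),
        x_continuous=tuple(x_continuous),
        x_factor=tuple(x_factor),
        has_day=has_day,
    )


def read_long_panel(
    path,
    column_map: dict,
    sep: str | None = None,
) -> LongPanel:
    """Read a CSV/TSV file into a validated :class:`LongPanel`.

    ``column_map`` keys: ``id`` (required), ``day`` (optional), ``beep``
    (optional), ``outcomes`` (required, list), ``x_continuous``,
    ``x_factor`` (optional lists).  Empty cells and "NA" are missing.
    When no day column is mapped, each person's rows form one continuous
    sequence; when no beep column is mapped, occasions are numbered by
    row order within (person, day).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True)
    if "id" not in column_map or "outcomes" not in column_map:
        raise PanelValidationError("column_map must define 'id' and 'outcomes'")
    for key in ("id", "day", "beep"):
        col = column_map.get(key)
        if col is not None and col not in raw.columns:
            raise PanelValidationError(f"mapped column {col!r} ({key}) not in file")
    for col in column_map["outcomes"]:
        if col not in raw.columns:
            raise PanelValidationError(f"outcome column {col!r} not in file")

    df = raw.copy()
    df[ID] = raw[column_map["id"]]
    has_day = column_map.get("day") is not None
    df[DAY] = raw[column_map["day"]] if has_day else 1
    if column_map.get("beep") is not None:
        df[BEEP] = raw[column_map["beep"]]
    else:
        df[BEEP] = df.groupby([ID, DAY]).cumcount() + 1
    return make_panel(
        df,
        outcomes=list(column_map["outcomes"]),
        x_continuous=list(column_map.get("x_continuous", []) or []),
        x_factor=list(column_map.get("x_factor", []) or []),
        has_day=has_day,
    )


def predictability_mask(
    panel: LongPanel, lag: int, use_day_breaks: bool = True
) -> PredictabilityMask:
    """Flag the rows predictable under a VAR(``lag``) model.

    A row is predictable iff it is fully observed and, for every
    a = 1..lag, an occasion at beep−a exists *as a fully observed row* in
    the same (person, day) — or same person when ``use_day_breaks`` is
    False, in which case days are concatenated in order with beeps
    re-counted consecutively only through explicit rows. A gap in beep
    numbering counts as a missing occasion.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    df = panel.data
    obs = panel.observed()

    if use_day_breaks:
        keys = pd.MultiIndex.from_arrays([df[ID], df[DAY], df[BEEP]])
        observed_at = pd.Series(obs, index=keys)
        ok = obs.copy()
        for a in range(1, lag + 1):
            prev = pd.MultiIndex.from_arrays([df[ID], df[DAY], df[BEEP] - a])
            ok &= observed_at.reindex(prev, fill_value=False).to_numpy()
    else:
        # one continuous sequence per person: consecutive *rows* of the
        # person are adjacent occasions only if their beep/day indices are
        # consecutive; we build a global occasion index per person.
        occ = _global_occasions(df)
        keys = pd.MultiIndex.from_arrays([df[ID], occ])
        observed_at = pd.Series(obs, index=keys)
        ok = obs.copy()
        for a in range(1, lag + 1):
            prev = pd.MultiIndex.from_arrays([df[ID], occ - a])
            ok &= observed_at.reindex(prev, fill_value=False).to_numpy()

    counts = (
        pd.Series(ok, index=df[ID].to_numpy()).groupby(level=0, sort=False).sum()
    ).reindex(panel.persons, fill_value=0)
    return PredictabilityMask(lag=lag, predictable=ok, counts=counts)


def _global_occasions(df: pd.DataFrame) -> np.ndarray:
    """Occasion index per row treating each person as one sequence.

    Within a (person, day) occasions advance with the beep integer; across
    days the sequence continues with no extra gap (day breaks ignored).
    """
    parts = []
    for _, g in df.groupby(ID, sort=False):
        offset, occ = 0, np.empty(len(g), int)
        pos = 0
        for _, gd in g.groupby(DAY, sort=False):
            b = gd[BEEP].to_numpy()
            occ[pos : pos + len(gd)] = offset + (b - b[0])
            offset = occ[pos + len(gd) - 1] + 1
            pos += len(gd)
        parts.append(occ)
    return np.concatenate(parts)


def center_within_person(panel: LongPanel) -> LongPanel:
    """Subtract each person's mean (over observed values) from each outcome.

    Missingness is unchanged; covariates are unchanged.  A person with no
    observed values on a variable is skipped with a warning.
    """
    df = panel.data.copy()
    for c in panel.outcomes:
        means = df.groupby(ID, sort=False)[c].transform("mean")
        if (all_missing := df.groupby(ID, sort=False)[c].count() == 0).any():
            who = list(all_missing.index[all_missing])
            warnings.warn(
                f"centering skipped for variable {c!r}, person(s) {who}: "
                "no observed values",
                stacklevel=2,
            )
        df[c] = df[c] - means.fillna(0.0)
    return replace(panel, data=df)


def zero_variance_report(panel: LongPanel) -> list[tuple[object, str]]:
    """(person, variable) pairs whose observed series cannot identify a VAR.

    A pair is listed when the person has fewer than two observed values on
    the variable or all observed values are identical.
    """
    out: list[tuple[object, str]] = []
    for person, g in panel.data.groupby(ID, sort=False):
        for c in panel.outcomes:
            vals = g[c].dropna()
            if len(vals) < 2 or vals.nunique() == 1:
                out.append((person, c))
    return out
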