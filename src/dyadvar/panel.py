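"""Event-log ingestion and monthly panel construction.

A coded observation session yields event rows (one per behavior bout or
per-session tally). This module reads such logs, validates them against
the 26-code vocabulary, and aggregates them into a :class:`MonthlyPanel`:
an equally spaced dyad x month x variable array, one array per encoding
(total seconds vs. number of occurrences). Equal spacing is not cosmetic:
the lagged regressions downstream assume cotemporaneous, evenly sampled
series, so a missing month is a hard error rather than an imputation
target.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GapError, SchemaError, ValidationError
from .vocabulary import ALL_CODES, ENCODINGS, canonical_group

EVENT_COLUMNS = ("dyad_id", "group", "month", "session", "code", "duration_s", "occurrences")

_ENCODING_COLUMN = {"duration_seconds": "duration_s", "occurrence_count": "occurrences"}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype={"dyad_id": str})


def read_event_log(path: str | Path, vocabulary: Sequence[str] = ALL_CODES) -> pd.DataFrame:
    """Read a delimited behavioral event log into a validated DataFrame.

    Parameters
    ----------
    path:
        CSV or TSV file (autodetected by extension) with a header row and
        columns ``dyad_id, group, month, session, code, duration_s,
        occurrences``.
    vocabulary:
        Allowed behavior-code names; rows using any other code are rejected.

    Returns
    -------
    pandas.DataFrame
        One row per event row in the file (row count preserved), with
        group labels canonicalized to lower case.
    """
    df = _read_delimited(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df.loc[:, list(EVENT_COLUMNS)].copy()
    return validate_events(df, vocabulary=vocabulary)


def validate_events(df: pd.DataFrame, vocabulary: Sequence[str] = ALL_CODES) -> pd.DataFrame:
    """Validate event rows against the domain invariants.

    Checks vocabulary membership, non-negative durations and counts, and
    a single group label per dyad. Raises :class:`ValidationError` or
    :class:`ConsistencyError` naming the first offending row.
    """
    vocab = set(vocabulary)
    bad = ~df["code"].isin(vocab)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {i}: code {df['code'].iloc[i]!r} is not in the {len(vocab)}-code vocabulary"
        )
    for col in ("duration_s", "occurrences"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(f"row {i}: non-numeric {col} {df[col].iloc[i]!r}")
        if (vals < 0).any():
            i = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise ValidationError(f"row {i}: negative {col} ({vals.iloc[i]})")
        df[col] = vals
    df["group"] = [canonical_group(g) for g in df["group"]]
    per_dyad = df.groupby("dyad_id")["group"].nunique()
    mixed = per_dyad[per_dyad > 1]
    if len(mixed):
        raise ConsistencyError(f"dyad(s) {list(mixed.index)} carry more than one group label")
    df["month"] = df["month"].astype(int)
    df["session"] = df["session"].astype(int)
    return df


@dataclasses.dataclass
class MonthlyPanel:
    """Equally spaced dyad x month x variable array of monthly values.

    ``values[d, t, v]`` is the aggregated value of behavior ``variables[v]``
    for dyad ``dyad_ids[d]`` in month ``months[t]`` under ``encoding``.
    The variable order is recorded and stable; it defines the default
    ordering used for Cholesky orthogonalization downstream.
    """

    dyad_ids: list[str]
    groups: list[str]
    months: np.ndarray
    variables: list[str]
    values: np.ndarray
    encoding: str

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.validate(require_nonnegative=False)

    # -- invariants ------------------------------------------------------
    def validate(self, require_nonnegative: bool = True) -> None:
        """Check structural invariants; optionally enforce values >= 0.

        Non-negativity holds for any panel aggregated from event logs or
        emitted as counts/durations; panels of raw Gaussian latent draws
        (used for exact parameter-recovery testing) are exempt.
        """
        n_d, n_t, m = self.values.shape
        if n_d != len(self.dyad_ids) or n_d != len(self.groups):
            raise ValidationError("dyad_ids/groups length does not match values")
        if n_t != len(self.months) or m != len(self.variables):
            raise ValidationError("months/variables length does not match values")
        if len(self.months) >= 2:
            steps = np.diff(self.months)
            if not np.all(steps == steps[0]) or steps[0] <= 0:
                raise GapError(f"month grid {self.months.tolist()} is not equally spaced")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("panel contains non-finite values")
        if require_nonnegative and (self.values < 0).any():
            raise ValidationError("panel contains negative values")
        if self.encoding not in ENCODINGS:
            raise ValidationError(f"unknown encoding {self.encoding!r}")

    # -- derived views ---------------------------------------------------
    @property
    def n_dyads(self) -> int:
        return self.values.shape[0]

    @property
    def n_months(self) -> int:
        return self.values.shape[1]

    @property
    def m(self) -> int:
        return self.values.shape[2]

    def subset_group(self, group: str) -> "MonthlyPanel":
        """Return the panel restricted to one group's dyads."""
        group = canonical_group(group)
        keep = [i for i, g in enumerate(self.groups) if g == group]
        if not keep:
            raise ValidationError(f"no dyads in group {group!r}")
        return MonthlyPanel(
            dyad_ids=[self.dyad_ids[i] for i in keep],
            groups=[self.groups[i] for i in keep],
            months=self.months.copy(),
            variables=list(self.variables),
            values=self.values[keep].copy(),
            encoding=self.encoding,
        )

    def reorder_variables(self, order: Sequence[str]) -> "MonthlyPanel":
        """Return a panel with columns permuted into ``order``."""
        if sorted(order) != sorted(self.variables):
            raise ValidationError("reorder must be a permutation of the panel variables")
        idx = [self.variables.index(v) for v in order]
        return MonthlyPanel(
            dyad_ids=list(self.dyad_ids),
            groups=list(self.groups),
            months=self.months.copy(),
            variables=list(order),
            values=self.values[:, :, idx].copy(),
            encoding=self.encoding,
        )

    # -- serialization ---------------------------------------------------
    def to_tidy(self) -> pd.DataFrame:
        """Long-format view: one row per (dyad, month, code)."""
        n_d, n_t, m = self.values.shape
        return pd.DataFrame(
            {
                "dyad_id": np.repeat(self.dyad_ids, n_t * m),
                "group": np.repeat(self.groups, n_t * m),
                "month": np.tile(np.repeat(self.months, m), n_d),
                "code": np.tile(self.variables, n_d * n_t),
                "value": self.values.ravel(),
                "encoding": self.encoding,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "MonthlyPanel":
        required = {"dyad_id", "group", "month", "code", "value", "encoding"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"tidy panel missing column(s) {sorted(missing)}")
        encodings = df["encoding"].unique()
        if len(encodings) != 1:
            raise ValidationError(f"tidy panel mixes encodings {list(encodings)}")
        dyads = list(dict.fromkeys(df["dyad_id"].astype(str)))
        months = np.array(sorted(df["month"].unique()), dtype=int)
        variables = list(dict.fromkeys(df["code"]))
        wide = df.pivot_table(
            index=["dyad_id", "month"], columns="code", values="value", aggfunc="sum"
        )
        values = np.empty((len(dyads), len(months), len(variables)))
        for d, dyad in enumerate(dyads):
            sub = wide.loc[dyad]
            if set(months) - set(sub.index):
                raise GapError(f"dyad {dyad} missing month(s) {sorted(set(months) - set(sub.index))}")
            values[d] = sub.reindex(index=months, columns=variables).to_numpy()
        groups = (
            df.drop_duplicates("dyad_id").set_index("dyad_id")["group"].astype(str).str.lower()
        )
        return cls(
            dyad_ids=dyads,
            groups=[groups[d] for d in dyads],
            months=months,
            variables=variables,
            values=values,
            encoding=str(encodings[0]),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "MonthlyPanel":
        return cls.from_tidy(pd.read_csv(path, dtype={"dyad_id": str}))


def aggregate_monthly(
    events: pd.DataFrame,
    encoding: str,
    vocabulary: Sequence[str] = ALL_CODES,
    months: Iterable[int] | None = None,
    stat: str = "sum",
) -> MonthlyPanel:
    """Pool session-level events into one value per (dyad, month, code).

    Parameters
    ----------
    events:
        Validated event rows (see :func:`read_event_log`).
    encoding:
        ``duration_seconds`` or ``occurrence_count``; selects which event
        column is aggregated.
    vocabulary:
        Variable order of the resulting panel.
    months:
        Month grid to enforce; default is the full range observed in the
        log. Every dyad must cover every month (sessions may vary), else
        :class:`GapError` — equal spacing is a modeling requirement.
    stat:
        ``sum`` (default) or ``mean`` across that month's sessions. With
        fixed-length sessions the two differ only by a constant factor.
    """
    if encoding not in _ENCODING_COLUMN:
        raise ValidationError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")
    if stat not in {"sum", "mean"}:
        raise ValidationError(f"unknown monthly stat {stat!r}")
    events = validate_events(events.copy(), vocabulary=vocabulary)
    col = _ENCODING_COLUMN[encoding]

    if months is None:
        lo, hi = int(events["month"].min()), int(events["month"].max())
        months = np.arange(lo, hi + 1)
    months = np.asarray(sorted(months), dtype=int)

    # sorted dyad order makes aggregation invariant to event-row order
    dyads = sorted(set(events["dyad_id"]))
    group_of = events.drop_duplicates("dyad_id").set_index("dyad_id")["group"]
    variables = list(vocabulary)
    vidx = {v: j for j, v in enumerate(variables)}
    midx = {mo: t for t, mo in enumerate(months)}

    observed = events.groupby("dyad_id")["month"].agg(set)
    for dyad in dyads:
        gap = set(months) - observed[dyad]
        if gap:
            raise GapError(f"dyad {dyad} has no events in month(s) {sorted(gap)}")

    if stat == "sum":
        agg = events.groupby(["dyad_id", "month", "code"], sort=False)[col].sum()
    else:
        # mean over sessions: sum within session first, then average sessions
        per_session = events.groupby(["dyad_id", "month", "session", "code"], sort=False)[col].sum()
        n_sessions = events.groupby(["dyad_id", "month"])["session"].nunique()
        agg = per_session.groupby(["dyad_id", "month", "code"]).sum() / n_sessions

    values = np.zeros((len(dyads), len(months), len(variables)))
    didx = {d: i for i, d in enumerate(dyads)}
    for (dyad, month, code), v in agg.items():
        if month in midx:
            values[didx[dyad], midx[month], vidx[code]] = v

    return MonthlyPanel(
        dyad_ids=dyads,
        groups=[group_of[d] for d in dyads],
        months=months,
        variables=variables,
        values=values,
        encoding=encoding,
    )
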