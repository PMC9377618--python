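"""Reading, validating and restructuring photo-identification sighting histories.

The atomic observation is one identified individual detected in one group
encounter on one calendar date.  Sightings are held in a pandas DataFrame with
a fixed column schema (:data:`SIGHTING_COLUMNS`).  From that table two derived
structures feed the downstream analyses:

* :class:`SamplingPeriods` — per-day group memberships, the unit of
  association analysis (the sampling period is one calendar day);
* :class:`CaptureHistoryTable` — per-individual binary detection histories
  pooled within survey sessions, the input to closed-population
  capture-mark-recapture models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SIGHTING_COLUMNS",
    "SamplingPeriods",
    "CaptureHistoryTable",
    "read_sightings",
    "write_sightings",
    "filter_usable",
    "build_sampling_periods",
    "build_capture_histories",
    "unique_by_inclusion_exclusion",
    "histories_from_session_counts",
]

#: Canonical column order for a sightings table.  ``session`` may be empty
#: (pd.NA) for records outside any survey session.
SIGHTING_COLUMNS = [
    "individual_id",
    "date",
    "group_id",
    "session",
    "habitat",
    "stratum",
    "mark_type",
    "photo_quality",
    "distinctiveness",
]

HABITATS = {"estuary", "coast"}
STRATA = {"SNCESS", "NNCESS", "mixed", "other"}
MARK_TYPES = {"LTM", "STM"}
PHOTO_QUALITIES = {"poor", "fair", "good", "excellent"}
DISTINCTIVENESS = {"not", "slightly", "distinctive", "very"}

_ENUM_FIELDS = {
    "habitat": HABITATS,
    "stratum": STRATA,
    "mark_type": MARK_TYPES,
    "photo_quality": PHOTO_QUALITIES,
    "distinctiveness": DISTINCTIVENESS,
}


class SchemaError(ValueError):
    """A required column is missing or a field is outside its enum."""


def _validate_enums(df: pd.DataFrame) -> None:
    for col, allowed in _ENUM_FIELDS.items():
        if col not in df.columns:
            continue
        values = df[col].dropna()
        bad = set(values.unique()) - allowed
        if bad:
            raise SchemaError(
                f"column {col!r} contains values outside {sorted(allowed)}: {sorted(bad)}"
            )


def read_sightings(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a sightings CSV into the canonical table.

    Parameters
    ----------
    path:
        CSV file with a header row, UTF-8, comma separated.
    schema:
        Optional mapping from canonical column name to the column name used in
        the file, for catalogs exported with different headers.

    Returns
    -------
    DataFrame with :data:`SIGHTING_COLUMNS`; duplicate
    (individual, date, group) rows are collapsed to one with a warning.

    Raises
    ------
    SchemaError
        if a required column is absent or an enum field has a foreign value.
    ValueError
        naming the offending row if a date does not parse as ISO 8601.
    """
    raw = pd.read_csv(path, dtype=str)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    required = {"individual_id", "date", "group_id"}
    missing = required - set(raw.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    for col in SIGHTING_COLUMNS:
        if col not in raw.columns:
            raw[col] = pd.NA
    df = raw[SIGHTING_COLUMNS].copy()

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = dates.isna() & df["date"].notna()
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(
            f"unparseable date(s) {df.loc[bad, 'date'].tolist()} in file row(s) {rows}"
        )
    if dates.isna().any():
        rows = (np.flatnonzero(dates.isna().to_numpy()) + 2).tolist()
        raise ValueError(f"missing date in file row(s) {rows}")
    df["date"] = dates.dt.date
    df["session"] = pd.to_numeric(df["session"], errors="coerce").astype("Int64")
    _validate_enums(df)

    n_before = len(df)
    df = df.drop_duplicates(subset=["individual_id", "date", "group_id"]).reset_index(
        drop=True
    )
    if len(df) < n_before:
        warnings.warn(
            f"collapsed {n_before - len(df)} duplicate (individual, date, group) row(s)",
            stacklevel=2,
        )
    return df


def write_sightings(df: pd.DataFrame, path) -> None:
    """Write a canonical sightings table to CSV (lossless round-trip)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[SIGHTING_COLUMNS].to_csv(path, index=False)


def filter_usable(
    df: pd.DataFrame,
    exclude_poor: bool = True,
    ltm_only: bool = False,
) -> pd.DataFrame:
    """Apply the photo-quality and mark-type usability rules.

    Records with photo quality ``poor`` are excluded; with ``ltm_only`` the
    catalog is restricted to individuals identified by long-term marks.
    Idempotent: filtering a filtered table is a no-op.
    """
    out = df
    if exclude_poor and "photo_quality" in out.columns:
        out = out[out["photo_quality"].isna() | (out["photo_quality"] != "poor")]
    if ltm_only and "mark_type" in out.columns:
        out = out[out["mark_type"] == "LTM"]
    return out.reset_index(drop=True)


@dataclass
class SamplingPeriods:
    """Day-indexed group memberships.

    ``groups[p]`` lists, for sampling period ``p``, the member sets of the
    groups encountered that day as arrays of indices into ``ids``.  An
    individual photographed in two groups on one day is a member of both
    (its dyads with co-members of either group count as associated that day).
    """

    ids: list[str]
    period_keys: list
    groups: list[list[np.ndarray]]

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_keys)

    def seen_matrix(self) -> np.ndarray:
        """Boolean (n_periods, n_individuals): identified that day."""
        seen = np.zeros((self.n_periods, self.n_individuals), dtype=bool)
        for p, gs in enumerate(self.groups):
            for g in gs:
                seen[p, g] = True
        return seen

    def sightings_per_individual(self) -> np.ndarray:
        """Number of sampling periods in which each individual was identified."""
        return self.seen_matrix().sum(axis=0)

    def together_matrix(self, p: int) -> np.ndarray:
        """Boolean (n, n) co-membership in any group of period ``p`` (hollow)."""
        n = self.n_individuals
        tog = np.zeros((n, n), dtype=bool)
        for g in self.groups[p]:
            tog[np.ix_(g, g)] = True
        np.fill_diagonal(tog, False)
        return tog

    def restrict(self, keep_ids) -> "SamplingPeriods":
        """Sub-population view: drop all other individuals, keep all periods."""
        keep = [i for i in self.ids if i in set(keep_ids)]
        remap = {self.ids.index(i): k for k, i in enumerate(keep)}
        old_keep = set(remap)
        new_groups = []
        for gs in self.groups:
            day = []
            for g in gs:
                sub = np.array(sorted(remap[j] for j in g if j in old_keep), dtype=int)
                if sub.size:
                    day.append(sub)
            new_groups.append(day)
        return SamplingPeriods(ids=keep, period_keys=list(self.period_keys), groups=new_groups)


def build_sampling_periods(df: pd.DataFrame) -> SamplingPeriods:
    """Collapse a sightings table into daily group memberships.

    A record seen twice in the same group on a day counts once; the period key
    is the record's calendar date.
    """
    ids = sorted(df["individual_id"].unique())
    index = {i: k for k, i in enumerate(ids)}
    period_keys = sorted(df["date"].unique())
    groups: list[list[np.ndarray]] = []
    by_day = df.groupby("date", sort=True)
    for day in period_keys:
        day_df = by_day.get_group(day)
        day_groups = []
        for _, g_df in day_df.groupby("group_id", sort=True):
            members = np.array(
                sorted({index[i] for i in g_df["individual_id"]}), dtype=int
            )
            day_groups.append(members)
        groups.append(day_groups)
    return SamplingPeriods(ids=ids, period_keys=period_keys, groups=groups)


# ---------------------------------------------------------------------------
# Capture histories


@dataclass
class CaptureHistoryTable:
    """Per-individual binary detection histories pooled by survey session.

    ``histories`` is (n_individuals, n_sessions) 0/1.  ``frequencies`` maps a
    history string such as ``"101"`` to its count; only observable histories
    (at least one detection) appear.
    """

    ids: list[str]
    histories: np.ndarray
    frequencies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.histories = np.asarray(self.histories, dtype=int)
        if self.histories.ndim != 2:
            raise ValueError("histories must be 2-D")
        if not self.frequencies:
            self.frequencies = self._count_frequencies()
        if self.histories.size and (self.histories.sum(axis=1) == 0).any():
            raise ValueError("capture history with no detection")

    def _count_frequencies(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for row in self.histories:
            key = "".join(str(v) for v in row)
            freq[key] = freq.get(key, 0) + 1
        return dict(sorted(freq.items(), reverse=True))

    @property
    def n_sessions(self) -> int:
        return self.histories.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def n_t(self) -> np.ndarray:
        """Detections per session (column sums)."""
        return self.histories.sum(axis=0)

    def pairwise_overlaps(self) -> dict[tuple[int, int], int]:
        """Individuals seen in both sessions of each (s, t) pair, s < t."""
        h = self.histories
        return {
            (s, t): int((h[:, s] & h[:, t]).sum())
            for s, t in itertools.combinations(range(self.n_sessions), 2)
        }

    def triple_overlap(self) -> int:
        """Individuals seen in all sessions (meaningful for 3-session designs)."""
        return int(self.histories.all(axis=1).sum())

    @classmethod
    def from_frequencies(cls, frequencies: dict[str, int]) -> "CaptureHistoryTable":
        """Expand a history-frequency table into anonymous individual rows."""
        rows, ids = [], []
        k = 0
        for key, count in sorted(frequencies.items(), reverse=True):
            vec = [int(c) for c in key]
            for _ in range(int(count)):
                rows.append(vec)
                ids.append(f"ind{k:04d}")
                k += 1
        return cls(ids=ids, histories=np.array(rows, dtype=int), frequencies=dict(frequencies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"history": list(self.frequencies), "count": list(self.frequencies.values())}
        )


def build_capture_histories(
    df: pd.DataFrame, sessions: dict[int, tuple] | None = None
) -> CaptureHistoryTable:
    """Pool sightings within sessions into binary capture histories.

    Parameters
    ----------
    sessions:
        Optional mapping session number -> (first_date, last_date) used to
        assign sessions when the table's ``session`` column is absent/empty.
        Dates are inclusive ISO strings or ``datetime.date``.

    Raises
    ------
    ValueError
        if any record cannot be assigned to a session.
    """
    df = df.copy()
    if sessions is not None:
        bounds = {
            s: (pd.Timestamp(a).date(), pd.Timestamp(b).date())
            for s, (a, b) in sessions.items()
        }

        def assign(d):
            for s, (a, b) in bounds.items():
                if a <= d <= b:
                    return s
            return pd.NA

        df["session"] = [assign(d) for d in df["date"]]
    if "session" not in df.columns or df["session"].isna().any():
        n_bad = int(df["session"].isna().sum()) if "session" in df.columns else len(df)
        raise ValueError(f"{n_bad} record(s) with no session assignment")

    session_values = sorted(int(s) for s in df["session"].unique())
    col = {s: k for k, s in enumerate(session_values)}
    ids = sorted(df["individual_id"].unique())
    row = {i: k for k, i in enumerate(ids)}
    hist = np.zeros((len(ids), len(session_values)), dtype=int)
    for ind, ses in zip(df["individual_id"], df["session"]):
        hist[row[ind], col[int(ses)]] = 1
    return CaptureHistoryTable(ids=ids, histories=hist)


def unique_by_inclusion_exclusion(
    n_t, pairwise, triple: int
) -> int:
    """Unique individuals across three sessions from printed summary counts.

    ``n_t`` are per-session totals (n1, n2, n3); ``pairwise`` the resighting
    overlaps in the order (S1&S2, S2&S3, S1&S3); ``triple`` the number seen in
    all three.  Returns ``Σn_t − Σpairwise + triple``.

    Raises ``ValueError`` if the overlaps are not jointly consistent
    (``triple`` exceeding a pairwise overlap, or an overlap exceeding either
    of its session totals).
    """
    n1, n2, n3 = (int(v) for v in n_t)
    n12, n23, n13 = (int(v) for v in pairwise)
    triple = int(triple)
    limits = {"S1&S2": (n12, n1, n2), "S2&S3": (n23, n2, n3), "S1&S3": (n13, n1, n3)}
    for name, (ov, a, b) in limits.items():
        if not (triple <= ov <= min(a, b)):
            raise ValueError(
                f"inconsistent overlap {name}={ov} (triple={triple}, sessions={a},{b})"
            )
    return n1 + n2 + n3 - (n12 + n23 + n13) + triple


def histories_from_session_counts(n_t, pairwise, triple: int) -> CaptureHistoryTable:
    """Reconstruct 3-session history frequencies from printed summary counts.

    Inverse of the marginal summaries via inclusion–exclusion: e.g.
    f(110) = n12 − n123 and f(100) = n1 − n12 − n13 + n123.  The resulting
    table has exactly ``unique_by_inclusion_exclusion`` rows.
    """
    n1, n2, n3 = (int(v) for v in n_t)
    n12, n23, n13 = (int(v) for v in pairwise)
    t = int(triple)
    unique_by_inclusion_exclusion(n_t, pairwise, triple)  # consistency check
    freq = {
        "111": t,
        "110": n12 - t,
        "101": n13 - t,
        "011": n23 - t,
        "100": n1 - n12 - n13 + t,
        "010": n2 - n12 - n23 + t,
        "001": n3 - n13 - n23 + t,
    }
    if any(v < 0 for v in freq.values()):
        raise ValueError(f"counts imply a negative history frequency: {freq}")
    freq = {k: v for k, v in freq.items() if v > 0}
    return CaptureHistoryTable.from_frequencies(freq)
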