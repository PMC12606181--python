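"""Reading, validation, time-binning and binarization of dyadic observation streams.

The observational design mixes two sampling schemes: nearest-neighbour *scan
sampling* (a no-contact proximity record at fixed 5-minute marks) and
*all-occurrence sampling* of physical contact behaviours.  Multiple observers
watch the same group simultaneously, so the same event can be logged more than
once.  Everything downstream works on a deduplicated binary representation:
for each unordered pair of birds (dyad), each behaviour, and each 5-minute
time bin, the behaviour either occurred (1) or did not (0).

Behaviours carry a risk tier reflecting the presumed cost of the social
investment: LOW (no-contact proximity), MODERATE (shoulder contact,
allopreening, beak touching), HIGH (allofeeding, copulation).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The closed behavioural repertoire.
REPERTOIRE: tuple[str, ...] = (
    "proximity",
    "shoulder_contact",
    "allopreen",
    "beak_touch",
    "allofeed",
    "copulation",
)

DEFAULT_BIN_WIDTH = 300  # seconds; the scan-sampling interval


class RiskTier(enum.IntEnum):
    """Ordered risk/investment category of a behaviour."""

    LOW = 0
    MODERATE = 1
    HIGH = 2


#: Total mapping behaviour -> risk tier.
TIER_OF: dict[str, RiskTier] = {
    "proximity": RiskTier.LOW,
    "shoulder_contact": RiskTier.MODERATE,
    "allopreen": RiskTier.MODERATE,
    "beak_touch": RiskTier.MODERATE,
    "allofeed": RiskTier.HIGH,
    "copulation": RiskTier.HIGH,
}


class FormatError(ValueError):
    """An input table is missing required structure."""


class RepertoireError(KeyError):
    """A behaviour label is not in the closed repertoire."""


def tier_of(behavior: str) -> RiskTier:
    """Return the risk tier of a behaviour label.

    Raises
    ------
    RepertoireError
        If the label is not one of the six repertoire behaviours.
    """
    try:
        return TIER_OF[behavior]
    except KeyError:
        raise RepertoireError(f"unknown behavior {behavior!r}; repertoire is {REPERTOIRE}") from None


# ---------------------------------------------------------------------------
# Roster and dyads
# ---------------------------------------------------------------------------

def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a bird roster CSV with columns ``id``, ``sex``, ``site``."""
    roster = pd.read_csv(path, dtype=str)
    return validate_roster(roster)


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "sex", "site"}
    missing = required - set(roster.columns)
    if missing:
        raise FormatError(f"roster is missing columns {sorted(missing)}")
    roster = roster.astype({"id": str, "sex": str, "site": str})
    if roster["id"].duplicated().any():
        dups = roster.loc[roster["id"].duplicated(), "id"].tolist()
        raise FormatError(f"duplicate bird ids in roster: {dups}")
    bad_sex = set(roster["sex"]) - {"F", "M"}
    if bad_sex:
        raise FormatError(f"sex must be 'F' or 'M'; got {sorted(bad_sex)}")
    if (roster["site"].str.len() == 0).any():
        raise FormatError("empty site identifier in roster")
    return roster.reset_index(drop=True)


def enumerate_dyads(roster: pd.DataFrame) -> pd.DataFrame:
    """Enumerate all C(n, 2) unordered pairs of birds with relationship labels.

    A dyad is *familiar* when both members were captured at the same site and
    *stranger* otherwise; capture site is the proxy for prior acquaintance.
    ``sex_composition`` is one of FF / MF / MM.

    Returns a DataFrame with one row per dyad, columns ``member_low``,
    ``member_high`` (lexicographically ordered ids), ``familiarity`` and
    ``sex_composition``, in a stable order.
    """
    roster = validate_roster(roster)
    ids = roster["id"].to_numpy()
    sex = dict(zip(roster["id"], roster["sex"]))
    site = dict(zip(roster["id"], roster["site"]))
    rows = []
    ordered = sorted(ids)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            fam = "familiar" if site[a] == site[b] else "stranger"
            comp = "".join(sorted((sex[a], sex[b])))  # FF, FM, MM
            comp = {"FM": "MF"}.get(comp, comp)
            rows.append((a, b, fam, comp))
    return pd.DataFrame(rows, columns=["member_low", "member_high", "familiarity", "sex_composition"])


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def read_schedule(path: str | Path) -> pd.DataFrame:
    """Read an observation-session schedule CSV.

    Columns: ``session_id``, ``date`` (ISO date), ``start``, ``end`` (ISO
    times).  Sessions are sorted chronologically; each gets a duration in
    seconds and a count of 5-minute bins (last partial bin rounded up).
    """
    sched = pd.read_csv(path, dtype=str)
    return validate_schedule(sched)


def validate_schedule(sched: pd.DataFrame) -> pd.DataFrame:
    required = {"session_id", "date", "start", "end"}
    missing = required - set(sched.columns)
    if missing:
        raise FormatError(f"schedule is missing columns {sorted(missing)}")
    sched = sched.copy()
    start = pd.to_datetime(sched["date"].astype(str) + " " + sched["start"].astype(str))
    end = pd.to_datetime(sched["date"].astype(str) + " " + sched["end"].astype(str))
    dur = (end - start).dt.total_seconds()
    if (dur <= 0).any():
        bad = sched.loc[dur <= 0, "session_id"].tolist()
        raise FormatError(f"non-positive session duration for sessions {bad}")
    sched["start_dt"] = start
    sched["duration_s"] = dur
    sched = sched.sort_values("start_dt", kind="stable").reset_index(drop=True)
    if sched["session_id"].duplicated().any():
        raise FormatError("duplicate session_id in schedule")
    return sched


def _session_bins(sched: pd.DataFrame, bin_width: int) -> pd.DataFrame:
    """Per-session bin counts and global bin offsets (sessions concatenated)."""
    nb = np.ceil(sched["duration_s"].to_numpy() / bin_width).astype(int)
    off = np.concatenate(([0], np.cumsum(nb)[:-1]))
    return pd.DataFrame({
        "session_id": sched["session_id"].to_numpy(),
        "n_bins": nb,
        "offset": off,
    })


# ---------------------------------------------------------------------------
# Observation records
# ---------------------------------------------------------------------------

_OBS_COLUMNS = ["session_id", "observer_id", "timestamp", "behavior", "actor", "receiver"]


def read_observations(
    path: str | Path,
    roster: pd.DataFrame,
    schedule: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read and validate a raw observation CSV.

    Each row is one sighting: session, observer, timestamp, behaviour label
    and the one or two birds involved.  Timestamps may be numeric seconds
    from session start, or ISO-8601 date-times (then ``schedule`` is required
    to anchor each session); both are normalized to a ``time_s`` column of
    seconds from session start.

    Rows are rejected (with a logged report naming the row) when the
    behaviour is outside the repertoire, a bird id is not on the roster, or
    actor equals receiver.  Solitary records (no receiver) are dropped: all
    analyses are dyad-level.  Exact duplicate rows are kept here —
    deduplication happens at the bin level in :func:`binarize`.
    """
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.columns.size == 0:
        logger.warning("observation file %s is empty", path)
        return pd.DataFrame(columns=_OBS_COLUMNS[:3] + ["time_s"] + _OBS_COLUMNS[3:])
    missing = set(_OBS_COLUMNS) - set(raw.columns)
    if missing:
        raise FormatError(f"observations file is missing columns {sorted(missing)}")
    roster = validate_roster(roster)
    known = set(roster["id"])

    reject = pd.Series(False, index=raw.index)
    reasons: list[str] = []

    solitary = raw["receiver"].isna() | (raw["receiver"].astype(str).str.strip() == "")
    n_solitary = int(solitary.sum())
    if n_solitary:
        logger.info("dropping %d solitary (no-receiver) records", n_solitary)
    reject |= solitary

    bad_beh = ~raw["behavior"].isin(REPERTOIRE)
    for i in raw.index[bad_beh & ~reject]:
        reasons.append(f"row {i}: behavior {raw.at[i, 'behavior']!r} not in repertoire")
    reject |= bad_beh

    bad_bird = ~raw["actor"].isin(known) | (~raw["receiver"].isin(known) & ~solitary)
    for i in raw.index[bad_bird & ~reject]:
        reasons.append(f"row {i}: unknown bird id ({raw.at[i, 'actor']!r}/{raw.at[i, 'receiver']!r})")
    reject |= bad_bird

    self_pair = (raw["actor"] == raw["receiver"]) & ~solitary
    for i in raw.index[self_pair & ~reject]:
        reasons.append(f"row {i}: actor == receiver ({raw.at[i, 'actor']!r})")
    reject |= self_pair

    for msg in reasons:
        logger.warning("rejected %s", msg)
    if reject.any():
        logger.info("rejected %d of %d observation rows", int(reject.sum()), len(raw))

    recs = raw.loc[~reject].copy()
    recs["time_s"] = _normalize_timestamps(recs, schedule)
    neg = recs["time_s"] < 0
    if neg.any():
        logger.warning("rejected %d records with negative timestamps", int(neg.sum()))
        recs = recs.loc[~neg]
    if recs.empty:
        logger.warning("no valid observation records after validation")
    return recs.reset_index(drop=True)


def _normalize_timestamps(recs: pd.DataFrame, schedule: pd.DataFrame | None) -> pd.Series:
    ts = pd.to_numeric(recs["timestamp"], errors="coerce")
    if ts.notna().all():
        return ts.astype(float)
    if schedule is None:
        raise FormatError(
            "non-numeric timestamps require a session schedule to resolve ISO date-times"
        )
    sched = validate_schedule(schedule)
    start = dict(zip(sched["session_id"], sched["start_dt"]))
    dt = pd.to_datetime(recs["timestamp"], errors="coerce", format="ISO8601")
    if dt.isna().any():
        bad = recs.loc[dt.isna() & ts.isna(), "timestamp"].head().tolist()
        raise FormatError(f"unparseable timestamps, e.g. {bad}")
    anchor = recs["session_id"].map(start)
    if anchor.isna().any():
        bad = recs.loc[anchor.isna(), "session_id"].unique().tolist()
        raise FormatError(f"sessions not in schedule: {bad}")
    out = (dt - anchor).dt.total_seconds()
    return out.where(ts.isna(), ts).astype(float)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@dataclass
class DyadBinMatrix:
    """Deduplicated binary occurrence data: dyad x behaviour x 5-min bin.

    ``occurrences`` is sparse long-format: one row per (dyad, behaviour, bin)
    that occurred at least once; everything absent is 0.  Bins form a single
    global chronological index concatenated across sessions, so "bin b comes
    before bin c" is meaningful across the whole study and b 5-minute bins
    correspond to ``b * bin_width / 3600`` observed hours.
    """

    dyads: pd.DataFrame
    behaviors: tuple[str, ...]
    n_bins: int
    bin_width: int
    occurrences: pd.DataFrame  # columns: dyad, behavior, tier, bin
    hours_observed: float
    session_bins: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_dyads(self) -> int:
        return len(self.dyads)

    def dyad_index(self) -> dict[tuple[str, str], int]:
        return {
            (a, b): i
            for i, (a, b) in enumerate(
                zip(self.dyads["member_low"], self.dyads["member_high"])
            )
        }

    def occ_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(dyad_idx, tier_idx, bin) integer arrays of the occurrence rows."""
        o = self.occurrences
        return (
            o["dyad"].to_numpy(np.int64),
            o["tier"].to_numpy(np.int64),
            o["bin"].to_numpy(np.int64),
        )

    def to_long_csv(self, path: str | Path) -> None:
        """Write the audit long-format table (dyad ids, behaviour, bin, occurred)."""
        o = self.occurrences.copy()
        o["member_low"] = self.dyads["member_low"].to_numpy()[o["dyad"]]
        o["member_high"] = self.dyads["member_high"].to_numpy()[o["dyad"]]
        o["occurred"] = 1
        o[["member_low", "member_high", "behavior", "bin", "occurred"]].to_csv(path, index=False)


def binarize(
    records: pd.DataFrame,
    roster: pd.DataFrame,
    schedule: pd.DataFrame,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> DyadBinMatrix:
    """Collapse validated records into the binary dyad x behaviour x bin tensor.

    Bins are half-open intervals ``[k*w, (k+1)*w)`` anchored at each session's
    start and concatenated across sessions in chronological order.  Any number
    of raw records of the same behaviour for the same dyad in the same bin
    (e.g. the same allopreen logged by two observers) collapses to a single
    occurrence.  Records falling outside their session are rejected with a
    warning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    roster = validate_roster(roster)
    sched = validate_schedule(schedule)
    dyads = enumerate_dyads(roster)
    sb = _session_bins(sched, bin_width)
    n_bins = int(sb["n_bins"].sum())
    hours = float(sched["duration_s"].sum()) / 3600.0

    if records.empty:
        occ = pd.DataFrame(columns=["dyad", "behavior", "tier", "bin"])
        occ = occ.astype({"dyad": np.int64, "tier": np.int64, "bin": np.int64})
        return DyadBinMatrix(dyads, REPERTOIRE, n_bins, bin_width, occ, hours, sb)

    recs = records.copy()
    if "time_s" not in recs.columns:
        # records straight from a generator or caller: numeric timestamps only
        recs["time_s"] = pd.to_numeric(recs["timestamp"])
    dur = dict(zip(sched["session_id"], sched["duration_s"]))
    off = dict(zip(sb["session_id"], sb["offset"]))

    unknown = ~recs["session_id"].isin(dur)
    if unknown.any():
        logger.warning(
            "rejected %d records in sessions absent from the schedule: %s",
            int(unknown.sum()), sorted(recs.loc[unknown, "session_id"].unique()),
        )
        recs = recs.loc[~unknown]
    out = (recs["time_s"] < 0) | (recs["time_s"] >= recs["session_id"].map(dur))
    if out.any():
        logger.warning("rejected %d records outside their session window", int(out.sum()))
        recs = recs.loc[~out]

    # symmetrize to the canonical unordered dyad
    lo = np.minimum(recs["actor"], recs["receiver"])
    hi = np.maximum(recs["actor"], recs["receiver"])
    didx = dyads.reset_index().set_index(["member_low", "member_high"])["index"]
    dyad_id = pd.MultiIndex.from_arrays([lo, hi]).map(didx)

    local_bin = (recs["time_s"].to_numpy() // bin_width).astype(np.int64)
    global_bin = recs["session_id"].map(off).to_numpy(np.int64) + local_bin

    occ = pd.DataFrame({
        "dyad": dyad_id.to_numpy(np.int64),
        "behavior": recs["behavior"].to_numpy(),
        "bin": global_bin,
    })
    n_raw = len(occ)
    occ = occ.drop_duplicates().sort_values(["dyad", "behavior", "bin"], kind="stable")
    if len(occ) < n_raw:
        logger.info("collapsed %d duplicate (dyad, behavior, bin) records", n_raw - len(occ))
    occ["tier"] = occ["behavior"].map(TIER_OF).astype(np.int64)
    occ = occ[["dyad", "behavior", "tier", "bin"]].reset_index(drop=True)
    return DyadBinMatrix(dyads, REPERTOIRE, n_bins, bin_width, occ, hours, sb)
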