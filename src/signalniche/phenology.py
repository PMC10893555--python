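"""Time-resolved community reconstruction from checklist occurrence data.

Checklists are filtered by standard quality rules (complete lists,
stationary/traveling protocols, <= 10 observers, <= 5 h, <= 5 km, inside the
season window), per-day occurrence is the percentage of filtered checklists
reporting a species, days are averaged over consecutive 3-day windows, and a
species is "present" in a window when its mean occurrence meets the
presence threshold (default 1.5%).

Day-of-year integers use leap-year numbering (day 96 = April 5, day 158 =
June 6); `to_day_of_year` maps calendar dates onto this coordinate system.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataIntegrityError

logger = logging.getLogger(__name__)

#: April 1 .. June 15 in leap-year day-of-year numbering
DEFAULT_DATE_WINDOW = (92, 167)
#: window-averaging span: April 5 .. June 6, 3-day windows
DEFAULT_WINDOW_RANGE = (96, 158, 3)
DEFAULT_PRESENCE_THRESHOLD = 1.5

REQUIRED_COLUMNS = (
    "checklist_id",
    "date",
    "protocol",
    "complete",
    "n_observers",
    "duration_h",
    "distance_km",
    "species_reported",
)

FILTER_RULES = (
    "incomplete",
    "protocol",
    "out_of_window",
    "observers",
    "duration",
    "distance",
    "duplicate",
)


def to_day_of_year(date, leap_numbering: bool = True) -> int:
    """Map a calendar date (ISO string or date) to a day-of-year integer.

    With ``leap_numbering`` (default) non-leap-year dates after February are
    shifted by +1 so that e.g. April 5 is always day 96.
    """
    if isinstance(date, (int, np.integer)):
        return int(date)
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(date, _dt.datetime):
        date = date.date()
    doy = date.timetuple().tm_yday
    is_leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    if leap_numbering and not is_leap and date.month > 2:
        doy += 1
    return doy


def filter_checklists(
    checklists: pd.DataFrame,
    date_window: tuple[int, int] = DEFAULT_DATE_WINDOW,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the checklist quality filters; return kept rows and a tally.

    Keeps a checklist iff it is complete, uses a stationary or traveling
    protocol, falls inside ``date_window``, and has <= 10 observers,
    <= 5 h duration, and <= 5 km distance (boundaries inclusive: only
    *more than* 10 observers, *greater than* 5 h, *over* 5 km are
    rejected).  Exact duplicate checklist ids are dropped.  The tally
    counts, per rule, how many rows violated it (a row can violate several).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in checklists.columns]
    if missing:
        raise DataIntegrityError(f"checklist table missing columns: {missing}")
    required_nonnull = [c for c in REQUIRED_COLUMNS if c != "species_reported"]
    nulls = checklists[required_nonnull].isna().any(axis=1)
    if nulls.any():
        bad = checklists.loc[nulls, "checklist_id"].tolist()[:5]
        raise DataIntegrityError(f"missing required field(s) in rows: {bad}")
    df = checklists.copy()
    df["date"] = [to_day_of_year(d) for d in df["date"]]
    dup = df.duplicated(subset="checklist_id", keep="first")
    start, end = date_window
    viol = {
        "incomplete": ~df["complete"].astype(bool),
        "protocol": ~df["protocol"].isin(["stationary", "traveling"]),
        "out_of_window": (df["date"] < start) | (df["date"] > end),
        "observers": df["n_observers"] > 10,
        "duration": df["duration_h"] > 5,
        "distance": df["distance_km"] > 5,
        "duplicate": dup,
    }
    tally = {rule: int(mask.sum()) for rule, mask in viol.items()}
    reject = np.logical_or.reduce([m.to_numpy() for m in viol.values()])
    tally["rejected"] = int(reject.sum())
    tally["kept"] = int((~reject).sum())
    return df.loc[~reject].reset_index(drop=True), tally


def _species_day_counts(filtered: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    per_day = filtered.groupby("date").size()
    long = filtered[["date", "species_reported"]].copy()
    long["species_reported"] = long["species_reported"].fillna("")
    long = long[long["species_reported"] != ""]
    long = long.assign(species=long["species_reported"].str.split(";")).explode("species")
    reports = long.groupby(["date", "species"]).size()
    return per_day, reports.unstack(fill_value=0)


def occurrence_matrix(
    filtered: pd.DataFrame,
    species: Sequence[str] | None = None,
    day_range: tuple[int, int] | None = None,
    per_year: bool = False,
) -> pd.DataFrame:
    """Per-day occurrence (%) for each species: day x species DataFrame.

    Occurrence on day d is 100 x (#checklists reporting the species on d) /
    (#checklists on d).  Days without any checklist are missing (NaN), not
    0%.  With ``per_year=True`` (requires a ``year`` column) occurrence is
    computed per year first and then averaged across years per day; the
    default pools checklists across years for each calendar day.
    """
    if per_year:
        if "year" not in filtered.columns:
            raise DataIntegrityError("per_year=True requires a 'year' column")
        mats = [
            occurrence_matrix(g, species=species, day_range=day_range)
            for _, g in filtered.groupby("year")
        ]
        combined = pd.concat(mats, keys=range(len(mats)))
        return combined.groupby(level=1).mean()
    per_day, reports = _species_day_counts(filtered)
    if species is None:
        species = list(reports.columns)
    occ = reports.reindex(columns=species, fill_value=0).reindex(index=per_day.index, fill_value=0)
    occ = 100.0 * occ.div(per_day, axis=0)
    if day_range is not None:
        days = range(day_range[0], day_range[1] + 1)
        occ = occ.reindex(index=days)
    occ.index.name = "date"
    return occ


def occurrence(filtered: pd.DataFrame, species: str, **kwargs) -> pd.Series:
    """Per-day occurrence series (%) for one species."""
    return occurrence_matrix(filtered, species=[species], **kwargs)[species]


def window_average(
    daily: pd.DataFrame,
    start_day: int = DEFAULT_WINDOW_RANGE[0],
    end_day: int = DEFAULT_WINDOW_RANGE[1],
    width: int = DEFAULT_WINDOW_RANGE[2],
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Average a per-day matrix over consecutive non-overlapping windows.

    The span [start_day, end_day] must divide exactly into windows of
    ``width`` days; missing days are excluded from a window's mean.
    Returns (window x species means, list of inclusive (start, end) days).
    """
    span = end_day - start_day + 1
    if span <= 0 or span % width != 0:
        raise ConfigError(
            f"[{start_day}, {end_day}] does not divide into {width}-day windows"
        )
    if isinstance(daily, pd.Series):
        daily = daily.to_frame()
    windows = [
        (start_day + i * width, start_day + (i + 1) * width - 1)
        for i in range(span // width)
    ]
    full = daily.reindex(index=range(start_day, end_day + 1))
    rows = [full.loc[ws:we].mean(axis=0, skipna=True) for ws, we in windows]
    out = pd.DataFrame(rows)
    out.index = pd.RangeIndex(len(windows), name="window_index")
    return out, windows


@dataclass(frozen=True)
class CommunitySnapshot:
    """Species present (occurrence >= threshold) in one time window."""

    window_index: int
    window_days: tuple[int, int]
    present_species: frozenset[str]
    n_migrants: int
    n_breeders: int


def reconstruct_communities(
    window_means: pd.DataFrame,
    windows: list[tuple[int, int]],
    statuses: Mapping[str, str],
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> list[CommunitySnapshot]:
    """Presence per window: mean occurrence >= threshold (missing = absent)."""
    snapshots = []
    n_missing = int(window_means.isna().sum().sum())
    if n_missing:
        logger.info("%d species-window means missing; treated as below threshold", n_missing)
    for idx in window_means.index:
        row = window_means.loc[idx]
        present = frozenset(sp for sp, v in row.items() if pd.notna(v) and v >= threshold)
        unknown = [sp for sp in present if sp not in statuses]
        if unknown:
            raise DataIntegrityError(f"species without status: {unknown}")
        n_mig = sum(1 for sp in present if statuses[sp] == "migrant")
        snapshots.append(
            CommunitySnapshot(
                window_index=int(idx),
                window_days=windows[int(idx)],
                present_species=present,
                n_migrants=n_mig,
                n_breeders=len(present) - n_mig,
            )
        )
    return snapshots
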