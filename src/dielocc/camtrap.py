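"""Camera-trap photo logs and day/night detection histories.

The raw material of a diel occupancy analysis is a stream of time-stamped
species photos at fixed camera stations.  This module turns that stream
into the quantities the model consumes:

* detection events — photos of the same species at the same site within a
  24-hour window collapsed into one event (reported for effort summaries);
* detection histories — for every site × species × diel period, the number
  of trap-day occasions ``k`` and the number of occasions with at least one
  photo ``y`` (the Bernoulli trials of the detection model);
* naive occurrence — the fraction of sampled sites with at least one
  detection, uncorrected for imperfect detection.

An occasion is one trap day within one diel period at one camera: every
trap day contributes exactly one day occasion and one night occasion, so
``k`` is identical for both periods of a site.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import DAY, NIGHT, SolarProvider

__all__ = [
    "PhotoRecord",
    "PERIODS",
    "SITE_TABLE_COLUMNS",
    "OCC_COVARIATES",
    "DET_COVARIATES",
    "read_photo_log",
    "read_site_table",
    "validate_site_table",
    "collapse_events",
    "build_history",
    "naive_occurrence",
    "trap_days",
]

PERIODS = (DAY, NIGHT)

#: occurrence-model covariates (site/landscape attributes)
OCC_COVARIATES = (
    "Elv", "Prk", "NF.plot", "NF250", "NF500",
    "Rd250", "Rd500", "Pch250", "Pch500",
)
#: detection-model covariates
DET_COVARIATES = ("Season", "Und")

SITE_TABLE_COLUMNS = (
    "site_id", "x", "y", "deploy_start", "deploy_end",
    *OCC_COVARIATES, *DET_COVARIATES,
)


@dataclass(frozen=True)
class PhotoRecord:
    """One time-stamped species photo at a site.

    The timestamp must carry an explicit UTC offset; naive timestamps are
    rejected rather than guessed.
    """

    site_id: str
    species: str
    timestamp: dt.datetime

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError(
                f"photo at site {self.site_id!r}: naive timestamp "
                f"{self.timestamp.isoformat()} (UTC offset required)"
            )


def read_photo_log(path) -> list[PhotoRecord]:
    """Read a delimited photo log with header ``site_id,species,timestamp``.

    Timestamps are ISO-8601 with an explicit offset.  Malformed rows raise
    with the 1-based line number of the offending record.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"site_id", "species", "timestamp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"photo log missing columns: {sorted(missing)}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ts = dt.datetime.fromisoformat(str(row.timestamp))
            records.append(PhotoRecord(str(row.site_id), str(row.species), ts))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"photo log line {idx}: {exc}") from exc
    return records


def write_photo_log(records: list[PhotoRecord], path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "species": [r.species for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_site_table(path) -> pd.DataFrame:
    """Read the site/deployment table and validate its schema."""
    df = pd.read_csv(path, dtype={"site_id": str})
    df["deploy_start"] = pd.to_datetime(df["deploy_start"]).dt.date
    df["deploy_end"] = pd.to_datetime(df["deploy_end"]).dt.date
    validate_site_table(df)
    return df


def validate_site_table(sites: pd.DataFrame) -> None:
    missing = set(SITE_TABLE_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if sites["site_id"].duplicated().any():
        dups = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site ids: {dups}")
    bad = sites["deploy_end"] < sites["deploy_start"]
    if bad.any():
        raise ValueError(
            f"deploy_end before deploy_start at sites "
            f"{sites.loc[bad, 'site_id'].tolist()}"
        )
    for col in ("NF250", "NF500", "Season"):
        v = sites[col].to_numpy(float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    und = sites["Und"].to_numpy(float)
    if ((und < 0) | (und > 100)).any():
        raise ValueError("Und (understory %) must lie in [0, 100]")


def trap_days(sites: pd.DataFrame) -> pd.Series:
    """Whole trap days per site; a partial first/last day counts as one."""
    start = pd.to_datetime(sites["deploy_start"])
    end = pd.to_datetime(sites["deploy_end"])
    k = (end - start).dt.days + 1
    return pd.Series(k.to_numpy(), index=sites["site_id"].to_numpy(), name="k")


def collapse_events(
    photos: list[PhotoRecord], window: dt.timedelta = dt.timedelta(hours=24)
) -> list[list[PhotoRecord]]:
    """Collapse one site × species photo stream into detection events.

    Greedy chaining from the earliest photo: a photo starts a new event iff
    it falls ``window`` or more after the *first* photo of the current
    event.  Events are disjoint and cover every photo.
    """
    if not photos:
        return []
    times = [p.timestamp for p in photos]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("photos must be sorted by timestamp")
    events: list[list[PhotoRecord]] = [[photos[0]]]
    anchor = photos[0].timestamp
    for photo in photos[1:]:
        if photo.timestamp - anchor >= window:
            events.append([photo])
            anchor = photo.timestamp
        else:
            events[-1].append(photo)
    return events


def build_history(
    photos: list[PhotoRecord],
    sites: pd.DataFrame,
    solar: SolarProvider,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Build per site × species × period detection histories.

    Returns a long-format frame with columns
    ``site_id, species, period, y, k`` covering every sampled site and
    every species (zero-filled where a species was never photographed).
    ``y`` counts occasions (trap-day × period) with at least one photo;
    ``k`` is the number of trap days of the site, identical for both
    periods.

    Photos outside their site's deployment window, or at unknown sites,
    raise with the full list of offending records.
    """
    validate_site_table(sites)
    site_ids = list(sites["site_id"])
    k = trap_days(sites)
    windows = {
        row.site_id: (row.deploy_start, row.deploy_end)
        for row in sites.itertuples(index=False)
    }
    if species is None:
        species = sorted({p.species for p in photos})

    bad: list[str] = []
    # detected (site, species, period, date) occasions
    hits: set[tuple[str, str, str, dt.date]] = set()
    for p in photos:
        win = windows.get(p.site_id)
        local_date = p.timestamp.astimezone(solar.timezone).date()
        if win is None:
            bad.append(f"{p.site_id}/{p.species}@{p.timestamp.isoformat()}: unknown site")
            continue
        if not (win[0] <= local_date <= win[1]):
            bad.append(
                f"{p.site_id}/{p.species}@{p.timestamp.isoformat()}: "
                f"outside deployment {win[0]}..{win[1]}"
            )
            continue
        period = solar.classify(p.timestamp)
        hits.add((p.site_id, p.species, period, local_date))
    if bad:
        raise ValueError("photos outside deployment:\n" + "\n".join(bad))

    counts: dict[tuple[str, str, str], int] = {}
    for site_id, sp, period, _date in hits:
        counts[(site_id, sp, period)] = counts.get((site_id, sp, period), 0) + 1

    rows = []
    for site_id in site_ids:
        for sp in species:
            for period in PERIODS:
                rows.append(
                    {
                        "site_id": site_id,
                        "species": sp,
                        "period": period,
                        "y": counts.get((site_id, sp, period), 0),
                        "k": int(k.loc[site_id]),
                    }
                )
    return pd.DataFrame(rows)


def naive_occurrence(history: pd.DataFrame) -> pd.DataFrame:
    """Fraction of sampled sites with ≥1 detection, per species × period.

    The denominator is every sampled site, including sites where the
    species was never detected — the uncorrected occurrence estimate that
    the occupancy model adjusts for imperfect detection.
    """
    if history.empty or history["site_id"].nunique() == 0:
        raise ValueError("no sites in detection history")
    out = (
        history.assign(detected=lambda d: (d["y"] > 0).astype(float))
        .groupby(["species", "period"], sort=True)["detected"]
        .mean()
        .rename("naive_occurrence")
        .reset_index()
    )
    assert np.all((out["naive_occurrence"] >= 0) & (out["naive_occurrence"] <= 1))
    return out
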