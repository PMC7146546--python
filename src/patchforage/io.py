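"""Event-log file format.

One row per poke, CSV with a fixed header, UTF-8, "." decimal separator.
Sites are written as letters L/R and mapped internally to +1/-1 (L = +1).
Timestamps are seconds from session start, half-open [poke_in, poke_out).
Comment lines starting with '#' at the top of the file carry provenance
(package version, seed, config hash) and are ignored on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

EVENT_COLUMNS = [
    "subject_id", "group", "day", "session", "protocol", "p_rwd", "p_sw",
    "barrier", "stim", "trial", "poke", "site", "reward",
    "poke_in", "poke_out", "reward_volume", "active_site",
]

SITE_TO_LETTER = {1: "L", -1: "R"}
LETTER_TO_SITE = {"L": 1, "R": -1, "NA": 0}


class EventLogError(ValueError):
    """Schema violation in an event log, reported with row numbers."""


def site_letter(sign: int) -> str:
    return SITE_TO_LETTER[int(sign)]


def site_sign(letter: str) -> int:
    return LETTER_TO_SITE[letter]


def validate_eventlog(df: pd.DataFrame) -> None:
    """Raise :class:`EventLogError` naming offending rows on violations."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"missing columns: {missing}")
    bad = df.index[df["poke_out"] <= df["poke_in"]].tolist()
    if bad:
        raise EventLogError(f"poke_out <= poke_in at rows {bad[:10]}")
    bad = df.index[~df["site"].isin(["L", "R"])].tolist()
    if bad:
        raise EventLogError(f"invalid site letters at rows {bad[:10]}")
    bad = df.index[~df["reward"].isin([0, 1])].tolist()
    if bad:
        raise EventLogError(f"reward not in {{0,1}} at rows {bad[:10]}")
    # sortedness within subject x session
    for (subj, sess), grp in df.groupby(["subject_id", "session"], sort=False):
        if not grp["poke_in"].is_monotonic_increasing:
            raise EventLogError(
                f"rows not sorted by poke_in for subject {subj} session {sess}"
            )


def write_eventlog(
    df: pd.DataFrame,
    path: str | Path,
    header: Optional[dict] = None,
) -> None:
    """Write an event log with optional '#'-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            for key, value in header.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, columns=[c for c in EVENT_COLUMNS if c in df.columns]
                  + [c for c in df.columns if c not in EVENT_COLUMNS])


def read_eventlog(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read an event log written by :func:`write_eventlog`."""
    df = pd.read_csv(path, comment="#")
    if validate:
        validate_eventlog(df)
    return df


def read_header(path: str | Path) -> dict:
    """Parse the '#'-prefixed provenance header of an event log."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
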