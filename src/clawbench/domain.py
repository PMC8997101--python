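"""Closed vocabularies and record types for claw-health data.

The coding standard is the harmonized international claw-lesion catalogue
(ICAR Claw Health Atlas terminology) plus the six digital-dermatitis (DD)
M-stages and the DD-associated claw horn lesions.  Every lesion code maps to
exactly one of 13 benchmark groups (or ``other`` for catalogued lesions that
the benchmark does not track individually):

======  =============================================
TS      thin sole
IP      interdigital phlegmon
SW      swelling of coronet/bulb (deep digital sepsis)
HF      horn fissure
IH      interdigital hyperplasia
DS      double sole
CC      corkscrew claw
HHE     heel horn erosion
SH      sole haemorrhage
WLA     white line disease / white line abscess
UL      ulcers (sole, toe, bulb) and toe necrosis
CD      concave dorsal wall (chronic laminitis)
DD      digital dermatitis (stages M1..M4.1)
======  =============================================

'Alarm' lesions are the always-painful subset: all ulcers and toe necroses,
white line abscesses (WLD of severity >= 2), coronet/bulb swellings with deep
sepsis, interdigital phlegmon, penetrating infected horn fissures, the acute
M2 stage of DD, and all DD-associated claw horn lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence, Union

import pandas as pd

#: The 13 benchmark lesion groups, in the report row order used throughout.
BENCHMARK_GROUPS: tuple[str, ...] = (
    "TS", "IP", "SW", "HF", "IH", "DS", "CC",
    "HHE", "SH", "WLA", "UL", "CD", "DD",
)
OTHER_GROUP = "other"

DD_STAGES: tuple[str, ...] = ("M0", "M1", "M2", "M3", "M4", "M4.1")
#: M-stages that count as DD lesion records (M0 is healthy skin).
DD_LESION_STAGES: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M4.1")

NO_LESION_CODE = "NL"

#: Severity score a record without an explicit score (farmer-app records)
#: is assumed to carry.  The app records only noteworthy lesions, so they are
#: treated as at least moderate.  Overridable everywhere it matters.
DEFAULT_FARMER_SEVERITY = 2

RECORDER_TYPES = ("trimmer", "farmer")

#: The ten coded culling reasons of the routine performance-testing reports;
#: exactly one of them is directly claw/limb related.
CULLING_REASONS: tuple[str, ...] = (
    "CLAW_LIMB",          # claw & limb disorders
    "LOW_PRODUCTION",
    "FERTILITY",
    "UDDER_DISEASE",
    "METABOLIC_DISEASE",
    "OTHER_DISEASE",
    "AGE",
    "SALE_FOR_DAIRY",
    "ACCIDENT",
    "OTHER",
)
CLAW_CULL_REASON = "CLAW_LIMB"

ZONE_MIN, ZONE_MAX = 0, 10  # modified 10-claw-zone scheme
SEVERITY_SCORES = (1, 2, 3)  # mild, moderate, severe
LOCOMOTION_SCORES = (1, 2, 3, 4, 5)  # Sprecher 5-point scale, 1 = non-lame


class UnknownLesionCodeError(KeyError):
    """A record carries a lesion code absent from the vocabulary."""

    def __init__(self, code: object):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown lesion code: {self.code!r}"


@lru_cache(maxsize=1)
def load_vocabulary() -> pd.DataFrame:
    """The versioned lesion vocabulary, indexed by code.

    Columns: ``name``, ``group`` (one of the 13 groups, ``other`` or empty for
    non-lesion codes), ``alarm_min_severity`` (NaN = never alarm, 1 = always,
    2 = alarm from severity 2 up), ``severity_sensitive`` (severity-1 trimmer
    records are excluded from KPI computation), ``dd_associated``,
    ``is_lesion``.
    """
    with resources.files("clawbench.data").joinpath("lesion_vocabulary.csv").open() as fh:
        vocab = pd.read_csv(fh, dtype={"code": str, "name": str, "group": str})
    vocab["severity_sensitive"] = vocab["severity_sensitive"].astype(bool)
    vocab["dd_associated"] = vocab["dd_associated"].astype(bool)
    vocab["is_lesion"] = vocab["is_lesion"].astype(bool)
    return vocab.set_index("code")


def known_codes() -> frozenset[str]:
    return frozenset(load_vocabulary().index)


def _resolve(code: str) -> pd.Series:
    vocab = load_vocabulary()
    try:
        return vocab.loc[code]
    except KeyError:
        raise UnknownLesionCodeError(code) from None


def _effective_severity(severity: Optional[int],
                        farmer_default: int = DEFAULT_FARMER_SEVERITY) -> int:
    if severity is None or (isinstance(severity, float) and pd.isna(severity)):
        return farmer_default
    return int(severity)


def lesion_group(record_or_code: Union["TrimmingRecord", str],
                 severity: Optional[int] = None) -> Optional[str]:
    """Benchmark group of a record: one of the 13 groups, ``other``, or
    ``None`` for non-lesion codes (``NL``, ``M0``).

    White line disease maps into the WLA group (its severity-1 records are
    removed upstream by the severity recoding, so surviving WLD records are
    white line abscesses); DD stages M1..M4.1 all map to DD.
    """
    if isinstance(record_or_code, TrimmingRecord):
        code = record_or_code.lesion_code
    else:
        code = record_or_code
    entry = _resolve(code)
    if not entry["is_lesion"]:
        return None
    return entry["group"]


def is_alarm(record_or_code: Union["TrimmingRecord", str],
             severity: Optional[int] = None,
             farmer_default_severity: int = DEFAULT_FARMER_SEVERITY) -> bool:
    """Whether a record documents an 'alarm' (always painful) lesion.

    Covers ulcers/toe necrosis, WLD at severity >= 2 (= white line abscess),
    coronet/bulb swelling, interdigital phlegmon, penetrating infected horn
    fissures, acute M2 DD and DD-associated claw horn lesions.  Chronic DD
    stages, plain fissures and all purely horn-quality lesions are not alarm.
    """
    if isinstance(record_or_code, TrimmingRecord):
        code = record_or_code.lesion_code
        severity = record_or_code.severity
    else:
        code = record_or_code
    entry = _resolve(code)
    if not entry["is_lesion"] or pd.isna(entry["alarm_min_severity"]):
        return False
    return _effective_severity(severity, farmer_default_severity) >= int(entry["alarm_min_severity"])


def annotate_records(records: pd.DataFrame,
                     farmer_default_severity: int = DEFAULT_FARMER_SEVERITY,
                     strict: bool = True) -> pd.DataFrame:
    """Vectorised vocabulary lookup: adds ``group``, ``alarm``, ``is_lesion``,
    ``severity_sensitive`` and ``dd_associated`` columns to a trimming-record
    frame (columns ``lesion_code`` and optionally ``severity``).

    With ``strict`` (default) an unknown code raises
    :class:`UnknownLesionCodeError`; otherwise unknown codes get NaN group.
    """
    vocab = load_vocabulary()
    out = records.copy()
    unknown = ~out["lesion_code"].isin(vocab.index)
    if strict and unknown.any():
        raise UnknownLesionCodeError(sorted(out.loc[unknown, "lesion_code"].unique()))
    joined = out.join(vocab, on="lesion_code", rsuffix="_vocab")
    out["is_lesion"] = joined["is_lesion"].fillna(False).astype(bool)
    out["group"] = joined["group"].where(out["is_lesion"])
    out["severity_sensitive"] = joined["severity_sensitive"].fillna(False).astype(bool)
    out["dd_associated"] = joined["dd_associated"].fillna(False).astype(bool)
    if "severity" in out.columns:
        eff = out["severity"].fillna(farmer_default_severity).astype(float)
    else:
        eff = pd.Series(float(farmer_default_severity), index=out.index)
    out["alarm"] = out["is_lesion"] & joined["alarm_min_severity"].notna() & (
        eff >= joined["alarm_min_severity"].fillna(99.0)
    )
    return out


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimmingRecord:
    """One lesion (or explicit no-lesion) observation at one trimming event."""

    herd_id: str
    cow_id: str
    date: Date
    lesion_code: str
    zone: int = 0
    severity: Optional[int] = None
    recorder: str = "trimmer"
    observer_id: str = ""

    def __post_init__(self) -> None:
        if not (ZONE_MIN <= self.zone <= ZONE_MAX):
            raise ValueError(f"zone {self.zone} outside {ZONE_MIN}..{ZONE_MAX}")
        if self.severity is not None and self.severity not in SEVERITY_SCORES:
            raise ValueError(f"severity {self.severity} not in {SEVERITY_SCORES}")
        if self.recorder not in RECORDER_TYPES:
            raise ValueError(f"recorder {self.recorder!r} not in {RECORDER_TYPES}")


@dataclass(frozen=True)
class LocomotionRecord:
    """One 5-point locomotion score of one cow at one test date."""

    herd_id: str
    cow_id: str
    date: Date
    score: int
    observer_id: str = ""

    def __post_init__(self) -> None:
        if self.score not in LOCOMOTION_SCORES:
            raise ValueError(f"locomotion score {self.score} not in 1..5")


@dataclass(frozen=True)
class CullingRecord:
    herd_id: str
    cow_id: str
    date: Date
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in CULLING_REASONS:
            raise ValueError(f"unknown culling reason {self.reason!r}")


@dataclass(frozen=True)
class CowInterval:
    """A cow's presence and lactation timeline within one herd.

    Presence is the half-open interval [entry, exit); ``exit`` of ``None``
    means the cow is still in the herd.  Calving and dry-off dates must fall
    inside the presence interval and alternate (dry-off precedes the next
    calving by the dry period).
    """

    cow_id: str
    herd_id: str
    entry: Date
    exit: Optional[Date] = None
    calvings: tuple[Date, ...] = field(default_factory=tuple)
    dryoffs: tuple[Date, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.exit is not None and self.entry > self.exit:
            raise ValueError(f"entry {self.entry} after exit {self.exit}")
        for d in (*self.calvings, *self.dryoffs):
            if d < self.entry or (self.exit is not None and d > self.exit):
                raise ValueError(f"event {d} outside presence [{self.entry}, {self.exit}]")
        if tuple(sorted(self.calvings)) != self.calvings:
            raise ValueError("calving dates not ordered")
        if tuple(sorted(self.dryoffs)) != self.dryoffs:
            raise ValueError("dry-off dates not ordered")

    def is_present(self, on: Date) -> bool:
        return self.entry <= on and (self.exit is None or on < self.exit)

    def last_calving(self, on: Date) -> Optional[Date]:
        prior = [c for c in self.calvings if c <= on]
        return max(prior) if prior else None

    def dim(self, on: Date) -> Optional[int]:
        """Days in milk: days since the most recent calving (None pre-calving)."""
        lc = self.last_calving(on)
        return None if lc is None else (on - lc).days

    def is_dry(self, on: Date) -> bool:
        """Dry iff the most recent lactation event at ``on`` is a dry-off."""
        lc = self.last_calving(on)
        prior_dry = [d for d in self.dryoffs if d <= on]
        if not prior_dry:
            return False
        return lc is None or max(prior_dry) > lc


def intervals_to_frame(intervals: Sequence[CowInterval]) -> pd.DataFrame:
    """Serialise CowIntervals to the roster frame schema (dates as Timestamps,
    event lists pipe-joined ISO strings)."""
    rows = []
    for iv in intervals:
        rows.append({
            "herd_id": iv.herd_id,
            "cow_id": iv.cow_id,
            "entry_date": pd.Timestamp(iv.entry),
            "exit_date": pd.Timestamp(iv.exit) if iv.exit is not None else pd.NaT,
            "calving_dates": "|".join(d.isoformat() for d in iv.calvings),
            "dryoff_dates": "|".join(d.isoformat() for d in iv.dryoffs),
        })
    return pd.DataFrame(rows, columns=["herd_id", "cow_id", "entry_date", "exit_date",
                                       "calving_dates", "dryoff_dates"])
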