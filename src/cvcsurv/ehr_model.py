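"""Domain model for the tabular EHR substrate consumed by the surveillance rules.

The surveillance pipeline operates on a small bundle of delimited text files
(admissions, blood-culture draws, CVC-tip cultures, vital observations, an
organism classification list, and optional per-episode reference labels).
This module defines the typed records, the organism pathogen/commensal
classification, and deterministic readers/writers for the bundle.

Timestamps are timezone-naive local clock times at minute resolution
(ISO-8601 ``YYYY-MM-DDTHH:MM``); all rule windows are hour/minute scale, so
durations are exact clock differences.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator

TS_FORMAT = "%Y-%m-%dT%H:%M"


class CohortValidationError(ValueError):
    """Raised when a cohort bundle violates a structural invariant."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class SurveillanceConfig(BaseModel):
    """Every numeric threshold of the CVC-BSI rule set, in one validated record.

    Defaults implement the ECDC-style rule set: fever strictly above 38 °C,
    hypotension as SBP strictly below 90 mmHg or DBP at or below 60 mmHg,
    symptoms within three days before or after the blood-culture draw,
    contaminant confirmation requiring two draws within 48 h, tip cultures
    at >= 10^3 CFU/ml within 48 h after the draw, paired central/peripheral
    draws at most 15 min apart with >= 2 h differential time to positivity
    (central flagging first), a 14-day repeat infection timeframe, and
    healthcare-associated onset on admission day 3 or later (admission day
    counts as day 1) or on day 1-2 with a previous discharge within 48 h.
    """

    fever_threshold: float = 38.0  # degrees C, symptom if strictly greater
    sbp_threshold: float = 90.0  # mmHg, symptom if strictly less
    dbp_threshold: float = 60.0  # mmHg, symptom if less-or-equal
    symptom_window_days: int = Field(3, ge=0)  # closed window before AND after anchor
    contaminant_pair_window_hours: float = 48.0
    tip_window_hours: float = 48.0  # after the BCx draw
    tip_cfu_threshold: float = 1000.0  # CFU/ml, greater-or-equal
    paired_draw_max_minutes: float = 15.0
    dtp_min_hours: float = 2.0  # greater-or-equal, central before peripheral
    rit_days: int = 14  # calendar days, index day counts as day 1
    ha_min_day: int = 3  # day of admission = day 1
    ha_readmission_window_hours: float = 48.0
    bootstrap_reps: int = 10_000
    ci_level: float = 0.95
    # Alternative reading of algorithm 1 in which the symptom requirement also
    # gates pathogen-anchored episodes; default mirrors the ECDC BSI logic
    # (pathogens: one culture; commensals: two cultures plus signs).
    require_symptoms_for_pathogens: bool = False

    @field_validator(
        "fever_threshold",
        "sbp_threshold",
        "dbp_threshold",
        "contaminant_pair_window_hours",
        "tip_window_hours",
        "tip_cfu_threshold",
        "paired_draw_max_minutes",
        "dtp_min_hours",
    )
    @classmethod
    def _strictly_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("threshold must be strictly positive")
        return v

    @field_validator("rit_days", "ha_min_day", "bootstrap_reps")
    @classmethod
    def _positive_int(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("must be a positive integer")
        return v

    @field_validator("ci_level")
    @classmethod
    def _open_unit(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveillanceConfig":
        """Load a config from a YAML key:value file; absent keys take defaults."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise CohortValidationError(f"config file {path} is not a mapping")
        known = set(cls.model_fields)
        unknown = set(data) - known
        if unknown:
            raise CohortValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Enumerations and records
# ---------------------------------------------------------------------------


class Site(str, enum.Enum):
    PERIPHERAL = "peripheral"
    CENTRAL = "central"
    UNSPECIFIED = "unspecified"


class OrganismClass(str, enum.Enum):
    PATHOGEN = "pathogen"
    COMMENSAL = "commensal"


class VitalKind(str, enum.Enum):
    TEMPERATURE = "temperature"
    SBP = "sbp"
    DBP = "dbp"


def _parse_ts(text: str) -> dt.datetime:
    return dt.datetime.strptime(text, TS_FORMAT)


def _format_ts(ts: dt.datetime) -> str:
    return ts.strftime(TS_FORMAT)


@dataclass(frozen=True)
class Admission:
    admission_id: str
    patient_id: str
    admit_ts: dt.datetime
    discharge_ts: dt.datetime

    def __post_init__(self) -> None:
        if self.discharge_ts < self.admit_ts:
            raise CohortValidationError(
                f"admission {self.admission_id}: discharge before admit"
            )


def normalise_code(code: str) -> str:
    """Canonical form of an organism code: trimmed and case-folded."""
    return code.strip().casefold()


@dataclass(frozen=True)
class CommensalList:
    """Set of organism codes classified as common commensals (contaminants).

    Membership is exact-match on the species-level code after trimming and
    case-folding; no taxonomy expansion is performed.
    """

    codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.codes:
            raise CohortValidationError("commensal list must be non-empty")
        object.__setattr__(
            self, "codes", frozenset(normalise_code(c) for c in self.codes)
        )

    def __contains__(self, code: str) -> bool:
        return normalise_code(code) in self.codes

    @classmethod
    def from_file(cls, path: str | Path) -> "CommensalList":
        codes = set()
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    codes.add(line)
        return cls(frozenset(codes))

    @classmethod
    def default(cls) -> "CommensalList":
        """Commensal list shipped with the package.

        A representative, user-replaceable subset of the CDC common-commensal
        organisms; it is configuration, not code.
        """
        text = (
            resources.files("cvcsurv").joinpath("data/commensals.txt").read_text()
        )
        codes = {
            ln.strip()
            for ln in text.splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        }
        return cls(frozenset(codes))


def classify_isolate(organism_code: str, commensal_list: CommensalList) -> OrganismClass:
    """Classify an organism code as recognised pathogen or common commensal.

    Commensal iff the code is a member of the classification list (exact
    species-level match after normalisation), pathogen otherwise.
    """
    if not organism_code or not organism_code.strip():
        raise CohortValidationError("organism_code must be non-empty")
    if organism_code in commensal_list:
        return OrganismClass.COMMENSAL
    return OrganismClass.PATHOGEN


@dataclass(frozen=True)
class Isolate:
    organism_code: str
    organism_class: OrganismClass


@dataclass(frozen=True)
class BloodCultureDraw:
    """One blood-culture draw event; multiple bottles collapse to one draw.

    An empty isolate list marks a negative draw (any growth of microorganisms,
    pathogen or commensal, makes the draw positive). ``ttp_hours`` is the
    draw-level time to positivity and may only be present on positive draws.
    """

    draw_id: str
    admission_id: str
    draw_ts: dt.datetime
    site: Site
    isolates: tuple[Isolate, ...]
    ttp_hours: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ttp_hours is not None:
            if not self.isolates:
                raise CohortValidationError(
                    f"draw {self.draw_id}: ttp_hours present on a negative draw"
                )
            if self.ttp_hours < 0:
                raise CohortValidationError(
                    f"draw {self.draw_id}: negative ttp_hours"
                )

    @property
    def is_positive(self) -> bool:
        return len(self.isolates) > 0

    def species(self) -> set[str]:
        return {normalise_code(i.organism_code) for i in self.isolates}


@dataclass(frozen=True)
class CvcTipCulture:
    admission_id: str
    collect_ts: dt.datetime
    organism_code: str
    cfu_per_ml: float

    def __post_init__(self) -> None:
        if self.cfu_per_ml < 0:
            raise CohortValidationError("cfu_per_ml must be non-negative")


@dataclass(frozen=True)
class VitalObservation:
    admission_id: str
    obs_ts: dt.datetime
    kind: VitalKind
    value: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.value) or self.value <= 0:
            raise CohortValidationError("vital value must be finite and positive")


@dataclass(frozen=True)
class ReferenceLabel:
    episode_id: str
    cvc_bsi: bool
    ha: bool


@dataclass
class CohortBundle:
    """The full tabular cohort: admissions plus their satellite tables."""

    admissions: list[Admission]
    blood_cultures: list[BloodCultureDraw]
    tip_cultures: list[CvcTipCulture]
    vitals: list[VitalObservation]
    commensal_list: CommensalList
    reference_labels: Optional[list[ReferenceLabel]] = None

    def validate(self) -> "CohortBundle":
        """Check referential integrity and uniqueness invariants; return self."""
        adm_ids = [a.admission_id for a in self.admissions]
        if len(set(adm_ids)) != len(adm_ids):
            dupes = sorted({i for i in adm_ids if adm_ids.count(i) > 1})
            raise CohortValidationError(f"duplicate admission ids: {dupes}")
        adm_by_id = {a.admission_id: a for a in self.admissions}

        draw_ids = [d.draw_id for d in self.blood_cultures]
        if len(set(draw_ids)) != len(draw_ids):
            dupes = sorted({i for i in draw_ids if draw_ids.count(i) > 1})
            raise CohortValidationError(f"duplicate draw ids: {dupes}")

        for d in self.blood_cultures:
            adm = adm_by_id.get(d.admission_id)
            if adm is None:
                raise CohortValidationError(
                    f"draw {d.draw_id}: unknown admission_id {d.admission_id!r}"
                )
            if not (adm.admit_ts <= d.draw_ts <= adm.discharge_ts):
                raise CohortValidationError(
                    f"draw {d.draw_id}: draw_ts outside admission interval"
                )
        for t in self.tip_cultures:
            if t.admission_id not in adm_by_id:
                raise CohortValidationError(
                    f"tip culture: unknown admission_id {t.admission_id!r}"
                )
        for v in self.vitals:
            if v.admission_id not in adm_by_id:
                raise CohortValidationError(
                    f"vital observation: unknown admission_id {v.admission_id!r}"
                )
        if self.reference_labels is not None:
            eids = [r.episode_id for r in self.reference_labels]
            if len(set(eids)) != len(eids):
                raise CohortValidationError("duplicate episode ids in reference labels")
        return self

    def draws_by_admission(self) -> dict[str, list[BloodCultureDraw]]:
        out: dict[str, list[BloodCultureDraw]] = {a.admission_id: [] for a in self.admissions}
        for d in self.blood_cultures:
            out[d.admission_id].append(d)
        for lst in out.values():
            lst.sort(key=lambda d: (d.draw_ts, d.draw_id))
        return out

    def vitals_by_admission(self) -> dict[str, list[VitalObservation]]:
        out: dict[str, list[VitalObservation]] = {a.admission_id: [] for a in self.admissions}
        for v in self.vitals:
            out[v.admission_id].append(v)
        return out

    def tips_by_admission(self) -> dict[str, list[CvcTipCulture]]:
        out: dict[str, list[CvcTipCulture]] = {a.admission_id: [] for a in self.admissions}
        for t in self.tip_cultures:
            out[t.admission_id].append(t)
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

ADMISSIONS_FILE = "admissions.csv"
BLOOD_CULTURES_FILE = "blood_cultures.csv"
TIP_CULTURES_FILE = "cvc_tip_cultures.csv"
VITALS_FILE = "vitals.csv"
COMMENSALS_FILE = "commensals.txt"
REFERENCE_LABELS_FILE = "reference_labels.csv"


def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _read_rows(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise CohortValidationError(
                f"{path.name}: expected header columns {list(required)}"
            )
        return list(reader)


def _row_ts(path_name: str, row_no: int, text: str) -> dt.datetime:
    try:
        return _parse_ts(text)
    except ValueError as exc:
        raise CohortValidationError(
            f"{path_name} row {row_no}: unparseable timestamp {text!r}"
        ) from exc


def read_cohort(directory: str | Path) -> CohortBundle:
    """Read and validate a cohort bundle from a directory of delimited files.

    Missing mandatory files, dangling foreign keys, duplicate ids and
    unparseable timestamps are all fatal, reported with the offending file
    (and row where applicable). ``reference_labels.csv`` is optional.
    """
    directory = Path(directory)
    for fname in (ADMISSIONS_FILE, BLOOD_CULTURES_FILE, TIP_CULTURES_FILE, VITALS_FILE, COMMENSALS_FILE):
        if not (directory / fname).exists():
            raise CohortValidationError(f"missing cohort file: {fname}")

    commensals = CommensalList.from_file(directory / COMMENSALS_FILE)

    admissions = []
    for i, row in enumerate(
        _read_rows(directory / ADMISSIONS_FILE, ["admission_id", "patient_id", "admit_ts", "discharge_ts"]),
        start=2,
    ):
        admissions.append(
            Admission(
                admission_id=row["admission_id"],
                patient_id=row["patient_id"],
                admit_ts=_row_ts(ADMISSIONS_FILE, i, row["admit_ts"]),
                discharge_ts=_row_ts(ADMISSIONS_FILE, i, row["discharge_ts"]),
            )
        )

    # One row per draw x isolate; draw-level fields repeat. An empty
    # organism_code marks a negative draw.
    draw_rows: dict[str, list[tuple[int, dict[str, str]]]] = {}
    order: list[str] = []
    for i, row in enumerate(
        _read_rows(
            directory / BLOOD_CULTURES_FILE,
            ["draw_id", "admission_id", "draw_ts", "site", "organism_code", "ttp_hours"],
        ),
        start=2,
    ):
        did = row["draw_id"]
        if did not in draw_rows:
            draw_rows[did] = []
            order.append(did)
        draw_rows[did].append((i, row))

    blood_cultures = []
    for did in order:
        rows = draw_rows[did]
        first_no, first = rows[0]
        for no, row in rows[1:]:
            for col in ("admission_id", "draw_ts", "site", "ttp_hours"):
                if row[col] != first[col]:
                    raise CohortValidationError(
                        f"{BLOOD_CULTURES_FILE} row {no}: draw-level field {col!r} "
                        f"disagrees with row {first_no} for draw {did}"
                    )
        isolates = []
        for no, row in rows:
            code = row["organism_code"].strip()
            if code:
                isolates.append(Isolate(code, classify_isolate(code, commensals)))
            elif len(rows) > 1:
                raise CohortValidationError(
                    f"{BLOOD_CULTURES_FILE} row {no}: empty organism_code mixed "
                    f"with isolates for draw {did}"
                )
        ttp = float(first["ttp_hours"]) if first["ttp_hours"].strip() else None
        blood_cultures.append(
            BloodCultureDraw(
                draw_id=did,
                admission_id=first["admission_id"],
                draw_ts=_row_ts(BLOOD_CULTURES_FILE, first_no, first["draw_ts"]),
                site=Site(first["site"]),
                isolates=tuple(isolates),
                ttp_hours=ttp,
            )
        )

    tip_cultures = []
    for i, row in enumerate(
        _read_rows(directory / TIP_CULTURES_FILE, ["admission_id", "collect_ts", "organism_code", "cfu_per_ml"]),
        start=2,
    ):
        tip_cultures.append(
            CvcTipCulture(
                admission_id=row["admission_id"],
                collect_ts=_row_ts(TIP_CULTURES_FILE, i, row["collect_ts"]),
                organism_code=row["organism_code"],
                cfu_per_ml=float(row["cfu_per_ml"]),
            )
        )

    vitals = []
    for i, row in enumerate(
        _read_rows(directory / VITALS_FILE, ["admission_id", "obs_ts", "kind", "value"]),
        start=2,
    ):
        vitals.append(
            VitalObservation(
                admission_id=row["admission_id"],
                obs_ts=_row_ts(VITALS_FILE, i, row["obs_ts"]),
                kind=VitalKind(row["kind"]),
                value=float(row["value"]),
            )
        )

    reference_labels = None
    ref_path = directory / REFERENCE_LABELS_FILE
    if ref_path.exists():
        reference_labels = []
        for row in _read_rows(ref_path, ["episode_id", "cvc_bsi", "ha"]):
            reference_labels.append(
                ReferenceLabel(
                    episode_id=row["episode_id"],
                    cvc_bsi=row["cvc_bsi"] == "True",
                    ha=row["ha"] == "True",
                )
            )

    return CohortBundle(
        admissions=admissions,
        blood_cultures=blood_cultures,
        tip_cultures=tip_cultures,
        vitals=vitals,
        commensal_list=commensals,
        reference_labels=reference_labels,
    ).validate()


def write_cohort(bundle: CohortBundle, directory: str | Path) -> list[Path]:
    """Write a validated bundle to a directory as the canonical file set.

    Row and column order are deterministic (sorted by id then timestamp), so
    two writes of the same bundle are byte-identical. When the optional
    reference labels are absent the file is simply omitted.
    """
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(fname: str, header: list[str], rows: Iterable[list[str]]) -> None:
        path = directory / fname
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)
        written.append(path)

    _write(
        ADMISSIONS_FILE,
        ["admission_id", "patient_id", "admit_ts", "discharge_ts"],
        (
            [a.admission_id, a.patient_id, _format_ts(a.admit_ts), _format_ts(a.discharge_ts)]
            for a in sorted(bundle.admissions, key=lambda a: a.admission_id)
        ),
    )

    def _bcx_rows():
        for d in sorted(bundle.blood_cultures, key=lambda d: (d.admission_id, d.draw_ts, d.draw_id)):
            common = [d.draw_id, d.admission_id, _format_ts(d.draw_ts), d.site.value]
            if d.isolates:
                for iso in sorted(d.isolates, key=lambda i: i.organism_code):
                    yield common + [iso.organism_code, _fmt_float(d.ttp_hours)]
            else:
                yield common + ["", ""]

    _write(
        BLOOD_CULTURES_FILE,
        ["draw_id", "admission_id", "draw_ts", "site", "organism_code", "ttp_hours"],
        _bcx_rows(),
    )

    _write(
        TIP_CULTURES_FILE,
        ["admission_id", "collect_ts", "organism_code", "cfu_per_ml"],
        (
            [t.admission_id, _format_ts(t.collect_ts), t.organism_code, _fmt_float(t.cfu_per_ml)]
            for t in sorted(bundle.tip_cultures, key=lambda t: (t.admission_id, t.collect_ts, t.organism_code))
        ),
    )

    _write(
        VITALS_FILE,
        ["admission_id", "obs_ts", "kind", "value"],
        (
            [v.admission_id, _format_ts(v.obs_ts), v.kind.value, _fmt_float(v.value)]
            for v in sorted(bundle.vitals, key=lambda v: (v.admission_id, v.obs_ts, v.kind.value))
        ),
    )

    commensals_path = directory / COMMENSALS_FILE
    with open(commensals_path, "w", encoding="utf-8", newline="\n") as fh:
        for code in sorted(bundle.commensal_list.codes):
            fh.write(code + "\n")
    written.append(commensals_path)

    if bundle.reference_labels is not None:
        _write(
            REFERENCE_LABELS_FILE,
            ["episode_id", "cvc_bsi", "ha"],
            (
                [r.episode_id, str(r.cvc_bsi), str(r.ha)]
                for r in sorted(bundle.reference_labels, key=lambda r: r.episode_id)
            ),
        )

    return written
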