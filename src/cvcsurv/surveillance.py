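"""Rule-based detection of central venous catheter-related bloodstream infection.

Two fully-automated algorithm variants are implemented over the EHR bundle:

* ``with_symptoms`` (algorithm 1): microbiological findings in blood cultures
  and CVC cultures combined with BSI symptoms (fever, hypotension);
* ``microbiology_only`` (algorithm 2): microbiological findings only.

The unit of surveillance is the *potential CVC-BSI episode*: one per
blood-culture draw during an admission, and one per admission in which no
blood culture was taken. Detection proceeds in four stages, mirroring how
the rules compose:

1. BSI confirmation — a recognised pathogen in a single draw suffices; a
   common commensal needs a second distinct draw growing the same species
   within 48 h, plus BSI symptoms under the symptom variant.
2. CVC attribution — a matching quantitative tip culture (>= 10^3 CFU/ml,
   same species, within 48 h after the draw) or a qualifying paired
   central/peripheral draw with >= 2 h differential time to positivity
   (central flagging first, draws at most 15 min apart).
3. Repeat infection timeframe (RIT) — within one admission, later positives
   falling inside the 14-day window opened by an episode's first positive
   draw are suppressed into that episode.
4. Healthcare-associated (HA) classification — onset on admission day >= 3
   (admission day = day 1), or on day 1-2 with a previous admission of the
   same patient discharged within 48 h before the current admission.

Every emitted label carries an evidence trail of the satisfied criteria so
that discrepancies against a reference standard can be audited rule by rule.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .ehr_model import (
    Admission,
    BloodCultureDraw,
    CohortBundle,
    CvcTipCulture,
    OrganismClass,
    Site,
    SurveillanceConfig,
    VitalKind,
    VitalObservation,
    normalise_code,
)

# Evidence tags
PATHOGEN_BSI = "pathogen_bsi"
COMMENSAL_PAIR = "commensal_pair"
SYMPTOMS = "symptoms"
TIP_MATCH = "tip_match"
DTP_MATCH = "dtp_match"
HA_DAY3 = "ha_day3"
HA_READMISSION = "ha_readmission"


class AlgorithmVariant(str, enum.Enum):
    """Which of the two rule sets to run."""

    WITH_SYMPTOMS = "with_symptoms"  # algorithm 1
    MICROBIOLOGY_ONLY = "microbiology_only"  # algorithm 2


class AnchorKind(str, enum.Enum):
    BCX_DRAW = "bcx_draw"
    ADMISSION_WITHOUT_BCX = "admission_without_bcx"


@dataclass(frozen=True)
class PotentialEpisode:
    episode_id: str
    admission_id: str
    anchor: AnchorKind
    anchor_draw_id: Optional[str]
    anchor_ts: dt.datetime


@dataclass(frozen=True)
class EpisodeLabel:
    episode_id: str
    admission_id: str
    anchor_ts: dt.datetime
    variant: AlgorithmVariant
    cvc_bsi: bool
    ha: bool = False
    suppressed_by_rit: bool = False
    index_episode_id: Optional[str] = None
    evidence: tuple[str, ...] = ()


def episode_id_for_draw(draw_id: str) -> str:
    return f"BCX:{draw_id}"


def episode_id_for_admission(admission_id: str) -> str:
    return f"ADM:{admission_id}"


def enumerate_potential_episodes(bundle: CohortBundle) -> list[PotentialEpisode]:
    """Enumerate the surveillance units of a cohort.

    One episode per blood-culture draw; one episode per admission without any
    draw (anchored on the admission time). Ordering is stable: by admission,
    then anchor timestamp, then draw id.
    """
    draws_by_adm = bundle.draws_by_admission()
    episodes: list[PotentialEpisode] = []
    for adm in sorted(bundle.admissions, key=lambda a: a.admission_id):
        draws = draws_by_adm[adm.admission_id]
        if not draws:
            episodes.append(
                PotentialEpisode(
                    episode_id=episode_id_for_admission(adm.admission_id),
                    admission_id=adm.admission_id,
                    anchor=AnchorKind.ADMISSION_WITHOUT_BCX,
                    anchor_draw_id=None,
                    anchor_ts=adm.admit_ts,
                )
            )
            continue
        for d in draws:
            episodes.append(
                PotentialEpisode(
                    episode_id=episode_id_for_draw(d.draw_id),
                    admission_id=adm.admission_id,
                    anchor=AnchorKind.BCX_DRAW,
                    anchor_draw_id=d.draw_id,
                    anchor_ts=d.draw_ts,
                )
            )
    return episodes


def has_bsi_symptoms(
    vitals_for_admission: Sequence[VitalObservation],
    anchor_ts: dt.datetime,
    config: SurveillanceConfig,
) -> bool:
    """True iff a qualifying symptom observation lies within the infection window.

    Symptoms: temperature strictly above the fever threshold (38 °C), SBP
    strictly below 90 mmHg, or DBP at or below 60 mmHg, observed within the
    closed window [anchor - 3 days, anchor + 3 days] (clock arithmetic).
    """
    half = dt.timedelta(days=config.symptom_window_days)
    lo, hi = anchor_ts - half, anchor_ts + half
    for obs in vitals_for_admission:
        if not (lo <= obs.obs_ts <= hi):
            continue
        if obs.kind is VitalKind.TEMPERATURE and obs.value > config.fever_threshold:
            return True
        if obs.kind is VitalKind.SBP and obs.value < config.sbp_threshold:
            return True
        if obs.kind is VitalKind.DBP and obs.value <= config.dbp_threshold:
            return True
    return False


@dataclass(frozen=True)
class BsiConfirmation:
    confirmed: bool
    evidence: tuple[str, ...]
    qualifying_species: frozenset[str]


def confirm_bsi(
    draw: BloodCultureDraw,
    all_draws_for_admission: Sequence[BloodCultureDraw],
    variant: AlgorithmVariant,
    config: SurveillanceConfig,
    vitals_for_admission: Sequence[VitalObservation] = (),
) -> BsiConfirmation:
    """Decide whether a positive draw confirms a bloodstream infection.

    A recognised pathogen needs one draw. A common commensal needs a second
    distinct draw growing the same species within the 48-h pair window; under
    the symptom variant the commensal pathway additionally requires BSI
    symptoms in the infection window anchored on the draw.

    Returns the decision together with the satisfied evidence tags and the
    set of (normalised) species that qualified the BSI — the species CVC
    attribution is allowed to match against.
    """
    if not draw.is_positive:
        raise ValueError(f"confirm_bsi called on negative draw {draw.draw_id}")

    evidence: list[str] = []
    qualifying: set[str] = set()

    symptoms_checked = False
    symptoms_present = False

    def _symptoms() -> bool:
        nonlocal symptoms_checked, symptoms_present
        if not symptoms_checked:
            symptoms_present = has_bsi_symptoms(vitals_for_admission, draw.draw_ts, config)
            symptoms_checked = True
        return symptoms_present

    pathogens = {
        normalise_code(i.organism_code)
        for i in draw.isolates
        if i.organism_class is OrganismClass.PATHOGEN
    }
    if pathogens:
        gate = (
            variant is AlgorithmVariant.WITH_SYMPTOMS
            and config.require_symptoms_for_pathogens
        )
        if not gate or _symptoms():
            evidence.append(PATHOGEN_BSI)
            qualifying |= pathogens
            if gate:
                evidence.append(SYMPTOMS)

    commensals = {
        normalise_code(i.organism_code)
        for i in draw.isolates
        if i.organism_class is OrganismClass.COMMENSAL
    }
    if commensals:
        window = dt.timedelta(hours=config.contaminant_pair_window_hours)
        paired: set[str] = set()
        for other in all_draws_for_admission:
            if other.draw_id == draw.draw_id or not other.is_positive:
                continue
            if abs(other.draw_ts - draw.draw_ts) > window:
                continue
            paired |= commensals & other.species()
        if paired:
            need_symptoms = variant is AlgorithmVariant.WITH_SYMPTOMS
            if not need_symptoms or _symptoms():
                evidence.append(COMMENSAL_PAIR)
                qualifying |= paired
                if need_symptoms:
                    evidence.append(SYMPTOMS)

    return BsiConfirmation(
        confirmed=bool(qualifying),
        evidence=tuple(dict.fromkeys(evidence)),
        qualifying_species=frozenset(qualifying),
    )


def cvc_attribution_tip(
    draw: BloodCultureDraw,
    tip_cultures: Sequence[CvcTipCulture],
    config: SurveillanceConfig,
    qualifying_species: Optional[frozenset[str]] = None,
) -> bool:
    """CVC attribution via a quantitative tip culture.

    True iff some tip culture of the admission grows a BSI-qualifying species
    of the draw at >= the CFU threshold, collected within the tip window
    *after* the draw (lower bound inclusive at the draw time; tips collected
    before the draw never match).
    """
    species = qualifying_species if qualifying_species is not None else frozenset(draw.species())
    hi = draw.draw_ts + dt.timedelta(hours=config.tip_window_hours)
    for tip in tip_cultures:
        if tip.cfu_per_ml < config.tip_cfu_threshold:
            continue
        if normalise_code(tip.organism_code) not in species:
            continue
        if draw.draw_ts <= tip.collect_ts <= hi:
            return True
    return False


def cvc_attribution_dtp(
    draw: BloodCultureDraw,
    all_draws_for_admission: Sequence[BloodCultureDraw],
    config: SurveillanceConfig,
    qualifying_species: Optional[frozenset[str]] = None,
) -> bool:
    """CVC attribution via differential time to positivity (DTP).

    True iff the draw is a member of a central/peripheral pair drawn at most
    15 min apart, both positive for the same qualifying species, with both
    times-to-positivity recorded and peripheral TTP minus central TTP >= 2 h
    (the central culture flags first). Draws with unspecified site never
    participate; a missing TTP on either member fails the criterion.
    """
    if draw.site is Site.UNSPECIFIED:
        return False
    species = qualifying_species if qualifying_species is not None else frozenset(draw.species())
    max_gap = dt.timedelta(minutes=config.paired_draw_max_minutes)
    for other in all_draws_for_admission:
        if other.draw_id == draw.draw_id or not other.is_positive:
            continue
        if other.site is Site.UNSPECIFIED or other.site is draw.site:
            continue
        if abs(other.draw_ts - draw.draw_ts) > max_gap:
            continue
        central, peripheral = (
            (draw, other) if draw.site is Site.CENTRAL else (other, draw)
        )
        if central.ttp_hours is None or peripheral.ttp_hours is None:
            continue
        if peripheral.ttp_hours - central.ttp_hours < config.dtp_min_hours:
            continue
        shared = species & central.species() & peripheral.species()
        if shared:
            return True
    return False


def detect_cvc_bsi(
    bundle: CohortBundle,
    variant: AlgorithmVariant,
    config: Optional[SurveillanceConfig] = None,
) -> list[EpisodeLabel]:
    """Label every potential episode, before RIT deduplication.

    An episode anchored on a positive draw is CVC-BSI iff the draw confirms
    a BSI and at least one CVC attribution criterion (tip culture or DTP)
    holds; episodes anchored on negative draws or culture-free admissions are
    always negative. Both attribution tags are recorded when both hold.
    """
    config = config or SurveillanceConfig()
    episodes = enumerate_potential_episodes(bundle)
    draws_by_adm = bundle.draws_by_admission()
    vitals_by_adm = bundle.vitals_by_admission()
    tips_by_adm = bundle.tips_by_admission()
    draw_by_id = {d.draw_id: d for d in bundle.blood_cultures}

    labels: list[EpisodeLabel] = []
    for ep in episodes:
        if ep.anchor is AnchorKind.ADMISSION_WITHOUT_BCX:
            labels.append(_negative(ep, variant))
            continue
        draw = draw_by_id[ep.anchor_draw_id]
        if not draw.is_positive:
            labels.append(_negative(ep, variant))
            continue
        adm_draws = draws_by_adm[ep.admission_id]
        conf = confirm_bsi(
            draw, adm_draws, variant, config, vitals_by_adm[ep.admission_id]
        )
        if not conf.confirmed:
            labels.append(_negative(ep, variant))
            continue
        evidence = list(conf.evidence)
        tip_ok = cvc_attribution_tip(
            draw, tips_by_adm[ep.admission_id], config, conf.qualifying_species
        )
        dtp_ok = cvc_attribution_dtp(draw, adm_draws, config, conf.qualifying_species)
        if tip_ok:
            evidence.append(TIP_MATCH)
        if dtp_ok:
            evidence.append(DTP_MATCH)
        labels.append(
            EpisodeLabel(
                episode_id=ep.episode_id,
                admission_id=ep.admission_id,
                anchor_ts=ep.anchor_ts,
                variant=variant,
                cvc_bsi=tip_ok or dtp_ok,
                evidence=tuple(evidence),
            )
        )
    return labels


def _negative(ep: PotentialEpisode, variant: AlgorithmVariant) -> EpisodeLabel:
    return EpisodeLabel(
        episode_id=ep.episode_id,
        admission_id=ep.admission_id,
        anchor_ts=ep.anchor_ts,
        variant=variant,
        cvc_bsi=False,
    )


def apply_rit(
    labels: Sequence[EpisodeLabel],
    episodes: Sequence[PotentialEpisode],
    config: Optional[SurveillanceConfig] = None,
) -> list[EpisodeLabel]:
    """Deduplicate positives with the repeat infection timeframe (RIT).

    Scanning the positives of each admission in time order (ties broken by
    draw id), the first positive opens an episode whose RIT spans
    ``rit_days`` calendar days counting the index day as day 1. Any later
    positive whose anchor date falls inside the RIT is suppressed into the
    index episode (its final CVC-BSI flag becomes false and it points at the
    index); the first positive on or after RIT expiry opens a new episode
    with a new RIT. The window is anchored on the index episode's first
    positive draw, never rolled forward by suppressed positives. Negative
    labels are untouched.
    """
    config = config or SurveillanceConfig()
    by_id = {ep.episode_id: ep for ep in episodes}
    out: list[EpisodeLabel] = []
    by_adm: dict[str, list[EpisodeLabel]] = {}
    for lab in labels:
        by_adm.setdefault(lab.admission_id, []).append(lab)

    for adm_labels in by_adm.values():
        positives = [l for l in adm_labels if l.cvc_bsi]
        positives.sort(
            key=lambda l: (l.anchor_ts, by_id[l.episode_id].anchor_draw_id or "")
        )
        rit_end: Optional[dt.date] = None
        index_id: Optional[str] = None
        suppression: dict[str, str] = {}
        for lab in positives:
            day = lab.anchor_ts.date()
            if rit_end is not None and day <= rit_end:
                suppression[lab.episode_id] = index_id  # type: ignore[assignment]
            else:
                index_id = lab.episode_id
                rit_end = day + dt.timedelta(days=config.rit_days - 1)
        for lab in adm_labels:
            if lab.episode_id in suppression:
                out.append(
                    replace(
                        lab,
                        cvc_bsi=False,
                        ha=False,
                        suppressed_by_rit=True,
                        index_episode_id=suppression[lab.episode_id],
                    )
                )
            else:
                out.append(lab)

    order = {ep.episode_id: i for i, ep in enumerate(episodes)}
    out.sort(key=lambda l: order[l.episode_id])
    return out


def classify_ha(
    anchor_ts: dt.datetime,
    admission: Admission,
    prior_admissions_of_patient: Sequence[Admission],
    config: Optional[SurveillanceConfig] = None,
) -> tuple[bool, tuple[str, ...]]:
    """Healthcare-associated classification of a CVC-BSI episode.

    HA iff the anchor falls on admission day >= 3 (calendar-date arithmetic,
    admission date = day 1), or on day 1-2 with a previous admission of the
    same patient whose discharge lies within 48 h before the current
    admission (clock-time comparison).
    """
    config = config or SurveillanceConfig()
    day = (anchor_ts.date() - admission.admit_ts.date()).days + 1
    if day >= config.ha_min_day:
        return True, (HA_DAY3,)
    window = dt.timedelta(hours=config.ha_readmission_window_hours)
    for prior in prior_admissions_of_patient:
        if prior.admission_id == admission.admission_id:
            continue
        if prior.admit_ts >= admission.admit_ts:
            continue
        if admission.admit_ts - window <= prior.discharge_ts <= admission.admit_ts:
            return True, (HA_READMISSION,)
    return False, ()


def run_surveillance(
    bundle: CohortBundle,
    variant: AlgorithmVariant,
    config: Optional[SurveillanceConfig] = None,
) -> list[EpisodeLabel]:
    """Run the full pipeline: detect, RIT-deduplicate, classify HA.

    Deterministic for a given bundle; every label carries the complete
    evidence trail. HA is evaluated only for episodes that remain CVC-BSI
    positive after RIT suppression (a suppressed positive never re-anchors
    the HA classification of its index episode).
    """
    config = config or SurveillanceConfig()
    bundle.validate()
    episodes = enumerate_potential_episodes(bundle)
    labels = detect_cvc_bsi(bundle, variant, config)
    labels = apply_rit(labels, episodes, config)

    adm_by_id = {a.admission_id: a for a in bundle.admissions}
    by_patient: dict[str, list[Admission]] = {}
    for a in bundle.admissions:
        by_patient.setdefault(a.patient_id, []).append(a)

    final: list[EpisodeLabel] = []
    for lab in labels:
        if not lab.cvc_bsi:
            final.append(lab)
            continue
        adm = adm_by_id[lab.admission_id]
        ha, tags = classify_ha(lab.anchor_ts, adm, by_patient[adm.patient_id], config)
        final.append(replace(lab, ha=ha, evidence=lab.evidence + tags))
    return final


# ---------------------------------------------------------------------------
# Label I/O
# ---------------------------------------------------------------------------

LABEL_COLUMNS = [
    "episode_id",
    "admission_id",
    "anchor_ts",
    "variant",
    "cvc_bsi",
    "ha",
    "suppressed_by_rit",
    "index_episode_id",
    "evidence",
]


def write_labels(labels: Sequence[EpisodeLabel], path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LABEL_COLUMNS)
        for l in labels:
            writer.writerow(
                [
                    l.episode_id,
                    l.admission_id,
                    l.anchor_ts.strftime("%Y-%m-%dT%H:%M"),
                    l.variant.value,
                    str(l.cvc_bsi),
                    str(l.ha),
                    str(l.suppressed_by_rit),
                    l.index_episode_id or "",
                    ";".join(l.evidence),
                ]
            )


def read_labels(path) -> list[EpisodeLabel]:
    import csv

    out: list[EpisodeLabel] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                EpisodeLabel(
                    episode_id=row["episode_id"],
                    admission_id=row["admission_id"],
                    anchor_ts=dt.datetime.strptime(row["anchor_ts"], "%Y-%m-%dT%H:%M"),
                    variant=AlgorithmVariant(row["variant"]),
                    cvc_bsi=row["cvc_bsi"] == "True",
                    ha=row["ha"] == "True",
                    suppressed_by_rit=row["suppressed_by_rit"] == "True",
                    index_episode_id=row["index_episode_id"] or None,
                    evidence=tuple(t for t in row["evidence"].split(";") if t),
                )
            )
    return out
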