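"""Synthetic EHR cohort generator with implanted, labelled CVC-BSI episodes.

Real surveillance cohorts cannot be shared, so every rule and statistic in
this package is exercised against generated cohorts whose ground truth is
known *by construction*: each implanted positive satisfies the full rule set
unambiguously, and every other episode violates at least one named conjunct.
Concretely,

* background positive draws carry organisms from pools disjoint from the
  implant pools and are drawn from an unspecified site, so they can never
  acquire a tip-culture or differential-time-to-positivity attribution;
* CVC-tip cultures are emitted only for implanted cases;
* at most one infection is implanted per admission, so the repeat infection
  timeframe never interacts with the random background (the peripheral
  member of an implanted paired draw *is* rule-positive before RIT and is
  recorded in the truth as suppressed into the index episode).

Default calibration mirrors the shape of a hospital-wide validation cohort:
1500 admissions of which ~5/6 have blood cultures, ~36% of draws positive,
episode-level CVC-BSI prevalence ~1.2% among draws, ~63% of infections
healthcare-associated, and log-normal length of stay with median ~8 days.
These are illustrative study conditions, not fitted parameters.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ehr_model import (
    Admission,
    BloodCultureDraw,
    CohortBundle,
    CommensalList,
    CvcTipCulture,
    Isolate,
    OrganismClass,
    ReferenceLabel,
    Site,
    SurveillanceConfig,
    VitalKind,
    VitalObservation,
    classify_isolate,
)
from .surveillance import (
    enumerate_potential_episodes,
    episode_id_for_draw,
)

# Organism pools. Background and implant pools are disjoint so that random
# background draws can never match an implanted tip culture or pair.
BACKGROUND_PATHOGENS = (
    "ESCHERICHIA_COLI",
    "KLEBSIELLA_PNEUMONIAE",
    "PSEUDOMONAS_AERUGINOSA",
    "ENTEROCOCCUS_FAECALIS",
    "CANDIDA_ALBICANS",
)
BACKGROUND_COMMENSALS = ("CORYNEBACTERIUM_SPP", "BACILLUS_SPP", "MICROCOCCUS_SPP")
IMPLANT_PATHOGENS = ("STAPHYLOCOCCUS_AUREUS", "SERRATIA_MARCESCENS")
IMPLANT_COMMENSALS = ("STAPHYLOCOCCUS_EPIDERMIDIS", "CUTIBACTERIUM_ACNES")


class CohortSimConfig(BaseModel):
    """Study conditions of the generated cohort."""

    n_admissions: int = Field(1500, gt=0)
    frac_with_bcx: float = Field(1250 / 1500, ge=0, le=1)
    frac_positive_bcx: float = Field(0.36, ge=0, le=1)  # of draws
    # probability that a draw anchors an implanted CVC-BSI (one per admission)
    cvc_bsi_prevalence: float = Field(0.012, ge=0, le=1)
    ha_fraction: float = Field(0.63, ge=0, le=1)  # of implanted CVC-BSI
    commensal_fraction: float = Field(0.30, ge=0, le=1)  # of positive isolates
    tip_vs_dtp_mix: float = Field(0.5, ge=0, le=1)  # implants attributed via tip
    symptom_recording_rate: float = Field(1.0, ge=0, le=1)
    mean_draws_per_bcx_admission: float = Field(3.9, gt=0)
    los_lognormal_mu: float = math.log(8.0)  # log-days; median ~8 d
    los_lognormal_sigma: float = 0.8
    start_date: dt.date = dt.date(2018, 1, 1)
    period_days: int = Field(730, gt=0)
    seed: int = 20240205

    @model_validator(mode="after")
    def _feasible(self) -> "CohortSimConfig":
        if self.cvc_bsi_prevalence > 0 and self.frac_with_bcx == 0:
            raise ValueError(
                "infeasible config: positive prevalence requested but no "
                "admission has blood cultures (frac_with_bcx = 0)"
            )
        if self.cvc_bsi_prevalence > self.frac_positive_bcx:
            raise ValueError(
                "infeasible config: cvc_bsi_prevalence exceeds the fraction "
                "of positive blood cultures"
            )
        return self


@dataclass(frozen=True)
class TruthRow:
    """Per-episode reference labels plus the implant recipe used."""

    episode_id: str
    admission_id: str
    cvc_bsi: bool  # reference (ECDC-style) label
    ha: bool
    alg1_cvc_bsi: bool  # expected label under the symptom variant
    alg1_ha: bool
    alg2_cvc_bsi: bool  # expected label under the microbiology-only variant
    alg2_ha: bool
    recipe: str  # e.g. "pathogen_tip", "commensal_dtp", "dtp_partner", "background"


@dataclass
class GroundTruth:
    rows: list[TruthRow] = field(default_factory=list)

    def by_episode(self) -> dict[str, TruthRow]:
        return {r.episode_id: r for r in self.rows}

    def reference_labels(self) -> list[ReferenceLabel]:
        return [ReferenceLabel(r.episode_id, r.cvc_bsi, r.ha) for r in self.rows]

    def expected(self, variant: str, flag: str = "cvc_bsi") -> dict[str, bool]:
        """Expected per-episode labels for ``variant`` in {"alg1", "alg2"}."""
        attr = f"{variant}_{flag}" if flag == "ha" else f"{variant}_cvc_bsi"
        return {r.episode_id: getattr(r, attr) for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def _minute(ts: dt.datetime) -> dt.datetime:
    return ts.replace(second=0, microsecond=0)


class _Builder:
    """Accumulates bundle rows and truth while generating."""

    def __init__(self, commensals: CommensalList):
        self.commensals = commensals
        self.admissions: list[Admission] = []
        self.draws: list[BloodCultureDraw] = []
        self.tips: list[CvcTipCulture] = []
        self.vitals: list[VitalObservation] = []
        self.truth: dict[str, TruthRow] = {}
        self._draw_no = 0

    def new_draw_id(self) -> str:
        self._draw_no += 1
        return f"D{self._draw_no:06d}"

    def add_draw(
        self,
        admission_id: str,
        ts: dt.datetime,
        site: Site,
        codes: tuple[str, ...],
        ttp: Optional[float],
    ) -> str:
        did = self.new_draw_id()
        isolates = tuple(
            Isolate(c, classify_isolate(c, self.commensals)) for c in codes
        )
        self.draws.append(
            BloodCultureDraw(did, admission_id, _minute(ts), site, isolates, ttp)
        )
        return did

    def set_truth(
        self,
        draw_id: str,
        admission_id: str,
        *,
        ref: bool,
        ha: bool,
        alg1: bool,
        alg2: bool,
        recipe: str,
    ) -> None:
        eid = episode_id_for_draw(draw_id)
        self.truth[eid] = TruthRow(
            episode_id=eid,
            admission_id=admission_id,
            cvc_bsi=ref,
            ha=ha and ref,
            alg1_cvc_bsi=alg1,
            alg1_ha=ha and alg1,
            alg2_cvc_bsi=alg2,
            alg2_ha=ha and alg2,
            recipe=recipe,
        )


def generate_cohort(config: Optional[CohortSimConfig] = None) -> tuple[CohortBundle, GroundTruth]:
    """Generate a labelled cohort bundle; deterministic under the config seed."""
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)
    commensals = CommensalList.default()
    b = _Builder(commensals)

    start = dt.datetime.combine(cfg.start_date, dt.time(0, 0))
    for i in range(cfg.n_admissions):
        adm_id = f"A{i:05d}"
        pat_id = f"P{i:05d}"
        admit = _minute(start + dt.timedelta(minutes=float(rng.uniform(0, cfg.period_days * 1440))))
        los_days = float(np.clip(rng.lognormal(cfg.los_lognormal_mu, cfg.los_lognormal_sigma), 0.25, 90.0))
        discharge = _minute(admit + dt.timedelta(days=los_days))

        has_bcx = rng.random() < cfg.frac_with_bcx
        n_draws = 0
        if has_bcx:
            n_draws = 1 + int(rng.poisson(max(cfg.mean_draws_per_bcx_admission - 1, 0.0)))

        implant = has_bcx and rng.random() < min(1.0, cfg.cvc_bsi_prevalence * n_draws)
        if implant:
            discharge = _implant_case(b, rng, cfg, adm_id, admit, discharge)

        adm = Admission(adm_id, pat_id, admit, discharge)
        b.admissions.append(adm)

        for _ in range(n_draws):
            ts = admit + dt.timedelta(
                minutes=float(rng.uniform(0, max((discharge - admit).total_seconds() / 60, 1)))
            )
            if rng.random() < cfg.frac_positive_bcx:
                if rng.random() < cfg.commensal_fraction:
                    code = str(rng.choice(BACKGROUND_COMMENSALS))
                else:
                    code = str(rng.choice(BACKGROUND_PATHOGENS))
                ttp = round(float(rng.uniform(6, 72)), 2)
                b.add_draw(adm_id, ts, Site.UNSPECIFIED, (code,), ttp)
            else:
                b.add_draw(adm_id, ts, Site.UNSPECIFIED, (), None)

        _baseline_vitals(b, rng, adm)

    bundle = CohortBundle(
        admissions=b.admissions,
        blood_cultures=b.draws,
        tip_cultures=b.tips,
        vitals=b.vitals,
        commensal_list=commensals,
    )
    truth = _complete_truth(bundle, b.truth)
    bundle.reference_labels = truth.reference_labels()
    bundle.validate()
    return bundle, truth


def _implant_case(
    b: _Builder,
    rng: np.random.Generator,
    cfg: CohortSimConfig,
    adm_id: str,
    admit: dt.datetime,
    discharge: dt.datetime,
) -> dt.datetime:
    """Implant one unambiguous CVC-BSI into an admission; returns new discharge."""
    ha_case = rng.random() < cfg.ha_fraction
    commensal_case = rng.random() < cfg.commensal_fraction
    tip_case = rng.random() < cfg.tip_vs_dtp_mix
    symptom_recorded = rng.random() < cfg.symptom_recording_rate

    anchor = _minute(admit + (dt.timedelta(days=2, hours=8) if ha_case else dt.timedelta(hours=6)))
    # leave room for the pair/tip windows inside the stay
    discharge = max(discharge, _minute(anchor + dt.timedelta(days=4)))

    if commensal_case:
        code = str(rng.choice(IMPLANT_COMMENSALS))
        alg1 = symptom_recorded
        recipe_org = "commensal"
    else:
        code = str(rng.choice(IMPLANT_PATHOGENS))
        alg1 = True
        recipe_org = "pathogen"

    if symptom_recorded:
        b.vitals.append(
            VitalObservation(
                adm_id,
                _minute(anchor + dt.timedelta(hours=4)),
                VitalKind.TEMPERATURE,
                round(float(rng.uniform(38.6, 39.5)), 1),
            )
        )

    if tip_case:
        recipe = f"{recipe_org}_tip"
        ttp = round(float(rng.uniform(8, 30)), 2)
        did = b.add_draw(adm_id, anchor, Site.CENTRAL, (code,), ttp)
        b.tips.append(
            CvcTipCulture(
                adm_id,
                _minute(anchor + dt.timedelta(hours=6)),
                code,
                float(round(10 ** rng.uniform(3.3, 5.5))),
            )
        )
        if commensal_case:
            # the second draw of the contaminant pair; the tip precedes it,
            # so it never acquires an attribution of its own
            did2 = b.add_draw(
                adm_id,
                anchor + dt.timedelta(hours=20),
                Site.UNSPECIFIED,
                (code,),
                round(float(rng.uniform(15, 40)), 2),
            )
            b.set_truth(did2, adm_id, ref=False, ha=False, alg1=False, alg2=False,
                        recipe="pair_second_draw")
        b.set_truth(did, adm_id, ref=True, ha=ha_case, alg1=alg1, alg2=True, recipe=recipe)
    else:
        recipe = f"{recipe_org}_dtp"
        ttp_c = round(float(rng.uniform(6, 15)), 2)
        ttp_p = round(ttp_c + float(rng.uniform(2.5, 6.0)), 2)
        did_c = b.add_draw(adm_id, anchor, Site.CENTRAL, (code,), ttp_c)
        did_p = b.add_draw(
            adm_id, anchor + dt.timedelta(minutes=10), Site.PERIPHERAL, (code,), ttp_p
        )
        b.set_truth(did_c, adm_id, ref=True, ha=ha_case, alg1=alg1, alg2=True, recipe=recipe)
        # the peripheral member is itself rule-positive before RIT and is
        # suppressed into the index episode; its final label is negative
        b.set_truth(did_p, adm_id, ref=False, ha=False, alg1=False, alg2=False,
                    recipe="dtp_partner")
    return discharge


def _baseline_vitals(b: _Builder, rng: np.random.Generator, adm: Admission) -> None:
    """Unremarkable vitals every 4-8 h; values never cross a symptom threshold."""
    horizon = min(adm.discharge_ts, adm.admit_ts + dt.timedelta(days=21))
    t = adm.admit_ts + dt.timedelta(hours=float(rng.uniform(0.5, 2.0)))
    while t <= horizon:
        t_m = _minute(t)
        b.vitals.append(
            VitalObservation(adm.admission_id, t_m, VitalKind.TEMPERATURE,
                             round(float(rng.uniform(36.4, 37.8)), 1))
        )
        b.vitals.append(
            VitalObservation(adm.admission_id, t_m, VitalKind.SBP,
                             float(int(rng.uniform(95, 150))))
        )
        b.vitals.append(
            VitalObservation(adm.admission_id, t_m, VitalKind.DBP,
                             float(int(rng.uniform(62, 95))))
        )
        t += dt.timedelta(hours=float(rng.uniform(4, 8)))


def _complete_truth(bundle: CohortBundle, partial: dict[str, TruthRow]) -> GroundTruth:
    """Fill in all-negative truth rows for every non-implanted episode."""
    rows: list[TruthRow] = []
    for ep in enumerate_potential_episodes(bundle):
        row = partial.get(ep.episode_id)
        if row is None:
            row = TruthRow(
                episode_id=ep.episode_id,
                admission_id=ep.admission_id,
                cvc_bsi=False,
                ha=False,
                alg1_cvc_bsi=False,
                alg1_ha=False,
                alg2_cvc_bsi=False,
                alg2_ha=False,
                recipe="background",
            )
        rows.append(row)
    return GroundTruth(rows)


# ---------------------------------------------------------------------------
# Boundary fixtures
# ---------------------------------------------------------------------------

_EDGE_BASE = dt.datetime(2021, 1, 4, 8, 0)


def implant_edge_cases(
    bundle: CohortBundle, truth: GroundTruth
) -> tuple[CohortBundle, GroundTruth]:
    """Append the boundary fixtures exercised by the unit tests.

    Each fixture sits in its own admission (in a quiet calendar period) and
    pins one rule boundary with its intended label:

    * contaminant pair exactly 48 h apart (inclusive -> positive);
    * paired draws with differential time to positivity exactly 2 h
      (inclusive -> positive);
    * paired draws exactly 15 min apart (inclusive -> positive);
    * tip culture exactly 48 h after the draw at exactly the CFU threshold
      (both inclusive -> positive);
    * temperature exactly 38.0 (strict threshold -> symptom absent: the
      symptom variant stays negative, the microbiology-only variant fires);
    * DBP exactly 60 (inclusive -> symptom present);
    * second positive on RIT day 14 (window expired -> second episode kept)
      and on day 13 (inside -> suppressed);
    * day-2 episode with a previous discharge exactly 48 h before admission
      (healthcare-associated) and 72 h before (not).
    """
    b = _Builder(bundle.commensal_list)
    b._draw_no = len(bundle.blood_cultures) + 100_000  # avoid id collisions
    base = _EDGE_BASE
    h = dt.timedelta
    pat = 0

    def new_adm(tag: str, admit: dt.datetime, discharge: dt.datetime,
                patient: Optional[str] = None) -> str:
        nonlocal pat
        pat += 1
        adm_id = f"EDGE_{tag}"
        b.admissions.append(Admission(adm_id, patient or f"EP{pat:03d}", _minute(admit), _minute(discharge)))
        return adm_id

    com = IMPLANT_COMMENSALS[0]
    path = IMPLANT_PATHOGENS[0]

    # 1. contaminant pair exactly 48 h apart, symptoms, tip on first draw
    a = new_adm("PAIR48", base, base + h(days=5))
    d1 = b.add_draw(a, base + h(hours=1), Site.UNSPECIFIED, (com,), 20.0)
    d2 = b.add_draw(a, base + h(hours=49), Site.UNSPECIFIED, (com,), 22.0)
    b.vitals.append(VitalObservation(a, _minute(base + h(hours=2)), VitalKind.TEMPERATURE, 38.6))
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=7)), com, 2000.0))
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_pair_48h")
    b.set_truth(d2, a, ref=False, ha=False, alg1=False, alg2=False, recipe="pair_second_draw")

    # 2. differential time to positivity exactly 2 h
    a = new_adm("DTP2H", base, base + h(days=3))
    d1 = b.add_draw(a, base + h(hours=1), Site.CENTRAL, (path,), 10.0)
    d2 = b.add_draw(a, base + h(hours=1, minutes=10), Site.PERIPHERAL, (path,), 12.0)
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_dtp_2h")
    b.set_truth(d2, a, ref=False, ha=False, alg1=False, alg2=False, recipe="dtp_partner")

    # 3. paired draws exactly 15 min apart
    a = new_adm("GAP15", base, base + h(days=3))
    d1 = b.add_draw(a, base + h(hours=1), Site.CENTRAL, (path,), 8.0)
    d2 = b.add_draw(a, base + h(hours=1, minutes=15), Site.PERIPHERAL, (path,), 11.0)
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_gap_15min")
    b.set_truth(d2, a, ref=False, ha=False, alg1=False, alg2=False, recipe="dtp_partner")

    # 4. tip exactly +48 h at exactly the CFU threshold
    a = new_adm("TIP48", base, base + h(days=4))
    d1 = b.add_draw(a, base + h(hours=1), Site.CENTRAL, (path,), 14.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=49)), path, 1000.0))
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_tip_48h")

    # 5. temperature exactly 38.0: symptom absent (strict threshold)
    a = new_adm("TEMP38", base, base + h(days=4))
    d1 = b.add_draw(a, base + h(hours=1), Site.UNSPECIFIED, (com,), 18.0)
    d2 = b.add_draw(a, base + h(hours=25), Site.UNSPECIFIED, (com,), 21.0)
    b.vitals.append(VitalObservation(a, _minute(base + h(hours=2)), VitalKind.TEMPERATURE, 38.0))
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=5)), com, 5000.0))
    b.set_truth(d1, a, ref=False, ha=False, alg1=False, alg2=True, recipe="edge_temp_38")
    b.set_truth(d2, a, ref=False, ha=False, alg1=False, alg2=False, recipe="pair_second_draw")

    # 6. DBP exactly 60: symptom present (inclusive threshold)
    a = new_adm("DBP60", base, base + h(days=4))
    d1 = b.add_draw(a, base + h(hours=1), Site.UNSPECIFIED, (com,), 18.0)
    d2 = b.add_draw(a, base + h(hours=25), Site.UNSPECIFIED, (com,), 21.0)
    b.vitals.append(VitalObservation(a, _minute(base), VitalKind.DBP, 60.0))
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=5)), com, 5000.0))
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_dbp_60")
    b.set_truth(d2, a, ref=False, ha=False, alg1=False, alg2=False, recipe="pair_second_draw")

    # 7a. RIT: second positive on day 14 -> new episode (window expired)
    a = new_adm("RIT14", base, base + h(days=17))
    d1 = b.add_draw(a, base + h(hours=1), Site.CENTRAL, (path,), 9.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=3)), path, 3000.0))
    d2 = b.add_draw(a, base + h(days=14, hours=1), Site.CENTRAL, (path,), 9.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(days=14, hours=3)), path, 3000.0))
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_rit_index")
    b.set_truth(d2, a, ref=True, ha=True, alg1=True, alg2=True, recipe="edge_rit_day14")

    # 7b. RIT: second positive on day 13 -> suppressed
    a = new_adm("RIT13", base, base + h(days=16))
    d1 = b.add_draw(a, base + h(hours=1), Site.CENTRAL, (path,), 9.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=3)), path, 3000.0))
    d2 = b.add_draw(a, base + h(days=13, hours=1), Site.CENTRAL, (path,), 9.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(days=13, hours=3)), path, 3000.0))
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_rit_index")
    b.set_truth(d2, a, ref=False, ha=False, alg1=False, alg2=False, recipe="edge_rit_day13_suppressed")

    # 8a. day-2 episode, previous discharge exactly 48 h before admission -> HA
    prior_admit = base - h(days=10)
    new_adm("READM48_PRIOR", prior_admit, base - h(hours=48), patient="EPRA")
    a = new_adm("READM48", base, base + h(days=4), patient="EPRA")
    d1 = b.add_draw(a, base + h(hours=26), Site.CENTRAL, (path,), 12.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=28)), path, 4000.0))
    b.set_truth(d1, a, ref=True, ha=True, alg1=True, alg2=True, recipe="edge_readmission_48h")

    # 8b. day-2 episode, previous discharge 72 h before admission -> not HA
    new_adm("READM72_PRIOR", prior_admit, base - h(hours=72), patient="EPRB")
    a = new_adm("READM72", base, base + h(days=4), patient="EPRB")
    d1 = b.add_draw(a, base + h(hours=26), Site.CENTRAL, (path,), 12.0)
    b.tips.append(CvcTipCulture(a, _minute(base + h(hours=28)), path, 4000.0))
    b.set_truth(d1, a, ref=True, ha=False, alg1=True, alg2=True, recipe="edge_readmission_72h")

    merged = CohortBundle(
        admissions=bundle.admissions + b.admissions,
        blood_cultures=bundle.blood_cultures + b.draws,
        tip_cultures=bundle.tip_cultures + b.tips,
        vitals=bundle.vitals + b.vitals,
        commensal_list=bundle.commensal_list,
    )
    new_truth_rows = list(truth.rows)
    # prior admissions of the readmission fixtures have no draws: they count
    # as potential episodes of their own and are negative
    existing = {r.episode_id for r in truth.rows}
    for ep in enumerate_potential_episodes(merged):
        if ep.episode_id in existing:
            continue
        row = b.truth.get(ep.episode_id)
        if row is None:
            row = TruthRow(ep.episode_id, ep.admission_id, False, False,
                           False, False, False, False, "edge_no_bcx_admission")
        new_truth_rows.append(row)
    merged_truth = GroundTruth(new_truth_rows)
    merged.reference_labels = merged_truth.reference_labels()
    merged.validate()
    return merged, merged_truth


# ---------------------------------------------------------------------------
# Group-structured bundle (fixed episode counts)
# ---------------------------------------------------------------------------


def generate_group_structured(
    n_pos_admissions: int,
    n_pos_draws: int,
    n_neg_admissions: int,
    n_neg_draws: int,
    n_no_bcx_admissions: int,
    seed: int = 0,
) -> CohortBundle:
    """Minimal bundle with exact per-stratum admission and draw counts.

    Admissions in the positive stratum each receive at least one positive
    draw, with the remaining draws distributed round-robin (positive draws
    carry a background pathogen); the negative stratum receives only
    negative draws; the last stratum has no draws. Useful for checking
    episode enumeration against a known design: the number of potential
    episodes is ``n_pos_draws + n_neg_draws + n_no_bcx_admissions``.
    """
    if n_pos_draws < n_pos_admissions or (n_neg_admissions > 0 and n_neg_draws < n_neg_admissions):
        raise ValueError("each admission with blood cultures needs at least one draw")
    rng = np.random.default_rng(seed)
    commensals = CommensalList.default()
    b = _Builder(commensals)
    start = dt.datetime(2018, 1, 1, 8, 0)

    def _add_admissions(n: int, prefix: str) -> list[Admission]:
        adms = []
        for i in range(n):
            admit = _minute(start + dt.timedelta(minutes=float(rng.uniform(0, 365 * 1440))))
            adm = Admission(f"{prefix}{i:05d}", f"P{prefix}{i:05d}", admit,
                            _minute(admit + dt.timedelta(days=7)))
            adms.append(adm)
            b.admissions.append(adm)
        return adms

    pos_adms = _add_admissions(n_pos_admissions, "GP")
    neg_adms = _add_admissions(n_neg_admissions, "GN")
    _add_admissions(n_no_bcx_admissions, "GZ")

    for k in range(n_pos_draws):
        adm = pos_adms[k % n_pos_admissions]
        ts = adm.admit_ts + dt.timedelta(hours=1 + (k // n_pos_admissions) * 3)
        if k < n_pos_admissions or rng.random() < 0.3:
            code = str(rng.choice(BACKGROUND_PATHOGENS))
            b.add_draw(adm.admission_id, ts, Site.UNSPECIFIED, (code,),
                       round(float(rng.uniform(6, 72)), 2))
        else:
            b.add_draw(adm.admission_id, ts, Site.UNSPECIFIED, (), None)
    for k in range(n_neg_draws):
        adm = neg_adms[k % n_neg_admissions]
        ts = adm.admit_ts + dt.timedelta(hours=1 + (k // n_neg_admissions) * 3)
        b.add_draw(adm.admission_id, ts, Site.UNSPECIFIED, (), None)

    return CohortBundle(
        admissions=b.admissions,
        blood_cultures=b.draws,
        tip_cultures=[],
        vitals=[],
        commensal_list=commensals,
    ).validate()
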