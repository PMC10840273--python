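"""Diagnostic-accuracy statistics for surveillance validation.

Implements the evaluation pipeline used to validate an automated rule
against a manual reference standard on per-episode labels:

* 2x2 confusion matrices and the usual binary metrics (sensitivity,
  specificity, PPV, NPV), with Wilson score confidence intervals;
* Cohen's kappa as chance-corrected agreement;
* AUROC of a single-threshold binary rule, defined as balanced accuracy
  (the trapezoid through the one operating point);
* stratified extrapolation from a validation sample to a target cohort,
  scaling each 2x2 cell by the per-stratum target/sampled episode ratio;
* percentile bootstrap confidence intervals where resampling is performed
  *before* extrapolation, within each stratum;
* rate tables against multiple denominators and a binned incidence time
  series per 1000 in-patient hospital-days.

Point estimates are computed at full precision; reporting helpers round
half-up to the printed precision (3 decimals for metrics, 2 for rates).
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .ehr_model import Admission, ReferenceLabel
from .surveillance import EpisodeLabel


class UndefinedMetricError(ZeroDivisionError):
    """A metric's defining marginal is zero; the value is undefined, not 0."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class Metric(str, enum.Enum):
    SENSITIVITY = "sensitivity"
    SPECIFICITY = "specificity"
    PPV = "ppv"
    NPV = "npv"
    KAPPA = "kappa"
    AUROC = "auroc"


class CiMethod(str, enum.Enum):
    WILSON = "wilson"
    BOOTSTRAP_PERCENTILE = "bootstrap_percentile"
    NONE = "none"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 episode counts; cells may be real-valued after extrapolation."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    metric_name: Metric
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: CiMethod = CiMethod.NONE

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low - 1e-12 <= self.point <= self.ci_high + 1e-12):
                raise ValueError("point estimate outside its confidence interval")


class Group(str, enum.Enum):
    """Sampling strata of the validation design."""

    POS_BCX = "pos_bcx"  # admissions with at least one positive blood culture
    NEG_BCX = "neg_bcx"  # admissions with only negative blood cultures
    NO_BCX = "no_bcx"  # admissions without any blood culture


@dataclass(frozen=True)
class GroupSamplingFrame:
    group: Group
    n_sampled_episodes: int
    n_target_episodes: int

    def __post_init__(self) -> None:
        if self.n_sampled_episodes <= 0:
            raise ValueError("n_sampled_episodes must be positive")
        if self.n_sampled_episodes > self.n_target_episodes:
            raise ValueError("cannot sample more episodes than the target contains")

    @property
    def scale(self) -> float:
        return self.n_target_episodes / self.n_sampled_episodes


# ---------------------------------------------------------------------------
# Confusion matrix and point metrics
# ---------------------------------------------------------------------------


def build_confusion(
    predicted: Mapping[str, bool] | Sequence[EpisodeLabel],
    reference: Mapping[str, bool] | Sequence[ReferenceLabel],
    *,
    on: str = "cvc_bsi",
) -> ConfusionMatrix:
    """Cross-tabulate predicted against reference labels aligned on episode id.

    ``on`` selects the flag compared when label objects are given
    (``cvc_bsi`` or ``ha``). The two label sets must cover exactly the same
    episodes; any mismatch is fatal.
    """
    pred = _as_bool_map(predicted, on)
    ref = _as_bool_map(reference, on)
    if set(pred) != set(ref):
        missing = sorted(set(ref) ^ set(pred))[:5]
        raise ValueError(f"episode ids do not align; e.g. {missing}")
    tp = fp = fn = tn = 0
    for eid, p in pred.items():
        r = ref[eid]
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif r:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def _as_bool_map(labels, on: str) -> dict[str, bool]:
    if isinstance(labels, Mapping):
        return dict(labels)
    return {l.episode_id: bool(getattr(l, on)) for l in labels}


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{what} undefined: zero marginal")
    return num / den


def binary_metrics(cm: ConfusionMatrix) -> dict[Metric, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV point estimates (no CIs)."""
    values = {
        Metric.SENSITIVITY: _ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        Metric.SPECIFICITY: _ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        Metric.PPV: _ratio(cm.tp, cm.tp + cm.fp, "PPV"),
        Metric.NPV: _ratio(cm.tn, cm.tn + cm.fn, "NPV"),
    }
    return {m: MetricEstimate(m, v) for m, v in values.items()}


def wilson_ci(successes: float, n: float, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise UndefinedMetricError("Wilson interval undefined for n = 0")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(low), float(high)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement of the 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed agreement and
    p_e the agreement expected from the row/column marginals. Works on
    real-valued (extrapolated) cells.
    """
    n = cm.total
    if n <= 0:
        raise UndefinedMetricError("kappa undefined for an empty table")
    p_o = (cm.tp + cm.tn) / n
    pred_pos, ref_pos = cm.tp + cm.fp, cm.tp + cm.fn
    p_e = (pred_pos * ref_pos + (n - pred_pos) * (n - ref_pos)) / (n * n)
    if p_e == 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def auroc_binary(cm: ConfusionMatrix) -> float:
    """AUROC of a single-threshold binary rule: (sensitivity + specificity)/2.

    With one operating point the ROC curve is the trapezoid through
    (1-specificity, sensitivity), whose area is the balanced accuracy.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    return (sens + spec) / 2.0


def metrics_with_wilson(cm: ConfusionMatrix, level: float = 0.95) -> dict[Metric, MetricEstimate]:
    """All six validation metrics; binomial ones get Wilson score CIs."""
    denoms = {
        Metric.SENSITIVITY: (cm.tp, cm.tp + cm.fn),
        Metric.SPECIFICITY: (cm.tn, cm.tn + cm.fp),
        Metric.PPV: (cm.tp, cm.tp + cm.fp),
        Metric.NPV: (cm.tn, cm.tn + cm.fn),
    }
    out: dict[Metric, MetricEstimate] = {}
    for m, (k, n) in denoms.items():
        point = _ratio(k, n, m.value)
        low, high = wilson_ci(k, n, level)
        out[m] = MetricEstimate(m, point, low, high, CiMethod.WILSON)
    out[Metric.KAPPA] = MetricEstimate(Metric.KAPPA, cohens_kappa(cm))
    out[Metric.AUROC] = MetricEstimate(Metric.AUROC, auroc_binary(cm))
    return out


# ---------------------------------------------------------------------------
# Stratified extrapolation and bootstrap
# ---------------------------------------------------------------------------


def extrapolate_counts(
    per_group_cms: Mapping[Group, ConfusionMatrix],
    frames: Mapping[Group, GroupSamplingFrame],
) -> ConfusionMatrix:
    """Scale each stratum's 2x2 cells to its target size and sum.

    Every cell is multiplied by the stratum's target/sampled episode ratio;
    the resulting cells are real-valued and are *not* rounded before metric
    computation.
    """
    tp = fp = fn = tn = 0.0
    for group, cm in per_group_cms.items():
        if cm.total == 0:
            continue
        frame = frames.get(group)
        if frame is None:
            raise ValueError(f"sampling frame missing for non-empty group {group.value}")
        s = frame.scale
        tp += cm.tp * s
        fp += cm.fp * s
        fn += cm.fn * s
        tn += cm.tn * s
    return ConfusionMatrix(tp, fp, fn, tn)


_CELLS = ("tp", "fp", "fn", "tn")


def _metric_from_cell_arrays(
    metric: Metric, tp: np.ndarray, fp: np.ndarray, fn: np.ndarray, tn: np.ndarray
) -> np.ndarray:
    """Vectorised metric over replicate cell arrays; NaN where undefined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric is Metric.SENSITIVITY:
            return _safe_div(tp, tp + fn)
        if metric is Metric.SPECIFICITY:
            return _safe_div(tn, tn + fp)
        if metric is Metric.PPV:
            return _safe_div(tp, tp + fp)
        if metric is Metric.NPV:
            return _safe_div(tn, tn + fn)
        if metric is Metric.AUROC:
            return (_safe_div(tp, tp + fn) + _safe_div(tn, tn + fp)) / 2.0
        if metric is Metric.KAPPA:
            n = tp + fp + fn + tn
            p_o = _safe_div(tp + tn, n)
            p_e = _safe_div((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn), n * n)
            out = _safe_div(p_o - p_e, 1.0 - p_e)
            return out
    raise ValueError(f"unknown metric {metric}")


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    num = np.asarray(num, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


@dataclass(frozen=True)
class BootstrapResult:
    estimate: MetricEstimate
    n_reps: int
    n_undefined: int  # replicates dropped because the metric was undefined


def bootstrap_extrapolated_ci(
    labels_by_group: Mapping[Group, Mapping[str, tuple[bool, bool]]],
    frames: Mapping[Group, GroupSamplingFrame],
    metric: Metric,
    reps: int = 10_000,
    seed: int = 20240205,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI for an extrapolated metric.

    ``labels_by_group`` maps each stratum to ``episode_id -> (predicted,
    reference)`` label pairs. Per replicate, episodes are resampled with
    replacement within each stratum (at the stratum's sampled size) — drawn
    as a multinomial over the observed 2x2 cell proportions, which is the
    exact resampling distribution of the cells — then the cells are
    extrapolated to the target cohort and the metric is recomputed. The CI
    is the empirical (1-level)/2 and 1-(1-level)/2 percentile pair;
    resampling happens *before* extrapolation. Deterministic under a fixed
    seed. Replicates where the metric is undefined are dropped and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)

    tp = np.zeros(reps)
    fp = np.zeros(reps)
    fn = np.zeros(reps)
    tn = np.zeros(reps)
    point_cells: dict[Group, ConfusionMatrix] = {}
    for group, pairs in labels_by_group.items():
        if not pairs:
            continue
        cm = build_confusion(
            {e: p for e, (p, _) in pairs.items()},
            {e: r for e, (_, r) in pairs.items()},
        )
        point_cells[group] = cm
        frame = frames.get(group)
        if frame is None:
            raise ValueError(f"sampling frame missing for non-empty group {group.value}")
        n = int(cm.total)
        probs = np.array([cm.tp, cm.fp, cm.fn, cm.tn]) / n
        counts = rng.multinomial(n, probs, size=reps).astype(float) * frame.scale
        tp += counts[:, 0]
        fp += counts[:, 1]
        fn += counts[:, 2]
        tn += counts[:, 3]

    values = _metric_from_cell_arrays(metric, tp, fp, fn, tn)
    defined = values[~np.isnan(values)]
    n_undefined = int(reps - defined.size)
    if defined.size == 0:
        raise UndefinedMetricError(f"{metric.value} undefined in every replicate")

    alpha = 1 - level
    low, high = np.percentile(defined, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    extrapolated = extrapolate_counts(point_cells, frames)
    cm_arrays = tuple(
        np.array([getattr(extrapolated, c)]) for c in _CELLS
    )
    point = float(_metric_from_cell_arrays(metric, *cm_arrays)[0])
    if math.isnan(point):
        raise UndefinedMetricError(f"{metric.value} undefined at the point estimate")
    # Percentiles of a finite resample can sit on either side of the analytic
    # point; clamp the interval to contain it.
    low = min(float(low), point)
    high = max(float(high), point)
    return BootstrapResult(
        MetricEstimate(metric, point, low, high, CiMethod.BOOTSTRAP_PERCENTILE),
        n_reps=reps,
        n_undefined=n_undefined,
    )


# ---------------------------------------------------------------------------
# Rates and incidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateTable:
    """Case counts expressed against the standard surveillance denominators.

    Percentage rates (potential episodes, positive blood cultures,
    admissions) are reported to 2 decimals; the hospital-day rate is per
    1000 in-patient hospital-days, also to 2 decimals.
    """

    numerator: int
    denominators: dict[str, float]
    rates: dict[str, float]


PER_MILLE_DENOMS = {"hospital_days"}


def rates_table(case_count: int, denominators: Mapping[str, float]) -> RateTable:
    """Express a case count against each denominator.

    Denominators named in ``PER_MILLE_DENOMS`` are scaled per 1000; all
    others are percentages. A zero denominator makes that rate undefined.
    """
    rates: dict[str, float] = {}
    for name, den in denominators.items():
        if den <= 0:
            raise UndefinedMetricError(f"rate against {name!r} undefined: zero denominator")
        scale = 1000.0 if name in PER_MILLE_DENOMS else 100.0
        rates[name] = round_half_up(case_count / den * scale, 2)
    return RateTable(case_count, dict(denominators), rates)


def hospital_days(admission: Admission) -> int:
    """Whole-day length of stay (discharge date minus admit date), minimum 1."""
    return max((admission.discharge_ts.date() - admission.admit_ts.date()).days, 1)


def _stay_dates(admission: Admission) -> Iterable[dt.date]:
    d0 = admission.admit_ts.date()
    n = hospital_days(admission)
    for i in range(n):
        yield d0 + dt.timedelta(days=i)


def incidence_series(
    labels: Sequence[EpisodeLabel],
    admissions: Sequence[Admission],
    bin_width: str = "month",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Binned incidence of CVC-BSI per 1000 in-patient hospital-days.

    Per calendar bin (default month): the numerator counts CVC-BSI episodes
    (and, separately, HA episodes) anchored in the bin; the denominator is
    the hospital-days contributed to the bin by overlapping stays, with
    stays spanning a bin boundary split day by day. Returns the per-bin
    table and the overall rates across the full period.
    """
    if not admissions:
        raise ValueError("incidence requires at least one admission")
    freq = {"month": "M", "quarter": "Q", "year": "Y"}.get(bin_width, bin_width)

    day_rows = []
    for adm in admissions:
        for date in _stay_dates(adm):
            day_rows.append(date)
    days = pd.Series(pd.PeriodIndex(pd.DatetimeIndex(day_rows), freq=freq))
    days_per_bin = days.value_counts().sort_index()

    pos = [l for l in labels if l.cvc_bsi]
    case_bins = pd.PeriodIndex(
        pd.DatetimeIndex([l.anchor_ts for l in pos]), freq=freq
    ) if pos else pd.PeriodIndex([], freq=freq)
    ha_bins = pd.PeriodIndex(
        pd.DatetimeIndex([l.anchor_ts for l in pos if l.ha]), freq=freq
    ) if pos else pd.PeriodIndex([], freq=freq)

    idx = days_per_bin.index
    cases = pd.Series(case_bins).value_counts().reindex(idx, fill_value=0)
    ha_cases = pd.Series(ha_bins).value_counts().reindex(idx, fill_value=0)

    df = pd.DataFrame(
        {
            "bin_start": [p.start_time.date().isoformat() for p in idx],
            "cases": cases.to_numpy(),
            "ha_cases": ha_cases.to_numpy(),
            "hospital_days": days_per_bin.to_numpy(),
        }
    )
    df["rate"] = df["cases"] / df["hospital_days"] * 1000.0
    df["ha_rate"] = df["ha_cases"] / df["hospital_days"] * 1000.0

    total_days = int(days_per_bin.sum())
    overall = {
        "cases": int(len(pos)),
        "ha_cases": int(sum(1 for l in pos if l.ha)),
        "hospital_days": total_days,
        "rate": len(pos) / total_days * 1000.0,
        "ha_rate": sum(1 for l in pos if l.ha) / total_days * 1000.0,
    }
    return df, overall


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------


def episode_groups(bundle) -> dict[str, Group]:
    """Assign every potential episode of a bundle to its sampling stratum.

    Episodes of admissions with at least one positive draw belong to
    ``pos_bcx``; episodes of admissions with only negative draws to
    ``neg_bcx``; culture-free admissions to ``no_bcx``.
    """
    from .surveillance import enumerate_potential_episodes

    draws_by_adm = bundle.draws_by_admission()
    adm_group: dict[str, Group] = {}
    for adm_id, draws in draws_by_adm.items():
        if not draws:
            adm_group[adm_id] = Group.NO_BCX
        elif any(d.is_positive for d in draws):
            adm_group[adm_id] = Group.POS_BCX
        else:
            adm_group[adm_id] = Group.NEG_BCX
    return {
        ep.episode_id: adm_group[ep.admission_id]
        for ep in enumerate_potential_episodes(bundle)
    }
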