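"""Synthetic patient-level trial data calibrated to the published cost and
utility summaries of an eHealth follow-up trial after acute myocardial
infarction.

The original trial (two arms of 100 patients enrolled, 88/92 analysed after
a modified intention-to-treat filter) deposited no patient-level data.  This
module generates datasets with the statistical structure the downstream
analysis assumes, calibrated so that in expectation they reproduce the
published per-item resource-use frequencies, per-patient mean +/- SD costs,
and per-timepoint utility means.

Cost model per resource item (two-part, frequency x severity):

* ``deterministic`` items are incurred exactly once by every patient in the
  arm at a fixed price (the home-monitoring kit, its allocated support).
* ``scheduled`` items (outpatient visits, Holter, echocardiography) are
  incurred by essentially every patient; the per-patient annual cost is
  drawn from a gamma distribution matched to the published per-patient
  mean and SD.
* ``event`` items (admissions, emergency visits, revascularisations) follow
  a two-part model: a Bernoulli incidence with probability equal to the
  published event count divided by the arm size, times a gamma
  cost-per-event whose mean and SD are solved so the per-patient cost
  matches the published mean and SD exactly in expectation.

Utilities at months 1/6/12 are drawn from an exchangeable-correlation
multivariate normal clipped to [0, 1]; the latent means are numerically
compensated so the post-clip marginal means equal the configured targets.
Missingness is MAR: the per-timepoint missingness probability depends on
age and on the most recent observed utility.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

INTERVENTION = "intervention"
CONTROL = "control"
ARMS = (INTERVENTION, CONTROL)

TIMEPOINTS_MONTHS = (1.0, 6.0, 12.0)
UTILITY_COLUMNS = ("u1", "u6", "u12")

#: MAR missingness: logit-free linear tilt of the base probability by age
#: (older patients answer web questionnaires less often) and by the last
#: observed utility (sicker patients respond less often).
MISSING_AGE_SLOPE = 0.004   # per year of age away from 60
MISSING_UTILITY_SLOPE = -0.3  # per utility unit away from 0.7


class ConfigurationError(ValueError):
    """Raised when generator parameters are infeasible or inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmItemParams:
    """Calibration targets for one resource item in one arm.

    ``mean``/``sd`` are the target per-patient annual cost in 2020 euros;
    ``event_prob`` is the Bernoulli incidence for ``event`` items (``None``
    for items incurred by every patient); ``count_mean`` is the expected
    number of occurrences per patient (drives patient-related visit costs,
    not department costs).
    """

    mean: float
    sd: float = 0.0
    event_prob: Optional[float] = None
    count_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0 or self.count_mean < 0:
            raise ConfigurationError(
                f"negative cost/count parameter: {self}")
        if self.event_prob is not None and not 0.0 <= self.event_prob <= 1.0:
            raise ConfigurationError(
                f"event probability outside [0, 1]: {self.event_prob}")


ItemKind = Literal["deterministic", "scheduled", "event"]


@dataclass(frozen=True)
class ItemModel:
    """Two-part cost model for one resource item, both arms."""

    item_id: str
    kind: ItemKind
    arms: Mapping[str, ArmItemParams]

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.arms:
                raise ConfigurationError(
                    f"item {self.item_id!r} missing parameters for arm {arm!r}")
        if self.kind == "event":
            for arm, p in self.arms.items():
                if p.mean > 0 and (p.event_prob is None or p.event_prob == 0):
                    raise ConfigurationError(
                        f"event item {self.item_id!r} arm {arm!r} has positive "
                        "mean cost but no event probability")


@dataclass(frozen=True)
class CovariateModel:
    """Baseline covariate distributions for the simulated AMI population."""

    age_mean: float = 59.0
    age_sd: float = 9.5
    age_min: float = 30.0
    age_max: float = 90.0
    male_prob: float = 0.78
    stemi_prob: float = 0.55
    log_troponin_mean: float = 7.2   # peak troponin, arbitrary units
    log_troponin_sd: float = 1.0


@dataclass(frozen=True)
class TrialConfig:
    """All generator parameters for one synthetic trial."""

    n_enrolled_per_arm: Mapping[str, int]
    dropout_counts: Mapping[str, int]
    item_models: Sequence[ItemModel]
    utility_means: Mapping[str, tuple[float, float, float]]
    utility_sd: float
    utility_correlation: float
    missing_prob: float
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for arm in ARMS:
            n = self.n_enrolled_per_arm[arm]
            d = self.dropout_counts[arm]
            if d < 0 or n < d:
                raise ConfigurationError(
                    f"arm {arm!r}: dropout count {d} exceeds enrolment {n}")
            for u in self.utility_means[arm]:
                if not 0.0 <= u <= 1.0:
                    raise ConfigurationError(f"utility mean {u} outside [0, 1]")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ConfigurationError("missing_prob must be in [0, 1)")
        if not 0.0 <= self.utility_correlation < 1.0:
            raise ConfigurationError("utility_correlation must be in [0, 1)")
        if self.utility_sd < 0:
            raise ConfigurationError("utility_sd must be nonnegative")


@dataclass(frozen=True)
class UtilityTrajectory:
    """Health utilities at months 1, 6 and 12; ``None`` marks a missing value."""

    u1: Optional[float]
    u6: Optional[float]
    u12: Optional[float]

    def as_tuple(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.u1, self.u6, self.u12)

    @property
    def complete(self) -> bool:
        return all(u is not None for u in self.as_tuple())


@dataclass
class PatientRecord:
    """One trial participant."""

    patient_id: str
    arm: str
    dropout_flag: bool
    age: float
    sex: str                  # "male" / "female"
    index_event: str          # "STEMI" / "NSTEMI"
    troponin: float
    item_counts: dict[str, int]
    item_costs: dict[str, float]
    utilities: UtilityTrajectory


# ---------------------------------------------------------------------------
# Default configuration: calibration to the published Table 2 summaries
# ---------------------------------------------------------------------------

#: Analysed arm sizes after the modified-ITT filter; the published per-item
#: event counts are divided by these to obtain frequencies.
_N_ANALYSED = {INTERVENTION: 88, CONTROL: 92}

# (item_id, kind, (int mean, int sd, int events), (ctl mean, ctl sd, ctl events))
# Event counts for the single-vessel PCI row are arm-swapped relative to the
# published table: only 4 intervention / 10 control events reproduce the
# published per-patient means from the published unit price (5999*4/88 = 273,
# 5999*10/92 = 652); the printed counts appear transposed.
_TABLE2_CALIBRATION = [
    ("the_box",            "deterministic", (318.0, 0.0, 88),   (0.0, 0.0, 0)),
    ("e_visit",            "scheduled",     (34.0, 13.0, 148),  (0.0, 0.0, 0)),
    ("in_office",          "scheduled",     (146.0, 58.0, 181), (288.0, 46.0, 373)),
    ("holter",             "scheduled",     (196.0, 108.0, 89), (360.0, 84.0, 171)),
    ("tte",                "scheduled",     (151.0, 76.0, 100), (256.0, 58.0, 178)),
    ("stress_echo",        "scheduled",     (468.0, 204.0, 76), (500.0, 144.0, 85)),
    ("emergency",          "event",         (38.0, 104.0, 12),  (75.0, 221.0, 25)),
    ("hospitalization",    "event",         (139.0, 697.0, 18), (186.0, 984.0, 25)),
    ("catheterization",    "event",         (308.0, 745.0, 13), (499.0, 946.0, 22)),
    ("single_vessel_pci",  "event",         (273.0, 1256.0, 4), (652.0, 2077.0, 10)),
    ("multivessel_pci",    "event",         (146.0, 963.0, 2),  (69.0, 670.0, 1)),
    # allocated in-hospital + vendor technical support: (15367 + 1758) / 88
    ("box_support",        "deterministic", ((15367.0 + 1758.0) / 88, 0.0, 88),
                                            (0.0, 0.0, 0)),
]


def default_config() -> TrialConfig:
    """Configuration calibrated to the published trial summaries.

    Item frequencies and per-patient mean costs reproduce the published
    per-item table in expectation (arm totals 2412/2885 euros, matching the
    published 2417/2888 up to the table's own rounding).  Utility means are
    the calibrated triples (0.745, 0.740, 0.735) intervention and
    (0.710, 0.685, 0.680) control, whose trapezoidal one-year QALYs are
    0.740 and 0.691 — the published 0.74 / 0.69.
    """
    items = []
    for item_id, kind, p_int, p_ctl in _TABLE2_CALIBRATION:
        arms = {}
        for arm, (mean, sd, events) in ((INTERVENTION, p_int), (CONTROL, p_ctl)):
            n = _N_ANALYSED[arm]
            count_mean = events / n
            event_prob = min(count_mean, 1.0) if kind == "event" else None
            arms[arm] = ArmItemParams(mean=mean, sd=sd, event_prob=event_prob,
                                      count_mean=count_mean)
        items.append(ItemModel(item_id=item_id, kind=kind, arms=arms))
    return TrialConfig(
        n_enrolled_per_arm={INTERVENTION: 100, CONTROL: 100},
        dropout_counts={INTERVENTION: 12, CONTROL: 8},
        item_models=tuple(items),
        utility_means={INTERVENTION: (0.745, 0.740, 0.735),
                       CONTROL: (0.710, 0.685, 0.680)},
        utility_sd=0.18,
        utility_correlation=0.6,
        missing_prob=0.2,
        covariate_model=CovariateModel(),
        seed=0,
    )


# ---------------------------------------------------------------------------
# Cost draws
# ---------------------------------------------------------------------------

def solve_event_severity(mean: float, sd: float, event_prob: float
                         ) -> tuple[float, float]:
    """Cost-per-event (mean, sd) such that Bernoulli(p) x severity has the
    target per-patient mean and SD.

    With incidence ``p`` and severity mean ``mu_c``, the per-patient mean is
    ``p * mu_c`` and the variance is ``p * (sd_c^2 + mu_c^2) - (p * mu_c)^2``;
    inverting gives ``mu_c = mean / p`` and
    ``sd_c^2 = sd^2 / p - (1 - p) * mu_c^2``.
    """
    if mean == 0:
        return 0.0, 0.0
    if event_prob <= 0:
        raise ConfigurationError(
            "positive mean cost requires a positive event probability")
    mu_c = mean / event_prob
    var_c = sd ** 2 / event_prob - (1.0 - event_prob) * mu_c ** 2
    if var_c < 0:
        raise ConfigurationError(
            f"per-patient SD {sd} is infeasible at event probability "
            f"{event_prob} (implied severity variance {var_c:.1f} < 0); "
            "increase the event probability")
    return mu_c, float(np.sqrt(var_c))


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float,
                size: int) -> np.ndarray:
    """Gamma draws with the given mean and SD; degenerate at ``mean`` if sd=0."""
    if mean == 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size=size)


def _draw_item(rng: np.random.Generator, model: ItemModel, arm: str,
               n: int) -> tuple[np.ndarray, np.ndarray]:
    """(counts, costs) for one item across the ``n`` patients of one arm."""
    p = model.arms[arm]
    if model.kind == "deterministic":
        count = int(round(p.count_mean)) if p.count_mean > 0 else (1 if p.mean > 0 else 0)
        counts = np.full(n, count if p.mean > 0 else 0, dtype=int)
        costs = np.full(n, p.mean)
        return counts, costs
    if model.kind == "scheduled":
        # Scheduled care: counts are low-variance (base + Bernoulli remainder),
        # per-patient cost calibrated directly to the published mean +/- SD.
        base = int(np.floor(p.count_mean))
        frac = p.count_mean - base
        counts = base + (rng.random(n) < frac).astype(int)
        costs = _gamma_draw(rng, p.mean, p.sd, n)
        return counts, costs
    # event: Bernoulli incidence x gamma severity
    prob = p.event_prob or 0.0
    mu_c, sd_c = solve_event_severity(p.mean, p.sd, prob) if p.mean > 0 else (0.0, 0.0)
    incurred = rng.random(n) < prob
    costs = np.where(incurred, _gamma_draw(rng, mu_c, sd_c, n), 0.0) if mu_c > 0 \
        else np.zeros(n)
    return incurred.astype(int), costs


# ---------------------------------------------------------------------------
# Utility draws
# ---------------------------------------------------------------------------

def _clipped_normal_mean(mu: float, sigma: float) -> float:
    """Mean of min(max(X, 0), 1) for X ~ N(mu, sigma^2)."""
    if sigma == 0:
        return float(np.clip(mu, 0.0, 1.0))
    a = (0.0 - mu) / sigma
    b = (1.0 - mu) / sigma
    phi_a, phi_b = stats.norm.pdf(a), stats.norm.pdf(b)
    cdf_a, cdf_b = stats.norm.cdf(a), stats.norm.cdf(b)
    return float(1.0 * (1.0 - cdf_b)
                 + mu * (cdf_b - cdf_a)
                 + sigma * (phi_a - phi_b))


def latent_utility_mean(target: float, sigma: float) -> float:
    """Latent normal mean whose [0,1]-clipped expectation equals ``target``."""
    if sigma == 0:
        return target
    lo, hi = target - 5 * sigma, target + 5 * sigma
    return float(optimize.brentq(
        lambda mu: _clipped_normal_mean(mu, sigma) - target, lo, hi, xtol=1e-12))


def _draw_utilities(rng: np.random.Generator, means: Sequence[float],
                    sigma: float, rho: float, n: int) -> np.ndarray:
    """n x 3 utilities: exchangeable-correlation MVN clipped to [0, 1] with
    mean-compensated latent locations."""
    latent = np.array([latent_utility_mean(m, sigma) for m in means])
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    cov = sigma ** 2 * corr
    draws = rng.multivariate_normal(latent, cov, size=n, method="cholesky")
    return np.clip(draws, 0.0, 1.0)


def _missingness_mask(rng: np.random.Generator, utilities: np.ndarray,
                      ages: np.ndarray, base_prob: float) -> np.ndarray:
    """MAR mask (True = missing), depending on age and the most recent
    observed utility; never on the value being deleted."""
    n, t = utilities.shape
    mask = np.zeros((n, t), dtype=bool)
    if base_prob == 0:
        return mask
    last_observed = np.full(n, np.nan)
    for j in range(t):
        tilt = MISSING_AGE_SLOPE * (ages - 60.0)
        prev = np.where(np.isnan(last_observed), 0.0,
                        MISSING_UTILITY_SLOPE * (last_observed - 0.7))
        prob = np.clip(base_prob + tilt + prev, 0.0, 0.95)
        mask[:, j] = rng.random(n) < prob
        last_observed = np.where(mask[:, j], last_observed, utilities[:, j])
    return mask


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def generate_trial(config: TrialConfig, seed: Optional[int] = None
                   ) -> list[PatientRecord]:
    """Generate one synthetic trial: enrolled patients in both arms, with
    dropout flags on exactly the configured counts.

    Dropout patients (withdrew within two weeks, excluded by the
    modified-ITT filter) carry no follow-up resource use and no utilities.
    Fully reproducible given ``seed`` (defaults to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = config.covariate_model
    records: list[PatientRecord] = []
    for arm in ARMS:
        n = config.n_enrolled_per_arm[arm]
        n_drop = config.dropout_counts[arm]
        ages = np.clip(rng.normal(cov.age_mean, cov.age_sd, n),
                       cov.age_min, cov.age_max)
        male = rng.random(n) < cov.male_prob
        stemi = rng.random(n) < cov.stemi_prob
        troponin = rng.lognormal(cov.log_troponin_mean, cov.log_troponin_sd, n)
        dropout = np.zeros(n, dtype=bool)
        dropout[rng.choice(n, size=n_drop, replace=False)] = True

        item_counts = {}
        item_costs = {}
        for model in config.item_models:
            counts, costs = _draw_item(rng, model, arm, n)
            counts[dropout] = 0
            costs = np.where(dropout, 0.0, costs)
            item_counts[model.item_id] = counts
            item_costs[model.item_id] = costs

        utilities = _draw_utilities(rng, config.utility_means[arm],
                                    config.utility_sd,
                                    config.utility_correlation, n)
        miss = _missingness_mask(rng, utilities, ages, config.missing_prob)

        prefix = "I" if arm == INTERVENTION else "C"
        for i in range(n):
            if dropout[i]:
                traj = UtilityTrajectory(None, None, None)
            else:
                vals = [None if miss[i, j] else float(utilities[i, j])
                        for j in range(3)]
                traj = UtilityTrajectory(*vals)
            records.append(PatientRecord(
                patient_id=f"{prefix}{i + 1:03d}",
                arm=arm,
                dropout_flag=bool(dropout[i]),
                age=float(ages[i]),
                sex="male" if male[i] else "female",
                index_event="STEMI" if stemi[i] else "NSTEMI",
                troponin=float(troponin[i]),
                item_counts={k: int(v[i]) for k, v in item_counts.items()},
                item_costs={k: float(v[i]) for k, v in item_costs.items()},
                utilities=traj,
            ))
    return records


def apply_mitt_filter(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Modified intention-to-treat population: drop early-dropout patients.

    Patients who died during follow-up are retained (they carry truncated
    utility data, not a dropout flag).  Warns if nothing remains.
    """
    kept = [r for r in records if not r.dropout_flag]
    if records and not kept:
        warnings.warn("modified-ITT filter removed every record",
                      stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# External interfaces: patient-level CSV and YAML config
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patient-level table: one row per patient, item columns prefixed
    ``cost_`` / ``count_``, utilities as ``u1,u6,u12`` (NaN = missing)."""
    item_ids = list(records[0].item_costs) if records else []
    rows = []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id,
            "arm": r.arm,
            "dropout_flag": int(r.dropout_flag),
            "age": r.age,
            "sex": r.sex,
            "index_event": r.index_event,
            "troponin": r.troponin,
        }
        for item in item_ids:
            row[f"count_{item}"] = r.item_counts.get(item, 0)
        for item in item_ids:
            row[f"cost_{item}"] = r.item_costs.get(item, 0.0)
        for col, val in zip(UTILITY_COLUMNS, r.utilities.as_tuple()):
            row[col] = np.nan if val is None else val
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame`."""
    cost_cols = [c for c in frame.columns if c.startswith("cost_")]
    count_cols = [c for c in frame.columns if c.startswith("count_")]
    records = []
    for _, row in frame.iterrows():
        utils = [None if pd.isna(row[c]) else float(row[c])
                 for c in UTILITY_COLUMNS]
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            arm=str(row["arm"]),
            dropout_flag=bool(row["dropout_flag"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            index_event=str(row["index_event"]),
            troponin=float(row["troponin"]),
            item_counts={c[len("count_"):]: int(row[c]) for c in count_cols},
            item_costs={c[len("cost_"):]: float(row[c]) for c in cost_cols},
            utilities=UtilityTrajectory(*utils),
        ))
    return records


def write_records_csv(records: Sequence[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path))


def config_to_yaml(config: TrialConfig) -> str:
    """Serialise a TrialConfig as YAML (key names match the field names)."""
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            d = {f.name: plain(getattr(obj, f.name))
                 for f in dataclasses.fields(obj)}
            if isinstance(obj, ItemModel):
                d["arms"] = {k: plain(v) for k, v in obj.arms.items()}
            return d
        if isinstance(obj, Mapping):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    return yaml.safe_dump(plain(config), sort_keys=False)


def config_from_yaml(text: str) -> TrialConfig:
    """Parse a TrialConfig from YAML produced by :func:`config_to_yaml`."""
    raw = yaml.safe_load(io.StringIO(text))
    items = []
    for it in raw["item_models"]:
        arms = {arm: ArmItemParams(**params) for arm, params in it["arms"].items()}
        items.append(ItemModel(item_id=it["item_id"], kind=it["kind"], arms=arms))
    return TrialConfig(
        n_enrolled_per_arm=dict(raw["n_enrolled_per_arm"]),
        dropout_counts=dict(raw["dropout_counts"]),
        item_models=tuple(items),
        utility_means={k: tuple(v) for k, v in raw["utility_means"].items()},
        utility_sd=float(raw["utility_sd"]),
        utility_correlation=float(raw["utility_correlation"]),
        missing_prob=float(raw["missing_prob"]),
        covariate_model=CovariateModel(**raw.get("covariate_model", {})),
        seed=int(raw.get("seed", 0)),
    )
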