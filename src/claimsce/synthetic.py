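"""Synthetic Medicaid-like claims with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, with every estimand's true value known by construction:

* **Confounded assignment.**  Treatment (the long-acting injectable vs an
  oral atypical agent) follows a Bernoulli draw with logit linear in a
  small set of patient covariates — age, sex, baseline psychiatric
  severity (count of mental-health-institute admissions) and comorbidity
  flags.  Confounding runs only through covariates the propensity model
  observes, so IPTW estimates are consistent by construction; an optional
  unmeasured-confounder switch exists for robustness experiments.
* **Adherence behavior.**  Index-agent fills form a renewal process:
  dispense, cover ``days_supply`` days, wait an extra gap drawn from a
  geometric (or fixed) distribution, refill — with a per-refill
  discontinuation probability.  Ignoring discontinuation, expected PDC is
  the renewal-reward ratio ``s / (s + E[extra gap])`` for supply ``s``.
  The first refill's extra gap is capped so the first two fills fall
  within 90 days, satisfying the index-event definition by construction.
* **Outcomes with known effects.**  Monthly cost per service category is
  a zero-inflated gamma whose mean is ``base_c * m(X) + delta_c * T``
  with a multiplicative covariate term ``m(X)``; the additive deltas sum
  to the true mean monthly cost difference.  Annual event counts are
  Poisson with log-rate linear in covariates plus ``log(RR_true) * T``;
  lengths of stay are ``1 + Poisson`` per event independent of treatment,
  so the true rate ratio for cumulative days equals the one for events.

Two outputs share one sampler: :func:`generate_frame` returns the
patient-level analysis frame (covariates, assignment, per-category
monthly costs and counts) for fast Monte-Carlo work, and
:func:`generate_bundle` materializes the same patients as a full claims
bundle — enrollment spans, diagnosis-carrying medical claims, pharmacy
fills and costed utilization events — for end-to-end pipeline runs.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import codelists
from .claims_io import ClaimsBundle, OAA_CLASSES, PP1M, from_day, to_day

# ---------------------------------------------------------------------------
# Configuration


@dataclasses.dataclass
class CovariateModel:
    age_mean: float = 42.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 80.0
    p_female: float = 0.5
    race_probs: dict = dataclasses.field(
        default_factory=lambda: {"white": 0.55, "black": 0.35, "other": 0.06, "unknown": 0.04}
    )
    state_probs: dict = dataclasses.field(
        default_factory=lambda: {"IA": 0.07, "KS": 0.08, "MS": 0.10, "MO": 0.50, "NJ": 0.25}
    )
    region_probs: dict = dataclasses.field(
        default_factory=lambda: {"urban": 0.55, "suburban": 0.26, "rural": 0.19}
    )
    p_capitated: float = 0.41
    p_dual: float = 0.40
    mhi_rate: float = 0.8  # baseline MHI admissions per year (severity proxy)
    mhi_1day_rate: float = 1.0
    # comorbidity prevalence: base + slope per year of age over 42
    comorb_base: dict = dataclasses.field(
        default_factory=lambda: {
            "diabetes": 0.10,
            "cardiovascular": 0.07,
            "obesity": 0.10,
            "drug_abuse": 0.20,
            "hepatitis_c": 0.03,
            "hiv_aids": 0.012,
        }
    )
    comorb_age_slope: dict = dataclasses.field(
        default_factory=lambda: {"diabetes": 0.004, "cardiovascular": 0.005}
    )


@dataclasses.dataclass
class TreatmentModel:
    """Logistic assignment model; keys name design columns."""

    beta: dict = dataclasses.field(
        default_factory=lambda: {
            "intercept": -0.85,
            "age_c": -0.30,  # age_c = (age - 42) / 10
            "female": -0.30,
            "n_mhi": 0.40,
            "drug_abuse": 0.25,
            "diabetes": -0.15,
            "cardiovascular": -0.15,
        }
    )
    unmeasured_sd: float = 0.0  # optional unobserved logit noise (default off)


@dataclasses.dataclass
class FillModel:
    days_supply: int = 30
    gap_mean_treated: float = 6.0  # mean extra days between supply end and refill
    gap_mean_comparator: float = 12.0
    gap_fixed: Optional[int] = None  # degenerate gap for closed-form checks
    disc_prob_treated: float = 0.04  # per-refill discontinuation probability
    disc_prob_comparator: float = 0.07
    second_fill_gap_cap: int = 55  # keeps fill 2 within 90 days of fill 1
    p_baseline_ap: float = 0.6
    p_second_ap: float = 0.25
    p_anxiolytic: float = 0.35
    p_antidepressant: float = 0.50
    p_mood_stabilizer: float = 0.40


@dataclasses.dataclass
class OutcomeModel:
    # baseline mean monthly cost (reference-year USD) per medical category
    base_monthly: dict = dataclasses.field(
        default_factory=lambda: {
            "inpatient": 600.0,
            "outpatient": 300.0,
            "emergency_room": 80.0,
            "long_term_care": 40.0,
            "mhi_admission": 250.0,
            "mhi_1day": 150.0,
            "home_care": 250.0,
            "other_medical": 100.0,
        }
    )
    # additive true monthly treatment effect per category; sums to the
    # true total-medical mean monthly cost difference
    delta_monthly: dict = dataclasses.field(
        default_factory=lambda: {"inpatient": -135.0, "home_care": -105.0, "mhi_admission": -60.0}
    )
    pharmacy_base: float = 250.0
    delta_pharmacy: float = 322.0
    zero_prob: dict = dataclasses.field(
        default_factory=lambda: {
            "inpatient": 0.35,
            "outpatient": 0.05,
            "emergency_room": 0.30,
            "long_term_care": 0.90,
            "mhi_admission": 0.50,
            "mhi_1day": 0.40,
            "home_care": 0.60,
            "other_medical": 0.40,
        }
    )
    gamma_shape: float = 1.2
    cost_sev_coef: float = 0.18  # m(X) = exp(sev*n_mhi + age*(age-42))
    cost_age_coef: float = 0.008
    # annual event rates per category and true rate ratio
    event_rates: dict = dataclasses.field(
        default_factory=lambda: {
            "inpatient": 0.9,
            "outpatient": 11.0,
            "emergency_room": 2.2,
            "long_term_care": 0.15,
            "mhi_admission": 1.2,
            "mhi_1day": 2.5,
            "home_care": 5.0,
            "other_medical": 1.5,
        }
    )
    rr_true: float = 0.84
    rate_sev_coef: float = 0.15
    los_extra_mean: dict = dataclasses.field(
        default_factory=lambda: {"inpatient": 4.0, "long_term_care": 20.0, "mhi_admission": 5.0}
    )


@dataclasses.dataclass
class EnrollmentModel:
    lead_days: int = 380  # enrollment starts this many days before index
    tail_days: int = 380  # and ends this many days after
    baseline_gap_prob: float = 0.0  # probability of a 30-day baseline gap
    followup_gap_prob: float = 0.0


@dataclasses.dataclass
class DegenerateCases:
    """Probabilities of deliberately ineligible patients (all default 0)."""

    p_no_second_fill: float = 0.0  # single index fill: fails two-claims rule
    p_washout_violation: float = 0.0  # index-agent claim 100 days pre-index
    p_single_dx: float = 0.0  # only one schizophrenia diagnosis date
    p_underage: float = 0.0  # age 16-17 at index


@dataclasses.dataclass
class GeneratorConfig:
    n_patients: int = 500
    seed: int = 0
    accrual_start: str = "2009-09-01"
    accrual_span_days: int = 1400
    covariates: CovariateModel = dataclasses.field(default_factory=CovariateModel)
    treatment: TreatmentModel = dataclasses.field(default_factory=TreatmentModel)
    fills: FillModel = dataclasses.field(default_factory=FillModel)
    outcomes: OutcomeModel = dataclasses.field(default_factory=OutcomeModel)
    enrollment: EnrollmentModel = dataclasses.field(default_factory=EnrollmentModel)
    degenerate: DegenerateCases = dataclasses.field(default_factory=DegenerateCases)

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        for name, probs in (
            ("race", self.covariates.race_probs),
            ("state", self.covariates.state_probs),
            ("region", self.covariates.region_probs),
        ):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if self.fills.days_supply < 1:
            raise ValueError("days_supply must be >= 1")
        if self.outcomes.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        for key, sub in (
            ("covariates", CovariateModel),
            ("treatment", TreatmentModel),
            ("fills", FillModel),
            ("outcomes", OutcomeModel),
            ("enrollment", EnrollmentModel),
            ("degenerate", DegenerateCases),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class GroundTruth:
    """True parameter values and per-patient latents for a generated cohort."""

    per_patient: pd.DataFrame  # patient_id, treated, p_treat, mean_extra_gap
    delta_medical: float
    delta_pharmacy: float
    delta_total: float
    rr_true: float


MEDICAL_CATEGORIES = (
    "inpatient",
    "outpatient",
    "emergency_room",
    "long_term_care",
    "mhi_admission",
    "mhi_1day",
    "home_care",
    "other_medical",
)

#: Columns of the treatment-assignment (and synthetic propensity) design.
DESIGN_COLUMNS = ("age_c", "female", "n_mhi", "drug_abuse", "diabetes", "cardiovascular")


# ---------------------------------------------------------------------------
# Covariates and assignment


def _choice(rng, probs: dict, n: int) -> np.ndarray:
    keys = list(probs)
    return rng.choice(keys, size=n, p=[probs[k] for k in keys])


def generate_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Patient-level covariate table (no treatment, no outcomes)."""
    cm = config.covariates
    n = config.n_patients
    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, n), cm.age_min, cm.age_max)
    age = np.floor(age)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "female": rng.random(n) < cm.p_female,
            "race": _choice(rng, cm.race_probs, n),
            "state": _choice(rng, cm.state_probs, n),
            "region": _choice(rng, cm.region_probs, n),
            "capitated": rng.random(n) < cm.p_capitated,
            "dual_coverage": rng.random(n) < cm.p_dual,
            "n_mhi": rng.poisson(cm.mhi_rate, n),
            "n_mhi_1day": rng.poisson(cm.mhi_1day_rate, n),
        }
    )
    for name, base in cm.comorb_base.items():
        slope = cm.comorb_age_slope.get(name, 0.0)
        p = np.clip(base + slope * (age - 42.0), 0.0, 1.0)
        df[f"comorb_{name}"] = rng.random(n) < p
    return df


def treatment_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Design columns of the assignment model (also the synthetic PS design)."""
    return pd.DataFrame(
        {
            "age_c": (cov["age"].to_numpy(float) - 42.0) / 10.0,
            "female": cov["female"].to_numpy(float),
            "n_mhi": cov["n_mhi"].to_numpy(float),
            "drug_abuse": cov["comorb_drug_abuse"].to_numpy(float),
            "diabetes": cov["comorb_diabetes"].to_numpy(float),
            "cardiovascular": cov["comorb_cardiovascular"].to_numpy(float),
        }
    )


def assign_treatment(
    cov: pd.DataFrame, beta: dict, rng: np.random.Generator, unmeasured_sd: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli treatment with logit linear in the design columns."""
    X = treatment_design(cov)
    unknown = set(beta) - {"intercept"} - set(X.columns)
    if unknown:
        raise ValueError(f"treatment beta names unknown design columns: {sorted(unknown)}")
    eta = np.full(len(cov), float(beta.get("intercept", 0.0)))
    for name, b in beta.items():
        if name != "intercept":
            eta += b * X[name].to_numpy()
    if unmeasured_sd > 0:
        eta = eta + rng.normal(0.0, unmeasured_sd, len(cov))
    p = 1.0 / (1.0 + np.exp(-eta))
    treated = rng.random(len(cov)) < p
    return treated, p


# ---------------------------------------------------------------------------
# Outcome sampling (vectorized, patient level)


def expected_monthly_cost(
    cov: pd.DataFrame, treated: np.ndarray, om: OutcomeModel
) -> dict[str, np.ndarray]:
    """Closed-form mean monthly cost per category given covariates/arm."""
    m = np.exp(
        om.cost_sev_coef * cov["n_mhi"].to_numpy(float)
        + om.cost_age_coef * (cov["age"].to_numpy(float) - 42.0)
    )
    t = np.asarray(treated, float)
    out = {}
    for cat in MEDICAL_CATEGORIES:
        mu = om.base_monthly[cat] * m + om.delta_monthly.get(cat, 0.0) * t
        if (mu <= 0).any():
            raise ValueError(f"outcome model implies non-positive mean for {cat}")
        out[cat] = mu
    out["pharmacy"] = np.full(len(t), om.pharmacy_base) + om.delta_pharmacy * t
    return out


def expected_event_rate(
    cov: pd.DataFrame, treated: np.ndarray, om: OutcomeModel
) -> dict[str, np.ndarray]:
    """Closed-form annual event rate per category given covariates/arm."""
    link = np.exp(om.rate_sev_coef * cov["n_mhi"].to_numpy(float))
    t = np.asarray(treated, float)
    return {
        cat: om.event_rates[cat] * link * om.rr_true**t for cat in MEDICAL_CATEGORIES
    }


def sample_outcomes(
    cov: pd.DataFrame, treated: np.ndarray, om: OutcomeModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-patient monthly costs, event counts and days (vectorized).

    Costs are zero-inflated gamma: zero with probability ``zero_prob``,
    else gamma with mean ``mu / (1 - zero_prob)`` so the marginal mean is
    exactly ``mu`` and the injected additive effect survives the mixture.
    """
    n = len(cov)
    mu = expected_monthly_cost(cov, treated, om)
    lam = expected_event_rate(cov, treated, om)
    out = {}
    for cat in MEDICAL_CATEGORIES:
        p0 = om.zero_prob[cat]
        if p0 >= 1.0:
            cost = np.zeros(n)
        else:
            mean_pos = mu[cat] / (1.0 - p0)
            k = om.gamma_shape
            cost = rng.gamma(k, mean_pos / k)
            cost[rng.random(n) < p0] = 0.0
        out[f"cost_{cat}"] = cost
        ev = rng.poisson(lam[cat])
        out[f"ev_{cat}"] = ev
        if cat in om.los_extra_mean:
            # sum of ev iid (1 + Poisson(m)) days
            out[f"days_{cat}"] = ev + rng.poisson(ev * om.los_extra_mean[cat])
    k = om.gamma_shape
    out["cost_pharmacy"] = rng.gamma(k, mu["pharmacy"] / k)
    df = pd.DataFrame(out, index=cov.index)
    df["cost_total_medical"] = df[[f"cost_{c}" for c in MEDICAL_CATEGORIES]].sum(axis=1)
    df["cost_total"] = df["cost_total_medical"] + df["cost_pharmacy"]
    return df


def generate_frame(config: GeneratorConfig, seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Patient-level analysis frame: covariates, assignment and outcomes.

    This is the fast path for Monte-Carlo work; :func:`generate_bundle`
    materializes the same patients as claims.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = generate_covariates(config, rng)
    treated, p = assign_treatment(cov, config.treatment.beta, rng, config.treatment.unmeasured_sd)
    outcomes = sample_outcomes(cov, treated, config.outcomes, rng)
    frame = pd.concat([cov, outcomes], axis=1)
    frame["treated"] = treated
    frame["p_treat"] = p
    fm = config.fills
    gap = np.where(treated, fm.gap_mean_treated, fm.gap_mean_comparator)
    om = config.outcomes
    truth = GroundTruth(
        per_patient=pd.DataFrame(
            {
                "patient_id": cov["patient_id"],
                "treated": treated,
                "p_treat": p,
                "mean_extra_gap": gap,
            }
        ),
        delta_medical=float(sum(om.delta_monthly.values())),
        delta_pharmacy=float(om.delta_pharmacy),
        delta_total=float(sum(om.delta_monthly.values()) + om.delta_pharmacy),
        rr_true=float(om.rr_true),
    )
    return frame, truth


def frame_ps_design(frame: pd.DataFrame) -> pd.DataFrame:
    """Propensity design for the fast analysis frame (the true confounders)."""
    return treatment_design(frame)


# ---------------------------------------------------------------------------
# Fill sequences


def generate_fills(
    index_day: int,
    horizon_end: int,
    fm: FillModel,
    treated: bool,
    rng: np.random.Generator,
) -> list[int]:
    """Index-agent fill days over ``[index_day, horizon_end]`` (renewal walk).

    The first fill is on the index day; each refill follows the previous
    supply end after an extra gap (geometric with the arm's mean, or the
    fixed value when configured).  The first refill's gap is capped so the
    second fill lands within 90 days of the first.  After the second fill
    the walk may discontinue with the arm's per-refill probability.
    """
    s = fm.days_supply
    gap_mean = fm.gap_mean_treated if treated else fm.gap_mean_comparator
    p_disc = fm.disc_prob_treated if treated else fm.disc_prob_comparator

    def draw_gap() -> int:
        if fm.gap_fixed is not None:
            return int(fm.gap_fixed)
        if gap_mean <= 0:
            return 0
        return int(rng.geometric(1.0 / (1.0 + gap_mean)) - 1)

    days = [index_day]
    # guaranteed second fill within the qualifying window
    first_gap = min(draw_gap(), fm.second_fill_gap_cap)
    nxt = index_day + s + first_gap
    if nxt <= horizon_end:
        days.append(nxt)
    while True:
        if rng.random() < p_disc:
            break
        nxt = days[-1] + s + draw_gap()
        if nxt > horizon_end:
            break
        days.append(nxt)
    return days


def _background_fills(
    index_day: int, horizon_end: int, rng: np.random.Generator, supply: int = 30
) -> list[int]:
    """Fill days for a concomitant agent over a random sub-period."""
    start = index_day + int(rng.integers(14, 120))
    stop = min(horizon_end, start + int(rng.integers(60, 366)))
    days = []
    t = start
    while t <= stop:
        days.append(t)
        t += supply + int(rng.integers(0, 15))
    return days


# ---------------------------------------------------------------------------
# Bundle materialization

_COMORB_DX = {
    "diabetes": "250.00",
    "cardiovascular": "428.0",
    "obesity": "278.00",
    "drug_abuse": "304.00",
    "hepatitis_c": "070.41",
    "hiv_aids": "042",
}

_MH_DX_POOL = ("296.20", "296.30", "300.00", "300.4", "309.81", "311", "301.9", "298.9")

_OAA_CODES = {cls: f"OAA_{cls.upper()[:4]}" for cls in OAA_CLASSES}
_PSYCH_CODES = {
    "anxiolytic": "ANX_001",
    "antidepressant": "ADP_001",
    "mood-stabilizer": "MST_001",
}


def _service_year(day: int) -> int:
    return int(from_day([day])[0].year)


def _deflate(amount_2015: float, year: int, cpi: dict[int, float]) -> float:
    """Express a reference-year amount in year-of-service dollars."""
    return amount_2015 * cpi[year] / cpi[2015]


def generate_bundle(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[ClaimsBundle, GroundTruth]:
    """Materialize a full claims bundle (plus ground truth) from the frame.

    The bundle passes strict validation unless enrollment gaps or
    degenerate cases are configured.  Costs are written in year-of-service
    dollars (deflated from the reference year with the packaged CPI
    table) so the pipeline's CPI standardization recovers the configured
    means.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frame, truth = generate_frame(config, seed=int(rng.integers(2**31)))
    cpi = codelists.load_cpi()
    fm, om, em, dg = config.fills, config.outcomes, config.enrollment, config.degenerate
    accrual_day = int(to_day([config.accrual_start])[0])

    patients, spans, rx_rows, med_rows = [], [], [], []

    index_days = accrual_day + rng.integers(0, config.accrual_span_days, len(frame))
    oaa_choice = rng.choice(list(OAA_CLASSES), len(frame))

    for i, rec in enumerate(frame.itertuples(index=False)):
        pid = rec.patient_id
        d0 = int(index_days[i])
        treated = bool(rec.treated)
        age = int(rec.age)
        if rng.random() < dg.p_underage:
            age = int(rng.integers(16, 18))
        index_date = from_day([d0])[0]
        birth = index_date - pd.DateOffset(years=age) - pd.Timedelta(days=int(rng.integers(0, 364)))
        patients.append((pid, birth, "female" if rec.female else "male", rec.race, rec.region, rec.state))

        # enrollment: one long span, optionally split by a 30-day gap
        e_start, e_end = d0 - em.lead_days, d0 + em.tail_days
        cap, dual = bool(rec.capitated), bool(rec.dual_coverage)
        if rng.random() < em.baseline_gap_prob:
            cut = d0 - 200
            spans.append((pid, e_start, cut - 1, cap, dual))
            spans.append((pid, cut + 30, e_end, cap, dual))
        elif rng.random() < em.followup_gap_prob:
            cut = d0 + 150
            spans.append((pid, e_start, cut - 1, cap, dual))
            spans.append((pid, cut + 30, e_end, cap, dual))
        else:
            spans.append((pid, e_start, e_end, cap, dual))

        # --- baseline diagnosis-carrying claims (zero cost) -------------
        n_dx_claims = 1 if rng.random() < dg.p_single_dx else int(rng.integers(2, 5))
        dx_days = sorted(rng.integers(d0 - 360, d0 - 5, n_dx_claims).tolist())
        extra_mh = rng.choice(_MH_DX_POOL, size=int(rng.integers(1, 6))).tolist()
        comorbs = [
            _COMORB_DX[name]
            for name in _COMORB_DX
            if getattr(rec, f"comorb_{name}")
        ]
        pool = ["295.30"] + extra_mh + comorbs
        for j, day in enumerate(dx_days):
            codes = ["295.30"] if j < 2 else [str(c) for c in rng.choice(pool, 2)]
            if j == 0:
                codes += extra_mh + comorbs
            yr = _service_year(day)
            med_rows.append((pid, day, day, "outpatient", ";".join(dict.fromkeys(codes)), 0.0, "", False, yr))

        # --- baseline severity admissions -------------------------------
        base_med_monthly = 1200.0 * np.exp(0.18 * rec.n_mhi)
        base_cost_claims = []
        for _ in range(int(rec.n_mhi)):
            day = int(rng.integers(d0 - 360, d0 - 10))
            los = 1 + int(rng.poisson(3))
            base_cost_claims.append((pid, day, min(day + los - 1, d0 - 1), "mhi_admission"))
        for _ in range(int(rec.n_mhi_1day)):
            day = int(rng.integers(d0 - 360, d0 - 10))
            base_cost_claims.append((pid, day, day, "mhi_1day"))
        if not base_cost_claims:
            day = int(rng.integers(d0 - 360, d0 - 10))
            base_cost_claims.append((pid, day, day, "outpatient"))
        annual_base_cost = float(rng.gamma(1.5, 12.0 * base_med_monthly / 1.5))
        share = annual_base_cost / len(base_cost_claims)
        for pid_, s_, e_, cat_ in base_cost_claims:
            yr = _service_year(s_)
            med_rows.append((pid_, s_, e_, cat_, "", round(_deflate(share, yr, cpi), 2), "", False, yr))

        # --- index agent ------------------------------------------------
        if treated:
            agent_code, agent_class = "PP1M", PP1M
        else:
            agent_class = oaa_choice[i]
            agent_code = _OAA_CODES[agent_class]

        if rng.random() < dg.p_washout_violation:
            day = d0 - 100
            yr = _service_year(day)
            rx_rows.append((pid, day, agent_code, agent_class, fm.days_supply, 0.0, treated, yr))

        horizon = d0 + 364
        idx_fill_days = generate_fills(d0, horizon, fm, treated, rng)
        if rng.random() < dg.p_no_second_fill:
            idx_fill_days = idx_fill_days[:1]

        # --- baseline AP fills (never the index agent: washout holds; and
        # spaced > 90 days apart so prior use never forms its own index
        # event, keeping the generated index date the true one) ----------
        baseline_fill_days: list[tuple[int, str, str]] = []
        if rng.random() < fm.p_baseline_ap:
            choices = [c for c in OAA_CLASSES if _OAA_CODES[c] != agent_code]
            cls = rng.choice(choices)
            day = d0 - 360 + int(rng.integers(0, 30))
            for _ in range(int(rng.integers(1, 4))):
                if day > d0 - 2:
                    break
                baseline_fill_days.append((day, _OAA_CODES[cls], cls))
                day += int(rng.integers(95, 131))

        # --- concomitant follow-up fills --------------------------------
        background: list[tuple[int, str, str]] = []
        if rng.random() < fm.p_second_ap:
            choices = [c for c in OAA_CLASSES if _OAA_CODES[c] != agent_code]
            cls = rng.choice(choices)
            for day in _background_fills(d0, horizon, rng):
                background.append((day, _OAA_CODES[cls], cls))
        for cls, pcls in (
            ("anxiolytic", fm.p_anxiolytic),
            ("antidepressant", fm.p_antidepressant),
            ("mood-stabilizer", fm.p_mood_stabilizer),
        ):
            if rng.random() < pcls:
                for day in _background_fills(d0, horizon, rng):
                    background.append((day, _PSYCH_CODES[cls], cls))

        # --- pharmacy costs ---------------------------------------------
        annual_rx = float(rec.cost_pharmacy) * 12.0
        idx_share = 0.7 if background else 1.0
        per_idx = annual_rx * idx_share / max(len(idx_fill_days), 1)
        per_bg = annual_rx * (1 - idx_share) / max(len(background), 1)
        for day in idx_fill_days:
            yr = _service_year(day)
            branded = treated or (rng.random() < 0.3)
            rx_rows.append(
                (pid, day, agent_code, agent_class, fm.days_supply, round(_deflate(per_idx, yr, cpi), 2), branded, yr)
            )
        for day, code, cls in background:
            yr = _service_year(day)
            rx_rows.append((pid, day, code, cls, 30, round(_deflate(per_bg, yr, cpi), 2), False, yr))
        for day, code, cls in baseline_fill_days:
            yr = _service_year(day)
            rx_rows.append((pid, day, code, cls, 30, round(_deflate(30.0, yr, cpi), 2), False, yr))

        # --- follow-up medical events with category costs ----------------
        leftover = 0.0
        for cat in MEDICAL_CATEGORIES:
            n_ev = int(getattr(rec, f"ev_{cat}"))
            annual = float(getattr(rec, f"cost_{cat}")) * 12.0
            if n_ev == 0:
                leftover += annual
                continue
            days_in = sorted(rng.integers(d0, horizon + 1, n_ev).tolist())
            share = annual / n_ev
            svc = "other" if cat == "other_medical" else cat
            for day in days_in:
                if cat in om.los_extra_mean:
                    los = 1 + int(rng.poisson(om.los_extra_mean[cat]))
                    end = min(day + los - 1, horizon)
                elif cat == "mhi_1day":
                    end = day
                else:
                    end = day
                yr = _service_year(day)
                med_rows.append((pid, day, end, svc, "", round(_deflate(share, yr, cpi), 2), "", False, yr))
        if leftover > 0:
            # cost in categories that drew no events rides on one carrier
            # claim in the residual category so arm totals stay unbiased
            day = int(rng.integers(d0, horizon + 1))
            yr = _service_year(day)
            med_rows.append((pid, day, day, "other", "", round(_deflate(leftover, yr, cpi), 2), "", False, yr))

    patients_df = pd.DataFrame(
        patients, columns=["patient_id", "birth_date", "sex", "race", "region", "state"]
    )
    enrollment_df = pd.DataFrame(
        spans, columns=["patient_id", "start_date", "end_date", "capitated", "dual_coverage"]
    )
    enrollment_df["start_date"] = from_day(enrollment_df["start_date"].to_numpy())
    enrollment_df["end_date"] = from_day(enrollment_df["end_date"].to_numpy())
    pharmacy_df = pd.DataFrame(
        rx_rows,
        columns=["patient_id", "dispense_date", "agent_code", "agent_class", "days_supply", "paid_amount", "branded", "service_year"],
    )
    pharmacy_df["dispense_date"] = from_day(pharmacy_df["dispense_date"].to_numpy())
    medical_df = pd.DataFrame(
        med_rows,
        columns=["patient_id", "start_date", "end_date", "service_category", "dx_codes", "paid_amount", "agent_code", "branded", "service_year"],
    )
    medical_df["start_date"] = from_day(medical_df["start_date"].to_numpy())
    medical_df["end_date"] = from_day(medical_df["end_date"].to_numpy())
    medical_df["branded"] = medical_df["branded"].astype(bool)

    strict = (
        em.baseline_gap_prob == 0
        and em.followup_gap_prob == 0
        and dg.p_washout_violation == 0
    )
    bundle = ClaimsBundle(
        patients=patients_df,
        enrollment=enrollment_df,
        pharmacy=pharmacy_df,
        medical=medical_df,
        strict=strict,
    )
    return bundle, truth


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    df = truth.per_patient.copy()
    df["delta_medical"] = truth.delta_medical
    df["delta_pharmacy"] = truth.delta_pharmacy
    df["delta_total"] = truth.delta_total
    df["rr_true"] = truth.rr_true
    df.to_csv(path, index=False)
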