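"""Synthetic recall-cohort generator with known ground truth.

The generator emits the tidy-CSV dialect of :mod:`recallvar.ingest`: a
participant table (covariates, 0-10 food-insecurity score, BMI, survey
weight) and a food-item table of timed consumption events, for a cohort in
which food insecurity (FI) shifts consumption-pattern features by known
amounts and BMI follows a configured linear model on FI and the realized
mediator values. Every derived statistic the pipeline computes therefore has
a known expectation, enabling null-calibration and parameter-recovery tests
without any data download.

Generative model (per participant i, secure-group baselines in the config,
additive FI shifts from ``fi_effects``):

* positive-valued latents (daily energy, gap dispersion, energy-per-event
  dispersion, foods-per-event rate, daily grams) are Gamma distributed with
  the configured mean and SD, so an additive shift on the mean is exact;
* day values around the participant latent use unit-mean lognormal noise,
  so day averages stay unbiased and the expected unsigned interday
  difference has the closed form ``E|e^X - e^Y| = 2(2 Phi(tau/sqrt 2) - 1)``
  for iid lognormal factors with log-SD ``tau``;
* within a day, the gap vector between the ``n`` consumption events is a
  one-long-rest-short pattern with exact mean (day span / gap count) and
  exact sample SD equal to the drawn dispersion, at a random position — so
  the intraday SD of time gaps is injected exactly; event energies use the
  same construction;
* foods per event are 1 + gamma-mixed Poisson counts (overdispersed);
  macronutrient grams are linear in total grams with FI composition shifts,
  fibre coupled to the carbohydrate deviation;
* BMI = intercept + c' * FI + sum_i b_i * mediator_i + noise, where the
  mediators are the participant's *realized* derived values (time-gap SD,
  mean foods per event, pooled-residual relative fibre).

Features whose FI effect cannot be injected additively (SD of foods per
event and four of the interday differences, which are emergent statistics of
the same draws) get their expected effects from
:func:`analytic_expectations`, by closed form where one exists and by
large-n Monte Carlo over the generator's own day-structure layer otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats as st

from . import schema as S

__all__ = ["SimConfig", "GroundTruth", "generate_cohort",
           "analytic_expectations", "null_config"]

_SQRT_HALF_PI = float(np.sqrt(np.pi) / 2.0)


def _default_fi_effects() -> dict[str, float]:
    """Additive FI shifts on directly injectable features (insecure - secure)."""
    return {
        S.ENERGY: 6.74,
        S.REL_CARB: 9.92,
        S.REL_PROTEIN: -4.50,
        S.REL_FAT: -3.22,
        S.REL_FIBRE: -2.02,
        S.FIRST_CE: 0.25,
        S.N_CES: -0.50,
        S.MEAN_FOODS_PER_CE: -1.49,
        S.SD_TIME_GAP: 16.15,
        S.SD_ENERGY_PER_CE: 22.07,
        S.IDD_ENERGY: 65.15,
        S.IDD_FIRST_CE: 0.52,
    }


def _default_mediator_coefs() -> dict[str, float]:
    # chosen so the plug-in decomposition gives total 2.21 and
    # 4.2% / 2.9% / 7.4% via the three mediator paths
    return {S.SD_TIME_GAP: 0.005748,
            S.MEAN_FOODS_PER_CE: -0.043,
            S.REL_FIBRE: -0.0809}


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort.

    Location/scale defaults are secure-group values backed out from the
    target population means so that, at the default 32% FI prevalence and
    default effect vector, population feature means land on the reference
    values (e.g. daily energy 1779 kcal, 5.57 events/day, first event
    7.93 h, gap SD 104.27 min).
    """

    n_participants: int = 3101
    seed: int = 0
    male_fraction: float = 0.0

    # sample structure
    p_any_recall: float = 2798 / 3101
    p_second_day: float = 2539 / 2798
    fi_prevalence: float = 0.32
    fourlevel_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    # covariates
    age_mean: float = 47.0
    age_sd: float = 17.0
    age_range: tuple[float, float] = (18.0, 80.0)
    income_mean: float = 2.6
    income_sd: float = 1.7
    income_range: tuple[float, float] = (0.0, 5.0)
    education_probs: tuple = (0.10, 0.15, 0.22, 0.31, 0.22)
    ethnicity_probs: tuple = (0.10, 0.17, 0.40, 0.21, 0.12)
    children_prob: float = 0.35
    weight_lognorm_sigma: float = 0.7

    # daily energy (kcal): Gamma latent, lognormal day noise solved from the
    # interday-difference target
    energy_mean: float = 1776.84
    energy_between_sd: float = 590.0
    idd_energy_secure: float = 607.06

    # first consumption event (hours from midnight)
    first_ce_mean: float = 7.85
    first_ce_between_sd: float = 1.6
    idd_first_ce_secure: float = 1.4836
    first_ce_range: tuple[float, float] = (0.5, 16.0)

    # last consumption event (defines the day's eating span)
    last_ce_mean: float = 20.8
    last_ce_sd: float = 1.2
    last_ce_min_after_first: float = 0.75
    last_ce_max: float = 23.4

    # events per day: 1 + Binomial(n, p), p participant-varying
    n_ces_binom_n: int = 8
    n_ces_mean_secure: float = 5.73
    n_ces_p_sd: float = 0.09

    # foods per event: 1 + gamma-mixed Poisson
    foods_per_ce_mean_secure: float = 10.157
    foods_lambda_between_sd: float = 2.6
    foods_dispersion: float = 3.6

    # intraday gap dispersion (minutes)
    sd_time_gap_mean_secure: float = 99.10
    sd_time_gap_between_sd: float = 43.0
    sd_time_gap_day_lognorm_sd: float = 0.2
    min_gap_min: float = 2.0

    # intraday energy-per-event dispersion (kcal)
    sd_energy_mean_secure: float = 315.14
    sd_energy_between_sd: float = 125.0
    sd_energy_day_lognorm_sd: float = 0.15
    min_event_kcal: float = 0.5

    # daily grams and macronutrient composition
    grams_mean: float = 2900.0
    grams_between_sd: float = 850.0
    grams_day_lognorm_sd: float = 0.18
    carb_slope: float = 0.0862
    carb_participant_sd: float = 27.0
    carb_day_sd: float = 10.0
    protein_slope: float = 0.0241
    protein_participant_sd: float = 18.0
    protein_day_sd: float = 7.0
    fat_slope: float = 0.0241
    fat_participant_sd: float = 17.0
    fat_day_sd: float = 7.0
    fibre_slope: float = 0.00552
    fibre_participant_sd: float = 4.2
    fibre_day_sd: float = 1.5
    fibre_carb_coupling: float = 0.06

    # FI effect vector and BMI path model
    fi_effects: dict[str, float] = field(default_factory=_default_fi_effects)
    bmi_intercept: float = 28.689
    bmi_direct_effect: float = 1.8896      # c'
    bmi_mediator_coefs: dict[str, float] = field(
        default_factory=_default_mediator_coefs)
    bmi_resid_sd: float = 7.6

    def validate(self) -> None:
        probs = [self.p_any_recall, self.p_second_day, self.fi_prevalence,
                 self.children_prob, self.male_fraction,
                 *self.fourlevel_probs, *self.education_probs,
                 *self.ethnicity_probs]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        span_h = (self.last_ce_mean - 2 * self.last_ce_sd
                  - (self.first_ce_mean + 2 * self.first_ce_between_sd))
        worst_gaps = self.n_ces_binom_n
        if span_h * 60.0 / worst_gaps <= self.min_gap_min:
            raise ValueError(
                "infeasible timing config: the typical eating span "
                f"({span_h:.1f} h) cannot hold {worst_gaps} gaps of at least "
                f"{self.min_gap_min} min; events would run past midnight")
        for name in (self.energy_mean, self.grams_mean,
                     self.sd_time_gap_mean_secure, self.sd_energy_mean_secure):
            if name <= 0:
                raise ValueError("location parameters must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("fourlevel_probs", "age_range", "income_range",
                    "education_probs", "ethnicity_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def null_config(**overrides) -> SimConfig:
    """A configuration with every FI effect (and the direct BMI effect) zero."""
    cfg = SimConfig(**overrides)
    cfg.fi_effects = {k: 0.0 for k in cfg.fi_effects}
    cfg.bmi_direct_effect = 0.0
    return cfg


@dataclass
class GroundTruth:
    """Expected feature effects and the mediation decomposition."""

    expected_effects: dict[str, float]        # insecure - secure, all 16
    exact: dict[str, bool]                    # closed form vs Monte Carlo
    mediation: dict                           # a, b, c', indirect, total, ...
    config: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), indent=2, default=default)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _gamma_mean_sd(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(np.broadcast_to(shape, size), np.broadcast_to(scale, size))


def _unit_lognormal(rng, tau, size):
    """Multiplicative noise with mean exactly 1."""
    tau = np.broadcast_to(tau, size)
    return np.exp(rng.normal(-0.5 * tau ** 2, tau))


def _truncnorm(rng, mean, sd, low, high, size):
    a = (np.asarray(low) - mean) / sd
    b = (np.asarray(high) - mean) / sd
    return st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                            random_state=rng)


def _lognorm_tau_for_ratio(r: float) -> float:
    """Solve E|e^X - e^Y| = r for iid X,Y ~ N(-tau^2/2, tau^2).

    Margrabe-type identity: the expectation equals 2(2 Phi(tau/sqrt 2) - 1).
    """
    if not 0 <= r < 2:
        raise ValueError("interday-difference ratio must be in [0, 2)")
    return float(np.sqrt(2.0) * st.norm.ppf(0.5 + r / 4.0))


def _effective_effects(cfg: SimConfig) -> dict[str, float]:
    eff = {k: 0.0 for k in S.ALL_FEATURES}
    eff.update(cfg.fi_effects)
    return eff


def _participant_latents(rng, fi: np.ndarray, cfg: SimConfig) -> dict:
    """Per-participant latent dispositions; FI shifts group means exactly."""
    n = fi.size
    eff = _effective_effects(cfg)
    energy_mean = cfg.energy_mean + eff[S.ENERGY] * fi
    idd_energy = cfg.idd_energy_secure + eff[S.IDD_ENERGY] * fi
    tau_sec = _lognorm_tau_for_ratio(cfg.idd_energy_secure / cfg.energy_mean)
    tau_ins = _lognorm_tau_for_ratio(
        (cfg.idd_energy_secure + eff[S.IDD_ENERGY])
        / (cfg.energy_mean + eff[S.ENERGY]))
    sigma_w_first = _SQRT_HALF_PI * (
        cfg.idd_first_ce_secure + eff[S.IDD_FIRST_CE] * fi)
    p_base = (cfg.n_ces_mean_secure - 1.0 + eff[S.N_CES] * fi) / cfg.n_ces_binom_n
    lam_mean = (cfg.foods_per_ce_mean_secure - 1.0
                + eff[S.MEAN_FOODS_PER_CE] * fi)
    return {
        "fi": fi,
        "energy": _gamma_mean_sd(rng, energy_mean, cfg.energy_between_sd, n),
        "energy_tau": np.where(fi == 1, tau_ins, tau_sec),
        "idd_energy_target": idd_energy,
        "first_ce": rng.normal(cfg.first_ce_mean + eff[S.FIRST_CE] * fi,
                               cfg.first_ce_between_sd),
        "first_ce_sigma_w": sigma_w_first,
        "nces_p": np.clip(p_base + rng.normal(0.0, cfg.n_ces_p_sd, n),
                          0.02, 0.98),
        "foods_lam": _gamma_mean_sd(rng, lam_mean,
                                    cfg.foods_lambda_between_sd, n),
        "gap_sd": _gamma_mean_sd(
            rng, cfg.sd_time_gap_mean_secure + eff[S.SD_TIME_GAP] * fi,
            cfg.sd_time_gap_between_sd, n),
        "energy_sd": _gamma_mean_sd(
            rng, cfg.sd_energy_mean_secure + eff[S.SD_ENERGY_PER_CE] * fi,
            cfg.sd_energy_between_sd, n),
        "grams": _gamma_mean_sd(rng, cfg.grams_mean, cfg.grams_between_sd, n),
        "eps_carb": rng.normal(0.0, cfg.carb_participant_sd, n),
        "eps_protein": rng.normal(0.0, cfg.protein_participant_sd, n),
        "eps_fat": rng.normal(0.0, cfg.fat_participant_sd, n),
        "eps_fibre": rng.normal(0.0, cfg.fibre_participant_sd, n),
    }


def _day_draws(rng, lat: dict, day_pid: np.ndarray, cfg: SimConfig,
               include_macros: bool = True) -> dict:
    """Per-day structural values; ``day_pid`` maps days to participants."""
    eff = _effective_effects(cfg)
    nd = day_pid.size
    fi_d = lat["fi"][day_pid]

    e_day = lat["energy"][day_pid] * _unit_lognormal(
        rng, lat["energy_tau"][day_pid], nd)
    f_day = np.clip(
        lat["first_ce"][day_pid]
        + rng.normal(0.0, lat["first_ce_sigma_w"][day_pid]),
        *cfg.first_ce_range)
    l_day = _truncnorm(rng, cfg.last_ce_mean, cfg.last_ce_sd,
                       f_day + cfg.last_ce_min_after_first,
                       cfg.last_ce_max, nd)
    k_day = 1 + rng.binomial(cfg.n_ces_binom_n, lat["nces_p"][day_pid])

    n_gaps = k_day - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_gap = np.where(n_gaps > 0, (l_day - f_day) * 60.0 / n_gaps, np.nan)
    s_day = lat["gap_sd"][day_pid] * _unit_lognormal(
        rng, cfg.sd_time_gap_day_lognorm_sd, nd)
    cap = (mean_gap - cfg.min_gap_min) * np.sqrt(np.maximum(n_gaps, 1))
    s_day = np.where(n_gaps >= 2, np.minimum(s_day, 0.999 * cap), s_day)

    v_day = lat["energy_sd"][day_pid] * _unit_lognormal(
        rng, cfg.sd_energy_day_lognorm_sd, nd)
    mean_event_kcal = e_day / k_day
    vcap = (mean_event_kcal - cfg.min_event_kcal) * np.sqrt(k_day)
    v_day = np.minimum(v_day, np.maximum(0.999 * vcap, 0.0))

    out = {"fi": fi_d, "energy": e_day, "first_ce": f_day, "last_ce": l_day,
           "n_ces": k_day, "mean_gap": mean_gap, "gap_sd": s_day,
           "energy_sd": v_day}
    if include_macros:
        g_day = lat["grams"][day_pid] * _unit_lognormal(
            rng, cfg.grams_day_lognorm_sd, nd)
        carb = np.maximum(
            cfg.carb_slope * g_day + eff[S.REL_CARB] * fi_d
            + lat["eps_carb"][day_pid] + rng.normal(0, cfg.carb_day_sd, nd), 0.5)
        protein = np.maximum(
            cfg.protein_slope * g_day + eff[S.REL_PROTEIN] * fi_d
            + lat["eps_protein"][day_pid]
            + rng.normal(0, cfg.protein_day_sd, nd), 0.5)
        fat = np.maximum(
            cfg.fat_slope * g_day + eff[S.REL_FAT] * fi_d
            + lat["eps_fat"][day_pid] + rng.normal(0, cfg.fat_day_sd, nd), 0.5)
        fibre = np.maximum(
            cfg.fibre_slope * g_day + eff[S.REL_FIBRE] * fi_d
            + cfg.fibre_carb_coupling * lat["eps_carb"][day_pid]
            + lat["eps_fibre"][day_pid] + rng.normal(0, cfg.fibre_day_sd, nd),
            0.05)
        out.update(grams=g_day, carb=carb, protein=protein, fat=fat,
                   fibre=fibre)
    return out


def _event_counts(rng, lam_event: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Foods per event: 1 + Poisson with gamma-mixed rate (overdispersed)."""
    r = cfg.foods_dispersion
    rate = rng.gamma(r, lam_event / r)
    return 1 + rng.poisson(rate)


def _one_long_pattern(rng, n_per_seg, mean_val, target_sd):
    """Flat vector of segment values with exact per-segment mean and sample SD.

    Each segment of length n gets n-1 identical "short" values and one
    "long" value at a random position; sample SD equals ``target_sd``
    exactly (for n >= 2) and the mean equals ``mean_val`` exactly.
    """
    offsets = np.concatenate([[0], np.cumsum(n_per_seg)[:-1]])
    a = np.where(n_per_seg >= 2, target_sd / np.sqrt(n_per_seg), 0.0)
    values = np.repeat(mean_val - a, n_per_seg)
    long_pos = offsets + rng.integers(0, n_per_seg)
    values[long_pos] += n_per_seg * a
    return values


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig | None = None, seed: int | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a cohort: participant table, food-item table, ground truth.

    Reproducible given (config, seed); ``seed`` defaults to ``config.seed``.
    The ground-truth dict records the realized configuration, the injected
    effect vector and the plug-in mediation decomposition.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_participants
    eff = _effective_effects(cfg)

    # --- participants -----------------------------------------------------
    male = rng.random(n) < cfg.male_fraction
    insecure = (rng.random(n) < cfg.fi_prevalence).astype(np.int64)
    level = 1 + rng.choice(3, size=n, p=np.asarray(cfg.fourlevel_probs)
                           / np.sum(cfg.fourlevel_probs))
    score = np.select(
        [level == 1, level == 2, level == 3],
        [rng.integers(1, 3, n), rng.integers(3, 6, n), rng.integers(6, 11, n)])
    score = np.where(insecure == 1, score, 0)

    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    income = _truncnorm(rng, cfg.income_mean, cfg.income_sd,
                        *cfg.income_range, size=n)
    education = 1 + rng.choice(5, size=n, p=cfg.education_probs)
    ethnicity = 1 + rng.choice(5, size=n, p=cfg.ethnicity_probs)
    children = (rng.random(n) < cfg.children_prob).astype(np.int64)
    sigma = cfg.weight_lognorm_sigma
    survey_weight = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n))

    any_recall = rng.random(n) < cfg.p_any_recall
    two_days = rng.random(n) < cfg.p_second_day
    n_days = np.where(any_recall, np.where(two_days, 2, 1), 0)

    lat = _participant_latents(rng, insecure, cfg)

    # --- day structure ----------------------------------------------------
    day_pid = np.repeat(np.arange(n), n_days)
    starts = np.concatenate([[0], np.cumsum(n_days)[:-1]])
    day_no = np.arange(day_pid.size) - np.repeat(starts, n_days) + 1
    days = _day_draws(rng, lat, day_pid, cfg)
    nd = day_pid.size

    # --- events -----------------------------------------------------------
    k = days["n_ces"]
    n_gaps = k - 1
    ev_day = np.repeat(np.arange(nd), k)
    n_events = ev_day.size

    # gap vector with exact mean and sample SD per day
    gd = np.flatnonzero(n_gaps > 0)
    gaps = _one_long_pattern(
        rng, n_gaps[gd], days["mean_gap"][gd],
        np.where(n_gaps[gd] >= 2, days["gap_sd"][gd], 0.0))
    # per-event "gap before this event" (0 for the first event of a day)
    gap_before = np.zeros(n_events)
    first_event = np.concatenate([[0], np.cumsum(k)[:-1]])
    mask = np.ones(n_events, dtype=bool)
    mask[first_event] = False
    gap_before[mask] = gaps
    csum = np.cumsum(gap_before)
    within = csum - np.repeat(csum[first_event], k)
    ev_time = days["first_ce"][ev_day] + within / 60.0

    # event energies: same exact-SD construction
    ev_kcal = _one_long_pattern(
        rng, k, days["energy"] / k, np.where(k >= 2, days["energy_sd"], 0.0))

    ev_foods = _event_counts(rng, lat["foods_lam"][day_pid][ev_day], cfg)

    # --- food rows --------------------------------------------------------
    food_ev = np.repeat(np.arange(n_events), ev_foods)
    share = (ev_kcal / ev_foods)[food_ev] / days["energy"][ev_day][food_ev]
    items = pd.DataFrame({
        S.PID: 1 + day_pid[ev_day][food_ev],
        S.DAY: day_no[ev_day][food_ev],
        S.TIME: ev_time[food_ev],
        S.FOOD_CODE: rng.integers(100000, 1000000, size=food_ev.size),
        S.GRAMS: days["grams"][ev_day][food_ev] * share,
        S.KCAL: (ev_kcal / ev_foods)[food_ev],
        S.CARB: days["carb"][ev_day][food_ev] * share,
        S.PROTEIN: days["protein"][ev_day][food_ev] * share,
        S.FAT: days["fat"][ev_day][food_ev] * share,
        S.FIBRE: days["fibre"][ev_day][food_ev] * share,
    })

    # --- realized mediators and BMI ---------------------------------------
    sd_gap_day = np.where(k >= 3, days["gap_sd"], np.nan)
    day_mean_foods = np.bincount(ev_day, weights=ev_foods, minlength=nd) / k

    def participant_mean(day_values):
        vals = np.where(np.isfinite(day_values), day_values, 0.0)
        cnt = np.bincount(day_pid, weights=np.isfinite(day_values).astype(float),
                          minlength=n)
        tot = np.bincount(day_pid, weights=vals, minlength=n)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    sd_gap_real = participant_mean(sd_gap_day)
    sd_gap_real = np.where(np.isfinite(sd_gap_real), sd_gap_real, lat["gap_sd"])
    mfpc_real = participant_mean(day_mean_foods)
    mfpc_real = np.where(np.isfinite(mfpc_real), mfpc_real,
                         1.0 + lat["foods_lam"])
    fib_avg = participant_mean(days["fibre"])
    g_avg = participant_mean(days["grams"])
    # pooled residualisation mirroring the pipeline's relative-fibre variable
    ok = np.isfinite(fib_avg) & np.isfinite(g_avg)
    fib_lat = (cfg.fibre_slope * lat["grams"] + eff[S.REL_FIBRE] * insecure
               + cfg.fibre_carb_coupling * lat["eps_carb"] + lat["eps_fibre"])
    fib_for_fit = np.where(ok, fib_avg, fib_lat)
    g_for_fit = np.where(ok, g_avg, lat["grams"])
    X = np.column_stack([np.ones(int(ok.sum())), g_avg[ok]])
    beta, *_ = np.linalg.lstsq(X, fib_avg[ok], rcond=None)
    rel_fibre_real = fib_for_fit - (beta[0] + beta[1] * g_for_fit)

    coefs = cfg.bmi_mediator_coefs
    bmi = (cfg.bmi_intercept + cfg.bmi_direct_effect * insecure
           + coefs[S.SD_TIME_GAP] * sd_gap_real
           + coefs[S.MEAN_FOODS_PER_CE] * mfpc_real
           + coefs[S.REL_FIBRE] * rel_fibre_real
           + rng.normal(0.0, cfg.bmi_resid_sd, n))
    bmi = np.maximum(bmi, 12.0)

    participants = pd.DataFrame({
        S.PID: np.arange(1, n + 1),
        S.GENDER: np.where(male, "male", "female"),
        S.AGE: age,
        S.INCOME: income,
        S.EDUCATION: education,
        S.ETHNICITY: ethnicity,
        S.CHILDREN: children,
        S.FI_SCORE: score,
        S.BMI: bmi,
        S.WEIGHT: survey_weight,
    })

    truth = {
        "seed": int(cfg.seed if seed is None else seed),
        "fi_effects": dict(eff),
        "mediation": _plugin_mediation(cfg),
        "config": cfg.to_dict(),
    }
    return participants, items, truth


def _plugin_mediation(cfg: SimConfig) -> dict:
    """Closed-form decomposition implied by the configured path model."""
    eff = _effective_effects(cfg)
    mediators = list(cfg.bmi_mediator_coefs)
    a = np.array([eff[m] for m in mediators])
    b = np.array([cfg.bmi_mediator_coefs[m] for m in mediators])
    indirect = a * b
    total = cfg.bmi_direct_effect + indirect.sum()
    prop = indirect / total if total != 0 else np.full(len(a), np.nan)
    return {
        "mediators": mediators,
        "a": a.tolist(), "b": b.tolist(),
        "direct": cfg.bmi_direct_effect,
        "indirect": indirect.tolist(),
        "total": float(total),
        "proportion": prop.tolist(),
        "proportion_total": float(indirect.sum() / total) if total else np.nan,
    }


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------

_EXACT_EFFECTS = [S.ENERGY, S.REL_CARB, S.REL_PROTEIN, S.REL_FAT, S.REL_FIBRE,
                  S.FIRST_CE, S.N_CES, S.MEAN_FOODS_PER_CE, S.SD_TIME_GAP,
                  S.IDD_ENERGY, S.IDD_FIRST_CE]

_MC_EFFECTS = [S.SD_FOODS_PER_CE, S.SD_ENERGY_PER_CE, S.IDD_N_FOODS,
               S.IDD_N_CES, S.IDD_MEAN_GAP]


def analytic_expectations(config: SimConfig | None = None,
                          n_mc: int = 2_000_000, seed: int = 777,
                          ) -> GroundTruth:
    """Expected FI effect on each derived feature under the configuration.

    Directly injected shifts have closed-form expectations (the injected
    value); emergent statistics (SD of foods per event, the interday
    differences in food count / event count / mean gap, and the
    feasibility-capped energy-per-event SD) are computed by Monte Carlo over
    the generator's day-structure layer with ``n_mc`` participants per FI
    group, two days each — precise to well below the recovery tolerances.
    """
    cfg = config or SimConfig()
    cfg.validate()
    eff = _effective_effects(cfg)
    expected = {k: float(eff[k]) for k in _EXACT_EFFECTS}
    exact = {k: True for k in _EXACT_EFFECTS}

    rng = np.random.default_rng(seed)
    group_means: dict[str, dict[int, float]] = {k: {} for k in _MC_EFFECTS}
    for fi_val in (0, 1):
        fi = np.full(n_mc, fi_val, dtype=np.int64)
        lat = _participant_latents(rng, fi, cfg)
        day_pid = np.repeat(np.arange(n_mc), 2)
        days = _day_draws(rng, lat, day_pid, cfg, include_macros=False)
        k = days["n_ces"]
        nd = day_pid.size

        # SD of foods per event: exact sample-SD of 1 + mixed-Poisson counts
        ev_day = np.repeat(np.arange(nd), k)
        counts = _event_counts(rng, lat["foods_lam"][day_pid][ev_day], cfg)
        cnt = np.bincount(ev_day, minlength=nd).astype(float)
        mean_c = np.bincount(ev_day, weights=counts, minlength=nd) / cnt
        dev = counts - mean_c[ev_day]
        ss = np.bincount(ev_day, weights=dev * dev, minlength=nd)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd_foods_day = np.where(cnt >= 2, np.sqrt(ss / (cnt - 1)), np.nan)
        day_total_foods = np.bincount(ev_day, weights=counts, minlength=nd)

        def pmean(day_vals):
            fin = np.isfinite(day_vals)
            c = np.bincount(day_pid, weights=fin.astype(float), minlength=n_mc)
            t = np.bincount(day_pid, weights=np.where(fin, day_vals, 0.0),
                            minlength=n_mc)
            with np.errstate(invalid="ignore"):
                vals = np.where(c > 0, t / np.maximum(c, 1), np.nan)
            return float(np.nanmean(vals))

        d1 = slice(0, nd, 2)
        d2 = slice(1, nd, 2)

        group_means[S.SD_FOODS_PER_CE][fi_val] = pmean(sd_foods_day)
        group_means[S.SD_ENERGY_PER_CE][fi_val] = pmean(
            np.where(k >= 2, days["energy_sd"], np.nan))
        group_means[S.IDD_N_FOODS][fi_val] = float(np.mean(
            np.abs(day_total_foods[d1] - day_total_foods[d2])))
        group_means[S.IDD_N_CES][fi_val] = float(np.mean(
            np.abs(k[d1] - k[d2]).astype(float)))
        mg = days["mean_gap"]
        group_means[S.IDD_MEAN_GAP][fi_val] = float(np.nanmean(
            np.abs(mg[d1] - mg[d2])))

    for name, means in group_means.items():
        expected[name] = means[1] - means[0]
        exact[name] = False

    return GroundTruth(expected_effects=expected, exact=exact,
                       mediation=_plugin_mediation(cfg), config=cfg.to_dict())
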