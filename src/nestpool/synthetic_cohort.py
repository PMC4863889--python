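"""Synthetic longitudinal cohorts with the statistical structure the model assumes.

The generator is the nested-domain model run forwards: person and
person-by-domain random intercepts and slopes induce within-domain outcome
correlation, residuals are Student-t, and group/exposure effects enter on
the standardized scale.  Marginals mirror the study cohort it stands in
for: 53 exposed / 104 matched controls, three waves (0, 18, 36 months)
with wave-specific retention, age ~ 70 +/- 6 years, WTAR IQ ~ 110 +/- 6.5,
~41% female, a highly right-skewed loss-of-consciousness duration (median
10 min, range 0.03-30240 min, log10-scale mixture) and age at first injury
(median 18, range 4-67 years).  Raw outcome columns get instrument-
plausible offsets/scales (cosmetic only — all inference happens after
standardization); "lower is better" columns are emitted on their natural
inverted scale.

Component SDs are calibrated so the standardized latent outcome has total
variance ~1 at baseline, hence recorded true effects live on (approximately)
the same scale the analysis reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .battery_schema import DomainMap, default_domain_map

__all__ = ["CohortParams", "SyntheticTruth", "generate_cohort", "null_cohort", "scenario_library"]


# cosmetic raw units per outcome: (offset, scale); orientation handled via the map
_RAW_UNITS = {
    "digit_span_total": (17.0, 4.0),
    "digit_symbol_coding": (55.0, 12.0),
    "stroop_words": (45.0, 12.0),
    "stroop_dots": (25.0, 6.0),
    "logical_memory_1": (13.0, 4.0),
    "logical_memory_2": (11.0, 4.0),
    "cvlt_total_learning": (45.0, 10.0),
    "cvlt_short_delay": (9.0, 3.0),
    "cvlt_long_delay": (9.0, 3.5),
    "cvlt_recognition": (14.0, 1.5),
    "cvlt_dprime": (3.0, 0.8),
    "rcft_copy": (32.0, 3.0),
    "rcft_copy_time": (180.0, 60.0),
    "rcft_recall_3min": (15.0, 6.0),
    "rcft_recall_30min": (15.0, 6.0),
    "rcft_recognition": (20.0, 2.0),
    "bnt": (27.0, 2.5),
    "letter_fluency": (40.0, 11.0),
    "category_fluency": (19.0, 5.0),
    "switching_fluency": (13.0, 3.0),
    "stroop_colours": (30.0, 8.0),
    "stroop_interference": (1.25, 0.2),
}

_LOC_LOG10_MIN = np.log10(0.03)
_LOC_LOG10_MAX = np.log10(30240.0)


@dataclass
class CohortParams:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_exposed: int = 53
    n_control: int = 104
    # retention per wave beyond baseline (independent Bernoulli given group;
    # the sessions tabulation shows nobody with a single session, so wave-1
    # retention defaults to 1)
    retention_exposed: tuple[float, float] = (1.0, 52.0 / 53.0)
    retention_control: tuple[float, float] = (1.0, 89.0 / 104.0)

    # true effects, standardized scale; per-outcome overrides on top of base values
    intercept_control: float = 0.0
    slope_control: float = -0.05  # modest age-related decline per 18 months
    contrast_intercept: dict[str, float] = field(default_factory=dict)  # exposed - control
    contrast_slope: dict[str, float] = field(default_factory=dict)  # interaction
    loc_effect: dict[str, float] = field(default_factory=dict)  # per SD of log10 LOC
    ageinj_effect: dict[str, float] = field(default_factory=dict)  # per SD of age at injury

    # random-effect SDs (standardized scale)
    sigma_u: float = 0.5  # person intercept
    sigma_w: float = 0.12  # person slope
    sigma_v: float = 0.3  # person x domain intercept
    sigma_z: float = 0.08  # person x domain slope

    # residual: t scale and df per outcome (overrides on top of base values)
    sigma_resid: float = 0.703  # => baseline total variance ~= 1 at nu = 8
    nu_resid: float = 8.0
    sigma_resid_overrides: dict[str, float] = field(default_factory=dict)
    nu_resid_overrides: dict[str, float] = field(default_factory=dict)

    # covariate distributions
    age_mean: float = 70.2
    age_sd: float = 5.7
    wtar_mean: float = 110.2
    wtar_sd: float = 6.5
    p_female: float = 0.41
    education_probs: tuple[float, float, float] = (0.37, 0.14, 0.49)
    apoe_probs: tuple[float, float, float] = (0.67, 0.29, 0.04)

    # log10 LOC-minutes mixture (minutes-scale bump + long tail to weeks),
    # truncated to the printed range; calibrated so the median is ~10 min
    loc_mix_weight: float = 0.8
    loc_comp1: tuple[float, float] = (0.83, 0.55)
    loc_comp2: tuple[float, float] = (2.9, 0.8)
    # age at first injury: lognormal around median 18, truncated to [4, 67]
    ageinj_log_mean: float = float(np.log(18.0))
    ageinj_log_sd: float = 0.55

    seed: int = 0
    dmap: DomainMap = field(default_factory=default_domain_map)

    def validate(self) -> None:
        for p in (*self.retention_exposed, *self.retention_control, self.p_female):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.sigma_u, self.sigma_w, self.sigma_v, self.sigma_z, self.sigma_resid):
            if s < 0:
                raise ValueError("SDs must be >= 0")
        for d in (self.nu_resid, *self.nu_resid_overrides.values()):
            if d <= 2:
                raise ValueError("residual df must exceed 2 (finite variance)")
        known = set(self.dmap.outcome_ids)
        for dct in (
            self.contrast_intercept,
            self.contrast_slope,
            self.loc_effect,
            self.ageinj_effect,
            self.sigma_resid_overrides,
            self.nu_resid_overrides,
        ):
            unknown = set(dct) - known
            if unknown:
                raise ValueError(f"effects reference unknown outcomes: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Every generator parameter actually used, plus realized random effects."""

    params: CohortParams
    intercept_control: dict[str, float]
    intercept_exposed: dict[str, float]
    slope_control: dict[str, float]
    slope_exposed: dict[str, float]
    contrast_intercept: dict[str, float]
    contrast_slope: dict[str, float]
    loc_effect: dict[str, float]
    ageinj_effect: dict[str, float]
    subject_u: np.ndarray
    subject_w: np.ndarray
    subject_v: np.ndarray  # (S, D)
    subject_z: np.ndarray  # (S, D)

    def to_dict(self) -> dict:
        return {
            "seed": self.params.seed,
            "intercept_control": self.intercept_control,
            "intercept_exposed": self.intercept_exposed,
            "slope_control": self.slope_control,
            "slope_exposed": self.slope_exposed,
            "contrast_intercept": self.contrast_intercept,
            "contrast_slope": self.contrast_slope,
            "loc_effect": self.loc_effect,
            "ageinj_effect": self.ageinj_effect,
        }


def _truncated_mixture_log10_loc(rng: np.random.Generator, params: CohortParams, size: int):
    out = np.empty(size)
    filled = 0
    while filled < size:
        take = size - filled
        comp = rng.random(take) < params.loc_mix_weight
        mean = np.where(comp, params.loc_comp1[0], params.loc_comp2[0])
        sd = np.where(comp, params.loc_comp1[1], params.loc_comp2[1])
        draw = rng.normal(mean, sd)
        ok = (draw >= _LOC_LOG10_MIN) & (draw <= _LOC_LOG10_MAX)
        n_ok = int(ok.sum())
        out[filled : filled + n_ok] = draw[ok]
        filled += n_ok
    return out


def _truncated_lognormal_ageinj(rng: np.random.Generator, params: CohortParams, size: int):
    out = np.empty(size)
    filled = 0
    while filled < size:
        take = size - filled
        draw = np.exp(rng.normal(params.ageinj_log_mean, params.ageinj_log_sd, take))
        ok = (draw >= 4.0) & (draw <= 67.0)
        n_ok = int(ok.sum())
        out[filled : filled + n_ok] = draw[ok]
        filled += n_ok
    return out


def generate_cohort(params: Optional[CohortParams] = None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a long-format battery table plus its ground truth.

    The same ``params`` (including seed) reproduce table and truth
    bit-exactly.  Attrition is monotone under the default retention values
    (everyone has a baseline row; wave presence is Bernoulli per later
    wave).
    """
    params = params or CohortParams()
    params.validate()
    dmap = params.dmap
    rng = np.random.default_rng(params.seed)
    K, D = dmap.n_outcomes, dmap.n_domains
    out_ids = dmap.outcome_ids
    dom_of = dmap.domain_index_of_outcome()

    n_exp, n_ctl = params.n_exposed, params.n_control
    S = n_exp + n_ctl
    exposed = np.concatenate([np.ones(n_exp, dtype=bool), np.zeros(n_ctl, dtype=bool)])
    subject_ids = np.array(
        [f"x{i + 1:03d}" for i in range(n_exp)] + [f"c{i + 1:03d}" for i in range(n_ctl)]
    )

    # covariates (time-constant; both groups share distributions — matched design)
    age = rng.normal(params.age_mean, params.age_sd, S)
    wtar = rng.normal(params.wtar_mean, params.wtar_sd, S)
    sex = np.where(rng.random(S) < params.p_female, "F", "M")
    education = rng.choice(["7-12", "13-15", "15+"], size=S, p=params.education_probs)
    apoe = rng.choice([0, 1, 2], size=S, p=params.apoe_probs)

    loc_minutes = np.full(S, np.nan)
    age_first_injury = np.full(S, np.nan)
    log10_loc = np.full(S, np.nan)
    loc_draw = _truncated_mixture_log10_loc(rng, params, n_exp)
    loc_minutes[:n_exp] = np.round(10.0**loc_draw, 3)
    log10_loc[:n_exp] = np.log10(loc_minutes[:n_exp])
    age_first_injury[:n_exp] = np.round(
        _truncated_lognormal_ageinj(rng, params, n_exp), 1
    )

    # exposure features enter the mean standardized within the exposed group,
    # which is exactly how the analysis codes them
    def _z(v):
        m, s = np.nanmean(v), np.nanstd(v)
        return (v - m) / (s if s > 0 else 1.0)

    logloc_z = np.full(S, 0.0)
    ageinj_z = np.full(S, 0.0)
    logloc_z[:n_exp] = _z(log10_loc[:n_exp])
    ageinj_z[:n_exp] = _z(age_first_injury[:n_exp])

    # random effects
    u = rng.normal(0.0, params.sigma_u, S)
    w = rng.normal(0.0, params.sigma_w, S)
    v = rng.normal(0.0, params.sigma_v, (S, D))
    z = rng.normal(0.0, params.sigma_z, (S, D))

    # composed true effects per outcome
    ic = {k: params.intercept_control for k in out_ids}
    sc = {k: params.slope_control for k in out_ids}
    cint = {k: params.contrast_intercept.get(k, 0.0) for k in out_ids}
    cslp = {k: params.contrast_slope.get(k, 0.0) for k in out_ids}
    locf = {k: params.loc_effect.get(k, 0.0) for k in out_ids}
    ainf = {k: params.ageinj_effect.get(k, 0.0) for k in out_ids}
    sig_k = {k: params.sigma_resid_overrides.get(k, params.sigma_resid) for k in out_ids}
    nu_k = {k: params.nu_resid_overrides.get(k, params.nu_resid) for k in out_ids}

    # wave presence: baseline always; later waves Bernoulli per group
    present = np.ones((S, 3), dtype=bool)
    for wv in (1, 2):
        r_exp = params.retention_exposed[wv - 1]
        r_ctl = params.retention_control[wv - 1]
        p = np.where(exposed, r_exp, r_ctl)
        present[:, wv] = rng.random(S) < p

    rows = []
    for i in range(S):
        for wv in range(3):
            if not present[i, wv]:
                continue
            row = {
                "subject_id": subject_ids[i],
                "group": "exposed" if exposed[i] else "control",
                "wave": wv,
                "age_baseline": round(float(age[i]), 1),
                "sex": sex[i],
                "wtar_iq": round(float(wtar[i]), 1),
                "education_band": education[i],
                "apoe_e4": int(apoe[i]),
                "loc_minutes": loc_minutes[i] if exposed[i] else np.nan,
                "age_first_injury": age_first_injury[i] if exposed[i] else np.nan,
            }
            for j, oid in enumerate(out_ids):
                d = dom_of[oid]
                mean = (
                    ic[oid]
                    + (cint[oid] if exposed[i] else 0.0)
                    + (sc[oid] + (cslp[oid] if exposed[i] else 0.0)) * wv
                    + locf[oid] * logloc_z[i]
                    + ainf[oid] * ageinj_z[i]
                    + u[i]
                    + v[i, d]
                    + (w[i] + z[i, d]) * wv
                )
                y_std = mean + sig_k[oid] * rng.standard_t(nu_k[oid])
                offset, scale = _RAW_UNITS.get(oid, (0.0, 1.0))
                raw = offset + scale * dmap.orientation_of(oid) * y_std
                row[oid] = round(float(raw), 3)
            rows.append(row)

    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        params=params,
        intercept_control=ic,
        intercept_exposed={k: ic[k] + cint[k] for k in out_ids},
        slope_control=sc,
        slope_exposed={k: sc[k] + cslp[k] for k in out_ids},
        contrast_intercept=cint,
        contrast_slope=cslp,
        loc_effect=locf,
        ageinj_effect=ainf,
        subject_u=u,
        subject_w=w,
        subject_v=v,
        subject_z=z,
    )
    return table, truth


def null_cohort(seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Default cohort with every group contrast and exposure effect exactly 0."""
    params = CohortParams(seed=seed)
    params.contrast_intercept = {}
    params.contrast_slope = {}
    params.loc_effect = {}
    params.ageinj_effect = {}
    return generate_cohort(params)


def scenario_library(seed: int = 0) -> dict[str, CohortParams]:
    """Named presets spanning the effect ranges the analysis reports.

    * ``null`` — no group or exposure effects (calibration fixture);
    * ``paper_scale`` — intercept contrasts ~0.2 and slope (interaction)
      contrasts ~0.1 on the outcomes that showed the largest effects;
    * ``strong`` — 0.5 intercept / 0.2 slope contrasts on the same outcomes;
    * ``heavy_tails`` — null effects with nu = 3 residuals on two outcomes;
    * ``severity`` — LOC-duration effects ~-0.3 on the logical-memory
      outcomes, mirroring the exploratory severity estimates.
    """
    base = dict(seed=seed)
    presets = {
        "null": CohortParams(**base),
        "paper_scale": CohortParams(
            **base,
            contrast_intercept={
                "stroop_words": 0.24,
                "cvlt_recognition": 0.21,
                "letter_fluency": 0.21,
                "stroop_colours": 0.17,
                "stroop_dots": 0.20,
            },
            contrast_slope={
                "cvlt_recognition": 0.09,
                "cvlt_short_delay": 0.08,
                "category_fluency": 0.11,
            },
        ),
        "strong": CohortParams(
            **base,
            contrast_intercept={
                k: 0.5
                for k in (
                    "stroop_words",
                    "cvlt_recognition",
                    "letter_fluency",
                    "stroop_colours",
                    "stroop_dots",
                )
            },
            contrast_slope={
                k: 0.2 for k in ("cvlt_recognition", "cvlt_short_delay", "category_fluency")
            },
        ),
        "heavy_tails": CohortParams(
            **base,
            nu_resid_overrides={"logical_memory_1": 3.0, "stroop_words": 3.0},
        ),
        "severity": CohortParams(
            **base,
            loc_effect={"logical_memory_1": -0.26, "logical_memory_2": -0.29},
        ),
    }
    return presets


def get_scenario(name: str, seed: int = 0) -> CohortParams:
    presets = scenario_library(seed=seed)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]
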