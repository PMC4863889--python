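"""Nested-domain hierarchical model construction and joint log-posterior.

The model partially pools standardized effects at three levels: every
effect family (e.g. the exposed-group intercepts across the 22 outcomes)
has an overarching mean, domain-level deviations and outcome-level
deviations,

    beta_k = mu + delta_domain[d(k)] + delta_outcome[k],

with ``N(0, 100^2)`` prior on the overarching mean and half-Cauchy(1)
priors on the two hierarchy SDs.  Longitudinal dependence comes from
person and person-by-domain random intercepts and slopes (SDs uniform on
(0, 10)); residuals are Student-t per outcome with scale uniform on
(0, 10) and degrees of freedom nu = 1/eta, eta uniform on (0.001, 0.5),
so nu ranges over (2, 1000) and small nu actively down-weights outliers.

Three variants are built here:

* ``nested_group`` — per-group intercept and slope families (group and
  interaction contrasts are derived quantities, exposed minus control);
* ``nested_exposure`` — within-exposed severity (log10 LOC duration) and
  age-at-first-injury families plus time and covariate (age, WTAR, sex)
  families, all nested;
* ``agnostic`` — outcome effects independent with diffuse N(0, 1000^2)
  priors, no domain deviations and no person-by-domain random effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .battery_schema import DomainMap
from .preprocess import DesignData

__all__ = [
    "Family",
    "ModelSpec",
    "build_group_model",
    "build_exposure_model",
    "build_agnostic_model",
    "log_posterior",
    "MU_PRIOR_SD",
    "CAUCHY_SCALE",
    "SD_BOUND",
    "ETA_BOUNDS",
    "AGNOSTIC_PRIOR_SD",
]

MU_PRIOR_SD = 100.0  # overarching effect prior SD
CAUCHY_SCALE = 1.0  # half-Cauchy scale for hierarchy SDs
SD_BOUND = 10.0  # uniform upper bound for random-effect and residual SDs
ETA_BOUNDS = (0.001, 0.5)  # eta = 1/nu; nu in (2, 1000)
AGNOSTIC_PRIOR_SD = 1000.0  # diffuse per-outcome prior in the agnostic variant


@dataclass(frozen=True)
class Family:
    """One effect family: a per-outcome coefficient vector on one regressor.

    ``x`` is the observation-level regressor (e.g. the exposed-group
    indicator, indicator x time, or a standardized subject covariate
    broadcast to observations).  ``nested=True`` gives the three-level
    composition mu + delta_domain + delta_outcome; ``nested=False`` gives
    independent per-outcome coefficients with prior SD ``prior_sd``.
    """

    name: str
    x: np.ndarray
    nested: bool = True
    prior_sd: float = AGNOSTIC_PRIOR_SD  # used only when nested=False

    def n_params(self, n_domains: int, n_outcomes: int) -> int:
        return (1 + n_domains + n_outcomes + 2) if self.nested else n_outcomes


@dataclass
class ModelSpec:
    """Fully specified likelihood + prior graph, ready for sampling.

    The parameter vector has a fixed documented ordering (see
    :meth:`param_names`); every free parameter has exactly one prior.
    """

    variant: str
    design: DesignData
    families: list[Family]
    use_u: bool = True  # person random intercept
    use_w: bool = True  # person random slope
    use_v: bool = True  # person-by-domain random intercept
    use_z: bool = True  # person-by-domain random slope
    fix_sigma: Optional[float] = None  # residual scale fixed (tests/toys)
    fix_nu: Optional[float] = None  # residual df fixed (tests/toys)
    mu_prior_sd: float = MU_PRIOR_SD
    cauchy_scale: float = CAUCHY_SCALE
    sd_bound: float = SD_BOUND
    eta_bounds: tuple[float, float] = ETA_BOUNDS

    # ---- layout ----------------------------------------------------------
    @property
    def n_outcomes(self) -> int:
        return self.design.n_outcomes

    @property
    def n_domains(self) -> int:
        return self.design.n_domains

    @property
    def re_flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.use_u, self.use_w, self.use_v, self.use_z)

    def param_names(self) -> list[str]:
        """Names of the *full* parameter vector (family/level/index), incl.
        individual random effects — the vector :func:`log_posterior` takes."""
        d = self.design
        names: list[str] = []
        for f in self.families:
            if f.nested:
                names.append(f"{f.name}/mu")
                names += [f"{f.name}/domain/{did}" for did in d.domain_ids]
                names += [f"{f.name}/outcome/{oid}" for oid in d.outcome_ids]
                names += [f"{f.name}/tau_domain", f"{f.name}/tau_outcome"]
            else:
                names += [f"{f.name}/outcome/{oid}" for oid in d.outcome_ids]
        if self.use_u:
            names += [f"re_u/{s}" for s in d.subject_ids]
        if self.use_w:
            names += [f"re_w/{s}" for s in d.subject_ids]
        if self.use_v:
            names += [f"re_v/{s}:{did}" for s in d.subject_ids for did in d.domain_ids]
        if self.use_z:
            names += [f"re_z/{s}:{did}" for s in d.subject_ids for did in d.domain_ids]
        for flag, nm in zip(self.re_flags, ("sigma_u", "sigma_w", "sigma_v", "sigma_z")):
            if flag:
                names.append(f"re/{nm}")
        if self.fix_sigma is None:
            names += [f"resid/sigma/{oid}" for oid in d.outcome_ids]
        if self.fix_nu is None:
            names += [f"resid/eta/{oid}" for oid in d.outcome_ids]
        return names

    def stored_param_names(self) -> list[str]:
        """Names of the parameters the sampler stores (hyper- and effect-level
        parameters; individual random effects are integrated over and not
        retained, eta is stored as nu = 1/eta)."""
        d = self.design
        names: list[str] = []
        for f in self.families:
            if f.nested:
                names.append(f"{f.name}/mu")
                names += [f"{f.name}/domain/{did}" for did in d.domain_ids]
                names += [f"{f.name}/outcome/{oid}" for oid in d.outcome_ids]
                names += [f"{f.name}/tau_domain", f"{f.name}/tau_outcome"]
            else:
                names += [f"{f.name}/outcome/{oid}" for oid in d.outcome_ids]
        for flag, nm in zip(self.re_flags, ("sigma_u", "sigma_w", "sigma_v", "sigma_z")):
            if flag:
                names.append(f"re/{nm}")
        if self.fix_sigma is None:
            names += [f"resid/sigma/{oid}" for oid in d.outcome_ids]
        if self.fix_nu is None:
            names += [f"resid/nu/{oid}" for oid in d.outcome_ids]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names())

    def x_matrix(self) -> np.ndarray:
        return np.column_stack([f.x for f in self.families])

    def to_json(self, path: str | Path) -> None:
        """Serialize the parameter naming/ordering and prior table for audit."""
        prior_table = {}
        for f in self.families:
            if f.nested:
                prior_table[f"{f.name}/mu"] = f"Normal(0, {self.mu_prior_sd}^2)"
                prior_table[f"{f.name}/domain/*"] = "Normal(0, tau_domain^2)"
                prior_table[f"{f.name}/outcome/*"] = "Normal(0, tau_outcome^2)"
                prior_table[f"{f.name}/tau_*"] = f"HalfCauchy({self.cauchy_scale})"
            else:
                prior_table[f"{f.name}/outcome/*"] = f"Normal(0, {f.prior_sd}^2)"
        prior_table["re/sigma_*"] = f"Uniform(0, {self.sd_bound})"
        prior_table["resid/sigma/*"] = (
            f"Uniform(0, {self.sd_bound})" if self.fix_sigma is None else f"fixed={self.fix_sigma}"
        )
        prior_table["resid/eta/*"] = (
            f"Uniform{self.eta_bounds}; nu = 1/eta"
            if self.fix_nu is None
            else f"nu fixed={self.fix_nu}"
        )
        Path(path).write_text(
            json.dumps(
                {
                    "variant": self.variant,
                    "families": [f.name for f in self.families],
                    "random_effects": dict(
                        zip(("u", "w", "v", "z"), self.re_flags)
                    ),
                    "stored_parameters": self.stored_param_names(),
                    "priors": prior_table,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# builders


def _subject_to_obs(design: DesignData, values: np.ndarray) -> np.ndarray:
    return values[design.subject_idx]


def build_group_model(design: DesignData, dmap: DomainMap) -> ModelSpec:
    """Group-by-time nested-domain model.

    Mean structure for observation (subject i, outcome k, time t):

        y = beta_int[g,k] + beta_slope[g,k] * t
            + u_i + v_{i,d(k)} + (w_i + z_{i,d(k)}) * t + eps_k

    with four nested effect families (per-group intercepts and slopes).
    The group contrast and the time-by-group interaction are derived draw-
    wise as exposed minus control, not free parameters.
    """
    groups = np.unique(design.subject_group)
    if groups.size < 2:
        raise ValueError("group model needs both exposed and control subjects")
    if np.unique(design.t).size < 2:
        raise ValueError("group model needs >=2 waves (slope unidentifiable)")
    g = design.g
    t = design.t
    families = [
        Family("intercept_control", 1.0 - g),
        Family("slope_control", (1.0 - g) * t),
        Family("intercept_exposed", g.copy()),
        Family("slope_exposed", g * t),
    ]
    return ModelSpec(variant="nested_group", design=design, families=families)


def build_exposure_model(design: DesignData, dmap: DomainMap) -> ModelSpec:
    """Within-exposed severity / age-at-injury model with covariates.

    Adds nested families for log10 LOC duration, age at first injury, time,
    and the covariates age at baseline, WTAR IQ and sex; random effects as
    in the group model.
    """
    if np.any(design.subject_group == 0):
        raise ValueError("exposure model takes exposed subjects only")
    for arr, nm in ((design.logloc_z, "log10 LOC"), (design.ageinj_z, "age at first injury")):
        if not np.any(np.isfinite(arr)):
            raise ValueError(f"exposure model requires {nm} values")
        finite = arr[np.isfinite(arr)]
        if np.unique(finite).size < 2:
            raise ValueError(f"zero variance exposure: {nm}")
    logloc = np.nan_to_num(design.logloc_z, nan=0.0)
    ageinj = np.nan_to_num(design.ageinj_z, nan=0.0)
    families = [
        Family("effect_logloc", _subject_to_obs(design, logloc)),
        Family("effect_age_injury", _subject_to_obs(design, ageinj)),
        Family("effect_time", design.t.copy()),
        Family("effect_age", _subject_to_obs(design, design.age_z)),
        Family("effect_wtar", _subject_to_obs(design, design.wtar_z)),
        Family("effect_sex", _subject_to_obs(design, design.sex01)),
    ]
    return ModelSpec(variant="nested_exposure", design=design, families=families)


def build_agnostic_model(
    design: DesignData, dmap: DomainMap, base: str = "group"
) -> ModelSpec:
    """Domain-agnostic exploratory variant.

    Per-outcome effects are independent with diffuse N(0, 1000^2) priors —
    no domain deviations, no hierarchy SDs.  Person-level random intercept
    and slope are retained (longitudinal dependence survives) but person-by-
    domain terms are dropped, since outcomes are not grouped into domains.
    For ``base="exposure"`` the covariate families are also dropped
    (supplementary exploratory analysis).
    """
    if base == "group":
        parent = build_group_model(design, dmap)
        keep = [f.name for f in parent.families]
    elif base == "exposure":
        parent = build_exposure_model(design, dmap)
        keep = ["effect_logloc", "effect_age_injury", "effect_time"]
    else:
        raise ValueError(f"unknown base {base!r}")
    families = [
        Family(f.name, f.x, nested=False, prior_sd=AGNOSTIC_PRIOR_SD)
        for f in parent.families
        if f.name in keep
    ]
    return ModelSpec(
        variant="agnostic",
        design=design,
        families=families,
        use_v=False,
        use_z=False,
    )


# ---------------------------------------------------------------------------
# log posterior


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((x / scale) ** 2)


def log_posterior(spec: ModelSpec, params: np.ndarray) -> float:
    """Joint log prior + log likelihood over observed cells only.

    ``params`` follows :meth:`ModelSpec.param_names` ordering.  Returns
    ``-inf`` outside prior support, a finite value on interior points.
    """
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(
            f"parameter vector has length {params.size}, spec requires {spec.n_params}"
        )
    d = spec.design
    K, D, S = d.n_outcomes, d.n_domains, d.n_subjects
    pos = 0
    lp = 0.0
    beta = np.zeros((len(spec.families), K))
    for fi, f in enumerate(spec.families):
        if f.nested:
            mu = params[pos]
            pos += 1
            dD = params[pos : pos + D]
            pos += D
            dO = params[pos : pos + K]
            pos += K
            tauD, tauO = params[pos], params[pos + 1]
            pos += 2
            if tauD <= 0 or tauO <= 0:
                return -np.inf
            lp += stats.norm.logpdf(mu, 0.0, spec.mu_prior_sd)
            lp += float(np.sum(stats.norm.logpdf(dD, 0.0, tauD)))
            lp += float(np.sum(stats.norm.logpdf(dO, 0.0, tauO)))
            lp += _half_cauchy_logpdf(tauD, spec.cauchy_scale)
            lp += _half_cauchy_logpdf(tauO, spec.cauchy_scale)
            beta[fi] = mu + dD[d.domain_of_outcome] + dO
        else:
            b = params[pos : pos + K]
            pos += K
            lp += float(np.sum(stats.norm.logpdf(b, 0.0, f.prior_sd)))
            beta[fi] = b

    mean = np.zeros(d.n_obs)
    for fi, f in enumerate(spec.families):
        mean += f.x * beta[fi][d.outcome_idx]

    pair = d.subject_idx * D + d.domain_idx
    re_vectors = {}
    for flag, nm, size in (
        (spec.use_u, "u", S),
        (spec.use_w, "w", S),
        (spec.use_v, "v", S * D),
        (spec.use_z, "z", S * D),
    ):
        if flag:
            re_vectors[nm] = params[pos : pos + size]
            pos += size
    re_sds = {}
    for flag, nm in zip(spec.re_flags, ("u", "w", "v", "z")):
        if flag:
            sd = params[pos]
            pos += 1
            if not (0.0 < sd < spec.sd_bound):
                return -np.inf
            re_sds[nm] = sd
            lp += float(np.sum(stats.norm.logpdf(re_vectors[nm], 0.0, sd)))
            # Uniform(0, bound) prior on the SD: constant inside support
            lp += -math.log(spec.sd_bound)
    if spec.use_u:
        mean += re_vectors["u"][d.subject_idx]
    if spec.use_w:
        mean += re_vectors["w"][d.subject_idx] * d.t
    if spec.use_v:
        mean += re_vectors["v"][pair]
    if spec.use_z:
        mean += re_vectors["z"][pair] * d.t

    if spec.fix_sigma is None:
        sigma = params[pos : pos + K]
        pos += K
        if np.any(sigma <= 0.0) or np.any(sigma >= spec.sd_bound):
            return -np.inf
        lp += -K * math.log(spec.sd_bound)
    else:
        sigma = np.full(K, float(spec.fix_sigma))
    if spec.fix_nu is None:
        eta = params[pos : pos + K]
        pos += K
        lo, hi = spec.eta_bounds
        if np.any(eta <= lo) or np.any(eta >= hi):
            return -np.inf
        nu = 1.0 / eta
        lp += -K * math.log(hi - lo)
    else:
        nu = np.full(K, float(spec.fix_nu))

    resid = d.y - mean
    k = d.outcome_idx
    lp += float(np.sum(stats.t.logpdf(resid, df=nu[k], loc=0.0, scale=sigma[k])))
    return float(lp)
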