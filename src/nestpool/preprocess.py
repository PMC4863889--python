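"""Raw battery tables -> model-ready standardized design data.

Transformations mirror the analysis conventions: timed measures are
sign-flipped so that larger always means better, every outcome and numeric
covariate is scaled to mean 0 / SD 1 pooled across groups and waves (so
standardized effects read like partial correlation coefficients), duration
of loss of consciousness is log10-transformed, and only observed outcome
cells enter the design (no imputation).  Also provides greedy 2:1
matched-control selection (exact on categorical keys, nearest-neighbour on
standardized numeric keys).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .battery_schema import DomainMap

__all__ = [
    "ScalingRecord",
    "DesignData",
    "MatchResult",
    "log_loc",
    "orient_and_standardize",
    "code_design",
    "match_controls",
    "stroop_interference",
]


def log_loc(minutes: float | np.ndarray) -> float | np.ndarray:
    """log10 of duration of loss of consciousness in minutes.

    The raw duration is extremely right-skewed (minutes to weeks), so the
    severity proxy enters the model on the log10 scale.
    """
    arr = np.asarray(minutes, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("loss-of-consciousness duration must be positive (minutes)")
    out = np.log10(arr)
    return float(out) if np.isscalar(minutes) or arr.ndim == 0 else out


def stroop_interference(colours: np.ndarray, dots: np.ndarray) -> np.ndarray:
    """Interference parameter: Stroop "Colours" time / "Dots" time."""
    c = np.asarray(colours, dtype=float)
    d = np.asarray(dots, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(d > 0, c / d, np.nan)


# ---------------------------------------------------------------------------


@dataclass
class ScalingRecord:
    """Means/SDs/orientations used for standardization; supports the inverse map.

    ``outcomes[oid] = (mean, sd, orientation)`` where mean/sd are computed on
    the *oriented* scale (after any sign flip), pooled over all non-missing
    observations across groups and waves.  ``covariates[name] = (mean, sd)``.
    """

    outcomes: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    covariates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def standardize_outcome(self, oid: str, raw: np.ndarray) -> np.ndarray:
        mean, sd, orient = self.outcomes[oid]
        return (orient * np.asarray(raw, dtype=float) - mean) / sd

    def raw_outcome(self, oid: str, std: np.ndarray) -> np.ndarray:
        mean, sd, orient = self.outcomes[oid]
        return orient * (np.asarray(std, dtype=float) * sd + mean)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "outcomes": {k: list(v) for k, v in self.outcomes.items()},
                    "covariates": {k: list(v) for k, v in self.covariates.items()},
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingRecord":
        raw = json.loads(Path(path).read_text())
        return cls(
            outcomes={k: (float(m), float(s), int(o)) for k, (m, s, o) in raw["outcomes"].items()},
            covariates={k: (float(m), float(s)) for k, (m, s) in raw["covariates"].items()},
        )


@dataclass
class DesignData:
    """Model-ready long design: one entry per observed outcome cell.

    Observation-level arrays (length ``n_obs``): standardized outcome value
    ``y``, subject / outcome / domain indices, group indicator ``g`` (1 =
    exposed) and time code ``t`` in wave units (one unit = 18 months, 0 at
    baseline).  Subject-level arrays (length ``n_subjects``) hold the
    standardized covariates; exposure features are NaN for controls.
    """

    y: np.ndarray
    subject_idx: np.ndarray
    outcome_idx: np.ndarray
    domain_idx: np.ndarray
    g: np.ndarray
    t: np.ndarray
    subject_ids: np.ndarray
    subject_group: np.ndarray  # 1 = exposed, per subject
    age_z: np.ndarray
    wtar_z: np.ndarray
    sex01: np.ndarray
    logloc_z: np.ndarray
    ageinj_z: np.ndarray
    outcome_ids: tuple[str, ...]
    domain_ids: tuple[str, ...]
    domain_of_outcome: np.ndarray  # outcome index -> domain index

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    @property
    def n_subjects(self) -> int:
        return int(self.subject_ids.size)

    @property
    def n_outcomes(self) -> int:
        return len(self.outcome_ids)

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    def restrict_to_exposed(self) -> "DesignData":
        """Design restricted to exposed subjects (severity/age-at-injury model)."""
        keep_subj = self.subject_group == 1
        new_index = -np.ones(self.n_subjects, dtype=np.int64)
        new_index[keep_subj] = np.arange(int(keep_subj.sum()))
        keep_obs = keep_subj[self.subject_idx]
        return DesignData(
            y=self.y[keep_obs],
            subject_idx=new_index[self.subject_idx[keep_obs]],
            outcome_idx=self.outcome_idx[keep_obs],
            domain_idx=self.domain_idx[keep_obs],
            g=self.g[keep_obs],
            t=self.t[keep_obs],
            subject_ids=self.subject_ids[keep_subj],
            subject_group=self.subject_group[keep_subj],
            age_z=self.age_z[keep_subj],
            wtar_z=self.wtar_z[keep_subj],
            sex01=self.sex01[keep_subj],
            logloc_z=self.logloc_z[keep_subj],
            ageinj_z=self.ageinj_z[keep_subj],
            outcome_ids=self.outcome_ids,
            domain_ids=self.domain_ids,
            domain_of_outcome=self.domain_of_outcome,
        )


def _standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    vals = np.sort(v[ok])  # sorted: moments independent of row order
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))  # sample SD, as R scale()
    if sd == 0:
        raise ValueError("zero variance")
    out = np.full_like(v, np.nan)
    out[ok] = (v[ok] - mean) / sd
    return out, mean, sd


def code_design(table: pd.DataFrame, dmap: DomainMap) -> DesignData:
    """Code groups, waves and covariates into a model-ready design.

    Equivalent to :func:`orient_and_standardize` but discards the scaling
    record.  ``g`` is 1 for exposed, 0 for control; ``t`` equals the wave
    index (one unit = 18 months), centred at baseline and deliberately not
    standardized so slopes read as change per 18 months.
    """
    design, _ = orient_and_standardize(table, dmap)
    return design


def orient_and_standardize(
    table: pd.DataFrame, dmap: DomainMap
) -> tuple[DesignData, ScalingRecord]:
    """Orient, standardize and flatten a battery table into design arrays.

    Orientation (sign flip of "lower is better" columns) is applied before
    scaling; means and SDs are pooled over both groups and all waves so that
    group and time effects live on one common standardized scale.  Missing
    cells are simply absent from the design (observed-data analysis).
    """
    unknown_groups = set(table["group"]) - {"exposed", "control"}
    if unknown_groups:
        raise ValueError(f"unknown group labels: {sorted(unknown_groups)}")
    unknown_waves = set(int(w) for w in table["wave"]) - {0, 1, 2}
    if unknown_waves:
        raise ValueError(f"unknown waves: {sorted(unknown_waves)}")

    scaling = ScalingRecord()

    # subject-level frame (covariates are time-constant; take first row)
    subj = (
        table.sort_values(["subject_id", "wave"])
        .groupby("subject_id", sort=True)
        .first()
        .reset_index()
    )
    subject_ids = subj["subject_id"].to_numpy()
    sub_index = {sid: i for i, sid in enumerate(subject_ids)}
    subject_group = (subj["group"] == "exposed").to_numpy().astype(np.int64)

    age_z, m, s = _standardize(subj["age_baseline"].to_numpy(dtype=float))
    scaling.covariates["age_baseline"] = (m, s)
    wtar_z, m, s = _standardize(subj["wtar_iq"].to_numpy(dtype=float))
    scaling.covariates["wtar_iq"] = (m, s)
    sex01 = subj["sex"].map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
    if np.any(~np.isfinite(sex01)):
        raise ValueError("sex column must contain only 'F'/'M'")

    logloc_z = np.full(len(subj), np.nan)
    ageinj_z = np.full(len(subj), np.nan)
    exposed = subject_group == 1
    if "loc_minutes" in subj.columns and subj.loc[exposed, "loc_minutes"].notna().any():
        ll = np.full(len(subj), np.nan)
        has = exposed & subj["loc_minutes"].notna().to_numpy()
        ll[has] = log_loc(subj.loc[has, "loc_minutes"].to_numpy(dtype=float))
        logloc_z, m, s = _standardize_masked(ll)
        scaling.covariates["log10_loc_minutes"] = (m, s)
    if "age_first_injury" in subj.columns and subj.loc[exposed, "age_first_injury"].notna().any():
        ai = np.full(len(subj), np.nan)
        has = exposed & subj["age_first_injury"].notna().to_numpy()
        ai[has] = subj.loc[has, "age_first_injury"].to_numpy(dtype=float)
        ageinj_z, m, s = _standardize_masked(ai)
        scaling.covariates["age_first_injury"] = (m, s)

    # outcome observations, long
    dom_of = dmap.domain_index_of_outcome()
    out_index = {o: i for i, o in enumerate(dmap.outcome_ids)}
    ys, sidx, oidx, didx, gs, ts = [], [], [], [], [], []
    for oid in dmap.outcome_ids:
        if oid not in table.columns:
            raise ValueError(f"outcome column {oid!r} missing from table")
        raw = table[oid].to_numpy(dtype=float)
        ok = np.isfinite(raw)
        if np.unique(raw[ok]).size < 2:
            raise ValueError(f"zero variance: outcome {oid!r} needs >=2 distinct values")
        oriented = dmap.orientation_of(oid) * raw
        vals = np.sort(oriented[ok])  # sorted: moments independent of row order
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        scaling.outcomes[oid] = (mean, sd, dmap.orientation_of(oid))
        z = (oriented[ok] - mean) / sd
        rows = table.loc[ok]
        ys.append(z)
        sidx.append(rows["subject_id"].map(sub_index).to_numpy(dtype=np.int64))
        oidx.append(np.full(ok.sum(), out_index[oid], dtype=np.int64))
        didx.append(np.full(ok.sum(), dom_of[oid], dtype=np.int64))
        gs.append((rows["group"] == "exposed").to_numpy().astype(np.float64))
        ts.append(rows["wave"].to_numpy(dtype=float))

    design = DesignData(
        y=np.concatenate(ys),
        subject_idx=np.concatenate(sidx),
        outcome_idx=np.concatenate(oidx),
        domain_idx=np.concatenate(didx),
        g=np.concatenate(gs),
        t=np.concatenate(ts),
        subject_ids=subject_ids,
        subject_group=subject_group,
        age_z=age_z,
        wtar_z=wtar_z,
        sex01=sex01,
        logloc_z=logloc_z,
        ageinj_z=ageinj_z,
        outcome_ids=tuple(dmap.outcome_ids),
        domain_ids=tuple(dmap.domain_ids),
        domain_of_outcome=np.array([dom_of[o] for o in dmap.outcome_ids], dtype=np.int64),
    )
    return design, scaling


def _standardize_masked(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    ok = np.isfinite(v)
    vals = np.sort(v[ok])
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if ok.sum() > 1 else 0.0
    if not sd > 0:
        raise ValueError("zero variance exposure")
    out = np.full_like(v, np.nan)
    out[ok] = (v[ok] - mean) / sd
    return out, mean, sd


# ---------------------------------------------------------------------------
# matched-control selection

_KEY_COLUMNS = {
    "age": ("age_baseline", "numeric"),
    "sex": ("sex", "categorical"),
    "wtar": ("wtar_iq", "numeric"),
    "apoe": ("apoe_e4", "categorical"),
    "education": ("education_band", "categorical"),
}


@dataclass
class MatchResult:
    """Selected controls plus a per-case log of who matched whom."""

    table: pd.DataFrame  # battery rows (all waves) of selected controls
    log: pd.DataFrame  # case_id, control_id, distance
    warnings: list[str]


def match_controls(
    pool: pd.DataFrame,
    cases: pd.DataFrame,
    ratio: int = 2,
    keys: Sequence[str] = ("age", "sex", "wtar", "apoe", "education"),
    seed: int = 0,
) -> MatchResult:
    """Greedy ratio:1 matched-control selection without replacement.

    Exact matching on categorical keys (sex, APOE allele count, education
    band) and nearest-neighbour Euclidean distance on standardized numeric
    keys (age, WTAR).  Cases are processed in subject-id order; ties are
    broken with a seeded RNG.  Cases with fewer than ``ratio`` eligible
    controls keep whatever is available ("where possible") and are logged.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    overlap = set(pool["subject_id"]) & set(cases["subject_id"])
    if overlap:
        raise ValueError(f"pool and cases overlap: {sorted(overlap)[:5]}")

    pool_s = pool[pool["wave"] == 0].set_index("subject_id")
    case_s = cases[cases["wave"] == 0].set_index("subject_id")

    cat_keys = [k for k in keys if _KEY_COLUMNS[k][1] == "categorical"]
    num_keys = [k for k in keys if _KEY_COLUMNS[k][1] == "numeric"]
    num_cols = [_KEY_COLUMNS[k][0] for k in num_keys]
    cat_cols = [_KEY_COLUMNS[k][0] for k in cat_keys]

    # standardize numeric keys over pool + cases jointly
    scales = {}
    for col in num_cols:
        both = np.concatenate(
            [pool_s[col].to_numpy(dtype=float), case_s[col].to_numpy(dtype=float)]
        )
        scales[col] = (float(np.nanmean(both)), float(np.nanstd(both)) or 1.0)

    rng = np.random.default_rng(seed)
    available = set(pool_s.index)
    records = []
    warnings: list[str] = []

    for cid in sorted(case_s.index):
        case_row = case_s.loc[cid]
        elig = [
            pid
            for pid in sorted(available)
            if all(pool_s.at[pid, c] == case_row[c] for c in cat_cols)
        ]
        if num_cols:
            dists = np.array(
                [
                    math.sqrt(
                        sum(
                            ((pool_s.at[pid, c] - case_row[c]) / scales[c][1]) ** 2
                            for c in num_cols
                        )
                    )
                    for pid in elig
                ]
            )
        else:
            dists = np.zeros(len(elig))
        picked = 0
        while picked < ratio and elig:
            best = np.min(dists)
            tied = np.flatnonzero(dists <= best + 1e-12)
            j = int(rng.choice(tied))
            pid = elig.pop(j)
            d = float(dists[j])
            dists = np.delete(dists, j)
            available.discard(pid)
            records.append({"case_id": cid, "control_id": pid, "distance": d})
            picked += 1
        if picked < ratio:
            warnings.append(
                f"case {cid}: only {picked} of {ratio} eligible controls available"
            )

    log = pd.DataFrame(records, columns=["case_id", "control_id", "distance"])
    chosen = set(log["control_id"]) if len(log) else set()
    table = pool[pool["subject_id"].isin(chosen)].copy()
    return MatchResult(table=table, log=log, warnings=warnings)
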