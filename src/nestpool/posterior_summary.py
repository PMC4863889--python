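"""Reporting surface: posterior means, 80%/95% HDIs, contrasts.

Outcome-level effects are composed draw-wise, beta_k = mu + delta_domain +
delta_outcome, before summarizing; domain-level effects use mu +
delta_domain.  Group and interaction contrasts are elementwise draw
differences (exposed minus control).  Intervals are highest-density
intervals computed with the sorted shortest-window estimator (unimodal
assumption); all quantities are reported on the standardized scale, where
they read like partial correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .inference import Diagnostics, PosteriorDraws, effective_sample_size, gelman_rubin
from .nested_model import ModelSpec

__all__ = ["hdi", "summarize", "group_contrast", "composed_effect_draws", "SUMMARY_COLUMNS"]

SUMMARY_COLUMNS = (
    "quantity",
    "level",
    "domain",
    "outcome",
    "mean",
    "hdi80_lo",
    "hdi80_hi",
    "hdi95_lo",
    "hdi95_hi",
    "psrf",
    "ess",
)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (unimodal HDI).

    Sorted-window estimator: among all windows of ceil(mass*n) consecutive
    sorted draws, return the narrowest.  Deterministic; ties resolve to the
    first (lowest) window.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError("HDI needs at least 10 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def composed_effect_draws(
    draws: PosteriorDraws, spec: ModelSpec, family: str
) -> tuple[np.ndarray, np.ndarray]:
    """Draw-wise composed effects for one family.

    Returns ``(outcome_draws, domain_draws)`` with shapes
    (n_draws_total, K) and (n_draws_total, D): outcome effects are
    mu + delta_domain + delta_outcome; domain effects are mu + delta_domain.
    For a non-nested (agnostic) family the outcome draws are the raw
    coefficients and the domain draws are their within-domain means.
    """
    d = spec.design
    fam = next((f for f in spec.families if f.name == family), None)
    if fam is None:
        raise KeyError(f"family {family!r} not in spec ({[f.name for f in spec.families]})")
    out_names = [f"{family}/outcome/{oid}" for oid in d.outcome_ids]
    for nm in out_names:
        if nm not in draws.names:
            raise KeyError(f"draws are missing parameter {nm!r}")
    out = np.stack([draws.flat(nm) for nm in out_names], axis=1)
    if fam.nested:
        mu = draws.flat(f"{family}/mu")[:, None]
        dom = np.stack(
            [draws.flat(f"{family}/domain/{did}") for did in d.domain_ids], axis=1
        )
        outcome_draws = mu + dom[:, d.domain_of_outcome] + out
        domain_draws = mu + dom
    else:
        outcome_draws = out
        domain_draws = np.stack(
            [
                out[:, d.domain_of_outcome == di].mean(axis=1)
                for di in range(d.n_domains)
            ],
            axis=1,
        )
    return outcome_draws, domain_draws


def group_contrast(
    draws: PosteriorDraws, spec: ModelSpec, family_pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise contrast draws (first family minus second).

    For ``(intercept_exposed, intercept_control)`` this is the chronic group
    contrast; for the slope pair it is the time-by-group interaction
    contrast.  Returns (outcome_contrast_draws, domain_contrast_draws).
    """
    a_out, a_dom = composed_effect_draws(draws, spec, family_pair[0])
    b_out, b_dom = composed_effect_draws(draws, spec, family_pair[1])
    if a_out.shape != b_out.shape:
        raise ValueError("family shapes do not match")
    return a_out - b_out, a_dom - b_dom


def _summary_rows(
    quantity: str,
    level: str,
    labels: list[tuple[str, str]],
    draw_matrix: np.ndarray,
    chains: int,
) -> list[dict]:
    rows = []
    n_total = draw_matrix.shape[0]
    per_chain = n_total // chains
    for j, (dom_label, out_label) in enumerate(labels):
        col = draw_matrix[:, j]
        chain_view = col.reshape(chains, per_chain)
        lo80, hi80 = hdi(col, 0.80)
        lo95, hi95 = hdi(col, 0.95)
        psrf = float(gelman_rubin(chain_view)[0]) if chains > 1 else np.nan
        ess = float(effective_sample_size(chain_view)[0])
        rows.append(
            {
                "quantity": quantity,
                "level": level,
                "domain": dom_label,
                "outcome": out_label,
                "mean": float(col.mean()),
                "hdi80_lo": lo80,
                "hdi80_hi": hi80,
                "hdi95_lo": lo95,
                "hdi95_hi": hi95,
                "psrf": psrf,
                "ess": ess,
            }
        )
    return rows


def summarize(
    draws: PosteriorDraws,
    spec: ModelSpec,
    diagnostics: Optional[Diagnostics] = None,
) -> pd.DataFrame:
    """Per-quantity posterior summary table, in fixed domain order (D1..D7).

    One row per outcome- and domain-level effect for every family, plus
    exposed-minus-control contrast rows when both members of a group pair
    are present (intercept contrast, and slope contrast = time-by-group
    interaction).
    """
    d = spec.design
    out_labels = [
        (d.domain_ids[d.domain_of_outcome[j]], oid) for j, oid in enumerate(d.outcome_ids)
    ]
    dom_labels = [(did, "") for did in d.domain_ids]
    chains = draws.n_chains

    rows: list[dict] = []
    for f in spec.families:
        o_draws, dom_draws = composed_effect_draws(draws, spec, f.name)
        rows += _summary_rows(f.name, "outcome", out_labels, o_draws, chains)
        rows += _summary_rows(f.name, "domain", dom_labels, dom_draws, chains)

    fam_names = {f.name for f in spec.families}
    for contrast_name, pair in (
        ("contrast_intercept", ("intercept_exposed", "intercept_control")),
        ("contrast_slope", ("slope_exposed", "slope_control")),
    ):
        if set(pair) <= fam_names:
            o_c, d_c = group_contrast(draws, spec, pair)
            rows += _summary_rows(contrast_name, "outcome", out_labels, o_c, chains)
            rows += _summary_rows(contrast_name, "domain", dom_labels, d_c, chains)

    table = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    table.attrs["meta"] = dict(draws.meta)
    return table


def write_summary_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
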