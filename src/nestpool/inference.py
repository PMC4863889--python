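"""Posterior sampling and MCMC convergence diagnostics.

:func:`run_mcmc` draws from a :class:`~nestpool.nested_model.ModelSpec`
with the blocked Gibbs kernel (see :mod:`nestpool._gibbs`); draws are
bit-reproducible for a fixed seed.  :func:`gelman_rubin` implements the
classic two-sided potential scale reduction factor (no rank
normalization), and :func:`effective_sample_size` the initial-positive-
sequence autocorrelation estimator.  The convergence gate used by the
pipeline requires PSRF < 1.1 and ESS > 1000 for every reported parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._gibbs import gibbs_chain
from .nested_model import ModelSpec

__all__ = [
    "PosteriorDraws",
    "Diagnostics",
    "run_mcmc",
    "gelman_rubin",
    "effective_sample_size",
    "diagnose",
    "PSRF_THRESHOLD",
    "ESS_FLOOR",
]

PSRF_THRESHOLD = 1.1  # documented cut-off; the source protocol states monitoring only
ESS_FLOOR = 1000  # "more than 1000 effective samples" gate


@dataclass
class PosteriorDraws:
    """MCMC output: chains x iterations x named parameters, with provenance."""

    draws: np.ndarray  # (chains, kept_per_chain, n_params)
    names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, iterations)."""
        return self.draws[:, :, self.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.names if n.startswith(prefix)]

    def to_csv(self, path: str | Path) -> None:
        c, i, p = self.draws.shape
        frame = pd.DataFrame(self.draws.reshape(c * i, p), columns=list(self.names))
        frame.insert(0, "iteration", np.tile(np.arange(i), c))
        frame.insert(0, "chain", np.repeat(np.arange(c), i))
        frame.to_csv(path, index=False)


def run_mcmc(
    spec: ModelSpec,
    n_samples: int = 50_000,
    thin: int = 5,
    chains: int = 4,
    seed: int = 0,
    n_warmup: int = 5_000,
) -> PosteriorDraws:
    """Draw posterior samples from a model spec.

    Parameters
    ----------
    n_samples
        Total kept samples across all chains after warm-up and thinning
        (defaults mirror the analysis protocol: 50,000 kept, thinned every
        5th step; the original chain count is not stated, 4 is the default
        so that the Gelman-Rubin statistic is computable).
    thin
        Keep every ``thin``-th post-warm-up iteration.
    n_warmup
        Discarded warm-up iterations per chain.
    """
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if chains < 1:
        raise ValueError("chains must be >= 1")
    if n_samples < chains * 100:
        raise ValueError("n_samples must be at least 100 per chain")
    kept_per_chain = int(np.ceil(n_samples / chains))

    d = spec.design
    names = tuple(spec.stored_param_names())
    X = np.ascontiguousarray(spec.x_matrix(), dtype=np.float64)
    fam_nested = np.array([f.nested for f in spec.families], dtype=np.bool_)
    fam_prior_sd = np.array([f.prior_sd for f in spec.families], dtype=np.float64)
    pair = (d.subject_idx * d.n_domains + d.domain_idx).astype(np.int64)

    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the design matrix")
    if not np.all(np.isfinite(d.y)):
        raise ValueError("non-finite outcome values reached the sampler")

    chain_seeds = (np.random.SeedSequence(seed).generate_state(chains) % np.uint32(2**31)).astype(
        np.int64
    )
    out = np.empty((chains, kept_per_chain, len(names)), dtype=np.float64)
    for c in range(chains):
        store = np.empty((kept_per_chain, len(names)), dtype=np.float64)
        gibbs_chain(
            np.ascontiguousarray(d.y, dtype=np.float64),
            np.ascontiguousarray(d.subject_idx, dtype=np.int64),
            np.ascontiguousarray(d.outcome_idx, dtype=np.int64),
            np.ascontiguousarray(d.domain_idx, dtype=np.int64),
            pair,
            np.ascontiguousarray(d.t, dtype=np.float64),
            X,
            fam_nested,
            fam_prior_sd,
            d.n_subjects,
            d.n_domains,
            d.n_outcomes,
            spec.use_u,
            spec.use_w,
            spec.use_v,
            spec.use_z,
            -1.0 if spec.fix_sigma is None else float(spec.fix_sigma),
            -1.0 if spec.fix_nu is None else float(spec.fix_nu),
            spec.mu_prior_sd,
            spec.cauchy_scale,
            spec.sd_bound,
            spec.eta_bounds[0],
            spec.eta_bounds[1],
            int(n_warmup),
            kept_per_chain,
            int(thin),
            int(chain_seeds[c]),
            store,
        )
        out[c] = store
    if not np.all(np.isfinite(out)):
        raise RuntimeError("sampler produced non-finite draws; check the design data")

    meta = {
        "seed": int(seed),
        "chain_seeds": [int(s) for s in chain_seeds],
        "n_warmup": int(n_warmup),
        "n_kept": int(chains * kept_per_chain),
        "kept_per_chain": int(kept_per_chain),
        "thin": int(thin),
        "chains": int(chains),
        "sampler": "blocked-gibbs/t-scale-mixture",
        "variant": spec.variant,
    }
    return PosteriorDraws(draws=out, names=names, meta=meta)


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class Diagnostics:
    """Per-parameter PSRF and ESS with the pipeline convergence gate."""

    names: tuple[str, ...]
    psrf: np.ndarray
    ess: np.ndarray
    psrf_threshold: float = PSRF_THRESHOLD
    ess_floor: float = ESS_FLOOR

    @property
    def converged(self) -> bool:
        return bool(np.all(self.psrf < self.psrf_threshold) and np.all(self.ess > self.ess_floor))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "psrf": self.psrf,
                "ess": self.ess,
                "pass": (self.psrf < self.psrf_threshold) & (self.ess > self.ess_floor),
            }
        )


def _as_chain_array(draws) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(draws, PosteriorDraws):
        return draws.draws, draws.names
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected (chains, iterations) or (chains, iterations, params)")
    return arr, tuple(f"p{i}" for i in range(arr.shape[2]))


def gelman_rubin(draws) -> np.ndarray:
    """Potential scale reduction factor, classic two-sided form.

    PSRF = sqrt(Vhat+ / W) with W the mean within-chain variance, B the
    iteration count times the variance of the chain means, and
    Vhat+ = (n-1)/n * W + B/n.  No rank normalization and no chain
    splitting, matching the 1992 statistic.
    """
    arr, _ = _as_chain_array(draws)
    m, n, p = arr.shape
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    if n < 2:
        raise ValueError("PSRF requires at least 2 iterations per chain")
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B = n * arr.mean(axis=1).var(axis=0, ddof=1)
    vhat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(vhat / W)
    return psrf if psrf.size > 1 else psrf.reshape(-1)


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance (normalized by n) of one chain via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def effective_sample_size(draws) -> np.ndarray:
    """ESS via initial-positive-sequence autocorrelation summation.

    Autocorrelations are estimated per chain and pooled; the lag sum is
    truncated at the first nonpositive pair of adjacent autocorrelations
    (Geyer's initial positive sequence) with the pair sums additionally
    forced monotone non-increasing.  A constant chain has no information
    and reports ESS = 0 with a warning.
    """
    arr, _ = _as_chain_array(draws)
    m, n, p = arr.shape
    if n < 10:
        raise ValueError("ESS requires at least 10 iterations")
    ess = np.empty(p)
    for j in range(p):
        x = arr[:, :, j]
        acov = np.zeros(n)
        for c in range(m):
            acov += _autocovariance(x[c])
        acov /= m
        W = acov[0] * n / max(n - 1, 1)
        if W <= 0 or not np.isfinite(W):
            warnings.warn("constant chain: ESS undefined, reported as 0")
            ess[j] = 0.0
            continue
        if m > 1:
            B = n * x.mean(axis=1).var(ddof=1)
            var_plus = (n - 1) / n * W + B / n
        else:
            var_plus = (n - 1) / n * W + acov[0] / n
        rho = 1.0 - (W - acov * n / max(n - 1, 1)) / var_plus
        rho[0] = 1.0
        # Geyer initial positive (and monotone) sequence on pair sums
        tau = 0.0
        prev_pair = np.inf
        tmax = (n - 1) // 2
        total = -1.0
        for tpair in range(tmax):
            pair_sum = rho[2 * tpair] + rho[2 * tpair + 1]
            if pair_sum <= 0:
                break
            pair_sum = min(pair_sum, prev_pair)
            prev_pair = pair_sum
            total += 2.0 * pair_sum
        tau = max(total, 1e-12)
        ess[j] = min(m * n / tau, float(m * n))
    return ess


def diagnose(draws: PosteriorDraws, names: Optional[Sequence[str]] = None) -> Diagnostics:
    """PSRF + ESS for all (or selected) stored parameters."""
    if names is None:
        names = draws.names
        arr = draws.draws
    else:
        idx = [draws.names.index(n) for n in names]
        arr = draws.draws[:, :, idx]
    psrf = gelman_rubin(arr)
    ess = effective_sample_size(arr)
    return Diagnostics(names=tuple(names), psrf=np.atleast_1d(psrf), ess=np.atleast_1d(ess))
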