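"""Microbial source attribution by collapsed Gibbs sampling.

Estimates the proportions of a sink community drawn from each of a set of
candidate source communities plus an "Unknown" source.  Each sink read i of
taxon ``x_i`` carries a latent source assignment ``z_i`` resampled from

    P(z_i = v | .) ∝ P(x_i | v) * (n_v^{-i} + beta)

where for a known source ``v`` with fixed (rarefied) counts ``m``,

    P(x_i | v) = (m_{x_i, v} + alpha) / (m_v + alpha * T),

``T`` is the number of taxa and ``alpha`` a Dirichlet pseudocount
(default 0.001).  The Unknown source has no fixed counts; its taxon
distribution is learned from the reads currently assigned to it, with the
same ``alpha`` smoothing on every taxon.  ``beta`` is a symmetric Dirichlet
prior on the mixing proportions.  Sink and sources are rarefied to a common
depth (default 9,648) before sampling; proportions are averaged over
post-burn-in draws and independent restarts.

Sources are processed in sorted-id order so results do not depend on the
column order of the input table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

__all__ = ["SourceModel", "AttributionResult", "attribute", "attribute_per_group"]

UNKNOWN = "Unknown"


@dataclass
class SourceModel:
    """Source count matrix (taxon x source) plus sampler settings."""

    source_counts: pd.DataFrame
    alpha: float = 0.001
    beta: float = 1.0
    rarefaction_depth: int | None = 9648
    n_burnin: int = 100
    n_draws: int = 100
    thin: int = 10
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if (self.source_counts.values < 0).any():
            raise ValueError("negative source counts")
        if self.source_counts.columns.has_duplicates:
            raise ValueError("duplicate source ids")


@dataclass(frozen=True)
class AttributionResult:
    """Posterior-mean mixing proportions (summing to 1) and their spread."""

    proportions: dict[str, float]
    credible_sd: dict[str, float]
    n_reads: int

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("negative proportion")


@njit(cache=False)
def _gibbs_chain(x, m, alpha, beta, n_burnin, n_keep, thin, seed):
    """One restart; returns (n_keep, V+1) per-draw assignment proportions."""
    np.random.seed(seed)
    T, V = m.shape
    K = V + 1
    n = x.size
    p_fixed = np.empty((T, V))
    for v in range(V):
        mv = 0.0
        for t in range(T):
            mv += m[t, v]
        denom = mv + alpha * T
        for t in range(T):
            p_fixed[t, v] = (m[t, v] + alpha) / denom

    z = np.empty(n, dtype=np.int64)
    nv = np.zeros(K)
    u = np.zeros(T)
    usum = 0.0
    for i in range(n):
        zi = np.random.randint(0, K)
        z[i] = zi
        nv[zi] += 1.0
        if zi == V:
            u[x[i]] += 1.0
            usum += 1.0

    draws = np.zeros((n_keep, K))
    probs = np.empty(K)
    kept = 0
    total_sweeps = n_burnin + n_keep * thin
    for s in range(total_sweeps):
        for i in range(n):
            zi = z[i]
            t = x[i]
            nv[zi] -= 1.0
            if zi == V:
                u[t] -= 1.0
                usum -= 1.0
            tot = 0.0
            for v in range(V):
                probs[v] = p_fixed[t, v] * (nv[v] + beta)
                tot += probs[v]
            probs[V] = (u[t] + alpha) / (usum + alpha * T) * (nv[V] + beta)
            tot += probs[V]
            r = np.random.random() * tot
            acc = 0.0
            zi = K - 1
            for v in range(K):
                acc += probs[v]
                if r <= acc:
                    zi = v
                    break
            z[i] = zi
            nv[zi] += 1.0
            if zi == V:
                u[t] += 1.0
                usum += 1.0
        if s >= n_burnin and (s - n_burnin) % thin == thin - 1:
            for v in range(K):
                draws[kept, v] = nv[v] / n
            kept += 1
    return draws


def _rarefy_vector(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"depth {depth} infeasible: community has {total} reads")
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def attribute(
    sink_counts: pd.Series, model: SourceModel
) -> AttributionResult:
    """Posterior source proportions (plus Unknown) for one sink community."""
    sources = model.source_counts[sorted(model.source_counts.columns)]
    if not sink_counts.index.equals(sources.index):
        common = sink_counts.index.intersection(sources.index)
        if len(common) != len(sink_counts.index) or len(common) != len(sources.index):
            raise ValueError("sink and sources must share one taxon index")
        sources = sources.loc[sink_counts.index]

    rng = np.random.default_rng(model.seed)
    sink = sink_counts.to_numpy(dtype=np.int64)
    m = sources.to_numpy(dtype=np.int64)
    if model.rarefaction_depth is not None:
        d = model.rarefaction_depth
        sink = _rarefy_vector(sink, d, rng)
        m = np.column_stack(
            [_rarefy_vector(m[:, j], d, rng) for j in range(m.shape[1])]
        )

    # expand sink to per-read taxon indices
    x = np.repeat(np.arange(len(sink)), sink).astype(np.int64)
    if x.size == 0:
        raise ValueError("empty sink")

    chain_seeds = np.random.SeedSequence(model.seed).generate_state(
        model.n_restarts
    ) % (2**31 - 1)
    all_draws = [
        _gibbs_chain(
            x,
            m.astype(np.float64),
            model.alpha,
            model.beta,
            model.n_burnin,
            model.n_draws,
            model.thin,
            int(s),
        )
        for s in chain_seeds
    ]
    draws = np.vstack(all_draws)
    mean = draws.mean(axis=0)
    mean = mean / mean.sum()
    sd = draws.std(axis=0)
    names = list(sources.columns) + [UNKNOWN]
    return AttributionResult(
        {name: float(p) for name, p in zip(names, mean)},
        {name: float(s) for name, s in zip(names, sd)},
        int(x.size),
    )


def attribute_per_group(
    sink_counts: pd.Series,
    source_groups: Mapping[str, pd.DataFrame],
    model: SourceModel | None = None,
    **settings,
) -> dict[str, AttributionResult]:
    """Run one independent attribution per source group against the same sink.

    Mirrors the two-analysis design in which contaminated and uncontaminated
    source sets are evaluated separately; returns group name -> result.
    """
    if not source_groups:
        raise ValueError("no source groups")
    if model is None:
        first = next(iter(source_groups.values()))
        model = SourceModel(first, **settings)
    out = {}
    for name, counts in source_groups.items():
        if counts.shape[1] == 0:
            raise ValueError(f"source group {name!r} is empty")
        out[name] = attribute(
            sink_counts, dataclasses.replace(model, source_counts=counts)
        )
    return out


def explained_share(result: AttributionResult) -> float:
    """Total share of the sink explained by known sources (1 - Unknown)."""
    return 1.0 - result.proportions[UNKNOWN]
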