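"""Gut-catalog mapping ratio of long shotgun reads, with saturation analysis.

Protocol: reads are trimmed to a fixed length (400 bp; shorter reads are
discarded to keep read length homogeneous), a fixed number (10,000) is
subsampled without replacement, and each read is matched against the gut
gene catalog at >=90% identity over >=200 aligned bp.  The mapping ratio —
the fraction of prepared reads with a passing best hit — is the shotgun
contamination statistic.  The saturation curve tracks the ratio over nested
prefixes of one shuffled read order, emulating accumulation during a
real-time sequencing run, and reports the smallest depth whose ratio is
within a tolerance (default 1 percentage point) of the full-depth value.

The 90% identity threshold derives from ~94% intraspecies nucleotide
identity degraded by ~5% read error, rounded to the nearest ten.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matcher import (
    SHOTGUN_MIN_ALN_LEN,
    SHOTGUN_MIN_IDENTITY,
    KmerIndex,
    MatchPolicy,
    best_hit,
)
from .synthetic import ShotgunRead, ShotgunReadSet

__all__ = [
    "ShotgunProtocol",
    "SaturationCurve",
    "prepare_reads",
    "map_reads",
    "mapping_ratio",
    "saturation",
    "derive_identity_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_TRIM_LEN = 400
DEFAULT_SUBSAMPLE_N = 10_000


@dataclass(frozen=True)
class ShotgunProtocol:
    """Trim / subsample / threshold settings for the shotgun statistic."""

    trim_len: int = DEFAULT_TRIM_LEN
    subsample_n: int = DEFAULT_SUBSAMPLE_N
    policy: MatchPolicy = field(
        default_factory=lambda: MatchPolicy(SHOTGUN_MIN_IDENTITY, SHOTGUN_MIN_ALN_LEN)
    )
    seed: int = 0

    def __post_init__(self):
        if self.trim_len < self.policy.min_aln_len:
            raise ValueError("trim_len must be >= policy.min_aln_len")
        if self.subsample_n < 1:
            raise ValueError("subsample_n must be >= 1")


@dataclass
class SaturationCurve:
    """Mapping ratio at nested read-depth prefixes of one shuffled order."""

    depths: tuple[int, ...]
    ratios: tuple[float, ...]
    stable_depth: int
    tolerance_pp: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.depths)
        if not np.all(np.diff(d) > 0):
            raise ValueError("depths must be strictly increasing")
        if not all(0.0 <= r <= 1.0 for r in self.ratios):
            raise ValueError("ratios outside [0, 1]")


def derive_identity_threshold(
    intraspecies_identity: float = 94.0,
    error_rate: float = 0.05,
    round_to: int = 10,
) -> float:
    """Identity cutoff for species-level matching of error-prone reads.

    Intraspecies nucleotide identity degraded by the per-base error rate,
    rounded to the nearest ``round_to``: 94% * (1 - 0.05) -> 89.3 -> 90.
    """
    raw = intraspecies_identity * (1.0 - error_rate)
    return round(raw / round_to) * round_to


def prepare_reads(
    reads: ShotgunReadSet, protocol: ShotgunProtocol = ShotgunProtocol()
) -> ShotgunReadSet:
    """Trim to ``trim_len``, discard shorter reads, subsample without replacement.

    Reads shorter than the trim length are discarded (count logged), keeping
    the prepared set homogeneous in length.  If fewer than ``subsample_n``
    reads survive, all survivors are kept and a warning is issued.
    """
    survivors = [
        ShotgunRead(r.id, r.sequence[: protocol.trim_len], r.true_origin_id)
        for r in reads.reads
        if len(r.sequence) >= protocol.trim_len
    ]
    n_discarded = len(reads.reads) - len(survivors)
    if n_discarded:
        logger.info("discarded %d reads shorter than %d bp", n_discarded, protocol.trim_len)
    if not survivors:
        raise ValueError("zero reads survive trimming")
    rng = np.random.default_rng(protocol.seed)
    if len(survivors) >= protocol.subsample_n:
        idx = rng.choice(len(survivors), size=protocol.subsample_n, replace=False)
        survivors = [survivors[i] for i in sorted(idx)]
    else:
        warnings.warn(
            f"only {len(survivors)} reads survive trimming; "
            f"requested subsample of {protocol.subsample_n}",
            stacklevel=2,
        )
    return ShotgunReadSet(
        survivors, reads.error_rate, float(protocol.trim_len), 0.0
    )


def map_reads(
    prepared: ShotgunReadSet,
    catalog: Mapping[str, str],
    policy: MatchPolicy | None = None,
) -> np.ndarray:
    """Boolean per-read flags: best hit against the catalog passes the policy."""
    if not catalog:
        raise ValueError("empty catalog")
    if policy is None:
        policy = MatchPolicy(SHOTGUN_MIN_IDENTITY, SHOTGUN_MIN_ALN_LEN)
    index = KmerIndex(catalog)
    flags = np.zeros(len(prepared.reads), dtype=bool)
    for i, read in enumerate(prepared.reads):
        hit = best_hit(
            read.sequence, catalog, policy, query_id=read.id, index=index
        )
        flags[i] = hit is not None
    return flags


def mapping_ratio(
    prepared: ShotgunReadSet,
    catalog: Mapping[str, str],
    policy: MatchPolicy | None = None,
) -> float:
    """Fraction of prepared reads mapping to the gut catalog, in [0, 1]."""
    if not prepared.reads:
        raise ValueError("empty read set")
    return float(np.mean(map_reads(prepared, catalog, policy)))


def saturation(
    prepared: ShotgunReadSet,
    catalog: Mapping[str, str],
    policy: MatchPolicy | None = None,
    depths: Sequence[int] | None = None,
    tolerance_pp: float = 1.0,
    seed: int = 0,
    mapped_flags: np.ndarray | None = None,
) -> SaturationCurve:
    """Mapping ratio over cumulative prefixes of one seeded shuffle.

    ``stable_depth`` is the smallest depth whose ratio is within
    ``tolerance_pp`` percentage points of the full-depth ratio.
    ``mapped_flags`` may be supplied to reuse per-read match results.
    """
    n = len(prepared.reads)
    if depths is None:
        depths = [d for d in (100, 250, 500, 1000, 2500, 5000, 10000) if d <= n]
        if not depths or depths[-1] != n:
            depths = sorted(set(depths) | {n})
    depths = sorted(set(int(d) for d in depths))
    if depths[-1] > n:
        raise ValueError(f"max depth {depths[-1]} exceeds {n} prepared reads")
    if mapped_flags is None:
        mapped_flags = map_reads(prepared, catalog, policy)
    order = np.random.default_rng(seed).permutation(n)
    shuffled = mapped_flags[order]
    cum = np.cumsum(shuffled)
    ratios = tuple(float(cum[d - 1] / d) for d in depths)
    final = ratios[-1]
    stable = depths[-1]
    for d, r in zip(depths, ratios):
        if abs(r - final) * 100.0 < tolerance_pp:
            stable = d
            break
    return SaturationCurve(tuple(depths), ratios, stable, tolerance_pp)
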