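"""Faecal-indicator sets and the DNA-yield-normalised contamination index.

Three ways of defining the faecal-indicator organism (FIO) set over an
amplicon sequence-type table, in increasing order of breadth:

1. a single indicator genus (Escherichia/Shigella);
2. a curated multi-genus indicator list;
3. every sequence type with >=99% identity to a human-gut marker reference.

For each sample the raw FIO fraction (FIO reads / total reads) is scaled by
the DNA yield (ng DNA per ml water) as a proxy for absolute microbial
concentration, giving an index comparable across samples and against
culture-based MPN counts.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .matcher import AMPLICON_MIN_IDENTITY, KmerIndex, MatchPolicy, best_hit
from .mpn import MPNEstimate
from .tables import AmpliconTable, taxon_rank_token

__all__ = [
    "FIOSet",
    "ContaminationIndex",
    "CorrelationResult",
    "default_fio_list",
    "build_fio_set_by_taxon",
    "build_fio_set_by_identity",
    "contamination_index",
    "correlate_index_mpn",
    "genome_equivalents",
    "reads_needed",
]

AVOGADRO = 6.02214076e23
BP_MOLAR_MASS_G = 649.0  # mean molar mass of one DNA base pair, g/mol


@dataclass(frozen=True)
class FIOSet:
    """A set of sequence-type ids counted as faecal indicators."""

    member_ids: frozenset[str]
    definition: str  # taxon_single | taxon_list | identity_match
    params: tuple

    def __post_init__(self):
        if self.definition not in ("taxon_single", "taxon_list", "identity_match"):
            raise ValueError(f"unknown definition {self.definition!r}")


@dataclass(frozen=True)
class ContaminationIndex:
    sample_id: str
    raw_fraction: float  # FIO reads / total reads
    dna_yield: float  # ng/ml
    index: float  # raw_fraction * dna_yield, "FIO-ng/ml"
    zero_fio: bool = False  # flagged: excluded from log-scale plots


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n_used: int
    n_censored: int
    transform: str


def default_fio_list(path: str | Path | None = None) -> list[str]:
    """Load an FIO genus list (one name per line, '#' comments)."""
    if path is None:
        text = (
            importlib.resources.files("stormtrace.data")
            .joinpath("fio_default.txt")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    names = [ln.strip() for ln in text.splitlines()]
    return [n for n in names if n and not n.startswith("#")]


def build_fio_set_by_taxon(
    table: AmpliconTable, taxon_names: Sequence[str], rank: str = "genus"
) -> FIOSet:
    """Rows whose rank token matches any name (case-insensitive exact)."""
    if not taxon_names:
        raise ValueError("empty taxon list")
    wanted = {n.lower() for n in taxon_names}
    tokens = table.rank_tokens(rank)
    members = frozenset(tokens.index[tokens.str.lower().isin(wanted)])
    definition = "taxon_single" if len(taxon_names) == 1 else "taxon_list"
    return FIOSet(members, definition, tuple(taxon_names))


def build_fio_set_by_identity(
    table: AmpliconTable,
    gut_markers: Mapping[str, str],
    threshold: float = AMPLICON_MIN_IDENTITY,
    min_aln_frac: float = 0.9,
) -> FIOSet:
    """Rows whose best hit against gut markers reaches ``threshold`` identity.

    The alignment is semi-global with a minimum alignment length of
    ``min_aln_frac`` times the marker length (so partial-window matches do
    not qualify).
    """
    marker_len = int(np.median([len(s) for s in gut_markers.values()]))
    policy = MatchPolicy(
        min_identity=threshold,
        min_aln_len=max(1, int(min_aln_frac * marker_len)),
    )
    index = KmerIndex(gut_markers)
    members = set()
    for rid in table.row_ids:
        hit = best_hit(
            table.sequences[rid], gut_markers, policy, query_id=rid, index=index
        )
        if hit is not None:
            members.add(rid)
    return FIOSet(frozenset(members), "identity_match", (threshold,))


def contamination_index(
    table: AmpliconTable, fio_set: FIOSet
) -> list[ContaminationIndex]:
    """Per-sample FIO fraction times DNA yield.

    Samples with zero FIO reads keep index 0 and are flagged (they cannot
    appear on log-scale plots and are excluded from log-transformed
    correlations).
    """
    if "dna_yield" not in table.sample_meta.columns:
        raise ValueError("sample_meta must carry dna_yield")
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {zero}")
    members = [r for r in table.row_ids if r in fio_set.member_ids]
    fio_counts = (
        table.counts.loc[members].sum(axis=0) if members else totals * 0
    )
    out = []
    for sid in table.sample_ids:
        dna = float(table.sample_meta.loc[sid, "dna_yield"])
        if dna <= 0:
            raise ValueError(f"{sid}: dna_yield must be > 0")
        frac = float(fio_counts[sid] / totals[sid])
        out.append(
            ContaminationIndex(sid, frac, dna, frac * dna, zero_fio=frac == 0.0)
        )
    return out


def correlate_index_mpn(
    indices: Sequence[ContaminationIndex],
    mpn_estimates: Sequence[MPNEstimate],
    transform: str = "log10",
    zero_policy: str = "drop",
    censored_policy: str = "substitute",
) -> CorrelationResult:
    """Pearson correlation between the sequence index and culture MPN.

    Pairing is positional.  Censored MPNs (below/above the reporting limits)
    are substituted by the limit value (default, mirroring how such samples
    are plotted at the limits) or dropped.  Under log10, zero indices are
    dropped (default) or floored to half the smallest positive index.
    """
    if len(indices) != len(mpn_estimates):
        raise ValueError("indices and MPN estimates must pair 1:1")
    if transform not in ("log10", "none"):
        raise ValueError("transform must be log10 or none")
    if zero_policy not in ("drop", "floor"):
        raise ValueError("zero_policy must be drop or floor")
    if censored_policy not in ("substitute", "drop"):
        raise ValueError("censored_policy must be substitute or drop")

    xs, ys = [], []
    n_censored = 0
    positive = [ci.index for ci in indices if ci.index > 0]
    floor_val = 0.5 * min(positive) if positive else float("nan")
    for ci, est in zip(indices, mpn_estimates):
        if est.status != "point":
            if censored_policy == "drop":
                continue
            n_censored += 1
            y = est.lod if est.status == "below_lod" else est.uod
        else:
            y = est.mpn
        x = ci.index
        if transform == "log10":
            if x <= 0:
                if zero_policy == "drop" or not positive:
                    continue
                x = floor_val
            x = math.log10(x)
            y = math.log10(y)
        xs.append(x)
        ys.append(y)
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable pairs; need >= 3")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(float(r), float(p), len(xs), n_censored, transform)


def genome_equivalents(
    dna_ng_per_ml: float, genome_bp: float = 3e6, bp_molar_mass: float = BP_MOLAR_MASS_G
) -> float:
    """Bacterial genome equivalents per ml for a given DNA yield.

    One genome of ``genome_bp`` base pairs weighs
    ``genome_bp * bp_molar_mass / N_A`` grams (~3.23 fg at the defaults), so
    1.15 ng/ml of extracted DNA corresponds to ~3.6e5 genomes/ml.
    """
    if dna_ng_per_ml <= 0 or genome_bp <= 0 or bp_molar_mass <= 0:
        raise ValueError("all inputs must be > 0")
    genome_mass_g = genome_bp * bp_molar_mass / AVOGADRO
    return dna_ng_per_ml * 1e-9 / genome_mass_g


def reads_needed(total_genomes_per_ml: float, fio_cells_per_ml: float) -> float:
    """Expected sequencing reads per one FIO read: total / FIO concentration."""
    if fio_cells_per_ml <= 0:
        raise ValueError("fio_cells_per_ml must be > 0")
    return total_genomes_per_ml / fio_cells_per_ml
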