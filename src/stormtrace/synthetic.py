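"""Synthetic study system: references, communities, reads, tables, wells.

Stormwater is modelled as a two-pool mixture: a human-gut community whose
total weight is the contamination fraction ``f``, and an environmental
freshwater background carrying the rest.  Each "organism" contributes a
16S-like marker (amplicon analog) and a longer catalog gene (shotgun
mapping target).  Generators are pure functions of (config, seed):

* amplicon counts are multinomial at fixed depth over marker weights;
* shotgun reads are windows of catalog genes with i.i.d. per-base errors
  (default 5%, split 60/20/20 substitution/insertion/deletion — a
  long-read-like profile);
* culture wells turn positive with probability 1 - exp(-c*v/d);
* DNA yield is LogUniform(0.16, 3.73) ng/ml for clean water plus a term
  proportional to f, and the true E. coli concentration is proportional to
  f with lognormal noise, so culture counts and sequence indices are
  correlated by construction.

Environment markers are divergence-mutated copies of gut markers (same gene
family, well below the 99% identity threshold); environment catalog genes
are independent random sequences, far from the gut catalog at the 90%/200 bp
mapping thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mpn import WellClass, WellOutcome
from .tables import AmpliconTable
from .io import FastqRead, error_to_q

import pandas as pd

__all__ = [
    "ReferenceRecord",
    "ReferenceCollection",
    "CommunityProfile",
    "ShotgunRead",
    "ShotgunReadSet",
    "make_reference",
    "compose_community",
    "simulate_amplicon_table",
    "simulate_shotgun_reads",
    "simulate_wells",
    "DEFAULT_WELL_LAYOUT",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# genus -> (phylum, class); gut genera first (Escherichia/Shigella is the
# single-genus indicator), then freshwater background genera.
GUT_GENERA: dict[str, tuple[str, str]] = {
    "Escherichia/Shigella": ("Proteobacteria", "Gammaproteobacteria"),
    "Bacteroides": ("Bacteroidetes", "Bacteroidia"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia"),
    "Faecalibacterium": ("Firmicutes", "Clostridia"),
    "Blautia": ("Firmicutes", "Clostridia"),
    "Agathobacter": ("Firmicutes", "Clostridia"),
    "Anaerostipes": ("Firmicutes", "Clostridia"),
    "Subdoligranulum": ("Firmicutes", "Clostridia"),
    "Bifidobacterium": ("Actinobacteria", "Actinobacteria"),
    "Enterococcus": ("Firmicutes", "Bacilli"),
}
ENV_GENERA: dict[str, tuple[str, str]] = {
    "Flavobacterium": ("Bacteroidetes", "Flavobacteriia"),
    "Arcicella": ("Bacteroidetes", "Cytophagia"),
    "Pseudomonas": ("Proteobacteria", "Gammaproteobacteria"),
    "Acinetobacter": ("Proteobacteria", "Gammaproteobacteria"),
    "Limnohabitans": ("Proteobacteria", "Betaproteobacteria"),
    "Polynucleobacter": ("Proteobacteria", "Betaproteobacteria"),
    "Rhodoferax": ("Proteobacteria", "Betaproteobacteria"),
    "Variovorax": ("Proteobacteria", "Betaproteobacteria"),
    "Sphingomonas": ("Proteobacteria", "Alphaproteobacteria"),
    "Novosphingobium": ("Proteobacteria", "Alphaproteobacteria"),
}

DNA_YIELD_RANGE_NG_PER_ML = (0.16, 3.73)  # observed clean-water range
DEFAULT_YIELD_PER_F = 20.0  # extra ng/ml per unit contamination fraction
DEFAULT_CONC_PER_F = 2.0e6  # E. coli per 100 ml at f=1
DEFAULT_CONC_NOISE_SD = 0.3  # lognormal sd on ecoli_conc

# Quanti-Tray/2000-like two-volume tray: 49 large + 48 small wells per 100 ml.
DEFAULT_WELL_LAYOUT: tuple[tuple[float, int], ...] = ((1.86, 49), (0.186, 48))


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    sequence: str
    pool: str  # gut | environment
    taxon: str  # domain;phylum;class;genus
    kind: str  # marker | gene
    organism: str


@dataclass
class ReferenceCollection:
    """Labelled marker + catalog-gene sequences split into gut/environment pools."""

    records: list[ReferenceRecord]
    marker_len: int = 400
    gene_len_range: tuple[int, int] = (500, 2000)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids")
        for r in self.records:
            if set(r.sequence) - set("ACGT"):
                raise ValueError(f"{r.id}: non-ACGT characters")
            if r.pool not in ("gut", "environment"):
                raise ValueError(f"{r.id}: unknown pool {r.pool!r}")

    def _select(self, kind: str, pool: str | None) -> list[ReferenceRecord]:
        return [
            r
            for r in self.records
            if r.kind == kind and (pool is None or r.pool == pool)
        ]

    def markers(self, pool: str | None = None) -> list[ReferenceRecord]:
        return self._select("marker", pool)

    def genes(self, pool: str | None = None) -> list[ReferenceRecord]:
        return self._select("gene", pool)

    def organisms(self, pool: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if pool is None or r.pool == pool:
                seen.setdefault(r.organism, None)
        return list(seen)

    def pool_of(self, organism: str) -> str:
        for r in self.records:
            if r.organism == organism:
                return r.pool
        raise KeyError(organism)

    def marker_of(self, organism: str) -> ReferenceRecord:
        return self._by_kind(organism, "marker")

    def gene_of(self, organism: str) -> ReferenceRecord:
        return self._by_kind(organism, "gene")

    def _by_kind(self, organism: str, kind: str) -> ReferenceRecord:
        for r in self.records:
            if r.organism == organism and r.kind == kind:
                return r
        raise KeyError(f"{organism}/{kind}")

    def gene_catalog(self, pool: str = "gut") -> dict[str, str]:
        """id -> sequence mapping of catalog genes (shotgun mapping target)."""
        return {r.id: r.sequence for r in self.genes(pool)}

    def marker_catalog(self, pool: str = "gut") -> dict[str, str]:
        return {r.id: r.sequence for r in self.markers(pool)}


@dataclass
class CommunityProfile:
    """Per-sample ground truth: organism weights, f, DNA yield, E. coli conc."""

    sample_id: str
    weights: dict[str, float]  # organism id -> weight, sums to 1
    contamination_fraction: float
    dna_yield: float  # ng DNA per ml water
    ecoli_conc: float  # cells per 100 ml

    def __post_init__(self):
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, not 1")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination fraction outside [0, 1]")


@dataclass(frozen=True)
class ShotgunRead:
    id: str
    sequence: str
    true_origin_id: str | None


@dataclass
class ShotgunReadSet:
    reads: list[ShotgunRead]
    error_rate: float
    length_mean: float
    length_sd: float

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate outside [0, 1)")
        if not self.reads:
            raise ValueError("empty read set")

    def to_fastq_reads(self) -> list[FastqRead]:
        q = error_to_q(self.error_rate) if self.error_rate > 0 else 40.0
        return [
            FastqRead(r.id, r.sequence, np.full(len(r.sequence), round(q, 0)))
            for r in self.reads
        ]


# ------------------------------------------------------------- reference


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_substitutions(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Substitute exactly n_sub distinct positions, each to a different base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def make_reference(
    seed: int,
    n_gut: int = 12,
    n_env: int = 12,
    marker_len: int = 400,
    gene_len_range: tuple[int, int] = (500, 2000),
    divergence: float = 0.1,
    prefilter_k: int = 11,
) -> ReferenceCollection:
    """Generate gut and environment pools of markers + catalog genes.

    ``divergence`` sets the exact substitution fraction separating each
    environment marker from its gut template, so the maximum cross-pool
    marker identity is ~100*(1 - divergence) — below the 99% indicator
    threshold for any divergence above ~0.015.  Environment catalog genes
    are independent random sequences.  Deterministic for a fixed seed.
    """
    if n_gut < 1 or n_env < 1:
        raise ValueError("n_gut and n_env must be >= 1")
    if not 0.0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    if marker_len < 2 * prefilter_k or gene_len_range[0] < 2 * prefilter_k:
        raise ValueError(f"sequence lengths must be >= 2*k = {2 * prefilter_k}")
    if gene_len_range[0] > gene_len_range[1]:
        raise ValueError("bad gene_len_range")
    n_sub = round(divergence * marker_len)
    if n_sub < 1:
        raise ValueError("divergence too small for marker length")

    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    gut_genera = list(GUT_GENERA)
    env_genera = list(ENV_GENERA)

    gut_markers: list[str] = []
    for i in range(n_gut):
        org = f"gut{i + 1:03d}"
        genus = gut_genera[i % len(gut_genera)]
        phylum, cls = GUT_GENERA[genus]
        taxon = f"Bacteria;{phylum};{cls};{genus}"
        marker = _random_seq(rng, marker_len)
        gut_markers.append(marker)
        gene = _random_seq(rng, int(rng.integers(gene_len_range[0], gene_len_range[1] + 1)))
        records.append(ReferenceRecord(f"{org}|marker", marker, "gut", taxon, "marker", org))
        records.append(ReferenceRecord(f"{org}|gene", gene, "gut", taxon, "gene", org))

    for i in range(n_env):
        org = f"env{i + 1:03d}"
        genus = env_genera[i % len(env_genera)]
        phylum, cls = ENV_GENERA[genus]
        taxon = f"Bacteria;{phylum};{cls};{genus}"
        template = gut_markers[i % len(gut_markers)]
        marker = _mutate_substitutions(rng, template, n_sub)
        gene = _random_seq(rng, int(rng.integers(gene_len_range[0], gene_len_range[1] + 1)))
        records.append(
            ReferenceRecord(f"{org}|marker", marker, "environment", taxon, "marker", org)
        )
        records.append(
            ReferenceRecord(f"{org}|gene", gene, "environment", taxon, "gene", org)
        )

    return ReferenceCollection(records, marker_len, tuple(gene_len_range))


# ------------------------------------------------------------- community


def compose_community(
    ref: ReferenceCollection,
    f: float,
    seed: int,
    sample_id: str = "S1",
    dirichlet_conc: float = 1.0,
    dna_yield_range: tuple[float, float] = DNA_YIELD_RANGE_NG_PER_ML,
    yield_per_f: float = DEFAULT_YIELD_PER_F,
    conc_per_f: float = DEFAULT_CONC_PER_F,
    conc_noise_sd: float = DEFAULT_CONC_NOISE_SD,
) -> CommunityProfile:
    """Mix a gut community (total weight ``f``) into environmental background.

    Within-pool relative abundances are Dirichlet(``dirichlet_conc``).  DNA
    yield is LogUniform over the clean-water range plus ``yield_per_f * f``;
    the true E. coli concentration is ``conc_per_f * f`` with lognormal
    noise (sd ``conc_noise_sd`` on the log scale).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gut = ref.organisms("gut")
    env = ref.organisms("environment")
    weights: dict[str, float] = {}
    gut_w = rng.dirichlet(np.full(len(gut), dirichlet_conc)) * f
    env_w = rng.dirichlet(np.full(len(env), dirichlet_conc)) * (1.0 - f)
    for org, w in zip(gut, gut_w):
        weights[org] = float(w)
    for org, w in zip(env, env_w):
        weights[org] = float(w)
    lo, hi = dna_yield_range
    base_yield = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    dna_yield = base_yield + yield_per_f * f
    if f > 0:
        ecoli = conc_per_f * f * math.exp(rng.normal(0.0, conc_noise_sd))
    else:
        ecoli = 0.0
    return CommunityProfile(sample_id, weights, f, dna_yield, ecoli)


# ------------------------------------------------------------- amplicon


def simulate_amplicon_table(
    profiles: Sequence[CommunityProfile],
    ref: ReferenceCollection,
    depth: int,
    seed: int,
    mutation_rate: float = 0.0,
) -> AmpliconTable:
    """Multinomial sequence-type counts at fixed ``depth`` per sample.

    Rows are the reference markers (both pools); row sequences are copied
    from the markers, optionally with a small per-base substitution rate to
    mimic sequence-type microdiversity.  Emulates an already-denoised,
    already-labelled amplicon table.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not profiles:
        raise ValueError("no community profiles given")
    rng = np.random.default_rng(seed)
    organisms = ref.organisms()
    marker_recs = [ref.marker_of(org) for org in organisms]
    row_ids = [r.id for r in marker_recs]

    sequences = {}
    for r in marker_recs:
        seq = r.sequence
        if mutation_rate > 0:
            n_sub = rng.binomial(len(seq), mutation_rate)
            if n_sub:
                seq = _mutate_substitutions(rng, seq, n_sub)
        sequences[r.id] = seq

    counts = {}
    meta_rows = {}
    for prof in profiles:
        w = np.array([prof.weights.get(org, 0.0) for org in organisms])
        if w.sum() <= 0:
            raise ValueError(f"{prof.sample_id}: all-zero weights")
        counts[prof.sample_id] = rng.multinomial(depth, w / w.sum())
        meta_rows[prof.sample_id] = {
            "dna_yield": prof.dna_yield,
            "true_f": prof.contamination_fraction,
            "ecoli_conc": prof.ecoli_conc,
        }

    counts_df = pd.DataFrame(counts, index=row_ids)
    taxa = pd.Series({r.id: r.taxon for r in marker_recs})
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return AmpliconTable(counts_df, pd.Series(sequences), taxa, meta)


# ------------------------------------------------------------- shotgun


def _apply_errors(
    rng: np.random.Generator,
    seq: str,
    error_rate: float,
    split: tuple[float, float, float],
) -> str:
    """i.i.d. per-base errors: substitution / insertion-before / deletion."""
    if error_rate == 0.0:
        return seq
    n = len(seq)
    err = rng.random(n) < error_rate
    pos = np.nonzero(err)[0]
    if pos.size == 0:
        return seq
    kinds = rng.choice(3, size=pos.size, p=split)  # 0 sub, 1 ins, 2 del
    out: list[str] = []
    prev = 0
    for p, kind in zip(pos, kinds):
        out.append(seq[prev:p])
        base = seq[p]
        if kind == 0:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        elif kind == 1:
            out.append("ACGT"[rng.integers(4)])
            out.append(base)
        # kind == 2: deletion, emit nothing
        prev = p + 1
    out.append(seq[prev:])
    return "".join(out)


def simulate_shotgun_reads(
    profile: CommunityProfile,
    ref: ReferenceCollection,
    n_reads: int,
    seed: int,
    read_len_mean: float = 600.0,
    read_len_sd: float = 60.0,
    error_rate: float = 0.05,
    error_split: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> ShotgunReadSet:
    """Draw reads from catalog genes in proportion to organism weights.

    Read lengths are Normal(mean, sd) truncated to [50, gene length]; the
    window start is uniform.  Errors are applied i.i.d. per base at
    ``error_rate`` with the given substitution/insertion/deletion split.
    ``true_origin_id`` records the source gene for oracle tests.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 <= error_rate <= 0.3:
        raise ValueError("error_rate outside [0, 0.3]")
    if abs(sum(error_split) - 1.0) > 1e-9:
        raise ValueError("error_split must sum to 1")
    rng = np.random.default_rng(seed)
    organisms = ref.organisms()
    w = np.array([profile.weights.get(org, 0.0) for org in organisms])
    if w.sum() <= 0:
        raise ValueError("profile has all-zero gene weights")
    w = w / w.sum()
    genes = [ref.gene_of(org) for org in organisms]

    origins = rng.choice(len(organisms), size=n_reads, p=w)
    reads: list[ShotgunRead] = []
    for i, oi in enumerate(origins):
        gene = genes[oi]
        glen = len(gene.sequence)
        length = int(round(rng.normal(read_len_mean, read_len_sd)))
        length = max(50, min(length, glen))
        start = int(rng.integers(0, glen - length + 1))
        raw = gene.sequence[start : start + length]
        seq = _apply_errors(rng, raw, error_rate, tuple(error_split))
        reads.append(ShotgunRead(f"read{i + 1:06d}", seq, gene.id))
    return ShotgunReadSet(reads, error_rate, read_len_mean, read_len_sd)


# ------------------------------------------------------------- wells


def simulate_wells(
    conc_per_100ml: float,
    seed: int,
    layout: Sequence[tuple[float, int]] = DEFAULT_WELL_LAYOUT,
    dilution: float = 1.0,
    sample_id: str = "",
) -> WellOutcome:
    """Simulate a multi-well tray: P(positive) = 1 - exp(-c*v/d), c per ml."""
    if conc_per_100ml < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    c_per_ml = conc_per_100ml / 100.0
    classes = []
    for volume_ml, n_wells in layout:
        p_pos = 1.0 - math.exp(-c_per_ml * volume_ml / dilution)
        positives = int(rng.binomial(n_wells, p_pos))
        classes.append(WellClass(volume_ml, n_wells, positives))
    return WellOutcome(tuple(classes), dilution, sample_id)
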