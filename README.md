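# stormtrace

Quantify human wastewater contamination in stormwater from three
measurement modalities, each with its own strengths:

1. **Culture counts** — a multi-well dilution assay (Colilert-style tray)
   scored as positive/negative wells, turned into a Most Probable Number
   (MPN) of *E. coli* per 100 ml by maximum likelihood.
2. **16S amplicon sequencing** — a sequence type × sample count table, from
   which faecal-indicator organism (FIO) read fractions are computed under
   three definitions (the *Escherichia/Shigella* genus, a curated
   multi-genus list, or ≥99% identity to human-gut marker sequences) and
   normalised by DNA yield (ng DNA per ml of water).
3. **Long-read shotgun sequencing** — error-prone reads (≈5% per-base
   error) trimmed to 400 bp, subsampled to 10,000, and matched against a
   gut gene catalog at ≥90% identity over ≥200 aligned bp; the fraction of
   matching reads is the mapping ratio, with a saturation curve showing how
   few reads suffice for a stable estimate.

The package is aimed at microbial water-quality researchers who want these
procedures as tested, reusable, seed-reproducible code. A synthetic-data
generator emulates the whole study system — stormwater as a mixture of a
human-gut community (weight = contamination fraction *f*) and an
environmental freshwater background — so every stage can be exercised and
validated without any sequencing download.

## The statistics at the core

**MPN.** A well of volume *v* receiving a sample diluted by *d* at cell
concentration *c* per ml is positive with probability 1 − e^(−cv/d). The
log-likelihood over well classes,

    ℓ(c) = Σ_classes [ p·log(1 − e^(−cv/d)) + (n − p)·(−cv/d) ],

is maximised by bounded Brent search on log c; all-negative and
all-positive trays are censored at the assay's reporting limits
(defaults <100 and ≥242,000 per 100 ml).

**Normalised FIO index.** For each sample,
index = (FIO reads / total reads) × (ng DNA extracted per ml water),
a DNA-yield-scaled proxy for the absolute concentration of faecal
organisms, correlated against MPN on log10 scales (Pearson).

**Mapping ratio.** Reads are matched semi-globally (query end-to-end,
free end gaps on the reference; match +1, mismatch −1, gap open −2,
extend −1) behind a lossless-in-practice k-mer prefilter; identity is
matches / aligned columns with gaps counted. The 90% cutoff follows from
~94% intraspecies nucleotide identity degraded by ~5% read error.

**Community statistics.** Bray–Curtis and Spearman-based dissimilarities,
non-metric MDS (Kruskal stress-1), average-linkage clustering,
hypergeometric rarefaction, and per-taxon Wilcoxon rank-sum tests with
Benjamini–Hochberg FDR control above rank-specific abundance floors.

**Source attribution.** A collapsed Gibbs sampler estimates the proportions
of a sink community drawn from candidate source communities plus an
"Unknown" source (Dirichlet smoothing α = 0.001, rarefaction depth 9,648
by default), run independently per source group.

## Worked example

```python
import numpy as np
from stormtrace import synthetic as syn, mpn, shotgun as shot
from stormtrace.amplicon import (build_fio_set_by_identity,
                                 contamination_index, genome_equivalents)

ref = syn.make_reference(seed=1, n_gut=10, n_env=10)
profiles = [syn.compose_community(ref, f, seed=100 + i, sample_id=f"S{i+1}")
            for i, f in enumerate([0.0, 0.02, 0.1, 0.3])]
table = syn.simulate_amplicon_table(profiles, ref, depth=10_000, seed=7)

estimates = [mpn.estimate_mpn(syn.simulate_wells(p.ecoli_conc, seed=50 + i,
                                                 dilution=100.0))
             for i, p in enumerate(profiles)]
fio = build_fio_set_by_identity(table, ref.marker_catalog("gut"))
indices = contamination_index(table, fio)

reads = syn.simulate_shotgun_reads(profiles[-1], ref, 600, seed=9, error_rate=0.05)
prep = shot.prepare_reads(reads, shot.ShotgunProtocol(400, 570, seed=11))
ratio = shot.mapping_ratio(prep, ref.gene_catalog("gut"))
```

which prints, when the estimates are tabulated:

```
S1  f=0.00  MPN/100ml=       0 (below_lod)  index=0.0000 FIO-ng/ml
S2  f=0.02  MPN/100ml=   44621 (point    )  index=0.0110 FIO-ng/ml
S3  f=0.10  MPN/100ml=     inf (above_uod)  index=0.2172 FIO-ng/ml
S4  f=0.30  MPN/100ml=     inf (above_uod)  index=1.8397 FIO-ng/ml
shotgun mapping ratio (S4): 0.282
genome equivalents at 1.15 ng DNA/ml: 355,699 per ml
```

Reading the output: the clean sample is censored below the lower reporting
limit, the heavily contaminated samples saturate the tray above the upper
one, the DNA-yield-normalised FIO index rises monotonically with the true
contamination fraction, and the shotgun mapping ratio of the f = 0.30
sample is close to 0.30 (its reads are ~30% gut-derived and the matcher
recovers nearly all of them at 5% read error). The genome-equivalents line
is the sensitivity arithmetic: 1.15 ng DNA/ml with 3 Mbp genomes is ≈3.6e5
genomes per ml, so detecting one FIO cell per ml needs on the order of
1e5–1e6 reads.

The same flow is available end-to-end:

```sh
stormtrace pipeline --seed 0 --outdir out/
```

writes MPN, index, mapping-ratio, saturation, ordination, clustering,
differential-abundance and attribution outputs plus a `report.json` whose
hash is a pure function of (config, seed). Other subcommands (`simulate`,
`mpn`, `amplicon`, `shotgun`, `community`, `attribute`) run single stages
on files.

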