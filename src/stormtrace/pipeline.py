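"""End-to-end pipeline driver over synthetic (or user-supplied) data.

A single seeded run regenerates the whole study at synthetic scale:
culture-well MPNs, the three amplicon FIO indices and their correlation
with MPN, shotgun mapping ratios with a saturation curve, community
dissimilarity / ordination / clustering / differential abundance, and
source attribution of a wastewater-like sink against contaminated and
uncontaminated source groups.  The report is a plain dict (JSON-serialisable)
whose content is a pure function of (config, seed); every output file embeds
the seed and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon as amp
from . import attribution as attr
from . import community as comm
from . import mpn as mpn_mod
from . import shotgun as shot
from . import synthetic as syn
from .io import write_fasta
from .matcher import MatchPolicy

__all__ = ["PipelineConfig", "run_pipeline", "report_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a synthetic run; defaults echo the study protocol
    (99 / 90 / 200 bp / 400 bp trim / 0.05 / 9,648 / 0.001)."""

    seed: int = 0
    # reference + community
    n_gut: int = 12
    n_env: int = 12
    marker_len: int = 400
    gene_len_range: tuple[int, int] = (500, 2000)
    divergence: float = 0.1
    n_clean: int = 10
    n_contaminated: int = 30
    f_range: tuple[float, float] = (0.01, 0.5)
    # 1:100 dilution puts the two-volume tray's reporting limits at
    # <100 and >=242,000 per 100 ml
    well_dilution: float = 100.0
    # amplicon
    amplicon_depth: int = 10_000
    fio_identity: float = 99.0
    # shotgun
    shotgun_samples: int = 10
    shotgun_reads: int = 600
    shotgun_error_rate: float = 0.05
    trim_len: int = 400
    min_identity: float = 90.0
    min_aln_len: int = 200
    # stats
    fdr_alpha: float = 0.05
    contaminated_f_min: float = 0.1
    # attribution
    attribution_depth: int = 9_648
    attribution_alpha: float = 0.001
    attribution_restarts: int = 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def report_hash(report: dict) -> str:
    clean = {k: v for k, v in report.items() if k != "report_hash"}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True).encode()
    ).hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def run_pipeline(config: PipelineConfig = PipelineConfig(), outdir: str | Path | None = None) -> dict:
    """Run every stage on freshly generated data; return the report dict."""
    cfg = config
    tag = f"stormtrace seed={cfg.seed} config={cfg.hash()}"
    seeds = iter(_child_seeds(cfg.seed, 64))

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # ---------------------------------------------------------- simulate
    ref = stage("reference")(
        lambda: syn.make_reference(
            next(seeds),
            n_gut=cfg.n_gut,
            n_env=cfg.n_env,
            marker_len=cfg.marker_len,
            gene_len_range=cfg.gene_len_range,
            divergence=cfg.divergence,
        )
    )
    f_values = [0.0] * cfg.n_clean + list(
        np.geomspace(cfg.f_range[0], cfg.f_range[1], cfg.n_contaminated)
    )
    profile_seeds = _child_seeds(next(seeds), len(f_values))
    profiles = [
        syn.compose_community(ref, f, s, sample_id=f"S{i + 1:03d}")
        for i, (f, s) in enumerate(zip(f_values, profile_seeds))
    ]

    well_seeds = _child_seeds(next(seeds), len(profiles))
    wells = [
        syn.simulate_wells(
            p.ecoli_conc, s, dilution=cfg.well_dilution, sample_id=p.sample_id
        )
        for p, s in zip(profiles, well_seeds)
    ]
    estimates = [mpn_mod.estimate_mpn(w) for w in wells]

    table = stage("amplicon_table")(
        lambda: syn.simulate_amplicon_table(profiles, ref, cfg.amplicon_depth, next(seeds))
    )

    # ---------------------------------------------------------- amplicon
    def amplicon_stage():
        gut_markers = ref.marker_catalog("gut")
        sets = {
            "escherichia_shigella": amp.build_fio_set_by_taxon(
                table, ["Escherichia/Shigella"]
            ),
            "fio_list": amp.build_fio_set_by_taxon(table, amp.default_fio_list()),
            "identity_match": amp.build_fio_set_by_identity(
                table, gut_markers, threshold=cfg.fio_identity
            ),
        }
        indices = {k: amp.contamination_index(table, s) for k, s in sets.items()}
        corr = {}
        for k, idx in indices.items():
            try:
                c = amp.correlate_index_mpn(idx, estimates)
                corr[k] = {"r": c.r, "p": c.p, "n_used": c.n_used}
            except ValueError as exc:
                corr[k] = {"error": str(exc)}
        return sets, indices, corr

    fio_sets, indices, correlations = stage("amplicon_index")(amplicon_stage)

    # ---------------------------------------------------------- shotgun
    def shotgun_stage():
        catalog = ref.gene_catalog("gut")
        policy = MatchPolicy(cfg.min_identity, cfg.min_aln_len)
        n_samples = len(profiles)
        pick = sorted(
            set(np.linspace(0, n_samples - 1, min(cfg.shotgun_samples, n_samples)).astype(int))
        )
        sub_n = max(1, int(0.95 * cfg.shotgun_reads))
        read_seeds = _child_seeds(next(seeds), len(pick))
        ratios = {}
        flags_by_sample = {}
        for s_idx, rs in zip(pick, read_seeds):
            prof = profiles[s_idx]
            reads = syn.simulate_shotgun_reads(
                prof, ref, cfg.shotgun_reads, rs, error_rate=cfg.shotgun_error_rate
            )
            protocol = shot.ShotgunProtocol(cfg.trim_len, sub_n, policy, rs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prepared = shot.prepare_reads(reads, protocol)
            flags = shot.map_reads(prepared, catalog, policy)
            ratios[prof.sample_id] = float(np.mean(flags))
            flags_by_sample[prof.sample_id] = (prepared, flags)
        # saturation on the most contaminated shotgun sample
        sat_sample = profiles[pick[-1]].sample_id
        prepared, flags = flags_by_sample[sat_sample]
        curve = shot.saturation(
            prepared, catalog, policy, seed=next(seeds), mapped_flags=flags
        )
        return pick, ratios, sat_sample, curve

    pick, shotgun_ratios, sat_sample, sat_curve = stage("shotgun_index")(shotgun_stage)

    # amplicon-vs-shotgun concordance on the shotgun subset
    id_idx = {ci.sample_id: ci for ci in indices["identity_match"]}
    amp_frac = [id_idx[sid].raw_fraction for sid in shotgun_ratios]
    shot_vals = list(shotgun_ratios.values())
    from scipy import stats as sps

    if len(shot_vals) >= 3:
        rho = float(sps.spearmanr(amp_frac, shot_vals).statistic)
    else:
        rho = float("nan")

    # ---------------------------------------------------------- community
    def community_stage():
        bc = comm.bray_curtis(table)
        sp = comm.spearman_dissim(table)
        coords, stress = comm.nmds(sp, seed=next(seeds))
        dendro = comm.hcluster(bc)
        clean_ids = [p.sample_id for p in profiles if p.contamination_fraction == 0]
        contam_ids = [
            p.sample_id
            for p in profiles
            if p.contamination_fraction >= cfg.contaminated_f_min
        ]
        diff = comm.differential_taxa(
            table,
            {"contaminated": contam_ids, "clean": clean_ids},
            rank="genus",
            alpha=cfg.fdr_alpha,
        )
        return bc, sp, coords, stress, dendro, diff, clean_ids, contam_ids

    bc, sp, coords, stress, dendro, diff, clean_ids, contam_ids = stage("community_stats")(
        community_stage
    )

    # ---------------------------------------------------------- attribution
    def attribution_stage():
        sink_prof = syn.compose_community(ref, 1.0, next(seeds), sample_id="WWTP")
        sink_table = syn.simulate_amplicon_table(
            [sink_prof], ref, max(cfg.amplicon_depth, cfg.attribution_depth), next(seeds)
        )
        sink = sink_table.counts["WWTP"]
        depth = min(cfg.attribution_depth, cfg.amplicon_depth)
        groups = {
            "contaminated": table.counts[contam_ids],
            "uncontaminated": table.counts[clean_ids],
        }
        model = attr.SourceModel(
            groups["contaminated"],
            alpha=cfg.attribution_alpha,
            rarefaction_depth=depth,
            n_restarts=cfg.attribution_restarts,
            seed=next(seeds),
        )
        results = attr.attribute_per_group(sink, groups, model)
        return {
            name: {
                "explained": attr.explained_share(res),
                "unknown": res.proportions[attr.UNKNOWN],
            }
            for name, res in results.items()
        }

    attribution = stage("source_attribution")(attribution_stage)

    report = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "n_samples": len(profiles),
        "mpn": {
            e.sample_id: {"mpn_per_100ml": e.mpn if np.isfinite(e.mpn) else None,
                          "status": e.status}
            for e in estimates
        },
        "fio_set_sizes": {k: len(s.member_ids) for k, s in fio_sets.items()},
        "contamination_index": {
            k: {ci.sample_id: ci.index for ci in v} for k, v in indices.items()
        },
        "index_mpn_correlation": correlations,
        "shotgun_mapping_ratio": shotgun_ratios,
        "saturation": {
            "sample": sat_sample,
            "depths": list(sat_curve.depths),
            "ratios": list(sat_curve.ratios),
            "stable_depth": sat_curve.stable_depth,
        },
        "amplicon_shotgun_spearman": rho,
        "nmds_stress": stress,
        "n_differential_significant": sum(
            1 for d in diff if d.p_adj < cfg.fdr_alpha
        ),
        "attribution": attribution,
    }
    report["report_hash"] = report_hash(report)

    if outdir is not None:
        _write_outputs(
            Path(outdir), tag, ref, table, wells, estimates, indices,
            shotgun_ratios, sat_curve, bc, sp, coords, dendro, diff, report,
        )
    return report


def _write_outputs(outdir, tag, ref, table, wells, estimates, indices,
                   shotgun_ratios, sat_curve, bc, sp, coords, dendro, diff,
                   report):
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fasta", [(r.id, r.sequence) for r in ref.records])
    table.to_tsv(outdir / "amplicon_counts.tsv", outdir / "sample_meta.tsv",
                 header_comment=tag)
    mpn_mod.wells_to_json(wells, outdir / "wells.json")
    with open(outdir / "mpn.tsv", "w") as fh:
        fh.write(f"# {tag}\nsample_id\tmpn_per_100ml\tstatus\n")
        for e in estimates:
            val = f"{e.mpn:.1f}" if np.isfinite(e.mpn) else f">={e.uod:g}"
            fh.write(f"{e.sample_id}\t{val}\t{e.status}\n")
    with open(outdir / "contamination_index.tsv", "w") as fh:
        fh.write(f"# {tag}\nfio_definition\tsample_id\traw_fraction\tdna_yield\tindex\n")
        for name, rows in indices.items():
            for ci in rows:
                fh.write(
                    f"{name}\t{ci.sample_id}\t{ci.raw_fraction:.6g}\t"
                    f"{ci.dna_yield:.4g}\t{ci.index:.6g}\n"
                )
    with open(outdir / "shotgun_ratio.tsv", "w") as fh:
        fh.write(f"# {tag}\nsample_id\tmapping_ratio\n")
        for sid, r in shotgun_ratios.items():
            fh.write(f"{sid}\t{r:.6g}\n")
    with open(outdir / "saturation.tsv", "w") as fh:
        fh.write(f"# {tag}\ndepth\tratio\n")
        for d, r in zip(sat_curve.depths, sat_curve.ratios):
            fh.write(f"{d}\t{r:.6g}\n")
    bc.to_tsv(outdir / "bray_curtis.tsv")
    sp.to_tsv(outdir / "spearman_dissim.tsv")
    coords.to_csv(outdir / "nmds_coords.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    with open(outdir / "differential_taxa.tsv", "w") as fh:
        fh.write(f"# {tag}\ntaxon\tmean_1\tmean_2\tdirection\tp_raw\tp_adj\n")
        for d in diff:
            fh.write(
                f"{d.taxon}\t{d.group_means[0]:.6g}\t{d.group_means[1]:.6g}\t"
                f"{d.direction}\t{d.p_raw:.4g}\t{d.p_adj:.4g}\n"
            )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
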