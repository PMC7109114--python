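"""End-to-end orchestration: filter -> scan -> regions -> intersection -> effect.

A run is fully determined by a :class:`RunConfig` plus its input files;
the manifest written next to the outputs records a hash of the config so
re-runs can be checked for reproducibility.  SNPs and InDels are scanned
and thresholded separately and reported jointly in one region table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association_scan import (
    DSNP,
    ED5,
    CandidateRegion,
    call_regions,
    dsnp_for_variant,
    ed5_for_variant,
    fit_windows,
    threshold_median_3sd,
    threshold_quantile,
)
from .mutant_intersection import (
    GenotypePattern,
    mutual_differential,
    prioritize_cds,
    select_by_pattern,
)
from .qc_filtering import FilterReport, GenotypeThresholds, filter_high_quality
from .sequence_effect import effect_report
from .synthetic_data import (
    CAUSAL_GENE_ID,
    CDS_DEL_END,
    CDS_DEL_START,
    CrossConfig,
    SimulatedDataset,
    simulate_dataset,
    write_dataset,
)
from .variant_io import (
    ROLES,
    SampleRoleMap,
    contig_lengths_from_vcf,
    read_gene_models,
    read_variants,
)

log = logging.getLogger("bsascan")


@dataclass
class RunConfig:
    """Everything that determines a scan run."""

    vcf: str = ""
    gff3: Optional[str] = None
    roles: Optional[SampleRoleMap] = None
    statistics: tuple = (ED5, DSNP)
    window: int = 2_000_000
    step: int = 10_000
    min_variants_per_window: int = 1
    # None = per-statistic default: median+3SD for ED5, 99th pct for dSNPindex
    threshold_method: Optional[str] = None
    quantile_level: float = 0.99
    delta_mode: str = "signed"  # or "absolute"
    min_pool_depth: int = 4
    depth_mode: str = "per_pool"
    min_allele_reads: int = 2
    min_allele_frac: float = 0.10
    updown_distance: int = 5_000
    outdir: str = "bsascan_out"
    seed: int = 0

    def genotype_thresholds(self) -> GenotypeThresholds:
        return GenotypeThresholds(self.min_allele_reads, self.min_allele_frac)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["statistics"] = list(self.statistics)
        if self.roles is not None:
            d["roles"] = self.roles.as_dict() | {
                "dominant_color": self.roles.dominant_color,
                "female_role": self.roles.female_role,
                "male_role": self.roles.male_role,
            }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScanResult:
    regions: pd.DataFrame
    thresholds: dict  # (statistic, variant_class) -> Threshold
    tracks: dict  # (statistic, variant_class) -> list[AssociationTrack]
    candidates: pd.DataFrame
    filter_report: FilterReport
    manifest: dict


def _per_variant_values(variants, roles, statistic, thresholds):
    """Split variants by class and compute the per-variant statistic."""
    out = {}
    for vclass in ("SNP", "InDel"):
        sub = [v for v in variants if v.variant_class == vclass]
        vals, kept = [], []
        for v in sub:
            if statistic == ED5:
                val, _ = ed5_for_variant(v, roles)
            else:
                val, _ = dsnp_for_variant(v, roles, thresholds)
            if val is not None:
                vals.append(val)
                kept.append(v)
        out[vclass] = (kept, vals)
    return out


def _region_rows(statistic, vclass, regions):
    method = "ED" if statistic == ED5 else "SNP index"
    for r in regions:
        yield dict(
            method=method,
            variant_type=vclass,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            size_mb=round(r.size_mb, 2),
            gene_number=r.gene_count,
            peak_pos=r.peak_pos,
            peak_value=r.peak_value,
        )


def _candidate_rows(ranked, roles):
    for rv in ranked:
        v = rv.variant
        row = dict(
            variant_type=v.variant_class,
            chrom=v.chrom,
            position=v.pos,
            reference=v.ref,
            alternate=",".join(v.alts),
            effect=rv.effect,
            gene_id=rv.gene_id or "",
            rank=rv.rank,
        )
        for role in ROLES:
            d = v.depth(role)
            row[role] = "N" if d.is_missing else ",".join(str(c) for c in d.counts)
        yield row


def run_scan(config: RunConfig) -> ScanResult:
    """Execute the full association workflow and write its tables."""
    os.makedirs(config.outdir, exist_ok=True)
    if config.roles is None:
        raise ValueError("run_scan requires a SampleRoleMap in config.roles")
    gt = config.genotype_thresholds()

    log.info("stage=read vcf=%s", config.vcf)
    variants = read_variants(config.vcf, config.roles)
    chrom_lengths = contig_lengths_from_vcf(config.vcf)
    for v in variants:
        chrom_lengths.setdefault(v.chrom, v.pos + len(v.ref))
        chrom_lengths[v.chrom] = max(chrom_lengths[v.chrom], v.pos + len(v.ref))
    genes = read_gene_models(config.gff3) if config.gff3 else None

    log.info("stage=filter n_in=%d", len(variants))
    survivors, report = filter_high_quality(
        variants,
        config.roles,
        thresholds=gt,
        min_pool_depth=config.min_pool_depth,
        depth_mode=config.depth_mode,
    )
    report.to_tsv(os.path.join(config.outdir, "filter_report.tsv"))

    region_rows, thresholds, all_tracks = [], {}, {}
    region_objects: list[CandidateRegion] = []
    for statistic in config.statistics:
        per_class = _per_variant_values(survivors, config.roles, statistic, gt)
        for vclass, (kept, vals) in per_class.items():
            tracks = []
            for chrom in sorted(chrom_lengths):
                pos = [v.pos for v in kept if v.chrom == chrom]
                val = [x for v, x in zip(kept, vals) if v.chrom == chrom]
                tracks.append(
                    fit_windows(
                        pos,
                        val,
                        chrom_lengths[chrom],
                        chrom=chrom,
                        kind=statistic,
                        window=config.window,
                        step=config.step,
                        min_variants_per_window=config.min_variants_per_window,
                    )
                )
            defined = sum(int(t.defined.sum()) for t in tracks)
            if defined < 2:
                log.warning("stage=scan statistic=%s class=%s: too few windows", statistic, vclass)
                continue
            method = config.threshold_method or (
                "median_plus_3sd" if statistic == ED5 else "quantile"
            )
            if method == "quantile":
                thr = threshold_quantile(tracks, config.quantile_level)
            else:
                thr = threshold_median_3sd(tracks)
            thresholds[(statistic, vclass)] = thr
            all_tracks[(statistic, vclass)] = tracks
            mode = config.delta_mode if statistic == DSNP else "signed"
            for t in tracks:
                regs = call_regions(t, thr, gene_models=genes, mode=mode)
                region_objects.extend(regs)
                region_rows.extend(_region_rows(statistic, vclass, regs))

    regions_df = pd.DataFrame(
        region_rows,
        columns=[
            "method", "variant_type", "chrom", "start", "end",
            "size_mb", "gene_number", "peak_pos", "peak_value",
        ],
    )
    regions_df.to_csv(os.path.join(config.outdir, "regions.tsv"), sep="\t", index=False)
    _write_tracks(all_tracks, config.outdir)

    # narrow to candidate variants inside the called regions
    candidates_df = pd.DataFrame(
        columns=["variant_type", "chrom", "position", "reference", "alternate",
                 "effect", "gene_id", "rank", *ROLES]
    )
    n_mutual = n_pattern = 0
    if region_objects and genes is not None:
        mutual = mutual_differential(
            survivors, "red_parent", ["original", "green_parent"], region_objects, gt
        )
        n_mutual = len(mutual)
        matched = select_by_pattern(mutual, GenotypePattern(), gt)
        n_pattern = len(matched)
        ranked = prioritize_cds(matched, genes, config.updown_distance)
        candidates_df = pd.DataFrame(list(_candidate_rows(ranked, config.roles)))
    candidates_df.to_csv(os.path.join(config.outdir, "candidates.tsv"), sep="\t", index=False)

    manifest = dict(
        bsascan_version=__version__,
        numpy_version=np.__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        config=config.to_dict(),
        stage_counts=dict(
            n_input=report.n_input,
            removed=dict(report.removed),
            n_high_quality=report.n_output,
            n_mutual_differential=n_mutual,
            n_pattern_matched=n_pattern,
            n_regions=len(region_objects),
        ),
        thresholds={
            f"{stat}/{vc}": thr.value for (stat, vc), thr in thresholds.items()
        },
    )
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ScanResult(regions_df, thresholds, all_tracks, candidates_df, report, manifest)


def _write_tracks(all_tracks, outdir):
    rows = []
    for (stat, vclass), tracks in all_tracks.items():
        for t in tracks:
            d = t.defined
            for s, mid, fit, nv in zip(
                t.window_start[d], t.midpoints[d], t.fitted[d], t.n_variants[d]
            ):
                rows.append(
                    dict(statistic=stat, variant_type=vclass, chrom=t.chrom,
                         window_start=int(s), midpoint=float(mid),
                         fitted=float(fit), n_variants=int(nv))
                )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "tracks.tsv"), sep="\t", index=False)


def run_simulate(config: CrossConfig, outdir: str, force: bool = False) -> dict:
    """Simulate a dataset and write VCF/GFF3/FASTA/truth plus a config copy."""
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    ds = simulate_dataset(config)
    paths = write_dataset(ds, outdir)
    cfg = asdict(config)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    ds.roles.to_yaml(os.path.join(outdir, "roles.yaml"))
    return paths


def causal_effect_report(ds: SimulatedDataset):
    """Convenience: consequence report for the planted deletion."""
    cds = ds.cds[CAUSAL_GENE_ID]
    return effect_report(cds, (CDS_DEL_START, CDS_DEL_END))
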