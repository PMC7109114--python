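"""Synthetic F1 pooled-sequencing data with known truth.

Emulates the study design the scan assumes: a heterozygous dominant red
parent crossed to a homozygous green parent, 1:1 phenotype segregation,
two 50-plant phenotype pools sequenced to ~50x, and marker alleles linked
to the causal locus decaying by Haldane recombination.  The causal
mutation is a planted 14-nt frameshift deletion inside the CDS of a
generated three-exon gene; the original cultivar shares the red parent's
genotype everywhere except at the mutation (bud-sport model).  Decoy
variants violating each quality filter, and pattern-matching decoys that
do not touch a CDS, are planted alongside.

Every random draw goes through one seeded generator, so a config + seed
pair reproduces the dataset byte for byte.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .variant_io import (
    AlleleDepth,
    GeneModel,
    SampleRoleMap,
    VariantRecord,
    write_fasta,
    write_variants,
)

DEFAULT_ROLES = SampleRoleMap(
    red_parent="mutant_red_parent",
    green_parent="green_parent",
    original="original_cultivar",
    red_pool="red_pool",
    green_pool="green_pool",
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
CAUSAL_GENE_ID = "syng_bbx24"  # synthetic stand-in for the candidate gene
CAUSAL_DELETED = "GCAGCTGAAGTTCC"  # 14 nt removed from the CDS
CDS_DEL_START, CDS_DEL_END = 568, 581  # 1-based CDS coordinates of the deletion
CDS_LENGTH = 720


@dataclass
class CrossConfig:
    """Study conditions for the simulated cross.

    Defaults follow the design the scan targets: a 17-chromosome genome of
    30-Mb chromosomes (~510 Mb, the scale of the real assembly) with the
    causal locus on Chr04, markers every 10 kb, 50-plant pools at mean
    depth 50, parents at mean depth 25, and a 2.5 cM/Mb genetic map.  The
    unlinked chromosomes provide the null background the genome-wide
    threshold statistics assume; chromosomes other than the causal one are
    entirely unlinked (r = 0.5 to the causal locus).
    """

    chrom_lengths: dict = field(
        default_factory=lambda: {f"Chr{i:02d}": 30_000_000 for i in range(1, 18)}
    )
    marker_spacing: int = 10_000
    causal_chrom: str = "Chr04"
    causal_pos: int = 18_388_296
    map_rate_cm_per_mb: float = 2.5
    pool_size: int = 50  # plants per pool
    mean_pool_depth: float = 50.0
    mean_parent_depth: float = 25.0
    error_rate: float = 0.01
    noninformative_fraction: float = 0.30
    indel_fraction: float = 0.39
    n_pattern_decoys: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1 or self.mean_pool_depth <= 0:
            raise ValueError("pool_size >= 1 and mean depth > 0 required")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError(
                f"causal chromosome {self.causal_chrom!r} not in chrom_lengths"
            )
        if not 1_300 < self.causal_pos < self.chrom_lengths[self.causal_chrom]:
            # the planted gene needs ~1.3 kb of room upstream of the locus
            raise ValueError("causal_pos outside its chromosome (or too close to 0)")


@dataclass
class CrossTruth:
    """Ground truth: causal locus plus per-marker linkage expectations."""

    causal_chrom: str
    causal_pos: int
    table: pd.DataFrame  # chrom,pos,r,phase,f_red_expected,f_green_expected,causal,informative


def recombination_fraction(distance_bp: float, map_rate_cm_per_mb: float) -> float:
    """Haldane map function: r = (1 - exp(-2d))/2, d in Morgans."""
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    d_morgans = distance_bp / 1e6 * map_rate_cm_per_mb / 100.0
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


# ---------------------------------------------------------------------------
# Causal gene construction


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> list[str]:
    bases = "ACGT"
    out = []
    while len(out) < n:
        codon = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return out


def make_causal_cds(rng: np.random.Generator) -> str:
    """Build a 720-nt ORF whose 14-nt deletion at 568..581 frameshifts to an
    early stop at mutant codon 206 (205 aa translated, 189 aa shared prefix).

    Codon 189 is fixed to GCA so the deletion's anchor base (CDS 567) is A
    and the removed segment matches the canonical 14-mer; a TAA is planted
    in the shifted frame; all other codons are random and stop-free, with
    rejection sampling guarding against chance stops in the shifted frame.
    """
    from .sequence_effect import translate_orf

    fixed = {189: "GCA", 190: "GCA", 191: "GCT", 192: "GAA", 193: "GTT", 194: "CCA",
             210: "GCT", 211: "AAC", 240: "TAA"}
    # wt bases 630..632 = TAA sit in the shifted frame at mutant codon 206
    # (codon 210 ends with T, codon 211 starts AA)
    for _ in range(200):
        codons = _random_nonstop_codons(rng, 240)
        codons[0] = "ATG"
        for idx, codon in fixed.items():
            codons[idx - 1] = codon
        cds = "".join(codons)
        assert len(cds) == CDS_LENGTH
        assert cds[CDS_DEL_START - 2] == "A"  # anchor base at CDS 567
        assert cds[CDS_DEL_START - 1 : CDS_DEL_END] == CAUSAL_DELETED
        mut = cds[: CDS_DEL_START - 1] + cds[CDS_DEL_END:]
        protein, stop = translate_orf(mut)
        if stop and len(protein) == 205:
            wt_protein, wt_stop = translate_orf(cds)
            assert wt_stop and len(wt_protein) == 239
            return cds
    raise RuntimeError("failed to construct causal CDS (rng exhausted)")


def make_causal_gene(config: CrossConfig) -> GeneModel:
    """Three-exon plus-strand gene whose CDS 567 lands on the causal position."""
    # exon CDS lengths 200 / 300 / 220; CDS 567 is 66 bases into exon 3
    g3 = config.causal_pos - 66
    e2_end = g3 - 201  # intron 2: 200 bp
    e2_start = e2_end - 299
    e1_end = e2_start - 301  # intron 1: 300 bp
    e1_start = e1_end - 199
    exons = ((e1_start, e1_end), (e2_start, e2_end), (g3, g3 + 219))
    return GeneModel(CAUSAL_GENE_ID, config.causal_chrom, "+", exons, exons)


def make_background_genes(config: CrossConfig, gene_every: int = 300_000) -> list[GeneModel]:
    genes = []
    for chrom, length in sorted(config.chrom_lengths.items()):
        i = 0
        for start in range(50_000, length - 2_000, gene_every):
            i += 1
            iv = ((start, start + 999),)
            genes.append(GeneModel(f"bg_{chrom}_{i:04d}", chrom, "+", iv, iv))
    return genes


# ---------------------------------------------------------------------------
# Pool simulation


@dataclass
class SimulatedDataset:
    variants: list
    truth: CrossTruth
    genes: list
    cds: dict  # gene_id -> CDS sequence (planted gene only)
    roles: SampleRoleMap
    config: CrossConfig


def _depth_vector(rng, n_alleles, depth, alt_fraction, alt_index=1):
    """Draw an AlleleDepth at given total depth and alt-read fraction."""
    if depth <= 0:
        return AlleleDepth((0,) * n_alleles)
    alt = rng.binomial(depth, alt_fraction)
    counts = [0] * n_alleles
    counts[0] = int(depth - alt)
    counts[alt_index] = int(alt)
    return AlleleDepth(tuple(counts))


def _observed_fraction(f: float, e: float) -> float:
    # a read flips to the other allele of the biallelic site with prob e
    return f * (1.0 - e) + (1.0 - f) * e


def simulate_dataset(config: CrossConfig) -> SimulatedDataset:
    """Simulate the full dataset: markers, decoys, causal gene and truth."""
    rng = np.random.default_rng(config.seed)
    e = config.error_rate
    n = config.pool_size
    roles = DEFAULT_ROLES

    cds = make_causal_cds(rng)
    causal_gene = make_causal_gene(config)
    genes = sorted(
        make_background_genes(config) + [causal_gene], key=lambda g: (g.chrom, g.start)
    )

    variants: list[VariantRecord] = []
    rows: list[dict] = []
    nucs = np.array(list("ACGT"))

    def pool_depth():
        return int(rng.poisson(config.mean_pool_depth))

    def parent_depth():
        return int(rng.poisson(config.mean_parent_depth))

    def depths_for(f_red, f_green, red_parent_het, original_het, n_alleles=2):
        """Standard biallelic depths: green parent hom ref."""
        return {
            "red_parent": _depth_vector(
                rng, n_alleles, parent_depth(), _observed_fraction(0.5 if red_parent_het else 0.0, e)
            ),
            "green_parent": _depth_vector(rng, n_alleles, parent_depth(), _observed_fraction(0.0, e)),
            "original": _depth_vector(
                rng, n_alleles, parent_depth(), _observed_fraction(0.5 if original_het else 0.0, e)
            ),
            "red_pool": _depth_vector(rng, n_alleles, pool_depth(), _observed_fraction(f_red, e)),
            "green_pool": _depth_vector(rng, n_alleles, pool_depth(), _observed_fraction(f_green, e)),
        }

    causal_span = range(config.causal_pos, config.causal_pos + 15)

    for chrom, length in sorted(config.chrom_lengths.items()):
        positions = np.arange(config.marker_spacing, length + 1, config.marker_spacing)
        if chrom == config.causal_chrom:
            keep = (positions < causal_span.start) | (positions >= causal_span.stop)
            positions = positions[keep]
        for pos in positions:
            pos = int(pos)
            if chrom == config.causal_chrom:
                r = recombination_fraction(abs(pos - config.causal_pos), config.map_rate_cm_per_mb)
            else:
                r = 0.5
            informative = rng.random() >= config.noninformative_fraction
            coupling = bool(rng.random() < 0.5)
            is_indel = rng.random() < config.indel_fraction
            ref_base = str(rng.choice(nucs))
            if is_indel:
                ref, alt = ref_base, ref_base + str(rng.choice(nucs))
            else:
                alt = str(rng.choice(nucs[nucs != ref_base]))
                ref = ref_base

            if informative:
                # red parent het; each F1 plant inherits the marker allele on
                # the transmitted haplotype, recombined at fraction r
                p_red = 1.0 - r if coupling else r
                p_green = r if coupling else 1.0 - r
                carriers_red = rng.binomial(n, p_red)
                carriers_green = rng.binomial(n, p_green)
                f_red = carriers_red / (2.0 * n)
                f_green = carriers_green / (2.0 * n)
                depths = depths_for(f_red, f_green, red_parent_het=True, original_het=True)
                f_red_exp = (1.0 - r) / 2.0 if coupling else r / 2.0
                f_green_exp = r / 2.0 if coupling else (1.0 - r) / 2.0
            else:
                # monomorphic background site: everyone hom ref
                depths = depths_for(0.0, 0.0, red_parent_het=False, original_het=False)
                f_red_exp = f_green_exp = 0.0
            variants.append(VariantRecord(chrom, pos, ref, (alt,), depths))
            rows.append(
                dict(
                    chrom=chrom,
                    pos=pos,
                    r=r,
                    phase="coupling" if coupling else "repulsion",
                    informative=informative,
                    f_red_expected=f_red_exp,
                    f_green_expected=f_green_exp,
                    causal=False,
                )
            )

    # --- the causal 14-nt deletion -----------------------------------------
    # VCF convention: POS anchors on the base before the deleted segment.
    ref_allele = cds[CDS_DEL_START - 2 : CDS_DEL_END]  # anchor + 14 deleted
    alt_allele = ref_allele[0]
    causal = VariantRecord(
        config.causal_chrom,
        config.causal_pos,
        ref_allele,
        (alt_allele,),
        depths_for(0.5, 0.0, red_parent_het=True, original_het=False),
    )
    variants.append(causal)
    rows.append(
        dict(
            chrom=config.causal_chrom,
            pos=config.causal_pos,
            r=0.0,
            phase="coupling",
            informative=True,
            f_red_expected=0.5,
            f_green_expected=0.0,
            causal=True,
        )
    )

    variants.extend(_pattern_decoys(config, rng, genes, depths_for))
    variants.extend(_qc_decoys(config, rng))

    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref))
    truth = CrossTruth(
        config.causal_chrom,
        config.causal_pos,
        pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True),
    )
    return SimulatedDataset(variants, truth, genes, {CAUSAL_GENE_ID: cds}, roles, config)


def _pattern_decoys(config, rng, genes, depths_for):
    """Tightly linked non-coding variants matching the mutant-specific
    genotype pattern (het in red parent + red pool, hom elsewhere), like
    the co-segregating neutral variants a bud sport accumulates."""
    out = []
    spans = [
        (g.start - 6_000, g.end + 6_000)
        for g in genes
        if g.chrom == config.causal_chrom
    ]
    placed = 0
    while placed < config.n_pattern_decoys:
        offset = int(rng.integers(-1_000_000, 1_000_001))
        pos = config.causal_pos + offset
        if pos < 1 or abs(offset) < 20:
            continue
        if any(s <= pos <= e for s, e in spans):
            continue
        r = recombination_fraction(abs(offset), config.map_rate_cm_per_mb)
        carriers_red = rng.binomial(config.pool_size, 1.0 - r)
        carriers_green = rng.binomial(config.pool_size, r)
        f_red = carriers_red / (2.0 * config.pool_size)
        f_green = carriers_green / (2.0 * config.pool_size)
        is_indel = placed % 2 == 0
        ref, alt = ("G", "GTT") if is_indel else ("C", "A")
        out.append(
            VariantRecord(
                config.causal_chrom,
                pos,
                ref,
                (alt,),
                depths_for(f_red, f_green, red_parent_het=True, original_het=False),
            )
        )
        placed += 1
    return out


def _qc_decoys(config, rng):
    """One variant violating each quality filter, at fixed early positions."""
    chrom = sorted(config.chrom_lengths)[0]
    base = 1_003
    d = lambda *counts: AlleleDepth(counts)
    multiallelic = VariantRecord(
        chrom, base, "A", ("C", "T"),
        {
            "red_parent": d(10, 5, 5), "green_parent": d(20, 0, 0),
            "original": d(12, 6, 0), "red_pool": d(30, 10, 10), "green_pool": d(35, 5, 0),
        },
    )
    low_depth = VariantRecord(
        chrom, base + 10, "G", ("T",),
        {
            "red_parent": d(10, 8), "green_parent": d(15, 0),
            "original": d(12, 9), "red_pool": d(2, 1), "green_pool": d(20, 0),
        },
    )
    identical = VariantRecord(
        chrom, base + 20, "T", ("C",),
        {
            "red_parent": d(11, 9), "green_parent": d(18, 0),
            "original": d(10, 10), "red_pool": d(25, 24), "green_pool": d(26, 27),
        },
    )
    foreign_allele = VariantRecord(
        chrom, base + 30, "C", ("G",),
        {
            "red_parent": d(20, 0), "green_parent": d(22, 0),
            "original": d(19, 0), "red_pool": d(40, 0), "green_pool": d(28, 12),
        },
    )
    return [multiallelic, low_depth, identical, foreign_allele]


def simulate_pools(config: CrossConfig):
    """Minimal surface: (variant records, truth)."""
    ds = simulate_dataset(config)
    return ds.variants, ds.truth


# ---------------------------------------------------------------------------
# Truth and dataset I/O


def write_truth(truth: CrossTruth, path: str) -> None:
    df = truth.table.copy()
    df.insert(0, "causal_locus", f"{truth.causal_chrom}:{truth.causal_pos}")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path: str) -> CrossTruth:
    df = pd.read_csv(path, sep="\t")
    locus = str(df["causal_locus"].iloc[0])
    chrom, pos = locus.rsplit(":", 1)
    table = df.drop(columns=["causal_locus"])
    table["phase"] = table["phase"].astype(str)
    return CrossTruth(chrom, int(pos), table)


def write_gff3(genes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tbsascan_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tbsascan_sim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tbsascan_sim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tbsascan_sim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def write_dataset(ds: SimulatedDataset, outdir: str) -> dict:
    """Write VCF + GFF3 + CDS FASTA + truth TSV; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "variants.vcf"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "fasta": os.path.join(outdir, "cds.fasta"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_variants(ds.variants, paths["vcf"], ds.roles, contig_lengths=ds.config.chrom_lengths)
    write_gff3(ds.genes, paths["gff3"])
    write_fasta(ds.cds, paths["fasta"])
    write_truth(ds.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Closed-form helpers for calibration checks


def simulate_marker_ed(
    r: float,
    depth: int,
    n_reps: int,
    rng: np.random.Generator,
    pool_size: Optional[int] = None,
    error_rate: float = 0.0,
) -> np.ndarray:
    """ED values for a coupling-phase marker at recombination fraction r.

    With ``pool_size=None`` the pools are treated as infinitely large
    (allele frequencies at their Mendelian expectations, read sampling
    only), which is the regime where E[ED] follows the closed form
    (1-2r)/sqrt(2); a finite pool adds plant-sampling noise.
    """
    if pool_size is None:
        f_red = np.full(n_reps, (1.0 - r) / 2.0)
        f_green = np.full(n_reps, r / 2.0)
    else:
        f_red = rng.binomial(pool_size, 1.0 - r, n_reps) / (2.0 * pool_size)
        f_green = rng.binomial(pool_size, r, n_reps) / (2.0 * pool_size)
    obs_red = rng.binomial(depth, _observed_fraction(f_red, error_rate)) / depth
    obs_green = rng.binomial(depth, _observed_fraction(f_green, error_rate)) / depth
    return math.sqrt(2.0) * np.abs(obs_red - obs_green)
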