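"""Narrowing candidate regions to a causal variant.

The mutant cultivar arose as a bud sport of the original cultivar, so the
causal mutation must (i) distinguish the mutant from the original and from
the other parent, (ii) segregate with the phenotype in the pools, and
(iii) plausibly alter a coding sequence.  Three operations implement that
narrowing: differential genotype calls restricted to the associated
regions, selection by the expected dominant-heterozygote genotype pattern
across all five samples, and ranking by predicted coding consequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .association_scan import CandidateRegion
from .qc_filtering import (
    AMBIGUOUS,
    GenotypeThresholds,
    HET,
    MISSING,
    call_genotype,
)
from .variant_io import GeneModel, VariantRecord

EFFECT_FRAMESHIFT = "Frame shift"
EFFECT_INFRAME = "In-frame CDS"
EFFECT_CDS_SNP = "CDS substitution"
EFFECT_EXON_NC = "Exon (non-coding)"
EFFECT_INTRON = "Intron"
EFFECT_UPSTREAM = "Upstream"
EFFECT_DOWNSTREAM = "Downstream"
EFFECT_INTERGENIC = "Intergenic"

# smaller rank = higher priority
EFFECT_RANK = {
    EFFECT_FRAMESHIFT: 0,
    EFFECT_INFRAME: 1,
    EFFECT_CDS_SNP: 1,
    EFFECT_EXON_NC: 2,
    EFFECT_INTRON: 2,
    EFFECT_UPSTREAM: 2,
    EFFECT_DOWNSTREAM: 2,
    EFFECT_INTERGENIC: 2,
}


def _in_regions(v: VariantRecord, regions: Sequence[CandidateRegion]) -> bool:
    return any(r.contains(v.chrom, v.pos) for r in regions)


def differential_variants(
    variants: Iterable[VariantRecord],
    role_a: str,
    role_b: str,
    regions: Sequence[CandidateRegion],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> tuple[list[VariantRecord], int]:
    """Variants inside the regions whose called genotypes differ between
    two roles; returns (subset, n excluded for a missing genotype)."""
    kept: list[VariantRecord] = []
    n_missing = 0
    for v in variants:
        if not _in_regions(v, regions):
            continue
        a = call_genotype(v.depth(role_a), thresholds)
        b = call_genotype(v.depth(role_b), thresholds)
        if a.state == MISSING or b.state == MISSING:
            n_missing += 1
            continue
        if not a.same_genotype(b):
            kept.append(v)
    return kept, n_missing


def mutual_differential(
    variants: Iterable[VariantRecord],
    mutant_role: str,
    reference_roles: Sequence[str],
    regions: Sequence[CandidateRegion],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> list[VariantRecord]:
    """Intersection of the mutant-vs-each-reference differential sets."""
    variants = list(variants)
    keys = None
    for ref_role in reference_roles:
        subset, _ = differential_variants(variants, mutant_role, ref_role, regions, thresholds)
        k = {v.key for v in subset}
        keys = k if keys is None else keys & k
    keys = keys or set()
    return [v for v in variants if v.key in keys]


@dataclass(frozen=True)
class GenotypePattern:
    """Required genotype per role for a dominant heterozygous mutation.

    The mutant parent and the dominant pool must be heterozygous; the other
    parent, the original cultivar and the recessive pool must all be
    homozygous *for the same shared allele* (the recessive background
    allele), which the mutant's heterozygote must also carry.
    """

    het_roles: tuple[str, ...] = ("red_parent", "red_pool")
    hom_roles: tuple[str, ...] = ("green_parent", "original", "green_pool")


def matches_pattern(
    variant: VariantRecord,
    pattern: GenotypePattern = GenotypePattern(),
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> bool:
    calls = {
        role: call_genotype(variant.depth(role), thresholds)
        for role in pattern.het_roles + pattern.hom_roles
    }
    if any(c.state in (MISSING, AMBIGUOUS) for c in calls.values()):
        return False
    hom_calls = [calls[r] for r in pattern.hom_roles]
    if not all(c.is_hom for c in hom_calls):
        return False
    shared = {c.alleles[0] for c in hom_calls}
    if len(shared) != 1:
        return False
    shared_allele = shared.pop()
    for role in pattern.het_roles:
        c = calls[role]
        if c.state != HET or shared_allele not in c.alleles:
            return False
    return True


def select_by_pattern(
    variants: Iterable[VariantRecord],
    pattern: GenotypePattern = GenotypePattern(),
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> list[VariantRecord]:
    """Variants whose five-role genotype calls match the pattern exactly."""
    return [v for v in variants if matches_pattern(v, pattern, thresholds)]


def classify_position(
    variant: VariantRecord,
    gene_models: Sequence[GeneModel],
    updown_distance: int = 5_000,
) -> tuple[str, Optional[str]]:
    """Classify a variant's position against gene models.

    Returns (effect label, gene id or None).  CDS hits distinguish
    frameshift (indel with length change not divisible by 3) from in-frame
    changes; near-gene hits are Upstream/Downstream relative to strand
    within ``updown_distance``; everything else is Intergenic.
    """
    pos = variant.pos
    span_end = pos + len(variant.ref) - 1
    best: tuple[int, str, Optional[str]] | None = None  # (priority, label, gene)

    def consider(priority: int, label: str, gene: Optional[str]) -> None:
        nonlocal best
        if best is None or priority < best[0]:
            best = (priority, label, gene)

    for g in gene_models:
        if g.chrom != variant.chrom:
            continue
        overlaps_gene = g.start <= span_end and g.end >= pos
        if overlaps_gene:
            in_cds = any(s <= span_end and e >= pos for s, e in g.cds)
            in_exon = any(s <= span_end and e >= pos for s, e in g.exons)
            if in_cds:
                if variant.variant_class == "SNP":
                    consider(0, EFFECT_CDS_SNP, g.gene_id)
                else:
                    delta = max(abs(len(a) - len(variant.ref)) for a in variant.alts)
                    label = EFFECT_FRAMESHIFT if delta % 3 != 0 else EFFECT_INFRAME
                    consider(0, label, g.gene_id)
            elif in_exon:
                consider(1, EFFECT_EXON_NC, g.gene_id)
            else:
                consider(1, EFFECT_INTRON, g.gene_id)
        else:
            upstream_iv = (
                (g.start - updown_distance, g.start - 1)
                if g.strand == "+"
                else (g.end + 1, g.end + updown_distance)
            )
            downstream_iv = (
                (g.end + 1, g.end + updown_distance)
                if g.strand == "+"
                else (g.start - updown_distance, g.start - 1)
            )
            if upstream_iv[0] <= span_end and upstream_iv[1] >= pos:
                consider(2, EFFECT_UPSTREAM, g.gene_id)
            elif downstream_iv[0] <= span_end and downstream_iv[1] >= pos:
                consider(2, EFFECT_DOWNSTREAM, g.gene_id)
    if best is None:
        return EFFECT_INTERGENIC, None
    return best[1], best[2]


@dataclass(frozen=True)
class RankedVariant:
    variant: VariantRecord
    effect: str
    gene_id: Optional[str]
    rank: int


def prioritize_cds(
    variants: Iterable[VariantRecord],
    gene_models: Sequence[GeneModel],
    updown_distance: int = 5_000,
) -> list[RankedVariant]:
    """Rank candidates by coding consequence: frameshift > in-frame CDS > other.

    Ordering within a rank is genomic; the sort is stable and deterministic.
    """
    ranked = []
    for v in variants:
        effect, gene_id = classify_position(v, gene_models, updown_distance)
        ranked.append(RankedVariant(v, effect, gene_id, EFFECT_RANK[effect]))
    ranked.sort(key=lambda r: (r.rank, r.variant.chrom, r.variant.pos))
    return ranked
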