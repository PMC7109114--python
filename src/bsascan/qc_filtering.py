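"""High-quality-variant filtering and depth-based genotype calls.

Four filters are applied, in a fixed order, to the raw multi-sample calls
before any association statistic is computed:

1. *multiple genotypes* — more than two segregating alleles at the site
   (both association statistics assume biallelic sites);
2. *low depth* — a pool supported by fewer than four reads (configurably
   per-sample instead of per-pool);
3. *identical pools* — the two phenotype pools have the same called
   genotype, so the site cannot discriminate them;
4. *recessive consistency* — the recessive-phenotype pool carries an
   allele that the recessive parent does not, which is impossible under
   clean Mendelian transmission and flags a calling artefact.

Genotypes are called directly from allele depths: an allele counts as
present when it reaches both a minimum read count and a minimum fraction
of the sample's depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variant_io import (
    AlleleDepth,
    ConfigurationError,
    SampleRoleMap,
    VariantRecord,
)

FILTER_STAGES = (
    "multiple_genotypes",
    "low_depth",
    "identical_pools",
    "recessive_consistency",
)

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class GenotypeThresholds:
    """An allele is *present* if count >= min_allele_reads and
    count/total >= min_allele_frac."""

    min_allele_reads: int = 2
    min_allele_frac: float = 0.10


@dataclass(frozen=True)
class GenotypeCall:
    state: str  # hom_ref | hom_alt | het | missing | ambiguous
    alleles: tuple[int, ...]  # indices of present alleles (0 = ref)
    depth: AlleleDepth

    @property
    def is_hom(self) -> bool:
        return self.state in (HOM_REF, HOM_ALT)

    def same_genotype(self, other: "GenotypeCall") -> bool:
        return self.state == other.state and self.alleles == other.alleles


def call_genotype(
    depth: AlleleDepth, thresholds: GenotypeThresholds = GenotypeThresholds()
) -> GenotypeCall:
    """Call hom/het/missing from an allele-depth vector."""
    if depth.is_missing:
        return GenotypeCall(MISSING, (), depth)
    total = depth.total
    present = tuple(
        i
        for i, c in enumerate(depth.counts)
        if c >= thresholds.min_allele_reads
        and total > 0
        and c / total >= thresholds.min_allele_frac
    )
    if not present:
        return GenotypeCall(MISSING, (), depth)
    if len(present) == 1:
        return GenotypeCall(HOM_REF if present[0] == 0 else HOM_ALT, present, depth)
    if len(present) == 2:
        return GenotypeCall(HET, present, depth)
    return GenotypeCall(AMBIGUOUS, present, depth)


@dataclass
class FilterReport:
    """Telescoping per-stage counts plus per-variant fail reasons."""

    n_input: int = 0
    removed: dict = field(default_factory=lambda: {s: 0 for s in FILTER_STAGES})
    fail_reasons: dict = field(default_factory=dict)  # (chrom,pos,ref) -> stage

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def stage_counts(self) -> list[tuple[str, int, int, int]]:
        """Rows of (stage, n_in, n_removed, n_out); counts telescope."""
        rows = []
        n_in = self.n_input
        for stage in FILTER_STAGES:
            n_rm = self.removed[stage]
            rows.append((stage, n_in, n_rm, n_in - n_rm))
            n_in -= n_rm
        return rows

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_removed\tn_out\n")
            for row in self.stage_counts():
                fh.write("\t".join(str(x) for x in row) + "\n")


def _resolve_recessive(roles: SampleRoleMap, recessive_role: str) -> tuple[str, str]:
    """Return (recessive parent role, recessive pool role) from a color or role name."""
    aliases = {
        "green": ("green_parent", "green_pool"),
        "green_parent": ("green_parent", "green_pool"),
        "red": ("red_parent", "red_pool"),
        "red_parent": ("red_parent", "red_pool"),
    }
    if recessive_role not in aliases:
        raise ConfigurationError(f"unknown recessive role {recessive_role!r}")
    return aliases[recessive_role]


def filter_high_quality(
    variants: list[VariantRecord],
    roles: SampleRoleMap,
    recessive_role: str = "green",
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    min_pool_depth: int = 4,
    depth_mode: str = "per_pool",
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the four high-quality filters in order; return survivors + report.

    ``depth_mode`` selects whether the read-support filter applies to the
    two pools only (default) or to every sample.
    """
    if depth_mode not in ("per_pool", "per_sample"):
        raise ConfigurationError(f"depth_mode must be per_pool|per_sample, got {depth_mode!r}")
    rec_parent, rec_pool = _resolve_recessive(roles, recessive_role)
    depth_roles = (
        ("red_pool", "green_pool")
        if depth_mode == "per_pool"
        else ("red_parent", "green_parent", "original", "red_pool", "green_pool")
    )

    report = FilterReport(n_input=len(variants))
    survivors: list[VariantRecord] = []
    for v in sorted(variants, key=lambda r: (r.chrom, r.pos, r.ref)):
        stage = _fail_stage(v, thresholds, min_pool_depth, depth_roles, rec_parent, rec_pool)
        if stage is None:
            survivors.append(v)
        else:
            report.removed[stage] += 1
            report.fail_reasons[v.key] = stage
    return survivors, report


def _fail_stage(
    v: VariantRecord,
    thresholds: GenotypeThresholds,
    min_pool_depth: int,
    depth_roles: tuple[str, ...],
    rec_parent: str,
    rec_pool: str,
) -> str | None:
    if len(v.alts) > 1:
        return "multiple_genotypes"
    for role in depth_roles:
        if v.depth(role).total < min_pool_depth:
            return "low_depth"
    red = call_genotype(v.depth("red_pool"), thresholds)
    green = call_genotype(v.depth("green_pool"), thresholds)
    if red.same_genotype(green):
        return "identical_pools"
    parent = call_genotype(v.depth(rec_parent), thresholds)
    pool = call_genotype(v.depth(rec_pool), thresholds)
    if parent.state == MISSING or not set(pool.alleles) <= set(parent.alleles):
        return "recessive_consistency"
    return None
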