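"""Reading, writing and normalising multi-sample variant calls and gene models.

The pipeline's data model is deliberately small: a :class:`VariantRecord`
carries one SNP/InDel with per-role allele depths, a :class:`GeneModel`
carries exon/CDS intervals, and a :class:`SampleRoleMap` names the five
sequenced samples of the cross design (two parents, two phenotype pools,
and the original cultivar the mutant arose from).

Coordinates are 1-based inclusive throughout, following VCF/GFF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import yaml

ROLES = ("red_parent", "green_parent", "original", "red_pool", "green_pool")
PARENT_ROLES = ("red_parent", "green_parent")
SNP = "SNP"
INDEL = "InDel"


class ConfigurationError(ValueError):
    """A sample-role configuration problem (missing role, duplicate sample...)."""


class ValidationError(ValueError):
    """Malformed record or model (empty allele, CDS outside exons...)."""


@dataclass(frozen=True)
class SampleRoleMap:
    """Mapping of pipeline roles to VCF sample identifiers.

    ``female_role``/``male_role`` pick which of the two parents is which;
    they matter only for the SNP-index statistic, whose M/P alleles are
    defined per parent of origin.
    """

    red_parent: str
    green_parent: str
    original: str
    red_pool: str
    green_pool: str
    dominant_color: str = "red"
    female_role: str = "green_parent"
    male_role: str = "red_parent"

    def __post_init__(self) -> None:
        ids = [getattr(self, r) for r in ROLES]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"sample ids must be distinct, got {ids}")
        if {self.female_role, self.male_role} != set(PARENT_ROLES):
            raise ConfigurationError(
                "female_role and male_role must be the two parent roles, got "
                f"{self.female_role!r}/{self.male_role!r}"
            )

    def sample_for(self, role: str) -> str:
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r}")
        return getattr(self, role)

    def as_dict(self) -> dict:
        return {r: getattr(self, r) for r in ROLES}

    @classmethod
    def from_yaml(cls, path: str) -> "SampleRoleMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        missing = [r for r in ROLES if r not in data]
        if missing:
            raise ConfigurationError(f"role config missing roles: {missing}")
        kwargs = {r: str(data[r]) for r in ROLES}
        for key in ("dominant_color", "female_role", "male_role"):
            if key in data:
                kwargs[key] = str(data[key])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        data = self.as_dict()
        data.update(
            dominant_color=self.dominant_color,
            female_role=self.female_role,
            male_role=self.male_role,
        )
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class AlleleDepth:
    """Per-allele read counts, reference allele first.

    ``counts is None`` means *no read support reported* (the "N" state in a
    depth table), which is distinct from an observed count of zero.
    """

    counts: Optional[tuple[int, ...]]

    def __post_init__(self) -> None:
        if self.counts is not None:
            if len(self.counts) < 1 or any(c < 0 for c in self.counts):
                raise ValidationError(f"bad allele depths {self.counts}")
            object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @classmethod
    def missing(cls) -> "AlleleDepth":
        return cls(None)

    @property
    def is_missing(self) -> bool:
        return self.counts is None

    @property
    def total(self) -> int:
        return 0 if self.counts is None else sum(self.counts)

    def count(self, allele_index: int) -> int:
        if self.counts is None or allele_index >= len(self.counts):
            return 0
        return self.counts[allele_index]


def classify_variant(ref: str, alts: Sequence[str] | str) -> str:
    """Classify a site as ``SNP`` (all alleles length 1) or ``InDel``.

    Mixed multiallelic sites count as InDel as soon as any allele's length
    differs from the reference's.
    """
    if isinstance(alts, str):
        alts = [alts]
    if not ref or any(not a for a in alts) or not alts:
        raise ValidationError(f"empty allele in ref={ref!r} alts={list(alts)!r}")
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return SNP
    return INDEL


@dataclass(frozen=True)
class Annotation:
    effect: str = ""
    gene_id: str = ""
    description: str = ""


@dataclass(frozen=True)
class VariantRecord:
    """One SNP/InDel with per-role allele depths."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alts: tuple[str, ...]
    depths: dict  # role -> AlleleDepth
    annotation: Optional[Annotation] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if any(a == self.ref for a in self.alts):
            raise ValidationError(f"alt equals ref at {self.chrom}:{self.pos}")
        object.__setattr__(self, "alts", tuple(self.alts))

    @property
    def variant_class(self) -> str:
        return classify_variant(self.ref, self.alts)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)

    def depth(self, role: str) -> AlleleDepth:
        return self.depths.get(role, AlleleDepth.missing())

    def with_annotation(self, annotation: Annotation) -> "VariantRecord":
        return replace(self, annotation=annotation)


def _depth_from_ad(ad, n_alleles: int) -> AlleleDepth:
    """Convert a cyvcf2 per-sample AD vector to an AlleleDepth.

    cyvcf2 encodes '.' as negative sentinels; any negative entry marks the
    whole vector as unreported.
    """
    if ad is None:
        return AlleleDepth.missing()
    vals = [int(v) for v in ad]
    if len(vals) < n_alleles or any(v < 0 for v in vals):
        return AlleleDepth.missing()
    return AlleleDepth(tuple(vals[:n_alleles]))


def read_variants(
    path: str,
    roles: SampleRoleMap,
    on_missing_ad: str = "skip",
) -> list[VariantRecord]:
    """Read a multi-sample VCF into sorted :class:`VariantRecord` objects.

    Allele depths come from each sample's ``AD`` FORMAT field.  A record
    where AD is absent for every sample is skipped or raises, per
    ``on_missing_ad`` ('skip' or 'fail'); per-sample absent AD becomes the
    explicit missing state.
    """
    from cyvcf2 import VCF

    if on_missing_ad not in ("skip", "fail"):
        raise ConfigurationError(f"on_missing_ad must be skip|fail, got {on_missing_ad!r}")
    vcf = VCF(path)
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    role_index = {}
    for role in ROLES:
        sample = roles.sample_for(role)
        if sample not in sample_index:
            raise ConfigurationError(
                f"sample {sample!r} for role {role!r} not in VCF header {vcf.samples}"
            )
        role_index[role] = sample_index[sample]

    records: list[VariantRecord] = []
    for v in vcf:
        n_alleles = 1 + len(v.ALT)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            if on_missing_ad == "fail":
                raise ValidationError(f"no AD field at {v.CHROM}:{v.POS}")
            continue
        depths = {
            role: _depth_from_ad(ad[idx], n_alleles) for role, idx in role_index.items()
        }
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                depths=depths,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref))
    return records


def write_variants(
    records: Iterable[VariantRecord],
    path: str,
    roles: SampleRoleMap,
    contig_lengths: Optional[dict] = None,
) -> None:
    """Write records as a minimal VCF 4.2 with per-sample AD genotypes."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref))
    samples = [roles.sample_for(r) for r in ROLES]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles in the order listed">',
    ]
    fixed = dict(contig_lengths or {})
    seen = dict(fixed)
    for r in records:
        if r.chrom not in fixed:
            seen[r.chrom] = max(seen.get(r.chrom, 0), r.pos + len(r.ref))
    for chrom, length in seen.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        fields = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            ",".join(rec.alts),
            ".",
            ".",
            ".",
            "AD",
        ]
        for role in ROLES:
            d = rec.depth(role)
            fields.append("." if d.is_missing else ",".join(str(c) for c in d.counts))
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon and CDS intervals (1-based, inclusive, sorted)."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    domains: tuple[tuple[str, int, int], ...] = ()  # (name, start_aa, end_aa)

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        cds = tuple(sorted((int(s), int(e)) for s, e in self.cds))
        for s, e in exons + cds:
            if s > e or s < 1:
                raise ValidationError(f"{self.gene_id}: bad interval ({s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        for s, e in cds:
            if not any(xs <= s and e <= xe for xs, xe in exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS ({s},{e}) not contained in any exon"
                )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def complete_orf(self) -> bool:
        """False flags a CDS whose total length is not a codon multiple."""
        return self.cds_length % 3 == 0

    def spliced_cds(self, chrom_seq: str) -> str:
        """Concatenate CDS pieces from a chromosome sequence (1-based)."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to its 1-based CDS coordinate, or None."""
        pieces = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        offset = 0
        for s, e in pieces:
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds`; raises for out-of-range input."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ValidationError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        pieces = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        offset = 0
        for s, e in pieces:
            length = e - s + 1
            if cds_pos <= offset + length:
                within = cds_pos - offset
                return s + within - 1 if self.strand == "+" else e - within + 1
            offset += length
        raise AssertionError("unreachable")


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons and cds:
            exons = list(cds)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def _read_interval_table(path: str) -> list[GeneModel]:
    # 4 columns: gene_id, chrom, start, end (single-exon genes, + strand)
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"interval table row needs 4 columns: {line!r}")
            gene_id, chrom, start, end = parts[:4]
            iv = ((int(start), int(end)),)
            models.append(GeneModel(gene_id, chrom, "+", iv, iv))
    return models


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from GFF3 or from a simple 4-column interval table."""
    with open(path) as fh:
        head = fh.read(4096)
    is_gff = head.startswith("##gff") or any(
        len(line.split("\t")) == 9 for line in head.splitlines() if line and line[0] != "#"
    )
    models = _read_gff3(path) if is_gff else _read_interval_table(path)
    models.sort(key=lambda g: (g.chrom, g.start))
    return models


def read_domain_table(path: str) -> dict:
    """Read a TSV of protein-domain coordinates: gene_id, name, start_aa, end_aa."""
    domains: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, name, start_aa, end_aa = line.split("\t")[:4]
            domains.setdefault(gene_id, []).append((name, int(start_aa), int(end_aa)))
    return {g: tuple(v) for g, v in domains.items()}


def read_fasta(path: str) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def contig_lengths_from_vcf(path: str) -> dict:
    from cyvcf2 import VCF

    vcf = VCF(path)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens or []))
    return {c: int(l) for c, l in lengths.items() if l}
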