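"""Coding-consequence analysis of a candidate variant on its CDS.

Applies a deletion to the coding sequence, translates both alleles with
the standard genetic code, and reports truncation: shared N-terminal
prefix, consequence class, and which annotated protein domains fall
beyond the shared prefix (reported as lost/disrupted).  Also holds two
small printed-formula helpers used around the main analysis: clone-type
classification of amplicon sequences and the FPKM expression unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .variant_io import ValidationError

CONSEQ_SYNONYMOUS = "synonymous"
CONSEQ_MISSENSE = "missense"
CONSEQ_INFRAME = "in-frame indel"
CONSEQ_FRAMESHIFT = "frameshift+early stop"
CONSEQ_STOP_LOST = "stop lost"
CONSEQ_NONCODING = "non-coding"


def apply_interval_deletion(cds: str, start: int, end: int) -> str:
    """Remove positions start..end (1-based, inclusive) from a sequence."""
    if not 1 <= start <= end <= len(cds):
        raise ValidationError(
            f"deletion {start}..{end} out of range for length {len(cds)}"
        )
    return cds[: start - 1] + cds[end:]


def translate_orf(cds: str) -> tuple[str, bool]:
    """Translate from position 1 to the first stop codon (standard code).

    Returns (protein, stop_found).  A trailing partial codon is ignored;
    sequences shorter than one codon give an empty protein.
    """
    usable = len(cds) - len(cds) % 3
    if usable < 3:
        return "", False
    aa = str(Seq(cds[:usable]).translate(table=1))
    stop = aa.find("*")
    if stop == -1:
        return aa, False
    return aa[:stop], True


def _shared_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


@dataclass(frozen=True)
class TranscriptEffect:
    consequence: str
    wt_protein: str
    mut_protein: str
    shared_prefix_aa: int
    wt_stop_found: bool
    mut_stop_found: bool
    lost_domains: tuple[str, ...] = ()

    @property
    def wt_length_aa(self) -> int:
        return len(self.wt_protein)

    @property
    def mut_length_aa(self) -> int:
        return len(self.mut_protein)


def effect_report(
    wt_cds: str,
    deletion: Optional[tuple[int, int]],
    domains: Sequence[tuple[str, int, int]] = (),
    mut_cds: Optional[str] = None,
) -> TranscriptEffect:
    """Full consequence report for a variant applied to a CDS.

    ``deletion`` is a 1-based inclusive interval in CDS coordinates;
    pass ``deletion=None`` with an explicit ``mut_cds`` for substitutions,
    or ``deletion=None, mut_cds=None`` for a variant outside the CDS
    (consequence 'non-coding', lengths unchanged).

    Domains are (name, start_aa, end_aa) on the wild-type protein; a domain
    whose interval extends beyond the shared prefix is reported lost.
    """
    wt_protein, wt_stop = translate_orf(wt_cds)
    if deletion is None and mut_cds is None:
        return TranscriptEffect(
            CONSEQ_NONCODING, wt_protein, wt_protein, len(wt_protein), wt_stop, wt_stop
        )
    if mut_cds is None:
        mut_cds = apply_interval_deletion(wt_cds, deletion[0], deletion[1])
    mut_protein, mut_stop = translate_orf(mut_cds)
    shared = _shared_prefix_len(wt_protein, mut_protein)

    length_change = len(mut_cds) - len(wt_cds)
    if length_change == 0:
        conseq = CONSEQ_SYNONYMOUS if mut_protein == wt_protein else CONSEQ_MISSENSE
    elif length_change % 3 == 0:
        conseq = CONSEQ_INFRAME
    elif not mut_stop:
        conseq = CONSEQ_STOP_LOST
    else:
        conseq = CONSEQ_FRAMESHIFT

    lost = tuple(
        name for name, _start_aa, end_aa in domains if end_aa > shared
    )
    return TranscriptEffect(conseq, wt_protein, mut_protein, shared, wt_stop, mut_stop, lost)


@dataclass(frozen=True)
class CloneCounts:
    full: int
    deleted: int
    unclassified: int

    @property
    def classified(self) -> int:
        return self.full + self.deleted

    @property
    def pct_full(self) -> float:
        return round(100.0 * self.full / self.classified, 2) if self.classified else 0.0

    @property
    def pct_deleted(self) -> float:
        return round(100.0 * self.deleted / self.classified, 2) if self.classified else 0.0


def classify_clone_haplotypes(
    reads: Iterable[str],
    reference: str,
    deletion: tuple[int, int],
    flank: int = 10,
) -> CloneCounts:
    """Classify amplicon/clone sequences as full type or deletion type.

    A read is *full* if it contains the reference junction (flank +
    deleted segment + flank), *del* if it contains the two flanks directly
    joined, and unclassified otherwise (e.g. it does not span the locus).
    """
    start, end = deletion
    if not 1 <= start <= end <= len(reference):
        raise ValidationError(f"deletion {start}..{end} outside reference")
    left = reference[max(0, start - 1 - flank) : start - 1]
    seg = reference[start - 1 : end]
    right = reference[end : end + flank]
    full_sig = left + seg + right
    del_sig = left + right
    n_full = n_del = n_un = 0
    for read in reads:
        if full_sig in read:
            n_full += 1
        elif del_sig in read:
            n_del += 1
        else:
            n_un += 1
    return CloneCounts(n_full, n_del, n_un)


def fpkm(
    cdna_fragments: float,
    mapped_fragments_millions: float,
    transcript_length_kb: float,
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if mapped_fragments_millions <= 0 or transcript_length_kb <= 0:
        raise ValidationError("FPKM denominators must be positive")
    return cdna_fragments / (mapped_fragments_millions * transcript_length_kb)
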