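"""Genome-wide pooled association scans: ED and ΔSNP-index statistics.

Two per-variant statistics quantify allele-frequency separation between
the two phenotype pools of an F1 cross:

* **ED** — the Euclidean distance between the pools' nucleotide-frequency
  vectors; raised to the fifth power (ED⁵) to suppress background noise.
  For a biallelic site ED = √2·|Δf| with Δf the alt-frequency difference.
* **ΔSNP index** — SNP index(aa) − SNP index(ab), where the SNP index of a
  pool is the read fraction of the female-parent-informative allele, aa is
  the recessive (green) pool and ab the dominant (red) pool.

Raw values are fitted along each chromosome with a sliding-window mean
(2 Mb windows, 10 kb steps by default), thresholds are derived from the
genome-wide distribution of fitted values (median + 3 SD, an empirical
quantile, or a simulated null envelope), and maximal runs of consecutive
above-threshold windows become candidate regions.

Window arithmetic is half-open [start, start+window) on a step-anchored
grid starting at 0; reported region bounds live on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .qc_filtering import GenotypeThresholds, call_genotype
from .variant_io import (
    SNP,
    GeneModel,
    SampleRoleMap,
    ValidationError,
    VariantRecord,
)

NUCLEOTIDES = ("A", "C", "G", "T")

ED5 = "ED5"
DSNP = "dSNPindex"


@dataclass(frozen=True)
class PoolFrequencies:
    """Per-pool allele-frequency vectors on shared axes.

    SNPs live on the four nucleotide axes (unused nucleotides at 0);
    InDels on a two-sided (ref, alt) axis.
    """

    axes: tuple[str, ...]
    red: np.ndarray
    green: np.ndarray


def pool_frequencies(
    variant: VariantRecord, roles: SampleRoleMap
) -> tuple[Optional[PoolFrequencies], Optional[str]]:
    """Compute pool allele frequencies, or (None, reason) when undefined."""
    red_d = variant.depth("red_pool")
    green_d = variant.depth("green_pool")
    if red_d.total == 0 or green_d.total == 0:
        return None, "zero_pool_depth"
    if len(variant.alts) != 1:
        return None, "multiallelic"

    if variant.variant_class == SNP:
        axes = NUCLEOTIDES
        idx = {n: i for i, n in enumerate(axes)}
        alleles = variant.alleles
        if any(a.upper() not in idx for a in alleles):
            return None, "non_acgt_allele"

        def vec(d):
            v = np.zeros(4)
            for ai, allele in enumerate(alleles):
                v[idx[allele.upper()]] += d.count(ai)
            return v / v.sum()

    else:
        axes = ("ref", "alt")

        def vec(d):
            v = np.array([d.count(0), d.count(1)], dtype=float)
            return v / v.sum()

    return PoolFrequencies(axes, vec(red_d), vec(green_d)), None


def ed_value(freq_red: PoolFrequencies | np.ndarray, freq_green: np.ndarray | None = None) -> float:
    """Euclidean distance between the two pools' frequency vectors."""
    if isinstance(freq_red, PoolFrequencies):
        red, green = freq_red.red, freq_red.green
    else:
        red, green = np.asarray(freq_red, float), np.asarray(freq_green, float)
    if red.shape != green.shape:
        raise ValidationError("mismatched frequency axes")
    return float(np.linalg.norm(red - green))


def ed_association_value(ed: float, power: int = 5) -> float:
    """The association value: ED raised to the fifth power."""
    if ed < 0:
        raise ValidationError("ED must be non-negative")
    return float(ed) ** power


# ---------------------------------------------------------------------------
# SNP index


@dataclass(frozen=True)
class ParentalAlleles:
    """Allele indices informative for each parent (m = female, p = male)."""

    m_allele: int
    p_allele: int


def assign_parental_alleles(
    variant: VariantRecord,
    roles: SampleRoleMap,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> Optional[ParentalAlleles]:
    """Decide which allele is female- (M) and which male- (P) informative.

    The female allele is the one the female parent carries homozygously, or
    carries uniquely when it is heterozygous against a homozygous male
    parent.  Sites where both parents have the same called genotype (or
    either is missing/ambiguous) are uninformative and return None.
    """
    female = call_genotype(variant.depth(roles.female_role), thresholds)
    male = call_genotype(variant.depth(roles.male_role), thresholds)
    if female.state in ("missing", "ambiguous") or male.state in ("missing", "ambiguous"):
        return None
    if female.same_genotype(male):
        return None
    if female.is_hom:
        m = female.alleles[0]
        others = [a for a in male.alleles if a != m]
        if not others:
            return None
        return ParentalAlleles(m_allele=m, p_allele=others[0])
    if male.is_hom:  # female het, male hom: female's unique allele is M
        p = male.alleles[0]
        uniques = [a for a in female.alleles if a != p]
        if len(uniques) != 1:
            return None
        return ParentalAlleles(m_allele=uniques[0], p_allele=p)
    return None  # both het with different allele sets: ambiguous phase


def snp_index(m_depth: int, p_depth: int) -> Optional[float]:
    """Read fraction of the female-parent allele; None when depth is zero."""
    if m_depth < 0 or p_depth < 0:
        raise ValidationError("depths must be non-negative")
    total = m_depth + p_depth
    if total == 0:
        return None
    return m_depth / total


def delta_snp_index(index_aa: float, index_ab: float) -> float:
    """ΔSNP index = SNP index(aa) − SNP index(ab); in [−1, 1]."""
    return index_aa - index_ab


def ed5_for_variant(
    variant: VariantRecord, roles: SampleRoleMap, power: int = 5
) -> tuple[Optional[float], Optional[str]]:
    freqs, reason = pool_frequencies(variant, roles)
    if freqs is None:
        return None, reason
    return ed_association_value(ed_value(freqs), power), None


def dsnp_for_variant(
    variant: VariantRecord,
    roles: SampleRoleMap,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> tuple[Optional[float], Optional[str]]:
    """ΔSNP index for one variant (aa = green pool, ab = red pool)."""
    assign = assign_parental_alleles(variant, roles, thresholds)
    if assign is None:
        return None, "uninformative_parents"
    green = variant.depth("green_pool")
    red = variant.depth("red_pool")
    idx_aa = snp_index(green.count(assign.m_allele), green.count(assign.p_allele))
    idx_ab = snp_index(red.count(assign.m_allele), red.count(assign.p_allele))
    if idx_aa is None or idx_ab is None:
        return None, "zero_informative_depth"
    return delta_snp_index(idx_aa, idx_ab), None


# ---------------------------------------------------------------------------
# Sliding windows, thresholds, regions


@dataclass
class AssociationTrack:
    """Per-variant raw values plus per-window fitted values for one chromosome."""

    chrom: str
    kind: str  # ED5 | dSNPindex
    positions: np.ndarray  # 1-based variant positions, sorted
    raw: np.ndarray
    window: int
    step: int
    chrom_length: int
    window_start: np.ndarray = field(default=None)
    fitted: np.ndarray = field(default=None)  # NaN where undefined
    n_variants: np.ndarray = field(default=None)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.fitted)

    @property
    def midpoints(self) -> np.ndarray:
        return self.window_start + self.window / 2.0


def fit_windows(
    positions: Sequence[int],
    values: Sequence[float],
    chrom_length: int,
    chrom: str = "",
    kind: str = ED5,
    window: int = 2_000_000,
    step: int = 10_000,
    min_variants_per_window: int = 1,
) -> AssociationTrack:
    """Fit raw per-variant values with a sliding-window arithmetic mean.

    Windows are [s, s+window) for s = 0, step, 2·step, ... while the window
    still fits the chromosome (s + window <= chrom_length; a chromosome
    shorter than one window gets the single window starting at 0).  Windows
    spilling past the chromosome end would hold only the few tail markers
    and produce unstable near-empty means, and every marker they contain is
    already covered by an earlier full window.  The fitted value of a
    window is the mean of the raw values of the variants inside it,
    undefined (NaN) when it holds fewer than ``min_variants_per_window``.
    """
    if window < step:
        raise ValidationError("window must be >= step")
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    order = np.argsort(positions, kind="stable")
    positions, values = positions[order], values[order]

    starts = np.arange(0, max(chrom_length - window, 0) + 1, step, dtype=np.int64)
    # variant at 1-based pos p sits at offset p-1; window holds s <= p-1 < s+window
    offs = positions - 1
    lo = np.searchsorted(offs, starts, side="left")
    hi = np.searchsorted(offs, starts + window, side="left")
    n = (hi - lo).astype(np.int64)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    sums = csum[hi] - csum[lo]
    with np.errstate(invalid="ignore"):
        fitted = np.where(n >= max(min_variants_per_window, 1), sums / np.maximum(n, 1), np.nan)
    return AssociationTrack(
        chrom=chrom,
        kind=kind,
        positions=positions,
        raw=values,
        window=window,
        step=step,
        chrom_length=chrom_length,
        window_start=starts,
        fitted=fitted,
        n_variants=n,
    )


@dataclass(frozen=True)
class Threshold:
    kind: str  # statistic the threshold applies to
    method: str  # median_plus_3sd | quantile | null_simulation
    value: float
    params: dict = field(default_factory=dict)


def _defined_fitted(tracks: Iterable[AssociationTrack]) -> tuple[np.ndarray, str]:
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("no tracks given")
    kinds = {t.kind for t in tracks}
    if len(kinds) > 1:
        raise ValidationError(f"mixed statistic kinds {kinds}")
    vals = np.concatenate([t.fitted[t.defined] for t in tracks]) if tracks else np.array([])
    return vals, kinds.pop()


def threshold_median_3sd(tracks: AssociationTrack | Iterable[AssociationTrack]) -> Threshold:
    """median + 3·SD (sample SD, n−1) of all defined fitted window values."""
    if isinstance(tracks, AssociationTrack):
        tracks = [tracks]
    vals, kind = _defined_fitted(tracks)
    if vals.size < 2:
        raise ValidationError("need >= 2 defined windows for median+3SD")
    sd = float(np.std(vals, ddof=1))
    value = float(np.median(vals)) + 3.0 * sd
    return Threshold(kind, "median_plus_3sd", value, {"sd": sd, "median": float(np.median(vals))})


def threshold_quantile(
    tracks: AssociationTrack | Iterable[AssociationTrack], level: float = 0.99
) -> Threshold:
    """Empirical quantile (linear interpolation) of defined fitted values."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"quantile level must be in (0,1), got {level}")
    if isinstance(tracks, AssociationTrack):
        tracks = [tracks]
    vals, kind = _defined_fitted(tracks)
    if vals.size < 1:
        raise ValidationError("need >= 1 defined window for a quantile")
    value = float(np.quantile(vals, level, method="linear"))
    return Threshold(kind, "quantile", value, {"level": level})


def threshold_null_simulation(
    depths: Sequence[int],
    pool_sizes: tuple[int, int] = (50, 50),
    level: float = 0.90,
    n_sims: int = 10_000,
    seed: int = 0,
) -> Threshold:
    """Per-depth confidence envelope of the ΔSNP index under no association.

    Under the null for a site heterozygous in one parent and homozygous in
    the other, an unselected F1 pool carries the female-parent allele at
    Mendelian frequency 0.75 (every offspring inherits it, half are
    heterozygous for the other parent's allele).  Pool reads are drawn
    binomially at that expectation and the two-sided (1−level) envelope of
    |Δ| is recorded per depth.  Finite pool size adds plant-sampling noise
    on top of read sampling.
    """
    import warnings

    if n_sims < 100:
        warnings.warn("n_sims < 100 gives an unreliable envelope", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_red, n_green = pool_sizes
    bounds: dict[int, float] = {}
    for depth in depths:
        # plant sampling: X ~ Bin(n, 1/2) het offspring -> female-allele
        # pool frequency 1 - X/(2n), expectation 0.75
        f_green = 1.0 - rng.binomial(n_green, 0.5, n_sims) / (2.0 * n_green)
        f_red = 1.0 - rng.binomial(n_red, 0.5, n_sims) / (2.0 * n_red)
        idx_aa = rng.binomial(depth, f_green) / depth
        idx_ab = rng.binomial(depth, f_red) / depth
        delta = np.abs(idx_aa - idx_ab)
        bounds[int(depth)] = float(np.quantile(delta, level))
    ref_depth = sorted(bounds)[len(bounds) // 2]
    return Threshold(
        DSNP,
        "null_simulation",
        bounds[ref_depth],
        {"level": level, "per_depth": bounds, "pool_sizes": tuple(pool_sizes), "n_sims": n_sims},
    )


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal run of consecutive above-threshold windows.

    ``start`` and ``end`` are the first and last window start of the run
    (so a single-window region has size 0); the physical footprint of the
    last window extends one window length beyond ``end``.
    """

    chrom: str
    start: int
    end: int
    peak_pos: float
    peak_value: float
    n_windows: int
    gene_count: Optional[int] = None
    window: int = 0

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @property
    def footprint_end(self) -> int:
        """Last base covered by the run's final window."""
        return self.end + self.window

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.footprint_end


def call_regions(
    track: AssociationTrack,
    threshold: Threshold | float,
    gene_models: Optional[Sequence[GeneModel]] = None,
    mode: str = "signed",
) -> list[CandidateRegion]:
    """Call maximal runs of consecutive defined windows with fitted >= threshold.

    Runs separated by any below-threshold or undefined window are kept
    separate.  ``mode='absolute'`` tests |fitted| >= threshold (an option
    for the signed ΔSNP statistic).
    """
    thr = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    fitted = track.fitted
    tested = np.abs(fitted) if mode == "absolute" else fitted
    with np.errstate(invalid="ignore"):
        mask = track.defined & (tested >= thr)
    regions: list[CandidateRegion] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return regions
    # split into runs of consecutive window indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_bounds = np.split(idx, breaks + 1)
    for run in run_bounds:
        i0, i1 = int(run[0]), int(run[-1])
        start = int(track.window_start[i0])
        end = min(int(track.window_start[i1]), track.chrom_length)
        peak_i = run[int(np.argmax(tested[run]))]
        footprint_end = min(end + track.window, track.chrom_length)
        gene_count = None
        if gene_models is not None:
            gene_count = sum(
                1
                for g in gene_models
                if g.chrom == track.chrom and g.start <= footprint_end and g.end >= start
            )
        regions.append(
            CandidateRegion(
                chrom=track.chrom,
                start=start,
                end=end,
                peak_pos=float(track.midpoints[peak_i]),
                peak_value=float(fitted[peak_i]),
                n_windows=len(run),
                gene_count=gene_count,
                window=track.window,
            )
        )
    return regions


def plot_scan(
    tracks: Iterable[AssociationTrack],
    threshold: Threshold | float,
    path: str,
) -> None:
    """Per-chromosome scan figure: raw values, fitted curve, threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tracks = list(tracks)
    thr = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    fig, axes = plt.subplots(
        1, len(tracks), figsize=(4 * len(tracks), 3), squeeze=False, sharey=True
    )
    for ax, t in zip(axes[0], tracks):
        ax.plot(t.positions / 1e6, t.raw, ".", ms=2, alpha=0.3, color="tab:blue")
        ax.plot(t.midpoints[t.defined] / 1e6, t.fitted[t.defined], "-", color="black", lw=1)
        ax.axhline(thr, color="red", ls=":", lw=1)
        ax.set_xlabel(f"{t.chrom} (Mb)")
    axes[0][0].set_ylabel(tracks[0].kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
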