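# Methods

`bsascan` implements bulked-segregant association (BSA-seq) mapping of a
dominant mutation in an F1 cross, as used to map qualitative traits (e.g. a
red-skin bud-sport mutation in pear) from pooled whole-genome sequencing of
phenotype-contrasted offspring. This note records the models, the defaults
and why, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Study design and model

The design assumes five sequenced DNA samples: a mutant parent heterozygous
for a dominant causal allele, a second (non-mutant) parent homozygous for
the recessive background, the *original* cultivar the mutant arose from as
a bud sport, and two pools of F1 offspring selected for the contrasting
phenotypes (default 50 plants each). With perfect penetrance the phenotype
segregates 1:1 and the pools partition offspring by their causal genotype.

For a marker at recombination fraction *r* from the causal locus with its
variant allele in coupling phase on the mutant parent's causal haplotype,
the expected pool allele frequencies are

    f_dominant-pool  = (1 − r)/2        f_recessive-pool = r/2

so at the causal locus itself f = 0.5 vs 0, and the separation decays to
zero as markers become unlinked (r → 0.5).

## Variant filtering

Four high-quality filters are applied in a fixed order so stage counts are
reproducible: (1) sites with more than two alleles; (2) sites where a pool
is supported by fewer than four reads (per-pool by default; a per-sample
mode exists); (3) sites whose called genotypes are identical in the two
pools; (4) sites where the recessive pool carries an allele the recessive
parent does not. Genotypes are called from allele depths: an allele is
present if it has ≥ 2 reads and ≥ 10% of the sample's depth (both
configurable). Missing depth ("N") is an explicit state, never 0.

Filter 3 and 4 are aggressive by design: an unlinked marker heterozygous in
one parent shows both pools at ~25% allele frequency and is removed as
"identical", so the surviving set is strongly enriched for association
signal. Threshold statistics (below) must therefore be computed genome-wide,
where most surviving windows are still background.

## Association statistics

* **ED** — the Euclidean distance between the two pools' allele-frequency
  vectors, on the four nucleotide axes for SNPs and on (ref, alt) for
  InDels. For a biallelic site ED = √2·|Δf|; its expectation under the
  linkage model is (1 − 2r)/√2 in the infinite-pool limit. The association
  value is ED⁵, which suppresses background noise relative to signal.
* **ΔSNP index** — per pool, the read fraction of the female-parent
  informative allele M: index = M/(M+P); Δ = index(recessive pool) −
  index(dominant pool). The female allele is the one the female parent
  carries homozygously (or uniquely against a homozygous male parent);
  sites where both parents have the same called genotype are uninformative
  and excluded. Region calling on Δ uses the signed value one-sided by
  default (an absolute-value mode is available).

## Sliding windows, thresholds, regions

Raw per-variant values are fitted as the arithmetic mean in sliding windows
(default 2 Mb, step 10 kb), anchored at 0. Only windows that fit entirely
inside the chromosome are evaluated: spill-over windows at chromosome ends
hold only the few tail markers — each already covered by an earlier full
window — and their near-empty means produce spurious end-of-chromosome
peaks. Windows with fewer than `min_variants_per_window` (default 1)
variants are undefined and excluded from threshold computation.

Thresholds are computed over all defined windows genome-wide, separately
per statistic and per variant class (SNP / InDel):

* median + 3·SD (sample SD) — default for ED⁵;
* empirical quantile, linear interpolation (default level 0.99) — default
  for the ΔSNP index;
* a simulated null envelope for Δ: per sequencing depth, pool reads are
  drawn binomially at the Mendelian null expectation of the female allele
  (0.75 for a hom × het site) on top of plant sampling, and the two-sided
  (1 − level) bound of |Δ| is tabulated per depth.

Candidate regions are maximal runs of consecutive defined windows with
fitted value ≥ threshold (ties count as above); runs separated by any
below-threshold or undefined window are not merged. Region `start`/`end`
are the first and last window start of the run — so a single-window region
has size 0 and the physical footprint extends one window length beyond
`end`; containment tests and gene counts use the footprint. This convention
is the only one consistent with published candidate-region tables that
contain both multi-megabase spans and zero-size rows with nonzero gene
counts.

## Candidate narrowing and coding consequence

Within the called regions, candidates must (i) differ in called genotype
between the mutant and the original cultivar AND between the mutant and the
other parent (a bud-sport mutation is absent from both), and (ii) match the
dominant-heterozygote pattern: heterozygous in the mutant parent and the
dominant pool, homozygous for one shared allele in the other parent, the
original, and the recessive pool. Survivors are ranked by predicted coding
consequence: CDS frameshift (indel length change ≢ 0 mod 3) > in-frame CDS
change > everything else (intron, up/downstream within 5 kb — a common
annotation default, configurable — or intergenic); ties are broken by
genomic order, deterministically.

Consequence analysis applies the variant to the CDS and translates both
alleles (standard genetic code, translation from position 1, stop at the
first stop codon; no start-codon scanning since the CDS is supplied
in-frame). The report gives both protein lengths, the shared N-terminal
prefix, the consequence class, and which annotated domains extend beyond
the shared prefix (reported lost/disrupted — domain coordinates are user
input; no domain discovery is attempted). Helper formulas: clone-type
classification of amplicon sequences by junction matching (flank + deleted
segment + flank vs directly joined flanks), and FPKM = fragments /
(mapped fragments in millions × transcript length in kb).

Note: for a 720-nt CDS with a 14-nt deletion at 568–581, the shared prefix
is 189 aa and the frameshifted protein ends at an early stop; published
descriptions of such a truncation as "48 fewer aa" alongside 239 → 205 aa
(a 34-aa difference) cannot both be exact without the true sequence; the
package reports what it computes from the sequence it is given.

## Synthetic data generator

The generator emulates the study conditions: default genome of 17
chromosomes × 30 Mb (~510 Mb, the scale of a pear assembly), markers every
10 kb, causal locus at Chr04:18,388,296, 50-plant pools at mean depth 50
(Poisson), parents at mean depth 25, sequencing error 0.01 (a read flips to
the other allele of the biallelic site), genetic map 2.5 cM/Mb (Haldane,
no interference), 30% uninformative (monomorphic) markers, and ~39% of
markers InDels. Only the causal chromosome is linked to the locus; the
other 16 provide the unlinked background that genome-wide threshold
statistics assume — with a single linked chromosome the whole fitted
distribution is signal and median+3SD is undefined in spirit (and fails in
practice). Markers' transmission is drawn per plant at the marker's
recombination fraction to the causal locus, independently across markers
given the causal genotype (no residual haplotype correlation along the
chromosome between markers — adequate for window means, not for
haplotype-based methods).

Planted features: a three-exon gene whose 720-nt CDS is engineered (by
rejection sampling of non-stop codons around a few fixed codons) so that
deleting CDS 568–581 (the 14-mer GCAGCTGAAGTTCC with an A anchor)
frameshifts to an early stop at mutant codon 206 — wild type 239 aa, mutant
205 aa, shared prefix 189 aa; twelve tightly linked intergenic "pattern
decoys" emulating the neutral co-variants a bud sport accumulates; one
decoy violating each quality filter; and background single-exon genes every
300 kb for region gene counts. The original cultivar shares the mutant
parent's genotype everywhere except at the planted mutation and the
decoys. All randomness flows through one seeded generator; a config + seed
reproduces the VCF byte for byte.

What passing the synthetic validation shows: the statistics, windowing,
thresholds, intersection logic and consequence ranking recover a planted
dominant frameshift under the stated design. What it does not show:
robustness to real-data pathologies the generator omits — mapping
artifacts, depth overdispersion beyond Poisson, segregation distortion,
incomplete penetrance, mis-specified parentage, reference bias.

## Numerical and validation choices

The closed-form recovery check (mean simulated ED vs (1 − 2r)/√2 at r ∈
{0, 0.1, 0.25, 0.5}) samples reads at the expected pool frequencies (depth
5000, 200 replicates, error 0): the closed form is the infinite-pool limit,
and with 50-plant pools the strictly positive statistic has a finite-pool
bias at r = 0.5 (E[ED] ≈ √2·E|Δf| ≈ 0.056) that is a property of the
design, not of the implementation. The end-to-end recovery test runs the
full pipeline on 20 seeded replicates of the default conditions and
requires the top ED⁵ region (highest fitted peak) to contain the causal
locus and the planted frameshift to rank first in ≥ 95% of them; problem
sizes (17 × 30 Mb, 10 kb markers, 20 seeds) keep the whole suite within a
few minutes on one CPU. Quantiles use linear interpolation (NumPy default);
the median+3SD uses the sample SD (n − 1); pipeline-level plumbing tests on
a miniature genome use the quantile threshold because a miniature
single-digit-megabase genome is linked end-to-end.

## Known limitations

* Biallelic association only; multiallelic sites are parsed but removed by
  the first filter.
* "Fitted" means the window mean; no loess or kernel smoother.
* The ΔSNP-index null envelope is a reconstruction of the confidence-level
  approach (the envelope's exact published form is not specified).
* No read-level simulation (FASTQ) and no reference sequence emission
  beyond the planted gene's CDS.
* Upstream variant calling, annotation, and RNA-seq quantification are out
  of scope; the pipeline starts from a multi-sample VCF with AD fields.
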