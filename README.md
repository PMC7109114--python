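# bsascan

Bulked-segregant association scanning (BSA-seq) for F1 crosses sequenced
as phenotype pools — the strategy used to map qualitative traits such as a
dominant red-skin bud-sport mutation in pear from five DNA samples: the
mutant parent, the other parent, the original (non-mutant) cultivar, and
two pools of 50 phenotype-selected F1 plants.

It is written for geneticists who have multi-sample variant calls (a VCF
with per-sample `AD` allele depths) from such a design and want a tested,
reproducible path from raw calls to a ranked causal-candidate table — plus
a pooled-sequencing simulator with known truth for validating the whole
workflow.

## What it computes

1. **High-quality variant filtering** — drop sites with >2 alleles, pools
   supported by <4 reads, identical pool genotypes, or recessive-pool
   alleles absent from the recessive parent; telescoping per-stage counts.
2. **Association scans** per variant class (SNP / InDel):
   * Euclidean distance between pool allele-frequency vectors,

         ED = √((A_red−A_green)² + (G_red−G_green)² + (C_red−C_green)² + (T_red−T_green)²)

     with **ED⁵** as the association value; for a biallelic site
     ED = √2·|Δf|, expectation (1−2r)/√2 at recombination fraction r.
   * **ΔSNP index** = M_aa/(M_aa+P_aa) − M_ab/(M_ab+P_ab), the difference
     between the pools' read fractions of the female-parent allele
     (aa = recessive pool, ab = dominant pool).
3. **Sliding-window fitting** (2 Mb windows, 10 kb steps) and empirical
   thresholds: median + 3 SD (ED⁵ default), 99th percentile (ΔSNP default),
   or a simulated Mendelian null envelope; maximal above-threshold runs
   become **candidate regions** with sizes and gene counts.
4. **Candidate narrowing** — variants inside the regions that differ
   mutant-vs-original *and* mutant-vs-other-parent and match the dominant
   heterozygote pattern (het in mutant parent and dominant pool, hom for
   one shared allele elsewhere), **ranked by coding consequence**
   (frameshift > in-frame CDS > other).
5. **Consequence analysis** — apply a CDS deletion, translate both
   alleles, report protein lengths, shared N-terminal prefix, and lost
   domains; helpers for clone-type classification and FPKM.

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example (simulated cross)

Simulate the default study: 17 chromosomes × 30 Mb, markers every 10 kb,
50-plant pools at ~50× depth, a causal 14-nt frameshift deletion planted at
Chr04:18,388,296 in the CDS of a generated gene:

```bash
bsascan simulate --outdir demo --seed 1
bsascan run --vcf demo/variants.vcf --gff3 demo/genes.gff3 \
            --roles demo/roles.yaml --outdir demo_out --seed 1
```

The region table starts:

```
   method variant_type chrom    start      end  size_mb  gene_number   peak_pos  peak_value
       ED          SNP Chr04 14000000 22180000     8.18           35 18540000.0    0.214328
       ED        InDel Chr04 13380000 13520000     0.14            7 14460000.0    0.105695
       ED        InDel Chr04 14160000 21720000     7.56           32 19360000.0    0.176080
```

The top ED⁵ region is an 8.18-Mb span of Chr04 whose peak window
(midpoint 18.54 Mb, fitted ED⁵ ≈ 0.21) sits right at the planted locus;
`start`/`end` are the first/last 10-kb window starts of the run, and
`gene_number` counts genes under the windows' footprint. The candidate
table ranks the planted deletion first:

```
variant_type chrom  position       reference alternate      effect    gene_id  rank ...
       InDel Chr04  18388296 AGCAGCTGAAGTTCC         A Frame shift syng_bbx24     0 ...
```

— a 14-nt deletion, heterozygous in the mutant parent and red pool,
absent everywhere else, the only candidate that alters a CDS (the linked
intergenic decoys rank below it). Its consequence:

```bash
bsascan effect --cds demo/cds.fasta --deletion 568-581
```

```json
{
  "gene": "syng_bbx24",
  "consequence": "frameshift+early stop",
  "wt_length_aa": 239,
  "mut_length_aa": 205,
  "shared_prefix_aa": 189,
  "lost_domains": []
}
```

The 720-nt wild-type CDS encodes 239 aa; deleting CDS 568–581 shifts the
frame after residue 189 and truncates the protein to 205 aa. Passing a
domain table (`--domains`) reports which domains fall beyond the shared
prefix.

The same workflow runs on real data: point `--vcf`/`--gff3` at your calls
and gene models and write a `roles.yaml` mapping the five roles
(`red_parent`, `green_parent`, `original`, `red_pool`, `green_pool`) to
your VCF sample names. Everything is also available as a library
(`bsascan.filter_high_quality`, `bsascan.fit_windows`,
`bsascan.call_regions`, `bsascan.prioritize_cds`, ...).

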