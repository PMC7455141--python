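# primsite

Genomic-safety analysis for Sleeping Beauty (SB100x) transposon gene
therapy: simulation of TA-dinucleotide-targeted integration, recovery of
integration sites from junction reads, in-silico inverse PCR, genomic
feature annotation, and a windowed **Poisson regression insertion model
(PRIM)** that tests every genomic window for integration-site enrichment.

## Who this is for

Groups assessing the integration behaviour of SB100x-based vectors (for
example HDAd5/35++-delivered IR/DR-flanked cargo in hematopoietic
stem/progenitor cells) need to answer: are the recovered vector-chromosome
junctions the canonical TA signature, are insertions spread over the genome
or clustered in particular windows, which gene features do they land in,
and is any clone over-represented?  `primsite` implements that analysis as
a tested, reusable pipeline, together with a synthetic-data generator that
produces every input it needs with known ground truth.

## The model

The genome is tiled into nonoverlapping windows of width *w* (default
20 kb).  For window *i* on chromosome *c(i)* with TA-dinucleotide count
*T\_i* and observed unique-insertion count *y\_i*, PRIM is the Poisson GLM

&nbsp;&nbsp;&nbsp;&nbsp;*y\_i* ~ Poisson(*μ\_i*),&nbsp;&nbsp;
log *μ\_i* = *β₀* + *γ\_{c(i)}* + *β\_T* · log *T\_i*,

fitted by iteratively reweighted least squares (first chromosome is the
reference level; windows with *T\_i* = 0 cannot receive TA-targeted
insertions and are excluded).  Each tested window gets the one-sided
upper-tail probability P(Y ≥ *y\_i* | *μ̂\_i*), Bonferroni-corrected over
the *m* tested windows; a window is *enriched* when *m*·p < α.  A
randomized null of TA-containing reference fragments, mapped back to the
genome, provides a per-chromosome chi-square homogeneity check, and clone
abundances are summarized by the maximum clone fraction and Shannon
entropy.

Junction calling exploits the SB100x signature: integration occurs at a TA
dinucleotide and duplicates it, so the left and right IR/DR junctions of
one event flank the same TA.  Reads beginning with a transposon-end
signature are trimmed, the genomic remainder is mapped (exact match plus
single-mismatch rescue, both strands; ambiguous hits are discarded), and
both junction sides canonicalize to the same T index, merging into one
unique site.

## Worked example

```bash
primsite simulate --seed 3 --out demo --n-integrations 20 \
    --n-chromosomes 2 --chromosome-length 100000
primsite call --reads demo/reads.fq --genome demo/genome.fa --out demo/sites.bed
# -> 20 unique sites from 120 reads
primsite annotate --sites demo/sites.bed --genes demo/genes.gff3 --out demo/ann.tsv
# -> cds 0 0.0% / utr5 0 0.0% / utr3 0 0.0% / intron 0 0.0% /
#    upstream_1kb 0 0.0% / downstream_1kb 1 5.0% / intergenic 19 95.0%
primsite prim --sites demo/sites.bed --genome demo/genome.fa \
    --width 20000 --out demo/windows.tsv
# -> 10 tested windows, 0 enriched at Bonferroni-adjusted alpha=0.05;
#    ta_coefficient=6.247
```

The `call` line reports every simulated integration recovered as one
deduplicated site (left- and right-junction reads merge because both
junctions carry the duplicated TA).  The `annotate` summary gives the
percentage of sites per feature category; on a gene-sparse simulated
genome most sites are intergenic.  The `prim` line reports how many 20 kb
windows were tested and how many showed Bonferroni-significant enrichment
— zero, as expected for unbiased TA-targeted integration.  The same chain
runs as one orchestrated, checksummed pipeline via `primsite run --config
cfg.yaml` (see `primsite run --help`).

The library surface mirrors the CLI: `generate_genome`,
`simulate_integrations`, `generate_junction_reads`, `call_unique_sites`,
`classify_sites`/`summarize_categories`, `build_windows`/`fit_prim`/
`test_windows`, and `digest`/`religate_and_amplify`/
`extract_ipcr_junction` for the inverse-PCR route (the packaged
`data/primers.yaml` ships the EF1α and 3′HS1 nested primer sets).

## Layout

| module | role |
| --- | --- |
| `primsite.synthetic_data` | genome/gene-model/transposon/read simulation |
| `primsite.junction_calling` | end detection, mapping, TA validation, dedup, clonality |
| `primsite.ipcr_insilico` | restriction digestion, religation, nested-PCR amplicons |
| `primsite.feature_annotation` | per-site feature categories and summaries |
| `primsite.prim_stats` | windows, TA counts, Poisson GLM, tests, occupancy |
| `primsite.pipeline` / `primsite.cli` | orchestration, validation, reports, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
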