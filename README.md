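# polykit

Analysis toolkit for allopolyploid subgenome dynamics: homoeologous-exchange
(HE) detection from subgenome read depth, synteny-fractionation and dating
statistics, a population-genetic statistic suite, and subgenome
expression-bias assessment — plus a synthetic-data generator that plants
every signal with a recorded ground truth, so the whole pipeline is testable
without external data.

## Modules

| module | what it does |
| --- | --- |
| `polykit.synthdata` | Seeded generators: syntelog landscapes with geometric deletion runs and pericentromeric retention gradients, negative-binomial coverage with planted HE dosage segments (4:0 / 3:1 / 2:2 / 1:3 / 0:4), Balding–Nichols genotypes with neutral-spectrum ancestral frequencies and outgroups, log-normal syntelog expression with planted bias, LTR divergences. `write_fixtures` emits VCF / GFF3 / TSV / BED deterministically. |
| `polykit.syntenyfrac` | Retention-rate tracks, deletion-run spectra, intergenic-gap profiles, Fisher enrichment of retention vs. duplicate origin, Ks KDE peaks (Silverman bandwidth, 512-point grid), LTR insertion ages (T = d / 2µ), interval-overlap Fisher tests. |
| `polykit.hedetect` | Per-gene coverage from depth tracks, 10-gene sliding-window allele balance A = 4·(CC/(CC+EE) − 0.5), dosage classification (±1.5 homozygous, ±0.5 balanced bands), segmentation with changepoint boundary refinement, chi-squared 3:1 tests with Bonferroni control, shared/private segments across accessions, HE-pair filtering. |
| `polykit.popstats` | Windowed π (100 kb / 10 kb) and Tajima's D, per-site and per-gene Weir–Cockerham F_ST (±2 kb flanks), SNP filters (missingness, MAF, LD pruning, di-haploid-control heterozygote removal, repeat masks), outgroup majority-vote polarization, folded/unfolded SFS, F3 with weighted block jackknife and Z→p→BH→Z adjustment, 20-kb ABBA/BABA D and f_d scans, generation↔year scaling (21-year default). |
| `polykit.exprbias` | log10(TPM + 1e−4) transform, per-pair bias classes, exact binomial global dominance test, per-family mosaic summaries. |
| `polykit.pipeline` | One-config orchestration of all stages with input validation, checksummed outputs and a JSON run report. |

## CLI

```sh
polykit fixtures --seed 1 --out fixtures/          # synthetic dataset + truth
polykit run --config config.yaml                   # full pipeline
polykit validate --config config.yaml

polykit synthdata generate --seed 1 --out fixtures/
polykit syntenyfrac retention|runs|gaps|kspeaks|ltrage ...
polykit hedetect run --coverage cov.tsv --syntelogs syntelogs.tsv --out he/
polykit popstats pi|tajd|fst|f3|scan|sfs|polarize|filter ...
polykit exprbias run --expr expr.tsv --pairs syntelogs.tsv --out bias.tsv
```

A pipeline config is plain YAML mirroring `polykit.pipeline.RunConfig`
(paths for syntelogs/coverage/VCF/popmap/expression, stage toggles and
parameters; defaults follow the published analysis: 10-gene HE windows,
±1.5/±0.5 balance thresholds, 100-kb/10-kb diversity windows, 2-kb F_ST
flanks, 20-kb scan windows, adjusted-α 0.0005, 21-year generation time).

## Conventions

VCF and GFF3 coordinates are 1-based inclusive; BED output is 0-based
half-open. Genotypes are diploid alt-allele counts with −1 for missing.
All randomness flows from explicit seeds; rerunning any generator or the
pipeline with the same seed reproduces byte-identical files.
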