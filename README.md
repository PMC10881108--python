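# cckit

Peak calling and downstream analysis for transposon calling-cards data.
Calling-cards experiments record transcription-factor binding by letting a
transposase–TF fusion deposit transposons at TTAA tetranucleotides near
binding sites; the analysis problem is to find genomic regions with more
insertions than expected, compare them across conditions or cell types, and
relate them to nearby genes.

## What's inside

| module | purpose |
| --- | --- |
| `cckit.ccio` | qbed / BED / bedGraph / gene-table I/O; TTAA tetranucleotide index |
| `cckit.peaks` | three peak callers (greedy CCcaller-style, window-scan MACCs-style, Bayesian-Blocks) over a shared TTAA-corrected Poisson test |
| `cckit.differential` | cells/groups-by-peaks matrices, Fisher / binomial differential binding, joint and separate-call strategies |
| `cckit.annotate` | two-nearest-gene annotation, peak–gene pairing against DE tables, GWAS-catalog intersection, signal-around-peaks matrices |
| `cckit.footprint` | two-component Gaussian-mixture refinement of binding sites |
| `cckit.simdata` | synthetic datasets with planted peaks and per-insertion ground truth |
| `cckit.cli` | `cckit` command-line interface |

## CLI

```sh
# generate a synthetic dataset with known ground truth
cckit simulate --seed 11 --out-dir sim/

# call peaks (BED6 + per-peak statistics sidecar)
cckit callpeaks --method cccaller --exp sim/exp.qbed --bkg sim/bkg.qbed \
    --ttaa sim/ttaa.bed --maxbetween 1100 --pvalue 1e-4 --out peaks.bed

# differential binding between two samples
cckit diff --strategy separate --test fisher \
    --groups a=exp_a.qbed --groups b=exp_b.qbed \
    --ttaa sim/ttaa.bed --out diff.tsv

# annotation, footprinting, GWAS intersection, signal heat-map input
cckit annotate  --peaks peaks.bed --genes genes.bed --out annotated.tsv
cckit footprint --peaks peaks.bed --exp sim/exp.qbed --out footprints.tsv
cckit gwas      --peaks peaks.bed --catalog gwas.tsv --out hits.tsv
cckit signal    --peaks peaks.bed --bedgraph coverage.bedgraph --out signal.tsv

# simulate -> call -> score in one step, fully seeded
cckit pipeline --config run.yaml --out-dir run/
```

Every subcommand writes a provenance JSON (tool version, parameters, seed)
next to its outputs; identical config + seed gives byte-identical files.

## Conventions

* Coordinates are 0-based, half-open everywhere (BED convention).
* All statistics count insertions, not reads; read counts are carried for
  plotting and export only.
* Every stochastic routine takes an explicit seed; there is no hidden
  global random state.
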