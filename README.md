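# tycircle

Analysis of extrachromosomal circular DNA (eccDNA) derived from yeast Ty
LTR retrotransposons, from multi-mapping sequencing reads.

Ty elements (families Ty1–Ty5) are flanked by long terminal repeats
(LTRs) and can leave the chromosome as covalently closed circles: by
nonhomologous end-joining of the linear element (a 2-LTR circle), by the
transpositional life cycle or LTR–LTR recombination within one element
(1-LTR circles carrying a single, possibly hybrid, LTR), by
autointegration (inverted or truncated circles), or by recombination
between LTRs of different elements.  Because Ty sequences are highly
redundant, eccDNA reads multi-map heavily; `tycircle` provides the
repeat-aware machinery needed to say *which* elements produce circles
and *how* the circles formed:

- **Weighted coverage** — a read with *n* genome placements contributes
  1/*n* at every base of each placement, so total coverage mass equals
  total mapped read length exactly.
- **Family intersection (Venn) accounting** — each Ty-mapping read is
  counted once, in the cell for the exact set of families its placements
  touch, with expected percentages from exhaustive 142-mer extraction
  over the annotation and a log2(observed/expected) ratio.
- **Circle coverage models** — for each circle topology, every rotation
  k-mer of the circle (junction-spanning ones included) is mapped back
  to the genome and averaged over elements in 50-bp windows with
  ±500 bp flanks, giving the expected coverage signature of that
  formation route.
- **Split-read mosaic detection** — the first and last 50 nt of each
  read are mapped onto the full-length elements; pairs inconsistent with
  a contiguous linear origin (downstream part mapping upstream, or
  flipped orientation) reveal circle junctions and classify against the
  formation scenarios.
- **Chimeric-LTR breakpoint inference** — the 5′ and 3′ LTR of each
  element are globally aligned; every possible recombination product
  (3′-LTR prefix + 5′-LTR suffix) is enumerated, deduplicated between
  *informative* columns (where the LTRs differ); reads that map
  end-to-end to a chimera but cannot be placed on the unmanipulated
  genome localize the recombination breakpoint to an interval between
  informative columns.  A U3–R–U5 region model separates genuine
  intrachromatid recombination from the apparent breakpoint at the
  transcription start site produced by transpositional circles.
- **Synthetic data** — a deterministic generator for toy genomes with
  implanted elements (divergent LTR pairs, solo LTRs), circles for every
  formation scenario, and error-bearing reads with full ground truth, so
  the whole pipeline is testable without any downloads.

## Worked example

```sh
tycircle run-all --seed 1 --out out/
```

or equivalently from Python:

```python
from dataclasses import replace
from tycircle.pipeline import RunConfig, run_pipeline

config = RunConfig(out_dir="out")
config.synthetic = replace(config.synthetic, seed=1, chrom_length=16000,
                           n_fullength_elements=1, n_solo_ltrs=1,
                           internal_length=2000, depth=20.0)
run_pipeline(config)
```

This simulates one full-length element plus a solo LTR, builds a 2-LTR
circle (scenario I) and a hybrid-LTR recombination circle (scenario V),
sequences them at 20×, and runs every stage.  Output of the run above:

```
simulate: completed
map: completed
coverage: completed
circles: completed
mosaic: completed
breakpoints: completed
simulated_reads: 703
total_reads: 703
mapped_reads: 680
deduplicated_reads: 628
ty_mapping_reads: 628
percent_ty: 100.0
circle_models: 5
mosaic_calls: 12
breakpoint_calls: 0
```

All 703 reads come from Ty circles, so 100% of deduplicated
nuclear-mapping reads touch Ty annotations.  23 reads fail to map:
these span the 2-LTR circle's ligation junction, a sequence absent from
the linear genome — and exactly those junctions resurface as the 12
order-reversed mosaic calls.  Breakpoint calls are 0 because at the
default 2% LTR divergence, junction reads remain explicable by genomic
LTR copies under the genome-exclusion rule; see
[docs/methods.md](docs/methods.md) for the recoverability analysis and
`tests/test_acceptance.py` for a divergent-LTR world where scenario II
and V circles are cleanly discriminated.

Per-stage outputs land in `out/`: `coverage.bedgraph`,
`family_venn.tsv`, `element_profile.tsv`, `locus_contribution.tsv`,
`circle_models.fa`, `expected_profiles.tsv`, `mosaic_calls.tsv`,
`breakpoint_calls.tsv`, `truth_*.tsv` and `run_summary.json`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full synthetic pipeline from scratch at the given seed
(simulation → mapping → coverage → circle models → mosaics →
breakpoints), prints the per-stage counts, and writes the results JSON.
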