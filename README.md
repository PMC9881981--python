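# hqalign

Hybrid quantized alignment of noisy long reads, with structural-variant
calling and benchmarking utilities.

Nanopore sequencing measures ionic current over Q consecutive bases at a
time (Q = 6), so its basecalling errors are biased toward substitutions
whose Q-mers produce similar currents.  `hqalign` turns that physics into
an alignment advantage without touching raw signal: it translates
basecalled sequences through a Q-mer → current map and hard-thresholds
the currents into a small alphabet (L = 3, "HQ3"), making
current-confusable sequences literally identical, then aligns in two
stages:

1. **stage 1** — align the nucleotide read to the nucleotide reference
   (minimizer seed–chain–extend) to find regions of interest;
2. **stage 2** — re-align the *quantized* read inside each region of
   interest, extended by `b = max(1 − f, 0.25)·n` on each side.  Because
   current levels have no complement structure, the quantized reverse
   complement is computed from the nucleotide sequence and aligned as a
   second query — which is what lets a single read express a +/−/+ split
   alignment across an inverted segment.

Around the pipeline the package provides the standard evaluation stack:
per-read alignment metrics (well-aligned fraction: ≥ 90% of the read at
mapping quality > 20; normalized edit distance `d(r, G[i:j])/|r|`;
normalized alignment length), a minimal SV caller (CIGAR and split-read
signatures, slippage-aware clustering), Truvari-style benchmarking
(breakpoint score `(|Δstart| + |Δend|)/2`, length similarity `min/max`,
one-to-one matching at refdist 500 / similarity 0.7, precision/recall/F1,
a union model over two call sets), and fully synthetic data generators
(repeat-seasoned genomes, planted INS/DEL/INV, nanopore-like reads whose
substitutions can be biased toward Q-mer confusability).

See `docs/methods.md` for the model, parameter defaults, and design
rationale.

## Worked example

```python
from hqalign import synthesize_qmer_map, compute_thresholds
from hqalign import synthetic_data as sd
from hqalign.hybrid_pipeline import HybridAligner, Read, ReferenceGenome
from hqalign.sv_call import call_svs
from hqalign.sv_eval import match_calls

qmap = synthesize_qmer_map(6, seed=1)          # synthetic 4096-entry Q-mer map
cfg = compute_thresholds(qmap, 3)              # ternary (HQ3) thresholds
g = sd.generate_genome(300_000, repeat_fraction=0.2, seed=2)
mutated, truth = sd.plant_svs(g, n_indel=24, n_inv=6, seed=3)
reads = sd.simulate_reads(mutated, coverage=40, mean_len=3000,
                          error_rate=0.1, qmap=qmap, cfg=cfg,
                          confusion_weight=0.5, seed=4, chrom=g.name)

aligner = HybridAligner(ReferenceGenome({g.name: g.sequence}), qmap, cfg)
hq = {}
for rd in reads:
    _, quantized_records = aligner.align_read(Read(rd.name, rd.sequence))
    hq[rd.name] = quantized_records

calls = call_svs(hq)
matches, bench = match_calls(truth, calls)
print(f"P={bench.precision:.3f} R={bench.recall:.3f} F1={bench.f1:.3f} "
      f"tp={bench.tp} fp={bench.fp} fn={bench.fn}")
```

On this 300 kb / 30-SV example the script prints

```
P=1.000 R=0.933 F1=0.966 tp=28 fp=0 fn=2
```

— 28 of the 30 planted variants (insertions, deletions and inversions,
lengths 50–10,000) recovered from ~10%-error reads with no false calls;
benchmarking the stage-1 nucleotide call set the same way, or the union
of both call sets, recovers all 30.

A command-line interface wraps the same functionality:

```
hqalign simulate  --genome-len 1000000 --coverage 40 --svs 100,20 --seed 1 --outdir sim/
hqalign align     --ref sim/genome.fa --reads sim/reads.fq --levels 3 --k-quant 18 --out out.sam
hqalign quantize  --fasta sim/genome.fa --out genome.hq3.fa
hqalign eval-align --sam-a a.sam --sam-b b.sam --ref sim/genome.fa --reads sim/reads.fq --out summary.tsv
hqalign eval-sv   --truth sim/truth.vcf --calls-a calls.vcf --out report.tsv
```

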