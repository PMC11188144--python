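# guideasm

Reference-guided metagenomic assembly at desk scale.

Given short reads and a collection of candidate reference genomes with
marker-gene annotations, `guideasm`:

1. **Selects** sample-relevant references by aligning reads to clustered
   universal single-copy marker genes — a genome is kept when breadth of
   coverage exceeds 90% on at least 75% of its 40 marker families.
2. **Culls** redundancy by grouping selected genomes into species-level
   clusters (single-linkage components at 95% sketch-estimated ANI) and
   prioritizes clusters by the exact k-mer intersection (k=28) between each
   cluster and the still-unassigned reads, recomputed before every pick.
3. **Assembles** each cluster greedily: genomes are visited in order of
   MinHash containment with the unassigned reads; reads are aligned to the
   current guide, covered runs ≥ 500 bp become contigs (placed on the guide
   via an AGP v2.1 file), consumed reads leave the pool, and the loop stops
   when (i) all reads are assembled, (ii) all references are assembled,
   (iii) the last guide yielded < 5% of its length, or (iv) its longest
   contig is < 2 kb — singleton clusters always retain their assembly.
4. **Polishes** every contig by realigning its supporting reads (with
   split-anchored single-indel detection) and applying a majority pileup
   consensus, so the output reflects the sampled organism rather than the
   reference guide.
5. **Reports** assembly statistics (NG25 per guide, fraction of reads
   mapped) and writes every unused read to FASTQ for downstream analysis.

All external tooling that the approach conventionally delegates to
(sketching, k-mer counting, ANI estimation, short-read alignment, identity
clustering, polishing) is implemented internally with exactly defined,
seeded, bit-reproducible semantics, which makes every stage testable against
independent oracles. A synthetic-community simulator
(`guideasm.simulate`) generates seeded reference databases and read sets
with complete ground truth.

## CLI

```sh
# generate a seeded synthetic community with ground truth
guideasm simulate --out sim/ --seed 1 --species 4 --genome-length 120000

# build the reusable marker index (optional; `run` builds one on the fly)
guideasm build-index --genomes sim/genomes.fasta --markers sim/markers.tsv --out index/

# run the full pipeline
guideasm run --reads sim/reads.fastq --genomes sim/genomes.fasta \
             --markers sim/markers.tsv --index index/ --out results/

# inspect metrics of a finished run
guideasm eval --summary results/summary.json
```

`run` writes: `contigs.fasta`, `contigs.polished.fasta`, `assembly.agp`,
`references_used.tsv`, `clusters.tsv`, `genome_log.tsv`, `marker_profiles.tsv`,
`polish_changes.tsv`, `unused_reads.fastq`, `used_read_ids.txt`, and
`summary.json`. When no reference clears the marker bar the run stops
gracefully, flags `no_reference` in the summary, and routes every read to
`unused_reads.fastq`.

Configuration defaults (all overridable via `--config config.yaml` or
flags): k=28 exact intersections, k=21/s=1000 sketches, 99% marker
clustering identity, breadth > 0.90 (strict), marker fraction ≥ 0.75,
ANI threshold 95, contig minimum 500 bp, termination thresholds 5% / 2 kb,
aligner identity 0.85 with 21 bp seeds, polishing depth ≥ 2 and majority 0.6.

## Library

```python
from guideasm import PipelineConfig, run_pipeline
from guideasm.simulate import make_community, simulate_reads

truth = make_community(seed=1)
reads = simulate_reads(truth, total_pairs=20_000, error_rate=0.005, seed=1)
result = run_pipeline(reads, truth.genomes, PipelineConfig(), outdir="out/")
print(result.summary.fraction_reads_mapped, result.summary.ng25_per_guide)
```

## Tests

```sh
python -m pytest -q tests/          # unit + property + acceptance (~5 min)
```

`tests/test_acceptance.py` holds the acceptance criteria: exact oracle
equivalence (aligner vs brute force, k-mer intersections vs string sets,
NG25 vs exhaustive search), threshold boundary checks, seeded clustering /
selection / ordering operating characteristics, polishing parameter
recovery, an end-to-end community recovery run, and the subsampling trend.

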