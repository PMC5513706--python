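# spacerkit

Analysis toolkit for **CRISPR spacer repertoires sequenced from
repeat-anchored amplicons**, built around the spacer pools of the
cyanobacterium *Arthrospira platensis* ("Spirulina"), whose genome carries
both an RT-Cas1-linked type III-B CRISPR locus and an RT-lacking type III-D
locus. PCR primers anchored in the CRISPR direct repeats amplify single
repeat–spacer–repeat units; sequencing those amplicons deeply yields
millions of spacer observations per locus. `spacerkit` turns such reads into
quantitative repertoire summaries, and ships a ground-truth simulator so
that every stage can be validated end to end.

## What it does

1. **Simulation** (`spacerkit.synthetic`) — truth pools of unique spacers
   with Zipf-by-rank abundances (`w_r ∝ r^(−a)`) and per-class length
   distributions (III-B shorter than III-D), packaged into 150-nt amplicon
   reads (random tail + forward repeat anchor + spacer + reverse repeat
   anchor + filler) with iid substitution errors and full per-read
   provenance.
2. **Extraction** (`spacerkit.extraction`) — locates both repeat anchors in
   each read (IUPAC-aware, ≤2 mismatches per anchor by default, both
   strands), trims them, and dereplicates the spacers into a counted pool,
   greedily merging equal-length sequences within Hamming distance 1
   (sequencing-error correction).
3. **Clustering** (`spacerkit.clustering`) — the conservative greedy
   procedure that groups unique spacers into presumed acquisition events:
   sweep spacers by abundance rank; absorb a candidate into the first parent
   differing at ≤4 sites in the best end-gap-free overlap (end deletions
   free, ≥20 nt overlap), or — for parents observed ≥100 times — sharing any
   exact 12-mer.
4. **Diversity** (`spacerkit.diversity`) — bias-corrected Chao-1 richness
   `Ŝ = S_obs + f1(f1−1)/(2(f2+1))` with a log-normal 95% lower bound,
   frequency/length histograms, and saturation curves (distinct units vs
   subsampled depth in 10% increments).
5. **Coincidence** (`spacerkit.coincidence`) — the co-clonality score
   `P(a,b) = Σ_s p_a(s)·p_b(s)`: the probability that one random spacer from
   each of two samples is the same sequence; replicates of one locus cluster,
   different loci score 0.
6. **Assembly & mapping** (`spacerkit.mapping`) — greedy exact
   suffix–prefix assembly of overlapping spacers into longer query contigs,
   exhaustive mapping of spacers onto reference genomes (both strands,
   bounded mismatches, BED exclusion of native arrays), and the analytic
   expectation of chance matches
   `E = n·2·(G−L+1)·Σ_{i≤m} C(L,i)(3/4)^i(1/4)^(L−i)`.

## Worked example

```python
import spacerkit as sk

truth = sk.generate_truth_pool(500, abundance_exponent=1.5, seed=0)
reads = sk.simulate_amplicon_reads(truth, n_reads=50_000,
                                   per_base_error=0.002, seed=1)
pool = sk.extract_pool([r.sequence for r in reads], sk.PLATENSIS_IIID,
                       sample_id="demo")
clusters = sk.cluster_spacers(pool)
est = sk.chao1_from_counts([c.total_count for c in clusters.clusters])
print(pool.reads_extracted, pool.n_unique, clusters.n_clusters,
      round(est.S_chao1, 1))
```

prints

```
31872 361 262 280.1
```

meaning: of the 50,000 simulated reads, 31,872 carried the type III-D
anchors and were extracted (the rest are III-B reads, rejected by this
array's anchors); dereplication left 361 unique spacers; the greedy
clustering collapsed their error satellites into 262 clusters — against 263
III-D truth spacers actually present in the reads at this depth — and the
Chao-1 estimate of ≈280 clusters sits above the observed count because the
Zipf tail still contributes singletons.

The same pipeline is available from the shell:

```bash
spacerkit simulate --n-spacers 500 --n-reads 50000 --error 0.002 \
    --seed 0 --out-prefix run
spacerkit extract --fastq run.fastq --array-class IIID --out pool.tsv
spacerkit cluster --pool pool.tsv --out clusters.tsv
spacerkit diversity --pool pool.tsv --out-prefix div
```

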