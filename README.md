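# promoterbench

A benchmarking framework for supervised promoter recognition.

Deep sequence classifiers for RNA polymerase II core promoters are
usually trained and evaluated on small, curated, roughly class-balanced
datasets of TSS-centred sequences, where cross-validation scores look
excellent.  On a genome, promoter windows are ~1% of the material, and
precision collapses.  `promoterbench` provides the machinery to measure
this honestly:

* **benchmark dataset construction** — slide a fixed window (default
  300 bases, stride 50) over a genome; tag a window `I` (inside a
  promoter) when at least 250 of its 300 bases contiguously overlap a
  single promoter region extrapolated from an annotated TSS (249 bases
  upstream + the TSS base + 50 downstream), `O` otherwise; drop windows
  containing `N`; deduplicate; split without sequence leakage,
* **classifier families** — CNN (one filter bank per filter length,
  max-pool, dense head), a fixed-element variant that concatenates
  one-hot "element" subsequences at TSS-relative positions with a
  max-pooled whole-sequence context, a convolutional BiLSTM (CLSTM),
  and a frozen-filter model whose convolution kernels are JASPAR
  position frequency matrices — each with a sigmoid or softmax head,
* **synthetic negatives** — promoter sequences degraded by uniform
  random substitution (UD) or by base shuffling that conserves the exact
  base multiset (OPD), plus genomic negatives sampled after genes' first
  exons or motif-matched outside promoter regions,
* **evaluation** — sensitivity, specificity, precision and the Matthews
  correlation coefficient

  `MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))`,

  stratified k-fold cross-validation with 99% Student-t intervals,
  over/under-sampling, and a cross-testing matrix (every model × every
  dataset),
* **analysis** — per-position class-discrimination logos in TSS-relative
  coordinates and per-filter convolution activation maps,
* **synthetic genomes** — seeded chromosome-like sequences with planted
  promoter regions (TATA box at −31, initiator at −2 by default), both
  strands, N-blocks, and ground-truth intervals, so the whole pipeline
  runs without downloads.

## Worked example

```python
import promoterbench as pb

# a tiny frozen fixture: 2,000-base genome, two planted promoters
we = pb.worked_example()
ds = pb.build_benchmark(we.genome, list(we.truth), we.benchmark_config)
print(pb.dataset_stats(ds))
```

prints

```
DatasetStats(total=33, n_promoter=4, n_nonpromoter=29,
             promoter_fraction=0.12121212121212122, empty=False)
```

A 2,000-base genome yields 35 stride-50 windows; two are removed because
they cover the planted N-block, and of the 33 kept, four overlap a
planted promoter region by at least 250 contiguous bases (each 300-base
promoter can be covered that well by at most three window offsets).

The same pipeline from the shell:

```sh
promoterbench synth --length 20000 --n-promoters 5 --seed 1 --out-prefix toy
promoterbench create --genome toy.fa --annot toy.sga --out toy.tsv
promoterbench train --family dprom --dataset toy.tsv --seed 0 --out model.json
promoterbench test --checkpoint model.json --dataset toy.tsv --out metrics.json
```

Every command writes a JSON manifest (config, seeds, input digests)
sufficient to re-run it.

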