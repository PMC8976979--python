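"""Sliding-window benchmark dataset construction and cleaning.

A promoter region is extrapolated around each annotated TSS (by default
249 bases strictly upstream, the TSS base itself, and 50 bases strictly
downstream: 300 bases).  A fixed window slides over the genome with a
fixed stride; a window is tagged ``I`` (inside a promoter) when at least
``min_overlap`` of its bases contiguously overlap a *single* promoter
region, else ``O``.  Windows containing the ambiguous base N are dropped.

Window sequences are stored as forward-strand text regardless of the
promoter's strand: a scanning classifier sees forward-strand sequence,
while minus-strand promoter regions still drive labeling through genomic
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import GenomeSequence, Interval, TssAnnotation, reverse_complement

logger = logging.getLogger(__name__)

#: window index of the TSS base under the default 249/50 region convention
DEFAULT_TSS_INDEX = 249


@dataclass(frozen=True)
class RegionSpec:
    """Promoter region extent around the TSS (bases strictly up/downstream)."""

    upstream: int = 249
    downstream: int = 50

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream and downstream must be >= 0")

    @property
    def length(self) -> int:
        return self.upstream + 1 + self.downstream


@dataclass(frozen=True)
class BenchmarkConfig:
    window: int = 300
    stride: int = 50
    min_overlap: int = 250
    drop_n: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window:
            raise ValueError("require 0 < stride <= window")
        if not 0 < self.min_overlap <= self.window:
            raise ValueError("require 0 < min_overlap <= window")


@dataclass(frozen=True)
class LabeledWindow:
    sequence: str
    tag: str
    provenance: Interval

    def __post_init__(self) -> None:
        if self.tag not in ("I", "O"):
            raise ValueError(f"tag must be 'I' or 'O', got {self.tag!r}")


@dataclass
class PromoterDataset:
    """Ordered labeled windows plus the recipe that produced them."""

    windows: list[LabeledWindow]
    config: BenchmarkConfig | None = None
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    @property
    def tags(self) -> list[str]:
        return [w.tag for w in self.windows]

    def subset(self, indices: Sequence[int]) -> "PromoterDataset":
        return PromoterDataset(
            windows=[self.windows[i] for i in indices],
            config=self.config,
            source=self.source,
            metadata=dict(self.metadata),
        )


def tss_relative_index(offset: int, tss_index: int = DEFAULT_TSS_INDEX) -> int:
    """Map a biological TSS-relative position to a window index.

    Promoter coordinates have no zero: +1 is the TSS base and -1 the base
    immediately upstream.  Under the default convention +1 maps to window
    index 249.
    """
    if offset == 0:
        raise ValueError("TSS-relative coordinates have no position 0 (+1 is the TSS)")
    return tss_index + offset - 1 if offset > 0 else tss_index + offset


def promoter_region_from_tss(
    tss: TssAnnotation, spec: RegionSpec = RegionSpec(), chrom_length: int | None = None
) -> Interval:
    """Extrapolate the promoter interval around a TSS, strand-aware.

    On '+': ``[pos0 - upstream, pos0 + downstream + 1)``; mirrored on '-'.
    The interval carries the TSS strand.  If ``chrom_length`` is given the
    region must lie fully inside the chromosome.
    """
    if tss.strand == "+":
        start = tss.pos0 - spec.upstream
        end = tss.pos0 + spec.downstream + 1
    else:
        start = tss.pos0 - spec.downstream
        end = tss.pos0 + spec.upstream + 1
    if start < 0 or (chrom_length is not None and end > chrom_length):
        raise ValueError(
            f"promoter region [{start}, {end}) for TSS {tss} extends past the "
            f"chromosome boundary"
        )
    return Interval(chrom=tss.chrom, start=start, end=end, strand=tss.strand)


def label_window(win: Interval, promoters: Iterable[Interval], min_overlap: int) -> str:
    """Tag a window ``I`` iff a *single* promoter interval overlaps it by
    >= ``min_overlap`` contiguous bases (inclusive boundary); overlaps with
    distinct promoters are never summed."""
    for p in promoters:
        if win.overlap(p) >= min_overlap:
            return "I"
    return "O"


def window_count(genome_length: int, window: int, stride: int) -> int:
    """Closed-form sliding-window count before any filtering."""
    if genome_length < window:
        return 0
    return (genome_length - window) // stride + 1


def build_benchmark(
    genome: GenomeSequence,
    promoters: Iterable[Interval],
    config: BenchmarkConfig = BenchmarkConfig(),
) -> PromoterDataset:
    """Slide a window over the genome and tag each one by promoter overlap."""
    promoters = [p for p in promoters if p.chrom == genome.name]
    n = window_count(genome.length, config.window, config.stride)
    if n == 0:
        logger.warning(
            "genome %s (length %d) shorter than window %d: empty dataset",
            genome.name, genome.length, config.window,
        )
    promoters.sort(key=lambda p: p.start)
    windows: list[LabeledWindow] = []
    w = config.window
    for i in range(n):
        s = i * config.stride
        seq = genome.bases[s : s + w]
        if config.drop_n and "N" in seq:
            continue
        iv = Interval(chrom=genome.name, start=s, end=s + w)
        windows.append(
            LabeledWindow(
                sequence=seq,
                tag=label_window(iv, promoters, config.min_overlap),
                provenance=iv,
            )
        )
    return PromoterDataset(
        windows=windows,
        config=config,
        source=genome.name,
        metadata={"genome_length": genome.length, "n_promoter_intervals": len(promoters)},
    )


def deduplicate(ds: PromoterDataset) -> tuple[PromoterDataset, int]:
    """Keep the first occurrence of each distinct sequence, preserving order.

    Duplicates whose tag conflicts with the kept occurrence are logged.
    """
    seen: dict[str, str] = {}
    kept: list[LabeledWindow] = []
    removed = 0
    for w in ds.windows:
        if w.sequence in seen:
            removed += 1
            if seen[w.sequence] != w.tag:
                logger.warning(
                    "duplicate sequence with conflicting tags (%s kept, %s dropped) at %s",
                    seen[w.sequence], w.tag, w.provenance,
                )
            continue
        seen[w.sequence] = w.tag
        kept.append(w)
    out = PromoterDataset(kept, config=ds.config, source=ds.source, metadata=dict(ds.metadata))
    out.metadata["deduplicated"] = removed
    return out, removed


@dataclass(frozen=True)
class DatasetStats:
    total: int
    n_promoter: int
    n_nonpromoter: int
    promoter_fraction: float
    empty: bool = False


def dataset_stats(ds: PromoterDataset) -> DatasetStats:
    n_i = sum(1 for w in ds.windows if w.tag == "I")
    total = len(ds.windows)
    return DatasetStats(
        total=total,
        n_promoter=n_i,
        n_nonpromoter=total - n_i,
        promoter_fraction=(n_i / total) if total else 0.0,
        empty=total == 0,
    )


class LeakageError(RuntimeError):
    """A sequence appears on both sides of a train/test split."""


@dataclass(frozen=True)
class SplitRequest:
    """Per-model promoter / non-promoter counts for train and test sides."""

    promoters_train: int
    promoters_test: int
    nonpromoters_train: int
    nonpromoters_test: int


def _verify_disjoint(train: PromoterDataset, test: PromoterDataset) -> None:
    shared = set(train.sequences) & set(test.sequences)
    if shared:
        raise LeakageError(
            f"{len(shared)} sequences shared between train and test "
            f"(e.g. {sorted(shared)[0][:30]!r}...)"
        )


def disjoint_split(
    full: PromoterDataset,
    subset_sizes: Mapping[str, SplitRequest],
    rng_seed: int,
) -> dict[str, tuple[PromoterDataset, PromoterDataset]]:
    """Nested train/test splits with no sequence shared across any boundary.

    A master split of the distinct promoter (and non-promoter) sequences is
    made first, sized for the largest request; every smaller model's sets
    are sampled strictly within the corresponding master side, so the
    promoter subsets of different models nest without leakage.  The final
    disjointness check is exhaustive over sequence strings.
    """
    rng = np.random.default_rng(rng_seed)
    deduped, _ = deduplicate(full)
    i_idx = [k for k, w in enumerate(deduped.windows) if w.tag == "I"]
    o_idx = [k for k, w in enumerate(deduped.windows) if w.tag == "O"]

    need_i_train = max((r.promoters_train for r in subset_sizes.values()), default=0)
    need_i_test = max((r.promoters_test for r in subset_sizes.values()), default=0)
    need_o_train = sum(r.nonpromoters_train for r in subset_sizes.values())
    need_o_test = sum(r.nonpromoters_test for r in subset_sizes.values())
    if need_i_train + need_i_test > len(i_idx):
        raise ValueError(
            f"infeasible promoter counts: need {need_i_train}+{need_i_test}, "
            f"have {len(i_idx)} distinct promoters"
        )
    if need_o_train + need_o_test > len(o_idx):
        raise ValueError(
            f"infeasible non-promoter counts: need {need_o_train}+{need_o_test}, "
            f"have {len(o_idx)} distinct non-promoters"
        )

    i_perm = rng.permutation(len(i_idx))
    o_perm = rng.permutation(len(o_idx))
    master_i_train = [i_idx[j] for j in i_perm[:need_i_train]]
    master_i_test = [i_idx[j] for j in i_perm[need_i_train : need_i_train + need_i_test]]
    o_pool_train = [o_idx[j] for j in o_perm[:need_o_train]]
    o_pool_test = [o_idx[j] for j in o_perm[need_o_train : need_o_train + need_o_test]]

    out: dict[str, tuple[PromoterDataset, PromoterDataset]] = {}
    o_tr_cursor = o_te_cursor = 0
    for name, req in subset_sizes.items():
        tr_i = list(rng.choice(master_i_train, size=req.promoters_train, replace=False)) \
            if req.promoters_train < len(master_i_train) else list(master_i_train)
        te_i = list(rng.choice(master_i_test, size=req.promoters_test, replace=False)) \
            if req.promoters_test < len(master_i_test) else list(master_i_test)
        tr_o = o_pool_train[o_tr_cursor : o_tr_cursor + req.nonpromoters_train]
        o_tr_cursor += req.nonpromoters_train
        te_o = o_pool_test[o_te_cursor : o_te_cursor + req.nonpromoters_test]
        o_te_cursor += req.nonpromoters_test
        train = deduped.subset(sorted(int(k) for k in tr_i + tr_o))
        test = deduped.subset(sorted(int(k) for k in te_i + te_o))
        train.metadata.update({"split": "train", "model": name, "seed": rng_seed})
        test.metadata.update({"split": "test", "model": name, "seed": rng_seed})
        _verify_disjoint(train, test)
        out[name] = (train, test)

    # cross-model exhaustive verification: no test sequence in any train set
    all_train = set()
    for train, _ in out.values():
        all_train.update(train.sequences)
    for name, (_, test) in out.items():
        shared = all_train & set(test.sequences)
        if shared:
            raise LeakageError(
                f"model {name}: {len(shared)} test sequences leak into a training set"
            )
    return out


def map_promoters_by_exact_match(
    genome: GenomeSequence, promoter_seqs: Iterable[str]
) -> set[Interval]:
    """All exact occurrences of each promoter sequence, on both strands.

    Minus-strand hits (the reverse complement occurs on the forward text)
    are reported as forward-coordinate intervals with strand '-'.
    """
    hits: set[Interval] = set()
    for seq in promoter_seqs:
        for strand, query in (("+", seq), ("-", reverse_complement(seq))):
            start = genome.bases.find(query)
            while start != -1:
                hits.add(
                    Interval(genome.name, start, start + len(query), strand=strand)
                )
                start = genome.bases.find(query, start + 1)
    return hits


# ---------------------------------------------------------------------------
# dataset file format: two-column TSV (sequence, tag) with '#' header comments
# ---------------------------------------------------------------------------

def write_dataset(path: str | Path, ds: PromoterDataset) -> None:
    with open(path, "w") as fh:
        if ds.config is not None:
            c = ds.config
            fh.write(
                f"# window={c.window} stride={c.stride} "
                f"min_overlap={c.min_overlap} drop_n={c.drop_n}\n"
            )
        if ds.source:
            fh.write(f"# source={ds.source}\n")
        for k, v in ds.metadata.items():
            fh.write(f"# {k}={v}\n")
        for w in ds.windows:
            fh.write(f"{w.sequence}\t{w.tag}\n")


def read_dataset(path: str | Path) -> PromoterDataset:
    windows: list[LabeledWindow] = []
    metadata: dict = {}
    config = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        metadata[k] = v
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'sequence<TAB>tag'")
            seq, tag = parts
            windows.append(
                LabeledWindow(seq, tag, Interval("unknown", 0, max(1, len(seq))))
            )
    if {"window", "stride", "min_overlap", "drop_n"} <= metadata.keys():
        config = BenchmarkConfig(
            window=int(metadata["window"]),
            stride=int(metadata["stride"]),
            min_overlap=int(metadata["min_overlap"]),
            drop_n=metadata["drop_n"] == "True",
        )
    return PromoterDataset(windows, config=config, source=metadata.get("source", ""), metadata=metadata)
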