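"""Seeded synthetic genomes with planted promoters.

The generator emulates the inputs the benchmark pipeline consumes in the
wild — a chromosome-scale FASTA plus TSS annotations — without any
download: an i.i.d. background at a configurable GC content, 300-base
promoter regions (249 upstream + TSS + 50 downstream) carrying core
motifs at fixed TSS-relative offsets (defaults: a TATA box at -31 and an
initiator straddling the TSS at -2), both strands, and N-blocks.  Ground
truth intervals are returned alongside the annotations so labeling tests
need no re-derivation.

The background is i.i.d., not Markov: sufficient for separability and
pipeline tests, simpler to reason about, and explicitly not a model of
repeat structure or isochores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .dataset_builder import (
    BenchmarkConfig,
    PromoterDataset,
    RegionSpec,
    promoter_region_from_tss,
    read_dataset,
    tss_relative_index,
)
from .seqio import GenomeSequence, Interval, TssAnnotation, reverse_complement

_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_MOTIFS = (("TATAAA", -31), ("TCAKTY", -2))


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    length: int = 50_000
    n_promoters: int = 10
    motifs: tuple[tuple[str, int], ...] = DEFAULT_MOTIFS
    gc_content: float = 0.41
    n_blocks: tuple[tuple[int, int], ...] = ()   # (start, length) runs of N
    strand_mix: float = 0.5                      # fraction of '-' strand promoters
    region: RegionSpec = RegionSpec()
    name: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValueError("strand_mix must lie in [0, 1]")
        for motif, offset in self.motifs:
            if offset == 0:
                raise ValueError("TSS-relative offsets skip 0 (+1 is the TSS)")
            bad = set(motif.upper()) - set(_IUPAC_CHOICES)
            if bad:
                raise ValueError(f"motif {motif!r} has non-IUPAC characters {bad}")


def _resolve_iupac(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else _IUPAC_CHOICES[c][rng.integers(0, len(_IUPAC_CHOICES[c]))]
        for c in motif.upper()
    )


def _plant_region(cfg: SyntheticGenomeConfig, rng: np.random.Generator) -> str:
    """A promoter region in promoter coordinates with motifs planted."""
    L = cfg.region.length
    tss_index = cfg.region.upstream
    p = [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2,
         (1 - cfg.gc_content) / 2]
    region = list("".join(np.random.default_rng(rng.integers(2**31)).choice(
        list("ACGT"), size=L, p=p)))
    for motif, offset in cfg.motifs:
        concrete = _resolve_iupac(motif, rng)
        start = tss_relative_index(offset, tss_index)
        if start < 0 or start + len(concrete) > L:
            raise ValueError(f"motif {motif!r} at offset {offset} leaves the region")
        region[start : start + len(concrete)] = concrete
    return "".join(region)


def generate_synthetic_genome(
    cfg: SyntheticGenomeConfig,
) -> tuple[GenomeSequence, list[TssAnnotation], list[Interval]]:
    """Background + planted promoters + N-blocks, deterministic under seed.

    Returns the genome, one TSS annotation per planted promoter, and the
    ground-truth promoter intervals (the regions actually written).
    """
    rng = np.random.default_rng(cfg.seed)
    p = [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2,
         (1 - cfg.gc_content) / 2]
    genome = rng.choice(list("ACGT"), size=cfg.length, p=p)

    region_len = cfg.region.length
    placed: list[tuple[int, int]] = []          # region (start, end) pairs
    annots: list[TssAnnotation] = []
    truth: list[Interval] = []
    max_tries = 200 * max(1, cfg.n_promoters)
    tries = 0
    while len(placed) < cfg.n_promoters:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"placed only {len(placed)} of {cfg.n_promoters} promoters "
                f"after {max_tries} tries; genome too short or too crowded"
            )
        start = int(rng.integers(0, cfg.length - region_len + 1))
        end = start + region_len
        if any(s < end and start < e for s, e in placed):
            continue
        strand = "-" if rng.random() < cfg.strand_mix else "+"
        region = _plant_region(cfg, rng)
        if strand == "+":
            pos0 = start + cfg.region.upstream
            genome[start:end] = list(region)
        else:
            pos0 = start + cfg.region.downstream
            genome[start:end] = list(reverse_complement(region))
        placed.append((start, end))
        annots.append(
            TssAnnotation(chrom=cfg.name, pos0=pos0, strand=strand,
                          label=f"synthP{len(placed)}")
        )
        truth.append(Interval(cfg.name, start, end, strand=strand))

    for start, length in cfg.n_blocks:
        if start < 0 or start + length > cfg.length:
            raise ValueError(f"N-block ({start}, {length}) outside the genome")
        genome[start : start + length] = "N"

    order = np.argsort([t.pos0 for t in annots])
    return (
        GenomeSequence(name=cfg.name, bases="".join(genome)),
        [annots[i] for i in order],
        [truth[i] for i in order],
    )


@dataclass(frozen=True)
class WorkedExample:
    """A tiny frozen bundle: genome, annotations, ground truth intervals,
    and the expected benchmark dataset (golden, computed once by a
    brute-force interval oracle)."""

    config: SyntheticGenomeConfig
    genome: GenomeSequence
    annotations: tuple[TssAnnotation, ...]
    truth: tuple[Interval, ...]
    benchmark_config: BenchmarkConfig
    expected: PromoterDataset


WORKED_EXAMPLE_CONFIG = SyntheticGenomeConfig(
    length=2_000,
    n_promoters=2,
    strand_mix=0.5,
    n_blocks=((1_900, 40),),
    seed=20_220_404,
)


def worked_example() -> WorkedExample:
    """The versioned worked example used in documentation and tests."""
    genome, annots, truth = generate_synthetic_genome(WORKED_EXAMPLE_CONFIG)
    golden = resources.files("promoterbench.data") / "worked_example_windows.tsv"
    with resources.as_file(golden) as path:
        expected = read_dataset(path)
    return WorkedExample(
        config=WORKED_EXAMPLE_CONFIG,
        genome=genome,
        annotations=tuple(annots),
        truth=tuple(truth),
        benchmark_config=BenchmarkConfig(),
        expected=expected,
    )


def planted_motif_dataset(
    n_promoters: int,
    n_nonpromoters: int,
    length: int = 300,
    motifs: tuple[tuple[str, int], ...] = DEFAULT_MOTIFS,
    gc_content: float = 0.41,
    seed: int = 0,
    region: RegionSpec = RegionSpec(),
) -> PromoterDataset:
    """A directly assembled labeled dataset of planted-motif positives and
    background negatives, for learnability and control experiments.

    With ``motifs=()`` the positives are plain background — the negative
    control in which no classifier should beat chance.
    """
    from .dataset_builder import LabeledWindow

    rng = np.random.default_rng(seed)
    cfg = SyntheticGenomeConfig(
        length=max(length, region.length), motifs=motifs, gc_content=gc_content,
        region=region, seed=seed,
    )
    p = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    windows = []
    for i in range(n_promoters):
        seq = _plant_region(cfg, rng)[: length]
        windows.append(LabeledWindow(seq, "I", Interval("synth", i * length, (i + 1) * length)))
    base = n_promoters * length
    for i in range(n_nonpromoters):
        seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
        windows.append(
            LabeledWindow(seq, "O", Interval("synth", base + i * length, base + (i + 1) * length))
        )
    perm = rng.permutation(len(windows))
    return PromoterDataset(
        windows=[windows[i] for i in perm],
        source="planted_motif_dataset",
        metadata={"seed": seed, "motifs": list(motifs), "gc_content": gc_content},
    )
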