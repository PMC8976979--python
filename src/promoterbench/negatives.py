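"""Non-promoter sequence generators.

Three classes of negatives used for promoter-classifier training:

* substitution-based synthetics derived from real promoters, either with
  bases redrawn uniformly from {A,C,G,T} ("uniform distribution", UD) or
  permuted so the original base multiset is conserved exactly ("original
  promoter distribution", OPD — a shuffle, not a redraw);
* genomic subsequences sampled from gene bodies downstream of the first
  exon;
* genomic windows outside promoter regions that contain a given motif
  (e.g. a TATA consensus), for motif-matched negative sets.

Substitution can target scattered positions or contiguous equal-length
segments; the default follows the segment convention (20 of 32 segments
substituted).  "Uniform" redraws may reproduce the original base, so the
expected per-position change rate is 3/4 within substituted material.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import GenomeSequence, Interval

_BASES = np.array(list("ACGT"))

IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


@dataclass(frozen=True)
class SubstitutionConfig:
    fraction: float = 20 / 32
    mode: str = "uniform"            # "uniform" | "promoter_distribution"
    rng_seed: int = 0
    unit: str = "segment"            # "segment" | "position"
    n_segments: int = 32

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if self.mode not in ("uniform", "promoter_distribution"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.unit not in ("segment", "position"):
            raise ValueError(f"unit must be 'segment' or 'position', got {self.unit!r}")


def _chosen_positions(L: int, cfg: SubstitutionConfig, rng: np.random.Generator) -> np.ndarray:
    """Indices targeted for substitution, per the config's unit."""
    if cfg.unit == "position":
        k = math.floor(cfg.fraction * L)
        return rng.choice(L, size=k, replace=False)
    n_seg = min(cfg.n_segments, L)
    k_seg = round(cfg.fraction * n_seg)
    bounds = np.linspace(0, L, n_seg + 1).astype(int)
    segs = rng.choice(n_seg, size=k_seg, replace=False)
    return np.concatenate(
        [np.arange(bounds[s], bounds[s + 1]) for s in segs]
    ) if k_seg else np.array([], dtype=int)


def substitute_uniform(seq: str, cfg: SubstitutionConfig) -> str:
    """UD negative: chosen positions redrawn uniformly from {A,C,G,T}."""
    if cfg.mode != "uniform":
        raise ValueError("substitute_uniform requires mode='uniform'")
    rng = np.random.default_rng(cfg.rng_seed)
    pos = _chosen_positions(len(seq), cfg, rng)
    out = np.array(list(seq))
    out[pos] = _BASES[rng.integers(0, 4, size=len(pos))]
    return "".join(out)


def substitute_promoter_distribution(
    seq: str,
    pool_composition: dict[str, float] | None = None,
    cfg: SubstitutionConfig = SubstitutionConfig(mode="promoter_distribution"),
) -> str:
    """OPD negative: chosen positions' bases permuted among themselves.

    With fraction 1 this is a full shuffle of the sequence; the base
    multiset is conserved exactly (a strict conservation law), which is
    what distinguishes OPD from the i.i.d. redraw of UD.
    ``pool_composition`` is accepted for API symmetry and recorded by
    callers in metadata; a permutation conserves composition by
    construction so it does not enter the computation.
    """
    if cfg.mode != "promoter_distribution":
        raise ValueError("substitute_promoter_distribution requires mode='promoter_distribution'")
    rng = np.random.default_rng(cfg.rng_seed)
    pos = np.sort(_chosen_positions(len(seq), cfg, rng))
    out = np.array(list(seq))
    out[pos] = out[rng.permutation(pos)]
    return "".join(out)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with the end of its first exon (all 0-based half-open)."""

    chrom: str
    start: int
    end: int
    first_exon_end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start <= self.first_exon_end <= self.end:
            raise ValueError("first_exon_end must lie within the gene body")


def sample_post_first_exon(
    genome: GenomeSequence,
    gene_models: Sequence[GeneModel],
    length: int,
    n: int,
    rng_seed: int,
) -> list[str]:
    """Random subsequences inside gene bodies downstream of the first exon."""
    eligible = [
        g for g in gene_models
        if g.chrom == genome.name and g.end - g.first_exon_end >= length
    ]
    skipped = len([g for g in gene_models if g.chrom == genome.name]) - len(eligible)
    if skipped:
        import logging
        logging.getLogger(__name__).warning(
            "%d genes shorter than %d bases after their first exon were skipped",
            skipped, length,
        )
    if not eligible:
        raise ValueError(f"no gene offers {length} bases after its first exon")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        g = eligible[rng.integers(0, len(eligible))]
        start = int(rng.integers(g.first_exon_end, g.end - length + 1))
        out.append(genome.bases[start : start + length])
    return out


def consensus_to_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC_REGEX[c] for c in motif.upper()))
    except KeyError as e:
        raise ValueError(f"not an IUPAC nucleotide code: {e.args[0]!r}") from None


def sample_genomic_with_motif(
    genome: GenomeSequence,
    excluded: Iterable[Interval],
    motif: str,
    length: int,
    n: int,
    rng_seed: int,
    max_draws_per_hit: int = 200,
) -> list[str]:
    """Windows disjoint from every excluded interval, each containing the motif."""
    if n == 0:
        return []
    if genome.length < length:
        raise ValueError("genome shorter than requested window length")
    pattern = consensus_to_regex(motif)
    excl = [iv for iv in excluded if iv.chrom == genome.name]
    rng = np.random.default_rng(rng_seed)
    out: list[str] = []
    for _ in range(max_draws_per_hit * n):
        s = int(rng.integers(0, genome.length - length + 1))
        iv = Interval(genome.name, s, s + length)
        if any(iv.overlap(e) > 0 for e in excl):
            continue
        seq = genome.bases[s : s + length]
        if pattern.search(seq):
            out.append(seq)
            if len(out) == n:
                return out
    raise RuntimeError(
        f"found only {len(out)} of {n} motif-containing non-promoter windows "
        f"within {max_draws_per_hit * n} draws"
    )
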