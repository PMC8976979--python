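"""Sequence -> model-input conversion.

One-hot matrices use the fixed row order (A, C, G, T) everywhere in the
package; N encodes as an all-zero column.  k-mer token text (overlapping
k-mers, space separated) is provided for interchange with external
transformer-style tools, together with the exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dataset_builder import DEFAULT_TSS_INDEX, tss_relative_index

ROW_ORDER = "ACGT"
_ROW_INDEX = {b: i for i, b in enumerate(ROW_ORDER)}


def one_hot(seq: str) -> np.ndarray:
    """4 x L one-hot matrix, rows (A, C, G, T); N -> all-zero column."""
    mat = np.zeros((4, len(seq)), dtype=np.float64)
    for j, b in enumerate(seq):
        if b == "N":
            continue
        try:
            mat[_ROW_INDEX[b], j] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {b!r} at position {j}") from None
    return mat


def one_hot_batch(seqs: Sequence[str]) -> np.ndarray:
    """(B, 4, L) stack; all sequences must share one length."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences of mixed lengths {sorted(lengths)}")
    return np.stack([one_hot(s) for s in seqs])


@dataclass(frozen=True)
class Element:
    """A named fixed-location motif region in TSS-relative coordinates
    (inclusive biological positions; there is no position 0)."""

    name: str
    from_pos: int
    to_pos: int


@dataclass(frozen=True)
class ElementProfile:
    """Fixed element locations plus the context-compression factor.

    The default profile places the TATA box at -33..-23 and the initiator
    at -2..+4; the exact table is user configuration (loadable from YAML),
    not a published constant.
    """

    elements: tuple[Element, ...] = (
        Element("TATA", -33, -23),
        Element("INR", -2, 4),
    )
    pool_size: int = 3
    window: int = 300
    tss_index: int = DEFAULT_TSS_INDEX

    def element_slices(self) -> list[tuple[str, int, int]]:
        """(name, start, end) window-index slices, end exclusive."""
        out = []
        for e in self.elements:
            a = tss_relative_index(e.from_pos, self.tss_index)
            b = tss_relative_index(e.to_pos, self.tss_index) + 1
            if not (0 <= a < b <= self.window):
                raise ValueError(f"element {e.name} [{a}, {b}) outside window")
            out.append((e.name, a, b))
        # elements must not overlap
        spans = sorted((a, b) for _, a, b in out)
        for (a1, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("element regions overlap")
        return out

    @property
    def context_width(self) -> int:
        return self.window // self.pool_size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ElementProfile":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            elements=tuple(
                Element(e["name"], int(e["from"]), int(e["to"]))
                for e in raw.get("elements", [])
            ),
            pool_size=int(raw.get("pool_size", 3)),
            window=int(raw.get("window", 300)),
            tss_index=int(raw.get("tss_index", DEFAULT_TSS_INDEX)),
        )


def extract_elements(
    seq: str, profile: ElementProfile
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Element one-hots at fixed offsets + max-pooled whole-sequence context.

    The context is the full one-hot reduced by non-overlapping max pooling
    of width ``pool_size`` along the position axis (trailing remainder
    dropped); output widths depend only on the profile.
    """
    if len(seq) != profile.window:
        raise ValueError(
            f"sequence length {len(seq)} does not match profile window {profile.window}"
        )
    full = one_hot(seq)
    elements = {
        name: full[:, a:b] for name, a, b in profile.element_slices()
    }
    p = profile.pool_size
    usable = (profile.window // p) * p
    context = full[:, :usable].reshape(4, usable // p, p).max(axis=2)
    return elements, context


def to_kmer_tokens(seq: str, k: int) -> str:
    """Space-separated overlapping k-mers in original order."""
    if not 1 <= k <= len(seq):
        raise ValueError(f"k must satisfy 1 <= k <= {len(seq)}, got {k}")
    return " ".join(seq[i : i + k] for i in range(len(seq) - k + 1))


def from_kmer_tokens(tokens: str, k: int) -> str:
    """Inverse of :func:`to_kmer_tokens`; validates the k-1 overlap."""
    parts = tokens.split()
    if not parts:
        raise ValueError("no tokens")
    for i, t in enumerate(parts):
        if len(t) != k:
            raise ValueError(f"token {i + 1} has length {len(t)}, expected {k}")
    seq = parts[0]
    for i, t in enumerate(parts[1:], start=2):
        if t[: k - 1] != seq[-(k - 1):] and k > 1:
            raise ValueError(
                f"token {i} ({t!r}) does not overlap the previous suffix {seq[-(k - 1):]!r}"
            )
        seq += t[-1]
    return seq


def write_kmer_dataset(path: str | Path, seqs: Iterable[str], tags: Iterable[str], k: int = 6) -> None:
    """Labeled k-mer token file: 'tokens<TAB>tag' per line (default k = 6)."""
    with open(path, "w") as fh:
        for seq, tag in zip(seqs, tags):
            fh.write(f"{to_kmer_tokens(seq, k)}\t{tag}\n")


def read_kmer_dataset(path: str | Path, k: int = 6) -> tuple[list[str], list[str]]:
    seqs, tags = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                tokens, tag = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: expected 'tokens<TAB>tag'") from None
            seqs.append(from_kmer_tokens(tokens, k))
            tags.append(tag)
    return seqs, tags
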