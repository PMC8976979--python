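"""Per-position class-discrimination logos and filter activation maps.

The logo matrix answers "which bases at which TSS-relative positions
separate promoters from non-promoters".  Two semantics are provided,
since either is a reasonable definition of a "differentiating base":

* ``frequency_difference`` — per position and base, frequency in the
  positive set minus frequency in the negative set (rows sum to zero per
  position);
* ``information_content`` — each set's frequencies scaled by that
  position's information content (2 - entropy, in bits), differenced.

TSS-relative coordinates follow the single package-wide convention: the
TSS base (+1) sits at window index 249 of a 300-base window built with
249 bases upstream and 50 downstream; biological coordinates skip zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset_builder import (
    DEFAULT_TSS_INDEX,
    LabeledWindow,
    PromoterDataset,
    tss_relative_index,
)
from .encoding import ROW_ORDER, one_hot_batch
from .models import Model

_SEMANTICS = ("frequency_difference", "information_content")


@dataclass(frozen=True)
class SeqLogoMatrix:
    """4 x L per-position base weights with a TSS-anchored origin."""

    values: np.ndarray
    tss_index: int
    semantics: str

    def __post_init__(self) -> None:
        if self.values.shape[0] != 4:
            raise ValueError("logo matrix must have 4 rows (A, C, G, T)")

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# semantics={self.semantics} tss_index={self.tss_index}\n")
            fh.write("position\t" + "\t".join(ROW_ORDER) + "\n")
            for j in range(self.length):
                offset = j - self.tss_index
                bio = offset + 1 if offset >= 0 else offset
                fh.write(
                    f"{bio}\t" + "\t".join(f"{v:.6g}" for v in self.values[:, j]) + "\n"
                )


def _base_frequencies(seqs: Sequence[str]) -> np.ndarray:
    """(4, L) per-position base frequencies (N contributes to no row)."""
    return one_hot_batch(list(seqs)).mean(axis=0)


def _information_weighted(freq: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=0)  # 2 - H per position, in bits
    return freq * ic[None, :]


def class_discrimination_logo(
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    tss_index: int = DEFAULT_TSS_INDEX,
    semantics: str = "frequency_difference",
) -> SeqLogoMatrix:
    """Positive-minus-negative per-position base weights."""
    if not pos_seqs or not neg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    if semantics not in _SEMANTICS:
        raise ValueError(f"semantics must be one of {_SEMANTICS}")
    lengths = {len(s) for s in pos_seqs} | {len(s) for s in neg_seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences of mixed lengths {sorted(lengths)}")
    fpos = _base_frequencies(pos_seqs)
    fneg = _base_frequencies(neg_seqs)
    if semantics == "information_content":
        values = _information_weighted(fpos) - _information_weighted(fneg)
    else:
        values = fpos - fneg
    return SeqLogoMatrix(values=values, tss_index=tss_index, semantics=semantics)


def subsequence_slice(
    ds: PromoterDataset,
    from_pos: int,
    to_pos: int,
    tss_index: int = DEFAULT_TSS_INDEX,
    inclusive_end: bool = True,
) -> PromoterDataset:
    """Replace every window by its TSS-relative slice, keeping tags/order.

    Bounds are biological TSS-relative positions (no zero); the end bound
    is inclusive by default, so ``(-33, -23)`` extracts the 11 window
    indices [216, 227) under the default convention.
    """
    a = tss_relative_index(from_pos, tss_index)
    b = tss_relative_index(to_pos, tss_index) + (1 if inclusive_end else 0)
    if not ds.windows:
        raise ValueError("empty dataset")
    L = len(ds.windows[0].sequence)
    if not (0 <= a < b <= L):
        raise ValueError(f"slice [{a}, {b}) outside the {L}-base window")
    out = PromoterDataset(
        windows=[
            LabeledWindow(w.sequence[a:b], w.tag, w.provenance) for w in ds.windows
        ],
        config=ds.config,
        source=ds.source,
        metadata=dict(ds.metadata),
    )
    out.metadata["slice"] = {
        "from_pos": from_pos,
        "to_pos": to_pos,
        "inclusive_end": inclusive_end,
        "window_indices": [a, b],
    }
    return out


@dataclass(frozen=True)
class ActivationMap:
    """Mean convolution activation per window start position for one filter."""

    name: str
    values: np.ndarray  # (Lo,)


def filter_activation_map(
    model: Model, seqs: Sequence[str]
) -> tuple[list[ActivationMap], ActivationMap]:
    """Per-filter mean activation profiles plus their combined sum.

    Filters of different widths yield different profile lengths; the
    combined map aligns all profiles at the window start and pads shorter
    ones with zeros, giving a global view of the positions that drive the
    convolution stage.
    """
    acts = model.conv_activation_maps(list(seqs))
    per_filter = [
        ActivationMap(name=name, values=a.mean(axis=0)) for name, a in acts.items()
    ]
    if not per_filter:
        raise ValueError("model exposes no convolution activations")
    width = max(m.values.shape[0] for m in per_filter)
    combined = np.zeros(width)
    for m in per_filter:
        combined[: m.values.shape[0]] += m.values
    return per_filter, ActivationMap(name="combined", values=combined)


def plot_logo(logo: SeqLogoMatrix, path: str | Path) -> None:
    """Optional thin rendering layer (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, logo.length / 20), 3))
    x = np.arange(logo.length) - logo.tss_index
    for i, base in enumerate(ROW_ORDER):
        ax.plot(x, logo.values[i], label=base, lw=0.8)
    ax.axvline(0, color="k", ls=":", lw=0.5)
    ax.set_xlabel("position relative to TSS")
    ax.set_ylabel(logo.semantics)
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
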