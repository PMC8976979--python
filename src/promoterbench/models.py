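"""Promoter classifier architectures with a uniform predict contract.

Four families are provided:

* ``cnnprom_tata`` / ``cnnprom_nontata`` — convolution (one bank per
  filter length, default lengths 15 and 21) -> max pool -> ReLU -> dense
  -> output head; the TATA variant uses fewer filters and a smaller pool
  than the non-TATA variant.
* ``icnnp`` — a 200-filter convolution over the full sequence plus a
  max-pooled "context" copy of the sequence, concatenated with one-hot
  "element" subsequences at fixed TSS-relative locations.
* ``dprom`` — convolutional embedding -> bidirectional LSTM -> dense ->
  head (a CLSTM).
* ``jaspar_fixed`` — convolution filters imported from JASPAR position
  frequency matrices and frozen; only the classifier head trains.  Each
  motif maps to exactly one filter, so activations are directly
  interpretable.

Output heads: ``sigmoid`` emits one score in [0, 1] (decision threshold
0.5, boundary inclusive); ``softmax`` emits two probabilities summing to
one with class order (non-promoter, promoter).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoding import ElementProfile, extract_elements, one_hot_batch
from .seqio import ParseError

FAMILIES = ("cnnprom_tata", "cnnprom_nontata", "icnnp", "dprom", "jaspar_fixed")

_FAMILY_DEFAULTS = {
    # conv_filters is per filter length
    "cnnprom_tata": dict(conv_filters=100, pool_size=2),
    "cnnprom_nontata": dict(conv_filters=200, pool_size=4),
    "icnnp": dict(conv_filters=200, pool_size=4),
    "dprom": dict(conv_filters=32, pool_size=6, recurrent_units=32),
    "jaspar_fixed": dict(conv_filters=0, pool_size=2),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    family: str
    input_length: int = 300
    conv_filters: int | None = None
    filter_lengths: tuple[int, ...] = (15, 21)
    pool_size: int | None = None
    recurrent_units: int | None = None
    dense_units: int = 64
    output_head: str = "sigmoid"
    dropout: float = 0.0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.output_head not in ("sigmoid", "softmax"):
            raise ValueError(f"output_head must be sigmoid or softmax, got {self.output_head!r}")
        if self.family != "jaspar_fixed" and self.input_length <= max(self.filter_lengths):
            raise ValueError("input_length must exceed the longest filter")
        if self.recurrent_units is not None and self.family != "dprom":
            raise ValueError("recurrent_units is only valid for the dprom family")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def resolved(self) -> "ArchitectureSpec":
        """Fill family defaults for unset width/pool/recurrent fields."""
        d = _FAMILY_DEFAULTS[self.family]
        kwargs = asdict(self)
        kwargs["filter_lengths"] = tuple(kwargs["filter_lengths"])
        for k, v in d.items():
            if kwargs.get(k) is None:
                kwargs[k] = v
        return ArchitectureSpec(**kwargs)


@dataclass(frozen=True)
class MotifFilter:
    """A motif as a fixed 4 x L convolution filter, rows (A, C, G, T)."""

    name: str
    matrix: tuple[tuple[float, ...], ...]
    mode: str = "frequency"

    @property
    def width(self) -> int:
        return len(self.matrix[0])

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=np.float64)


def import_jaspar_filters(
    pfm_file: str | Path, mode: str = "frequency"
) -> list[MotifFilter]:
    """Read JASPAR-format PFM text into convolution-ready motif filters.

    Counts are normalized per column to frequencies; ``mode='log_odds'``
    further converts to log2(freq / 0.25) against a uniform background
    (with the motif's own per-column pseudo-smoothing cancelling for
    uniform columns).
    """
    if mode not in ("frequency", "log_odds"):
        raise ValueError(f"mode must be 'frequency' or 'log_odds', got {mode!r}")
    from Bio import motifs as bio_motifs

    parsed = None
    for fmt in ("jaspar", "pfm-four-columns", "pfm"):
        try:
            with open(pfm_file) as fh:
                parsed = list(bio_motifs.parse(fh, fmt))
            if parsed:
                break
        except Exception:
            parsed = None
    if not parsed:
        raise ParseError(f"{pfm_file}: not parseable as JASPAR/PFM motif text")

    out: list[MotifFilter] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=np.float64)
        if counts.ndim != 2:
            raise ParseError(f"{pfm_file}: motif {m.name}: rows of unequal length")
        if (counts < 0).any():
            raise ParseError(f"{pfm_file}: motif {m.name}: negative counts")
        colsum = counts.sum(axis=0)
        if (colsum == 0).any():
            raise ParseError(f"{pfm_file}: motif {m.name}: all-zero column")
        freq = counts / colsum
        if mode == "log_odds":
            # pseudocount proportional to column depth keeps uniform columns at 0
            pc = 1e-6
            freq = np.log2((freq + pc) / (0.25 * (1 + 4 * pc)))
        name = m.name or m.base_id or f"motif{len(out)}"
        out.append(
            MotifFilter(name=str(name), matrix=tuple(map(tuple, freq)), mode=mode)
        )
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Model:
    """A built architecture: spec + parameter store + predict."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0,
                 element_profile: ElementProfile | None = None,
                 motif_filters: Sequence[MotifFilter] | None = None):
        self.spec = spec.resolved()
        self.seed = seed
        self.element_profile = element_profile
        self.motif_filters = list(motif_filters or [])
        self.params: dict[str, Tensor] = {}
        self.frozen: set[str] = set()
        self._build(np.random.default_rng(seed))

    # -- construction -------------------------------------------------------

    def _param(self, name: str, value: np.ndarray, frozen: bool = False) -> Tensor:
        t = Tensor(value, requires_grad=not frozen, name=name)
        self.params[name] = t
        if frozen:
            self.frozen.add(name)
        return t

    def _head_dim(self) -> int:
        return 2 if self.spec.output_head == "softmax" else 1

    def _build(self, rng: np.random.Generator) -> None:
        s = self.spec
        fam = s.family
        if fam in ("cnnprom_tata", "cnnprom_nontata"):
            feat = 0
            for k in s.filter_lengths:
                self._param(f"conv{k}_w", _glorot(rng, (s.conv_filters, 4, k)))
                self._param(f"conv{k}_b", np.zeros(s.conv_filters))
                feat += s.conv_filters * ((s.input_length - k + 1) // s.pool_size)
        elif fam == "icnnp":
            if self.element_profile is None:
                self.element_profile = ElementProfile(window=s.input_length)
            k = s.filter_lengths[0]
            self._param(f"conv{k}_w", _glorot(rng, (s.conv_filters, 4, k)))
            self._param(f"conv{k}_b", np.zeros(s.conv_filters))
            feat = s.conv_filters * ((s.input_length - k + 1) // s.pool_size)
            feat += 4 * self.element_profile.context_width
            feat += sum(4 * (b - a) for _, a, b in self.element_profile.element_slices())
        elif fam == "dprom":
            k = s.filter_lengths[0]
            self._param(f"conv{k}_w", _glorot(rng, (s.conv_filters, 4, k)))
            self._param(f"conv{k}_b", np.zeros(s.conv_filters))
            H = s.recurrent_units
            for d in ("fw", "bw"):
                self._param(f"lstm_{d}_wx", _glorot(rng, (s.conv_filters, 4 * H)))
                self._param(f"lstm_{d}_wh", _glorot(rng, (H, 4 * H)))
                b = np.zeros(4 * H)
                b[H : 2 * H] = 1.0  # forget-gate bias
                self._param(f"lstm_{d}_b", b)
            T = (s.input_length - k + 1) // s.pool_size
            feat = 2 * H * T  # full hidden sequence is flattened into the head
        elif fam == "jaspar_fixed":
            if not self.motif_filters:
                raise ValueError("jaspar_fixed requires imported motif filters")
            for i, f in enumerate(self.motif_filters):
                self._param(f"motif{i}_w", f.array[None, :, :], frozen=True)
            feat = len(self.motif_filters)
        else:  # pragma: no cover
            raise AssertionError(fam)

        self._param("dense_w", _glorot(rng, (feat, s.dense_units)))
        self._param("dense_b", np.zeros(s.dense_units))
        self._param("out_w", _glorot(rng, (s.dense_units, self._head_dim())))
        self._param("out_b", np.zeros(self._head_dim()))

    def trainable_params(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k not in self.frozen}

    # -- forward ------------------------------------------------------------

    def encode(self, seqs: Sequence[str]) -> dict[str, np.ndarray]:
        bad = [i for i, s in enumerate(seqs) if len(s) != self.spec.input_length]
        if bad:
            raise ValueError(
                f"record {bad[0]}: sequence length {len(seqs[bad[0]])} does not "
                f"match model input length {self.spec.input_length}"
            )
        enc: dict[str, np.ndarray] = {"onehot": one_hot_batch(seqs)}
        if self.spec.family == "icnnp":
            rows = []
            for s in seqs:
                elements, context = extract_elements(s, self.element_profile)
                rows.append(
                    np.concatenate(
                        [context.ravel()] + [e.ravel() for e in elements.values()]
                    )
                )
            enc["side"] = np.stack(rows)
        return enc

    def _maybe_normalize(self, x: Tensor) -> Tensor:
        if not self.spec.normalize:
            return x
        m = x.mean(axis=2, keepdims=True)
        centered = x - m
        var = (centered * centered).mean(axis=2, keepdims=True)
        return centered * (var + 1e-8).pow(-0.5)

    def _dropout(self, x: Tensor, train: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.spec.dropout
        if not train or p == 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def forward(self, enc: dict[str, np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        s = self.spec
        x = Tensor(enc["onehot"])
        fam = s.family
        if fam in ("cnnprom_tata", "cnnprom_nontata"):
            parts = []
            for k in s.filter_lengths:
                h = ad.conv1d(x, self.params[f"conv{k}_w"], self.params[f"conv{k}_b"])
                h = self._maybe_normalize(h)
                h = ad.max_pool1d(h, s.pool_size).relu()
                B = h.shape[0]
                parts.append(h.reshape(B, -1))
            feat = ad.concat(parts, axis=1)
        elif fam == "icnnp":
            k = s.filter_lengths[0]
            h = ad.conv1d(x, self.params[f"conv{k}_w"], self.params[f"conv{k}_b"])
            h = self._maybe_normalize(h)
            h = ad.max_pool1d(h, s.pool_size).relu()
            B = h.shape[0]
            feat = ad.concat([h.reshape(B, -1), Tensor(enc["side"])], axis=1)
        elif fam == "dprom":
            k = s.filter_lengths[0]
            h = ad.conv1d(x, self.params[f"conv{k}_w"], self.params[f"conv{k}_b"])
            h = self._maybe_normalize(h)
            h = ad.max_pool1d(h, s.pool_size).relu()
            feat = self._bilstm(h)
        elif fam == "jaspar_fixed":
            parts = []
            for i in range(len(self.motif_filters)):
                w = self.params[f"motif{i}_w"]
                b = Tensor(np.zeros(1))
                h = ad.conv1d(x, w, b).relu()
                parts.append(ad.global_max_pool1d(h))
            feat = ad.concat(parts, axis=1)
        else:  # pragma: no cover
            raise AssertionError(fam)

        feat = self._dropout(feat, train, rng)
        hidden = (feat @ self.params["dense_w"] + self.params["dense_b"]).relu()
        hidden = self._dropout(hidden, train, rng)
        return hidden @ self.params["out_w"] + self.params["out_b"]

    def _lstm_pass(self, h: Tensor, direction: str) -> Tensor:
        """One LSTM direction over (B, F, T); returns the full hidden
        sequence flattened to (B, T*H), in forward position order."""
        H = self.spec.recurrent_units
        wx = self.params[f"lstm_{direction}_wx"]
        wh = self.params[f"lstm_{direction}_wh"]
        b = self.params[f"lstm_{direction}_b"]
        B, F, T = h.shape
        hs = Tensor(np.zeros((B, H)))
        cs = Tensor(np.zeros((B, H)))
        steps = range(T) if direction == "fw" else range(T - 1, -1, -1)
        outputs: list[Tensor] = []
        for t in steps:
            xt = h[:, :, t]
            z = xt @ wx + hs @ wh + b
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            cs = f * cs + i * g
            hs = o * cs.tanh()
            outputs.append(hs)
        if direction == "bw":
            outputs.reverse()
        return ad.concat(outputs, axis=1)

    def _bilstm(self, h: Tensor) -> Tensor:
        return ad.concat([self._lstm_pass(h, "fw"), self._lstm_pass(h, "bw")], axis=1)

    # -- prediction ---------------------------------------------------------

    def predict_scores(self, seqs: Sequence[str], batch_size: int = 256) -> np.ndarray:
        """Raw probabilities: (B,) for sigmoid, (B, 2) for softmax."""
        chunks = []
        for i in range(0, len(seqs), batch_size):
            enc = self.encode(seqs[i : i + batch_size])
            z = self.forward(enc).data
            if self.spec.output_head == "sigmoid":
                chunks.append(1.0 / (1.0 + np.exp(-z[:, 0])))
            else:
                chunks.append(ad.softmax(z))
        return np.concatenate(chunks) if chunks else np.empty(0)

    def conv_activation_maps(self, seqs: Sequence[str]) -> dict[str, np.ndarray]:
        """Raw first-stage convolution activations per filter: name -> (B, Lo).

        These are sliding dot-products of the filter with the one-hot
        input, before pooling or nonlinearity.
        """
        x = self.encode(seqs)["onehot"]
        out: dict[str, np.ndarray] = {}
        if self.spec.family == "jaspar_fixed":
            for i, f in enumerate(self.motif_filters):
                w = self.params[f"motif{i}_w"].data
                cols = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
                out[f.name] = np.einsum("bclk,fck->bfl", cols, w)[:, 0, :]
            return out
        conv_keys = sorted(k for k in self.params if k.startswith("conv") and k.endswith("_w"))
        if not conv_keys:
            raise ValueError(f"family {self.spec.family} has no convolution stage")
        for key in conv_keys:
            w = self.params[key].data
            b = self.params[key[:-2] + "_b"].data
            cols = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
            act = np.einsum("bclk,fck->bfl", cols, w) + b[None, :, None]
            for f in range(w.shape[0]):
                out[f"{key[:-2]}_f{f}"] = act[:, f, :]
        return out


def build_model(spec: ArchitectureSpec, seed: int = 0,
                element_profile: ElementProfile | None = None,
                motif_filters: Sequence[MotifFilter] | None = None) -> Model:
    """Instantiate a model with seeded weight initialization."""
    return Model(spec, seed=seed, element_profile=element_profile,
                 motif_filters=motif_filters)


def predict(
    model: Model, sequences: Sequence[str], threshold: float = 0.5
) -> tuple[list[str], np.ndarray]:
    """Tag sequences I/O.  Sigmoid: I iff score >= threshold (inclusive at
    the 0.5 boundary); softmax: I iff the promoter class (index 1) has the
    larger probability — the threshold is unused."""
    scores = model.predict_scores(list(sequences))
    if model.spec.output_head == "sigmoid":
        tags = ["I" if sc >= threshold else "O" for sc in scores]
    else:
        tags = ["I" if sc[1] > sc[0] else "O" for sc in scores]
    return tags, scores


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(model: Model, path: str | Path, extra: dict | None = None) -> None:
    """Self-describing JSON archive: spec + weights + init seed."""
    payload = {
        "spec": asdict(model.spec),
        "seed": model.seed,
        "frozen": sorted(model.frozen),
        "weights": {k: v.data.tolist() for k, v in model.params.items()},
        "motif_filters": [asdict(f) for f in model.motif_filters],
        "element_profile": (
            {
                "elements": [
                    {"name": e.name, "from": e.from_pos, "to": e.to_pos}
                    for e in model.element_profile.elements
                ],
                "pool_size": model.element_profile.pool_size,
                "window": model.element_profile.window,
                "tss_index": model.element_profile.tss_index,
            }
            if model.element_profile is not None
            else None
        ),
        "extra": extra or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str | Path) -> Model:
    with open(path) as fh:
        payload = json.load(fh)
    spec_kwargs = payload["spec"]
    spec_kwargs["filter_lengths"] = tuple(spec_kwargs["filter_lengths"])
    spec = ArchitectureSpec(**spec_kwargs)
    profile = None
    if payload.get("element_profile"):
        ep = payload["element_profile"]
        from .encoding import Element

        profile = ElementProfile(
            elements=tuple(Element(e["name"], e["from"], e["to"]) for e in ep["elements"]),
            pool_size=ep["pool_size"],
            window=ep["window"],
            tss_index=ep["tss_index"],
        )
    filters = [
        MotifFilter(f["name"], tuple(map(tuple, f["matrix"])), f["mode"])
        for f in payload.get("motif_filters", [])
    ]
    model = Model(spec, seed=payload["seed"], element_profile=profile,
                  motif_filters=filters)
    for k, w in payload["weights"].items():
        model.params[k].data = np.asarray(w, dtype=np.float64)
    return model
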