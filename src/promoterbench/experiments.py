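"""Canned end-to-end experiments on synthetic study conditions.

These bundle the standard desk-scale checks of the framework so tests and
the reproduction script run the identical procedure:

* a learnability smoke test — a CLSTM ("dprom"-family) classifier trained
  on a planted-motif benchmark must separate promoters from background,
  and must fall to chance when the motifs are disabled;
* the imbalance experiment — a fixed model trained on TSS-centred
  promoter windows, evaluated on sliding-window benchmarks at increasing
  non-promoter:promoter ratios, reproducing the precision collapse seen
  when classifiers meet genome-scale class ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_builder import PromoterDataset, build_benchmark
from .models import ArchitectureSpec, Model, build_model
from .synthetic import SyntheticGenomeConfig, generate_synthetic_genome, planted_motif_dataset
from .training_eval import MetricsReport, TrainingConfig, evaluate, train


def dprom_smoke_spec() -> ArchitectureSpec:
    """The CLSTM configuration used by the synthetic smoke tests."""
    return ArchitectureSpec(
        family="dprom", input_length=300, conv_filters=32, filter_lengths=(15,),
        pool_size=6, recurrent_units=32, dense_units=64, dropout=0.2,
        normalize=True,
    )


@dataclass(frozen=True)
class LearnabilityResult:
    report: MetricsReport
    best_val_mcc: float
    epochs: int


def learnability_experiment(
    seed: int = 0,
    n_train: int = 1000,
    n_test: int = 500,
    motifs_enabled: bool = True,
) -> LearnabilityResult:
    """Train the smoke-test CLSTM on a planted-motif benchmark.

    ``motifs_enabled=False`` is the negative control: positives are plain
    background, so any skill beyond chance indicates leakage.
    """
    motifs = None if motifs_enabled else ()
    kwargs = {} if motifs is None else {"motifs": motifs}
    train_ds = planted_motif_dataset(n_train // 2, n_train - n_train // 2,
                                     length=300, seed=seed * 1000 + 11, **kwargs)
    test_ds = planted_motif_dataset(n_test // 2, n_test - n_test // 2,
                                    length=300, seed=seed * 1000 + 12, **kwargs)
    model = build_model(dprom_smoke_spec(), seed=seed)
    result = train(
        model, train_ds,
        TrainingConfig(max_epochs=50, patience=5, batch_size=32,
                       validation_fraction=0.15, seed=seed),
    )
    return LearnabilityResult(
        report=evaluate(model, test_ds),
        best_val_mcc=result.best_val_mcc,
        epochs=len(result.history),
    )


@dataclass(frozen=True)
class ImbalanceResult:
    ratios: tuple[int, ...]
    reports: tuple[MetricsReport, ...]
    sizes: tuple[int, ...] = ()

    @property
    def ppv(self) -> tuple[float, ...]:
        return tuple(r.PPV for r in self.reports)


def train_centered_window_model(seed: int = 0) -> Model:
    """A promoter classifier trained on TSS-centred planted windows, the
    way literature models are trained on curated promoter databases."""
    train_ds = planted_motif_dataset(300, 300, length=300, seed=seed * 1000 + 21)
    spec = ArchitectureSpec(
        family="cnnprom_nontata", input_length=300, conv_filters=16,
        filter_lengths=(15,), pool_size=12, dense_units=32,
    )
    model = build_model(spec, seed=seed)
    train(model, train_ds,
          TrainingConfig(max_epochs=15, patience=5, batch_size=32, seed=seed))
    return model


def imbalance_experiment(
    seed: int = 0,
    ratios: tuple[int, ...] = (1, 10, 100),
    genome_length: int = 400_000,
    n_promoters: int = 60,
    model: Model | None = None,
) -> ImbalanceResult:
    """Evaluate one fixed model at increasing O:I ratios.

    The promoter (I) windows are held fixed; the non-promoter pool of a
    sliding-window benchmark over a fresh synthetic chromosome is
    subsampled to each ratio.  Because the model's false-positive rate on
    genomic windows is fixed, precision falls as the non-promoter count
    grows.
    """
    if model is None:
        model = train_centered_window_model(seed)
    genome, _, truth = generate_synthetic_genome(
        SyntheticGenomeConfig(length=genome_length, n_promoters=n_promoters,
                              seed=seed * 1000 + 22)
    )
    bench = build_benchmark(genome, list(truth))
    i_idx = [k for k, w in enumerate(bench.windows) if w.tag == "I"]
    o_idx = [k for k, w in enumerate(bench.windows) if w.tag == "O"]
    rng = np.random.default_rng(seed * 1000 + 23)
    reports = []
    sizes = []
    for ratio in ratios:
        n_o = min(len(o_idx), ratio * len(i_idx))
        keep_o = [int(j) for j in rng.choice(o_idx, size=n_o, replace=False)]
        ds = bench.subset(sorted(i_idx + keep_o))
        sizes.append(len(ds))
        reports.append(evaluate(model, ds))
    return ImbalanceResult(ratios=tuple(ratios), reports=tuple(reports),
                           sizes=tuple(sizes))
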