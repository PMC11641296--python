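"""Training loop, metrics, splits, thermodynamic conversion, ablations."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hydrobind.autodiff import Adam, Tensor
from hydrobind.graph import build_graph
from hydrobind.model import AffinityModel, EncodedGraph, ModelConfig, encode_graph
from hydrobind.structures_io import ComplexStructure

__all__ = [
    "AffinityRecord",
    "SplitSpec",
    "TrainConfig",
    "pearson_r",
    "rmse",
    "dg_from_kd",
    "make_split",
    "read_affinity_index",
    "train_model",
    "run_ablation",
]

#: ideal gas constant, kcal / (mol K)
R_KCAL = 1.987204259e-3

ABLATION_MODES = ("full", "no_water", "hydramap_only", "rism_only")


@dataclass
class AffinityRecord:
    complex_id: str
    measured: float
    predicted: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.measured):
            raise ValueError("measured affinity must be finite")
        if self.predicted is not None and not math.isfinite(self.predicted):
            raise ValueError("predicted affinity must be finite")


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


# ---------------------------------------------------------------------------
# Metrics & conversions
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Pearson correlation cov(X,Y) / (sigma_X sigma_Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).mean())
    sy = np.sqrt((yc * yc).mean())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float((xc * yc).mean() / (sx * sy))


def rmse(x, y) -> float:
    """Root-mean-square deviation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def dg_from_kd(kd: float, temperature: float = 298.15) -> float:
    """Binding free energy Delta G = R T ln(Kd), kcal/mol (Kd in mol/L)."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("kd and temperature must be positive")
    return R_KCAL * temperature * math.log(kd)


def make_split(all_ids, test_ids) -> SplitSpec:
    """Train = all \\ test, preserving the input order of ``all_ids``."""
    all_ids = list(all_ids)
    test_set = set(test_ids)
    missing = test_set - set(all_ids)
    if missing:
        raise ValueError(f"test ids not present in the id list: {sorted(missing)[:5]}")
    train = [i for i in all_ids if i not in test_set]
    if not train:
        warnings.warn("empty training split: every id is in the test set",
                      stacklevel=2)
    return SplitSpec(train_ids=train, test_ids=[i for i in all_ids if i in test_set])


def read_affinity_index(path: str | Path) -> dict[str, float]:
    """Read a PDBbind-style index: ``code resolution year pK ...`` lines,
    '#' comments tolerated; returns code -> pK (the -log10 molar affinity).
    """
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"malformed index line: {line!r}")
            table[fields[0]] = float(fields[3])
    return table


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 30
    lr: float = 1e-4
    batch_size: int = 8
    val_fraction: float = 0.1
    seed: int = 0
    patience: int | None = None  # early stopping on validation pearson
    init_output_bias: bool = True  # start the head at the train-label mean


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo : lo + batch_size]


def train_model(
    model: AffinityModel,
    graphs_b: list[EncodedGraph],
    graphs_c: list[EncodedGraph],
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> dict:
    """Minimise MSE on pKd with Adam; returns a history dict.

    A ``val_fraction`` share of the data is held out by seeded shuffle for
    monitoring (and early stopping when ``patience`` is set).
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]

    if config.init_output_bias and np.allclose(model.params["b_out"].data, 0.0):
        model.params["b_out"].data[:] = labels[tr_idx].mean()
    opt = Adam(model.parameters(), lr=config.lr)
    history = {"train_loss": [], "val_pearson": []}
    best = (-np.inf, None, 0)
    for epoch in range(config.epochs):
        losses = []
        for batch in _iter_batches(len(tr_idx), config.batch_size, rng):
            ids = tr_idx[batch]
            pred = model.forward([graphs_b[i] for i in ids],
                                 [graphs_c[i] for i in ids])
            err = pred - Tensor(labels[ids])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        if len(val_idx) >= 2:
            val_pred = model.predict([graphs_b[i] for i in val_idx],
                                     [graphs_c[i] for i in val_idx])
            vp = _safe_pearson(labels[val_idx], val_pred)
            history["val_pearson"].append(vp)
            if config.patience is not None:
                if vp > best[0]:
                    best = (vp, {k: p.data.copy()
                                 for k, p in model.params.items()}, epoch)
                elif epoch - best[2] >= config.patience:
                    break
    if config.patience is not None and best[1] is not None:
        for k, p in model.params.items():
            p.data = best[1][k]
    return history


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson that degrades to 0 (with a warning) on zero-variance input."""
    try:
        return pearson_r(x, y)
    except ValueError:
        warnings.warn("zero-variance input; reporting correlation 0.0",
                      stacklevel=2)
        return 0.0


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

def _mode_variants(mode: str) -> tuple[str, str]:
    return {
        "full": ("G_B", "G_C"),
        "no_water": ("G_A", "G_A"),
        "hydramap_only": ("G_B", "G_B"),
        "rism_only": ("G_C", "G_C"),
    }[mode]


def run_ablation(
    complexes: list[ComplexStructure],
    modes: tuple[str, ...] = ("full", "no_water"),
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    test_fraction: float = 0.2,
    T: float = 6.0,
    base_cutoff: float = 6.0,
) -> dict[str, dict[str, float]]:
    """Train one seeded model per mode on identical splits; report metrics.

    ``no_water`` uses the waterless graph for both branches; single-source
    modes duplicate the surviving water graph.  A mode whose water source is
    empty for every complex falls back to the waterless topology with a loud
    warning (the graph builder already warns per complex).
    """
    for mode in modes:
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    labels = np.array([c.affinity_label for c in complexes], dtype=float)
    if not np.all(np.isfinite(labels)):
        raise ValueError("every complex needs a finite affinity label")

    # featurize each variant once and share across modes
    encoded: dict[str, list[EncodedGraph]] = {}
    needed = {v for m in modes for v in _mode_variants(m)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for variant in needed:
            encoded[variant] = [
                encode_graph(
                    build_graph(c, variant=variant, T=T, base_cutoff=base_cutoff),
                    model_config,
                )
                for c in complexes
            ]
    for variant in sorted(needed - {"G_A"}):
        source = "hydramap" if variant == "G_B" else "rism"
        if all(not c.waters_of(source) for c in complexes):
            warnings.warn(
                f"no {source!r} water sites anywhere in the dataset; "
                f"{variant} graphs degenerate to the waterless topology",
                stacklevel=2,
            )

    rng = np.random.default_rng(train_config.seed)
    order = rng.permutation(len(complexes))
    n_test = max(1, int(round(test_fraction * len(complexes))))
    test_idx, train_idx = order[:n_test], order[n_test:]

    results: dict[str, dict[str, float]] = {}
    for mode in modes:
        vb, vc = _mode_variants(mode)
        gb, gc = encoded[vb], encoded[vc]
        model = AffinityModel(model_config)
        train_model(
            model,
            [gb[i] for i in train_idx],
            [gc[i] for i in train_idx],
            labels[train_idx],
            train_config,
        )
        pred = model.predict([gb[i] for i in test_idx],
                             [gc[i] for i in test_idx])
        truth = labels[test_idx]
        results[mode] = {
            "pearson_r": _safe_pearson(truth, pred),
            "rmse": rmse(truth, pred),
            "n_test": int(len(test_idx)),
        }
    return results
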