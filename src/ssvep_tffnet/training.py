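"""Training protocol and leave-one-subject-out cross-validation.

The published protocol: Adam at learning rate 0.001, cross-entropy
loss, dropout 0.5, a fixed epoch budget with no early stopping, and
per-paradigm batch size / L2 coefficient (32 / 1e-4 for the 12-class
paradigm, 128 / 1e-3 for the 40-class ones). Cross-subject evaluation
is leave-one-subject-out: each subject's trials form the test set once
while all remaining subjects train a fresh model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import FoldResult, accuracy as _accuracy, itr as _itr
from .model import ModelConfig, SSVEPTFFNet, build_ablation_model
from .nn import Adam, cross_entropy
from .preprocessing import EpochSet
from .spectra import SpectralConfig, spectra_for_epochs

__all__ = ["TrainConfig", "train_fold", "predict", "run_losocv"]


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the 12-class protocol."""

    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 32
    weight_decay: float = 1e-4
    base_seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def for_paradigm(cls, n_classes: int, **overrides) -> "TrainConfig":
        """12-class: batch 32, L2 1e-4; 40-class: batch 128, L2 1e-3."""
        if n_classes >= 40:
            defaults = dict(batch_size=128, weight_decay=1e-3)
        else:
            defaults = dict(batch_size=32, weight_decay=1e-4)
        defaults.update(overrides)
        return cls(**defaults)


def train_fold(model: SSVEPTFFNet, epochs: np.ndarray, spectra: np.ndarray,
               labels: np.ndarray, cfg: TrainConfig,
               rng: np.random.Generator | None = None) -> list[float]:
    """Train ``model`` in place; returns the per-epoch mean loss history.

    All shuffling randomness comes from ``rng`` (or a stream derived
    from ``cfg.base_seed``); dropout randomness comes from the model's
    own seeded stream, so a fresh model plus a fixed seed reproduces
    the run exactly.
    """
    n = len(labels)
    if n == 0:
        raise ValueError("empty training set")
    rng = rng or np.random.default_rng(cfg.base_seed)
    x = np.ascontiguousarray(epochs, dtype=np.float32) if epochs is not None else None
    s = np.ascontiguousarray(spectra, dtype=np.float32) if spectra is not None else None
    y = np.asarray(labels)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    model.train()
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(None if x is None else x[idx],
                           None if s is None else s[idx])
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
        history.append(sum(losses) / n)
    return history


def predict(model: SSVEPTFFNet, epochs: np.ndarray | None,
            spectra: np.ndarray | None, batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode argmax labels; ties resolve to the lowest index."""
    model.eval()
    n = len(epochs) if epochs is not None else len(spectra)
    preds = []
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        logits = model(None if epochs is None else epochs[sl],
                       None if spectra is None else spectra[sl])
        preds.append(np.argmax(logits.data, axis=1))
    return np.concatenate(preds)


def run_losocv(data: EpochSet, model_cfg: ModelConfig, train_cfg: TrainConfig,
               spectral_cfg: SpectralConfig = SpectralConfig(),
               branch: str = "full",
               spectra: np.ndarray | None = None,
               checkpoint_dir: str | None = None) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation.

    One fold per subject, in sorted subject order; the fold seed is
    ``base_seed + fold_index`` so folds are independently reproducible.
    Returns one :class:`FoldResult` (accuracy, ITR) per held-out subject.
    """
    subjects = data.subject_ids()
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    if spectra is None:
        spectra = spectra_for_epochs(data.epochs, data.fs, spectral_cfg).astype(np.float32)
    need_time = branch != "frequency_only"
    need_freq = branch != "time_only"
    results = []
    for fold_index, subject in enumerate(subjects):
        seed = int(train_cfg.base_seed) + fold_index
        test_mask = data.subjects == subject
        train_mask = ~test_mask
        model = build_ablation_model(model_cfg, branch, seed=seed)
        fold_cfg = replace(train_cfg, base_seed=seed)
        history = train_fold(
            model,
            data.epochs[train_mask] if need_time else None,
            spectra[train_mask] if need_freq else None,
            data.labels[train_mask],
            fold_cfg,
            rng=np.random.default_rng(seed),
        )
        preds = predict(model,
                        data.epochs[test_mask] if need_time else None,
                        spectra[test_mask] if need_freq else None)
        if checkpoint_dir is not None:
            from pathlib import Path

            from .model import save_checkpoint

            out = Path(checkpoint_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, out / f"fold_subject{subject}.npz")
        acc = _accuracy(preds, data.labels[test_mask])
        results.append(FoldResult(
            held_out_subject=subject.item() if hasattr(subject, "item") else subject,
            window_s=data.window_s,
            accuracy=acc,
            itr=_itr(model_cfg.n_classes, acc, data.window_s),
            n_test_trials=int(test_mask.sum()),
            seed=seed,
            loss_history=history,
        ))
    return results
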