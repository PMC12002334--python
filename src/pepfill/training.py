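"""Supervised training of the infilling model on source-target pairs."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _autograd as ag
from .datagen import TrainingPair
from .model import ModelConfig, Seq2SeqModel
from .tokenizer import Vocabulary

logger = logging.getLogger(__name__)


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    #: Adam warm-up; scaled down from the full-scale 4000 steps proportionally
    #: to the corpus size when left at None
    warmup_steps: int | None = None
    grad_clip: float = 5.0
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    #: keep the checkpoint with the best validation loss (early selection)
    select_best: bool = True


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def mean_nll(model: Seq2SeqModel, pairs: Sequence[TrainingPair],
             batch_size: int = 64) -> float:
    """Mean per-sequence NLL over a pair set (no gradients)."""
    totals = []
    with ag.no_grad():
        for i in range(0, len(pairs), batch_size):
            chunk = pairs[i : i + batch_size]
            nll = model.sequence_nll(
                [p.source for p in chunk], [p.target for p in chunk]
            )
            totals.extend(nll.data.tolist())
    return float(np.mean(totals))


def train(
    pairs: Sequence[TrainingPair],
    config: TrainConfig | None = None,
    validation_pairs: Sequence[TrainingPair] = (),
    vocab: Vocabulary | None = None,
) -> tuple[Seq2SeqModel, TrainLog]:
    """Fit the seq2seq model; batches reshuffle each epoch, Adam with
    inverse-sqrt warm-up, early selection at the best validation loss."""
    config = config or TrainConfig()
    if vocab is None:
        vocab = Vocabulary.build(
            [p.source for p in pairs] + [p.target for p in pairs]
            + [p.target for p in validation_pairs]
            + [p.source for p in validation_pairs]
        )
    model = Seq2SeqModel(vocab, config.model, seed=config.seed)
    steps_per_epoch = max(1, len(pairs) // config.batch_size)
    warmup = (
        config.warmup_steps
        if config.warmup_steps is not None
        else max(50, steps_per_epoch * config.epochs // 10)
    )
    opt = ag.Adam(
        model.params, lr=config.learning_rate, warmup_steps=warmup
    )
    rng = np.random.default_rng(config.seed)
    log = TrainLog()
    best_val = np.inf
    best_state = None

    # bucket by source length to limit padding waste, reshuffled every epoch
    order0 = np.argsort([len(p.source) for p in pairs], kind="stable")
    for epoch in range(config.epochs):
        t0 = time.time()
        n_batches = (len(pairs) + config.batch_size - 1) // config.batch_size
        batch_ids = [
            order0[i * config.batch_size : (i + 1) * config.batch_size]
            for i in range(n_batches)
        ]
        rng.shuffle(batch_ids)
        epoch_loss, n_tokens = 0.0, 0
        for ids in batch_ids:
            chunk = [pairs[i] for i in ids]
            opt.zero_grad()
            nll = model.sequence_nll(
                [p.source for p in chunk], [p.target for p in chunk]
            )
            tok = sum(len(vocab.encode(p.target)) + 1 for p in chunk)
            loss = ag.mul(ag.total(nll), 1.0 / tok)
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(f"NaN loss at epoch {epoch}")
            loss.backward()
            opt.step(clip=config.grad_clip)
            epoch_loss += float(ag.total(nll).data)
            n_tokens += tok
        log.train_loss.append(epoch_loss / max(n_tokens, 1))
        if validation_pairs:
            val = mean_nll(model, validation_pairs)
            log.val_loss.append(val)
            if config.select_best and val < best_val:
                best_val = val
                best_state = model.state_dict()
                log.best_epoch = epoch
        logger.info(
            "epoch %d: train %.4f/token%s (%.1fs)",
            epoch,
            log.train_loss[-1],
            f", val {log.val_loss[-1]:.2f}/seq" if validation_pairs else "",
            time.time() - t0,
        )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log
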