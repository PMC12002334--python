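"""Conditional sequence-to-sequence model for peptide infilling.

The model reads a masked peptide string (the source) and generates the filler
amino acids (the target) token by token.  Architecture: embedding, single
layer bidirectional GRU encoder, GRU decoder with multiplicative attention
over the encoder states, and a softmax output head — a compact recurrent
encoder-decoder sized for CPU training.

``f(x, y_{<t})`` is a probability vector over the vocabulary; the training
loss is the negative log-likelihood of the target token at every step.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .tokenizer import Vocabulary

MAX_SEQUENCE_LENGTH = 500

_PEPTIDE_LABEL_RE = re.compile(r"%\d{2}")


@dataclass
class ModelConfig:
    embed_dim: int = 64
    enc_hidden: int = 64  # per direction
    dec_hidden: int = 128
    #: width of the remaining-mask-count embedding fed to the decoder; the
    #: count is a deterministic function of (x, y_{<t}): masks in the source
    #: minus separators already generated
    count_embed: int = 16
    max_count: int = 12
    #: width of the open-ring-label flag embedding; the flag is the parity of
    #: peptide-level %nn tokens seen in source plus generated prefix
    ring_embed: int = 8
    max_len: int = MAX_SEQUENCE_LENGTH
    init_scale: float = 0.1


def _init(rng: np.random.Generator, *shape) -> Tensor:
    fan_in = shape[0] if len(shape) > 1 else 1
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Seq2SeqModel:
    """Encoder-decoder over a fixed vocabulary with trainable parameters."""

    def __init__(self, vocab: Vocabulary, config: ModelConfig | None = None,
                 seed: int = 0):
        self.vocab = vocab
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        V = len(vocab)
        E, H, D = self.config.embed_dim, self.config.enc_hidden, self.config.dec_hidden
        p: dict[str, Tensor] = {}
        p["emb"] = _init(rng, V, E)
        for name in ("enc_f", "enc_b"):
            p[f"{name}_Wx"] = _init(rng, E, 3 * H)
            p[f"{name}_Wh"] = _init(rng, H, 3 * H)
            p[f"{name}_b"] = Tensor(np.zeros(3 * H), requires_grad=True)
        p["cnt_emb"] = _init(rng, self.config.max_count + 1, self.config.count_embed)
        p["ring_emb"] = _init(rng, 2, self.config.ring_embed)
        p["dec_Wx"] = _init(
            rng, E + self.config.count_embed + self.config.ring_embed, 3 * D
        )
        p["dec_Wh"] = _init(rng, D, 3 * D)
        p["dec_b"] = Tensor(np.zeros(3 * D), requires_grad=True)
        p["init_W"] = _init(rng, 2 * H, D)
        p["init_b"] = Tensor(np.zeros(D), requires_grad=True)
        p["att_W"] = _init(rng, D, 2 * H)
        p["out_W"] = _init(rng, D + 2 * H, V)
        p["out_b"] = Tensor(np.zeros(V), requires_grad=True)
        self.params = p

    # -- parameter plumbing ---------------------------------------------------

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def clone(self) -> "Seq2SeqModel":
        other = Seq2SeqModel(self.vocab, self.config)
        other.load_state_dict(self.state_dict())
        return other

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.vocab.save(directory / "vocab.txt")
        np.savez(directory / "weights.npz", **self.state_dict())
        (directory / "model.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, directory: str | Path) -> "Seq2SeqModel":
        directory = Path(directory)
        vocab = Vocabulary.load(directory / "vocab.txt")
        config = ModelConfig(**json.loads((directory / "model.json").read_text()))
        model = cls(vocab, config)
        with np.load(directory / "weights.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model

    # -- forward passes -------------------------------------------------------

    def _encode(self, src_ids: np.ndarray):
        """src_ids (B, Ts) padded with vocab.pad."""
        p = self.params
        H = self.config.enc_hidden
        B, Ts = src_ids.shape
        src_mask = src_ids != self.vocab.pad
        mask_cols = src_mask[:, :, None].astype(ag.DTYPE)
        x3d = ag.embedding(p["emb"], src_ids)  # (B, Ts, E)

        fwd_states, bwd_states = [None] * Ts, [None] * Ts
        h = Tensor(np.zeros((B, H)))
        for t in range(Ts):
            h = ag.gru_step(
                x3d, t, h, p["enc_f_Wx"], p["enc_f_Wh"], p["enc_f_b"],
                mask_cols[:, t],
            )
            fwd_states[t] = h
        h_fwd_last = h

        h = Tensor(np.zeros((B, H)))
        for t in reversed(range(Ts)):
            h = ag.gru_step(
                x3d, t, h, p["enc_b_Wx"], p["enc_b_Wh"], p["enc_b_b"],
                mask_cols[:, t],
            )
            bwd_states[t] = h
        h_bwd_last = h

        enc_out = ag.stack_pair_last(
            ag.stack_time(fwd_states), ag.stack_time(bwd_states)
        )
        h0 = ag.tanh(
            ag.affine2(h_fwd_last, h_bwd_last, p["init_W"], p["init_b"])
        )
        return enc_out, h0, src_mask

    def _decode_step(self, y_prev: np.ndarray, counts: np.ndarray,
                     rings: np.ndarray, h, enc_out, src_mask):
        p = self.params
        counts = np.clip(counts, 0, self.config.max_count)
        x3d = ag.stack_pair_last(
            ag.stack_pair_last(
                ag.embedding(p["emb"], y_prev[:, None]),
                ag.embedding(p["cnt_emb"], counts[:, None]),
            ),
            ag.embedding(p["ring_emb"], rings[:, None]),
        )
        h = ag.gru_step(x3d, 0, h, p["dec_Wx"], p["dec_Wh"], p["dec_b"])
        ctx = ag.attention(enc_out, h, p["att_W"], src_mask)
        logits = ag.affine2(h, ctx, p["out_W"], p["out_b"])
        return logits, h

    def _separator_id(self) -> int:
        return self.vocab._index.get("|", -1)

    def _ring_label_ids(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.vocab.tokens) if t.startswith("%")],
            dtype=np.int64,
        )

    def _remaining_counts(self, sources: Sequence[str], tgt_in: np.ndarray) -> np.ndarray:
        """Masks left to fill at each decoder step: source '?' count minus
        separators consumed so far (inclusive of the current input token)."""
        n_masks = np.array([s.count("?") for s in sources])[:, None]
        seps = np.cumsum(tgt_in == self._separator_id(), axis=1)
        return np.clip(n_masks - seps, 0, self.config.max_count)

    def _open_ring_flags(self, sources: Sequence[str], tgt_in: np.ndarray) -> np.ndarray:
        """Parity of peptide-level ring labels over source plus generated
        prefix: 1 while a macrocycle closure is still owed."""
        src_labels = np.array(
            [len(_PEPTIDE_LABEL_RE.findall(s)) for s in sources]
        )[:, None]
        label_tok = np.isin(tgt_in, self._ring_label_ids())
        return (src_labels + np.cumsum(label_tok, axis=1)) % 2

    def _pad_batch(self, seqs: Sequence[Sequence[int]]) -> np.ndarray:
        T = max(len(s) for s in seqs)
        out = np.full((len(seqs), T), self.vocab.pad, dtype=np.int64)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out

    def sequence_nll(self, sources: Sequence[str], targets: Sequence[str]):
        """Per-sequence NLL (sum of token NLLs) as an autograd tensor (B,)."""
        src_ids = self._pad_batch([self.vocab.encode(s) for s in sources])
        tgt = [self.vocab.encode(t, add_end=True) for t in targets]
        for seq in (src_ids[0], *tgt):
            if len(seq) > self.config.max_len:
                raise ValueError(
                    f"sequence longer than max_len={self.config.max_len}"
                )
        tgt_out = self._pad_batch(tgt)
        B, T = tgt_out.shape
        tgt_in = np.concatenate(
            [np.full((B, 1), self.vocab.start, dtype=np.int64), tgt_out[:, :-1]],
            axis=1,
        )
        tgt_mask = (tgt_out != self.vocab.pad).astype(ag.DTYPE)

        enc_out, h, src_mask = self._encode(src_ids)
        # attention only feeds the output head, so the GRU recursion can run
        # first and attention for every step be computed in one batched matmul
        p = self.params
        counts = self._remaining_counts(sources, tgt_in)
        rings = self._open_ring_flags(sources, tgt_in)
        x3d = ag.stack_pair_last(
            ag.stack_pair_last(
                ag.embedding(p["emb"], tgt_in),
                ag.embedding(p["cnt_emb"], counts),
            ),
            ag.embedding(p["ring_emb"], rings),
        )
        states = []
        for t in range(T):
            h = ag.gru_step(x3d, t, h, p["dec_Wx"], p["dec_Wh"], p["dec_b"])
            states.append(h)
        hs = ag.stack_time(states)  # (B, T, D)
        ctx = ag.attention_seq(enc_out, hs, p["att_W"], src_mask)
        D, A = self.config.dec_hidden, 2 * self.config.enc_hidden
        flat_h = ag.reshape(hs, (B * T, D))
        flat_ctx = ag.reshape(ctx, (B * T, A))
        logits = ag.affine2(flat_h, flat_ctx, p["out_W"], p["out_b"])
        rows = ag.nll_rows(logits, tgt_out.reshape(-1), tgt_mask.reshape(-1))
        return ag.sum_axis(ag.reshape(rows, (B, T)), 1)

    def nll(self, source: str, target: str) -> float:
        """Negative log-likelihood of one source-target pair."""
        with ag.no_grad():
            return float(self.sequence_nll([source], [target]).data[0])

    # -- sampling -------------------------------------------------------------

    def sample_multinomial(
        self,
        source: str,
        n: int,
        rng: np.random.Generator,
        max_len: int | None = None,
        temperature: float = 1.0,
    ) -> list[tuple[list[str], float]]:
        """Draw ``n`` filler sets token-by-token from the model distribution.

        Returns ``(fillers, nll)`` per sample, where fillers is the generated
        string split on the residue separator.
        """
        max_len = max_len or self.config.max_len
        with ag.no_grad():
            src_ids = self._pad_batch([self.vocab.encode(source)] * n)
            enc_out, h, src_mask = self._encode(src_ids)
            y_prev = np.full(n, self.vocab.start, dtype=np.int64)
            remaining = np.full(n, source.count("?"), dtype=np.int64)
            open_ring = np.full(
                n, len(_PEPTIDE_LABEL_RE.findall(source)) % 2, dtype=np.int64
            )
            sep = self._separator_id()
            label_ids = set(self._ring_label_ids().tolist())
            alive = np.ones(n, dtype=bool)
            nll = np.zeros(n)
            seqs: list[list[int]] = [[] for _ in range(n)]
            for _ in range(max_len):
                logits, h = self._decode_step(
                    y_prev, remaining, open_ring, h, enc_out, src_mask
                )
                z = logits.data / temperature
                z = z - z.max(axis=1, keepdims=True)
                probs = np.exp(z)
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random((n, 1))
                choice = (probs.cumsum(axis=1) < u).sum(axis=1)
                choice = np.minimum(choice, len(self.vocab) - 1)
                logp = np.log(probs[np.arange(n), choice] + 1e-300)
                for i in range(n):
                    if alive[i]:
                        nll[i] -= logp[i]
                        if choice[i] == self.vocab.end:
                            alive[i] = False
                        else:
                            seqs[i].append(int(choice[i]))
                            if choice[i] == sep:
                                remaining[i] -= 1
                            elif int(choice[i]) in label_ids:
                                open_ring[i] ^= 1
                y_prev = np.where(alive, choice, self.vocab.pad)
                if not alive.any():
                    break
        return [
            (self.vocab.decode(seq).split("|"), float(nll_i))
            for seq, nll_i in zip(seqs, nll)
        ]

    def sample_beam(
        self, source: str, beam_size: int, max_len: int | None = None
    ) -> list[tuple[list[str], float]]:
        """Deterministic length-normalized beam search, deduplicated at
        string level, ranked best-first."""
        if beam_size < 1:
            raise ValueError("beam_size must be >= 1")
        max_len = max_len or self.config.max_len
        with ag.no_grad():
            src_ids = self._pad_batch([self.vocab.encode(source)])
            enc_out1, h1, src_mask1 = self._encode(src_ids)
            # beams: token ids, cumulative logp, finished flag
            beams: list[tuple[tuple[int, ...], float, bool]] = [((), 0.0, False)]
            states = {(): h1}
            for _ in range(max_len):
                live = [b for b in beams if not b[2]]
                if not live:
                    break
                B = len(live)
                enc_rep = Tensor(np.repeat(enc_out1.data, B, axis=0))
                mask_rep = np.repeat(src_mask1, B, axis=0)
                h = Tensor(
                    np.concatenate([states[b[0]].data for b in live], axis=0)
                )
                y_prev = np.array(
                    [b[0][-1] if b[0] else self.vocab.start for b in live],
                    dtype=np.int64,
                )
                sep = self._separator_id()
                n_masks = source.count("?")
                src_labels = len(_PEPTIDE_LABEL_RE.findall(source))
                label_ids = set(self._ring_label_ids().tolist())
                remaining = np.array(
                    [n_masks - b[0].count(sep) for b in live], dtype=np.int64
                )
                open_ring = np.array(
                    [
                        (src_labels + sum(t in label_ids for t in b[0])) % 2
                        for b in live
                    ],
                    dtype=np.int64,
                )
                logits, h_new = self._decode_step(
                    y_prev, remaining, open_ring, h, enc_rep, mask_rep
                )
                logp = ag.log_softmax(logits).data
                candidates: list[tuple[tuple[int, ...], float, bool]] = [
                    b for b in beams if b[2]
                ]
                new_states = {}
                order = np.argsort(-logp, axis=1)[:, :beam_size]
                for i, (ids, lp, _) in enumerate(live):
                    for j in order[i]:
                        tok = int(j)
                        score = lp + float(logp[i, tok])
                        if tok == self.vocab.end:
                            candidates.append((ids, score, True))
                        else:
                            new_ids = ids + (tok,)
                            candidates.append((new_ids, score, False))
                            new_states[new_ids] = Tensor(h_new.data[i : i + 1])
                # length-normalized ranking
                candidates.sort(key=lambda b: -b[1] / max(len(b[0]) + 1, 1))
                beams = candidates[:beam_size]
                states = {
                    b[0]: new_states.get(b[0], states.get(b[0]))
                    for b in beams
                    if not b[2]
                }
        finished = [b for b in beams if b[2]] or beams
        seen: set[str] = set()
        out = []
        for ids, lp, _ in sorted(
            finished, key=lambda b: -b[1] / max(len(b[0]) + 1, 1)
        ):
            s = self.vocab.decode(ids)
            if s in seen:
                continue
            seen.add(s)
            out.append((s.split("|"), -lp))
        return out
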