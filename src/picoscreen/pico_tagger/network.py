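"""The recogniser network: embeddings -> char/word biLSTM -> projection -> CRF.

Implemented directly on numpy arrays with hand-written backpropagation, so
the model runs on any CPU with no deep-learning framework behind it.

Each token is represented by the concatenation of a word embedding (mapped
to a shared, trainable UNK vector when out of vocabulary) and the final
states of a character-level biLSTM.  A sentence-level biLSTM processes the
sequence and an affine projection produces the CRF's unary tag potentials.
Because the combined embedding width equals the biLSTM output width, the
sequence layer can be re-applied to its own output for nested decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit as sigmoid

from picoscreen.pico_tagger.crf import crf_marginals
from picoscreen.textprep import normalise_for_tagger

__all__ = ["TaggerConfig", "TaggerParams", "score_sentence"]

UNK = 0  # reserved row in both the word and the character embedding tables


@dataclass
class TaggerConfig:
    """Architecture and optimisation settings.

    Defaults follow the reference 3-layer architecture: 200-d word vectors,
    28-d character embeddings with a 28-per-direction character biLSTM
    (combined embedding 256 = 200 + 2x28), a 128-per-direction sequence
    biLSTM, and 41 CRF tags for the default category hierarchy.
    ``combined_dim`` must equal ``2 * seq_lstm_dim`` so that the sequence
    layer can consume its own output during nested decoding.
    """

    word_dim: int = 200
    char_dim: int = 28
    char_lstm_dim: int = 28
    seq_lstm_dim: int = 128
    n_tags: int = 41
    max_layers: int = 3
    batch_size: int = 32
    learning_rate: float = 1e-3
    gradient_clip: float = 5.0
    dropout_rate: float = 0.5
    weight_decay: float = 1e-8
    early_stopping_patience: int = 5
    max_epochs: int = 50
    singleton_unk_prob: float = 0.5
    seed: int = 0

    @property
    def combined_dim(self) -> int:
        return self.word_dim + 2 * self.char_lstm_dim

    def validate(self) -> None:
        if self.combined_dim != 2 * self.seq_lstm_dim:
            raise ValueError(
                f"combined embedding width {self.combined_dim} must equal "
                f"2 x seq_lstm_dim = {2 * self.seq_lstm_dim} for iterative nested decoding"
            )
        if self.n_tags < 3 or self.n_tags % 2 == 0:
            raise ValueError("n_tags must be 2 x n_categories + 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _glorot(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _lstm_params(rng, d_in, d_hid):
    b = np.zeros(4 * d_hid)
    b[d_hid : 2 * d_hid] = 1.0  # forget-gate bias
    return {
        "Wx": _glorot(rng, d_in, 4 * d_hid),
        "Wh": _glorot(rng, d_hid, 4 * d_hid),
        "b": b,
    }


@dataclass
class TaggerParams:
    """All trainable arrays, keyed by name in ``arrays``.

    ``word_emb_frozen`` marks pretrained word vectors that are kept fixed;
    the UNK row (index 0) is always trainable.
    """

    arrays: dict[str, np.ndarray]
    word_emb_frozen: bool = False

    @classmethod
    def init(
        cls,
        config: TaggerConfig,
        n_words: int,
        n_chars: int,
        rng: np.random.Generator,
        pretrained: np.ndarray | None = None,
    ) -> "TaggerParams":
        config.validate()
        K = config.n_tags
        arrays = {
            "word_emb": rng.normal(0.0, 0.1, size=(n_words, config.word_dim)),
            "char_emb": rng.normal(0.0, 0.1, size=(n_chars, config.char_dim)),
            "proj_W": _glorot(rng, 2 * config.seq_lstm_dim, K),
            "proj_b": np.zeros(K),
            "trans": np.zeros((K, K)),
            "start": np.zeros(K),
            "end": np.zeros(K),
        }
        for prefix, d_in, d_hid in (
            ("char_f", config.char_dim, config.char_lstm_dim),
            ("char_b", config.char_dim, config.char_lstm_dim),
            ("seq_f", config.combined_dim, config.seq_lstm_dim),
            ("seq_b", config.combined_dim, config.seq_lstm_dim),
        ):
            for k, v in _lstm_params(rng, d_in, d_hid).items():
                arrays[f"{prefix}_{k}"] = v
        frozen = False
        if pretrained is not None:
            if pretrained.shape != (n_words, config.word_dim):
                raise ValueError("pretrained embedding table has the wrong shape")
            arrays["word_emb"] = pretrained.copy()
            frozen = True
        return cls(arrays, word_emb_frozen=frozen)

    def copy(self) -> "TaggerParams":
        return TaggerParams({k: v.copy() for k, v in self.arrays.items()}, self.word_emb_frozen)

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.arrays.items()}


# ---------------------------------------------------------------------------
# LSTM primitives
# ---------------------------------------------------------------------------


def lstm_forward(Wx, Wh, b, X):
    """Run an LSTM over X (T, d_in); returns hidden states (T, H) and a cache."""
    T = X.shape[0]
    H = Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    out = np.empty((T, H))
    cache = []
    for t in range(T):
        z = X[t] @ Wx + h @ Wh + b
        i, f, o = sigmoid(z[:H]), sigmoid(z[H : 2 * H]), sigmoid(z[2 * H : 3 * H])
        g = np.tanh(z[3 * H :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        cache.append((X[t], h, c, i, f, o, g, c_new))
        h, c = h_new, c_new
        out[t] = h
    return out, cache


def lstm_backward(Wx, Wh, cache, dH):
    """Backpropagate through an LSTM; returns (dX, dWx, dWh, db)."""
    T = len(cache)
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty((T, Wx.shape[0]))
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, g, c_new = cache[t]
        dh = dH[t] + dh_next
        tc = np.tanh(c_new)
        dc = dh * o * (1.0 - tc * tc) + dc_next
        dz = np.concatenate(
            [
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dh * tc * o * (1.0 - o),
                dc * i * (1.0 - g * g),
            ]
        )
        dWx += np.outer(x_t, dz)
        dWh += np.outer(h_prev, dz)
        db += dz
        dX[t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dX, dWx, dWh, db


def bilstm_forward(arrays, prefix, X):
    """Bidirectional LSTM: concatenated forward and reversed-input hidden states."""
    hf, cache_f = lstm_forward(
        arrays[f"{prefix}_f_Wx"], arrays[f"{prefix}_f_Wh"], arrays[f"{prefix}_f_b"], X
    )
    hb_rev, cache_b = lstm_forward(
        arrays[f"{prefix}_b_Wx"], arrays[f"{prefix}_b_Wh"], arrays[f"{prefix}_b_b"], X[::-1]
    )
    return np.concatenate([hf, hb_rev[::-1]], axis=1), (cache_f, cache_b)


def bilstm_backward(arrays, prefix, caches, dH, grads):
    """Backward pass for :func:`bilstm_forward`; accumulates into ``grads``."""
    cache_f, cache_b = caches
    H = arrays[f"{prefix}_f_Wh"].shape[0]
    dXf, dWxf, dWhf, dbf = lstm_backward(
        arrays[f"{prefix}_f_Wx"], arrays[f"{prefix}_f_Wh"], cache_f, dH[:, :H]
    )
    dXb_rev, dWxb, dWhb, dbb = lstm_backward(
        arrays[f"{prefix}_b_Wx"], arrays[f"{prefix}_b_Wh"], cache_b, dH[::-1, H:]
    )
    grads[f"{prefix}_f_Wx"] += dWxf
    grads[f"{prefix}_f_Wh"] += dWhf
    grads[f"{prefix}_f_b"] += dbf
    grads[f"{prefix}_b_Wx"] += dWxb
    grads[f"{prefix}_b_Wh"] += dWhb
    grads[f"{prefix}_b_b"] += dbb
    return dXf + dXb_rev[::-1]


# ---------------------------------------------------------------------------
# Sentence encoding
# ---------------------------------------------------------------------------


def embed_sentence(params: TaggerParams, word_ids, char_ids):
    """Combined word + character-biLSTM embedding for one sentence.

    Returns the (T, combined_dim) matrix and a cache for backpropagation.
    Out-of-vocabulary words carry the UNK vector; the character channel is
    still computed from the surface characters.
    """
    if len(word_ids) == 0:
        raise ValueError("cannot embed an empty sentence")
    arrays = params.arrays
    word_vecs = arrays["word_emb"][np.asarray(word_ids, dtype=int)]
    char_reps = []
    char_caches = []
    Hc = arrays["char_f_Wh"].shape[0]
    for chars in char_ids:
        cx = arrays["char_emb"][np.asarray(chars, dtype=int)]
        hf, cf = lstm_forward(arrays["char_f_Wx"], arrays["char_f_Wh"], arrays["char_f_b"], cx)
        hb, cb = lstm_forward(
            arrays["char_b_Wx"], arrays["char_b_Wh"], arrays["char_b_b"], cx[::-1]
        )
        char_reps.append(np.concatenate([hf[-1], hb[-1]]))
        char_caches.append((chars, cf, cb))
    X = np.concatenate([word_vecs, np.stack(char_reps)], axis=1)
    return X, (word_ids, char_caches, Hc)


def embed_backward(params: TaggerParams, cache, dX, grads):
    """Backpropagate embedding gradients into the word/char tables and char LSTMs."""
    arrays = params.arrays
    word_ids, char_caches, Hc = cache
    word_dim = arrays["word_emb"].shape[1]
    dword = dX[:, :word_dim]
    dchar = dX[:, word_dim:]
    for t, wid in enumerate(word_ids):
        if params.word_emb_frozen and wid != UNK:
            continue
        grads["word_emb"][wid] += dword[t]
    for t, (chars, cf, cb) in enumerate(char_caches):
        Tc = len(chars)
        dHf = np.zeros((Tc, Hc))
        dHf[-1] = dchar[t, :Hc]
        dXf, dWx, dWh, db = lstm_backward(arrays["char_f_Wx"], arrays["char_f_Wh"], cf, dHf)
        grads["char_f_Wx"] += dWx
        grads["char_f_Wh"] += dWh
        grads["char_f_b"] += db
        dHb = np.zeros((Tc, Hc))
        dHb[-1] = dchar[t, Hc:]
        dXb_rev, dWx, dWh, db = lstm_backward(arrays["char_b_Wx"], arrays["char_b_Wh"], cb, dHb)
        grads["char_b_Wx"] += dWx
        grads["char_b_Wh"] += dWh
        grads["char_b_b"] += db
        dchars = dXf + dXb_rev[::-1]
        for ci, cid in enumerate(chars):
            grads["char_emb"][cid] += dchars[ci]


def score_sentence(params: TaggerParams, word_ids, char_ids=None, layer_input=None):
    """Unary tag potentials for one sentence.

    ``layer_input`` replaces the embedding as the sequence-layer input during
    nested decoding iterations; at the first iteration it is ``None`` and the
    combined embedding (built from ``word_ids``/``char_ids``) is used.
    Returns ``(potentials (T, K), hidden (T, 2*seq_lstm_dim))``.
    """
    if layer_input is None:
        if char_ids is None:
            raise ValueError("char_ids required when no layer_input is given")
        layer_input, _ = embed_sentence(params, word_ids, char_ids)
    h, _ = bilstm_forward(params.arrays, "seq", layer_input)
    potentials = h @ params.arrays["proj_W"] + params.arrays["proj_b"]
    if not np.all(np.isfinite(potentials)):
        raise FloatingPointError("non-finite potentials")
    return potentials, h


# ---------------------------------------------------------------------------
# Training-time forward/backward over nested layers
# ---------------------------------------------------------------------------


def _dropout_mask(rng, shape, rate):
    if rate <= 0.0 or rng is None:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _apply(mask, X):
    return X if mask is None else X * mask


def sentence_loss_and_grads(
    params: TaggerParams,
    word_ids,
    char_ids,
    target_layers: list[np.ndarray],
    rng: np.random.Generator | None = None,
    dropout_rate: float = 0.0,
):
    """Negative CRF log-likelihood summed over a sentence's target layers.

    Layer ``l``'s potentials are computed from the sequence biLSTM applied to
    the previous layer's hidden output (the embedding for layer 0); the
    sequence-layer, projection and CRF parameters are shared across layers.
    Returns ``(nll, grads)`` where grads maps array names to gradients.
    """
    arrays = params.arrays
    grads = params.zeros_like()
    K = arrays["proj_b"].shape[0]

    x0, emb_cache = embed_sentence(params, word_ids, char_ids)
    T = x0.shape[0]
    m_in = [_dropout_mask(rng, x0.shape, dropout_rate)]
    inputs = [_apply(m_in[0], x0)]
    h_raw, h_drop, caches, m_out, dpots = [], [], [], [], []
    nll = 0.0
    for l, tags in enumerate(target_layers):
        h, cache = bilstm_forward(arrays, "seq", inputs[l])
        mask = _dropout_mask(rng, h.shape, dropout_rate)
        hd = _apply(mask, h)
        pot = hd @ arrays["proj_W"] + arrays["proj_b"]
        log_z, unary, pairwise, first, last = crf_marginals(
            pot, arrays["trans"], arrays["start"], arrays["end"]
        )
        tags = np.asarray(tags, dtype=int)
        gold_score = (
            arrays["start"][tags[0]]
            + pot[np.arange(T), tags].sum()
            + arrays["trans"][tags[:-1], tags[1:]].sum()
            + arrays["end"][tags[-1]]
        )
        nll += log_z - gold_score
        dpot = unary.copy()
        dpot[np.arange(T), tags] -= 1.0
        grads["trans"] += pairwise.sum(axis=0)
        np.add.at(grads["trans"], (tags[:-1], tags[1:]), -1.0)
        grads["start"] += first
        grads["start"][tags[0]] -= 1.0
        grads["end"] += last
        grads["end"][tags[-1]] -= 1.0
        h_raw.append(h)
        h_drop.append(hd)
        caches.append(cache)
        m_out.append(mask)
        dpots.append(dpot)
        if l + 1 < len(target_layers):
            m_next = _dropout_mask(rng, h.shape, dropout_rate)
            m_in.append(m_next)
            inputs.append(_apply(m_next, h))

    d_next_input = None
    for l in range(len(target_layers) - 1, -1, -1):
        grads["proj_W"] += h_drop[l].T @ dpots[l]
        grads["proj_b"] += dpots[l].sum(axis=0)
        dh = dpots[l] @ arrays["proj_W"].T
        dh = _apply(m_out[l], dh)
        if d_next_input is not None:
            dh = dh + _apply(m_in[l + 1], d_next_input)
        d_next_input = bilstm_backward(arrays, "seq", caches[l], dh, grads)
    dx0 = _apply(m_in[0], d_next_input)
    embed_backward(params, emb_cache, dx0, grads)
    return float(nll), grads


def build_char_ids(surface: str, char_vocab: dict[str, int]) -> list[int]:
    norm = normalise_for_tagger(surface)
    return [char_vocab.get(ch, UNK) for ch in norm] or [UNK]


def build_word_id(surface: str, word_vocab: dict[str, int]) -> int:
    return word_vocab.get(normalise_for_tagger(surface), UNK)
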