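"""Neural N-gram conditional model over amino-acid tokens.

The model estimates p(next residue | previous n-1 residues) with a small
feed-forward network in the classic neural language-model layout:

    token embeddings (length m, trainable, randomly initialized)
    -> concatenation of the n-1 context embeddings
    -> fully connected hidden layer (tanh, default width 128)
    -> linear output layer over the 20 amino acids
    -> softmax

Contexts shorter than n-1 residues (at segment starts) are left-padded with
a dedicated PAD token whose embedding is trained like any other. Training
minimizes average cross-entropy of next-residue prediction over all sliding
windows of the training segments, with Adam. Everything is plain numpy and
fully deterministic given (corpus, config, seed).

A count-based oracle (:func:`count_oracle`) provides the empirical
conditional frequencies the network should converge to; it is used for
testing, never for generation.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from oligomine.corpus import AMINO_ACIDS

PAD = "-"

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised on invalid model configuration, input, or model files."""


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between tokens (20 amino acids + PAD) and integer indices.

    Amino acids take indices 0..19 in alphabetical order; PAD takes the
    reserved final index 20. PAD is a context filler only — it is never a
    prediction target, so the output alphabet has size 20.
    """

    tokens: tuple[str, ...] = tuple(AMINO_ACIDS) + (PAD,)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ModelError("vocabulary tokens must be unique")
        if self.tokens[-1] != PAD:
            raise ModelError("PAD must hold the reserved final index")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def n_outputs(self) -> int:
        return len(self.tokens) - 1

    @property
    def pad_index(self) -> int:
        return len(self.tokens) - 1

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise ModelError(f"residue {token!r} not in vocabulary") from None

    def encode(self, sequence: str) -> np.ndarray:
        lut = {t: i for i, t in enumerate(self.tokens)}
        try:
            return np.array([lut[c] for c in sequence], dtype=np.int64)
        except KeyError as exc:
            raise ModelError(f"residue {exc.args[0]!r} not in vocabulary") from None


@dataclass
class NGramConfig:
    """Hyperparameters of the conditional model.

    n is the N-gram order: the context comprises the n-1 preceding
    residues. m is the embedding length. The default hidden width is 128
    and the output size equals the 20-residue alphabet.
    """

    n: int = 4
    m: int = 16
    hidden_units: int = 128
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 256
    seed: int = 0
    early_stop_delta: float = 1e-5
    early_stop_patience: int = 10

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ModelError("n must be >= 2 (at least one context position)")
        if self.m < 1 or self.hidden_units < 1:
            raise ModelError("m and hidden_units must be positive")


@dataclass
class ModelParameters:
    """Trainable weights: embedding table plus two affine layers."""

    embeddings: np.ndarray      # (vocab_size, m)
    hidden_weights: np.ndarray  # (m*(n-1), hidden_units)
    hidden_bias: np.ndarray     # (hidden_units,)
    output_weights: np.ndarray  # (hidden_units, N)
    output_bias: np.ndarray     # (N,)

    def validate(self, config: NGramConfig, vocab: Vocabulary) -> None:
        ctx = config.n - 1
        expected = {
            "embeddings": (vocab.size, config.m),
            "hidden_weights": (config.m * ctx, config.hidden_units),
            "hidden_bias": (config.hidden_units,),
            "output_weights": (config.hidden_units, vocab.n_outputs),
            "output_bias": (vocab.n_outputs,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ModelError(f"{name}: shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ModelError(f"{name}: non-finite values")


def _init_parameters(config: NGramConfig, vocab: Vocabulary, rng: np.random.Generator) -> ModelParameters:
    # uniform(-0.1, 0.1) everywhere; the PAD embedding trains like any other
    def u(*shape: int) -> np.ndarray:
        return rng.uniform(-0.1, 0.1, size=shape)

    ctx = config.n - 1
    return ModelParameters(
        embeddings=u(vocab.size, config.m),
        hidden_weights=u(config.m * ctx, config.hidden_units),
        hidden_bias=np.zeros(config.hidden_units),
        output_weights=u(config.hidden_units, vocab.n_outputs),
        output_bias=np.zeros(vocab.n_outputs),
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def encode_context(context: str, vocab: Vocabulary, config: NGramConfig,
                   params: ModelParameters) -> np.ndarray:
    """Concatenated embedding vector for a context, left-padded to n-1 tokens."""
    ids = context_ids(context, vocab, config)
    return params.embeddings[ids].reshape(-1)


def context_ids(context: str, vocab: Vocabulary, config: NGramConfig) -> np.ndarray:
    """Token indices for a context, truncated to the last n-1 residues and
    left-padded with PAD."""
    ctx_len = config.n - 1
    context = context[-ctx_len:] if len(context) > ctx_len else context
    pad = ctx_len - len(context)
    ids = np.full(ctx_len, vocab.pad_index, dtype=np.int64)
    if context:
        ids[pad:] = vocab.encode(context)
    return ids


def _windows(segments: Iterable[str], vocab: Vocabulary, config: NGramConfig) -> tuple[np.ndarray, np.ndarray]:
    """All (context ids, target id) training windows.

    Every residue of every segment is a target; its context is its up to n-1
    left neighbors within the same segment, PAD-filled at the start. Contexts
    never cross segment boundaries.
    """
    ctx_rows: list[np.ndarray] = []
    targets: list[int] = []
    for seg in segments:
        ids = vocab.encode(seg)
        for k in range(len(seg)):
            ctx_rows.append(context_ids(seg[:k], vocab, config))
            targets.append(int(ids[k]))
    if not targets:
        raise ModelError("training corpus produced no windows")
    return np.stack(ctx_rows), np.array(targets, dtype=np.int64)


class NeuralNGramModel(BaseEstimator):
    """Scikit-learn style estimator for the neural N-gram conditional model.

    Parameters mirror :class:`NGramConfig`. ``fit`` takes an iterable of
    training sequences (IDR segments). Fitted attributes:

    - ``params_`` : :class:`ModelParameters` with the trained weights
    - ``vocab_`` : the :class:`Vocabulary`
    - ``loss_trace_`` : per-epoch mean cross-entropy
    - ``n_windows_`` : number of training windows seen

    ``predict_proba`` maps contexts (strings of 0..n-1 residues) to
    length-20 conditional distributions over the next residue.
    """

    def __init__(self, n: int = 4, m: int = 16, hidden_units: int = 128,
                 epochs: int = 200, learning_rate: float = 1e-3,
                 batch_size: int = 256, seed: int = 0,
                 early_stop_delta: float = 1e-5, early_stop_patience: int = 10):
        self.n = n
        self.m = m
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.early_stop_delta = early_stop_delta
        self.early_stop_patience = early_stop_patience

    # -- configuration ----------------------------------------------------
    def _config(self) -> NGramConfig:
        return NGramConfig(**{k: getattr(self, k) for k in (
            "n", "m", "hidden_units", "epochs", "learning_rate",
            "batch_size", "seed", "early_stop_delta", "early_stop_patience")})

    # -- training ---------------------------------------------------------
    def fit(self, X: Sequence[str], y: None = None) -> "NeuralNGramModel":
        """Train on an iterable of residue strings (one per IDR segment)."""
        config = self._config()
        vocab = Vocabulary()
        segments = [s for s in X if s]
        if not segments:
            raise ModelError("cannot train on an empty corpus")
        ctx, targets = _windows(segments, vocab, config)
        rng = np.random.default_rng(config.seed)
        params = _init_parameters(config, vocab, rng)

        n_samples = len(targets)
        ctx_len = config.n - 1

        # Adam state
        fields = ("embeddings", "hidden_weights", "hidden_bias",
                  "output_weights", "output_bias")
        m_state = {f: np.zeros_like(getattr(params, f)) for f in fields}
        v_state = {f: np.zeros_like(getattr(params, f)) for f in fields}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        loss_trace: list[float] = []
        best = np.inf
        stale = 0
        for _epoch in range(config.epochs):
            order = rng.permutation(n_samples)
            epoch_loss = 0.0
            for start in range(0, n_samples, config.batch_size):
                idx = order[start:start + config.batch_size]
                cb, tb = ctx[idx], targets[idx]
                bsz = len(idx)

                # forward
                emb = params.embeddings[cb]                    # (b, ctx, m)
                x = emb.reshape(bsz, ctx_len * config.m)
                h_pre = x @ params.hidden_weights + params.hidden_bias
                h = np.tanh(h_pre)
                logits = h @ params.output_weights + params.output_bias
                probs = _softmax(logits)
                epoch_loss += -np.log(
                    np.clip(probs[np.arange(bsz), tb], 1e-300, None)
                ).sum()

                # backward (mean cross-entropy over the batch)
                dlogits = probs
                dlogits[np.arange(bsz), tb] -= 1.0
                dlogits /= bsz
                grads = {
                    "output_weights": h.T @ dlogits,
                    "output_bias": dlogits.sum(axis=0),
                }
                dh = dlogits @ params.output_weights.T
                dh_pre = dh * (1.0 - h * h)
                grads["hidden_weights"] = x.T @ dh_pre
                grads["hidden_bias"] = dh_pre.sum(axis=0)
                dx = dh_pre @ params.hidden_weights.T
                demb = dx.reshape(bsz, ctx_len, config.m)
                g_emb = np.zeros_like(params.embeddings)
                np.add.at(g_emb, cb.reshape(-1), demb.reshape(-1, config.m))
                grads["embeddings"] = g_emb

                # Adam update
                step += 1
                for f in fields:
                    g = grads[f]
                    m_state[f] = beta1 * m_state[f] + (1 - beta1) * g
                    v_state[f] = beta2 * v_state[f] + (1 - beta2) * g * g
                    m_hat = m_state[f] / (1 - beta1 ** step)
                    v_hat = v_state[f] / (1 - beta2 ** step)
                    getattr(params, f)[...] -= (
                        config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    )

            mean_loss = epoch_loss / n_samples
            loss_trace.append(float(mean_loss))
            if best - mean_loss < config.early_stop_delta:
                stale += 1
                if stale >= config.early_stop_patience:
                    break
            else:
                stale = 0
            best = min(best, mean_loss)

        params.validate(config, vocab)
        self.params_ = params
        self.vocab_ = vocab
        self.loss_trace_ = loss_trace
        self.n_windows_ = n_samples
        return self

    # -- inference --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise ModelError("model is not fitted; call fit() or load_model()")

    def predict_proba(self, X: Sequence[str] | str) -> np.ndarray:
        """Conditional next-residue distribution(s) for context string(s).

        Accepts a single context or a sequence of contexts; returns an array
        of shape (n_contexts, 20) (or (20,) for a single string) whose rows
        sum to 1 over the alphabet :data:`~oligomine.corpus.AMINO_ACIDS`.
        """
        self._check_fitted()
        single = isinstance(X, str)
        contexts = [X] if single else list(X)
        config = self._config()
        rows = np.stack([
            context_ids(c, self.vocab_, config) for c in contexts
        ])
        emb = self.params_.embeddings[rows]
        x = emb.reshape(len(contexts), -1)
        h = np.tanh(x @ self.params_.hidden_weights + self.params_.hidden_bias)
        logits = h @ self.params_.output_weights + self.params_.output_bias
        probs = _softmax(logits)
        return probs[0] if single else probs

    def sample_next(self, context: str, rng: np.random.Generator) -> tuple[str, float]:
        """Draw the next residue by inverse-CDF sampling from the model's
        conditional distribution; returns (residue, its probability)."""
        probs = self.predict_proba(context)
        u = rng.random()
        idx = int(np.searchsorted(np.cumsum(probs), u, side="right"))
        idx = min(idx, len(probs) - 1)  # guard the u ~= 1 edge
        return AMINO_ACIDS[idx], float(probs[idx])


def forward(context: str, params: ModelParameters, config: NGramConfig,
            vocab: Vocabulary | None = None) -> np.ndarray:
    """Functional forward pass: softmax over the next residue given a context."""
    vocab = vocab or Vocabulary()
    params.validate(config, vocab)
    x = encode_context(context, vocab, config, params)
    h = np.tanh(x @ params.hidden_weights + params.hidden_bias)
    logits = h @ params.output_weights + params.output_bias
    return _softmax(logits)


def train(segments: Sequence[str], config: NGramConfig | None = None) -> NeuralNGramModel:
    """Convenience wrapper: fit a :class:`NeuralNGramModel` on segments."""
    config = config or NGramConfig()
    model = NeuralNGramModel(**asdict(config))
    return model.fit(segments)


def count_oracle(segments: Sequence[str], n: int) -> dict[str, np.ndarray]:
    """Empirical next-residue frequencies per observed (n-1)-context.

    Contexts at segment starts are PAD-extended, mirroring the network's
    training windows. The mapping's keys are context strings (with PAD
    characters where padded); querying an unseen context yields the uniform
    distribution — callers should use ``.get(ctx, uniform)``.
    """
    vocab = Vocabulary()
    counts: dict[str, np.ndarray] = {}
    ctx_len = n - 1
    for seg in segments:
        for k in range(len(seg)):
            raw = seg[max(0, k - ctx_len):k]
            ctx = PAD * (ctx_len - len(raw)) + raw
            if ctx not in counts:
                counts[ctx] = np.zeros(vocab.n_outputs)
            counts[ctx][vocab.index(seg[k])] += 1
    return {c: v / v.sum() for c, v in counts.items()}


def uniform_distribution() -> np.ndarray:
    """The fallback for unseen contexts: 1/20 per residue."""
    return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))


# -- persistence ---------------------------------------------------------

def save_model(model: NeuralNGramModel, path: str | Path) -> None:
    """Serialize config, vocabulary and weights to a single archive."""
    model._check_fitted()
    path = Path(path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(model._config()),
        "tokens": list(model.vocab_.tokens),
        "loss_trace": model.loss_trace_,
        "n_windows": model.n_windows_,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for f in ("embeddings", "hidden_weights", "hidden_bias",
                  "output_weights", "output_bias"):
            arr = getattr(model.params_, f)
            zf.writestr(f + ".npy", _array_bytes(arr))


def _array_bytes(arr: np.ndarray) -> bytes:
    import io

    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def load_model(path: str | Path, expect_n: int | None = None) -> NeuralNGramModel:
    """Load a saved model; forward outputs are bit-identical after round-trip."""
    import io

    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != MODEL_FORMAT_VERSION:
                raise ModelError(
                    f"{path}: unsupported model format version "
                    f"{meta.get('format_version')!r}"
                )
            arrays = {
                f: np.load(io.BytesIO(zf.read(f + ".npy")))
                for f in ("embeddings", "hidden_weights", "hidden_bias",
                          "output_weights", "output_bias")
            }
    except (zipfile.BadZipFile, KeyError, EOFError, ValueError) as exc:
        if isinstance(exc, ModelError):
            raise
        raise ModelError(f"{path}: corrupt or truncated model file ({exc})") from exc

    config = NGramConfig(**meta["config"])
    if expect_n is not None and config.n != expect_n:
        raise ModelError(
            f"{path}: model has n={config.n}, caller requires n={expect_n}"
        )
    vocab = Vocabulary(tokens=tuple(meta["tokens"]))
    params = ModelParameters(**arrays)
    params.validate(config, vocab)

    model = NeuralNGramModel(**meta["config"])
    model.params_ = params
    model.vocab_ = vocab
    model.loss_trace_ = list(meta["loss_trace"])
    model.n_windows_ = int(meta["n_windows"])
    return model
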