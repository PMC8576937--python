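"""The affinity network: descriptor embeddings, five-branch 1D convolutional
encoder, Vina-term fusion, dot-product attention over descriptors, and a
feed-forward regression head.

Architecture, for a descriptor count vector ``d`` of length ``u``:

1. each embedding row is scaled by its (learnable) frequency weight times the
   observed count: ``E'_i = (w_i d_i) E_i``;
2. a shared dense layer maps each of the ``h`` columns of ``E'`` (length
   ``u``) to ``column_dense_out`` values; the result is flattened row-major
   into a single-channel sequence;
3. five convolution branches (window sizes 2/4/6/8/10, four layers deep with
   3/6/6/9 filters, ELU, max-pool 2/2 after each layer) read the sequence;
   their flattened outputs concatenate to one vector (513 in the reference
   geometry), which is fused with the six Vina terms and encoded to ``e``;
4. attention: query ``q = dense(e)``, keys = values ``k_i = dense(E_i)``,
   weights ``softmax(q . k_i)``, context = weighted sum of values, encoded to
   ``c``;
5. ``[e; c]`` passes through the 512/256/128 ELU feed-forward head to the
   predicted affinity (pK units).

Training minimizes MSE + L2 with Adam. Everything runs on the package's
NumPy autodiff engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from ..descriptors import DescriptorVocabulary
from .autograd import Tensor, concat, conv1d, elu, maxpool1d, softmax
from .config import ModelConfig

_CONV_CHANNELS = lambda filters: (1,) + tuple(filters[:-1])  # noqa: E731


@dataclass
class AttentionOutput:
    """Per-complex attention weights plus the vectors they were built from."""

    weights: np.ndarray  # (u,), non-negative, sums to 1
    context: np.ndarray
    encoded: np.ndarray


class Model:
    """Parameter container with forward / training methods."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self.trained = False
        # Vina-term standardization (fit on the training set): the raw terms
        # live on very different scales (gauss2 sums vs. rotatable-bond counts)
        self.vina_mean = np.zeros(6)
        self.vina_std = np.ones(6)
        self._init_params()

    # -- initialization ----------------------------------------------------
    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        # embedding: truncated standard normal, |z| <= 2
        E = truncnorm.rvs(-2.0, 2.0, size=(cfg.u, cfg.h), random_state=rng)
        self.params["E"] = Tensor(E, requires_grad=True)
        self.params["w"] = Tensor(np.ones(cfg.u), requires_grad=True)
        self._add_dense(rng, "col", cfg.u, cfg.column_dense_out, bias_shape=(cfg.column_dense_out, 1))
        channels = _CONV_CHANNELS(cfg.filters_per_depth)
        for bi, window in enumerate(cfg.window_sizes):
            for depth, (cin, cout) in enumerate(zip(channels, cfg.filters_per_depth)):
                limit = math.sqrt(6.0 / (cin * window + cout * window))
                self.params[f"conv{bi}_{depth}_w"] = Tensor(
                    rng.uniform(-limit, limit, size=(cout, cin, window)), requires_grad=True
                )
                self.params[f"conv{bi}_{depth}_b"] = Tensor(np.zeros(cout), requires_grad=True)
        fused = cfg.flatten_length + (6 if cfg.use_vina else 0)
        self._add_dense(rng, "enc", fused, cfg.encoded_dim)
        if cfg.use_attention:
            self._add_dense(rng, "q", cfg.encoded_dim, cfg.attention_dim)
            self._add_dense(rng, "k", cfg.h, cfg.attention_dim)
            self._add_dense(rng, "ctx", cfg.attention_dim, cfg.context_dim)
            head_in = cfg.encoded_dim + cfg.context_dim
        else:
            head_in = cfg.encoded_dim
        sizes = (head_in,) + cfg.ffn_sizes + (1,)
        for i, (fan_in, fan_out) in enumerate(zip(sizes, sizes[1:])):
            self._add_dense(rng, f"ffn{i}", fan_in, fan_out)

    def _add_dense(self, rng, name: str, fan_in: int, fan_out: int, bias_shape=None) -> None:
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        self.params[f"{name}_w"] = Tensor(
            rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True
        )
        shape = bias_shape if bias_shape is not None else (fan_out,)
        self.params[f"{name}_b"] = Tensor(np.zeros(shape), requires_grad=True)

    # -- forward -----------------------------------------------------------
    def _encode(self, d: np.ndarray, vina: np.ndarray) -> Tensor:
        cfg, p = self.config, self.params
        B = d.shape[0]
        if d.shape[1] != cfg.u:
            raise ValueError(f"descriptor vector length {d.shape[1]} != u={cfg.u}")
        scaled = p["w"] * Tensor(d)  # (B, u)
        rows = scaled.reshape(B, cfg.u, 1) * p["E"]  # (B, u, h)
        cols = p["col_w"].transpose() @ rows + p["col_b"]  # (B, c, h)
        seq = cols.reshape(B, 1, cfg.conv_input_length)
        branches = []
        for bi, window in enumerate(cfg.window_sizes):
            x = seq
            for depth in range(len(cfg.filters_per_depth)):
                x = conv1d(x, p[f"conv{bi}_{depth}_w"], p[f"conv{bi}_{depth}_b"], window)
                x = maxpool1d(elu(x))
            branches.append(x.reshape(B, -1))
        flat = concat(branches, axis=1)
        if cfg.use_vina:
            flat = concat([flat, Tensor((vina - self.vina_mean) / self.vina_std)], axis=1)
        return elu(flat @ p["enc_w"] + p["enc_b"])

    def _attend(self, e: Tensor) -> tuple[Tensor, Tensor]:
        p = self.params
        q = elu(e @ p["q_w"] + p["q_b"])  # (B, a)
        K = elu(p["E"] @ p["k_w"] + p["k_b"])  # (u, a); values share the keys
        weights = softmax(q @ K.transpose(), axis=-1)  # (B, u)
        context = weights @ K  # (B, a)
        c = elu(context @ p["ctx_w"] + p["ctx_b"])
        return weights, c

    def forward(self, d: np.ndarray, vina: np.ndarray) -> tuple[Tensor, Tensor]:
        """Batched forward pass -> (predictions (B,), attention weights (B,u))."""
        cfg, p = self.config, self.params
        d = np.atleast_2d(np.asarray(d, dtype=float))
        vina = np.atleast_2d(np.asarray(vina, dtype=float))
        e = self._encode(d, vina)
        if cfg.use_attention:
            weights, c = self._attend(e)
            z = concat([e, c], axis=1)
        else:
            weights = Tensor(np.full((d.shape[0], cfg.u), 1.0 / cfg.u))
            z = e
        x = z
        n_hidden = len(cfg.ffn_sizes)
        for i in range(n_hidden):
            x = elu(x @ p[f"ffn{i}_w"] + p[f"ffn{i}_b"])
        out = x @ p[f"ffn{n_hidden}_w"] + p[f"ffn{n_hidden}_b"]
        return out.reshape(d.shape[0]), weights

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: t.data.copy() for k, t in self.params.items()}
        state["__vina_mean"] = self.vina_mean.copy()
        state["__vina_std"] = self.vina_std.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(state[k], dtype=t.data.dtype)
        if "__vina_mean" in state:
            self.vina_mean = np.asarray(state["__vina_mean"], dtype=float)
            self.vina_std = np.asarray(state["__vina_std"], dtype=float)

    def save(self, path) -> None:
        import json
        import zipfile

        arrays = {k: v for k, v in self.state_dict().items()}
        meta = {"config": self.config.to_dict(), "trained": self.trained}
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(meta))
            import io

            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "Model":
        import io
        import json
        import zipfile

        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("config.json"))
            state = dict(np.load(io.BytesIO(zf.read("params.npz"))))
        model = cls(ModelConfig.from_dict(meta["config"]))
        model.load_state_dict(state)
        model.trained = meta.get("trained", False)
        return model


def init_model(config: ModelConfig) -> Model:
    """Freshly initialized model (embedding ~ truncated standard normal)."""
    return Model(config)


def encode(model: Model, d: np.ndarray, vina: np.ndarray) -> np.ndarray:
    """Encoded vector e for one complex."""
    e = model._encode(np.atleast_2d(np.asarray(d, float)), np.atleast_2d(np.asarray(vina, float)))
    return e.data[0]


def attend(model: Model, e: np.ndarray) -> AttentionOutput:
    """Attention pass on a precomputed encoded vector."""
    if not model.config.use_attention:
        raise ValueError("model was built without an attention head")
    weights, c = model._attend(Tensor(np.atleast_2d(np.asarray(e, float))))
    return AttentionOutput(weights=weights.data[0], context=c.data[0], encoded=np.asarray(e, float))


def predict(model: Model, d: np.ndarray, vina) -> tuple[float, np.ndarray]:
    """Predicted affinity (pK units) and attention weights for one complex."""
    vina_arr = vina.as_tuple() if hasattr(vina, "as_tuple") else vina
    pred, weights = model.forward(np.asarray(d, float), np.asarray(vina_arr, float))
    return float(pred.data[0]), weights.data[0]


def predict_batch(model: Model, D: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred, weights = model.forward(D, V)
    return pred.data, weights.data


class Adam:
    """Adam optimizer over the model's parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, tensor in self.params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _l2_penalty(model: Model) -> Tensor:
    """Sum of squared weights over all weight matrices (biases excluded)."""
    total = None
    for name, tensor in model.params.items():
        if name.endswith("_b"):
            continue
        sq = (tensor * tensor).sum()
        total = sq if total is None else total + sq
    return total


def _stack_dataset(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    D = np.array([np.asarray(d, float) for d, _, _ in data])
    V = np.array(
        [np.asarray(v.as_tuple() if hasattr(v, "as_tuple") else v, float) for _, v, _ in data]
    )
    y = np.array([float(t) for _, _, t in data])
    return D, V, y


def train_model(train, valid, config: ModelConfig) -> tuple[Model, dict]:
    """Fit the network with Adam on MSE + L2; restore best-validation weights.

    ``train``/``valid`` are sequences of ``(descriptor_counts, vina, affinity)``
    triples. Returns the model and a history dict with per-epoch training loss
    and validation MSE.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    model = Model(config)
    Dtr, Vtr, ytr = _stack_dataset(train)
    model.vina_mean = Vtr.mean(axis=0)
    model.vina_std = np.where(Vtr.std(axis=0) > 0, Vtr.std(axis=0), 1.0)
    has_valid = valid is not None and len(valid) > 0
    if has_valid:
        Dva, Vva, yva = _stack_dataset(valid)
    opt = Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n = len(ytr)
    history: dict[str, list[float]] = {"train_loss": [], "valid_mse": []}
    best_mse, best_state, since_best = math.inf, None, 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred, _ = model.forward(Dtr[idx], Vtr[idx])
            err = pred - Tensor(ytr[idx])
            loss = (err * err).mean() + config.l2_lambda * _l2_penalty(model)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["train_loss"].append(epoch_loss / n)
        if has_valid:
            pva, _ = model.forward(Dva, Vva)
            mse = float(np.mean((pva.data - yva) ** 2))
            history["valid_mse"].append(mse)
            if mse < best_mse - 1e-9:
                best_mse, best_state, since_best = mse, model.state_dict(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.trained = True
    return model, history


def top_attention_descriptors(
    weights: np.ndarray, vocab: DescriptorVocabulary, fraction: float = 0.1
) -> list[str]:
    """The ceil(fraction*u) descriptors with the largest attention weights.

    Ties are broken by vocabulary order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    weights = np.asarray(weights, float)
    if len(weights) != len(vocab):
        raise ValueError("weights length does not match vocabulary size")
    k = math.ceil(fraction * len(vocab))
    order = np.lexsort((np.arange(len(weights)), -weights))
    return [vocab.entries[i] for i in order[:k]]
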