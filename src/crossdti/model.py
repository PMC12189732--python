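"""Cross-modal attention DTI classifier: forward passes, losses, gradients.

Architecture
------------
Protein and compound embeddings are projected by separate three-layer
ReLU feed-forward stacks into a shared latent space of width ``p``::

    L1 = ReLU(W1ᵀE + b1);  L2 = ReLU(W2ᵀL1 + b2);  L3 = ReLU(W3ᵀL2 + b3)

The two latents are fused by dual-headed cross-modal attention: head 1
queries with the target and attends over the compound's keys/values, head 2
mirrors this.  With ``token_count = t`` each latent is reshaped into t tokens
of width p/t; per-head output width is p/(2t) so the concatenated heads have
width p, which a global mixing matrix WG (p x p) combines::

    A = concat( softmax(Q1·K2ᵀ/√h)·V2 , softmax(Q2·K1ᵀ/√h)·V1 ) · WG

with h = p/(2t) (at t = 1 this is the √(p/2) scaling).  A residual sum
Â = L3_target + L3_compound + A is layer-normalised (gain α, bias β, ε) and a
single linear layer W4, b4 emits one logit; the sigmoid lives inside the
numerically fused BCE loss.  Contrastive fine-tuning uses a Euclidean triplet
hinge on the projected latents.

Everything is float64 NumPy with hand-derived gradients; a finite-difference
check in the test suite guards the backward pass.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


class ShapeError(ValueError):
    pass


@dataclass
class ModelConfig:
    target_dim: int = 100
    compound_dim: int = 2048
    p: int = 1024
    hidden: int | None = None  # width of the two inner projection layers; default p
    token_count: int = 1
    epsilon: float = 1e-5
    margin: float = 1.0
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden is None:
            self.hidden = self.p
        if self.p % 2 != 0:
            raise ValueError("latent width p must be even")
        if self.p % (2 * self.token_count) != 0:
            raise ValueError("p must be divisible by 2*token_count")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.margin <= 0:
            raise ValueError("margin must be positive")

    @property
    def token_dim(self) -> int:
        return self.p // self.token_count

    @property
    def head_dim(self) -> int:
        return self.p // (2 * self.token_count)


# Parameter names: projection stacks t_/c_ (target/compound), attention
# heads h1 (target queries compound) and h2 (compound queries target).
_STACK_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3")


@dataclass
class ModelState:
    """All learnable weights plus the configuration that shapes them."""

    config: ModelConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState(config=self.config, params={k: v.copy() for k, v in self.params.items()})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self.config), sort_keys=True).encode()).hexdigest()[:12]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        manifest = {
            "config": asdict(self.config),
            "config_hash": self.config_hash(),
            "shapes": {k: list(v.shape) for k, v in self.params.items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelState":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = ModelConfig(**manifest["config"])
        data = np.load(directory / "weights.npz")
        return cls(config=config, params={k: data[k] for k in data.files})


def init_model(config: ModelConfig) -> ModelState:
    """Seeded Glorot-style initialisation of all weight matrices; zero biases."""
    rng = np.random.default_rng(config.seed)
    p, h, td, hd = config.p, config.hidden, config.token_dim, config.head_dim

    def mat(d_in: int, d_out: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / (d_in + d_out)), size=(d_in, d_out))

    params: dict[str, np.ndarray] = {}
    for prefix, d_in in (("t", config.target_dim), ("c", config.compound_dim)):
        params[f"{prefix}_W1"] = mat(d_in, h)
        params[f"{prefix}_b1"] = np.zeros(h)
        params[f"{prefix}_W2"] = mat(h, h)
        params[f"{prefix}_b2"] = np.zeros(h)
        params[f"{prefix}_W3"] = mat(h, p)
        params[f"{prefix}_b3"] = np.zeros(p)
    for head in ("h1", "h2"):
        for name in ("Wq", "Wk", "Wv"):
            params[f"{head}_{name}"] = mat(td, hd)
    params["WG"] = mat(p, p)
    params["ln_alpha"] = np.ones(p)
    params["ln_beta"] = np.zeros(p)
    params["W4"] = mat(p, 1)[:, 0]
    params["b4"] = np.zeros(1)
    return ModelState(config=config, params=params)


# ---------------------------------------------------------------------------
# Forward pieces (operate on batches, rows = samples)
# ---------------------------------------------------------------------------


def project(x: np.ndarray, state: ModelState, modality: str, cache: dict | None = None) -> np.ndarray:
    """Apply a modality's three-layer ReLU projection stack.  x: (B, d_in)."""
    prefix = {"target": "t", "compound": "c"}[modality]
    P = state.params
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    expected = state.config.target_dim if modality == "target" else state.config.compound_dim
    if x.shape[1] != expected:
        raise ShapeError(f"{modality} stack layer 1: input width {x.shape[1]}, expected {expected}")
    z1 = x @ P[f"{prefix}_W1"] + P[f"{prefix}_b1"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ P[f"{prefix}_W2"] + P[f"{prefix}_b2"]
    a2 = np.maximum(z2, 0.0)
    z3 = a2 @ P[f"{prefix}_W3"] + P[f"{prefix}_b3"]
    a3 = np.maximum(z3, 0.0)
    if cache is not None:
        cache[prefix] = {"x": x, "z1": z1, "a1": a1, "z2": z2, "a2": a2, "z3": z3, "a3": a3}
    return a3


def _softmax(s: np.ndarray) -> np.ndarray:
    m = s.max(axis=-1, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(axis=-1, keepdims=True)


def cross_attention(
    latent_target: np.ndarray,
    latent_compound: np.ndarray,
    state: ModelState,
    cache: dict | None = None,
) -> np.ndarray:
    """Dual-headed cross-modal attention over token-reshaped latents.

    Returns the fused vector A of width p.  Attention weights in each head are
    a softmax over that head's keys; with a single token the weight is exactly
    1 and each head passes its value projection through.
    """
    cfg = state.config
    P = state.params
    lt = np.atleast_2d(np.asarray(latent_target, dtype=np.float64))
    lc = np.atleast_2d(np.asarray(latent_compound, dtype=np.float64))
    if lt.shape[1] != cfg.p or lc.shape[1] != cfg.p:
        raise ShapeError(f"latents must have width p={cfg.p}")
    B, t = lt.shape[0], cfg.token_count
    T = lt.reshape(B, t, cfg.token_dim)
    C = lc.reshape(B, t, cfg.token_dim)
    scale = np.sqrt(cfg.head_dim)

    heads = {}
    for head, (Qsrc, Ksrc) in (("h1", (T, C)), ("h2", (C, T))):
        Q = Qsrc @ P[f"{head}_Wq"]
        K = Ksrc @ P[f"{head}_Wk"]
        V = Ksrc @ P[f"{head}_Wv"]
        S = Q @ K.transpose(0, 2, 1) / scale
        W = _softmax(S)
        O = W @ V
        heads[head] = {"Q": Q, "K": K, "V": V, "W": W, "O": O}
    concat = np.concatenate([heads["h1"]["O"].reshape(B, -1), heads["h2"]["O"].reshape(B, -1)], axis=1)
    A = concat @ P["WG"]
    if cache is not None:
        cache["attn"] = {"T": T, "C": C, "heads": heads, "concat": concat, "scale": scale}
    return A


def attention_weights(
    latent_target: np.ndarray, latent_compound: np.ndarray, state: ModelState
) -> tuple[np.ndarray, np.ndarray]:
    """Return the (head-1, head-2) attention weight matrices, shape (B, t, t)."""
    cache: dict = {}
    cross_attention(latent_target, latent_compound, state, cache=cache)
    h = cache["attn"]["heads"]
    return h["h1"]["W"], h["h2"]["W"]


def classify(
    latent_target: np.ndarray,
    latent_compound: np.ndarray,
    A: np.ndarray,
    state: ModelState,
    cache: dict | None = None,
) -> np.ndarray:
    """Residual sum + layer normalisation + linear classifier -> logit per row."""
    cfg = state.config
    P = state.params
    lt = np.atleast_2d(np.asarray(latent_target, dtype=np.float64))
    lc = np.atleast_2d(np.asarray(latent_compound, dtype=np.float64))
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    if not (lt.shape[1] == lc.shape[1] == A.shape[1] == cfg.p):
        raise ShapeError(f"classify inputs must all have width p={cfg.p}")
    ahat = lt + lc + A
    mu = ahat.mean(axis=1, keepdims=True)
    var = ahat.var(axis=1, keepdims=True)
    std = np.sqrt(var + cfg.epsilon)
    xhat = (ahat - mu) / std
    y = xhat * P["ln_alpha"] + P["ln_beta"]
    logits = y @ P["W4"] + P["b4"][0]
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite value in classifier stage")
    if cache is not None:
        cache["cls"] = {"ahat": ahat, "xhat": xhat, "std": std, "y": y}
    return logits


def forward(
    target_emb: np.ndarray, compound_emb: np.ndarray, state: ModelState, cache: dict | None = None
) -> np.ndarray:
    """Full forward pass: embeddings -> logits (shape (B,))."""
    lt = project(target_emb, state, "target", cache)
    lc = project(compound_emb, state, "compound", cache)
    A = cross_attention(lt, lc, state, cache)
    return classify(lt, lc, A, state, cache)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_sigmoid_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Numerically fused sigmoid + binary cross-entropy, averaged over the batch.

    Uses the stable form max(z,0) - z*y + log(1+exp(-|z|)).
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if z.shape != y.shape:
        raise ValueError("logits and labels must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def triplet_loss(
    anchor: np.ndarray, positive: np.ndarray, negatives: np.ndarray, margin: float = 1.0
) -> float:
    """Mean Euclidean hinge max(0, d(a,p) - d(a,n) + m) over the negatives."""
    a = np.asarray(anchor, dtype=np.float64).ravel()
    p = np.asarray(positive, dtype=np.float64).ravel()
    n = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if n.shape[0] == 0:
        raise ValueError("negatives must be non-empty")
    d_ap = np.linalg.norm(a - p)
    d_an = np.linalg.norm(a - n, axis=1)
    return float(np.maximum(0.0, d_ap - d_an + margin).mean())


# ---------------------------------------------------------------------------
# Backward passes
# ---------------------------------------------------------------------------


def _zeros_like_params(state: ModelState) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in state.params.items()}


def _project_backward(
    d_out: np.ndarray, state: ModelState, prefix: str, cache: dict, grads: dict[str, np.ndarray]
) -> None:
    P, c = state.params, cache[prefix]
    d3 = d_out * (c["z3"] > 0)
    grads[f"{prefix}_W3"] += c["a2"].T @ d3
    grads[f"{prefix}_b3"] += d3.sum(axis=0)
    d2 = (d3 @ P[f"{prefix}_W3"].T) * (c["z2"] > 0)
    grads[f"{prefix}_W2"] += c["a1"].T @ d2
    grads[f"{prefix}_b2"] += d2.sum(axis=0)
    d1 = (d2 @ P[f"{prefix}_W2"].T) * (c["z1"] > 0)
    grads[f"{prefix}_W1"] += c["x"].T @ d1
    grads[f"{prefix}_b1"] += d1.sum(axis=0)


def bce_backward(
    target_emb: np.ndarray, compound_emb: np.ndarray, labels: np.ndarray, state: ModelState
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients of the mean sigmoid-BCE over a batch."""
    cache: dict = {}
    logits = forward(target_emb, compound_emb, state, cache)
    y = np.asarray(labels, dtype=np.float64).ravel()
    loss = bce_sigmoid_loss(logits, y)

    cfg, P = state.config, state.params
    B, p = cache["cls"]["ahat"].shape
    grads = _zeros_like_params(state)

    dz = (sigmoid(logits) - y) / B  # (B,)

    # classifier
    cls = cache["cls"]
    grads["b4"] += np.array([dz.sum()])
    grads["W4"] += cls["y"].T @ dz
    dy = np.outer(dz, P["W4"])
    grads["ln_alpha"] += (dy * cls["xhat"]).sum(axis=0)
    grads["ln_beta"] += dy.sum(axis=0)
    dxhat = dy * P["ln_alpha"]
    xhat, std = cls["xhat"], cls["std"]
    d_ahat = (dxhat - dxhat.mean(axis=1, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)) / std

    dL_t = d_ahat.copy()
    dL_c = d_ahat.copy()
    dA = d_ahat

    # attention
    at = cache["attn"]
    t, hd = cfg.token_count, cfg.head_dim
    grads["WG"] += at["concat"].T @ dA
    dconcat = dA @ P["WG"].T
    dO1 = dconcat[:, : cfg.p // 2].reshape(B, t, hd)
    dO2 = dconcat[:, cfg.p // 2 :].reshape(B, t, hd)
    dT = np.zeros_like(at["T"])
    dC = np.zeros_like(at["C"])
    for head, dO, Qsrc, Ksrc, dQsrc, dKsrc in (
        ("h1", dO1, at["T"], at["C"], dT, dC),
        ("h2", dO2, at["C"], at["T"], dC, dT),
    ):
        h = at["heads"][head]
        W, V, Q, K = h["W"], h["V"], h["Q"], h["K"]
        dW = dO @ V.transpose(0, 2, 1)
        dV = W.transpose(0, 2, 1) @ dO
        dS = W * (dW - (dW * W).sum(axis=-1, keepdims=True))
        dS /= at["scale"]
        dQ = dS @ K
        dK = dS.transpose(0, 2, 1) @ Q
        grads[f"{head}_Wq"] += np.einsum("bij,bik->jk", Qsrc, dQ)
        grads[f"{head}_Wk"] += np.einsum("bij,bik->jk", Ksrc, dK)
        grads[f"{head}_Wv"] += np.einsum("bij,bik->jk", Ksrc, dV)
        dQsrc += dQ @ P[f"{head}_Wq"].T
        dKsrc += dK @ P[f"{head}_Wk"].T + dV @ P[f"{head}_Wv"].T

    dL_t += dT.reshape(B, p)
    dL_c += dC.reshape(B, p)

    _project_backward(dL_t, state, "t", cache, grads)
    _project_backward(dL_c, state, "c", cache, grads)
    return loss, grads


def triplet_backward(
    anchor_emb: np.ndarray,
    positive_emb: np.ndarray,
    negative_embs: np.ndarray,
    state: ModelState,
    margin: float,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and gradients of the Euclidean triplet hinge on projected latents.

    The anchor is a target embedding; positive and negatives are compound
    embeddings.  Only the two projection stacks receive gradient.
    """
    cache_a: dict = {}
    cache_p: dict = {}
    cache_n: dict = {}
    a = project(anchor_emb, state, "target", cache_a)[0]
    pos = project(positive_emb, state, "compound", cache_p)[0]
    negs = project(negative_embs, state, "compound", cache_n)

    diff_p = a - pos
    d_ap = np.linalg.norm(diff_p)
    diff_n = a - negs
    d_an = np.linalg.norm(diff_n, axis=1)
    terms = d_ap - d_an + margin
    active = terms > 0
    K = negs.shape[0]
    loss = float(np.maximum(terms, 0.0).mean())

    grads = _zeros_like_params(state)
    eps = 1e-12
    n_active = int(active.sum())
    # d loss / d d_ap = n_active/K ; d loss / d d_an_k = -active_k/K
    g_ap = n_active / K
    u_p = diff_p / max(d_ap, eps)
    dn_scale = -active.astype(np.float64) / K
    u_n = diff_n / np.maximum(d_an, eps)[:, None]

    da = g_ap * u_p + (dn_scale[:, None] * u_n).sum(axis=0)
    dpos = -g_ap * u_p
    dnegs = -dn_scale[:, None] * u_n

    _project_backward(da[None, :], state, "t", cache_a, grads)
    _project_backward(dpos[None, :], state, "c", cache_p, grads)
    _project_backward(dnegs, state, "c", cache_n, grads)
    return loss, grads
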