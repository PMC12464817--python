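"""Sparse-autoencoder interpretability for per-residue embeddings.

Layer-wise sparse autoencoders (SAEs) are trained on the per-residue
hidden states of a fine-tuned classifier.  A residue counts as
*activated* when its maximum rectified latent unit exceeds a threshold
τ.  The domain-activation statistic

    A = (1/N_l) Σ_j (1/N_s) Σ_i  A_ij / R

averages, over layers j and test samples i, the fraction of
functional-domain residues that are activated, where A_ij is the number
of activated residues inside annotated domains and R the total number of
domain residues (constant per protein).  The relative change after
applying hint tokens is

    ΔA_rel = (A_HTL − A_NO_HTL) / max(A_HTL, A_NO_HTL),

antisymmetric in its arguments and zero when both agree (the (0, 0)
input returns 0 by continuity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np


class SAEError(ValueError):
    """Invalid SAE configuration or divergent training."""


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAnnotation:
    """Functional-domain intervals of one protein, 1-based inclusive."""

    protein_id: str
    intervals: tuple[tuple[int, int], ...]
    protein_length: Optional[int] = None

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not 1 <= s <= e:
                raise SAEError(f"bad interval ({s}, {e})")
            if self.protein_length is not None and e > self.protein_length:
                raise SAEError(f"interval ({s}, {e}) beyond protein length")

    @property
    def residues(self) -> frozenset[int]:
        """Union of the intervals as a residue-position set."""
        out: set[int] = set()
        for s, e in self.intervals:
            out.update(range(s, e + 1))
        return frozenset(out)

    @property
    def R(self) -> int:
        return len(self.residues)


def count_domain_activations(active: Iterable[int], dom: DomainAnnotation) -> int:
    """|active ∩ domain residues| — the A_ij count for one sample/layer."""
    active = set(active)
    if dom.protein_length is not None and any(
        p < 1 or p > dom.protein_length for p in active
    ):
        raise SAEError("activated position outside protein")
    return len(active & dom.residues)


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingTensor:
    """Per-residue hidden states: values (N_l, N_s, T, D) with a mask.

    ``residue_positions`` is (N_s, T) holding the 1-based residue position
    of each token slot, or -1 for hint-token and pad slots, which are
    excluded from all residue statistics.
    """

    values: np.ndarray
    residue_positions: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise SAEError("values must have shape (n_layers, n_samples, T, D)")
        if self.residue_positions.shape != self.values.shape[1:3]:
            raise SAEError("residue_positions must be (n_samples, T)")
        if self.n_layers < 1 or self.n_samples < 1:
            raise SAEError("need at least one layer and one sample")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def dim(self) -> int:
        return self.values.shape[3]

    def layer_vectors(self, layer: int) -> np.ndarray:
        """All residue vectors of one layer, pooled across samples: (n, D)."""
        mask = self.residue_positions >= 0
        return self.values[layer][mask]


def extract_embeddings(
    model,
    ids: np.ndarray,
    residue_positions: np.ndarray,
    layers: Optional[Sequence[int]] = None,
) -> EmbeddingTensor:
    """Collect per-layer hidden states from a classifier.

    ``layers`` selects 1-based layer indices (default: all).  Hint-token
    and pad slots must already be marked -1 in ``residue_positions``.
    """
    hidden = model.hidden_states(np.asarray(ids))  # (n_layers, N, T, D)
    n_layers = hidden.shape[0]
    if layers is None:
        layers = list(range(1, n_layers + 1))
    layers = list(layers)
    if not layers:
        raise SAEError("empty layer set")
    if any(l < 1 or l > n_layers for l in layers):
        raise SAEError(f"layer out of range 1..{n_layers}: {layers}")
    values = hidden[[l - 1 for l in layers]]
    return EmbeddingTensor(values, np.asarray(residue_positions))


# ---------------------------------------------------------------------------
# The sparse autoencoder
# ---------------------------------------------------------------------------

@dataclass
class SAEModel:
    """One-hidden-layer SAE: rectified latent, loss = MSE + λ·L1(latent)."""

    W_enc: np.ndarray  # (d, m)
    b_enc: np.ndarray  # (m,)
    W_dec: np.ndarray  # (m, d)
    b_dec: np.ndarray  # (d,)
    sparsity_weight: float
    threshold: float
    seed: int
    history: list[float] = field(default_factory=list, repr=False)

    @property
    def latent_dim(self) -> int:
        return self.W_enc.shape[1]

    def encode(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(np.asarray(x) @ self.W_enc + self.b_enc, 0.0)

    def decode(self, z: np.ndarray) -> np.ndarray:
        return z @ self.W_dec + self.b_dec

    def reconstruction_error(self, x: np.ndarray) -> float:
        x = np.asarray(x)
        return float(np.mean((self.decode(self.encode(x)) - x) ** 2))


def train_sae(
    X: np.ndarray,
    latent_dim: int,
    sparsity_weight: float = 1e-3,
    threshold: float = 1e-6,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 256,
    lr: float = 1e-3,
    init: str = "random",
) -> SAEModel:
    """Train one SAE with seeded minibatch Adam.

    ``init="identity"`` (requires ``latent_dim == d``) starts at the
    identity map, which already achieves zero reconstruction error for
    λ = 0.  Non-finite losses raise :class:`SAEError`.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or len(X) < 1:
        raise SAEError("need a (n, d) matrix with n >= 1")
    if latent_dim < 1 or sparsity_weight < 0 or threshold < 0:
        raise SAEError("invalid SAE hyperparameters")
    n, d = X.shape
    rng = np.random.default_rng(seed)
    if init == "identity":
        if latent_dim != d:
            raise SAEError("identity init requires latent_dim == d")
        W_enc = np.eye(d)
        W_dec = np.eye(d)
    elif init == "random":
        W_enc = rng.normal(0, 1 / math.sqrt(d), size=(d, latent_dim))
        W_dec = rng.normal(0, 1 / math.sqrt(latent_dim), size=(latent_dim, d))
    else:
        raise SAEError(f"unknown init {init!r}")
    b_enc = np.zeros(latent_dim)
    b_dec = X.mean(axis=0)

    params = {"W_enc": W_enc, "b_enc": b_enc, "W_dec": W_dec, "b_dec": b_dec}
    m_st = {k: np.zeros_like(v) for k, v in params.items()}
    v_st = {k: np.zeros_like(v) for k, v in params.items()}
    t = 0
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            xb = X[order[i : i + batch_size]]
            B = len(xb)
            pre = xb @ params["W_enc"] + params["b_enc"]
            z = np.maximum(pre, 0.0)
            xhat = z @ params["W_dec"] + params["b_dec"]
            err = xhat - xb
            loss = float(np.mean(err**2) + sparsity_weight * np.mean(np.abs(z)))
            if not np.isfinite(loss):
                raise SAEError("SAE training diverged (non-finite loss)")
            history.append(loss)
            dxhat = 2.0 * err / err.size
            grads = {
                "W_dec": z.T @ dxhat,
                "b_dec": dxhat.sum(0),
            }
            dz = dxhat @ params["W_dec"].T
            dz += sparsity_weight * np.sign(z) / z.size
            dpre = dz * (pre > 0)
            grads["W_enc"] = xb.T @ dpre
            grads["b_enc"] = dpre.sum(0)
            t += 1
            for k, g in grads.items():
                m_st[k] = 0.9 * m_st[k] + 0.1 * g
                v_st[k] = 0.999 * v_st[k] + 0.001 * g * g
                mh = m_st[k] / (1 - 0.9**t)
                vh = v_st[k] / (1 - 0.999**t)
                params[k] -= lr * mh / (np.sqrt(vh) + 1e-8)
    return SAEModel(
        params["W_enc"], params["b_enc"], params["W_dec"], params["b_dec"],
        sparsity_weight, threshold, seed, history,
    )


def train_layerwise_saes(
    emb: EmbeddingTensor,
    latent_dim: Optional[int] = None,
    sparsity_weight: float = 1e-3,
    threshold: float = 1e-6,
    seed: int = 0,
    **kwargs,
) -> list[SAEModel]:
    """One SAE per layer, trained on that layer's residue vectors.

    Default latent width is 4× the embedding dimension.
    """
    m = latent_dim if latent_dim is not None else 4 * emb.dim
    return [
        train_sae(
            emb.layer_vectors(j), m, sparsity_weight, threshold,
            seed=seed + j, **kwargs,
        )
        for j in range(emb.n_layers)
    ]


def activated_residues(
    sae: SAEModel,
    embeddings: np.ndarray,
    residue_positions: Sequence[int],
    threshold: Optional[float] = None,
) -> set[int]:
    """Residue positions whose max latent activation exceeds τ.

    ``embeddings`` is (T, d) for one sample and layer;
    ``residue_positions`` marks hint/pad slots with -1.
    """
    tau = sae.threshold if threshold is None else threshold
    z = sae.encode(np.asarray(embeddings))
    peaks = z.max(axis=1) if z.size else np.zeros(len(embeddings))
    return {
        int(p)
        for p, peak in zip(residue_positions, peaks)
        if p >= 0 and peak > tau
    }


# ---------------------------------------------------------------------------
# The activation statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationCounts:
    """Counts A_ij of activated in-domain residues: shape (N_s, N_l)."""

    counts: np.ndarray
    strategy: str  # "HTL" or "NO_HTL"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise SAEError("counts must be (n_samples, n_layers)")
        if (c < 0).any():
            raise SAEError("counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class ActivationSummary:
    """The A statistic plus its per-layer decomposition."""

    value: float
    per_layer_means: tuple[float, ...]
    strategy: str


@dataclass(frozen=True)
class DeltaRel:
    """Relative change in domain activation after HTL."""

    value: float


def compute_A(counts: ActivationCounts, R: int) -> ActivationSummary:
    """Mean over layers of the per-layer mean of A_ij / R."""
    if R <= 0:
        raise SAEError("R must be positive")
    c = counts.counts
    if (c > R).any():
        raise SAEError("some A_ij exceed R")
    per_layer = (c / R).mean(axis=0)  # mean over samples, per layer
    return ActivationSummary(
        float(per_layer.mean()), tuple(float(x) for x in per_layer), counts.strategy
    )


def deeper_layer_summary(
    counts: ActivationCounts, R: int, layers: Optional[Sequence[int]] = None
) -> ActivationSummary:
    """The A statistic restricted to a 1-based layer subset.

    Default subset: the last ⌈N_l/3⌉ layers ("deeper layers").
    """
    n_layers = counts.counts.shape[1]
    if layers is None:
        k = math.ceil(n_layers / 3)
        layers = list(range(n_layers - k + 1, n_layers + 1))
    layers = list(layers)
    if not layers:
        raise SAEError("empty layer subset")
    if any(l < 1 or l > n_layers for l in layers):
        raise SAEError(f"layer subset out of range 1..{n_layers}")
    sub = ActivationCounts(counts.counts[:, [l - 1 for l in layers]], counts.strategy)
    return compute_A(sub, R)


def compute_delta_rel(a_htl: float, a_no_htl: float) -> DeltaRel:
    """ΔA_rel = (A_HTL − A_NO_HTL) / max(A_HTL, A_NO_HTL); (0,0) → 0."""
    for v in (a_htl, a_no_htl):
        if not 0.0 <= v <= 1.0:
            raise SAEError(f"A statistic {v} outside [0, 1]")
    denom = max(a_htl, a_no_htl)
    if denom == 0.0:
        return DeltaRel(0.0)
    return DeltaRel((a_htl - a_no_htl) / denom)


def domain_activation_counts(
    saes: Sequence[SAEModel],
    emb: EmbeddingTensor,
    dom: DomainAnnotation,
    strategy: str,
    threshold: Optional[float] = None,
) -> ActivationCounts:
    """Assemble the full A_ij matrix for one tokenization strategy."""
    if len(saes) != emb.n_layers:
        raise SAEError("need one SAE per layer")
    counts = np.zeros((emb.n_samples, emb.n_layers), dtype=int)
    for j, sae in enumerate(saes):
        for i in range(emb.n_samples):
            active = activated_residues(
                sae, emb.values[j, i], emb.residue_positions[i], threshold
            )
            counts[i, j] = count_domain_activations(active, dom)
    return ActivationCounts(counts, strategy)
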