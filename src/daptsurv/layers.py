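"""Network building blocks: feature embedding, per-token autoencoder,
multi-head self-attention encoder, mean pooling, and the task heads.

The input module turns one patient's covariates into an M x N embedding
matrix (M features, embedding size N): each categorical value indexes a
learnable lookup table (with a reserved unknown-code row), and each numeric
value is standardized to a z-score that scales a learnable base vector, so
every feature contributes one N-vector regardless of its type.

The autoencoder compresses each feature token row-wise (N -> N', shared
weights across features) under an MSE reconstruction loss; the transformer
encoder then self-attends over the M compressed tokens with no positional
encoding — clinical covariates are an unordered set, and the encoder is
permutation-equivariant over them.  Mean pooling over tokens yields the
patient representation f(x) consumed by the contrastive loss and both task
heads (event classification; per-interval hazards).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, softmax
from .cohort import FeatureSchema, SurvivalRecord


@dataclass(frozen=True)
class AttentionConfig:
    """Transformer encoder hyperparameters."""

    heads: int = 4
    layers: int = 2
    ff_width: int = 64

    def __post_init__(self) -> None:
        if self.heads < 1 or self.layers < 0 or self.ff_width < 1:
            raise ValueError(f"invalid attention config: {self}")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Sizes of the full stack: embedding N, bottleneck N', attention, heads."""

    embed_dim: int = 32          # N
    bottleneck_dim: int = 16     # N'
    ae_hidden: int = 24
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    init_scale: float = 0.05     # uniform(-s, s) parameter initialization

    def __post_init__(self) -> None:
        if self.bottleneck_dim < 1 or self.embed_dim < 1:
            raise ValueError("embedding and bottleneck sizes must be >= 1")
        if self.bottleneck_dim % self.attention.heads != 0:
            raise ValueError(
                f"bottleneck width {self.bottleneck_dim} not divisible by "
                f"{self.attention.heads} heads"
            )


@dataclass
class EmbeddingMatrix:
    """Per-patient M x N array of feature embeddings, rows in schema order."""

    values: np.ndarray
    feature_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.feature_order):
            raise ValueError(
                f"embedding matrix shape {self.values.shape} does not match "
                f"{len(self.feature_order)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in embedding matrix")

    @property
    def embedding_size(self) -> int:
        return self.values.shape[1]


def _uniform(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class EmbeddingParameters:
    """Learnable lookup tables (categoricals) and base vectors (numerics).

    Each categorical table has ``vocab + 1`` rows; the final row is the
    reserved unknown-category slot, initialized at zero.
    """

    def __init__(self, schema: FeatureSchema, embed_dim: int,
                 rng: np.random.Generator, init_scale: float = 0.05):
        self.schema = schema
        self.embed_dim = embed_dim
        self.tables: dict[str, Tensor] = {}
        for name, vocab in schema.categorical.items():
            table = rng.uniform(-init_scale, init_scale, size=(len(vocab) + 1, embed_dim))
            table[-1] = 0.0  # unknown slot
            self.tables[name] = Tensor(table, requires_grad=True)
        self.base_vectors: dict[str, Tensor] = {
            name: _uniform(rng, (embed_dim,), init_scale) for name in schema.numeric
        }

    def parameters(self) -> list[Tensor]:
        return list(self.tables.values()) + list(self.base_vectors.values())


def embed_categorical(feature: str, code: str, params: EmbeddingParameters) -> np.ndarray:
    """Lookup-table row for a categorical value; unseen codes hit the unknown slot."""
    if feature not in params.schema.categorical:
        raise KeyError(f"{feature!r} is not a categorical feature of the schema")
    idx = params.schema.category_index(feature, code)
    return params.tables[feature].data[idx].copy()

def embed_numeric(feature: str, raw_value: float, schema: FeatureSchema,
                  params: EmbeddingParameters) -> np.ndarray:
    """Standardized value z = (raw - mean)/sd scaling the feature's base vector."""
    if feature not in schema.numeric:
        raise KeyError(f"{feature!r} is not a numeric feature of the schema")
    z = schema.standardize(feature, raw_value)
    return z * params.base_vectors[feature].data


def build_embedding_matrix(record: SurvivalRecord, schema: FeatureSchema,
                           params: EmbeddingParameters) -> EmbeddingMatrix:
    """Stack one N-vector per feature, in schema order, into the M x N matrix."""
    rows = []
    for name in schema.categorical:
        if name not in record.categorical_values:
            raise KeyError(f"record {record.patient_id}: missing feature {name!r}")
        rows.append(embed_categorical(name, record.categorical_values[name], params))
    for name in schema.numeric:
        if name not in record.numeric_values:
            raise KeyError(f"record {record.patient_id}: missing feature {name!r}")
        rows.append(embed_numeric(name, record.numeric_values[name], schema, params))
    return EmbeddingMatrix(np.stack(rows), schema.feature_names)


def embed_batch(cat_idx: np.ndarray, num_z: np.ndarray,
                params: EmbeddingParameters) -> Tensor:
    """Differentiable batched input module: (B, M, N) embedding tensor.

    ``cat_idx``/``num_z`` come from :meth:`Cohort.encode`; rows follow the
    schema feature order (categoricals first).
    """
    pieces = []
    for j, name in enumerate(params.schema.categorical):
        rows = params.tables[name].gather_rows(cat_idx[:, j])  # (B, N)
        pieces.append(rows.reshape(rows.shape[0], 1, params.embed_dim))
    for j, name in enumerate(params.schema.numeric):
        z = Tensor(num_z[:, j][:, None, None])                 # (B, 1, 1)
        base = params.base_vectors[name].reshape(1, 1, params.embed_dim)
        pieces.append(z * base)
    return concat(pieces, axis=1)


class Dense:
    """Affine layer y = x W + b with uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None, bias_init: float = 0.0):
        s = scale if scale is not None else 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-s, s, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.full(n_out, bias_init, dtype=float), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = 1e-6

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Autoencoder:
    """Row-wise compressor: encoder N -> hidden -> N', decoder N' -> hidden -> N.

    Weights are shared across the M feature tokens, so identical input rows map
    to identical bottleneck rows.
    """

    def __init__(self, n: int, n_hidden: int, n_bottleneck: int, rng: np.random.Generator):
        self.enc1 = Dense(n, n_hidden, rng)
        self.enc2 = Dense(n_hidden, n_bottleneck, rng)
        self.dec1 = Dense(n_bottleneck, n_hidden, rng)
        self.dec2 = Dense(n_hidden, n, rng)

    def encode(self, h: Tensor) -> Tensor:
        return self.enc2(self.enc1(h).tanh())

    def decode(self, z: Tensor) -> Tensor:
        return self.dec2(self.dec1(z).tanh())

    def parameters(self) -> list[Tensor]:
        return (self.enc1.parameters() + self.enc2.parameters()
                + self.dec1.parameters() + self.dec2.parameters())


def attention(q: Tensor, k: Tensor, v: Tensor, d_k: int,
              return_scores: bool = False):
    """Scaled dot-product attention: softmax(QK^T / sqrt(d_k)) V.

    Works on (..., M, d) stacks; the score matrix rows are a probability
    distribution over key positions.
    """
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(f"query dim {q.shape[-1]} != key dim {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"key count {k.shape[-2]} != value count {v.shape[-2]}")
    scores = softmax(q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(d_k)), axis=-1)
    out = scores @ v
    return (out, scores) if return_scores else out


class MultiHeadSelfAttention:
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"width {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.d_k = dim, heads, dim // heads
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)
        self.last_scores: np.ndarray | None = None  # (B, H, M, M), diagnostics

    def _split(self, x: Tensor) -> Tensor:
        b, m, _ = x.shape
        return x.reshape(b, m, self.heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, m, _ = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        out, scores = attention(q, k, v, self.d_k, return_scores=True)
        self.last_scores = scores.data
        merged = out.transpose(0, 2, 1, 3).reshape(b, m, self.dim)
        return self.wo(merged)

    def parameters(self) -> list[Tensor]:
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())


class TransformerLayer:
    """Pre-norm residual block: x + MHSA(LN(x)); x + FF(LN(x))."""

    def __init__(self, dim: int, heads: int, ff_width: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Dense(dim, ff_width, rng)
        self.ff2 = Dense(ff_width, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())

    def parameters(self) -> list[Tensor]:
        return (self.ln1.parameters() + self.attn.parameters()
                + self.ln2.parameters() + self.ff1.parameters() + self.ff2.parameters())


class TransformerEncoder:
    def __init__(self, dim: int, cfg: AttentionConfig, rng: np.random.Generator):
        self.layers = [
            TransformerLayer(dim, cfg.heads, cfg.ff_width, rng) for _ in range(cfg.layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def attention_scores(self) -> list[np.ndarray]:
        return [l.attn.last_scores for l in self.layers]

    def parameters(self) -> list[Tensor]:
        return [p for l in self.layers for p in l.parameters()]


def pool(tokens: Tensor) -> Tensor:
    """Mean over the token axis: (B, M, D) -> (B, D); the representation f(x)."""
    return tokens.mean(axis=-2)


class SurvivalNet:
    """The full stack: embedding -> autoencoder bottleneck -> transformer ->
    pooled representation -> {classification logit, per-interval hazard rates}.

    ``forward`` returns (reconstruction h', embedding h, representation f(x),
    event probability p, hazards lambda) for a batch.
    """

    def __init__(self, schema: FeatureSchema, n_intervals: int,
                 arch: ArchitectureConfig, rng: np.random.Generator):
        self.schema = schema
        self.arch = arch
        self.n_intervals = n_intervals
        self.embedding = EmbeddingParameters(schema, arch.embed_dim, rng, arch.init_scale)
        self.autoencoder = Autoencoder(arch.embed_dim, arch.ae_hidden,
                                       arch.bottleneck_dim, rng)
        self.transformer = TransformerEncoder(arch.bottleneck_dim, arch.attention, rng)
        self.cls_head = Dense(arch.bottleneck_dim, 1, rng)
        # hazards start near e^-6 per day so early lambda*rho terms stay small
        self.hazard_head = Dense(arch.bottleneck_dim, n_intervals, rng, bias_init=-6.0)

    def forward(self, cat_idx: np.ndarray, num_z: np.ndarray):
        h = embed_batch(cat_idx, num_z, self.embedding)          # (B, M, N)
        z = self.autoencoder.encode(h)                           # (B, M, N')
        h_rec = self.autoencoder.decode(z)                       # (B, M, N)
        tokens = self.transformer(z)                             # (B, M, N')
        fx = pool(tokens)                                        # (B, N')
        p = self.cls_head(fx).reshape(fx.shape[0]).sigmoid()     # (B,)
        lam = self.hazard_head(fx).softplus()                    # (B, J) per-day rates
        return h_rec, h, fx, p, lam

    def parameters(self) -> list[Tensor]:
        return (self.embedding.parameters() + self.autoencoder.parameters()
                + self.transformer.parameters() + self.cls_head.parameters()
                + self.hazard_head.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.copy()
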