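"""Convolutional autoencoder surrogate for valve-closure analysis.

Architecture (channels-last, one 2D "image" per leaflet control grid):

* three leaflet branches apply the NURBS-aware convolution — ordinary 2D
  convolutions acting on the m x n x 3 control-point texture — followed by a
  dense layer to a per-leaflet embedding (encoder weights shared across
  leaflets by default, exploiting the valve's 3-fold symmetry);
* the three embeddings are concatenated with the standardized material vector
  (c0, c1, c2, thickness) and the standardized pressure repeated 10 times,
  and fused by a dense layer into the code layer — the bottleneck from which
  everything downstream is predicted;
* a decoder maps the code through one dense layer per leaflet back to grid
  shape and through mirrored convolutions to the three displacement grids
  (linear output activation: displacements may be negative);
* a separate head maps the code to the coaptation area through a ReLU output,
  enforcing non-negativity.

The displacement loss is boundary-condition weighted: each squared nodal
error is scaled by ``|u_true| / max|u_true|``, so fixed attachment nodes
(zero true displacement) contribute exactly nothing and the optimizer is not
penalized for tiny non-zero predictions there.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from .closure import SimulationSample, ValveDataset
from .nn import Adam, Conv2D, Dense, ReLU, Sequential

__all__ = [
    "SurrogateConfig",
    "Standardizer",
    "PredictionBundle",
    "ClosureSurrogate",
    "TrainHistory",
    "bc_weighted_loss",
    "bc_weights",
    "total_loss",
    "augment_translate",
    "encode_input",
    "train",
]


@dataclass(frozen=True)
class SurrogateConfig:
    grid: tuple[int, int] = (8, 8)
    conv_channels: tuple[int, ...] = (16, 32)
    kernel: int = 3
    embedding_size: int = 64
    code_size: int = 128
    head_hidden: int = 32
    pressure_repeat: int = 10
    share_encoder: bool = True
    lambda_c: float = 1.0
    tau: float = 1e-12
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    augment: bool = True
    augment_range: float = 0.5
    augment_prob: float = 0.5
    enforce_fixed_boundary: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pressure_repeat != 10:
            raise ValueError("pressure vector length is fixed at 10")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.lambda_c < 0:
            raise ValueError("lambda_c must be >= 0")


@dataclass
class Standardizer:
    """Affine feature standardization fitted on the training split."""

    mat_mean: np.ndarray = field(default_factory=lambda: np.zeros(4))
    mat_std: np.ndarray = field(default_factory=lambda: np.ones(4))
    press_mean: float = 0.0
    press_std: float = 1.0
    area_mean: float = 0.0
    area_std: float = 1.0

    @classmethod
    def fit(cls, material: np.ndarray, pressure: np.ndarray,
            coaptation: np.ndarray) -> "Standardizer":
        def safe_std(x, axis=None):
            s = np.std(x, axis=axis)
            return np.where(np.asarray(s) > 1e-12, s, 1.0)

        return cls(
            mat_mean=np.mean(material, axis=0), mat_std=safe_std(material, 0),
            press_mean=float(np.mean(pressure)), press_std=float(safe_std(pressure)),
            area_mean=float(np.mean(coaptation)), area_std=float(safe_std(coaptation)))

    def material(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.mat_mean) / self.mat_std

    def material_inverse(self, std: np.ndarray) -> np.ndarray:
        return std * self.mat_std + self.mat_mean

    def pressure_vector(self, pressure, repeat: int = 10) -> np.ndarray:
        p = (np.atleast_1d(np.asarray(pressure, float)) - self.press_mean) / self.press_std
        return np.repeat(p[:, None], repeat, axis=1)

    def pressure_inverse(self, std) -> np.ndarray:
        return np.asarray(std) * self.press_std + self.press_mean


@dataclass(frozen=True)
class PredictionBundle:
    """Model outputs for a batch: displacement grids (N,3,m,n,3) in cm,
    coaptation areas (N,) in cm^2 (non-negative by ReLU), and the code-layer
    activations (N, code_size)."""

    displacement: np.ndarray
    coaptation_area: np.ndarray
    code: np.ndarray


def encode_input(sample: SimulationSample, standardizer: Standardizer,
                 config: SurrogateConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model input bundle for one sample: raw leaflet textures (3,m,n,3), the
    standardized 4-feature material vector, and the standardized pressure
    repeated into a length-10 vector."""
    tex = np.asarray(sample.reference, dtype=float)
    if tex.shape[1:3] != tuple(config.grid):
        raise ValueError(f"sample grid {tex.shape[1:3]} does not match config {config.grid}")
    mat = standardizer.material(np.asarray(sample.material, dtype=float))
    press = standardizer.pressure_vector(sample.pressure, config.pressure_repeat)[0]
    return tex, mat, press


# ---------------------------------------------------------------------------
# losses


def bc_weights(u_true: np.ndarray, tau: float = 1e-12,
               vector_axis: int | None = None) -> np.ndarray:
    """Weights |u_true| / max|u_true| in [0, 1]; all-ones when the target is
    (numerically) all zero, falling back to unweighted MSE.

    With ``vector_axis`` set, |u_true| is the Euclidean norm over that axis
    (the nodal displacement magnitude), broadcast back over the components:
    a node's three components share one weight, so every component of a
    moving node is supervised while fixed nodes are suppressed entirely.
    """
    u_true = np.asarray(u_true, dtype=float)
    if vector_axis is None:
        mag = np.abs(u_true)
    else:
        mag = np.broadcast_to(
            np.linalg.norm(u_true, axis=vector_axis, keepdims=True), u_true.shape)
    peak = np.max(mag)
    if peak < tau:
        return np.ones_like(u_true)
    return mag / peak


def bc_weighted_loss(u_pred: np.ndarray, u_true: np.ndarray,
                     tau: float = 1e-12) -> float:
    """Boundary-condition weighted MSE: mean of w * (u_pred - u_true)^2 with
    w = |u_true| / max|u_true|.  Errors at fixed (zero-target) nodes are
    suppressed entirely."""
    u_pred = np.asarray(u_pred, dtype=float)
    u_true = np.asarray(u_true, dtype=float)
    if u_pred.shape != u_true.shape:
        raise ValueError("shape mismatch between prediction and target")
    if np.any(~np.isfinite(u_pred)) or np.any(~np.isfinite(u_true)):
        raise FloatingPointError("non-finite displacement values")
    w = bc_weights(u_true, tau)
    return float(np.mean(w * (u_pred - u_true) ** 2))


def bc_weighted_loss_grad(u_pred: np.ndarray, u_true: np.ndarray,
                          tau: float = 1e-12) -> np.ndarray:
    """Analytic gradient of :func:`bc_weighted_loss` with respect to u_pred."""
    w = bc_weights(np.asarray(u_true, float), tau)
    return 2.0 * w * (np.asarray(u_pred, float) - u_true) / u_true.size


def total_loss(u_pred: np.ndarray, u_true: np.ndarray,
               area_pred: float, area_true: float,
               lambda_c: float = 1.0, area_scale: float = 1.0,
               tau: float = 1e-12) -> float:
    """Per-sample training loss: sum over leaflets of the BC-weighted
    displacement loss plus ``lambda_c`` times the squared coaptation error on
    the standardized (area_scale-divided) scale."""
    if lambda_c < 0:
        raise ValueError("lambda_c must be >= 0")
    u_pred = np.asarray(u_pred, float)
    u_true = np.asarray(u_true, float)
    def_term = sum(bc_weighted_loss(u_pred[k], u_true[k], tau)
                   for k in range(u_pred.shape[0]))
    area_term = ((area_pred - area_true) / area_scale) ** 2
    return float(def_term + lambda_c * area_term)


def augment_translate(sample: SimulationSample, rng: np.random.Generator,
                      translation_range: float = 0.5) -> SimulationSample:
    """Shift the whole reference valve by one random translation vector
    (uniform per axis in [-range, range] cm).  Displacement and coaptation
    targets are translation-invariant and stay bit-identical."""
    t = rng.uniform(-translation_range, translation_range, size=3)
    return SimulationSample(
        reference=sample.reference + t, pressure=sample.pressure,
        material=sample.material, displacement=sample.displacement,
        coaptation_area=sample.coaptation_area, design_params=sample.design_params)


# ---------------------------------------------------------------------------
# the network


class _Encoder:
    """Conv stack + dense to the per-leaflet embedding."""

    def __init__(self, cfg: SurrogateConfig, rng: np.random.Generator):
        m, n = cfg.grid
        layers = []
        c_prev = 3
        for c in cfg.conv_channels:
            layers += [Conv2D(c_prev, c, cfg.kernel, rng), ReLU()]
            c_prev = c
        self.conv = Sequential(*layers)
        self.flat_dim = m * n * c_prev
        self.embed = Dense(self.flat_dim, cfg.embedding_size, rng)
        self.embed_act = ReLU()

    def params(self):
        return self.conv.params() + self.embed.params()

    def grads(self):
        return self.conv.grads() + self.embed.grads()

    def forward(self, x):
        h = self.conv.forward(x)
        self._conv_shape = h.shape
        return self.embed_act.forward(self.embed.forward(h.reshape(len(h), -1)))

    def backward(self, dy):
        dh = self.embed.backward(self.embed_act.backward(dy))
        return self.conv.backward(dh.reshape(self._conv_shape))


class ClosureSurrogate:
    """The trained (or initializable) surrogate network."""

    def __init__(self, config: SurrogateConfig,
                 standardizer: Standardizer | None = None):
        self.config = config
        self.standardizer = standardizer or Standardizer()
        rng = np.random.default_rng(config.seed)
        cfg = config
        m, n = cfg.grid
        n_enc = 1 if cfg.share_encoder else 3
        self.encoders = [_Encoder(cfg, rng) for _ in range(n_enc)]
        fusion_in = 3 * cfg.embedding_size + 4 + cfg.pressure_repeat
        self.fusion = Dense(fusion_in, cfg.code_size, rng)
        self.fusion_act = ReLU()
        dec_c = tuple(reversed(cfg.conv_channels))
        self.dec_flat = m * n * dec_c[0]
        self.dec_dense = [Dense(cfg.code_size, self.dec_flat, rng) for _ in range(3)]
        self.dec_dense_act = [ReLU() for _ in range(3)]
        layers = []
        c_prev = dec_c[0]
        for c in dec_c[1:]:
            layers += [Conv2D(c_prev, c, cfg.kernel, rng), ReLU()]
            c_prev = c
        layers += [Conv2D(c_prev, 3, cfg.kernel, rng)]  # linear output
        self.dec_conv = Sequential(*layers)
        self.head1 = Dense(cfg.code_size, cfg.head_hidden, rng)
        self.head_act = ReLU()
        self.head2 = Dense(cfg.head_hidden, 1, rng)
        self.head_out = ReLU()  # coaptation area is non-negative
        # The head predicts the *standardized* area; the output map
        # ReLU(mean + std * z) restores cm^2 and non-negativity.  This keeps
        # head gradients O(1) regardless of the raw area scale (a raw-scale
        # ReLU output is easily knocked permanently negative early in
        # training) and starts alive at the mean training area.
        # The essential boundary conditions are imposed strongly on the
        # decoder output: attachment-edge entries (grid edges i=0, i=m-1,
        # j=0 — the fixed mask shared by every valve in the schema) are
        # zeroed.  They carry zero BC-loss weight anyway, so this constrains
        # nothing the loss ever sees.
        if cfg.enforce_fixed_boundary:
            mask = np.ones((m, n))
            mask[0, :] = mask[-1, :] = 0.0
            mask[:, 0] = 0.0
            self._bc_mask = mask[None, None, :, :, None]
        else:
            self._bc_mask = None

    # -- parameter plumbing

    def _modules(self):
        return (self.encoders + [self.fusion] + self.dec_dense
                + [self.dec_conv, self.head1, self.head2])

    def params(self) -> list[np.ndarray]:
        return [p for mod in self._modules() for p in mod.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for mod in self._modules() for g in mod.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    # -- forward / backward

    def forward(self, textures: np.ndarray, material_std: np.ndarray,
                pressure_vec: np.ndarray) -> PredictionBundle:
        """Batch forward pass.

        textures: (N, 3, m, n, 3) raw cm; material_std: (N, 4) standardized;
        pressure_vec: (N, 10) standardized.
        """
        cfg = self.config
        N = len(textures)
        m, n = cfg.grid
        if textures.shape[1:] != (3, m, n, 3):
            raise ValueError(f"texture batch shape {textures.shape} does not match config")
        if cfg.share_encoder:
            emb = self.encoders[0].forward(textures.reshape(N * 3, m, n, 3))
            emb = emb.reshape(N, 3 * cfg.embedding_size)
        else:
            emb = np.concatenate(
                [self.encoders[k].forward(textures[:, k]) for k in range(3)], axis=1)
        fusion_in = np.concatenate([emb, material_std, pressure_vec], axis=1)
        self._emb_width = emb.shape[1]
        code = self.fusion_act.forward(self.fusion.forward(fusion_in))
        dec_stack = np.empty((N, 3, m, n, self.dec_flat // (m * n)))
        for k in range(3):
            hk = self.dec_dense_act[k].forward(self.dec_dense[k].forward(code))
            dec_stack[:, k] = hk.reshape(N, m, n, -1)
        u = self.dec_conv.forward(dec_stack.reshape(N * 3, m, n, -1))
        u = u.reshape(N, 3, m, n, 3)
        if self._bc_mask is not None:
            u = u * self._bc_mask
        h = self.head_act.forward(self.head1.forward(code))
        std = self.standardizer
        z = std.area_mean + std.area_std * self.head2.forward(h)
        area = self.head_out.forward(z)[:, 0]
        return PredictionBundle(u, area, code)

    def backward(self, d_u: np.ndarray, d_area: np.ndarray) -> None:
        """Backpropagate gradients of the loss wrt displacement (N,3,m,n,3)
        and coaptation (N,), accumulating parameter gradients."""
        cfg = self.config
        N = len(d_u)
        m, n = cfg.grid
        d_head = self.head_out.backward(d_area[:, None]) * self.standardizer.area_std
        d_code = self.head1.backward(self.head_act.backward(self.head2.backward(d_head)))
        if self._bc_mask is not None:
            d_u = d_u * self._bc_mask
        d_dec_stack = self.dec_conv.backward(d_u.reshape(N * 3, m, n, 3))
        d_dec_stack = d_dec_stack.reshape(N, 3, m, n, -1)
        for k in range(3):
            d_hk = d_dec_stack[:, k].reshape(N, -1)
            d_code = d_code + self.dec_dense[k].backward(
                self.dec_dense_act[k].backward(d_hk))
        d_fusion_in = self.fusion.backward(self.fusion_act.backward(d_code))
        d_emb = d_fusion_in[:, : self._emb_width]
        if cfg.share_encoder:
            self.encoders[0].backward(d_emb.reshape(N * 3, cfg.embedding_size))
        else:
            w = cfg.embedding_size
            for k in range(3):
                self.encoders[k].backward(d_emb[:, k * w:(k + 1) * w])

    def predict(self, dataset: ValveDataset, indices=None,
                batch_size: int = 256) -> PredictionBundle:
        """Inference over dataset rows (all rows when ``indices`` is None)."""
        idx = np.arange(len(dataset)) if indices is None else np.asarray(indices)
        outs_u, outs_a, outs_c = [], [], []
        for start in range(0, len(idx), batch_size):
            sel = idx[start:start + batch_size]
            tex = dataset.reference[sel]
            mat = self.standardizer.material(dataset.material[sel])
            press = self.standardizer.pressure_vector(dataset.pressure[sel],
                                                      self.config.pressure_repeat)
            bundle = self.forward(tex, mat, press)
            outs_u.append(bundle.displacement)
            outs_a.append(bundle.coaptation_area)
            outs_c.append(bundle.code)
        return PredictionBundle(np.concatenate(outs_u), np.concatenate(outs_a),
                                np.concatenate(outs_c))

    def extract_code(self, textures: np.ndarray, material_std: np.ndarray,
                     pressure_vec: np.ndarray) -> np.ndarray:
        """Code-layer (fusion bottleneck) activations, shape (N, code_size)."""
        return self.forward(textures, material_std, pressure_vec).code

    # -- persistence

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "standardizer": self.standardizer,
                         "weights": self.get_weights()}, fh)

    @classmethod
    def load(cls, path) -> "ClosureSurrogate":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["config"], blob["standardizer"])
        model.set_weights(blob["weights"])
        return model


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def _batch_loss_and_grad(model: ClosureSurrogate, u_pred, u_true, a_pred, a_true):
    """Mean-over-batch loss (sum over leaflets of BC-weighted MSE + lambda_c
    standardized coaptation term) and its gradients wrt the outputs.

    BC weights are nodal (vector-magnitude) and computed per sample and per
    leaflet, so one sample's large displacements never rescale another's."""
    cfg = model.config
    N, L = u_true.shape[:2]
    numel = u_true[0, 0].size
    mag = np.linalg.norm(u_true, axis=4, keepdims=True)
    peak = np.max(mag, axis=(2, 3, 4), keepdims=True)
    w = np.where(peak < cfg.tau, 1.0, mag / np.where(peak < cfg.tau, 1.0, peak))
    diff = u_pred - u_true
    def_loss = float(np.sum(w * diff * diff) / (numel * N))
    d_u = 2.0 * w * diff / (numel * N)
    scale = model.standardizer.area_std
    a_diff = (a_pred - a_true) / scale
    area_loss = float(cfg.lambda_c * np.mean(a_diff ** 2))
    d_area = 2.0 * cfg.lambda_c * a_diff / (scale * N)
    return def_loss + area_loss, d_u, d_area


def train(dataset: ValveDataset, train_idx, val_idx,
          config: SurrogateConfig | None = None,
          verbose: bool = False) -> tuple[ClosureSurrogate, TrainHistory]:
    """Minibatch Adam training with best-validation checkpoint selection.

    Fully seeded: initialization, shuffling and augmentation all derive from
    ``config.seed``.  Raises on divergence (non-finite loss).
    """
    cfg = config or SurrogateConfig(grid=dataset.grid)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation splits must be non-empty")
    std = Standardizer.fit(dataset.material[train_idx], dataset.pressure[train_idx],
                           dataset.coaptation[train_idx])
    model = ClosureSurrogate(cfg, std)
    history = TrainHistory()
    if cfg.epochs == 0:
        return model, history
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA5]))

    def eval_loss(idx):
        total, count = 0.0, 0
        for start in range(0, len(idx), 256):
            sel = idx[start:start + 256]
            tex = dataset.reference[sel]
            mat = std.material(dataset.material[sel])
            press = std.pressure_vector(dataset.pressure[sel], cfg.pressure_repeat)
            bundle = model.forward(tex, mat, press)
            loss, _, _ = _batch_loss_and_grad(
                model, bundle.displacement, dataset.displacement[sel],
                bundle.coaptation_area, dataset.coaptation[sel])
            total += loss * len(sel)
            count += len(sel)
        return total / count

    best_weights = model.get_weights()
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            tex = dataset.reference[sel].copy()
            if cfg.augment:
                hit = rng.random(len(sel)) < cfg.augment_prob
                shifts = rng.uniform(-cfg.augment_range, cfg.augment_range,
                                     size=(len(sel), 3))
                tex[hit] += shifts[hit][:, None, None, None, :]
            mat = std.material(dataset.material[sel])
            press = std.pressure_vector(dataset.pressure[sel], cfg.pressure_repeat)
            bundle = model.forward(tex, mat, press)
            loss, d_u, d_area = _batch_loss_and_grad(
                model, bundle.displacement, dataset.displacement[sel],
                bundle.coaptation_area, dataset.coaptation[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}")
            model.backward(d_u, d_area)
            opt.step(model.grads())
            epoch_loss += loss * len(sel)
            seen += len(sel)
        val_loss = eval_loss(val_idx)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val_loss)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_weights = model.get_weights()
        if verbose:
            print(f"epoch {epoch:3d}  train {history.train_loss[-1]:.5f}  "
                  f"val {val_loss:.5f}")
    model.set_weights(best_weights)
    return model, history
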