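"""Convolutional variational autoencoder for 3-channel fluorescence traces.

The encoder maps a ``(3, 750)`` trace through three strided 1-D convolutions
(channel progression 3→4→8→16, kernel 3, stride 2, padding 1, batch-normalised,
tanh activations), flattens the resulting ``16 × 94 = 1504`` features, passes a
1504→256 fully connected trunk and two 256→128→32 heads that output the
posterior mean ``mu`` and log-variance over a 32-dimensional diagonal-Gaussian
latent space. The decoder mirrors the encoder: 32→128→256→1504 fully connected
layers, a reshape to ``(B, 16, 94)``, and three transposed convolutions whose
output paddings are solved at construction so that the temporal length returns
exactly to 750. Final layers of the heads and of the decoder are linear.

Training minimises the negative ELBO with a unit-variance Gaussian decoder
likelihood: the reconstruction term is the sum of squared errors over channels
and time, and the regulariser is the closed-form KL of the posterior to the
standard-normal prior. Encoder inputs are perturbed with N(0, 0.01 I) noise
during training while reconstruction targets stay clean, a denoising scheme
that encourages robust representations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import DTYPE


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the trace VAE; defaults define the reference model."""

    input_channels: int = 3
    input_length: int = 750
    latent_dim: int = 32
    conv_channels: tuple[tuple[int, int], ...] = ((3, 4), (4, 8), (8, 16))
    kernel: int = 3
    stride: int = 2
    padding: int = 1
    trunk_width: int = 256
    head_hidden: int = 128

    def encoder_lengths(self) -> list[int]:
        """Temporal lengths at each encoder stage, input first."""
        lengths = [self.input_length]
        for _ in self.conv_channels:
            lengths.append(
                nn.conv_output_length(lengths[-1], self.kernel, self.stride, self.padding)
            )
        return lengths

    @property
    def flat_width(self) -> int:
        """Flattened feature width entering the fully connected trunk."""
        return self.conv_channels[-1][1] * self.encoder_lengths()[-1]

    @property
    def reshape_length(self) -> int:
        """Temporal length at the decoder reshape."""
        return self.encoder_lengths()[-1]

    def decoder_output_paddings(self) -> list[int]:
        """Output paddings that invert the encoder length sequence exactly."""
        lengths = self.encoder_lengths()
        targets = lengths[-2::-1]  # e.g. 94 -> [188, 375, 750]
        pads = []
        cur = lengths[-1]
        for tgt in targets:
            base = nn.conv_transpose_output_length(cur, self.kernel, self.stride, self.padding, 0)
            op = tgt - base
            if not 0 <= op < self.stride:
                raise ValueError(f"cannot restore length {tgt} from {cur}")
            pads.append(op)
            cur = tgt
        return pads

    def validate(self) -> None:
        if self.conv_channels[0][0] != self.input_channels:
            raise ValueError("first conv stage must accept the input channels")
        for (a, b), (c, _) in zip(self.conv_channels, self.conv_channels[1:]):
            if b != c:
                raise ValueError("conv channel chain is inconsistent")
        self.decoder_output_paddings()  # raises if lengths cannot be inverted


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    train_fraction: float = 0.8
    input_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs > 100:
            raise ValueError("epoch budget is capped at 100")


@dataclass
class LatentGaussian:
    """Diagonal-Gaussian posterior of one cell: mean and positive variances."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mu.shape != self.var.shape:
            raise ValueError("mu and var must have matching shapes")
        if np.any(self.var <= 0):
            raise ValueError("variances must be strictly positive")


@dataclass
class LatentTable:
    """Per-cell posterior parameters aligned with cell ids."""

    cell_ids: np.ndarray
    mu: np.ndarray  # (n, d)
    var: np.ndarray  # (n, d)

    def __len__(self) -> int:
        return len(self.cell_ids)

    def row(self, i: int) -> LatentGaussian:
        return LatentGaussian(self.mu[i], self.var[i])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        d = self.mu.shape[1]
        cols = {"cell_id": self.cell_ids}
        cols.update({f"mu_{i}": self.mu[:, i] for i in range(d)})
        cols.update({f"var_{i}": self.var[:, i] for i in range(d)})
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LatentTable":
        import pandas as pd

        df = pd.read_csv(path)
        d = sum(c.startswith("mu_") for c in df.columns)
        mu = df[[f"mu_{i}" for i in range(d)]].to_numpy()
        var = df[[f"var_{i}" for i in range(d)]].to_numpy()
        return cls(df["cell_id"].to_numpy(), mu, var)


class VAE:
    """Encoder/decoder pair with hand-rolled backpropagation."""

    def __init__(self, arch: ArchitectureSpec | None = None, seed: int = 0) -> None:
        self.arch = arch or ArchitectureSpec()
        self.arch.validate()
        rng = np.random.default_rng(seed)
        a = self.arch
        k, s, p = a.kernel, a.stride, a.padding

        conv_layers: list[nn.Layer] = []
        for c_in, c_out in a.conv_channels:
            conv_layers += [
                nn.Conv1d(c_in, c_out, rng, kernel=k, stride=s, padding=p),
                nn.BatchNorm1d(c_out),
                nn.Tanh(),
            ]
        self.enc_conv = nn.Sequential(*conv_layers)
        self.enc_trunk = nn.Sequential(nn.Linear(a.flat_width, a.trunk_width, rng), nn.Tanh())
        self.mu_head = nn.Sequential(
            nn.Linear(a.trunk_width, a.head_hidden, rng),
            nn.Tanh(),
            nn.Linear(a.head_hidden, a.latent_dim, rng),
        )
        self.logvar_head = nn.Sequential(
            nn.Linear(a.trunk_width, a.head_hidden, rng),
            nn.Tanh(),
            nn.Linear(a.head_hidden, a.latent_dim, rng),
        )
        self.dec_fc = nn.Sequential(
            nn.Linear(a.latent_dim, a.head_hidden, rng),
            nn.Tanh(),
            nn.Linear(a.head_hidden, a.trunk_width, rng),
            nn.Tanh(),
            nn.Linear(a.trunk_width, a.flat_width, rng),
            nn.Tanh(),
        )
        out_pads = a.decoder_output_paddings()
        dec_channels = [(b, c) for (c, b) in a.conv_channels[::-1]]  # (16,8),(8,4),(4,3)
        dec_layers: list[nn.Layer] = []
        for i, ((c_in, c_out), op) in enumerate(zip(dec_channels, out_pads)):
            dec_layers.append(
                nn.ConvTranspose1d(
                    c_in, c_out, rng, kernel=k, stride=s, padding=p, output_padding=op
                )
            )
            if i < len(dec_channels) - 1:  # final layer stays linear, no batchnorm
                dec_layers += [nn.BatchNorm1d(c_out), nn.Tanh()]
        self.dec_conv = nn.Sequential(*dec_layers)

        self._modules = [
            self.enc_conv,
            self.enc_trunk,
            self.mu_head,
            self.logvar_head,
            self.dec_fc,
            self.dec_conv,
        ]

    # ---- low-level passes -------------------------------------------------

    def parameters(self) -> list[tuple[nn.Layer, str]]:
        out: list[tuple[nn.Layer, str]] = []
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def zero_grad(self) -> None:
        for m in self._modules:
            m.zero_grad()

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        a = self.arch
        if x.ndim != 3 or x.shape[1] != a.input_channels or x.shape[2] != a.input_length:
            raise ValueError(
                f"expected input of shape (B, {a.input_channels}, {a.input_length}), "
                f"got {x.shape}"
            )
        return x

    def forward_encoder(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, np.ndarray]:
        h = self.enc_conv.forward(x, train=train)
        B = h.shape[0]
        h = h.reshape(B, -1)
        h = self.enc_trunk.forward(h, train=train)
        mu = self.mu_head.forward(h, train=train)
        logvar = self.logvar_head.forward(h, train=train)
        return mu, logvar

    def backward_encoder(self, dmu: np.ndarray, dlogvar: np.ndarray) -> None:
        dh = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        dh = self.enc_trunk.backward(dh)
        a = self.arch
        dh = dh.reshape(-1, a.conv_channels[-1][1], a.reshape_length)
        self.enc_conv.backward(dh)

    def forward_decoder(self, z: np.ndarray, train: bool) -> np.ndarray:
        a = self.arch
        h = self.dec_fc.forward(z.astype(DTYPE), train=train)
        h = h.reshape(-1, a.conv_channels[-1][1], a.reshape_length)
        return self.dec_conv.forward(h, train=train)

    def backward_decoder(self, dxhat: np.ndarray) -> np.ndarray:
        dh = self.dec_conv.backward(dxhat)
        dh = dh.reshape(dh.shape[0], -1)
        return self.dec_fc.backward(dh)

    # ---- public API -------------------------------------------------------

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior means and variances (evaluation mode). Returns (mu, var)."""
        x = self._check_input(x)
        mu, logvar = self.forward_encoder(x, train=False)
        return mu.astype(float), np.exp(logvar).astype(float)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode latent vectors to (B, channels, length) traces (eval mode)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.arch.latent_dim:
            raise ValueError(f"latent dimension must be {self.arch.latent_dim}")
        return self.forward_decoder(z, train=False).astype(float)

    # ---- checkpointing ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for mi, m in enumerate(self._modules):
            for li, layer in enumerate(m.layers):
                for k, v in layer.params.items():
                    state[f"{mi}.{li}.{k}"] = v
                if isinstance(layer, nn.BatchNorm1d):
                    state[f"{mi}.{li}.running_mean"] = layer.running_mean
                    state[f"{mi}.{li}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for mi, m in enumerate(self._modules):
            for li, layer in enumerate(m.layers):
                for k in layer.params:
                    layer.params[k] = np.asarray(state[f"{mi}.{li}.{k}"], dtype=DTYPE)
                layer.grads = {k: np.zeros_like(v) for k, v in layer.params.items()}
                if isinstance(layer, nn.BatchNorm1d):
                    layer.running_mean = np.asarray(
                        state[f"{mi}.{li}.running_mean"], dtype=DTYPE
                    )
                    layer.running_var = np.asarray(
                        state[f"{mi}.{li}.running_var"], dtype=DTYPE
                    )


def sample_latent(lg: LatentGaussian, rng: np.random.Generator) -> np.ndarray:
    """Reparameterised draw z = mu + sqrt(var) * eps, eps ~ N(0, I)."""
    eps = rng.standard_normal(lg.mu.shape)
    return lg.mu + np.sqrt(lg.var) * eps


def kl_to_prior(lg: LatentGaussian) -> float:
    """KL(q || N(0, I)) for a diagonal Gaussian q, in nats.

    Closed form: 0.5 * sum_i (var_i + mu_i^2 - 1 - ln var_i).
    """
    return float(0.5 * np.sum(lg.var + lg.mu**2 - 1.0 - np.log(lg.var)))


def elbo_loss(
    x: np.ndarray, x_hat: np.ndarray, lg: LatentGaussian
) -> tuple[float, float, float]:
    """Negative-ELBO components: (reconstruction SSE, KL, total)."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have the same shape")
    recon = float(np.sum((x - x_hat) ** 2))
    kl = kl_to_prior(lg)
    return recon, kl, recon + kl


@dataclass
class TrainedVAE:
    vae: VAE
    history: list[dict[str, float]] = field(default_factory=list)
    config: TrainConfig | None = None
    train_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        """Binary parameter blob (.npz) plus a JSON sidecar with the config."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.vae.state_arrays())
        sidecar = {
            "architecture": asdict(self.vae.arch),
            "train_config": asdict(self.config) if self.config else None,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedVAE":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        arch_kw = dict(sidecar["architecture"])
        arch_kw["conv_channels"] = tuple(tuple(p) for p in arch_kw["conv_channels"])
        vae = VAE(ArchitectureSpec(**arch_kw))
        with np.load(path.with_suffix(".npz")) as blob:
            vae.load_state_arrays(dict(blob))
        cfg = TrainConfig(**sidecar["train_config"]) if sidecar["train_config"] else None
        return cls(vae=vae, history=sidecar["history"], config=cfg)


def _epoch_losses(vae: VAE, X: np.ndarray, batch_size: int) -> tuple[float, float]:
    """Mean per-cell (recon, kl) on clean inputs, eval mode, z = mu."""
    n = len(X)
    recon_sum = kl_sum = 0.0
    for start in range(0, n, batch_size):
        xb = X[start : start + batch_size]
        mu, logvar = vae.forward_encoder(xb, train=False)
        var = np.exp(logvar)
        xhat = vae.forward_decoder(mu, train=False)
        recon_sum += float(np.sum((xb - xhat) ** 2))
        kl_sum += float(0.5 * np.sum(var + mu**2 - 1.0 - logvar))
    return recon_sum / n, kl_sum / n


def train(
    X: np.ndarray,
    arch: ArchitectureSpec | None = None,
    config: TrainConfig | None = None,
) -> TrainedVAE:
    """Train a VAE on traces ``X`` of shape (cells, channels, length).

    A seeded 80/20 train/validation split is drawn once. Each training batch's
    encoder input is perturbed with Gaussian noise of sd ``input_noise_sd``
    while the reconstruction target remains the clean trace. History records
    per-epoch mean train and validation loss components.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=DTYPE)
    if X.ndim != 3 or len(X) == 0:
        raise ValueError("X must be a non-empty (cells, channels, length) array")
    if len(X) < 2:
        raise ValueError("training requires at least 2 cells")

    vae = VAE(arch, seed=config.seed)
    vae._check_input(X[:1])
    rng = np.random.default_rng(config.seed)

    n = len(X)
    perm = rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    n_train = min(n_train, n - 1)
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    Xtr, Xval = X[train_idx], X[val_idx]

    batch_size = min(config.batch_size, len(Xtr))
    opt = nn.Adam(vae.parameters(), lr=config.learning_rate)
    history: list[dict[str, float]] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        tr_recon = tr_kl = 0.0
        for start in range(0, len(Xtr), batch_size):
            idx = order[start : start + batch_size]
            x_clean = Xtr[idx]
            B = len(x_clean)
            x_noisy = x_clean + rng.normal(
                0.0, config.input_noise_sd, size=x_clean.shape
            ).astype(DTYPE)

            vae.zero_grad()
            mu, logvar = vae.forward_encoder(x_noisy, train=True)
            var = np.exp(logvar)
            eps = rng.standard_normal(mu.shape).astype(DTYPE)
            z = mu + np.sqrt(var) * eps
            xhat = vae.forward_decoder(z, train=True)

            recon = float(np.sum((xhat - x_clean) ** 2))
            kl = float(0.5 * np.sum(var + mu**2 - 1.0 - logvar))
            tr_recon += recon
            tr_kl += kl

            dxhat = (2.0 / B) * (xhat - x_clean)
            dz = vae.backward_decoder(dxhat)
            dmu = dz + mu / B
            dlogvar = dz * (0.5 * np.sqrt(var) * eps) + 0.5 * (var - 1.0) / B
            vae.backward_encoder(dmu, dlogvar)
            opt.step()

        val_recon, val_kl = _epoch_losses(vae, Xval, batch_size)
        history.append(
            {
                "epoch": epoch + 1,
                "train_recon": tr_recon / len(Xtr),
                "train_kl": tr_kl / len(Xtr),
                "train_total": (tr_recon + tr_kl) / len(Xtr),
                "val_recon": val_recon,
                "val_kl": val_kl,
                "val_total": val_recon + val_kl,
            }
        )
    return TrainedVAE(
        vae=vae,
        history=history,
        config=config,
        train_indices=train_idx,
        val_indices=val_idx,
    )


def embed(vae: VAE, X: np.ndarray, cell_ids: np.ndarray | None = None) -> LatentTable:
    """Posterior parameters for every cell, evaluation mode, id-aligned."""
    X = np.asarray(X, dtype=DTYPE)
    mus, vars_ = [], []
    for start in range(0, len(X), 256):
        mu, var = vae.encode(X[start : start + 256])
        mus.append(mu)
        vars_.append(var)
    d = vae.arch.latent_dim
    mu = np.concatenate(mus) if mus else np.empty((0, d))
    var = np.concatenate(vars_) if vars_ else np.empty((0, d))
    if cell_ids is None:
        cell_ids = np.arange(len(X))
    return LatentTable(np.asarray(cell_ids), mu, var)
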