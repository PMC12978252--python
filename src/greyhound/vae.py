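"""Variational autoencoder over RBP expression profiles.

Compresses a D-dimensional RBP expression vector (log-TPM scale) into a
low-dimensional Gaussian latent code.  The encoder mean vector is the
cell-state representation consumed by the stability model; the decoder is
used only during pretraining.

Loss = MSE(x, x_hat) + beta * KL(q(z|x) || N(0, I)), with

    KL = -1/2 * sum_d (1 + logvar_d - mu_d^2 - exp(logvar_d))

and beta ramped linearly from 0 to its final value over the first half of
training so that reconstruction is learned before the prior is enforced.

Because the panel typically has only a handful of cell-line profiles, the
training set is augmented with Gaussian-jittered copies of each profile
(sigma = ``augment_sd_frac`` x per-feature SD), which makes fitting a
D -> hidden -> latent network on few profiles stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from greyhound import nn

__all__ = ["VAEConfig", "LatentCode", "RBPVAE", "VAEResults", "vae_loss", "kl_divergence"]


@dataclass
class VAEConfig:
    hidden_size: int = 500
    latent_size: int = 50
    epochs: int = 200
    learning_rate: float = 0.001
    #: final KL weight; None resolves to 1/D, the weight at which the summed
    #: KL is commensurate with the per-feature (mean) reconstruction error
    beta_max: float | None = None
    beta_ramp_frac: float = 0.5
    batch_size: int = 64
    augment_draws: int = 200
    augment_sd_frac: float = 0.05
    val_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_size < 1 or self.latent_size < 1:
            raise ValueError("layer sizes must be positive")
        if self.beta_max is not None and self.beta_max < 0:
            raise ValueError("beta_max must be non-negative")
        if not 0.0 <= self.beta_ramp_frac <= 1.0:
            raise ValueError("beta ramp fraction must be in [0,1]")

    def resolved_beta(self, dim: int) -> float:
        return 1.0 / dim if self.beta_max is None else self.beta_max

    def beta_at(self, epoch: int, dim: int) -> float:
        """Linear 0 -> final ramp over the first ``beta_ramp_frac`` of epochs."""
        ramp = max(1, int(np.ceil(self.epochs * self.beta_ramp_frac)))
        return self.resolved_beta(dim) * min(1.0, (epoch + 1) / ramp)


@dataclass
class LatentCode:
    """Posterior parameters and one reparameterised draw for a profile batch."""

    mu: np.ndarray
    logvar: np.ndarray
    sample: np.ndarray
    eta: np.ndarray  # the recorded standard-normal noise of the draw


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL(q || N(0,I)) summed over latent dims, mean over batch."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    per_sample = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    return float(per_sample.mean())


def vae_loss(
    x: np.ndarray, reconstruction: np.ndarray, mu: np.ndarray, logvar: np.ndarray, beta: float
) -> tuple[float, float, float]:
    """(total, mse, kl); mse averaged over features and batch."""
    x = np.atleast_2d(x)
    reconstruction = np.atleast_2d(reconstruction)
    if x.shape != reconstruction.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    mse = float(np.mean((x - reconstruction) ** 2))
    kl = kl_divergence(mu, logvar)
    return mse + beta * kl, mse, kl


class RBPVAE:
    """VAE over RBP expression profiles (statsmodels-style model object).

    Parameters
    ----------
    profiles : (n_samples, D) array — one RBP expression profile per row.
    rbp_ids : the D RBP identifiers, in column order.
    config : VAEConfig.
    """

    def __init__(self, profiles: np.ndarray, rbp_ids: list[str], config: VAEConfig | None = None):
        self.config = config or VAEConfig()
        self.config.validate()
        profiles = np.asarray(profiles, dtype=float)
        if profiles.ndim != 2:
            raise ValueError("profiles must be 2-D (n_samples, D)")
        if profiles.shape[0] < 2:
            raise ValueError("need at least 2 training profiles")
        if len(rbp_ids) != profiles.shape[1]:
            raise ValueError("rbp_ids length must match profile dimension")
        self.profiles = profiles
        self.rbp_ids = list(rbp_ids)
        self.dim = profiles.shape[1]
        # per-feature standardisation: the net trains on z-scored profiles
        self._x_mean = profiles.mean(axis=0)
        sd = profiles.std(axis=0, ddof=0)
        overall = profiles.std() or 1.0
        sd[sd == 0] = overall
        self._x_sd = sd
        self._build()

    @classmethod
    def from_dataframe(cls, rbp_matrix: pd.DataFrame, config: VAEConfig | None = None) -> "RBPVAE":
        """Build from an RBP x sample matrix (rows = RBPs, columns = samples)."""
        return cls(rbp_matrix.to_numpy(dtype=float).T, list(rbp_matrix.index), config)

    # -- architecture ------------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 10)))
        D, H, Z = self.dim, cfg.hidden_size, cfg.latent_size
        self.enc_hidden = nn.Dense(D, H, rng, "enc.hidden")
        self.enc_act = nn.LeakyReLU()
        self.enc_mu = nn.Dense(H, Z, rng, "enc.mu")
        self.enc_logvar = nn.Dense(H, Z, rng, "enc.logvar")
        self.dec = nn.Sequential(
            [nn.Dense(Z, H, rng, "dec.hidden"), nn.LeakyReLU(), nn.Dense(H, D, rng, "dec.out")]
        )
        self._rng = rng

    def encoder_params(self) -> list[nn.Param]:
        return self.enc_hidden.params() + self.enc_mu.params() + self.enc_logvar.params()

    def params(self) -> list[nn.Param]:
        return self.encoder_params() + self.dec.params()

    # -- forward passes ----------------------------------------------------

    def encode(self, profile: np.ndarray, eta: np.ndarray | None = None) -> LatentCode:
        """Posterior (mu, logvar) and a reparameterised sample.

        ``sample = mu + exp(logvar / 2) * eta`` with recorded eta; pass
        ``eta`` explicitly for a reproducible draw, otherwise the model's
        seeded generator is used.
        """
        x = np.atleast_2d(np.asarray(profile, dtype=float))
        if x.shape[1] != self.dim:
            raise ValueError(f"profile has dimension {x.shape[1]}, expected D={self.dim}")
        x = (x - self._x_mean) / self._x_sd
        h = self.enc_act.forward(self.enc_hidden.forward(x))
        mu = self.enc_mu.forward(h)
        logvar = self.enc_logvar.forward(h)
        if eta is None:
            eta = self._rng.standard_normal(mu.shape)
        sample = mu + np.exp(logvar / 2.0) * eta
        return LatentCode(mu=mu, logvar=logvar, sample=sample, eta=eta)

    def _forward_train(self, x: np.ndarray, rng: np.random.Generator):
        h_pre = self.enc_hidden.forward(x)
        h = self.enc_act.forward(h_pre)
        mu = self.enc_mu.forward(h)
        logvar = self.enc_logvar.forward(h)
        eta = rng.standard_normal(mu.shape)
        z = mu + np.exp(logvar / 2.0) * eta
        recon = self.dec.forward(z)
        return mu, logvar, eta, z, recon

    def _backward_train(self, x, mu, logvar, eta, recon, beta) -> None:
        n, D = x.shape
        Z = mu.shape[1]
        # reconstruction MSE head
        g_recon = 2.0 * (recon - x) / (n * D)
        g_z = self.dec.backward(g_recon)
        # z = mu + exp(logvar/2) * eta
        g_mu = g_z.copy()
        g_logvar = g_z * eta * 0.5 * np.exp(logvar / 2.0)
        # KL head (mean over batch)
        g_mu += beta * mu / n
        g_logvar += beta * 0.5 * (np.exp(logvar) - 1.0) / n
        g_h = self.enc_mu.backward(g_mu) + self.enc_logvar.backward(g_logvar)
        self.enc_hidden.backward(self.enc_act.backward(g_h))

    def reconstruct(self, profiles: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the mu path, original scale."""
        code = self.encode(profiles, eta=np.zeros((np.atleast_2d(profiles).shape[0], self.config.latent_size)))
        return self.dec.forward(code.mu) * self._x_sd + self._x_mean

    # -- training ----------------------------------------------------------

    def fit(self, verbose: bool = False) -> "VAEResults":
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
        X = (self._augmented(rng) - self._x_mean) / self._x_sd
        n_val = max(1, int(round(cfg.val_frac * X.shape[0])))
        perm = rng.permutation(X.shape[0])
        X_val, X_train = X[perm[:n_val]], X[perm[n_val:]]

        params = self.params()
        opt = nn.Adam(params, lr=cfg.learning_rate)
        history = []
        best = None
        beta_final = cfg.resolved_beta(self.dim)
        for epoch in range(cfg.epochs):
            beta = cfg.beta_at(epoch, self.dim)
            order = rng.permutation(X_train.shape[0])
            ep_loss = 0.0
            n_batches = 0
            for i in range(0, len(order), cfg.batch_size):
                xb = X_train[order[i : i + cfg.batch_size]]
                mu, logvar, eta, _z, recon = self._forward_train(xb, rng)
                total, _mse, _kl = vae_loss(xb, recon, mu, logvar, beta)
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"non-finite VAE loss at epoch {epoch}: total={total}"
                    )
                opt.zero_grad()
                self._backward_train(xb, mu, logvar, eta, recon, beta)
                opt.step()
                ep_loss += total
                n_batches += 1
            # validation at the final beta so epochs are comparable
            h_v = self.enc_act.forward(self.enc_hidden.forward(X_val))
            mu_v, logvar_v = self.enc_mu.forward(h_v), self.enc_logvar.forward(h_v)
            recon_v = self.dec.forward(mu_v)
            val_total, val_mse, val_kl = vae_loss(X_val, recon_v, mu_v, logvar_v, beta_final)
            history.append(
                {
                    "epoch": epoch,
                    "beta": beta,
                    "train_loss": ep_loss / max(1, n_batches),
                    "val_total": val_total,
                    "val_mse": val_mse,
                    "val_kl": val_kl,
                }
            )
            if best is None or val_total < best[0]:
                best = (val_total, nn.snapshot_params(params), epoch)
            if verbose:
                print(f"epoch {epoch}: beta={beta:.3f} val={val_total:.5f}")
        nn.restore_params(params, best[1])
        return VAEResults(
            model=self,
            history=pd.DataFrame(history),
            best_epoch=best[2],
            best_val_loss=best[0],
        )

    def _augmented(self, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        sd = self.profiles.std(axis=0, ddof=0)
        sd[sd == 0] = self.profiles.std() or 1.0
        draws = [self.profiles]
        for _ in range(cfg.augment_draws):
            draws.append(self.profiles + rng.normal(0.0, cfg.augment_sd_frac * sd, self.profiles.shape))
        return np.vstack(draws)


@dataclass
class VAEResults:
    """Trained VAE plus its training history and selection diagnostics."""

    model: RBPVAE
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float

    def encode(self, profile: np.ndarray, eta: np.ndarray | None = None) -> LatentCode:
        return self.model.encode(profile, eta=eta)

    def reconstruction_quality(self, profiles: np.ndarray | pd.DataFrame) -> float:
        """Pearson r between inputs and mu-path reconstructions, flattened."""
        if isinstance(profiles, pd.DataFrame):
            profiles = profiles.to_numpy(dtype=float).T
        profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
        recon = self.model.reconstruct(profiles)
        x, y = profiles.ravel(), recon.ravel()
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    def plot_history(self, ax=None):
        """Training vs validation loss over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        ax.plot(self.history["epoch"], self.history["val_total"], label="validation")
        ax.axvline(self.best_epoch, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "RBP expression VAE",
            "=" * 40,
            f"input dimension D:   {self.model.dim}",
            f"hidden size:         {cfg.hidden_size}",
            f"latent size:         {cfg.latent_size}",
            f"epochs:              {cfg.epochs} (best: {self.best_epoch})",
            f"best val loss:       {self.best_val_loss:.6f}",
            f"training profiles:   {self.model.profiles.shape[0]}"
            f" (+{cfg.augment_draws} jitter draws each)",
            f"beta:                0 -> {cfg.resolved_beta(self.model.dim):.4g}"
            f" over first {cfg.beta_ramp_frac:.0%}",
            f"seed:                {cfg.seed}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Single-file .npz with weights, config and the RBP id list."""
        import json

        arrays = {"x_mean": self.model._x_mean, "x_sd": self.model._x_sd}
        for i, p in enumerate(self.model.params()):
            arrays[f"param_{i}_{p.name}"] = p.value
        arrays["config_json"] = np.frombuffer(
            json.dumps({"config": asdict(self.model.config), "rbp_ids": self.model.rbp_ids}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "VAEResults":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["config_json"].tobytes()).decode())
        cfg = VAEConfig(**meta["config"])
        rbp_ids = meta["rbp_ids"]
        model = RBPVAE(np.zeros((2, len(rbp_ids))), rbp_ids, cfg)
        model._x_mean = data["x_mean"]
        model._x_sd = data["x_sd"]
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}_{p.name}"]
        return cls(model=model, history=pd.DataFrame(), best_epoch=-1, best_val_loss=float("nan"))
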