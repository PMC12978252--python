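"""Hybrid sequence + cell-state model of mRNA decay.

Maps (one-hot transcript sequence, RBP expression profile) to a predicted
log decay rate.  The sequence head is a CNN — two conv blocks
(conv -> leaky ReLU -> batch norm -> max pool -> dropout) followed by three
residual parallel dilated convolutions (dilations 1, 2, 4, branch outputs
summed with the block input).  The cell-state head is the encoder of a
pretrained RBP expression VAE; its mean (mu) vector is concatenated with
the flattened sequence features and passed through a fully connected
integration network to a scalar.

Training follows a two-stage protocol: stage 1 trains everything except the
transferred VAE encoder (frozen); stage 2 fine-tunes all parameters.  The
loss is MSE on (train-split z-scored) log decay, optimised by Adam with
global-norm gradient clipping; the snapshot with the best validation
Pearson correlation is returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from greyhound import nn
from greyhound.slam import DecayMatrix
from greyhound.vae import VAEResults, RBPVAE

__all__ = [
    "OneHotSequence",
    "ModelConfig",
    "InstanceSet",
    "one_hot_encode",
    "build_instances",
    "GreyHound",
    "GreyHoundResults",
]

_CHANNEL = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass
class OneHotSequence:
    """4 x max_length one-hot matrix (channels A, C, G, T) with padding mask."""

    matrix: np.ndarray
    length: int

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.matrix.shape[1], dtype=bool)
        m[: self.length] = True
        return m


def one_hot_encode(sequence: str, max_length: int) -> OneHotSequence:
    """One-hot encode a DNA/RNA string, right-padded with zero columns.

    U is treated as T; ambiguous IUPAC letters become all-zero columns;
    anything else raises.  Sequences longer than ``max_length`` raise
    ValueError (callers exclude such transcripts rather than truncate).
    """
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    if L > max_length:
        raise ValueError(f"sequence length {L} exceeds max_length {max_length}")
    mat = np.zeros((4, max_length))
    for i, base in enumerate(seq):
        if base not in _IUPAC:
            raise ValueError(f"illegal character {base!r} at position {i}")
        ch = _CHANNEL.get(base)
        if ch is not None:
            mat[ch, i] = 1.0
    return OneHotSequence(matrix=mat, length=L)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``conv_blocks`` entries are (filters, kernel, pool, dropout); the
    dilated stage uses dilations (1, 2, 4) with branch outputs summed
    residually onto the block input (1x1 projection when channel counts
    differ).  Default sizes are block1 128/12/4/0.2, block2 64/6/4/0.2, dilated 64x5.
    """

    max_length: int = 4096
    min_length: int = 512
    conv_blocks: tuple = ((128, 12, 4, 0.2), (64, 6, 4, 0.2))
    dilated_filters: int = 64
    dilated_kernel: int = 5
    dilations: tuple = (1, 2, 4)
    integration: tuple = (64,)
    latent_size: int = 50
    learning_rate: float = 0.001
    batch_size: int = 32
    stage1_epochs: int = 10
    stage2_epochs: int = 5
    grad_clip_norm: float = 5.0
    standardize_targets: bool = True
    #: "float64" (default; exact gradient checks) or "float32" (faster
    #: training at large problem sizes)
    dtype: str = "float64"
    seed: int = 0

    def validate(self) -> None:
        if tuple(sorted(self.dilations)) != (1, 2, 4):
            raise ValueError("dilations must be exactly (1, 2, 4)")
        if self.stage1_epochs < 0 or self.stage2_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


@dataclass
class InstanceSet:
    """Gene x cell instances with their split labels.

    ``X`` holds one one-hot matrix per *gene* (genes x 4 x max_length);
    each instance references a gene row and a cell profile, so the encoding
    of a sequence is shared across the cells it pairs with.
    """

    genes: list[str]
    cells: list[str]
    X: np.ndarray  # (n_genes, 4, max_length)
    lengths: np.ndarray  # (n_genes,)
    profiles: np.ndarray  # (n_cells, D)
    rbp_ids: list[str]
    gene_idx: np.ndarray  # (n_instances,)
    cell_idx: np.ndarray  # (n_instances,)
    y: np.ndarray  # (n_instances,)
    split: np.ndarray  # (n_instances,) of {"train","val","test"}
    excluded: dict = field(default_factory=dict)

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)

    def __len__(self) -> int:
        return len(self.y)


def _assign_splits(n: int, fractions, rng: np.random.Generator) -> np.ndarray:
    f_train, f_val, _f_test = fractions
    order = rng.permutation(n)
    n_train = int(round(f_train * n))
    n_val = int(round(f_val * n))
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train : n_train + n_val]] = "val"
    labels[order[n_train + n_val :]] = "test"
    return labels.astype("U5")


def build_instances(
    sequences: dict[str, str],
    decay: DecayMatrix | pd.DataFrame,
    rbp_matrix: pd.DataFrame,
    split_fractions: tuple[float, float, float] = (0.80, 0.05, 0.15),
    seed: int = 0,
    mode: str = "random",
    max_length: int = 4096,
    min_length: int = 512,
    min_cells: int = 1,
) -> InstanceSet:
    """Assemble (sequence, profile) -> decay instances and split them.

    Masked decay entries are skipped; transcripts outside
    [min_length, max_length] are excluded (recorded in ``excluded``), as
    are genes with fewer than ``min_cells`` unmasked cell-line values.
    ``mode`` is "random" (instance-level split), "gene_holdout"
    (gene-disjoint splits), or "loo:<cell>" (that cell line is the test
    set; remaining instances are split train/val).
    """
    if abs(sum(split_fractions) - 1.0) > 1e-8:
        raise ValueError("split fractions must sum to 1")
    if isinstance(decay, DecayMatrix):
        values, mask = decay.values, decay.mask
    else:
        values, mask = decay, decay.isna()
    cells = [c for c in values.columns if c in rbp_matrix.columns]
    if not cells:
        raise ValueError("no shared cells between decay matrix and RBP matrix")

    excluded: dict[str, str] = {}
    kept_genes: list[str] = []
    for g in values.index:
        if g not in sequences:
            excluded[g] = "no sequence"
            continue
        L = len(sequences[g])
        if not (min_length <= L <= max_length):
            excluded[g] = f"length {L} outside [{min_length}, {max_length}]"
            continue
        if int((~mask.loc[g, cells]).sum()) < min_cells:
            excluded[g] = f"fewer than {min_cells} cell-line estimates"
            continue
        kept_genes.append(g)
    if not kept_genes:
        raise ValueError("no usable gene remains after filtering")

    X = np.zeros((len(kept_genes), 4, max_length))
    lengths = np.zeros(len(kept_genes), dtype=int)
    for i, g in enumerate(kept_genes):
        oh = one_hot_encode(sequences[g], max_length)
        X[i] = oh.matrix
        lengths[i] = oh.length

    gi, ci, y = [], [], []
    for i, g in enumerate(kept_genes):
        for j, c in enumerate(cells):
            if not mask.loc[g, c]:
                gi.append(i)
                ci.append(j)
                y.append(float(values.loc[g, c]))
    gi = np.array(gi, dtype=int)
    ci = np.array(ci, dtype=int)
    y = np.array(y, dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 20)))
    if mode == "random":
        split = _assign_splits(len(y), split_fractions, rng)
    elif mode == "gene_holdout":
        gene_labels = _assign_splits(len(kept_genes), split_fractions, rng)
        split = gene_labels[gi]
    elif mode.startswith("loo:"):
        held = mode.split(":", 1)[1]
        if held not in cells:
            raise ValueError(f"unknown held-out cell {held!r}")
        j = cells.index(held)
        split = np.empty(len(y), dtype="U5")
        is_test = ci == j
        split[is_test] = "test"
        rest = np.flatnonzero(~is_test)
        f_train, f_val, _ = split_fractions
        frac_val = f_val / (f_train + f_val)
        inner = _assign_splits(len(rest), (1.0 - frac_val, frac_val, 0.0), rng)
        split[rest] = inner
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    profiles = rbp_matrix[cells].to_numpy(dtype=float).T
    return InstanceSet(
        genes=kept_genes,
        cells=cells,
        X=X,
        lengths=lengths,
        profiles=profiles,
        rbp_ids=list(rbp_matrix.index),
        gene_idx=gi,
        cell_idx=ci,
        y=y,
        split=split,
        excluded=excluded,
    )


class _ResidualDilated(nn.Layer):
    """Three parallel dilated convolutions summed residually with the input."""

    def __init__(self, c_in, c_out, kernel, dilations, rng):
        self.branches = [
            nn.Conv1d(c_in, c_out, kernel, rng, dilation=d, name=f"dil{d}") for d in dilations
        ]
        self.project = None
        if c_in != c_out:
            self.project = nn.Conv1d(c_in, c_out, 1, rng, name="proj")

    def params(self):
        out = []
        for b in self.branches:
            out.extend(b.params())
        if self.project is not None:
            out.extend(self.project.params())
        return out

    def forward(self, x, train=False):
        skip = x if self.project is None else self.project.forward(x, train)
        out = skip.copy()
        for b in self.branches:
            out += b.forward(x, train)
        return out

    def backward(self, grad_out):
        gx = grad_out if self.project is None else self.project.backward(grad_out)
        gx = gx.copy()
        for b in self.branches:
            gx += b.backward(grad_out)
        return gx


class GreyHound:
    """The hybrid decay-rate predictor (model object; ``fit`` returns results).

    Parameters
    ----------
    instances : InstanceSet from :func:`build_instances`.
    vae : trained RBP VAE (``VAEResults``) or a bare ``RBPVAE``; its encoder
        and mu head are transferred (copied) into this model.
    config : ModelConfig.
    """

    def __init__(self, instances: InstanceSet, vae: VAEResults | RBPVAE, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.config.validate()
        self.instances = instances
        vae_model = vae.model if isinstance(vae, VAEResults) else vae
        if vae_model.dim != instances.profiles.shape[1]:
            raise ValueError(
                f"VAE expects D={vae_model.dim}, instances carry D={instances.profiles.shape[1]}"
            )
        if vae_model.config.latent_size != self.config.latent_size:
            raise ValueError("latent_size mismatch between VAE and model config")
        self._source_vae = vae_model
        self._build(vae_model)

    # -- architecture ------------------------------------------------------

    def _build(self, vae_model: RBPVAE) -> None:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 30)))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 31)))
        layers: list[nn.Layer] = []
        c_prev = 4
        L = cfg.max_length
        for filters, kernel, pool, dropout in cfg.conv_blocks:
            layers += [
                nn.Conv1d(c_prev, filters, kernel, rng),
                nn.LeakyReLU(),
                nn.BatchNorm1d(filters),
                nn.MaxPool1d(pool),
                nn.Dropout(dropout, self._dropout_rng),
            ]
            c_prev = filters
            L //= pool
        layers.append(_ResidualDilated(c_prev, cfg.dilated_filters, cfg.dilated_kernel, cfg.dilations, rng))
        layers.append(nn.LeakyReLU())
        layers.append(nn.Flatten())
        self.seq_trunk = nn.Sequential(layers)
        self.seq_feature_dim = cfg.dilated_filters * L

        # transferred encoder (copied so the source VAE is never mutated)
        self.enc_hidden = copy.deepcopy(vae_model.enc_hidden)
        self.enc_act = nn.LeakyReLU()
        self.enc_mu = copy.deepcopy(vae_model.enc_mu)

        widths = list(cfg.integration) + [1]
        mlp: list[nn.Layer] = []
        d_prev = self.seq_feature_dim + cfg.latent_size
        for i, w in enumerate(widths):
            mlp.append(nn.Dense(d_prev, w, rng, f"integ{i}"))
            if i < len(widths) - 1:
                mlp.append(nn.LeakyReLU())
            d_prev = w
        self.integration = nn.Sequential(mlp)

        self._y_mean, self._y_sd = 0.0, 1.0
        if cfg.dtype == "float32":
            for p in self.params():
                p.value = p.value.astype(np.float32)
                p.grad = p.grad.astype(np.float32)
            for bn in self._bn_layers():
                bn.running_mean = bn.running_mean.astype(np.float32)
                bn.running_var = bn.running_var.astype(np.float32)
            self.instances.X = self.instances.X.astype(np.float32)
            self.instances.profiles = self.instances.profiles.astype(np.float32)

    def encoder_params(self) -> list[nn.Param]:
        return self.enc_hidden.params() + self.enc_mu.params()

    def params(self) -> list[nn.Param]:
        return self.seq_trunk.params() + self.encoder_params() + self.integration.params()

    def _bn_layers(self) -> list[nn.BatchNorm1d]:
        return [l for l in self.seq_trunk.layers if isinstance(l, nn.BatchNorm1d)]

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray, P: np.ndarray, train: bool = False) -> np.ndarray:
        """Predictions (standardised scale) for a batch.

        X: (N, 4, L) one-hot sequences; P: (N, D) RBP profiles.
        Deterministic when ``train`` is False (dropout off, batch norm on
        running statistics).
        """
        feats = self.seq_trunk.forward(X, train=train)
        h = self.enc_act.forward(self.enc_hidden.forward(P, train=train))
        mu = self.enc_mu.forward(h, train=train)
        z = np.concatenate([feats, mu], axis=1)
        out = self.integration.forward(z, train=train)
        self._last_split = feats.shape[1]
        return out[:, 0]

    def backward(self, grad_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backprop through the last forward; returns (dX, dP)."""
        g = self.integration.backward(grad_pred[:, None])
        g_feats, g_mu = g[:, : self._last_split], g[:, self._last_split :]
        gX = self.seq_trunk.backward(g_feats)
        gP = self.enc_hidden.backward(self.enc_act.backward(self.enc_mu.backward(g_mu)))
        return gX, gP

    def predict(self, X: np.ndarray, P: np.ndarray) -> np.ndarray:
        """Predicted log decay on the original (unstandardised) scale."""
        return self.forward(X, P, train=False) * self._y_sd + self._y_mean

    def _batch(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        inst = self.instances
        return inst.X[inst.gene_idx[idx]], inst.profiles[inst.cell_idx[idx]], inst.y[idx]

    # -- training ----------------------------------------------------------

    def fit(self, verbose: bool = False) -> "GreyHoundResults":
        cfg = self.config
        inst = self.instances
        train_idx = inst.indices("train")
        val_idx = inst.indices("val")
        if len(train_idx) == 0:
            raise ValueError("empty training split")
        use_final = False
        if len(val_idx) == 0:
            import warnings

            warnings.warn("empty validation split; returning final-epoch model")
            use_final = True

        if cfg.standardize_targets:
            self._y_mean = float(inst.y[train_idx].mean())
            self._y_sd = float(inst.y[train_idx].std() or 1.0)
        else:
            self._y_mean, self._y_sd = 0.0, 1.0

        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 32)))
        history: list[dict] = []
        grad_norms: list[tuple[float, float]] = []
        best: tuple | None = None

        stages = [
            (1, cfg.stage1_epochs, self.seq_trunk.params() + self.integration.params()),
            (2, cfg.stage2_epochs, self.params()),
        ]
        epoch_no = 0
        for stage, n_epochs, params in stages:
            if n_epochs == 0:
                continue
            opt = nn.Adam(params, lr=cfg.learning_rate)
            for _ in range(n_epochs):
                order = rng.permutation(train_idx)
                ep_loss, n_b = 0.0, 0
                for i in range(0, len(order), cfg.batch_size):
                    Xb, Pb, yb = self._batch(order[i : i + cfg.batch_size])
                    yb_std = (yb - self._y_mean) / self._y_sd
                    pred = self.forward(Xb, Pb, train=True)
                    loss = float(np.mean((pred - yb_std) ** 2))
                    if not np.isfinite(loss):
                        raise FloatingPointError(f"non-finite loss at epoch {epoch_no}")
                    opt.zero_grad()
                    self.backward((2.0 * (pred - yb_std) / len(yb)).astype(pred.dtype))
                    pre = nn.clip_global_norm(params, cfg.grad_clip_norm)
                    grad_norms.append((pre, nn.global_grad_norm(params)))
                    opt.step()
                    ep_loss += loss
                    n_b += 1
                val_r = self._pearson(val_idx) if len(val_idx) else float("nan")
                history.append(
                    {
                        "epoch": epoch_no,
                        "stage": stage,
                        "train_mse": ep_loss / max(1, n_b),
                        "val_pearson": val_r,
                    }
                )
                if verbose:
                    print(f"epoch {epoch_no} (stage {stage}): mse={ep_loss / max(1, n_b):.4f} val_r={val_r:.4f}")
                if not use_final and (best is None or val_r > best[0]):
                    best = (val_r, nn.snapshot_params(self.params()), self._bn_snapshot(), epoch_no)
                epoch_no += 1

        if best is not None:
            nn.restore_params(self.params(), best[1])
            self._bn_restore(best[2])
            best_epoch, best_val = best[3], best[0]
        else:
            best_epoch, best_val = epoch_no - 1, float("nan")

        return GreyHoundResults(
            model=self,
            history=pd.DataFrame(history),
            grad_norms=np.array(grad_norms),
            best_epoch=best_epoch,
            best_val_pearson=best_val,
        )

    def _bn_snapshot(self):
        return [(bn.running_mean.copy(), bn.running_var.copy()) for bn in self._bn_layers()]

    def _bn_restore(self, snap) -> None:
        for bn, (m, v) in zip(self._bn_layers(), snap):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def _pearson(self, idx: np.ndarray, chunk: int = 256) -> float:
        preds = []
        for i in range(0, len(idx), chunk):
            Xb, Pb, _ = self._batch(idx[i : i + chunk])
            preds.append(self.forward(Xb, Pb, train=False))
        pred = np.concatenate(preds)
        y = (self.instances.y[idx] - self._y_mean) / self._y_sd
        if np.std(pred) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(pred, y)[0, 1])


@dataclass
class GreyHoundResults:
    """Trained model with history, gradient-norm log and evaluation helpers."""

    model: GreyHound
    history: pd.DataFrame
    grad_norms: np.ndarray  # (steps, 2): pre-clip, post-clip global norms
    best_epoch: int
    best_val_pearson: float

    def predictions(self, split: str = "test", chunk: int = 256) -> pd.DataFrame:
        inst = self.model.instances
        idx = inst.indices(split) if split != "all" else np.arange(len(inst))
        rows = []
        for i in range(0, len(idx), chunk):
            sub = idx[i : i + chunk]
            Xb, Pb, yb = self.model._batch(sub)
            pred = self.model.predict(Xb, Pb)
            for j, k in enumerate(sub):
                rows.append(
                    (
                        inst.genes[inst.gene_idx[k]],
                        inst.cells[inst.cell_idx[k]],
                        yb[j],
                        pred[j],
                        inst.split[k],
                    )
                )
        return pd.DataFrame(rows, columns=["gene", "cell", "y_true", "y_pred", "split"])

    def evaluate(self, split: str = "test") -> dict:
        """Overall and per-cell-line Pearson r on a split."""
        table = self.predictions(split)
        if len(table) < 3:
            raise ValueError(f"need >= 3 instances in split {split!r}")
        r, _ = stats.pearsonr(table["y_true"], table["y_pred"])
        per_cell = {}
        for cell, sub in table.groupby("cell"):
            if len(sub) >= 3 and sub["y_true"].std() > 0 and sub["y_pred"].std() > 0:
                per_cell[cell], _ = stats.pearsonr(sub["y_true"], sub["y_pred"])
        return {"pearson": float(r), "per_cell": per_cell, "table": table}

    def plot_fit(self, split: str = "test", ax=None):
        """Scatter of measured vs predicted log decay for one split."""
        import matplotlib.pyplot as plt

        ev = self.evaluate(split)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        t = ev["table"]
        ax.scatter(t["y_true"], t["y_pred"], s=6, alpha=0.4, linewidths=0)
        lim = [min(t["y_true"].min(), t["y_pred"].min()),
               max(t["y_true"].max(), t["y_pred"].max())]
        ax.plot(lim, lim, color="grey", lw=0.8)
        ax.set_xlabel("measured log decay")
        ax.set_ylabel("predicted log decay")
        ax.set_title(f"{split}: r = {ev['pearson']:.3f}")
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        inst = self.model.instances
        ev = None
        try:
            ev = self.evaluate("test")
        except ValueError:
            pass
        lines = [
            "GreyHound decay-rate model",
            "=" * 40,
            f"instances:         {len(inst)} "
            f"(train {len(inst.indices('train'))} / val {len(inst.indices('val'))} / test {len(inst.indices('test'))})",
            f"genes x cells:     {len(inst.genes)} x {len(inst.cells)}",
            f"max length:        {cfg.max_length}",
            f"latent size:       {cfg.latent_size}",
            f"epochs:            {cfg.stage1_epochs} frozen + {cfg.stage2_epochs} fine-tune"
            f" (best: {self.best_epoch})",
            f"val Pearson:       {self.best_val_pearson:.4f}",
        ]
        if ev is not None:
            lines.append(f"test Pearson:      {ev['pearson']:.4f}")
        return "\n".join(lines)
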