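"""Minimal numpy feed-forward network with a locally connected genotype
layer, manual backpropagation, Adam, dropout, and early stopping.

Exists because the deliverable must train on one CPU with no deep-learning
framework available; gradients with respect to the *inputs* are exposed for
integrated-gradients attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class NetArch:
    """Architecture/optimization knobs for :class:`LocalNet`.

    ``lc_window`` counts one-hot variant groups per locally connected window
    (no weight sharing, non-overlapping); ``lc_units`` is the output width
    per window.
    """

    lc_window: int = 4
    lc_units: int = 4
    hidden: tuple[int, ...] = (128, 64)
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 400
    patience: int = 30
    weight_decay: float = 1e-5
    l1_lc: float = 1.0  # proximal L1 on the locally connected weights
    group_size: int = 4  # one-hot columns per variant


def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LocalNet:
    """Locally-connected-then-dense regressor on (genotype one-hot, covariate)
    inputs, trained by Adam on mean-squared error with early stopping."""

    def __init__(self, n_geno_cols: int, n_cov: int, arch: NetArch, seed: int = 0):
        if n_geno_cols % arch.group_size != 0:
            raise ValueError("genotype columns must be a multiple of group_size")
        self.arch = arch
        self.n_geno_cols = n_geno_cols
        self.n_cov = n_cov
        n_groups = n_geno_cols // arch.group_size
        w = arch.lc_window
        self.n_windows = (n_groups + w - 1) // w
        self.win_in = w * arch.group_size
        self.pad_cols = self.n_windows * self.win_in - n_geno_cols

        rng = np.random.default_rng(seed)
        u = arch.lc_units
        # He-style init per layer
        self.W_lc = rng.normal(
            0, np.sqrt(2.0 / self.win_in), size=(self.n_windows, self.win_in, u)
        )
        self.b_lc = np.zeros((self.n_windows, u))
        dims = [self.n_windows * u + n_cov, *arch.hidden, 1]
        self.W = [
            rng.normal(0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._rng = rng

    # -- plumbing ----------------------------------------------------------

    def _params(self):
        return [self.W_lc, self.b_lc, *self.W, *self.b]

    def _pad(self, Xg: np.ndarray) -> np.ndarray:
        if self.pad_cols:
            Xg = np.hstack([Xg, np.zeros((Xg.shape[0], self.pad_cols))])
        return Xg.reshape(Xg.shape[0], self.n_windows, self.win_in)

    # -- forward / backward ------------------------------------------------

    def _forward(self, Xg, Xc, dropout_rng=None):
        cache = {}
        Xw = self._pad(Xg)
        z_lc = np.einsum("nkw,kwu->nku", Xw, self.W_lc) + self.b_lc
        a_lc = _elu(z_lc)
        h = a_lc.reshape(Xg.shape[0], -1)
        if self.n_cov:
            h = np.hstack([h, Xc])
        cache["Xw"], cache["z_lc"], cache["h0"] = Xw, z_lc, h

        acts, zs, masks = [h], [], []
        a = h
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = a @ self.W[i] + self.b[i]
            a = _elu(z)
            if dropout_rng is not None and self.arch.dropout > 0:
                mask = (dropout_rng.random(a.shape) >= self.arch.dropout) / (
                    1 - self.arch.dropout
                )
                a = a * mask
            else:
                mask = None
            zs.append(z)
            masks.append(mask)
            acts.append(a)
        out = (a @ self.W[-1] + self.b[-1]).ravel()
        cache["zs"], cache["masks"], cache["acts"], cache["out"] = zs, masks, acts, out
        return out, cache

    def _backward(self, cache, d_out, want_input_grad=False):
        """Backprop d_out (n,) through the net; returns (param_grads, dXg, dXc)."""
        n = d_out.shape[0]
        acts, zs, masks = cache["acts"], cache["zs"], cache["masks"]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)

        delta = d_out[:, None]  # (n, 1)
        gW[-1] = acts[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            if masks[i] is not None:
                da = da * masks[i]
            dz = da * _elu_grad(zs[i])
            gW[i] = acts[i].T @ dz
            gb[i] = dz.sum(axis=0)
            da = dz @ self.W[i].T

        # split into LC output part and covariate part
        lc_width = self.n_windows * self.arch.lc_units
        d_h = da[:, :lc_width].reshape(n, self.n_windows, self.arch.lc_units)
        dXc = da[:, lc_width:] if self.n_cov else np.zeros((n, 0))
        dz_lc = d_h * _elu_grad(cache["z_lc"])
        gW_lc = np.einsum("nkw,nku->kwu", cache["Xw"], dz_lc)
        gb_lc = dz_lc.sum(axis=0)

        dXg = None
        if want_input_grad:
            dXw = np.einsum("nku,kwu->nkw", dz_lc, self.W_lc)
            dXg = dXw.reshape(n, -1)
            if self.pad_cols:
                dXg = dXg[:, : self.n_geno_cols]
        return [gW_lc, gb_lc, *gW, *gb], dXg, dXc

    # -- public API --------------------------------------------------------

    def predict(self, Xg: np.ndarray, Xc: np.ndarray) -> np.ndarray:
        out, _ = self._forward(Xg, Xc)
        return out

    def input_gradient(self, Xg: np.ndarray, Xc: np.ndarray):
        """Gradient of the scalar output w.r.t. each input column, per sample."""
        out, cache = self._forward(Xg, Xc)
        _, dXg, dXc = self._backward(cache, np.ones_like(out), want_input_grad=True)
        return dXg, dXc

    def fit(
        self,
        Xg_train,
        Xc_train,
        y_train,
        Xg_val,
        Xc_val,
        y_val,
        seed: int = 0,
        verbose: bool = False,
    ) -> dict:
        arch = self.arch
        rng = np.random.default_rng(seed)
        params = self._params()
        opt = _Adam([p.shape for p in params], arch.lr)
        n = len(y_train)
        best_loss = np.inf
        best_state = [p.copy() for p in params]
        bad_checks = 0
        history = []

        if arch.max_epochs == 0:
            return {"epochs": 0, "val_loss": float(np.mean((self.predict(Xg_val, Xc_val) - y_val) ** 2)), "history": []}

        for epoch in range(arch.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, arch.batch_size):
                idx = order[start : start + arch.batch_size]
                out, cache = self._forward(
                    Xg_train[idx], Xc_train[idx], dropout_rng=rng
                )
                err = out - y_train[idx]
                if not np.isfinite(err).all():
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "try a lower learning rate"
                    )
                d_out = 2.0 * err / len(idx)
                grads, _, _ = self._backward(cache, d_out)
                if arch.weight_decay:
                    for g, p in zip(grads, params):
                        g += arch.weight_decay * p
                opt.step(params, grads)
                if arch.l1_lc:
                    # proximal soft-threshold keeps unused genotype windows sparse
                    thr = opt.lr * arch.l1_lc
                    self.W_lc[...] = np.sign(self.W_lc) * np.maximum(
                        np.abs(self.W_lc) - thr, 0.0
                    )

            val_pred = self.predict(Xg_val, Xc_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            history.append(val_loss)
            if val_loss < best_loss - 1e-7:
                best_loss = val_loss
                best_state = [p.copy() for p in params]
                bad_checks = 0
            else:
                bad_checks += 1
                if bad_checks >= arch.patience:
                    break
        for p, s in zip(params, best_state):
            p[...] = s
        return {"epochs": len(history), "val_loss": best_loss, "history": history}
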