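"""Compact feed-forward neural-network classifier for small tabular data.

Two hidden layers (default 64 and 16 units) with batch normalization,
rectifier activations and dropout (probability 0.5) for regularization,
trained with Adam on the binary cross-entropy and early-stopped on a 10%
validation slice.  Implemented directly on numpy with a scikit-learn
estimator interface so it plugs into the same cross-validation machinery
as the other classifier families.  Training is single-threaded and
deterministic for a given ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array

__all__ = ["DropoutMLPClassifier"]

_EPS = 1e-5


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class DropoutMLPClassifier(BaseEstimator, ClassifierMixin):
    """Binary MLP with batch normalization and dropout.

    Parameters
    ----------
    hidden : tuple of int
        Hidden layer widths.
    dropout : float
        Drop probability applied after each hidden activation.
    lr : float
        Adam learning rate.
    batch_size, max_epochs, patience : int
        Minibatch size, epoch cap, and early-stopping patience (epochs
        without validation-loss improvement).
    val_fraction : float
        Fraction of the training rows held out (stratified) for early
        stopping; if the slice would be empty the training loss is used.
    """

    def __init__(self, hidden=(64, 16), dropout=0.5, lr=0.01, batch_size=16,
                 max_epochs=300, patience=25, val_fraction=0.1,
                 random_state=0):
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- forward/backward ------------------------------------------------
    def _init_params(self, n_in, rng):
        dims = [n_in, *self.hidden]
        self._w = [rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
                   for i in range(len(self.hidden))]
        self._gamma = [np.ones(h) for h in self.hidden]
        self._beta = [np.zeros(h) for h in self.hidden]
        self._w_out = rng.normal(0, np.sqrt(2.0 / dims[-1]), (dims[-1], 1))
        self._b_out = np.zeros(1)
        self._run_mu = [np.zeros(h) for h in self.hidden]
        self._run_var = [np.ones(h) for h in self.hidden]

    def _params(self):
        return [*self._w, *self._gamma, *self._beta, self._w_out, self._b_out]

    def _forward_train(self, x, rng):
        cache = []
        a = x
        for li in range(len(self.hidden)):
            z = a @ self._w[li]
            mu, var = z.mean(0), z.var(0)
            self._run_mu[li] = 0.9 * self._run_mu[li] + 0.1 * mu
            self._run_var[li] = 0.9 * self._run_var[li] + 0.1 * var
            std = np.sqrt(var + _EPS)
            xhat = (z - mu) / std
            h = self._gamma[li] * xhat + self._beta[li]
            relu_mask = h > 0
            act = h * relu_mask
            drop_mask = (rng.random(act.shape) >= self.dropout) / (1 - self.dropout)
            out = act * drop_mask
            cache.append((a, z, mu, std, xhat, relu_mask, drop_mask))
            a = out
        logits = (a @ self._w_out + self._b_out).ravel()
        return logits, a, cache

    def _backward(self, x, y, logits, a_last, cache):
        m = y.size
        grads_w = [None] * len(self.hidden)
        grads_g = [None] * len(self.hidden)
        grads_b = [None] * len(self.hidden)
        dlogits = (_sigmoid(logits) - y)[:, None] / m
        gw_out = a_last.T @ dlogits
        gb_out = dlogits.sum(0)
        da = dlogits @ self._w_out.T
        for li in reversed(range(len(self.hidden))):
            a_in, z, mu, std, xhat, relu_mask, drop_mask = cache[li]
            dact = da * drop_mask
            dh = dact * relu_mask
            grads_g[li] = (dh * xhat).sum(0)
            grads_b[li] = dh.sum(0)
            dxhat = dh * self._gamma[li]
            n = z.shape[0]
            dz = (dxhat - dxhat.mean(0)
                  - xhat * (dxhat * xhat).mean(0)) / std
            grads_w[li] = a_in.T @ dz
            da = dz @ self._w[li].T
        return [*grads_w, *grads_g, *grads_b, gw_out, gb_out]

    def _forward_infer(self, x):
        a = x
        for li in range(len(self.hidden)):
            z = a @ self._w[li]
            xhat = (z - self._run_mu[li]) / np.sqrt(self._run_var[li] + _EPS)
            a = np.maximum(self._gamma[li] * xhat + self._beta[li], 0.0)
        return (a @ self._w_out + self._b_out).ravel()

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("DropoutMLPClassifier is binary only")
        yb = (y == self.classes_[1]).astype(float)

        self._mu_in = X.mean(0)
        self._sd_in = X.std(0)
        self._sd_in[self._sd_in == 0] = 1.0
        xs = (X - self._mu_in) / self._sd_in

        rng = np.random.default_rng(self.random_state)
        self._init_params(xs.shape[1], rng)
        opt = _Adam(self._params(), self.lr)

        # stratified validation slice for early stopping
        n_val = int(round(self.val_fraction * xs.shape[0]))
        if n_val >= 2:
            order = np.concatenate([rng.permutation(np.flatnonzero(yb == c))
                                    for c in (0.0, 1.0)])
            val_idx = np.concatenate([order[yb[order] == c][:max(1, n_val // 2)]
                                      for c in (0.0, 1.0)])
            val_mask = np.zeros(xs.shape[0], dtype=bool)
            val_mask[val_idx] = True
        else:
            val_mask = np.zeros(xs.shape[0], dtype=bool)
        x_tr, y_tr = xs[~val_mask], yb[~val_mask]
        x_va, y_va = xs[val_mask], yb[val_mask]

        best_loss, best_state, stale = np.inf, None, 0
        bs = max(2, min(self.batch_size, x_tr.shape[0]))
        for _ in range(self.max_epochs):
            perm = rng.permutation(x_tr.shape[0])
            for start in range(0, x_tr.shape[0], bs):
                sel = perm[start:start + bs]
                if sel.size < 2:       # batch norm needs >= 2 rows
                    continue
                logits, a_last, cache = self._forward_train(x_tr[sel], rng)
                grads = self._backward(x_tr[sel], y_tr[sel], logits,
                                       a_last, cache)
                opt.step(self._params(), grads)
            xe, ye = (x_va, y_va) if x_va.shape[0] else (x_tr, y_tr)
            logits = self._forward_infer(xe)
            p = np.clip(_sigmoid(logits), 1e-12, 1 - 1e-12)
            loss = -np.mean(ye * np.log(p) + (1 - ye) * np.log(1 - p))
            if loss < best_loss - 1e-5:
                best_loss, stale = loss, 0
                best_state = [p.copy() for p in self._params()] + \
                    [m.copy() for m in self._run_mu] + \
                    [v.copy() for v in self._run_var]
            else:
                stale += 1
                if stale > self.patience:
                    break
        if best_state is not None:
            k = len(self._params())
            h = len(self.hidden)
            for p, src in zip(self._params(), best_state[:k]):
                p[...] = src
            self._run_mu = best_state[k:k + h]
            self._run_var = best_state[k + h:k + 2 * h]
        return self

    def predict_proba(self, X):
        X = check_array(X)
        xs = (X - self._mu_in) / self._sd_in
        p1 = _sigmoid(self._forward_infer(xs))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
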