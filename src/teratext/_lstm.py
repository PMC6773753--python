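"""Minimal LSTM sequence classifier in pure numpy.

Architecture: trainable embedding -> single LSTM layer (tanh cell/hidden
activation, sigmoid gates) whose *last* hidden state only is used ->
dropout -> dense softmax. Trained with Adam on categorical cross-entropy,
full backpropagation through time. Deterministic given the seed.

No neural-network framework is available in the runtime environment, so
the forward and backward passes are implemented here directly.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class AdamState:
    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LSTMNetwork:
    """Embedding + LSTM(H) + dropout + dense(K) softmax, last state only."""

    def __init__(self, vocab_size, embed_dim, hidden_dim, n_classes, rng,
                 pretrained=None):
        V, D, H, K = vocab_size, embed_dim, hidden_dim, n_classes
        self.D, self.H, self.K = D, H, K
        # embeddings: pretrained rows where given, zeros elsewhere (OOV/pad);
        # all rows are fine-tuned during training
        E = np.zeros((V, D))
        if pretrained is not None:
            for idx, vec in pretrained.items():
                E[idx] = vec
        lim_x = np.sqrt(6.0 / (D + 4 * H))
        lim_h = np.sqrt(6.0 / (H + 4 * H))
        lim_y = np.sqrt(6.0 / (H + K))
        self.params = {
            "E": E,
            "Wx": rng.uniform(-lim_x, lim_x, (D, 4 * H)),
            "Wh": rng.uniform(-lim_h, lim_h, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wy": rng.uniform(-lim_y, lim_y, (H, K)),
            "by": np.zeros(K),
        }
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias

    def forward(self, seqs, dropout_mask=None, cache=False):
        """seqs: int array (B, T). Returns probabilities (B, K)."""
        p = self.params
        B, T = seqs.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            x = p["E"][seqs[:, t]]
            z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if cache:
                steps.append((x, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        h_drop = h if dropout_mask is None else h * dropout_mask
        logits = h_drop @ p["Wy"] + p["by"]
        probs = softmax(logits)
        if cache:
            return probs, (steps, h, h_drop, dropout_mask, seqs)
        return probs

    def backward(self, probs, y_onehot, cache):
        p = self.params
        steps, h_last, h_drop, dropout_mask, seqs = cache
        B, T = seqs.shape
        H = self.H
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = (probs - y_onehot) / B
        grads["Wy"] = h_drop.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wy"].T
        if dropout_mask is not None:
            dh = dh * dropout_mask
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, tanh_c = steps[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dx = dz @ p["Wx"].T
            np.add.at(grads["E"], seqs[:, t], dx)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return grads
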