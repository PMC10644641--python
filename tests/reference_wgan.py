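"""Self-contained single-critic conditional WGAN-GP reference loop.

Written independently of the package's network code (plain per-layer
loops, explicit gradient formulas) to serve as the oracle for the
"auxiliary views disabled" reduction: with lambda_g = lambda_d = 0 the
package's training loop must follow this trajectory step for step under
the same seed.  Random-stream usage mirrors the package's documented
order: SeedSequence(seed).spawn(5) -> (init, shuffle, noise,
interpolation, validation) streams; the validation stream is not needed
here because it feeds no parameter update.
"""

import numpy as np


def he_init(sizes, rng):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def forward(weights, biases, x):
    """Returns (output, per-layer inputs, per-layer ReLU masks)."""
    h = x
    hs, masks = [], []
    for l in range(len(weights)):
        hs.append(h)
        a = h @ weights[l].T + biases[l]
        if l < len(weights) - 1:
            mask = (a > 0).astype(float)
            masks.append(mask)
            h = a * mask
        else:
            h = a
    return h, hs, masks


def backward(weights, hs, masks, dout):
    """Parameter gradients and input gradient for upstream dout."""
    grads = []
    delta = dout
    for l in range(len(weights) - 1, -1, -1):
        grads.insert(0, (delta.T @ hs[l], delta.sum(axis=0)))
        delta = delta @ weights[l]
        if l > 0:
            delta = delta * masks[l - 1]
    return grads, delta


def penalty_and_grads(weights, biases, x, n_expr, lam):
    """WGAN-GP penalty on the expression block of the input, with its
    parameter gradients (ReLU masks treated as locally constant)."""
    n = x.shape[0]
    _, hs, masks = forward(weights, biases, x)
    # input gradient via explicit product of masked weight matrices
    bs = [None] * len(weights)
    bs[-1] = np.ones((n, 1))
    for l in range(len(weights) - 2, -1, -1):
        bs[l] = (bs[l + 1] @ weights[l + 1]) * masks[l]
    g = (bs[0] @ weights[0])[:, :n_expr]
    norms = np.sqrt((g**2).sum(axis=1))
    value = lam * np.mean((norms - 1.0) ** 2)
    coeff = np.where(norms > 0, (2.0 * lam / n) * (norms - 1.0) / norms, 0.0)
    u = np.zeros_like(x)
    u[:, :n_expr] = coeff[:, None] * g
    grads = []
    t = u
    for l in range(len(weights)):
        grads.append((bs[l].T @ t, np.zeros_like(biases[l])))
        if l < len(weights) - 1:
            t = (t @ weights[l].T) * masks[l]
    return value, grads


class RefRMSProp:
    def __init__(self, n_arrays, lr, alpha=0.99, eps=1e-8):
        self.v = [None] * n_arrays
        self.lr, self.alpha, self.eps = lr, alpha, eps

    def step(self, arrays, grads):
        for i, (p, g) in enumerate(zip(arrays, grads)):
            if self.v[i] is None:
                self.v[i] = np.zeros_like(p)
            self.v[i] = self.alpha * self.v[i] + (1 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(self.v[i]) + self.eps)


def train_reference(
    x_train, onehot, n_iterations, noise_dim, hidden, lr, lambda_gp,
    n_critic, batch_size, seed
):
    """Run the reference loop.

    Returns a list with one (gen_params, critic_params) snapshot (flat
    [W1, b1, ...] copies) per iteration.
    """
    n, n_genes = x_train.shape
    nc = onehot.shape[1]
    ss = np.random.SeedSequence(seed)
    rng_init, rng_shuffle, rng_noise, rng_gp, _rng_val = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    gw, gb = he_init([noise_dim + nc, *hidden, n_genes], rng_init)
    cw, cb = he_init([n_genes + nc, *hidden, 1], rng_init)
    opt_c = RefRMSProp(2 * len(cw), lr)
    opt_g = RefRMSProp(2 * len(gw), lr)

    order = rng_shuffle.permutation(n)
    pos = 0

    def next_batch():
        nonlocal order, pos
        if pos >= n:
            order = rng_shuffle.permutation(n)
            pos = 0
        idx = order[pos : pos + batch_size]
        pos += batch_size
        return idx

    def flatten(pairs):
        out = []
        for w, b in pairs:
            out.extend((w, b))
        return out

    snapshots = []
    for _ in range(n_iterations):
        for _ in range(n_critic):
            idx = next_batch()
            bsz = len(idx)
            y = onehot[idx]
            z = rng_noise.standard_normal((bsz, noise_dim))
            fake, _, _ = forward(gw, gb, np.hstack([z, y]))
            # fake term: +mean D(fake)
            _, hs_f, m_f = forward(cw, cb, np.hstack([fake, y]))
            g_fake, _ = backward(cw, hs_f, m_f, np.full((bsz, 1), 1.0 / bsz))
            # real term: -mean D(x)
            _, hs_r, m_r = forward(cw, cb, np.hstack([x_train[idx], y]))
            g_real, _ = backward(cw, hs_r, m_r, np.full((bsz, 1), -1.0 / bsz))
            # penalty at the interpolate
            eps = rng_gp.uniform(size=(bsz, 1))
            xhat = eps * x_train[idx] + (1.0 - eps) * fake
            _, g_pen = penalty_and_grads(
                cw, cb, np.hstack([xhat, y]), n_genes, lambda_gp
            )
            total = [
                (a[0] + b[0] + c[0], a[1] + b[1] + c[1])
                for a, b, c in zip(g_fake, g_real, g_pen)
            ]
            opt_c.step(flatten(list(zip(cw, cb))), flatten(total))
        # generator step on the last critic batch's labels
        z = rng_noise.standard_normal((bsz, noise_dim))
        fake, hs_g, m_g = forward(gw, gb, np.hstack([z, y]))
        _, hs_c, m_c = forward(cw, cb, np.hstack([fake, y]))
        _, dx = backward(cw, hs_c, m_c, np.full((bsz, 1), -1.0 / bsz))
        g_gen, _ = backward(gw, hs_g, m_g, dx[:, :n_genes])
        opt_g.step(flatten(list(zip(gw, gb))), flatten(g_gen))
        snapshots.append(
            (
                [p.copy() for p in flatten(list(zip(gw, gb)))],
                [p.copy() for p in flatten(list(zip(cw, cb)))],
            )
        )

    return snapshots
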