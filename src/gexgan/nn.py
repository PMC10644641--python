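"""Minimal fully-connected ReLU networks with manual differentiation.

The generator and the critic are small multilayer perceptrons (hidden
layers ReLU, output linear).  Besides the usual parameter backprop this
module provides two less common derivatives the adversarial losses need:

* ``input_gradient`` — the gradient of the scalar critic output with
  respect to its input rows (used by the gradient-penalty value and by the
  generator update, which chains the critic's input gradient through the
  generator);
* ``penalty_gradients`` — the gradient of the WGAN-GP penalty
  ``lam * mean_i (||g_i|| - 1)^2`` (``g_i`` the critic's input gradient
  restricted to the expression coordinates) with respect to the critic
  parameters.  For ReLU networks the activation masks are locally constant
  almost everywhere, so the input gradient is a product of weight matrices
  and masks; differentiating it again reduces to one extra forward-style
  pass (a Jacobian-vector product) and yields zero for the biases.  This
  matches what reverse-mode automatic differentiation produces for ReLU
  nets, and is verified against finite differences in the test suite.

Weights are He-initialized; RMSProp follows the convention
``v <- alpha*v + (1-alpha)*g^2;  theta <- theta - lr*g/(sqrt(v)+eps)``.
"""

from __future__ import annotations

import numpy as np

from .errors import AlignmentError, ParameterError

__all__ = ["MLP", "RMSProp"]


class MLP:
    """Fully connected net: sizes[0] -> ... -> sizes[-1].

    All layers but the last apply ReLU; the last is linear.  Weight ``W``
    of layer l has shape (fan_out, fan_in); activations are row-major
    batches, ``a = h @ W.T + b``.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator | None = None):
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ParameterError(f"invalid layer sizes {sizes}")
        self.sizes = list(sizes)
        rng = rng or np.random.default_rng()
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_out, fan_in)))
            self.biases.append(np.zeros(fan_out))

    # ------------------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self) -> list[np.ndarray]:
        """Flat view: [W1, b1, W2, b2, ...] (aliases, not copies)."""
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(params):
            raise AlignmentError("parameter collection length mismatch")
        for dst, src in zip(own, params):
            if dst.shape != src.shape:
                raise AlignmentError("parameter shape mismatch")
            dst[...] = src

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, with_cache: bool = False):
        """Forward pass; with_cache also returns (inputs, masks) per layer."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.sizes[0]:
            raise AlignmentError(
                f"input has shape {x.shape}, expected (*, {self.sizes[0]})"
            )
        h = x
        inputs, masks = [], []
        last = self.n_layers - 1
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            inputs.append(h)
            a = h @ w.T + b
            if l < last:
                mask = a > 0
                masks.append(mask)
                h = np.where(mask, a, 0.0)
            else:
                h = a
        if with_cache:
            return h, (inputs, masks)
        return h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, cache, dout: np.ndarray):
        """Backprop ``dout`` (dL/doutput) through the cached forward pass.

        Returns (grads, dx) where grads matches :meth:`parameters` order.
        """
        inputs, masks = cache
        delta = np.asarray(dout, dtype=float)
        grads_w = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        for l in range(self.n_layers - 1, -1, -1):
            grads_w[l] = delta.T @ inputs[l]
            grads_b[l] = delta.sum(axis=0)
            delta = delta @ self.weights[l]
            if l > 0:
                delta = delta * masks[l - 1]
        grads: list[np.ndarray] = []
        for gw, gb in zip(grads_w, grads_b):
            grads.extend((gw, gb))
        return grads, delta

    # ------------------------------------------------------------------
    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Per-row gradient of the scalar output w.r.t. the input.

        Requires output width 1; returns an array of x's shape.
        """
        if self.sizes[-1] != 1:
            raise ParameterError("input_gradient requires a scalar output")
        _, cache = self.forward(x, with_cache=True)
        n = np.asarray(x).shape[0]
        _, dx = self.backward(cache, np.ones((n, 1)))
        return dx

    def penalty_gradients(
        self, x: np.ndarray, n_grad_dims: int, lam: float
    ) -> tuple[float, list[np.ndarray]]:
        """Value and parameter gradients of the gradient penalty at ``x``.

        penalty = lam * mean_i (||g_i|| - 1)^2,  g_i = dD/dx_i restricted to
        the first ``n_grad_dims`` input coordinates (the expression part of
        a [expression, label] concatenation).
        """
        if self.sizes[-1] != 1:
            raise ParameterError("penalty requires a scalar-output critic")
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        _, (inputs, masks) = self.forward(x, with_cache=True)

        # reverse sweep: B[l] = d(output)/d(pre-activation of layer l)
        bs = [None] * self.n_layers
        bs[-1] = np.ones((n, 1))
        for l in range(self.n_layers - 2, -1, -1):
            bs[l] = (bs[l + 1] @ self.weights[l + 1]) * masks[l]
        g_full = bs[0] @ self.weights[0]  # (n, d0) input gradients
        g = g_full[:, :n_grad_dims]
        norms = np.linalg.norm(g, axis=1)
        value = lam * float(np.mean((norms - 1.0) ** 2))

        # u_i = d(penalty)/d(g_i); safe at the measure-zero point norm = 0
        safe = np.where(norms > 0, norms, 1.0)
        coeff = (2.0 * lam / n) * (norms - 1.0) / safe
        u = np.zeros_like(x)
        u[:, :n_grad_dims] = coeff[:, None] * g
        # forward (tangent) sweep of the Jacobian-vector product
        grads: list[np.ndarray] = []
        t = u
        for l in range(self.n_layers):
            grads.append(bs[l].T @ t)  # dW_l
            grads.append(np.zeros_like(self.biases[l]))  # db_l = 0 a.e.
            if l < self.n_layers - 1:
                t = (t @ self.weights[l].T) * masks[l]
        return value, grads


class RMSProp:
    """Root-mean-square propagation with the mainstream framework defaults."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        alpha: float = 0.99,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ParameterError("learning rate must be positive")
        self.params = params
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self.square_avg = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise AlignmentError("gradient collection length mismatch")
        for p, g, v in zip(self.params, grads, self.square_avg):
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def add_scaled(
    acc: list[np.ndarray] | None, grads: list[np.ndarray], scale: float = 1.0
) -> list[np.ndarray]:
    """acc += scale * grads, allocating on first use."""
    if acc is None:
        return [scale * g for g in grads]
    for a, g in zip(acc, grads):
        a += scale * g
    return acc
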