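"""Adam optimizer with optional L2 weight penalty."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    """Standard Adam (Kingma & Ba) on a list of parameter tensors.

    ``l2`` adds the classic ridge penalty gradient ``2 * l2 * w`` to the
    weights listed in ``decay_params`` (convolution and dense weights;
    norms and biases are excluded by the caller).
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, l2: float = 0.0,
                 decay_params: list[Tensor] | None = None):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.l2 = l2
        decay_ids = {id(p) for p in (decay_params or [])}
        self._decay = [id(p) in decay_ids for p in self.params]
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self._t
        bias2 = 1.0 - b2 ** self._t
        for p, m, v, decay in zip(self.params, self._m, self._v, self._decay):
            if p.grad is None:
                continue
            g = p.grad
            if decay and self.l2:
                g = g + 2.0 * self.l2 * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
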