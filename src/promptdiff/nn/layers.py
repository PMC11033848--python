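"""Parameterized layers and the Adam optimizer used by the denoiser."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Linear", "MLP", "GaussianDistanceEncoding", "Adam", "collect_params"]


class Linear:
    """Affine map ``x W + b`` applied along the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(d_in)
        self.W = Tensor.param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Tensor.param(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class MLP:
    """Two-layer perceptron with SiLU hidden activation."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, zero_last: bool = False):
        self.lin1 = Linear(d_in, d_hidden, rng)
        self.lin2 = Linear(d_hidden, d_out, rng, zero_init=zero_last)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).silu())

    def params(self):
        return self.lin1.params() + self.lin2.params()


class GaussianDistanceEncoding:
    """Radial-basis expansion of interatomic distances followed by an MLP.

    Centers span [0, r_max] Å; widths equal the center spacing, giving a
    smooth, bounded-support featurization of the ligand–protein distance
    matrix before it enters the cross-attention similarity network.
    """

    def __init__(self, n_centers: int, d_out: int, rng: np.random.Generator,
                 r_max: float = 10.0):
        self.centers = np.linspace(0.0, r_max, n_centers)
        self.width = self.centers[1] - self.centers[0] if n_centers > 1 else 1.0
        self.mlp = MLP(n_centers, d_out, d_out, rng)

    def __call__(self, d: Tensor) -> Tensor:
        # d: (..., 1) distances in Å -> (..., n_centers) -> (..., d_out)
        diff = (d - Tensor(self.centers)) * (1.0 / self.width)
        return self.mlp((-0.5 * diff * diff).exp())

    def params(self):
        return self.mlp.params()


def collect_params(*modules) -> list[Tensor]:
    out: list[Tensor] = []
    for m in modules:
        if isinstance(m, Tensor):
            out.append(m)
        else:
            out.extend(m.params())
    return out


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
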