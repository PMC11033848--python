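"""Diffusion-process mathematics for ligand coordinates and atom types.

The forward (noising) chain treats the two data modalities differently:

* coordinates follow a variance-preserving Gaussian chain,
  ``q(x_t | x_{t-1}) = N(x_t | sqrt(1-beta_t) x_{t-1}, beta_t I)``,
  whose marginal from ``x_0`` is ``N(sqrt(abar_t) x_0, (1-abar_t) I)``;
* one-hot atom types follow a uniform-mixing categorical chain,
  ``C(h_t | (1-beta_t) h_{t-1} + beta_t / K)``, with marginal
  ``C(h_t | abar_t h_0 + (1-abar_t)/K)``.

Both admit closed-form single-step posteriors given the clean sample,
which is what the learned reverse process plugs its predictions into.
Protein atoms are conditioning context and are never noised here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autodiff import Tensor

__all__ = [
    "Schedule",
    "LossWeights",
    "PosteriorParams",
    "AtomVocabulary",
    "LossBreakdown",
    "make_schedule",
    "forward_noise",
    "posterior_params",
    "training_loss",
    "loss_terms",
]

DEFAULT_T = 1000
DEFAULT_BETA_MIN = 1e-7
DEFAULT_BETA_MAX = 2e-2

#: number of interaction classes for the protein classification head:
#: none + {cation-pi, halogen, hydrogen, pi-pi}
N_INTERACTION_CLASSES = 5


@dataclass(frozen=True)
class Schedule:
    """Diffusion timetable: per-step variances and their cumulative products.

    ``beta[t-1]`` is the variance added at step ``t`` (1-based steps);
    ``alpha = 1 - beta``; ``alpha_bar[t-1]`` is the running product of
    alpha up to step ``t``.  ``gamma`` weights the coordinate loss per
    step (unit weights by default).
    """

    T: int
    beta: np.ndarray
    kind: str = "sigmoid"
    gamma: np.ndarray | None = None
    params: dict | None = None   # construction params (beta_min/beta_max)

    alpha: np.ndarray = field(init=False)
    alpha_bar: np.ndarray = field(init=False)

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.shape != (self.T,):
            raise ValueError(f"beta must have length T={self.T}, got {beta.shape}")
        bad = np.where((beta <= 0.0) | (beta >= 1.0))[0]
        if bad.size:
            raise ValueError(
                f"beta[t] must lie in (0,1); offending step t={bad[0] + 1} "
                f"with beta={beta[bad[0]]!r}"
            )
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", 1.0 - beta)
        object.__setattr__(self, "alpha_bar", np.cumprod(1.0 - beta))
        if self.gamma is None:
            object.__setattr__(self, "gamma", np.ones(self.T))
        else:
            object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=np.float64))

    # 1-based accessors; alpha_bar(0) := 1 so the t=1 posterior is defined
    def beta_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.beta[t - 1])

    def alpha_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha[t - 1])

    def alpha_bar_at(self, t: int) -> float:
        if t == 0:
            return 1.0
        self._check_t(t)
        return float(self.alpha_bar[t - 1])

    def beta_tilde_at(self, t: int) -> float:
        """Posterior variance beta~_t = (1-abar_{t-1})/(1-abar_t) * beta_t."""
        self._check_t(t)
        return (1.0 - self.alpha_bar_at(t - 1)) / (1.0 - self.alpha_bar_at(t)) \
            * self.beta_at(t)

    def _check_t(self, t: int):
        if not (1 <= t <= self.T):
            raise ValueError(f"step index t={t} outside 1..{self.T}")

    def to_config(self) -> dict:
        cfg = {"T": self.T, "kind": self.kind}
        if self.params:
            cfg.update({k: v for k, v in self.params.items()
                        if k in ("beta_min", "beta_max")})
        return cfg


@dataclass(frozen=True)
class LossWeights:
    """Weights for the coordinate (lambda_x), type (lambda_h) and
    protein-interaction classification (lambda_c) loss terms."""

    lambda_x: float = 1.0
    lambda_h: float = 1.0
    lambda_c: float = 1.0

    def __post_init__(self):
        if min(self.lambda_x, self.lambda_h, self.lambda_c) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_x == self.lambda_h == self.lambda_c == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class PosteriorParams:
    """Closed-form single-step denoising posterior.

    mu_tilde: (N_L, 3) Gaussian mean for x_{t-1};
    beta_tilde: scalar Gaussian variance;
    theta_post: (N_L, K) categorical distribution for h_{t-1}.
    """

    mu_tilde: np.ndarray
    beta_tilde: float
    theta_post: np.ndarray


@dataclass(frozen=True)
class AtomVocabulary:
    """Ordered element alphabet for the categorical diffusion (hydrogens
    implicit)."""

    symbols: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate element symbols in vocabulary")
        if len(self.symbols) < 2:
            raise ValueError("vocabulary needs at least 2 symbols")

    @property
    def K(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"element {symbol!r} not in vocabulary") from None

    def one_hot(self, symbols) -> np.ndarray:
        out = np.zeros((len(symbols), self.K))
        for i, s in enumerate(symbols):
            out[i, self.index(s)] = 1.0
        return out

    def decode(self, h: np.ndarray) -> list[str]:
        return [self.symbols[k] for k in np.argmax(h, axis=-1)]


# ---------------------------------------------------------------------------
# schedules


def _sigmoid_betas(T, beta_min, beta_max):
    s = np.linspace(-6.0, 6.0, T)
    sig = 1.0 / (1.0 + np.exp(-s))
    return beta_min + (beta_max - beta_min) * sig


def _linear_betas(T, beta_min, beta_max):
    return np.linspace(beta_min, beta_max, T)


def _cosine_betas(T, max_beta=0.999):
    # abar follows a squared-cosine decay; betas derived from its ratios
    s = 0.008
    steps = np.arange(T + 1)
    f = np.cos((steps / T + s) / (1 + s) * np.pi / 2) ** 2
    betas = 1.0 - f[1:] / f[:-1]
    return np.clip(betas, 1e-9, max_beta)


def make_schedule(T: int = DEFAULT_T, kind: str = "sigmoid",
                  params: dict | None = None) -> Schedule:
    """Build a diffusion Schedule.

    kind: 'sigmoid' (default), 'linear' or 'cosine'; params may override
    beta_min / beta_max (sigmoid, linear) or supply an explicit `beta`
    array (kind='explicit').
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    params = dict(params or {})
    beta_min = params.get("beta_min", DEFAULT_BETA_MIN)
    beta_max = params.get("beta_max", DEFAULT_BETA_MAX)
    if kind == "sigmoid":
        beta = _sigmoid_betas(T, beta_min, beta_max)
    elif kind == "linear":
        beta = _linear_betas(T, beta_min, beta_max)
    elif kind == "cosine":
        beta = _cosine_betas(T)
    elif kind == "explicit":
        beta = np.asarray(params["beta"], dtype=np.float64)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    gamma = params.pop("gamma", None)
    return Schedule(T=T, beta=beta, kind=kind, gamma=gamma, params=params)


def schedule_from_config(cfg: dict) -> Schedule:
    cfg = dict(cfg)
    T = int(cfg.pop("T", DEFAULT_T))
    kind = cfg.pop("kind", "sigmoid")
    return make_schedule(T, kind, cfg)


# ---------------------------------------------------------------------------
# forward process


def _check_one_hot(h0: np.ndarray):
    h0 = np.asarray(h0, dtype=np.float64)
    if h0.ndim != 2:
        raise ValueError("h0 must be (N, K)")
    if not np.allclose(h0.sum(axis=1), 1.0, atol=1e-9) or \
            not np.all((h0 == 0.0) | (h0 == 1.0)):
        raise ValueError("rows of h0 must be valid one-hot vectors")
    return h0


def forward_noise(x0: np.ndarray, h0: np.ndarray, t: int, schedule: Schedule,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x_t, h_t) from the closed-form forward marginals at step t.

    x_t ~ N(sqrt(abar_t) x0, (1-abar_t) I); each h_t row is a one-hot
    sample from C(abar_t h0 + (1-abar_t)/K).
    """
    x0 = np.asarray(x0, dtype=np.float64)
    h0 = _check_one_hot(h0)
    ab = schedule.alpha_bar_at(t)
    x_t = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * rng.standard_normal(x0.shape)
    K = h0.shape[1]
    probs = ab * h0 + (1.0 - ab) / K
    h_t = np.zeros_like(h0)
    for i in range(h0.shape[0]):
        k = rng.choice(K, p=probs[i] / probs[i].sum())
        h_t[i, k] = 1.0
    return x_t, h_t


def forward_noise_step(x_prev: np.ndarray, h_prev: np.ndarray, t: int,
                       schedule: Schedule,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Single-step forward kernel q(.|M_{t-1}) (used to cross-check the
    closed-form marginal by composition)."""
    b = schedule.beta_at(t)
    x_t = np.sqrt(1.0 - b) * x_prev + np.sqrt(b) * rng.standard_normal(x_prev.shape)
    K = h_prev.shape[1]
    probs = (1.0 - b) * h_prev + b / K
    h_t = np.zeros_like(h_prev)
    for i in range(h_prev.shape[0]):
        k = rng.choice(K, p=probs[i] / probs[i].sum())
        h_t[i, k] = 1.0
    return x_t, h_t


# ---------------------------------------------------------------------------
# posterior


def _theta_post(h_t, h0, t, schedule: Schedule):
    """Unnormalized-then-normalized categorical posterior.

    Works on numpy arrays or autodiff Tensors (h0 may carry gradients
    when it is the network prediction).
    """
    a_t = schedule.alpha_at(t)
    ab_prev = schedule.alpha_bar_at(t - 1)
    K = h_t.shape[-1]
    lik = a_t * h_t + (1.0 - a_t) / K
    prior = ab_prev * h0 + (1.0 - ab_prev) / K
    theta = lik * prior
    return theta / theta.sum(axis=-1, keepdims=True)


def posterior_params(x_t: np.ndarray, x0: np.ndarray, h_t: np.ndarray,
                     h0: np.ndarray, t: int, schedule: Schedule) -> PosteriorParams:
    """Evaluate the closed-form posterior q(. at t-1 | state at t, clean).

    mu~_t = [sqrt(abar_{t-1}) beta_t x0 + sqrt(alpha_t)(1-abar_{t-1}) x_t]
            / (1-abar_t);
    beta~_t = (1-abar_{t-1})/(1-abar_t) beta_t;
    theta_post ∝ [alpha_t h_t + (1-alpha_t)/K] ⊙ [abar_{t-1} h0 + (1-abar_{t-1})/K].
    """
    if t == 0:
        raise ValueError("no posterior step exists at t=0")
    schedule._check_t(t)
    x_t = np.asarray(x_t, dtype=np.float64)
    x0 = np.asarray(x0, dtype=np.float64)
    b_t = schedule.beta_at(t)
    a_t = schedule.alpha_at(t)
    ab_t = schedule.alpha_bar_at(t)
    ab_prev = schedule.alpha_bar_at(t - 1)
    mu = (np.sqrt(ab_prev) * b_t * x0 + np.sqrt(a_t) * (1.0 - ab_prev) * x_t) \
        / (1.0 - ab_t)
    beta_tilde = (1.0 - ab_prev) / (1.0 - ab_t) * b_t
    theta = _theta_post(np.asarray(h_t, dtype=np.float64),
                        np.asarray(h0, dtype=np.float64), t, schedule)
    return PosteriorParams(mu_tilde=mu, beta_tilde=float(beta_tilde),
                           theta_post=theta)


# ---------------------------------------------------------------------------
# training loss


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    coord: float      # L^x before lambda weighting
    types: float      # L^h before lambda weighting
    classification: float  # Cls before lambda weighting


def _log_softmax(logits: Tensor) -> Tensor:
    m = Tensor(np.max(logits.data, axis=-1, keepdims=True))
    z = logits - m
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def loss_terms(x0, x0_hat, h_t, h0, h0_hat, protein_class_logits,
               protein_class_labels, t: int, schedule: Schedule) -> tuple:
    """Differentiable loss components (autodiff Tensors).

    L^x = gamma_t * mean-per-atom squared coordinate error;
    L^h = KL( theta_post(h_t, h0) || theta_post(h_t, h0_hat) ), mean per atom;
    Cls = cross-entropy of protein interaction-class logits, mean per atom.
    Predictions may be Tensors (gradients flow) or arrays.
    """
    def T_(v):
        return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))

    x0, x0_hat = T_(x0), T_(x0_hat)
    gamma_t = float(schedule.gamma[t - 1])
    diff = x0 - x0_hat
    l_x = (diff * diff).sum(axis=-1).mean() * gamma_t

    h_t_arr = np.asarray(h_t, dtype=np.float64)
    theta_true = _theta_post(h_t_arr, np.asarray(h0, dtype=np.float64), t, schedule)
    theta_pred = _theta_post(Tensor(h_t_arr), T_(h0_hat), t, schedule)
    eps = 1e-30
    ratio = (Tensor(theta_true) + eps) / (theta_pred + eps)
    l_h = (Tensor(theta_true) * ratio.log()).sum(axis=-1).mean()

    logits = T_(protein_class_logits)
    labels = np.asarray(protein_class_labels, dtype=int)
    if labels.min() < 0 or labels.max() >= logits.shape[-1]:
        raise ValueError("interaction-class label outside the class set")
    logp = _log_softmax(logits)
    onehot = np.zeros(logits.shape)
    idx = np.indices(labels.shape)
    onehot[(*idx, labels)] = 1.0
    l_c = -(Tensor(onehot) * logp).sum(axis=-1).mean()
    return l_x, l_h, l_c


def training_loss(x0, x0_hat, h_t, h0, h0_hat, protein_class_logits,
                  protein_class_labels, t: int, schedule: Schedule,
                  weights: LossWeights) -> LossBreakdown:
    """Total loss  L = lambda_x L^x + lambda_h L^h + lambda_c Cls  with
    its per-term breakdown (plain floats; use `loss_terms` for gradients)."""
    l_x, l_h, l_c = loss_terms(x0, x0_hat, h_t, h0, h0_hat,
                               protein_class_logits, protein_class_labels,
                               t, schedule)
    lx, lh, lc = float(l_x.data), float(l_h.data), float(l_c.data)
    total = weights.lambda_x * lx + weights.lambda_h * lh + weights.lambda_c * lc
    return LossBreakdown(total=total, coord=lx, types=lh, classification=lc)
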