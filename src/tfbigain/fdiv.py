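"""f-divergences, Fenchel conjugates, critic activations, adversarial losses.

An f-divergence D_f(P||Q) = E_Q[f(p/q)] for convex f with f(1) = 0 admits the
variational lower bound

    D_f(P||Q) >= sup_T  E_P[T(x)] - E_Q[f*(T(x))],

where f*(t) = sup_u {ut - f(u)} is the convex conjugate and T any critic whose
range lies in dom f*. Adversarial training realises the critic as a neural
network S(x) composed with a divergence-specific output activation g_f that
maps the reals into dom f*. Registered divergences:

name         f(u)                          f*(t)               dom f*    g_f(v)
-----------  ----------------------------  ------------------  --------  ---------------------
forward_kl   u log u                       exp(t - 1)          R         v
reverse_kl   -log u                        -1 - log(-t)        t < 0     -exp(v)
js           u log u - (u+1) log((u+1)/2)  -log(2 - exp(t))    t < log2  log2 - log(1+exp(-v))
pearson      (u - 1)^2                     t^2/4 + t           R         v

"wasserstein" is registered alongside these for convenience but is not an
f-divergence: it uses an unconstrained critic (identity activation, no
conjugate) kept approximately Lipschitz by weight clipping in the trainer.

All callables accept either numpy arrays or autodiff tensors, so the same
registry entry serves both numeric evaluation and backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "DivergenceSpec",
    "DIVERGENCES",
    "get_divergence",
    "conjugate",
    "discriminator_loss",
    "generator_adv_loss",
    "estimate_divergence",
]

EXP_CLIP = 30.0  # clamp exp arguments
DOMAIN_EPS = 1e-7  # interior margin at conjugate-domain boundaries


def _exp(x):
    return ad.exp(ad.clip(ad.astensor(x), -EXP_CLIP, EXP_CLIP))


def _is_tensor_input(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _num(x):
    v = x.value if isinstance(x, Tensor) else np.asarray(x)
    return float(v) if np.ndim(v) == 0 else v


# ---- generator functions f (numeric only; used for checks and docs) ------


def _f_forward_kl(u):
    u = np.asarray(u, dtype=float)
    return u * np.log(u)


def _f_reverse_kl(u):
    return -np.log(np.asarray(u, dtype=float))


def _f_js(u):
    u = np.asarray(u, dtype=float)
    return u * np.log(u) - (u + 1.0) * np.log((u + 1.0) / 2.0)


def _f_pearson(u):
    u = np.asarray(u, dtype=float)
    return (u - 1.0) ** 2


# ---- conjugates f* and activations g_f (tensor-aware) --------------------


def _fstar_forward_kl(t):
    return _exp(ad.astensor(t) - 1.0)


def _fstar_reverse_kl(t):
    return -1.0 - ad.log(-ad.astensor(t))


def _fstar_js(t):
    return -ad.log(2.0 - _exp(t))


def _fstar_pearson(t):
    t = ad.astensor(t)
    return t * t / 4.0 + t


def _g_identity(v):
    return ad.astensor(v)


def _g_reverse_kl(v):
    # strictly negative output: dom f* for reverse KL is t < 0
    return -_exp(v)


def _g_js(v):
    # log 2 - softplus(-v), kept an epsilon inside the conjugate domain so
    # softplus underflow at huge scores cannot reach the boundary t = log 2
    return (np.log(2.0) - DOMAIN_EPS) - ad.softplus(-ad.astensor(v))


@dataclass(frozen=True)
class DivergenceSpec:
    """One named divergence: generator f, conjugate f*, critic activation g_f."""

    name: str
    f: Callable | None
    f_star: Callable | None
    g_f: Callable
    conjugate_domain: tuple = (-np.inf, np.inf)  # open upper bound where finite
    critic_based: bool = False  # Wasserstein: no conjugate, Lipschitz critic
    domain_guard: str = ""

    def in_domain(self, t) -> np.ndarray:
        t = np.asarray(_num(t), dtype=float)
        lo, hi = self.conjugate_domain
        return (t > lo) & (t < hi)


DIVERGENCES = {
    "forward_kl": DivergenceSpec(
        "forward_kl", _f_forward_kl, _fstar_forward_kl, _g_identity,
        domain_guard="t in R",
    ),
    "reverse_kl": DivergenceSpec(
        "reverse_kl", _f_reverse_kl, _fstar_reverse_kl, _g_reverse_kl,
        conjugate_domain=(-np.inf, 0.0), domain_guard="t < 0",
    ),
    "js": DivergenceSpec(
        "js", _f_js, _fstar_js, _g_js,
        conjugate_domain=(-np.inf, np.log(2.0)), domain_guard="t < log 2",
    ),
    "pearson": DivergenceSpec(
        "pearson", _f_pearson, _fstar_pearson, _g_identity,
        domain_guard="t in R",
    ),
    "wasserstein": DivergenceSpec(
        "wasserstein", None, None, _g_identity, critic_based=True,
        domain_guard="unconstrained critic, weight-clipped to ~Lipschitz",
    ),
}


def get_divergence(name: str) -> DivergenceSpec:
    try:
        return DIVERGENCES[name]
    except KeyError:
        raise ValueError(
            f"unknown divergence {name!r}; available: {sorted(DIVERGENCES)}"
        ) from None


def conjugate(spec: DivergenceSpec, t):
    """Evaluate f*(t), rejecting arguments outside the conjugate domain."""
    if spec.critic_based:
        raise ValueError(f"{spec.name} has no convex conjugate (critic-based)")
    tv = np.asarray(t, dtype=float)
    lo, hi = spec.conjugate_domain
    if np.any(tv <= lo + DOMAIN_EPS) or np.any(tv >= hi - DOMAIN_EPS):
        raise ValueError(
            f"argument outside dom f* for {spec.name} ({spec.domain_guard})"
        )
    return _num(spec.f_star(tv))


def discriminator_loss(real_scores, fake_scores, spec: DivergenceSpec):
    """L_D^f = mean g_f(real) - mean f*(g_f(fake)); Wasserstein: mean difference.

    The trainer MAXIMIZES this (it minimizes the negation). Raw critic
    outputs S(x) are expected; the activation is applied here.
    """
    tensor_mode = _is_tensor_input(real_scores, fake_scores)
    real = ad.astensor(real_scores)
    fake = ad.astensor(fake_scores)
    if real.value.size == 0 or fake.value.size == 0:
        raise ValueError("score vectors must be nonempty")
    if spec.critic_based:
        out = ad.tmean(real) - ad.tmean(fake)
    else:
        out = ad.tmean(spec.g_f(real)) - ad.tmean(spec.f_star(spec.g_f(fake)))
    return out if tensor_mode else _num(out)


def generator_adv_loss(fake_scores, spec: DivergenceSpec):
    """L_GA^f = -mean f*(g_f(fake)); Wasserstein: -mean(fake). Minimized by G."""
    tensor_mode = _is_tensor_input(fake_scores)
    fake = ad.astensor(fake_scores)
    if fake.value.size == 0:
        raise ValueError("score vector must be nonempty")
    if spec.critic_based:
        out = -ad.tmean(fake)
    else:
        out = -ad.tmean(spec.f_star(spec.g_f(fake)))
    return out if tensor_mode else _num(out)


def estimate_divergence(samples_p, samples_q, critic, spec: DivergenceSpec) -> float:
    """Empirical variational bound mean_P[T(x)] - mean_Q[f*(T(x))].

    `critic` maps an array of samples to critic values T(x) (already in the
    conjugate domain). For any critic this under-estimates D_f(P||Q) in
    expectation; equality needs the optimal critic T*(x) = f'(p(x)/q(x)).
    """
    if spec.critic_based:
        raise ValueError("variational bound requires an f-divergence")
    tp = np.asarray(critic(np.asarray(samples_p, dtype=float)), dtype=float)
    tq = np.asarray(critic(np.asarray(samples_q, dtype=float)), dtype=float)
    for tv in (tp, tq):
        if not spec.in_domain(tv).all():
            raise ValueError(
                f"critic output outside dom f* for {spec.name} ({spec.domain_guard})"
            )
    return float(np.mean(tp) - np.mean(_num(spec.f_star(tq))))
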