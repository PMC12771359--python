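"""Quadratic expressions of jointly Gaussian variables, with exact moments.

A :class:`QuadExpr` is ``c0 + sum_i a_i z_i + sum_{ij} b_ij z_i z_j`` over a
zero-mean Gaussian vector ``z`` with covariance ``Sigma``.  Means, variances
and covariances of such expressions follow from Wick's theorem:

    E[z_a z_b]            = S_ab
    Cov(z_a, z_b z_c)     = 0
    Cov(z_a z_b, z_c z_d) = S_ac S_bd + S_ad S_bc

which is everything needed to compute, in closed form, the signal variance of
a target law built from linear and pairwise-product terms -- and hence the
exact R-squared ceiling of any regressor on data generated from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class QuadExpr:
    const: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    quad: dict[tuple[str, str], float] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def var(cls, name: str, coef: float = 1.0) -> "QuadExpr":
        return cls(linear={name: coef})

    def __add__(self, other) -> "QuadExpr":
        if not isinstance(other, QuadExpr):
            return QuadExpr(self.const + float(other), dict(self.linear), dict(self.quad))
        lin = dict(self.linear)
        for k, v in other.linear.items():
            lin[k] = lin.get(k, 0.0) + v
        quad = dict(self.quad)
        for k, v in other.quad.items():
            quad[k] = quad.get(k, 0.0) + v
        return QuadExpr(self.const + other.const, lin, quad)

    __radd__ = __add__

    def __mul__(self, factor) -> "QuadExpr":
        if isinstance(factor, QuadExpr):
            return self.product(factor)
        f = float(factor)
        return QuadExpr(
            self.const * f,
            {k: v * f for k, v in self.linear.items()},
            {k: v * f for k, v in self.quad.items()},
        )

    __rmul__ = __mul__

    def __sub__(self, other) -> "QuadExpr":
        return self + (other * -1.0 if isinstance(other, QuadExpr) else -float(other))

    def product(self, other: "QuadExpr") -> "QuadExpr":
        """Product of two purely linear expressions (degree stays <= 2)."""
        if self.quad or other.quad:
            raise ValueError("can only multiply linear expressions (degree would exceed 2)")
        out = QuadExpr(self.const * other.const)
        for k, v in self.linear.items():
            out.linear[k] = out.linear.get(k, 0.0) + v * other.const
        for k, v in other.linear.items():
            out.linear[k] = out.linear.get(k, 0.0) + v * self.const
        for ka, va in self.linear.items():
            for kb, vb in other.linear.items():
                key = _key(ka, kb)
                out.quad[key] = out.quad.get(key, 0.0) + va * vb
        return out

    @property
    def is_linear(self) -> bool:
        return not self.quad

    def latents(self) -> set[str]:
        names = set(self.linear)
        for a, b in self.quad:
            names.update((a, b))
        return names

    def restrict(self, keep: set[str]) -> "QuadExpr":
        """Drop every term involving a latent outside ``keep``."""
        return QuadExpr(
            self.const,
            {k: v for k, v in self.linear.items() if k in keep},
            {k: v for k, v in self.quad.items() if k[0] in keep and k[1] in keep},
        )

    # -- moments under a latent covariance ---------------------------------

    def mean(self, cov: pd.DataFrame) -> float:
        m = self.const
        for (a, b), coef in self.quad.items():
            m += coef * float(cov.loc[a, b])
        return m

    def cov_with(self, other: "QuadExpr", cov: pd.DataFrame) -> float:
        total = 0.0
        for a, va in self.linear.items():
            for b, vb in other.linear.items():
                total += va * vb * float(cov.loc[a, b])
        for (a, b), vab in self.quad.items():
            for (c, d), vcd in other.quad.items():
                total += vab * vcd * (
                    float(cov.loc[a, c]) * float(cov.loc[b, d])
                    + float(cov.loc[a, d]) * float(cov.loc[b, c])
                )
        return total

    def variance(self, cov: pd.DataFrame) -> float:
        return self.cov_with(self, cov)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, samples: dict[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(samples.values())))
        out = np.full(n, self.const, dtype=float)
        for k, v in self.linear.items():
            out += v * samples[k]
        for (a, b), v in self.quad.items():
            out += v * samples[a] * samples[b]
        return out
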