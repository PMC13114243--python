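"""Residual (within-arm) error models shared by the simulator and the fitter.

Three models cover the usual assay/biological noise structures:

* ``additive``       y = f + eps,                 eps ~ N(0, sigma^2)
* ``log_additive``   ln y = ln f + eps            (multiplicative lognormal)
* ``power``          y = f + f^gamma * eps        (gamma = 1 is proportional)

``neg2ll`` returns the exact -2 log-likelihood including all constants, so
values are comparable across error models (the log-additive density carries
the Jacobian term 2*sum(ln y) of the log transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorModel"]

_KINDS = ("additive", "log_additive", "power")
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ErrorModel:
    kind: str = "additive"
    sigma: float = 1.0
    gamma: float = 1.0  # power exponent; ignored by the other kinds

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown error model {self.kind!r}")
        # sigma = 0 is the noise-free degenerate case (simulation only);
        # likelihood evaluation requires sigma > 0.
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def with_sigma(self, sigma: float, gamma: float | None = None) -> "ErrorModel":
        return ErrorModel(self.kind, sigma, self.gamma if gamma is None else gamma)

    # -- simulation -------------------------------------------------------
    def sample(
        self,
        rng: np.random.Generator,
        f: np.ndarray,
        truncate_negative: bool = True,
        max_redraws: int = 1000,
    ) -> np.ndarray:
        """Draw observations about true values ``f`` (> 0 for log/power).

        Under additive and power error a draw can be negative; real assay
        values are not, so negative draws are redrawn by default
        (``truncate_negative=False`` disables this).
        """
        f = np.asarray(f, dtype=float)
        if self.sigma == 0:
            return f.copy()
        if self.kind == "log_additive":
            if np.any(f <= 0):
                raise ValueError("log-additive error requires positive true values")
            return f * np.exp(rng.normal(0.0, self.sigma, size=f.shape))
        sd = self.sigma if self.kind == "additive" else self.sigma * f**self.gamma
        y = f + rng.normal(size=f.shape) * sd
        if truncate_negative:
            for _ in range(max_redraws):
                bad = y < 0
                if not np.any(bad):
                    break
                y[bad] = f[bad] + rng.normal(size=int(bad.sum())) * np.broadcast_to(
                    sd, f.shape
                )[bad]
            else:
                raise RuntimeError("could not draw non-negative concentrations")
        return y

    # -- likelihood -------------------------------------------------------
    def neg2ll(self, y, f) -> float:
        """Exact -2 log-likelihood of observations ``y`` given predictions ``f``."""
        y = np.asarray(y, dtype=float)
        f = np.asarray(f, dtype=float)
        if self.sigma == 0:
            raise ValueError("likelihood evaluation requires sigma > 0")
        s2 = self.sigma**2
        if self.kind == "additive":
            return float(np.sum(_LOG2PI + np.log(s2) + (y - f) ** 2 / s2))
        if self.kind == "log_additive":
            if np.any(y <= 0):
                raise ValueError(
                    "nonpositive observation under log-additive error "
                    "(impute BLQ values first)"
                )
            if np.any(f <= 0):
                raise ValueError("nonpositive prediction under log-additive error")
            r = np.log(y) - np.log(f)
            return float(np.sum(_LOG2PI + np.log(s2) + r**2 / s2) + 2.0 * np.sum(np.log(y)))
        # power: variance sigma^2 * f^(2*gamma)
        if np.any(f <= 0):
            raise ValueError("nonpositive prediction under power error")
        v = s2 * f ** (2.0 * self.gamma)
        return float(np.sum(_LOG2PI + np.log(v) + (y - f) ** 2 / v))

    def scaled_residuals(self, y, f) -> np.ndarray:
        """Standardized residuals on the model's own scale (unit sd if correct)."""
        y = np.asarray(y, dtype=float)
        f = np.asarray(f, dtype=float)
        if self.kind == "additive":
            return (y - f) / self.sigma
        if self.kind == "log_additive":
            return (np.log(y) - np.log(f)) / self.sigma
        return (y - f) / (self.sigma * f**self.gamma)

    @property
    def n_params(self) -> int:
        """Estimated error parameters (sigma; gamma is held fixed)."""
        return 1
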