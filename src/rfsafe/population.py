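"""Intersubject variation from peak-SAR populations.

A population of 10-g-averaged peak SAR (pSAR) values over body models and RF
shims is summarized either by fitting a gamma distribution and comparing its
99.9% quantile (pSAR99) to the sample mean, or — for small databases — by the
conservative max/min spread.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GammaFit",
    "PSARPopulation",
    "fit_gamma",
    "psar99",
    "intersubject_variation_gamma",
    "intersubject_variation_minmax",
]


@dataclasses.dataclass(frozen=True)
class GammaFit:
    """Two-parameter gamma MLE (location fixed at 0) with diagnostics."""

    shape: float
    scale: float
    log_likelihood: float
    n: int
    # method-of-moments fallback, reported when it disagrees with the MLE
    mom_shape: float
    mom_scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def disagrees_with_moments(self, rel_tol: float = 0.05) -> bool:
        return (
            abs(self.mom_shape - self.shape) > rel_tol * self.shape
            or abs(self.mom_scale - self.scale) > rel_tol * self.scale
        )


def _validate_samples(samples: Sequence[float], min_n: int) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("pSAR samples must be finite and > 0")
    return x


def fit_gamma(samples: Sequence[float]) -> GammaFit:
    """Maximum-likelihood two-parameter gamma fit with location fixed at 0."""
    x = _validate_samples(samples, min_n=10)
    if np.ptp(x) == 0:
        raise ValueError("samples are degenerate (zero variance); cannot fit gamma")
    shape, loc, scale = stats.gamma.fit(x, floc=0.0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise RuntimeError(
            f"gamma fit did not converge: shape={shape}, scale={scale}"
        )
    ll = float(np.sum(stats.gamma.logpdf(x, shape, loc=0.0, scale=scale)))
    m, v = float(np.mean(x)), float(np.var(x))
    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        log_likelihood=ll,
        n=int(x.size),
        mom_shape=m * m / v,
        mom_scale=v / m,
    )


def psar99(shape: float, scale: float, quantile: float = 0.999) -> float:
    """Inverse gamma CDF at ``quantile`` — the pSAR value not exceeded in
    99.9% of examinations by default."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma parameters must be > 0")
    return float(stats.gamma.ppf(quantile, shape, loc=0.0, scale=scale))


def intersubject_variation_gamma(psar99_value: float, mean_psar: float) -> float:
    """Relative intersubject variation pSAR99 / mean(pSAR) − 1."""
    if mean_psar <= 0:
        raise ValueError("mean pSAR must be > 0")
    if psar99_value <= 0:
        raise ValueError("pSAR99 must be > 0")
    return psar99_value / mean_psar - 1.0


def intersubject_variation_minmax(samples: Sequence[float]) -> float:
    """Conservative small-database estimator: max(samples)/min(samples) − 1."""
    x = _validate_samples(samples, min_n=2)
    return float(np.max(x) / np.min(x) - 1.0)


@dataclasses.dataclass(frozen=True)
class PSARPopulation:
    """pSAR samples with their gamma fit and derived summaries.

    ``mean_psar`` is the arithmetic sample mean (the fitted-distribution mean
    is available from ``fit``); ``psar99`` is the 0.999 quantile of the fit.
    """

    samples: np.ndarray
    labels: tuple[str, ...] | None
    fit: GammaFit
    mean_psar: float
    psar99: float
    quantile: float = 0.999

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[float],
        labels: Sequence[str] | None = None,
        quantile: float = 0.999,
    ) -> "PSARPopulation":
        x = _validate_samples(samples, min_n=10)
        if labels is not None and len(labels) != x.size:
            raise ValueError("labels must match sample count")
        fit = fit_gamma(x)
        return cls(
            samples=x,
            labels=tuple(labels) if labels is not None else None,
            fit=fit,
            mean_psar=float(np.mean(x)),
            psar99=psar99(fit.shape, fit.scale, quantile),
            quantile=quantile,
        )

    def intersubject_variation(self) -> float:
        return intersubject_variation_gamma(self.psar99, self.mean_psar)

    def to_dict(self) -> dict:
        return {
            "n": int(self.samples.size),
            "gamma_shape": self.fit.shape,
            "gamma_scale": self.fit.scale,
            "log_likelihood": self.fit.log_likelihood,
            "mom_shape": self.fit.mom_shape,
            "mom_scale": self.fit.mom_scale,
            "mean_psar": self.mean_psar,
            "fitted_mean": self.fit.mean,
            "psar99": self.psar99,
            "quantile": self.quantile,
            "intersubject_variation": self.intersubject_variation(),
        }
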