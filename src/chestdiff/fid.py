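"""Fréchet-distance evaluation of generated image sets.

The Fréchet distance between Gaussian fits N(mu_a, S_a), N(mu_b, S_b) of two
feature sets is

    d^2 = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}),

zero when the feature statistics coincide.  Feature extraction is pluggable;
the built-in "projection-pool" extractor is download-free and deterministic:
pixels are mapped to [0, 1], flattened, and passed through a fixed-seed
semi-orthogonal linear map to the requested dimension (64 and 2048 mirror the
widths of the pooling layers conventionally used for this metric).

Covariances use the n-1 denominator; this matters at small sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .images import Domain, ImageBatch

__all__ = [
    "FeatureExtractor",
    "ProjectionPoolExtractor",
    "GaussianSummary",
    "summarize",
    "frechet_distance",
    "fid",
    "fid_table",
]

logger = logging.getLogger("chestdiff")


@dataclass(frozen=True)
class GaussianSummary:
    """Mean vector and covariance matrix of a feature set."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=np.float64))
        if self.n < 2:
            raise ValueError(f"need at least 2 samples, got n={self.n}")
        d = self.mu.shape[0]
        if self.sigma.shape != (d, d):
            raise ValueError(f"sigma must be {d}x{d}, got {self.sigma.shape}")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric to 1e-10")

    @property
    def dim(self) -> int:
        return self.mu.shape[0]


class FeatureExtractor:
    """Deterministic map from an image batch to (n, dim) features."""

    name: str = "identity"
    dim: int

    def __call__(self, batch: ImageBatch) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _unit_pixels(batch: ImageBatch) -> np.ndarray:
    """Canonicalize any batch to flat float pixels in [0, 1]."""
    if batch.domain is Domain.UINT8:
        flat = batch.pixels.reshape(len(batch), -1).astype(np.float64) / 255.0
    else:
        flat = (np.clip(batch.pixels.reshape(len(batch), -1), -1.0, 1.0) + 1.0) / 2.0
    return flat


class ProjectionPoolExtractor(FeatureExtractor):
    """Fixed-seed semi-orthogonal projection of flattened pixels.

    For dim <= n_pixels the projection matrix has orthonormal columns (a true
    orthogonal projection); for dim > n_pixels it has orthonormal rows (an
    isometric embedding), since more than n_pixels orthonormal directions do
    not exist.  The matrix depends only on (n_pixels, dim, seed), so features
    are reproducible across platforms.
    """

    def __init__(self, dim: int = 64, image_size: int = 28, seed: int = 7_777):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.dim = int(dim)
        self.name = f"projection-pool-{dim}"
        n_pix = image_size * image_size
        rng = np.random.default_rng([seed, dim, n_pix])
        g = rng.standard_normal((n_pix, dim))
        if dim <= n_pix:
            q, _ = np.linalg.qr(g)          # (n_pix, dim), orthonormal columns
            self._w = q
        else:
            q, _ = np.linalg.qr(g.T)        # (dim, n_pix), orthonormal columns
            self._w = q.T                   # (n_pix, dim), orthonormal rows
        self._n_pix = n_pix

    def __call__(self, batch: ImageBatch) -> np.ndarray:
        flat = _unit_pixels(batch)
        if flat.shape[1] != self._n_pix:
            raise ValueError(
                f"extractor built for {self._n_pix} pixels, got {flat.shape[1]}"
            )
        return flat @ self._w


class ShiftedExtractor(FeatureExtractor):
    """Wrap an extractor and add a constant vector (diagnostics/testing)."""

    def __init__(self, base: FeatureExtractor, shift: np.ndarray):
        self.base = base
        self.shift = np.asarray(shift, dtype=np.float64)
        self.dim = base.dim
        self.name = f"{base.name}+shift"

    def __call__(self, batch: ImageBatch) -> np.ndarray:
        return self.base(batch) + self.shift


def summarize(features: np.ndarray) -> GaussianSummary:
    """Column means and n-1 sample covariance (symmetrized) of a feature matrix."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError(f"features must be 2-D (n, d), got shape {features.shape}")
    n = features.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 feature rows, got {n}")
    mu = features.mean(axis=0)
    cov = np.cov(features, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = (cov + cov.T) / 2.0
    return GaussianSummary(mu=mu, sigma=cov, n=n)


def _stable_sqrtm_product(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    """Principal square root of S_a S_b, with diagonal jitter on failure."""
    for jitter in (0.0, 1e-6, 1e-4):
        a = sa + jitter * np.eye(sa.shape[0]) if jitter else sa
        b = sb + jitter * np.eye(sb.shape[0]) if jitter else sb
        try:
            root = scipy.linalg.sqrtm(a @ b)
        except Exception:
            continue
        root = np.asarray(root)
        if np.iscomplexobj(root):
            imag = np.abs(root.imag).max()
            if imag > 1e-3:
                if jitter == 0.0:
                    logger.info("sqrtm imaginary residue %.2e; retrying with jitter", imag)
                continue
            root = root.real
        if np.all(np.isfinite(root)):
            if jitter:
                logger.info("sqrtm stabilized with jitter %.0e", jitter)
            return root
    raise FloatingPointError(
        "matrix square root of the covariance product failed after jitter "
        f"stabilization (dims {sa.shape[0]}); covariance traces "
        f"{np.trace(sa):.3e}, {np.trace(sb):.3e}"
    )


def frechet_distance(a: GaussianSummary, b: GaussianSummary) -> float:
    """Fréchet distance between two Gaussian summaries of equal dimension."""
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
    diff = a.mu - b.mu
    covmean = _stable_sqrtm_product(a.sigma, b.sigma)
    value = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma)
                  - 2.0 * np.trace(covmean))
    if value < 0:
        logger.info("clipping small negative Fréchet distance %.3e to 0", value)
        value = 0.0
    return value


def fid(real: ImageBatch, generated: ImageBatch, extractor: FeatureExtractor) -> float:
    """Fréchet distance between feature summaries of two image sets."""
    if len(real) < 2 or len(generated) < 2:
        raise ValueError(
            f"both sets need >= 2 images, got {len(real)} real, {len(generated)} generated"
        )
    value = frechet_distance(summarize(extractor(real)), summarize(extractor(generated)))
    logger.info("fid=%.6f extractor=%s n_real=%d n_generated=%d",
                value, extractor.name, len(real), len(generated))
    return value


def fid_table(
    real: ImageBatch,
    generated_by_loss: dict[str, ImageBatch],
    extractors: list[FeatureExtractor],
) -> pd.DataFrame:
    """Rectangular loss x dimension table of Fréchet distances."""
    if not generated_by_loss or not extractors:
        raise ValueError("need at least one generated set and one extractor")
    table = pd.DataFrame(
        index=list(generated_by_loss),
        columns=[str(e.dim) for e in extractors],
        dtype=float,
    )
    for loss_name, batch in generated_by_loss.items():
        for ext in extractors:
            table.loc[loss_name, str(ext.dim)] = fid(real, batch, ext)
    table.index.name = "loss"
    return table
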