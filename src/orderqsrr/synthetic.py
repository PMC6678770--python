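"""Synthetic retention datasets with known ground truth.

Emulates the statistical structure the linear QSRR models assume:
descriptors drawn from a multivariate normal, a linear retention response
with additive Gaussian noise, and — optionally — a monotone convex warp

    y  →  y + warp_strength · y² / max(y)

that preserves the true elution order while bending the response away
from linearity, so an ordinary least-squares fit starts misordering
analytes.  That is exactly the regime in which the order-constrained
model earns its keep, which makes the warp the main dial for stress
testing.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ChromatographicCondition, RetentionDataset

__all__ = ["SimulationConfig", "simulate_dataset", "make_benchmark_suite"]

_MIN_RETENTION = 0.1  # minutes; floor after shifting to keep y > 0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth settings for one simulated chromatographic run.

    Defaults mimic a small-molecule RP-LC screen: ~60 analytes, three
    descriptors, retention centered around 12 min with ~0.3 min noise.
    """

    n_analytes: int = 60
    n_descriptors: int = 3
    true_coefficients: tuple[float, ...] = (2.0, -1.0, 0.5)
    descriptor_covariance: np.ndarray | str = "identity"
    baseline_retention: float = 12.0  # minutes
    noise_sd: float = 0.3  # minutes
    warp_strength: float = 0.0  # 0 = linear response
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_analytes < self.n_descriptors + 4:
            raise ValueError("need n_analytes >= K + 4")
        if len(self.true_coefficients) != self.n_descriptors:
            raise ValueError("true_coefficients must have length K")
        if self.noise_sd < 0 or self.warp_strength < 0:
            raise ValueError("noise_sd and warp_strength must be >= 0")

    def covariance_matrix(self) -> np.ndarray:
        k = self.n_descriptors
        if isinstance(self.descriptor_covariance, str):
            if self.descriptor_covariance != "identity":
                raise ValueError(
                    f"unknown covariance spec {self.descriptor_covariance!r}"
                )
            return np.eye(k)
        cov = np.asarray(self.descriptor_covariance, dtype=float)
        if cov.shape != (k, k):
            raise ValueError(f"covariance must be {k}×{k}")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise ValueError("covariance is not positive semi-definite")
        return cov


def simulate_dataset(config: SimulationConfig) -> RetentionDataset:
    """Draw one retention dataset from the generative model."""
    rng = np.random.default_rng(config.seed)
    cov = config.covariance_matrix()
    X = rng.multivariate_normal(
        np.zeros(config.n_descriptors), cov, size=config.n_analytes
    )
    beta = np.asarray(config.true_coefficients, dtype=float)
    y = config.baseline_retention + X @ beta
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=config.n_analytes)
    if config.warp_strength > 0:
        # monotone for y > 0, so the true elution order is untouched
        y = y + config.warp_strength * y**2 / np.max(np.abs(y))
    if np.min(y) <= 0:
        y = y - np.min(y) + _MIN_RETENTION
    return RetentionDataset(
        ids=tuple(f"analyte_{i + 1:03d}" for i in range(config.n_analytes)),
        X=X,
        y=y,
        descriptor_names=tuple(
            f"descriptor_{i + 1}" for i in range(config.n_descriptors)
        ),
        condition=ChromatographicCondition(column_name="simulated"),
    )


def make_benchmark_suite(
    n_instances: int, seed: int = 0
) -> list[tuple[SimulationConfig, RetentionDataset]]:
    """A seeded family of instances spanning noise and warp levels.

    Noise SD cycles over {0.1, 0.3, 0.6} min and warp strength over
    {0.2, 0.5, 1.0}, crossed round-robin, so the suite covers mild to
    strongly non-linear responses.
    """
    if n_instances < 1:
        raise ValueError("need n_instances >= 1")
    rng = np.random.default_rng(seed)
    noise_levels = (0.1, 0.3, 0.6)
    warp_levels = (0.2, 0.5, 1.0)
    suite = []
    for i in range(n_instances):
        cfg = SimulationConfig(
            noise_sd=noise_levels[i % len(noise_levels)],
            warp_strength=warp_levels[(i // len(noise_levels)) % len(warp_levels)],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suite.append((cfg, simulate_dataset(cfg)))
    return suite
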