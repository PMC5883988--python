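"""Synthetic multi-subject panels with modular signed connectivity.

Generates inputs with the statistical shape of a resting-state group
study: a block-structured population correlation matrix with positively
correlated modules and anticorrelated module systems, plus per-subject
Gaussian time-series panels drawn from noisy copies of it. Defaults
emulate a 30-subject x 230-timepoint x 105-region group whose
full-density absolute threshold splits roughly 70% positive / 30%
negative links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix, TimeSeriesPanel

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "make_population_connectivity",
    "sample_subject_panels",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic population and subject sampling.

    Regions are split into two anticorrelated systems; each system is
    subdivided into modules. Entries are ``within_module_corr`` inside a
    module, ``within_system_corr`` between modules of the same system,
    and ``between_module_corr`` (negative) across systems.
    ``anti_system_fraction`` sets the share of regions in the second
    system, which controls the negative-link fraction at full density.
    """

    n_subjects: int = 30
    n_timepoints: int = 230
    n_regions: int = 105
    n_modules: int = 6
    within_module_corr: float = 0.6
    between_module_corr: float = -0.3
    within_system_corr: float = 0.15
    anti_system_fraction: float = 0.181
    subject_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 3 or self.n_regions < 2:
            raise ValueError("degenerate fixture dimensions")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError("n_modules must be in [1, n_regions]")
        if not 0.0 < self.within_module_corr < 1.0:
            raise ValueError("within_module_corr must be in (0, 1)")
        if not -1.0 < self.between_module_corr <= 0.0:
            raise ValueError("between_module_corr must be in (-1, 0]")
        if not 0.0 <= self.anti_system_fraction < 1.0:
            raise ValueError("anti_system_fraction must be in [0, 1)")
        if self.subject_noise_sd < 0.0:
            raise ValueError("subject_noise_sd must be >= 0")

    def region_labels(self) -> list[str]:
        return [f"roi{i:03d}" for i in range(self.n_regions)]

    def module_assignment(self) -> tuple[np.ndarray, np.ndarray]:
        """(module index per region, system index per region).

        System 1 (the anticorrelated system) gets one module when
        ``anti_system_fraction`` > 0 and ``n_modules`` >= 2; the rest of
        the modules partition system 0 near-evenly.
        """
        n = self.n_regions
        n_anti = int(round(self.anti_system_fraction * n))
        if n_anti > 0 and self.n_modules >= 2:
            n_main_modules = self.n_modules - 1
        else:
            n_anti = 0
            n_main_modules = self.n_modules
        n_main = n - n_anti
        module = np.empty(n, dtype=int)
        sizes = [n_main // n_main_modules + (1 if m < n_main % n_main_modules else 0)
                 for m in range(n_main_modules)]
        start = 0
        for m, s in enumerate(sizes):
            module[start:start + s] = m
            start += s
        if n_anti:
            module[start:] = n_main_modules
        system = np.where(module == self.n_modules - 1, 1, 0) if n_anti else np.zeros(n, dtype=int)
        return module, system


def _nearest_correlation(mat: np.ndarray, min_eig: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    if w.min() >= min_eig:
        return mat, False
    w_clipped = np.clip(w, min_eig, None)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, True


def make_population_connectivity(spec: FixtureSpec) -> ConnectivityMatrix:
    """Block-structured population correlation matrix.

    Positive semi-definiteness is checked; a nearest-correlation repair
    (eigenvalue clipping + diagonal renormalization) is applied and
    logged if the requested block values violate it.
    """
    module, system = spec.module_assignment()
    same_module = module[:, None] == module[None, :]
    same_system = system[:, None] == system[None, :]
    mat = np.where(
        same_module, spec.within_module_corr,
        np.where(same_system, spec.within_system_corr, spec.between_module_corr),
    ).astype(float)
    np.fill_diagonal(mat, 1.0)
    mat, repaired = _nearest_correlation(mat)
    if repaired:
        logger.info("population connectivity repaired to nearest PSD correlation")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-10:
        raise ValueError(f"population matrix irreparably non-PSD "
                         f"(min eigenvalue {w.min():.3e})")
    return ConnectivityMatrix(mat, spec.region_labels())


def sample_subject_panels(
    population: ConnectivityMatrix, spec: FixtureSpec
) -> list[TimeSeriesPanel]:
    """Draw one Gaussian time-series panel per subject.

    Each subject's correlation is the population matrix perturbed by
    symmetric Gaussian noise of SD ``subject_noise_sd`` (PSD-repaired),
    and the panel rows are i.i.d. zero-mean multivariate normal draws
    from it. Fully seeded and reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    n = population.n_regions
    panels = []
    for s in range(spec.n_subjects):
        c = population.values.copy()
        if spec.subject_noise_sd > 0:
            noise = rng.normal(0.0, spec.subject_noise_sd, size=(n, n))
            noise = (noise + noise.T) / 2.0
            np.fill_diagonal(noise, 0.0)
            c = np.clip(c + noise, -0.999, 0.999)
            np.fill_diagonal(c, 1.0)
        c, _ = _nearest_correlation(c)
        # cholesky with jitter fallback for numerically semidefinite c
        try:
            chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(c + 1e-8 * np.eye(n))
        z = rng.standard_normal((spec.n_timepoints, n))
        values = z @ chol.T
        panels.append(TimeSeriesPanel(values, population.region_labels.copy(),
                                      subject_id=f"sub{s:03d}"))
    return panels
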