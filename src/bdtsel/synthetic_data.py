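"""Seeded synthetic breeding populations for offline pipeline testing.

Generates single-cycle populations with exactly the statistical structure
the multi-trait genomic mixed model assumes: genetic values drawn from a
matrix normal with row covariance G (the genomic relationship matrix) and
column covariance Σg (the t×t genetic covariance), plus independent
trait-specific Gaussian residuals — one phenotype record per line.

Three named fixtures emulate the shape of real wheat panels: a tiny
deterministic 12-line/2-trait set, a 200-line/4-trait panel with one
strongly genetically correlated trait pair and mixed improvement directions
(three decreasing traits, one increasing, as in elite yield-trial panels),
and a 160-line/4-trait biofortification-style panel where all traits are
weakly positively correlated and all improve upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import center_scale_markers, compute_grm, ensure_psd

__all__ = ["SimulationTruth", "simulate_markers", "simulate_population", "make_fixture"]


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a simulated population.

    h2[t] = Σg[t,t] / (Σg[t,t] + r_diag[t]) is the narrow-sense
    heritability implied by the variance components.
    """

    mu: np.ndarray          # t-vector of trait means
    sigma_g: np.ndarray     # t×t genetic covariance, PSD
    r_diag: np.ndarray      # t-vector of residual variances, > 0
    g: np.ndarray           # n×t true genetic values

    @property
    def h2(self) -> np.ndarray:
        dg = np.diag(self.sigma_g)
        return dg / (dg + self.r_diag)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_g = np.asarray(self.sigma_g, dtype=float)
        self.r_diag = np.asarray(self.r_diag, dtype=float)
        if np.any(self.r_diag <= 0):
            raise ValueError("residual variances must be strictly positive")
        if not np.allclose(self.sigma_g, self.sigma_g.T):
            raise ValueError("sigma_g must be symmetric")
        if np.linalg.eigvalsh(self.sigma_g)[0] < -1e-10:
            raise ValueError("sigma_g must be positive semidefinite")


def simulate_markers(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> np.ndarray:
    """Draw an n×p dosage matrix in {0,1,2} with per-marker allele frequency
    sampled uniformly from ``maf_range``; monomorphic columns are resampled."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 lines and p >= 1 markers")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    X = rng.binomial(2, freqs, size=(n, p)).astype(float)
    # resample any column that came out constant
    for _ in range(1000):
        mono = np.flatnonzero(X.std(axis=0) == 0.0)
        if mono.size == 0:
            return X
        f = rng.uniform(lo, hi, size=mono.size)
        X[:, mono] = rng.binomial(2, f, size=(n, mono.size))
    raise RuntimeError("could not produce polymorphic markers; widen maf_range or n")


def simulate_population(
    grm: np.ndarray,
    mu: np.ndarray,
    sigma_g: np.ndarray,
    r_diag: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, SimulationTruth]:
    """Simulate phenotypes y = μ + g + ε for one record per line.

    g is matrix-normal with row covariance ``grm`` and column covariance
    ``sigma_g`` (equivalently vec(g) ~ MVN(0, Σg ⊗ G) in trait-major
    order); residuals are independent across lines and traits with per-trait
    variances ``r_diag`` and zero residual covariance between traits.
    """
    mu = np.asarray(mu, dtype=float)
    sigma_g = np.asarray(sigma_g, dtype=float)
    r_diag = np.asarray(r_diag, dtype=float)
    t = mu.size
    if sigma_g.shape != (t, t):
        raise ValueError("sigma_g shape does not match number of traits")
    wg = np.linalg.eigvalsh(0.5 * (sigma_g + sigma_g.T))
    if wg[0] < -1e-10 * max(1.0, wg[-1]):
        raise ValueError("sigma_g is not positive semidefinite")

    G, _ = ensure_psd(np.asarray(grm, dtype=float))
    n = G.shape[0]
    rng = np.random.default_rng(seed)

    # factor both covariances; eigen-factorization tolerates PSD inputs
    wG, UG = np.linalg.eigh(G)
    Lg = UG * np.sqrt(np.clip(wG, 0.0, None))
    ws, Us = np.linalg.eigh(0.5 * (sigma_g + sigma_g.T))
    Ls = Us * np.sqrt(np.clip(ws, 0.0, None))

    Z = rng.standard_normal((n, t))
    g = Lg @ Z @ Ls.T
    eps = rng.standard_normal((n, t)) * np.sqrt(r_diag)
    y = mu + g + eps
    return y, SimulationTruth(mu=mu, sigma_g=sigma_g, r_diag=r_diag, g=g)


def _corr_to_cov(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    return corr * np.outer(sd, sd)


_PRESETS = ("tiny", "dataset1_like", "dataset2_like")


def make_fixture(name: str, seed: int = 20210120):
    """Build a named synthetic fixture: (phenotypes, grm, truth, trait_specs).

    Returns
    -------
    phenotypes : pandas.DataFrame indexed by line id
    grm : RelationshipMatrix derived from simulated markers
    truth : SimulationTruth
    directions : list of per-trait improvement directions
    """
    from .grm import RelationshipMatrix  # noqa: F401  (type in signature docs)

    if name == "tiny":
        n, traits = 12, ["T1", "T2"]
        sd = np.array([1.0, 2.0])
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        mu = np.array([10.0, 50.0])
        h2 = np.array([0.5, 0.5])
        directions = ["increase", "increase"]
        p = 60
    elif name == "dataset1_like":
        # elite-panel style: three traits improved downward (phenology,
        # height), one upward (yield); traits 1-2 genetically correlated 0.8
        n, traits = 200, ["DTHD", "DTMT", "Height", "GY"]
        sd = np.array([2.0, 2.2, 3.0, 0.35])
        corr = np.array(
            [
                [1.0, 0.8, 0.2, 0.0],
                [0.8, 1.0, 0.15, -0.05],
                [0.2, 0.15, 1.0, 0.2],
                [0.0, -0.05, 0.2, 1.0],
            ]
        )
        mu = np.array([80.0, 120.0, 100.0, 6.3])
        h2 = np.array([0.6, 0.6, 0.5, 0.4])
        directions = ["decrease", "decrease", "decrease", "increase"]
        p = 500
    elif name == "dataset2_like":
        # biofortification style: all traits upward, weak positive genetic
        # correlations throughout
        n, traits = 160, ["GY", "TKW", "GZnC", "GFeC"]
        sd = np.array([0.4, 2.5, 2.2, 2.4])
        corr = np.full((4, 4), 0.2)
        np.fill_diagonal(corr, 1.0)
        mu = np.array([5.3, 33.1, 28.1, 38.6])
        h2 = np.array([0.4, 0.5, 0.5, 0.45])
        directions = ["increase", "increase", "increase", "increase"]
        p = 500
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {_PRESETS}")

    sigma_g = _corr_to_cov(sd, corr)
    r_diag = np.diag(sigma_g) * (1.0 - h2) / h2

    markers = simulate_markers(n, p, seed=seed)
    G = compute_grm(center_scale_markers(markers))
    y, truth = simulate_population(G.values, mu, sigma_g, r_diag, seed=seed + 1)

    ids = [f"L{i + 1:03d}" for i in range(n)]
    phenotypes = pd.DataFrame(y, index=pd.Index(ids, name="line"), columns=traits)
    return phenotypes, G, truth, directions
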