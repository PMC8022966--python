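"""Genomic relationship matrix from centered, standardized markers.

The GRM is the row-covariance of the matrix-normal prior on genetic values:
``G = W Wᵀ / p`` where ``W`` is the n×p marker matrix with each column
centered to mean zero and scaled to unit (population) standard deviation.
With unit-variance columns the mean diagonal element converges to 1 as the
number of markers grows, so no further 2Σp(1−p) rescaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RelationshipMatrix", "center_scale_markers", "compute_grm", "ensure_psd"]


@dataclass
class RelationshipMatrix:
    """An n×n genomic relationship matrix with provenance."""

    values: np.ndarray
    provenance: str = "from_markers"  # or "supplied"
    jitter: float = field(default=0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"relationship matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")
        if np.any(np.diag(v) < 0):
            raise ValueError("relationship matrix has negative diagonal entries")
        self.values = 0.5 * (v + v.T)


def center_scale_markers(raw: np.ndarray) -> np.ndarray:
    """Center each marker column to mean 0 and scale to unit population SD.

    Parameters
    ----------
    raw
        n×p genotype matrix (e.g. {0,1,2} allele dosages).

    Raises
    ------
    ValueError
        If any column is monomorphic (zero variance); the message names
        the first offending column index.
    """
    X = np.asarray(raw, dtype=float)
    if X.ndim != 2:
        raise ValueError("marker matrix must be 2-dimensional")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (divide-by-n) convention
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(f"marker column {bad[0]} has zero variance (monomorphic)")
    return (X - mu) / sd


def compute_grm(scaled: np.ndarray) -> RelationshipMatrix:
    """Cross-product GRM ``W Wᵀ / p`` from centered/standardized markers."""
    W = np.asarray(scaled, dtype=float)
    if W.ndim != 2 or W.shape[1] == 0:
        raise ValueError("need an n×p matrix with p >= 1 markers")
    p = W.shape[1]
    G = W @ W.T / p
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    return RelationshipMatrix(values=G, provenance="from_markers")


def ensure_psd(G: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Return a PSD version of ``G`` and the diagonal jitter that was added.

    Eigenvalues more negative than ``-tol``·max(1, λmax) indicate a genuinely
    indefinite input and raise; small negative eigenvalues from round-off are
    repaired by adding the smallest power-of-ten jitter that succeeds.
    """
    G = 0.5 * (G + G.T)
    w = np.linalg.eigvalsh(G)
    lo, hi = w[0], w[-1]
    if lo >= 0:
        return G, 0.0
    if lo < -tol * max(1.0, hi):
        raise ValueError(f"matrix is not PSD (min eigenvalue {lo:.3e})")
    jitter = 10.0 ** np.ceil(np.log10(-lo + 1e-300))
    return G + jitter * np.eye(G.shape[0]), float(jitter)
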