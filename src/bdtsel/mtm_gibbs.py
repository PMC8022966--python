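"""Gibbs sampler for the multi-trait genomic mixed model (GBLUP).

Model, per trait t = 1..T with one record per line (Z = I):

    y_t = 1 μ_t + g_t + ε_t,
    vec(g) ~ MVN(0, Σg ⊗ G),      ε ~ MVN(0, R ⊗ I),  R diagonal.

Conjugate full conditionals: trait intercepts are normal (flat prior),
genetic values are sampled trait-by-trait in the eigenbasis of G (one
eigendecomposition up front makes every sweep O(nT) plus one T×T solve per
trait), Σg is inverse-Wishart and each residual variance is a scaled
inverse chi-square draw.

Priors default to a weakly informative 50/50 split of the observed
phenotypic variance: Σg ~ InvWishart(df = T+2, scale = diag(0.5·var(y))),
σe²_t ~ Scale-inv-χ²(df = 4, scale = 0.5·var(y_t)); both overridable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg
from scipy.stats import invwishart

from .config_io import DataBundle
from .grm import ensure_psd

__all__ = [
    "MCMCConfig",
    "PosteriorChain",
    "fit_mtm",
    "gblup_fixed_variance",
    "predictive_components",
]

logger = logging.getLogger("bdtsel")

_EIG_FLOOR = 1e-8  # relative floor on relationship-matrix eigenvalues


@dataclass
class MCMCConfig:
    """Chain schedule and prior hyperparameters.

    ``n_burn`` sweeps are discarded, then every ``thin``-th sweep is stored
    until ``n_kept`` draws accumulate. Priors left as ``None`` are filled
    from the phenotypic variances at fit time.
    """

    n_burn: int = 1000
    n_kept: int = 1000
    thin: int = 1
    seed: int = 0
    prior_sigma_g_df: float | None = None       # default: t + 2
    prior_sigma_g_scale: np.ndarray | None = None  # default: diag(0.5 var(y))
    prior_resid_df: float = 4.0
    prior_resid_scale: np.ndarray | None = None  # default: 0.5 var(y_t)

    def __post_init__(self) -> None:
        for name in ("n_burn", "n_kept", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.prior_resid_df <= 0:
            raise ValueError("prior_resid_df must be > 0")


@dataclass
class PosteriorChain:
    """Stored posterior draws of the multi-trait model.

    Arrays are indexed draw-first: ``mu`` (K×t), ``sigma_g`` (K×t×t),
    ``r_diag`` (K×t) and ``g`` (K×n×t). ``eigen_cache`` holds the
    (eigenvalues, eigenvectors) of the relationship matrix used in fitting.
    """

    mu: np.ndarray
    sigma_g: np.ndarray
    r_diag: np.ndarray
    g: np.ndarray
    line_ids: list[str]
    traits: list[str]
    eigen_cache: tuple[np.ndarray, np.ndarray] | None = None
    config: MCMCConfig | None = None
    gebv_mean: np.ndarray = field(init=False)
    gebv_var: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gebv_mean = self.g.mean(axis=0)
        self.gebv_var = (
            self.g.var(axis=0, ddof=1)
            if self.g.shape[0] > 1
            else np.zeros_like(self.g[0])
        )

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def n(self) -> int:
        return self.g.shape[1]

    @property
    def t(self) -> int:
        return self.mu.shape[1]

    def save(self, outdir: str | Path) -> None:
        """Persist the chain: small parameters as CSV, g draws as npz."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        t = self.t
        np.savetxt(out / "mu.csv", self.mu, delimiter=",",
                   header=",".join(self.traits), comments="")
        np.savetxt(out / "sigma_g.csv", self.sigma_g.reshape(self.n_draws, t * t),
                   delimiter=",",
                   header=",".join(f"{a}:{b}" for a in self.traits for b in self.traits),
                   comments="")
        np.savetxt(out / "r_diag.csv", self.r_diag, delimiter=",",
                   header=",".join(self.traits), comments="")
        np.savez_compressed(out / "g_draws.npz", g=self.g)
        manifest = {
            "line_ids": self.line_ids,
            "traits": self.traits,
            "n_draws": self.n_draws,
            "seed": None if self.config is None else self.config.seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "PosteriorChain":
        out = Path(outdir)
        manifest = json.loads((out / "manifest.json").read_text())
        t = len(manifest["traits"])
        mu = np.loadtxt(out / "mu.csv", delimiter=",", skiprows=1, ndmin=2)
        sg = np.loadtxt(out / "sigma_g.csv", delimiter=",", skiprows=1, ndmin=2)
        r = np.loadtxt(out / "r_diag.csv", delimiter=",", skiprows=1, ndmin=2)
        g = np.load(out / "g_draws.npz")["g"]
        return cls(
            mu=mu, sigma_g=sg.reshape(-1, t, t), r_diag=r, g=g,
            line_ids=[str(x) for x in manifest["line_ids"]],
            traits=list(manifest["traits"]),
        )


def _prepare_eigen(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G, jit = ensure_psd(G)
    if jit:
        logger.info("relationship matrix jittered by %.1e to restore PSD", jit)
    d, U = np.linalg.eigh(G)
    d = np.maximum(d, _EIG_FLOOR * max(d[-1], 1.0))
    return d, U


def fit_mtm(
    bundle: DataBundle,
    config: MCMCConfig,
    fix_sigma_g: np.ndarray | None = None,
    fix_r_diag: np.ndarray | None = None,
) -> PosteriorChain:
    """Run the Gibbs sampler and return the stored posterior chain.

    ``fix_sigma_g``/``fix_r_diag`` clamp the variance components at given
    values (degenerate priors), which reduces the sampler to Bayesian GBLUP
    with known variances — the configuration used by the closed-form
    mixed-model-equation cross-checks.
    """
    Y = bundle.phenotypes.to_numpy(dtype=float)
    n, t = Y.shape
    d, U = _prepare_eigen(bundle.grm().values)
    Yt = U.T @ Y                      # phenotypes rotated to the eigenbasis
    u1 = U.T @ np.ones(n)

    # floor keeps the default priors proper even for (near-)constant traits
    var_y = np.maximum(Y.var(axis=0, ddof=1), 1e-8)
    nu_g = config.prior_sigma_g_df if config.prior_sigma_g_df is not None else t + 2.0
    S_g = (
        np.asarray(config.prior_sigma_g_scale, dtype=float)
        if config.prior_sigma_g_scale is not None
        else np.diag(0.5 * var_y)
    )
    nu_e = config.prior_resid_df
    s2_e = (
        np.asarray(config.prior_resid_scale, dtype=float)
        if config.prior_resid_scale is not None
        else 0.5 * var_y
    )

    rng = np.random.default_rng(config.seed)
    mu = Y.mean(axis=0)
    sigma_g = np.diag(0.5 * var_y) if fix_sigma_g is None else np.array(fix_sigma_g, dtype=float)
    r_diag = 0.5 * var_y if fix_r_diag is None else np.array(fix_r_diag, dtype=float)
    gt = np.zeros((n, t))             # genetic values in the eigenbasis

    K = config.n_kept
    out_mu = np.empty((K, t))
    out_sg = np.empty((K, t, t))
    out_r = np.empty((K, t))
    out_g = np.empty((K, n, t))

    total = config.n_burn + K * config.thin
    stored = 0
    t0 = time.perf_counter()
    idx = np.arange(t)
    for sweep in range(total):
        W = Yt - np.outer(u1, mu)     # rotated residuals around the intercepts
        # --- genetic values, trait by trait, conditioned on the other traits
        for j in range(t):
            rest = idx != j
            if t > 1:
                c = linalg.solve(sigma_g[np.ix_(rest, rest)], sigma_g[rest, j],
                                 assume_a="pos")
                a = gt[:, rest] @ c
                s2 = max(sigma_g[j, j] - sigma_g[j, rest] @ c, 1e-12)
            else:
                a = np.zeros(n)
                s2 = sigma_g[0, 0]
            pv = d * s2               # per-line conditional prior variance
            ev = r_diag[j]
            V = pv * ev / (pv + ev)
            mean = V * (a / pv + W[:, j] / ev)
            gt[:, j] = mean + np.sqrt(V) * rng.standard_normal(n)
        g = U @ gt
        # --- trait intercepts (flat prior)
        resid_mean = (Y - g).mean(axis=0)
        mu = resid_mean + np.sqrt(r_diag / n) * rng.standard_normal(t)
        # --- genetic covariance (inverse-Wishart full conditional)
        if fix_sigma_g is None:
            Sg_post = S_g + gt.T @ (gt / d[:, None])
            sigma_g = invwishart.rvs(df=nu_g + n, scale=Sg_post, random_state=rng)
            sigma_g = np.atleast_2d(sigma_g)
        # --- residual variances (scaled inverse chi-square full conditionals)
        if fix_r_diag is None:
            E = Y - mu - g
            sse = np.einsum("ij,ij->j", E, E)
            r_diag = (nu_e * s2_e + sse) / rng.chisquare(nu_e + n, size=t)
        if not (np.all(np.isfinite(r_diag)) and np.all(np.isfinite(sigma_g))) or np.any(
            r_diag > 1e12
        ):
            raise RuntimeError(f"divergent variance draw at sweep {sweep}")
        # --- storage
        k = sweep - config.n_burn
        if k >= 0 and (k + 1) % config.thin == 0:
            out_mu[stored] = mu
            out_sg[stored] = sigma_g
            out_r[stored] = r_diag
            out_g[stored] = g
            stored += 1
        if (sweep + 1) % max(total // 10, 1) == 0:
            logger.info(
                "sweep %d/%d (%d draws stored, %.1fs)",
                sweep + 1, total, stored, time.perf_counter() - t0,
            )

    return PosteriorChain(
        mu=out_mu, sigma_g=out_sg, r_diag=out_r, g=out_g,
        line_ids=bundle.line_ids, traits=bundle.traits,
        eigen_cache=(d, U), config=config,
    )


def gblup_fixed_variance(
    bundle: DataBundle,
    sigma_g: np.ndarray,
    r_diag: np.ndarray,
) -> np.ndarray:
    """Exact multi-trait BLUP of genetic values for known variance components.

    Solves the mixed-model equations for the trait-major stacked system
    y = (I_t ⊗ 1)β + g with var(g) = Σg ⊗ G and var(ε) = R ⊗ I by direct
    linear algebra; intended for small n as the sampler's oracle.
    """
    Y = bundle.phenotypes.to_numpy(dtype=float)
    n, t = Y.shape
    sigma_g = np.atleast_2d(np.asarray(sigma_g, dtype=float))
    r_diag = np.atleast_1d(np.asarray(r_diag, dtype=float))
    G, _ = ensure_psd(bundle.grm().values)
    w = np.linalg.eigvalsh(G)
    if w[0] < _EIG_FLOOR * max(w[-1], 1.0):
        G = G + _EIG_FLOOR * max(w[-1], 1.0) * np.eye(n)

    Rinv = np.diag(1.0 / r_diag)
    Ginv = np.linalg.inv(G)
    Sginv = np.linalg.inv(sigma_g)
    yvec = Y.T.reshape(-1)                       # trait-major stack
    ones = np.ones((n, 1))

    Cxx = n * Rinv
    Cxz = np.kron(Rinv, ones.T)                  # t × nt
    Czz = np.kron(Rinv, np.eye(n)) + np.kron(Sginv, Ginv)
    C = np.block([[Cxx, Cxz], [Cxz.T, Czz]])
    rhs = np.concatenate([Rinv @ Y.T @ np.ones(n), np.kron(Rinv, np.eye(n)) @ yvec])
    sol = np.linalg.solve(C, rhs)
    ghat = sol[t:].reshape(t, n).T
    return ghat


def predictive_components(
    chain: PosteriorChain,
    k: int,
    o: int,
    candidate_cov: str = "phenotypic",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of candidate o's predictive MVN at posterior draw k.

    m_o = μ^(k) + g_o^(k); the covariance is the phenotypic P^(k) = Σg^(k)
    + diag(r^(k)) by default, or Σg^(k) alone with ``candidate_cov='genetic'``.
    """
    m = chain.mu[k] + chain.g[k, o]
    if candidate_cov == "phenotypic":
        P = chain.sigma_g[k] + np.diag(chain.r_diag[k])
    elif candidate_cov == "genetic":
        P = chain.sigma_g[k].copy()
    else:
        raise ValueError("candidate_cov must be 'phenotypic' or 'genetic'")
    return m, P
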