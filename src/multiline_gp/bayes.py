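"""Gibbs samplers for BayesC and BSSVS marker-effect models.

Both models put a two-component prior on each SNP effect and decide, in
every iteration of the chain, whether the SNP currently has a "large"
effect.  BayesC mixes a point mass at zero (prior probability ``pi``) with
a normal of common variance sigma_w^2; BSSVS replaces the point mass by a
small-variance normal sigma_w^2 / c, so every SNP always contributes a
(possibly tiny) effect.

The samplers use standard single-site full conditionals with residual
updating: for SNP j with current-residual inner product r_j = z_j'e and
column norm c_j, the marginal likelihood ratio of the large state is

    sqrt(sigma_e^2 / (c_j v + sigma_e^2))
      * exp(r_j^2 v / (2 sigma_e^2 (c_j v + sigma_e^2)))

with v the effect variance of the state, and the effect is drawn from
N(r_j / (c_j + sigma_e^2 / v), sigma_e^2 / (c_j + sigma_e^2 / v)).
Variance components get scaled-inverse-chi-square updates; the overall mean
is sampled as an unpenalized location.  The per-SNP prior variance is
initialized as the total genetic variance divided by the number of SNPs
(genotypes are centred and scaled to unit variance beforehand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .datatypes import VarianceComponents
from .predictors import CenterScale, MarkerEffects

__all__ = [
    "GibbsConfig",
    "PosteriorSummary",
    "gibbs_bayesc",
    "gibbs_bssvs",
    "posterior_summaries",
]


@dataclass(frozen=True)
class GibbsConfig:
    """Chain settings and priors for the variable-selection samplers."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    pi: float = 0.9
    c: float = 100.0          # BSSVS small-to-large variance ratio
    nu_w: float = 4.2         # prior df, SNP-effect variance
    nu_e: float = 4.2         # prior df, residual variance
    seed: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must lie in [0, 1)")
        if self.c < 1.0:
            raise ValueError("c must be at least 1 (c = 1 collapses the "
                             "mixture to equal shrinkage)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@njit(cache=True)
def _gibbs_kernel(z, y, pi, small_ratio, bssvs, n_iter, burn_in, thin,
                  nu_w, scale_w, nu_e, scale_e, sw2_init, se2_init, seed):
    np.random.seed(seed)
    n, p = z.shape
    zz = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += z[i, j] * z[i, j]
        zz[j] = acc

    mu = y.mean()
    e = y - mu
    w = np.zeros(p)
    delta = np.zeros(p, dtype=np.int8)
    sw2 = sw2_init
    se2 = se2_init

    n_kept = (n_iter - burn_in + thin - 1) // thin
    kept_w = np.zeros((n_kept, p))
    kept_delta = np.zeros((n_kept, p), dtype=np.int8)
    kept_se2 = np.zeros(n_kept)
    kept_sw2 = np.zeros(n_kept)
    kept_mu = np.zeros(n_kept)
    kept = 0
    ok = True

    log_prior_odds = 0.0
    if pi > 0.0:
        log_prior_odds = np.log(1.0 - pi) - np.log(pi)

    for it in range(n_iter):
        # overall mean
        val_mean = 0.0
        for i in range(n):
            val_mean += e[i]
        val_mean = val_mean / n + mu
        new_mu = val_mean + np.random.normal() * np.sqrt(se2 / n)
        shift = new_mu - mu
        for i in range(n):
            e[i] -= shift
        mu = new_mu

        # SNP effects
        for j in range(p):
            wj = w[j]
            if wj != 0.0:
                for i in range(n):
                    e[i] += z[i, j] * wj
            r = 0.0
            for i in range(n):
                r += z[i, j] * e[i]
            cj = zz[j]
            v_large = sw2
            if bssvs:
                v_small = sw2 / small_ratio
            else:
                v_small = 0.0

            if pi <= 0.0:
                dj = 1
            else:
                # log marginal-likelihood ratio large vs small/null state
                t_large = cj * v_large + se2
                log_l1 = -0.5 * np.log(t_large / se2) \
                    + 0.5 * r * r * v_large / (se2 * t_large)
                if bssvs:
                    t_small = cj * v_small + se2
                    log_l0 = -0.5 * np.log(t_small / se2) \
                        + 0.5 * r * r * v_small / (se2 * t_small)
                else:
                    log_l0 = 0.0
                log_odds = log_prior_odds + log_l1 - log_l0
                if log_odds > 35.0:
                    prob1 = 1.0
                elif log_odds < -35.0:
                    prob1 = 0.0
                else:
                    prob1 = 1.0 / (1.0 + np.exp(-log_odds))
                dj = 1 if np.random.random() < prob1 else 0
            delta[j] = dj

            if dj == 1:
                v = v_large
            else:
                v = v_small
            if v > 0.0:
                denom = cj + se2 / v
                mean_w = r / denom
                sd_w = np.sqrt(se2 / denom)
                wj_new = mean_w + np.random.normal() * sd_w
            else:
                wj_new = 0.0
            w[j] = wj_new
            if wj_new != 0.0:
                for i in range(n):
                    e[i] -= z[i, j] * wj_new

        # SNP-effect variance
        if bssvs:
            ss = 0.0
            for j in range(p):
                if delta[j] == 1:
                    ss += w[j] * w[j]
                else:
                    ss += w[j] * w[j] * small_ratio
            df = nu_w + p
        else:
            ss = 0.0
            m = 0
            for j in range(p):
                if delta[j] == 1:
                    ss += w[j] * w[j]
                    m += 1
            df = nu_w + m
        sw2 = (ss + nu_w * scale_w) / np.random.chisquare(df)

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        se2 = (sse + nu_e * scale_e) / np.random.chisquare(nu_e + n)
        if not np.isfinite(se2) or se2 <= 0.0:
            ok = False
            break

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_w[kept] = w
            kept_delta[kept] = delta
            kept_se2[kept] = se2
            kept_sw2[kept] = sw2
            kept_mu[kept] = mu
            kept += 1

    return kept_w, kept_delta, kept_se2, kept_sw2, kept_mu, kept, ok


@dataclass
class ChainStore:
    """Raw thinned post-burn-in draws from one Gibbs run."""

    w: np.ndarray            # n_kept x p
    delta: np.ndarray        # n_kept x p, large-effect indicators
    sigma_e2: np.ndarray
    sigma_w2: np.ndarray
    mu: np.ndarray
    model: str
    config: GibbsConfig


@dataclass
class PosteriorSummary:
    """Posterior means plus inclusion probabilities and diagnostics."""

    effects: MarkerEffects
    inclusion_prob: np.ndarray
    mean_mu: float
    mean_sigma_e2: float
    sd_sigma_e2: float
    mean_sigma_w2: float
    ess_sigma_e2: float
    model: str
    config: GibbsConfig
    chain: ChainStore | None = None

    def predict(self, z: np.ndarray, include_mean: bool = False) -> np.ndarray:
        ebv = np.asarray(z, dtype=float) @ self.effects.weights
        return ebv + self.mean_mu if include_mean else ebv


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS; NaN for constant chains."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    if m < 4 or np.var(x) == 0:
        return float("nan")
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[m - 1:] / (np.arange(m, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, m):
        if acf[k] < 0:
            break
        s += acf[k]
    return float(m / (1.0 + 2.0 * s))


def _run_chain(z, y, cfg: GibbsConfig, vc: VarianceComponents, bssvs: bool,
               scaling: CenterScale | None, model: str) -> PosteriorSummary:
    z = np.ascontiguousarray(z, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if z.shape[0] != len(y):
        raise ValueError("Z and y dimensions disagree")
    p = z.shape[1]
    vc_p = vc if vc.n_snps else vc.with_n_snps(p)
    sw2_init = vc_p.snp_variance
    if bssvs:
        # calibrate the large-effect variance so the mixture-implied genetic
        # variance p * (pi/c + (1 - pi)) * sigma_w^2 matches sigma_a^2;
        # without this the chain must inflate sigma_w^2 by ~c and mixes badly
        sw2_init = sw2_init / ((1.0 - cfg.pi) + cfg.pi / cfg.c)
    se2_init = vc_p.residual if vc_p.residual > 0 else 0.1 * np.var(y)
    # scaled-inv-chi2 prior with mean at the initial values (df > 2)
    scale_w = sw2_init * (cfg.nu_w - 2.0) / cfg.nu_w
    scale_e = se2_init * (cfg.nu_e - 2.0) / cfg.nu_e
    out = _gibbs_kernel(
        z, y, cfg.pi, cfg.c, bssvs, cfg.n_iter, cfg.burn_in, cfg.thin,
        cfg.nu_w, scale_w, cfg.nu_e, scale_e, sw2_init, se2_init,
        int(cfg.seed) & 0x7FFFFFFF,
    )
    kept_w, kept_delta, kept_se2, kept_sw2, kept_mu, kept, ok = out
    if not ok:
        raise RuntimeError(
            f"{model} chain diverged (non-finite residual variance) after "
            f"{kept} kept draws; check scaling of y and Z")
    store = ChainStore(
        w=kept_w[:kept], delta=kept_delta[:kept], sigma_e2=kept_se2[:kept],
        sigma_w2=kept_sw2[:kept], mu=kept_mu[:kept], model=model, config=cfg,
    )
    return posterior_summaries(store, scaling=scaling)


def posterior_summaries(store: ChainStore,
                        scaling: CenterScale | None = None) -> PosteriorSummary:
    """Means over kept draws, inclusion probabilities, and an ESS diagnostic."""
    if store.w.shape[0] == 0:
        raise ValueError("no kept iterations in the chain store")
    mean_w = store.w.mean(axis=0)
    incl = store.delta.mean(axis=0)
    p = store.w.shape[1]
    snp_ids = scaling.snp_ids if scaling is not None else np.arange(p).astype(object)
    effects = MarkerEffects(
        snp_ids=snp_ids, weights=mean_w, scaling=scaling,
        intercept=float(store.mu.mean()),
        metadata={"model": store.model, "pi": store.config.pi},
    )
    return PosteriorSummary(
        effects=effects,
        inclusion_prob=incl,
        mean_mu=float(store.mu.mean()),
        mean_sigma_e2=float(store.sigma_e2.mean()),
        sd_sigma_e2=float(store.sigma_e2.std()),
        mean_sigma_w2=float(store.sigma_w2.mean()),
        ess_sigma_e2=_effective_sample_size(store.sigma_e2),
        model=store.model,
        config=store.config,
        chain=store,
    )


def gibbs_bayesc(z, y, cfg: GibbsConfig | None = None,
                 vc: VarianceComponents | None = None,
                 scaling: CenterScale | None = None) -> PosteriorSummary:
    """BayesC: point mass at zero with prior probability pi, else N(0, sigma_w^2)."""
    cfg = cfg or GibbsConfig(pi=0.9)
    if vc is None:
        raise ValueError("variance components are required")
    return _run_chain(z, y, cfg, vc, bssvs=False, scaling=scaling, model="bayesc")


def gibbs_bssvs(z, y, cfg: GibbsConfig | None = None,
                vc: VarianceComponents | None = None,
                scaling: CenterScale | None = None) -> PosteriorSummary:
    """BSSVS: mixture of N(0, sigma_w^2) and N(0, sigma_w^2 / c) per SNP."""
    cfg = cfg or GibbsConfig(pi=0.999)
    if vc is None:
        raise ValueError("variance components are required")
    return _run_chain(z, y, cfg, vc, bssvs=True, scaling=scaling, model="bssvs")
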