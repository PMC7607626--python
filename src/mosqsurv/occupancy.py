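"""Data-augmented multi-species occupancy model (MSOM).

Estimates regional species richness and community structure from binary
detection histories while separating presence from detectability.  The
hierarchy, for site j, occasion k and species slot i in a supercommunity of
n observed + n_aug augmented all-zero slots:

    w_i     ~ Bernoulli(Omega)            community inclusion
    Z_{j,i} ~ Bernoulli(psi_i * w_i)      occupancy,  logit(psi_i) = u_i
    X_{j,k,i} ~ Bernoulli(p_i * Z_{j,i})  detection,  logit(p_i)   = v_i
    u_i ~ Normal(mu_u, 1/tau_u),  v_i ~ Normal(mu_v, 1/tau_v)

with weakly informative Normal(0, 2.25^2) priors on mu_u and mu_v, vague
Gamma(0.1, 0.1) priors on the precisions tau_u and tau_v, and a flat
Uniform(0, 1) prior on Omega.  Regional richness is R = n + sum of w over
augmented slots; derived community metrics (alpha-, beta-, zeta-diversity
and per-species occupied-site counts) are monitored per draw.

Sampling is Metropolis-within-Gibbs: the discrete layer (w, Z, Omega) has
exact full conditionals — w is updated with Z marginalized out (collapsed)
to avoid the sticky joint mode, then Z is refreshed; the logits u, v use
per-slot Gaussian random-walk Metropolis with step sizes tuned to a 0.3-0.5
acceptance rate during an adaptation phase and frozen afterwards; the
community means and precisions are conjugate Normal/Gamma updates over all
supercommunity slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .data import DetectionArray

logger = logging.getLogger("mosqsurv")

MONITORED = ("omega", "mu_u", "sigma_u", "mu_v", "sigma_v", "R", "alpha", "beta", "zeta")


@dataclass
class MsomConfig:
    """Sampler settings and priors for the occupancy model."""

    n_chains: int = 3
    n_iter: int = 20_000
    n_adapt: int = 1_000
    n_burn: int = 10_000
    thin: int = 1
    prior_mean: float = 0.0
    prior_sd: float = 2.25
    gamma_r: float = 0.1
    gamma_lambda: float = 0.1
    step_init: float = 0.5
    seed: int = 0
    store_latent: bool = False

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if min(self.prior_sd, self.gamma_r, self.gamma_lambda, self.step_init) <= 0:
            raise ValueError("prior parameters and step sizes must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MsomState:
    """Current sampler state over the augmented supercommunity."""

    w: np.ndarray  # (M,) inclusion indicators
    Z: np.ndarray  # (J, M) occupancy
    u: np.ndarray  # (M,) occupancy logits
    v: np.ndarray  # (M,) detection logits
    mu_u: float
    tau_u: float
    mu_v: float
    tau_v: float
    omega: float


def _detection_summaries(data: DetectionArray) -> tuple[np.ndarray, np.ndarray]:
    """Per (site, slot) detection counts and per-site sampled-occasion counts."""
    det = (data.X * data.occasion_mask[:, :, None]).sum(axis=1)
    K = data.occasion_mask.sum(axis=1)
    return det.astype(np.int64), K.astype(np.int64)


def initial_state(data: DetectionArray, rng: np.random.Generator) -> MsomState:
    det, _ = _detection_summaries(data)
    M = data.n_slots
    observed = det.any(axis=0)
    w = np.where(observed, 1, (rng.random(M) < 0.5)).astype(np.int8)
    Z = np.where(det > 0, 1, (rng.random(det.shape) < 0.5) & (w[None, :] == 1)).astype(np.int8)
    return MsomState(
        w=w,
        Z=Z,
        u=rng.normal(0.0, 1.0, M),
        v=rng.normal(-1.0, 1.0, M),
        mu_u=0.0,
        tau_u=1.0,
        mu_v=0.0,
        tau_v=1.0,
        omega=float(rng.uniform(0.25, 0.75)),
    )


def gibbs_update_discrete(
    state: MsomState,
    data: DetectionArray,
    rng: np.random.Generator,
    update_omega: bool = True,
) -> MsomState:
    """Exact full-conditional update of (w, Z, Omega).

    Inclusion w is sampled with Z marginalized over sites — for a slot with
    no detections anywhere, P(w=1 | .) has odds  Omega * prod_j [psi (1-p)^{K_j}
    + (1-psi)]  against (1-Omega); detected slots are pinned at w=1.  Z is
    then refreshed given w: pinned to 1 where detections exist, else
    Bernoulli with odds psi (1-p)^{K_j} : (1-psi).  Omega draws from its
    Beta(1 + sum w, 1 + M - sum w) conditional (flat prior).
    """
    det, K = _detection_summaries(data)
    J, M = det.shape
    psi = expit(state.u)
    p = expit(state.v)
    log_no_det = K[:, None] * log_expit(-state.v)[None, :]  # log (1-p)^{K_j}

    detected_slot = det.any(axis=0)
    with np.errstate(divide="ignore"):
        # site-wise log [ psi (1-p)^K + (1-psi) ]
        site_terms = np.log(psi[None, :] * np.exp(log_no_det) + (1.0 - psi)[None, :])
        logL = site_terms.sum(axis=0)
        logit_w = np.log(state.omega) - np.log1p(-state.omega) + logL
    w = np.where(
        detected_slot, 1, (rng.random(M) < expit(logit_w)).astype(np.int8)
    ).astype(np.int8)

    q = psi[None, :] * np.exp(log_no_det)
    denom = q + (1.0 - psi)[None, :]
    pz = np.divide(q, denom, out=np.zeros_like(q), where=denom > 0)
    Z = ((rng.random((J, M)) < pz) & (w[None, :] == 1)).astype(np.int8)
    Z[det > 0] = 1

    state.w, state.Z = w, Z
    if update_omega:
        s = int(w.sum())
        state.omega = float(rng.beta(1 + s, 1 + M - s))
    return state


def mh_update_logits(
    state: MsomState,
    data: DetectionArray,
    step_u: np.ndarray,
    step_v: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk Metropolis update of every u_i and v_i.

    Slots are conditionally independent given the hyperparameters, so all
    proposals are made and accepted elementwise in one block.  A slot with
    w_i = 0 contributes no likelihood (its Z row is degenerate at zero), so
    its logits follow the community prior.  Returns the per-slot acceptance
    indicators for step adaptation.
    """
    det, K = _detection_summaries(data)
    J, M = det.shape
    occ = state.Z.sum(axis=0)  # occupied sites per slot
    d = (state.Z * det).sum(axis=0)  # detections at occupied sites
    ko = (state.Z * K[:, None]).sum(axis=0)  # occasions at occupied sites
    w = state.w.astype(float)

    def target_u(u: np.ndarray) -> np.ndarray:
        lik = occ * log_expit(u) + (J - occ) * log_expit(-u)
        return w * lik - 0.5 * state.tau_u * (u - state.mu_u) ** 2

    def target_v(v: np.ndarray) -> np.ndarray:
        lik = d * log_expit(v) + (ko - d) * log_expit(-v)
        return w * lik - 0.5 * state.tau_v * (v - state.mu_v) ** 2

    prop_u = state.u + step_u * rng.standard_normal(M)
    acc_u = np.log(rng.random(M)) < target_u(prop_u) - target_u(state.u)
    state.u = np.where(acc_u, prop_u, state.u)

    prop_v = state.v + step_v * rng.standard_normal(M)
    acc_v = np.log(rng.random(M)) < target_v(prop_v) - target_v(state.v)
    state.v = np.where(acc_v, prop_v, state.v)
    return acc_u, acc_v


def gibbs_update_hyper(
    state: MsomState, config: MsomConfig, rng: np.random.Generator
) -> MsomState:
    """Conjugate update of (mu_u, tau_u, mu_v, tau_v).

    All supercommunity slots carry (u_i, v_i) draws whether or not they are
    currently included, so the conjugate updates run over every slot: a
    precision-weighted Normal for each mean, and a Gamma(r + M/2,
    lambda + sum of squares / 2) for each precision.
    """
    p0 = 1.0 / config.prior_sd**2
    for mean_attr, tau_attr, x in (("mu_u", "tau_u", state.u), ("mu_v", "tau_v", state.v)):
        m = len(x)
        if m == 0:
            setattr(state, mean_attr, float(rng.normal(config.prior_mean, config.prior_sd)))
            setattr(state, tau_attr, float(rng.gamma(config.gamma_r, 1.0 / config.gamma_lambda)))
            continue
        tau = getattr(state, tau_attr)
        prec = p0 + m * tau
        mean = (p0 * config.prior_mean + tau * x.sum()) / prec
        mu = float(rng.normal(mean, 1.0 / np.sqrt(prec)))
        setattr(state, mean_attr, mu)
        shape = config.gamma_r + m / 2.0
        rate = config.gamma_lambda + 0.5 * ((x - mu) ** 2).sum()
        setattr(state, tau_attr, float(rng.gamma(shape, 1.0 / rate)))
    return state


def _diversity_draw(
    w: np.ndarray, Z: np.ndarray, n_obs: int
) -> tuple[int, float, float, int, np.ndarray, np.ndarray]:
    """Per-draw diversity metrics from the latent (w, Z)."""
    R = int(w.sum())
    site_richness = (Z * w[None, :]).sum(axis=1)
    alpha = float(site_richness.mean())
    beta = R / alpha if alpha > 0 else np.nan
    zeta = int(((Z * w[None, :]).min(axis=0) == 1).sum())
    sites_per_species = Z[:, :n_obs].sum(axis=0)
    return R, alpha, beta, zeta, site_richness, sites_per_species


@dataclass
class MsomPosterior:
    """Post-burn-in MCMC draws and per-draw derived diversity metrics."""

    draws: dict[str, np.ndarray]  # each (n_chains, n_draws)
    site_richness: np.ndarray  # (n_chains, n_draws, n_sites)
    sites_per_species: np.ndarray  # (n_chains, n_draws, n_obs)
    species: list[str]
    sites: list[str]
    n_obs_species: int
    n_aug: int
    accept_u: np.ndarray = None
    accept_v: np.ndarray = None
    w_draws: np.ndarray | None = None  # (n_chains, n_draws, M) when stored
    Z_draws: np.ndarray | None = None  # (n_chains, n_draws, J, M) when stored

    @property
    def n_chains(self) -> int:
        return self.draws["R"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["R"].shape[1]

    def stacked(self, parameter: str) -> np.ndarray:
        return self.draws[parameter].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.draws.items():
            C, D = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), D),
                        "iteration": np.tile(np.arange(D), C),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        for i, sp in enumerate(self.species[: self.n_obs_species]):
            arr = self.sites_per_species[:, :, i]
            C, D = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), D),
                        "iteration": np.tile(np.arange(D), C),
                        "parameter": f"n_sites[{sp}]",
                        "value": arr.reshape(-1).astype(float),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def rhat(posterior: MsomPosterior, parameter: str) -> float:
    """Rank-normalized split Gelman-Rubin potential scale reduction factor."""
    draws = posterior.draws[parameter]
    return rhat_from_draws(draws)


def rhat_from_draws(draws: np.ndarray) -> float:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat needs draws shaped (n_chains >= 2, n_draws)")
    if draws.shape[1] < 4:
        raise ValueError("rhat needs at least 4 draws per chain")
    if np.allclose(draws, draws.flat[0]):
        return 1.0  # degenerate chains: a pinned parameter has converged trivially
    value = az.rhat(az.convert_to_dataset(draws[:, :, None]))
    return float(np.asarray(value["x"]).reshape(-1)[0])


@dataclass
class DiversitySummary:
    """Posterior medians and 90% equal-tailed credible intervals."""

    table: pd.DataFrame  # parameter, median, q5, q95
    beta_excluded_draws: int = 0

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.2f}")


def derive_diversity(posterior: MsomPosterior) -> DiversitySummary:
    """Summarize richness and diversity draws into the reporting table.

    Draws with alpha = 0 (no occupancy anywhere) leave beta undefined and
    are excluded from the beta summary; their count is logged.
    """
    if posterior.n_draws == 0:
        raise ValueError("posterior has no draws")
    rows = []
    excluded = 0
    for name in ("R", "alpha", "beta", "zeta"):
        x = posterior.stacked(name)
        if name == "beta":
            excluded = int(np.isnan(x).sum())
            if excluded:
                logger.info("derive_diversity: %d draw(s) with alpha=0 excluded from beta", excluded)
            x = x[~np.isnan(x)]
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(x)),
                "q5": float(np.quantile(x, 0.05)),
                "q95": float(np.quantile(x, 0.95)),
            }
        )
    for i, sp in enumerate(posterior.species[: posterior.n_obs_species]):
        x = posterior.sites_per_species[:, :, i].reshape(-1)
        rows.append(
            {
                "parameter": f"n_sites[{sp}]",
                "median": float(np.median(x)),
                "q5": float(np.quantile(x, 0.05)),
                "q95": float(np.quantile(x, 0.95)),
            }
        )
    return DiversitySummary(table=pd.DataFrame(rows), beta_excluded_draws=excluded)


def _run_chain(
    data: DetectionArray, config: MsomConfig, chain: int
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng([config.seed, 7919, chain])
    state = initial_state(data, rng)
    M = data.n_slots
    step_u = np.full(M, config.step_init)
    step_v = np.full(M, config.step_init)
    acc_u = np.zeros(M)
    acc_v = np.zeros(M)
    batch = 0

    n_keep = (config.n_iter - config.n_burn + config.thin - 1) // config.thin
    out = {name: np.empty(n_keep) for name in MONITORED}
    site_rich = np.empty((n_keep, data.n_sites), dtype=np.int16)
    sps = np.empty((n_keep, data.n_obs_species), dtype=np.int16)
    w_draws = np.empty((n_keep, M), dtype=np.int8) if config.store_latent else None
    Z_draws = (
        np.empty((n_keep, data.n_sites, M), dtype=np.int8) if config.store_latent else None
    )
    total_acc_u = np.zeros(M)
    total_acc_v = np.zeros(M)
    kept = 0

    for it in range(config.n_adapt + config.n_iter):
        gibbs_update_discrete(state, data, rng)
        au, av = mh_update_logits(state, data, step_u, step_v, rng)
        gibbs_update_hyper(state, config, rng)

        if it < config.n_adapt:
            acc_u += au
            acc_v += av
            batch += 1
            if batch == 50:
                rate_u, rate_v = acc_u / batch, acc_v / batch
                step_u *= np.where(rate_u < 0.3, 0.85, np.where(rate_u > 0.5, 1.15, 1.0))
                step_v *= np.where(rate_v < 0.3, 0.85, np.where(rate_v > 0.5, 1.15, 1.0))
                acc_u[:] = 0
                acc_v[:] = 0
                batch = 0
            continue

        total_acc_u += au
        total_acc_v += av
        post = it - config.n_adapt
        if post < config.n_burn or (post - config.n_burn) % config.thin:
            continue
        R, alpha, beta, zeta, rich, per_sp = _diversity_draw(
            state.w, state.Z, data.n_obs_species
        )
        out["omega"][kept] = state.omega
        out["mu_u"][kept] = state.mu_u
        out["sigma_u"][kept] = 1.0 / np.sqrt(state.tau_u)
        out["mu_v"][kept] = state.mu_v
        out["sigma_v"][kept] = 1.0 / np.sqrt(state.tau_v)
        out["R"][kept] = R
        out["alpha"][kept] = alpha
        out["beta"][kept] = beta
        out["zeta"][kept] = zeta
        site_rich[kept] = rich
        sps[kept] = per_sp
        if config.store_latent:
            w_draws[kept] = state.w
            Z_draws[kept] = state.Z
        kept += 1

    out["_site_richness"] = site_rich
    out["_sites_per_species"] = sps
    out["_accept_u"] = total_acc_u / config.n_iter
    out["_accept_v"] = total_acc_v / config.n_iter
    if config.store_latent:
        out["_w"] = w_draws
        out["_Z"] = Z_draws
    return out


def run_msom(data: DetectionArray, config: MsomConfig | None = None) -> MsomPosterior:
    """Run independent seeded chains (adapt, burn, sample) and pool draws."""
    config = config or MsomConfig()
    if data.n_aug == 0:
        logger.warning(
            "run_msom: no augmented slots; richness cannot exceed the %d observed species",
            data.n_obs_species,
        )
    chains = [_run_chain(data, config, c) for c in range(config.n_chains)]
    draws = {
        name: np.stack([c[name] for c in chains]) for name in MONITORED
    }
    posterior = MsomPosterior(
        draws=draws,
        site_richness=np.stack([c["_site_richness"] for c in chains]),
        sites_per_species=np.stack([c["_sites_per_species"] for c in chains]),
        species=list(data.species),
        sites=list(data.sites),
        n_obs_species=data.n_obs_species,
        n_aug=data.n_aug,
        accept_u=np.stack([c["_accept_u"] for c in chains]),
        accept_v=np.stack([c["_accept_v"] for c in chains]),
        w_draws=np.stack([c["_w"] for c in chains]) if config.store_latent else None,
        Z_draws=np.stack([c["_Z"] for c in chains]) if config.store_latent else None,
    )
    if data.n_aug > 0:
        ceiling = data.n_obs_species + data.n_aug
        mass = float((posterior.stacked("R") == ceiling).mean())
        if mass > 0.01:
            logger.warning(
                "run_msom: posterior mass %.3f at R = n + n_aug = %d; increase n_aug",
                mass,
                ceiling,
            )
    return posterior


# ---------------------------------------------------------------------------
# statsmodels-style front end


class MultiSpeciesOccupancy:
    """Model object: detection histories plus augmentation and sampler config.

    Parameters
    ----------
    data
        Observed detection histories.  If the array carries no augmented
        slots, ``n_aug`` all-zero slots are appended here.
    n_aug
        Supercommunity padding; richness estimates can reach
        n_observed + n_aug.  Ignored when ``data`` is already augmented.
    config
        Sampler settings; defaults follow the survey protocol (3 chains of
        20,000 iterations after 1,000 adaptation sweeps, first 10,000
        discarded as burn-in).
    """

    def __init__(
        self,
        data: DetectionArray,
        n_aug: int = 50,
        config: MsomConfig | None = None,
    ) -> None:
        if data.n_aug == 0 and n_aug > 0:
            J, K, n = data.X.shape
            X = np.concatenate([data.X, np.zeros((J, K, n_aug), dtype=np.int8)], axis=2)
            data = DetectionArray(
                X=X,
                occasion_mask=data.occasion_mask,
                n_obs_species=n,
                n_aug=n_aug,
                sites=list(data.sites),
                species=list(data.species),
            )
        self.data = data
        self.config = config or MsomConfig()

    def fit(self) -> "MsomResults":
        posterior = run_msom(self.data, self.config)
        return MsomResults(self, posterior)


class MsomResults:
    """Fitted occupancy model: posterior draws, diagnostics and summaries."""

    def __init__(self, model: MultiSpeciesOccupancy, posterior: MsomPosterior) -> None:
        self.model = model
        self.posterior = posterior

    def rhat(self, parameter: str) -> float:
        return rhat(self.posterior, parameter)

    def rhat_table(self) -> pd.DataFrame:
        rows = [{"parameter": p, "rhat": self.rhat(p)} for p in MONITORED]
        df = pd.DataFrame(rows)
        df["flag"] = np.where(df["rhat"] > 1.1, "NOT CONVERGED", "")
        return df

    def diversity(self) -> DiversitySummary:
        return derive_diversity(self.posterior)

    def summary(self) -> pd.DataFrame:
        """Parameter medians with 90% credible intervals and R-hat."""
        rows = []
        for name in MONITORED:
            x = self.posterior.stacked(name)
            x = x[~np.isnan(x)]
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(x)),
                    "q5": float(np.quantile(x, 0.05)),
                    "q95": float(np.quantile(x, 0.95)),
                    "rhat": self.rhat(name),
                }
            )
        return pd.DataFrame(rows)

    def site_richness_summary(self) -> pd.DataFrame:
        """Per-site richness medians and 90% CrIs (for covariate scatter)."""
        arr = self.posterior.site_richness.reshape(-1, len(self.posterior.sites))
        return pd.DataFrame(
            {
                "site_id": self.posterior.sites,
                "richness_median": np.median(arr, axis=0),
                "richness_q5": np.quantile(arr, 0.05, axis=0),
                "richness_q95": np.quantile(arr, 0.95, axis=0),
            }
        )

    def mean_occupancy_probability(self) -> dict[str, float]:
        """Posterior-median community occupancy on the probability scale.

        Reported two ways because the back-transform from the logit-scale
        community mean is ambiguous: the naive inverse logit of the median
        mu_u, and the logit-normal mean E[expit(N(mu_u, sigma_u^2))]
        evaluated per draw by quadrature and then summarized.
        """
        mu = self.posterior.stacked("mu_u")
        sd = self.posterior.stacked("sigma_u")
        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        grid = mu[:, None] + sd[:, None] * nodes[None, :]
        lognorm_mean = expit(grid) @ (weights / weights.sum())
        return {
            "plogis_median_mu_u": float(expit(np.median(mu))),
            "logit_normal_mean": float(np.median(lognorm_mean)),
        }
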