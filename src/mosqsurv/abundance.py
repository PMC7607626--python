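"""Negative-binomial mixed-effects models of trap counts.

Models the monthly per-species trap count y_(i,j,s) (site i, month j,
species s) as NB2 with log mean

    log mu = beta0 + a0(s) + (beta1 + a1(s)) * Precip_j
             + [land-cover and mangrove-trait terms]
             + a2(i),
    Var(y) = mu (1 + mu / phi),

where the species (intercept, precipitation-slope) pairs (a0, a1) are
bivariate normal with correlation rho, site intercepts a2 are normal, and
phi is the NB2 size parameter.  Twelve candidate fixed-effect structures
(H1-H12) encode competing hypotheses about which land covers drive each
species; candidates are screened for collinearity (VIF > 5), fitted by
maximizing the Laplace-approximated marginal likelihood, and ranked by AIC.

The Laplace fit integrates the random effects out at their conditional
mode (found by an inner Newton iteration; the objective is concave in the
random effects for the log link) and optimizes the marginal likelihood
over (beta, log SDs, atanh rho, log phi) with a quasi-Newton outer loop.
The gradient is analytic in beta via implicit differentiation through the
inner mode and finite-differenced in the five variance/dispersion
parameters.  Goodness of fit uses simulation-based quantile residuals
(uniform under a correct model, checked by a one-sample KS test) and
latent-scale marginal/conditional R2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln, polygamma

from .data import CountTable, PrecipSeries, SiteTable, TraitTable

logger = logging.getLogger("mosqsurv")

#: vocabulary of fixed-effect term descriptors
COVER_TERMS = {
    "agriculture_by_species": "local_agriculture",
    "urban_by_species": "local_urban",
    "rainforest_by_species": "local_rainforest",
    "scrub_by_species": "local_scrub",
    "mangrove_by_species": "local_mangrove",
    "anthropogenic_by_species": "local_anthropogenic",
}
SCALAR_TERMS = ("m_trait", "mangrove_site", "m_trait:mangrove_site", "m_trait*mangrove_site")

#: parameters beyond the fixed effects: three random-effect SDs + their
#: correlation, plus the NB2 dispersion
N_VARIANCE_PARAMS = 5

ETA_CLIP = 30.0  # log-mean clamp; counts beyond e^30 are outside any survey


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure.

    Every candidate shares the random-effect structure (site intercepts;
    correlated species intercept and precipitation slope) and always
    includes precipitation.  ``m_trait:mangrove_site`` contributes the
    interaction column only; ``m_trait*mangrove_site`` contributes both
    mains and the interaction.
    """

    name: str
    fixed_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if "precip" not in self.fixed_terms:
            raise ValueError(f"{self.name}: every candidate includes precip")
        for term in self.fixed_terms:
            if term != "precip" and term not in COVER_TERMS and term not in SCALAR_TERMS:
                raise ValueError(f"{self.name}: unknown term {term!r}")

    def n_fixed(self, n_species: int) -> int:
        n = 1  # intercept
        for term in self.fixed_terms:
            if term == "precip":
                n += 1
            elif term in COVER_TERMS:
                n += n_species
            elif term == "m_trait*mangrove_site":
                n += 3
            else:
                n += 1
        return n

    def n_params(self, n_species: int) -> int:
        """AIC parameter count: fixed effects + 4 variance/correlation + dispersion."""
        return self.n_fixed(n_species) + N_VARIANCE_PARAMS


def build_candidate_set(species: list[str], traits: TraitTable) -> list[ModelSpec]:
    """The twelve candidate hypotheses about land-cover effects (H1-H12)."""
    if len(species) < 2:
        raise ValueError("need at least two species to build the candidate set")
    for sp in species:
        traits.m_trait(sp)
    ag, urb, rf, scrub, mang, anth = (
        "agriculture_by_species",
        "urban_by_species",
        "rainforest_by_species",
        "scrub_by_species",
        "mangrove_by_species",
        "anthropogenic_by_species",
    )
    inter = "m_trait:mangrove_site"
    full = "m_trait*mangrove_site"
    rows = [
        ("H1", ("precip", ag, urb, rf, mang, full)),
        ("H2", ("precip", anth)),
        ("H3", ("precip", ag, urb)),
        ("H4", ("precip", anth, inter)),
        ("H5", ("precip", ag, urb, inter)),
        ("H6", ("precip", scrub, anth, inter)),
        ("H7", ("precip", ag, urb, scrub, inter)),
        ("H8", ("precip", rf, anth, inter)),
        ("H9", ("precip", ag, urb, rf, inter)),
        ("H10", ("precip", rf, scrub, anth, inter)),
        ("H11", ("precip", ag, urb, rf, scrub, inter)),
        ("H12", ("precip", ag, urb, rf, full)),
    ]
    return [ModelSpec(name, terms) for name, terms in rows]


@dataclass
class DesignMatrices:
    """Model matrices plus the long-format frame they were built from."""

    X: np.ndarray  # (N, p) fixed effects
    columns: list[str]
    y: np.ndarray  # (N,) counts
    site_index: np.ndarray  # (N,) 0-based site
    species_index: np.ndarray  # (N,) 0-based species
    x_precip: np.ndarray  # (N,) standardized precipitation
    sites: list[str]
    species: list[str]
    frame: pd.DataFrame  # site_id, month_index, species + covariates
    site_table: SiteTable

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def random_effects_design(self) -> np.ndarray:
        """Dense (N, J + 2S) incidence matrix, ordered sites then species
        intercepts then species slopes."""
        N, J, S = self.n_obs, self.n_sites, self.n_species
        Z = np.zeros((N, J + 2 * S))
        rows = np.arange(N)
        Z[rows, self.site_index] = 1.0
        Z[rows, J + self.species_index] = 1.0
        Z[rows, J + S + self.species_index] = self.x_precip
        return Z


def design_matrices(
    spec: ModelSpec,
    table: CountTable,
    sites: SiteTable,
    precip: PrecipSeries,
    traits: TraitTable,
) -> DesignMatrices:
    """Expand a candidate spec into fixed- and random-effect matrices.

    Column order: intercept, precipitation, scalar trait/mangrove terms,
    then one block per land-cover term with one column per species
    (species alphabetical).  Months absent from the table (untrapped) are
    simply absent from the rows.
    """
    if table.frame["genus_only"].any():
        raise ValueError("filter genus-only records before building design matrices")
    df = table.sorted().frame
    species = sorted(df["species"].unique())
    missing = set(df["site_id"]) - set(sites.sites)
    if missing:
        raise ValueError(f"no covariates for site(s): {sorted(missing)}")

    cov = sites.with_anthropogenic().set_index("site_id")
    std = precip.std_lookup()
    absent = set(df["month_index"]) - set(std)
    if absent:
        raise ValueError(f"no precipitation for month(s): {sorted(absent)}")

    frame = df.copy()
    for col in list(SiteTable.proportion_columns) + ["local_anthropogenic"]:
        frame[col] = cov[col].reindex(frame["site_id"]).to_numpy()
    frame["mangrove_site"] = (
        cov["mangrove_site"].reindex(frame["site_id"]).to_numpy().astype(float)
    )
    frame["stratum"] = cov["stratum"].reindex(frame["site_id"]).to_numpy()
    frame["precip_std"] = frame["month_index"].map(std).to_numpy()
    frame["m_trait"] = (
        frame["species"].map(lambda s: float(traits.m_trait(s))).to_numpy()
    )

    sp_ix = {s: i for i, s in enumerate(species)}
    site_list = sorted(frame["site_id"].unique())
    site_ix = {s: j for j, s in enumerate(site_list)}

    cols: list[np.ndarray] = [np.ones(len(frame))]
    names = ["(Intercept)"]
    cols.append(frame["precip_std"].to_numpy())
    names.append("precip")
    for term in spec.fixed_terms:
        if term == "precip" or term in COVER_TERMS:
            continue
        if term == "m_trait":
            cols.append(frame["m_trait"].to_numpy())
            names.append("m_trait")
        elif term == "mangrove_site":
            cols.append(frame["mangrove_site"].to_numpy())
            names.append("mangrove_site")
        elif term == "m_trait:mangrove_site":
            cols.append(frame["m_trait"].to_numpy() * frame["mangrove_site"].to_numpy())
            names.append("m_trait:mangrove_site")
        elif term == "m_trait*mangrove_site":
            cols.append(frame["m_trait"].to_numpy())
            names.append("m_trait")
            cols.append(frame["mangrove_site"].to_numpy())
            names.append("mangrove_site")
            cols.append(frame["m_trait"].to_numpy() * frame["mangrove_site"].to_numpy())
            names.append("m_trait:mangrove_site")
    species_onehot = {
        s: (frame["species"] == s).to_numpy(float) for s in species
    }
    for term in spec.fixed_terms:
        if term not in COVER_TERMS:
            continue
        covariate = frame[COVER_TERMS[term]].to_numpy()
        for s in species:
            cols.append(covariate * species_onehot[s])
            names.append(f"{COVER_TERMS[term]}[{s}]")

    return DesignMatrices(
        X=np.column_stack(cols),
        columns=names,
        y=frame["count"].to_numpy(np.int64),
        site_index=frame["site_id"].map(site_ix).to_numpy(),
        species_index=frame["species"].map(sp_ix).to_numpy(),
        x_precip=frame["precip_std"].to_numpy(),
        sites=site_list,
        species=species,
        frame=frame,
        site_table=sites,
    )


# ---------------------------------------------------------------------------
# NB2 likelihood pieces


def nb2_loglik(y, mu, phi) -> float:
    """Sum of NB2 log-pmf values; Var(y) = mu (1 + mu/phi)."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or np.any(y % 1 != 0):
        raise ValueError("y must contain non-negative integers")
    if np.any(mu <= 0) or phi <= 0:
        raise ValueError("mu and phi must be positive")
    y = y.astype(float)
    return float(np.sum(_nb2_logpmf(y, mu, phi)))


def _nb2_logpmf(y, mu, phi):
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def _nb2_score_weight(y, mu, phi):
    """d/deta and -d2/deta2 of the NB2 log-pmf at eta = log mu, plus dW/deta."""
    g = y - (y + phi) * mu / (mu + phi)
    W = (y + phi) * phi * mu / (mu + phi) ** 2
    Wp = (y + phi) * phi * mu * (phi - mu) / (mu + phi) ** 3
    return g, W, Wp


# ---------------------------------------------------------------------------
# Laplace machinery


class _LaplaceCore:
    """Laplace-approximated marginal log-likelihood and its gradient."""

    def __init__(self, matrices: DesignMatrices):
        self.m = matrices
        self.X = matrices.X
        self.y = matrices.y.astype(float)
        self.Z = matrices.random_effects_design()
        self.J = matrices.n_sites
        self.S = matrices.n_species
        self.q = self.J + 2 * self.S
        self.p = self.X.shape[1]
        self.b = np.zeros(self.q)  # warm-started inner mode

    def unpack(self, x: np.ndarray):
        beta = x[: self.p]
        sd_site, sd_int, sd_slope = np.exp(x[self.p : self.p + 3])
        rho = np.tanh(x[self.p + 3])
        phi = np.exp(x[self.p + 4])
        return beta, sd_site, sd_int, sd_slope, rho, phi

    def _lambda_inv(self, sd_site, sd_int, sd_slope, rho):
        """Dense precision of the random effects and log det of their covariance."""
        J, S = self.J, self.S
        Lam_inv = np.zeros((self.q, self.q))
        Lam_inv[np.arange(J), np.arange(J)] = 1.0 / sd_site**2
        det2 = (sd_int * sd_slope) ** 2 * (1.0 - rho**2)
        inv2 = (
            np.array(
                [
                    [sd_slope**2, -rho * sd_int * sd_slope],
                    [-rho * sd_int * sd_slope, sd_int**2],
                ]
            )
            / det2
        )
        ii = np.arange(J, J + S)
        ss = np.arange(J + S, J + 2 * S)
        Lam_inv[ii, ii] = inv2[0, 0]
        Lam_inv[ss, ss] = inv2[1, 1]
        Lam_inv[ii, ss] = inv2[0, 1]
        Lam_inv[ss, ii] = inv2[1, 0]
        logdet_lam = 2 * J * np.log(sd_site) + S * np.log(det2)
        return Lam_inv, logdet_lam

    def _eta(self, beta, b):
        return np.clip(self.X @ beta + self.Z @ b, -ETA_CLIP, ETA_CLIP)

    def _penalized(self, beta, phi, Lam_inv, b):
        mu = np.exp(self._eta(beta, b))
        return float(np.sum(_nb2_logpmf(self.y, mu, phi)) - 0.5 * b @ Lam_inv @ b)

    def inner_mode(self, beta, phi, Lam_inv, tol=1e-8, max_iter=100):
        """Newton ascent to the conditional mode of the random effects."""
        b = self.b.copy()
        f = self._penalized(beta, phi, Lam_inv, b)
        for _ in range(max_iter):
            mu = np.exp(self._eta(beta, b))
            g, W, _ = _nb2_score_weight(self.y, mu, phi)
            grad = self.Z.T @ g - Lam_inv @ b
            if np.abs(grad).max() < tol:
                break
            H = (self.Z * W[:, None]).T @ self.Z + Lam_inv
            try:
                step = cho_solve(cho_factor(H, lower=True), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-8 * np.eye(self.q), grad)
            t = 1.0
            for _ in range(30):
                cand = b + t * step
                fc = self._penalized(beta, phi, Lam_inv, cand)
                if fc >= f - 1e-12:
                    b, f = cand, fc
                    break
                t *= 0.5
            else:
                break
        self.b = b
        mu = np.exp(self._eta(beta, b))
        g, W, Wp = _nb2_score_weight(self.y, mu, phi)
        H = (self.Z * W[:, None]).T @ self.Z + Lam_inv
        return b, mu, g, W, Wp, H

    def marginal_loglik(self, x: np.ndarray) -> float:
        beta, sd_site, sd_int, sd_slope, rho, phi = self.unpack(x)
        Lam_inv, logdet_lam = self._lambda_inv(sd_site, sd_int, sd_slope, rho)
        b, mu, g, W, Wp, H = self.inner_mode(beta, phi, Lam_inv)
        chol = cho_factor(H, lower=True)
        logdet_H = 2.0 * np.sum(np.log(np.diag(chol[0])))
        pll = float(np.sum(_nb2_logpmf(self.y, mu, phi)) - 0.5 * b @ Lam_inv @ b)
        return pll - 0.5 * logdet_lam - 0.5 * logdet_H

    def neg_loglik(self, x: np.ndarray) -> float:
        try:
            return -self.marginal_loglik(x)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e10

    def neg_loglik_grad(self, x: np.ndarray, fd_step: float = 1e-6) -> np.ndarray:
        """Gradient: analytic in beta, forward differences in the rest."""
        beta, sd_site, sd_int, sd_slope, rho, phi = self.unpack(x)
        Lam_inv, logdet_lam = self._lambda_inv(sd_site, sd_int, sd_slope, rho)
        b, mu, g, W, Wp, H = self.inner_mode(beta, phi, Lam_inv)
        chol = cho_factor(H, lower=True)
        logdet_H = 2.0 * np.sum(np.log(np.diag(chol[0])))
        pll = float(np.sum(_nb2_logpmf(self.y, mu, phi)) - 0.5 * b @ Lam_inv @ b)
        f0 = pll - 0.5 * logdet_lam - 0.5 * logdet_H

        # beta block, differentiating through the inner mode:
        #   d eta_hat / d beta_r = x_r - Z H^{-1} Z' W x_r
        #   d loglik / d beta_r  = x_r' g - 0.5 tr(H^{-1} Z' diag(W' d eta) Z)
        V = cho_solve(chol, self.Z.T)  # (q, N)
        s = np.einsum("nq,qn->n", self.Z, V)  # z_n' H^{-1} z_n
        M1 = cho_solve(chol, self.Z.T @ (W[:, None] * self.X))  # (q, p)
        deta = self.X - self.Z @ M1  # (N, p)
        grad_beta = self.X.T @ g - 0.5 * deta.T @ (Wp * s)

        grad = np.empty_like(x)
        grad[: self.p] = -grad_beta
        b_save = self.b.copy()
        for k in range(self.p, self.p + N_VARIANCE_PARAMS):
            xp = x.copy()
            h = fd_step * max(1.0, abs(x[k]))
            xp[k] += h
            self.b = b_save.copy()
            grad[k] = -(self.marginal_loglik(xp) - f0) / h
        self.b = b_save
        return grad

    def beta_vcov(self, x: np.ndarray) -> np.ndarray:
        """Wald covariance of beta conditional on the variance parameters."""
        beta, sd_site, sd_int, sd_slope, rho, phi = self.unpack(x)
        Lam_inv, _ = self._lambda_inv(sd_site, sd_int, sd_slope, rho)
        b, mu, g, W, Wp, H = self.inner_mode(beta, phi, Lam_inv)
        chol = cho_factor(H, lower=True)
        XtW = self.X.T * W
        A = XtW @ self.X
        B = XtW @ self.Z  # (p, q)
        fisher = A - B @ cho_solve(chol, B.T)
        return np.linalg.inv(fisher)

    def beta_vcov_full(self, x: np.ndarray, fd_step: float = 1e-4) -> np.ndarray:
        """Wald covariance of beta from the full observed information.

        Differentiates the marginal-likelihood gradient over *all* outer
        parameters (beta and the variance/dispersion block) by central
        differences, inverts the symmetrized Hessian, and returns the beta
        block.  Unlike :meth:`beta_vcov` this propagates the uncertainty of
        the variance components into the fixed-effect standard errors —
        material when a random-slope SD is estimated from few groups.
        """
        n = len(x)
        Hess = np.empty((n, n))
        b_save = self.b.copy()
        for k in range(n):
            h = fd_step * max(1.0, abs(x[k]))
            xp = x.copy()
            xp[k] += h
            self.b = b_save.copy()
            gp = self.neg_loglik_grad(xp)
            xm = x.copy()
            xm[k] -= h
            self.b = b_save.copy()
            gm = self.neg_loglik_grad(xm)
            Hess[k] = (gp - gm) / (2.0 * h)
        self.b = b_save
        Hess = 0.5 * (Hess + Hess.T)
        p = self.p
        try:
            cov = np.linalg.inv(Hess)
            cov_beta = cov[:p, :p]
            if np.any(np.diag(cov_beta) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            return cov_beta
        except np.linalg.LinAlgError:
            # boundary or singular information: fall back to the beta block
            # inverse conditional on the other parameters
            return np.linalg.inv(Hess[:p, :p])


def aghq_marginal_loglik(
    y: np.ndarray,
    eta_fixed: np.ndarray,
    group_index: np.ndarray,
    sd: float,
    phi: float,
    n_points: int = 61,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, single random intercept.

    Independent oracle for the Laplace approximation on models with one
    grouping factor: per group, the random intercept is integrated out on a
    Hermite grid centred and scaled at the group's conditional mode.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_points)
    y = np.asarray(y, float)
    total = 0.0
    for gidx in np.unique(group_index):
        sel = group_index == gidx
        yg, eg = y[sel], eta_fixed[sel]

        def neg(bv: float) -> float:
            mu = np.exp(eg + bv)
            return -(np.sum(_nb2_logpmf(yg, mu, phi)) - 0.5 * bv**2 / sd**2)

        res = optimize.minimize_scalar(neg, bounds=(-20 * sd - 5, 20 * sd + 5), method="bounded")
        mode = res.x
        mu = np.exp(eg + mode)
        _, W, _ = _nb2_score_weight(yg, mu, phi)
        hess = W.sum() + 1.0 / sd**2
        scale = 1.0 / np.sqrt(hess)
        bgrid = mode + np.sqrt(2.0) * scale * nodes
        logf = np.array(
            [
                np.sum(_nb2_logpmf(yg, np.exp(eg + bv), phi))
                + stats.norm.logpdf(bv, 0.0, sd)
                for bv in bgrid
            ]
        )
        log_terms = np.log(weights) + nodes**2 + logf
        total += np.log(np.sqrt(2.0) * scale) + _logsumexp(log_terms)
    return float(total)


def _logsumexp(a: np.ndarray) -> float:
    m = a.max()
    return float(m + np.log(np.exp(a - m).sum()))


# ---------------------------------------------------------------------------
# model front end


class NegBinomMixedModel:
    """NB2 mixed-effects count model for one candidate specification."""

    def __init__(self, spec: ModelSpec, matrices: DesignMatrices) -> None:
        self.spec = spec
        self.matrices = matrices

    @classmethod
    def from_tables(
        cls,
        spec: ModelSpec,
        table: CountTable,
        sites: SiteTable,
        precip: PrecipSeries,
        traits: TraitTable,
    ) -> "NegBinomMixedModel":
        return cls(spec, design_matrices(spec, table, sites, precip, traits))

    def _start(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        m = self.matrices
        p = m.X.shape[1]
        x0 = np.zeros(p + N_VARIANCE_PARAMS)
        ybar = max(m.y.mean(), 0.1)
        x0[0] = np.log(ybar)
        # method-of-moments dispersion from the intercept-only mean
        excess = max(((m.y - ybar) ** 2).mean() - ybar, 1e-6)
        phi0 = np.clip(ybar**2 / excess, 1e-3, 1e3)
        x0[p : p + 3] = np.log(0.5)
        x0[p + 3] = 0.0
        x0[p + 4] = np.log(phi0)
        if jitter > 0:
            x0 = x0 + rng.normal(0.0, jitter, x0.shape)
        return x0

    def fit(
        self,
        restarts: int = 3,
        seed: int = 0,
        maxiter: int = 400,
        gtol: float = 1e-5,
    ) -> "NegBinomMixedResults":
        """Maximize the Laplace marginal likelihood; best of jittered restarts."""
        core = _LaplaceCore(self.matrices)
        p = core.p
        rng = np.random.default_rng([seed, 104729])
        bounds = [(None, None)] * p + [(-10.0, 5.0)] * 3 + [(-5.0, 5.0)] + [(-10.0, 12.0)]
        best = None
        for r in range(max(1, restarts)):
            core.b = np.zeros(core.q)
            x0 = self._start(rng, jitter=0.0 if r == 0 else 0.3)
            res = optimize.minimize(
                core.neg_loglik,
                x0,
                jac=core.neg_loglik_grad,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
        grad_norm = float(np.abs(best.jac).max()) if best.jac is not None else np.inf
        converged = bool(best.success) or grad_norm < 1e-4
        if not converged:
            logger.warning(
                "fit %s did not converge (grad inf-norm %.2e)", self.spec.name, grad_norm
            )
        return NegBinomMixedResults(self, core, best.x, -float(best.fun), converged)


class NegBinomMixedResults:
    """Fitted candidate model: estimates, variance components, diagnostics."""

    def __init__(
        self,
        model: NegBinomMixedModel,
        core: _LaplaceCore,
        params_internal: np.ndarray,
        loglik: float,
        converged: bool,
    ) -> None:
        self.model = model
        self.spec = model.spec
        self.matrices = model.matrices
        self._core = core
        self._x = params_internal
        self.loglik = loglik
        self.converged = converged

        beta, sd_site, sd_int, sd_slope, rho, phi = core.unpack(params_internal)
        self.params = pd.Series(beta, index=self.matrices.columns)
        self.phi = float(phi)
        self.vc = {
            "sd_site": float(sd_site),
            "sd_species_intercept": float(sd_int),
            "sd_species_slope": float(sd_slope),
            "corr_species": float(rho),
        }
        if min(sd_site, sd_int, sd_slope) < 1e-4:
            self.singular = True
            logger.warning("fit %s: a variance component is near zero (singular fit)", self.spec.name)
        else:
            self.singular = False

        Lam_inv, _ = core._lambda_inv(sd_site, sd_int, sd_slope, rho)
        b_hat, mu, *_ = core.inner_mode(beta, phi, Lam_inv)
        self._b_hat = b_hat
        self.fittedvalues = mu
        J, S = core.J, core.S
        self.blups = {
            "site_intercept": pd.Series(b_hat[:J], index=self.matrices.sites),
            "species_intercept": pd.Series(b_hat[J : J + S], index=self.matrices.species),
            "species_slope": pd.Series(b_hat[J + S :], index=self.matrices.species),
        }
        self._bse: pd.Series | None = None

    @property
    def bse(self) -> pd.Series:
        """Standard errors from the full observed information (lazy)."""
        if self._bse is None:
            try:
                vcov = self._core.beta_vcov_full(self._x)
                self._bse = pd.Series(
                    np.sqrt(np.diag(vcov)), index=self.matrices.columns
                )
            except np.linalg.LinAlgError:
                self._bse = pd.Series(np.nan, index=self.matrices.columns)
        return self._bse

    # -- information criteria ------------------------------------------------

    @property
    def K(self) -> int:
        return self.spec.n_params(self.matrices.n_species)

    @property
    def aic(self) -> float:
        return 2.0 * self.K - 2.0 * self.loglik

    # -- inference -----------------------------------------------------------

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def summary(self) -> pd.DataFrame:
        """Coefficient table in the reporting layout (estimate, CI, P)."""
        ci = self.conf_int()
        table = pd.DataFrame(
            {
                "predictor": self.params.index,
                "estimate": self.params.to_numpy(),
                "ci_lower": ci["lower"].to_numpy(),
                "ci_upper": ci["upper"].to_numpy(),
                "p_value": self.pvalues.to_numpy(),
            }
        )
        return table

    def random_effects_summary(self) -> pd.DataFrame:
        rows = [{"component": k, "value": v} for k, v in self.vc.items()]
        rows.append({"component": "phi", "value": self.phi})
        return pd.DataFrame(rows)

    # -- variance explained ---------------------------------------------------

    def nakagawa_r2(self, method: str = "lognormal") -> tuple[float, float]:
        """Latent-scale marginal and conditional R2.

        Marginal: fixed-effect variance over the total (fixed + random +
        observation-level).  The NB2 log-link observation-level variance
        uses the lognormal/delta approximation ln(1 + 1/mu_bar + 1/phi) by
        default, or the trigamma form behind ``method='trigamma'``.
        """
        m = self.matrices
        eta_f = m.X @ self.params.to_numpy()
        var_f = float(np.var(eta_f))
        x = m.x_precip
        sd0 = self.vc["sd_species_intercept"]
        sd1 = self.vc["sd_species_slope"]
        rho = self.vc["corr_species"]
        var_r = float(
            self.vc["sd_site"] ** 2
            + sd0**2
            + 2.0 * rho * sd0 * sd1 * x.mean()
            + sd1**2 * np.mean(x**2)
        )
        mu_bar = float(np.exp(eta_f.mean()))
        if method == "lognormal":
            var_o = float(np.log1p(1.0 / mu_bar + 1.0 / self.phi))
        elif method == "trigamma":
            var_o = float(polygamma(1, 1.0 / (1.0 / mu_bar + 1.0 / self.phi)))
        else:
            raise ValueError("method must be 'lognormal' or 'trigamma'")
        total = var_f + var_r + var_o
        if total <= 0:
            raise ValueError("total latent variance is zero")
        return var_f / total, (var_f + var_r) / total

    # -- diagnostics -----------------------------------------------------------

    def simulate_residuals(
        self,
        n_sim: int = 250,
        seed: int = 0,
        resimulate_random_effects: bool = False,
    ) -> "ResidualDiagnostics":
        """Simulation-based randomized quantile residuals.

        Simulates ``n_sim`` replicate datasets from the fitted model (new
        NB2 noise; random effects fixed at their conditional modes unless
        ``resimulate_random_effects``) and scores each observation by its
        randomized empirical quantile among its simulations.  Under a
        correct model the residuals are Uniform(0, 1); a one-sample KS test
        quantifies the departure.
        """
        if n_sim < 50:
            raise ValueError("n_sim must be at least 50")
        rng = np.random.default_rng([seed, 24593])
        m = self.matrices
        N = m.n_obs
        # tie-breaking uniforms drawn first so residuals share them across
        # different n_sim (common random numbers; stabilizes the quantiles)
        tie_u = rng.random(N)
        if resimulate_random_effects:
            J, S = m.n_sites, m.n_species
            sd0 = self.vc["sd_species_intercept"]
            sd1 = self.vc["sd_species_slope"]
            rho = self.vc["corr_species"]
            cov = np.array(
                [[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]]
            )
            eta_f = m.X @ self.params.to_numpy()
            sims = np.empty((n_sim, N))
            for r in range(n_sim):
                b_site = rng.normal(0.0, self.vc["sd_site"], J)
                sp = rng.multivariate_normal(np.zeros(2), cov, size=S)
                eta = (
                    eta_f
                    + b_site[m.site_index]
                    + sp[m.species_index, 0]
                    + sp[m.species_index, 1] * m.x_precip
                )
                mu = np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
                sims[r] = rng.negative_binomial(self.phi, self.phi / (self.phi + mu))
        else:
            mu = self.fittedvalues
            sims = rng.negative_binomial(
                self.phi, self.phi / (self.phi + mu), size=(n_sim, N)
            )
        below = (sims < m.y[None, :]).sum(axis=0)
        ties = (sims == m.y[None, :]).sum(axis=0)
        resid = (below + tie_u * (ties + 1)) / (n_sim + 1)
        ks = stats.kstest(resid, "uniform")
        return ResidualDiagnostics(
            residuals=resid, ks_D=float(ks.statistic), ks_p=float(ks.pvalue), n_sim=n_sim
        )

    # -- prediction -----------------------------------------------------------

    def predict_timeseries(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Predicted relative abundance per (site, month, species), BLUPs in.

        Returns the per-site predictions and the stratum-averaged series
        (mean over the replicate sites of each land-cover stratum).
        """
        m = self.matrices
        eta = (
            m.X @ self.params.to_numpy()
            + self.blups["site_intercept"].to_numpy()[m.site_index]
            + self.blups["species_intercept"].to_numpy()[m.species_index]
            + self.blups["species_slope"].to_numpy()[m.species_index] * m.x_precip
        )
        per_site = m.frame[["site_id", "month_index", "species", "stratum"]].copy()
        per_site["predicted"] = np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
        by_stratum = (
            per_site.groupby(["stratum", "month_index", "species"], as_index=False)[
                "predicted"
            ]
            .mean()
            .rename(columns={"predicted": "mean_predicted"})
        )
        return per_site, by_stratum


@dataclass
class ResidualDiagnostics:
    """Simulation-based quantile residuals and their uniformity test."""

    residuals: np.ndarray
    ks_D: float
    ks_p: float
    n_sim: int


# ---------------------------------------------------------------------------
# screening and selection


def vif_screen(
    matrices: DesignMatrices, threshold: float = 5.0, mode: str = "hypothesis"
) -> tuple[bool, pd.Series]:
    """Variance inflation factors: 1/(1-R2) of each column on the others.

    Returns (keep, per-column VIFs); a candidate is excluded when any VIF
    exceeds the threshold.  Perfect collinearity yields infinite VIF.

    ``mode='hypothesis'`` (the screen used before model evaluation) checks
    collinearity among the distinct covariates a candidate draws on —
    precipitation, each land-cover proportion, the trait and mangrove-site
    indicators — without interaction products or per-species replication:
    an interaction column is structurally collinear with its mains and a
    species-replicated block duplicates its covariate, so screening the
    expanded matrix would veto those candidate structures wholesale rather
    than detect redundant information.  ``mode='full'`` screens the
    expanded fixed-effects matrix as-is.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    if mode == "full":
        X = matrices.X
        names = matrices.columns[1:]
    elif mode == "hypothesis":
        frame = matrices.frame
        cols, names = [np.ones(matrices.n_obs)], []
        seen = set()
        for name in matrices.columns[1:]:
            base = name.split("[")[0]  # strip species replication
            if ":" in base or base in seen:
                continue
            seen.add(base)
            source = "precip_std" if base == "precip" else base
            cols.append(frame[source].to_numpy(float))
            names.append(base)
        X = np.column_stack(cols)
    else:
        raise ValueError("mode must be 'hypothesis' or 'full'")
    if X.shape[1] < 3:
        raise ValueError("need at least two non-intercept columns for a VIF screen")
    vifs = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(1, X.shape[1]):
            try:
                v = variance_inflation_factor(X, k)
            except Exception:
                v = np.inf
            vifs[names[k - 1]] = np.inf if not np.isfinite(v) else float(v)
    series = pd.Series(vifs)
    keep = bool((series <= threshold).all())
    return keep, series


def aic_table(fits: list[NegBinomMixedResults]) -> pd.DataFrame:
    """Rank candidate fits by AIC difference from the best model.

    Ties in AIC are broken toward the smaller parameter count.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to rank")
    rows = [
        {
            "name": f.spec.name,
            "K": f.K,
            "loglik": f.loglik,
            "aic": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    best = df.loc[df["converged"], "aic"].min()
    df["delta_aic"] = df["aic"] - best
    df = df.sort_values(["delta_aic", "K"], kind="mergesort").reset_index(drop=True)
    return df


def nakagawa_r2(fit: NegBinomMixedResults, method: str = "lognormal") -> tuple[float, float]:
    return fit.nakagawa_r2(method=method)


def fit_model(
    spec: ModelSpec, matrices: DesignMatrices, restarts: int = 3, seed: int = 0
) -> NegBinomMixedResults:
    return NegBinomMixedModel(spec, matrices).fit(restarts=restarts, seed=seed)
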