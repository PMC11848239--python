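"""Bayesian three-source mixing of mean-centered delta13C eAA tracers.

Each consumer's centered tracer vector is modelled as a convex
combination of the basal-source fingerprints:

    y_ij ~ Normal( sum_k p_k^c mu_jk ,
                   sqrt( sum_k (p_k^c)^2 sigma_jk^2 + sigma_res,j^2 ) )

with an independent proportion vector p^c on the simplex for every
species x litter cell (a fully saturated fixed-effects layout) and a
per-tracer residual SD shared across cells. Source moments (mu, sigma)
come from the endmember library; trophic fractionation of eAA delta13C
is taken as zero (essential amino acids are routed, not synthesized),
with an optional offset for sensitivity analysis.

Sampling is random-walk Metropolis on isometric log-ratio (ILR)
coordinates of p and on log residual SDs — two free parameters per
cell plus one per tracer. Proposals are auto-tuned during burn-in to a
20-40% acceptance rate and then frozen; all randomness flows from one
seed. Convergence is assessed by the split Gelman-Rubin statistic
(accept when every R-hat < 1.05) and an autocorrelation-based
effective sample size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ValidationError
from .fingerprinting import SourceLibrary, mean_center

logger = logging.getLogger(__name__)

DEFAULT_TRACERS = ("Leu", "Phe", "Val")

#: Upper bound of the uniform prior on each residual SD, per mil.
SIGMA_RES_MAX = 10.0


# ---------------------------------------------------------------------------
# ILR transform (Helmert basis) — the sampler's unconstrained coordinates
# ---------------------------------------------------------------------------

def _helmert_basis(d: int) -> np.ndarray:
    """Orthonormal (d x d-1) contrast basis for the ILR transform."""
    V = np.zeros((d, d - 1))
    for j in range(1, d):
        V[:j, j - 1] = 1.0 / np.sqrt(j * (j + 1))
        V[j, j - 1] = -j / np.sqrt(j * (j + 1))
    return V


def ilr(p: np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates of compositions (last axis sums to 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise DomainError("ILR requires strictly positive compositions")
    V = _helmert_basis(p.shape[-1])
    logp = np.log(p)
    clr = logp - logp.mean(axis=-1, keepdims=True)
    return clr @ V


def ilr_inv(z: np.ndarray, d: int | None = None) -> np.ndarray:
    """Inverse ILR: map unconstrained coordinates back onto the simplex."""
    z = np.asarray(z, dtype=float)
    d = d if d is not None else z.shape[-1] + 1
    V = _helmert_basis(d)
    clr = z @ V.T
    clr -= clr.max(axis=-1, keepdims=True)
    e = np.exp(clr)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class MixingModelSpec:
    """Everything the sampler needs: source moments, grouped consumers, prior."""

    sources: list[str]                  # class order
    tracers: tuple[str, ...]
    mu: np.ndarray                      # (K, J) centered source means
    sigma: np.ndarray                   # (K, J) centered source SDs
    cells: list[tuple[str, str]]        # (species, litter_treatment)
    y: np.ndarray                       # (n, J) centered consumer tracers
    cell_index: np.ndarray              # (n,) index into cells
    prior_alpha: np.ndarray             # (K,)
    error_model: str                    # residual_only | source_plus_residual
    mu_se: np.ndarray | None = None     # (K, J) standard errors of the source means
    fractionation_offset: np.ndarray | None = None   # (J,), added to mixture mean
    fixed_residual_sd: np.ndarray | None = None      # (J,), skip sampling sigma_res

    def __post_init__(self) -> None:
        if self.error_model not in ("residual_only", "source_plus_residual"):
            raise ConfigurationError(f"unknown error model {self.error_model!r}")
        if np.any(self.sigma < 0):
            raise ValidationError("source SDs must be >= 0")
        if np.any(self.prior_alpha <= 0):
            raise ValidationError("Dirichlet alpha must be positive")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def build_spec(
    library: SourceLibrary,
    consumers,
    tracers: tuple[str, ...] = DEFAULT_TRACERS,
    prior_alpha=(1.0, 1.0, 1.0),
    error_model: str = "source_plus_residual",
    center_panel: tuple[str, ...] | None = None,
    propagate_source_mean_error: bool = True,
    fractionation_offset=None,
    fixed_residual_sd=None,
) -> MixingModelSpec:
    """Assemble a :class:`MixingModelSpec` from library and consumer tables.

    The library is mean-centered over ``center_panel`` (default: its
    full eAA panel, even though only a tracer subset enters the
    likelihood) and per-class sample means/SDs of the tracer columns
    become the source moments. ``consumers`` is an :class:`AAMatrix`
    whose values are already centered the same way; its metadata
    (species, litter_treatment) defines the cells.

    With ``propagate_source_mean_error`` (default), the sampling error
    of each source mean (sigma_jk / sqrt(n_k)) is marginalized as a
    shared per-cell mean offset — the endmember library is itself a
    finite sample, and ignoring that makes credible intervals too
    narrow once consumers are numerous.
    """
    lib = library.centered(center_panel)
    missing = [t for t in tracers if t not in lib.panel]
    if missing:
        raise ValidationError(f"tracers not in library panel: {missing}")
    classes = lib.classes
    counts = lib.labels.value_counts()
    if (counts < 2).any():
        raise ValidationError(
            f"every source class needs >= 2 specimens for an SD: {dict(counts[counts < 2])}"
        )
    mu = np.vstack(
        [lib.values.loc[(lib.labels == c).to_numpy(), list(tracers)].mean(axis=0) for c in classes]
    )
    sigma = np.vstack(
        [lib.values.loc[(lib.labels == c).to_numpy(), list(tracers)].std(ddof=1) for c in classes]
    )
    n_k = np.array([counts[c] for c in classes], dtype=float)
    mu_se = sigma / np.sqrt(n_k)[:, None] if propagate_source_mean_error else None

    cons_missing = [t for t in tracers if t not in consumers.values.columns]
    if cons_missing:
        raise ValidationError(f"tracers not measured in consumers: {cons_missing}")
    y = consumers.values[list(tracers)].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("consumers contain missing tracer values")

    meta = consumers.meta
    labels = list(zip(meta["species"], meta["litter_treatment"]))
    cells = list(dict.fromkeys(labels))
    cell_index = np.array([cells.index(l) for l in labels], dtype=int)

    # a tracer with zero variance everywhere carries no information
    for j, t in enumerate(tracers):
        if sigma[:, j].max() == 0 and np.ptp(mu[:, j]) == 0 and y[:, j].std() == 0:
            raise ValidationError(f"tracer {t!r} has zero variance in sources and consumers")

    alpha = np.asarray(prior_alpha, dtype=float)
    if alpha.shape != (len(classes),):
        raise ConfigurationError(
            f"prior_alpha must have one entry per source class ({len(classes)}), got {alpha.shape}"
        )
    offset = None if fractionation_offset is None else np.asarray(fractionation_offset, float)
    fixed = None if fixed_residual_sd is None else np.asarray(fixed_residual_sd, float)
    return MixingModelSpec(
        sources=classes,
        tracers=tuple(tracers),
        mu=mu,
        sigma=sigma,
        cells=cells,
        y=y,
        cell_index=cell_index,
        prior_alpha=alpha,
        error_model=error_model,
        mu_se=mu_se,
        fractionation_offset=offset,
        fixed_residual_sd=fixed,
    )


# ---------------------------------------------------------------------------
# MCMC settings and posterior container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCSettings:
    """Sampler run lengths and tuning knobs."""

    n_iter: int = 300_000
    n_burnin: int = 200_000
    n_chains: int = 3
    thin: int = 100
    seed: int = 0
    proposal_scale: float = 0.5
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ConfigurationError("n_burnin must be < n_iter")
        if self.n_chains < 2:
            raise ConfigurationError("need >= 2 chains for the Gelman-Rubin diagnostic")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "MCMCSettings":
        """Reduced profile for desk-scale runs: 20k iterations, 10k burn-in, thin 10."""
        return cls(n_iter=20_000, n_burnin=10_000, thin=10, seed=seed, **kw)


@dataclass
class MixingPosterior:
    """Thinned post-burn-in draws plus diagnostics and summaries.

    ``p_draws`` has shape (n_chains, n_kept, n_cells, K) and
    ``sigma_res_draws`` (n_chains, n_kept, J). ``converged`` is True
    when every R-hat is below the threshold; summaries should not be
    trusted (and the pipeline refuses to report them) otherwise.
    """

    spec: MixingModelSpec
    settings: MCMCSettings
    p_draws: np.ndarray
    sigma_res_draws: np.ndarray
    acceptance: dict[str, float]
    diagnostics: pd.DataFrame
    converged: bool

    def cell_draws(self, cell) -> np.ndarray:
        """Pooled draws (n_total, K) for one cell label."""
        c = self.spec.cells.index(tuple(cell))
        return self.p_draws[:, :, c, :].reshape(-1, self.spec.n_sources)


@dataclass(frozen=True)
class RhatResult:
    """Split Gelman-Rubin statistic; ``degenerate`` marks constant chains."""

    rhat: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.rhat


def gelman_rubin(chains) -> RhatResult:
    """Split-R-hat for one scalar parameter.

    Each chain is halved, then between- and within-half variances are
    compared; values near 1 indicate the chains explore the same
    distribution. Chains with zero within-variance everywhere (all
    constant and equal) return exactly 1.0 with the degenerate flag.
    """
    X = np.asarray(chains, dtype=float)
    if X.ndim != 2:
        raise DomainError("chains must be a (n_chains, n_draws) array")
    m, n = X.shape
    if m < 2:
        raise DomainError("need >= 2 chains")
    if n < 20:
        raise DomainError("need >= 20 draws per chain (>= 10 per half)")
    half = n // 2
    halves = np.vstack([X[:, :half], X[:, half : 2 * half]])   # (2m, half)
    W = halves.var(axis=1, ddof=1).mean()
    means = halves.mean(axis=1)
    B = half * means.var(ddof=1)
    if W == 0.0:
        if B == 0.0:
            return RhatResult(1.0, degenerate=True)
        return RhatResult(float("inf"))
    var_hat = (half - 1) / half * W + B / half
    return RhatResult(float(np.sqrt(var_hat / W)))


def effective_sample_size(chains) -> float:
    """ESS from the multi-chain autocorrelation (Geyer initial positive pairs)."""
    X = np.asarray(chains, dtype=float)
    m, n = X.shape
    W = X.var(axis=1, ddof=1).mean()
    B = n * X.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_hat = (n - 1) / n * W + B / n
    if var_hat == 0:
        return float(m * n)
    centered = X - X.mean(axis=1, keepdims=True)
    max_lag = n - 1
    acov = np.zeros(max_lag)
    for t in range(max_lag):
        acov[t] = np.mean([np.dot(c[: n - t], c[t:]) / n for c in centered])
    rho = 1.0 - (W - acov) / var_hat
    # sum lag pairs while positive
    tau = 1.0
    t = 1
    while t + 1 < max_lag:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / max(tau, 1.0))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def _log_posterior_parts(spec, P, log_sig):
    """Cell-wise log likelihood + simplex prior, and the sigma prior.

    P : (C_, n_cells, K) proposals per chain; log_sig : (C_, J).
    Returns (cell_terms (C_, n_cells), sigma_prior (C_,)). Uses the
    per-cell sufficient statistics cached on the spec.

    When source-mean standard errors are present, a shared per-cell
    mean offset with variance v = sum_k p_k^2 mu_se_jk^2 is
    marginalized analytically: the cell's covariance is
    s^2 I + v 11', whose likelihood splits into a within-cell part
    (variance s^2) and a cell-mean part (variance s^2 + n v).
    """
    n_c, Sy, Sy2 = spec._suffstats
    mu, sig = spec.mu, spec.sigma
    n = n_c[None, :, None]
    M = P @ mu                                          # (C_, n_cells, J)
    if spec.fractionation_offset is not None:
        M = M + spec.fractionation_offset
    s2 = np.exp(2.0 * log_sig)[:, None, :]              # (C_, 1, J)
    if spec.error_model == "source_plus_residual":
        s2 = s2 + (P ** 2) @ (sig ** 2)
    ybar = Sy[None] / n
    ssw = Sy2[None] - Sy[None] ** 2 / n                 # within-cell scatter
    if spec.mu_se is not None:
        v = (P ** 2) @ (spec.mu_se ** 2)
        s2_mean = s2 + n * v
    else:
        s2_mean = s2
    ll = -0.5 * ((n - 1.0) * np.log(s2) + np.log(s2_mean)
                 + ssw / s2 + n * (ybar - M) ** 2 / s2_mean)
    cell_terms = ll.sum(axis=2)
    # Dirichlet(alpha) prior on p in ILR coordinates (Jacobian absorbed)
    cell_terms = cell_terms + (np.log(P) * spec.prior_alpha).sum(axis=2)
    # uniform prior on sigma_res in (0, SIGMA_RES_MAX), log-scale Jacobian e^u
    sig_prior = np.where(
        (np.exp(log_sig) < SIGMA_RES_MAX).all(axis=1), log_sig.sum(axis=1), -np.inf
    )
    return cell_terms, sig_prior


def fit_mixing_model(spec: MixingModelSpec, settings: MCMCSettings) -> MixingPosterior:
    """Sample the mixing posterior by blocked random-walk Metropolis.

    Per iteration, every cell's two ILR coordinates are updated with an
    independent Gaussian proposal (accepted cell-by-cell — the cells
    are conditionally independent given the residual SDs), then the
    log residual SDs jointly. Proposal scales adapt in batches of 100
    iterations during burn-in toward ~30% acceptance and are frozen
    afterwards. All chains run in lockstep on vectorized state.
    """
    K, J, C = spec.n_sources, len(spec.tracers), spec.n_cells
    if C == 0:
        raise ValidationError("no consumer cells to fit")
    if np.allclose(spec.mu, spec.mu[0:1], atol=1e-12):
        warnings.warn("identical source means for all tracers: proportions unidentifiable; "
                      "expect prior-wide posteriors", stacklevel=2)

    # per-cell sufficient statistics of the consumers
    n_c = np.zeros(C)
    Sy = np.zeros((C, J))
    Sy2 = np.zeros((C, J))
    for c in range(C):
        yc = spec.y[spec.cell_index == c]
        n_c[c] = len(yc)
        Sy[c] = yc.sum(axis=0)
        Sy2[c] = (yc ** 2).sum(axis=0)
    empty = np.flatnonzero(n_c == 0)
    if len(empty):
        warnings.warn(f"cells with zero consumers dropped: {[spec.cells[i] for i in empty]}",
                      stacklevel=2)
    spec._suffstats = (n_c, Sy, Sy2)

    nch = settings.n_chains
    rng = np.random.default_rng(settings.seed)
    sample_sigma = spec.fixed_residual_sd is None

    # overdispersed initialization: proportions from the prior, sigma near
    # the data scale
    Z = ilr(rng.dirichlet(spec.prior_alpha, size=(nch, C)))
    if sample_sigma:
        y_sd = max(spec.y.std(), 1e-3)
        U = np.log(y_sd) + 0.5 * rng.standard_normal((nch, J))
        U = np.minimum(U, np.log(SIGMA_RES_MAX) - 0.1)
    else:
        U = np.broadcast_to(np.log(np.maximum(spec.fixed_residual_sd, 1e-300)),
                            (nch, J)).copy()

    scale_cell = np.full((nch, C), settings.proposal_scale)
    scale_sig = np.full(nch, settings.proposal_scale * 0.6)

    P = ilr_inv(Z, K)
    cell_lp, sig_lp = _log_posterior_parts(spec, P, U)

    n_kept = (settings.n_iter - settings.n_burnin) // settings.thin
    p_draws = np.empty((nch, n_kept, C, K))
    sig_draws = np.empty((nch, n_kept, J))
    kept = 0

    acc_cell = np.zeros((nch, C))
    acc_sig = np.zeros(nch)
    total_acc_cell = 0.0
    total_acc_sig = 0.0
    n_after = 0
    batch = 100

    for it in range(settings.n_iter):
        # --- cell blocks (conditionally independent given sigma_res) ---
        Zp = Z + scale_cell[:, :, None] * rng.standard_normal((nch, C, 2))
        Pp = ilr_inv(Zp, K)
        cell_lp_p, _ = _log_posterior_parts(spec, Pp, U)
        accept = np.log(rng.random((nch, C))) < cell_lp_p - cell_lp
        Z = np.where(accept[:, :, None], Zp, Z)
        P = np.where(accept[:, :, None], Pp, P)
        cell_lp = np.where(accept, cell_lp_p, cell_lp)
        acc_cell += accept

        # --- residual-SD block ---
        if sample_sigma:
            Up = U + scale_sig[:, None] * rng.standard_normal((nch, J))
            cell_lp_u, sig_lp_u = _log_posterior_parts(spec, P, Up)
            accept_u = np.log(rng.random(nch)) < (
                cell_lp_u.sum(axis=1) + sig_lp_u - cell_lp.sum(axis=1) - sig_lp
            )
            U = np.where(accept_u[:, None], Up, U)
            cell_lp = np.where(accept_u[:, None], cell_lp_u, cell_lp)
            sig_lp = np.where(accept_u, sig_lp_u, sig_lp)
            acc_sig += accept_u

        # --- adaptation during burn-in, frozen afterwards ---
        if it < settings.n_burnin:
            if (it + 1) % batch == 0:
                rate_c = acc_cell / batch
                scale_cell *= np.exp(1.0 * (rate_c - 0.3))
                acc_cell[:] = 0.0
                if sample_sigma:
                    rate_s = acc_sig / batch
                    scale_sig *= np.exp(1.0 * (rate_s - 0.3))
                    acc_sig[:] = 0.0
        else:
            if it == settings.n_burnin:
                acc_cell[:] = 0.0
                acc_sig[:] = 0.0
            n_after += 1
            if (it - settings.n_burnin + 1) % settings.thin == 0 and kept < n_kept:
                p_draws[:, kept] = P
                sig_draws[:, kept] = np.exp(U)
                kept += 1

    total_acc_cell = float(acc_cell.mean() / max(n_after, 1))
    total_acc_sig = float(acc_sig.mean() / max(n_after, 1)) if sample_sigma else float("nan")
    logger.info("post-burn-in acceptance: cells %.3f, sigma %.3f",
                total_acc_cell, total_acc_sig)

    # diagnostics per scalar parameter
    rows = []
    worst = 1.0
    for c in range(C):
        for k in range(K):
            chains = p_draws[:, :, c, k]
            rr = gelman_rubin(chains)
            ess = effective_sample_size(chains)
            rows.append({"parameter": f"p[{spec.cells[c]}][{spec.sources[k]}]",
                         "rhat": rr.rhat, "degenerate": rr.degenerate, "ess": ess})
            if not rr.degenerate:
                worst = max(worst, rr.rhat)
    if sample_sigma:
        for j in range(J):
            chains = sig_draws[:, :, j]
            rr = gelman_rubin(chains)
            ess = effective_sample_size(chains)
            rows.append({"parameter": f"sigma_res[{spec.tracers[j]}]",
                         "rhat": rr.rhat, "degenerate": rr.degenerate, "ess": ess})
            if not rr.degenerate:
                worst = max(worst, rr.rhat)
    diagnostics = pd.DataFrame(rows)
    converged = bool(worst < settings.rhat_threshold)
    if not converged:
        logger.warning("Gelman-Rubin check failed: max R-hat = %.4f >= %.3f; "
                       "summaries should not be reported", worst, settings.rhat_threshold)

    return MixingPosterior(
        spec=spec,
        settings=settings,
        p_draws=p_draws,
        sigma_res_draws=sig_draws,
        acceptance={"cells": total_acc_cell, "sigma": total_acc_sig},
        diagnostics=diagnostics,
        converged=converged,
    )


def summarize_posterior(post: MixingPosterior, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD and equal-tail credible interval per cell x source.

    Per cell the three posterior means sum to 1 (every draw lives on
    the simplex). Columns: species, litter_treatment, source, mean,
    sd, cri_low, cri_high, n_draws.
    """
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1), got {level}")
    a = (1.0 - level) / 2.0
    rows = []
    for c, (species, litter) in enumerate(post.spec.cells):
        draws = post.p_draws[:, :, c, :].reshape(-1, post.spec.n_sources)
        lo, hi = np.quantile(draws, [a, 1 - a], axis=0)
        for k, src in enumerate(post.spec.sources):
            rows.append({
                "species": species,
                "litter_treatment": litter,
                "source": src,
                "mean": float(draws[:, k].mean()),
                "sd": float(draws[:, k].std(ddof=1)),
                "cri_low": float(lo[k]),
                "cri_high": float(hi[k]),
                "n_draws": draws.shape[0],
            })
    return pd.DataFrame(rows)


def least_squares_simplex(spec: MixingModelSpec, cell_idx: int = 0,
                          resolution: float = 0.01) -> np.ndarray:
    """Brute-force grid search for the least-squares proportion vector.

    Enumerates the simplex at the given resolution and returns the p
    minimizing the residual sum of squares of one cell's consumers
    against the mixture mean. Independent of the sampler — used as the
    zero-noise-limit oracle.
    """
    yc = spec.y[spec.cell_index == cell_idx]
    K = spec.n_sources
    if K != 3:
        raise DomainError("grid oracle implemented for 3 sources")
    steps = int(round(1.0 / resolution))
    best, best_sse = None, np.inf
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            p = np.array([i, j, steps - i - j], dtype=float) / steps
            m = p @ spec.mu
            if spec.fractionation_offset is not None:
                m = m + spec.fractionation_offset
            sse = float(((yc - m) ** 2).sum())
            if sse < best_sse:
                best_sse, best = sse, p
    return best
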