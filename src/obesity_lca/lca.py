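"""Latent class analysis for binary indicators, fitted by EM.

The model is a finite mixture of product-Bernoulli distributions: patient i's
binary feature vector y_i arises from latent class k with probability π_k, and
given the class the J indicators are independent with class-conditional
probabilities ρ_kj. The log-likelihood is

    ℓ = Σ_i log Σ_k π_k Π_j ρ_kj^{y_ij} (1 − ρ_kj)^{1 − y_ij}

maximized by EM: the E-step computes posterior memberships τ_ik ∝ π_k
Π_j ρ_kj^{y_ij}(1−ρ_kj)^{1−y_ij}; the M-step sets π_k = mean_i τ_ik and
ρ_kj = Σ_i τ_ik y_ij / Σ_i τ_ik. Model size is chosen by fitting a range of
class counts and comparing AIC = −2ℓ + 2P and BIC = −2ℓ + P·ln(N), with
P = (K−1) + K·J free parameters.

All arithmetic is done in log space; ρ is clamped to [1e-6, 1−1e-6] so the
likelihood never degenerates. Classes are relabelled in descending π̂ order
after fitting so reports are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

RHO_CLAMP = 1e-6


@dataclass
class LCAModel:
    K: int
    pi: np.ndarray
    rho: np.ndarray  # K x J
    log_likelihood: float
    converged: bool
    n_iterations: int
    n_obs: int
    ll_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K * self.rho.shape[1]

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_obs)


@dataclass
class PosteriorMatrix:
    """N × K posterior membership probabilities with max-posterior assignments.

    Ties in the argmax go to the lowest class index.
    """

    tau: np.ndarray
    patient_ids: list[str]

    @property
    def assigned_class(self) -> np.ndarray:
        return np.argmax(self.tau, axis=1)


def _validate_features(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("features must be binary 0/1")
    return y.astype(float)


def log_likelihood(y: np.ndarray, pi: np.ndarray, rho: np.ndarray) -> float:
    """Mixture log-likelihood ℓ(π, ρ | y), computed in log space."""
    y = _validate_features(y)
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(pi), y.shape[1]):
        raise ValueError("rho must have shape (K, J) matching pi and features")
    return float(logsumexp(_log_joint(y, pi, rho), axis=1).sum())


def _log_joint(y: np.ndarray, pi: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """N × K matrix of log(π_k · P(y_i | class k))."""
    rho = np.clip(rho, RHO_CLAMP, 1.0 - RHO_CLAMP)
    return np.log(pi)[None, :] + y @ np.log(rho).T + (1.0 - y) @ np.log(1.0 - rho).T


def _em_single(
    y: np.ndarray,
    pi: np.ndarray,
    rho: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool, int]:
    n = y.shape[0]
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    tau = None
    for it in range(1, max_iter + 1):
        log_joint = _log_joint(y, pi, rho)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        tau = np.exp(log_joint - log_norm[:, None])
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        # M-step
        weight = tau.sum(axis=0)
        pi = weight / n
        rho = np.clip((tau.T @ y) / weight[:, None], RHO_CLAMP, 1.0 - RHO_CLAMP)
    if not converged:
        # sync reported likelihood/posteriors with the final M-step parameters
        log_joint = _log_joint(y, pi, rho)
        log_norm = logsumexp(log_joint, axis=1)
        trace.append(float(log_norm.sum()))
        tau = np.exp(log_joint - log_norm[:, None])
    return pi, rho, tau, trace, converged, len(trace)


def fit_em(
    features,
    K: int,
    n_starts: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int | None = None,
) -> tuple[LCAModel, PosteriorMatrix]:
    """Fit a K-class model from ``n_starts`` random initializations and keep
    the best-likelihood run.

    ``features`` is a :class:`~obesity_lca.cohort_builder.FeatureMatrix` or a
    binary array. Initialization draws π from a flat Dirichlet and ρ entries
    uniform on (0.2, 0.8); per-start RNG streams are derived from ``seed`` so
    fits are reproducible. After fitting, classes are ordered by descending π̂.
    """
    data = features.data if hasattr(features, "data") else features
    patient_ids = (
        list(data.index) if isinstance(data, pd.DataFrame) else [str(i) for i in range(len(data))]
    )
    y = _validate_features(np.asarray(data))
    n, J = y.shape
    if K < 1:
        raise ValueError("K must be at least 1")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of patients ({n})")

    best = None
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, start]))
        pi0 = rng.dirichlet(np.ones(K))
        rho0 = rng.uniform(0.2, 0.8, size=(K, J))
        pi, rho, tau, trace, converged, n_iter = _em_single(y, pi0, rho0, max_iter, tol)
        if best is None or trace[-1] > best[3][-1]:
            best = (pi, rho, tau, trace, converged, n_iter)

    pi, rho, tau, trace, converged, n_iter = best
    order = np.argsort(-pi, kind="stable")
    pi, rho, tau = pi[order], rho[order], tau[:, order]
    model = LCAModel(
        K=K,
        pi=pi,
        rho=rho,
        log_likelihood=trace[-1],
        converged=converged,
        n_iterations=n_iter,
        n_obs=n,
        ll_trace=trace,
    )
    return model, PosteriorMatrix(tau, patient_ids)


def percent_reduction(previous: float, current: float) -> float:
    """Percent reduction of an information criterion between successive model
    sizes: (IC_prev − IC_cur) / IC_prev × 100, rounded to 2 decimals."""
    return round((previous - current) / previous * 100.0, 2)


def ic_table_from_values(ks, aics, bics) -> pd.DataFrame:
    """Comparison table of information criteria across class counts.

    Percent-reduction columns relate each row to the previous (smaller-K) row;
    the first row has no predecessor and is left blank (NaN).
    """
    ks, aics, bics = list(ks), list(aics), list(bics)
    rows = []
    for i, (k, a, b) in enumerate(zip(ks, aics, bics)):
        rows.append(
            {
                "K": k,
                "AIC": a,
                "pct_reduction_AIC": percent_reduction(aics[i - 1], a) if i else np.nan,
                "BIC": b,
                "pct_reduction_BIC": percent_reduction(bics[i - 1], b) if i else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    models: dict[int, LCAModel]
    posteriors: dict[int, PosteriorMatrix]
    ic_table: pd.DataFrame
    selected_K: int

    @property
    def selected_model(self) -> LCAModel:
        return self.models[self.selected_K]

    @property
    def selected_posterior(self) -> PosteriorMatrix:
        return self.posteriors[self.selected_K]


def derive_seed(master_seed: int, *keys: int) -> int:
    """A reproducible 31-bit child seed for a keyed sub-stream."""
    return int(np.random.SeedSequence([master_seed, *keys]).generate_state(1)[0] % (2**31))


def sweep_models(
    features,
    k_min: int = 3,
    k_max: int = 8,
    n_starts: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
) -> SweepResult:
    """Fit every class count in [k_min, k_max] and select the minimum-BIC model
    (ties go to the smallest K; the AIC minimum is visible in the table)."""
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    models: dict[int, LCAModel] = {}
    posteriors: dict[int, PosteriorMatrix] = {}
    for K in range(k_min, k_max + 1):
        model, posterior = fit_em(
            features, K, n_starts=n_starts, max_iter=max_iter, tol=tol,
            seed=derive_seed(seed, K),
        )
        models[K] = model
        posteriors[K] = posterior
    ks = sorted(models)
    table = ic_table_from_values(
        ks, [models[k].aic for k in ks], [models[k].bic for k in ks]
    )
    bics = np.array([models[k].bic for k in ks])
    selected = ks[int(np.argmin(bics))]
    return SweepResult(models, posteriors, table, selected)


def membership_summary(posterior: PosteriorMatrix, flag_threshold: float = 5.0):
    """K × K table of mean (and SD) posterior membership by assigned class.

    Cell (g, k) is the mean posterior probability of class k among patients
    assigned to class g, in percent; the diagonal is the self-membership
    confidence. Off-diagonal means above ``flag_threshold`` percent are
    flagged. Empty classes yield NaN rows (flagged as empty, not an error).

    Returns (mean_pct, sd_pct, flags) DataFrames indexed by assigned class.
    """
    tau = posterior.tau
    K = tau.shape[1]
    assigned = posterior.assigned_class
    mean = np.full((K, K), np.nan)
    sd = np.full((K, K), np.nan)
    for g in range(K):
        members = tau[assigned == g]
        if len(members) == 0:
            continue
        mean[g] = members.mean(axis=0) * 100.0
        sd[g] = members.std(axis=0, ddof=0) * 100.0
    idx = pd.Index(range(K), name="assigned_class")
    cols = pd.Index(range(K), name="class")
    mean_df = pd.DataFrame(mean, index=idx, columns=cols)
    sd_df = pd.DataFrame(sd, index=idx, columns=cols)
    off_diag = ~np.eye(K, dtype=bool)
    flags = pd.DataFrame(
        (np.nan_to_num(mean) > flag_threshold) & off_diag, index=idx, columns=cols
    )
    return mean_df, sd_df, flags


# -- disk output -------------------------------------------------------------

def write_sweep(sweep: SweepResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for K in sorted(sweep.models):
        m = sweep.models[K]
        rows.append(
            {
                "K": K,
                "logLik": m.log_likelihood,
                "n_params": m.n_params,
                "AIC": m.aic,
                "pct_reduction_AIC": sweep.ic_table.set_index("K")["pct_reduction_AIC"].loc[K],
                "BIC": m.bic,
                "pct_reduction_BIC": sweep.ic_table.set_index("K")["pct_reduction_BIC"].loc[K],
                "converged": int(m.converged),
                "n_iter": m.n_iterations,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "lca_models.csv", index=False, float_format="%.10g")
    for K, m in sweep.models.items():
        params = pd.DataFrame(m.rho, columns=[f"rho_{j}" for j in range(m.rho.shape[1])])
        params.insert(0, "pi", m.pi)
        params.insert(0, "class", range(K))
        params.to_csv(outdir / f"params_K{K}.csv", index=False, float_format="%.10g")
    post = sweep.selected_posterior
    df = pd.DataFrame(
        post.tau, columns=[f"tau_{k}" for k in range(post.tau.shape[1])]
    )
    df.insert(0, "patient_id", post.patient_ids)
    df["assigned_class"] = post.assigned_class
    df.to_csv(outdir / "posteriors.csv", index=False, float_format="%.10g")
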