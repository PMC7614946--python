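"""Sum-of-single-effects fine-mapping of cis windows.

Implements the additive-single-effects Bayesian regression (fitted by
iterative Bayesian stepwise selection), 95% credible-set extraction with
purity filtering, a grid search over the number of effects L that
rejects fits whose credible sets are in LD, the genome-wide-significance
joint model over credible-set lead variants, variance explained, and a
genotype-by-sex interaction test.

The model is y = Σ_l X b_l + e with e ~ N(0, σ²I); each b_l has exactly
one nonzero coordinate, uniform over variants a priori, with effect
prior N(0, σ0l²). Fitting cycles over effects: the expected contribution
of the other effects is subtracted from y and a single-effect Bayesian
regression is solved in closed form; the residual variance σ² is updated
by its expected-residual maximizer and each σ0l² by maximizing the
single-effect Bayes factor (an effect whose optimized Bayes factor does
not beat the null is switched off). The variational objective (ELBO) is
non-decreasing across iterations and is used as the stopping rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

import statsmodels.api as sm

GENOME_WIDE_P = 5e-8


@dataclass
class SusieFit:
    """Posterior summary of one sum-of-single-effects fit."""

    L: int
    alpha: np.ndarray  # (L, m) per-effect posterior inclusion weights
    mu: np.ndarray  # (L, m) posterior mean of the standardized effect
    mu2: np.ndarray  # (L, m) posterior second moment
    lbf_variable: np.ndarray  # (L, m) per-variant log Bayes factors
    sigma2: float
    prior_var: np.ndarray  # (L,) per-effect prior effect variance
    elbo_trace: list[float]
    converged: bool

    @property
    def pip(self) -> np.ndarray:
        """Per-variant posterior inclusion probability across effects."""
        return 1.0 - np.prod(1.0 - self.alpha, axis=0)


@dataclass
class CredibleSet:
    """A coverage-level credible set for one independent signal."""

    variant_indices: list[int]  # ordered by descending inclusion weight
    lead: int
    attained_coverage: float
    purity: float
    effect_slot: int

    def __contains__(self, j: int) -> bool:
        return j in self.variant_indices


@dataclass
class JointModelResult:
    """Joint multiple regression of the trait on all credible-set leads."""

    table: pd.DataFrame  # lead_index, beta, se, p, retained
    dropped: list[int] = field(default_factory=list)
    threshold: float = GENOME_WIDE_P
    r_squared: float = float("nan")

    @property
    def retained_leads(self) -> list[int]:
        return list(self.table.loc[self.table["retained"], "lead_index"])


def single_effect_regression(
    X: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    prior_var: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form Bayesian single-effect regression.

    For each variant j with least-squares estimate b̂_j and sampling
    variance s²_j = σ²/(X_jᵀX_j), the log Bayes factor of the
    N(0, σ0²) effect against the point-null is

        lbf_j = log N(b̂_j; 0, σ0² + s²_j) − log N(b̂_j; 0, s²_j)

    and the inclusion weights are the softmax of lbf under a uniform
    prior over variants. Returns (alpha, mu, mu2, lbf).
    """
    if prior_var < 0:
        raise ValueError(f"prior_var must be non-negative, got {prior_var}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    d = np.einsum("ij,ij->j", X, X)
    if (d == 0).any():
        raise ValueError("zero-variance column in X")
    Xty = X.T @ y
    return _ser_from_sufficient(Xty, d, sigma2, prior_var)


def _ser_from_sufficient(
    Xty: np.ndarray, d: np.ndarray, sigma2: float, prior_var: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    m = Xty.size
    bhat = Xty / d
    s2 = sigma2 / d
    if prior_var == 0:
        return np.full(m, 1.0 / m), np.zeros(m), np.zeros(m), np.zeros(m)
    lbf = 0.5 * np.log(s2 / (s2 + prior_var)) + 0.5 * bhat**2 / s2 * (
        prior_var / (s2 + prior_var)
    )
    shifted = lbf - lbf.max()
    w = np.exp(shifted)
    alpha = w / w.sum()
    post_var = 1.0 / (1.0 / prior_var + d / sigma2)
    mu = post_var * Xty / sigma2
    mu2 = post_var + mu**2
    return alpha, mu, mu2, lbf


def _lbf_model(Xty: np.ndarray, d: np.ndarray, sigma2: float, V: float) -> float:
    """Log Bayes factor of the whole single-effect model vs the null."""
    if V == 0:
        return 0.0
    bhat = Xty / d
    s2 = sigma2 / d
    lbf = 0.5 * np.log(s2 / (s2 + V)) + 0.5 * bhat**2 / s2 * (V / (s2 + V))
    return float(logsumexp(lbf) - np.log(Xty.size))


def _optimize_prior_variance(
    Xty: np.ndarray, d: np.ndarray, sigma2: float, v_max: float
) -> float:
    """Maximize the single-effect Bayes factor over the prior variance.

    Search is on the log scale; if the optimum does not beat the null
    (model log-BF ≤ 0) the effect is switched off by returning 0.
    """
    res = minimize_scalar(
        lambda lv: -_lbf_model(Xty, d, sigma2, float(np.exp(lv))),
        bounds=(-30.0, np.log(max(v_max, 1e-6))),
        method="bounded",
        options={"xatol": 1e-8},
    )
    V = float(np.exp(res.x))
    if _lbf_model(Xty, d, sigma2, V) <= 0:
        return 0.0
    return V


def susie_fit(
    X: np.ndarray,
    y: np.ndarray,
    L: int = 10,
    max_iter: int = 100,
    tol: float = 1e-3,
    estimate_prior_var: bool = True,
    prior_var: float | None = None,
    standardize: bool = True,
) -> SusieFit:
    """Fit the sum-of-single-effects model by iterative stepwise updates.

    Parameters
    ----------
    X, y:
        Dosage matrix and (residualized) trait. Columns of X are
        standardized internally by default; y is centered.
    L:
        Maximum number of single effects.
    tol, max_iter:
        Stop when the ELBO improves by less than ``tol`` (default 1e-3)
        or after ``max_iter`` sweeps; a non-converged fit is returned
        with ``converged=False`` and a warning.
    estimate_prior_var:
        Optimize each effect's prior variance by maximizing its Bayes
        factor (the default); otherwise keep it fixed at ``prior_var``
        or 0.2·var(y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n <= 1 or L < 1:
        raise ValueError("need n > 1 and L >= 1")
    if y.size != n:
        raise ValueError("y length does not match X rows")

    if standardize:
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("monomorphic columns cannot be standardized")
        X = (X - X.mean(axis=0)) / sd
    y = y - y.mean()

    d = np.einsum("ij,ij->j", X, X)
    var_y = float(y.var())
    if var_y == 0:
        raise ValueError("constant trait")
    sigma2 = var_y
    v_init = prior_var if prior_var is not None else 0.2 * var_y
    V = np.full(L, float(v_init))

    alpha = np.full((L, m), 1.0 / m)
    mu = np.zeros((L, m))
    mu2 = np.zeros((L, m))
    lbf_var = np.zeros((L, m))
    Xr = np.zeros((L, n))  # per-effect expected contribution X·(alpha∘mu)
    fitted = np.zeros(n)

    elbo_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        kl_sum = 0.0
        for l in range(L):
            fitted -= Xr[l]
            r = y - fitted
            Xtr = X.T @ r
            if estimate_prior_var:
                V[l] = _optimize_prior_variance(Xtr, d, sigma2, v_max=max(var_y, 1.0))
            alpha[l], mu[l], mu2[l], lbf_var[l] = _ser_from_sufficient(
                Xtr, d, sigma2, V[l]
            )
            b_bar = alpha[l] * mu[l]
            Xr[l] = X @ b_bar
            fitted += Xr[l]
            # KL(q_l || prior) = E_q log p(r_l|b_l) − log p(r_l) for the exact
            # single-effect posterior
            lbf_model = _lbf_model(Xtr, d, sigma2, V[l])
            e_quad = -2.0 * (Xtr @ b_bar) + float(alpha[l] @ (d * mu2[l]))
            kl_sum += -lbf_model - e_quad / (2.0 * sigma2)

        resid = y - fitted
        er2 = (
            float(resid @ resid)
            - sum(float(Xr[l] @ Xr[l]) for l in range(L))
            + sum(float(alpha[l] @ (d * mu2[l])) for l in range(L))
        )
        elbo = -0.5 * n * np.log(2 * np.pi * sigma2) - er2 / (2.0 * sigma2) - kl_sum
        elbo_trace.append(float(elbo))
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break
        sigma2 = max(er2 / n, 1e-12)

    if not converged:
        warnings.warn("susie_fit did not converge within max_iter", stacklevel=2)
    return SusieFit(
        L=L,
        alpha=alpha,
        mu=mu,
        mu2=mu2,
        lbf_variable=lbf_var,
        sigma2=float(sigma2),
        prior_var=V,
        elbo_trace=elbo_trace,
        converged=converged,
    )


def extract_credible_sets(
    fit: SusieFit,
    X: np.ndarray,
    coverage: float = 0.95,
    min_purity: float = 0.5,
    marginal_p: np.ndarray | None = None,
    allow_unconverged: bool = False,
) -> list[CredibleSet]:
    """Derive coverage-level credible sets from a fit.

    Per effect: variants are ranked by inclusion weight and the smallest
    prefix reaching the target coverage is taken. Effects whose optimized
    Bayes factor never beats the null (max per-variant log-BF ≤ 0) are
    skipped; sets whose purity (minimum absolute genotype correlation
    among members) falls below ``min_purity`` are discarded, and exact
    duplicate sets across effects are reported once. The lead is the
    maximum-weight member, ties broken by smaller marginal p (when
    supplied) then by lower variant index.
    """
    if not fit.converged and not allow_unconverged:
        raise ValueError("fit did not converge; pass allow_unconverged=True to proceed")
    X = np.asarray(X, dtype=float)
    sets: list[CredibleSet] = []
    seen: set[tuple[int, ...]] = set()
    for l in range(fit.L):
        if fit.prior_var[l] == 0 or fit.lbf_variable[l].max() <= 0:
            continue
        order = np.argsort(-fit.alpha[l], kind="stable")
        cum = np.cumsum(fit.alpha[l][order])
        size = int(np.searchsorted(cum, coverage) + 1)
        size = min(size, len(order))
        members = order[:size]
        attained = float(cum[size - 1])
        if attained < coverage:  # numerical shortfall (weights sum to 1)
            attained = float(cum[-1])
        if len(members) > 1:
            C = np.corrcoef(X[:, members], rowvar=False)
            iu = np.triu_indices(len(members), k=1)
            purity = float(np.abs(C[iu]).min())
        else:
            purity = 1.0
        if purity < min_purity:
            continue
        key = tuple(sorted(members))
        if key in seen:
            continue
        seen.add(key)
        lead = _pick_lead(fit.alpha[l], members, marginal_p)
        sets.append(
            CredibleSet(
                variant_indices=[int(j) for j in members],
                lead=int(lead),
                attained_coverage=attained,
                purity=purity,
                effect_slot=l,
            )
        )
    return sets


def _pick_lead(alpha_row, members, marginal_p):
    w = alpha_row[members]
    best = w == w.max()
    cands = np.asarray(members)[best]
    if marginal_p is not None and len(cands) > 1:
        cands = cands[np.argsort(np.asarray(marginal_p)[cands], kind="stable")]
    return int(cands[0]) if len(cands) else int(members[0])


def _cross_set_max_r2(X: np.ndarray, a: CredibleSet, b: CredibleSet) -> float:
    A = X[:, a.variant_indices]
    B = X[:, b.variant_indices]
    Ac = (A - A.mean(0)) / A.std(0)
    Bc = (B - B.mean(0)) / B.std(0)
    r = (Ac.T @ Bc) / X.shape[0]
    return float((r**2).max())


def sets_admissible(
    X: np.ndarray, sets: list[CredibleSet], cs_ld_threshold: float = 0.1
) -> bool:
    """True when all credible sets are disjoint and cross-set r² ≤ threshold."""
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if set(sets[i].variant_indices) & set(sets[j].variant_indices):
                return False
            if _cross_set_max_r2(X, sets[i], sets[j]) > cs_ld_threshold:
                return False
    return True


def select_L_grid(
    X: np.ndarray,
    y: np.ndarray,
    grid: range | list[int] = range(2, 11),
    cs_ld_threshold: float = 0.1,
    coverage: float = 0.95,
    min_purity: float = 0.5,
    marginal_p: np.ndarray | None = None,
    **susie_opts,
) -> tuple[SusieFit, list[CredibleSet]]:
    """Grid search over the number of effects L.

    Fits are evaluated from the largest L downward and the first
    admissible one is returned — equivalent to fitting every L and
    keeping the largest admissible, since admissibility is checked per
    fit. A fit is admissible when its credible sets are pairwise
    disjoint with maximum cross-set r² at or below ``cs_ld_threshold``.
    If no L in the grid is admissible the model falls back to L = 1.
    """
    grid = sorted(set(int(L) for L in grid), reverse=True)
    if not grid:
        raise ValueError("empty L grid")
    for L in grid:
        fit = susie_fit(X, y, L=L, **susie_opts)
        sets = extract_credible_sets(
            fit, X, coverage=coverage, min_purity=min_purity,
            marginal_p=marginal_p, allow_unconverged=True,
        )
        if sets_admissible(X, sets, cs_ld_threshold):
            return fit, sets
    fit = susie_fit(X, y, L=1, **susie_opts)
    sets = extract_credible_sets(
        fit, X, coverage=coverage, min_purity=min_purity,
        marginal_p=marginal_p, allow_unconverged=True,
    )
    return fit, sets


def joint_lead_test(
    G_leads: np.ndarray,
    y: np.ndarray,
    lead_indices: list[int] | None = None,
    threshold: float = GENOME_WIDE_P,
) -> JointModelResult:
    """Joint multiple regression of the trait on all credible-set leads.

    One OLS fit of y on all lead dosages plus an intercept; per-lead
    two-sided p from the t statistic; a lead is retained when its joint
    p-value passes genome-wide significance (default 5e-8). Linearly
    dependent leads are dropped (later lead loses) with a warning.
    """
    G_leads = np.atleast_2d(np.asarray(G_leads, dtype=float))
    if G_leads.shape[0] == 1 and G_leads.shape[1] == y.size:
        G_leads = G_leads.T
    n, k = G_leads.shape
    if lead_indices is None:
        lead_indices = list(range(k))
    if n <= k + 1:
        raise ValueError(f"too few samples (n={n}) for {k} leads plus intercept")

    keep: list[int] = []
    dropped: list[int] = []
    for j in range(k):
        cols = keep + [j]
        D = np.column_stack([np.ones(n), G_leads[:, cols]])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            dropped.append(lead_indices[j])
            warnings.warn(
                f"lead {lead_indices[j]} linearly dependent on earlier leads; dropped",
                stacklevel=2,
            )
        else:
            keep.append(j)

    D = sm.add_constant(G_leads[:, keep])
    res = sm.OLS(np.asarray(y, dtype=float), D).fit()
    table = pd.DataFrame(
        {
            "lead_index": [lead_indices[j] for j in keep],
            "beta": res.params[1:],
            "se": res.bse[1:],
            "p": res.pvalues[1:],
        }
    )
    table["retained"] = table["p"] < threshold
    return JointModelResult(
        table=table, dropped=dropped, threshold=threshold,
        r_squared=float(res.rsquared),
    )


def variance_explained(G_leads: np.ndarray, y: np.ndarray) -> float:
    """R² of the joint lead-variant model: the variance explained estimate."""
    G_leads = np.atleast_2d(np.asarray(G_leads, dtype=float))
    if G_leads.shape[0] == 1 and G_leads.shape[1] == np.asarray(y).size:
        G_leads = G_leads.T
    D = sm.add_constant(G_leads)
    return float(sm.OLS(np.asarray(y, dtype=float), D).fit().rsquared)


def sex_interaction_test(
    g: np.ndarray,
    y: np.ndarray,
    sex: np.ndarray,
    C: pd.DataFrame | None = None,
) -> dict:
    """Test effect modification of a cis-pQTL by sex.

    Fits y ~ g + sex + g×sex (+ covariates) by OLS and returns the
    interaction coefficient with its p-value plus sex-stratified
    genotype effects. Requires both sexes present.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if len(np.unique(sex)) < 2:
        raise ValueError("both sexes must be present for the interaction test")

    cols = [g, sex, g * sex]
    names = ["g", "sex", "g_x_sex"]
    if C is not None and C.shape[1] > 0:
        from cispqtl.preprocess import _expand_design

        D_cov, cov_names = _expand_design(
            C.drop(columns=[c for c in ("sample_id",) if c in C.columns])
        )
        cols.extend(D_cov[:, 1:].T)  # skip the intercept; added below
        names.extend(cov_names[1:])
    D = sm.add_constant(np.column_stack(cols))
    res = sm.OLS(y, D).fit()

    beta_by_sex = {}
    for level in np.unique(sex):
        mask = sex == level
        Ds = sm.add_constant(g[mask])
        sub = sm.OLS(y[mask], Ds).fit()
        beta_by_sex[float(level)] = float(sub.params[1])
    return {
        "beta_interaction": float(res.params[3]),
        "se_interaction": float(res.bse[3]),
        "p_interaction": float(res.pvalues[3]),
        "beta_by_sex": beta_by_sex,
        "terms": names,
    }
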