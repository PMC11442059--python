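"""Information-theoretic multi-model inference on contrast tables.

Candidate linear mixed models (random intercept per individual, ML fit) are
enumerated over four categorical predictors and their pairwise interactions
under marginality, ranked by AICc, and combined by Akaike-weight model
averaging with per-term importance and strong-effect flags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

MAINS = ("species", "morph", "substrate", "predator")

#: treatment-coding levels; first entry is the reference level
LEVELS = {
    "species": ["granulifera", "pumilio"],
    "morph": ["green", "red"],
    "substrate": ["green_leaf", "leaf_litter", "trunk"],
    "predator": ["bird", "lizard", "crab"],
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure: main-effect factors plus pairwise interactions.

    Marginality: every interaction's parents must be present in ``mains``.
    The intercept is always included.
    """

    mains: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.mains or b not in self.mains:
                raise ValueError(f"interaction {a}:{b} violates marginality")

    @property
    def terms(self) -> list[str]:
        return list(self.mains) + [f"{a}:{b}" for a, b in self.interactions]

    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"~ {rhs}"


def enumerate_candidates(
    mains: tuple[str, ...] = MAINS, max_order: int = 2
) -> list[ModelSpec]:
    """All marginality-respecting specs from intercept-only up to all mains
    plus all pairwise interactions (113 specs for 4 mains)."""
    specs = []
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            pairs = list(itertools.combinations(subset, 2)) if max_order >= 2 else []
            for k in range(len(pairs) + 1):
                for inter in itertools.combinations(pairs, k):
                    specs.append(ModelSpec(mains=subset, interactions=inter))
    return specs


def _main_columns(data: pd.DataFrame, factor: str) -> tuple[np.ndarray, list[str]]:
    levels = LEVELS[factor]
    obs = set(data[factor].astype(str))
    unknown = obs - set(levels)
    if unknown:
        raise ValueError(f"factor {factor!r}: unknown levels {sorted(unknown)}")
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((data[factor].astype(str) == lev).to_numpy(dtype=float))
        names.append(f"{factor}[{lev}]")
    return np.column_stack(cols), names


def design_matrix(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept, mains, then interactions."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    main_cols: dict[str, tuple[np.ndarray, list[str]]] = {}
    for factor in spec.mains:
        X, nm = _main_columns(data, factor)
        main_cols[factor] = (X, nm)
        blocks.append(X)
        names.extend(nm)
    for a, b in spec.interactions:
        Xa, na = main_cols[a]
        Xb, nb = main_cols[b]
        for i, ni in enumerate(na):
            for j, nj in enumerate(nb):
                blocks.append((Xa[:, i] * Xb[:, j])[:, None])
                names.append(f"{ni}:{nj}")
    X = np.hstack(blocks)
    return X, names


@dataclass
class ModelFit:
    """ML fit of a random-intercept Gaussian mixed model."""

    spec: ModelSpec
    coef: pd.Series
    se: pd.Series
    loglik: float
    k: int  # fixed effects + 2 variance parameters
    n: int
    sigma2_between: float
    sigma2_resid: float
    aicc: float = field(default=np.nan)
    delta_aicc: float = field(default=np.nan)
    weight: float = field(default=np.nan)
    evidence_ratio: float = field(default=np.nan)

    @property
    def terms(self) -> list[str]:
        return self.spec.terms


def _profile_loglik(
    lam: float,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    SX: np.ndarray,
    Sy: np.ndarray,
    msizes: np.ndarray,
    n: int,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled ML log-likelihood for variance ratio lam = s2_b / s2_e.

    Uses (I + lam J)^-1 = I - lam/(1 + lam m) J per group, so all
    V-weighted crossproducts follow from plain crossproducts and group sums.
    Returns (loglik, beta, info matrix XtV^-1X, sigma2_resid).
    """
    c = lam / (1.0 + lam * msizes)  # per-group shrinkage
    XtVX = XtX - (SX.T * c) @ SX
    XtVy = Xty - (SX.T * c) @ Sy
    ytVy = yty - float((c * Sy) @ Sy)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - 2.0 * beta @ XtVy + beta @ XtVX @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(lam * msizes)))
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, XtVX, sigma2


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, response: str) -> ModelFit:
    """Maximum-likelihood fit of response ~ spec fixed effects + (1 | individual).

    The deviance is profiled over the between/within variance ratio, which is
    then optimized on a log scale (with the boundary ratio 0 also checked).
    """
    y = data[response].to_numpy(dtype=float)
    X, names = design_matrix(spec, data)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"singular design for terms {spec.terms}: aliased columns")
    groups, ginv = np.unique(data["individual"].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 individuals for a random intercept")
    counts = np.bincount(ginv)
    if counts.min() < 2:
        raise ValueError("need >= 2 records per individual")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    SX = np.zeros((len(groups), p))
    np.add.at(SX, ginv, X)
    Sy = np.bincount(ginv, weights=y)

    def neg_ll(log_lam: float) -> float:
        return -_profile_loglik(np.exp(log_lam), XtX, Xty, yty, SX, Sy, counts, n)[0]

    res = minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam_hat = float(np.exp(res.x))
    ll_hat = -res.fun
    ll0 = _profile_loglik(0.0, XtX, Xty, yty, SX, Sy, counts, n)[0]
    if ll0 >= ll_hat:
        lam_hat, ll_hat = 0.0, ll0
    ll, beta, XtVX, sigma2 = _profile_loglik(lam_hat, XtX, Xty, yty, SX, Sy, counts, n)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    return ModelFit(
        spec=spec,
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        loglik=float(ll),
        k=p + 2,
        n=n,
        sigma2_between=lam_hat * sigma2,
        sigma2_resid=sigma2,
    )


def loglik_dense(fit: ModelFit, data: pd.DataFrame, response: str) -> float:
    """Direct marginal Gaussian log-density at the fitted parameters, via the
    dense n x n covariance. Independent check of the profiled likelihood."""
    from scipy.stats import multivariate_normal

    y = data[response].to_numpy(dtype=float)
    X, _ = design_matrix(fit.spec, data)
    groups, ginv = np.unique(data["individual"].to_numpy(), return_inverse=True)
    Z = np.zeros((len(y), len(groups)))
    Z[np.arange(len(y)), ginv] = 1.0
    V = fit.sigma2_resid * np.eye(len(y)) + fit.sigma2_between * (Z @ Z.T)
    mu = X @ fit.coef.to_numpy()
    return float(multivariate_normal.logpdf(y, mean=mu, cov=V))


def aicc(fit: ModelFit) -> float:
    """Small-sample-corrected Akaike information criterion."""
    k, n = fit.k, fit.n
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def weights_and_ratios(fits: list[ModelFit]) -> list[ModelFit]:
    """Compute AICc, delta-AICc, Akaike weights and evidence ratios in place;
    returns the fits sorted by ascending AICc."""
    if not fits:
        raise ValueError("no fits")
    for f in fits:
        f.aicc = aicc(f)
    best = min(f.aicc for f in fits)
    rel = np.array([np.exp(-0.5 * (f.aicc - best)) for f in fits])
    w = rel / rel.sum()
    for f, wi in zip(fits, w):
        f.delta_aicc = f.aicc - best
        f.weight = float(wi)
        # w_best / w_i, computed from deltas so underflowing weights give inf
        with np.errstate(over="ignore"):
            f.evidence_ratio = float(np.exp(0.5 * f.delta_aicc))
    return sorted(fits, key=lambda f: f.aicc)


def confidence_set(fits: list[ModelFit], mass: float = 0.95) -> list[ModelFit]:
    """Smallest weight-ordered prefix with cumulative Akaike weight >= mass."""
    ordered = sorted(fits, key=lambda f: -f.weight)
    out, cum = [], 0.0
    for f in ordered:
        out.append(f)
        cum += f.weight
        if cum >= mass - 1e-12:
            break
    return out


def model_average(
    fits: list[ModelFit],
    conditional: bool = True,
    importance_threshold: float = 0.80,
) -> pd.DataFrame:
    """Model-averaged coefficients over a (confidence) set of fits.

    Weights are renormalized within the set. Importance of a model term is
    the summed weight of set members containing it; coefficient averages are
    conditional on the models containing the coefficient (weights
    renormalized to that subset) unless ``conditional=False``, in which case
    absent models contribute zero. The unconditional standard error is
    sum_i w_i * sqrt(se_i^2 + (b_i - bbar)^2); CI = bbar +/- 1.96 SE.
    """
    if not fits:
        raise ValueError("empty model set")
    wsum = sum(f.weight for f in fits)
    weights = {id(f): f.weight / wsum for f in fits}

    coef_names: list[str] = []
    for f in fits:
        for nm in f.coef.index:
            if nm not in coef_names:
                coef_names.append(nm)

    def term_of(coef_name: str) -> str:
        if coef_name == "(Intercept)":
            return "(Intercept)"
        parts = coef_name.split(":")
        return ":".join(p.split("[")[0] for p in parts)

    rows = []
    for nm in coef_names:
        term = term_of(nm)
        members = [f for f in fits if nm in f.coef.index]
        if not members:
            raise ValueError(f"coefficient {nm} in no model of the set")
        have_term = [
            f for f in fits if term == "(Intercept)" or term in f.terms
        ]
        importance = sum(weights[id(f)] for f in have_term)
        w_members = np.array([weights[id(f)] for f in members])
        betas = np.array([f.coef[nm] for f in members])
        ses = np.array([f.se[nm] for f in members])
        if conditional:
            wt = w_members / w_members.sum()
        else:
            # zero substitution: absent models contribute beta = 0, se = 0
            betas = np.append(betas, 0.0)
            ses = np.append(ses, 0.0)
            wt = np.append(w_members, 1.0 - w_members.sum())
        bbar = float(wt @ betas)
        se_u = float(wt @ np.sqrt(ses**2 + (betas - bbar) ** 2))
        lo, hi = bbar - 1.96 * se_u, bbar + 1.96 * se_u
        rows.append(
            {
                "coef": nm,
                "term": term,
                "n_models": len(members),
                "importance": importance,
                "estimate": bbar,
                "se": se_u,
                "ci_lower": lo,
                "ci_upper": hi,
                "strong": bool(lo > 0 or hi < 0),
                "important": bool(importance >= importance_threshold),
            }
        )
    return pd.DataFrame(rows)


def ranking_frame(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.spec.formula() for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.delta_aicc for f in fits],
            "weight": [f.weight for f in fits],
            "evidence_ratio": [f.evidence_ratio for f in fits],
        }
    )


def multimodel_analysis(
    data: pd.DataFrame,
    response: str,
    mass: float = 0.95,
    importance_threshold: float = 0.80,
    candidate_cap: int | None = 100,
    weight_floor: float | None = None,
    conditional: bool = True,
) -> dict:
    """Full pipeline: enumerate, fit by ML, rank by AICc, cap, select the
    cumulative-mass confidence set, and model-average.

    ``weight_floor`` optionally replaces the cumulative-mass rule with an
    absolute Akaike-weight cutoff for set membership.
    """
    specs = enumerate_candidates()
    fits = [fit_lmm(s, data, response) for s in specs]
    fits = weights_and_ratios(fits)
    if candidate_cap is not None and len(fits) > candidate_cap:
        fits = weights_and_ratios(fits[:candidate_cap])
    if weight_floor is not None:
        top = [f for f in fits if f.weight > weight_floor]
    else:
        top = confidence_set(fits, mass=mass)
    averaged = model_average(
        top, conditional=conditional, importance_threshold=importance_threshold
    )
    return {
        "fits": fits,
        "confidence_set": top,
        "averaged": averaged,
        "ranking": ranking_frame(fits),
    }
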