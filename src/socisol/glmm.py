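"""Random-intercept logistic regression for individuals nested in areas.

Model
-----
For participant *i* in FSA *j*,

    y_ij ~ Bernoulli(p_ij),   logit(p_ij) = x_ij' beta + u_j,
    u_j ~ Normal(0, sigma_u^2)  independently across FSAs.

Estimation is maximum likelihood: the marginal log-likelihood

    l(beta, sigma_u) = sum_j log INT prod_i p_ij^y (1-p_ij)^(1-y)
                                  phi(u; 0, sigma_u^2) du

is evaluated by adaptive Gauss-Hermite quadrature (AGHQ).  For each cluster
the integrand's mode and curvature are located by a damped Newton iteration
and the Gauss-Hermite rule is recentred and rescaled there, which keeps a
modest node count (default 15) accurate even for large clusters.  The outer
optimisation is quasi-Newton (L-BFGS-B) over (beta, log sigma_u), with
starting values from an ordinary logistic fit; Wald standard errors come
from the inverse of a finite-difference observed-information matrix.

This is deliberately a likelihood-based fit, not the linearised
pseudo-likelihood some mixed-model software defaults to; with a boundary
estimate sigma_u -> 0 it degenerates to ordinary logistic regression.

Adjusted odds ratios are exp(beta) with Wald confidence intervals, reported
at the 99% level with significance assessed at p < .01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

from .geolink import CENSUS_MEASURES
from .scoring import AGE_GROUP_LEVELS

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "build_design",
    "fit_random_intercept_logit",
    "marginal_loglik",
    "aor_table",
    "run_model_sequence",
    "sequence_table",
]

_SIGMA_FLOOR = 1e-6
_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    ``model`` is ``"m1"`` (individual-level terms only) or ``"m2"`` (adds
    the FSA-level census measures).  For the isolation outcome the
    definitional variables (marital status, living alone) and the
    % living alone census measure are excluded; the sex term enters only in
    the total-sample stratum.
    """

    outcome: str = "isolated"  # "isolated" | "lonely"
    model: str = "m2"          # "m1" | "m2"
    stratum: str = "total"     # "total" | "women" | "men"
    alpha: float = 0.01
    ci_level: float = 0.99

    def __post_init__(self):
        if self.outcome not in ("isolated", "lonely"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.model not in ("m1", "m2"):
            raise ValueError(f"model must be 'm1' or 'm2', got {self.model!r}")
        if self.stratum not in ("total", "women", "men"):
            raise ValueError(f"unknown stratum {self.stratum!r}")

    @property
    def categorical_terms(self) -> list[tuple[str, str]]:
        """Ordered (column, reference-level) pairs of categorical terms."""
        terms: list[tuple[str, str]] = [("age_group", AGE_GROUP_LEVELS[-1])]
        if self.stratum == "total":
            terms.append(("sex", "woman"))
        if self.outcome == "lonely":
            terms.append(("marital_status", "married_commonlaw"))
        terms += [
            ("education_binary", "postsecondary"),
            ("income_band", "lt20k"),
            ("functional_binary", "no_impairment"),
        ]
        return terms

    @property
    def numeric_terms(self) -> list[str]:
        """Ordered numeric (linearly-entered) terms."""
        terms = ["chronic_count"]
        if self.model == "m2":
            measures = [m for m in CENSUS_MEASURES
                        if not (self.outcome == "isolated" and m == "pct_living_alone")]
            terms += measures
        return terms

    @property
    def boolean_terms(self) -> list[str]:
        return ["living_alone"] if self.outcome == "lonely" else []


@dataclass
class Design:
    """Materialized regression design: response, fixed-effect matrix, clusters."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    cluster_index: np.ndarray
    cluster_ids: np.ndarray
    n_used: int
    n_dropped: int
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def build_design(records: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the treatment-coded design for one model specification.

    One indicator column per non-reference categorical level; numeric terms
    entered untransformed (FSA measures in percentage points, so odds
    ratios are per 1-point increase).  Rows missing any term or the outcome
    are dropped listwise with a logged count.  A reference level absent
    from the data is a hard error; an absent non-reference level is dropped
    from the design and recorded.
    """
    df = records
    if spec.stratum != "total":
        level = {"women": "woman", "men": "man"}[spec.stratum]
        df = df[df["sex"] == level]

    needed = [spec.outcome] + [c for c, _ in spec.categorical_terms] \
        + spec.boolean_terms + spec.numeric_terms
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records missing required columns: {missing_cols}")
    complete = df[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df[complete]

    cols: list[str] = []
    mats: list[np.ndarray] = []
    dropped: list[str] = []
    # urban/rural sits between chronic_count and the FSA measures in the
    # published table order; keep that order here
    cat_terms = list(spec.categorical_terms)
    cat_after_chronic = [("urban_rural", "rural")]

    def add_categorical(col: str, ref: str):
        vals = df[col]
        levels = list(vals.dtype.categories) if isinstance(vals.dtype, pd.CategoricalDtype) \
            else sorted(vals.unique(), key=str)
        if ref not in levels or not (vals == ref).any():
            raise ValueError(f"reference level {ref!r} absent from data for term {col!r}")
        for lev in levels:
            if lev == ref:
                continue
            name = f"{col}[{lev}]"
            ind = (vals == lev).to_numpy(dtype=float)
            if ind.sum() == 0:
                dropped.append(name)
                continue
            cols.append(name)
            mats.append(ind)

    def add_numeric(col: str):
        cols.append(col)
        mats.append(df[col].to_numpy(dtype=float))

    cols.append("intercept")
    mats.append(np.ones(len(df)))
    for col, ref in cat_terms:
        add_categorical(col, ref)
    for col in spec.boolean_terms:
        cols.append(f"{col}[True]")
        mats.append(df[col].astype(float).to_numpy())
    add_numeric("chronic_count")
    for col, ref in cat_after_chronic:
        add_categorical(col, ref)
    for col in spec.numeric_terms:
        if col != "chronic_count":
            add_numeric(col)

    X = np.column_stack(mats)
    y = df[spec.outcome].astype(float).to_numpy()
    ids, idx = np.unique(df["fsa_code"].to_numpy(), return_inverse=True)
    return Design(y=y, X=X, columns=cols, cluster_index=idx, cluster_ids=ids,
                  n_used=len(df), n_dropped=n_dropped, dropped_columns=dropped)


@dataclass
class FitResult:
    """Estimates from one random-intercept logistic fit."""

    spec: ModelSpec | None
    columns: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    sigma_u: float
    se_log_sigma_u: float
    loglik: float
    n_used: int
    n_clusters: int
    converged: bool
    iterations: int
    n_nodes: int
    message: str = ""
    boundary: bool = False
    loglik_path: list[float] = field(default_factory=list)
    vcov: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def as_dict(self) -> dict:
        return {
            "columns": self.columns,
            "beta": [float(b) for b in self.beta],
            "se_beta": [float(s) for s in self.se_beta],
            "sigma_u": float(self.sigma_u),
            "loglik": float(self.loglik),
            "n_used": self.n_used,
            "n_clusters": self.n_clusters,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "n_nodes": int(self.n_nodes),
            "boundary": bool(self.boundary),
            "message": self.message,
            "warnings": list(self.warnings),
        }


def _cluster_modes(eta0, y, cidx, n_clusters, sigma2, u0, tol=1e-10, maxit=60):
    """Per-cluster mode and negative curvature of the log integrand.

    The integrand log f_j(u) = sum_i [y eta - softplus(eta)] - u^2/(2 s^2)
    is strictly concave in u, so a (step-clipped) Newton iteration from the
    previous mode converges quadratically.
    """
    u = u0.copy()
    ssum = np.bincount(cidx, weights=np.ones_like(y), minlength=n_clusters)
    for _ in range(maxit):
        p = special.expit(eta0 + u[cidx])
        g = np.bincount(cidx, weights=y - p, minlength=n_clusters) - u / sigma2
        h = np.bincount(cidx, weights=p * (1.0 - p), minlength=n_clusters) + 1.0 / sigma2
        step = np.clip(g / h, -4.0, 4.0)
        u = u + step
        if np.max(np.abs(g) / (1.0 + ssum)) < tol:
            break
    p = special.expit(eta0 + u[cidx])
    h = np.bincount(cidx, weights=p * (1.0 - p), minlength=n_clusters) + 1.0 / sigma2
    return u, h


def marginal_loglik(
    params: np.ndarray,
    design: Design,
    n_nodes: int = 15,
    *,
    warm_modes: np.ndarray | None = None,
    return_modes: bool = False,
):
    """AGHQ marginal log-likelihood at ``params = (beta..., log sigma_u)``."""
    beta = params[:-1]
    sigma = float(np.exp(params[-1]))
    sigma2 = sigma * sigma
    y, X, cidx = design.y, design.X, design.cluster_index
    J = design.n_clusters
    eta0 = X @ beta

    u0 = warm_modes if warm_modes is not None else np.zeros(J)
    mode, h = _cluster_modes(eta0, y, cidx, J, sigma2, u0)
    tau = 1.0 / np.sqrt(h)

    z, wq = np.polynomial.hermite.hermgauss(n_nodes)
    log_wq = np.log(wq)
    contrib = np.empty((n_nodes, J))
    const = -0.5 * np.log(2.0 * np.pi * sigma2)
    for k in range(n_nodes):
        u_k = mode + np.sqrt(2.0) * tau * z[k]
        eta = eta0 + u_k[cidx]
        ll_i = y * eta - np.logaddexp(0.0, eta)
        per_cluster = np.bincount(cidx, weights=ll_i, minlength=J)
        per_cluster += const - u_k * u_k / (2.0 * sigma2)
        contrib[k] = per_cluster + log_wq[k] + z[k] * z[k] \
            + 0.5 * np.log(2.0) + np.log(tau)
    ll = float(special.logsumexp(contrib, axis=0).sum())
    if return_modes:
        return ll, mode
    return ll


def _plain_logit_start(design: Design) -> np.ndarray:
    """Starting beta from an ordinary logistic fit (zeros on failure)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(design.y, design.X).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)):
            return np.asarray(res.params, dtype=float)
    except Exception:
        pass
    return np.zeros(design.X.shape[1])


def _fd_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / (h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_random_intercept_logit(
    design: Design,
    n_nodes: int = 15,
    *,
    spec: ModelSpec | None = None,
    start_sigma_u: float = 0.1,
    start_beta: np.ndarray | None = None,
    fix_sigma_u: float | None = None,
    maxiter: int = 300,
) -> FitResult:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Optimises (beta, log sigma_u) by L-BFGS-B over the AGHQ marginal
    log-likelihood, starting from an ordinary logistic fit and a small
    random-intercept SD.  A variance estimate at the lower boundary is
    reported as sigma_u = 0 (the fit degenerates to ordinary logistic
    regression); ``fix_sigma_u`` profiles the fixed effects at a given
    random-intercept SD instead of estimating it (0 gives exactly the
    ordinary-logistic limit).  Non-convergence and suspected separation are
    flagged on the result, never silent.
    """
    if design.n_clusters < 2:
        raise ValueError("need at least 2 clusters for a random-intercept fit")
    p = design.X.shape[1]
    if np.linalg.matrix_rank(design.X) < p:
        raise ValueError("fixed-effect design is rank deficient; "
                         f"columns: {design.columns}")

    # optimize on a column-standardized design: percent-scale measures next
    # to 0/1 indicators make the raw problem badly conditioned
    spread = design.X.ptp(axis=0) if hasattr(design.X, "ptp") else np.ptp(design.X, axis=0)
    const = spread == 0
    m = np.where(const, 0.0, design.X.mean(axis=0))
    s = np.where(const, 1.0, design.X.std(axis=0))
    Xs = (design.X - m) / s
    dstd = Design(y=design.y, X=Xs, columns=design.columns,
                  cluster_index=design.cluster_index,
                  cluster_ids=design.cluster_ids,
                  n_used=design.n_used, n_dropped=design.n_dropped)
    # back-transform matrix over (beta, log sigma): beta_raw = T @ beta_std,
    # with the intercept (a constant column, if any) absorbing the centering
    T = np.eye(p + 1)
    T[:p, :p] = np.diag(1.0 / s)
    i0 = int(np.argmax(const)) if const.any() else None
    if i0 is not None:
        adj = -m / s
        adj[i0] = 1.0
        T[i0, :p] = adj

    if start_beta is not None:
        b0 = np.asarray(start_beta, dtype=float) * s
        if i0 is not None:
            b0[i0] = start_beta[i0] + float(np.sum(start_beta * m))
    else:
        b0 = _plain_logit_start(dstd)
    fixed = fix_sigma_u is not None
    if fixed:
        if fix_sigma_u < 0:
            raise ValueError("fix_sigma_u must be >= 0")
        theta0 = np.log(max(fix_sigma_u, _SIGMA_FLOOR))
    else:
        theta0 = np.log(max(start_sigma_u, _SIGMA_FLOOR))
    x0 = np.append(b0, theta0)

    warm = {"modes": np.zeros(design.n_clusters)}

    def negll(params):
        ll, modes = marginal_loglik(params, dstd, n_nodes,
                                    warm_modes=warm["modes"], return_modes=True)
        warm["modes"] = modes
        return -ll

    path: list[float] = []

    def callback(xk):
        path.append(-negll(xk))

    theta_bounds = (theta0, theta0) if fixed else (np.log(_SIGMA_FLOOR), np.log(20.0))
    bounds = [(-35.0, 35.0)] * p + [theta_bounds]
    opt = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds, callback=callback,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-7},
    )
    params = opt.x
    sigma_u = float(np.exp(params[-1]))
    boundary = params[-1] <= np.log(_SIGMA_FLOOR) + 1e-8
    if fixed:
        sigma_u = float(fix_sigma_u) if fix_sigma_u > _SIGMA_FLOOR else 0.0
    loglik = -float(opt.fun)

    warns: list[str] = []
    # observed information (standardized scale, then mapped back); at a
    # boundary (or with sigma_u fixed) the log-sigma direction is flat or
    # pinned, so invert only the beta block
    if boundary or fixed:
        def negll_beta(b):
            return negll(np.append(b, params[-1]))
        H = _fd_hessian(negll_beta, params[:-1])
        vcov_std = np.full((p + 1, p + 1), np.nan)
        try:
            vcov_std[:p, :p] = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warns.append("observed information not invertible")
        se_log_sigma = np.nan
    else:
        H = _fd_hessian(negll, params)
        try:
            vcov_std = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov_std = np.full((p + 1, p + 1), np.nan)
            warns.append("observed information not invertible")
        se_log_sigma = float(np.sqrt(max(vcov_std[p, p], 0.0)))

    beta_raw = T[:p, :p] @ params[:-1]
    vcov_full = T @ vcov_std @ T.T
    se_beta = np.sqrt(np.maximum(np.diag(vcov_full)[:p], 0.0))
    if np.isnan(se_log_sigma) and not boundary:
        se_log_sigma = np.nan

    big = np.abs(params[:-1]) > _SEPARATION_BETA
    at_bound = np.abs(params[:-1]) >= 35.0 - 1e-6
    if at_bound.any() or (big.any() and np.any(se_beta[big] > _SEPARATION_BETA)):
        bad = [design.columns[i] for i in np.where(big | at_bound)[0]]
        warns.append(f"possible separation on terms: {bad}")
        warnings.warn(warns[-1], stacklevel=2)

    return FitResult(
        spec=spec,
        columns=list(design.columns),
        beta=beta_raw,
        se_beta=se_beta,
        sigma_u=0.0 if boundary else sigma_u,
        se_log_sigma_u=se_log_sigma,
        loglik=loglik,
        n_used=design.n_used,
        n_clusters=design.n_clusters,
        converged=bool(opt.success),
        iterations=int(opt.nit),
        n_nodes=n_nodes,
        message=str(opt.message),
        boundary=bool(boundary),
        loglik_path=path,
        vcov=vcov_full,
        warnings=warns,
    )


def aor_table(fit: FitResult, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Adjusted odds ratios with Wald 99% CIs and p < .01 significance.

    AOR = exp(beta); CI = exp(beta -/+ z_{1-(1-ci)/2} * SE).  The intercept
    row is kept (labelled) but carries no star.
    """
    spec = spec or fit.spec or ModelSpec()
    z = stats.norm.ppf(0.5 + spec.ci_level / 2.0)
    beta, se = fit.beta, fit.se_beta
    zstat = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    rows = []
    with np.errstate(over="ignore"):  # huge SEs (flagged upstream) -> inf CI bound
        for name, b, s, pv in zip(fit.columns, beta, se, pvals):
            rows.append({
                "term": name,
                "beta": float(b),
                "se": float(s),
                "aor": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)),
                "ci_high": float(np.exp(b + z * s)),
                "p_value": float(pv),
                "significant": bool(pv < spec.alpha) and name != "intercept",
            })
    out = pd.DataFrame(rows)
    out["stars"] = np.where(out["significant"], "*", "")
    return out


def run_model_sequence(
    records: pd.DataFrame,
    outcome: str,
    *,
    n_nodes: int = 15,
    strata: tuple[str, ...] = ("total", "women", "men"),
) -> dict[tuple[str, str], FitResult]:
    """Fit the Model-1 / Model-2 x total / women / men sequence.

    Returns a dict keyed by ``(model, stratum)``; non-convergence in any
    cell is flagged on that cell's result rather than aborting the others.
    """
    fits: dict[tuple[str, str], FitResult] = {}
    for model in ("m1", "m2"):
        for stratum in strata:
            spec = ModelSpec(outcome=outcome, model=model, stratum=stratum)
            design = build_design(records, spec)
            fits[(model, stratum)] = fit_random_intercept_logit(
                design, n_nodes=n_nodes, spec=spec)
    return fits


def sequence_table(fits: dict[tuple[str, str], FitResult]) -> pd.DataFrame:
    """Side-by-side AOR (99% CI) table across models and strata.

    Rows follow the Model-2 total-sample term order; each (model, stratum)
    contributes an ``aor``, ``ci_low``, ``ci_high``, ``significant`` block.
    """
    order_fit = fits.get(("m2", "total")) or next(iter(fits.values()))
    terms = [t for t in order_fit.columns]
    out = pd.DataFrame({"term": terms})
    for (model, stratum), fit in fits.items():
        tab = aor_table(fit).set_index("term")
        prefix = f"{model}_{stratum}"
        for col in ("aor", "ci_low", "ci_high", "p_value", "significant"):
            out[f"{prefix}_{col}"] = [
                tab.at[t, col] if t in tab.index else np.nan for t in terms
            ]
    return out
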