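"""Synthetic clustered-survey generator with known ground truth.

Emulates a national aging-cohort questionnaire sample: participants aged
45-85 clustered into hundreds of FSAs of variable size (including some
below the small-area exclusion threshold), questionnaire items from which
the isolation index and loneliness indicator are derived, analytic survey
weights, and an FSA-level census table whose five measures are drawn from
truncated normals within published ranges.

Two outcome mechanisms are available:

``from_items``
    Contact-recency, participation and loneliness items are drawn from
    ordinal-logistic latents loaded on a per-person "connectedness" factor
    (with an FSA-level share, so the five criteria are positively
    associated and outcomes cluster geographically).  A single item-level
    shift parameter is calibrated by bisection so the index-derived
    isolation prevalence hits a configurable target (default 5.09%); the
    loneliness item has its own shift (default target 10.20%).

``from_linear_predictor``
    In addition to the items, a binary outcome is drawn directly from
    logistic(x'beta + u_j) with u_j ~ N(0, sigma_u^2), for
    parameter-recovery testing of the mixed model.

Everything is driven by one integer seed; the same seed reproduces the
tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from . import scoring
from .geolink import CENSUS_MEASURES
from .scoring import CHRONIC_COLUMNS, PARTICIPATION_COLUMNS

__all__ = [
    "SimulationConfig",
    "generate_census",
    "generate_participants",
    "generate_tables",
    "simulate_clustered_binary",
]

#: Per-measure (mean, sd, min, max) in percentage points; the default
#: emulation targets for the FSA census table.
DEFAULT_CENSUS_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "pct_women": (51.04, 1.54, 42.30, 56.00),
    "pct_65plus": (18.05, 5.37, 4.00, 40.20),
    "pct_nonofficial_language": (17.60, 16.04, 0.19, 75.44),
    "pct_65plus_low_income": (5.44, 6.06, 0.0, 51.00),
    "pct_living_alone": (28.94, 9.90, 8.48, 66.77),
}

#: Default covariate marginals (probabilities) for the participant table.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {"45_54": 0.3719, "55_64": 0.3125, "65_74": 0.1936, "75_85": 0.1219},
    "sex": {"woman": 0.5148, "man": 0.4852},
    "marital_status": {
        "married_commonlaw": 0.7471, "never_married": 0.0788, "widowed": 0.0723,
        "divorced": 0.0781, "separated": 0.0237,
    },
    "education": {"less_than_postsecondary": 0.3957, "postsecondary": 0.6043},
    "income_band": {
        "lt20k": 0.0493, "20to50k": 0.2226, "50to100k": 0.3384,
        "100to150k": 0.1851, "ge150k": 0.1503, "missing": 0.0543,
    },
    "urban_rural": {
        "rural": 0.2176, "urban_core": 0.6569, "urban_fringe": 0.0158,
        "urban_outside_cma_ca": 0.0554, "not_defined": 0.0543,
    },
}

#: Overall share living alone and mean chronic-condition count emulated.
DEFAULT_PCT_LIVING_ALONE = 0.1711
DEFAULT_MEAN_CHRONIC = 3.05

# Baseline cumulative shares for contact codes 1..6 per channel; the
# remainder is "has no such network members" (internal code 7).
_CONTACT_BASE_CUM = {
    "children": (0.30, 0.55, 0.70, 0.80, 0.84, 0.88),
    "siblings": (0.15, 0.35, 0.55, 0.68, 0.78, 0.88),
    "close_friends": (0.30, 0.60, 0.80, 0.90, 0.94, 0.97),
    "neighbors": (0.30, 0.55, 0.70, 0.82, 0.90, 0.94),
}
# Baseline cumulative shares for participation codes 1..4 (code 5 = never
# takes the remainder), shared across the eight activities.
_PARTICIPATION_BASE_CUM = (0.08, 0.45, 0.72, 0.86)
# Baseline shares of the loneliness item from the lonely end:
# P(code=1), P(code<=2), P(code<=3); code 4 takes the remainder.
_LONELY_BASE_CUM = (0.02, 0.08, 0.20)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the published study conditions."""

    n_fsa: int = 250
    cluster_size_mean: float = 40.0
    #: negative-binomial dispersion k (variance = m + m^2/k); small k gives
    #: strongly variable sizes including FSAs below the exclusion threshold
    cluster_size_dispersion: float = 2.0
    min_cluster_size: int = 1
    census_params: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENSUS_PARAMS))
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    pct_living_alone: float = DEFAULT_PCT_LIVING_ALONE
    mean_chronic: float = DEFAULT_MEAN_CHRONIC
    #: Gaussian-copula correlation between the FSA urbanicity propensity and
    #: the % 65+ low-income measure (drives Model-1 -> Model-2 attenuation)
    urbanicity_lowincome_corr: float = 0.5
    #: log-odds slope of urban-core residence on the urbanicity propensity
    urbanicity_slope: float = 1.0
    outcome_mode: str = "from_items"  # "from_items" | "from_linear_predictor"
    target_isolated_pct: float = 5.09
    target_lonely_pct: float = 10.20
    #: loading of the per-person connectedness latent on the ordinal items
    connectedness_strength: float = 1.0
    #: FSA-level share of the connectedness latent (outcome clustering)
    item_cluster_sd: float = 0.3
    true_beta: Mapping[str, float] | None = None
    sigma_u: float = 0.5
    weight_dispersion: float = 0.3
    seed: int = 12345

    def __post_init__(self):
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.outcome_mode not in ("from_items", "from_linear_predictor"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        for name, probs in self.covariate_marginals.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-3:
                raise ValueError(f"marginals for {name!r} sum to {total}, not 1")
        for m, (mean, sd, lo, hi) in self.census_params.items():
            if not (lo <= mean <= hi) or sd < 0 or lo > hi:
                raise ValueError(f"infeasible census range for {m!r}: "
                                 f"mean {mean}, sd {sd}, range [{lo}, {hi}]")


def _fsa_codes(n: int) -> list[str]:
    letters = "ABCEGHJKLMNPRSTVXY"  # letters actually used in postal codes
    codes = []
    for a in letters:
        for d in "0123456789":
            for b in letters:
                codes.append(f"{a}{d}{b}")
                if len(codes) == n:
                    return codes
    raise ValueError(f"cannot enumerate {n} distinct FSA codes")


def _truncnorm_ppf(q: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(q, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(q, a, b, loc=mean, scale=sd)


def generate_census(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the FSA census table plus its ground-truth record.

    Measures are truncated normals within the configured ranges; the
    % 65+ low-income measure is drawn correlated (Gaussian copula) with a
    latent per-FSA urbanicity propensity that later drives urban-core
    residence, so that area deprivation and urbanicity confound.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    codes = _fsa_codes(config.n_fsa)
    urbanicity = rng.standard_normal(config.n_fsa)
    table = {"fsa_code": codes}
    for m, (mean, sd, lo, hi) in config.census_params.items():
        if m == "pct_65plus_low_income":
            rho = config.urbanicity_lowincome_corr
            z = rho * urbanicity + np.sqrt(max(1.0 - rho**2, 0.0)) \
                * rng.standard_normal(config.n_fsa)
            q = stats.norm.cdf(z)
        else:
            q = rng.uniform(size=config.n_fsa)
        q = np.clip(q, 1e-12, 1 - 1e-12)
        table[m] = np.round(_truncnorm_ppf(q, mean, sd, lo, hi), 4)
    census = pd.DataFrame(table)
    truth = {"urbanicity": urbanicity.tolist(),
             "fsa_codes": codes,
             "census_params": {k: list(v) for k, v in config.census_params.items()}}
    return census, truth


def _draw_categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return np.asarray(labels, dtype=object)[idx]


def _ordinal_from_latent(u: np.ndarray, mu: np.ndarray, cum: tuple[float, ...]) -> np.ndarray:
    """Draw ordinal codes 1..len(cum)+1 from a logistic latent.

    ``P(code <= j) = sigmoid(t_j - mu)`` with thresholds ``t_j`` at the
    logit of the baseline cumulative shares; ``u`` supplies the uniform
    noise, so codes are a deterministic, monotone function of ``mu``.
    """
    t = special.logit(np.asarray(cum))
    latent = mu + special.logit(np.clip(u, 1e-12, 1 - 1e-12))
    return 1 + (latent[:, None] >= t[None, :]).sum(axis=1)


def generate_participants(
    config: SimulationConfig,
    census: pd.DataFrame,
    census_truth: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the raw participant table and its ground-truth record.

    Covariates are drawn from the configured marginals with mild
    age-retirement, age-income and age-impairment dependence; ordinal
    questionnaire items load on a per-person connectedness latent with an
    FSA-level share.  The item-level shift is calibrated by bisection so
    the index-derived isolation prevalence matches the configured target;
    the loneliness item is calibrated the same way.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    n_fsa = len(census)
    k = config.cluster_size_dispersion
    m = config.cluster_size_mean
    sizes = rng.negative_binomial(k, k / (k + m), size=n_fsa)
    sizes = np.maximum(sizes, config.min_cluster_size)
    n = int(sizes.sum())
    fsa_idx = np.repeat(np.arange(n_fsa), sizes)
    marg = config.covariate_marginals

    age_group = _draw_categorical(rng, dict(marg["age_group"]), n)
    lo = {"45_54": 45, "55_64": 55, "65_74": 65, "75_85": 75}
    hi = {"45_54": 54, "55_64": 64, "65_74": 74, "75_85": 85}
    a_lo = np.vectorize(lo.get)(age_group)
    a_hi = np.vectorize(hi.get)(age_group)
    age = a_lo + rng.integers(0, a_hi - a_lo + 1, size=n)

    sex = _draw_categorical(rng, dict(marg["sex"]), n)
    marital = _draw_categorical(rng, dict(marg["marital_status"]), n)
    married = marital == "married_commonlaw"
    p_married = married.mean()
    # split the overall living-alone share between married (rare) and
    # unmarried so the configured marginal is hit in expectation
    p_alone_married = 0.02
    p_alone_unmarried = np.clip(
        (config.pct_living_alone - p_married * p_alone_married) / max(1 - p_married, 1e-9),
        0.0, 1.0)
    alone = np.where(married,
                     rng.uniform(size=n) < p_alone_married,
                     rng.uniform(size=n) < p_alone_unmarried)
    household_size = np.where(alone, 1, 2 + rng.poisson(0.8, size=n))

    education = _draw_categorical(rng, dict(marg["education"]), n)

    income_base = dict(marg["income_band"])
    labels = list(income_base)
    base = np.asarray([income_base[x] for x in labels])
    tilt_old = np.asarray([1.5, 1.2, 1.0, 0.8, 0.6, 1.0])  # 65+ skews lower-income
    probs_young = base / base.sum()
    probs_old = base * tilt_old
    probs_old = probs_old / probs_old.sum()
    u_inc = rng.uniform(size=n)
    old = np.isin(age_group, ["65_74", "75_85"])
    cum_y = np.cumsum(probs_young)
    cum_o = np.cumsum(probs_old)
    income = np.where(
        old,
        np.asarray(labels, dtype=object)[np.searchsorted(cum_o, u_inc, side="right").clip(0, 5)],
        np.asarray(labels, dtype=object)[np.searchsorted(cum_y, u_inc, side="right").clip(0, 5)],
    )

    p_impair = {"45_54": 0.04, "55_64": 0.06, "65_74": 0.10, "75_85": 0.25}
    any_imp = rng.uniform(size=n) < np.vectorize(p_impair.get)(age_group)
    level = _draw_categorical(rng, {"mild": 0.70, "moderate": 0.20,
                                    "severe": 0.07, "total": 0.03}, n)
    functional = np.where(any_imp, level, "none")

    age_factor = {"45_54": 0.70, "55_64": 0.95, "65_74": 1.20, "75_85": 1.50}
    lam = np.vectorize(age_factor.get)(age_group)
    lam = config.mean_chronic * lam / float(np.mean(list(age_factor.values())))
    chronic_count = np.minimum(rng.poisson(lam), scoring.N_CHRONIC_CONDITIONS)
    ranks = rng.uniform(size=(n, scoring.N_CHRONIC_CONDITIONS)).argsort(axis=1).argsort(axis=1)
    chronic_flags = ranks < chronic_count[:, None]

    # urban-core residence loads on the FSA urbanicity propensity
    if census_truth is not None and "urbanicity" in census_truth:
        urbanicity = np.asarray(census_truth["urbanicity"], dtype=float)
    else:
        urbanicity = np.zeros(n_fsa)
    ur = dict(marg["urban_rural"])
    p_core = special.expit(special.logit(ur["urban_core"])
                           + config.urbanicity_slope * urbanicity[fsa_idx])
    is_core = rng.uniform(size=n) < p_core
    rest = {kk: v for kk, v in ur.items() if kk != "urban_core"}
    urban_rural = np.where(is_core, "urban_core", _draw_categorical(rng, rest, n))

    retired = np.where(rng.uniform(size=n) < special.expit((age - 62) / 4.0),
                       "retired", "working")

    # connectedness latent: FSA share induces within-area outcome clustering
    v_fsa = rng.standard_normal(n_fsa)
    c = config.item_cluster_sd * v_fsa[fsa_idx] + rng.standard_normal(n)
    mu_items = -config.connectedness_strength * c  # higher c -> more contact

    u_contact = {ch: rng.uniform(size=n) for ch in scoring.CONTACT_CHANNELS}
    u_part = rng.uniform(size=(n, 8))
    u_lonely = rng.uniform(size=n)

    base_frame = pd.DataFrame({
        "marital_status": marital,
        "household_size": household_size,
        "retired": retired,
    })

    def contact_codes(shift: float) -> dict[str, np.ndarray]:
        return {
            f"contact_{ch}": _ordinal_from_latent(
                u_contact[ch], mu_items + shift, _CONTACT_BASE_CUM[ch])
            for ch in scoring.CONTACT_CHANNELS
        }

    def participation_codes(shift: float) -> np.ndarray:
        out = np.empty((n, 8), dtype=int)
        for j in range(8):
            out[:, j] = _ordinal_from_latent(
                u_part[:, j], mu_items + shift, _PARTICIPATION_BASE_CUM)
        return out

    def isolated_pct(shift: float) -> float:
        df = base_frame.copy()
        for col, codes in contact_codes(shift).items():
            df[col] = codes
        part = participation_codes(shift)
        for j, col in enumerate(PARTICIPATION_COLUMNS):
            df[col] = part[:, j]
        idx = scoring.compute_isolation_index(df)["index"]
        return 100.0 * float(scoring.classify_isolated(idx, 3).mean())

    shift = _bisect_to_target(isolated_pct, config.target_isolated_pct,
                              lo=-12.0, hi=12.0, tol_pct=0.02,
                              what="index-derived isolation prevalence")

    def lonely_pct(shift_l: float) -> float:
        t = -special.logit(np.asarray(_LONELY_BASE_CUM))  # thresholds, lonely end
        latent = mu_items + shift_l + special.logit(np.clip(u_lonely, 1e-12, 1 - 1e-12))
        code = 4 - (latent[:, None] >= t[::-1][None, :]).sum(axis=1)
        return 100.0 * float(np.mean(code <= 2))

    shift_l = _bisect_to_target(lonely_pct, config.target_lonely_pct,
                                lo=-12.0, hi=12.0, tol_pct=0.02,
                                what="loneliness prevalence")

    df = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "fsa_code": census["fsa_code"].to_numpy()[fsa_idx],
        "age_years": age.astype(int),
        "sex": sex,
        "marital_status": marital,
        "household_size": household_size.astype(int),
    })
    for col, codes in contact_codes(shift).items():
        df[col] = codes
    df["retired"] = retired
    part = participation_codes(shift)
    for j, col in enumerate(PARTICIPATION_COLUMNS):
        df[col] = part[:, j]
    t = -special.logit(np.asarray(_LONELY_BASE_CUM))
    latent = mu_items + shift_l + special.logit(np.clip(u_lonely, 1e-12, 1 - 1e-12))
    df["cesd_lonely"] = (4 - (latent[:, None] >= t[::-1][None, :]).sum(axis=1)).astype(int)
    df["education"] = education
    df["income_band"] = income
    df["functional_level"] = functional
    for j, col in enumerate(CHRONIC_COLUMNS):
        df[col] = chronic_flags[:, j].astype(int)
    df["urban_rural"] = urban_rural
    w = np.exp(config.weight_dispersion * rng.standard_normal(n))
    df["weight"] = np.round(w / w.mean(), 8)

    truth: dict = {
        "n_participants": n,
        "cluster_sizes": sizes.tolist(),
        "isolation_item_shift": float(shift),
        "loneliness_item_shift": float(shift_l),
        "realized_isolated_pct": isolated_pct(shift),
        "realized_lonely_pct": lonely_pct(shift_l),
        "connectedness_fsa_sd": float(config.item_cluster_sd),
    }

    if config.outcome_mode == "from_linear_predictor":
        beta = dict(config.true_beta or {"intercept": -3.0})
        u_j = config.sigma_u * rng.standard_normal(n_fsa)
        eta = np.zeros(n)
        cov = scoring.derive_covariates(df)
        cov_census = census.iloc[fsa_idx].reset_index(drop=True)
        for name, b in beta.items():
            if name == "intercept":
                eta += b
            elif "[" in name:
                col, levtxt = name.split("[", 1)
                lev = levtxt.rstrip("]")
                src = cov if col in cov.columns else df
                eta += b * (src[col].astype(str).to_numpy() == lev)
            elif name in CENSUS_MEASURES:
                eta += b * cov_census[name].to_numpy(dtype=float)
            else:
                src = cov if name in cov.columns else df
                eta += b * src[name].to_numpy(dtype=float)
        eta += u_j[fsa_idx]
        df["sim_outcome"] = (rng.uniform(size=n) < special.expit(eta)).astype(int)
        truth["true_beta"] = {kk: float(v) for kk, v in beta.items()}
        truth["sigma_u"] = float(config.sigma_u)
        truth["u_fsa"] = u_j.tolist()
        truth["realized_sim_outcome_pct"] = 100.0 * float(df["sim_outcome"].mean())

    return df, truth


def _bisect_to_target(fn, target: float, *, lo: float, hi: float,
                      tol_pct: float, what: str, maxit: int = 80) -> float:
    f_lo, f_hi = fn(lo), fn(hi)
    if not (min(f_lo, f_hi) - tol_pct <= target <= max(f_lo, f_hi) + tol_pct):
        raise ValueError(
            f"target {what} {target:.2f}% unattainable; feasible range is "
            f"[{min(f_lo, f_hi):.2f}%, {max(f_lo, f_hi):.2f}%]")
    increasing = f_hi >= f_lo
    a, b = lo, hi
    x = 0.5 * (a + b)
    for _ in range(maxit):
        x = 0.5 * (a + b)
        fx = fn(x)
        if abs(fx - target) <= tol_pct or (b - a) < 1e-9:
            return x
        if (fx < target) == increasing:
            a = x
        else:
            b = x
    return x


def generate_tables(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (participants, census, truth) in one call."""
    census, census_truth = generate_census(config)
    participants, truth = generate_participants(config, census, census_truth)
    truth["census"] = census_truth
    truth["config"] = {
        "n_fsa": config.n_fsa,
        "cluster_size_mean": config.cluster_size_mean,
        "cluster_size_dispersion": config.cluster_size_dispersion,
        "outcome_mode": config.outcome_mode,
        "target_isolated_pct": config.target_isolated_pct,
        "target_lonely_pct": config.target_lonely_pct,
        "sigma_u": config.sigma_u,
        "weight_dispersion": config.weight_dispersion,
        "seed": config.seed,
    }
    return participants, census, truth


def simulate_clustered_binary(
    n_clusters: int,
    cluster_size: int,
    beta: tuple[float, float],
    sigma_u: float,
    seed: int | np.random.Generator = 0,
):
    """Minimal clustered-binary simulator for parameter-recovery studies.

    One Bernoulli(0.5) covariate; logit P(y=1) = beta0 + beta1 x + u_j with
    u_j ~ N(0, sigma_u^2).  Returns ``(y, X, cluster_index, u)`` with X
    carrying an intercept column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_clusters * cluster_size
    cidx = np.repeat(np.arange(n_clusters), cluster_size)
    x = (rng.uniform(size=n) < 0.5).astype(float)
    u = sigma_u * rng.standard_normal(n_clusters)
    eta = beta[0] + beta[1] * x + u[cidx]
    y = (rng.uniform(size=n) < special.expit(eta)).astype(float)
    X = np.column_stack([np.ones(n), x])
    return y, X, cidx, u
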