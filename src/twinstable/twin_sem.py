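"""Longitudinal Cholesky ACE twin modeling.

A trait measured at *v* visits on both members of MZ and DZ twin pairs is
modeled with lower-triangular path matrices ``a``, ``c``, ``e`` loading
additive-genetic, shared-environmental and unique-environmental latent
factors: visit *k* loads on its own factors plus those of all earlier
visits, separating variance persisting from baseline from variance newly
emerging at later visits. With A = a a', C = c c', E = e e':

    within-person covariance  V = A + C + E
    cross-twin covariance     R = A + C      (MZ)
                              R = 0.5 A + C  (DZ, classic twin assumption)

and each pair's 2v-vector is multivariate normal with covariance
``[[V, R], [R', V]]``. The joint MZ + DZ likelihood is maximized by
bounded quasi-Newton with random restarts; the sign indeterminacy of
Cholesky columns is resolved by forcing non-negative diagonals.

Standardized squared path coefficients (each path divided by its visit's
implied SD, then squared) sum to 1 within each visit and are the reported
proportions of variance (A1..Av, C1..Cv, E1..Ev). Confidence intervals are
profile-likelihood on the squared standardized scale. Age and sex enter the
mean model only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TwinPairData",
    "CholeskyACEFit",
    "StandardizedDecomposition",
    "build_pair_data",
    "expected_covariance",
    "check_assumptions",
    "fit_cholesky_ace",
    "standardize_paths",
    "confidence_intervals",
    "simulate_power",
    "saturated_minus2ll",
]

_DELTA_95 = float(stats.chi2.ppf(0.95, 1))


@dataclass(frozen=True)
class TwinPairData:
    """Complete twin pairs for one trait: per-family visit vectors.

    ``mz``/``dz`` have one row per pair, columns = twin-1 visits 1..v then
    twin-2 visits 1..v. ``mz_covariates``/``dz_covariates`` carry the
    pair-level mean-model covariates (age, sex), possibly empty.
    """

    mz: np.ndarray
    dz: np.ndarray
    mz_covariates: np.ndarray
    dz_covariates: np.ndarray
    covariate_names: tuple[str, ...] = ()

    @property
    def n_visits(self) -> int:
        return self.mz.shape[1] // 2

    @property
    def n_mz(self) -> int:
        return self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return self.dz.shape[0]


def build_pair_data(
    bins_wide: pd.DataFrame,
    cohort: pd.DataFrame,
    bin_label: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> TwinPairData:
    """Assemble complete twin pairs for one bin.

    ``bins_wide`` is indexed by (individual_id, visit) with bins as columns.
    Families missing a co-twin or any visit are dropped with a logged count.
    """
    values = bins_wide[bin_label].unstack("visit")  # individuals x visits
    visits = sorted(values.columns)
    rows = {"MZ": [], "DZ": []}
    covs = {"MZ": [], "DZ": []}
    dropped = 0
    for fam, members in cohort.groupby("family_id"):
        members = members.sort_values("twin_order")
        if len(members) != 2:
            dropped += 1
            continue
        ids = members["individual_id"].tolist()
        if not all(i in values.index for i in ids):
            dropped += 1
            continue
        block = values.loc[ids, visits].to_numpy(float)
        if not np.all(np.isfinite(block)):
            dropped += 1
            continue
        z = members["zygosity"].iloc[0]
        rows[z].append(np.concatenate([block[0], block[1]]))
        covs[z].append([members.iloc[0][c] for c in covariates])
    if dropped:
        logger.info("dropped %d incomplete families", dropped)
    return TwinPairData(
        mz=np.array(rows["MZ"]).reshape(len(rows["MZ"]), -1),
        dz=np.array(rows["DZ"]).reshape(len(rows["DZ"]), -1),
        mz_covariates=np.array(covs["MZ"], dtype=float).reshape(len(covs["MZ"]), -1),
        dz_covariates=np.array(covs["DZ"], dtype=float).reshape(len(covs["DZ"]), -1),
        covariate_names=tuple(covariates),
    )


def expected_covariance(
    a: np.ndarray, c: np.ndarray, e: np.ndarray, zygosity: str, dz_coef: float = 0.5
) -> np.ndarray:
    """Implied 2v x 2v twin-pair covariance for one zygosity."""
    a, c, e = (np.atleast_2d(np.asarray(m, float)) for m in (a, c, e))
    if not np.all(np.isfinite(a)) or not np.all(np.isfinite(c)) or not np.all(np.isfinite(e)):
        raise ValueError("path matrices must be finite")
    A, C, E = a @ a.T, c @ c.T, e @ e.T
    V = A + C + E
    R = (1.0 if zygosity == "MZ" else dz_coef) * A + C
    return np.block([[V, R], [R.T, V]])


@dataclass
class CholeskyACEFit:
    a_paths: np.ndarray
    c_paths: np.ndarray
    e_paths: np.ndarray
    mean_model: pd.Series  # visit intercepts + covariate coefficients
    minus2LL: float
    n_mz: int
    n_dz: int
    dz_coef: float = 0.5
    converged: bool = True
    grad_norm: float = np.nan
    data: TwinPairData = field(repr=False, default=None)

    @property
    def n_visits(self) -> int:
        return self.a_paths.shape[0]

    def implied_variances(self) -> np.ndarray:
        a, c, e = self.a_paths, self.c_paths, self.e_paths
        return np.diag(a @ a.T + c @ c.T + e @ e.T)


@dataclass(frozen=True)
class StandardizedDecomposition:
    """Squared standardized path coefficients, lower-triangular per component.

    ``a2[r, k]`` is the proportion of visit ``r+1`` variance from the
    genetic factor of visit ``k+1`` (the table entry A(k+1) in row r+1);
    likewise ``c2`` and ``e2``. Per-visit rows over all three components
    sum to 1.
    """

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    ci_95: dict = field(default_factory=dict)  # (comp, visit, factor) -> (lo, hi)

    def visit_total(self, visit: int) -> float:
        r = visit - 1
        return float(self.a2[r].sum() + self.c2[r].sum() + self.e2[r].sum())


# ---------------------------------------------------------------------------
# likelihood machinery


class _ACEModel:
    """Packed-parameter Gaussian likelihood for the joint MZ + DZ sample."""

    def __init__(self, pairs: TwinPairData, dz_coef: float = 0.5):
        self.pairs = pairs
        self.v = pairs.n_visits
        self.dz_coef = dz_coef
        self.tril = np.tril_indices(self.v)
        self.k = len(self.tril[0])
        self.n_cov = pairs.mz_covariates.shape[1] if pairs.covariate_names else 0
        self.n_params = 3 * self.k + self.v + self.n_cov
        # sufficient statistics per zygosity: likelihood cost is then
        # independent of the number of pairs
        self._stats = []
        for zyg, Y, X in (
            ("MZ", pairs.mz, pairs.mz_covariates),
            ("DZ", pairs.dz, pairs.dz_covariates),
        ):
            n = Y.shape[0]
            if n == 0:
                continue
            Xz = X if self.n_cov else np.zeros((n, 0))
            self._stats.append(
                {
                    "zyg": zyg,
                    "n": n,
                    "Syy": Y.T @ Y,
                    "Sy": Y.sum(axis=0),
                    "XtY": Xz.T @ Y,
                    "Xs": Xz.sum(axis=0),
                    "XtX": Xz.T @ Xz,
                }
            )

    def unpack(self, theta: np.ndarray):
        v, k = self.v, self.k
        mats = []
        for i in range(3):
            m = np.zeros((v, v))
            m[self.tril] = theta[i * k : (i + 1) * k]
            mats.append(m)
        mu = theta[3 * k : 3 * k + v]
        beta = theta[3 * k + v :]
        return mats[0], mats[1], mats[2], mu, beta

    def minus2ll(self, theta: np.ndarray) -> float:
        a, c, e, mu, beta = self.unpack(theta)
        total = 0.0
        mu2 = np.concatenate([mu, mu])
        ones = np.ones(2 * self.v)
        for st in self._stats:
            n = st["n"]
            sigma = expected_covariance(a, c, e, st["zyg"], self.dz_coef)
            sigma = sigma + 1e-10 * np.eye(sigma.shape[0])
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return np.inf
            si = np.linalg.inv(sigma)
            # sum_f r_f r_f' with r_f = y_f - mu2 - (x_f . beta) 1
            w = st["XtY"].T @ beta if self.n_cov else np.zeros(2 * self.v)
            sb = float(st["Xs"] @ beta) if self.n_cov else 0.0
            s2 = float(beta @ st["XtX"] @ beta) if self.n_cov else 0.0
            K = (
                st["Syy"]
                - np.outer(st["Sy"], mu2)
                - np.outer(mu2, st["Sy"])
                - np.outer(w, ones)
                - np.outer(ones, w)
                + n * np.outer(mu2, mu2)
                + sb * (np.outer(mu2, ones) + np.outer(ones, mu2))
                + s2 * np.outer(ones, ones)
            )
            total += n * logdet + float(np.sum(si * K))
            total += n * sigma.shape[0] * np.log(2 * np.pi)
        return total

    def start(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Data-driven start: moment estimates of A, C, E, PSD-projected."""
        p = self.pairs
        v = self.v

        def blocks(Y):
            if Y.shape[0] < 2:
                return np.eye(v), np.zeros((v, v))
            S = np.cov(Y.T)
            within = 0.5 * (S[:v, :v] + S[v:, v:])
            cross = 0.5 * (S[:v, v:] + S[:v, v:].T)
            return within, cross

        w_mz, r_mz = blocks(p.mz)
        w_dz, r_dz = blocks(p.dz)
        V = 0.5 * (w_mz + w_dz)
        A = 2.0 * (r_mz - r_dz)
        C = 2.0 * r_dz - r_mz
        E = V - A - C

        def chol_psd(M, floor=0.05):
            M = 0.5 * (M + M.T)
            w, q = np.linalg.eigh(M)
            w = np.clip(w, floor * max(np.trace(V) / v, 1e-3), None)
            return np.linalg.cholesky(q @ np.diag(w) @ q.T)

        a0, c0, e0 = chol_psd(A), chol_psd(C), chol_psd(E)
        mu0 = np.concatenate([p.mz, p.dz]).reshape(-1, 2, v).mean(axis=(0, 1))
        theta = np.concatenate(
            [a0[self.tril], c0[self.tril], e0[self.tril], mu0, np.zeros(self.n_cov)]
        )
        if rng is not None:
            scale = max(np.sqrt(np.trace(V) / v), 1e-3)
            theta = theta + rng.normal(0.0, 0.3 * scale, theta.size)
        return theta

    def fit(self, n_restarts: int = 5, seed: int = 0, gtol: float = 1e-6):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE]))
        best = None
        for i in range(max(1, n_restarts)):
            theta0 = self.start(rng if i else None)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    self.minus2ll,
                    theta0,
                    method="L-BFGS-B",
                    options={"maxiter": 2000, "ftol": 1e-11},
                )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-7):
                best = res
        if best is None:
            raise RuntimeError("Cholesky ACE fit failed from every start")
        return best


def _canonicalize(m: np.ndarray) -> np.ndarray:
    """Flip column signs so diagonals are non-negative (M M' unchanged)."""
    m = m.copy()
    for j in range(m.shape[1]):
        if m[j, j] < 0:
            m[:, j] *= -1.0
    return m


def fit_cholesky_ace(
    pairs: TwinPairData,
    dz_coef: float = 0.5,
    n_restarts: int = 5,
    seed: int = 0,
) -> CholeskyACEFit:
    """ML fit of the longitudinal Cholesky ACE model to MZ + DZ pairs."""
    if pairs.n_mz == 0 or pairs.n_dz == 0:
        raise ValueError("both zygosity groups are required to separate A from C")
    model = _ACEModel(pairs, dz_coef)
    best = model.fit(n_restarts=n_restarts, seed=seed)
    a, c, e, mu, beta = model.unpack(best.x)
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    mean_index = [f"mu_visit{i + 1}" for i in range(model.v)] + list(pairs.covariate_names)
    return CholeskyACEFit(
        a_paths=_canonicalize(a),
        c_paths=_canonicalize(c),
        e_paths=_canonicalize(e),
        mean_model=pd.Series(np.concatenate([mu, beta]), index=mean_index),
        minus2LL=float(best.fun),
        n_mz=pairs.n_mz,
        n_dz=pairs.n_dz,
        dz_coef=dz_coef,
        converged=bool(best.success),
        grad_norm=grad_norm,
        data=pairs,
    )


def standardize_paths(fit: CholeskyACEFit) -> StandardizedDecomposition:
    """Squared standardized path coefficients; rows sum to 1 per visit."""
    variances = fit.implied_variances()
    if np.any(variances <= 0):
        raise ValueError("zero implied variance at some visit")
    inv_sd = 1.0 / np.sqrt(variances)
    out = []
    for m in (fit.a_paths, fit.c_paths, fit.e_paths):
        out.append((m * inv_sd[:, None]) ** 2)
    return StandardizedDecomposition(a2=out[0], c2=out[1], e2=out[2])


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _std_sq_coef(model: _ACEModel, theta: np.ndarray, comp: str, visit: int, factor: int):
    a, c, e, _, _ = model.unpack(theta)
    m = {"A": a, "C": c, "E": e}[comp]
    V = np.diag(a @ a.T + c @ c.T + e @ e.T)
    return m[visit - 1, factor - 1] ** 2 / V[visit - 1]


def _profile_m2ll(model: _ACEModel, theta0: np.ndarray, comp, visit, factor, t):
    cons = {
        "type": "eq",
        "fun": lambda th: _std_sq_coef(model, th, comp, visit, factor) - t,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            model.minus2ll,
            theta0,
            method="SLSQP",
            constraints=[cons],
            options={"maxiter": 400, "ftol": 1e-10},
        )
    return (res.fun, res.x) if np.isfinite(res.fun) else (np.inf, theta0)


def confidence_intervals(
    fit: CholeskyACEFit,
    coefficients: list[tuple[str, int, int]] | None = None,
    level: float = 0.95,
) -> dict[tuple[str, int, int], tuple[float, float]]:
    """Profile-likelihood CIs on the squared standardized scale.

    Keys are ``(component, visit, factor)``; e.g. ``("C", 3, 1)`` is the
    visit-3 proportion of variance from the shared-environment factor of
    visit 1 (table entry C1, row 3). Intervals are clipped to [0, 1]; a
    coefficient estimated at 0 gets a lower bound of exactly 0 (one-sided).
    """
    if fit.data is None:
        raise ValueError("fit carries no data; cannot profile")
    model = _ACEModel(fit.data, fit.dz_coef)
    theta_hat = np.concatenate(
        [
            fit.a_paths[model.tril],
            fit.c_paths[model.tril],
            fit.e_paths[model.tril],
            fit.mean_model.to_numpy(),
        ]
    )
    m2ll_hat = fit.minus2LL
    delta = float(stats.chi2.ppf(level, 1))
    if coefficients is None:
        coefficients = [
            (comp, r + 1, k + 1)
            for comp in ("A", "C", "E")
            for r in range(fit.n_visits)
            for k in range(r + 1)
        ]
    out = {}
    for comp, visit, factor in coefficients:
        point = float(_std_sq_coef(model, theta_hat, comp, visit, factor))
        out[(comp, visit, factor)] = (
            _profile_bound(model, theta_hat, m2ll_hat, comp, visit, factor, point, delta, "lower"),
            _profile_bound(model, theta_hat, m2ll_hat, comp, visit, factor, point, delta, "upper"),
        )
    return out


def _profile_bound(model, theta_hat, m2ll_hat, comp, visit, factor, point, delta, side):
    lo_edge, hi_edge = 0.0, 1.0
    edge = hi_edge if side == "upper" else lo_edge
    if abs(point - edge) < 1e-9:
        return edge

    theta_warm = theta_hat.copy()

    def lrt(t):
        nonlocal theta_warm
        f, x = _profile_m2ll(model, theta_warm, comp, visit, factor, t)
        theta_warm = x
        return f - m2ll_hat - delta

    # step from the point toward the edge until the LRT crosses delta
    t_in, f_in = point, -delta
    step = max(0.02, 0.25 * abs(edge - point))
    t = point
    for _ in range(30):
        t = t + step if side == "upper" else t - step
        t = min(hi_edge, max(lo_edge, t))
        f = lrt(t)
        if f > 0:
            try:
                return float(
                    optimize.brentq(lrt, *(sorted((t_in, t))), xtol=1e-4, maxiter=60)
                )
            except ValueError:
                return t
        t_in, f_in = t, f
        if t in (lo_edge, hi_edge):
            return edge  # boundary interval (one-sided)
    return edge


# ---------------------------------------------------------------------------
# assumption checks (saturated-model LRTs)


def _mvn_m2ll(n: int, S: np.ndarray, d: np.ndarray | None = None) -> float:
    p = S.shape[0]
    M = S if d is None else S + np.outer(d, d)
    sign, logdet_s = np.linalg.slogdet(S)
    si = np.linalg.inv(S)
    return n * (p * np.log(2 * np.pi) + logdet_s + float(np.trace(si @ M)))


def _group_stats(Y: np.ndarray):
    n = Y.shape[0]
    m = Y.mean(axis=0)
    S = (Y - m).T @ (Y - m) / n
    return n, m, S


def saturated_minus2ll(pairs: TwinPairData) -> float:
    """-2 log-likelihood of the unstructured per-zygosity Gaussian model."""
    total = 0.0
    for Y in (pairs.mz, pairs.dz):
        if Y.shape[0] == 0:
            continue
        n, m, S = _group_stats(Y)
        total += _mvn_m2ll(n, S)
    return total


def _constrained_mean_m2ll(groups, M_list):
    """ML with mean = M theta per group (theta shared), free cov per group."""
    stats_ = [(Y.shape[0], Y.mean(axis=0)) for Y in groups]
    sigmas = [_group_stats(Y)[2] for Y in groups]
    theta = None
    for _ in range(200):
        lhs = 0.0
        rhs = 0.0
        for (n, ybar), S, M in zip(stats_, sigmas, M_list):
            si = np.linalg.inv(S)
            lhs = lhs + n * M.T @ si @ M
            rhs = rhs + n * M.T @ si @ ybar
        new_theta = np.linalg.solve(lhs, rhs)
        sigmas_new = []
        for Y, M in zip(groups, M_list):
            d = Y - (M @ new_theta)[None, :]
            sigmas_new.append(d.T @ d / Y.shape[0])
        done = theta is not None and np.max(np.abs(new_theta - theta)) < 1e-10
        theta, sigmas = new_theta, sigmas_new
        if done:
            break
    total = 0.0
    for Y, S, M in zip(groups, sigmas, M_list):
        n, ybar = Y.shape[0], Y.mean(axis=0)
        total += _mvn_m2ll(n, S, ybar - M @ theta)
    return total


def _equal_variance_m2ll(groups, v: int, equal: bool):
    """Numeric ML with per-visit SDs optionally pooled across order/zygosity.

    Correlation matrices stay free per group; means fixed at sample means.
    Full model (equal=False) is the closed-form saturated fit.
    """
    if not equal:
        return saturated_minus2ll_from_groups(groups)
    stats_ = [_group_stats(Y) for Y in groups]
    p = 2 * v
    tril = np.tril_indices(p, k=-1)
    k_corr = len(tril[0])

    def build_sigma(log_sd, corr_raw):
        L = np.eye(p)
        L[tril] = corr_raw
        L = L / np.linalg.norm(L, axis=1, keepdims=True)
        R = L @ L.T
        sd = np.exp(log_sd)
        sd2 = np.concatenate([sd, sd])  # same per-visit SD for both twins
        return R * np.outer(sd2, sd2)

    def obj(theta):
        log_sd = theta[:v]
        total = 0.0
        for gi, (n, _, S) in enumerate(stats_):
            raw = theta[v + gi * k_corr : v + (gi + 1) * k_corr]
            sigma = build_sigma(log_sd, raw)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return np.inf
            total += n * (p * np.log(2 * np.pi) + logdet + float(np.trace(np.linalg.inv(sigma) @ S)))
        return total

    pooled_var = np.mean(
        [0.5 * (np.diag(S)[:v] + np.diag(S)[v:]) for _, _, S in stats_], axis=0
    )
    theta0 = np.concatenate(
        [0.5 * np.log(np.maximum(pooled_var, 1e-8)), np.zeros(len(stats_) * k_corr)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(obj, theta0, method="L-BFGS-B", options={"maxiter": 3000})
    return float(res.fun)


def saturated_minus2ll_from_groups(groups) -> float:
    total = 0.0
    for Y in groups:
        n, m, S = _group_stats(Y)
        total += _mvn_m2ll(n, S)
    return total


def check_assumptions(pairs: TwinPairData) -> pd.DataFrame:
    """Likelihood-ratio checks of twin-model regularity assumptions.

    Tests (i) equal means across twin order, (ii) equal means across
    zygosity, (iii) equal per-visit variances across order and zygosity.
    With a single zygosity group the zygosity tests are skipped with a
    warning. Returns a table with ``test, lrt, df, p_value``.
    """
    v = pairs.n_visits
    groups = [Y for Y in (pairs.mz, pairs.dz) if Y.shape[0] >= 2]
    if len(groups) == 0:
        raise ValueError("need at least 2 pairs in some zygosity group")
    single = len(groups) == 1
    if single:
        warnings.warn("single zygosity group: zygosity equality tests skipped")
    rows = []
    m2ll_sat = saturated_minus2ll_from_groups(groups)

    # (i) equal means across twin order (per group, free covariances)
    M_order = np.vstack([np.eye(v), np.eye(v)])  # mean = repeat(v-vector)
    m2ll_order = sum(_constrained_mean_m2ll([Y], [M_order]) for Y in groups)
    lrt = max(0.0, m2ll_order - m2ll_sat)
    df = v * len(groups)
    rows.append({"test": "means_equal_across_order", "lrt": lrt, "df": df,
                 "p_value": float(stats.chi2.sf(lrt, df))})

    # (ii) equal means across zygosity (shared 2v mean, free covariances)
    if not single:
        m2ll_zyg = _constrained_mean_m2ll(groups, [np.eye(2 * v)] * len(groups))
        lrt = max(0.0, m2ll_zyg - m2ll_sat)
        df = 2 * v * (len(groups) - 1)
        rows.append({"test": "means_equal_across_zygosity", "lrt": lrt, "df": df,
                     "p_value": float(stats.chi2.sf(lrt, df))})

    # (iii) equal per-visit variances across order and zygosity
    m2ll_eqvar = _equal_variance_m2ll(groups, v, equal=True)
    lrt = max(0.0, m2ll_eqvar - m2ll_sat)
    df = 2 * v * len(groups) - v
    rows.append({"test": "variances_equal", "lrt": lrt, "df": df,
                 "p_value": float(stats.chi2.sf(lrt, df))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate ACE power simulation


def _univariate_m2ll(params, stats_, include_a):
    if include_a:
        va, vc, ve, mu = params
    else:
        va = 0.0
        vc, ve, mu = params
    total = 0.0
    for zyg, n, m, S in stats_:
        r = va * (1.0 if zyg == "MZ" else 0.5) + vc
        vtot = va + vc + ve
        sigma = np.array([[vtot, r], [r, vtot]])
        det = vtot * vtot - r * r
        if det <= 0 or vtot <= 0:
            return np.inf
        si = np.array([[vtot, -r], [-r, vtot]]) / det
        d = m - mu
        M = S + np.outer(d, d)
        total += n * (2 * np.log(2 * np.pi) + np.log(det) + float(np.sum(si * M)))
    return total


def _fit_univariate(stats_, include_a: bool):
    # moment start from pooled stats
    vtot = np.mean([np.trace(S) / 2 for _, _, _, S in stats_])
    mu0 = np.mean([m.mean() for _, _, m, _ in stats_])
    if include_a:
        x0 = np.array([0.3 * vtot, 0.2 * vtot, 0.5 * vtot, mu0])
        bounds = [(0.0, 20 * vtot)] * 3 + [(None, None)]
    else:
        x0 = np.array([0.3 * vtot, 0.7 * vtot, mu0])
        bounds = [(0.0, 20 * vtot)] * 2 + [(None, None)]
    with warnings.catch_warnings():
        # finite differences step across the inf region at the PSD boundary
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            _univariate_m2ll,
            x0,
            args=(stats_, include_a),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12},
        )
    return res


def simulate_power(
    n_mz_pairs: int,
    n_dz_pairs: int,
    proportions: tuple[float, float, float],
    alpha: float = 0.05,
    reps: int = 500,
    seed: int = 0,
    mixture: bool = True,
) -> float:
    """Simulated power of the LRT for the additive genetic component.

    Generates ``reps`` univariate twin samples with standardized ACE
    proportions ``(A, C, E)``, fits ACE and CE by ML, and tests A = 0 with
    the 50:50 chi2(0)/chi2(1) boundary mixture (plain chi2(1) when
    ``mixture=False``). Returns the rejection fraction.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a usable power estimate")
    A, C, E = proportions
    if abs(A + C + E - 1.0) > 1e-8 or min(A, C, E) < 0:
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x50]))
    crit = float(stats.chi2.ppf(1.0 - (2.0 * alpha if mixture else alpha), 1))
    cov = {
        "MZ": np.array([[1.0, A + C], [A + C, 1.0]]),
        "DZ": np.array([[1.0, 0.5 * A + C], [0.5 * A + C, 1.0]]),
    }
    chol = {z: np.linalg.cholesky(cov[z] + 1e-12 * np.eye(2)) for z in cov}
    n_by_z = {"MZ": n_mz_pairs, "DZ": n_dz_pairs}
    rejections = 0
    for _ in range(reps):
        stats_ = []
        for z in ("MZ", "DZ"):
            Y = rng.standard_normal((n_by_z[z], 2)) @ chol[z].T
            n, m, S = _group_stats(Y)
            stats_.append((z, n, m, S))
        full = _fit_univariate(stats_, include_a=True)
        red = _fit_univariate(stats_, include_a=False)
        lrt = max(0.0, red.fun - full.fun)
        if lrt > crit:
            rejections += 1
    return rejections / reps
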