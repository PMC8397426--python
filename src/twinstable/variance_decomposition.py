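"""Per-bin variance decomposition with a two-level random-intercept model.

For a normalized, transformed bin level ``Y_ij`` of twin *i* in family *j*:

    Y_ij = X beta + B_ij + F_j + e,   B_ij ~ N(0, s_B^2),
                                      F_j  ~ N(0, s_F^2),
                                      e    ~ N(0, s_W^2)

``s_B^2`` is interindividual variance (the "usual level" in the population),
``s_W^2`` intraindividual (visit-to-visit) variance, and ``s_F^2`` the
intrafamily variance induced by relatedness. The intraclass correlation

    ICC = (s_B^2 + s_F^2) / (s_B^2 + s_F^2 + s_W^2)

is the proportion of biological variability due to interindividual plus
intrafamily variation. Fixed effects for age, sex, fat-free mass (FFM) and
diet quality (HEI score) extend the null model; covariates are tested by
likelihood-ratio ANOVA with Benjamini-Hochberg FDR control across the full
bin-by-covariate family.

The Gaussian likelihood is profiled over the fixed effects (GLS) and
maximized over the three variance components with analytic gradients;
variances are constrained non-negative by bounded optimization rather than
post-hoc truncation. Both ML and REML objectives are available; by default
components and ICC are reported from REML fits while likelihood-ratio tests
refit by ML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VarianceComponents",
    "MixedModelFit",
    "NonIdentifiableError",
    "UndefinedICCError",
    "fit_null_model",
    "fit_covariate_model",
    "compute_icc",
    "test_covariates",
    "covariate_r2",
    "decompose_bins",
    "attach_covariates",
]

DEFAULT_COVARIATE_NAMES = ("age", "sex", "ffm", "hei")


class NonIdentifiableError(ValueError):
    """Design cannot separate the three variance components."""


class UndefinedICCError(ValueError):
    """ICC undefined because total variance is zero."""


@dataclass(frozen=True)
class VarianceComponents:
    sigma_B2: float
    sigma_W2: float
    sigma_F2: float

    def __post_init__(self) -> None:
        for v in (self.sigma_B2, self.sigma_W2, self.sigma_F2):
            if v < 0 or not np.isfinite(v):
                raise ValueError("variance components must be finite and >= 0")

    @property
    def sigma_T2(self) -> float:
        return self.sigma_B2 + self.sigma_W2 + self.sigma_F2

    @property
    def icc(self) -> float:
        return compute_icc(self)


def compute_icc(components: VarianceComponents) -> float:
    """ICC = (s_B^2 + s_F^2) / total; undefined at zero total variance."""
    if components.sigma_T2 <= 0:
        raise UndefinedICCError("total variance is zero; ICC undefined")
    return (components.sigma_B2 + components.sigma_F2) / components.sigma_T2


@dataclass
class MixedModelFit:
    components: VarianceComponents
    fixed_effects: pd.Series  # index: intercept + covariate names
    log_likelihood: float
    n_obs: int
    method: str  # "reml" | "ml"
    covariates: tuple[str, ...]
    _design: pd.DataFrame = field(repr=False, default=None)

    @property
    def icc(self) -> float:
        return self.components.icc


class _FamilyBlocks:
    """Per-family data grouped by identical block shape for batched algebra."""

    def __init__(self, data: pd.DataFrame, x_cols: Sequence[str]):
        fam = np.asarray(pd.factorize(data["family_id"], sort=True)[0])
        ind = np.asarray(pd.factorize(data["individual_id"], sort=True)[0])
        order = np.lexsort((ind, fam))
        fam, ind = fam[order], ind[order]
        y = data["value"].to_numpy(float)[order]
        X = data[list(x_cols)].to_numpy(float)[order]
        self.n_obs = len(y)
        fam_bounds = np.concatenate(
            [[0], np.flatnonzero(np.diff(fam)) + 1, [len(fam)]]
        )
        by_shape: dict[tuple, list] = {}
        for a, b in zip(fam_bounds[:-1], fam_bounds[1:]):
            _, counts = np.unique(ind[a:b], return_counts=True)
            by_shape.setdefault(tuple(counts), []).append((a, b))
        if all(sum(c) == 1 for c in by_shape):
            raise NonIdentifiableError(
                "one observation per family: components are not identifiable"
            )
        if all(len(c) == 1 for c in by_shape) or all(max(c) == 1 for c in by_shape):
            # single individual per family, or single visit per individual:
            # at most two of the three components are identifiable
            raise NonIdentifiableError(
                "design cannot separate individual, family and residual variance"
            )
        self.groups = []  # (Y (f,s), X (f,s,p), G_B (s,s), n_fam)
        for counts, slices in by_shape.items():
            s = sum(counts)
            gb = np.zeros((s, s))
            k = 0
            for c in counts:
                gb[k : k + c, k : k + c] = 1.0
                k += c
            Yg = np.stack([y[a:b] for a, b in slices])
            Xg = np.stack([X[a:b] for a, b in slices])
            self.groups.append((Yg, Xg, gb, len(slices)))
        self.p = len(x_cols)
        self.scale = max(float(np.var(y)), 1e-12)

    def neg2ll_and_grad(self, v: np.ndarray, reml: bool):
        """Profile -2 log-likelihood over beta, with gradient in (vB, vF, vW)."""
        vB, vF, vW = v
        # sigma is singular at vW == 0; keep the boundary approachable but
        # numerically safe with a floor far below any data scale
        vW = max(vW, 1e-10 * self.scale)
        pre = []
        XtSiX = np.zeros((self.p, self.p))
        XtSiY = np.zeros(self.p)
        logdet = 0.0
        for Y, X, gb, nf in self.groups:
            s = gb.shape[0]
            sigma = vW * np.eye(s) + vB * gb + vF
            try:
                si = np.linalg.inv(sigma)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(3)
            sign, ld = np.linalg.slogdet(sigma)
            if sign <= 0 or not np.all(np.isfinite(si)):
                return np.inf, np.zeros(3)
            logdet += nf * ld
            XtSiX += np.einsum("fsp,st,ftq->pq", X, si, X)
            XtSiY += np.einsum("fsp,st,ft->p", X, si, Y)
            pre.append((Y, X, gb, nf, si))
        try:
            beta = np.linalg.solve(XtSiX, XtSiY)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(3)
        quad = 0.0
        grad = np.zeros(3)
        xtsix_inv = np.linalg.inv(XtSiX) if reml else None
        for Y, X, gb, nf, si in pre:
            s = gb.shape[0]
            r = Y - X @ beta
            sir = r @ si  # (f, s)
            quad += float(np.einsum("fs,fs->", r, sir))
            g_mats = (gb, np.ones((s, s)), np.eye(s))
            six = np.einsum("st,ftp->fsp", si, X)  # Sigma^-1 X
            for k, g in enumerate(g_mats):
                sig = si @ g
                grad[k] += nf * np.trace(sig) - float(
                    np.einsum("fs,st,ft->", sir, g, sir)
                )
                if reml:
                    m = np.einsum("fsp,st,ftq->pq", six, g, six)
                    grad[k] -= float(np.trace(xtsix_inv @ m))
        n2ll = self.n_obs * np.log(2 * np.pi) + logdet + quad
        if reml:
            sign, ld2 = np.linalg.slogdet(XtSiX)
            n2ll += ld2 - self.p * np.log(2 * np.pi)
        self._beta = beta
        return n2ll, grad

    def gls_beta(self, v: np.ndarray) -> np.ndarray:
        self.neg2ll_and_grad(v, reml=False)
        return self._beta


def _moment_start(data: pd.DataFrame) -> np.ndarray:
    y = data["value"].to_numpy(float)
    tot = max(y.var(), 1e-8)
    return np.array([0.3 * tot, 0.2 * tot, 0.5 * tot])


def _fit_mixed(
    data: pd.DataFrame,
    x_cols: Sequence[str],
    method: str = "reml",
    start: np.ndarray | None = None,
) -> MixedModelFit:
    reml = method == "reml"
    blocks = _FamilyBlocks(data, x_cols)
    if start is None:
        start = _moment_start(data)
    else:
        start = np.maximum(np.asarray(start, float), 1e-6 * blocks.scale)
    tot = start.sum()
    bounds = [(0.0, 50.0 * tot)] * 3
    best = None
    # the profile likelihood is well-behaved in these three components; extra
    # starts only run when the first one fails to converge cleanly
    for i, s in enumerate(
        (start, np.array([0.01, 0.01, 1.0]) * tot, np.array([0.6, 0.3, 0.3]) * tot)
    ):
        res = optimize.minimize(
            lambda v: blocks.neg2ll_and_grad(v, reml),
            s,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if i == 0 and res.success and np.isfinite(res.fun):
            break
    vB, vF, vW = best.x
    beta = blocks.gls_beta(best.x)
    comp = VarianceComponents(sigma_B2=float(vB), sigma_W2=float(vW), sigma_F2=float(vF))
    fe = pd.Series(beta, index=list(x_cols))
    return MixedModelFit(
        components=comp,
        fixed_effects=fe,
        log_likelihood=-0.5 * float(best.fun),
        n_obs=blocks.n_obs,
        method=method,
        covariates=tuple(c for c in x_cols if c != "intercept"),
        _design=data[["value"] + [c for c in x_cols if c != "intercept"]].copy(),
    )


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    d = data.copy()
    d["intercept"] = 1.0
    return d


def fit_null_model(data: pd.DataFrame, method: str = "reml") -> MixedModelFit:
    """Fit the intercept-only variance-component model for one bin.

    ``data`` needs columns ``value, individual_id, family_id``.
    """
    return _fit_mixed(_prepare(data), ["intercept"], method=method)


def fit_covariate_model(
    data: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATE_NAMES,
    method: str = "reml",
    start: np.ndarray | None = None,
) -> MixedModelFit:
    """Fit the covariate-extended model for one bin.

    Constant covariates are dropped (their fixed effects are exactly absent,
    reducing to the null model); a collinear design raises.
    """
    d = _prepare(data)
    kept = [c for c in covariates if d[c].nunique() > 1]
    x_cols = ["intercept"] + kept
    if kept:
        X = d[x_cols].to_numpy(float)
        Xs = X / np.maximum(np.abs(X).max(axis=0), 1e-30)
        if np.linalg.cond(Xs) > 1e8:
            raise ValueError("collinear covariate design (condition number > 1e8)")
    return _fit_mixed(d, x_cols, method=method, start=start)


def covariate_r2(fit: MixedModelFit, covariate: str) -> float:
    """Percent of total variance attributable to one covariate.

    Defined as var(beta_c * x_c) over observations divided by
    (var(full fixed-effect predictor) + s_B^2 + s_F^2 + s_W^2), times 100.
    """
    if covariate not in fit.covariates:
        raise ValueError(f"covariate {covariate!r} not in fit")
    d = fit._design
    contrib = fit.fixed_effects[covariate] * d[covariate].to_numpy(float)
    full = np.zeros(len(d))
    for c in fit.covariates:
        full = full + fit.fixed_effects[c] * d[c].to_numpy(float)
    denom = full.var() + fit.components.sigma_T2
    if denom <= 0:
        return 0.0
    return float(100.0 * contrib.var() / denom)


def attach_covariates(bins_long: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Join a long bin table with cohort identifiers and covariates."""
    cols = ["individual_id", "family_id"] + [
        c for c in DEFAULT_COVARIATE_NAMES if c in cohort.columns
    ]
    return bins_long.merge(cohort[cols], on="individual_id", validate="many_to_one")


def test_covariates(
    data: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATE_NAMES,
    alpha: float = 0.05,
    family: str = "joint",
) -> pd.DataFrame:
    """Likelihood-ratio ANOVA of each covariate in each bin, BH-adjusted.

    ``data`` is long format with columns ``bin, value, individual_id,
    family_id`` plus the covariates. For every bin the full model and each
    drop-one-covariate model are refit by ML; the LRT p-value (chi-square,
    1 df) is adjusted by Benjamini-Hochberg either across the joint
    bin-by-covariate family (default) or per covariate
    (``family="per_covariate"``).

    Returns one row per (bin, covariate): ``beta, r2, p_value, q_value,
    significant``.
    """
    if family not in ("joint", "per_covariate"):
        raise ValueError("family must be 'joint' or 'per_covariate'")
    rows = []
    for bin_label, grp in data.groupby("bin", sort=True):
        full = fit_covariate_model(grp, covariates, method="ml")
        warm = np.array(
            [full.components.sigma_B2, full.components.sigma_F2, full.components.sigma_W2]
        )
        for c in covariates:
            others = [o for o in covariates if o != c]
            red = fit_covariate_model(grp, others, method="ml", start=warm)
            lrt = max(0.0, 2.0 * (full.log_likelihood - red.log_likelihood))
            p = float(stats.chi2.sf(lrt, df=1))
            rows.append(
                {
                    "bin": bin_label,
                    "covariate": c,
                    "beta": float(full.fixed_effects.get(c, 0.0)),
                    "r2": covariate_r2(full, c) if c in full.covariates else 0.0,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if family == "joint":
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = np.nan
        for c in covariates:
            m = out["covariate"] == c
            out.loc[m, "q_value"] = multipletests(out.loc[m, "p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < alpha
    return out


def decompose_bins(
    data: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATE_NAMES,
    alpha: float = 0.05,
    method: str = "reml",
    bh_family: str = "joint",
) -> pd.DataFrame:
    """Full per-bin decomposition mirroring the stable-metabolome table.

    Tests the covariates with FDR control, refits each bin keeping only its
    significant covariates, and reports that model's components and ICC.
    Output columns: ``bin, icc, sigma_B2, sigma_W2, sigma_F2`` plus, per
    covariate, ``<c>_r2, <c>_beta, <c>_q``.
    """
    tests = test_covariates(data, covariates, alpha=alpha, family=bh_family)
    rows = []
    for bin_label, grp in data.groupby("bin", sort=True):
        t = tests[tests["bin"] == bin_label].set_index("covariate")
        sig = [c for c in covariates if bool(t.loc[c, "significant"])]
        fit = fit_covariate_model(grp, sig, method=method) if sig else fit_null_model(
            grp, method=method
        )
        row = {
            "bin": bin_label,
            "icc": fit.icc,
            "sigma_B2": fit.components.sigma_B2,
            "sigma_W2": fit.components.sigma_W2,
            "sigma_F2": fit.components.sigma_F2,
        }
        for c in covariates:
            is_sig = bool(t.loc[c, "significant"])
            row[f"{c}_r2"] = covariate_r2(fit, c) if (is_sig and c in fit.covariates) else np.nan
            row[f"{c}_beta"] = fit.fixed_effects[c] if (is_sig and c in fit.covariates) else np.nan
            row[f"{c}_q"] = float(t.loc[c, "q_value"])
        rows.append(row)
    return pd.DataFrame(rows)
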