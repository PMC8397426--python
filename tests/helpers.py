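"""Shared generators and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from twinstable import twin_sem


def nested_anova_data(
    seed: int,
    n_families: int = 16,
    sigma_f: float = 1.0,
    sigma_b: float = 1.0,
    sigma_w: float = 1.0,
    n_visits: int = 3,
) -> pd.DataFrame:
    """Balanced family/individual/visit data with known variance components."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        fe = rng.normal(0.0, sigma_f)
        for i in range(2):
            be = rng.normal(0.0, sigma_b)
            for v in range(n_visits):
                rows.append(
                    {
                        "family_id": f,
                        "individual_id": 2 * f + i,
                        "visit": v + 1,
                        "value": fe + be + rng.normal(0.0, sigma_w),
                    }
                )
    return pd.DataFrame(rows)


def likelihood_grid_oracle(
    df: pd.DataFrame, step: float = 0.01, vmax: float = 3.0
) -> tuple[float, float, float]:
    """Brute-force ML grid search for the balanced 2-twin 3-visit design.

    Exploits the closed-form eigenstructure of the family covariance
    sigma_W I6 + sigma_B (I2 x J3) + sigma_F J6: eigenvalues
    (vW + 3 vB + 6 vF), (vW + 3 vB), and vW (multiplicity 4), with
    eigenspaces independent of the parameters — so the profile likelihood
    reduces to three residual sums of squares and the full grid can be
    scanned exactly. The ML mean is the grand mean for a balanced design.
    Returns the grid argmax ``(vB, vF, vW)``.
    """
    y = df.sort_values(["family_id", "individual_id", "visit"])["value"].to_numpy()
    n_fam = df["family_id"].nunique()
    R = (y - y.mean()).reshape(n_fam, 6)
    u0 = np.ones(6) / np.sqrt(6)
    u1 = np.array([1, 1, 1, -1, -1, -1]) / np.sqrt(6)
    ss0 = float(((R @ u0) ** 2).sum())
    ss1 = float(((R @ u1) ** 2).sum())
    ss2 = float((R**2).sum()) - ss0 - ss1
    g = np.arange(0.0, vmax + step / 2, step)
    best_val, best = np.inf, None
    lam2 = g + 1e-12
    t2 = 4 * n_fam * np.log(lam2) + ss2 / lam2
    for iw, vw in enumerate(g):
        lam1 = vw + 3 * g + 1e-12
        t1 = n_fam * np.log(lam1) + ss1 / lam1
        lam0 = lam1[:, None] + 6 * g[None, :] + 1e-12
        tot = n_fam * np.log(lam0) + ss0 / lam0 + t1[:, None] + t2[iw]
        ib, if_ = np.unravel_index(np.argmin(tot), tot.shape)
        if tot[ib, if_] < best_val:
            best_val = float(tot[ib, if_])
            best = (float(g[ib]), float(g[if_]), float(vw))
    return best


def univariate_pairs(
    n_mz: int, n_dz: int, a2: float, c2: float, seed: int
) -> twin_sem.TwinPairData:
    """Univariate twin pairs with standardized ACE proportions (a2, c2, 1-a2-c2)."""
    rng = np.random.default_rng(seed)
    r = {"MZ": a2 + c2, "DZ": 0.5 * a2 + c2}
    out = {}
    for z, n in (("MZ", n_mz), ("DZ", n_dz)):
        cov = np.array([[1.0, r[z]], [r[z], 1.0]])
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        out[z] = rng.standard_normal((n, 2)) @ L.T
    return twin_sem.TwinPairData(
        mz=out["MZ"],
        dz=out["DZ"],
        mz_covariates=np.zeros((n_mz, 0)),
        dz_covariates=np.zeros((n_dz, 0)),
        covariate_names=(),
    )


def path_diagram_covariance_oracle(
    a: np.ndarray, c: np.ndarray, e: np.ndarray, zygosity: str, n_draws: int, seed: int
) -> np.ndarray:
    """Empirical twin-pair covariance from explicit latent-variable simulation."""
    rng = np.random.default_rng(seed)
    v = a.shape[0]
    rho = 1.0 if zygosity == "MZ" else 0.5
    za1 = rng.standard_normal((n_draws, v))
    za2 = rho * za1 + np.sqrt(1 - rho**2) * rng.standard_normal((n_draws, v))
    zc = rng.standard_normal((n_draws, v))
    y1 = za1 @ a.T + zc @ c.T + rng.standard_normal((n_draws, v)) @ e.T
    y2 = za2 @ a.T + zc @ c.T + rng.standard_normal((n_draws, v)) @ e.T
    return np.cov(np.hstack([y1, y2]).T)
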