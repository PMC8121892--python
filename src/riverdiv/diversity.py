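"""Alpha diversity: richness, distance-decay GLM, accumulation curves, PCA.

Local richness is per-site taxon count on the presence matrix. Its decay
with along-network distance from the outlet is modelled by a Poisson GLM
with log link, log mu = b0 + b1 * distance_km. Species accumulation
curves give the expected richness after sampling k sites, either by the
exact hypergeometric formula or by seeded permutation of site order.
Environmental site variables (mixed units) are summarised by a PCA on the
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from riverdiv.tables_io import CommunityMatrix


@dataclass(frozen=True)
class GLMFit:
    """Poisson regression fit of richness on distance."""

    intercept: float
    slope: float  # per km
    intercept_se: float
    slope_se: float
    z_intercept: float
    z_slope: float
    log_likelihood: float
    aic: float
    deviance: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["intercept", "distance_km"],
                "estimate": [self.intercept, self.slope],
                "se": [self.intercept_se, self.slope_se],
                "z": [self.z_intercept, self.z_slope],
            }
        ).assign(aic=self.aic, log_likelihood=self.log_likelihood, deviance=self.deviance, n=self.n)


@dataclass
class AccumulationCurve:
    """Expected richness (mean, SD) as a function of sites accumulated.

    ``mean`` and ``sd`` are indexed by k = 1..n_sites; for grouped curves
    one :class:`AccumulationCurve` is produced per river.
    """

    k: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "mean_richness": self.mean, "sd_richness": self.sd})


def local_richness(m: CommunityMatrix) -> pd.Series:
    """Per-site taxon richness (row sums of the presence matrix)."""
    if m.mode != "presence":
        raise ValueError("local_richness requires a presence matrix")
    return m.values.sum(axis=1).rename("richness")


def fit_richness_glm(richness, distance, tol: float = 1e-8, max_iter: int = 100) -> GLMFit:
    """Poisson GLM of richness counts on distance-to-outlet (km).

    Fitted by IRLS to relative tolerance ``tol``; raises on
    non-convergence with the iteration diagnostics.
    """
    y = np.asarray(richness, dtype=float)
    d = np.asarray(distance, dtype=float)
    if y.shape != d.shape:
        raise ValueError("richness and distance lengths differ")
    if y.size < 3:
        raise ValueError("need at least 3 sites")
    X = sm.add_constant(d)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations (deviance {res.deviance:.4g})"
        )
    b0, b1 = res.params
    se0, se1 = res.bse
    return GLMFit(
        intercept=float(b0),
        slope=float(b1),
        intercept_se=float(se0),
        slope_se=float(se1),
        z_intercept=float(b0 / se0),
        z_slope=float(b1 / se1),
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        deviance=float(res.deviance),
        n=int(y.size),
    )


def _exact_accumulation_mean(presence: np.ndarray) -> np.ndarray:
    """E[S(k)] for k=1..N by the exact sample-based rarefaction formula.

    E[S(k)] = S_obs - sum_i C(N - n_i, k) / C(N, k), with n_i the number
    of sites occupied by taxon i; evaluated through log-gamma for
    numerical safety.
    """
    n_sites = presence.shape[0]
    occupancy = presence.sum(axis=0)
    occupancy = occupancy[occupancy > 0]
    ks = np.arange(1, n_sites + 1)

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    means = np.empty(n_sites)
    for idx, k in enumerate(ks):
        absent = n_sites - occupancy  # sites each taxon is missing from
        with np.errstate(invalid="ignore"):
            log_p = np.where(
                absent >= k, log_comb(absent, k) - log_comb(n_sites, k), -np.inf
            )
        means[idx] = len(occupancy) - np.exp(log_p[np.isfinite(log_p)]).sum()
    return means


def accumulation_curve(
    m: CommunityMatrix,
    method: str = "exact",
    n_perm: int = 1000,
    seed: int | None = None,
) -> AccumulationCurve:
    """Species accumulation curve over the matrix's sites.

    ``exact`` gives the analytic expectation (SD still estimated from
    ``n_perm`` seeded site-order permutations, since the plotted curves
    show both mean and spread); ``permutation`` estimates both moments
    from the permutations.
    """
    if m.mode != "presence":
        raise ValueError("accumulation_curve requires a presence matrix")
    presence = m.values.to_numpy()
    n_sites = presence.shape[0]
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    richness = np.empty((n_perm, n_sites))
    for p in range(n_perm):
        order = rng.permutation(n_sites)
        cum = np.maximum.accumulate(presence[order], axis=0)
        richness[p] = cum.sum(axis=1)
    sd = richness.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n_sites)
    if method == "exact":
        mean = _exact_accumulation_mean(presence)
    elif method == "permutation":
        mean = richness.mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AccumulationCurve(k=np.arange(1, n_sites + 1), mean=mean, sd=sd, method=method)


def accumulation_by_group(
    m: CommunityMatrix,
    groups: pd.Series,
    method: str = "exact",
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[str, AccumulationCurve]:
    """One accumulation curve per site group (e.g. per river)."""
    out = {}
    for g in pd.unique(groups.loc[m.site_ids]):
        sites = [s for s in m.site_ids if groups[s] == g]
        sub = CommunityMatrix(values=m.values.loc[sites], mode="presence")
        out[g] = accumulation_curve(sub, method=method, n_perm=n_perm, seed=seed)
    return out


@dataclass
class PCAResult:
    """Correlation-matrix PCA of per-site environmental variables."""

    scores: pd.DataFrame  # sites x components
    loadings: pd.DataFrame  # variables x components
    explained: np.ndarray  # variance fractions, sum to 1


def env_pca(env: pd.DataFrame) -> PCAResult:
    """PCA of site environmental variables on the correlation matrix.

    Columns are centred and scaled to unit variance (the variables mix
    units: m, pH, uS/cm), so components are eigenvectors of the
    correlation matrix. Loadings' signs are fixed by making the largest-
    magnitude loading of each component positive. Zero-variance columns
    are rejected by name.
    """
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 variables")
    if env.isna().any().any():
        raise ValueError("missing values in environmental table")
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dead = env.columns[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{i+1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(Z @ eigvec, index=env.index, columns=comps),
        loadings=pd.DataFrame(eigvec, index=env.columns, columns=comps),
        explained=eigval / eigval.sum(),
    )
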