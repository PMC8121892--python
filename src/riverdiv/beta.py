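"""Incidence-based beta diversity and Mantel distance-decay tests.

Pairwise Jaccard dissimilarity is additively partitioned (Baselga) into a
turnover component (taxon replacement) and a nestedness-resultant
component (richness difference of nested assemblages):

    b_jac = (b + c) / (a + b + c)
    b_jtu = 2 min(b, c) / (a + 2 min(b, c))
    b_jne = b_jac - b_jtu

with a = taxa shared by the two sites and b, c the taxa unique to each.
Distance decay of community dissimilarity along the river network is
tested with a Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from riverdiv.tables_io import CommunityMatrix


@dataclass
class BetaResult:
    """Pairwise Jaccard, turnover and nestedness matrices.

    All three are symmetric with zero diagonal, values in [0, 1], and
    satisfy jaccard = turnover + nestedness elementwise.
    """

    jaccard: pd.DataFrame
    turnover: pd.DataFrame
    nestedness: pd.DataFrame


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_perm: int
    alternative: str
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [self.statistic],
                "p_value": [self.p_value],
                "n_perm": [self.n_perm],
                "alternative": [self.alternative],
            }
        )


def jaccard_partition(m: CommunityMatrix) -> BetaResult:
    """Baselga partition of pairwise Jaccard dissimilarity.

    Pairs of empty communities (a = b = c = 0) are defined as
    dissimilarity 0 in all three components.
    """
    if m.mode != "presence":
        raise ValueError("jaccard_partition requires a presence matrix")
    if m.values.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    P = m.values.to_numpy(dtype=float)
    a = P @ P.T  # shared
    row = P.sum(axis=1)
    b = row[:, None] - a  # unique to i
    c = row[None, :] - a  # unique to j
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(denom > 0, (b + c) / denom, 0.0)
        mn = np.minimum(b, c)
        tu_den = a + 2 * mn
        jtu = np.where(tu_den > 0, 2 * mn / tu_den, 0.0)
    jne = jac - jtu
    sites = m.site_ids
    for arr in (jac, jtu, jne):
        np.fill_diagonal(arr, 0.0)
    return BetaResult(
        jaccard=pd.DataFrame(jac, index=sites, columns=sites),
        turnover=pd.DataFrame(jtu, index=sites, columns=sites),
        nestedness=pd.DataFrame(jne, index=sites, columns=sites),
    )


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices_from(mat, k=-1)]


def mantel_test(
    d1,
    d2,
    n_perm: int = 999,
    alternative: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test of correlation between two distance matrices.

    The statistic is the Pearson correlation of the strictly-lower-triangle
    entries. The null distribution simultaneously permutes the rows and
    columns of ``d2``; the p-value uses the add-one correction
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) for ``alternative='greater'``
    (mirror-image for 'less', |r| for 'two-sided'), so p is never 0.
    """
    D1 = np.asarray(d1, dtype=float)
    D2 = np.asarray(d2, dtype=float)
    if D1.shape != D2.shape or D1.ndim != 2 or D1.shape[0] != D1.shape[1]:
        raise ValueError("distance matrices must share a square shape")
    n = D1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 objects")
    for name, D in (("d1", D1), ("d2", D2)):
        if not np.allclose(D, D.T):
            raise ValueError(f"{name} is not symmetric")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _lower_triangle(D1)
    y = _lower_triangle(D2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant lower triangle: correlation undefined")
    xz = (x - x.mean()) / x.std()
    r_obs = float(np.dot(xz, (y - y.mean()) / y.std()) / x.size)

    rng = np.random.default_rng(seed)
    tril = np.tril_indices(n, k=-1)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = D2[np.ix_(perm, perm)][tril]
        r_p = float(np.dot(xz, (yp - yp.mean()) / yp.std()) / x.size)
        if alternative == "greater":
            exceed += r_p >= r_obs
        elif alternative == "less":
            exceed += r_p <= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(
        statistic=r_obs, p_value=float(p), n_perm=n_perm, alternative=alternative, seed=seed
    )
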