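"""Distance matrices, Mantel / partial Mantel permutation tests, OLS fits.

Community--environment association is assessed the standard
community-ecology way: a Bray--Curtis dissimilarity matrix over the rhodopsin
(or PPR) abundance profiles of the water samples is correlated against a
Euclidean distance matrix over z-scored environmental variables with a
Mantel permutation test (Pearson r over the off-diagonal triangles;
one-tailed positive-association p from joint row/column permutations of the
second matrix, with the add-one correction).  The partial variant controls a
third matrix by correlating the residuals of simple linear regressions on
its triangle vector.

Matrices are carried as :class:`skbio.DistanceMatrix` so symmetry, hollow
diagonals and label bookkeeping are validated on construction.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

#: environmental variables used for the distance matrix, with units
ENV_VARIABLES = (
    "no2",  # umol/L
    "po4",  # umol/L
    "no3_no2",  # nitrate plus nitrite, umol/L
    "sio3",  # umol/L
    "depth_m",
    "temperature_c",
    "salinity",  # PSU
    "np_ratio",  # dimensionless
)

EXHAUSTIVE = "exhaustive"

# permutations whose statistic ties the observed one (e.g. the identity
# relabeling) must count as >=; the epsilon absorbs float noise between the
# scalar and vectorized correlation paths
_TIE_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    partial: bool
    seed: int | None


def read_env_table(path_or_df) -> pd.DataFrame:
    """Load the environmental-factor table, indexed by water_sample_id.

    ``np_ratio`` is computed as no3_no2 / po4 (null where po4 == 0) when the
    column is absent.
    """
    if isinstance(path_or_df, pd.DataFrame):
        env = path_or_df.copy()
    else:
        env = pd.read_csv(path_or_df, sep="\t")
    if "water_sample_id" in env.columns:
        env = env.set_index("water_sample_id")
    if "np_ratio" not in env.columns and {"no3_no2", "po4"} <= set(env.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = env["no3_no2"] / env["po4"]
        env["np_ratio"] = ratio.where(env["po4"] > 0)
    return env


def abundance_distance(
    tpm_matrix: pd.DataFrame, metric: str = "bray_curtis"
) -> DistanceMatrix:
    """Pairwise sample distances from an abundance matrix (samples x groups).

    Bray--Curtis by default.  Convention for all-zero samples under
    Bray--Curtis: distance 1 to any sample with signal, 0 to another
    all-zero sample.
    """
    if len(tpm_matrix) < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    values = tpm_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    if metric == "bray_curtis":
        with np.errstate(invalid="ignore"):
            dist = squareform(pdist(values, metric="braycurtis"))
        zero = values.sum(axis=1) == 0
        if zero.any():  # scipy yields nan for 0/0 pairs
            dist[np.ix_(zero, ~zero)] = 1.0
            dist[np.ix_(~zero, zero)] = 1.0
            dist[np.ix_(zero, zero)] = 0.0
    elif metric == "euclidean":
        dist = squareform(pdist(values, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(dist, ids=[str(i) for i in tpm_matrix.index])


def env_distance(
    env: pd.DataFrame,
    variables: Sequence[str] = ENV_VARIABLES,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance over (optionally z-scored) environmental variables.

    Z-scoring (mean 0, SD 1 per variable, sample SD) puts nutrients, depth
    and temperature on a common scale so no single variable dominates.
    Zero-variance variables are excluded with a warning.
    """
    env = read_env_table(env)
    missing = set(variables) - set(env.columns)
    if missing:
        raise ValueError(f"environmental table lacks variables: {sorted(missing)}")
    if len(env) < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    sub = env[list(variables)].astype(float)
    if sub.isna().any().any():
        raise ValueError("chosen environmental variables contain nulls")
    if standardize:
        sd = sub.std(ddof=1)
        flat = sd[sd == 0].index.tolist()
        if flat:
            warnings.warn(
                f"zero-variance variables excluded: {flat}", stacklevel=2
            )
            sub = sub.drop(columns=flat)
        sub = (sub - sub.mean()) / sub.std(ddof=1)
    dist = squareform(pdist(sub.to_numpy(), metric="euclidean"))
    return DistanceMatrix(dist, ids=[str(i) for i in env.index])


def _as_condensed(dm: DistanceMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(dm, DistanceMatrix):
        return dm.data, list(dm.ids)
    arr = np.asarray(dm, dtype=float)
    return arr, [str(i) for i in range(len(arr))]


def _check_pair(dx, dy) -> tuple[np.ndarray, np.ndarray, int]:
    mx, idx = _as_condensed(dx)
    my, idy = _as_condensed(dy)
    if idx != idy:
        raise ValueError("distance matrices have mismatched labels/order")
    n = len(mx)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    return mx, my, n


def _tri(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(m), k=1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in a distance triangle; r undefined")
    return float(xc @ yc / denom)


def _permuted_triangles(
    m: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Triangle vectors of m under each row/column permutation (vectorized)."""
    n = len(m)
    iu, ju = np.triu_indices(n, k=1)
    return m[perms[:, iu], perms[:, ju]]


def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def mantel(
    dx: DistanceMatrix | np.ndarray,
    dy: DistanceMatrix | np.ndarray,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> MantelResult:
    """Mantel test between two distance matrices.

    r is the Pearson correlation of the off-diagonal triangle vectors; the
    one-tailed p-value counts joint row/column permutations of ``dy`` whose
    correlation reaches the observed one, with the add-one correction:
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).

    Pass ``n_permutations="exhaustive"`` to enumerate all n! relabelings
    (identity included); the p-value is then the exact enumeration fraction.
    """
    mx, my, n = _check_pair(dx, dy)
    x = _tri(mx)
    r_obs = _pearson(x, _tri(my))

    if n_permutations == EXHAUSTIVE:
        perms = _all_permutations(n)
        y_perm = _permuted_triangles(my, perms)
        r_perm = _bulk_pearson(x, y_perm)
        p = float((r_perm >= r_obs - _TIE_EPS).sum()) / len(perms)
        return MantelResult(r_obs, p, len(perms), False, seed)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(int(n_permutations))])
    y_perm = _permuted_triangles(my, perms)
    r_perm = _bulk_pearson(x, y_perm)
    p = (1.0 + float((r_perm >= r_obs - _TIE_EPS).sum())) / (1.0 + len(perms))
    return MantelResult(r_obs, p, int(n_permutations), False, seed)


def _bulk_pearson(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r of x against each row of ys."""
    xc = x - x.mean()
    xn = math.sqrt(xc @ xc)
    yc = ys - ys.mean(axis=1, keepdims=True)
    yn = np.sqrt((yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (yc @ xc) / (yn * xn)


def _partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom = math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise ValueError("controlled matrix is collinear with a triangle vector")
    return (r_xy - r_xz * r_yz) / denom


def partial_mantel(
    dx: DistanceMatrix | np.ndarray,
    dy: DistanceMatrix | np.ndarray,
    dz: DistanceMatrix | np.ndarray,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> MantelResult:
    """Partial Mantel test: correlation of dx and dy controlling for dz.

    r is the partial correlation of the triangle vectors (equivalently, the
    Pearson correlation of the residuals from simple linear regressions of x
    and y on z).  Permutations shuffle ``dy`` as in :func:`mantel`, with r_xz
    held fixed.
    """
    mx, my, n = _check_pair(dx, dy)
    mz, idz = _as_condensed(dz)
    _, idx = _as_condensed(dx)
    if idz != idx:
        raise ValueError("distance matrices have mismatched labels/order")
    x, y, z = _tri(mx), _tri(my), _tri(mz)
    r_xz = _pearson(x, z)
    r_obs = _partial_r(_pearson(x, y), r_xz, _pearson(y, z))

    def _perm_stats(perms: np.ndarray) -> np.ndarray:
        y_perm = _permuted_triangles(my, perms)
        r_xy = _bulk_pearson(x, y_perm)
        r_yz = _bulk_pearson(z, y_perm)
        denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (r_xy - r_xz * r_yz) / denom

    if n_permutations == EXHAUSTIVE:
        perms = _all_permutations(n)
        r_perm = _perm_stats(perms)
        p = float((r_perm >= r_obs - _TIE_EPS).sum()) / len(perms)
        return MantelResult(r_obs, p, len(perms), True, seed)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(int(n_permutations))])
    r_perm = _perm_stats(perms)
    p = (1.0 + float((r_perm >= r_obs - _TIE_EPS).sum())) / (1.0 + len(perms))
    return MantelResult(r_obs, p, int(n_permutations), True, seed)


def expression_abundance_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Pearson correlation and OLS fit of PPR expression vs taxon abundance.

    Returns ``(pearson_r, r_squared, slope, intercept)`` for ``y ~ x``; this
    is the scatter-fit behind taxon-level expression/abundance panels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    fit = sps.linregress(x, y)
    return float(fit.rvalue), float(fit.rvalue**2), float(fit.slope), float(
        fit.intercept
    )
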