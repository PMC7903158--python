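"""Inferential toolbox: behavior transforms, permutation tests, circular tests.

Nonparametric tests follow the resampling conventions standard in
neuroimaging group analyses:

* paired contrasts use sign-flip permutation of per-participant difference
  scores, with the classical dependent-samples t as the test statistic and a
  two-sided p-value given by the fraction of permuted |t| values at or above
  the observed |t|;
* correlations use Spearman's rho with permutation of one variable across
  participants;
* circular phase angles use the Rayleigh test for uniformity and the paired
  Hotelling (second-order) test for equal angular means on the Cartesian
  components of per-participant angle differences (Zar's formulation).

Permutation p-values use the (k+1)/(n_perm+1) convention, guarding against
p = 0; when 2^n does not exceed the requested permutation count, the
sign-flip null is enumerated exhaustively instead (p = k / 2^n, which counts
the identity assignment and is therefore never 0 either).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, DataError

__all__ = [
    "logit_adj",
    "response_speed",
    "perm_ttest_paired",
    "sign_flip_pvalues",
    "perm_spearman",
    "rayleigh_test",
    "hotelling_paired_circular",
    "linear_trend_test",
    "bootstrap_ci_mean",
    "circ_mean",
    "resultant_length",
]

_T_TOL = 1e-10


def logit_adj(pc):
    """Adjusted logit transform of a proportion-correct score.

    Proportions are shrunk toward 0.5 by a factor 0.95 before the logit, so
    the transform stays finite at 0 and 1:
    ln( (0.5 + 0.95*(pc-0.5)) / (1 - (0.5 + 0.95*(pc-0.5))) ).
    """
    pc_arr = np.asarray(pc, dtype=float)
    if np.any(pc_arr < 0) or np.any(pc_arr > 1):
        raise DataError("proportion correct must lie in [0, 1]")
    shrunk = 0.5 + 0.95 * (pc_arr - 0.5)
    out = np.log(shrunk / (1.0 - shrunk))
    return float(out) if np.isscalar(pc) else out


def response_speed(rts, cutoff: float = 3.0) -> np.ndarray:
    """Convert response times to speeds 1/RT, excluding RTs above ``cutoff`` s."""
    rts = np.asarray(rts, dtype=float)
    if np.any(rts <= 0):
        raise DataError("response times must be > 0")
    kept = rts[rts <= cutoff]
    if kept.size == 0 and rts.size > 0:
        warnings.warn("all response times exceeded the cutoff; empty cell", stacklevel=2)
    return 1.0 / kept


def _paired_t(diffs: np.ndarray) -> float:
    """Classical paired t on difference scores; sd = 0 maps to 0 or +/-inf."""
    n = diffs.size
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0 if mean == 0 else np.inf * np.sign(mean)
    return float(mean / (sd / np.sqrt(n)))


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """All (exhaustive) or sampled sign-flip assignments, one row per permutation."""
    if n <= 30 and 2**n <= n_perm:
        codes = np.arange(2**n, dtype=np.int64)[:, None]
        signs = 1 - 2 * ((codes >> np.arange(n)) & 1)
        return signs.astype(float), True
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def _t_from_signs(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Paired t for every sign-flip row; sums of squares are flip-invariant."""
    n = diffs.size
    means = signs @ diffs / n
    ssq = float(np.sum(diffs**2))
    var = np.maximum(ssq - n * means**2, 0.0) / (n - 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # 0/0: zero mean with zero spread
    return t


def perm_ttest_paired(
    a, b=None, n_perm: int = 10000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Two-sided sign-flip permutation test for paired samples.

    ``a`` and ``b`` are per-participant scores; with ``b=None`` the entries
    of ``a`` are treated as difference scores (one-sample test against 0).
    Returns ``(t, p)``. If all differences are exactly zero, ``p = 1`` by
    convention.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    a = np.asarray(a, dtype=float)
    diffs = a if b is None else a - np.asarray(b, dtype=float)
    if diffs.ndim != 1 or diffs.size < 2:
        raise DataError("need at least two paired observations")
    if np.isnan(diffs).any():
        raise DataError("difference scores contain NaN")
    t_obs = _paired_t(diffs)
    if np.all(diffs == 0):
        return 0.0, 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(diffs.size, n_perm, rng)
    t_perm = _t_from_signs(signs, diffs)
    if np.isinf(t_obs):
        exceed = np.isinf(t_perm)
    else:
        exceed = np.abs(t_perm) >= np.abs(t_obs) - _T_TOL * (1.0 + abs(t_obs))
    k = int(exceed.sum())
    p = k / signs.shape[0] if exhaustive else (k + 1) / (signs.shape[0] + 1)
    return t_obs, float(p)


def sign_flip_pvalues(
    z: np.ndarray, n_perm: int = 10000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Per-column two-sided sign-flip p-values for a participants x points matrix.

    One shared set of sign-flip assignments is applied to every column
    (time point), mirroring multiple uncorrected permutation tests against
    zero. Columns that are identically zero get p = 1.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise DataError("z must be participants x points with >= 2 participants")
    n = z.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    n_rows = signs.shape[0]
    ssq = np.sum(z**2, axis=0)  # flip-invariant per column
    means = signs @ z / n
    var = np.maximum(ssq[None, :] - n * means**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[np.isnan(t)] = 0.0
    # observed t per column (sd = 0 maps to 0 or +/-inf as in _paired_t)
    m_obs = z.mean(axis=0)
    sd_obs = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = m_obs / (sd_obs / np.sqrt(n))
    with np.errstate(invalid="ignore"):
        t_obs = np.where(
            sd_obs == 0, np.where(m_obs == 0, 0.0, np.inf * np.sign(m_obs)), t_obs
        )
    abs_obs = np.abs(t_obs)
    with np.errstate(invalid="ignore"):
        thresh = np.where(
            np.isinf(abs_obs), np.inf, abs_obs - _T_TOL * (1.0 + abs_obs)
        )
    exceed = np.abs(t) >= thresh[None, :]
    k = exceed.sum(axis=0)
    if exhaustive:
        p = k / n_rows
    else:
        p = (k + 1) / (n_rows + 1)
    p = np.where(np.all(z == 0, axis=0), 1.0, p)
    return p


def perm_spearman(
    x, y, n_perm: int = 10000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Spearman correlation with a two-sided permutation p-value.

    The null is built by permuting one variable's values across participants.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DataError("need two equal-length vectors with >= 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("Spearman correlation is undefined for a constant vector")
    rx = sps.rankdata(x) - (x.size + 1) / 2.0
    ry = sps.rankdata(y) - (y.size + 1) / 2.0
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    rho = float(np.dot(rx, ry) / denom)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rho_perm = perms @ rx / denom
    k = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, float((k + 1) / (n_perm + 1))


def circ_mean(angles: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular mean direction in (-pi, pi]."""
    angles = np.asarray(angles, dtype=float)
    return np.angle(np.exp(1j * angles).mean(axis=axis))


def resultant_length(angles: np.ndarray, axis=None) -> np.ndarray | float:
    """Mean resultant vector length R-bar in [0, 1]."""
    angles = np.asarray(angles, dtype=float)
    return np.abs(np.exp(1j * angles).mean(axis=axis))


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test for uniformity of circular data.

    Returns ``(z, p)`` with z = n * R-bar^2 and the standard small-sample
    correction p = exp( sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n) ), R = n*R-bar.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 1 or angles.size < 2:
        raise DataError("need at least two angles")
    n = angles.size
    rbar = float(resultant_length(angles))
    z = n * rbar**2
    big_r = n * rbar
    p = float(np.exp(np.sqrt(1.0 + 4 * n + 4 * (n**2 - big_r**2)) - (1.0 + 2 * n)))
    return float(z), min(p, 1.0)


def hotelling_paired_circular(a, b) -> tuple[float, float]:
    """Paired Hotelling (second-order) test for equal angular means.

    Per-participant angle differences are represented by their Cartesian
    components X_j = cos(a_j) - cos(b_j), Y_j = sin(a_j) - sin(b_j) and the
    mean vector (X-bar, Y-bar) is tested against (0, 0):

        F = n*(n-2)/2 * (X̄²·Σy² − 2·X̄·Ȳ·Σxy + Ȳ²·Σx²)
            / (Σx²·Σy² − (Σxy)²),

    with x, y the deviations from the component means, F-distributed with
    (2, n-2) degrees of freedom under the null. Identical samples (all
    difference vectors zero) return the no-difference boundary (F=0, p=1);
    zero-variance components otherwise are degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise DataError("need two equal-length angle vectors with >= 3 entries")
    n = a.size
    X = np.cos(a) - np.cos(b)
    Y = np.sin(a) - np.sin(b)
    scale = max(np.max(np.abs(X)), np.max(np.abs(Y)))
    if scale < 1e-12:
        return 0.0, 1.0
    x = X - X.mean()
    y = Y - Y.mean()
    sxx = float(np.sum(x**2))
    syy = float(np.sum(y**2))
    sxy = float(np.sum(x * y))
    det = sxx * syy - sxy**2
    if det <= 1e-20 * scale**4:
        raise DataError("degenerate (zero-variance) difference components")
    num = X.mean() ** 2 * syy - 2 * X.mean() * Y.mean() * sxy + Y.mean() ** 2 * sxx
    F = float(n * (n - 2) / 2.0 * num / det)
    p = float(sps.f.sf(F, 2, n - 2))
    return F, p


def linear_trend_test(
    values: np.ndarray,
    positions: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Test per-participant linear slopes across positions against zero.

    ``values`` is a participants x positions matrix (e.g. logit-transformed
    proportion correct per probed number position). A least-squares slope is
    fitted per participant and the slopes are submitted to the one-sample
    sign-flip permutation test. Participants with missing cells are dropped
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise DataError("values must be participants x positions with >= 2 positions")
    if positions is None:
        positions = np.arange(1, values.shape[1] + 1, dtype=float)
    positions = np.asarray(positions, dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} participants with missing cells",
            stacklevel=2,
        )
    vals = values[complete]
    if vals.shape[0] < 2:
        raise DataError("need at least two participants with complete data")
    pc = positions - positions.mean()
    slopes = vals @ pc / np.sum(pc**2)
    _, p = perm_ttest_paired(slopes, n_perm=n_perm, seed=seed)
    return float(slopes.mean()), p


def bootstrap_ci_mean(
    x: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap confidence interval for the mean over axis 0."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise DataError("need at least two observations to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.shape[0], size=(n_boot, x.shape[0]))
    means = x[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0 * 100.0
    return (
        np.percentile(means, lo, axis=0),
        np.percentile(means, 100.0 - lo, axis=0),
    )
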