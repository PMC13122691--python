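"""Normality-gated location tests, RM-ANOVA with GG correction, Holm step-down.

The inference stack mirrors common practice in systems-neuroscience group
analyses: each sample is first screened with a Lilliefors test (a
Kolmogorov-Smirnov test against a normal with mean and SD estimated from the
sample); samples that pass the gate are analysed with t tests, samples that
fail with Wilcoxon signed-rank tests.  Repeated-measures designs (light x
tone) use a two-way within-subject ANOVA with the Greenhouse-Geisser
sphericity correction, and families of comparisons are corrected with the
Holm-Bonferroni step-down procedure.

The Lilliefors p-value is Monte-Carlo exact: the null distribution of the
statistic is simulated with standard-normal samples of the same size and the
same estimator, so no lookup-table interpolation is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigError, DataError, DegenerateDataError, InsufficientDataError

ONE_SAMPLE_T = "one_sample_t"
PAIRED_T = "paired_t"
WILCOXON = "wilcoxon_signed_rank"

#: largest sample size for which the exact signed-rank distribution is used
_WILCOXON_EXACT_N = 25

_ZERO = 1e-12


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo null)
# ---------------------------------------------------------------------------

_NULL_TABLES: dict = {}


def _lilliefors_statistic(x: np.ndarray) -> float:
    """sup |ecdf - Phi((x - xbar)/s)| with s the sample SD (ddof=1)."""
    n = x.size
    xs = np.sort(x)
    z = (xs - xs.mean()) / xs.std(ddof=1)
    cdf = sps.norm.cdf(z)
    hi = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(hi.max(), lo.max()))


def _null_table(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Simulated null distribution of the Lilliefors statistic (cached)."""
    key = (n, n_mc, seed)
    if key not in _NULL_TABLES:
        rng = np.random.default_rng(seed)
        sims = np.sort(rng.standard_normal((n_mc, n)), axis=1)
        z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf(z)
        grid_hi = np.arange(1, n + 1) / n
        grid_lo = np.arange(0, n) / n
        d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
        _NULL_TABLES[key] = d
    return _NULL_TABLES[key]


def lilliefors_test(x, n_mc: int = 10000, seed: int = 0):
    """Lilliefors normality test with a Monte-Carlo p-value.

    Returns ``(statistic, p)`` where ``p = (1 + #{D_mc >= D}) / (n_mc + 1)``
    over ``n_mc`` standard-normal null samples of the same size.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("Lilliefors test needs n >= 4")
    if x.std(ddof=1) <= _ZERO:
        raise DegenerateDataError("Lilliefors test is undefined for a constant sample")
    d = _lilliefors_statistic(x)
    null = _null_table(x.size, n_mc, seed)
    p = (1 + int(np.sum(null >= d))) / (n_mc + 1)
    return d, float(p)


# ---------------------------------------------------------------------------
# Gated location tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatedTestResult:
    test_used: str
    statistic: float
    p_value: float
    n: int
    lilliefors_p: float | None
    alpha_gate: float
    degenerate: bool = False

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise DataError("p-value out of [0, 1]")


def _wilcoxon(d: np.ndarray) -> tuple:
    """Signed-rank test on differences: zeros dropped, mid-rank ties,
    exact distribution for small tie-free samples, otherwise normal
    approximation with continuity correction."""
    nz = d[np.abs(d) > _ZERO]
    if nz.size == 0:
        return 0.0, 1.0, True
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= _WILCOXON_EXACT_N and not ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=True, method=method)
    return float(res.statistic), float(res.pvalue), False


def gated_one_sample_test(
    x,
    null_value: float = 0.0,
    alpha_gate: float = 0.05,
    n_mc: int = 10000,
    seed: int = 0,
    force: str | None = None,
) -> GatedTestResult:
    """One-sample location test with a Lilliefors normality gate.

    If the sample passes the gate (Lilliefors p >= ``alpha_gate``) a
    two-sided one-sample t test against ``null_value`` is used, otherwise a
    two-sided Wilcoxon signed-rank test of ``x - null_value``.  ``force``
    ("t" or "wilcoxon") bypasses the gate.  A sample identical to the null
    value is flagged degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x - null_value
    if np.all(np.abs(d) <= _ZERO):
        return GatedTestResult(WILCOXON, 0.0, 1.0, x.size, None, alpha_gate, True)
    lillie_p = None
    if force is None:
        _, lillie_p = lilliefors_test(x, n_mc=n_mc, seed=seed)
        branch = "t" if lillie_p >= alpha_gate else "wilcoxon"
    elif force in ("t", "wilcoxon"):
        branch = force
    else:
        raise ConfigError(f"force must be None, 't' or 'wilcoxon', got {force!r}")
    if branch == "t":
        if x.std(ddof=1) <= _ZERO:
            raise DegenerateDataError("t test undefined: zero sample variance")
        res = sps.ttest_1samp(x, null_value)
        return GatedTestResult(
            ONE_SAMPLE_T, float(res.statistic), float(res.pvalue), x.size, lillie_p, alpha_gate
        )
    stat, p, degen = _wilcoxon(d)
    return GatedTestResult(WILCOXON, stat, p, x.size, lillie_p, alpha_gate, degen)


def gated_paired_test(
    x,
    y,
    alpha_gate: float = 0.05,
    n_mc: int = 10000,
    seed: int = 0,
    force: str | None = None,
) -> GatedTestResult:
    """Paired location test gated on the normality of the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("paired samples must have equal length")
    d = x - y
    if np.all(np.abs(d) <= _ZERO):
        return GatedTestResult(WILCOXON, 0.0, 1.0, x.size, None, alpha_gate, True)
    if d.std(ddof=1) <= _ZERO:
        raise DegenerateDataError(
            "paired differences have zero variance; paired t is undefined"
        )
    lillie_p = None
    if force is None:
        _, lillie_p = lilliefors_test(d, n_mc=n_mc, seed=seed)
        branch = "t" if lillie_p >= alpha_gate else "wilcoxon"
    elif force in ("t", "wilcoxon"):
        branch = force
    else:
        raise ConfigError(f"force must be None, 't' or 'wilcoxon', got {force!r}")
    if branch == "t":
        res = sps.ttest_rel(x, y)
        return GatedTestResult(
            PAIRED_T, float(res.statistic), float(res.pvalue), x.size, lillie_p, alpha_gate
        )
    stat, p, degen = _wilcoxon(d)
    return GatedTestResult(WILCOXON, stat, p, x.size, lillie_p, alpha_gate, degen)


# ---------------------------------------------------------------------------
# Two-way repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectResult:
    name: str
    ss: float
    ss_error: float
    df: float
    df_error: float
    F: float
    epsilon: float
    df_corr: float
    df_error_corr: float
    p_uncorrected: float
    p_gg: float


@dataclass(frozen=True)
class RmAnovaResult:
    effects: dict  # name -> EffectResult
    n_subjects: int
    factor_levels: tuple  # (a, b)

    def summary(self):
        import pandas as pd

        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name,
                    "F": e.F,
                    "df1": e.df,
                    "df2": e.df_error,
                    "eps_gg": e.epsilon,
                    "df1_gg": e.df_corr,
                    "df2_gg": e.df_error_corr,
                    "p_uncorrected": e.p_uncorrected,
                    "p_gg": e.p_gg,
                }
            )
        return pd.DataFrame(rows)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis.T)
    return q[:, : k - 1].T


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from orthonormal-contrast scores.

    ``eps = tr(S)^2 / (d * tr(S^2))`` with ``S`` the covariance of the
    (n_subjects x d) score matrix; bounded in [1/d, 1].  A single contrast
    (d = 1) gives exactly 1.
    """
    d = scores.shape[1]
    if d == 1:
        return 1.0
    s = np.cov(scores, rowvar=False)
    eps = np.trace(s) ** 2 / (d * np.sum(s * s))
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova_gg(data, factor_names=("light", "tone")) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA with GG-corrected p-values.

    ``data`` is a complete balanced (n_subjects, a, b) array; both factors
    are within-subject, with subject-by-effect interactions as error terms.
    Each effect's epsilon comes from the covariance of its orthonormal
    contrast scores, and its corrected p uses F with both degrees of freedom
    scaled by epsilon.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise DataError("data must be (subjects, factor A levels, factor B levels)")
    if not np.all(np.isfinite(x)):
        raise DataError("RM-ANOVA table contains missing or non-finite cells")
    n, a, b = x.shape
    if n < 3:
        raise InsufficientDataError("RM-ANOVA needs at least 3 subjects")
    if a < 2 or b < 2:
        raise DataError("each factor needs at least 2 levels")

    grand = x.mean()
    subj = x.mean(axis=(1, 2))  # (n,)
    mean_a = x.mean(axis=(0, 2))  # (a,)
    mean_b = x.mean(axis=(0, 1))  # (b,)
    mean_ab = x.mean(axis=0)  # (a, b)
    mean_sa = x.mean(axis=2)  # (n, a)
    mean_sb = x.mean(axis=1)  # (n, b)

    ss_a = n * b * np.sum((mean_a - grand) ** 2)
    ss_b = n * a * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((mean_sa - mean_a[None, :] - subj[:, None] + grand) ** 2)
    ss_bs = a * np.sum((mean_sb - mean_b[None, :] - subj[:, None] + grand) ** 2)
    resid = (
        x
        - mean_sa[:, :, None]
        - mean_sb[:, None, :]
        - mean_ab[None, :, :]
        + subj[:, None, None]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    scores_a = mean_sa @ ca.T
    scores_b = mean_sb @ cb.T
    cab = np.kron(ca, cb)
    scores_ab = x.reshape(n, a * b) @ cab.T

    specs = [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), scores_a),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), scores_b),
        (
            f"{factor_names[0]}*{factor_names[1]}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
            scores_ab,
        ),
    ]
    effects = {}
    for name, ss, df, ss_err, df_err, scores in specs:
        ms = ss / df
        ms_err = ss_err / df_err
        if ms_err <= 0:
            raise DegenerateDataError(f"zero error variance for effect {name!r}")
        f = ms / ms_err
        eps = _gg_epsilon(scores)
        p_unc = float(sps.f.sf(f, df, df_err))
        p_gg = float(sps.f.sf(f, eps * df, eps * df_err))
        effects[name] = EffectResult(
            name, float(ss), float(ss_err), float(df), float(df_err), float(f),
            eps, eps * df, eps * df_err, p_unc, p_gg,
        )
    return RmAnovaResult(effects, n, (a, b))


# ---------------------------------------------------------------------------
# Holm-Bonferroni step-down adjustment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    alpha: float
    reject: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "adjusted", np.asarray(self.adjusted, dtype=float))
        object.__setattr__(self, "reject", np.asarray(self.reject, dtype=bool))


def holm_bonferroni_adjust(p, alpha: float = 0.05) -> AdjustedPValues:
    """Holm step-down adjusted p-values and rejection flags.

    Sorted ascending, ``adj(i) = min(1, max_{j<=i} (m - j + 1) * p(j))``
    (1-based), mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(scaled))
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustedPValues(p, adjusted, alpha, adjusted <= alpha)
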