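"""Statistical analysis: one-way ANOVA, K-S normality screening, Pearson
correlation matrices and the permutation Mantel test.

The ANOVA is the classical fixed-effects decomposition reported in the
standard spreadsheet layout (SS / df / MS / F / P-value / F crit).  The
Mantel test correlates the unfolded upper triangles of two distance
matrices and assesses significance by permuting the objects of one
matrix, with the add-one rule p = (1 + #{r* >= r}) / (1 + N) so a
permutation p-value is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, DomainError
from .schema import PARAMETER_COLUMNS, SurveyDataset

__all__ = [
    "AnovaTable", "one_way_anova", "KsResult", "ks_normality",
    "pearson_matrix", "MantelResult", "mantel_test", "mantel_screen",
]


@dataclass
class AnovaTable:
    """One-way fixed-effects ANOVA decomposition."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float
    f_crit: float
    alpha: float = 0.05

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        """Render in the conventional spreadsheet layout."""
        return pd.DataFrame(
            {
                "Source of Variation": ["Between Groups", "Within Groups", "Total"],
                "SS": [self.ss_between, self.ss_within, self.ss_total],
                "df": [self.df_between, self.df_within, self.df_total],
                "MS": [self.ms_between, self.ms_within, np.nan],
                "F": [self.F, np.nan, np.nan],
                "P-value": [self.p, np.nan, np.nan],
                "F crit": [self.f_crit, np.nan, np.nan],
            }
        )


def one_way_anova(groups, alpha: float = 0.05) -> AnovaTable:
    """Classical one-way ANOVA over ``groups`` (sequence of 1-d arrays).

    Unbalanced groups are allowed; each group needs at least two
    observations and the pooled within-group variance must be nonzero.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise DegenerateInputError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise DegenerateInputError(f"group {i}: need >= 2 observations")
        if np.isnan(g).any():
            raise DegenerateInputError(f"group {i}: missing values not allowed")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(g) for g in arrays) - len(arrays)
    if ss_within == 0:
        raise DegenerateInputError("zero within-group variance: F undefined")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    f_crit = float(sps.f.ppf(1 - alpha, df_between, df_within))
    return AnovaTable(ss_between=float(ss_between), ss_within=float(ss_within),
                      df_between=df_between, df_within=df_within,
                      F=float(F), p=p, f_crit=f_crit, alpha=alpha)


@dataclass
class KsResult:
    """Normality screen outcome for one parameter."""

    statistic: float
    p: float
    passed: bool
    method: str


def ks_normality(values, alpha: float = 0.05,
                 lilliefors: bool = False) -> KsResult:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with moments estimated from the data.

    The default reports the asymptotic two-tailed p of the plain K-S
    statistic (the common statistics-package convention); set
    ``lilliefors=True`` for the estimated-parameter correction from
    statsmodels.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise DegenerateInputError(f"need >= 5 observations, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample: normality undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf
        stat, p = _lf(x, dist="norm")
        method = "lilliefors"
    else:
        stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
        method = "ks-asymptotic"
    return KsResult(statistic=float(stat), p=float(p),
                    passed=bool(p > alpha), method=method)


def pearson_matrix(X) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix with p-values.

    Returns ``(r, p)`` DataFrames: symmetric, unit diagonal.  Pairs with
    fewer than 3 complete observations or zero variance yield NaN entries
    (flagged, never silently zeroed).
    """
    table = pd.DataFrame(X)
    cols = list(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].apply(
                pd.to_numeric, errors="coerce").dropna()
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclass
class MantelResult:
    """Permutation Mantel test outcome."""

    r: float
    p: float
    n_permutations: int
    seed: int


def _check_distance_matrix(D, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DomainError(f"{name}: distance matrix must be square")
    if D.shape[0] < 4:
        raise DomainError(f"{name}: need dimension >= 4")
    if not np.allclose(D, D.T):
        raise DomainError(f"{name}: distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise DomainError(f"{name}: diagonal must be zero")
    return D


def mantel_test(A, B, n_permutations: int = 999,
                alternative: str = "greater", seed: int = 0) -> MantelResult:
    """Mantel test between two distance matrices over the same objects.

    ``r`` is the Pearson correlation of the unfolded upper triangles; the
    permutation null shuffles the objects of ``B``.  Deterministic given
    ``seed``.
    """
    A = _check_distance_matrix(A, "A")
    B = _check_distance_matrix(B, "B")
    if A.shape != B.shape:
        raise DomainError(f"dimension mismatch: {A.shape} vs {B.shape}")
    if alternative not in ("greater", "less", "two-sided"):
        raise DomainError(f"unknown alternative {alternative!r}")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    if a.std() == 0 or B[iu].std() == 0:
        raise DegenerateInputError("constant distances: Mantel r undefined")
    a = (a - a.mean()) / a.std()

    def corr_with(Bperm):
        b = Bperm[iu]
        b = (b - b.mean()) / b.std()
        return float(np.mean(a * b))

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_star = corr_with(B[np.ix_(perm, perm)])
        if alternative == "greater":
            hit = r_star >= r_obs
        elif alternative == "less":
            hit = r_star <= r_obs
        else:
            hit = abs(r_star) >= abs(r_obs)
        count += hit
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=float(p),
                        n_permutations=n_permutations, seed=seed)


def _euclidean_1d(x: np.ndarray) -> np.ndarray:
    return np.abs(x[:, None] - x[None, :])


def mantel_screen(dataset, indices: pd.DataFrame, parameters=None,
                  n_permutations: int = 999, seed: int = 0,
                  strong_threshold: float = 0.4) -> pd.DataFrame:
    """Per-parameter Mantel screen against the WQI and TLI matrices.

    For each parameter, builds the Euclidean distance matrix of its
    z-scored values and tests it against the distance matrix of each
    composite index over the records where both are available.  Rows with
    ``r >= strong_threshold`` are flagged strong.  Every parameter's test
    uses the same seed, so duplicated columns give identical rows.
    """
    frame = dataset.frame if isinstance(dataset, SurveyDataset) else pd.DataFrame(dataset)
    if parameters is None:
        parameters = [p for p in PARAMETER_COLUMNS
                      if PARAMETER_COLUMNS[p] in frame.columns]
    indices = pd.DataFrame(indices)
    rows = []
    for param in parameters:
        col = PARAMETER_COLUMNS.get(param, param)
        x = pd.to_numeric(frame[col], errors="coerce")
        row = {"parameter": param}
        for index_name in indices.columns:
            y = pd.to_numeric(indices[index_name], errors="coerce")
            ok = x.notna() & y.notna()
            xs = x[ok].to_numpy()
            if xs.std(ddof=1) == 0:
                raise DegenerateInputError(f"{param}: zero variance")
            xs = (xs - xs.mean()) / xs.std(ddof=1)
            res = mantel_test(_euclidean_1d(xs), _euclidean_1d(y[ok].to_numpy()),
                              n_permutations=n_permutations, seed=seed)
            key = index_name.lower()
            row[f"r_{key}"] = res.r
            row[f"p_{key}"] = res.p
            row[f"strong_{key}"] = res.r >= strong_threshold
        rows.append(row)
    return pd.DataFrame(rows)
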