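"""Exact and rank-based phenotype-covariate association tests.

Fisher's exact test for 2x2 and r-by-c tables (Freeman-Halton extension by
exhaustive enumeration over tables with the observed margins), the
Mann-Whitney-Wilcoxon rank test, and Welch's unequal-variance t-test — the
battery used to cross-tabulate tumor phenotypes against clinical covariates
and CT acquisition parameters.

The two-sided exact p-value follows the usual ``fisher.test`` convention: the
sum of probabilities of all margin-consistent tables no more probable than
the observed one, with a 1e-7 relative slack so floating-point ties count as
ties.  Factorials live in log space (log-gamma) so tables with N up to 200
are exact.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "mann_whitney",
    "welch_t",
    "association_report",
]

_REL_SLACK = 1e-7
ENUMERATION_N_MAX = 200


def _as_int_table(table, min_dim: int = 1) -> np.ndarray:
    arr = np.asarray(table)
    if np.any(arr < 0):
        raise ValueError("contingency table must have non-negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must hold integer counts")
    arr = np.round(arr).astype(np.int64)
    if arr.ndim != 2 or min(arr.shape) < min_dim:
        raise ValueError(f"expected a 2-D table, got shape {arr.shape}")
    if arr.sum() < 1:
        raise ValueError("table total must be >= 1")
    return arr


def _log_table_prob(table: np.ndarray, row: np.ndarray, col: np.ndarray, n: int) -> float:
    """log P(table | margins) under the multiple hypergeometric."""
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of counts."""
    t = _as_int_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    row, col = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    lp_obs = _log_table_prob(t, row, col, n)
    a_lo = max(0, row[0] - col[1])
    a_hi = min(row[0], col[0])
    if a_lo == a_hi:  # single attainable table
        return 1.0
    a = np.arange(a_lo, a_hi + 1)
    tables = np.stack([a, row[0] - a, col[0] - a, n - row[0] - col[0] + a], axis=1)
    lps = (
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(tables + 1).sum(axis=1)
    )
    p = np.exp(lps[lps <= lp_obs + _REL_SLACK]).sum()
    return float(min(p, 1.0))


def _enumerate_margin_tables(row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """All non-negative integer tables with the given margins.

    Returns an (n_tables, r*c) array of flattened cell counts; pure-python
    recursion over rows with the last row forced by the column margins.
    """
    r, c = len(row), len(col)
    out: list[tuple[int, ...]] = []

    def fill(i: int, remaining_col: tuple[int, ...], cells: tuple[int, ...]):
        if i == r - 1:
            if min(remaining_col) >= 0:
                out.append(cells + remaining_col)
            return
        target = int(row[i])

        def fill_row(j: int, left: int, row_cells: tuple[int, ...]):
            if j == c - 1:
                if left <= remaining_col[j]:
                    yield row_cells + (left,)
                return
            for v in range(min(left, remaining_col[j]) + 1):
                yield from fill_row(j + 1, left - v, row_cells + (v,))

        for row_cells in fill_row(0, target, ()):
            rem = tuple(rc - v for rc, v in zip(remaining_col, row_cells))
            fill(i + 1, rem, cells + row_cells)

    fill(0, tuple(int(v) for v in col), ())
    return np.asarray(out, dtype=np.int64).reshape(len(out), r * c)


def fisher_exact_rxc(table, monte_carlo: bool = False, n_draws: int = 1_000_000, seed: int = 0) -> float:
    """Two-sided Freeman-Halton exact p for an r-by-c table.

    Exhaustive enumeration of all tables with the observed margins, limited to
    N <= 200; beyond that raises unless ``monte_carlo=True``, which estimates
    the p-value from seeded Patefield draws of margin-conditional tables.
    """
    t = _as_int_table(table)
    row, col = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    # degenerate dimensions: only one attainable table
    if min(t.shape) == 1 or np.count_nonzero(row) <= 1 or np.count_nonzero(col) <= 1:
        return 1.0
    lp_obs = _log_table_prob(t, row, col, n)
    if n > ENUMERATION_N_MAX and not monte_carlo:
        raise ValueError(
            f"N={n} exceeds the exact-enumeration bound {ENUMERATION_N_MAX}; "
            "pass monte_carlo=True for a seeded Monte-Carlo estimate"
        )
    if monte_carlo:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(row, col)
        hits = 0
        chunk = 20_000
        done = 0
        while done < n_draws:
            m = min(chunk, n_draws - done)
            draws = dist.rvs(m, random_state=rng)
            lps = (
                gammaln(row + 1).sum()
                + gammaln(col + 1).sum()
                - gammaln(n + 1)
                - gammaln(draws + 1).sum(axis=(1, 2))
            )
            hits += int(np.sum(lps <= lp_obs + _REL_SLACK))
            done += m
        return (hits + 1) / (n_draws + 1)
    tables = _enumerate_margin_tables(row, col)
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    lps = const - gammaln(tables + 1.0).sum(axis=1)
    p = np.exp(lps[lps <= lp_obs + _REL_SLACK]).sum()
    return float(min(p, 1.0))


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon U and two-sided p.

    Exact null distribution when both samples have <= 8 observations and no
    ties; otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t statistic, Satterthwaite df, and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# covariate -> (kind, test) for the patient-characteristics block
_TABLE1_SPEC = [
    ("age", "continuous", "mann-whitney"),
    ("sex", "categorical", "fisher"),
    ("smoking_status", "categorical", "fisher"),
    ("ecog", "continuous", "mann-whitney"),
    ("line_of_therapy", "categorical", "fisher"),
    ("egfr_mutation", "categorical", "fisher"),
    ("n_mutations", "continuous", "welch"),
    ("driver_af", "continuous", "mann-whitney"),
]


def association_report(clinical, phenotype) -> list[dict]:
    """Patient-characteristics association block: phenotype vs each covariate.

    Categorical covariates get Fisher's exact test (Freeman-Halton when the
    covariate has more than two levels); continuous covariates get
    Mann-Whitney, except mutation count which uses Welch's t — matching the
    test battery of the emulated study.
    """
    import pandas as pd

    clinical = pd.DataFrame(clinical)
    phen = np.asarray(phenotype)
    groups = np.unique(phen)
    rows = []
    for name, kind, test in _TABLE1_SPEC:
        if name not in clinical.columns:
            continue
        values = clinical[name]
        entry: dict = {"covariate": name, "test": test}
        if kind == "categorical":
            tab = pd.crosstab(values, pd.Series(phen, index=clinical.index))
            entry["table"] = {str(k): [int(v) for v in tab.loc[k]] for k in tab.index}
            r_dim, c_dim = tab.shape
            if (r_dim, c_dim) == (2, 2):
                entry["p"] = fisher_exact_2x2(tab.to_numpy())
            elif (r_dim - 1) * (c_dim - 1) <= 8:
                entry["p"] = fisher_exact_rxc(tab.to_numpy())
            else:  # enumeration infeasible: seeded margin-conditional sampling
                entry["p"] = fisher_exact_rxc(
                    tab.to_numpy(), monte_carlo=True, n_draws=100_000, seed=0
                )
                entry["test"] = "fisher (monte-carlo)"
        else:
            samples = [values[phen == g].to_numpy(dtype=float) for g in groups]
            entry["group_means"] = [float(np.mean(s)) for s in samples]
            entry["group_medians"] = [float(np.median(s)) for s in samples]
            if test == "welch":
                entry["test"] = "welch-t"
                _, _, entry["p"] = welch_t(*samples[:2])
            else:
                _, entry["p"] = mann_whitney(*samples[:2])
        rows.append(entry)
    return rows
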