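"""Clinical/demographic group-comparison statistics.

Numeric variables: median (IQR) per group, Kruskal-Wallis across the
three groups, Dunn's pairwise post-hoc z tests (tie-corrected, optional
Bonferroni).  Categorical variables: Fisher's exact test, extended to
r x c tables with the Freeman-Halton two-sided definition (sum of the
probabilities, under fixed margins, of every table no more probable
than the observed one).
"""

from __future__ import annotations

import itertools
import warnings
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

PAIRWISE = (("HC", "RA"), ("HC", "SLE"), ("RA", "SLE"))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value
    (k - 1 degrees of freedom)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigurationError("need >=2 groups with >=2 observations each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; H = 0, p = 1", stacklevel=2)
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_test(
    values: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], dict[str, float]]:
    """Dunn's pairwise post-hoc test after Kruskal-Wallis.

    z = (mean-rank difference) / SE with the usual tie correction
    ``sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values,
    optionally Bonferroni-adjusted over the number of pairs.
    """
    if adjust not in ("none", "bonferroni"):
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    names = list(values)
    arrays = [np.asarray(values[g], float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ConfigurationError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, a in zip(names, arrays):
        mean_ranks[g] = ranks[start : start + len(a)].mean()
        sizes[g] = len(a)
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1)))
    base_var = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out: dict[tuple[str, str], dict[str, float]] = {}
    for g1, g2 in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        p_adj = min(1.0, len(pairs) * p) if adjust == "bonferroni" else p
        out[(g1, g2)] = {"z": float(z), "p": p, "p_adjusted": p_adj}
    return out


# ---------------------------------------------------------------------------
# Freeman-Halton Fisher exact test
# ---------------------------------------------------------------------------


def _log_table_probability(
    table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray, n: int
) -> float:
    num = sum(lgamma(r + 1) for r in row_sums) + sum(
        lgamma(c + 1) for c in col_sums
    )
    den = lgamma(n + 1) + sum(lgamma(v + 1) for v in table.ravel())
    return num - den


def _enumerate_tables(row_sums, col_sums):
    """All non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill(rows_left, col_remaining):
        if rows_left == 1:
            yield [list(col_remaining)]
            return
        target = row_sums[r - rows_left]
        for combo in _row_options(target, col_remaining):
            rest = [cr - x for cr, x in zip(col_remaining, combo)]
            for tail in fill(rows_left - 1, rest):
                yield [list(combo)] + tail

    yield from fill(r, list(col_sums))


def _row_options(total, caps):
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    for x in range(min(total, caps[0]) + 1):
        for rest in _row_options(total - x, caps[1:]):
            yield (x,) + rest


def fisher_exact(table: np.ndarray | list) -> float:
    """Two-sided Fisher exact p for an r x c contingency table
    (Freeman-Halton): the sum of the conditional probabilities of all
    tables with the observed margins whose probability does not exceed
    the observed table's (within a 1e-7 relative tolerance for
    floating-point ties).  Enumeration is feasible for r, c <= 3 at the
    cohort's sample sizes."""
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (np.asarray(table) < 0).any():
        raise ConfigurationError("table must be a 2-D array of counts >= 0")
    if obs.shape[0] > 3 or obs.shape[1] > 3:
        raise ConfigurationError("enumeration supported for tables up to 3x3")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())
    if (row_sums == 0).any() or (col_sums == 0).any():
        warnings.warn("zero margin; p = 1", stacklevel=2)
        return 1.0
    log_p_obs = _log_table_probability(obs, row_sums, col_sums, n)
    cutoff = log_p_obs + 1e-7
    total = 0.0
    for t in _enumerate_tables(list(row_sums), list(col_sums)):
        lp = _log_table_probability(np.asarray(t), row_sums, col_sums, n)
        if lp <= cutoff:
            total += np.exp(lp)
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# Table-1-style summary
# ---------------------------------------------------------------------------


def group_comparison_table(
    metadata: pd.DataFrame,
    numeric: list[str],
    categorical: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Median [IQR] per group with Kruskal-Wallis p and Dunn flags for
    numeric variables, Fisher exact p for categorical ones — the
    machinery behind a clinical characteristics table."""
    bio = metadata[metadata[group_col] != "QC"]
    groups = [g for g in ("HC", "RA", "SLE") if (bio[group_col] == g).any()]
    rows = []
    for var in numeric:
        vals = {
            g: bio.loc[bio[group_col] == g, var].dropna().to_numpy()
            for g in groups
        }
        vals = {g: v for g, v in vals.items() if len(v) >= 2}
        row: dict[str, object] = {"variable": var, "type": "numeric"}
        for g, v in vals.items():
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            row[g] = f"{med:.2f} [{q1:.2f}-{q3:.2f}]"
        if len(vals) >= 2:
            _, p = kruskal_wallis(list(vals.values()))
            row["p_value"] = p
            if len(vals) >= 2:
                dunn = dunn_test(vals, adjust="none")
                flags = [
                    f"{a} vs {b}"
                    for (a, b), res in dunn.items()
                    if res["p"] < 0.05
                ]
                row["dunn_significant"] = "; ".join(flags)
        rows.append(row)
    for var in categorical or []:
        sub = bio[[group_col, var]].dropna()
        counts = pd.crosstab(sub[group_col], sub[var])
        row = {"variable": var, "type": "categorical"}
        for g in groups:
            if g in counts.index:
                total = counts.loc[g].sum()
                row[g] = "; ".join(
                    f"{lvl}: {cnt} ({100 * cnt / total:.1f}%)"
                    for lvl, cnt in counts.loc[g].items()
                )
        row["p_value"] = fisher_exact(counts.to_numpy())
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
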