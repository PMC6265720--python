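"""Statistical battery over pooled labeled alignment sites.

Given per-site records (z-normalized rate + conserved binary factor labels),
this module runs the full analysis: Mann-Whitney two-group contrasts for each
factor, a Kruskal-Wallis test over the eight tri-factor cells followed by
mean-rank multiple pairwise comparisons with a Bonferroni-adjusted normal
critical difference, an unbalanced (type III) 2x2x2 factorial ANOVA with
zero-sum contrasts, cell/trace means, and a loess regression of family
disorder content against the mean rate of disordered-structured sites.

Sites are pooled across families and treated as independent observations,
matching the design of large-scale rate-vs-structure analyses; a stratified
per-family variant of the two-group contrasts is available but off by
default.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

EXACT_MAX_N = 8

FACTORS = {
    "disorder": ("ordered", "disordered"),
    "ss": ("structured", "coil"),
    "domain": ("domain", "linker"),
}


class InestimableTermError(ValueError):
    """Raised when empty factorial cells make ANOVA terms inestimable."""


# ---------------------------------------------------------------------------
# Mann-Whitney


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of group a
    p: float  # two-sided
    delta_median: float  # median(b) - median(a)
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic"


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = EXACT_MAX_N
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test of group_a vs group_b.

    For groups both of size <= ``exact_max_n`` the p-value is computed by
    exhaustive enumeration of all rank assignments (ties handled via
    midranks); otherwise the tie-corrected normal approximation with
    continuity correction is used. ``delta_median`` is
    median(group_b) - median(group_a), so callers pass the reference group
    first (e.g. ordered, then disordered).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    delta = float(np.median(b) - np.median(a))
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if n_a <= exact_max_n and n_b <= exact_max_n:
        # enumerate all C(n_a+n_b, n_a) assignments of pooled ranks to group a
        total = 0
        n_ge = 0
        n_le = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            total += 1
            if u >= u_obs - 1e-12:
                n_ge += 1
            if u <= u_obs + 1e-12:
                n_le += 1
        p = min(1.0, 2.0 * min(n_ge / total, n_le / total))
        return MannWhitneyResult(u_obs, p, delta, n_a, n_b, "exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), delta, n_a, n_b, "asymptotic")


# ---------------------------------------------------------------------------
# Kruskal-Wallis + kruskalmc-style pairwise comparisons


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df).

    Degenerate input (all values identical across all groups) returns
    H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    nonempty = [g for g in groups if g.size > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(nonempty)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*nonempty)
    return float(h), float(p)


def pairwise_rank_comparisons(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Post-hoc multiple pairwise comparisons on pooled mean ranks.

    For k groups and N pooled observations, the pair (i, j) is significant
    when::

        |Rbar_i - Rbar_j| >= z_{1 - alpha/(k(k-1))} *
                             sqrt( N(N+1)/12 * (1/n_i + 1/n_j) )

    i.e. the published critical-difference rule of the "kruskalmc" method.
    Pairs involving an empty group are marked not evaluable (significant =
    NA). Returns one row per unordered pair: group_a, group_b, obs_diff,
    critical_diff, significant.
    """
    names = list(groups)
    sizes = {k: np.asarray(groups[k], dtype=float).size for k in names}
    nonempty = [k for k in names if sizes[k] > 0]
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in nonempty])
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    pos = 0
    for k in nonempty:
        mean_rank[k] = float(ranks[pos : pos + sizes[k]].mean())
        pos += sizes[k]
    n_total = pooled.size
    k_groups = len(names)
    z_crit = sps.norm.ppf(1.0 - alpha / (k_groups * (k_groups - 1)))
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        if sizes[ga] == 0 or sizes[gb] == 0:
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "obs_diff": np.nan,
                    "critical_diff": np.nan,
                    "significant": pd.NA,
                }
            )
            continue
        diff = abs(mean_rank[ga] - mean_rank[gb])
        crit = z_crit * math.sqrt(
            n_total * (n_total + 1) / 12.0 * (1.0 / sizes[ga] + 1.0 / sizes[gb])
        )
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "obs_diff": diff,
                "critical_diff": crit,
                "significant": bool(diff >= crit),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# type-III factorial ANOVA


@dataclass
class AnovaResult:
    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, PR(>F)
    adj_r_squared: float
    n_obs: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


_TERM_RENAME = {
    "C(disorder, Sum)": "disorder",
    "C(ss, Sum)": "ss",
    "C(domain, Sum)": "domain",
    "C(disorder, Sum):C(ss, Sum)": "disorder:ss",
    "C(disorder, Sum):C(domain, Sum)": "disorder:domain",
    "C(ss, Sum):C(domain, Sum)": "ss:domain",
    "C(disorder, Sum):C(ss, Sum):C(domain, Sum)": "disorder:ss:domain",
}


def anova_type3(records: pd.DataFrame) -> AnovaResult:
    """Unbalanced 2x2x2 factorial ANOVA of z_rate with zero-sum contrasts.

    ``records`` needs columns disorder, ss, domain (two-level factors) and
    z_rate. Type-III sums of squares compare the full model against the
    model lacking each term with all other terms retained, under effects
    (zero-sum) coding. Raises :class:`InestimableTermError` when any of the
    eight cells is empty.
    """
    df = records.copy()
    missing = _missing_cells(df)
    if missing:
        raise InestimableTermError(
            f"empty factorial cells make terms inestimable: {missing}"
        )
    model = smf.ols(
        "z_rate ~ C(disorder, Sum) * C(ss, Sum) * C(domain, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(index=_TERM_RENAME)
    return AnovaResult(
        table=table, adj_r_squared=float(model.rsquared_adj), n_obs=len(df)
    )


def _missing_cells(df: pd.DataFrame) -> list[tuple]:
    present = set(map(tuple, df[["disorder", "ss", "domain"]].values))
    expected = {
        (d, s, m)
        for d in FACTORS["disorder"]
        for s in FACTORS["ss"]
        for m in FACTORS["domain"]
    }
    return sorted(expected - present)


# ---------------------------------------------------------------------------
# cell and trace means


@dataclass
class CellMeans:
    cells: pd.DataFrame  # disorder, ss, domain, n, mean_z (8 rows, NaN if empty)

    def mean(self, disorder: str, ss: str, domain: str) -> float:
        c = self.cells
        row = c[(c.disorder == disorder) & (c.ss == ss) & (c.domain == domain)]
        return float(row.mean_z.iloc[0])

    def margin(self, f1: str, f2: str) -> pd.DataFrame:
        """2x2 trace-plot means for a factor pair, pooling over the third
        factor weighted by cell counts."""
        c = self.cells.dropna(subset=["mean_z"])
        grouped = c.groupby([f1, f2], observed=True).apply(
            lambda g: np.average(g.mean_z, weights=g.n),
            include_groups=False,
        )
        return grouped.rename("mean_z").reset_index()


def cell_means(records: pd.DataFrame) -> CellMeans:
    """Mean z_rate per (disorder, ss, domain) cell; empty cells are NaN."""
    rows = []
    for d in FACTORS["disorder"]:
        for s in FACTORS["ss"]:
            for m in FACTORS["domain"]:
                sub = records[
                    (records.disorder == d)
                    & (records.ss == s)
                    & (records.domain == m)
                ]
                rows.append(
                    {
                        "disorder": d,
                        "ss": s,
                        "domain": m,
                        "n": len(sub),
                        "mean_z": float(sub.z_rate.mean()) if len(sub) else np.nan,
                    }
                )
    return CellMeans(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# loess


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel: (1 - |u|^3)^3 on [-1, 1], 0 outside."""
    u = np.abs(np.asarray(u, dtype=float))
    w = (1.0 - u**3) ** 3
    w[u >= 1.0] = 0.0
    return w


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local linear regression with tricube weights (loess, degree 1).

    At each grid point the ``ceil(span * n)`` nearest x-neighbors receive
    tricube weights scaled by the window radius and a weighted straight line
    is fitted; the fit at the grid point is returned. Duplicated x with zero
    window radius fall back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    q = int(math.ceil(span * n))
    if q < 2:
        raise ValueError(
            f"span window of {q} point(s) over {n} observations is too small"
        )
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, dtype=float)
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if h == 0:
            inside = d == 0
            fitted[i] = float(np.mean(y[inside]))
            continue
        w = tricube(d / h)
        mask = w > 0
        xw, yw, ww = x[mask], y[mask], w[mask]
        # weighted least squares for intercept + slope
        X = np.column_stack([np.ones(xw.size), xw - x0])
        W = ww
        beta, *_ = np.linalg.lstsq(X * W[:, None] ** 0.5, yw * W**0.5, rcond=None)
        fitted[i] = beta[0]
    return grid, fitted


def loess_disorder_content(
    disorder_fraction: np.ndarray,
    mean_z_disordered_structured: np.ndarray,
    span: float = 0.75,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Loess of per-family mean disordered-structured z-rate against the
    family's disorder content (disordered columns / gap-free columns).

    Requires at least 10 families contributing a disordered-structured mean.
    """
    x = np.asarray(disorder_fraction, dtype=float)
    y = np.asarray(mean_z_disordered_structured, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValueError(
            f"need >= 10 families with disordered-structured sites, got {x.size}"
        )
    gx, gy = loess_fit(x, y, span=span, grid=grid)
    return pd.DataFrame({"disorder_fraction": gx, "mean_z": gy})


# ---------------------------------------------------------------------------
# model-style front end


@dataclass
class RateFactorResults:
    """Results of the pooled multi-factor site-rate analysis."""

    mw: dict[str, MannWhitneyResult]
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame
    anova: AnovaResult | None
    cell_means: CellMeans
    n_sites: dict[str, int]
    alpha: float
    anova_error: str | None = None

    def summary(self) -> str:
        lines = ["Multi-factor site-rate analysis", "=" * 48]
        lines.append(f"tri-factor sites: {self.n_sites.get('tri_factor', 0)}")
        lines.append("")
        lines.append("Mann-Whitney contrasts (delta = median(second) - median(first)):")
        for name, r in self.mw.items():
            lines.append(
                f"  {name:28s} delta_median={r.delta_median:+.4f}  "
                f"U={r.u:.1f}  p={r.p:.3g}  (n={r.n_a}/{r.n_b}, {r.method})"
            )
        lines.append("")
        lines.append(
            f"Kruskal-Wallis over 8 cells: H={self.kruskal_h:.2f} "
            f"p={self.kruskal_p:.3g}"
        )
        n_sig = int((self.pairwise.significant == True).sum())  # noqa: E712 (NA-safe)
        lines.append(
            f"Pairwise mean-rank comparisons: {n_sig}/{len(self.pairwise)} "
            f"significant at alpha={self.alpha}"
        )
        lines.append("")
        if self.anova is not None:
            lines.append("Type-III factorial ANOVA (zero-sum contrasts):")
            tab = self.anova.table
            for term in tab.index:
                if term in ("Intercept", "Residual"):
                    continue
                row = tab.loc[term]
                lines.append(
                    f"  {term:22s} SS={row['sum_sq']:.3f}  F={row['F']:.2f}  "
                    f"p={row['PR(>F)']:.3g}"
                )
            lines.append(f"  adjusted R^2 = {self.anova.adj_r_squared:.4f}")
        else:
            lines.append(f"ANOVA not estimable: {self.anova_error}")
        lines.append("")
        lines.append("Cell means (disorder/ss/domain -> mean z-rate):")
        for _, row in self.cell_means.cells.iterrows():
            mz = "NA" if np.isnan(row.mean_z) else f"{row.mean_z:+.4f}"
            lines.append(
                f"  {row.disorder}/{row.ss}/{row.domain:8s} n={row.n:<7d} {mz}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        out = {
            "mann_whitney": {
                k: {
                    "U": r.u,
                    "p": r.p,
                    "delta_median": r.delta_median,
                    "n": [r.n_a, r.n_b],
                    "method": r.method,
                }
                for k, r in self.mw.items()
            },
            "kruskal_wallis": {"H": self.kruskal_h, "p": self.kruskal_p},
            "n_pairwise_significant": int((self.pairwise.significant == True).sum()),  # noqa: E712
            "anova": None
            if self.anova is None
            else {
                "adj_r_squared": self.anova.adj_r_squared,
                "terms": {
                    term: {
                        "sum_sq": float(self.anova.table.loc[term, "sum_sq"]),
                        "F": float(self.anova.table.loc[term, "F"]),
                        "p": float(self.anova.table.loc[term, "PR(>F)"]),
                    }
                    for term in self.anova.table.index
                    if term not in ("Intercept", "Residual")
                },
            },
            "cell_means": self.cell_means.cells.to_dict(orient="records"),
            "n_sites": self.n_sites,
            "alpha": self.alpha,
        }
        Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")


class RateFactorAnalysis:
    """Pooled multi-factor analysis of labeled site rates.

    Parameters
    ----------
    site_table : DataFrame
        One row per alignment column, with columns family_id, column_index,
        z_rate, disorder_label, ss_label, domain_label, tri_factor_complete
        (the joined output of labeling + rate inference).
    alpha : float
        Significance level for the post-hoc pairwise comparisons.
    """

    def __init__(self, site_table: pd.DataFrame, alpha: float = 0.05) -> None:
        required = {
            "family_id",
            "z_rate",
            "disorder_label",
            "ss_label",
            "domain_label",
            "tri_factor_complete",
        }
        missing = required - set(site_table.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        self.site_table = site_table
        self.alpha = alpha

    def _two_group(self, column: str, level_a: str, level_b: str):
        t = self.site_table
        a = t.loc[t[column] == level_a, "z_rate"].to_numpy()
        b = t.loc[t[column] == level_b, "z_rate"].to_numpy()
        return mann_whitney(a, b)

    def tri_factor_records(self) -> pd.DataFrame:
        t = self.site_table
        rec = t[t.tri_factor_complete].rename(
            columns={
                "disorder_label": "disorder",
                "ss_label": "ss",
                "domain_label": "domain",
            }
        )
        return rec[["family_id", "z_rate", "disorder", "ss", "domain"]]

    def fit(self) -> RateFactorResults:
        mw = {
            "disorder_minus_order": self._two_group(
                "disorder_label", "ordered", "disordered"
            ),
            "coil_minus_structure": self._two_group(
                "ss_label", "structured", "coil"
            ),
            "linker_minus_domain": self._two_group(
                "domain_label", "domain", "linker"
            ),
        }
        rec = self.tri_factor_records()
        groups = {}
        for d in FACTORS["disorder"]:
            for s in FACTORS["ss"]:
                for m in FACTORS["domain"]:
                    key = f"{d}/{s}/{m}"
                    groups[key] = rec.loc[
                        (rec.disorder == d) & (rec.ss == s) & (rec.domain == m),
                        "z_rate",
                    ].to_numpy()
        h, p = kruskal_wallis([g for g in groups.values() if g.size > 0])
        pairwise = pairwise_rank_comparisons(groups, alpha=self.alpha)
        anova = None
        anova_error = None
        try:
            anova = anova_type3(rec)
        except InestimableTermError as exc:
            anova_error = str(exc)
        means = cell_means(rec)
        n_sites = {
            "total": len(self.site_table),
            "tri_factor": len(rec),
            **{
                f"{lvl}": int((self.site_table[f"{fac}_label"] == lvl).sum())
                for fac, levels in FACTORS.items()
                for lvl in levels
            },
        }
        return RateFactorResults(
            mw=mw,
            kruskal_h=h,
            kruskal_p=p,
            pairwise=pairwise,
            anova=anova,
            cell_means=means,
            n_sites=n_sites,
            alpha=self.alpha,
            anova_error=anova_error,
        )
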