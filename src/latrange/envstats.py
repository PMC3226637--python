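"""Environmental correlates of gridded mean range size.

Per-cell mean latitudinal extent is related to nine environmental
predictors in four groups — mean climate condition (AMT, AP), climate
variability (TAR, TS, PS), ambient energy (NDVI, PET) and topography
(ALT, ALR) — via Pearson correlations (both with range size, r_m, and
with latitude, r_l), a collinearity screen, and per-group stepwise
Gaussian linear models. Spatial autocorrelation among cells is not
corrected; reports carry an explicit note to that effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from latrange.grid import EqualAreaGrid, RangeSizeMap
from latrange.ranges import ValidationError

ENV_VARS = ("AMT", "AP", "TAR", "TS", "PS", "NDVI", "PET", "ALT", "ALR")

VARIABLE_GROUPS: dict[str, tuple[str, ...]] = {
    "mean_climate": ("AMT", "AP"),
    "climate_variability": ("TAR", "TS", "PS"),
    "ambient_energy": ("NDVI", "PET"),
    "topography": ("ALT", "ALR"),
}

SPATIAL_NOTE = (
    "Cells are spatially autocorrelated; significance tests treat them as "
    "independent and are therefore anti-conservative."
)


def build_env_table(
    grid: EqualAreaGrid,
    range_map: RangeSizeMap,
    layers: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Assemble the per-cell analysis table.

    Rows are unmasked cells with a defined mean extent and no missing
    environmental value; columns are the nine predictors plus centroid
    latitude and ``mean_extent``. The retained row count is what model
    degrees of freedom are based on.
    """
    missing = [v for v in ENV_VARS if v not in layers]
    if missing:
        raise ValidationError(f"missing environmental layer(s): {', '.join(missing)}")
    _, lat = grid.centroids_geographic()
    cols = {v: np.asarray(layers[v], dtype=float).ravel() for v in ENV_VARS}
    cols["latitude"] = lat.ravel()
    cols["mean_extent"] = range_map.mean_extent.ravel()
    df = pd.DataFrame(cols)
    keep = ~grid.mask.ravel() & np.isfinite(range_map.mean_extent.ravel())
    df = df[keep].dropna().reset_index(drop=True)
    return df


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson r of each variable with mean range size (r_m) and latitude (r_l)."""

    table: pd.DataFrame  # variable, r_m, p_m, r_l, p_l
    n: int
    note: str = SPATIAL_NOTE

    def sign_pattern(self, which: str = "r_l") -> dict[str, int]:
        return {
            row["variable"]: int(np.sign(row[which]))
            for _, row in self.table.iterrows()
        }


def correlation_report(table: pd.DataFrame) -> CorrelationReport:
    """Pearson correlations of each predictor with mean extent and latitude.

    Constant columns yield undefined (NaN) correlations rather than an
    error; two-sided p-values otherwise.
    """
    if len(table) < 3:
        raise ValidationError("correlation report requires >= 3 rows")
    rows = []
    for v in ENV_VARS:
        if v not in table.columns:
            continue
        x = table[v].to_numpy(float)
        rec = {"variable": v}
        for suffix, target in (("m", "mean_extent"), ("l", "latitude")):
            y = table[target].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rec[f"r_{suffix}"], rec[f"p_{suffix}"] = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x, y)
                rec[f"r_{suffix}"], rec[f"p_{suffix}"] = float(r), float(p)
        rows.append(rec)
    return CorrelationReport(table=pd.DataFrame(rows), n=len(table))


def collinearity_screen(
    table: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Flag predictor pairs with |Pearson r| above ``threshold``.

    Informational: stepwise selection, not manual removal, handles the
    flagged redundancy.
    """
    cols = [v for v in ENV_VARS if v in table.columns]
    if len(cols) < 2:
        raise ValidationError("collinearity screen requires >= 2 predictors")
    corr = table[cols].corr()
    rows = [
        {"var_a": a, "var_b": b, "r": float(corr.loc[a, b])}
        for i, a in enumerate(cols)
        for b in cols[i + 1:]
        if abs(corr.loc[a, b]) > threshold
    ]
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])


@dataclass(frozen=True)
class GlmResult:
    """A stepwise-selected Gaussian linear model for one variable group."""

    group: str
    selected: tuple[str, ...]  # in entry order
    coef: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    cumulative_adj_r2: tuple[float, ...]  # adjusted R² after each entry step
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    df_model: int
    df_resid: int
    n: int
    step_log: tuple[str, ...] = field(default=(), compare=False)
    note: str = SPATIAL_NOTE

    @property
    def empty(self) -> bool:
        return not self.selected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.selected,
                "beta": [self.coef[v] for v in self.selected],
                "t": [self.t_values[v] for v in self.selected],
                "p": [self.p_values[v] for v in self.selected],
                "cumulative_adj_r2": self.cumulative_adj_r2,
            }
        )


def _fit_ols(table: pd.DataFrame, response: str, variables: list[str]):
    X = sm.add_constant(table[variables], has_constant="add") if variables else (
        pd.DataFrame({"const": np.ones(len(table))})
    )
    return sm.OLS(table[response], X).fit()


def stepwise_glm(
    table: pd.DataFrame,
    group: str,
    variables: tuple[str, ...] | None = None,
    response: str = "mean_extent",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    min_rows_per_var: int = 10,
    protected_entry: bool = True,
) -> GlmResult:
    """Bidirectional stepwise Gaussian linear model for one variable group.

    Forward steps add the candidate with the smallest partial-F p-value
    below the entry threshold; after each entry, backward steps drop any
    included variable whose p-value exceeds ``p_remove``. With no
    candidate ever entering, the result is an explicit empty model
    (R² = 0). The partial F for a single added variable equals the
    square of its t statistic, so entry tests use coefficient p-values
    directly.

    With ``protected_entry`` (the default) the per-step threshold is
    Šidák-adjusted for the number of candidates screened,
    1 − (1 − p_enter)^(1/k), so ``p_enter`` is the family-wise
    probability of admitting any variable into a model when the response
    is pure noise, independent of group size. Setting it False compares
    the best candidate's raw p-value against ``p_enter`` (the classic
    uncorrected rule).
    """
    if variables is None:
        if group not in VARIABLE_GROUPS:
            raise ValidationError(f"unknown variable group {group!r}")
        variables = VARIABLE_GROUPS[group]
    candidates = [v for v in variables]
    missing = [v for v in candidates if v not in table.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    if len(table) < min_rows_per_var * len(candidates):
        raise ValidationError(
            f"need >= {min_rows_per_var} rows per candidate "
            f"({min_rows_per_var * len(candidates)}), got {len(table)}"
        )

    included: list[str] = []
    cum_adj: list[float] = []
    log: list[str] = []
    while True:
        changed = False
        remaining = [v for v in candidates if v not in included]
        if remaining:
            pvals = {}
            for v in remaining:
                res = _fit_ols(table, response, included + [v])
                pvals[v] = float(res.pvalues[v])
            best = min(pvals, key=pvals.get)
            if protected_entry:
                thr = 1.0 - (1.0 - p_enter) ** (1.0 / len(remaining))
            else:
                thr = p_enter
            if pvals[best] < thr or thr >= 1.0:
                included.append(best)
                res = _fit_ols(table, response, included)
                cum_adj.append(float(res.rsquared_adj))
                log.append(f"enter {best} (p={pvals[best]:.3g})")
                changed = True
        if included:
            res = _fit_ols(table, response, included)
            worst = max(included, key=lambda v: float(res.pvalues[v]))
            if float(res.pvalues[worst]) > p_remove:
                idx = included.index(worst)
                included.remove(worst)
                del cum_adj[min(idx, len(cum_adj) - 1)]
                log.append(f"remove {worst} (p={float(res.pvalues[worst]):.3g})")
                # recompute the cumulative trace for the surviving order
                cum_adj = [
                    float(_fit_ols(table, response, included[: k + 1]).rsquared_adj)
                    for k in range(len(included))
                ]
                changed = True
        if not changed:
            break

    if not included:
        log.append("no candidate met the entry criterion; empty model")
        return GlmResult(
            group=group, selected=(), coef={}, t_values={}, p_values={},
            cumulative_adj_r2=(), r2=0.0, adj_r2=0.0,
            f_stat=float("nan"), f_p=float("nan"),
            df_model=0, df_resid=len(table) - 1, n=len(table),
            step_log=tuple(log),
        )
    res = _fit_ols(table, response, included)
    return GlmResult(
        group=group,
        selected=tuple(included),
        coef={v: float(res.params[v]) for v in included},
        t_values={v: float(res.tvalues[v]) for v in included},
        p_values={v: float(res.pvalues[v]) for v in included},
        cumulative_adj_r2=tuple(cum_adj),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n=int(res.nobs),
        step_log=tuple(log),
    )


def group_variance_explained(results: list[GlmResult]) -> pd.DataFrame:
    """Tabulate per-group overall R² and per-variable adjusted-R² increments."""
    if not results:
        raise ValidationError("no GLM results to summarise")
    rows = []
    for res in results:
        if res.empty:
            rows.append(
                {"group": res.group, "variable": None, "increment_adj_r2": 0.0,
                 "cumulative_adj_r2": 0.0, "group_r2": 0.0}
            )
            continue
        prev = 0.0
        for v, cum in zip(res.selected, res.cumulative_adj_r2):
            rows.append(
                {"group": res.group, "variable": v,
                 "increment_adj_r2": cum - prev, "cumulative_adj_r2": cum,
                 "group_r2": res.r2}
            )
            prev = cum
    return pd.DataFrame(rows)
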