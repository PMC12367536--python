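"""2030 nitrogen-surplus projection: named scenarios, BAU trend, reduction grid.

All intervention scenarios share one mechanism.  From the baseline window
(2015–2019) the mean input components are taken; fertilizer and manure are
scaled by ``(1 - r_fert)`` and ``(1 - r_man)`` while deposition and
fixation stay fixed (there is no policy lever on them); the 2030 output
follows the hyperbolic response at the chosen technology mode, and

    surplus_2030 = in_2030 - out_2030,
    reduction%   = 100 * (surplus_base - surplus_2030) / surplus_base.

The named policy story lines are fixed input-reduction pairs:

========  =======  ======  =========================================
scenario  r_fert   r_man   story
========  =======  ======  =========================================
GD-F      0.20     0       Green Deal fertilizer target
FAO-F     0.43     0       FAO towards-sustainability fertilizer cut
FAO-FM    0.43     0.04    FAO fertilizer + manure cut
BAF       0.20     0.10    better animal feed (lower N excretion)
LAP       0.20     0.20    less animal products (dietary shift)
========  =======  ======  =========================================

BAU instead extrapolates the historical surplus trend (1961–2019) with a
smooth spline GLM to 2030.  The bottom-up analysis evaluates the same
scenario arithmetic on the full 101 x 101 grid of reduction fractions and
extracts the 50%-reduction frontier, cross-checkable against the analytic
inversion of the response function.

NAT (natural-landscape) scopes are refused: the agricultural surplus
analysis excludes them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import budget, response
from .response import BASELINE_WINDOW, ResponseFit, TrendFit

logger = logging.getLogger(__name__)

#: (r_fert, r_man) for the five named intervention scenarios
NAMED_SCENARIOS: dict[str, tuple[float, float]] = {
    "GD-F": (0.20, 0.00),
    "FAO-F": (0.43, 0.00),
    "FAO-FM": (0.43, 0.04),
    "BAF": (0.20, 0.10),
    "LAP": (0.20, 0.20),
}

TARGET_REDUCTION_PCT = 50.0
#: Green Deal target zone: fertilizer cut of at least 20% ...
TARGET_MIN_R_FERT = 0.20


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    r_fert: float
    r_man: float
    tmp_mode: Literal["same", "improved"] = "same"
    bound: Literal["point", "low", "high"] = "point"
    baseline_window: tuple[int, int] = BASELINE_WINDOW

    def __post_init__(self):
        for r, what in ((self.r_fert, "r_fert"), (self.r_man, "r_man")):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{what} must be in [0, 1], got {r}")


def named_scenarios(
    tmp_mode: Literal["same", "improved"] = "same",
    bound: Literal["point", "low", "high"] = "point",
) -> list[ScenarioConfig]:
    return [
        ScenarioConfig(name=n, r_fert=rf, r_man=rm, tmp_mode=tmp_mode, bound=bound)
        for n, (rf, rm) in NAMED_SCENARIOS.items()
    ]


@dataclass(frozen=True)
class Baseline:
    """Baseline-window (default 2015–2019) mean budget of one scope."""

    scope: str
    window: tuple[int, int]
    in_fert: float
    in_man: float
    in_dep: float
    in_bnf: float
    total_out: float

    @property
    def total_in(self) -> float:
        return self.in_fert + self.in_man + self.in_dep + self.in_bnf

    @property
    def surplus(self) -> float:
        return self.total_in - self.total_out


@dataclass(frozen=True)
class ScenarioResult:
    scope: str
    name: str
    tmp_mode: str
    bound: str
    baseline_surplus: float
    in_2030: float
    out_2030: float
    surplus_2030: float
    surplus_reduction_pct: float
    output_reduction_pct: float
    target_met: bool


@dataclass(frozen=True)
class GridSurface:
    """Bottom-up reduction surfaces over the fertilizer x manure plane."""

    scope: str
    tmp_mode: str
    bound: str
    r_fert: np.ndarray               # (nf,)
    r_man: np.ndarray                # (nm,)
    surplus_reduction_pct: np.ndarray  # (nf, nm)
    output_reduction_pct: np.ndarray   # (nf, nm)
    #: minimal fertilizer reduction achieving 50% per manure level (NaN if never)
    contour_r_fert: np.ndarray       # (nm,)
    #: Green Deal desired space: r_fert >= 0.20 and reduction in [50, 100]%
    target_zone: np.ndarray          # (nf, nm) bool


def extract_baseline(
    series: pd.DataFrame,
    scope: str = "",
    window: tuple[int, int] = BASELINE_WINDOW,
) -> Baseline:
    """Window-mean input components and output of a per-year series."""
    sel = series[(series["year"] >= window[0]) & (series["year"] <= window[1])]
    if sel.empty:
        raise ValueError(f"no data in baseline window {window}")
    return Baseline(
        scope=scope,
        window=window,
        in_fert=float(sel["in_fert"].mean()),
        in_man=float(sel["in_man"].mean()),
        in_dep=float(sel["in_dep"].mean()),
        in_bnf=float(sel["in_bnf"].mean()),
        total_out=float(sel[["out_crops", "out_past"]].sum(axis=1).mean()),
    )


def _project(baseline: Baseline, c: float, r_fert, r_man):
    """Vectorized scenario arithmetic; returns (in, out, surplus) arrays."""
    in_2030 = (
        baseline.in_dep
        + baseline.in_bnf
        + (1.0 - np.asarray(r_fert, float)) * baseline.in_fert
        + (1.0 - np.asarray(r_man, float)) * baseline.in_man
    )
    out_2030 = c * in_2030 / (c + in_2030)
    return in_2030, out_2030, in_2030 - out_2030


def run_scenario(
    config: ScenarioConfig,
    baseline: Baseline,
    fit: ResponseFit,
    trend: TrendFit | None = None,
) -> ScenarioResult:
    """Project one scope under one named scenario configuration."""
    if baseline.scope == "NAT":
        raise ValueError("NAT typology is excluded from agricultural surplus analysis")
    if baseline.surplus <= 0:
        raise ValueError(f"baseline surplus non-positive for scope {baseline.scope!r}")
    c = response.apply_tmp_mode(fit.c, trend, config.tmp_mode, config.bound)
    in_2030, out_2030, surplus_2030 = _project(baseline, c, config.r_fert, config.r_man)
    red = 100.0 * (baseline.surplus - surplus_2030) / baseline.surplus
    out_red = 100.0 * (baseline.total_out - out_2030) / baseline.total_out
    return ScenarioResult(
        scope=baseline.scope,
        name=config.name,
        tmp_mode=config.tmp_mode,
        bound=config.bound,
        baseline_surplus=baseline.surplus,
        in_2030=float(in_2030),
        out_2030=float(out_2030),
        surplus_2030=float(surplus_2030),
        surplus_reduction_pct=float(red),
        output_reduction_pct=float(out_red),
        target_met=bool(red >= TARGET_REDUCTION_PCT),
    )


def run_grid(
    baseline: Baseline,
    fit: ResponseFit,
    trend: TrendFit | None = None,
    tmp_mode: Literal["same", "improved"] = "same",
    bound: Literal["point", "low", "high"] = "point",
    step: float = 0.01,
) -> GridSurface:
    """Bottom-up sweep of fertilizer x manure reductions (0..100%).

    The 50%-surplus-reduction frontier is interpolated linearly between
    bracketing grid cells along the fertilizer axis for every manure level.
    """
    if not 0.0 < step <= 0.5:
        raise ValueError(f"grid step must be in (0, 0.5], got {step}")
    if baseline.scope == "NAT":
        raise ValueError("NAT typology is excluded from agricultural surplus analysis")
    c = response.apply_tmp_mode(fit.c, trend, tmp_mode, bound)
    n = int(round(1.0 / step)) + 1
    # k/(n-1) by true division: grid values are exactly the representable
    # decimal fractions, so named-scenario cells match scalar runs bitwise
    r_fert = np.arange(n) / float(n - 1)
    r_man = np.arange(n) / float(n - 1)
    RF, RM = np.meshgrid(r_fert, r_man, indexing="ij")
    _, out_2030, surplus_2030 = _project(baseline, c, RF, RM)
    red = 100.0 * (baseline.surplus - surplus_2030) / baseline.surplus
    out_red = 100.0 * (baseline.total_out - out_2030) / baseline.total_out

    contour = np.full(n, np.nan)
    for j in range(n):
        col = red[:, j]
        if col[0] >= TARGET_REDUCTION_PCT:
            contour[j] = r_fert[0]
            continue
        above = np.nonzero(col >= TARGET_REDUCTION_PCT)[0]
        if len(above) == 0:
            continue
        i = above[0]
        f = (TARGET_REDUCTION_PCT - col[i - 1]) / (col[i] - col[i - 1])
        contour[j] = r_fert[i - 1] + f * (r_fert[i] - r_fert[i - 1])

    zone = (RF >= TARGET_MIN_R_FERT) & (red >= TARGET_REDUCTION_PCT) & (red <= 100.0)
    return GridSurface(
        scope=baseline.scope, tmp_mode=tmp_mode, bound=bound,
        r_fert=r_fert, r_man=r_man,
        surplus_reduction_pct=red, output_reduction_pct=out_red,
        contour_r_fert=contour, target_zone=zone,
    )


def analytic_contour_r_fert(
    baseline: Baseline,
    c: float,
    r_man: float = 0.0,
    target_pct: float = TARGET_REDUCTION_PCT,
) -> float:
    """Closed-form fertilizer reduction achieving the surplus target.

    Inverts the response for the input level whose surplus equals
    ``(1 - target/100) * baseline surplus`` and converts it to a
    fertilizer-axis fraction at fixed manure reduction.  NaN when even a
    100% fertilizer cut cannot reach the target.
    """
    s_target = (1.0 - target_pct / 100.0) * baseline.surplus
    in_req = response.required_input_for_surplus(c, s_target)
    fixed = baseline.in_dep + baseline.in_bnf + (1.0 - r_man) * baseline.in_man
    r = (fixed + baseline.in_fert - in_req) / baseline.in_fert
    if r > 1.0:
        return float("nan")
    return float(max(r, 0.0))


# --------------------------------------------------------------------------
# BAU: smooth-trend extrapolation of the historical surplus

def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline design matrix (linear beyond boundary knots)."""
    x = np.asarray(x, float)
    k = np.asarray(knots, float)
    K = len(k)

    def d(j):
        return (np.clip(x - k[j], 0, None) ** 3 - np.clip(x - k[-1], 0, None) ** 3) / (
            k[-1] - k[j]
        )

    cols = [x]
    for j in range(K - 2):
        cols.append(d(j) - d(K - 2))
    return np.column_stack(cols)


@dataclass
class BAUModel:
    """Fitted smooth surplus trend and its 2030 projection."""

    scope: str
    family: str
    years: np.ndarray
    fitted: np.ndarray
    knots: np.ndarray
    params: np.ndarray
    scale_factor: float
    projection_2030: float


def fit_bau(
    series: pd.DataFrame,
    scope: str = "",
    years: tuple[int, int] = (1961, 2019),
    family: Literal["negative-binomial", "gaussian"] = "negative-binomial",
    n_knots: int = 5,
    alpha: float = 1.0,
    count_scale: float = 10.0,
    projection_year: int = 2030,
) -> BAUModel:
    """Smooth-trend fit of annual surplus and extrapolation to 2030.

    The default fit is a GLM with negative-binomial family and log link
    (over-dispersion-tolerant, as the surplus record is), on a natural
    cubic spline basis of year; the basis is linear beyond the boundary
    knots, which defines the extrapolation.  Continuous surpluses are
    rescaled by ``count_scale`` into count-like magnitudes for the
    negative-binomial fit and scaled back for reporting.  A Gaussian
    identity-link fallback is available for series with non-positive
    values, where the log link is undefined.
    """
    sel = series[(series["year"] >= years[0]) & (series["year"] <= years[1])]
    sel = sel.sort_values("year")
    if sel.empty:
        raise ValueError(f"no surplus data in {years}")
    yr = sel["year"].to_numpy(float)
    surp = sel["surplus"].to_numpy(float)
    knots = np.quantile(yr, np.linspace(0.0, 1.0, n_knots))
    X = sm.add_constant(_natural_spline_basis(yr, knots))
    Xp = sm.add_constant(
        _natural_spline_basis(np.array([float(projection_year)]), knots),
        has_constant="add",
    )
    if family == "negative-binomial":
        if (surp <= 0).any():
            raise ValueError(
                "non-positive surplus values: the log link is undefined; "
                "refit with family='gaussian' (identity link) or offset the series"
            )
        fam = sm.families.NegativeBinomial(alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-integer endog is deliberate
            res = sm.GLM(surp * count_scale, X, family=fam).fit()
        fitted = res.fittedvalues / count_scale
        proj = float(res.predict(Xp)[0]) / count_scale
    elif family == "gaussian":
        res = sm.OLS(surp, X).fit()
        fitted = res.fittedvalues
        proj = float(res.predict(Xp)[0])
        count_scale = 1.0
    else:
        raise ValueError(f"unknown family {family!r}")
    return BAUModel(
        scope=scope, family=family, years=yr, fitted=np.asarray(fitted),
        knots=knots, params=np.asarray(res.params),
        scale_factor=count_scale, projection_2030=proj,
    )


def run_bau(
    series: pd.DataFrame,
    baseline: Baseline,
    scope: str = "",
    **kwargs,
) -> ScenarioResult:
    """BAU scenario: trend-extrapolated 2030 surplus vs the baseline mean.

    An increasing trend yields a negative reduction (surplus growth).
    Output and input columns are not projected by the trend model, so the
    output-reduction field is NaN for BAU.
    """
    model = fit_bau(series, scope=scope, **kwargs)
    red = 100.0 * (baseline.surplus - model.projection_2030) / baseline.surplus
    return ScenarioResult(
        scope=scope or baseline.scope,
        name="BAU",
        tmp_mode="trend",
        bound="point",
        baseline_surplus=baseline.surplus,
        in_2030=float("nan"),
        out_2030=float("nan"),
        surplus_2030=model.projection_2030,
        surplus_reduction_pct=float(red),
        output_reduction_pct=float("nan"),
        target_met=bool(red >= TARGET_REDUCTION_PCT),
    )


# --------------------------------------------------------------------------
# scope orchestration

def scope_series(
    records: pd.DataFrame,
    scope: str,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Member-mean agricultural per-year series per scope unit."""
    agg = budget.aggregate(records, scope=scope, groups=groups, sector="agricultural")
    mm = budget.member_mean(agg)
    mm = budget.compute_surplus(mm)
    return {sid: g.sort_values("year") for sid, g in mm.groupby("scope_id")}


def run_all_scenarios(
    records: pd.DataFrame,
    scope: str,
    groups: Mapping[str, str] | pd.Series | None = None,
    tmp_modes: Sequence[str] = ("same", "improved"),
    bounds: Sequence[str] = ("point", "low", "high"),
    include_bau: bool = True,
    baseline_window: tuple[int, int] = BASELINE_WINDOW,
) -> pd.DataFrame:
    """Named scenarios (and BAU) for every unit of a scope, as a flat table.

    Units with an undefined response (output >= input in the baseline
    window) or with the NAT label are excluded with a warning.  Results are
    computed on the member-mean series; ensemble bands are the business of
    :func:`ensemble_propagate`.
    """
    per_scope = scope_series(records, scope, groups)
    rows = []
    for sid, series in per_scope.items():
        if sid == "NAT":
            logger.info("skipping NAT scope (natural landscapes)")
            continue
        baseline = extract_baseline(series, scope=sid, window=baseline_window)
        try:
            fit = response.fit_window(series, baseline_window, scope=sid)
        except ValueError as exc:
            warnings.warn(f"excluding scope {sid!r}: {exc}", stacklevel=2)
            continue
        trend = response.fit_trend_windows(series, scope=sid)
        if include_bau:
            rows.append(run_bau(series, baseline, scope=sid).__dict__)
        for mode in tmp_modes:
            mode_bounds = bounds if mode == "improved" else ("point",)
            for b in mode_bounds:
                for cfg in named_scenarios(tmp_mode=mode, bound=b):
                    rows.append(run_scenario(cfg, baseline, fit, trend).__dict__)
    return pd.DataFrame(rows)


def country_breakdown(
    records: pd.DataFrame,
    tmp_modes: Sequence[str] = ("same", "improved"),
    baseline_window: tuple[int, int] = BASELINE_WINDOW,
) -> pd.DataFrame:
    """Per-country scenario reductions with the >= 50% flag.

    Response and trend are fitted on the country's own area-weighted
    aggregate.  Countries with an undefined coefficient are excluded with
    a warning (standard behaviour of :func:`run_all_scenarios`).
    """
    return run_all_scenarios(
        records, scope="country", tmp_modes=tmp_modes,
        include_bau=False, baseline_window=baseline_window,
    )


def ensemble_propagate(
    records: pd.DataFrame,
    config: ScenarioConfig,
    scope: str,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Min–max band of scenario reductions over the 16 ensemble members.

    The full pipeline (baseline, response fit, trend when needed, scenario)
    is rerun per member; the headline row (member_id = 0) is the result on
    the member-mean series, which the band must contain.  Member-level
    failures are reported as warnings, not silently dropped.
    """
    agg = budget.aggregate(records, scope=scope, groups=groups, sector="agricultural")
    agg = budget.compute_surplus(agg)
    rows = []
    units = [u for u in agg["scope_id"].unique() if u != "NAT"]
    for sid in units:
        sub = agg[agg["scope_id"] == sid]
        results = {}
        for member, g in list(sub.groupby("member_id")) + [(0, budget.member_mean(sub))]:
            g = budget.compute_surplus(g).sort_values("year")
            try:
                baseline = extract_baseline(g, scope=sid, window=config.baseline_window)
                fit = response.fit_window(g, config.baseline_window, scope=sid)
                trend = (
                    response.fit_trend_windows(g, scope=sid)
                    if config.tmp_mode == "improved"
                    else None
                )
                results[member] = run_scenario(config, baseline, fit, trend)
            except ValueError as exc:
                warnings.warn(f"member {member} failed for scope {sid!r}: {exc}",
                              stacklevel=2)
        member_reds = [r.surplus_reduction_pct for m, r in results.items() if m != 0]
        head = results.get(0)
        rows.append(
            {
                "scope": sid,
                "name": config.name,
                "tmp_mode": config.tmp_mode,
                "bound": config.bound,
                "headline_reduction_pct": head.surplus_reduction_pct if head else np.nan,
                "mean_reduction_pct": float(np.mean(member_reds)) if member_reds else np.nan,
                "min_reduction_pct": float(np.min(member_reds)) if member_reds else np.nan,
                "max_reduction_pct": float(np.max(member_reds)) if member_reds else np.nan,
                "n_members": len(member_reds),
            }
        )
    return pd.DataFrame(rows)
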