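"""One-parameter hyperbolic yield response and technology-trend extrapolation.

The N output (harvest removal) response to N input is modelled as the
saturating hyperbola

    Out = c * In / (c + In)

whose single coefficient ``c`` (kgN ha^-1 yr^-1) is the asymptotic maximum
achievable N output and parameterizes the prevailing technological and
management practices (TMPs): precision fertilization, inhibitors, improved
cultivars all move ``c`` upward.  Given window-mean input and output the
coefficient has the exact closed form ``c = In*Out/(In - Out)``.

Two 2030 technology modes are supported:

* ``same``     — TMPs frozen at the baseline window (2015–2019): c = c_baseline;
* ``improved`` — TMPs keep improving at the historically observed pace:
  ``c(2030) = c_baseline * (1 + dc_tmp)`` where ``dc_tmp`` comes from an
  ordinary-least-squares line through the eight window estimates of ``c``
  (1981–1985, …, 2016–2019) extrapolated to 2030, with a 95% mean-response
  confidence interval (t distribution, df = 6) carried as low/high bounds.

The surplus implied by the response, ``S(In) = In - Out = In^2/(c + In)``,
is strictly increasing in ``In``, so the input level required to hit a
surplus target has the closed-form positive root
``In = (S + sqrt(S^2 + 4cS)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: c-trend estimation windows (inclusive), seven 5-year plus one 4-year
TREND_WINDOWS: tuple[tuple[int, int], ...] = (
    (1981, 1985), (1986, 1990), (1991, 1995), (1996, 2000),
    (2001, 2005), (2006, 2010), (2011, 2015), (2016, 2019),
)
BASELINE_WINDOW = (2015, 2019)
PROJECTION_YEAR = 2030


@dataclass(frozen=True)
class ResponseFit:
    """Hyperbolic coefficient for one scope and averaging window."""

    scope: str
    window: tuple[int, int]
    mean_in: float
    mean_out: float
    c: float


@dataclass(frozen=True)
class TrendFit:
    """OLS line through windowed c estimates, extrapolated to 2030."""

    scope: str
    midpoints: tuple[float, ...]
    c_values: tuple[float, ...]
    slope: float
    intercept: float
    c_2030: float
    c_low: float
    c_high: float

    def c_at_bound(self, bound: Literal["point", "low", "high"]) -> float:
        return {"point": self.c_2030, "low": self.c_low, "high": self.c_high}[bound]


def fit_c(mean_in: float, mean_out: float) -> float:
    """Closed-form coefficient from window-mean input and output."""
    if mean_out <= 0:
        raise ValueError(f"mean output must be positive, got {mean_out}")
    if mean_out >= mean_in:
        raise ValueError(
            f"response undefined: mean output {mean_out} >= mean input {mean_in} "
            "(non-positive surplus)"
        )
    return mean_in * mean_out / (mean_in - mean_out)


def predict_output(c: float, in_level):
    """Hyperbolic output at a given input level (vectorized over inputs)."""
    if c <= 0:
        raise ValueError(f"coefficient c must be positive, got {c}")
    in_level = np.asarray(in_level, dtype=float)
    if (in_level < 0).any():
        raise ValueError("negative N input")
    out = c * in_level / (c + in_level)
    return float(out) if out.ndim == 0 else out


def surplus_at(c: float, in_level):
    """Implied surplus S(In) = In^2 / (c + In)."""
    in_level = np.asarray(in_level, dtype=float)
    s = in_level * in_level / (c + in_level)
    return float(s) if s.ndim == 0 else s


def required_input_for_surplus(c: float, target_surplus: float) -> float:
    """Input level whose hyperbolic-response surplus equals the target.

    Positive root of ``In^2 - S*In - c*S = 0``.
    """
    if c <= 0:
        raise ValueError(f"coefficient c must be positive, got {c}")
    if target_surplus <= 0:
        raise ValueError(f"target surplus must be positive, got {target_surplus}")
    s = float(target_surplus)
    return (s + np.sqrt(s * s + 4.0 * c * s)) / 2.0


def fit_window(
    series: pd.DataFrame,
    window: tuple[int, int],
    scope: str = "",
    method: Literal["window-mean", "annual-lsq"] = "window-mean",
) -> ResponseFit:
    """Fit c for one scope from a per-year series with total_in/total_out.

    ``window-mean`` (default) uses the closed form on window means;
    ``annual-lsq`` least-squares fits the hyperbola to the annual points
    inside the window instead.
    """
    sel = series[(series["year"] >= window[0]) & (series["year"] <= window[1])]
    if sel.empty:
        raise ValueError(f"no data in window {window}")
    mean_in = float(sel["total_in"].mean())
    mean_out = float(sel["total_out"].mean())
    c = fit_c(mean_in, mean_out)
    if method == "annual-lsq":
        import scipy.optimize

        x = sel["total_in"].to_numpy(float)
        y = sel["total_out"].to_numpy(float)
        (c,), _ = scipy.optimize.curve_fit(
            lambda xx, cc: cc * xx / (cc + xx), x, y, p0=[c]
        )
        c = float(c)
    elif method != "window-mean":
        raise ValueError(f"unknown fit method {method!r}")
    return ResponseFit(scope=scope, window=window, mean_in=mean_in, mean_out=mean_out, c=c)


def fit_c_trend(fits: Sequence[ResponseFit], year: int = PROJECTION_YEAR) -> TrendFit:
    """OLS of c on window-midpoint year with a 95% mean-response interval.

    Requires exactly the eight trend windows in increasing order; the
    midpoint of a window is the arithmetic mean of its endpoints.
    """
    if len(fits) != len(TREND_WINDOWS):
        raise ValueError(f"need {len(TREND_WINDOWS)} window fits, got {len(fits)}")
    windows = [f.window for f in fits]
    if windows != sorted(windows) or len(set(windows)) != len(windows):
        raise ValueError("windows must be strictly increasing")
    x = np.array([(w[0] + w[1]) / 2.0 for w in windows])
    y = np.array([f.c for f in fits])
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    pred = ols.get_prediction(np.array([[1.0, float(year)]]))
    frame = pred.summary_frame(alpha=0.05)
    c_2030 = float(frame["mean"].iloc[0])
    c_low = float(frame["mean_ci_lower"].iloc[0])
    c_high = float(frame["mean_ci_upper"].iloc[0])
    if ols.ssr < 1e-20:  # exact line: zero-width interval, not NaN
        c_low = c_high = c_2030
    return TrendFit(
        scope=fits[0].scope,
        midpoints=tuple(x),
        c_values=tuple(y),
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        c_2030=c_2030,
        c_low=c_low,
        c_high=c_high,
    )


def apply_tmp_mode(
    c_baseline: float,
    trend: TrendFit | None,
    mode: Literal["same", "improved"],
    bound: Literal["point", "low", "high"] = "point",
) -> float:
    """2030 coefficient under a technology mode.

    ``same`` returns the baseline coefficient; ``improved`` scales it by
    ``1 + dc_tmp`` where ``dc_tmp = c_extrapolated/c_baseline - 1`` at the
    requested interval bound.  The baseline coefficient comes from the
    2015–2019 window even though the last trend window is 2016–2019.
    """
    if mode == "same":
        return c_baseline
    if mode != "improved":
        raise ValueError(f"unknown TMP mode {mode!r}")
    if trend is None:
        raise ValueError("mode='improved' requires a TrendFit")
    dc_tmp = trend.c_at_bound(bound) / c_baseline - 1.0
    c = c_baseline * (1.0 + dc_tmp)
    if c <= 0:
        raise ValueError(
            f"improved-TMP coefficient non-positive (dc_tmp={dc_tmp:.3f}); "
            "trend extrapolation collapsed the response"
        )
    return c


def delta_c_tmp(trend: TrendFit, c_baseline: float,
                bound: Literal["point", "low", "high"] = "point") -> float:
    """Relative technology advancement by 2030 vs the baseline-window c."""
    return trend.c_at_bound(bound) / c_baseline - 1.0


def fit_trend_windows(
    series: pd.DataFrame,
    scope: str = "",
    windows: Sequence[tuple[int, int]] = TREND_WINDOWS,
    method: Literal["window-mean", "annual-lsq"] = "window-mean",
) -> TrendFit:
    """Convenience: window fits over the historical record, then the trend."""
    fits = [fit_window(series, w, scope=scope, method=method) for w in windows]
    return fit_c_trend(fits)


def fits_table(fits: Sequence[ResponseFit]) -> pd.DataFrame:
    """Flat table of window fits (scope, window, means, c)."""
    return pd.DataFrame(
        {
            "scope": [f.scope for f in fits],
            "window_start": [f.window[0] for f in fits],
            "window_end": [f.window[1] for f in fits],
            "mean_in": [f.mean_in for f in fits],
            "mean_out": [f.mean_out for f in fits],
            "c": [f.c for f in fits],
        }
    )
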