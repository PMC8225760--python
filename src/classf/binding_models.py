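"""BRET assay arithmetic, saturation/dose-response models and nested-model
selection.

Exact-arithmetic transforms
    net BRET (control-well subtraction), %ΔBRET and its vehicle
    correction, surface-expression normalization, dual-reporter fold
    change.

Curve models (unweighted least squares on untransformed responses)
    * 3-parameter saturation: y = y0 + A·C / (Kd + C)
    * 4-parameter saturation: y = y0 + A·C^h / (Kd^h + C^h)
    * bell (biphasic rise-then-fall over x = log10 C): sum of two
      logistics with midpoint constraint m1 ≤ m2
    * titration: straight line vs one-phase association
      y = Y0 + (P − Y0)(1 − e^{−K·x})

Dissociation constants are parameterized as log10 Kd; affinities are
reported as pKd = −log10(Kd / M) with the asymptotic standard error of
the fit. Nested models are compared with the extra-sum-of-squares
F-test at α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "net_bret",
    "delta_bret_percent",
    "vehicle_correct",
    "normalize_by_expression",
    "reporter_ratio",
    "saturation_response",
    "bell_response",
    "fit_saturation",
    "fit_bell",
    "fit_titration",
    "extra_ss_f_test",
]


# ---------------------------------------------------------------------------
# Exact plate arithmetic
# ---------------------------------------------------------------------------

def net_bret(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean raw BRET ratio of acceptor-free control wells from
    all labelled wells; control rows are dropped from the output."""
    controls = table[table["is_control"]]
    if controls.empty:
        raise ValueError("net BRET requires at least one control row")
    baseline = controls["response"].mean()
    out = table[~table["is_control"]].copy()
    out["response"] = out["response"] - baseline
    return out


def delta_bret_percent(stimulated, basal):
    """%ΔBRET = (stimulated − basal) / basal × 100."""
    basal = np.asarray(basal, dtype=float)
    if np.any(basal <= 0):
        raise ValueError("basal BRET ratio must be positive")
    return (np.asarray(stimulated, dtype=float) - basal) / basal * 100.0


def vehicle_correct(delta_percent, vehicle_deltas):
    """Vehicle-corrected %ΔBRET: subtract the mean vehicle-well %ΔBRET."""
    return np.asarray(delta_percent, dtype=float) - float(np.mean(vehicle_deltas))


def normalize_by_expression(
    table: pd.DataFrame, reference_condition: str | None = None
) -> pd.DataFrame:
    """Divide responses by each condition's surface expression relative to
    the reference condition (first condition by appearance if not given)."""
    if "surface_expression" not in table.columns:
        raise ValueError("table lacks a surface_expression column")
    expr = table.groupby("condition", sort=False)["surface_expression"].mean()
    if (expr <= 0).any():
        raise ValueError("surface expression must be positive for every condition")
    if reference_condition is None:
        reference_condition = table["condition"].iloc[0]
    ref = expr[reference_condition]
    out = table.copy()
    rel = out["condition"].map(expr) / ref
    out["response"] = out["response"] / rel
    return out


def reporter_ratio(firefly, renilla, vehicle_mean_ratio):
    """Dual-luciferase fold change: (firefly / renilla) ÷ vehicle mean ratio."""
    renilla = np.asarray(renilla, dtype=float)
    if np.any(renilla <= 0) or vehicle_mean_ratio <= 0:
        raise ValueError("renilla signal and vehicle mean ratio must be positive")
    return (np.asarray(firefly, dtype=float) / renilla) / vehicle_mean_ratio


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def saturation_response(conc, y0, amplitude, log_kd, hill=1.0):
    """Hyperbolic / Hill saturation curve over molar concentration."""
    conc = np.asarray(conc, dtype=float)
    kd = 10.0 ** log_kd
    c_h = conc ** hill
    return y0 + amplitude * c_h / (kd ** hill + c_h)


def bell_response(x, p0, p1, p2, m1, m2, h1=1.0, h2=1.0):
    """Biphasic rise-then-fall over x = log10 concentration.

    Baseline p0 rises to plateau p1 with midpoint m1, then falls to p2
    with midpoint m2 (m1 ≤ m2 for an interior maximum).
    """
    x = np.asarray(x, dtype=float)
    rise = (p1 - p0) / (1.0 + 10.0 ** ((m1 - x) * h1))
    fall = (p2 - p1) / (1.0 + 10.0 ** (-(x - m2) * h2))
    return p0 + rise + fall


@dataclass
class FitResult:
    """A least-squares fit: parameters, asymptotic SEs, goodness of fit."""

    model: str
    params: dict[str, float]
    se: dict[str, float]
    ss: float
    df: int
    n_obs: int
    converged: bool
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError(f"{self.model}: non-positive residual degrees of freedom")
        if self.ss < 0:
            raise ValueError(f"{self.model}: negative residual sum of squares")


def _xy(table: pd.DataFrame, xcol: str) -> tuple[np.ndarray, np.ndarray]:
    rows = table[~table.get("is_control", False)] if "is_control" in table.columns else table
    rows = rows.dropna(subset=[xcol])
    return rows[xcol].to_numpy(dtype=float), rows["response"].to_numpy(dtype=float)


def _ls_fit(residual_fn, x0, bounds, names, y, n_extra_starts=0, jitter_rng=None):
    """Bounded least squares with optional jittered restarts; returns the
    best solution, its covariance-based SEs and convergence flag."""
    best = None
    starts = [np.asarray(x0, dtype=float)]
    if n_extra_starts and jitter_rng is not None:
        lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
        for _ in range(n_extra_starts):
            jitter = starts[0] * (1 + 0.2 * jitter_rng.standard_normal(len(starts[0])))
            starts.append(np.clip(jitter, lo + 1e-9, hi - 1e-9))
    for s in starts:
        try:
            res = optimize.least_squares(residual_fn, s, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("least-squares fit failed from every start")
    ss = float(2 * best.cost)
    n = len(y)
    p = len(best.x)
    df = n - p
    se = np.full(p, np.nan)
    if df > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (ss / df)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    params = dict(zip(names, (float(v) for v in best.x)))
    ses = dict(zip(names, (float(v) for v in se)))
    return params, ses, ss, df, bool(best.success)


def fit_saturation(table: pd.DataFrame, n_params: int = 3) -> FitResult:
    """Fit a 3- or 4-parameter saturation binding model.

    The 3-parameter model is a hyperbola with baseline (y0, amplitude,
    Kd); the 4-parameter model adds a Hill slope. log10 Kd is the fitted
    parameter; the result carries pKd = −log10 Kd with its asymptotic SE.
    Multi-start initialization places log10 Kd at each quartile of the
    observed log-concentrations. Fits whose Kd falls outside the
    concentration range by more than 100-fold are flagged.
    """
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    conc, y = _xy(table, "concentration_M")
    if len(np.unique(conc)) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} distinct concentrations for a "
            f"{n_params}-parameter fit"
        )
    logc = np.log10(conc)
    y0_init = float(np.min(y))
    amp_init = float(np.ptp(y)) or 1.0
    lo_lkd, hi_lkd = logc.min() - 3.0, logc.max() + 3.0

    if n_params == 3:
        names = ["y0", "amplitude", "log_kd"]
        bounds = ([-np.inf, 0.0, lo_lkd], [np.inf, np.inf, hi_lkd])

        def model(theta):
            return saturation_response(conc, theta[0], theta[1], theta[2]) - y
    else:
        names = ["y0", "amplitude", "log_kd", "hill"]
        bounds = ([-np.inf, 0.0, lo_lkd, 0.1], [np.inf, np.inf, hi_lkd, 10.0])

        def model(theta):
            return saturation_response(conc, theta[0], theta[1], theta[2], theta[3]) - y

    best = None
    for q in (0.25, 0.5, 0.75):
        lkd0 = float(np.quantile(logc, q))
        x0 = [y0_init, amp_init, lkd0] + ([1.0] if n_params == 4 else [])
        fit = _ls_fit(model, x0, bounds, names, y)
        if best is None or fit[2] < best[2]:
            best = fit
    params, se, ss, df, converged = best

    pkd = -params["log_kd"]
    flags = {"pKd": pkd, "pKd_se": se["log_kd"], "kd": 10.0 ** params["log_kd"]}
    if params["log_kd"] < logc.min() - 2.0 or params["log_kd"] > logc.max() + 2.0:
        flags["kd_outside_range"] = True
    return FitResult(
        f"saturation_{n_params}p", params, se, ss, df, len(y), converged, flags
    )


def fit_bell(table: pd.DataFrame) -> FitResult:
    """Fit the biphasic (bell-shaped) dose-response model over
    x = log10 concentration, with the rise midpoint constrained to lie
    at or below the fall midpoint (m2 = m1 + gap, gap ≥ 0).

    Monotone data collapse the fall phase (amplitude ≈ 0); the result is
    then flagged ``degenerate_fall`` with a wide confidence interval.
    """
    conc, y = _xy(table, "concentration_M")
    if len(np.unique(conc)) < 7:
        raise ValueError("bell fit needs at least 7 distinct concentrations")
    x = np.log10(conc)
    order = np.argsort(x)
    xs, ys = x[order], y[order]

    p0_init = float(ys[0])
    peak_idx = int(np.argmax(ys))
    p1_init = float(ys[peak_idx])
    p2_init = float(ys[-1])
    m1_init = float(xs[max(peak_idx // 2, 0)])
    m2_init = float(xs[min((peak_idx + len(xs) - 1) // 2, len(xs) - 1)])
    gap_init = max(m2_init - m1_init, 0.1)

    names = ["p0", "p1", "p2", "m1", "gap", "h1", "h2"]
    lo = [-np.inf, -np.inf, -np.inf, xs.min() - 3, 0.0, 0.1, 0.1]
    hi = [np.inf, np.inf, np.inf, xs.max() + 3, (xs.max() - xs.min()) + 6, 10.0, 10.0]

    def model(theta):
        p0, p1, p2, m1, gap, h1, h2 = theta
        return bell_response(xs, p0, p1, p2, m1, m1 + gap, h1, h2) - ys

    rng = np.random.default_rng(0)
    params, se, ss, df, converged = _ls_fit(
        model,
        [p0_init, p1_init, p2_init, m1_init, gap_init, 1.0, 1.0],
        (lo, hi),
        names,
        ys,
        n_extra_starts=4,
        jitter_rng=rng,
    )
    params["m2"] = params["m1"] + params["gap"]
    fall_amp = params["p2"] - params["p1"]
    flags = {"fall_amplitude": fall_amp}
    scale = float(np.ptp(ys)) or 1.0
    if abs(fall_amp) < 0.02 * scale or (np.isfinite(se["p2"]) and se["p2"] > abs(fall_amp)):
        flags["degenerate_fall"] = True
    return FitResult("bell", params, se, ss, df, len(ys), converged, flags)


def _fit_linear(x: np.ndarray, y: np.ndarray) -> FitResult:
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss = float(resid @ resid)
    df = len(y) - 2
    sigma2 = ss / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        "linear",
        {"intercept": float(coef[0]), "slope": float(coef[1])},
        {"intercept": float(se[0]), "slope": float(se[1])},
        ss,
        df,
        len(y),
        True,
    )


def _one_phase_profile_ss(k: float, x: np.ndarray, y: np.ndarray):
    """For fixed rate K the model y0 + (P - y0)(1 - e^{-Kx}) is linear in
    (y0, P) with basis (e^{-Kx}, 1 - e^{-Kx}); solve it in closed form."""
    e = np.exp(-k * x)
    A = np.column_stack([e, 1.0 - e])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def _fit_one_phase(x: np.ndarray, y: np.ndarray) -> FitResult:
    """One-phase association fit by variable projection: profile the
    residual SS over the rate constant (log grid + Brent refinement),
    solving the conditionally linear (y0, plateau) pair exactly.

    The rate is not sign-constrained (negative K curves the other way);
    the K → 0 end of the grid reproduces a straight line, so the
    association fit never loses to the nested linear model."""
    xscale = float(np.max(x) - np.min(x)) or 1.0
    pos = np.logspace(math.log10(1e-7 / xscale), math.log10(30.0 / xscale), 50)
    k_grid = np.concatenate([-pos[::-1], pos])
    ss_grid = np.array([_one_phase_profile_ss(k, x, y)[0] for k in k_grid])
    i0 = int(np.argmin(ss_grid))
    lo = k_grid[max(i0 - 1, 0)]
    hi = k_grid[min(i0 + 1, len(k_grid) - 1)]
    res = optimize.minimize_scalar(
        lambda k: _one_phase_profile_ss(k, x, y)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 / xscale},
    )
    k_best = float(res.x) if res.fun <= ss_grid[i0] else float(k_grid[i0])
    ss, coef = _one_phase_profile_ss(k_best, x, y)
    y0, plateau = float(coef[0]), float(coef[1])

    n = len(y)
    df = n - 3
    e = np.exp(-k_best * x)
    jac = np.column_stack([e, 1.0 - e, (plateau - y0) * x * e])
    se = np.full(3, np.nan)
    if df > 0:
        try:
            cov = np.linalg.inv(jac.T @ jac) * (ss / df)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        "one_phase_association",
        {"y0": y0, "plateau": plateau, "k": k_best},
        dict(zip(["y0", "plateau", "k"], (float(v) for v in se))),
        ss, df, n, True,
    )


def extra_ss_f_test(simple: FitResult, complex: FitResult, alpha: float = 0.05):
    """Extra-sum-of-squares F-test between nested fits.

    F = ((SS_s − SS_c)/(df_s − df_c)) / (SS_c/df_c), p from
    F(df_s − df_c, df_c); the complex model is selected iff p < alpha.
    If the complex fit has the larger SS (numerically possible with
    bounded optimization), the simple model is selected with F = 0.
    """
    if complex.df >= simple.df:
        raise ValueError("models are not nested: complex fit must have fewer df")
    if complex.ss >= simple.ss:
        return 0.0, 1.0, simple
    d_df = simple.df - complex.df
    if complex.ss == 0.0:
        return np.inf, 0.0, complex
    f_stat = ((simple.ss - complex.ss) / d_df) / (complex.ss / complex.df)
    p = float(stats.f.sf(f_stat, d_df, complex.df))
    return float(f_stat), p, (complex if p < alpha else simple)


def fit_titration(table: pd.DataFrame, alpha: float = 0.05):
    """Fit a BRET titration to both a straight line and a one-phase
    association and select the preferred model by extra-sum-of-squares
    F-test.

    Returns ``(linear fit, association fit, selected fit)``; the
    association fit carries the plateau parameter when selected.
    """
    x, y = _xy(table, "acceptor_dose")
    if len(x) < 4:
        raise ValueError("titration fit needs at least 4 points")
    lin = _fit_linear(x, y)
    assoc = _fit_one_phase(x, y)
    f_stat, p, selected = extra_ss_f_test(lin, assoc, alpha=alpha)
    selected.flags["f_stat"] = f_stat
    selected.flags["p_value"] = p
    if selected is assoc:
        selected.flags["plateau"] = assoc.params["plateau"]
    return lin, assoc, selected
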