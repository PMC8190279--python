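"""Nonlinear least-squares estimation of (FLUOR, ke, Q) per compound.

One parameter set per compound is fitted jointly across all available
routes: the closed-form model covers both limbs (an injection regimen
zeroes M, an immersion regimen zeroes the dose), and fitting them
together is what makes the three parameters identifiable — the injection
decay pins ``fluor·Dose`` and ``ke``, the immersion uptake then pins
``Q``.  Parameters are optimized on the log scale, which enforces
positivity and makes the problem well scaled; the optimizer is
Levenberg–Marquardt (damped Gauss–Newton).  Standard errors come from the
Jacobian at the optimum and are mapped to the natural scale with the
delta method.

Because injection depots self-quench shortly after microinjection, the
early injection observations can sit systematically below the model.
Two censoring strategies are provided: an automated standardized-residual
rule (iterated fit → flag rounds; the censored set only grows), and a
fixed time-window rule that drops injection-route observations before a
cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_pk import ExposureRegimen, PKParameters, Route, amount_at_time
from .synthetic_data import Dataset

__all__ = [
    "FitOptions",
    "PKFit",
    "IdentifiabilityWarning",
    "initial_estimates",
    "fit_pk",
    "censor_outliers",
    "censor_window",
    "fit_with_censoring",
    "half_life",
    "residual_diagnostics",
    "fits_to_frame",
]


class IdentifiabilityWarning(UserWarning):
    """Raised when the data cannot separate the fitted parameters."""


@dataclass(frozen=True)
class FitOptions:
    max_iterations: int = 200
    relative_tolerance: float = 1e-8
    censor_threshold: float = 2.5       # standardized-residual multiple
    max_censor_rounds: int = 3
    damping: float = 1e-3               # initial Levenberg lambda
    censor_mode: str = "residual"       # "residual" | "window"
    window_cutoff_h: float = 1.0        # injection points before this are dropped in window mode

    def __post_init__(self) -> None:
        if self.censor_threshold <= 0 or self.max_iterations <= 0:
            raise ValueError("thresholds and iteration caps must be positive")
        if self.censor_mode not in ("residual", "window"):
            raise ValueError(f"unknown censor mode {self.censor_mode!r}")


@dataclass(frozen=True)
class PKFit:
    """Result of one per-compound fit."""

    compound: str
    params: PKParameters
    half_life_h: float
    se: dict[str, float]                 # natural-scale SEs for fluor, ke, q
    residual_standard_error: float       # RFU scale, sqrt(SSE/(n-3))
    n_used: int
    n_censored: int
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        expected = half_life(self.params.ke)
        if not math.isclose(self.half_life_h, expected, rel_tol=1e-12):
            raise ValueError("half_life_h must equal ln(2)/ke")


def half_life(ke: float) -> float:
    """Elimination half-life t1/2 = ln(2)/ke, in hours."""
    if not ke > 0:
        raise ValueError(f"ke must be positive, got {ke}")
    return math.log(2.0) / ke


def _rows_for(dataset: Dataset, compound: str, include_censored: bool = False) -> pd.DataFrame:
    return dataset.for_compound(compound, include_censored=include_censored)


def _predict(
    rows: pd.DataFrame,
    params: PKParameters,
    regimens: dict[str, ExposureRegimen],
    mw: float,
) -> np.ndarray:
    out = np.empty(len(rows))
    for route, sub in rows.groupby("route", sort=False):
        regimen = regimens[route]
        a = amount_at_time(params, regimen, sub["time_h"].to_numpy(), mw=mw)
        out[rows.index.get_indexer(sub.index)] = params.fluor * a
    return out


def initial_estimates(dataset: Dataset, compound: str) -> PKParameters:
    """Moment-style starting values from route-wise summary curves.

    ke0 and fluor0 come from a log-linear regression of per-time mean
    injection signal over the late window (t >= 1 h, past the quench
    zone): the slope is -ke and the extrapolated intercept is
    fluor·Dose.  q0 comes from the initial immersion uptake slope, since
    A(t) ≈ M·Q·t while ke·t is small.  All values are clipped positive.
    """
    rows = _rows_for(dataset, compound)
    record = dataset.compounds[compound]
    inj = rows[rows["route"].isin((Route.PC.value, Route.IP.value))]
    imm = rows[rows["route"] == Route.IMMERSION.value]
    if len(inj) < 3 or len(imm) < 3:
        raise ValueError(
            f"{compound}: need >= 3 injection and >= 3 immersion observations "
            f"for starting values (got {len(inj)}, {len(imm)})"
        )

    # injection limb: log-linear decay on per-time means
    inj_means = inj.groupby("time_h")["rfu"].mean()
    late = inj_means[inj_means.index >= 1.0]
    if len(late) < 2:
        late = inj_means
    late = late[late > 0]
    t = late.index.to_numpy()
    slope, intercept = np.polyfit(t, np.log(late.to_numpy()), 1)
    ke0 = max(-slope, 1e-4)
    inj_regimen = dataset.regimens[str(inj["route"].iloc[0])]
    dose = inj_regimen.dose_mg_per_kg * inj_regimen.body_weight_mg
    fluor0 = max(math.exp(intercept) / dose, 1e-12) if dose > 0 else 1.0

    # immersion limb: early uptake slope through the origin
    imm_means = imm.groupby("time_h")["rfu"].mean()
    early = imm_means.iloc[: max(3, len(imm_means) // 2)]
    t = early.index.to_numpy()
    s = float(t @ early.to_numpy() / (t @ t)) if t.size else 0.0
    imm_regimen = dataset.regimens[Route.IMMERSION.value]
    m = imm_regimen.medium_conc_um * record.mw * 1000.0
    q0 = s / (fluor0 * m) if (s > 0 and m > 0) else 0.0
    if q0 <= 1e-15:
        warnings.warn(
            f"{compound}: immersion signal uninformative, clipping q0 to floor",
            IdentifiabilityWarning,
            stacklevel=2,
        )
        q0 = 1e-12
    return PKParameters(fluor=fluor0, ke=ke0, q=q0)


def fit_pk(
    dataset: Dataset,
    compound: str,
    options: FitOptions | None = None,
    start: PKParameters | None = None,
) -> PKFit:
    """Fit (fluor, ke, q) for one compound by joint nonlinear least squares.

    Minimizes Σ (rfu_obs − fluor·A(t))² over the non-censored
    observations of every route at once.  Raises on non-convergence;
    warns if only one route is present (fluor is then confounded with
    the dose or exchange term).
    """
    options = options or FitOptions()
    rows = _rows_for(dataset, compound)
    if rows.empty:
        raise ValueError(f"no usable observations for {compound}")
    routes = set(rows["route"])
    if len(routes) < 2:
        warnings.warn(
            f"{compound}: single-route data — fluor cannot be separated from "
            "the dose/exchange product",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    record = dataset.compounds[compound]
    regimens = dataset.regimens
    rfu = rows["rfu"].to_numpy()
    if start is None:
        start = initial_estimates(dataset, compound)

    def residuals(theta: np.ndarray) -> np.ndarray:
        fluor, ke, q = np.exp(theta)
        p = PKParameters(fluor=fluor, ke=ke, q=q)
        return _predict(rows, p, regimens, record.mw) - rfu

    x0 = np.log([start.fluor, start.ke, max(start.q, 1e-15)])
    result = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=options.relative_tolerance,
        ftol=options.relative_tolerance,
        gtol=options.relative_tolerance,
        max_nfev=options.max_iterations * 10,
    )
    fluor, ke, q = np.exp(result.x)
    params = PKParameters(fluor=fluor, ke=ke, q=q)
    n = len(rows)
    dof = max(n - 3, 1)
    sse = float(result.fun @ result.fun)
    rse = math.sqrt(sse / dof)

    # asymptotic covariance on the log scale, delta method to natural scale
    jtj = result.jac.T @ result.jac
    try:
        cov_log = (sse / dof) * np.linalg.inv(jtj)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(3, np.nan)
    se = {
        "fluor": float(se_log[0] * fluor),
        "ke": float(se_log[1] * ke),
        "q": float(se_log[2] * q),
    }

    n_censored = int(
        dataset.for_compound(compound, include_censored=True)["censored"].sum()
    )
    if not result.success:
        raise RuntimeError(
            f"{compound}: fit did not converge ({result.message}); "
            f"best-so-far fluor={fluor:.4g} ke={ke:.4g} q={q:.4g}"
        )
    return PKFit(
        compound=compound,
        params=params,
        half_life_h=half_life(ke),
        se=se,
        residual_standard_error=rse,
        n_used=n,
        n_censored=n_censored,
        converged=bool(result.success),
        iterations=int(result.nfev),
    )


def censor_outliers(dataset: Dataset, fit: PKFit, options: FitOptions | None = None) -> Dataset:
    """Flag observations whose standardized residual exceeds the threshold.

    Standardization divides by the fit's residual standard error.
    Already-censored flags are never cleared (the censored set only
    grows).  Refuses to censor more than half of a compound's data.
    """
    options = options or FitOptions()
    if not math.isfinite(options.censor_threshold):
        return dataset
    out = dataset.copy()
    obs = out.observations
    mask = (obs["compound"] == fit.compound) & (~obs["censored"])
    rows = obs[mask]
    record = out.compounds[fit.compound]
    pred = _predict(rows, fit.params, out.regimens, record.mw)
    scale = fit.residual_standard_error or 1.0
    std_resid = (rows["rfu"].to_numpy() - pred) / scale
    new_flags = np.abs(std_resid) > options.censor_threshold
    obs.loc[rows.index[new_flags], "censored"] = True

    total = (obs["compound"] == fit.compound).sum()
    censored = ((obs["compound"] == fit.compound) & obs["censored"]).sum()
    if censored > 0.5 * total:
        raise RuntimeError(
            f"{fit.compound}: censoring would remove {censored}/{total} observations "
            "(> 50%); refusing — the model is misspecified for these data"
        )
    return out


def censor_window(dataset: Dataset, compound: str, cutoff_h: float = 1.0) -> Dataset:
    """Window-style censoring: drop injection-route points before ``cutoff_h``.

    Mirrors modelling the microinjection data only from 1 h (or 3 h)
    onward when the early depot signal is quenched.
    """
    out = dataset.copy()
    obs = out.observations
    inj_routes = [r.value for r in (Route.PC, Route.IP, Route.COMBINATION)]
    mask = (
        (obs["compound"] == compound)
        & obs["route"].isin(inj_routes)
        & (obs["time_h"] < cutoff_h)
    )
    obs.loc[mask, "censored"] = True
    return out


def fit_with_censoring(
    dataset: Dataset,
    compound: str,
    options: FitOptions | None = None,
) -> tuple[PKFit, Dataset]:
    """Iterate fit → censor until the censored set stabilizes.

    In ``residual`` mode: fit, flag standardized residuals beyond the
    threshold, refit; stop when no new flags appear or after
    ``max_censor_rounds``.  In ``window`` mode the early injection
    points are dropped up front and a single fit is performed.
    Returns the final fit and the dataset with flags applied.
    """
    options = options or FitOptions()
    current = dataset.copy()
    if options.censor_mode == "window":
        current = censor_window(current, compound, options.window_cutoff_h)
        return fit_pk(current, compound, options), current

    fit = fit_pk(current, compound, options)
    for _ in range(options.max_censor_rounds):
        updated = censor_outliers(current, fit, options)
        before = current.observations["censored"].sum()
        after = updated.observations["censored"].sum()
        current = updated
        if after == before:
            break
        fit = fit_pk(current, compound, options)
    return fit, current


def residual_diagnostics(dataset: Dataset, fit: PKFit) -> pd.DataFrame:
    """Per-observation residual table for the non-censored data.

    Columns: route, time_h, replicate, rfu, fitted, residual,
    standardized_residual.  Summary statistics (mean residual = bias,
    residual standard error) are attached in ``.attrs``.
    """
    rows = dataset.for_compound(fit.compound)
    record = dataset.compounds[fit.compound]
    pred = _predict(rows, fit.params, dataset.regimens, record.mw)
    resid = rows["rfu"].to_numpy() - pred
    scale = fit.residual_standard_error or 1.0
    table = pd.DataFrame({
        "route": rows["route"].to_numpy(),
        "time_h": rows["time_h"].to_numpy(),
        "replicate": rows["replicate"].to_numpy(),
        "rfu": rows["rfu"].to_numpy(),
        "fitted": pred,
        "residual": resid,
        "standardized_residual": resid / scale,
    })
    table.attrs["bias"] = float(resid.mean())
    table.attrs["residual_standard_error"] = fit.residual_standard_error
    return table


def fits_to_frame(fits: "list[PKFit]") -> pd.DataFrame:
    """Tidy per-compound parameter table (one row per compound)."""
    return pd.DataFrame([
        {
            "compound": f.compound,
            "ke": f.params.ke,
            "t_half": f.half_life_h,
            "Q": f.params.q,
            "fluor": f.params.fluor,
            "se_ke": f.se["ke"],
            "se_Q": f.se["q"],
            "residual_standard_error": f.residual_standard_error,
            "n_used": f.n_used,
            "n_censored": f.n_censored,
        }
        for f in fits
    ])
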