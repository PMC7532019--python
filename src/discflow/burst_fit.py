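"""Error-weighted fitting of the capillary-pinning flow model to measured
flow-rate-vs-speed tables.

The measured quantity is the mean flow per rotation speed with its replicate
standard deviation.  The pinned model Q(ω) = B·max(0, ω² − ω₀²) is fitted by
weighted least squares with weights 1/σ_i², σ_i = sd_i/√n_i (the standard
error of the mean — the natural weight when the fitted points are replicate
means).  Because the model is non-smooth in ω₀ wherever the threshold
crosses a data speed, a generic gradient optimizer stalls; instead the fit
profiles ω₀ on a dense grid (B has a closed-form weighted solution at each
candidate) and polishes the best grid point with a bounded scalar search.

The burst pressure follows from the threshold via
p_v = Δp_h + ω₀²·½ρ(r₂²−r₁²) and is only reported when the column radii are
supplied — with the default geometry these are assumed, not printed, and the
estimate is flagged accordingly.  Uncertainty comes from a seeded parametric
bootstrap (the threshold parameter is non-regular, so asymptotic covariance
is unreliable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .hydraulics import hydrostatic_pressure
from .perfusion_model import B_from_geometry, FlowModelSpec
from .rotation import rpm_to_omega
from .units_geometry import (
    M3_PER_S_TO_UL_PER_H,
    DiscGeometry,
    FluidProperties,
    weakest_provenance,
)

LONG_COLUMNS = ["speed_rpm", "flow_ul_per_h"]
SUMMARY_COLUMNS = ["speed_rpm", "mean_ul_per_h", "sd_ul_per_h", "n"]

#: ω₀ profile-search grid resolution.
N_OMEGA0_GRID = 2000


class UnidentifiableModelError(ValueError):
    """Raised when the data cannot pin down the model parameters."""


@dataclass(frozen=True)
class FlowMeasurementSet:
    """A flow-measurement campaign: per-speed replicate flows and summaries.

    ``summary`` always exists (speed_rpm, mean_ul_per_h, sd_ul_per_h, n,
    sorted by unique speed); ``replicates`` is present when individual
    replicate flows are known and is guaranteed consistent with the summary.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame | None = None
    duration_s: float = 3600.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.summary
        missing = [c for c in SUMMARY_COLUMNS if c not in s.columns]
        if missing:
            raise ValueError(f"summary table missing columns {missing}")
        if s["speed_rpm"].duplicated().any():
            raise ValueError("duplicate speeds in summary table")
        if not s["speed_rpm"].is_monotonic_increasing:
            raise ValueError("summary table must be sorted by speed")
        if (s["n"] < 1).any():
            raise ValueError("every speed needs n >= 1 replicates")
        if (s["sd_ul_per_h"] < 0).any():
            raise ValueError("standard deviations must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("collection duration must be > 0 s")

    @classmethod
    def from_replicates(
        cls,
        replicates: pd.DataFrame,
        duration_s: float = 3600.0,
        metadata: dict | None = None,
    ) -> "FlowMeasurementSet":
        """Build the set from a long table (speed_rpm, flow_ul_per_h[, ...])."""
        rep = replicates.sort_values("speed_rpm", kind="stable").reset_index(drop=True)
        grouped = rep.groupby("speed_rpm")["flow_ul_per_h"]
        summary = pd.DataFrame(
            {
                "speed_rpm": grouped.mean().index.to_numpy(float),
                "mean_ul_per_h": grouped.mean().to_numpy(float),
                "sd_ul_per_h": grouped.std(ddof=1).fillna(0.0).to_numpy(float),
                "n": grouped.size().to_numpy(int),
            }
        )
        return cls(summary, rep, duration_s, metadata or {})

    @classmethod
    def from_summary(
        cls,
        summary: pd.DataFrame,
        duration_s: float = 3600.0,
        metadata: dict | None = None,
    ) -> "FlowMeasurementSet":
        s = summary.sort_values("speed_rpm", kind="stable").reset_index(drop=True)
        return cls(s[SUMMARY_COLUMNS].copy(), None, duration_s, metadata or {})

    # -- CSV dialects ------------------------------------------------------

    @classmethod
    def read_csv(cls, path, duration_s: float = 3600.0) -> "FlowMeasurementSet":
        """Read either CSV dialect, auto-detected from the header row."""
        df = pd.read_csv(path)
        cols = list(df.columns)
        if set(LONG_COLUMNS).issubset(cols):
            return cls.from_replicates(df, duration_s)
        if set(SUMMARY_COLUMNS).issubset(cols):
            return cls.from_summary(df, duration_s)
        raise ValueError(
            f"unrecognized measurement CSV header {cols}; expected "
            f"{LONG_COLUMNS} (long) or {SUMMARY_COLUMNS} (summary)"
        )

    def to_long_csv(self, path) -> None:
        if self.replicates is None:
            raise ValueError("no replicate-level data to write")
        self.replicates.to_csv(path, index=False)

    def to_summary_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    # -- fit-ready arrays --------------------------------------------------

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(omega rad/s, mean μl/h, sd μl/h, n) as aligned numpy arrays."""
        s = self.summary
        return (
            rpm_to_omega(s["speed_rpm"].to_numpy(float)),
            s["mean_ul_per_h"].to_numpy(float),
            s["sd_ul_per_h"].to_numpy(float),
            s["n"].to_numpy(float),
        )


class TwoPointSolution(NamedTuple):
    """Closed-form pinned-model parameters through two measured points."""

    B: float        # m^3/s per (rad/s)^2
    omega0: float   # rad/s

    @property
    def B_ul_per_h(self) -> float:
        return self.B * M3_PER_S_TO_UL_PER_H


def two_point_solve(
    point1: tuple[float, float], point2: tuple[float, float]
) -> TwoPointSolution:
    """Solve Q = B(ω²−ω₀²) exactly through two (rpm, μl/h) points.

    With k = Q₂/Q₁ the threshold is ω₀² = (k ω₁² − ω₂²)/(k − 1) and
    B = Q₁/(ω₁² − ω₀²); the solution is symmetric in the point order.  When
    the flow ratio equals the ω² ratio the threshold is indeterminate at
    zero and ω₀ = 0 is returned; a sublinear pair (negative ω₀²) is clamped
    to ω₀ = 0 with B the through-origin least-squares slope.
    """
    (rpm1, q1), (rpm2, q2) = point1, point2
    if rpm1 == rpm2:
        raise ValueError("the two points must have distinct speeds")
    if q1 <= 0 or q2 <= 0:
        raise ValueError("both flows must be > 0")
    w1sq, w2sq = rpm_to_omega(rpm1) ** 2, rpm_to_omega(rpm2) ** 2
    if q1 == q2:
        raise ValueError("equal flows at distinct speeds: B would be zero")
    omega0_sq = (q2 * w1sq - q1 * w2sq) / (q2 - q1)
    if omega0_sq <= 0:
        omega0_sq = 0.0
        b_ulh = (q1 * w1sq + q2 * w2sq) / (w1sq**2 + w2sq**2)
    else:
        b_ulh = q1 / (w1sq - omega0_sq)
    return TwoPointSolution(b_ulh / M3_PER_S_TO_UL_PER_H, float(np.sqrt(omega0_sq)))


@dataclass(frozen=True)
class FlowModelFit:
    """Result of fitting a flow model to a measurement set."""

    spec: FlowModelSpec
    B_mode: str                      # "fitted" | "fixed_from_geometry"
    weighted_ssr: float
    r_squared: float
    n_points: int
    p_v_estimate: float | None = None   # Pa; None when radii unavailable
    p_v_se: float | None = None
    p_v_ci95: tuple[float, float] | None = None
    #: Signed threshold a with Q = B·max(0, ω² − a): a = ω₀² in the pinned
    #: regime, a < 0 when the fit prefers a burst pressure below the
    #: hydrostatic head (valve open at rest).
    threshold_sq_signed: float | None = None
    provenance: str = "assumed"
    seed: int | None = None
    geom: DiscGeometry | None = field(default=None, repr=False)
    fluid: FluidProperties | None = field(default=None, repr=False)

    @property
    def omega0(self) -> float:
        return self.spec.omega0

    @property
    def B_ul_per_h(self) -> float:
        return (self.spec.B or 0.0) * M3_PER_S_TO_UL_PER_H


def _weights_from_sem(sd: np.ndarray, n: np.ndarray) -> np.ndarray:
    sem = sd / np.sqrt(n)
    if np.all(sem == 0):
        warnings.warn(
            "all replicate scatters are zero; falling back to an unweighted fit",
            stacklevel=3,
        )
        return np.ones_like(sem)
    if np.any(sem == 0):
        raise ValueError(
            "some (not all) points have zero standard error; error weights "
            "1/sigma^2 are undefined — supply scatter for every speed"
        )
    return 1.0 / sem**2


def _stationary_threshold(
    omega_sq: np.ndarray,
    q: np.ndarray,
    w: np.ndarray,
    active: np.ndarray,
    b_fixed: float | None,
) -> float | None:
    """Closed-form stationary threshold a for a fixed active set.

    Over the active points the model Q = B(ω² − a) = B ω² − c is linear in
    (B, c); the weighted normal equations give (B, c) and a = c/B.  With B
    fixed, stationarity in a alone gives a = Σw(Bω² − q)/(B Σw).  Returns
    None when the system is degenerate or yields B ≤ 0.
    """
    if active.sum() < (2 if b_fixed is None else 1):
        return None
    x, y, ww = omega_sq[active], q[active], w[active]
    if b_fixed is not None:
        sw = np.sum(ww)
        return float(np.sum(ww * (b_fixed * x - y)) / (b_fixed * sw))
    sw = np.sum(ww)
    sx = np.sum(ww * x)
    sxx = np.sum(ww * x * x)
    sy = np.sum(ww * y)
    sxy = np.sum(ww * x * y)
    det = sxx * sw - sx * sx
    if det == 0:
        return None
    b = (sxy * sw - sx * sy) / det
    c = (sx * sxy - sxx * sy) / det  # model intercept is −c
    if b <= 0:
        return None
    return float(c / b)


def _profile_fit(
    omega: np.ndarray,
    q: np.ndarray,
    w: np.ndarray,
    b_fixed: float | None,
    a_min: float | None,
) -> tuple[float, float, float]:
    """Profile the signed threshold a = sign(p_v − p_h)·ω₀² on a grid; B has
    a closed-form weighted solution at each candidate; the best grid point is
    polished by a bounded scalar search.  Returns (B μl/h units, a, wSSR).

    The flow law is Q = B·max(0, ω² − a).  a ≥ 0 is the pinned regime
    (threshold at ω₀ = √a); a < 0 means the valve is open at rest and the
    excess hydrostatic drive produces a constant flow offset — exactly the
    unpinned combined model, which is thereby nested in the fit family.
    ``a_min`` bounds a below at the p_v = 0 point when the column geometry is
    known; otherwise at −max(ω)².
    """
    omega_sq = omega**2
    a_floor = -float(np.max(omega_sq)) if a_min is None else a_min

    def b_and_ssr(a: float) -> tuple[float, float]:
        x = np.maximum(0.0, omega_sq - a)
        if b_fixed is not None:
            b = b_fixed
        else:
            den = np.sum(w * x * x)
            b = max(0.0, np.sum(w * q * x) / den) if den > 0 else 0.0
        resid = q - b * x
        return b, float(np.sum(w * resid * resid))

    grid = np.linspace(a_floor, float(np.max(omega_sq)), N_OMEGA0_GRID)
    # vectorized grid pass
    x_grid = np.maximum(0.0, omega_sq[None, :] - grid[:, None])
    if b_fixed is not None:
        b_grid = np.full(len(grid), b_fixed)
    else:
        den = np.einsum("ij,ij->i", w * x_grid, x_grid)
        num = x_grid @ (w * q)
        with np.errstate(invalid="ignore", divide="ignore"):
            b_grid = np.where(den > 0, np.maximum(0.0, num / np.where(den > 0, den, 1.0)), 0.0)
    resid = q[None, :] - b_grid[:, None] * x_grid
    ssr_grid = np.einsum("ij,ij->i", w * resid, resid)
    i = int(np.argmin(ssr_grid))

    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    candidates = [float(grid[i])]
    if hi > lo:
        res = minimize_scalar(
            lambda a: b_and_ssr(a)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        candidates.append(float(res.x))
    # Exact polish: within one active set {i: ω_i² > a} the model is linear
    # in (B, c) with Q = B ω² − c and a = c/B, so the joint weighted
    # least-squares stationary point is closed-form.  Try the active sets
    # induced by the grid optimum and its neighbours.
    for a_probe in {float(grid[i]), lo, hi}:
        active = omega_sq > a_probe
        a_exact = _stationary_threshold(omega_sq, q, w, active, b_fixed)
        if a_exact is not None and a_floor <= a_exact <= grid[-1]:
            candidates.append(a_exact)
    if grid[0] <= 0.0 <= grid[-1]:
        candidates.append(0.0)  # the pinning-free breakpoint, snapped exactly
    best = min(candidates, key=lambda a: b_and_ssr(a)[1])
    b, ssr = b_and_ssr(best)
    return b, best, ssr


def _fit_arrays(
    omega: np.ndarray,
    q: np.ndarray,
    sd: np.ndarray,
    n: np.ndarray,
    b_fixed: float | None = None,
    a_min: float | None = None,
) -> tuple[float, float, float, float]:
    """Core fit on numpy arrays.  Returns (B μl/h, signed a, wSSR, R²)."""
    if np.all(q == 0):
        raise UnidentifiableModelError(
            "model unidentifiable: every mean flow is zero"
        )
    if b_fixed is None and np.count_nonzero(q) < 2:
        raise UnidentifiableModelError(
            "fitting both B and omega0 needs at least two speeds with "
            "nonzero mean flow"
        )
    w = _weights_from_sem(sd, n)
    b, a, ssr = _profile_fit(omega, q, w, b_fixed, a_min)
    qhat = b * np.maximum(0.0, omega**2 - a)
    sst = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 - float(np.sum((q - qhat) ** 2)) / sst if sst > 0 else float("nan")
    return b, a, ssr, r2


def fit_threshold_model(
    data: FlowMeasurementSet,
    geom: DiscGeometry | None = None,
    fluid: FluidProperties | None = None,
    B_mode: str = "fitted",
) -> FlowModelFit:
    """Weighted least-squares fit of the pinned model to a measurement set.

    ``B_mode="fitted"`` frees both parameters; ``"fixed_from_geometry"``
    pins B to its geometry-derived value and profiles only ω₀ (requires
    geometry and fluid).  The burst pressure is reported only when the
    column radii are available, and carries the weakest provenance among the
    geometry fields it depends on.
    """
    if B_mode not in ("fitted", "fixed_from_geometry"):
        raise ValueError(f"unknown B_mode {B_mode!r}")
    omega, q, sd, n = data.arrays()

    b_fixed = None
    if B_mode == "fixed_from_geometry":
        if geom is None or fluid is None:
            raise ValueError("fixed_from_geometry requires geometry and fluid")
        b_fixed = B_from_geometry(geom, fluid) * M3_PER_S_TO_UL_PER_H

    a_min = None
    half_col = None
    p_h = None
    if geom is not None and fluid is not None:
        p_h = hydrostatic_pressure(fluid, geom.head_height)
        half_col = 0.5 * fluid.density * (geom.r_outer**2 - geom.r_inner**2)
        a_min = -p_h / half_col  # the p_v = 0 point: valve fully open at rest

    b_ulh, a, ssr, r2 = _fit_arrays(omega, q, sd, n, b_fixed, a_min)
    if b_ulh <= 0:
        raise UnidentifiableModelError("fitted flow coefficient is nonpositive")
    omega0 = float(np.sqrt(max(0.0, a)))
    spec = FlowModelSpec(
        "combined_pinned", B=b_ulh / M3_PER_S_TO_UL_PER_H, omega0=omega0
    )

    p_v = None
    provenance = "assumed"
    if geom is not None and fluid is not None:
        p_v = p_h + a * half_col  # >= 0 by the a_min bound
        provenance = weakest_provenance(
            geom.provenance_of(f) for f in ("r_inner", "r_outer", "head_height")
        )

    return FlowModelFit(
        spec=spec,
        B_mode=B_mode,
        weighted_ssr=ssr,
        r_squared=r2,
        n_points=len(omega),
        p_v_estimate=p_v,
        threshold_sq_signed=a,
        provenance=provenance,
        geom=geom,
        fluid=fluid,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Parametric-bootstrap uncertainty of the burst-pressure estimate."""

    se: float
    ci95: tuple[float, float]
    n_failures: int
    samples: np.ndarray = field(repr=False)


def fit_uncertainty(
    fit: FlowModelFit,
    data: FlowMeasurementSet,
    n_boot: int = 1000,
    seed: int = 0,
    resample: str = "replicates",
) -> BootstrapResult:
    """Seeded parametric bootstrap of the burst pressure.

    ``resample="replicates"`` (default) redraws each point's n_i replicates
    from Normal(mean_i, sd_i) and recomputes both the mean and the sd before
    refitting, so the sampling variability of the replicate scatter — and
    through it, of the fit weights — is propagated.  ``resample="means"``
    redraws only the means from Normal(mean_i, sd_i/√n_i) with the scatter
    held fixed; with n = 8 replicates per point this ignores the sd's own
    noise and yields intervals ~20% too narrow (a z-versus-t effect), so it
    is kept only for comparison.  Reported: sd of the bootstrap p_v samples
    and their percentile 95% interval.  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentiles")
    if resample not in ("replicates", "means"):
        raise ValueError(f"unknown resample scheme {resample!r}")
    if fit.p_v_estimate is None:
        raise ValueError(
            "fit carries no burst pressure (column radii missing); bootstrap "
            "uncertainty of p_v is undefined"
        )
    omega, q, sd, n = data.arrays()
    sem = sd / np.sqrt(n)
    p_h = hydrostatic_pressure(fit.fluid, fit.geom.head_height)
    half_col = 0.5 * fit.fluid.density * (
        fit.geom.r_outer**2 - fit.geom.r_inner**2
    )
    a_min = -p_h / half_col
    b_fixed = None
    if fit.B_mode == "fixed_from_geometry":
        b_fixed = B_from_geometry(fit.geom, fit.fluid) * M3_PER_S_TO_UL_PER_H

    rng = np.random.default_rng(seed)
    n_int = n.astype(int)
    samples = np.empty(n_boot)
    failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # repeated all-zero-sem warnings
        for b in range(n_boot):
            if resample == "replicates":
                q_star = np.empty_like(q)
                sd_star = np.empty_like(sd)
                for i in range(len(q)):
                    reps = rng.normal(q[i], sd[i], n_int[i])
                    q_star[i] = reps.mean()
                    sd_star[i] = reps.std(ddof=1) if n_int[i] > 1 else 0.0
            else:
                q_star = rng.normal(q, sem)
                sd_star = sd
            try:
                _, a_star, _, _ = _fit_arrays(
                    omega, q_star, sd_star, n, b_fixed, a_min
                )
            except (UnidentifiableModelError, ValueError):
                failures += 1
                samples[b] = np.nan
                continue
            samples[b] = p_h + a_star * half_col
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"bootstrap refit failure rate {failures}/{n_boot} exceeds 20%; "
            "the data barely identify the model"
        )
    good = samples[~np.isnan(samples)]
    se = float(np.std(good, ddof=1)) if len(good) > 1 else 0.0
    lo, hi = np.percentile(good, [2.5, 97.5])
    return BootstrapResult(se, (float(lo), float(hi)), failures, good)


def with_uncertainty(
    fit: FlowModelFit,
    data: FlowMeasurementSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> FlowModelFit:
    """Return a copy of ``fit`` with bootstrap se/CI of p_v filled in."""
    import dataclasses

    boot = fit_uncertainty(fit, data, n_boot=n_boot, seed=seed)
    return dataclasses.replace(
        fit, p_v_se=boot.se, p_v_ci95=boot.ci95, seed=seed
    )


def compare_variants(
    data: FlowMeasurementSet,
    geom: DiscGeometry,
    fluid: FluidProperties,
) -> pd.DataFrame:
    """Score the four model variants against one measurement set.

    The non-pinned variants are pure predictions (geometry-derived B, no free
    parameters); the pinned variant is fitted.  Rows are ranked by weighted
    SSR, best first.
    """
    from .perfusion_model import predict_flow

    omega, q, sd, n = data.arrays()
    w = _weights_from_sem(sd, n)
    sst = float(np.sum((q - q.mean()) ** 2))

    rows = []
    for variant in ("hydrostatic_only", "centrifugal_only", "combined"):
        spec = FlowModelSpec(variant)
        qhat = (
            np.asarray(predict_flow(spec, omega, geom, fluid))
            * M3_PER_S_TO_UL_PER_H
        )
        ssr_w = float(np.sum(w * (q - qhat) ** 2))
        r2 = 1.0 - float(np.sum((q - qhat) ** 2)) / sst if sst > 0 else float("nan")
        rows.append(
            {
                "variant": variant,
                "weighted_SSR": ssr_w,
                "r_squared": r2,
                "omega0_rpm": 0.0,
                "B_ul_per_h_per_rad2_s2": B_from_geometry(geom, fluid)
                * M3_PER_S_TO_UL_PER_H
                if variant != "hydrostatic_only"
                else np.nan,
            }
        )

    pinned = fit_threshold_model(data, geom, fluid, B_mode="fitted")
    rows.append(
        {
            "variant": "combined_pinned",
            "weighted_SSR": pinned.weighted_ssr,
            "r_squared": pinned.r_squared,
            "omega0_rpm": pinned.spec.omega0_rpm,
            "B_ul_per_h_per_rad2_s2": pinned.B_ul_per_h,
        }
    )
    table = pd.DataFrame(rows).sort_values("weighted_SSR", kind="stable")
    return table.reset_index(drop=True)


def fit_report(fit: FlowModelFit) -> dict:
    """JSON-serializable report of a fit (parameters, uncertainty, flags)."""
    return {
        "variant": fit.spec.variant,
        "B": fit.spec.B,
        "B_ul_per_h_per_rad2_s2": fit.B_ul_per_h,
        "omega0_rad_s": fit.spec.omega0,
        "omega0_rpm": fit.spec.omega0_rpm,
        "p_v_Pa": fit.p_v_estimate,
        "se_Pa": fit.p_v_se,
        "ci95_Pa": list(fit.p_v_ci95) if fit.p_v_ci95 else None,
        "weighted_SSR": fit.weighted_ssr,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "B_mode": fit.B_mode,
        "provenance": fit.provenance,
    }


def write_fit_report(fit: FlowModelFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_report(fit), fh, indent=2)
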