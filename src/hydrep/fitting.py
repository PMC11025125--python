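"""The Landau-Ginzburg fitting chain.

Profile fits of the sinh-shaped antisymmetric solution give the
correlation length ``lambda`` and the surface value ``m_s`` at each
separation; one-parameter fits of the surface-value law
``m_s(d) = (h/a)/lambda * tanh(d/(2 lambda))`` (lambda held fixed) give
the rescaled surface field ``h/a``; two-parameter fits of the indirect
pressure ``Pi_ind(d) = K / (1 + cosh(d/lambda))`` give ``lambda`` and
the amplitude ``K = h^2/b``, from which the order-parameter stiffness
follows as ``a = K lambda^2 / (h/a)^2``.  Total-pressure curves are fit
with a plain exponential after excluding strictly negative points
(numerical noise).  ``extract_parameter_table`` chains all stages into
a per-system parameter summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .lg_model import OrderParameterProfile
from .thermo import PressureDistanceCurve


@dataclass(frozen=True)
class FitResult:
    """Estimates, 1-sigma uncertainties and diagnostics of one fit."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    residual_norm: float
    n_points_used: int
    excluded_points: tuple[int, ...] = ()
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.std_errors.values() if np.isfinite(v)):
            raise ValidationError("standard errors must be nonnegative")


def _perr(pcov: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(pcov))


def _sinh_profile(z: np.ndarray, lam: float, m_s: float, d: float) -> np.ndarray:
    return m_s * np.sinh(z / lam) / np.sinh(0.5 * d / lam)


def fit_profile_sinh(
    profile: OrderParameterProfile,
    weights: np.ndarray | None = None,
    antisymmetry_tol: float = 0.5,
) -> FitResult:
    """Fit the sinh-shaped antisymmetric profile; returns lambda and m_s.

    Weighted nonlinear least squares of
    ``m(z) = m_s sinh(z/lambda)/sinh(d/(2 lambda))`` with multi-start
    initialization of lambda.  Profiles whose even (symmetric) component
    dominates the odd one are rejected: the model cannot represent them
    and a converged fit would be meaningless.
    """
    z, y, d = profile.z, profile.values, profile.d
    if z.size < 6:
        raise ValidationError("profile fit needs at least 6 grid points")
    # antisymmetry screen on the symmetrized grid
    y_rev = np.interp(-z, z, y)
    even = 0.5 * (y + y_rev)
    odd = 0.5 * (y - y_rev)
    norm_even, norm_odd = np.linalg.norm(even), np.linalg.norm(odd)
    if norm_odd == 0 or norm_even / max(norm_odd, 1e-300) > antisymmetry_tol:
        raise FitError(
            "profile is not approximately antisymmetric "
            f"(even/odd norm ratio {norm_even / max(norm_odd, 1e-300):.2f}); "
            "the sinh model does not apply"
        )
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))

    edge = y[-1] if abs(y[-1]) > 0 else 1.0
    starts = [d / 4.0, d / 8.0, d / 16.0, d / 2.0]
    best = None
    for lam0 in starts:
        try:
            popt, pcov = curve_fit(
                lambda zz, lam, m_s: _sinh_profile(zz, lam, m_s, d),
                z, y, p0=[lam0, edge], sigma=sigma,
                bounds=([1e-4, -np.inf], [10.0 * d, np.inf]), maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(y - _sinh_profile(z, *popt, d)))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise FitError(
            f"profile fit failed to converge from starts lambda0={starts}"
        )
    (lam, m_s), pcov, resid = best
    err = _perr(pcov)
    return FitResult(
        estimates={"lam": float(lam), "m_s": float(m_s)},
        std_errors={"lam": float(err[0]), "m_s": float(err[1])},
        residual_norm=resid,
        n_points_used=z.size,
        diagnostics={"d": d, "even_odd_ratio": float(norm_even / norm_odd)},
    )


def fit_surface_values(
    points, lam_fixed: float, weights: np.ndarray | None = None
) -> FitResult:
    """One-parameter fit of the surface-value law with lambda held fixed.

    ``m_s(d) = (h/a)/lambda * tanh(d/(2 lambda))`` is linear in ``h/a``,
    so the weighted least-squares solution is closed-form.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 (d, m_s) pairs")
    if not lam_fixed > 0:
        raise ValidationError(f"lam_fixed must be positive, got {lam_fixed}")
    d, ms = pts[:, 0], pts[:, 1]
    if np.any(d <= 0):
        raise ValidationError("separations must be positive")
    x = np.tanh(0.5 * d / lam_fixed) / lam_fixed
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    sxx = float(np.sum(w * x * x))
    h_over_a = float(np.sum(w * x * ms) / sxx)
    resid = ms - h_over_a * x
    dof = max(d.size - 1, 1)
    s2 = float(np.sum(w * resid**2) / dof)
    return FitResult(
        estimates={"h_over_a": h_over_a},
        std_errors={"h_over_a": float(np.sqrt(s2 / sxx))},
        residual_norm=float(np.linalg.norm(np.sqrt(w) * resid)),
        n_points_used=d.size,
        diagnostics={"lam_fixed": lam_fixed},
    )


def _lg_pressure(d: np.ndarray, amplitude: float, lam: float) -> np.ndarray:
    return amplitude / (1.0 + np.cosh(d / lam))


def _tail_lambda(d: np.ndarray, p: np.ndarray) -> float:
    """Initial decay length from the log-slope of the two largest-d points."""
    if d.size >= 2 and p[-1] > 0 and p[-2] > 0 and p[-2] != p[-1]:
        lam0 = (d[-1] - d[-2]) / np.log(p[-2] / p[-1])
        if np.isfinite(lam0) and lam0 > 0:
            return float(lam0)
    return float((d[-1] - d[0]) / 4.0) or 0.1


def fit_indirect_pressure(
    curve: PressureDistanceCurve,
    h_over_a_fixed: float | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Fit the Landau-Ginzburg indirect pressure; returns lambda and K.

    Model ``Pi_ind(d) = K/(1 + cosh(d/lambda))`` with the amplitude
    ``K = h^2/b`` and lambda free.  Nonpositive pressures are excluded
    (and reported) before fitting.  When ``h_over_a_fixed`` from the
    surface-value fits is supplied, the stiffness is recovered as
    ``a = K lambda^2/(h/a)^2`` with first-order error propagation.
    """
    d_all, p_all = curve.d, curve.pressure
    keep = p_all > 0
    excluded = tuple(int(i) for i in np.nonzero(~keep)[0])
    d, p = d_all[keep], p_all[keep]
    if d.size < 4:
        raise FitError(
            f"need >= 4 positive pressures, have {d.size} after excluding {excluded}"
        )
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float)[keep])

    lam_tail = _tail_lambda(d, p)
    best = None
    for lam0 in {lam_tail, lam_tail / 2.0, 2.0 * lam_tail}:
        k0 = float(p[0] * (1.0 + np.cosh(d[0] / lam0)))
        try:
            popt, pcov = curve_fit(
                _lg_pressure, d, p, p0=[k0, lam0], sigma=sigma,
                bounds=([0.0, 1e-4], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(p - _lg_pressure(d, *popt)))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise FitError("indirect-pressure fit failed to converge")
    (amp, lam), pcov, resid = best
    err = _perr(pcov)
    estimates = {"lam": float(lam), "amplitude": float(amp)}
    std_errors = {"lam": float(err[1]), "amplitude": float(err[0])}
    if h_over_a_fixed is not None:
        if h_over_a_fixed == 0:
            raise ValidationError("h_over_a_fixed must be nonzero")
        a = amp * lam**2 / h_over_a_fixed**2
        # var(a) from var(K), var(lam) and their covariance
        da_dk = lam**2 / h_over_a_fixed**2
        da_dl = 2.0 * amp * lam / h_over_a_fixed**2
        var = (
            da_dk**2 * pcov[0, 0]
            + da_dl**2 * pcov[1, 1]
            + 2.0 * da_dk * da_dl * pcov[0, 1]
        )
        estimates["a"] = float(a)
        std_errors["a"] = float(np.sqrt(max(var, 0.0)))
    return FitResult(
        estimates=estimates,
        std_errors=std_errors,
        residual_norm=resid,
        n_points_used=int(d.size),
        excluded_points=excluded,
        diagnostics={"lam0_tail": lam_tail},
    )


def fit_total_exponential(
    curve: PressureDistanceCurve, weights: np.ndarray | None = None
) -> FitResult:
    """Exponential fit ``A exp(-d/lambda)`` of a total-pressure curve.

    Strictly negative pressures (numerical noise in the data this
    emulates) are excluded before fitting; zeros are retained.  The
    excluded indices are reported in the result.
    """
    d_all, p_all = curve.d, curve.pressure
    keep = p_all >= 0
    excluded = tuple(int(i) for i in np.nonzero(~keep)[0])
    d, p = d_all[keep], p_all[keep]
    if d.size < 3:
        raise FitError(
            f"need >= 3 surviving points, have {d.size} after excluding {excluded}"
        )
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float)[keep])

    pos = p > 0
    if np.count_nonzero(pos) >= 2:
        slope, intercept = np.polyfit(d[pos], np.log(p[pos]), 1)
        lam0 = -1.0 / slope if slope < 0 else (d[-1] - d[0])
        a0 = float(np.exp(intercept))
    else:
        lam0, a0 = (d[-1] - d[0]) / 2.0, float(np.max(p))
    try:
        popt, pcov = curve_fit(
            lambda dd, amp, lam: amp * np.exp(-dd / lam),
            d, p, p0=[a0, lam0], sigma=sigma,
            bounds=([0.0, 1e-4], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    err = _perr(pcov)
    resid = float(np.linalg.norm(p - popt[0] * np.exp(-d / popt[1])))
    return FitResult(
        estimates={"amplitude": float(popt[0]), "lam_tilde": float(popt[1])},
        std_errors={"amplitude": float(err[0]), "lam_tilde": float(err[1])},
        residual_norm=resid,
        n_points_used=int(d.size),
        excluded_points=excluded,
    )


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

@dataclass
class SystemDataset:
    """Inputs of the full fitting chain for one surface system."""

    label: str
    profiles: dict[str, list[OrderParameterProfile]] = dc_field(default_factory=dict)
    indirect_pressure: PressureDistanceCurve | None = None


def extract_parameter_table(datasets: list[SystemDataset]) -> pd.DataFrame:
    """Per-system parameter summary from the full fitting chain.

    For every profile kind: each profile is fit for (lambda, m_s), the
    per-kind lambda is the mean over separations, and the surface
    values are refit with lambda fixed to obtain h/a.  The indirect
    pressure gives lambda_Pi_ind and the amplitude K; stiffnesses
    follow as ``a = K lambda_Pi_ind^2/(h/a)^2`` per kind.  Missing or
    failing stages leave NaN cells and are reported in
    ``df.attrs["messages"]``; the remaining cells are still computed.
    """
    columns: dict[str, dict[str, float]] = {}
    messages: list[str] = []
    for ds in datasets:
        col: dict[str, float] = {}
        amp = lam_pi = None
        if ds.indirect_pressure is not None:
            try:
                fr = fit_indirect_pressure(ds.indirect_pressure)
                lam_pi, amp = fr.estimates["lam"], fr.estimates["amplitude"]
                col["lam_Pi_ind [nm]"] = lam_pi
                col["amplitude_h2_over_b [kT/nm^3]"] = amp
            except (FitError, ValidationError) as exc:
                messages.append(f"{ds.label}: indirect-pressure fit failed: {exc}")
        else:
            messages.append(f"{ds.label}: no indirect-pressure curve supplied")
        for kind, profiles in ds.profiles.items():
            lams, points = [], []
            for prof in profiles:
                try:
                    fr = fit_profile_sinh(prof)
                except (FitError, ValidationError) as exc:
                    messages.append(
                        f"{ds.label}/{kind}: profile fit at d={prof.d} failed: {exc}"
                    )
                    continue
                lams.append(fr.estimates["lam"])
                points.append((prof.d, fr.estimates["m_s"]))
            if not lams:
                continue
            lam_kind = float(np.mean(lams))
            col[f"lam_{kind} [nm]"] = lam_kind
            if len(points) >= 3:
                try:
                    fr6 = fit_surface_values(points, lam_fixed=lam_kind)
                    hoa = fr6.estimates["h_over_a"]
                    col[f"h_over_a_{kind} [e/nm]"] = hoa
                    if amp is not None and hoa != 0:
                        col[f"a_{kind} [nm/e^2]"] = amp * lam_pi**2 / hoa**2
                except (FitError, ValidationError) as exc:
                    messages.append(f"{ds.label}/{kind}: surface-value fit failed: {exc}")
            else:
                messages.append(
                    f"{ds.label}/{kind}: only {len(points)} separations; "
                    "surface-value fit needs >= 3"
                )
        columns[ds.label] = col
    df = pd.DataFrame(columns)
    df.attrs["messages"] = messages
    return df
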