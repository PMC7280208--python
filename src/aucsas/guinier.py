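"""Guinier and extended-Guinier analysis of scattering profiles.

At low q a globular particle obeys the Guinier law

    I(q) = I(0) * exp(-(q*Rg)^2 / 3),

so ln I is linear in q^2 with slope -Rg^2/3.  :func:`guinier_fit` performs the
weighted linear fit with a self-consistent window q*Rg <= qRg_max.  The
extended fit adds even polynomial terms in (q*Rg)^2 to ln I, which tracks the
true curve to roughly q*Rg ~ 2 and is used when a wider window is needed than
the plain Guinier region provides.  :func:`guinier_quality` runs residual
diagnostics, in particular a low-q upturn flag that signals aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles_io import ScatteringProfile

__all__ = [
    "GuinierResult",
    "GuinierError",
    "guinier_fit",
    "extended_guinier_fit",
    "guinier_quality",
    "QualityReport",
]

DEFAULT_QRG_MAX = 1.3        # community convention for globular particles
DEFAULT_QRG_MAX_EXT = 2.0    # extended-window limit
_MAX_WINDOW_ITER = 20


class GuinierError(RuntimeError):
    """No usable Guinier region (positive slope, too few points, no convergence)."""


@dataclass(frozen=True)
class GuinierResult:
    """Fitted forward intensity and radius of gyration."""

    I0: float
    Rg: float                       # [Å]
    q_window: tuple[float, float]   # (q_min, q_max) actually used
    I0_err: float
    Rg_err: float
    chi2_reduced: float
    n_points: int
    coeffs: tuple[float, ...] = ()  # polynomial coefficients of ln I in q^2
    qRg_max: float = np.nan

    def __post_init__(self) -> None:
        if not self.Rg > 0:
            raise GuinierError(f"non-physical Rg = {self.Rg}")

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        """Model intensity on ``q`` from the fitted polynomial."""
        q2 = np.asarray(q, dtype=float) ** 2
        ln_i = np.full_like(q2, np.log(self.I0))
        for m, c in enumerate(self.coeffs, start=1):
            ln_i = ln_i + c * q2 ** m
        return np.exp(ln_i)


def _window_mask(profile: ScatteringProfile, q_max: float) -> np.ndarray:
    return (profile.q <= q_max) & (profile.intensity > 0) & np.isfinite(profile.intensity)


def _weighted_polyfit(q2: np.ndarray, y: np.ndarray, w: np.ndarray, order: int,
                      y0: float | None = None):
    """Weighted LS of y = b0 + b1*q2 + ... + b_order*q2^order.

    ``w`` are inverse-variance weights on y.  With ``y0`` given, the constant
    term is fixed and not fitted.  Returns (beta, cov, chi2) where beta always
    includes the constant term first.
    """
    cols = [q2 ** m for m in range(0 if y0 is None else 1, order + 1)]
    X = np.column_stack(cols)
    target = y if y0 is None else y - y0
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], target * sw, rcond=None)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.inv(xtwx)
    resid = target - X @ beta
    chi2 = float(np.sum(w * resid ** 2))
    if y0 is not None:
        beta = np.concatenate([[y0], beta])
        cov_full = np.zeros((order + 1, order + 1))
        cov_full[1:, 1:] = cov
        cov = cov_full
    return beta, cov, chi2


def _fit_window(profile: ScatteringProfile, qRg_max: float, order: int,
                min_points: int, i0_fixed: float | None) -> GuinierResult:
    """Self-consistent window iteration shared by plain and extended fits."""
    q, i, s = profile.q, profile.intensity, profile.sigma
    mask = _window_mask(profile, np.inf)
    if mask.sum() < min_points:
        raise GuinierError("fewer than %d positive points" % min_points)
    idx = np.flatnonzero(mask)
    if order > 1:
        # seed the wide-window polynomial fit with a plain Guinier estimate,
        # otherwise the high-order terms are degenerate on a narrow window
        pre = _fit_window(profile, min(qRg_max, DEFAULT_QRG_MAX), order=1,
                          min_points=min_points, i0_fixed=None)
        q_max = qRg_max / pre.Rg
    else:
        # start from the low-q fifth of the usable points (at least min_points)
        n0 = max(min_points, idx.size // 5)
        q_max = q[idx[min(n0, idx.size) - 1]]
    prev_count = -1
    for _ in range(_MAX_WINDOW_ITER):
        m = _window_mask(profile, q_max)
        if m.sum() < min_points:
            # widen until enough points are available
            k = np.flatnonzero(mask)[:min_points]
            m = np.zeros_like(mask)
            m[k] = True
        q2 = q[m] ** 2
        y = np.log(i[m])
        w = (i[m] / s[m]) ** 2          # var(ln I) = (sigma/I)^2
        beta, cov, chi2 = _weighted_polyfit(q2, y, w, order, y0=np.log(i0_fixed)
                                            if i0_fixed is not None else None)
        if beta[1] >= 0:
            # a noise-positive slope on a narrow window: widen before giving up
            if m.sum() < mask.sum():
                q_max = q[idx[min(2 * int(m.sum()), idx.size) - 1]]
                prev_count = -1
                continue
            raise GuinierError("positive ln I vs q^2 slope: no Guinier region")
        rg = float(np.sqrt(-3.0 * beta[1]))
        q_max_new = qRg_max / rg
        count = int(_window_mask(profile, q_max_new).sum())
        if count == m.sum() or count == prev_count:
            q_max = q_max_new if count >= min_points else q_max
            # converged: recompute stats on the final window; parameter errors
            # are inflated by sqrt(chi2_red) when the fit is worse than the
            # stated sigmas claim (conservative convention)
            n = int(m.sum())
            dof = max(n - (order + (0 if i0_fixed is not None else 1)), 1)
            scale = max(1.0, np.sqrt(chi2 / dof))
            rg_err = float(1.5 / rg * np.sqrt(cov[1, 1])) * scale
            i0 = float(np.exp(beta[0]))
            i0_err = 0.0 if i0_fixed is not None else \
                float(i0 * np.sqrt(cov[0, 0])) * scale
            return GuinierResult(
                I0=i0, Rg=rg, q_window=(float(q[m][0]), float(q[m][-1])),
                I0_err=i0_err, Rg_err=rg_err, chi2_reduced=chi2 / dof,
                n_points=n, coeffs=tuple(beta[1:]), qRg_max=qRg_max)
        prev_count = int(m.sum())
        q_max = q_max_new
    raise GuinierError("Guinier window did not stabilize in %d iterations"
                       % _MAX_WINDOW_ITER)


def guinier_fit(profile: ScatteringProfile, qRg_max: float = DEFAULT_QRG_MAX,
                min_points: int = 5) -> GuinierResult:
    """Weighted Guinier fit with a self-consistent q*Rg <= ``qRg_max`` window.

    The window limit depends on the fitted Rg, so the fit iterates: fit,
    recompute the limit, refit, until the point set is stable (at most 20
    rounds).  Points with non-positive intensity are excluded.
    """
    return _fit_window(profile, qRg_max, order=1, min_points=min_points, i0_fixed=None)


def extended_guinier_fit(profile: ScatteringProfile, order: int = 2,
                         qRg_max_ext: float = DEFAULT_QRG_MAX_EXT,
                         min_points: int = 5,
                         i0_fixed: float | None = None) -> GuinierResult:
    """Extended Guinier fit: ln I = ln I(0) - (q*Rg)^2/3 + A4*(q*Rg)^4 + ...

    A polynomial in q^2 of the given ``order`` (default 2, i.e. one shape term
    beyond Guinier) fitted over the wider window q*Rg <= ``qRg_max_ext``.
    With ``i0_fixed`` the forward intensity is constrained rather than fitted,
    which anchors the fit when I(0) is known independently.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    return _fit_window(profile, qRg_max_ext, order=order,
                       min_points=max(min_points, order + 2), i0_fixed=i0_fixed)


@dataclass(frozen=True)
class QualityReport:
    """Residual diagnostics for a Guinier fit."""

    upturn: bool                 # systematic positive residuals at lowest q
    mean_z_low: float            # mean standardized residual, lowest 20% of window
    frac_positive_low: float
    n_runs: int                  # sign runs over the window
    n_runs_expected: float
    n_points: int
    residuals: np.ndarray = field(repr=False, default=None)


def guinier_quality(profile: ScatteringProfile, result: GuinierResult,
                    z_threshold: float = 1.0,
                    frac_threshold: float = 0.75) -> QualityReport:
    """Residual-run diagnostics and a low-q upturn flag.

    The upturn flag fires when the lowest 20% of window points (at least 3)
    show a mean standardized residual above ``z_threshold`` with at least
    ``frac_threshold`` of them positive — the signature of residual
    aggregates, which add intensity fastest at the smallest angles.
    """
    q_lo, q_hi = result.q_window
    m = (profile.q >= q_lo) & (profile.q <= q_hi) & (profile.intensity > 0)
    q, i, s = profile.q[m], profile.intensity[m], profile.sigma[m]
    z = (np.log(i) - np.log(result.evaluate(q))) * (i / s)
    n = z.size
    n_low = max(3, int(np.ceil(0.2 * n)))
    z_low = z[:n_low]
    mean_z_low = float(z_low.mean())
    frac_pos = float(np.mean(z_low > 0))
    signs = np.sign(z)
    n_runs = int(1 + np.count_nonzero(np.diff(signs[signs != 0]) != 0)) if n else 0
    n_pos, n_neg = int((z > 0).sum()), int((z < 0).sum())
    exp_runs = 1.0 + 2.0 * n_pos * n_neg / max(n_pos + n_neg, 1)
    upturn = (mean_z_low > z_threshold) and (frac_pos >= frac_threshold)
    return QualityReport(upturn=upturn, mean_z_low=mean_z_low,
                         frac_positive_low=frac_pos, n_runs=n_runs,
                         n_runs_expected=exp_runs, n_points=n, residuals=z)
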