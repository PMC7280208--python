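"""Extraction of the monomer scattering profile from an aggregate-bearing solution.

The pipeline combines one SAXS/SANS measurement of the whole solution with the
species weight fractions from a sedimentation-velocity AUC run:

1. Guinier analysis of the measured curve gives the apparent forward intensity
   c*i_exp(0) (and an apparent Rg, inflated by the aggregates).
2. The monomer's share of the forward intensity follows from the weight
   fractions alone: t1 = w1 / sum_j w_j*j, because forward intensity per unit
   mass scales with the aggregation number j.  Hence i_1(0) = t1*c*i_exp(0)/c1.
3. At high q (q > q* = 1/Rg1) the per-mass intensity of a compact j-mer is
   indistinguishable from the monomer's within a small Debye-model bound, so
   the monomer curve is read directly off the measured one there.
4. The gap below q* is bridged by a Guinier branch anchored at i_1(0), with
   Rg chosen so the logarithmic slope matches the data at a connection point
   q_c, then refined against an extended Guinier model until the stitched
   curve is self-consistent.

The residual c_a*i_a(q) = c*i_exp(q) - c1*i_1(q) is the aggregate contribution.
The method is reliable up to roughly 12% total aggregate weight fraction and
is refused above 25%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import oligomers
from .guinier import (GuinierError, GuinierResult, extended_guinier_fit,
                      guinier_fit, guinier_quality)
from .profiles_io import ComponentTable, ScatteringProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "MonomerExtractionResult",
    "ConnectionResult",
    "forward_fraction",
    "monomer_forward_intensity",
    "assign_high_q",
    "connect_low_q",
    "refine",
    "extract_monomer",
]

AGGREGATE_WARN_FRACTION = 0.12   # validity boundary of the protocol
AGGREGATE_REFUSE_FRACTION = 0.25


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the monomer-extraction pipeline."""

    qRg_max: float = 1.3            # plain Guinier window limit
    qRg_max_ext: float = 2.0        # extended-Guinier window limit
    expansion_order: int = 2        # polynomial order in q^2 of the extended fit
    qc_qRg_max: float = 1.3         # upper bound of the q_c scan: q_c*Rg <= this
    refine_window_start: float = 1.15  # refinement window starts at this/Rg1
    contact_distance: float | None = None  # Debye-model d [Å]; None -> 2*sqrt(5/3)*Rg1
    aggregate_warn: float = AGGREGATE_WARN_FRACTION
    aggregate_refuse: float = AGGREGATE_REFUSE_FRACTION
    allow_upturn: bool = False      # proceed despite a low-q upturn flag
    rg_tol: float = 1e-4            # refinement convergence on |dRg|/Rg
    max_refine_iter: int = 50
    outer_tol: float = 1e-3         # q* update loop convergence
    max_outer_iter: int = 4


@dataclass(frozen=True)
class ConnectionResult:
    """Low-q Guinier branch connected to the high-q experimental branch."""

    Rg1_star: float
    q_c: float
    mismatch: float          # |ln i1l*(q_c) - ln i1h*(q_c)| at the chosen q_c
    Rg1_star_err: float
    stitched: ScatteringProfile
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class MonomerExtractionResult:
    """Full output of the monomer-extraction pipeline (per-mass scale)."""

    i1: ScatteringProfile            # per-mass monomer intensity i_1(q)
    i1_0: float                      # forward intensity i_1(0)
    i1_0_err: float
    Rg1: float                       # monomer radius of gyration [Å]
    Rg1_err: float
    t1: float                        # monomer share of forward scattering
    q_star: float                    # high-q validity threshold [1/Å]
    q_c: float                       # connection point [1/Å]
    aggregate_intensity: ScatteringProfile   # c_a*i_a(q) = c*i_exp - c1*i_1
    model_bound: dict[str, float]    # max |r-1| above q* per Debye geometry
    guinier_exp: GuinierResult       # Guinier fit of the measured mixture
    iterations: int
    warnings: tuple[str, ...] = ()

    def report(self) -> dict:
        """Flat serializable summary of the extraction."""
        return {
            "t1": self.t1, "i1_0": self.i1_0, "i1_0_err": self.i1_0_err,
            "Rg1": self.Rg1, "Rg1_err": self.Rg1_err,
            "q_star": self.q_star, "q_c": self.q_c,
            "Rg_apparent": self.guinier_exp.Rg,
            "model_bound_linear": self.model_bound.get("linear"),
            "model_bound_close_packed": self.model_bound.get("close_packed"),
            "iterations": self.iterations,
            "warnings": list(self.warnings),
        }


def forward_fraction(components: ComponentTable) -> float:
    """Monomer share of the forward scattering: t1 = w1 / sum_j w_j*j.

    Only concentration ratios enter, so weight fractions suffice; the result
    is invariant under any common rescaling of the concentrations.
    """
    w1 = components.monomer_fraction
    denom = sum(e.weight_fraction * e.j for e in components.entries)
    return w1 / denom


def monomer_forward_intensity(i_exp_0: float, c: float,
                              components: ComponentTable) -> tuple[float, float]:
    """Monomer forward intensity from the mixture's: i1(0) = t1*c*i_exp(0)/c1.

    Returns ``(i1_0, aggregate_forward)`` where the second term is the excess
    forward scattering (1 - t1)*c*i_exp(0) contributed by the aggregates.
    ``i_exp_0`` is per unit total mass; ``c`` the total mass concentration.
    """
    w1 = components.monomer_fraction
    if w1 <= 0:
        raise ValueError("monomer concentration c1 is zero")
    t1 = forward_fraction(components)
    ci_exp0 = c * i_exp_0
    return t1 * ci_exp0 / (w1 * c), (1.0 - t1) * ci_exp0


def assign_high_q(i_exp: ScatteringProfile, q_star: float) -> ScatteringProfile:
    """Tentative monomer intensity at high q: i_1h(q_h)* = i_exp(q_h), q_h > q*.

    Valid because compact homo-oligomers scatter per unit mass like the
    monomer once q exceeds q* = 1/Rg1 (Debye-model deviation below ~1.8%).
    The input must be on the per-mass scale.
    """
    if q_star >= i_exp.q[-1]:
        raise ValueError(f"q* = {q_star:.4g} is beyond the measured range "
                         f"(q_max = {i_exp.q[-1]:.4g})")
    return i_exp.restrict(q_min=q_star, inclusive=False)


def _local_log_slopes(qh: np.ndarray, y: np.ndarray, w: np.ndarray,
                      half: int) -> tuple[np.ndarray, np.ndarray]:
    """Weighted linear slope of y vs q^2 in a sliding window around each point."""
    n = qh.size
    slopes = np.full(n, np.nan)
    errs = np.full(n, np.nan)
    q2 = qh ** 2
    for c in range(half, n - half):
        sl = slice(c - half, c + half + 1)
        x, yy, ww = q2[sl], y[sl], w[sl]
        xm = np.average(x, weights=ww)
        ym = np.average(yy, weights=ww)
        sxx = np.sum(ww * (x - xm) ** 2)
        if sxx <= 0:
            continue
        slopes[c] = np.sum(ww * (x - xm) * (yy - ym)) / sxx
        errs[c] = np.sqrt(1.0 / sxx)
    return slopes, errs


def connect_low_q(i1_0: float, i1h_star: ScatteringProfile, q_star: float,
                  q_full: np.ndarray | None = None, i1_0_err: float = 0.0,
                  qc_qRg_max: float = 1.3,
                  mismatch_warn: float = 0.05) -> ConnectionResult:
    """Bridge i_1(0) and the high-q branch with a slope-matched Guinier arc.

    Scans candidate connection points q_c over the grid above ``q_star``.  At
    each candidate the local logarithmic slope s = d ln(i1h*)/d(q^2) is taken
    from a weighted linear fit over a sliding window; the Guinier branch
    i1l*(q) = i1(0)*exp(-Rg*^2 q^2/3) with Rg* = sqrt(-3 s) then matches the
    data's slope there by construction.  The q_c minimizing the remaining
    value mismatch |ln i1l*(q_c) - ln i1h*(q_c)| is selected (restricted to
    candidates with q_c*Rg* <= ``qc_qRg_max``, the edge of Guinier validity).

    Returns the stitched per-mass profile on ``q_full`` (default: the high-q
    grid plus nothing below — pass the full measured grid to cover low q).
    """
    pos = i1h_star.intensity > 0
    qh = i1h_star.q[pos]
    ih = i1h_star.intensity[pos]
    sh = i1h_star.sigma[pos]
    if qh.size < 7:
        raise GuinierError("high-q branch too short for slope matching")
    y = np.log(ih)
    w = (ih / sh) ** 2
    half = max(3, int(round(0.025 * qh.size)))   # window = max(7, 5% of grid)
    slopes, errs = _local_log_slopes(qh, y, w, half)

    warnings: list[str] = []
    valid = np.isfinite(slopes) & (slopes < 0)
    rg = np.sqrt(-3.0 * np.where(valid, slopes, np.nan))
    valid &= qh * rg <= qc_qRg_max
    if not valid.any():
        raise GuinierError("no candidate connection point with a physical, "
                           "Guinier-compatible local slope above q*")
    ln_low = np.log(i1_0) - rg ** 2 * qh ** 2 / 3.0
    mismatch = np.abs(ln_low - y)
    mismatch[~valid] = np.inf
    c = int(np.argmin(mismatch))
    q_c, rg_star = float(qh[c]), float(rg[c])
    rg_err = float(1.5 / rg_star * errs[c]) if np.isfinite(errs[c]) else 0.0
    mis = float(mismatch[c])
    if mis > mismatch_warn:
        warnings.append(
            f"stitch mismatch {mis:.3f} in ln-intensity at q_c = {q_c:.4g} "
            "(> {:.0f}%): i1(0) and the high-q branch may be inconsistent".format(
                100 * mismatch_warn))

    if q_full is None:
        q_full = i1h_star.q
    stitched = _stitch(np.asarray(q_full, float), i1h_star, i1_0, i1_0_err,
                       rg_star, rg_err, q_c)
    return ConnectionResult(Rg1_star=rg_star, q_c=q_c, mismatch=mis,
                            Rg1_star_err=rg_err, stitched=stitched,
                            warnings=tuple(warnings))


def _stitch(q_full: np.ndarray, i1h_star: ScatteringProfile, i1_0: float,
            i1_0_err: float, rg: float, rg_err: float, q_c: float) -> ScatteringProfile:
    """Guinier branch below q_c, experimental branch at and above q_c."""
    low = q_full < q_c
    i_low = i1_0 * np.exp(-(rg * q_full[low]) ** 2 / 3.0)
    # first-order propagation through the Guinier formula
    rel_var = (i1_0_err / i1_0) ** 2 + (2.0 * rg * q_full[low] ** 2 * rg_err / 3.0) ** 2
    s_low = i_low * np.sqrt(rel_var)
    s_low = np.maximum(s_low, 1e-8 * i1_0)      # keep sigma positive
    i_high = np.interp(q_full[~low], i1h_star.q, i1h_star.intensity)
    s_high = np.interp(q_full[~low], i1h_star.q, i1h_star.sigma)
    return ScatteringProfile(q_full,
                             np.concatenate([i_low, i_high]),
                             np.concatenate([s_low, s_high]),
                             concentration=1.0, label="i1_star")


def _best_connection(i1h: ScatteringProfile, i1_0: float, rg: float,
                     q_lo: float, q_hi: float) -> tuple[float, float]:
    """Connection point for a *fixed* Rg1: the grid q in [q_lo, q_hi] where the
    Guinier branch and the measured branch agree best in ln-intensity."""
    m = (i1h.q >= q_lo) & (i1h.q <= q_hi) & (i1h.intensity > 0)
    if not m.any():
        m = i1h.intensity > 0
    qm = i1h.q[m]
    mis = np.abs(np.log(i1_0) - (rg * qm) ** 2 / 3.0 - np.log(i1h.intensity[m]))
    k = int(np.argmin(mis))
    return float(qm[k]), float(mis[k])


def refine(i1_star: ScatteringProfile, i1_0: float, q_c: float,
           i1_0_err: float = 0.0, config: ExtractionConfig = ExtractionConfig(),
           rg_init: float | None = None, model_band=None,
           ) -> tuple[ScatteringProfile, GuinierResult, int, float, tuple[str, ...]]:
    """Fixed-point refinement of the candidate monomer profile.

    Fits the extended Guinier model ln i = ln i1(0) + b1 q^2 + b2 q^4 (+ ...)
    with the intercept held at ``i1_0`` to the *measured* branch of the
    candidate: points with q >= max(q_c, refine_window_start/Rg1) and
    q <= qRg_max_ext/Rg1.  The anchored intercept carries the low-q
    information, so the regenerated Guinier branch never feeds back into its
    own fit, and the window edges are deterministic functions of Rg1 rather
    than of a noisy per-curve choice.  Both window edges depend on Rg1, hence
    the iteration: fit -> update Rg1 -> re-window -> refit; on convergence
    (relative Rg1 change below ``config.rg_tol``) the low-q Guinier branch is
    regenerated with the final Rg1 and re-stitched at the best connection
    point.  ``model_band(q, Rg1)``, if given, returns the relative systematic
    bound on the measured branch (the Debye-model |r - 1| band); it widens the
    effective sigma instead of correcting the data.  Non-convergence raises
    with the last iterate attached.
    """
    from .guinier import _weighted_polyfit  # shared weighted LS core

    pos = (i1_star.q >= q_c) & (i1_star.intensity > 0)
    qh = i1_star.q[pos]
    ih = i1_star.intensity[pos]
    yh = np.log(ih)
    sh = i1_star.sigma[pos]
    rg = rg_init if rg_init is not None else float(
        np.sqrt(-3.0 * (yh[0] - np.log(i1_0)) / qh[0] ** 2))
    order = config.expansion_order
    fit: GuinierResult | None = None
    history: list[float] = []
    for it in range(1, config.max_refine_iter + 1):
        m = (qh <= config.qRg_max_ext / rg) & (qh >= config.refine_window_start / rg)
        if m.sum() < order + 2:
            m = qh <= config.qRg_max_ext / rg
        if m.sum() < order + 2:
            m = np.zeros_like(m)
            m[:order + 2] = True
        s_eff = sh[m]
        if model_band is not None:
            s_eff = np.sqrt(s_eff ** 2 + (model_band(qh[m], rg) * ih[m]) ** 2)
        wh = (ih[m] / s_eff) ** 2
        beta, cov, chi2 = _weighted_polyfit(qh[m] ** 2, yh[m], wh, order,
                                            y0=np.log(i1_0))
        if beta[1] >= 0:
            raise GuinierError("positive refined ln i vs q^2 slope: no Guinier region")
        rg = float(np.sqrt(-3.0 * beta[1]))
        rg_err = float(1.5 / rg * np.sqrt(cov[1, 1]))
        n = int(m.sum())
        fit = GuinierResult(I0=i1_0, Rg=rg, q_window=(float(qh[m][0]), float(qh[m][-1])),
                            I0_err=i1_0_err, Rg_err=rg_err,
                            chi2_reduced=chi2 / max(n - order, 1), n_points=n,
                            coeffs=tuple(beta[1:]), qRg_max=config.qRg_max_ext)
        # single grid points entering/leaving the window can toggle Rg1 by
        # more than the tolerance, producing short limit cycles: returning to
        # within tolerance of any recent iterate counts as converged
        if any(abs(rg - prev) / prev < config.rg_tol for prev in history[-4:]):
            high = i1_star.restrict(q_min=q_c, inclusive=True)
            q_c_final, mis = _best_connection(high, i1_0, rg, q_c,
                                              config.qc_qRg_max / rg)
            current = _stitch(i1_star.q, high, i1_0, i1_0_err, rg, rg_err,
                              q_c_final)
            warn = ()
            if mis > 0.05:
                warn = (f"stitch mismatch {mis:.3f} in ln-intensity at the "
                        f"refined connection point q_c = {q_c_final:.4g}",)
            return current, fit, it, q_c_final, warn
        history.append(rg)
    err = GuinierError(f"refinement did not converge in {config.max_refine_iter} "
                       f"iterations (last Rg1 = {rg:.4g})")
    err.last_iterate = (i1_star, fit)  # type: ignore[attr-defined]
    raise err


def extract_monomer(i_exp: ScatteringProfile, components: ComponentTable,
                    config: ExtractionConfig = ExtractionConfig(),
                    ) -> MonomerExtractionResult:
    """Full pipeline: measured mixture + AUC fractions -> monomer profile.

    ``i_exp`` should carry its total mass concentration; if it does not, its
    intensities are taken as already per unit mass.  Returns the per-mass
    monomer profile i_1(q), the aggregate residual c_a*i_a(q), and all
    intermediate scalars.
    """
    warnings: list[str] = []
    c = i_exp.concentration if i_exp.concentration is not None else 1.0
    ipm = i_exp.per_mass() if i_exp.concentration is not None else i_exp

    agg = components.aggregate_fraction
    if agg > config.aggregate_refuse:
        raise ValueError(
            f"aggregate weight fraction {agg:.1%} exceeds the {config.aggregate_refuse:.0%} "
            "hard cap; the high-q monomer identity breaks down — purify further")
    if agg > config.aggregate_warn:
        warnings.append(f"aggregate fraction {agg:.1%} above the {config.aggregate_warn:.0%} "
                        "validity boundary; extracted parameters may be biased")

    g_exp = guinier_fit(ipm, qRg_max=config.qRg_max)
    quality = guinier_quality(ipm, g_exp)
    if quality.upturn:
        msg = ("low-q upturn detected in the Guinier residuals "
               f"(mean z = {quality.mean_z_low:.2f}); the sample likely contains "
               "large aggregates outside the protocol's validity")
        if not config.allow_upturn:
            raise GuinierError(msg)
        warnings.append(msg)
    logger.info("mixture Guinier: Rg_app = %.3f Å, c*i_exp(0) = %.4g",
                g_exp.Rg, c * g_exp.I0)

    w1 = components.monomer_fraction
    t1 = forward_fraction(components)
    i1_0, agg_forward = monomer_forward_intensity(g_exp.I0, c, components)
    i1_0_err = t1 * c * g_exp.I0_err / (w1 * c)
    logger.info("t1 = %.5f, i1(0) = %.4g (aggregate forward share %.4g)",
                t1, i1_0, agg_forward)

    def band(qs: np.ndarray, rg: float) -> np.ndarray:
        # Debye-model |r(q) - 1| band, worst case over the two geometries:
        # treated as a systematic uncertainty of the measured branch, never
        # as a correction to it
        d = (config.contact_distance if config.contact_distance is not None
             else oligomers.default_contact_distance(rg))
        worst = np.zeros_like(qs)
        for geom in oligomers.GEOMETRIES:
            model = oligomers.OligomerModel(geometry=geom, contact_distance=d)
            r = np.zeros_like(qs)
            for e in components.entries:
                r += e.weight_fraction * oligomers.structure_factor(qs, e.j, model)
            worst = np.maximum(worst, np.abs(r - 1.0))
        return worst

    # tentative stitch at the apparent size, then refinement against the
    # measured branch with q* tracking the refined Rg1
    q_star = oligomers.critical_q(g_exp.Rg)
    i1h = assign_high_q(ipm, q_star)
    conn = connect_low_q(i1_0, i1h, q_star, q_full=ipm.q, i1_0_err=i1_0_err,
                         qc_qRg_max=config.qc_qRg_max)
    rg_current = conn.Rg1_star
    iterations = 0
    for outer in range(config.max_outer_iter):
        q_star = oligomers.critical_q(min(rg_current, g_exp.Rg))
        measured = ipm.restrict(q_min=q_star, inclusive=False)
        refined, fit, n_iter, q_c, ref_warn = refine(
            measured, i1_0, q_c=q_star, i1_0_err=i1_0_err, config=config,
            rg_init=rg_current, model_band=band)
        iterations += n_iter
        warnings.extend(ref_warn)
        logger.info("outer %d: q* = %.4g, q_c = %.4g, Rg1 = %.3f Å (%d inner)",
                    outer + 1, q_star, q_c, fit.Rg, n_iter)
        if abs(fit.Rg - rg_current) / rg_current < config.outer_tol:
            rg_current = fit.Rg
            break
        rg_current = fit.Rg
    warnings.extend(conn.warnings)
    rg1, rg1_err = fit.Rg, fit.Rg_err
    # q* tracks the final Rg1 but never overtakes the connection point
    q_star = min(oligomers.critical_q(rg1), q_c)
    # the refined profile covers q >= old q*; rebuild on the full grid
    high = refined.restrict(q_min=q_c, inclusive=True)
    i1 = _stitch(ipm.q, high, i1_0, i1_0_err, rg1, rg1_err, q_c)

    d = (config.contact_distance if config.contact_distance is not None
         else oligomers.default_contact_distance(rg1))
    bound = oligomers.max_deviation_both(i1, components, d, q_from=q_star)
    if bound["worst"] > oligomers.DEBYE_BOUND:
        warnings.append(
            f"Debye-model deviation above q* is {bound['worst']:.2%} "
            f"(> {oligomers.DEBYE_BOUND:.1%}); the aggregate load strains the "
            "high-q monomer identity")

    agg_i = c * ipm.intensity - (w1 * c) * i1.intensity
    agg_s = np.sqrt((c * ipm.sigma) ** 2 + (w1 * c * i1.sigma) ** 2)
    aggregate = ScatteringProfile(ipm.q, agg_i, agg_s, concentration=None,
                                  label="c_a*i_a")

    return MonomerExtractionResult(
        i1=i1, i1_0=i1_0, i1_0_err=i1_0_err, Rg1=rg1, Rg1_err=rg1_err, t1=t1,
        q_star=q_star, q_c=q_c, aggregate_intensity=aggregate,
        model_bound=bound, guinier_exp=g_exp, iterations=iterations,
        warnings=tuple(warnings))
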