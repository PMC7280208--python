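"""Association-dissociation equilibrium: SE-AUC K_D fitting and complex extraction.

For a heterodimer system A + B <-> AB, sedimentation equilibrium in a
centrifugal field produces the radial absorbance profile

    a(r) = eps_A cA(r0) exp[s_A (r^2 - r0^2)]
         + eps_B cB(r0) exp[s_B (r^2 - r0^2)]
         + eps_AB cA(r0) cB(r0) / K_D * exp[s_AB (r^2 - r0^2)]  (+ baseline)

with the reduced buoyant term s_X = omega^2 M_X (1 - vbar_X rho) / (2RT).
The complex amplitude is slaved to the free-species reference concentrations
through mass action, which is what makes K_D identifiable.  K_D is shared
across scans at several rotor speeds and loading concentrations in a global
weighted least-squares fit.

With K_D known, mass action at the SAXS loading concentrations gives
(c_A, c_B, c_AB), and the complex scattering profile follows by subtraction:

    i_AB(q) = [c i_exp(q) - c_A i_A(q) - c_B i_B(q)] / c_AB.

Units: molar concentrations in µM at the interface (molar internally), mass
concentrations in mg/mL, M in Da, K_D reported in µM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .profiles_io import ComponentTable, ScatteringProfile, SEScan, regrid

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "EquilibriumSystem",
    "Concentrations",
    "ComplexExtractionResult",
    "KDFitResult",
    "se_model",
    "global_fit_kd",
    "mass_action",
    "molar_to_mass",
    "decompose_complex",
    "check_aggregation_free",
    "system_from_dict",
]

R_GAS = 8.314462618  # J / (mol K)


@dataclass(frozen=True)
class Species:
    """One solute species: mass, buoyancy and absorbance constants."""

    name: str
    M: float               # molecular weight [Da]
    vbar: float = 0.73     # partial specific volume [mL/g]
    epsilon: float = 0.0   # extinction coefficient [AU / M], path length folded in

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError("M must be > 0")
        if not (0.3 < self.vbar < 1.2):
            raise ValueError(f"implausible partial specific volume {self.vbar}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class EquilibriumSystem:
    """A + B <-> AB system constants; M_AB = M_A + M_B by construction."""

    A: Species
    B: Species
    KD_uM: float | None = None          # dissociation constant [µM], if known
    loadings: tuple[tuple[float, float], ...] = ()  # (total_A, total_B) [µM] per cell
    solvent_density: float = 1.0        # rho [g/mL]
    temperature: float = 298.15         # [K]
    vbar_AB: float | None = None        # default: mass-weighted mean of A and B
    epsilon_AB: float | None = None     # default: eps_A + eps_B (additive chromophores)

    @property
    def M_AB(self) -> float:
        return self.A.M + self.B.M

    @property
    def AB(self) -> Species:
        vbar = self.vbar_AB if self.vbar_AB is not None else \
            (self.A.M * self.A.vbar + self.B.M * self.B.vbar) / self.M_AB
        eps = self.epsilon_AB if self.epsilon_AB is not None else \
            self.A.epsilon + self.B.epsilon
        return Species("AB", self.M_AB, vbar, eps)


def _reduced_buoyancy(omega: float, M: float, vbar: float, rho: float,
                      T: float) -> float:
    """s_X = omega^2 M (1 - vbar*rho) / (2RT) in cm^-2 (M in Da, r in cm)."""
    return omega ** 2 * (M * 1e-3) * (1.0 - vbar * rho) / (2.0 * R_GAS * T) * 1e-4


def se_model(radius: np.ndarray, rpm: float, system: EquilibriumSystem,
             cA0: float, cB0: float, KD_M: float, baseline: float = 0.0,
             r0: float | None = None, temperature: float | None = None) -> np.ndarray:
    """Predicted absorbance a(r) of the equilibrium system at one rotor speed.

    ``cA0``/``cB0`` are the *free* molar concentrations [M] at the reference
    radius ``r0`` (default: innermost radius; only differences r^2 - r0^2
    enter, so the reference is a convention).  ``KD_M`` in molar.
    """
    if cA0 < 0 or cB0 < 0:
        raise ValueError("reference concentrations must be >= 0")
    r = np.asarray(radius, dtype=float)
    if r0 is None:
        r0 = float(r[0])
    T = temperature if temperature is not None else system.temperature
    omega = 2.0 * np.pi * rpm / 60.0
    rho = system.solvent_density
    dr2 = r ** 2 - r0 ** 2
    ab = system.AB
    sA = _reduced_buoyancy(omega, system.A.M, system.A.vbar, rho, T)
    sB = _reduced_buoyancy(omega, system.B.M, system.B.vbar, rho, T)
    sAB = _reduced_buoyancy(omega, ab.M, ab.vbar, rho, T)
    a = (system.A.epsilon * cA0 * np.exp(sA * dr2)
         + system.B.epsilon * cB0 * np.exp(sB * dr2)
         + ab.epsilon * cA0 * cB0 / KD_M * np.exp(sAB * dr2))
    return a + baseline


@dataclass(frozen=True)
class KDFitResult:
    """Global SE-AUC fit output."""

    KD_uM: float
    KD_err_uM: float
    per_scan: tuple[dict, ...]       # cA0_uM, cB0_uM, baseline, chi2_reduced per scan
    chi2_reduced: float
    n_points: int
    n_parameters: int
    success: bool


def _init_reference_conc(scan: SEScan, system: EquilibriumSystem,
                         kd_M: float) -> tuple[float, float]:
    """Heuristic starting reference concentrations for one scan.

    Picks cA0 = cB0 = c0 matching the scan's mean absorbance under the model,
    i.e. solves the quadratic eps_AB*mAB/KD * c0^2 + (eps_A*mA + eps_B*mB)*c0
    = mean(a), with mX the radial means of the exponential factors.
    """
    ab = system.AB
    omega = scan.omega
    rho, T = system.solvent_density, scan.temperature
    dr2 = scan.radius ** 2 - scan.radius[0] ** 2
    mA = np.mean(np.exp(_reduced_buoyancy(omega, system.A.M, system.A.vbar, rho, T) * dr2))
    mB = np.mean(np.exp(_reduced_buoyancy(omega, system.B.M, system.B.vbar, rho, T) * dr2))
    mAB = np.mean(np.exp(_reduced_buoyancy(omega, ab.M, ab.vbar, rho, T) * dr2))
    a_mean = max(float(np.mean(scan.absorbance)), 1e-6)
    qa = ab.epsilon * mAB / kd_M
    qb = system.A.epsilon * mA + system.B.epsilon * mB
    c0 = (-qb + np.sqrt(qb ** 2 + 4.0 * qa * a_mean)) / (2.0 * qa) if qa > 0 \
        else a_mean / qb
    return max(c0, 1e-9), max(c0, 1e-9)


def global_fit_kd(scans: list[SEScan], system: EquilibriumSystem,
                  fit_baseline: bool = True, kd_init_uM: float = 10.0,
                  sigma_AU: float | None = None) -> KDFitResult:
    """Global weighted least-squares fit of the SE model across all scans.

    K_D is shared; the free reference concentrations (and optionally an
    additive baseline) vary per scan.  Positivity is enforced by fitting
    log-concentrations and log K_D (Levenberg-Marquardt on the unconstrained
    parameterization, so the result is a local minimizer from the stated
    initialization).  K_D +/- sigma comes from the covariance at the optimum
    with the residual variance estimated from the fit.
    """
    if len(scans) < 1:
        raise ValueError("at least one scan required")
    if len(scans) < 2:
        logger.warning("global fit with a single scan: K_D is weakly constrained")
    kd0 = kd_init_uM * 1e-6
    x0 = [np.log(kd0)]
    for scan in scans:
        cA0, cB0 = _init_reference_conc(scan, system, kd0)
        x0 += [np.log(cA0), np.log(cB0)]
        if fit_baseline:
            x0.append(0.0)
    x0 = np.asarray(x0)
    n_per = 3 if fit_baseline else 2
    weights = [1.0 / (sigma_AU if sigma_AU else 1.0)] * len(scans)

    def residuals(x: np.ndarray) -> np.ndarray:
        kd = np.exp(x[0])
        out = []
        for k, scan in enumerate(scans):
            off = 1 + k * n_per
            cA0, cB0 = np.exp(x[off]), np.exp(x[off + 1])
            base = x[off + 2] if fit_baseline else 0.0
            model = se_model(scan.radius, scan.rpm, system, cA0, cB0, kd,
                             baseline=base, temperature=scan.temperature)
            out.append((model - scan.absorbance) * weights[k])
        return np.concatenate(out)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=20000)
    n_pts = sum(len(s) for s in (sc.absorbance for sc in scans))
    n_par = x0.size
    dof = max(n_pts - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    # covariance of the log-parameters from the Gauss-Newton approximation
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("rank-deficient Jacobian in the global fit") from exc
    kd = float(np.exp(sol.x[0]))
    # delta method on log K_D; a non-positive variance signals a numerically
    # degenerate fit, reported as an undetermined (infinite) error
    var_log_kd = float(cov[0, 0])
    kd_err = kd * np.sqrt(var_log_kd) if var_log_kd > 0 else np.inf

    per_scan = []
    for k, scan in enumerate(scans):
        off = 1 + k * n_per
        cA0, cB0 = float(np.exp(sol.x[off])), float(np.exp(sol.x[off + 1]))
        base = float(sol.x[off + 2]) if fit_baseline else 0.0
        model = se_model(scan.radius, scan.rpm, system, cA0, cB0, kd,
                         baseline=base, temperature=scan.temperature)
        resid = (model - scan.absorbance) * weights[k]
        chi2 = float(np.sum(resid ** 2)) / max(len(scan.absorbance) - n_per, 1)
        per_scan.append({"rpm": scan.rpm, "loading_uM": scan.loading,
                         "cA0_uM": cA0 * 1e6, "cB0_uM": cB0 * 1e6,
                         "baseline": base, "chi2_reduced": chi2})
    return KDFitResult(KD_uM=kd * 1e6, KD_err_uM=kd_err * 1e6,
                       per_scan=tuple(per_scan),
                       chi2_reduced=s2 if sigma_AU else 2.0 * sol.cost / dof,
                       n_points=n_pts, n_parameters=n_par, success=bool(sol.success))


def mass_action(KD: float, total_A: float, total_B: float) -> tuple[float, float, float]:
    """Free and complex concentrations from K_D and totals (same molar unit).

    Solves A_free*B_free = K_D*AB with A_free + AB = total_A and
    B_free + AB = total_B; returns ``(free_A, free_B, AB)``.  The physical
    root of the quadratic AB^2 - (tA + tB + KD)*AB + tA*tB = 0 is the smaller
    one (the larger root exceeds min(tA, tB)).
    """
    if KD <= 0:
        raise ValueError("KD must be > 0")
    if total_A < 0 or total_B < 0:
        raise ValueError("totals must be >= 0")
    s = total_A + total_B + KD
    disc = s * s - 4.0 * total_A * total_B
    ab = 2.0 * total_A * total_B / (s + np.sqrt(disc))  # numerically stable small root
    return total_A - ab, total_B - ab, ab


def molar_to_mass(c_uM: float, M: float) -> float:
    """Convert a molar concentration [µM] to mass concentration [mg/mL]."""
    return c_uM * 1e-6 * M


@dataclass(frozen=True)
class Concentrations:
    """Mass concentrations [mg/mL] of the three species, with optional 1-sigma errors."""

    c_A: float
    c_B: float
    c_AB: float
    c_A_err: float = 0.0
    c_B_err: float = 0.0
    c_AB_err: float = 0.0

    def __post_init__(self) -> None:
        if min(self.c_A, self.c_B, self.c_AB) < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def total(self) -> float:
        return self.c_A + self.c_B + self.c_AB

    @classmethod
    def from_mass_action(cls, system: EquilibriumSystem, KD_uM: float,
                         total_A_uM: float, total_B_uM: float,
                         KD_err_uM: float = 0.0) -> "Concentrations":
        """Mass concentrations at a SAXS loading from the fitted K_D."""
        fa, fb, ab = mass_action(KD_uM, total_A_uM, total_B_uM)
        # K_D uncertainty propagated by finite difference through mass action
        if KD_err_uM > 0:
            h = 1e-4 * KD_uM
            fa2, fb2, ab2 = mass_action(KD_uM + h, total_A_uM, total_B_uM)
            dfa, dfb, dab = (fa2 - fa) / h, (fb2 - fb) / h, (ab2 - ab) / h
        else:
            dfa = dfb = dab = 0.0
        return cls(
            c_A=molar_to_mass(fa, system.A.M),
            c_B=molar_to_mass(fb, system.B.M),
            c_AB=molar_to_mass(ab, system.M_AB),
            c_A_err=abs(molar_to_mass(dfa * KD_err_uM, system.A.M)),
            c_B_err=abs(molar_to_mass(dfb * KD_err_uM, system.B.M)),
            c_AB_err=abs(molar_to_mass(dab * KD_err_uM, system.M_AB)),
        )


@dataclass(frozen=True)
class ComplexExtractionResult:
    i_AB: ScatteringProfile
    concentrations: Concentrations
    KD_uM: float | None = None
    KD_err_uM: float | None = None
    chi2_per_scan: tuple[float, ...] = ()


def decompose_complex(i_exp: ScatteringProfile, i_A: ScatteringProfile,
                      i_B: ScatteringProfile, concentrations: Concentrations,
                      KD_uM: float | None = None, KD_err_uM: float | None = None,
                      ) -> ComplexExtractionResult:
    """Subtraction decomposition: i_AB = (c i_exp - c_A i_A - c_B i_B)/c_AB.

    Profiles may be on different q-grids; they are restricted to the common
    overlap and the component profiles linearly resampled onto the mixture's
    grid.  Profiles carrying a concentration are converted to per-mass scale;
    otherwise they are assumed per-mass already.  Uncertainties combine the
    three intensity errors and the concentration errors in quadrature.
    """
    cc = concentrations
    if cc.c_AB <= 0:
        raise ValueError("c_AB must be > 0 to extract the complex profile")
    c = i_exp.concentration if i_exp.concentration is not None else cc.total

    def _pm(p: ScatteringProfile) -> ScatteringProfile:
        return p.per_mass() if p.concentration is not None else p

    exp_pm, a_pm, b_pm = _pm(i_exp), _pm(i_A), _pm(i_B)
    lo = max(exp_pm.q[0], a_pm.q[0], b_pm.q[0])
    hi = min(exp_pm.q[-1], a_pm.q[-1], b_pm.q[-1])
    if lo >= hi:
        raise ValueError("q-grids of the three profiles do not overlap")
    mix = exp_pm.restrict(lo, hi)
    a_r = regrid(a_pm, mix.q)
    b_r = regrid(b_pm, mix.q)

    num = c * mix.intensity - cc.c_A * a_r.intensity - cc.c_B * b_r.intensity
    i_ab = num / cc.c_AB
    var = ((c * mix.sigma) ** 2
           + (cc.c_A * a_r.sigma) ** 2 + (a_r.intensity * cc.c_A_err) ** 2
           + (cc.c_B * b_r.sigma) ** 2 + (b_r.intensity * cc.c_B_err) ** 2)
    var = var / cc.c_AB ** 2 + (i_ab * cc.c_AB_err / cc.c_AB) ** 2
    sigma = np.sqrt(var)
    prof = ScatteringProfile(mix.q, i_ab, sigma, concentration=1.0,
                             label="i_AB")
    return ComplexExtractionResult(i_AB=prof, concentrations=cc,
                                   KD_uM=KD_uM, KD_err_uM=KD_err_uM)


@dataclass(frozen=True)
class AggregationCheck:
    passed: bool
    extra_fraction: float
    warnings: tuple[str, ...] = ()


def check_aggregation_free(components: ComponentTable,
                           system: EquilibriumSystem | None = None,
                           threshold: float = 0.02,
                           mass_rtol: float = 0.15) -> AggregationCheck:
    """Verify the SV-AUC species table of the mixture shows no aggregates.

    Species whose mass matches M_A, M_B or M_AB within ``mass_rtol`` (or whose
    mass is not annotated) are the expected equilibrium participants; any
    other species failing that match is an aggregate.  Total extra fraction
    above ``threshold`` fails the check; a nonzero fraction at or below it
    passes with a warning.  Run this before trusting an SE-AUC K_D.
    """
    expected = []
    if system is not None:
        expected = [system.A.M, system.B.M, system.M_AB]
    extra = 0.0
    for e in components.entries:
        if e.mass is None:
            continue  # unannotated: assumed to be a declared participant
        if expected and any(abs(e.mass - m) <= mass_rtol * m for m in expected):
            continue
        if not expected and e.j == 1:
            continue
        extra += e.weight_fraction
    warnings: tuple[str, ...] = ()
    if extra > threshold:
        return AggregationCheck(False, extra,
                                (f"extra species carry {extra:.1%} of the mass "
                                 f"(> {threshold:.0%}): aggregation suspected",))
    if extra > 0:
        warnings = (f"trace extra species at {extra:.1%} (<= {threshold:.0%})",)
    return AggregationCheck(True, extra, warnings)


def system_from_dict(d: dict) -> EquilibriumSystem:
    """Build an :class:`EquilibriumSystem` from a plain config mapping (YAML/JSON)."""
    def species(key: str) -> Species:
        s = d[key]
        return Species(name=s.get("name", key), M=float(s["M"]),
                       vbar=float(s.get("vbar", 0.73)),
                       epsilon=float(s.get("epsilon", 0.0)))
    loadings = tuple(tuple(float(x) for x in pair) for pair in d.get("loadings", ()))
    return EquilibriumSystem(
        A=species("A"), B=species("B"),
        KD_uM=float(d["KD_uM"]) if "KD_uM" in d else None,
        loadings=loadings,
        solvent_density=float(d.get("solvent_density", 1.0)),
        temperature=float(d.get("temperature", 298.15)),
        vbar_AB=float(d["vbar_AB"]) if "vbar_AB" in d else None,
        epsilon_AB=float(d["epsilon_AB"]) if "epsilon_AB" in d else None,
    )
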