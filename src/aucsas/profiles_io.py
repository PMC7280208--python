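"""Reading, writing and resampling of scattering profiles and AUC tables.

Containers and IO shared by every analysis module:

* :class:`ScatteringProfile` — one reduced 1-D small-angle scattering curve
  (q [1/Å], I(q), sigma), optionally carrying the total mass concentration.
* :class:`ComponentTable` — the species list delivered by a sedimentation
  velocity c(s) analysis: aggregation number j and weight fraction per species.
* :class:`SEScan` — one sedimentation-equilibrium radial absorbance scan.

File formats are plain text: ATSAS-style 3-column ``.dat`` for profiles, CSV
for component tables and SE scans.  Units are fixed package-wide: q in 1/Å,
intensity in 1/cm (or a consistent arbitrary scale), mass concentration in
mg/mL, molar concentration in µM, molecular weight in Da.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringProfile",
    "ComponentTable",
    "SEScan",
    "MalformedInputError",
    "read_profile",
    "write_profile",
    "read_components",
    "write_components",
    "read_se_scan",
    "regrid",
]


class MalformedInputError(ValueError):
    """Raised when an input file or table violates the format contract."""


@dataclass(frozen=True)
class ScatteringProfile:
    """A reduced 1-D scattering curve.

    Parameters
    ----------
    q : array
        Scattering-vector magnitudes [1/Å], strictly increasing, all > 0.
    intensity : array
        I(q), absolute [1/cm] or consistent arbitrary scale.
    sigma : array
        1-sigma uncertainties on ``intensity``, same scale; > 0 where
        intensity is finite.
    concentration : float, optional
        Total mass concentration c [mg/mL] of the measured solution.
    label : str
        Free-text identifier.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    concentration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if not (q.shape == i.shape == s.shape) or q.ndim != 1:
            raise MalformedInputError("q, intensity, sigma must be equal-length 1-D arrays")
        if q.size < 1:
            raise MalformedInputError("profile needs at least 1 point")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise MalformedInputError("q must be positive and strictly increasing")
        finite = np.isfinite(i)
        if np.any(s[finite] <= 0):
            raise MalformedInputError("sigma must be > 0 wherever intensity is finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.q.size

    def per_mass(self) -> "ScatteringProfile":
        """Return the per-unit-mass profile i(q) = I(q)/c (requires c)."""
        if self.concentration is None:
            raise ValueError("concentration is not set")
        c = float(self.concentration)
        return replace(self, intensity=self.intensity / c, sigma=self.sigma / c,
                       concentration=1.0)

    def restrict(self, q_min: float = -np.inf, q_max: float = np.inf,
                 inclusive: bool = True) -> "ScatteringProfile":
        """Slice to q in [q_min, q_max] (or open interval)."""
        if inclusive:
            m = (self.q >= q_min) & (self.q <= q_max)
        else:
            m = (self.q > q_min) & (self.q < q_max)
        if m.sum() < 2:
            raise ValueError("fewer than 2 points in the requested q-range")
        return replace(self, q=self.q[m], intensity=self.intensity[m], sigma=self.sigma[m])

    def scaled(self, k: float) -> "ScatteringProfile":
        return replace(self, intensity=self.intensity * k, sigma=self.sigma * abs(k))


@dataclass(frozen=True)
class ComponentEntry:
    j: int                      # aggregation number (1 = monomer)
    weight_fraction: float      # dimensionless, in [0, 1]
    s20w: float | None = None   # sedimentation coefficient [S]
    mass: float | None = None   # molecular weight [Da]


@dataclass(frozen=True)
class ComponentTable:
    """AUC-derived species list: aggregation number and weight fraction.

    Weight fractions must sum to 1 (within 1e-6 after construction); j values
    are unique.  The monomer row (j = 1) is required by the monomer-extraction
    pipeline but not by the table itself.
    """

    entries: tuple[ComponentEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        if not entries:
            raise MalformedInputError("component table is empty")
        js = [e.j for e in entries]
        if len(set(js)) != len(js):
            raise MalformedInputError(f"duplicate aggregation numbers: {js}")
        if any(e.j < 1 for e in entries):
            raise MalformedInputError("aggregation numbers must be >= 1")
        if any(not (0 <= e.weight_fraction <= 1) for e in entries):
            raise MalformedInputError("weight fractions must lie in [0, 1]")
        total = sum(e.weight_fraction for e in entries)
        if abs(total - 1.0) > 1e-6:
            raise MalformedInputError(f"weight fractions sum to {total:.6g}, expected 1")
        object.__setattr__(self, "entries", tuple(sorted(entries, key=lambda e: e.j)))

    @classmethod
    def from_fractions(cls, fractions: dict[int, float],
                       normalize: bool = False) -> "ComponentTable":
        """Build a table from a ``{j: weight_fraction}`` mapping.

        With ``normalize=True`` the values may be raw mass concentrations and
        are divided by their sum (relative ratios are preserved exactly).
        """
        total = float(sum(fractions.values()))
        if normalize:
            if total <= 0:
                raise MalformedInputError("fractions sum to zero")
            scale = total
        else:
            if not (0.98 <= total <= 1.02):
                raise MalformedInputError(
                    f"weight fractions sum to {total:.4g}, outside [0.98, 1.02]")
            scale = total  # renormalize small rounding in either case
        return cls(tuple(ComponentEntry(int(j), w / scale)
                         for j, w in fractions.items()))

    def fraction(self, j: int) -> float:
        for e in self.entries:
            if e.j == j:
                return e.weight_fraction
        return 0.0

    @property
    def js(self) -> tuple[int, ...]:
        return tuple(e.j for e in self.entries)

    @property
    def monomer_fraction(self) -> float:
        w1 = self.fraction(1)
        if w1 == 0.0 and 1 not in self.js:
            raise MalformedInputError("component table has no monomer (j = 1) row")
        return w1

    @property
    def aggregate_fraction(self) -> float:
        """Total weight fraction of species with j >= 2."""
        return sum(e.weight_fraction for e in self.entries if e.j >= 2)


@dataclass(frozen=True)
class SEScan:
    """One sedimentation-equilibrium absorbance scan a(r) at a rotor speed."""

    radius: np.ndarray              # [cm], strictly increasing
    absorbance: np.ndarray          # [AU]
    rpm: float                      # rotor speed [r.p.m.]
    loading: tuple[float, float] = (np.nan, np.nan)  # nominal (A, B) [µM]
    temperature: float = 298.15     # [K]

    def __post_init__(self) -> None:
        r = np.asarray(self.radius, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if r.shape != a.shape or r.ndim != 1:
            raise MalformedInputError("radius and absorbance must be equal-length 1-D")
        if np.any(np.diff(r) <= 0):
            raise MalformedInputError("radius must be strictly increasing")
        if not self.rpm > 0:
            raise MalformedInputError("rpm must be > 0")
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "absorbance", a)

    @property
    def omega(self) -> float:
        """Angular velocity [rad/s]."""
        return 2.0 * np.pi * self.rpm / 60.0


# ---------------------------------------------------------------------------
# file IO


def _numeric_rows(text: str) -> list[list[float]]:
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.replace(",", " ").split()
        try:
            rows.append([float(t) for t in tokens])
        except ValueError:
            continue  # header / footer line with non-numeric tokens
    return rows


def read_profile(path: str | Path | io.TextIOBase,
                 concentration: float | None = None,
                 label: str | None = None) -> ScatteringProfile:
    """Read a 3-column (q, I, sigma) text profile.

    Lines starting with ``#`` and lines with non-numeric tokens are skipped;
    delimiters may be any mix of whitespace and commas.  Rows whose intensity
    is non-finite are dropped (count logged).
    """
    if isinstance(path, io.TextIOBase):
        text, name = path.read(), getattr(path, "name", "<stream>")
    else:
        path = Path(path)
        text, name = path.read_text(), path.name
    rows = [r for r in _numeric_rows(text) if len(r) >= 3]
    if len(rows) < 2:
        raise MalformedInputError(f"{name}: fewer than 2 valid (q, I, sigma) rows")
    arr = np.array([r[:3] for r in rows], dtype=float)
    finite = np.isfinite(arr[:, 1])
    n_drop = int((~finite).sum())
    if n_drop:
        logger.warning("%s: dropped %d rows with non-finite intensity", name, n_drop)
        arr = arr[finite]
    if len(arr) < 2:
        raise MalformedInputError(f"{name}: fewer than 2 finite rows")
    return ScatteringProfile(arr[:, 0], arr[:, 1], arr[:, 2],
                             concentration=concentration,
                             label=label if label is not None else name)


def write_profile(profile: ScatteringProfile, path: str | Path,
                  header: str | None = None) -> None:
    """Write a profile as 3-column text with a ``#`` header."""
    path = Path(path)
    lines = []
    if header:
        lines += [f"# {h}" for h in header.splitlines()]
    lines.append("# q[1/A]  I  sigma")
    if profile.concentration is not None:
        lines.append(f"# concentration_mg_per_ml = {profile.concentration!r}")
    for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
        lines.append(f"{q:.17e} {i:.17e} {s:.17e}")
    path.write_text("\n".join(lines) + "\n")


def read_components(path: str | Path) -> ComponentTable:
    """Read a component table CSV with columns ``j, weight_fraction[, s20w, mass]``.

    The fraction column may instead hold mass concentrations; values are
    renormalized to sum to 1 when their sum lies in [0.98, 1.02] or when a
    column named ``mass_concentration`` / ``concentration`` is used.  A sum
    outside tolerance in the ``weight_fraction`` column is an error.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if "j" not in df.columns:
        raise MalformedInputError(f"{path}: missing 'j' column")
    frac_col = next((c for c in ("weight_fraction", "mass_concentration",
                                 "concentration", "fraction") if c in df.columns), None)
    if frac_col is None:
        raise MalformedInputError(f"{path}: missing weight_fraction/concentration column")
    raw = df[frac_col].to_numpy(dtype=float)
    total = raw.sum()
    if frac_col == "weight_fraction":
        if not (0.98 <= total <= 1.02):
            raise MalformedInputError(
                f"{path}: weight fractions sum to {total:.4g}, outside [0.98, 1.02]")
    elif total <= 0:
        raise MalformedInputError(f"{path}: concentrations sum to {total:.4g}")
    frac = raw / total
    entries = []
    for k, row in df.iterrows():
        entries.append(ComponentEntry(
            j=int(row["j"]), weight_fraction=float(frac[k]),
            s20w=float(row["s20w"]) if "s20w" in df.columns and np.isfinite(row["s20w"]) else None,
            mass=float(row["mass"]) if "mass" in df.columns and np.isfinite(row["mass"]) else None,
        ))
    return ComponentTable(tuple(entries))


def write_components(table: ComponentTable, path: str | Path) -> None:
    df = pd.DataFrame({
        "j": [e.j for e in table.entries],
        "weight_fraction": [e.weight_fraction for e in table.entries],
        "s20w": [e.s20w for e in table.entries],
        "mass": [e.mass for e in table.entries],
    })
    df.to_csv(path, index=False)


def read_se_scan(path: str | Path, rpm: float | None = None,
                 loading: tuple[float, float] | None = None,
                 temperature: float | None = None) -> SEScan:
    """Read one SE scan CSV (``radius,absorbance``).

    Scan metadata (rpm, loading, temperature) is taken from ``#``-comment
    key=value lines in the file (e.g. ``# rpm = 20000``) or from the keyword
    arguments, which take precedence.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.lstrip().startswith("#") and "=" in line:
            key, val = line.lstrip("# ").split("=", 1)
            meta[key.strip().lower()] = val.strip()
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if rpm is None:
        rpm = float(meta.get("rpm", "nan"))
    if loading is None and "loading_um" in meta:
        loading = tuple(float(x) for x in meta["loading_um"].replace(",", " ").split())  # type: ignore
    if temperature is None:
        temperature = float(meta.get("temperature_k", 298.15))
    if not np.isfinite(rpm):
        raise MalformedInputError(f"{path}: rotor speed not given in file or arguments")
    return SEScan(df["radius"].to_numpy(float), df["absorbance"].to_numpy(float),
                  rpm=rpm, loading=loading if loading else (np.nan, np.nan),
                  temperature=temperature)


def write_se_scan(scan: SEScan, path: str | Path) -> None:
    lines = [f"# rpm = {scan.rpm}",
             f"# loading_um = {scan.loading[0]} {scan.loading[1]}",
             f"# temperature_k = {scan.temperature}",
             "radius,absorbance"]
    lines += [f"{r:.8f},{a:.8e}" for r, a in zip(scan.radius, scan.absorbance)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# resampling


def regrid(profile: ScatteringProfile, q_new: Sequence[float],
           mode: str = "linear") -> ScatteringProfile:
    """Interpolate a profile onto a new q-grid inside its measured range.

    Intensity and sigma are interpolated linearly; sigma is additionally
    floored at the larger of the two bracketing measured sigmas, so resampling
    never claims a smaller uncertainty than the data carry.  Extrapolation is
    refused.
    """
    if mode != "linear":
        raise ValueError(f"unsupported interpolation mode {mode!r}")
    q_new = np.asarray(q_new, dtype=float)
    if q_new.min() < profile.q[0] or q_new.max() > profile.q[-1]:
        raise ValueError(
            f"q_new range [{q_new.min():.4g}, {q_new.max():.4g}] outside measured "
            f"[{profile.q[0]:.4g}, {profile.q[-1]:.4g}]")
    i_new = np.interp(q_new, profile.q, profile.intensity)
    s_lin = np.interp(q_new, profile.q, profile.sigma)
    # bracketing neighbours: right index of the enclosing interval
    hi = np.clip(np.searchsorted(profile.q, q_new, side="left"), 1, len(profile) - 1)
    s_floor = np.maximum(profile.sigma[hi - 1], profile.sigma[hi])
    # exact grid hits keep their own sigma
    exact = np.isclose(q_new, profile.q[np.clip(hi, 0, len(profile) - 1)]) | \
        np.isclose(q_new, profile.q[hi - 1])
    s_new = np.where(exact, s_lin, np.maximum(s_lin, s_floor))
    return ScatteringProfile(q_new, i_new, s_new,
                             concentration=profile.concentration, label=profile.label)
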