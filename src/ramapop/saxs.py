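"""Debye scattering profiles and Guinier estimation of the effective Rgyr.

The orientationally averaged scattering intensity of a rigid set of point
scatterers is given exactly by the Debye equation,

    I(q) = Σᵢ Σⱼ fᵢ fⱼ sin(q rᵢⱼ) / (q rᵢⱼ),   q = 2π s,

evaluated here in vacuum with atomic electron counts as q-independent form
factors (heavy atoms only; hydrogens are neither built nor folded in).  At
small angles the profile follows the Guinier law

    I(s) = I(0) exp(−(1/3) (2π s Rgyr)²),

so a straight-line fit of ln I against s² yields the effective radius of
gyration; the fit window is restricted iteratively to the validity regime
2π·s·Rgyr < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import Conformation

__all__ = ["ScatteringProfile", "GuinierResult", "default_s_grid",
           "debye_profile", "average_profiles", "ensemble_profile",
           "guinier_fit"]


@dataclass(frozen=True)
class ScatteringProfile:
    """I(s) on a scattering grid s (Å⁻¹, momentum transfer q = 2πs)."""

    s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if s.shape != i.shape or s.ndim != 1:
            raise ValueError("s and intensity must be matching 1-D arrays")
        if np.any(s < 0) or np.any(np.diff(s) <= 0):
            raise ValueError("s grid must be non-negative and strictly increasing")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "intensity", i)

    def write(self, path):
        np.savetxt(path, np.column_stack([self.s, self.intensity]),
                   header="s_invA\tintensity", delimiter="\t")

    @classmethod
    def read(cls, path):
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1])


@dataclass(frozen=True)
class GuinierResult:
    """Fitted Guinier parameters: Rgyr (Å), I(0), and the fit window."""

    rgyr: float
    i0: float
    fit_range: tuple[float, float]
    n_points: int
    r_squared: float

    def report(self) -> str:
        return "\n".join([
            f"rgyr_A\t{self.rgyr:.4f}",
            f"i0\t{self.i0:.6g}",
            f"s_min_invA\t{self.fit_range[0]:.6g}",
            f"s_max_invA\t{self.fit_range[1]:.6g}",
            f"n_points\t{self.n_points}",
            f"r_squared\t{self.r_squared:.8f}",
        ])


def default_s_grid(s_min: float = 0.001, s_max: float = 0.05,
                   n: int = 100) -> np.ndarray:
    """Default scattering grid, 0.001–0.05 Å⁻¹ in 100 points."""
    return np.linspace(s_min, s_max, n)


def debye_profile(conf: Conformation, s_grid=None,
                  heavy_only: bool = True) -> ScatteringProfile:
    """Vacuum Debye profile of one conformation.

    Form factors are atomic electron counts; the i = j and q·r → 0 terms
    evaluate to fᵢfⱼ (sinc → 1), so I(0) = (Σ fᵢ)².
    """
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = np.asarray(s_grid, dtype=float)
    mask = conf.heavy_mask if heavy_only else np.ones(len(conf.atoms), bool)
    xyz = conf.coordinates[mask]
    f = np.array([a.electrons for a, m in zip(conf.atoms, mask) if m], dtype=float)
    if f.size == 0:
        raise ValueError("empty structure")
    diff = xyz[:, None, :] - xyz[None, :, :]
    rij = np.sqrt((diff ** 2).sum(axis=-1))
    q = 2.0 * np.pi * s_grid
    # np.sinc(x) = sin(pi x)/(pi x), so sinc(q r / pi) = sin(q r)/(q r),
    # with the q r -> 0 limit handled exactly.
    kernel = np.sinc(q[:, None, None] * rij[None, :, :] / np.pi)
    ff = f[:, None] * f[None, :]
    intensity = (ff[None, :, :] * kernel).sum(axis=(1, 2))
    return ScatteringProfile(s_grid, intensity)


def average_profiles(profiles) -> ScatteringProfile:
    """Pointwise unweighted mean of profiles sharing one s grid."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    s = profiles[0].s
    for p in profiles[1:]:
        if p.s.shape != s.shape or not np.allclose(p.s, s, rtol=0, atol=0):
            raise ValueError("profiles are on different s grids")
    return ScatteringProfile(s, np.mean([p.intensity for p in profiles], axis=0))


def ensemble_profile(confs, s_grid=None, n_sample: int = 100,
                     rng=None) -> ScatteringProfile:
    """Ensemble-average profile from ``n_sample`` frames drawn uniformly at
    random without replacement (all frames if the ensemble is smaller)."""
    confs = list(confs)
    if rng is None:
        rng = np.random.default_rng()
    if len(confs) > n_sample:
        idx = rng.choice(len(confs), size=n_sample, replace=False)
        confs = [confs[i] for i in sorted(idx)]
    return average_profiles(debye_profile(c, s_grid) for c in confs)


def guinier_fit(profile: ScatteringProfile, max_iter: int = 20) -> GuinierResult:
    """Guinier analysis: least-squares line through (s², ln I).

    Rgyr = sqrt(−3·slope)/(2π).  The fit starts on the full window and is
    restricted iteratively to points with 2π·s·Rgyr < 1 until the included
    set is stable (at most ``max_iter`` refits).  Raises ``ValueError`` for
    non-decaying profiles or too few admissible points.
    """
    if np.any(profile.intensity <= 0):
        raise ValueError("Guinier fit requires strictly positive intensities")
    s2 = profile.s ** 2
    ln_i = np.log(profile.intensity)
    include = np.ones(s2.size, dtype=bool)
    rgyr = i0 = r2 = None
    for _ in range(max_iter):
        if include.sum() < 3:
            raise ValueError("fewer than 3 points in the Guinier-valid range")
        fit = stats.linregress(s2[include], ln_i[include])
        if fit.slope >= 0:
            raise ValueError("profile does not decay: no Guinier regime")
        rgyr = float(np.sqrt(-3.0 * fit.slope) / (2.0 * np.pi))
        i0 = float(np.exp(fit.intercept))
        r2 = float(fit.rvalue ** 2)
        new = 2.0 * np.pi * profile.s * rgyr < 1.0
        if new.sum() < 3:
            raise ValueError("fewer than 3 points in the Guinier-valid range")
        if np.array_equal(new, include):
            break
        include = new
    s_used = profile.s[include]
    return GuinierResult(
        rgyr=rgyr, i0=i0,
        fit_range=(float(s_used.min()), float(s_used.max())),
        n_points=int(include.sum()), r_squared=r2,
    )
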