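"""Density-map analytics: rendering, filtering, FSC resolution, variance maps.

Maps are simple voxel grids with a physical voxel size and origin; MRC/CCP4
I/O goes through gemmi so headers round-trip.  Resolution estimation follows
the half-map Fourier shell correlation (FSC) protocol: shell-wise normalised
cross-correlation of Fourier coefficients, a sigmoid fit

    FSC(x) = 1 / (exp((x - A)/B) + 1)**C        (x = spatial frequency, 1/A)

for a robust estimate, and the reciprocal of the frequency where the curve
(or its fit) crosses a criterion value (0.143 for half maps by convention).

The isosurface-variance map quantifies structural variability across
bootstrap map replicates: each replicate is low-pass filtered, binarised at
a density threshold, the binary mask Gaussian-smoothed, and the per-voxel
variance over replicates reported.  Variance concentrates where the
isosurface moves between replicates, not where the density is merely noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq, curve_fit

__all__ = [
    "DensityMap",
    "FSCCurve",
    "FscFitResults",
    "FscSigmoidModel",
    "render_map",
    "sharpen_map",
    "lowpass_filter",
    "compute_fsc",
    "fit_fsc_sigmoid",
    "resolution_at",
    "isosurface_variance",
    "bootstrap_replicates",
    "read_mrc",
    "write_mrc",
]


@dataclass
class DensityMap:
    """A 3-D density grid with voxel size (A) and physical origin (A)."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 voxels per axis")

    def copy(self):
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())


def write_mrc(density: DensityMap, path):
    """Write a map to MRC/CCP4 format, preserving voxel size and origin."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(density.grid, dtype=np.float32))
    n = density.grid.shape
    m.grid.set_unit_cell(gemmi.UnitCell(density.voxel_size * n[0],
                                        density.voxel_size * n[1],
                                        density.voxel_size * n[2],
                                        90, 90, 90))
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.set_header_float(50, float(density.origin[0]))
    m.set_header_float(51, float(density.origin[1]))
    m.set_header_float(52, float(density.origin[2]))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityMap:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True, dtype=float)
    voxel = m.grid.unit_cell.a / m.grid.nu
    origin = np.array([m.header_float(50), m.header_float(51),
                       m.header_float(52)])
    return DensityMap(grid, voxel, origin)


def render_map(positions, voxel_size: float, shape, atom_sigma: float = None,
               origin=(0.0, 0.0, 0.0)) -> DensityMap:
    """Render a model as a sum of unit-mass isotropic Gaussians.

    Each atom contributes exp(-|r - r_atom|^2 / (2 sigma^2)); the default
    width is one voxel.  Atoms falling outside the box raise, listing the
    offenders.  The density is linear in the atom list: rendering a model
    plus one atom equals the rendered model plus that atom's density.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    if atom_sigma is None:
        atom_sigma = voxel_size
    grid = np.zeros(shape)
    if len(positions) == 0:
        return DensityMap(grid, voxel_size, origin)

    frac = (positions - origin) / voxel_size
    upper = np.array(shape) - 1
    bad = np.where(np.any((frac < 0) | (frac > upper), axis=1))[0]
    if bad.size:
        raise ValueError(f"atoms outside box (indices): {bad.tolist()}")

    cut = max(int(np.ceil(4 * atom_sigma / voxel_size)), 1)
    axes = [np.arange(s) for s in shape]
    for f in frac:
        sl, local = [], []
        for ax in range(3):
            lo = max(int(np.floor(f[ax])) - cut, 0)
            hi = min(int(np.ceil(f[ax])) + cut + 1, shape[ax])
            sl.append(slice(lo, hi))
            d = (axes[ax][lo:hi] - f[ax]) * voxel_size
            local.append(np.exp(-d**2 / (2 * atom_sigma**2)))
        grid[tuple(sl)] += (local[0][:, None, None] * local[1][None, :, None]
                            * local[2][None, None, :])
    return DensityMap(grid, voxel_size, origin)


def _freq_grid(density: DensityMap):
    """Spatial-frequency magnitude |s| (1/A) for each Fourier voxel."""
    fx, fy, fz = (np.fft.fftfreq(n, d=density.voxel_size)
                  for n in density.grid.shape)
    return np.sqrt(fx[:, None, None]**2 + fy[None, :, None]**2
                   + fz[None, None, :]**2)


def sharpen_map(density: DensityMap, b_factor: float) -> DensityMap:
    """Scale Fourier amplitudes by exp(-B s^2 / 4) (negative B sharpens)."""
    if b_factor == 0:
        return density.copy()
    s2 = _freq_grid(density) ** 2
    f = np.fft.fftn(density.grid) * np.exp(-b_factor * s2 / 4.0)
    return DensityMap(np.fft.ifftn(f).real, density.voxel_size,
                      density.origin.copy())


def lowpass_filter(density: DensityMap, cutoff: float,
                   edge_width: float | None = None) -> DensityMap:
    """Soft Fourier low-pass at 1/cutoff; the DC component is untouched.

    The transition is a raised cosine of width ``edge_width`` in frequency
    (default: two reciprocal voxels) centred on the cutoff; frequencies above
    cutoff + edge/2 are removed entirely.
    """
    if cutoff <= 2 * density.voxel_size:
        raise ValueError("cutoff must be above the Nyquist limit (2 * voxel)")
    s = _freq_grid(density)
    sc = 1.0 / cutoff
    if edge_width is None:
        edge_width = 2.0 / (min(density.grid.shape) * density.voxel_size)
    lo, hi = sc - edge_width / 2, sc + edge_width / 2
    w = np.clip((hi - s) / edge_width, 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)
    w[s <= lo] = 1.0
    f = np.fft.fftn(density.grid) * w
    return DensityMap(np.fft.ifftn(f).real, density.voxel_size,
                      density.origin.copy())


@dataclass
class FSCCurve:
    """Fourier shell correlation at shell-centre frequencies (1/A)."""

    frequencies: np.ndarray
    correlations: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if len(self.frequencies) != len(self.correlations):
            raise ValueError("frequencies and correlations must match")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frequency_inv_A": self.frequencies,
                             "fsc": self.correlations})

    def plot(self, ax=None, fit=None, threshold=0.143):
        """Plot the curve, an optional sigmoid fit, and the criterion line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.frequencies, self.correlations, "o-", ms=3, label="FSC")
        if fit is not None:
            x = np.linspace(self.frequencies[0], self.frequencies[-1], 300)
            ax.plot(x, fit.predict(x), lw=1, label="sigmoid fit")
        ax.axhline(threshold, color="0.5", ls="--", lw=0.8)
        ax.set_xlabel("spatial frequency (1/A)")
        ax.set_ylabel("FSC")
        ax.legend()
        return ax


def compute_fsc(half1: DensityMap, half2: DensityMap) -> FSCCurve:
    """Shell-wise normalised cross-correlation of two half maps.

    Shells are one reciprocal voxel wide, from the first shell to Nyquist.
    """
    if half1.grid.shape != half2.grid.shape:
        raise ValueError("half maps must share a grid")
    if half1.voxel_size != half2.voxel_size:
        raise ValueError("half maps must share a voxel size")
    f1 = np.fft.fftn(half1.grid)
    f2 = np.fft.fftn(half2.grid)
    n = min(half1.grid.shape)
    ds = 1.0 / (n * half1.voxel_size)          # shell width: one reciprocal voxel
    shell = np.rint(_freq_grid(half1) / ds).astype(int)
    n_shells = n // 2
    num = np.bincount(shell.ravel(), (f1 * np.conj(f2)).real.ravel(),
                      minlength=n_shells + 1)
    p1 = np.bincount(shell.ravel(), np.abs(f1.ravel())**2, minlength=n_shells + 1)
    p2 = np.bincount(shell.ravel(), np.abs(f2.ravel())**2, minlength=n_shells + 1)
    idx = np.arange(1, n_shells + 1)
    denom = np.sqrt(p1[idx] * p2[idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(denom > 0, num[idx] / denom, 0.0)
    return FSCCurve(idx * ds, fsc)


def _sigmoid(x, a, b, c):
    return 1.0 / (np.exp((x - a) / b) + 1.0) ** c


@dataclass
class FscFitResults:
    """Fitted FSC sigmoid parameters: inflection A (1/A), width B (1/A),
    exponent C, and the residual sum of squares of the fit."""

    A: float
    B: float
    C: float
    residual: float
    converged: bool = True
    flags: list = field(default_factory=list)

    def predict(self, x):
        return _sigmoid(np.asarray(x, dtype=float), self.A, self.B, self.C)

    def resolution_at(self, threshold: float) -> float:
        return resolution_at(self, threshold)

    def summary(self) -> str:
        lines = ["FSC sigmoid fit  1/(exp((x-A)/B)+1)^C",
                 f"A = {self.A:.6g} 1/A",
                 f"B = {self.B:.6g} 1/A",
                 f"C = {self.C:.6g}",
                 f"residual = {self.residual:.3g}"]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class FscSigmoidModel:
    """Least-squares sigmoid fit to an FSC curve.

    Multi-start over candidate inflection points; parameters B and C are
    kept positive by bounds.  A fitted width below the shell spacing is
    flagged (the curve is then effectively a step at the data resolution).
    """

    def __init__(self, curve: FSCCurve):
        if len(curve.frequencies) < 5:
            raise ValueError("need at least 5 shells to fit the sigmoid")
        self.curve = curve

    def fit(self) -> FscFitResults:
        x, y = self.curve.frequencies, self.curve.correlations
        span = x[-1] - x[0]
        best = None
        for q in (0.25, 0.4, 0.5, 0.6, 0.75):
            p0 = (x[0] + q * span, max(span / 10, 1e-4), 0.3)
            try:
                popt, _ = curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000,
                                    bounds=([x[0] - span, 1e-8, 1e-6],
                                            [x[-1] + span, span, 50.0]))
            except RuntimeError:
                continue
            resid = float(np.sum((_sigmoid(x, *popt) - y) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        if best is None:
            return FscFitResults(np.nan, np.nan, np.nan, np.inf,
                                 converged=False, flags=["non-convergence"])
        (a, b, c), resid = best
        flags = []
        shell_spacing = float(np.min(np.diff(x)))
        if b < shell_spacing:
            flags.append("width below shell spacing")
        return FscFitResults(float(a), float(b), float(c), resid, flags=flags)


def fit_fsc_sigmoid(curve: FSCCurve) -> FscFitResults:
    """Fit the FSC sigmoid 1/(exp((x-A)/B)+1)^C by least squares."""
    return FscSigmoidModel(curve).fit()


def resolution_at(fit_or_curve, threshold: float) -> float:
    """Resolution (A) where the FSC reaches a criterion value.

    For a sigmoid fit the crossing is solved in closed form,
    x* = A + B*ln(t^(-1/C) - 1); for a raw curve the first downward crossing
    is located by linear interpolation between shells.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(fit_or_curve, FscFitResults):
        fit = fit_or_curve
        x = fit.A + fit.B * np.log(threshold ** (-1.0 / fit.C) - 1.0)
        if not np.isfinite(x) or x <= 0:
            raise ValueError("fitted curve does not cross the threshold at a "
                             "positive frequency")
        return 1.0 / x
    curve = fit_or_curve
    x, y = curve.frequencies, curve.correlations
    below = np.where(y < threshold)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError("curve does not cross the threshold")
    i = below[0]
    x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    if y[i - 1] == threshold:
        return 1.0 / x0
    xc = x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)
    return 1.0 / xc


def _bisect_resolution(fit: FscFitResults, threshold: float,
                       lo=1e-6, hi=10.0) -> float:
    """Independent root-solve of the sigmoid criterion by bisection."""
    xc = brentq(lambda x: fit.predict(x) - threshold, lo, hi, xtol=1e-14)
    return 1.0 / xc


def bootstrap_replicates(member_maps, n_boot: int = 300, seed: int = 0):
    """Bootstrap map replicates: mean of a with-replacement resample.

    The member maps stand in for per-segment contributions to a
    reconstruction; each replicate averages a resample (with replacement)
    of the members, preserving the resample-reconstruct-compare structure
    of a reconstruction-level bootstrap.
    """
    member_maps = list(member_maps)
    if len(member_maps) < 2:
        raise ValueError("need at least 2 member maps")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    _check_same_grids(member_maps)
    rng = np.random.default_rng(seed)
    stack = np.stack([m.grid for m in member_maps])
    out = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(member_maps), len(member_maps))
        out.append(DensityMap(stack[pick].mean(axis=0),
                              member_maps[0].voxel_size,
                              member_maps[0].origin.copy()))
    return out


def _check_same_grids(maps):
    m0 = maps[0]
    for m in maps[1:]:
        if m.grid.shape != m0.grid.shape or m.voxel_size != m0.voxel_size:
            raise ValueError("all maps must share grid shape and voxel size")


def isosurface_variance(maps, threshold: float = 0.162,
                        lowpass: float | None = 8.0,
                        smooth_sigma: float = 2.0) -> DensityMap:
    """Per-voxel variance of smoothed binary masks across map replicates.

    Each replicate is optionally low-pass filtered, binarised at the density
    ``threshold``, and the binary mask smoothed with a Gaussian of
    ``smooth_sigma`` voxels before the variance across replicates is taken.
    The result highlights regions where the isosurface moves between
    replicates and is zero wherever all replicates agree.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    _check_same_grids(maps)
    if all(threshold >= m.grid.max() or threshold <= m.grid.min()
           for m in maps):
        raise ValueError("threshold outside the density range of every map")
    masks = []
    for m in maps:
        filtered = lowpass_filter(m, lowpass) if lowpass else m
        mask = (filtered.grid > threshold).astype(float)
        masks.append(gaussian_filter(mask, smooth_sigma))
    var = np.var(np.stack(masks), axis=0)
    return DensityMap(var, maps[0].voxel_size, maps[0].origin.copy())
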