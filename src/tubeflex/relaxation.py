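"""Spin-relaxation rate estimation and two-site exchange dispersion fitting.

This module estimates longitudinal (R1) and rotating-frame (R1rho) relaxation
rates from peak-height decay series, corrects observed R1rho values to
on-resonance rates in the tilted rotating frame, and fits on-resonance
dispersion profiles to a fast-exchange two-site model

    R1rho(omega1) = R1rho0 + phi_ex * k_ex / (omega1**2 + k_ex**2)

with a single exchange rate ``k_ex`` shared across residues and individual
``phi_ex`` (= pA*pB*delta_delta**2) and baseline ``R1rho0`` per residue.
Spinlock strengths and offsets are converted to angular frequency
(rad/s) before entering the model so that ``omega1`` and ``k_ex`` are
commensurate.

Parameter uncertainties follow a Monte-Carlo scheme: the dispersion fit is
repeated (default 250 times) with every R1rho point perturbed by its error
multiplied by a uniform random number in (0, 1) and a random sign, and the
spread over repeats is reported as the parameter error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

__all__ = [
    "RelaxationDecay",
    "RateEstimate",
    "DispersionProfile",
    "DispersionResults",
    "MonoexponentialModel",
    "TwoSiteDispersionModel",
    "khz_to_angular",
    "two_site_model",
    "fit_monoexponential",
    "correct_on_resonance",
    "fit_dispersion_global",
    "monte_carlo_errors",
    "estimate_rate_errors",
]

# sin^2(theta) below which the tilted-frame correction is numerically
# meaningless (tilt angle under ~5 degrees off resonance)
SINSQ_TOL = 0.0075


def khz_to_angular(nu_khz):
    """Convert a spinlock strength in kHz to angular frequency in rad/s."""
    return 2.0 * np.pi * 1.0e3 * np.asarray(nu_khz, dtype=float)


def two_site_model(omega1, r1rho0, phi_ex, k_ex):
    """Fast-exchange two-site dispersion: R1rho0 + phi_ex*k_ex/(omega1^2+k_ex^2)."""
    omega1 = np.asarray(omega1, dtype=float)
    return r1rho0 + phi_ex * k_ex / (omega1**2 + k_ex**2)


@dataclass
class RelaxationDecay:
    """One peak-height decay series for a single residue.

    ``x`` is the relaxation delay (s) for R1 series or the spinlock duration
    (s) for R1rho series.  ``sigma`` is the per-series noise estimate in the
    same intensity units as ``heights``.  R1rho series additionally carry the
    spinlock strength ``spinlock_nu`` (kHz) and the chemical-shift offset
    from the carrier ``offset_omega`` (rad/s).
    """

    residue: str
    x: np.ndarray
    heights: np.ndarray
    sigma: float | None = None
    spinlock_nu: float | None = None
    offset_omega: float | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.x.shape != self.heights.shape:
            raise ValueError("x and heights must have equal length")
        if len(self.x) < 3:
            raise ValueError("a decay series needs at least 3 points")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x values must be strictly increasing")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class RateEstimate:
    """A fitted relaxation rate with its uncertainty.

    ``kind`` is one of ``R1``, ``R1rho_obs`` or ``R1rho_onres``.  Estimates
    from non-converged or unphysical (negative-rate) fits carry
    ``converged=False`` and should be excluded from downstream analysis.
    """

    residue: str
    rate: float
    rate_err: float
    kind: str
    amplitude: float | None = None
    converged: bool = True

    def __post_init__(self):
        if self.kind not in ("R1", "R1rho_obs", "R1rho_onres"):
            raise ValueError(f"unknown rate kind {self.kind!r}")


@dataclass
class DispersionProfile:
    """On-resonance R1rho versus spinlock strength for one residue.

    ``omega1`` is in angular units (rad/s); use :func:`khz_to_angular` when
    building profiles from spectrometer settings quoted in kHz.
    """

    residue: str
    omega1: np.ndarray
    r1rho: np.ndarray
    r1rho_err: np.ndarray

    def __post_init__(self):
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.r1rho = np.asarray(self.r1rho, dtype=float)
        self.r1rho_err = np.asarray(self.r1rho_err, dtype=float)
        if not (len(self.omega1) == len(self.r1rho) == len(self.r1rho_err)):
            raise ValueError("omega1, r1rho and r1rho_err must have equal length")
        if np.any(self.omega1 <= 0):
            raise ValueError("spinlock strengths must be positive")


# ---------------------------------------------------------------------------
# monoexponential decay fitting
# ---------------------------------------------------------------------------


class MonoexponentialModel:
    """Least-squares model h(t) = A * exp(-R*t) for one decay series."""

    def __init__(self, decay: RelaxationDecay):
        self.decay = decay

    def fit(self) -> RateEstimate:
        d = self.decay
        if np.all(d.heights == 0):
            raise ValueError("heights are all zero; nothing to fit")
        kind = "R1" if d.spinlock_nu is None else "R1rho_obs"

        # log-linear initial guess where heights allow it
        pos = d.heights > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(d.x[pos], np.log(d.heights[pos]), 1)
            p0 = (float(np.exp(intercept)), max(-slope, 0.0))
        else:
            p0 = (float(d.heights[0]), 0.0)

        def f(t, a, r):
            return a * np.exp(-r * t)

        try:
            popt, pcov = curve_fit(f, d.x, d.heights, p0=p0, maxfev=10000)
        except RuntimeError:
            return RateEstimate(d.residue, np.nan, np.nan, kind, converged=False)
        a, r = popt
        r_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        converged = bool(np.isfinite(r)) and r >= 0
        return RateEstimate(d.residue, float(r), r_err, kind,
                            amplitude=float(a), converged=converged)


def fit_monoexponential(decay: RelaxationDecay) -> RateEstimate:
    """Fit h(t) = A*exp(-R*t) to one decay series and return the rate."""
    return MonoexponentialModel(decay).fit()


def estimate_rate_errors(decays, n_repeats: int = 1000, seed: int = 0):
    """Monte-Carlo rate errors: resample heights with the stated noise and refit.

    Each series is refit ``n_repeats`` times with Gaussian noise of its own
    ``sigma`` added to the heights; the standard deviation of the refitted
    rates is reported as ``rate_err``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be at least 2")
    rng = np.random.default_rng(seed)
    out = []
    for d in decays:
        if d.sigma is None:
            raise ValueError(f"decay for residue {d.residue!r} has no sigma")
        base = fit_monoexponential(d)
        if d.sigma == 0:
            out.append(replace(base, rate_err=0.0))
            continue
        rates = []
        for _ in range(n_repeats):
            noisy = replace(d, heights=d.heights + rng.normal(0, d.sigma, len(d.heights)))
            est = fit_monoexponential(noisy)
            if est.converged:
                rates.append(est.rate)
        out.append(replace(base, rate_err=float(np.std(rates))))
    return out


# ---------------------------------------------------------------------------
# tilted-frame on-resonance correction
# ---------------------------------------------------------------------------


def correct_on_resonance(r1rho_obs: RateEstimate, r1: RateEstimate,
                         omega1: float, offset_omega: float,
                         sinsq_tol: float = SINSQ_TOL) -> RateEstimate:
    """Correct an observed R1rho to the on-resonance rate.

    The effective field tilts by theta = atan(omega1/Omega) from the z axis;
    the observed rate mixes R1rho and R1 as
    R1rho_obs = R1rho*sin^2(theta) + R1*cos^2(theta), which is inverted here.
    Errors are propagated to first order.  Offsets much larger than the
    spinlock strength (sin^2 theta below ``sinsq_tol``) are rejected.
    """
    if omega1 <= 0:
        raise ValueError("omega1 must be positive")
    theta = np.arctan2(omega1, offset_omega)
    sinsq = np.sin(theta) ** 2
    if sinsq < sinsq_tol:
        raise ValueError("tilt too far off-resonance: sin^2(theta) = %g" % sinsq)
    cossq = 1.0 - sinsq
    rate = (r1rho_obs.rate - r1.rate * cossq) / sinsq
    err = np.sqrt(r1rho_obs.rate_err**2 + (cossq * r1.rate_err) ** 2) / sinsq
    return RateEstimate(r1rho_obs.residue, float(rate), float(err),
                        "R1rho_onres",
                        converged=r1rho_obs.converged and r1.converged)


# ---------------------------------------------------------------------------
# global two-site dispersion fit
# ---------------------------------------------------------------------------


@dataclass
class DispersionResults:
    """Results of the combined two-site dispersion fit.

    ``k_ex`` is shared across residues; ``phi_ex`` and ``r1rho0`` are
    per-residue arrays ordered as ``residues``.  Errors are filled in by
    :meth:`TwoSiteDispersionModel.monte_carlo` and are None until then.
    ``k_ex_identifiable`` is False when the data carry no dispersion
    (all profiles flat), in which case phi_ex is pinned at zero.
    """

    residues: list
    k_ex: float
    phi_ex: np.ndarray
    r1rho0: np.ndarray
    chi2: float
    k_ex_identifiable: bool = True
    k_ex_err: float | None = None
    phi_ex_err: np.ndarray | None = None
    r1rho0_err: np.ndarray | None = None
    n_mc: int = 0
    model: "TwoSiteDispersionModel | None" = field(default=None, repr=False)

    def predict(self, residue, omega1):
        i = self.residues.index(residue)
        return two_site_model(omega1, self.r1rho0[i], self.phi_ex[i], self.k_ex)

    def plot(self, ax=None):
        """Plot the measured dispersion profiles with the fitted curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        profiles = self.model.profiles if self.model else []
        for i, res in enumerate(self.residues):
            if profiles:
                p = profiles[i]
                ax.errorbar(p.omega1 / (2e3 * np.pi), p.r1rho, yerr=p.r1rho_err,
                            fmt="o", ms=3, label=res)
                w = np.linspace(p.omega1.min(), p.omega1.max(), 200)
            else:
                w = np.linspace(1e3, 1e5, 200)
            ax.plot(w / (2e3 * np.pi),
                    two_site_model(w, self.r1rho0[i], self.phi_ex[i], self.k_ex),
                    lw=1, color="0.3")
        ax.set_xlabel("spinlock strength (kHz)")
        ax.set_ylabel(r"$R_{1\rho}$ (s$^{-1}$)")
        return ax

    def summary(self) -> str:
        lines = ["Two-site exchange dispersion fit",
                 "=" * 56,
                 f"shared k_ex : {self.k_ex:.6g} s^-1"
                 + (f" +/- {self.k_ex_err:.3g}" if self.k_ex_err is not None else "")
                 + ("" if self.k_ex_identifiable else "   [unidentifiable]"),
                 f"chi^2       : {self.chi2:.6g}",
                 f"n residues  : {len(self.residues)}"
                 + (f"   (MC repeats: {self.n_mc})" if self.n_mc else ""),
                 "-" * 56,
                 f"{'residue':<10}{'phi_ex (rad^2/s^2)':>22}{'R1rho_0 (1/s)':>18}"]
        for i, res in enumerate(self.residues):
            phi = f"{self.phi_ex[i]:.6g}"
            if self.phi_ex_err is not None:
                phi += f" +/- {self.phi_ex_err[i]:.2g}"
            r0 = f"{self.r1rho0[i]:.6g}"
            if self.r1rho0_err is not None:
                r0 += f" +/- {self.r1rho0_err[i]:.2g}"
            lines.append(f"{res:<10}{phi:>22}{r0:>18}")
        return "\n".join(lines)


class TwoSiteDispersionModel:
    """Combined fit of dispersion profiles with one shared exchange rate.

    For fixed ``k_ex`` the model is linear in each residue's
    (R1rho0, phi_ex), so the chi-square is profiled over ``k_ex`` alone:
    every evaluation solves a weighted 2x2 linear system per residue, with
    phi_ex clamped at zero when the unconstrained solution is negative.
    The 1-D profile is minimised from a log-spaced grid of starting points
    (1e2-1e5 1/s, 7 starts) to avoid local minima.
    """

    KEX_STARTS = np.logspace(2, 5, 7)
    LOG_KEX_BOUNDS = (0.0, 8.0)  # log10 bounds for the scalar search

    def __init__(self, profiles):
        profiles = list(profiles)
        if not profiles:
            raise ValueError("at least one dispersion profile is required")
        for p in profiles:
            if len(p.omega1) < 3:
                raise ValueError(
                    f"profile {p.residue!r} has fewer than 3 spinlock points")
        self.profiles = profiles
        # broadcast per-series errors; zero errors fall back to unit weights
        self._w = []
        for p in profiles:
            err = np.where(p.r1rho_err > 0, p.r1rho_err, 1.0)
            self._w.append(1.0 / err)

    def _solve_linear(self, k_ex):
        """Per-residue weighted linear solve at fixed k_ex; returns params, chi2.

        The model is linear in (r1rho0, phi_ex) at fixed k_ex, so each
        residue reduces to closed-form 2x2 weighted normal equations; a
        negative phi_ex solution is pinned at zero and the baseline re-solved.
        """
        r0 = np.empty(len(self.profiles))
        phi = np.empty(len(self.profiles))
        chi2 = 0.0
        for i, p in enumerate(self.profiles):
            w2 = self._w[i] ** 2
            basis = k_ex / (p.omega1**2 + k_ex**2)
            y = p.r1rho
            s0 = w2.sum()
            s1 = float(w2 @ basis)
            s2 = float(w2 @ (basis * basis))
            sy = float(w2 @ y)
            sby = float(w2 @ (basis * y))
            det = s0 * s2 - s1 * s1
            b = (s0 * sby - s1 * sy) / det if det > 0 else 0.0
            if b < 0:  # non-negativity of phi_ex
                b = 0.0
            a = (sy - b * s1) / s0
            r0[i], phi[i] = a, b
            resid2 = w2 * (y - a - b * basis) ** 2
            chi2 += float(resid2.sum())
        return r0, phi, chi2

    def _profile_chi2(self, log10_kex):
        return self._solve_linear(10.0 ** log10_kex)[2]

    def fit(self) -> DispersionResults:
        best = None
        for start in self.KEX_STARTS:
            lo = max(self.LOG_KEX_BOUNDS[0], np.log10(start) - 1.6)
            hi = min(self.LOG_KEX_BOUNDS[1], np.log10(start) + 1.6)
            res = minimize_scalar(self._profile_chi2, bounds=(lo, hi),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        k_ex = 10.0 ** float(best.x)
        r0, phi, chi2 = self._solve_linear(k_ex)

        # judge identifiability by the dispersion amplitude the fitted phi_ex
        # actually produces across the measured spinlock range, not by its
        # raw magnitude (the basis is tiny in angular units)
        scale = max(float(np.max(np.abs(p.r1rho))) for p in self.profiles)
        amplitude = 0.0
        for i, p in enumerate(self.profiles):
            b = k_ex / (p.omega1**2 + k_ex**2)
            amplitude = max(amplitude, phi[i] * (b.max() - b.min()))
        identifiable = amplitude > 1e-8 * max(scale, 1e-300)
        if not identifiable:
            # flat profiles: k_ex has no leverage on the model
            phi = np.zeros_like(phi)
            r0, _, chi2 = self._solve_linear(k_ex)
            r0 = np.array([float(np.average(p.r1rho, weights=self._w[i]**2))
                           for i, p in enumerate(self.profiles)])
            chi2 = sum(float((((p.r1rho - r0[i]) * self._w[i]) ** 2).sum())
                       for i, p in enumerate(self.profiles))
        return DispersionResults(
            residues=[p.residue for p in self.profiles],
            k_ex=k_ex, phi_ex=phi, r1rho0=r0, chi2=chi2,
            k_ex_identifiable=identifiable, model=self)

    def _refit_local(self, k_ex_center):
        """Refit with the scalar search bracketed around a known solution."""
        c = np.log10(k_ex_center)
        res = minimize_scalar(self._profile_chi2,
                              bounds=(max(c - 2, self.LOG_KEX_BOUNDS[0]),
                                      min(c + 2, self.LOG_KEX_BOUNDS[1])),
                              method="bounded", options={"xatol": 1e-6})
        k_ex = 10.0 ** float(res.x)
        r0, phi, _ = self._solve_linear(k_ex)
        return k_ex, phi, r0

    def monte_carlo(self, results: DispersionResults, n_repeats: int = 250,
                    seed: int = 0, scheme: str = "gaussian") -> DispersionResults:
        """Monte-Carlo parameter errors for a converged fit.

        Each repeat perturbs every R1rho point by its stated error, refits,
        and reports the standard deviation of each parameter over repeats as
        its error.  ``scheme`` selects the perturbation distribution:
        ``gaussian`` (default) draws err * N(0, 1), so the repeat spread
        estimates the sampling distribution at the nominal noise level;
        ``signed_uniform`` draws err * U(0, 1) * (random sign), whose
        variance is err^2/3 and therefore understates the sampling spread
        by a factor sqrt(3).
        """
        if n_repeats < 2:
            raise ValueError("n_repeats must be at least 2")
        if scheme not in ("gaussian", "signed_uniform"):
            raise ValueError("scheme must be 'gaussian' or 'signed_uniform'")
        rng = np.random.default_rng(seed)
        kexs = np.empty(n_repeats)
        phis = np.empty((n_repeats, len(self.profiles)))
        r0s = np.empty((n_repeats, len(self.profiles)))
        originals = [p.r1rho.copy() for p in self.profiles]
        try:
            for rep in range(n_repeats):
                for p, orig in zip(self.profiles, originals):
                    if scheme == "gaussian":
                        delta = p.r1rho_err * rng.normal(0, 1, len(orig))
                    else:
                        delta = (p.r1rho_err * rng.uniform(0, 1, len(orig))
                                 * rng.choice([-1.0, 1.0], len(orig)))
                    p.r1rho = orig + delta
                kexs[rep], phis[rep], r0s[rep] = self._refit_local(results.k_ex)
        finally:
            for p, orig in zip(self.profiles, originals):
                p.r1rho = orig
        return replace(results,
                       k_ex_err=float(np.std(kexs)),
                       phi_ex_err=np.std(phis, axis=0),
                       r1rho0_err=np.std(r0s, axis=0),
                       n_mc=n_repeats)


def fit_dispersion_global(profiles) -> DispersionResults:
    """Fit all profiles jointly with a single shared k_ex."""
    return TwoSiteDispersionModel(profiles).fit()


def monte_carlo_errors(fit: DispersionResults, profiles, n_repeats: int = 250,
                       seed: int = 0, scheme: str = "gaussian") -> DispersionResults:
    """Attach Monte-Carlo errors to an existing global dispersion fit."""
    model = fit.model or TwoSiteDispersionModel(profiles)
    return model.monte_carlo(fit, n_repeats=n_repeats, seed=seed, scheme=scheme)
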