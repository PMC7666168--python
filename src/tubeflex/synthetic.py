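"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of the study inputs without
any download: monoexponential peak-height decays on the experimental delay
grid, two-site exchange dispersion profiles on the experimental spinlock
grid, pseudo-atomic subunits for symmetry assembly, and Gaussian-atom voxel
maps with controllable rigid jitter for isosurface-variance analysis.

All generators are pure functions of their explicit integer seed; there is
no global RNG state.  Noise is additive Gaussian on peak heights / voxel
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relaxation import (DispersionProfile, RelaxationDecay, khz_to_angular,
                         two_site_model)

__all__ = [
    "SyntheticMonomer",
    "NoiseSpec",
    "DispersionDataset",
    "R1_DELAYS_S",
    "SPINLOCKS_KHZ",
    "make_monomer",
    "make_decay_table",
    "make_dispersion_dataset",
    "make_half_maps",
]

# experimental acquisition grids: delay times (s) of the R1 pseudo-3D series
# and spinlock strengths (kHz) of the R1rho dispersion series
R1_DELAYS_S = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 8.0, 16.0, 32.0)
SPINLOCKS_KHZ = (9.0, 7.0, 5.5, 5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0)


@dataclass
class NoiseSpec:
    """Additive Gaussian noise on peak heights: standard deviation and seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self):
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticMonomer:
    """A pseudo-atom stand-in for one tube subunit.

    One pseudo-atom per residue (labels ``R{i}:CA``); ``strands`` marks
    residue-index runs playing the role of beta-strands for register tests.
    """

    labels: list
    positions: np.ndarray
    strands: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atom labels must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        spans = sorted((lo, hi) for lo, hi in self.strands)
        for (l0, h0), (l1, h1) in zip(spans, spans[1:]):
            if l1 <= h0:
                raise ValueError("strand runs must not overlap")

    @property
    def n_atoms(self):
        return len(self.labels)

    def translated(self, shift):
        return SyntheticMonomer(list(self.labels),
                                self.positions + np.asarray(shift, float),
                                list(self.strands))


def make_monomer(n_atoms: int, extent: float, seed: int) -> SyntheticMonomer:
    """Reproducible pseudo-atom cloud of the given extent with two strand runs.

    Atoms are sampled uniformly in a cube of side ``extent`` centred on the
    origin (so all pairwise distances are at most extent*sqrt(3)); the first
    and last quarters of the residue range are designated strands.
    """
    if n_atoms < 4:
        raise ValueError("n_atoms must be at least 4")
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(-extent / 2, extent / 2, size=(n_atoms, 3))
    labels = [f"R{i}:CA" for i in range(n_atoms)]
    q = max(n_atoms // 4, 2)
    strands = [(0, q - 1), (n_atoms - q, n_atoms - 1)]
    return SyntheticMonomer(labels, positions, strands)


def make_decay_table(rates, delays=R1_DELAYS_S, amplitude: float = 1.0,
                     noise: NoiseSpec | None = None):
    """Generate monoexponential decay series, one per residue.

    ``rates`` maps residue label to R1 (1/s).  Heights are
    amplitude*exp(-R1*delay) plus Gaussian noise of sd ``noise.sigma``;
    the sigma is recorded on every series.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("delay grid must not be empty")
    if np.any(delays <= 0):
        raise ValueError("delays must be strictly positive")
    noise = noise or NoiseSpec()
    rng = noise.rng()
    out = []
    for residue, r1 in rates.items():
        if r1 < 0:
            raise ValueError("rates must be non-negative")
        heights = amplitude * np.exp(-r1 * delays)
        if noise.sigma > 0:
            heights = heights + rng.normal(0, noise.sigma, delays.size)
        out.append(RelaxationDecay(str(residue), delays, heights,
                                   sigma=noise.sigma))
    return out


@dataclass
class DispersionDataset:
    """Synthetic dispersion profiles plus the parameters that generated them."""

    profiles: list
    k_ex: float
    phi_ex: dict
    r1rho0: dict
    sigma: float


def make_dispersion_dataset(k_ex: float, phi_ex: dict, r1rho0: dict,
                            spinlocks_khz=SPINLOCKS_KHZ,
                            noise: NoiseSpec | None = None) -> DispersionDataset:
    """Forward-evaluate the two-site dispersion model and add noise.

    ``phi_ex`` (rad^2/s^2) and ``r1rho0`` (1/s) map residue label to the
    per-residue generating parameters; ``k_ex`` (1/s) is shared.  Spinlock
    strengths are given in kHz and converted to angular frequency.
    """
    if k_ex <= 0:
        raise ValueError("k_ex must be positive")
    spinlocks_khz = np.asarray(spinlocks_khz, dtype=float)
    if np.any(spinlocks_khz <= 0):
        raise ValueError("spinlock strengths must be positive")
    if set(phi_ex) != set(r1rho0):
        raise ValueError("phi_ex and r1rho0 must cover the same residues")
    noise = noise or NoiseSpec()
    rng = noise.rng()
    omega1 = khz_to_angular(spinlocks_khz)
    order = np.argsort(omega1)
    omega1 = omega1[order]
    profiles = []
    for residue in phi_ex:
        r = two_site_model(omega1, r1rho0[residue], phi_ex[residue], k_ex)
        if noise.sigma > 0:
            r = r + rng.normal(0, noise.sigma, omega1.size)
        err = np.full(omega1.size, noise.sigma)
        profiles.append(DispersionProfile(str(residue), omega1, r, err))
    return DispersionDataset(profiles, k_ex, dict(phi_ex), dict(r1rho0),
                             noise.sigma)


def make_half_maps(model, voxel: float, noise_sigma: float = 0.0,
                   jitter: float = 0.0, n_replicates: int = 2, seed: int = 0,
                   jitter_selection=None, atom_sigma: float | None = None,
                   pad: float = 6.0):
    """Render replicate Gaussian-atom maps from a model, with optional jitter.

    ``model`` is anything with ``positions`` (n, 3); ``jitter_selection``
    names the atom indices of the substructure given an independent rigid
    random translation (sd ``jitter`` Angstrom per axis) in every replicate —
    by default all atoms move together.  Gaussian voxel noise of sd
    ``noise_sigma`` is added independently per replicate.  All replicates
    share one grid sized to hold the model plus ``pad`` on every side.
    """
    from .density import render_map

    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    positions = np.asarray(model.positions if hasattr(model, "positions")
                           else model, dtype=float)
    if atom_sigma is None:
        atom_sigma = voxel
    rng = np.random.default_rng(seed)
    lo = positions.min(axis=0) - pad
    hi = positions.max(axis=0) + pad
    shape = tuple(int(np.ceil(d / voxel)) + 1 for d in hi - lo)
    sel = (np.arange(len(positions)) if jitter_selection is None
           else np.asarray(jitter_selection, dtype=int))
    maps = []
    for _ in range(n_replicates):
        pos = positions.copy()
        if jitter > 0:
            pos[sel] = pos[sel] + rng.normal(0, jitter, 3)
        m = render_map(pos, voxel, shape, atom_sigma=atom_sigma, origin=lo)
        if noise_sigma > 0:
            m.grid = m.grid + rng.normal(0, noise_sigma, m.grid.shape)
        maps.append(m)
    return maps
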