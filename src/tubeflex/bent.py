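"""Geometry and restraint analysis of bent tube models.

A bent tube is modelled as a rigid arc: rings of the straight tube are
rotated about an axis through the curvature centre (perpendicular to the
bending plane) so that the ring-to-ring spacing on the *inside* edge of the
curve stays equal to the straight-tube value, while the outside edge
stretches.  The per-ring bend angle follows directly from the arc:

    bend_angle = inner_spacing / inner_radius        (radians)
    inner_radius = curvature_radius - tube_diameter/2
    outer_radius = curvature_radius + tube_diameter/2
    outer_spacing = bend_angle * outer_radius

To ask which parts of the protein absorb the deformation, a network of
harmonic distance restraints (random atom pairs between 3 and 15 A apart)
is built with target distances taken from the straight tube; the bent model
is optionally relaxed under the network, and the fraction of fulfilled
restraints per residue flags the regions exposed to the geometry change
(low fulfilment = stretched, i.e. hinge candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

__all__ = [
    "BentGeometry",
    "AtomSet",
    "TubeModel",
    "RestraintNetwork",
    "RelaxResult",
    "compute_bend_geometry",
    "build_bent_tube",
    "build_straight_tube",
    "ring_from_assembly",
    "make_restraint_network",
    "network_energy",
    "relax_under_restraints",
    "score_restraint_fulfilment",
]


@dataclass
class BentGeometry:
    """Arc geometry of a bent tube (all lengths in Angstrom, angle in degrees).

    ``measured_outer_spacing`` carries an independently measured outside
    spacing as metadata; the arc-predicted value is ``outer_spacing``.
    """

    curvature_radius: float
    tube_diameter: float
    inner_radius: float
    outer_radius: float
    inner_spacing: float
    outer_spacing: float
    bend_angle_deg: float
    measured_outer_spacing: float | None = None

    def __post_init__(self):
        if self.inner_radius <= 0:
            raise ValueError("inner radius must be positive")
        if self.bend_angle_deg <= 0:
            raise ValueError("bend angle must be positive")

    @property
    def bend_angle_rad(self):
        return np.radians(self.bend_angle_deg)


def compute_bend_geometry(curvature_radius: float, tube_diameter: float,
                          inner_spacing: float,
                          measured_outer_spacing: float | None = None
                          ) -> BentGeometry:
    """Arc geometry from curvature radius, tube diameter and inside spacing."""
    if curvature_radius <= tube_diameter / 2:
        raise ValueError("curvature radius must exceed the tube radius")
    if inner_spacing <= 0:
        raise ValueError("inner_spacing must be positive")
    inner = curvature_radius - tube_diameter / 2
    outer = curvature_radius + tube_diameter / 2
    angle = inner_spacing / inner  # radians
    return BentGeometry(curvature_radius, tube_diameter, inner, outer,
                        inner_spacing, angle * outer, np.degrees(angle),
                        measured_outer_spacing)


@dataclass
class AtomSet:
    """A labelled point cloud (one ring, a monomer, any rigid atom group)."""

    labels: list
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")


def ring_from_assembly(assembly) -> AtomSet:
    """Flatten an assembly into one labelled atom set (chain-prefixed labels)."""
    labels, positions = [], []
    for i in range(assembly.n_subunits):
        cid = assembly.chain_ids[i]
        labels.extend(f"{cid}/{lab}" for lab in assembly.monomer.labels)
        positions.append(assembly.positions(i))
    return AtomSet(labels, np.concatenate(positions))


@dataclass
class TubeModel:
    """A multi-ring tube model built from rigid copies of one ring."""

    labels: list
    positions: np.ndarray
    ring_index: np.ndarray
    n_rings: int
    geometry: BentGeometry | None = None
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.ring_index = np.asarray(self.ring_index, dtype=int)

    def index_of(self, label: str) -> int:
        if self._index is None:
            self._index = {lab: i for i, lab in enumerate(self.labels)}
        return self._index[label]

    def with_positions(self, positions):
        return TubeModel(list(self.labels), positions,
                         self.ring_index.copy(), self.n_rings, self.geometry)

    def residue_of(self, i: int) -> str:
        return self.labels[i].rsplit(":", 1)[0]


def _ring_labels(ring, r):
    return [f"r{r}/{lab}" for lab in ring.labels]


def build_straight_tube(ring, rise: float, n_rings: int) -> TubeModel:
    """Stack rigid copies of one ring along +z with the given rise."""
    if n_rings < 1:
        raise ValueError("n_rings must be at least 1")
    labels, positions, ring_idx = [], [], []
    for r in range(n_rings):
        labels.extend(_ring_labels(ring, r))
        positions.append(ring.positions + np.array([0.0, 0.0, r * rise]))
        ring_idx.extend([r] * len(ring.labels))
    return TubeModel(labels, np.concatenate(positions), np.array(ring_idx),
                     n_rings)


def build_bent_tube(ring, geometry: BentGeometry, n_rings: int = 10) -> TubeModel:
    """Place rigid ring copies along the bending arc.

    The tube axis of ring 0 is +z with the ring centred near the origin; the
    curvature centre sits at (-curvature_radius, 0, 0), so the inside edge of
    the curve is at negative x.  Ring r is ring 0 rotated by r*bend_angle
    about the y axis through the curvature centre; the rotation is evaluated
    as a displacement (using 1-cos = 2 sin^2(a/2)) so that very large
    curvature radii stay numerically exact.
    """
    if n_rings < 2:
        raise ValueError("n_rings must be at least 2")
    if len(ring.labels) == 0:
        raise ValueError("ring must not be empty")
    radial = np.hypot(ring.positions[:, 0], ring.positions[:, 1]).max()
    if geometry.inner_radius <= radial:
        raise ValueError("geometry inconsistent with ring extent: inner "
                         f"radius {geometry.inner_radius} <= ring radius {radial}")
    rc = geometry.curvature_radius
    theta = geometry.bend_angle_rad
    labels, positions, ring_idx = [], [], []
    px, py, pz = ring.positions.T
    pxc = px + rc  # distance from the curvature axis along x
    for r in range(n_rings):
        a = r * theta
        s, cm1 = np.sin(a), -2.0 * np.sin(a / 2.0) ** 2
        q = np.stack([px + cm1 * pxc - s * pz,
                      py,
                      pz + s * pxc + cm1 * pz], axis=1)
        labels.extend(_ring_labels(ring, r))
        positions.append(q)
        ring_idx.extend([r] * len(ring.labels))
    return TubeModel(labels, np.concatenate(positions), np.array(ring_idx),
                     n_rings, geometry)


@dataclass
class RestraintNetwork:
    """Harmonic distance and position restraints with straight-tube targets.

    ``pairs``: (label_i, label_j, target_distance, force_constant);
    ``position_restraints``: (label, target_position, force_constant).
    """

    pairs: list
    position_restraints: list = field(default_factory=list)

    def __post_init__(self):
        for _, _, d0, k in self.pairs:
            if not (k > 0):
                raise ValueError("force constants must be positive")
            if d0 <= 0:
                raise ValueError("target distances must be positive")


def make_restraint_network(model: TubeModel, n_pairs: int, seed: int,
                           min_d: float = 3.0, max_d: float = 15.0,
                           position_restraint_labels=(),
                           force_constant: float = 1.0) -> RestraintNetwork:
    """Sample random atom pairs between min_d and max_d apart (targets from
    the given model) plus position restraints for the designated atoms."""
    tree = cKDTree(model.positions)
    pairs = sorted(tree.query_pairs(max_d))
    eligible = []
    for i, j in pairs:
        d = float(np.linalg.norm(model.positions[i] - model.positions[j]))
        if d >= min_d:
            eligible.append((i, j, d))
    if len(eligible) < n_pairs:
        raise ValueError(f"only {len(eligible)} eligible pairs for {n_pairs} "
                         "requested")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_pairs, replace=False)
    restraints = [(model.labels[eligible[c][0]], model.labels[eligible[c][1]],
                   eligible[c][2], force_constant) for c in sorted(chosen)]
    pos_restraints = [(lab, model.positions[model.index_of(lab)].copy(),
                       force_constant) for lab in position_restraint_labels]
    return RestraintNetwork(restraints, pos_restraints)


def _network_arrays(model: TubeModel, network: RestraintNetwork):
    ii = np.array([model.index_of(a) for a, _, _, _ in network.pairs], int)
    jj = np.array([model.index_of(b) for _, b, _, _ in network.pairs], int)
    d0 = np.array([d for _, _, d, _ in network.pairs])
    kk = np.array([k for _, _, _, k in network.pairs])
    pi = np.array([model.index_of(lab) for lab, _, _ in
                   network.position_restraints], int)
    px = (np.stack([x for _, x, _ in network.position_restraints])
          if network.position_restraints else np.zeros((0, 3)))
    pk = np.array([k for _, _, k in network.position_restraints])
    return ii, jj, d0, kk, pi, px, pk


def network_energy(model: TubeModel, network: RestraintNetwork) -> float:
    """Sum of k*(d-d0)^2 over pairs plus k*|x-x0|^2 over position restraints."""
    ii, jj, d0, kk, pi, px, pk = _network_arrays(model, network)
    d = np.linalg.norm(model.positions[ii] - model.positions[jj], axis=1)
    e = float(np.sum(kk * (d - d0) ** 2))
    if len(pi):
        e += float(np.sum(pk * np.sum((model.positions[pi] - px) ** 2, axis=1)))
    return e


@dataclass
class RelaxResult:
    model: TubeModel
    initial_energy: float
    final_energy: float
    n_iter: int
    converged: bool
    energy_trace: list = field(default_factory=list)


def relax_under_restraints(model: TubeModel, network: RestraintNetwork,
                           max_iter: int = 500, tol: float = 1e-10) -> RelaxResult:
    """Minimise the harmonic network energy by L-BFGS with analytic gradients.

    Returns the best-so-far model with a convergence flag; the energy trace
    over accepted iterations is recorded and is non-increasing.
    """
    if not np.all(np.isfinite(model.positions)):
        raise ValueError("starting coordinates must be finite")
    ii, jj, d0, kk, pi, px, pk = _network_arrays(model, network)
    n = len(model.positions)
    trace = []

    def fg(flat):
        x = flat.reshape(n, 3)
        g = np.zeros_like(x)
        diff = x[ii] - x[jj]
        d = np.linalg.norm(diff, axis=1)
        d_safe = np.where(d > 0, d, 1.0)
        e = float(np.sum(kk * (d - d0) ** 2))
        coef = (2.0 * kk * (d - d0) / d_safe)[:, None] * diff
        np.add.at(g, ii, coef)
        np.add.at(g, jj, -coef)
        if len(pi):
            dp = x[pi] - px
            e += float(np.sum(pk * np.sum(dp**2, axis=1)))
            np.add.at(g, pi, 2.0 * pk[:, None] * dp)
        return e, g.ravel()

    e0 = fg(model.positions.ravel())[0]
    res = minimize(fg, model.positions.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
                   callback=lambda xk: trace.append(fg(xk)[0]))
    best = model.with_positions(res.x.reshape(n, 3))
    return RelaxResult(best, e0, float(res.fun), int(res.nit),
                       bool(res.success or res.fun <= e0), trace)


def score_restraint_fulfilment(model: TubeModel, network: RestraintNetwork,
                               tolerance: float = 0.5):
    """Per-residue fraction of incident pair restraints within tolerance.

    A pair is fulfilled when |d - d0| <= tolerance (A).  Residues with no
    incident pairs get NaN, not zero.  Returns a pandas Series indexed by
    residue label.
    """
    import pandas as pd

    ii, jj, d0, _, _, _, _ = _network_arrays(model, network)
    d = np.linalg.norm(model.positions[ii] - model.positions[jj], axis=1)
    ok = np.abs(d - d0) <= tolerance
    incident: dict = {}
    for col, flags in ((ii, ok), (jj, ok)):
        for atom, f in zip(col, flags):
            res = model.residue_of(int(atom))
            tot, ful = incident.get(res, (0, 0))
            incident[res] = (tot + 1, ful + int(f))
    residues = sorted({model.residue_of(i) for i in range(len(model.labels))})
    vals = [incident[r][1] / incident[r][0] if r in incident else np.nan
            for r in residues]
    return pd.Series(vals, index=residues, name="fulfilment")
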