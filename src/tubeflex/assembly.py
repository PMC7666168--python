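"""Helical-symmetry assembly and ambiguous distance restraints.

A tube model is generated from one subunit by C-symmetry within a ring plus
a helical rise/twist between rings: slot k of ring r is the subunit rotated
by (k*360/c_sym + r*twist) degrees about the +z tube axis (right-handed) and
translated by (0, 0, r*rise).  The default symmetry is the tube's optimised
C6 with a rise of 38.46 A and a twist of 21.89 degrees per ring.

An NMR cross-peak between two atoms cannot be assigned to specific subunits
under this symmetry, so it is expanded into an ambiguous restraint: the
first atom in the reference subunit against the second atom in every subunit
of the assembly (all 12 subunits of two stacked hexameric rings).  Candidate
distances are combined by r^-6 sum averaging, d_eff = (sum d_i^-6)^(-1/6),
the standard treatment that lets the closest candidate dominate, and checked
against a generous upper bound (7 A by default).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymmetryParams",
    "SubunitPose",
    "AssemblyModel",
    "AmbiguousRestraint",
    "RegisterPosterior",
    "ViolationReport",
    "symmetry_operators",
    "build_assembly",
    "expand_restraint",
    "effective_distance",
    "check_violations",
    "infer_register",
    "chain_id",
]

DEFAULT_UPPER_BOUND = 7.0  # A; generous bound for ambiguous NMR restraints


@dataclass
class SymmetryParams:
    """Helical symmetry: rotational order, rise (A) and twist (deg) per ring."""

    c_sym: int = 6
    rise: float = 38.46
    twist: float = 21.89
    handedness: str = "right"

    def __post_init__(self):
        if self.c_sym < 1:
            raise ValueError("c_sym must be at least 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")


@dataclass
class SubunitPose:
    ring_index: int
    slot_index: int
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-10) or np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper orthonormal")

    def apply(self, positions):
        return np.asarray(positions, float) @ self.rotation.T + self.translation


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def symmetry_operators(params: SymmetryParams, n_rings: int):
    """Poses for every subunit of an n-ring assembly.

    Slot k in ring r: rotation by (k*360/c_sym + r*twist) degrees about +z
    (sign flipped for left-handed tubes) and translation (0, 0, r*rise).
    """
    if n_rings < 1:
        raise ValueError("n_rings must be at least 1")
    sign = 1.0 if params.handedness == "right" else -1.0
    poses = []
    for r in range(n_rings):
        for k in range(params.c_sym):
            ang = sign * (k * 360.0 / params.c_sym + r * params.twist)
            poses.append(SubunitPose(r, k, _rot_z(ang),
                                     np.array([0.0, 0.0, r * params.rise])))
    return poses


def chain_id(index: int) -> str:
    """Deterministic chain identifier for pose number ``index`` (A, B, ... AA, AB, ...)."""
    letters = string.ascii_uppercase
    if index < 26:
        return letters[index]
    index -= 26
    return letters[index // 26] + letters[index % 26]


@dataclass
class AssemblyModel:
    """A symmetric tube assembly: one monomer replicated by a pose list."""

    monomer: object
    poses: list
    params: SymmetryParams

    def __post_init__(self):
        ids = [chain_id(i) for i in range(len(self.poses))]
        if len(set(ids)) != len(ids):
            raise ValueError("clashing chain identifiers")
        self.chain_ids = ids

    @property
    def n_rings(self):
        return max(p.ring_index for p in self.poses) + 1

    @property
    def n_subunits(self):
        return len(self.poses)

    def positions(self, pose_index: int) -> np.ndarray:
        return self.poses[pose_index].apply(self.monomer.positions)

    def atom_position(self, pose_index: int, label: str) -> np.ndarray:
        i = self.monomer.labels.index(label)
        return self.positions(pose_index)[i]

    def all_positions(self) -> np.ndarray:
        return np.concatenate([self.positions(i) for i in range(len(self.poses))])


def build_assembly(monomer, params: SymmetryParams, n_rings: int) -> AssemblyModel:
    """Replicate a monomer into an n-ring assembly under the given symmetry."""
    if monomer.n_atoms == 0:
        raise ValueError("monomer must not be empty")
    return AssemblyModel(monomer, symmetry_operators(params, n_rings), params)


@dataclass
class AmbiguousRestraint:
    """One cross-peak expanded over symmetry-related subunit pairs.

    ``candidates`` holds (pose_i, pose_j) index pairs: atom_a in pose_i
    against atom_b in pose_j.  ``intermolecular_only`` marks peaks from
    heterogeneously mixed samples, whose self pair is excluded.
    """

    atom_a: str
    atom_b: str
    upper_bound: float = DEFAULT_UPPER_BOUND
    candidates: list = field(default_factory=list)
    intermolecular_only: bool = False

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")
        if not self.candidates:
            raise ValueError("candidates must be non-empty")


def expand_restraint(atom_a: str, atom_b: str, assembly: AssemblyModel,
                     upper_bound: float = DEFAULT_UPPER_BOUND,
                     intermolecular_only: bool = False) -> AmbiguousRestraint:
    """Expand one cross-peak into its symmetry-related candidate contacts.

    atom_a stays in the reference subunit (pose 0); atom_b is placed in every
    subunit of the assembly, the self pair included unless the peak is known
    to be intermolecular (mixed-labelled sample), in which case it is
    dropped.  Two stacked hexameric rings give 12 candidates (11 for
    intermolecular-only peaks).
    """
    for atom in (atom_a, atom_b):
        if atom not in assembly.monomer.labels:
            raise ValueError(f"atom {atom!r} absent from monomer")
    candidates = [(0, j) for j in range(assembly.n_subunits)
                  if not (intermolecular_only and j == 0)]
    return AmbiguousRestraint(atom_a, atom_b, upper_bound, candidates,
                              intermolecular_only)


def candidate_distances(restraint: AmbiguousRestraint,
                        assembly: AssemblyModel) -> np.ndarray:
    pa = {i: assembly.atom_position(i, restraint.atom_a)
          for i in {c[0] for c in restraint.candidates}}
    pb = {j: assembly.atom_position(j, restraint.atom_b)
          for j in {c[1] for c in restraint.candidates}}
    return np.array([np.linalg.norm(pa[i] - pb[j])
                     for i, j in restraint.candidates])


def effective_distance(restraint: AmbiguousRestraint,
                       assembly: AssemblyModel) -> float:
    """r^-6 sum-averaged distance over all candidates: (sum d^-6)^(-1/6)."""
    d = candidate_distances(restraint, assembly)
    if np.any(d == 0):
        raise ValueError("candidate at zero distance")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


@dataclass
class ViolationReport:
    """Restraints whose effective distance exceeds the upper bound."""

    violations: list          # (restraint, effective_distance, excess), sorted
    n_satisfied: int
    n_violated: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"atom_a": r.atom_a, "atom_b": r.atom_b, "bound": r.upper_bound,
              "effective": d, "excess": e} for r, d, e in self.violations])


def check_violations(restraints, assembly: AssemblyModel) -> ViolationReport:
    """List restraints violated by the assembly, sorted by decreasing excess."""
    violations = []
    n_sat = 0
    for r in restraints:
        d = effective_distance(r, assembly)
        if d > r.upper_bound:
            violations.append((r, d, d - r.upper_bound))
        else:
            n_sat += 1
    violations.sort(key=lambda t: -t[2])
    return ViolationReport(violations, n_sat, len(violations))


# ---------------------------------------------------------------------------
# beta-strand register inference
# ---------------------------------------------------------------------------


def residue_index(label: str) -> int:
    """Residue number from a ``R{i}:{atom}`` label."""
    res = label.split(":")[0]
    if not res.startswith("R"):
        raise ValueError(f"cannot parse residue from label {label!r}")
    return int(res[1:])


@dataclass
class RegisterPosterior:
    """Posterior over integer register offsets between two adjacent strands."""

    strand_a: tuple
    strand_b: tuple
    registers: np.ndarray
    probabilities: np.ndarray
    uninformative: bool = False

    def __post_init__(self):
        self.registers = np.asarray(self.registers, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")

    @property
    def best(self) -> int:
        return int(self.registers[np.argmax(self.probabilities)])


# ideal antiparallel beta geometry: cross-strand pair distance and
# per-residue ladder spacing along a strand, both in Angstrom
PAIR_DISTANCE = 5.0
LADDER_SPACING = 3.3


def infer_register(strand_a, strand_b, restraints, assembly: AssemblyModel,
                   sigma_reg: float = 1.0) -> RegisterPosterior:
    """Posterior over relative registers of two antiparallel strands.

    Register r means residue ``a_lo + i`` of strand A pairs with residue
    ``b_hi - i - r`` of strand B.  Each observed contact between strand
    residues is scored by a Gaussian (scale ``sigma_reg``) on the deviation
    of its idealised distance from the paired-contact distance: a contact
    whose partners mismatch the register by m residues sits roughly
    sqrt(PAIR_DISTANCE^2 + (LADDER_SPACING*m)^2) apart in ideal antiparallel
    geometry.  With no contacts touching both strands the posterior is
    uniform and flagged uninformative.
    """
    a_lo, a_hi = strand_a
    b_lo, b_hi = strand_b
    len_a, len_b = a_hi - a_lo + 1, b_hi - b_lo + 1
    if len_a < 3 or len_b < 3:
        raise ValueError("strand runs must be at least 3 residues long")
    span = max(len_a, len_b)
    registers = np.arange(-span, span + 1)

    contacts = []
    for r in restraints:
        for atom in (r.atom_a, r.atom_b):
            if atom not in assembly.monomer.labels:
                raise ValueError(f"atom {atom!r} absent from monomer")
        ra, rb = residue_index(r.atom_a), residue_index(r.atom_b)
        if a_lo <= ra <= a_hi and b_lo <= rb <= b_hi:
            contacts.append((ra, rb))
        elif a_lo <= rb <= a_hi and b_lo <= ra <= b_hi:
            contacts.append((rb, ra))

    if not contacts:
        p = np.full(len(registers), 1.0 / len(registers))
        return RegisterPosterior(tuple(strand_a), tuple(strand_b),
                                 registers, p, uninformative=True)

    loglik = np.zeros(len(registers))
    for k, reg in enumerate(registers):
        for ra, rb in contacts:
            partner = b_hi - (ra - a_lo) - reg
            m = rb - partner
            d_pred = np.hypot(PAIR_DISTANCE, LADDER_SPACING * m)
            loglik[k] -= (d_pred - PAIR_DISTANCE) ** 2 / (2 * sigma_reg**2)
    loglik -= loglik.max()
    p = np.exp(loglik)
    p /= p.sum()
    return RegisterPosterior(tuple(strand_a), tuple(strand_b), registers, p)
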