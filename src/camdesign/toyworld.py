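"""Synthetic stand-ins for molecular simulation and stability scoring.

Everything the design pipeline would obtain from all-atom molecular
dynamics, experimental structure ensembles, or an external stability scorer
is emulated here at desk scale, with the planted ground truth emitted
alongside the data so downstream recovery is directly assertable:

* analytic toy potentials (harmonic, tilted double well, Müller-Brown) with
  vectorized energies and gradients,
* an overdamped Langevin (Euler-Maruyama) engine in reduced units (kT = 1 is
  the natural scale; all lengths share the contact-cutoff unit),
* residue-trajectory generators with planted contact graphs and
  community-structured displacement correlations,
* active/inactive structure-ensemble generators with planted state-exclusive
  contacts,
* an additive per-(position, amino acid, state) stability-energy table with
  seeded replicate noise, satisfying the stability-scorer contract of the
  mutation-scanning module.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .allonet import ResidueTrajectory
from .statecontacts import (
    ACTIVE, CONTACT_CUTOFF, INACTIVE, STATES,
    ExclusiveContactSet, Structure, StructureEnsemble,
)

#: Separation of the bridge atoms realizing a planted contact (well inside
#: the cutoff) and of a planted non-contact (well outside it).
_BRIDGE_NEAR = 2.0
_BRIDGE_FAR = 3.0 * CONTACT_CUTOFF
#: Lattice spacing between residue markers in planted fixtures.
_LATTICE = 10.0 * CONTACT_CUTOFF
#: Per-coordinate displacement amplitude of correlated fluctuations.
_FLUCTUATION_AMP = 0.2


# ---------------------------------------------------------------------------
# Toy potentials
# ---------------------------------------------------------------------------

class ToyPotential:
    """Analytic potential with vectorized energy and gradient.

    Subclasses define :meth:`energy` and :meth:`gradient` for arrays of
    shape (..., dimension).
    """

    name: str = "potential"
    dimension: int = 1
    params: dict = {}

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Harmonic(ToyPotential):
    """V(x) = 1/2 · k |x - center|²."""

    def __init__(self, k: float = 1.0, center=None, dimension: int = 1):
        self.name = "harmonic"
        self.dimension = dimension
        self.k = float(k)
        self.center = (np.zeros(dimension) if center is None
                       else np.asarray(center, dtype=float))
        self.params = {"k": self.k, "center": tuple(self.center)}

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.k * np.sum((x - self.center) ** 2, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.k * (x - self.center)


class DoubleWell(ToyPotential):
    """Tilted 1-D double well, optionally padded with harmonic dimensions.

    V(x) = (x₀² - 1)² + tilt·x₀ + 1/2 · k_harmonic Σ_{i>0} x_i².

    With tilt = 0 the two minima sit at x₀ = ±1 separated by a unit barrier
    at x₀ = 0. A negative tilt lowers the x₀ = +1 basin.
    """

    def __init__(self, tilt: float = 0.0, n_harmonic: int = 0,
                 k_harmonic: float = 1.0):
        self.name = "double_well"
        self.dimension = 1 + int(n_harmonic)
        self.tilt = float(tilt)
        self.k_harmonic = float(k_harmonic)
        self.params = {"tilt": self.tilt, "n_harmonic": int(n_harmonic),
                       "k_harmonic": self.k_harmonic}

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        x0 = x[..., 0]
        e = (x0 ** 2 - 1.0) ** 2 + self.tilt * x0
        if self.dimension > 1:
            e = e + 0.5 * self.k_harmonic * np.sum(x[..., 1:] ** 2, axis=-1)
        return e

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        x0 = x[..., 0]
        g[..., 0] = 4.0 * x0 * (x0 ** 2 - 1.0) + self.tilt
        if self.dimension > 1:
            g[..., 1:] = self.k_harmonic * x[..., 1:]
        return g


class MullerBrown(ToyPotential):
    """The standard four-Gaussian Müller-Brown surface in 2-D.

    V(x, y) = Σ_k A_k exp(a_k(x-x0_k)² + b_k(x-x0_k)(y-y0_k) + c_k(y-y0_k)²)

    Deep minimum near (-0.558, 1.442), second minimum near (0.623, 0.028).
    """

    _A = np.array([-200.0, -100.0, -170.0, 15.0])
    _a = np.array([-1.0, -1.0, -6.5, 0.7])
    _b = np.array([0.0, 0.0, 11.0, 0.6])
    _c = np.array([-10.0, -10.0, -6.5, 0.7])
    _x0 = np.array([1.0, 0.0, -0.5, -1.0])
    _y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def __init__(self):
        self.name = "muller_brown"
        self.dimension = 2
        self.params = {"A": tuple(self._A), "a": tuple(self._a),
                       "b": tuple(self._b), "c": tuple(self._c),
                       "x0": tuple(self._x0), "y0": tuple(self._y0)}

    def _terms(self, x):
        dx = x[..., 0, None] - self._x0
        dy = x[..., 1, None] - self._y0
        expo = self._a * dx ** 2 + self._b * dx * dy + self._c * dy ** 2
        return dx, dy, self._A * np.exp(expo)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self._terms(x)[2].sum(axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        dx, dy, terms = self._terms(x)
        gx = np.sum(terms * (2.0 * self._a * dx + self._b * dy), axis=-1)
        gy = np.sum(terms * (self._b * dx + 2.0 * self._c * dy), axis=-1)
        return np.stack([gx, gy], axis=-1)


def evaluate_potential(potential: ToyPotential, point):
    """Energy and gradient at a single point, with a dimension check."""
    point = np.asarray(point, dtype=float)
    if point.shape != (potential.dimension,):
        raise ValueError(
            f"point has dimension {point.shape}, but potential "
            f"{potential.name!r} has dimension {potential.dimension}"
        )
    return float(potential.energy(point)), potential.gradient(point)


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinConfig:
    """Reduced-unit parameters of the overdamped Langevin integrator."""

    time_step: float
    friction: float = 1.0
    thermal_energy: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError(f"time_step must be > 0, got {self.time_step}")
        if self.friction <= 0:
            raise ValueError(f"friction must be > 0, got {self.friction}")
        if self.thermal_energy < 0:
            raise ValueError(
                f"thermal_energy must be >= 0, got {self.thermal_energy}"
            )


@dataclass
class ToyTrajectory:
    """Ordered frames of point coordinates, shape (n_frames, dimension)."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dimension(self) -> int:
        return self.coords.shape[1]


def langevin_step_batch(potential: ToyPotential, x: np.ndarray,
                        noise: np.ndarray, dt: float, friction: float,
                        anchors: np.ndarray | None = None,
                        k_restraint: float = 0.0) -> np.ndarray:
    """One Euler-Maruyama step for a batch of walkers, pre-drawn noise.

    x <- x - (dt/γ)(∇V + k_r (x - anchor)) + noise, with ``noise`` already
    scaled by sqrt(2 kT dt / γ).
    """
    force = potential.gradient(x)
    if anchors is not None and k_restraint > 0.0:
        force = force + k_restraint * (x - anchors)
    return x - (dt / friction) * force + noise


def simulate_langevin(potential: ToyPotential, start, config: LangevinConfig,
                      n_steps: int, restraint=None) -> ToyTrajectory:
    """Overdamped Langevin trajectory; includes the start frame.

    ``restraint`` is an optional (anchor point, force constant) harmonic
    tether. Raises if a non-finite energy is encountered, reporting the step.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    anchor, k_r = None, 0.0
    if restraint is not None:
        anchor, k_r = restraint
        anchor = np.asarray(anchor, dtype=float)
        if k_r < 0:
            raise ValueError(f"restraint force constant must be >= 0, got {k_r}")
    x = np.asarray(start, dtype=float).copy()
    if x.shape != (potential.dimension,):
        raise ValueError(
            f"start has shape {x.shape}, potential dimension is "
            f"{potential.dimension}"
        )
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(2.0 * config.thermal_energy * config.time_step
                    / config.friction)
    noise = sigma * rng.standard_normal((n_steps, potential.dimension))
    frames = np.empty((n_steps + 1, potential.dimension))
    frames[0] = x
    for step in range(n_steps):
        x = langevin_step_batch(potential, x, noise[step], config.time_step,
                                config.friction, anchor, k_r)
        if not np.all(np.isfinite(x)) or not np.isfinite(potential.energy(x)):
            raise FloatingPointError(
                f"non-finite energy at step {step + 1} of Langevin run "
                f"on {potential.name!r}"
            )
        frames[step + 1] = x
    return ToyTrajectory(coords=frames)


# ---------------------------------------------------------------------------
# Planted-network fixture
# ---------------------------------------------------------------------------

def _lattice_positions(n: int) -> np.ndarray:
    """Well-separated base positions for n residue markers on a cubic grid."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = []
    for i in range(n):
        pts.append([i % side, (i // side) % side, i // side ** 2])
    return _LATTICE * np.asarray(pts, dtype=float)


def _nonadjacent_pairs(n: int):
    return [(i, j) for i in range(n) for j in range(i + 2, n)]


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Ground-truth description of a correlated residue trajectory.

    ``contact_prob_within`` / ``contact_prob_between`` are the edge
    probabilities of the planted random contact graph inside / across
    communities; planted edges are realized as always-in-contact pairs and
    non-edges never come within the cutoff. ``correlation_within`` /
    ``correlation_between`` are target displacement correlations.
    """

    n_residues: int
    community_assignment: tuple  # residue index -> community id, as a tuple
    contact_prob_within: float = 0.6
    contact_prob_between: float = 0.1
    correlation_within: float = 0.9
    correlation_between: float = 0.05
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self):
        if len(self.community_assignment) != self.n_residues:
            raise ValueError("community_assignment must cover every residue")
        if len(set(self.community_assignment)) < 2:
            raise ValueError("need at least 2 communities")
        for p in (self.contact_prob_within, self.contact_prob_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contact probability {p} outside [0, 1]")
        for c in (self.correlation_within, self.correlation_between):
            if not 0.0 <= abs(c) <= 1.0:
                raise ValueError(f"correlation magnitude {c} outside [0, 1]")


def _correlation_matrix(spec: PlantedNetworkSpec) -> np.ndarray:
    comm = np.asarray(spec.community_assignment)
    same = comm[:, None] == comm[None, :]
    sigma = np.where(same, spec.correlation_within, spec.correlation_between)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def make_correlated_trajectory(spec: PlantedNetworkSpec):
    """Residue trajectory with a planted contact graph and correlations.

    Returns ``(trajectory, edges, partition)`` where ``edges`` is the set of
    planted residue pairs (tuples, i < j) and ``partition`` maps residue
    index -> community id. Planted pairs are within the contact cutoff in
    every frame; non-planted pairs never are. Marker displacements follow a
    multivariate normal with the block correlation structure of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    comm = list(spec.community_assignment)
    edges = set()
    for i, j in _nonadjacent_pairs(n):
        p = (spec.contact_prob_within if comm[i] == comm[j]
             else spec.contact_prob_between)
        if rng.random() < p:
            edges.add((i, j))

    sigma = _correlation_matrix(spec)
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-8:
        raise ValueError(
            "infeasible correlation structure: target correlation matrix is "
            f"not positive semi-definite (min eigenvalue {w.min():.3e})"
        )
    transform = v * np.sqrt(np.clip(w, 0.0, None))

    markers = _lattice_positions(n)
    base, resids = _plant_bridges(markers, {e: _BRIDGE_NEAR for e in edges})
    disp = rng.standard_normal((spec.n_frames, 3, n)) @ transform.T
    disp = _FLUCTUATION_AMP * np.transpose(disp, (0, 2, 1))  # (F, n, 3)
    coords = base[None, :, :] + disp[:, resids, :]
    traj = ResidueTrajectory(coords=coords, atom_resids=np.asarray(resids))
    partition = {i: comm[i] for i in range(n)}
    return traj, edges, partition


def _plant_bridges(markers: np.ndarray, pair_separation: dict):
    """Base coordinates realizing an exact planted contact geometry.

    Each residue gets a marker atom on the (widely spaced) marker lattice
    plus, per planted pair, one bridge atom at a dedicated interaction site:
    the two bridge atoms of a pair sit ``pair_separation[pair]`` apart at a
    site of a second lattice placed well away from the markers, one site
    per pair. This non-physical gadget realizes *any* planted contact graph
    exactly — the only residue pairs within the contact cutoff are those
    whose separation says so — because distinct sites, and sites versus
    markers, are always at least one lattice spacing apart.
    """
    atoms = [[m] for m in markers]
    ordered = sorted(pair_separation.items())
    m_side = max(int(np.ceil(np.sqrt(len(ordered)))), 1)
    for k, ((i, j), sep) in enumerate(ordered):
        site = _LATTICE * np.array([k % m_side, (k // m_side) % m_side,
                                    -3.0 - (k // m_side ** 2)])
        atoms[i].append(site - np.array([0.5 * sep, 0.0, 0.0]))
        atoms[j].append(site + np.array([0.5 * sep, 0.0, 0.0]))
    coords = np.concatenate([np.asarray(a) for a in atoms])
    resids = np.concatenate(
        [np.full(len(a), i, dtype=int) for i, a in enumerate(atoms)]
    )
    return coords, resids


# ---------------------------------------------------------------------------
# Two-state structure-ensemble fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateEnsembleSpec:
    """Planted state-exclusive contacts for active/inactive toy ensembles."""

    n_residues: int
    contacts_inactive_only: frozenset = frozenset()
    contacts_active_only: frozenset = frozenset()
    contacts_shared: frozenset = frozenset()
    members_per_state: int = 4
    coordinate_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        sets = [frozenset(map(tuple, s)) for s in
                (self.contacts_inactive_only, self.contacts_active_only,
                 self.contacts_shared)]
        object.__setattr__(self, "contacts_inactive_only", sets[0])
        object.__setattr__(self, "contacts_active_only", sets[1])
        object.__setattr__(self, "contacts_shared", sets[2])
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            if sets[a] & sets[b]:
                raise ValueError("the three contact sets must be disjoint")
        for i, j in sets[0] | sets[1] | sets[2]:
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise ValueError(f"contact ({i}, {j}) outside residue range")
            if abs(i - j) <= 1:
                raise ValueError(
                    f"contact ({i}, {j}) is sequence-adjacent; planted "
                    "contacts must satisfy |Δindex| > 1"
                )
        if self.members_per_state < 1:
            raise ValueError("members_per_state must be >= 1")
        if self.coordinate_noise < 0:
            raise ValueError("coordinate_noise must be >= 0")


def make_two_state_ensembles(spec: TwoStateEnsembleSpec):
    """Active and inactive toy ensembles with planted exclusive contacts.

    Returns ``(active_ensemble, inactive_ensemble, truth)`` where ``truth``
    is the planted inactive-exclusive :class:`ExclusiveContactSet` (idealized
    frequencies 0 in active, 1 in inactive members). Inactive-only pairs are
    within the cutoff in every inactive member and far outside it in every
    active member; active-only pairs are the mirror image; shared pairs are
    in contact in both states.
    """
    # The closest planted separation is _BRIDGE_NEAR with a 1.0+ margin to
    # the cutoff; Gaussian member noise beyond ~6 sigma of that margin can
    # flip contacts.
    margin = (CONTACT_CUTOFF - _BRIDGE_NEAR - 1.5) / np.sqrt(2.0)
    if spec.coordinate_noise > margin / 6.0:
        raise ValueError(
            f"coordinate_noise {spec.coordinate_noise} is too large to keep "
            f"planted contacts exact; lower it to <= {margin / 6.0:.3f}"
        )
    rng = np.random.default_rng(spec.seed)
    markers = _lattice_positions(spec.n_residues)
    all_pairs = sorted(spec.contacts_inactive_only | spec.contacts_active_only
                       | spec.contacts_shared)
    seps = {
        ACTIVE: {p: (_BRIDGE_FAR if p in spec.contacts_inactive_only
                     else _BRIDGE_NEAR) for p in all_pairs},
        INACTIVE: {p: (_BRIDGE_FAR if p in spec.contacts_active_only
                       else _BRIDGE_NEAR) for p in all_pairs},
    }
    ensembles = {}
    for state in STATES:
        base, resids = _plant_bridges(markers, seps[state])
        members = []
        for m in range(spec.members_per_state):
            noisy = base + rng.normal(0.0, spec.coordinate_noise, base.shape)
            residues = {
                int(r): noisy[resids == r]
                for r in range(spec.n_residues)
            }
            members.append(Structure(identifier=f"{state}_{m}", state=state,
                                     residues=residues))
        ensembles[state] = StructureEnsemble(members=members)
    truth = ExclusiveContactSet(
        target_state=INACTIVE,
        pairs=[(p, 0.0, 1.0) for p in sorted(spec.contacts_inactive_only)],
    )
    return ensembles[ACTIVE], ensembles[INACTIVE], truth


# ---------------------------------------------------------------------------
# Toy stability scorer
# ---------------------------------------------------------------------------

@dataclass
class ToyStabilityTable:
    """Additive per-(position, amino acid, state) stability energies.

    The score of a sequence in a state is the sum of its per-position
    entries (missing entries contribute 0) plus Gaussian replicate noise of
    scale ``replicate_sigma`` seeded deterministically by
    (seed, sequence, state, replicate); with zero sigma repeated evaluation
    is identical. Satisfies the stability-scorer contract
    ``score(state, sequence, replicate_index)``.
    """

    energies: dict = field(default_factory=dict)
    replicate_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.replicate_sigma < 0:
            raise ValueError("replicate_sigma must be >= 0")

    def score(self, state: str, sequence: str, replicate_index: int = 0
              ) -> float:
        return toy_stability_score(self, sequence, state, replicate_index)


def _replicate_noise_rng(seed: int, sequence: str, state: str,
                         replicate_index: int) -> np.random.Generator:
    key = f"{seed}|{sequence}|{state}|{replicate_index}".encode()
    digest = hashlib.sha256(key).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def toy_stability_score(table: ToyStabilityTable, sequence: str, state: str,
                        replicate_index: int = 0) -> float:
    """Additive toy stability energy of ``sequence`` in ``state``."""
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}, got {state!r}")
    base = sum(
        table.energies.get((pos, aa, state), 0.0)
        for pos, aa in enumerate(sequence)
    )
    if table.replicate_sigma > 0.0:
        rng = _replicate_noise_rng(table.seed, sequence, state,
                                   replicate_index)
        base += table.replicate_sigma * float(rng.standard_normal())
    return float(base)
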