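"""String method with swarms of trajectories.

Finds the most probable transition pathway between two metastable states in
a collective-variable (CV) space: a string of images with fixed endpoints is
iteratively refined by (1) restrained equilibration at each image under a
stiff harmonic CV tether, (2) launching a swarm of short unbiased
trajectories from each equilibrated configuration, (3) moving each image by
the mean swarm drift in scaled CV space, and (4) reparameterizing the
string to equal arclength. Convergence is monitored by the displacement
between consecutive block-averaged strings.

The dynamics engine is an in-process object propagating configurations of a
toy potential; CV kinds cover raw coordinates, interatomic distances and
RMSD to a reference over an atom set. String dynamics (restrained
equilibration) requires a CV set that is an invertible map of the
configuration space, which for the toy engines means a full set of raw
coordinate CVs; distance and RMSD CVs serve analysis projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .toyworld import ToyPotential, ToyTrajectory, langevin_step_batch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Collective variables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawCoordinateCV:
    """A single configuration coordinate, divided by ``scale``."""

    index: int
    scale: float = 1.0
    label: str = ""

    def evaluate(self, conformation) -> float:
        x = np.asarray(conformation, dtype=float).ravel()
        return float(x[self.index]) / self.scale


@dataclass(frozen=True)
class DistanceCV:
    """Distance between two atoms of an (n_atoms, 3) conformation."""

    atom_a: int
    atom_b: int
    scale: float = 1.0
    label: str = ""

    def evaluate(self, conformation) -> float:
        x = np.asarray(conformation, dtype=float)
        return float(np.linalg.norm(x[self.atom_a] - x[self.atom_b])) \
            / self.scale


@dataclass(frozen=True)
class RMSDCV:
    """RMSD to a reference over an atom subset, after Kabsch superposition."""

    atom_indices: tuple
    reference: tuple  # ((n, 3) coordinates, stored as nested tuples)
    scale: float = 1.0
    label: str = ""

    def evaluate(self, conformation) -> float:
        x = np.asarray(conformation, dtype=float)[list(self.atom_indices)]
        ref = np.asarray(self.reference, dtype=float)
        x = x - x.mean(axis=0)
        ref = ref - ref.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, x)
        rmsd = np.sqrt(np.mean(np.sum((rot.apply(x) - ref) ** 2, axis=1)))
        return float(rmsd) / self.scale


@dataclass
class CollectiveVariableSet:
    """An ordered list of CVs; evaluation yields a scaled CV vector."""

    cvs: list

    def __post_init__(self):
        if not self.cvs:
            raise ValueError("need at least one collective variable")
        for cv in self.cvs:
            if cv.scale <= 0:
                raise ValueError(f"CV scale must be > 0, got {cv.scale}")

    @property
    def n_cvs(self) -> int:
        return len(self.cvs)

    @property
    def labels(self) -> list:
        return [cv.label or f"cv{i}" for i, cv in enumerate(self.cvs)]

    def evaluate(self, conformation) -> np.ndarray:
        return np.array([cv.evaluate(conformation) for cv in self.cvs])

    def evaluate_batch(self, conformations: np.ndarray) -> np.ndarray:
        if self.is_raw() and conformations.ndim == 2:
            idx = [cv.index for cv in self.cvs]
            scales = np.array([cv.scale for cv in self.cvs])
            return conformations[:, idx] / scales
        return np.array([self.evaluate(c) for c in conformations])

    def is_raw(self) -> bool:
        return all(isinstance(cv, RawCoordinateCV) for cv in self.cvs)

    def invert(self, cv_vector: np.ndarray) -> np.ndarray:
        """Configuration matching a scaled CV vector (raw CV sets only)."""
        if not self.is_raw():
            raise ValueError(
                "only raw-coordinate CV sets are invertible; distance/RMSD "
                "CVs are analysis projections"
            )
        indices = [cv.index for cv in self.cvs]
        if sorted(indices) != list(range(len(indices))):
            raise ValueError(
                "raw CV set must cover configuration coordinates 0..d-1 "
                "exactly once to be invertible"
            )
        x = np.empty(len(indices))
        for cv, v in zip(self.cvs, np.asarray(cv_vector, dtype=float)):
            x[cv.index] = v * cv.scale
        return x


def raw_cv_set(dimension: int, scales=None, labels=None
               ) -> CollectiveVariableSet:
    """Identity-like CV set over a configuration space of given dimension."""
    scales = scales if scales is not None else [1.0] * dimension
    labels = labels if labels is not None else [f"cv{i}" for i in range(dimension)]
    return CollectiveVariableSet(
        cvs=[RawCoordinateCV(index=i, scale=s, label=l)
             for i, (s, l) in enumerate(zip(scales, labels))]
    )


def microswitch_cv_presets(references: dict, atom_sets: dict,
                           ionic_lock_atoms: tuple) -> CollectiveVariableSet:
    """The four named activation-microswitch projections for a receptor.

    RMSD CVs for the CWxP, PIF-connector and NPxxY motifs (heavy atoms of
    the motif residues against an active-state reference) plus the
    TM3-TM6 ionic-lock Cα distance. ``references`` maps motif name ->
    reference coordinates, ``atom_sets`` maps motif name -> atom indices,
    ``ionic_lock_atoms`` is the Cα atom index pair.
    """
    cvs = []
    for motif in ("CWxP", "PIF", "NPxxY"):
        cvs.append(RMSDCV(
            atom_indices=tuple(atom_sets[motif]),
            reference=tuple(map(tuple, np.asarray(references[motif]))),
            label=f"rmsd_{motif}",
        ))
    cvs.append(DistanceCV(atom_a=ionic_lock_atoms[0],
                          atom_b=ionic_lock_atoms[1],
                          label="dist_ionic_lock"))
    return CollectiveVariableSet(cvs=cvs)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StringPath:
    """Ordered images in scaled CV space with (by default) fixed endpoints."""

    images: np.ndarray
    endpoints_fixed: tuple = (True, True)

    def __post_init__(self):
        self.images = np.atleast_2d(np.asarray(self.images, dtype=float))
        if self.images.shape[0] < 3:
            raise ValueError(
                f"a string needs at least 3 images, got {self.images.shape[0]}"
            )

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def dimension(self) -> int:
        return self.images.shape[1]


@dataclass(frozen=True)
class SwarmConfig:
    """Per-iteration sampling parameters of the swarm-of-trajectories step."""

    n_swarms: int = 32
    swarm_length: int = 10
    equil_length: int = 30
    restraint_constant: float = 1.0e4
    seed: int = 0

    def __post_init__(self):
        if self.n_swarms < 1:
            raise ValueError("n_swarms must be >= 1")
        if self.swarm_length < 1 or self.equil_length < 1:
            raise ValueError("swarm and equilibration lengths must be >= 1")
        if self.restraint_constant <= 0:
            raise ValueError("restraint_constant must be > 0")


@dataclass
class IterationRecord:
    """Everything one string iteration produced."""

    iteration: int
    string_before: np.ndarray
    string_after: np.ndarray
    equilibrated: np.ndarray          # per-image equilibrated CV point
    swarm_starts: np.ndarray          # (n_images, n_swarms, d) CV
    swarm_ends: np.ndarray            # (n_images, n_swarms, d) CV

    def drifts(self) -> np.ndarray:
        return (self.swarm_ends - self.swarm_starts).mean(axis=1)


@dataclass
class ConvergenceProfile:
    """Mean displacement between consecutive block-averaged strings."""

    block: int
    values: np.ndarray


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class OverdampedLangevinEngine:
    """Batched Euler-Maruyama propagator over a toy potential.

    Noise is pre-drawn per walker from caller-supplied RNG streams, so
    results do not depend on batch composition or evaluation order.
    """

    def __init__(self, potential: ToyPotential, time_step: float,
                 friction: float = 1.0, thermal_energy: float = 1.0):
        if time_step <= 0 or friction <= 0 or thermal_energy < 0:
            raise ValueError("need time_step > 0, friction > 0, "
                             "thermal_energy >= 0")
        self.potential = potential
        self.time_step = float(time_step)
        self.friction = float(friction)
        self.thermal_energy = float(thermal_energy)

    @property
    def dimension(self) -> int:
        return self.potential.dimension

    @property
    def noise_sigma(self) -> float:
        return np.sqrt(2.0 * self.thermal_energy * self.time_step
                       / self.friction)

    def propagate(self, x0: np.ndarray, noise: np.ndarray,
                  anchors: np.ndarray | None = None,
                  k_restraint: float = 0.0, context: str = "") -> np.ndarray:
        """Advance a batch of walkers; ``noise`` has shape (steps, m, d)."""
        x = np.array(x0, dtype=float)
        for step in range(noise.shape[0]):
            x = langevin_step_batch(self.potential, x, noise[step],
                                    self.time_step, self.friction,
                                    anchors, k_restraint)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"dynamics diverged at step {step + 1}"
                    + (f" ({context})" if context else "")
                )
        return x


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _arclength_resample(points: np.ndarray, n_out: int) -> np.ndarray:
    """Points at equal arclength along the piecewise-linear curve."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise ValueError("degenerate path: total arclength is zero")
    s = np.concatenate([[0.0], np.cumsum(seg)]) / total
    targets = np.linspace(0.0, 1.0, n_out)
    out = np.empty((n_out, points.shape[1]))
    for d in range(points.shape[1]):
        out[:, d] = np.interp(targets, s, points[:, d])
    return out


def initialize_string(start, end, n_images: int = 18, mode: str = "linear",
                      path: ToyTrajectory | None = None,
                      cvset: CollectiveVariableSet | None = None
                      ) -> StringPath:
    """Initial string between two endpoint states.

    ``linear`` interpolates in CV space; ``from_path`` places interior
    images at equal arclength along the CV trace of a supplied trajectory
    (e.g. a steered toy trajectory standing in for a steered-MD transition
    path). Endpoints are exactly ``start`` and ``end`` in either mode.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.array_equal(start, end):
        raise ValueError("start and end images must differ")
    if mode == "linear":
        t = np.linspace(0.0, 1.0, n_images)[:, None]
        images = (1.0 - t) * start + t * end
    elif mode == "from_path":
        if path is None:
            raise ValueError("from_path mode requires a trajectory")
        trace = (cvset.evaluate_batch(path.coords) if cvset is not None
                 else np.asarray(path.coords, dtype=float))
        images = _arclength_resample(trace, n_images)
        images[0] = start
        images[-1] = end
    else:
        raise ValueError(f"unknown initialization mode {mode!r}")
    images[0] = start
    images[-1] = end
    return StringPath(images=images)


def reparameterize(points: np.ndarray,
                   endpoints_fixed: tuple = (True, True)) -> np.ndarray:
    """Equal-arclength redistribution along the piecewise-linear string.

    Endpoints are preserved bit-identically when fixed; the point count is
    unchanged. Coincident consecutive points making the arclength zero are
    an error.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points to reparameterize")
    out = _arclength_resample(points, points.shape[0])
    if endpoints_fixed[0]:
        out[0] = points[0]
    if endpoints_fixed[1]:
        out[-1] = points[-1]
    return out


def _swarm_noise(seed: int, iteration: int, image: int, stream: int,
                 shape: tuple, sigma: float) -> np.ndarray:
    """Noise block from the (seed, iteration, image, stream) RNG stream."""
    ss = np.random.SeedSequence((seed, iteration, image, stream))
    return sigma * np.random.default_rng(ss).standard_normal(shape)


def string_iteration(string: StringPath, engine: OverdampedLangevinEngine,
                     cvset: CollectiveVariableSet, config: SwarmConfig,
                     iteration: int = 0):
    """One restrained-equilibration / swarm / drift / reparameterize cycle.

    Every image (including fixed endpoints) is equilibrated under a
    harmonic CV restraint and launches its swarm — endpoint swarms sample
    the end basins for the downstream Markov-state model — but only
    non-fixed images move: proposed image = equilibrated CV point + mean
    swarm drift, followed by equal-arclength reparameterization that leaves
    fixed endpoints bit-identical.
    """
    d = string.dimension
    n_img = string.n_images
    sigma = engine.noise_sigma
    try:
        anchors = np.stack([cvset.invert(img) for img in string.images])
    except ValueError as exc:
        raise ValueError(f"string iteration {iteration}: {exc}") from exc

    # Restrained equilibration (each image its own RNG stream, batched).
    eq_noise = np.stack([
        _swarm_noise(config.seed, iteration, i, 0,
                     (config.equil_length, d), sigma)
        for i in range(n_img)
    ], axis=1)                                   # (steps, n_img, d)
    try:
        x_eq = engine.propagate(anchors, eq_noise, anchors=anchors,
                                k_restraint=config.restraint_constant,
                                context=f"equilibration, iteration {iteration}")
    except FloatingPointError as exc:
        raise FloatingPointError(
            f"iteration {iteration}: {exc}") from exc
    cv_eq = cvset.evaluate_batch(x_eq)

    # Swarms: n_img * n_swarms walkers, one RNG stream per (image, swarm).
    starts = np.repeat(x_eq, config.n_swarms, axis=0)
    swarm_noise = np.stack([
        _swarm_noise(config.seed, iteration, i, 1 + s,
                     (config.swarm_length, d), sigma)
        for i in range(n_img) for s in range(config.n_swarms)
    ], axis=1)
    try:
        ends = engine.propagate(starts, swarm_noise,
                                context=f"swarms, iteration {iteration}")
    except FloatingPointError as exc:
        raise FloatingPointError(f"iteration {iteration}: {exc}") from exc

    cv_starts = cvset.evaluate_batch(starts).reshape(n_img, config.n_swarms, d)
    cv_ends = cvset.evaluate_batch(ends).reshape(n_img, config.n_swarms, d)
    drift = (cv_ends - cv_starts).mean(axis=1)

    proposed = cv_eq + drift
    if string.endpoints_fixed[0]:
        proposed[0] = string.images[0]
    if string.endpoints_fixed[1]:
        proposed[-1] = string.images[-1]
    new_images = reparameterize(proposed, string.endpoints_fixed)
    new_string = StringPath(images=new_images,
                            endpoints_fixed=string.endpoints_fixed)
    record = IterationRecord(iteration=iteration,
                             string_before=string.images.copy(),
                             string_after=new_images.copy(),
                             equilibrated=cv_eq,
                             swarm_starts=cv_starts, swarm_ends=cv_ends)
    return new_string, record


def convergence_profile(history: list, block: int) -> ConvergenceProfile:
    """Displacements between consecutive block-averaged strings.

    Strings are averaged image-wise over blocks of ``block`` iterations; the
    profile reports, for each consecutive block pair, the mean Euclidean
    displacement per image. Length is floor(n_iterations / block) - 1.
    """
    n = len(history)
    if block < 1:
        raise ValueError("block must be >= 1")
    if block > n // 2:
        raise ValueError(
            f"block {block} larger than half the history length {n}"
        )
    strings = np.stack([rec.string_after for rec in history])
    n_blocks = n // block
    means = strings[: n_blocks * block].reshape(
        n_blocks, block, *strings.shape[1:]).mean(axis=1)
    disp = np.linalg.norm(np.diff(means, axis=0), axis=-1).mean(axis=-1)
    return ConvergenceProfile(block=block, values=disp)


def run_string(initial: StringPath, engine: OverdampedLangevinEngine,
               cvset: CollectiveVariableSet, config: SwarmConfig,
               max_iterations: int = 200, conv_tolerance: float = 1.0e-3,
               block: int = 20):
    """Iterate the string to convergence or ``max_iterations``.

    Stops once the latest inter-block displacement of the convergence
    profile drops below ``conv_tolerance``. Returns ``(history, final)``
    with the full per-iteration records needed by the free-energy stage.
    """
    if max_iterations < 2 * block:
        raise ValueError(
            f"max_iterations ({max_iterations}) must be at least twice the "
            f"block size ({block})"
        )
    history: list = []
    string = initial
    for it in range(max_iterations):
        string, record = string_iteration(string, engine, cvset, config,
                                          iteration=it)
        history.append(record)
        if len(history) >= 2 * block and len(history) % block == 0:
            profile = convergence_profile(history, block)
            if profile.values[-1] < conv_tolerance:
                logger.info("string converged after %d iterations "
                            "(block displacement %.3e)", it + 1,
                            profile.values[-1])
                break
    return history, string
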