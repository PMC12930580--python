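"""End-to-end design pipeline, configuration, file I/O and assay arithmetic.

The pipeline mirrors the four-step rational-design loop for constitutively
active receptor mutants on a fully synthetic system:

1. **contacts** — compare active/inactive structure ensembles and extract
   inactive-exclusive contacts and mutable positions;
2. **ddg** — two-state substitution scanning at those positions with the
   stability scorer, selecting the most active-stabilizing mutants;
3. **string + fel** — for the wild type and each selected mutant, refine a
   transition string on a toy two-basin landscape whose tilt is coupled to
   the mutant's computed ΔΔG, then estimate the Markov-state-model
   free-energy surface and the equilibrium active-basin population;
4. **network** — dynamic-network analysis (optimal paths, betweenness,
   communities) on a correlated residue trajectory.

The final report ranks mutants by their active-population shift against the
wild-type baseline. Every stage is a deterministic function of the run
configuration and global seed, and all artifacts are plain text.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from pydantic import BaseModel, ConfigDict

from . import allonet, ddgscan, felmsm, statecontacts, stringpath, toyworld
from .statecontacts import ACTIVE, INACTIVE

logger = logging.getLogger(__name__)


def configure_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureStage(_Stage):
    """Synthetic-system parameters: the study conditions of the toy world."""

    sequence_length: int = 14
    n_exclusive: int = 4          # planted inactive-only contacts
    n_shared: int = 3
    n_active_only: int = 2
    members_per_state: int = 4
    coordinate_noise: float = 0.1
    replicate_sigma: float = 0.05
    planted_ddg: float = -6.0     # active-state stabilization of the planted CAM
    network_residues: int = 16
    network_frames: int = 400
    contact_prob_within: float = 0.7
    contact_prob_between: float = 0.15
    correlation_within: float = 0.9
    correlation_between: float = 0.05


class ContactsStage(_Stage):
    cutoff: float = statecontacts.CONTACT_CUTOFF
    presence_min: float = 0.5
    absence_max: float = 0.0
    exclusions: dict = {}         # residue id -> reason


class DdgStage(_Stage):
    n_replicates: int = 3
    delta_similar: float = 0.5


class StringStage(_Stage):
    n_images: int = 5
    n_swarms: int = 32
    swarm_length: int = 10
    equil_length: int = 30
    restraint_constant: float = 50.0
    time_step: float = 0.01
    friction: float = 1.0
    thermal_energy: float = 0.5
    max_iterations: int = 80
    block: int = 10
    conv_tolerance: float = 1.0e-3
    ddg_tilt_coupling: float = 0.2
    k_harmonic: float = 1.0


class FelStage(_Stage):
    last_n: int = 40
    k: int = 20
    bins: int = 32
    kT_proj: float | None = None  # default: the engine's thermal energy


class NetworkStage(_Stage):
    cutoff: float = statecontacts.CONTACT_CUTOFF
    occupancy_min: float = allonet.DEFAULT_OCCUPANCY_MIN
    epsilon: float = 1.0e-6
    source: int | None = None     # default: first node of the largest component
    sinks: list | None = None     # default: last three nodes of that component


class RunConfig(_Stage):
    """Fully validated pipeline configuration; unknown keys are rejected."""

    seed: int = 1
    output_dir: str = "camdesign_run"
    fixtures: FixtureStage = FixtureStage()
    contacts: ContactsStage = ContactsStage()
    ddg: DdgStage = DdgStage()
    string: StringStage = StringStage()
    fel: FelStage = FelStage()
    network: NetworkStage = NetworkStage()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def _derived_seed(seed: int, tag: str) -> int:
    digest = hashlib.sha256(f"{seed}|{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_string_json(string: stringpath.StringPath, path) -> None:
    payload = {
        "images": [[float(v) for v in img] for img in string.images],
        "endpoints_fixed": list(string.endpoints_fixed),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def read_string_json(path) -> stringpath.StringPath:
    with open(path) as fh:
        payload = json.load(fh)
    return stringpath.StringPath(
        images=np.array(payload["images"], dtype=float),
        endpoints_fixed=tuple(payload["endpoints_fixed"]),
    )


def write_ensemble_pdb(ensemble: statecontacts.StructureEnsemble,
                       path) -> None:
    """Structure ensemble as a multi-model PDB; residue numbering preserved."""
    builder = StructureBuilder()
    builder.init_structure("ensemble")
    for model_i, member in enumerate(ensemble.members):
        builder.init_model(model_i)
        builder.init_chain("A")
        builder.init_seg("    ")
        for resid in sorted(member.residues, key=repr):
            builder.init_residue("TOY", " ", int(resid), " ")
            for ai, xyz in enumerate(member.residues[resid]):
                name = f"C{ai + 1}"
                builder.init_atom(name, np.asarray(xyz, dtype=float), 0.0,
                                  1.0, " ", name, element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_ensemble_pdb(path, state: str, identifier_prefix: str = "member"
                      ) -> statecontacts.StructureEnsemble:
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    members = []
    for model in structure:
        residues = {}
        for chain in model:
            for residue in chain:
                coords = np.array([atom.coord for atom in residue],
                                  dtype=float)
                residues[residue.id[1]] = coords
        members.append(statecontacts.Structure(
            identifier=f"{identifier_prefix}_{model.id}", state=state,
            residues=residues))
    return statecontacts.StructureEnsemble(members=members)


def write_xyz(coords: np.ndarray, path, names=None,
              comment: str = "frame") -> None:
    """Full-precision XYZ trajectory writer; coords (n_frames, n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    names = names if names is not None else ["C"] * n_atoms
    with open(path, "w") as fh:
        for f, frame in enumerate(coords):
            fh.write(f"{n_atoms}\n{comment} {f}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path) -> np.ndarray:
    """XYZ trajectory reader; errors name the offending frame."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, frame_i = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"malformed atom count at frame {frame_i} "
                f"(line {pos + 1})") from exc
        body = lines[pos + 2: pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ValueError(
                f"truncated XYZ frame {frame_i}: expected {n_atoms} atom "
                f"records, found {len(body)}"
            )
        try:
            frames.append([[float(v) for v in ln.split()[1:4]]
                           for ln in body])
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"malformed coordinate record in frame {frame_i}") from exc
        pos += 2 + n_atoms
        frame_i += 1
    if not frames:
        raise ValueError("XYZ file contains no frames")
    return np.asarray(frames, dtype=float)


def write_residue_trajectory(traj: allonet.ResidueTrajectory, xyz_path,
                             meta_path) -> None:
    write_xyz(traj.coords, xyz_path)
    meta = {
        "atom_resids": [int(r) for r in traj.atom_resids],
        "marker_atoms": {str(r): int(i) for r, i in traj.marker_atoms.items()},
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)


def read_residue_trajectory(xyz_path, meta_path) -> allonet.ResidueTrajectory:
    coords = read_xyz(xyz_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    return allonet.ResidueTrajectory(
        coords=coords,
        atom_resids=np.array(meta["atom_resids"], dtype=int),
        marker_atoms={int(r): i for r, i in meta["marker_atoms"].items()},
    )


def write_contact_table(table: statecontacts.ContactTable, path) -> None:
    rows = [{"res_a": a, "res_b": b, "freq_active": fa, "freq_inactive": fi}
            for (a, b), (fa, fi) in sorted(table.frequencies.items(),
                                           key=lambda kv: repr(kv[0]))]
    pd.DataFrame(rows, columns=["res_a", "res_b", "freq_active",
                                "freq_inactive"]).to_csv(
        path, sep="\t", index=False)


def write_network_graphml(network: allonet.DynamicNetwork, path,
                          betweenness: dict | None = None,
                          partition: allonet.CommunityPartition | None = None
                          ) -> None:
    graph = network.graph.copy()
    if betweenness:
        for edge, value in betweenness.items():
            graph.edges[edge]["betweenness"] = float(value)
    if partition:
        for node, cid in partition.assignment.items():
            graph.nodes[node]["community"] = int(cid)
    nx.write_graphml(graph, str(path))


def write_fel(surface: felmsm.FESurface, grid_path, meta_path) -> None:
    np.savetxt(grid_path, surface.free_energy, fmt="%.17g", delimiter="\t")
    meta = {
        "cv_labels": list(surface.cv_labels),
        "x_edges": [float(v) for v in surface.x_edges],
        "y_edges": [float(v) for v in surface.y_edges],
        "kT": surface.kT,
        "metadata": surface.metadata,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Assay-normalization arithmetic
# ---------------------------------------------------------------------------

@dataclass
class AssayPlate:
    """One plate: (construct, luminescence, fluorescence) per well, plus
    untransfected background wells for both channels."""

    wells: list                   # [(construct, lum, fluo), ...]
    background: list              # [(lum, fluo), ...] untransfected wells

    def __post_init__(self):
        if not self.background:
            raise ValueError("need at least one background well per channel")
        for label, lum, fluo in self.wells:
            if lum < 0 or fluo < 0:
                raise ValueError(
                    f"negative counts in well of construct {label!r}")
        for lum, fluo in self.background:
            if lum < 0 or fluo < 0:
                raise ValueError("negative counts in background well")


def normalize_assay(plate: AssayPlate, reference_label: str = "WT"
                    ) -> pd.DataFrame:
    """Per-construct activity and expression as percent of the reference.

    Luminescence and fluorescence are background-subtracted against the
    untransfected wells; activity is the luminescence/fluorescence ratio
    (averaged over replicate wells) as a percentage of the reference
    construct's ratio on the same plate, and expression is the
    background-subtracted fluorescence as a percentage of the reference's.
    """
    labels = [w[0] for w in plate.wells]
    if reference_label not in labels:
        raise ValueError(f"reference construct {reference_label!r} absent "
                         f"from plate (has {sorted(set(labels))})")
    lum_bg = float(np.mean([b[0] for b in plate.background]))
    fluo_bg = float(np.mean([b[1] for b in plate.background]))

    ref_lum = np.mean([w[1] for w in plate.wells
                       if w[0] == reference_label])
    ref_fluo = np.mean([w[2] for w in plate.wells
                        if w[0] == reference_label])
    if lum_bg >= ref_lum or fluo_bg >= ref_fluo:
        raise ValueError(
            "background means must lie strictly below the reference "
            f"construct's signal means (lum {lum_bg} vs {ref_lum}, "
            f"fluo {fluo_bg} vs {ref_fluo})"
        )
    bad = [i for i, (_, _, fluo) in enumerate(plate.wells)
           if fluo - fluo_bg <= 0]
    if bad:
        raise ValueError(
            f"non-positive background-subtracted fluorescence in wells {bad}"
        )
    per_construct = {}
    for label in dict.fromkeys(labels):
        ws = [w for w in plate.wells if w[0] == label]
        ratios = [(lum - lum_bg) / (fluo - fluo_bg) for _, lum, fluo in ws]
        fluos = [fluo - fluo_bg for _, _, fluo in ws]
        per_construct[label] = (float(np.mean(ratios)), float(np.mean(fluos)),
                                len(ws))
    ref_ratio, ref_expr, _ = per_construct[reference_label]
    rows = []
    for label, (ratio, expr, n) in per_construct.items():
        rows.append({"construct": label,
                     "activity_pct": 100.0 * ratio / ref_ratio,
                     "expression_pct": 100.0 * expr / ref_expr,
                     "n_wells": n})
    return pd.DataFrame(rows).set_index("construct")


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

_TOY_AA_POOL = "ACDEFHIKLMNQRSTVWY"   # standard set minus G and P


@dataclass
class FixtureBundle:
    """In-memory synthetic system plus its planted ground truth."""

    wt_sequence: str
    active_ensemble: statecontacts.StructureEnsemble
    inactive_ensemble: statecontacts.StructureEnsemble
    exclusive_truth: statecontacts.ExclusiveContactSet
    stability_table: toyworld.ToyStabilityTable
    planted_stabilizer: tuple      # (position, mutant aa, planted ddg)
    network_trajectory: allonet.ResidueTrajectory
    network_edges: set
    network_partition: dict
    seed: int


def _random_disjoint_pairs(n_residues: int, counts, rng) -> list:
    pools = [(i, j) for i in range(n_residues)
             for j in range(i + 2, n_residues)]
    rng.shuffle(pools)
    used: set = set()
    groups = []
    idx = 0
    for count in counts:
        group = set()
        while len(group) < count and idx < len(pools):
            pair = pools[idx]
            idx += 1
            if pair not in used:
                group.add(pair)
                used.add(pair)
        if len(group) < count:
            raise ValueError("not enough residue pairs for the requested "
                             "planted contact counts")
        groups.append(frozenset(group))
    return groups


def build_fixtures(cfg: FixtureStage, seed: int) -> FixtureBundle:
    """Deterministically generate the synthetic system from its spec."""
    rng = np.random.default_rng(_derived_seed(seed, "fixtures"))
    n = cfg.sequence_length
    wt_sequence = "".join(rng.choice(list(_TOY_AA_POOL), size=n))

    inactive_only, active_only, shared = _random_disjoint_pairs(
        n, (cfg.n_exclusive, cfg.n_active_only, cfg.n_shared), rng)
    ens_spec = toyworld.TwoStateEnsembleSpec(
        n_residues=n,
        contacts_inactive_only=inactive_only,
        contacts_active_only=active_only,
        contacts_shared=shared,
        members_per_state=cfg.members_per_state,
        coordinate_noise=cfg.coordinate_noise,
        seed=_derived_seed(seed, "ensembles"),
    )
    active_ens, inactive_ens, truth = toyworld.make_two_state_ensembles(
        ens_spec)

    mutable = truth.residues()
    pos = int(mutable[int(rng.integers(len(mutable)))])
    choices = ddgscan.enumerate_substitutions(wt_sequence[pos])
    aa = choices[int(rng.integers(len(choices)))]
    table = toyworld.ToyStabilityTable(
        energies={(pos, aa, ACTIVE): float(cfg.planted_ddg)},
        replicate_sigma=cfg.replicate_sigma,
        seed=_derived_seed(seed, "stability"),
    )

    n_net = cfg.network_residues
    communities = tuple(0 if i < n_net // 2 else 1 for i in range(n_net))
    net_spec = toyworld.PlantedNetworkSpec(
        n_residues=n_net,
        community_assignment=communities,
        contact_prob_within=cfg.contact_prob_within,
        contact_prob_between=cfg.contact_prob_between,
        correlation_within=cfg.correlation_within,
        correlation_between=cfg.correlation_between,
        n_frames=cfg.network_frames,
        seed=_derived_seed(seed, "network"),
    )
    traj, edges, partition = toyworld.make_correlated_trajectory(net_spec)
    return FixtureBundle(
        wt_sequence=wt_sequence, active_ensemble=active_ens,
        inactive_ensemble=inactive_ens, exclusive_truth=truth,
        stability_table=table, planted_stabilizer=(pos, aa, cfg.planted_ddg),
        network_trajectory=traj, network_edges=edges,
        network_partition=partition, seed=seed,
    )


def make_fixtures(seed: int, output_dir,
                  cfg: FixtureStage | None = None) -> FixtureBundle:
    """Write the full synthetic bundle and its ground-truth manifest."""
    cfg = cfg or FixtureStage()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = build_fixtures(cfg, seed)
    write_ensemble_pdb(bundle.active_ensemble, out / "active.pdb")
    write_ensemble_pdb(bundle.inactive_ensemble, out / "inactive.pdb")
    rows = [{"position": p, "amino_acid": a, "state": s, "energy": e}
            for (p, a, s), e in sorted(bundle.stability_table.energies.items())]
    pd.DataFrame(rows, columns=["position", "amino_acid", "state", "energy"]
                 ).to_csv(out / "stability_table.tsv", sep="\t", index=False)
    write_residue_trajectory(bundle.network_trajectory,
                             out / "network_traj.xyz",
                             out / "network_traj.meta.json")
    truth = {
        "seed": seed,
        "spec": cfg.model_dump(),
        "wt_sequence": bundle.wt_sequence,
        "exclusive_contacts": [list(p) for p, _, _ in
                               bundle.exclusive_truth.pairs],
        "planted_stabilizer": {
            "position": bundle.planted_stabilizer[0],
            "mutant": bundle.planted_stabilizer[1],
            "ddg": bundle.planted_stabilizer[2],
        },
        "network_edges": sorted([list(e) for e in bundle.network_edges]),
        "network_partition": {str(k): v for k, v in
                              sorted(bundle.network_partition.items())},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
    return bundle


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineManifest:
    """Per-stage status, artifact paths and seeds, plus the ranked report."""

    output_dir: str
    seed: int
    stages: dict = field(default_factory=dict)
    ranked_candidates: list = field(default_factory=list)

    def record(self, stage: str, status: str, artifacts: list,
               seed: int, wall_time: float) -> None:
        self.stages[stage] = {
            "status": status,
            "artifacts": [str(a) for a in artifacts],
            "seed": seed,
            "wall_time_s": wall_time,
        }

    def write(self, path) -> None:
        payload = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "stages": self.stages,
            "ranked_candidates": self.ranked_candidates,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)


class StageError(RuntimeError):
    """A pipeline stage failed; completed stages remain reusable."""


def _string_fel_for_mutant(label: str, ddg: float, cfg: RunConfig,
                           out: Path) -> dict:
    """String refinement + MSM free-energy surface on the mutant's
    landscape; returns the active-basin population summary."""
    scfg, fcfg = cfg.string, cfg.fel
    tilt = scfg.ddg_tilt_coupling * ddg
    potential = toyworld.DoubleWell(tilt=tilt, n_harmonic=1,
                                    k_harmonic=scfg.k_harmonic)
    engine = stringpath.OverdampedLangevinEngine(
        potential, time_step=scfg.time_step, friction=scfg.friction,
        thermal_energy=scfg.thermal_energy)
    cvset = stringpath.raw_cv_set(2, labels=["cv_activation", "cv_orth"])
    initial = stringpath.initialize_string((-1.0, 0.0), (1.0, 0.0),
                                           n_images=scfg.n_images)
    swarm_cfg = stringpath.SwarmConfig(
        n_swarms=scfg.n_swarms, swarm_length=scfg.swarm_length,
        equil_length=scfg.equil_length,
        restraint_constant=scfg.restraint_constant,
        seed=_derived_seed(cfg.seed, f"string|{label}"))
    history, final = stringpath.run_string(
        initial, engine, cvset, swarm_cfg,
        max_iterations=scfg.max_iterations,
        conv_tolerance=scfg.conv_tolerance, block=scfg.block)

    last_n = min(fcfg.last_n, len(history))
    data = felmsm.select_converged(history, last_n)
    points = data.all_points()
    disc = felmsm.discretize(points, k=min(fcfg.k, len(points)),
                             seed=_derived_seed(cfg.seed, f"kmeans|{label}"),
                             feature_labels=["cv_activation", "cv_orth"])
    model = felmsm.estimate_msm(data, disc, reversible=True)
    samples = pd.DataFrame(points, columns=["cv_activation", "cv_orth"])
    kT = fcfg.kT_proj if fcfg.kT_proj is not None else scfg.thermal_energy
    surface = felmsm.weighted_fel(samples, model, disc,
                                  ("cv_activation", "cv_orth"),
                                  bins=fcfg.bins, kT_proj=kT,
                                  on_unassigned="drop")
    states = model.model_state(disc.assign(points))
    weights = felmsm.msm_sample_weights(states, model)
    valid = states >= 0
    active = valid & (points[:, 0] > 0.0)
    population = float(weights[active].sum() / weights[valid].sum())

    out.mkdir(parents=True, exist_ok=True)
    write_string_json(final, out / "string.json")
    profile = stringpath.convergence_profile(history, cfg.string.block)
    pd.DataFrame({"block_pair": np.arange(len(profile.values)),
                  "displacement": profile.values}).to_csv(
        out / "convergence.tsv", sep="\t", index=False)
    write_fel(surface, out / "fel.tsv", out / "fel.meta.json")
    summary = {"label": label, "ddg": ddg, "tilt": tilt,
               "active_population": population,
               "n_iterations": len(history), "last_n": last_n,
               "n_msm_states": model.n_states}
    with open(out / "population.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    return summary


def run_pipeline(config: RunConfig) -> PipelineManifest:
    """Execute the four-stage design loop on the synthetic system.

    Returns the manifest; a stage failure raises :class:`StageError` after
    writing a manifest that marks completed stages reusable.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(config.resolved_yaml())
    manifest = PipelineManifest(output_dir=str(out), seed=config.seed)
    manifest_path = out / "manifest.json"

    def run_stage(name, fn):
        logger.info("stage %s: starting (seed %d)", name, config.seed)
        t0 = time.perf_counter()
        try:
            artifacts, payload = fn()
        except Exception as exc:
            manifest.record(name, "failed", [], config.seed,
                            time.perf_counter() - t0)
            manifest.write(manifest_path)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, "completed", artifacts, config.seed,
                        time.perf_counter() - t0)
        return payload

    # Stage 0: synthetic inputs (stands in for collecting structures).
    def stage_fixtures():
        bundle = make_fixtures(config.seed, out / "fixtures", config.fixtures)
        arts = [out / "fixtures" / n for n in
                ("active.pdb", "inactive.pdb", "stability_table.tsv",
                 "network_traj.xyz", "network_traj.meta.json",
                 "ground_truth.json")]
        return arts, bundle

    bundle = run_stage("fixtures", stage_fixtures)

    # Stage 1: structural comparison -> mutable positions.
    def stage_contacts():
        ccfg = config.contacts
        ensemble = statecontacts.StructureEnsemble(
            members=bundle.active_ensemble.members
            + bundle.inactive_ensemble.members)
        table = statecontacts.contact_frequencies(ensemble,
                                                  cutoff=ccfg.cutoff)
        exclusive = statecontacts.exclusive_contacts(
            table, target_state=INACTIVE, presence_min=ccfg.presence_min,
            absence_max=ccfg.absence_max)
        selection = statecontacts.select_positions(
            exclusive, {int(k): v for k, v in ccfg.exclusions.items()})
        d = out / "contacts"
        d.mkdir(exist_ok=True)
        write_contact_table(table, d / "contact_table.tsv")
        pd.DataFrame(
            [{"res_a": a, "res_b": b, "freq_active": fa, "freq_inactive": fi}
             for (a, b), fa, fi in exclusive.pairs],
            columns=["res_a", "res_b", "freq_active", "freq_inactive"]
        ).to_csv(d / "exclusive_contacts.tsv", sep="\t", index=False)
        with open(d / "positions.json", "w") as fh:
            json.dump({"candidates": selection.candidates,
                       "excluded": {str(k): v for k, v in
                                    selection.excluded.items()},
                       "warning": selection.warning},
                      fh, sort_keys=True, indent=1)
        return ([d / "contact_table.tsv", d / "exclusive_contacts.tsv",
                 d / "positions.json"], selection)

    selection = run_stage("contacts", stage_contacts)

    # Stage 2: two-state residue scanning.
    def stage_ddg():
        if not selection.candidates:
            raise ValueError("no mutable positions survived the contact "
                             "stage")
        candidates = ddgscan.scan_positions(
            [int(p) for p in selection.candidates], bundle.wt_sequence,
            bundle.stability_table, n_replicates=config.ddg.n_replicates)
        report = ddgscan.classify_and_select(
            candidates, delta_similar=config.ddg.delta_similar)
        d = out / "ddg"
        d.mkdir(exist_ok=True)
        report.to_frame().to_csv(d / "scan_report.tsv", sep="\t", index=False)
        selections = {str(pos): [c.name for c in sel]
                      for pos, sel in sorted(report.selections.items())}
        with open(d / "selections.json", "w") as fh:
            json.dump({"delta_similar": report.delta_similar,
                       "selections": selections}, fh, sort_keys=True,
                      indent=1)
        return [d / "scan_report.tsv", d / "selections.json"], report

    report = run_stage("ddg", stage_ddg)

    # Stage 3: enhanced sampling + free-energy landscape per mutant.
    def stage_string_fel():
        selected = [c for sel in report.selections.values() for c in sel]
        selected.sort(key=lambda c: (c.position, c.mutant_aa))
        summaries = [_string_fel_for_mutant(
            "WT", 0.0, config, out / "string_fel" / "WT")]
        for cand in selected:
            summaries.append(_string_fel_for_mutant(
                cand.name, cand.ddg, config,
                out / "string_fel" / cand.name))
        arts = []
        for s in summaries:
            d = out / "string_fel" / s["label"]
            arts += [d / n for n in ("string.json", "convergence.tsv",
                                     "fel.tsv", "fel.meta.json",
                                     "population.json")]
        return arts, summaries

    summaries = run_stage("string_fel", stage_string_fel)

    # Stage 4: dynamic-network allostery on the correlated trajectory.
    def stage_network():
        ncfg = config.network
        traj = bundle.network_trajectory
        network = allonet.build_network(traj, cutoff=ncfg.cutoff,
                                        occupancy_min=ncfg.occupancy_min)
        corr = allonet.displacement_correlation(traj)
        network = allonet.weight_edges(network, corr, epsilon=ncfg.epsilon)
        comp = max(nx.connected_components(network.graph),
                   key=lambda c: (len(c), -min(c)))
        comp = sorted(comp)
        source = ncfg.source if ncfg.source is not None else comp[0]
        sinks = ncfg.sinks if ncfg.sinks is not None else comp[-3:]
        paths = allonet.optimal_paths(network, source, sinks)
        betw = allonet.edge_betweenness(network)
        partition = allonet.detect_communities(network)
        d = out / "network"
        d.mkdir(exist_ok=True)
        write_network_graphml(network, d / "network.graphml",
                              betweenness=betw, partition=partition)
        pd.DataFrame(
            [{"source": paths.source, "sink": sink,
              "length": length, "path": "-".join(map(str, nodes))}
             for sink, (nodes, length) in sorted(paths.paths.items())]
        ).to_csv(d / "paths.tsv", sep="\t", index=False)
        with open(d / "communities.json", "w") as fh:
            json.dump({"modularity": partition.modularity,
                       "assignment": {str(k): v for k, v in
                                      sorted(partition.assignment.items())}},
                      fh, sort_keys=True, indent=1)
        return ([d / "network.graphml", d / "paths.tsv",
                 d / "communities.json"],
                {"n_communities": len(partition.communities()),
                 "modularity": partition.modularity,
                 "paths": {str(s): l for s, (_, l) in paths.paths.items()}})

    net_summary = run_stage("network", stage_network)

    # Final ranked report: population shift vs the wild-type baseline.
    baseline = next(s for s in summaries if s["label"] == "WT")
    ranked = []
    for s in summaries:
        if s["label"] == "WT":
            continue
        ranked.append({
            "mutant": s["label"], "ddg": s["ddg"],
            "active_population": s["active_population"],
            "population_shift": s["active_population"]
            - baseline["active_population"],
        })
    ranked.sort(key=lambda r: (-r["population_shift"], r["ddg"], r["mutant"]))
    for rank, row in enumerate(ranked, start=1):
        row["rank"] = rank
    d = out / "report"
    d.mkdir(exist_ok=True)
    pd.DataFrame(ranked, columns=["rank", "mutant", "ddg",
                                  "active_population", "population_shift"]
                 ).to_csv(d / "ranked_candidates.tsv", sep="\t", index=False)
    payload = {"baseline_active_population": baseline["active_population"],
               "network": net_summary, "ranked": ranked}
    with open(d / "ranked_candidates.json", "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    manifest.ranked_candidates = ranked
    manifest.record("report", "completed",
                    [d / "ranked_candidates.tsv",
                     d / "ranked_candidates.json"], config.seed, 0.0)
    manifest.write(manifest_path)
    return manifest
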