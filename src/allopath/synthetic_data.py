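"""Synthetic trajectories with planted, recoverable statistical structure.

The energy generator emulates the statistical signatures the analysis
pipeline looks for in a steered-MD energy decomposition of an allosteric
protein, without any physics:

* a latent *pathway factor* F (one standard-normal value per snapshot)
  that drives the electrostatic energy of the designated source, sink
  and pathway residues.  A residue with loading ``l`` has electrostatic
  series ``l*F + sqrt(1-l^2)*noise`` before scaling, so the expected
  correlation between two planted residues is exactly the product of
  their loadings, and ``noise_sigma`` sets the kJ/mol amplitude without
  touching any correlation;
* a per-residue *compensation* coupling between electrostatic and
  dihedral energy: every residue's dihedral series is built to correlate
  with its own electrostatic series at ``compensation_rho`` (negative by
  default), reproducing the electrostatic/dihedral energy-transformation
  signature at both the residue and the pooled-matrix level;
* optional *end-state offsets* per residue and term, ramped in linearly
  over the 90-98% stretch of the trajectory and held thereafter, so
  windowed start-vs-end differences recover them while single-frame
  differences stay noise-dominated.

All other residues and terms are independent Gaussian noise.  Every
stream is derived deterministically from the seed and the residue id, so
the same config reproduces bit-identical output and adding residues
never perturbs existing ones.

The coordinate generator builds a backbone-only helical toy chain whose
designated loop residues are displaced in the final frames, with a
random rigid transform applied to every frame so that superposition is
actually exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

import yaml

from .energy_io import COMPONENT_TERMS, EnergyTrajectory
from .errors import ValidationError
from .structure_metrics import CoordinateTrajectory

#: Stream key for the shared latent factor (outside the residue-id range).
_FACTOR_STREAM = 1 << 20

#: Relative amplitude of each component; van der Waals noise is kept far
#: below the electrostatic amplitude so the non-bond composite is
#: electrostatics-dominated, as in force-field decompositions of charged
#: binding sites.
DEFAULT_TERM_SCALES: dict[str, float] = {
    "bond": 1.0,
    "angle": 1.0,
    "dihedral": 1.0,
    "electrostatic": 1.0,
    "vdw": 0.05,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic energy/coordinate generators.

    Defaults emulate the AKIII steered-MD setting: a 449-residue chain
    sampled over 2000 snapshots, three lysine-site sources, four
    aspartate-site sinks, a 7-residue planted transduction backbone with
    factor loading 0.9, and an electrostatic-dihedral compensation
    coupling of -0.5.
    """

    n_residues: int = 449
    n_snapshots: int = 2000
    noise_sigma: float = 1.0  # kJ/mol amplitude scale
    pathway_residues: tuple[int, ...] = (106, 165, 245, 292, 296, 306, 443)
    sources: tuple[int, ...] = (338, 340, 346)
    sinks: tuple[int, ...] = (39, 119, 202, 201)
    loading: float = 0.9  # factor loading of planted residues, in (0, 1]
    compensation_rho: float = -0.5  # target electrostatic-dihedral correlation
    end_state_offsets: dict[int, dict[str, float]] = field(default_factory=dict)
    term_scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TERM_SCALES))
    seed: int = 0
    # Coordinate-generator conditions
    coord_frames: int = 50
    loop_residues: tuple[int, ...] | None = None  # None: 10 residues from n/4
    loop_displacement: float = 12.0  # Angstrom, applied over the final 10% of frames
    thermal_sigma: float = 0.02  # Angstrom, per-coordinate positional noise
    rigid_jitter: bool = True

    def __post_init__(self) -> None:
        planted = set(self.pathway_residues) | set(self.sources) | set(self.sinks)
        if self.n_snapshots < 2:
            raise ValidationError("n_snapshots must be >= 2")
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")
        out_of_range = sorted(r for r in planted if not 1 <= r <= self.n_residues)
        if out_of_range:
            raise ValidationError(
                f"planted residues outside 1..{self.n_residues}: {out_of_range}"
            )
        if not 0 < self.loading <= 1:
            raise ValidationError("loading must be in (0, 1]")
        if not -1 <= self.compensation_rho <= 0:
            raise ValidationError("compensation_rho must be in [-1, 0]")
        if set(self.sources) & set(self.sinks):
            raise ValidationError("sources and sinks must be disjoint")
        bad_terms = set(self.term_scales) - set(COMPONENT_TERMS)
        if bad_terms:
            raise ValidationError(f"unknown terms in term_scales: {sorted(bad_terms)}")
        for rid, terms in self.end_state_offsets.items():
            if not 1 <= int(rid) <= self.n_residues:
                raise ValidationError(f"offset residue {rid} out of range")
            unknown = set(terms) - set(COMPONENT_TERMS)
            if unknown:
                raise ValidationError(f"unknown offset terms for residue {rid}: {sorted(unknown)}")
        if self.loop_residues is not None:
            bad = sorted(r for r in self.loop_residues if not 1 <= r <= self.n_residues)
            if bad:
                raise ValidationError(f"loop residues outside 1..{self.n_residues}: {bad}")

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(1, self.n_residues + 1)

    @property
    def effective_loop_residues(self) -> tuple[int, ...]:
        """Loop residues for the coordinate generator.

        When unset, a contiguous segment starting a quarter of the way
        along the chain, sized at roughly 2% of the residues (2-10).  A
        small loop fraction keeps the displaced atoms from dragging the
        global backbone superposition, as in a full-length protein where
        a mobile loop is a few percent of the chain.
        """
        if self.loop_residues is not None:
            return tuple(sorted(self.loop_residues))
        start = max(2, self.n_residues // 4)
        length = min(10, max(2, self.n_residues // 45), self.n_residues - start)
        return tuple(range(start, start + max(length, 1)))

    @property
    def planted_residues(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.pathway_residues) | set(self.sources) | set(self.sinks)))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pathway_residues", "sources", "sinks", "loop_residues"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if "end_state_offsets" in raw:
            raw["end_state_offsets"] = {
                int(r): {str(t): float(v) for t, v in terms.items()}
                for r, terms in raw["end_state_offsets"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key in ("pathway_residues", "sources", "sinks", "loop_residues"):
            if raw[key] is not None:
                raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth manifest: everything needed to predict recovery.

    ``loadings`` maps each planted residue to its realised factor
    loading; the expected electrostatic correlation between two planted
    residues is the product of their loadings, and the expected C score
    of a pathway residue is loading_a * loading_x^2 * loading_b ... i.e.
    the product of the two pairwise expectations.
    """

    seed: int
    pathway_residues: tuple[int, ...]
    sources: tuple[int, ...]
    sinks: tuple[int, ...]
    loadings: dict[int, float]
    compensation_rho: float
    end_state_offsets: dict[int, dict[str, float]]
    config: dict

    def expected_correlation(self, res_a: int, res_b: int) -> float:
        """Expected electrostatic correlation between two planted residues."""
        return self.loadings[res_a] * self.loadings[res_b]

    def expected_c_score(self, source: int, x: int, sink: int) -> float:
        return self.expected_correlation(source, x) * self.expected_correlation(x, sink)

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["pathway_residues"] = list(raw["pathway_residues"])
        raw["sources"] = list(raw["sources"])
        raw["sinks"] = list(raw["sinks"])
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["pathway_residues"] = tuple(raw["pathway_residues"])
        raw["sources"] = tuple(raw["sources"])
        raw["sinks"] = tuple(raw["sinks"])
        raw["loadings"] = {int(k): float(v) for k, v in raw["loadings"].items()}
        raw["end_state_offsets"] = {
            int(r): {str(t): float(v) for t, v in terms.items()}
            for r, terms in raw["end_state_offsets"].items()
        }
        return cls(**raw)


def _offset_ramp(n_snapshots: int) -> np.ndarray:
    """End-state offset schedule: 0 until 90% of the trajectory, linear
    rise to 1 at 98%, then held at 1.

    Holding the plateau over the final 2% means a trailing window of up
    to 2% of the snapshots averages the *full* offset, so windowed
    start-vs-end differences are unbiased while single-frame differences
    remain noise-dominated.
    """
    i = np.arange(n_snapshots)
    t0 = 0.9 * (n_snapshots - 1)
    t1 = 0.98 * (n_snapshots - 1)
    return np.clip((i - t0) / max(t1 - t0, 1.0), 0.0, 1.0)


def generate_energy_trajectory(
    config: GeneratorConfig,
) -> tuple[EnergyTrajectory, SyntheticTruth]:
    """Sample an energy trajectory with the configured planted structure.

    Per residue, the five unit-variance signals are built first and then
    scaled by ``noise_sigma * term_scales[term]``:

    * electrostatic: ``l*F + sqrt(1-l^2)*eps`` for planted residues
      (loading ``l``), pure noise otherwise;
    * dihedral: ``rho*z_elec + sqrt(1-rho^2)*eps`` where ``z_elec`` is
      the residue's unit-variance electrostatic signal, so the expected
      electrostatic-dihedral correlation is ``compensation_rho`` for
      every residue;
    * bond, angle, vdw: independent noise.

    End-state offsets are then added on the saturating end ramp.
    Identical config (including seed) gives bit-identical output.
    """
    n, n_res = config.n_snapshots, config.n_residues
    rho = config.compensation_rho
    factor = np.random.default_rng([config.seed, _FACTOR_STREAM]).standard_normal(n)
    planted = set(config.planted_residues)
    loadings = {int(r): float(config.loading) for r in sorted(planted)}
    ramp = _offset_ramp(n)

    components = {term: np.empty((n_res, n)) for term in COMPONENT_TERMS}
    scale = {t: config.noise_sigma * config.term_scales.get(t, 1.0) for t in COMPONENT_TERMS}
    for i, rid in enumerate(config.residue_ids):
        rng = np.random.default_rng([config.seed, int(rid)])
        noise = {term: rng.standard_normal(n) for term in COMPONENT_TERMS}
        if int(rid) in planted:
            l = loadings[int(rid)]
            z_elec = l * factor + np.sqrt(1.0 - l * l) * noise["electrostatic"]
        else:
            z_elec = noise["electrostatic"]
        z_dih = rho * z_elec + np.sqrt(1.0 - rho * rho) * noise["dihedral"]
        components["bond"][i] = scale["bond"] * noise["bond"]
        components["angle"][i] = scale["angle"] * noise["angle"]
        components["dihedral"][i] = scale["dihedral"] * z_dih
        components["electrostatic"][i] = scale["electrostatic"] * z_elec
        components["vdw"][i] = scale["vdw"] * noise["vdw"]
        for term, offset in config.end_state_offsets.get(int(rid), {}).items():
            components[term][i] += offset * ramp

    traj = EnergyTrajectory(
        residue_ids=config.residue_ids, components=components, time_per_snapshot=1.0
    )
    truth = SyntheticTruth(
        seed=config.seed,
        pathway_residues=tuple(sorted(config.pathway_residues)),
        sources=tuple(config.sources),
        sinks=tuple(config.sinks),
        loadings=loadings,
        compensation_rho=rho,
        end_state_offsets={
            int(r): dict(t) for r, t in config.end_state_offsets.items()
        },
        config=_config_echo(config),
    )
    return traj, truth


@dataclass(frozen=True)
class CoordinateTruth:
    """Planted facts of a synthetic coordinate trajectory."""

    seed: int
    loop_residues: tuple[int, ...]
    loop_displacement: float
    displaced_frames: tuple[int, ...]


def generate_coordinate_trajectory(
    config: GeneratorConfig,
) -> tuple[CoordinateTrajectory, CoordinateTruth]:
    """Backbone-only helical toy chain with a displaced loop.

    Each residue contributes N, CA, C, O atoms placed on an ideal helix.
    The loop residues are rigidly translated by ``loop_displacement``
    Angstrom in the final 10% of frames; small positional noise
    (``thermal_sigma``) is added everywhere, and (optionally) a random
    proper rigid transform is applied to every frame so downstream
    superposition does real work.
    """
    n_res, n_frames = config.n_residues, config.coord_frames
    if n_frames < 2:
        raise ValidationError("coord_frames must be >= 2")
    rng = np.random.default_rng([config.seed, _FACTOR_STREAM + 1])

    # Ideal helix: CA radius 2.3 A, 100 deg turn and 1.5 A rise per residue.
    idx = np.arange(n_res)
    theta = np.deg2rad(100.0) * idx
    ca = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])
    offsets = {
        "N": np.array([-0.8, 0.6, -0.6]),
        "CA": np.zeros(3),
        "C": np.array([0.9, 0.4, 0.6]),
        "O": np.array([1.1, 1.3, 0.7]),
    }
    atom_names = np.array(list(offsets) * n_res, dtype=object)
    atom_rids = np.repeat(config.residue_ids, len(offsets))
    base = np.repeat(ca, len(offsets), axis=0) + np.tile(
        np.array(list(offsets.values())), (n_res, 1)
    )

    loop_residues = config.effective_loop_residues
    loop_atoms = np.isin(atom_rids, np.asarray(loop_residues, dtype=int))
    direction = np.array([1.0, 0.0, 0.0])
    first_displaced = int(np.ceil(0.9 * n_frames))
    displaced_frames = tuple(range(first_displaced, n_frames))

    frames = np.empty((n_frames, base.shape[0], 3))
    for f in range(n_frames):
        coords = base + config.thermal_sigma * rng.standard_normal(base.shape)
        if f in displaced_frames:
            coords[loop_atoms] += config.loop_displacement * direction
        if config.rigid_jitter:
            quat = rng.standard_normal(4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            trans = 5.0 * rng.standard_normal(3)
            coords = coords @ rot.T + trans
        frames[f] = coords

    traj = CoordinateTrajectory(
        frames=frames, atom_residue_ids=atom_rids, atom_names=atom_names
    )
    truth = CoordinateTruth(
        seed=config.seed,
        loop_residues=loop_residues,
        loop_displacement=float(config.loop_displacement),
        displaced_frames=displaced_frames,
    )
    return traj, truth


def _config_echo(config: GeneratorConfig) -> dict:
    raw = dataclasses.asdict(config)
    for key in ("pathway_residues", "sources", "sinks", "loop_residues"):
        if raw[key] is not None:
            raw[key] = list(raw[key])
    return raw
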