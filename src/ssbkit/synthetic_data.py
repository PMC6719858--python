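"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of (spec, seed): the same inputs give
bit-identical outputs, and every output carries a provenance record with
the generating spec, seed and ground truth so downstream recovery tests
read the truth only from provenance.

What is emulated, and what is not:

* ``build_toy_tetramer`` places four copies of a Cα (optionally with one
  charged-group pseudo-atom per K/R/E/D residue) monomer with exact D2
  symmetry — a dimer-of-dimers arrangement like the SSBP1 homotetramer.
  It is a geometric scaffold, not a folded protein.
* ``simulate_harmonic_trajectory`` draws memoryless isotropic Gaussian
  displacements about the reference (per-coordinate SD = the residue's σ),
  so RMSF has the exact expectation √3·σ.  This is *not* physical
  molecular dynamics: there are no correlated modes, no solvent and no
  kinetics — only the stationary fluctuation statistics that the
  trajectory estimators are meant to recover.
* Assay generators add Gaussian noise to the closed-form instrument
  responses (Morrison isotherm, logistic melt transitions), draw droplet
  counts binomially from Poisson occupancy and per-base read depths from
  Poisson counts with a heteroplasmic depth drop across the deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .binding_assays import MeltCurve, TitrationCurve, predict_anisotropy
from .mtdna_tools import CircularDeletion, CoverageProfile, DdpcrAssay
from .structure_io import Atom, StructureModel, TrajectoryEnsemble

__all__ = [
    "ToyTetramerSpec",
    "HarmonicTrajSpec",
    "TitrationSimSpec",
    "MeltSimSpec",
    "DdpcrSimSpec",
    "CoverageSimSpec",
    "build_toy_tetramer",
    "simulate_harmonic_trajectory",
    "simulate_titration",
    "simulate_melt_curve",
    "simulate_ddpcr",
    "simulate_coverage",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# representative charged-group atom for the minimal side-chain representation
_PSEUDO_ATOM = {"LYS": "NZ", "ARG": "NH1", "GLU": "OE1", "ASP": "OD1"}


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ToyTetramerSpec:
    monomer_sequence: str  # 1-letter codes
    ring_radius: float = 15.0  # Angstrom, centroid offset from the symmetry centre
    axial_offset: float = 5.0  # Angstrom, offset along z
    twist_deg: float = 20.0  # monomer pre-rotation about z
    representation: str = "ca_spheres"  # or "minimal_sidechain"
    ca_radius: float = 3.0  # Angstrom, coarse sphere radius
    mutant_chains: frozenset = frozenset()  # subset of {"a","b","c","d"}
    mutation: tuple[int, str, str] | None = None  # (1-based position, wt, mut)

    def __post_init__(self) -> None:
        seq = self.monomer_sequence.upper()
        if not seq or any(c not in _ONE_TO_THREE for c in seq):
            raise ValueError("monomer_sequence must be non-empty standard 1-letter codes")
        object.__setattr__(self, "monomer_sequence", seq)
        if self.representation not in ("ca_spheres", "minimal_sidechain"):
            raise ValueError(f"unknown representation {self.representation!r}")
        self.mutant_chains = frozenset(self.mutant_chains)
        if not self.mutant_chains <= {"a", "b", "c", "d"}:
            raise ValueError("mutant_chains must be a subset of {'a','b','c','d'}")
        if self.mutant_chains and self.mutation is None:
            raise ValueError("mutant_chains given without a mutation")
        if self.mutation is not None:
            pos, wt, _mut = self.mutation
            if not 1 <= pos <= len(seq):
                raise ValueError(f"mutation position {pos} outside sequence")
            if seq[pos - 1] != wt.upper():
                raise ValueError(f"sequence has {seq[pos - 1]} at {pos}, mutation says wt {wt}")


def _rot(axis: str, deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def build_toy_tetramer(spec: ToyTetramerSpec) -> StructureModel:
    """Deterministic D2-symmetric four-chain toy structure (chains a-d).

    The monomer is a gently kinked Cα trace (3.8 Å spacing); chain a sits
    with its centroid at (ring_radius, 0, axial_offset) and chains b, c, d
    are its images under 180° rotations about z, x and y — the three
    orthogonal two-fold axes of D2, so all four centroids are exactly
    equidistant from the origin.  Mutant chains carry the substituted
    residue name (and pseudo-atom, in the minimal_sidechain
    representation).
    """
    seq = spec.monomer_sequence
    n = len(seq)
    i = np.arange(n)
    local = np.column_stack([
        (i - (n - 1) / 2.0) * 3.8,
        1.5 * np.sin(0.7 * i),
        0.8 * np.cos(0.9 * i),
    ])
    local = local @ _rot("z", spec.twist_deg).T
    offset = np.array([spec.ring_radius, 0.0, spec.axial_offset])
    ops = {
        "a": np.eye(3),
        "b": _rot("z", 180.0),
        "c": _rot("x", 180.0),
        "d": _rot("y", 180.0),
    }
    atoms: list[Atom] = []
    serial = 1
    for chain in "abcd":
        R = ops[chain]
        chain_seq = list(seq)
        if chain in spec.mutant_chains and spec.mutation is not None:
            pos, _wt, mut = spec.mutation
            chain_seq[pos - 1] = mut.upper()
        for res_i, letter in enumerate(chain_seq, start=1):
            resname = _ONE_TO_THREE[letter]
            ca = R @ (local[res_i - 1] + offset)
            atoms.append(Atom(serial, "CA", "C", resname, res_i, chain, ca, radius=spec.ca_radius))
            serial += 1
            if spec.representation == "minimal_sidechain" and resname in _PSEUDO_ATOM:
                side = R @ (local[res_i - 1] + offset + np.array([0.0, 2.0, 0.0]))
                element = "N" if resname in ("LYS", "ARG") else "O"
                atoms.append(Atom(serial, _PSEUDO_ATOM[resname], element, resname, res_i, chain, side))
                serial += 1
    model = StructureModel(atoms)
    coords = model.coords
    chains = np.array([a.chain_id for a in model.atoms])
    tree = cKDTree(coords)
    for pi, pj in tree.query_pairs(1.0):
        if chains[pi] != chains[pj]:
            raise ValueError("inter-chain clash (< 1 Angstrom) in toy tetramer placement")
    return model


@dataclass
class HarmonicTrajSpec:
    n_frames: int
    sigma: float | np.ndarray  # Angstrom, per-residue isotropic SD (scalar broadcasts)
    drift_per_frame: np.ndarray | None = None  # rigid translation per frame, Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sig < 0):
            raise ValueError("sigma must be non-negative")
        self.sigma = sig
        if self.drift_per_frame is not None:
            self.drift_per_frame = np.asarray(self.drift_per_frame, dtype=float).reshape(3)


def simulate_harmonic_trajectory(structure: StructureModel, spec: HarmonicTrajSpec) -> TrajectoryEnsemble:
    """Gaussian fluctuation ensemble about ``structure`` with known σ profile.

    Frame 0 is the reference exactly; frames t >= 1 add independent
    N(0, σ_residue) noise to every coordinate plus the optional rigid
    drift t·drift_per_frame.
    """
    residues = structure.residues()
    sig = spec.sigma
    if sig.size == 1:
        sig = np.full(len(residues), float(sig[0]))
    elif sig.size != len(residues):
        raise ValueError(f"sigma profile length {sig.size} != residue count {len(residues)}")
    atom_sigma = np.empty(len(structure))
    for r, (_c, _s, _n, idx) in enumerate(residues):
        atom_sigma[idx] = sig[r]
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ref = structure.coords
    frames = np.empty((spec.n_frames, len(structure), 3))
    frames[0] = ref
    for t in range(1, spec.n_frames):
        noise = rng.standard_normal((len(structure), 3)) * atom_sigma[:, None]
        drift = t * spec.drift_per_frame if spec.drift_per_frame is not None else 0.0
        frames[t] = ref + noise + drift
    traj = TrajectoryEnsemble(structure, frames)
    return traj


@dataclass
class TitrationSimSpec:
    kd: float = 2.3  # nM, tetramer
    dna_total: float = 20.0  # nM
    a_free: float = 0.05
    a_bound: float = 0.20
    noise_sd: float = 0.002
    replicates: int = 3
    grid: np.ndarray | None = None  # nM; default 15 log points 0.1x..50x dna_total
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kd, self.dna_total, self.replicates) <= 0 or self.noise_sd < 0:
            raise ValueError("kd, dna_total, replicates must be positive; noise_sd >= 0")
        if self.grid is None:
            self.grid = np.geomspace(0.1 * self.dna_total, 50.0 * self.dna_total, 15)
        else:
            self.grid = np.asarray(self.grid, dtype=float)


def simulate_titration(spec: TitrationSimSpec) -> TitrationCurve:
    """Replicate-averaged synthetic anisotropy titration with known truth."""
    import warnings as _warnings

    if spec.grid.min() > spec.kd or spec.grid.max() < 20.0 * spec.kd:
        _warnings.warn("concentration grid barely spans the true Kd; fit may be weakly identified")
    truth = predict_anisotropy(spec.grid, spec.kd, spec.a_free, spec.a_bound, spec.dna_total)
    streams = _rng_streams(spec.seed, spec.replicates)
    reps = np.stack([truth + rng.standard_normal(spec.grid.size) * spec.noise_sd for rng in streams])
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if spec.replicates > 1 else None
    return TitrationCurve(
        spec.grid, mean, spec.dna_total, sd,
        provenance={
            "generator": "simulate_titration", "seed": spec.seed,
            "truth": {"kd": spec.kd, "a_free": spec.a_free, "a_bound": spec.a_bound,
                      "dna_total": spec.dna_total, "noise_sd": spec.noise_sd,
                      "replicates": spec.replicates},
        },
    )


@dataclass
class MeltSimSpec:
    transitions: Sequence[tuple[float, float, float]] = ((75.1, 1.0, 1.0),)
    # each (midpoint degC, steepness degC, amplitude)
    baseline_intercept: float = 0.2
    baseline_slope: float = 0.002  # per degC
    t_min: float = 25.0
    t_max: float = 95.0
    t_step: float = 0.25
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mid, steep, _amp in self.transitions:
            if not self.t_min <= mid <= self.t_max:
                raise ValueError(f"transition midpoint {mid} outside [{self.t_min}, {self.t_max}]")
            if steep <= 0:
                raise ValueError("transition steepness must be positive")


def melt_signal(temps: np.ndarray, spec: MeltSimSpec) -> np.ndarray:
    """Noise-free melt-curve model: sloping baseline + logistic transitions."""
    sig = spec.baseline_intercept + spec.baseline_slope * (temps - spec.t_min)
    for mid, steep, amp in spec.transitions:
        sig = sig + amp / (1.0 + np.exp(-(temps - mid) / steep))
    return sig


def simulate_melt_curve(spec: MeltSimSpec) -> MeltCurve:
    """Multi-transition sigmoidal melt curve on a uniform temperature ramp."""
    temps = np.arange(spec.t_min, spec.t_max + 0.5 * spec.t_step, spec.t_step)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    signal = melt_signal(temps, spec) + rng.standard_normal(temps.size) * spec.noise_sd
    return MeltCurve(
        temps, signal,
        provenance={
            "generator": "simulate_melt_curve", "seed": spec.seed,
            "truth": {"transitions": [tuple(t) for t in spec.transitions],
                      "noise_sd": spec.noise_sd},
        },
    )


@dataclass
class DdpcrSimSpec:
    heteroplasmy: float = 0.68  # deleted fraction
    droplets_per_well: int = 15000
    copies_per_droplet: float = 1.0  # mean reference-target copies per droplet
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heteroplasmy <= 1.0:
            raise ValueError("heteroplasmy must be in [0, 1]")
        if self.droplets_per_well < 1000:
            raise ValueError("need at least 1000 droplets per well")
        p_ref = 1.0 - np.exp(-self.copies_per_droplet)
        if p_ref > 0.999:
            raise ValueError("occupancy saturates (> 99.9% positive); lower copies_per_droplet")


def simulate_ddpcr(spec: DdpcrSimSpec) -> DdpcrAssay:
    """Binomial droplet partitioning for the two-probe triplicate design.

    The reference probe sees all genomes (mean λ copies per droplet); the
    in-deletion probe sees only non-deleted genomes, λ·(1 − heteroplasmy).
    """
    lam = spec.copies_per_droplet
    p_ref = 1.0 - np.exp(-lam)
    p_in = 1.0 - np.exp(-lam * (1.0 - spec.heteroplasmy))
    streams = _rng_streams(spec.seed, 2)
    n = spec.droplets_per_well
    ref = streams[0].binomial(n, p_ref, size=spec.replicates)
    ind = streams[1].binomial(n, p_in, size=spec.replicates)
    totals = np.full(spec.replicates, n)
    return DdpcrAssay(
        ind, totals, ref, totals,
        provenance={
            "generator": "simulate_ddpcr", "seed": spec.seed,
            "truth": {"heteroplasmy": spec.heteroplasmy, "copies_per_droplet": lam,
                      "droplets_per_well": n, "replicates": spec.replicates},
        },
    )


@dataclass
class CoverageSimSpec:
    depth: float = 20000.0  # mean read depth outside the deletion
    genome_length: int = 16569
    deletion: tuple[int, int] = (8629, 14068)  # 1-based inclusive; end < start wraps
    heteroplasmy: float = 0.68
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.heteroplasmy <= 1.0:
            raise ValueError("heteroplasmy must be in [0, 1]")
        CircularDeletion(self.deletion[0], self.deletion[1], self.genome_length)


def simulate_coverage(spec: CoverageSimSpec) -> CoverageProfile:
    """Poisson per-base depth with a heteroplasmic drop across the deletion."""
    deletion = CircularDeletion(spec.deletion[0], spec.deletion[1], spec.genome_length)
    mean = np.full(spec.genome_length, spec.depth)
    mean[deletion.positions() - 1] = spec.depth * (1.0 - spec.heteroplasmy)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    depth = rng.poisson(mean).astype(float)
    return CoverageProfile(
        depth,
        provenance={
            "generator": "simulate_coverage", "seed": spec.seed,
            "truth": {"depth": spec.depth, "deletion": tuple(spec.deletion),
                      "heteroplasmy": spec.heteroplasmy,
                      "genome_length": spec.genome_length},
        },
    )
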