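"""Trajectory statistics: superposition/RMSD, Cα deviation maps, pair
mobility fractions, RMSF / normalized B-factors and convergence checks.

A deviation map holds the signed, window-averaged change of every Cα–Cα
distance relative to the initial frame: Δ_ij = <d_ij(t)>_window − d_ij(0).
Negative entries mean a residue pair moved closer over the simulation,
positive entries farther apart.  Because pairwise distances are invariant
under rigid motion, no superposition enters the map.  The pair mobility
fraction summarises a map as the share of residue pairs whose |Δ_ij| stays
within a threshold (2 Å by default), split by intra-/inter-monomer scope —
a semi-quantitative mobility measure for multimeric assemblies.

B-factors follow the crystallographic convention B_i = (8π²/3)·RMSF_i² and
the "normalized" profile is B_i divided by its mean over residues (so a
uniform profile normalizes to 1 everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import (
    AtomSelection,
    RosterMismatchError,
    StructureModel,
    TrajectoryEnsemble,
    resolve_selection,
)

__all__ = [
    "SuperpositionResult",
    "DeviationMap",
    "MobilityFraction",
    "FluctuationProfile",
    "ConvergenceResult",
    "kabsch_superpose",
    "rmsd_series",
    "ca_deviation_map",
    "pair_mobility_fraction",
    "rmsf_profile",
    "convergence_check",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing the
    (weighted) RMSD of ``mobile @ R.T + t`` against ``reference``.  The
    reflection case is resolved by the standard determinant correction
    (sign flip on the smallest singular vector).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    cp = wn @ P
    cq = wn @ Q
    Pc = P - cp
    Qc = Q - cq
    H = Pc.T @ (Qc * wn[:, None])
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear or coincident) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.sum(wn * np.sum(diff**2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


def rmsd_series(
    traj: TrajectoryEnsemble,
    reference: "StructureModel | np.ndarray | None" = None,
    selection: "AtomSelection | str | None" = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the trajectory against a reference structure.

    By default each frame is optimally superposed (Kabsch) onto the
    reference before the RMSD is taken; ``superpose=False`` gives the raw
    coordinate RMSD.
    """
    if reference is None:
        ref_coords = traj.reference.coords
    elif isinstance(reference, StructureModel):
        ref_coords = reference.coords
    else:
        ref_coords = np.asarray(reference, dtype=float)
    if selection is not None:
        idx = resolve_selection(selection).indices(traj.reference)
        ref_coords = ref_coords[idx] if ref_coords.shape[0] == traj.n_atoms else ref_coords
        frames = traj.frames[:, idx]
    else:
        frames = traj.frames
    if ref_coords.shape != frames.shape[1:]:
        raise RosterMismatchError(
            f"reference has {ref_coords.shape[0]} atoms, trajectory frames have {frames.shape[1]}"
        )
    out = np.empty(frames.shape[0])
    for t, frame in enumerate(frames):
        if superpose:
            out[t] = kabsch_superpose(frame, ref_coords).rmsd
        else:
            out[t] = float(np.sqrt(np.mean(np.sum((frame - ref_coords) ** 2, axis=1))))
    return out


@dataclass
class DeviationMap:
    residue_labels: list[tuple[str, int]]  # (chain_id, residue_seq)
    matrix: np.ndarray  # (n, n), signed Angstrom
    window: tuple[int, int]  # [start, stop) frame index range averaged

    def __post_init__(self) -> None:
        n = len(self.residue_labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix dimensions must equal the residue label count")

    @property
    def chains(self) -> np.ndarray:
        return np.array([c for c, _ in self.residue_labels])


def _resolve_window(n_frames: int, window) -> tuple[int, int]:
    """Window spec -> [start, stop) frame range.  Floats are trailing fractions."""
    if window is None:
        window = 1.0 / 3.0
    if isinstance(window, float):
        if not 0 < window <= 1:
            raise ValueError("trailing window fraction must be in (0, 1]")
        start = max(0, n_frames - max(1, round(n_frames * window)))
        return start, n_frames
    start, stop = window
    if not (0 <= start < stop <= n_frames):
        raise ValueError(f"window {window} outside frame range [0, {n_frames})")
    return int(start), int(stop)


def ca_deviation_map(
    traj: TrajectoryEnsemble,
    window=None,
    reference_frame: int = 0,
) -> DeviationMap:
    """Signed Cα deviation map over a trailing window of the trajectory.

    The ensemble must carry exactly one Cα per residue (build it with the
    "CA" selection).  Entry (i, j) is the mean over window frames of the
    Cα_i–Cα_j distance minus the same distance in the initial frame.
    """
    residues = traj.reference.residues()
    bad = [(c, s) for c, s, _name, idx in residues if len(idx) != 1]
    ca_ok = all(traj.reference.atoms[idx[0]].name == "CA" for _, _, _, idx in residues if len(idx) == 1)
    if bad or not ca_ok:
        raise ValueError(
            "deviation map requires exactly one CA atom per residue; offending residues: "
            f"{bad[:5] if bad else 'non-CA atoms present'}"
        )
    start, stop = _resolve_window(traj.n_frames, window)
    d0 = pdist(traj.frames[reference_frame])
    mean_d = np.mean([pdist(traj.frames[t]) for t in range(start, stop)], axis=0)
    matrix = squareform(mean_d - d0)
    labels = [(c, s) for c, s, _, _ in residues]
    return DeviationMap(labels, matrix, (start, stop))


@dataclass
class MobilityFraction:
    threshold: float  # Angstrom
    scope: str  # intra_monomer | inter_monomer | overall
    fraction: float
    n_pairs: int


def pair_mobility_fraction(
    devmap: DeviationMap,
    threshold: float = 2.0,
    scope: str = "intra_monomer",
) -> MobilityFraction:
    """Fraction of residue pairs (i<j) whose |Δ_ij| is within ``threshold``."""
    if scope not in ("intra_monomer", "inter_monomer", "overall"):
        raise ValueError(f"unknown scope {scope!r}")
    chains = devmap.chains
    n = len(chains)
    iu, ju = np.triu_indices(n, k=1)
    same = chains[iu] == chains[ju]
    if scope == "intra_monomer":
        mask = same
    elif scope == "inter_monomer":
        mask = ~same
    else:
        mask = np.ones_like(same)
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise ValueError(f"no residue pairs in scope {scope!r}")
    dev = np.abs(devmap.matrix[iu[mask], ju[mask]])
    frac = float(np.mean(dev <= threshold))
    return MobilityFraction(threshold, scope, frac, n_pairs)


@dataclass
class FluctuationProfile:
    residue_labels: list[tuple[str, int]]
    rmsf: np.ndarray  # Angstrom
    b_factor: np.ndarray  # Angstrom^2
    normalized_b: np.ndarray  # unitless, mean 1


def rmsf_profile(
    traj: TrajectoryEnsemble,
    align: bool = True,
) -> FluctuationProfile:
    """Per-residue RMSF about the trajectory-mean position, plus B-factors.

    RMSF_i = sqrt(<|r_i(t) − r̄_i|²>_t), after optional Kabsch alignment of
    every frame onto the reference.  For an isotropic per-coordinate spread
    σ the expectation is √3·σ.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    frames = traj.frames
    if align:
        ref = traj.reference.coords
        frames = np.stack([kabsch_superpose(f, ref).apply(f) for f in frames])
    mean_pos = frames.mean(axis=0)
    msf = np.mean(np.sum((frames - mean_pos) ** 2, axis=2), axis=0)
    # collapse atoms to residues (mean MSF over the residue's atoms)
    residues = traj.reference.residues()
    labels = [(c, s) for c, s, _, _ in residues]
    res_msf = np.array([msf[idx].mean() for _, _, _, idx in residues])
    rmsf = np.sqrt(res_msf)
    b = (8.0 * np.pi**2 / 3.0) * res_msf
    mean_b = b.mean()
    # a numerically static trajectory (B ~ alignment round-off) normalizes to 1
    normalized = b / mean_b if mean_b > 1e-12 else np.ones_like(b)
    return FluctuationProfile(labels, rmsf, b, normalized)


@dataclass
class ConvergenceResult:
    converged: bool
    window: tuple[int, int]
    mean: float
    min: float
    max: float

    @property
    def range(self) -> float:
        return self.max - self.min


def convergence_check(series: np.ndarray, window=None, tolerance: float = 0.5) -> ConvergenceResult:
    """Declare a series converged when its trailing-window range ≤ tolerance."""
    series = np.asarray(series, dtype=float)
    start, stop = _resolve_window(series.size, window)
    if stop - start < 10:
        raise ValueError("convergence window must contain at least 10 points")
    tail = series[start:stop]
    lo, hi = float(tail.min()), float(tail.max())
    return ConvergenceResult(bool(hi - lo <= tolerance), (start, stop), float(tail.mean()), lo, hi)
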