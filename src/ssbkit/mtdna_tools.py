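"""mtDNA deletion arithmetic, ddPCR heteroplasmy, coverage scanning and
relative copy number.

Coordinates follow the rCRS convention: the human mitochondrial genome is
a 16,569-bp circle with 1-based inclusive positions, and a deletion label
"m.<start>_<end>del<len>" removes positions start..end inclusive (the span
may wrap past position 16,569 back through position 1).

ddPCR heteroplasmy compares a probe inside the deletion (detecting only
non-deleted genomes) to a reference probe outside it (detecting all
genomes): heteroplasmy = 1 − λ_in/λ_ref.  Per-well concentrations use the
Poisson correction λ = −ln(1 − positives/total) by default; the raw
positive-droplet fraction is available for literal two-probe ratios.  The
95% confidence interval is a normal interval with the standard analytic
ddPCR variance var(λ̂) = p/(n(1−p)) per well propagated through the ratio
by the delta method (a replicate-sample-variance option exists).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "RCRS_LENGTH",
    "CircularDeletion",
    "DdpcrAssay",
    "HeteroplasmyEstimate",
    "CoverageProfile",
    "QpcrMeasurement",
    "deletion_length",
    "parse_deletion_label",
    "heteroplasmy_from_ddpcr",
    "scan_coverage_for_deletion",
    "relative_copy_number",
    "load_ddpcr_tsv",
    "load_coverage_tsv",
    "load_ct_tsv",
]

RCRS_LENGTH = 16569


@dataclass
class CircularDeletion:
    start: int  # 1-based rCRS position, inclusive
    end: int  # 1-based rCRS position, inclusive; end < start wraps the origin
    genome_length: int = RCRS_LENGTH
    label: str | None = None

    def __post_init__(self) -> None:
        for pos in (self.start, self.end):
            if not 1 <= pos <= self.genome_length:
                raise ValueError(f"position {pos} outside 1..{self.genome_length}")
        if self.label is not None:
            parsed = parse_deletion_label(self.label, self.genome_length)
            if (parsed.start, parsed.end) != (self.start, self.end):
                raise ValueError(f"label {self.label!r} disagrees with ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return self.genome_length - self.start + 1 + self.end

    def hgvs_label(self) -> str:
        return f"m.{self.start}_{self.end}del{self.length}"

    def positions(self) -> np.ndarray:
        """1-based positions removed by the deletion, in circular order."""
        if self.end >= self.start:
            return np.arange(self.start, self.end + 1)
        return np.concatenate(
            [np.arange(self.start, self.genome_length + 1), np.arange(1, self.end + 1)]
        )


def deletion_length(deletion: CircularDeletion) -> int:
    """Inclusive span of a (possibly origin-wrapping) circular deletion, bp."""
    return deletion.length


_LABEL_RE = re.compile(r"^m\.(\d+)_(\d+)del(\d+)$")


def parse_deletion_label(label: str, genome_length: int = RCRS_LENGTH) -> CircularDeletion:
    """Parse "m.<start>_<end>del<len>" and validate the embedded length."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse deletion label {label!r} (expected m.<start>_<end>del<len>)")
    start, end, stated = (int(g) for g in m.groups())
    deletion = CircularDeletion(start, end, genome_length)
    if deletion.length != stated:
        raise ValueError(
            f"label {label!r}: stated length {stated} != computed span {deletion.length}"
        )
    return deletion


@dataclass
class DdpcrAssay:
    """Droplet counts for the in-deletion and reference probes (triplicates)."""

    in_deletion_positives: np.ndarray
    in_deletion_totals: np.ndarray
    reference_positives: np.ndarray
    reference_totals: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("in_deletion_positives", "in_deletion_totals",
                     "reference_positives", "reference_totals"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        for pos, tot in ((self.in_deletion_positives, self.in_deletion_totals),
                         (self.reference_positives, self.reference_totals)):
            if pos.shape != tot.shape:
                raise ValueError("positives and totals must have matching shapes")
            if np.any(tot <= 0) or np.any(pos < 0) or np.any(pos > tot):
                raise ValueError("droplet counts must satisfy 0 <= positives <= totals, totals > 0")


@dataclass
class HeteroplasmyEstimate:
    fraction_deleted: float  # in [0, 1]
    ci95: tuple[float, float]
    method: str  # raw_ratio | poisson_ratio
    clamped: bool = False


def _well_lambda(pos: np.ndarray, tot: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-well concentration estimate and its analytic variance."""
    p = pos / tot
    if method == "poisson_ratio":
        if np.any(p >= 1.0):
            raise ValueError("saturated wells (all droplets positive); dilute the sample")
        lam = -np.log1p(-p)
        var = p / (tot * (1.0 - p))
    elif method == "raw_ratio":
        lam = p
        var = p * (1.0 - p) / tot
    else:
        raise ValueError(f"unknown method {method!r}")
    return lam, var


def heteroplasmy_from_ddpcr(
    assay: DdpcrAssay,
    method: str = "poisson_ratio",
    variance: str = "analytic",
) -> HeteroplasmyEstimate:
    """Deletion heteroplasmy (1 − λ_in/λ_ref) with a normal 95% CI.

    ``variance="analytic"`` propagates the per-well binomial/Poisson
    variance through the ratio by the delta method; ``"replicate"`` uses
    the sample variance across replicate wells instead.
    """
    if np.all(assay.reference_positives == 0):
        raise ValueError("reference assay has no positive droplets")
    lam_in, var_in = _well_lambda(assay.in_deletion_positives, assay.in_deletion_totals, method)
    lam_ref, var_ref = _well_lambda(assay.reference_positives, assay.reference_totals, method)
    m_in, m_ref = float(lam_in.mean()), float(lam_ref.mean())
    if m_ref <= 0:
        raise ValueError("reference concentration is zero")
    if variance == "analytic":
        v_in = float(var_in.sum()) / lam_in.size**2
        v_ref = float(var_ref.sum()) / lam_ref.size**2
    elif variance == "replicate":
        v_in = float(lam_in.var(ddof=1)) / lam_in.size if lam_in.size > 1 else 0.0
        v_ref = float(lam_ref.var(ddof=1)) / lam_ref.size if lam_ref.size > 1 else 0.0
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    ratio = m_in / m_ref
    het = 1.0 - ratio
    se = abs(ratio) * np.sqrt(v_in / m_in**2 + v_ref / m_ref**2) if m_in > 0 else np.sqrt(v_in) / m_ref
    lo, hi = het - 1.96 * se, het + 1.96 * se
    clamped = bool(het < 0 or het > 1 or lo < 0 or hi > 1)
    return HeteroplasmyEstimate(
        fraction_deleted=float(np.clip(het, 0.0, 1.0)),
        ci95=(float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))),
        method=method,
        clamped=clamped,
    )


@dataclass
class CoverageProfile:
    depth: np.ndarray  # per-base read depth, index 0 <-> rCRS position 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size < 2:
            raise ValueError("depth must be a per-base 1-D array")
        if np.any(~np.isfinite(self.depth)) or np.any(self.depth < 0):
            raise ValueError("depth values must be finite and non-negative")

    @property
    def genome_length(self) -> int:
        return int(self.depth.size)


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array as (start, length), 0-based."""
    n = mask.size
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    # rotate so index 0 is False, find linear runs, map back
    shift = int(np.argmin(mask))  # first False
    rolled = np.roll(mask, -shift)
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], rolled.astype(np.int8), [0]])))
    for s, e in zip(idx[::2], idx[1::2]):
        runs.append((int((s + shift) % n), int(e - s)))
    return runs


def scan_coverage_for_deletion(
    profile: CoverageProfile,
    drop_fraction: float = 0.3,
    min_length: int = 1000,
    baseline_window: int | None = None,
) -> list[tuple[CircularDeletion, float]]:
    """Candidate deletions from heteroplasmic coverage drops.

    Bases whose depth falls below (1 − drop_fraction) times the baseline
    are collected into maximal circular runs; runs of at least
    ``min_length`` bp are reported as (CircularDeletion, depth_ratio)
    where depth_ratio = mean in-run depth / baseline (so 1 − depth_ratio
    is a heteroplasmy proxy).  The baseline is the global circular median
    depth, or a circular rolling median when ``baseline_window`` (odd bp)
    is given — note a rolling window must exceed about twice the deletion
    length to stay uncontaminated inside it.
    """
    depth = profile.depth
    med = float(np.median(depth))
    if med <= 0:
        raise ValueError("median depth is zero; profile carries no signal")
    if baseline_window is None:
        baseline = np.full_like(depth, med)
    else:
        if baseline_window % 2 == 0 or baseline_window < 3:
            raise ValueError("baseline_window must be odd and >= 3")
        baseline = median_filter(depth, size=baseline_window, mode="wrap")
    below = depth < (1.0 - drop_fraction) * baseline
    out = []
    for start0, length in _circular_runs(below):
        if length < min_length:
            continue
        end0 = (start0 + length - 1) % depth.size
        deletion = CircularDeletion(start0 + 1, end0 + 1, genome_length=depth.size)
        run_idx = (np.arange(start0, start0 + length)) % depth.size
        ratio = float(depth[run_idx].mean() / baseline[run_idx].mean())
        out.append((deletion, ratio))
    out.sort(key=lambda c: c[0].start)
    return out


@dataclass
class QpcrMeasurement:
    """Replicate Ct values for one sample's mtDNA and nuclear targets."""

    label: str
    ct_mt: np.ndarray  # e.g. MT-ND1 or MT-CO3
    ct_nuclear: np.ndarray  # e.g. B2M

    def __post_init__(self) -> None:
        self.ct_mt = np.atleast_1d(np.asarray(self.ct_mt, dtype=float))
        self.ct_nuclear = np.atleast_1d(np.asarray(self.ct_nuclear, dtype=float))
        for ct in (self.ct_mt, self.ct_nuclear):
            if ct.size < 2:
                raise ValueError("at least 2 Ct replicates are required")
            if np.any(ct <= 0) or np.any(ct >= 45):
                raise ValueError("Ct values must lie in (0, 45)")


def relative_copy_number(sample: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative mtDNA:nDNA copy number of sample vs control (2^-ΔΔCt).

    Per-sample ratio is 2^(mean Ct_nuclear − mean Ct_mt) assuming perfect
    amplification efficiency; the return value is sample ratio divided by
    control ratio.  A replicate Ct spread above one cycle raises a warning.
    """
    for m in (sample, control):
        for name, ct in (("mt", m.ct_mt), ("nuclear", m.ct_nuclear)):
            if np.ptp(ct) > 1.0:
                warnings.warn(f"{m.label}: {name} Ct replicates spread {np.ptp(ct):.2f} cycles (> 1)")
    r_sample = 2.0 ** (sample.ct_nuclear.mean() - sample.ct_mt.mean())
    r_control = 2.0 ** (control.ct_nuclear.mean() - control.ct_mt.mean())
    return float(r_sample / r_control)


# ---------------------------------------------------------------------------
# Plain-text I/O


def load_ddpcr_tsv(path) -> DdpcrAssay:
    """TSV with columns: assay (in_deletion|reference), replicate, positives, total."""
    df = pd.read_csv(path, sep="\t")
    df["assay"] = df["assay"].str.lower()
    sub = {a: df[df["assay"] == a].sort_values("replicate") for a in ("in_deletion", "reference")}
    for a, d in sub.items():
        if d.empty:
            raise ValueError(f"no rows for assay {a!r}")
    return DdpcrAssay(
        sub["in_deletion"]["positives"].to_numpy(),
        sub["in_deletion"]["total"].to_numpy(),
        sub["reference"]["positives"].to_numpy(),
        sub["reference"]["total"].to_numpy(),
    )


def load_coverage_tsv(path) -> CoverageProfile:
    """Two-column TSV (pos, depth) covering every base 1..genome_length."""
    df = pd.read_csv(path, sep="\t")
    pos = df.iloc[:, 0].to_numpy(dtype=int)
    depth = df.iloc[:, 1].to_numpy(dtype=float)
    n = pos.max()
    if sorted(pos) != list(range(1, n + 1)):
        raise ValueError("coverage table must contain each position 1..N exactly once")
    out = np.empty(n)
    out[pos - 1] = depth
    return CoverageProfile(out)


def load_ct_tsv(path) -> dict[str, QpcrMeasurement]:
    """TSV with columns: sample, mt_ct, nuclear_ct (one row per replicate)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for label, grp in df.groupby("sample"):
        out[str(label)] = QpcrMeasurement(str(label), grp["mt_ct"].to_numpy(), grp["nuclear_ct"].to_numpy())
    return out
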