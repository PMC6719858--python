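"""Minimal fixed-column PDB I/O, atom selection and trajectory containers.

The rest of the package works on :class:`StructureModel` and
:class:`TrajectoryEnsemble` objects; no downstream module touches raw PDB
text.  Only the v3.3 ATOM/HETATM/MODEL/ENDMDL subset is supported, which is
sufficient for multi-model trajectory files at desk scale.  Coordinates are
in Angstrom, residue numbering is 1-based as found in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "TrajectoryEnsemble",
    "AtomSelection",
    "PDBParseError",
    "RosterMismatchError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "to_trajectory",
]


class PDBParseError(ValueError):
    """A malformed record in a PDB file (carries the 1-based line number)."""


class RosterMismatchError(ValueError):
    """Atom rosters differ between models that must share one."""


class EmptySelectionError(ValueError):
    """An atom selection matched no atoms."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom
    radius: float | None = None  # Angstrom, assigned on demand

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.chain_id:
            raise ValueError(f"atom {self.serial}: empty chain_id")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.name)


@dataclass
class StructureModel:
    """One set of atomic coordinates (a PDB MODEL or a trajectory frame)."""

    atoms: list[Atom]
    model_index: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("StructureModel requires at least one atom")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (chain, residue, atom) entries: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_index: int | None = None) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = [replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms, self.model_index if model_index is None else model_index)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str, list[int]]]:
        """Residues in atom order as (chain_id, residue_seq, residue_name, atom indices)."""
        out: list[tuple[str, int, str, list[int]]] = []
        index: dict[tuple[str, int], int] = {}
        for i, a in enumerate(self.atoms):
            k = (a.chain_id, a.residue_seq)
            if k not in index:
                index[k] = len(out)
                out.append((a.chain_id, a.residue_seq, a.residue_name, []))
            out[index[k]][3].append(i)
        return out

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        return StructureModel([self.atoms[i] for i in indices], self.model_index)


_PRESETS: dict[str, Callable[[Atom], bool]] = {
    "CA": lambda a: a.name == "CA" and a.element != "H",
    "backbone": lambda a: a.name in ("N", "CA", "C", "O") and a.element != "H",
    "all": lambda a: True,
}


@dataclass(frozen=True)
class AtomSelection:
    """Predicate-based atom selection with named presets CA / backbone / all."""

    label: str
    predicate: Callable[[Atom], bool]

    @classmethod
    def preset(cls, name: str) -> "AtomSelection":
        try:
            return cls(name, _PRESETS[name])
        except KeyError:
            raise KeyError(f"unknown selection preset {name!r}; choose from {sorted(_PRESETS)}") from None

    @classmethod
    def chains(cls, chain_ids: Iterable[str]) -> "AtomSelection":
        wanted = frozenset(chain_ids)
        return cls(f"chains:{','.join(sorted(wanted))}", lambda a: a.chain_id in wanted)

    def indices(self, model: StructureModel) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(model.atoms) if self.predicate(a)], dtype=int)
        if idx.size == 0:
            raise EmptySelectionError(f"selection {self.label!r} matched no atoms")
        return idx


def resolve_selection(selection: "AtomSelection | str | None") -> AtomSelection:
    if selection is None:
        return AtomSelection.preset("all")
    if isinstance(selection, str):
        return AtomSelection.preset(selection)
    return selection


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames over the fixed atom roster of ``reference``."""

    reference: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must have shape (n_frames >= 1, n_atoms, 3)")
        if self.frames.shape[1:] != (len(self.reference), 3):
            raise RosterMismatchError(
                f"frames have shape {self.frames.shape[1:]}, reference roster is {(len(self.reference), 3)}"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.frames.shape[0],):
                raise ValueError("frame_times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def frame_model(self, t: int) -> StructureModel:
        return self.reference.with_coords(self.frames[t], model_index=t + 1)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float]:
    """Parse one ATOM/HETATM record -> (atom, altloc, occupancy)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {exc}") from None
    if icode:
        raise PDBParseError(f"line {lineno}: insertion codes are not supported (found {icode!r})")
    if not element:
        # fall back on the first letter of the atom name (adequate for C/N/O/S/H/P)
        element = next((c for c in name if c.isalpha()), "C")
    atom = Atom(serial, name, element.upper(), resname, resseq, chain or "A", np.array([x, y, z]))
    return atom, altloc, occupancy


def _resolve_altlocs(records: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep the highest-occupancy alternate location; ties go to the first seen."""
    best: dict[tuple[str, int, str], tuple[float, int, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for i, (atom, _altloc, occ) in enumerate(records):
        k = atom.key
        if k not in best:
            best[k] = (occ, i, atom)
            order.append(k)
        elif occ > best[k][0]:
            best[k] = (occ, best[k][1], atom)  # keep original ordering slot
    return [best[k][2] for k in order]


def read_pdb(path, include_hetatm: bool = False) -> list[StructureModel]:
    """Read a (possibly multi-model) PDB file into a list of StructureModel.

    Alternate locations keep the highest occupancy (ties: first encountered);
    insertion codes are rejected; HETATM records are skipped unless
    ``include_hetatm``.
    """
    models: list[StructureModel] = []
    records: list[tuple[Atom, str, float]] = []
    model_index = 0
    in_model = False

    def flush() -> None:
        nonlocal records, model_index
        if records:
            model_index += 1
            models.append(StructureModel(_resolve_altlocs(records), model_index))
            records = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                flush()
                in_model = True
            elif rec == "ENDMDL":
                flush()
                in_model = False
            elif rec == "ATOM" or (rec == "HETATM" and include_hetatm):
                records.append(_parse_atom_line(line, lineno))
    flush()
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")
    return models


def _format_atom_name(name: str) -> str:
    # Names shorter than 4 characters start in column 14 by convention.
    return name.ljust(4) if len(name) >= 4 else (" " + name).ljust(4)


def write_pdb(models: Sequence[StructureModel], path) -> None:
    """Write models as fixed-column PDB; >1 model uses MODEL/ENDMDL blocks."""
    models = list(models)
    if not models:
        raise ValueError("write_pdb requires at least one model")
    roster = [a.key for a in models[0].atoms]
    for m in models[1:]:
        if [a.key for a in m.atoms] != roster:
            raise RosterMismatchError("models do not share an identical atom roster")
    multi = len(models) > 1
    with open(path, "w") as fh:
        for i, m in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {i:>4d}\n")
            for a in m.atoms:
                x, y, z = a.position
                fh.write(
                    f"ATOM  {a.serial % 100000:>5d} {_format_atom_name(a.name)}"
                    f" {a.residue_name:>3s} {a.chain_id[0]}{a.residue_seq:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def to_trajectory(
    models: Sequence[StructureModel],
    selection: "AtomSelection | str | None" = None,
    frame_times: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Stack models into a TrajectoryEnsemble restricted to ``selection``.

    Frame 0 is the first model; the reference is the first model restricted
    to the selection.  All models must share the first model's roster.
    """
    models = list(models)
    if not models:
        raise ValueError("to_trajectory requires at least one model")
    sel = resolve_selection(selection)
    idx = sel.indices(models[0])
    roster = [models[0].atoms[i].key for i in idx]
    frames = np.empty((len(models), len(idx), 3), dtype=float)
    for t, m in enumerate(models):
        try:
            m_idx = sel.indices(m)
        except EmptySelectionError:
            raise RosterMismatchError(f"model {t}: selection {sel.label!r} matched no atoms") from None
        if [m.atoms[i].key for i in m_idx] != roster:
            raise RosterMismatchError(f"model {t}: atom roster drifts from the first model")
        frames[t] = m.coords[m_idx]
    return TrajectoryEnsemble(models[0].subset(idx), frames, frame_times)
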