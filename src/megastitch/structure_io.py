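"""Reading, writing and in-memory representation of macromolecular structures.

The in-memory model is a flat, array-backed atom table (``StructureModel``)
that preserves author residue numbering and carries per-residue predictor
confidence (pLDDT-style, conventionally stored in the B-factor column of
PDB/mmCIF files). Parsing and serialization are delegated to :mod:`gemmi`;
this module only enforces the package's invariants on top of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import SeqIO

from .constants import AA_3TO1, vdw_radius
from .errors import (
    EmptyInputError,
    FormatError,
    LookupError_,
)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "residue_numbering_gaps",
    "read_fasta",
]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with coordinates in Å and predictor confidence in [0, 100]."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    element: str
    confidence: float

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)


@dataclass
class StructureModel:
    """Ordered atom table for one structure (single coordinate model).

    Parallel numpy arrays, one entry per atom, in file order. Residue
    numbering is 1-based and preserved verbatim from the source.
    """

    serial: np.ndarray
    atom_name: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    residue_number: np.ndarray
    coords: np.ndarray  # (n, 3) float64, Å
    element: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.serial = np.asarray(self.serial, dtype=np.int64)
        self.residue_number = np.asarray(self.residue_number, dtype=np.int64)
        self.confidence = np.asarray(self.confidence, dtype=float)
        for name in ("atom_name", "residue_name", "chain_id", "element"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c)
        return list(seen)

    def validate(self) -> None:
        """Check model invariants; warn on recoverable issues, raise otherwise."""
        if len(self) == 0:
            raise EmptyInputError("structure model contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in structure model")
        if np.any(self.residue_number < 1):
            raise FormatError("residue numbers must be >= 1 (1-based numbering)")
        bad = (self.confidence < 0) | (self.confidence > 100)
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} atoms with confidence outside [0, 100]; clamped",
                stacklevel=2,
            )
            self.confidence = np.clip(self.confidence, 0.0, 100.0)
        for chain in self.chains():
            mask = self.chain_id == chain
            nums = self.residue_number[mask]
            # residue numbers must be non-decreasing atom-to-atom and
            # strictly increasing residue-to-residue
            firsts = nums[np.r_[True, nums[1:] != nums[:-1]]]
            if np.any(np.diff(firsts) <= 0):
                warnings.warn(
                    f"residue numbers not strictly increasing in chain {chain!r}",
                    stacklevel=2,
                )
            has_ca = set(nums[(self.atom_name[mask] == "CA")])
            std = [
                (n, rn)
                for n, rn in zip(nums, self.residue_name[mask])
                if rn in AA_3TO1
            ]
            missing = {n for n, _ in std} - has_ca
            if missing:
                warnings.warn(
                    f"{len(missing)} standard residues without CA in chain {chain!r}",
                    stacklevel=2,
                )

    # -- indexing ---------------------------------------------------------

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            atom_name=str(self.atom_name[i]),
            residue_name=str(self.residue_name[i]),
            chain_id=str(self.chain_id[i]),
            residue_number=int(self.residue_number[i]),
            x=float(self.coords[i, 0]),
            y=float(self.coords[i, 1]),
            z=float(self.coords[i, 2]),
            element=str(self.element[i]),
            confidence=float(self.confidence[i]),
        )

    def residue_numbers(self, chain: str | None = None) -> np.ndarray:
        """Unique residue numbers, in order of first appearance."""
        mask = self._chain_mask(chain)
        nums = self.residue_number[mask]
        if nums.size == 0:
            return nums
        keep = np.r_[True, nums[1:] != nums[:-1]]
        return nums[keep]

    @property
    def n_residues(self) -> int:
        return sum(len(self.residue_numbers(c)) for c in self.chains())

    def residue_index(self, chain: str | None = None) -> dict[int, slice]:
        """Map residue number -> contiguous atom span (slice into the table)."""
        mask = self._chain_mask(chain)
        idx = np.flatnonzero(mask)
        spans: dict[int, slice] = {}
        start = 0
        nums = self.residue_number[idx]
        for i in range(1, len(nums) + 1):
            if i == len(nums) or nums[i] != nums[start]:
                spans[int(nums[start])] = slice(int(idx[start]), int(idx[i - 1]) + 1)
                start = i
        return spans

    def _chain_mask(self, chain: str | None) -> np.ndarray:
        if chain is None:
            return np.ones(len(self), dtype=bool)
        if chain not in self.chains():
            raise LookupError_(f"chain {chain!r} not present (have {self.chains()})")
        return self.chain_id == chain

    def _subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            serial=self.serial[mask],
            atom_name=self.atom_name[mask],
            residue_name=self.residue_name[mask],
            chain_id=self.chain_id[mask],
            residue_number=self.residue_number[mask],
            coords=self.coords[mask],
            element=self.element[mask],
            confidence=self.confidence[mask],
        )

    def select_residues(self, start: int, end: int, chain: str | None = None) -> "StructureModel":
        """Atoms of residues with number in [start, end] (1-based inclusive)."""
        mask = self._chain_mask(chain) & (self.residue_number >= start) & (self.residue_number <= end)
        return self._subset(mask)

    def select_atom_name(self, name: str) -> "StructureModel":
        return self._subset(self.atom_name == name)

    def ca_coords(self, chain: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(residue numbers, (n,3) Cα coordinates), ordered by residue number."""
        mask = self._chain_mask(chain) & (self.atom_name == "CA")
        nums = self.residue_number[mask]
        xyz = self.coords[mask]
        order = np.argsort(nums, kind="stable")
        return nums[order], xyz[order]

    # -- geometry ---------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped x -> R x + t."""
        new = self.copy()
        new.coords = self.coords @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        return new

    def copy(self) -> "StructureModel":
        return StructureModel(
            serial=self.serial.copy(),
            atom_name=self.atom_name.copy(),
            residue_name=self.residue_name.copy(),
            chain_id=self.chain_id.copy(),
            residue_number=self.residue_number.copy(),
            coords=self.coords.copy(),
            element=self.element.copy(),
            confidence=self.confidence.copy(),
        )

    @staticmethod
    def concat(models: list["StructureModel"]) -> "StructureModel":
        if not models:
            raise EmptyInputError("no models to concatenate")
        return StructureModel(
            serial=np.concatenate([m.serial for m in models]),
            atom_name=np.concatenate([m.atom_name for m in models]),
            residue_name=np.concatenate([m.residue_name for m in models]),
            chain_id=np.concatenate([m.chain_id for m in models]),
            residue_number=np.concatenate([m.residue_number for m in models]),
            coords=np.concatenate([m.coords for m in models]),
            element=np.concatenate([m.element for m in models]),
            confidence=np.concatenate([m.confidence for m in models]),
        )

    def vdw_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.element], dtype=float)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _guess_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The B-factor column is interpreted as per-residue predictor confidence
    and clamped to [0, 100] (with a warning) if out of range. Only the first
    coordinate model of multi-model files is used (with a warning). Altloc
    conformers are reduced to the highest-occupancy one; insertion codes are
    rejected because predictor outputs never carry them.
    """
    if format not in _FORMATS:
        raise FormatError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no coordinate model found")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models; using the first", stacklevel=2)

    rows: list[tuple] = []
    for chain in st[0]:
        for res in chain:
            if res.seqid.icode not in (" ", "\x00", ""):
                raise FormatError(
                    f"{path}: insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} not supported"
                )
            # keep highest-occupancy altloc per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                rows.append(
                    (
                        atom.serial,
                        atom.name,
                        res.name,
                        chain.name,
                        res.seqid.num,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.element.name,
                        round(float(atom.b_iso), 2),
                    )
                )
    if not rows:
        raise EmptyInputError(f"{path}: file contains zero atoms")
    cols = list(zip(*rows))
    model = StructureModel(
        serial=np.array(cols[0]),
        atom_name=np.array(cols[1], dtype=object),
        residue_name=np.array(cols[2], dtype=object),
        chain_id=np.array(cols[3], dtype=object),
        residue_number=np.array(cols[4]),
        coords=np.column_stack([cols[5], cols[6], cols[7]]).astype(float),
        element=np.array(cols[8], dtype=object),
        confidence=np.array(cols[9], dtype=float),
    )
    model.validate()
    return model


def write_structure(model: StructureModel, path, format: str = "auto") -> None:
    """Write a model to PDB or mmCIF; confidence goes to the B-factor column.

    ``format='auto'`` chooses from the file extension (``.cif``/``.mmcif``
    -> mmCIF, anything else -> PDB).
    """
    if len(model) == 0:
        raise EmptyInputError("refusing to write an empty model")
    if format == "auto":
        format = _guess_format(path)
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r}")
    if format == "pdb":
        too_long = [c for c in model.chains() if len(str(c)) > 1]
        if too_long:
            raise FormatError(
                f"chain id(s) {too_long} exceed the 1-character PDB limit; "
                "write mmCIF instead"
            )

    st = gemmi.Structure()
    st.name = "megastitch"
    gmodel = gemmi.Model("1")
    for chain_name in model.chains():
        chain = gemmi.Chain(str(chain_name))
        spans = model.residue_index(chain_name)
        for resnum, span in spans.items():
            res = gemmi.Residue()
            res.name = str(model.residue_name[span.start])
            res.seqid = gemmi.SeqId(int(resnum), " ")
            res.het_flag = "A"
            for i in range(span.start, span.stop):
                atom = gemmi.Atom()
                atom.name = str(model.atom_name[i])
                atom.serial = int(model.serial[i])
                atom.pos = gemmi.Position(*model.coords[i])
                atom.element = gemmi.Element(str(model.element[i]))
                atom.occ = 1.0
                atom.b_iso = round(float(model.confidence[i]), 2)
                res.add_atom(atom)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def extract_sequence(model: StructureModel, chain: str | None = None) -> str:
    """One-letter sequence in residue-number order; unknown residues -> 'X'.

    Numbering gaps are silently spanned (use :func:`residue_numbering_gaps`
    to report them); the returned string has one letter per present residue.
    """
    if chain is None:
        chain = model.chains()[0]
    spans = model.residue_index(chain)
    letters = [str(model.residue_name[spans[n].start]) for n in sorted(spans)]
    return "".join(AA_3TO1.get(name, "X") for name in letters)


def residue_numbering_gaps(model: StructureModel, chain: str | None = None) -> list[tuple[int, int]]:
    """Pairs of consecutive present residue numbers that are not adjacent."""
    if chain is None:
        chain = model.chains()[0]
    nums = np.array(sorted(model.residue_index(chain)))
    jumps = np.flatnonzero(np.diff(nums) > 1)
    return [(int(nums[j]), int(nums[j + 1])) for j in jumps]


def read_fasta(path) -> str:
    """Sequence of the first record of a FASTA file, upper-cased."""
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise EmptyInputError(f"{path}: no FASTA records") from None
    return str(record.seq).upper()
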