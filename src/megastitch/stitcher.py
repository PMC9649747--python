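"""Rigid superposition of overlapping fragments and splicing into one model.

Each fragment of a megaprotein is predicted independently and therefore
lives in its own arbitrary frame. The stitcher aligns fragment i+1 onto the
growing assembly using a least-squares (Kabsch) fit of the Cα atoms shared
in the planned overlap, then splices the chain at a single crossover residue
so every residue of the final model comes from exactly one fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    EmptyInputError,
    InsufficientAtomsError,
    ParameterError,
    SequenceMismatchError,
)
from .fragment_planner import FragmentPlan
from .structure_io import StructureModel
from .constants import AA_3TO1

__all__ = [
    "RigidTransform",
    "OverlapSuperposition",
    "StitchReport",
    "kabsch_superpose",
    "superpose_on_overlap",
    "assemble",
    "clash_report",
]

#: overlap Cα-RMSD (Å) above which a junction is flagged as suspicious
RMSD_WARN_THRESHOLD = 5.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation matrix + translation, Å)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ParameterError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ParameterError("rotation matrix is not proper (det != +1)")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class OverlapSuperposition:
    """Result of fitting a fragment onto its neighbour over their overlap."""

    transform: RigidTransform
    rmsd: float  # Å, over paired overlap Cα atoms
    n_atoms: int
    overlap_interval: tuple[int, int]


@dataclass
class StitchReport:
    """Quality-control summary of one assembly run."""

    junction_rmsd: list[float]  # Å, per junction, left-to-right
    crossover_residues: list[int]
    clash_count: int
    total_residues: int

    def to_dict(self) -> dict:
        return {
            "junction_rmsd_A": self.junction_rmsd,
            "crossover_residues": self.crossover_residues,
            "clash_count": self.clash_count,
            "total_residues": self.total_residues,
        }


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid fit of paired point sets (Kabsch).

    Returns the transform minimizing RMSD of ``R @ Q + t`` onto ``P``, with
    reflections excluded (det R = +1), and the minimized RMSD in Å.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ParameterError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise InsufficientAtomsError(f"need >= 3 paired points, got {n}")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    # near-degenerate configurations (collinear points) make the rotation
    # about the point axis unidentifiable
    scale = S[0] if S[0] > 0 else 1.0
    if S[1] / scale < 1e-8:
        warnings.warn("superposition points are nearly collinear", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    rmsd = float(np.sqrt(np.mean(np.sum((Pc - Qc @ R.T) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def superpose_on_overlap(
    ref: StructureModel,
    mov: StructureModel,
    overlap: tuple[int, int],
    trim: int = 0,
) -> OverlapSuperposition:
    """Fit ``mov`` onto ``ref`` using the Cα atoms of the shared overlap.

    Atoms are paired by residue number within ``overlap`` (1-based
    inclusive); residue identity must agree letter-for-letter at every
    shared number. ``trim`` drops that many residues at each overlap end
    before fitting (default 0: the full overlap is used).
    """
    a, b = int(overlap[0]) + trim, int(overlap[1]) - trim
    ref_nums, ref_ca = ref.ca_coords()
    mov_nums, mov_ca = mov.ca_coords()
    ref_map = {int(n): i for i, n in enumerate(ref_nums) if a <= n <= b}
    mov_map = {int(n): i for i, n in enumerate(mov_nums) if a <= n <= b}
    shared = sorted(ref_map.keys() & mov_map.keys())
    if len(shared) < 3:
        raise InsufficientAtomsError(
            f"only {len(shared)} shared overlap Cα residues in [{a},{b}]; need >= 3"
        )

    ref_res = {int(n): str(r) for n, r in zip(ref.residue_number, ref.residue_name)}
    mov_res = {int(n): str(r) for n, r in zip(mov.residue_number, mov.residue_name)}
    for n in shared:
        la = AA_3TO1.get(ref_res[n], "X")
        lb = AA_3TO1.get(mov_res[n], "X")
        if la != lb:
            raise SequenceMismatchError(
                f"overlap sequence mismatch at residue {n}: {la} (reference) vs "
                f"{lb} (moving) — check fragment residue numbering"
            )

    P = ref_ca[[ref_map[n] for n in shared]]
    Q = mov_ca[[mov_map[n] for n in shared]]
    transform, rmsd = kabsch_superpose(P, Q)
    return OverlapSuperposition(
        transform=transform,
        rmsd=rmsd,
        n_atoms=len(shared),
        overlap_interval=(a, b),
    )


def _choose_crossover(
    left: StructureModel,
    right: StructureModel,
    overlap: tuple[int, int],
    splice_rule: str,
) -> int:
    a, b = overlap
    if splice_rule == "midpoint":
        return (a + b) // 2
    if splice_rule == "max_confidence":
        # residues <= c come from the left fragment, > c from the right;
        # pick c maximizing the weaker of the two contributed mean confidences
        def res_conf(model: StructureModel) -> dict[int, float]:
            out: dict[int, float] = {}
            for n, span in model.residue_index().items():
                if a <= n <= b:
                    out[n] = float(model.confidence[span].mean())
            return out

        lc = res_conf(left)
        rc = res_conf(right)
        best_c, best_score = (a + b) // 2, -np.inf
        for c in range(a, b):
            l_vals = [v for n, v in lc.items() if n <= c]
            r_vals = [v for n, v in rc.items() if n > c]
            if not l_vals or not r_vals:
                continue
            score = min(float(np.mean(l_vals)), float(np.mean(r_vals)))
            if score > best_score:
                best_score, best_c = score, c
        return best_c
    raise ParameterError(f"unknown splice rule {splice_rule!r}")


def assemble(
    fragments: list[StructureModel],
    plan: FragmentPlan,
    splice_rule: str = "midpoint",
    trim_overlap: int = 0,
    clash_cutoff: float = 2.0,
) -> tuple[StructureModel, StitchReport]:
    """Superpose and splice planned fragments into one full-length model.

    Fragment 1 defines the global frame. Fragment i+1 is superposed onto the
    already-assembled model over planned overlap i, then the chain is spliced
    at a crossover residue c (``midpoint`` of the overlap, or the
    ``max_confidence`` balance point): residues <= c keep the left-side
    coordinates, residues > c come from the newly placed fragment.
    """
    if len(fragments) != plan.n_fragments:
        raise ParameterError(
            f"plan has {plan.n_fragments} fragments but {len(fragments)} supplied"
        )
    for frag, (a, b) in zip(fragments, plan.intervals):
        if frag is None or len(frag) == 0:
            raise EmptyInputError(f"missing/empty fragment for interval [{a},{b}]")
        nums = frag.residue_numbers()
        if nums.min() < a or nums.max() > b:
            raise ParameterError(
                f"fragment residues [{nums.min()},{nums.max()}] outside planned "
                f"interval [{a},{b}]"
            )

    assembled = fragments[0].copy()
    junction_rmsd: list[float] = []
    crossovers: list[int] = []
    for i in range(1, plan.n_fragments):
        overlap = plan.overlaps()[i - 1]
        sup = superpose_on_overlap(assembled, fragments[i], overlap, trim=trim_overlap)
        if sup.rmsd > RMSD_WARN_THRESHOLD:
            warnings.warn(
                f"junction {i}: overlap RMSD {sup.rmsd:.2f} Å exceeds "
                f"{RMSD_WARN_THRESHOLD} Å — fragments may be incompatible",
                stacklevel=2,
            )
        placed = fragments[i].transformed(sup.transform.rotation, sup.transform.translation)
        c = _choose_crossover(assembled, placed, overlap, splice_rule)
        left_part = assembled.select_residues(1, c)
        right_part = placed.select_residues(c + 1, plan.intervals[i][1])
        assembled = StructureModel.concat([left_part, right_part])
        junction_rmsd.append(sup.rmsd)
        crossovers.append(c)

    clashes = clash_report(assembled, cutoff=clash_cutoff)
    report = StitchReport(
        junction_rmsd=junction_rmsd,
        crossover_residues=crossovers,
        clash_count=len(clashes),
        total_residues=int(assembled.n_residues),
    )
    nums = assembled.residue_numbers()
    if report.total_residues != plan.L or nums[0] != plan.intervals[0][0] or nums[-1] != plan.L:
        warnings.warn(
            f"assembled model covers {report.total_residues} residues, plan expects "
            f"{plan.L}",
            stacklevel=2,
        )
    return assembled, report


def clash_report(
    model: StructureModel,
    cutoff: float = 2.0,
    min_sequence_separation: int = 3,
) -> list[tuple[int, int, float]]:
    """Atom pairs closer than ``cutoff`` Å and >= 3 residues apart in sequence.

    Returns (atom index i, atom index j, distance) triples. A k-d tree keeps
    this near-linear in atom count; bonded and near-bonded contacts (residue
    separation < ``min_sequence_separation``) are excluded.
    """
    if len(model) == 0:
        raise EmptyInputError("clash report on empty model")
    tree = cKDTree(model.coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    out: list[tuple[int, int, float]] = []
    for i, j in pairs:
        if abs(int(model.residue_number[i]) - int(model.residue_number[j])) >= min_sequence_separation:
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            out.append((int(i), int(j), d))
    return out
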