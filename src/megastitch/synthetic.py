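"""Ground-truthed synthetic megaprotein structures for pipeline testing.

Real inputs to the pipeline are structure-predictor outputs, which cannot
be regenerated deterministically at test time. The generator builds the
same *geometry class* the pipeline targets — a long hollow rod with a
hydrophobic lumen — as an explicit helical wall of Cα plus single-sphere
pseudo-side-chain atoms, with every ground-truth quantity (axis, lumen
radius, per-fragment rigid transforms, noise level) recorded alongside.
``fragment_and_perturb`` is the exact inverse of the stitcher: it cuts a
model into planned overlapping fragments and scatters each into its own
random frame, emulating independent per-fragment predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import AA_1TO3, VDW_RADII
from .errors import ParameterError
from .fragment_planner import FragmentPlan
from .stitcher import RigidTransform
from .structure_io import StructureModel
from .tunnel import AxisPolyline

__all__ = ["TubeParams", "SyntheticTruth", "make_tube", "fragment_and_perturb"]

# geometry constants of the generated wall (Å)
CA_RING_OFFSET = 2.5  # Cα ring sits this far outside the inner wall ring
MIN_CA_SPACING = 3.8  # physical minimum for consecutive Cα atoms
CONF_HIGH = 90.0
CONF_LOW = 50.0
CONF_RAMP_RESIDUES = 50  # confidence decays over this many terminal residues


@dataclass(frozen=True)
class TubeParams:
    """Parameters of a synthetic hollow tubular rod.

    ``inner_wall_radius`` is the distance of inner-wall *atom centres* from
    the axis; the open lumen radius is that minus the wall atom's vdW
    radius (carbon, 1.70 Å). ``turns=None`` picks the smallest winding that
    keeps consecutive Cα spacing physical (>= 3.8 Å).
    """

    n_res: int = 900
    length: float = 300.0
    inner_wall_radius: float = 7.7
    turns: int | None = None
    lumen_aa: tuple[str, ...] = ("I", "L", "V")
    outer_aa: tuple[str, ...] = ("D", "E", "K", "R")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParameterError("tube length must be positive")
        if self.inner_wall_radius <= 2.0:
            raise ParameterError("inner_wall_radius must exceed 2 Å")
        if self.n_res < 50:
            raise ParameterError("tube needs at least 50 residues")
        for aa in self.lumen_aa + self.outer_aa:
            if aa not in AA_1TO3:
                raise ParameterError(f"unknown residue letter {aa!r}")

    @property
    def lumen_radius(self) -> float:
        return self.inner_wall_radius - VDW_RADII["C"]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for downstream oracles."""

    axis: AxisPolyline
    lumen_radius: float  # Å
    transforms: list[RigidTransform] | None  # per fragment, None for intact tube
    sigma: float  # Å per-coordinate noise, 0 for intact tube
    seed: int


def _chord_spacing(n_res: int, length: float, radius: float, turns: int) -> float:
    dz = length / (n_res - 1)
    dtheta = 2 * np.pi * turns / (n_res - 1)
    return float(np.hypot(dz, 2 * radius * np.sin(dtheta / 2)))


def _auto_turns(params: TubeParams, ca_radius: float) -> int:
    dz = params.length / (params.n_res - 1)
    if dz >= MIN_CA_SPACING:
        return 1
    arc_needed = np.sqrt(MIN_CA_SPACING**2 - dz**2)
    turns = max(1, int(np.ceil((params.n_res - 1) * arc_needed / (2 * np.pi * ca_radius))))
    while _chord_spacing(params.n_res, params.length, ca_radius, turns) < MIN_CA_SPACING:
        turns += 1
    return turns


def make_tube(params: TubeParams) -> tuple[StructureModel, SyntheticTruth]:
    """Build a hollow helical-wall rod with alternating lumen/outer residues.

    Cα atoms wind about the z axis on a ring of radius
    ``inner_wall_radius + 2.5``; every residue also carries one pseudo
    side-chain sphere ("CB", carbon): even-index residues point it into the
    lumen (centre at ``inner_wall_radius``), odd-index residues point it
    outward. Residue identities are drawn from the respective alphabets
    with the given seed; confidence is 90 everywhere.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_res
    ca_radius = params.inner_wall_radius + CA_RING_OFFSET
    turns = params.turns if params.turns is not None else _auto_turns(params, ca_radius)

    z = np.linspace(0.0, params.length, n)
    theta = 2 * np.pi * turns * np.arange(n) / (n - 1)
    ca = np.column_stack([ca_radius * np.cos(theta), ca_radius * np.sin(theta), z])
    spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if spacing.min() < MIN_CA_SPACING - 1e-9:
        raise ParameterError(
            f"infeasible geometry: consecutive Cα spacing {spacing.min():.2f} Å "
            f"< {MIN_CA_SPACING} Å (increase turns or shorten the tube)"
        )

    lumen_facing = np.arange(n) % 2 == 0
    letters = np.where(
        lumen_facing,
        rng.choice(np.array(params.lumen_aa, dtype=object), size=n),
        rng.choice(np.array(params.outer_aa, dtype=object), size=n),
    )
    cb_radius = np.where(lumen_facing, params.inner_wall_radius, ca_radius + CA_RING_OFFSET)
    cb = np.column_stack([cb_radius * np.cos(theta), cb_radius * np.sin(theta), z])

    n_atoms = 2 * n
    coords = np.empty((n_atoms, 3))
    coords[0::2] = ca
    coords[1::2] = cb
    resnum = np.repeat(np.arange(1, n + 1), 2)
    resname = np.repeat([AA_1TO3[str(aa)] for aa in letters], 2)
    model = StructureModel(
        serial=np.arange(1, n_atoms + 1),
        atom_name=np.array(["CA", "CB"] * n, dtype=object),
        residue_name=np.array(resname, dtype=object),
        chain_id=np.array(["A"] * n_atoms, dtype=object),
        residue_number=resnum,
        coords=coords,
        element=np.array(["C"] * n_atoms, dtype=object),
        confidence=np.full(n_atoms, CONF_HIGH),
    )

    s = np.arange(0.0, params.length + 1e-9, 2.0)
    axis_pts = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    truth = SyntheticTruth(
        axis=AxisPolyline(points=axis_pts, arclength=s),
        lumen_radius=params.lumen_radius,
        transforms=None,
        sigma=0.0,
        seed=params.seed,
    )
    return model, truth


def _random_transform(rng: np.random.Generator, max_translation: float = 100.0) -> RigidTransform:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    R = Rotation.from_quat(quat).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)


def _confidence_ramp(resnums: np.ndarray) -> np.ndarray:
    """Per-atom confidence: 90 in the core, decaying linearly to 50 at ends."""
    lo, hi = resnums.min(), resnums.max()
    dist_to_end = np.minimum(resnums - lo, hi - resnums).astype(float)
    frac = np.clip(dist_to_end / CONF_RAMP_RESIDUES, 0.0, 1.0)
    return CONF_LOW + (CONF_HIGH - CONF_LOW) * frac


def fragment_and_perturb(
    model: StructureModel,
    plan: FragmentPlan,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[StructureModel], SyntheticTruth]:
    """Cut a model into planned fragments, each in a random rigid frame.

    Each fragment keeps its source residue numbering, is moved by an
    independently sampled proper rigid transform (uniform rotation,
    translation within ±100 Å), and receives iid Gaussian coordinate noise
    of ``sigma`` Å per coordinate. Confidence ramps from 90 down to 50 over
    the terminal 50 residues of every fragment, mimicking the predictor
    confidence decay at artificial termini that motivates the overlaps.
    All randomness streams from the single ``seed``.
    """
    nums = model.residue_numbers()
    if plan.intervals[0][0] < nums.min() or plan.L > nums.max():
        raise ParameterError(
            f"plan spans [1,{plan.L}] but model covers [{nums.min()},{nums.max()}]"
        )
    rng = np.random.default_rng(seed)
    fragments: list[StructureModel] = []
    transforms: list[RigidTransform] = []
    for a, b in plan.intervals:
        frag = model.select_residues(a, b)
        tf = _random_transform(rng)
        frag = frag.transformed(tf.rotation, tf.translation)
        if sigma > 0:
            frag.coords = frag.coords + rng.normal(0.0, sigma, size=frag.coords.shape)
        else:
            # keep the rng stream aligned across sigma values so the same
            # seed yields the same transforms regardless of noise level
            rng.normal(0.0, 1.0, size=frag.coords.shape)
        frag.confidence = _confidence_ramp(frag.residue_number)
        fragments.append(frag)
        transforms.append(tf)
    truth = SyntheticTruth(
        axis=None,  # type: ignore[arg-type]
        lumen_radius=float("nan"),
        transforms=transforms,
        sigma=sigma,
        seed=seed,
    )
    return fragments, truth
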