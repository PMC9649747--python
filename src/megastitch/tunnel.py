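"""Rod and tunnel geometry of an assembled model.

Bridge-like lipid transfer proteins are elongated rods with a continuous
hydrophobic conduit running along their inside. This module estimates a
central axis from the Cα trace, computes a HOLE-style maximal-ball radius
profile along that axis (largest sphere centred on the axis that touches no
atom's van der Waals surface), annotates the residues lining the conduit
with their Kyte-Doolittle hydropathy, and models the local radius change
caused by a point substitution (e.g. a glycine-to-glutamate mutation whose
side chain protrudes into the lumen).

The fixed-centre profile is a deterministic, conservative lower bound on
the true pore radius: no Monte-Carlo centre optimization is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    AA_1TO3,
    AA_3TO1,
    KYTE_DOOLITTLE,
    SIDE_CHAIN_SPHERE_OFFSET,
    SIDE_CHAIN_SPHERE_RADII,
)
from .errors import EmptyInputError, InsufficientAtomsError, ParameterError
from .structure_io import StructureModel

__all__ = [
    "AxisPolyline",
    "AxisProfile",
    "MutationSpec",
    "estimate_axis",
    "radius_profile",
    "rod_length",
    "tunnel_summary",
    "mutation_blockage",
]

DEFAULT_AXIS_WINDOW = 50  # residues per sliding-centroid window
DEFAULT_STATION_STEP = 2.0  # Å between resampled axis stations
DEFAULT_SHELL = 3.0  # Å beyond the maximal ball counted as "lining"
DEFAULT_PROBE = 1.4  # Å, water-sized probe for continuity
DEFAULT_MOUTH_FRACTION = 0.05  # arclength excluded at each tunnel mouth
TORTUOSITY_WARN = 2.0  # raw centroid path length / end-to-end distance


@dataclass(frozen=True)
class AxisPolyline:
    """Ordered points (Å) tracing a model's central axis, with arclength."""

    points: np.ndarray  # (m, 3)
    arclength: np.ndarray  # (m,), strictly increasing, starts at 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float).reshape(-1, 3))
        object.__setattr__(self, "arclength", np.asarray(self.arclength, dtype=float))
        if np.any(np.diff(self.arclength) <= 0):
            raise ParameterError("axis arclength must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])


@dataclass
class AxisProfile:
    """Per-station tunnel geometry along an axis."""

    s: np.ndarray  # arclength (Å)
    points: np.ndarray  # (m, 3) station centres
    radius: np.ndarray  # (m,) maximal-ball radius (Å), clamped at 0
    lining_residues: list[np.ndarray]  # residue numbers within radius + shell
    mean_hydropathy: np.ndarray  # (m,), NaN where no lining residue
    blocked: np.ndarray  # (m,) bool, True where the raw radius was negative

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": self.s,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "radius": self.radius,
                "n_lining": [len(r) for r in self.lining_residues],
                "mean_hydropathy": self.mean_hydropathy,
                "blocked": self.blocked,
            }
        )


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution, e.g. MutationSpec(200, 'G', 'E') for G200E."""

    residue_number: int
    from_aa: str
    to_aa: str

    @staticmethod
    def parse(text: str) -> "MutationSpec":
        """Parse compact notation like 'G200E'."""
        text = text.strip().upper()
        if len(text) < 3 or text[0] not in AA_1TO3 or text[-1] not in AA_1TO3:
            raise ParameterError(f"cannot parse mutation {text!r} (expected e.g. G200E)")
        try:
            num = int(text[1:-1])
        except ValueError:
            raise ParameterError(f"cannot parse residue number in {text!r}") from None
        return MutationSpec(num, text[0], text[-1])


# ---------------------------------------------------------------------------
# axis estimation
# ---------------------------------------------------------------------------

def estimate_axis(
    model: StructureModel,
    window: int = DEFAULT_AXIS_WINDOW,
    step: float = DEFAULT_STATION_STEP,
) -> AxisPolyline:
    """Central axis as smoothed sliding-window Cα centroids, resampled evenly.

    Centroids of ``window`` consecutive residues (in residue-number order)
    trace the centre of a possibly curved rod; a width-5 moving average
    removes residual winding, and the polyline is resampled at uniform
    arclength ``step``. A tangled trace (path length far exceeding its
    end-to-end extent) is flagged with a warning.
    """
    _, ca = model.ca_coords()
    n = ca.shape[0]
    if n < 2 * window:
        raise InsufficientAtomsError(
            f"axis estimation needs >= {2 * window} Cα residues, got {n}"
        )
    # sliding-window centroids via cumulative sums
    cs = np.cumsum(np.vstack([np.zeros(3), ca]), axis=0)
    centroids = (cs[window:] - cs[:-window]) / window
    # moving-average smoothing, width 5 (kept inside the valid range)
    w = min(5, centroids.shape[0])
    kernel = np.ones(w) / w
    smoothed = np.column_stack(
        [np.convolve(centroids[:, k], kernel, mode="valid") for k in range(3)]
    )
    seg = np.linalg.norm(np.diff(smoothed, axis=0), axis=1)
    s_raw = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_raw[-1]
    if total <= 0:
        raise InsufficientAtomsError("degenerate axis: all centroids coincide")
    end_to_end = float(np.linalg.norm(smoothed[-1] - smoothed[0]))
    if end_to_end > 0 and total / end_to_end > TORTUOSITY_WARN:
        warnings.warn(
            f"axis tortuosity {total / end_to_end:.2f} exceeds {TORTUOSITY_WARN}; "
            "Cα trace may not follow a rod-like path",
            stacklevel=2,
        )
    # drop duplicate arclength values before interpolation
    keep = np.r_[True, np.diff(s_raw) > 1e-12]
    s_raw, smoothed = s_raw[keep], smoothed[keep]
    s_new = np.arange(0.0, total + 1e-9, step)
    pts = np.column_stack([np.interp(s_new, s_raw, smoothed[:, k]) for k in range(3)])
    return AxisPolyline(points=pts, arclength=s_new)


# ---------------------------------------------------------------------------
# radius profile
# ---------------------------------------------------------------------------

def _station_radii(points: np.ndarray, atom_xyz: np.ndarray, atom_vdw: np.ndarray) -> np.ndarray:
    """Maximal-ball radius at each station (may be negative if inside an atom)."""
    radii = np.empty(points.shape[0])
    chunk = 256
    for lo in range(0, points.shape[0], chunk):
        sub = points[lo : lo + chunk]
        d = np.linalg.norm(sub[:, None, :] - atom_xyz[None, :, :], axis=2) - atom_vdw[None, :]
        radii[lo : lo + chunk] = d.min(axis=1)
    return radii


def radius_profile(
    model: StructureModel,
    axis: AxisPolyline,
    shell: float = DEFAULT_SHELL,
) -> AxisProfile:
    """HOLE-style fixed-centre radius profile along ``axis``.

    At each station the radius is ``min over atoms of (distance to atom
    centre - atom vdW radius)`` — the largest ball centred there touching no
    atom. Residues owning an atom within ``radius + shell`` of the station
    are recorded as lining, and their mean Kyte-Doolittle hydropathy is
    reported (non-standard residues contribute 0). Stations whose raw radius
    is negative (axis passes through an atom) are clamped to 0 and flagged.
    """
    if len(model) == 0:
        raise EmptyInputError("radius profile on empty model")
    lo = model.coords.min(axis=0) - 1e-6
    hi = model.coords.max(axis=0) + 1e-6
    if np.any(axis.points < lo) or np.any(axis.points > hi):
        warnings.warn("axis extends outside the model bounding box", stacklevel=2)

    vdw = model.vdw_radii()
    raw = _station_radii(axis.points, model.coords, vdw)
    blocked = raw < 0
    radius = np.maximum(raw, 0.0)

    lining: list[np.ndarray] = []
    hydro = np.full(axis.points.shape[0], np.nan)
    kd = np.array(
        [KYTE_DOOLITTLE.get(AA_3TO1.get(str(rn), "X"), 0.0) for rn in model.residue_name]
    )
    for i, p in enumerate(axis.points):
        d = np.linalg.norm(model.coords - p, axis=1)
        mask = d <= radius[i] + shell
        res = np.unique(model.residue_number[mask])
        lining.append(res)
        if res.size:
            # mean over unique residues, not atoms
            vals = []
            for rnum in res:
                sel = model.residue_number == rnum
                vals.append(kd[sel][0])
            hydro[i] = float(np.mean(vals))
    return AxisProfile(
        s=axis.arclength.copy(),
        points=axis.points.copy(),
        radius=radius,
        lining_residues=lining,
        mean_hydropathy=hydro,
        blocked=blocked,
    )


def rod_length(model: StructureModel) -> float:
    """End-to-end extent (Å) of the Cα cloud along its first principal axis."""
    _, ca = model.ca_coords()
    if ca.shape[0] < 2:
        raise InsufficientAtomsError("rod length needs >= 2 Cα atoms")
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    return float(proj.max() - proj.min())


def axis_length(axis: AxisPolyline) -> float:
    """Arclength (Å) of the estimated central axis (curved-path length)."""
    return axis.length


@dataclass(frozen=True)
class TunnelSummary:
    continuous: bool
    min_radius: float  # Å, over interior stations
    argmin_s: float  # Å arclength of the narrowest interior station
    mean_lining_hydropathy: float

    def to_dict(self) -> dict:
        return {
            "continuous": self.continuous,
            "min_radius_A": self.min_radius,
            "argmin_s_A": self.argmin_s,
            "mean_lining_hydropathy": self.mean_lining_hydropathy,
        }


def tunnel_summary(
    profile: AxisProfile,
    probe: float = DEFAULT_PROBE,
    mouth_fraction: float = DEFAULT_MOUTH_FRACTION,
) -> TunnelSummary:
    """Continuity verdict over interior stations (tunnel mouths excluded).

    The tunnel is called continuous when every interior station admits the
    probe sphere (radius >= ``probe``); the first and last
    ``mouth_fraction`` of the arclength have no enclosing wall and are
    excluded. A station profile with no interior stations is degenerate and
    reported as not continuous.
    """
    if profile.s.size == 0:
        raise EmptyInputError("empty axis profile")
    total = profile.s[-1] - profile.s[0]
    lo = profile.s[0] + mouth_fraction * total
    hi = profile.s[-1] - mouth_fraction * total
    interior = (profile.s >= lo) & (profile.s <= hi)
    if not np.any(interior):
        return TunnelSummary(False, 0.0, float(profile.s[0]), float("nan"))
    r = profile.radius[interior]
    s = profile.s[interior]
    i_min = int(np.argmin(r))
    hyd = profile.mean_hydropathy[interior]
    return TunnelSummary(
        continuous=bool(np.all(r >= probe)),
        min_radius=float(r[i_min]),
        argmin_s=float(s[i_min]),
        mean_lining_hydropathy=float(np.nanmean(hyd)) if np.any(np.isfinite(hyd)) else float("nan"),
    )


# ---------------------------------------------------------------------------
# point-mutation blockage
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O"}


def _ideal_cb_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Unit Cα->Cβ direction from backbone N, Cα, C (ideal tetrahedral Cα)."""
    u_n = (n - ca) / np.linalg.norm(n - ca)
    u_c = (c - ca) / np.linalg.norm(c - ca)
    bisector = -(u_n + u_c)
    nb = np.linalg.norm(bisector)
    perp = np.cross(u_c, u_n)
    npp = np.linalg.norm(perp)
    if nb < 1e-9 or npp < 1e-9:
        raise ParameterError("degenerate backbone geometry for Cβ construction")
    bisector /= nb
    perp /= npp
    half_tet = np.deg2rad(54.75)  # half the tetrahedral angle
    return np.cos(half_tet) * bisector + np.sin(half_tet) * perp


def _side_chain_anchor(model: StructureModel, resnum: int) -> np.ndarray:
    """Centre for the pseudo-side-chain sphere of a residue."""
    span = model.residue_index().get(resnum)
    if span is None:
        raise ParameterError(f"residue {resnum} not in model")
    names = {str(model.atom_name[i]): model.coords[i] for i in range(span.start, span.stop)}
    if "CA" not in names:
        raise ParameterError(f"residue {resnum} has no CA atom")
    ca = names["CA"]
    if "CB" in names:
        u = names["CB"] - ca
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            raise ParameterError(f"residue {resnum}: CB coincides with CA")
        u = u / nu
    elif {"N", "C"} <= names.keys():
        u = _ideal_cb_direction(names["N"], ca, names["C"])
    else:
        raise ParameterError(
            f"residue {resnum}: no CB and no N/C backbone to construct one"
        )
    return ca + SIDE_CHAIN_SPHERE_OFFSET * u


def mutation_blockage(
    model: StructureModel,
    mut: MutationSpec,
    axis: AxisPolyline | None = None,
    shell: float = DEFAULT_SHELL,
    window_arclength: float = 15.0,
) -> pd.DataFrame:
    """Per-station tunnel radius change caused by a point substitution.

    Both the wild-type and the mutant side chain are modelled as a single
    volume-equivalent sphere placed ``2.4`` Å from Cα along the Cα->Cβ
    direction (constructed with ideal tetrahedral geometry for glycine), so
    the identity substitution is exactly a no-op. Radii are recomputed only
    at stations within ``window_arclength`` Å of the residue's nearest
    station. Columns: s, radius_before, radius_after, delta_radius.
    """
    mut_from = mut.from_aa.upper()
    mut_to = mut.to_aa.upper()
    for aa in (mut_from, mut_to):
        if aa not in AA_1TO3:
            raise ParameterError(f"unknown amino acid {aa!r}")
    span = model.residue_index().get(mut.residue_number)
    if span is None:
        raise ParameterError(f"residue {mut.residue_number} not in model")
    actual = AA_3TO1.get(str(model.residue_name[span.start]), "X")
    if actual != mut_from:
        raise ParameterError(
            f"mutation {mut_from}{mut.residue_number}{mut_to}: model has "
            f"{actual} at {mut.residue_number} — residue numbering may have drifted"
        )

    if axis is None:
        axis = estimate_axis(model)

    centre = _side_chain_anchor(model, mut.residue_number)

    # stations near the mutated residue
    ca_idx = None
    for i in range(span.start, span.stop):
        if str(model.atom_name[i]) == "CA":
            ca_idx = i
            break
    anchor = model.coords[ca_idx] if ca_idx is not None else centre
    s0 = axis.arclength[int(np.argmin(np.linalg.norm(axis.points - anchor, axis=1)))]
    near = np.abs(axis.arclength - s0) <= window_arclength
    pts = axis.points[near]
    s_near = axis.arclength[near]

    # background: all atoms except the mutated residue's side chain
    keep = np.ones(len(model), dtype=bool)
    for i in range(span.start, span.stop):
        if str(model.atom_name[i]) not in _BACKBONE:
            keep[i] = False
    bg_xyz = model.coords[keep]
    bg_vdw = model.vdw_radii()[keep]
    bg = _station_radii(pts, bg_xyz, bg_vdw)

    d_sphere = np.linalg.norm(pts - centre, axis=1)
    before = np.minimum(bg, d_sphere - SIDE_CHAIN_SPHERE_RADII[mut_from])
    after = np.minimum(bg, d_sphere - SIDE_CHAIN_SPHERE_RADII[mut_to])
    before = np.maximum(before, 0.0)
    after = np.maximum(after, 0.0)
    return pd.DataFrame(
        {
            "s": s_near,
            "radius_before": before,
            "radius_after": after,
            "delta_radius": after - before,
        }
    )
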