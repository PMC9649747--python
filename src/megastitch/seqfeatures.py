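"""Sequence-level annotation of membrane-interacting termini.

Covers the classical toolkit for spotting how a rod-shaped lipid-transfer
bridge anchors to its two membranes: sliding-window Kyte-Doolittle
hydropathy and transmembrane-segment calling for the N-terminal membrane
anchor, the Eisenberg hydrophobic moment for C-terminal amphiphilic
patches that lie on a membrane surface, and the polybasic K-x-K-K motif
that binds acidic phosphoinositides (PIP2/PIP3) electrostatically.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

from .constants import KYTE_DOOLITTLE
from .errors import EmptyInputError, ParameterError

__all__ = [
    "FeatureSet",
    "hydropathy_profile",
    "detect_tm_segments",
    "hydrophobic_moment",
    "moment_scan",
    "find_polybasic",
    "molecular_weight",
    "annotate_sequence",
]

DEFAULT_WINDOW = 19
DEFAULT_TM_THRESHOLD = 1.6
DEFAULT_TM_MIN_LEN = 15
DEFAULT_DELTA_DEG = 100.0  # helical twist per residue
DEFAULT_MOMENT_WINDOW = 18


def _hydropathies(seq: str) -> np.ndarray:
    seq = seq.upper()
    vals = np.empty(len(seq))
    n_x = 0
    for i, aa in enumerate(seq):
        if aa == "X":
            vals[i] = 0.0
            n_x += 1
        elif aa in KYTE_DOOLITTLE:
            vals[i] = KYTE_DOOLITTLE[aa]
        else:
            raise ParameterError(f"unknown residue letter {aa!r} at position {i + 1}")
    if n_x:
        warnings.warn(f"{n_x} 'X' residues contribute 0 hydropathy", stacklevel=3)
    return vals


def hydropathy_profile(seq: str, window: int = DEFAULT_WINDOW) -> pd.Series:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    Returns a Series indexed by 1-based *centre* position; positions whose
    full window would overhang a sequence end are undefined and omitted
    (no padding). Requires an odd window no longer than the sequence.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    if len(seq) < window:
        raise ParameterError(f"sequence ({len(seq)}) shorter than window ({window})")
    h = _hydropathies(seq)
    kernel = np.ones(window) / window
    means = np.convolve(h, kernel, mode="valid")
    half = window // 2
    centres = np.arange(half + 1, half + 1 + means.size)
    return pd.Series(means, index=centres, name="hydropathy")


def detect_tm_segments(
    profile: pd.Series,
    threshold: float = DEFAULT_TM_THRESHOLD,
    min_len: int = DEFAULT_TM_MIN_LEN,
) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive profile positions >= threshold.

    Runs shorter than ``min_len`` positions are dropped; each surviving run
    is reported as (start centre, end centre, mean window hydropathy).
    """
    if profile.empty:
        return []
    positions = profile.index.to_numpy()
    above = profile.to_numpy() >= threshold
    segments: list[tuple[int, int, float]] = []
    start = None
    for i in range(len(above) + 1):
        contiguous = (
            i < len(above)
            and above[i]
            and (start is None or positions[i] == positions[i - 1] + 1)
        )
        if contiguous:
            if start is None:
                start = i
        else:
            if start is not None:
                run = slice(start, i)
                if i - start >= min_len:
                    segments.append(
                        (
                            int(positions[run][0]),
                            int(positions[run][-1]),
                            float(profile.to_numpy()[run].mean()),
                        )
                    )
                start = None
            if i < len(above) and above[i]:
                start = i
    return segments


def hydrophobic_moment(seq: str, delta: float = DEFAULT_DELTA_DEG) -> float:
    """Eisenberg hydrophobic moment of a window, per residue.

    Magnitude of ``sum_i h_i * (cos(i*delta), sin(i*delta)) / n`` with h the
    Kyte-Doolittle hydropathies and delta the helical twist per residue in
    degrees (100° for an alpha helix). High values flag amphipathic faces.
    """
    if len(seq) < 1:
        raise EmptyInputError("empty window")
    h = _hydropathies(seq)
    angles = np.deg2rad(delta) * np.arange(len(seq))
    vec = np.array([np.sum(h * np.cos(angles)), np.sum(h * np.sin(angles))])
    return float(np.linalg.norm(vec) / len(seq))


def moment_scan(
    seq: str,
    window: int = DEFAULT_MOMENT_WINDOW,
    delta: float = DEFAULT_DELTA_DEG,
) -> pd.Series:
    """Hydrophobic moment of every window, indexed by 1-based start position."""
    if window < 9:
        raise ParameterError(f"moment window must be >= 9, got {window}")
    if len(seq) < window:
        raise ParameterError(f"sequence ({len(seq)}) shorter than window ({window})")
    vals = [hydrophobic_moment(seq[i : i + window], delta) for i in range(len(seq) - window + 1)]
    return pd.Series(vals, index=np.arange(1, len(vals) + 1), name="moment")


def find_polybasic(seq: str, pattern: str = "K.KK") -> list[tuple[int, str]]:
    """All (overlapping) matches of the polybasic motif, 1-based positions.

    The default K-x-K-K pattern is the phosphoinositide-binding lysine
    cluster; ``.`` matches any residue.
    """
    seq = seq.upper()
    rx = re.compile(f"(?=({pattern}))")
    return [(m.start() + 1, m.group(1)) for m in rx.finditer(seq)]


def molecular_weight(seq: str) -> float:
    """Average molecular weight (Da) of the unmodified peptide.

    Sum of average residue masses plus one water; standard letters only.
    """
    if not seq:
        raise EmptyInputError("cannot compute molecular weight of empty sequence")
    try:
        return float(_bio_molecular_weight(seq.upper(), seq_type="protein"))
    except ValueError as exc:
        raise ParameterError(str(exc)) from exc


@dataclass
class FeatureSet:
    """Terminal membrane-interaction features of a sequence."""

    sequence_length: int
    molecular_weight_da: float
    tm_segments: list[tuple[int, int, float]]
    amphiphilic_windows: list[tuple[int, int, float]]  # (start, end, moment)
    polybasic_sites: list[tuple[int, str]]
    region: tuple[int, int] | None = None  # restriction applied, if any

    def to_dict(self) -> dict:
        return {
            "sequence_length": self.sequence_length,
            "molecular_weight_da": self.molecular_weight_da,
            "molecular_weight_kda": round(self.molecular_weight_da / 1000.0),
            "tm_segments": [list(seg) for seg in self.tm_segments],
            "amphiphilic_windows": [list(w) for w in self.amphiphilic_windows],
            "polybasic_sites": [list(site) for site in self.polybasic_sites],
            "region": list(self.region) if self.region else None,
        }


def annotate_sequence(
    seq: str,
    tm_region: tuple[int, int] | None = None,
    amphiphilic_region: tuple[int, int] | None = None,
    window: int = DEFAULT_WINDOW,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
    tm_min_len: int = DEFAULT_TM_MIN_LEN,
    moment_window: int = DEFAULT_MOMENT_WINDOW,
    top_windows: int = 3,
) -> FeatureSet:
    """Annotate TM segments, amphiphilic windows and polybasic sites.

    Optional ``tm_region`` / ``amphiphilic_region`` (1-based inclusive)
    confine the scans to stated terminal regions; positions in the result
    are always in full-sequence coordinates. Polybasic sites are always
    scanned genome-wide (the motif is only four residues).
    """
    seq = seq.upper()
    if not seq:
        raise EmptyInputError("empty sequence")

    def _sub(region: tuple[int, int] | None) -> tuple[str, int]:
        if region is None:
            return seq, 0
        a, b = region
        if not (1 <= a <= b <= len(seq)):
            raise ParameterError(f"region {region} outside [1, {len(seq)}]")
        return seq[a - 1 : b], a - 1

    tm_seq, tm_off = _sub(tm_region)
    tm_segments: list[tuple[int, int, float]] = []
    if len(tm_seq) >= window:
        prof = hydropathy_profile(tm_seq, window=window)
        tm_segments = [
            (a + tm_off, b + tm_off, m)
            for a, b, m in detect_tm_segments(prof, tm_threshold, tm_min_len)
        ]

    amp_seq, amp_off = _sub(amphiphilic_region)
    amphiphilic: list[tuple[int, int, float]] = []
    if len(amp_seq) >= moment_window:
        scan = moment_scan(amp_seq, window=moment_window)
        best = scan.sort_values(ascending=False).head(top_windows)
        amphiphilic = [
            (int(start) + amp_off, int(start) + amp_off + moment_window - 1, float(m))
            for start, m in best.items()
        ]

    return FeatureSet(
        sequence_length=len(seq),
        molecular_weight_da=molecular_weight(seq),
        tm_segments=tm_segments,
        amphiphilic_windows=amphiphilic,
        polybasic_sites=find_polybasic(seq),
        region=amphiphilic_region,
    )
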