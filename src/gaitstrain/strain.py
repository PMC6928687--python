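"""Garment strain field from marker-grid trajectories.

Candidate sensor positions are neighboring marker pairs in vertical,
horizontal and both diagonal orientations. Strain per candidate is
``(max(L, 4 cm) - L0) / L0`` where ``L`` is the 3-D marker distance and
``L0`` the neutral standing distance: distances shorter than 4 cm mean the
fabric has wrinkled and carry no mechanical signal, so they are clamped.
Candidates that never reach 10% peak strain during running are discarded —
a real sensor sewn there would produce almost no signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import MarkerGridSeries

__all__ = [
    "WRINKLE_LIMIT_CM",
    "MIN_PEAK_STRAIN",
    "CandidatePosition",
    "StrainMatrix",
    "enumerate_candidates",
    "compute_strain",
    "filter_candidates",
    "select_top_candidates",
]

WRINKLE_LIMIT_CM = 4.0
MIN_PEAK_STRAIN = 0.10

_ORIENTATION_STEPS = {
    "vertical": (1, 0),
    "horizontal": (0, 1),
    "diagonal_1": (1, 1),
    "diagonal_2": (1, -1),
}


@dataclass(frozen=True)
class CandidatePosition:
    """One candidate sensor position: a neighboring marker pair."""

    pair_id: str
    marker_a: int
    marker_b: int
    orientation: str
    l0: float  # cm, neutral distance

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATION_STEPS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.l0 < WRINKLE_LIMIT_CM:
            raise ValueError(
                f"neutral distance {self.l0:.2f} cm below the "
                f"{WRINKLE_LIMIT_CM} cm wrinkle limit"
            )


@dataclass(frozen=True)
class StrainMatrix:
    """Time x candidate strain values for one participant/speed."""

    strains: np.ndarray  # (frames, n_candidates), unitless
    candidates: tuple[CandidatePosition, ...]
    participant_id: str = ""
    speed: float = float("nan")

    @property
    def n_frames(self) -> int:
        return self.strains.shape[0]

    @property
    def peak_strains(self) -> np.ndarray:
        """Per-candidate maximum strain over the trial."""
        return self.strains.max(axis=0)


def enumerate_candidates(
    grid_rows: int, grid_cols: int, neutral: np.ndarray
) -> list[CandidatePosition]:
    """Every neighboring marker pair in the four orientations.

    ``neutral`` is the (rows*cols, 3) standing-posture marker array, indexed
    row-major. Interior markers participate in 8 pairs.
    """
    neutral = np.asarray(neutral, dtype=float)
    if neutral.shape[0] != grid_rows * grid_cols:
        raise ValueError(
            f"neutral has {neutral.shape[0]} markers, grid is "
            f"{grid_rows} x {grid_cols}"
        )
    out: list[CandidatePosition] = []
    for orientation, (dr, dc) in _ORIENTATION_STEPS.items():
        for r in range(grid_rows):
            for c in range(grid_cols):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < grid_rows and 0 <= c2 < grid_cols):
                    continue
                a = r * grid_cols + c
                b = r2 * grid_cols + c2
                l0 = float(np.linalg.norm(neutral[a] - neutral[b]))
                out.append(
                    CandidatePosition(
                        pair_id=f"{orientation}_r{r}c{c}",
                        marker_a=a,
                        marker_b=b,
                        orientation=orientation,
                        l0=l0,
                    )
                )
    return out


def compute_strain(
    grid: MarkerGridSeries, candidates: list[CandidatePosition] | tuple[CandidatePosition, ...]
) -> StrainMatrix:
    """Strain time series per candidate with the 4 cm wrinkle clamp.

    strain(t) = (max(L(t), 4) - L0) / L0, L in cm.
    """
    pos = np.asarray(grid.positions, dtype=float)
    if pos.ndim != 3 or not np.all(np.isfinite(pos)):
        raise ValueError("marker positions must be a finite (frames, markers, 3) array")
    ia = np.array([c.marker_a for c in candidates])
    ib = np.array([c.marker_b for c in candidates])
    l0 = np.array([c.l0 for c in candidates])
    dist = np.linalg.norm(pos[:, ia, :] - pos[:, ib, :], axis=2)
    dist = np.maximum(dist, WRINKLE_LIMIT_CM)
    strains = (dist - l0) / l0
    return StrainMatrix(
        strains=strains,
        candidates=tuple(candidates),
        participant_id=grid.participant_id,
        speed=grid.speed,
    )


def filter_candidates(
    strains: StrainMatrix, min_peak: float = MIN_PEAK_STRAIN
) -> StrainMatrix:
    """Keep candidates whose peak strain reaches ``min_peak`` (inclusive).

    Order is preserved. If nothing survives, an empty matrix is returned
    with a warning.
    """
    if len(strains.candidates) == 0:
        raise ValueError("strain matrix has no candidates")
    keep = strains.peak_strains >= min_peak
    if not keep.any():
        warnings.warn("no candidate reaches the minimum peak strain", stacklevel=2)
    kept = tuple(c for c, k in zip(strains.candidates, keep) if k)
    return replace(strains, strains=strains.strains[:, keep], candidates=kept)


def select_top_candidates(
    strain_matrices: list[StrainMatrix],
    n_select: int = 40,
    min_peak: float = MIN_PEAK_STRAIN,
) -> list[int]:
    """Reduce enumerated pairs to the fixed candidate pool for optimization.

    A candidate survives only if its peak strain reaches ``min_peak`` in
    every trial of the placement dataset (strictest reading of the 10%
    rule: no speed-dependent candidate sets); the pool is the ``n_select``
    survivors with the highest worst-case (minimum over trials) peak strain.
    Returns indices into the shared candidate list.
    """
    if not strain_matrices:
        raise ValueError("need at least one strain matrix")
    cands = strain_matrices[0].candidates
    for sm in strain_matrices[1:]:
        if sm.candidates != cands:
            raise ValueError("strain matrices have mismatched candidate lists")
    peaks = np.stack([sm.peak_strains for sm in strain_matrices], axis=0)
    worst = peaks.min(axis=0)
    survivors = np.flatnonzero(worst >= min_peak)
    if survivors.size < n_select:
        warnings.warn(
            f"only {survivors.size} candidates survive the {min_peak:.0%} rule; "
            f"returning all of them",
            stacklevel=2,
        )
        order = survivors[np.argsort(-worst[survivors], kind="stable")]
        return [int(i) for i in order]
    order = survivors[np.argsort(-worst[survivors], kind="stable")][:n_select]
    return sorted(int(i) for i in order)
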