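"""Ready-made experiment builders for sensor-placement studies.

Couples the gait simulator, the marker-grid strain field and the placement
optimizers into the experiments a placement study actually runs: build a
multi-runner placement dataset with known informative positions, then ask
an optimizer to recover them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .placement import PrecomputedLOPO
from .strain import compute_strain, enumerate_candidates, select_top_candidates
from .synthetic import (
    GridModel,
    ProtocolSpec,
    sample_profile,
    simulate_joint_angles,
    simulate_marker_grid,
)

__all__ = ["PlacementDataset", "build_placement_dataset"]


@dataclass(frozen=True)
class PlacementDataset:
    """Per-participant strain matrices over a common candidate pool."""

    strains: list  # per participant: (frames, n_candidates)
    hip_angles: list  # per participant: (frames, 3) degrees
    candidate_indices: list  # indices into the full enumerated pair list
    candidates: tuple  # CandidatePosition objects of the pool
    true_indices: tuple[int, ...]  # pool positions of the informative pairs

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_indices)

    def objective(self) -> PrecomputedLOPO:
        """The leave-one-person-out OLS objective over this dataset."""
        return PrecomputedLOPO(self.strains, self.hip_angles)


def build_placement_dataset(
    n_participants: int = 5,
    speeds: tuple[float, ...] = (8.0, 10.0, 12.0),
    duration: float = 10.0,
    grid_model: GridModel | None = None,
    n_candidates: int = 40,
    seed: int = 0,
) -> PlacementDataset:
    """Simulate the marker-grid placement study for a virtual cohort.

    Every participant runs each speed once while the pelvis marker grid is
    tracked; garment strains are computed for all neighbor pairs, reduced to
    the ``n_candidates`` positions that strain at least 10% in every trial
    (ranked by worst-case peak strain), and stacked across speeds per
    participant. The returned dataset records where the generator's
    designated informative pairs landed in the candidate pool.
    """
    gm = grid_model or GridModel()
    protocol = ProtocolSpec(speeds=speeds, trial_duration=duration, repeats=1)
    root = np.random.SeedSequence(seed)
    all_candidates = enumerate_candidates(gm.grid_rows, gm.grid_cols, gm.neutral_grid())

    strain_mats = []  # flat list over (participant, speed)
    hip_per_participant = []
    per_participant_slices = []
    informative_pairs = None
    for pseed in root.spawn(n_participants):
        profile_ss, *trial_ss = pseed.spawn(1 + len(speeds))
        profile = sample_profile(np.random.default_rng(profile_ss), "placement")
        hips = []
        start = len(strain_mats)
        for i, speed in enumerate(speeds):
            rng = np.random.default_rng(trial_ss[i])
            ja = simulate_joint_angles(profile, speed, i, protocol, rng)
            grid = simulate_marker_grid(ja, gm, rng, sample_rate=protocol.sample_rate)
            informative_pairs = grid.informative_pairs
            strain_mats.append(compute_strain(grid, all_candidates))
            hips.append(ja.angles[:, :3])
        per_participant_slices.append(slice(start, len(strain_mats)))
        hip_per_participant.append(np.vstack(hips))

    pool = select_top_candidates(strain_mats, n_select=n_candidates)
    pool_candidates = tuple(all_candidates[i] for i in pool)

    pair_to_pool = {
        (c.marker_a, c.marker_b): j for j, c in enumerate(pool_candidates)
    }
    true_idx = tuple(
        pair_to_pool[pair] for pair in informative_pairs if pair in pair_to_pool
    )

    strains_per_participant = [
        np.vstack([strain_mats[i].strains[:, pool] for i in range(s.start, s.stop)])
        for s in per_participant_slices
    ]
    return PlacementDataset(
        strains=strains_per_participant,
        hip_angles=hip_per_participant,
        candidate_indices=list(pool),
        candidates=pool_candidates,
        true_indices=true_idx,
    )
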