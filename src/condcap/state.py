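"""In-memory containers for instantaneous and time-resolved configurations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SystemState", "Trajectory"]


@dataclass
class SystemState:
    """Instantaneous rigid-body configuration of N subunits.

    Centers are wrapped into the box ``[-L/2, L/2)^3``; ``images`` counts
    box crossings so that ``centers + L * images`` is the unwrapped
    coordinate (used for diffusion measurements).  Orientations are unit
    quaternions (scalar first); angular momenta are body-frame.
    """

    centers: np.ndarray          # (N, 3)
    orientations: np.ndarray     # (N, 4)
    velocities: np.ndarray       # (N, 3)
    angular_momenta: np.ndarray  # (N, 3) body frame
    box_L: float
    time: float = 0.0
    rng_seed: int | None = None
    images: np.ndarray | None = None  # (N, 3) integer box crossings

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.images is None:
            self.images = np.zeros_like(self.centers, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.centers)

    @property
    def unwrapped(self) -> np.ndarray:
        return self.centers + self.box_L * self.images

    def validate(self, tol: float = 1e-8) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=tol):
            raise ValueError("orientations are not unit quaternions")
        half = self.box_L / 2.0
        if np.any(self.centers < -half) or np.any(self.centers >= half):
            raise ValueError("centers are not wrapped into [-L/2, L/2)")

    def copy(self) -> "SystemState":
        return SystemState(
            centers=self.centers.copy(),
            orientations=self.orientations.copy(),
            velocities=self.velocities.copy(),
            angular_momenta=self.angular_momenta.copy(),
            box_L=self.box_L,
            time=self.time,
            rng_seed=self.rng_seed,
            images=self.images.copy(),
        )


@dataclass
class Trajectory:
    """A time-ordered sequence of snapshots plus run metadata."""

    frames: list[SystemState] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> SystemState:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])
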