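"""Kinetic schemes and simulation configuration for smFRET binding traces.

A :class:`KineticScheme` is a continuous-time Markov chain over one unbound
state ("U", apparent FRET 0) and one or more bound states (the polymerase
binding conformations, each with its own apparent-FRET mean).  Binding is
pseudo-first-order: the protein concentration is folded into the U->bound
entry rates.  :class:`Photophysics` holds the fluorescence rendering
parameters, and :class:`SimConfig` bundles everything needed to simulate a
dataset reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNBOUND = "U"

__all__ = [
    "UNBOUND",
    "KineticScheme",
    "Photophysics",
    "SimConfig",
    "GroundTruth",
]


@dataclass(frozen=True)
class KineticScheme:
    """CTMC over one unbound and >=1 bound states.

    Parameters
    ----------
    state_names
        Labels; must contain exactly one ``"U"``.
    fret_mean
        Per-state apparent-FRET mean in [0, 1]; ``fret_mean`` of U must be 0.
    rate_matrix
        ``(n, n)`` array of first-order transition rates (per second) between
        states, including dissociation (bound -> U) and sub-state
        interconversion.  The diagonal is ignored (derived as the negative
        row sum).
    """

    state_names: tuple[str, ...]
    fret_mean: np.ndarray
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.state_names)
        object.__setattr__(self, "state_names", names)
        fret = np.asarray(self.fret_mean, dtype=float)
        rates = np.asarray(self.rate_matrix, dtype=float)
        object.__setattr__(self, "fret_mean", fret)
        object.__setattr__(self, "rate_matrix", rates)
        n = len(names)
        if names.count(UNBOUND) != 1:
            raise ValueError("scheme must contain exactly one unbound state 'U'")
        if fret.shape != (n,):
            raise ValueError("fret_mean must have one entry per state")
        if rates.shape != (n, n):
            raise ValueError("rate_matrix must be square with one row per state")
        off_diag = rates[~np.eye(n, dtype=bool)]
        if np.any(off_diag < 0) or not np.all(np.isfinite(off_diag)):
            raise ValueError("transition rates must be finite and >= 0")
        if fret[self.unbound_index] != 0.0:
            raise ValueError("fret_mean of the unbound state must be 0")
        if np.any((fret < 0) | (fret > 1)):
            raise ValueError("fret_mean values must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def unbound_index(self) -> int:
        return self.state_names.index(UNBOUND)

    @property
    def bound_indices(self) -> list[int]:
        u = self.unbound_index
        return [i for i in range(self.n_states) if i != u]

    @property
    def koff_per_state(self) -> dict[str, float]:
        """Dissociation rate (bound -> U) of each bound state."""
        u = self.unbound_index
        return {self.state_names[i]: float(self.rate_matrix[i, u]) for i in self.bound_indices}

    def exit_rate(self, state: int) -> float:
        """Total exit rate from ``state`` (negative CTMC diagonal)."""
        row = self.rate_matrix[state].copy()
        row[state] = 0.0
        return float(row.sum())

    def index(self, name: str) -> int:
        return self.state_names.index(name)


@dataclass(frozen=True)
class Photophysics:
    """Fluorescence rendering parameters.

    ``total_intensity`` is the mean detected counts per frame summed over
    both channels while the donor is active; ``shot_noise_scale`` converts
    signal above background into Poisson-like variance (Gaussian
    approximation).  Bleach rates are per second; a rate of 0 means the dye
    never bleaches.
    """

    total_intensity: float = 500.0
    background: float = 50.0
    read_noise_sd: float = 30.0
    shot_noise_scale: float = 1.0
    donor_bleach_rate: float = 0.01
    acceptor_bleach_rate: float = 0.003

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        for name in ("background", "read_noise_sd", "shot_noise_scale",
                     "donor_bleach_rate", "acceptor_bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    scheme: KineticScheme
    photophysics: Photophysics = field(default_factory=Photophysics)
    frame_interval: float = 0.08
    n_molecules: int = 100
    max_duration: float = 60.0
    rng_seed: int = 0
    scenario_label: str = ""

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.max_duration < self.frame_interval:
            raise ValueError("max_duration must cover at least one frame")


@dataclass(frozen=True)
class GroundTruth:
    """Per-molecule simulation truth: the continuous-time state path
    (``(state_name, entry_time)`` pairs, first entry at t = 0), the bleach
    time of each dye, and the config that produced it."""

    molecule_id: str
    path: tuple[tuple[str, float], ...]
    donor_bleach: float
    acceptor_bleach: float
    config: SimConfig

    def __post_init__(self) -> None:
        times = [t for _, t in self.path]
        if not times or times[0] != 0.0:
            raise ValueError("state path must start at t = 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("state entry times must be strictly increasing")

    def state_at(self, t: float) -> str:
        """State occupied at time ``t`` (ignoring bleaching)."""
        idx = 0
        for i, (_, entry) in enumerate(self.path):
            if entry <= t:
                idx = i
            else:
                break
        return self.path[idx][0]
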