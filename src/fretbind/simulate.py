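"""Stochastic simulation of Cy3/Cy5 intensity traces with known ground truth.

The generator emulates a surface-immobilized-DNA TIRF experiment in which a
Cy5-labeled polymerase binds a Cy3-labeled primer-template: unbound epochs
sit at 0 FRET, bound epochs shuttle between conformational sub-states with
distinct FRET means, and the informative trace ends when the donor
photobleaches (both channels drop to baseline in one step).

Pipeline: :func:`gillespie_path` draws the continuous-time state path,
:func:`sample_bleach_times` the dye lifetimes, :func:`render_trace` turns
both into noisy per-frame donor/acceptor intensities, and
:func:`simulate_dataset` runs the lot over independent per-molecule RNG
sub-streams.
"""

from __future__ import annotations

import numpy as np

from .scheme import UNBOUND, GroundTruth, KineticScheme, Photophysics, SimConfig
from .traces import IntensityTrace

__all__ = [
    "gillespie_path",
    "sample_bleach_times",
    "render_trace",
    "simulate_dataset",
]


def gillespie_path(
    scheme: KineticScheme,
    max_duration: float,
    rng: np.random.Generator,
    start_state: str = UNBOUND,
) -> list[tuple[str, float]]:
    """Simulate one continuous-time state path by the Gillespie algorithm.

    The path starts in ``start_state`` at t = 0; the holding time in each
    state is exponential with the state's total exit rate and the successor
    is chosen proportionally to the individual rates.  A state with zero
    exit rate is absorbing: the path ends there, spanning ``max_duration``.

    Returns a list of ``(state_name, entry_time)`` pairs.
    """
    if max_duration <= 0:
        raise ValueError("max_duration must be > 0")
    state = scheme.index(start_state)
    t = 0.0
    path = [(scheme.state_names[state], 0.0)]
    n = scheme.n_states
    while True:
        rates = scheme.rate_matrix[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total <= 0.0:
            break  # absorbing state: epoch spans the rest of the trace
        t += rng.exponential(1.0 / total)
        if t >= max_duration:
            break
        state = int(rng.choice(n, p=rates / total))
        path.append((scheme.state_names[state], t))
    return path


def sample_bleach_times(
    photophysics: Photophysics, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (donor, acceptor) photobleach times; a zero rate never bleaches."""

    def draw(rate: float) -> float:
        return rng.exponential(1.0 / rate) if rate > 0 else np.inf

    return draw(photophysics.donor_bleach_rate), draw(photophysics.acceptor_bleach_rate)


def _segment_emissions(
    path: list[tuple[str, float]],
    fret_of: dict[str, float],
    donor_bleach: float,
    acceptor_bleach: float,
    duration: float,
) -> list[tuple[float, float, float, float]]:
    """Split [0, duration) at state changes and bleach events.

    Returns ``(t0, t1, frac_acceptor, frac_donor)`` segments where the
    fractions are of ``total_intensity`` above background: while both dyes
    live, (E, 1-E); acceptor dark but donor alive, (0, 1); donor dark,
    (0, 0).  Donor bleach silences both channels (FRET requires an excited
    donor).
    """
    cuts = {0.0, duration}
    cuts.update(t for _, t in path if 0.0 < t < duration)
    for b in (donor_bleach, acceptor_bleach):
        if 0.0 < b < duration:
            cuts.add(b)
    edges = sorted(cuts)
    entries = [t for _, t in path]
    states = [s for s, _ in path]
    segments = []
    for t0, t1 in zip(edges, edges[1:]):
        mid = 0.5 * (t0 + t1)
        i = np.searchsorted(entries, mid, side="right") - 1
        e = fret_of[states[i]]
        if mid >= donor_bleach:
            fa, fd = 0.0, 0.0
        elif mid >= acceptor_bleach:
            fa, fd = 0.0, 1.0
        else:
            fa, fd = e, 1.0 - e
        segments.append((t0, t1, fa, fd))
    return segments


def render_trace(
    path: list[tuple[str, float]],
    bleach_times: tuple[float, float],
    photophysics: Photophysics,
    frame_interval: float,
    rng: np.random.Generator,
    scheme: KineticScheme,
    max_duration: float,
    molecule_id: str = "mol",
) -> IntensityTrace:
    """Integrate a state path into noisy per-frame donor/acceptor counts.

    Per frame the time-weighted mean emission over the frame's occupancy is
    computed, so a frame split between states carries the occupancy-weighted
    FRET.  Additive Gaussian noise has per-channel variance
    ``read_noise_sd**2 + shot_noise_scale * (signal - background)``.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    n_frames = int(np.floor(max_duration / frame_interval + 1e-9))
    if n_frames < 1:
        raise ValueError("path must cover at least one full frame")
    duration = n_frames * frame_interval
    donor_bleach, acceptor_bleach = bleach_times
    fret_of = dict(zip(scheme.state_names, scheme.fret_mean))

    acc = np.zeros(n_frames)
    don = np.zeros(n_frames)
    for t0, t1, fa, fd in _segment_emissions(path, fret_of, donor_bleach,
                                             acceptor_bleach, duration):
        first = int(np.floor(t0 / frame_interval + 1e-12))
        last = min(int(np.ceil(t1 / frame_interval - 1e-12)), n_frames)
        for f in range(first, last):
            lo = max(t0, f * frame_interval)
            hi = min(t1, (f + 1) * frame_interval)
            if hi > lo:
                w = (hi - lo) / frame_interval
                acc[f] += w * fa
                don[f] += w * fd

    ph = photophysics
    acc_signal = acc * ph.total_intensity
    don_signal = don * ph.total_intensity
    acc_noiseless = acc_signal + ph.background
    don_noiseless = don_signal + ph.background
    var_a = ph.read_noise_sd**2 + ph.shot_noise_scale * acc_signal
    var_d = ph.read_noise_sd**2 + ph.shot_noise_scale * don_signal
    acceptor = acc_noiseless + rng.standard_normal(n_frames) * np.sqrt(var_a)
    donor = don_noiseless + rng.standard_normal(n_frames) * np.sqrt(var_d)
    return IntensityTrace(
        molecule_id=molecule_id,
        frame_interval=frame_interval,
        donor=donor,
        acceptor=acceptor,
    )


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    """Simulate ``config.n_molecules`` traces with ground truth.

    Each molecule gets an independent RNG sub-stream seeded by
    ``(rng_seed, molecule_index)``, so outputs are bit-reproducible and
    changing ``n_molecules`` never reshuffles earlier molecules.
    """
    traces: list[IntensityTrace] = []
    truths: list[GroundTruth] = []
    for i in range(config.n_molecules):
        rng = np.random.default_rng([config.rng_seed, i])
        mol_id = f"mol{i:04d}"
        path = gillespie_path(config.scheme, config.max_duration, rng)
        bleach = sample_bleach_times(config.photophysics, rng)
        trace = render_trace(
            path, bleach, config.photophysics, config.frame_interval, rng,
            config.scheme, config.max_duration, molecule_id=mol_id,
        )
        traces.append(trace)
        truths.append(GroundTruth(
            molecule_id=mol_id,
            path=tuple(path),
            donor_bleach=bleach[0],
            acceptor_bleach=bleach[1],
            config=config,
        ))
    return traces, truths
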