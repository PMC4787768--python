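"""Raw intensity traces and their conversion to apparent-FRET trajectories.

Apparent FRET is E_app = I_A / (I_A + I_D) on background-subtracted
intensities.  Processing order in the pipeline: photobleach detection and
truncation, FRET computation with validity filtering, then moving-average
smoothing (window 3 or 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityTrace",
    "FretTrajectory",
    "compute_fret",
    "detect_photobleach",
    "smooth",
    "read_traces_tsv",
    "write_traces_tsv",
    "read_traces_hdf5",
    "write_traces_hdf5",
    "TraceFormatError",
]


class TraceFormatError(ValueError):
    """Malformed trace file (missing columns, bad frame indexing, ...)."""


@dataclass
class IntensityTrace:
    """Per-frame donor (Cy3) and acceptor (Cy5) intensities for one molecule."""

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must be equal-length 1-D series")
        if len(self.donor) < 1:
            raise ValueError("trace must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval


@dataclass
class FretTrajectory:
    """Apparent-FRET series with a validity mask.

    ``fret`` is meaningful only where ``valid_mask`` is True (frames after
    the photobleach, below the total-intensity floor, or with artifactual
    FRET are invalid).  Valid values are clamped to [0, 1].
    """

    molecule_id: str
    frame_interval: float
    fret: np.ndarray
    valid_mask: np.ndarray
    smoothing_window: int = 1
    bleach_frame: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fret = np.asarray(self.fret, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.fret.shape != self.valid_mask.shape:
            raise ValueError("fret and valid_mask must have equal length")
        if self.smoothing_window not in (1, 3, 5):
            raise ValueError("smoothing_window must be 1, 3 or 5")

    def __len__(self) -> int:
        return len(self.fret)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_values(self) -> np.ndarray:
        return self.fret[self.valid_mask]


def compute_fret(
    trace: IntensityTrace,
    background_d: float = 0.0,
    background_a: float = 0.0,
    total_floor: float | None = None,
    bleach_frame: int | None = None,
) -> FretTrajectory:
    """Apparent FRET per frame with validity filtering.

    E_app = (I_A - bg_A) / ((I_A - bg_A) + (I_D - bg_D)).  Frames are marked
    invalid when (a) at/after ``bleach_frame``, (b) the background-subtracted
    total falls below ``total_floor`` (default: 25% of the median pre-bleach
    total — this excludes donor-only tails after acceptor bleach, which would
    otherwise masquerade as FRET ~ 0), or (c) E_app falls outside
    [-0.1, 1.1] (treated as artifact, not clamped, to avoid biasing
    histograms).  Surviving values are clamped to [0, 1].
    """
    if not (np.isfinite(background_d) and np.isfinite(background_a)):
        raise ValueError("backgrounds must be finite")
    d = trace.donor - background_d
    a = trace.acceptor - background_a
    total = d + a

    n = len(trace)
    pre_bleach = np.ones(n, dtype=bool)
    if bleach_frame is not None:
        pre_bleach[bleach_frame:] = False

    if total_floor is None:
        ref = total[pre_bleach]
        total_floor = 0.25 * float(np.median(ref)) if ref.size else np.inf

    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total != 0, a / total, np.nan)
    valid = pre_bleach & (total >= total_floor) & np.isfinite(e)
    valid &= (e >= -0.1) & (e <= 1.1)
    fret = np.where(valid, np.clip(e, 0.0, 1.0), np.nan)

    if not valid.any():
        logger.warning("molecule %s: no valid FRET frames", trace.molecule_id)
    return FretTrajectory(
        molecule_id=trace.molecule_id,
        frame_interval=trace.frame_interval,
        fret=fret,
        valid_mask=valid,
        bleach_frame=bleach_frame,
    )


def detect_photobleach(
    trace: IntensityTrace,
    background_d: float = 0.0,
    background_a: float = 0.0,
    threshold_sd: float = 3.0,
) -> int | None:
    """Find the one-step donor photobleach: the first frame from which the
    total intensity stays at the tail baseline for the rest of the trace.

    The detector is self-calibrating and needs no prior background level:
    the tail baseline comes from the last frames, the signal level from the
    95th percentile of the total, and the noise scale robustly from first
    differences (MAD-based).  The threshold sits ``threshold_sd`` noise
    units above the baseline (at least a quarter of the drop, so a slow
    baseline estimate cannot defeat a large step).  Occasional post-bleach
    noise excursions are tolerated (98% of the tail must be below).
    Returns ``None`` when the trace never drops to a sustained baseline.
    """
    total = (trace.donor - background_d) + (trace.acceptor - background_a)
    n = len(total)
    if n < 3:
        return None
    diffs = np.diff(total)
    sigma = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2.0)
    sigma = max(sigma, 1e-12)
    baseline = float(np.median(total[-min(5, n):]))
    if n >= 5:
        from scipy.signal import medfilt
        signal = float(medfilt(total, 5).max())  # robust to short bright spans
    else:
        signal = float(np.median(total))
    if signal - baseline < 2 * threshold_sd * sigma:
        return None  # no sustained drop
    threshold = baseline + max(threshold_sd * sigma, 0.25 * (signal - baseline))
    below = total < threshold
    if not below[-1]:
        return None
    # first frame whose suffix stays below (isolated noise blips tolerated)
    suffix_frac = np.cumsum(below[::-1])[::-1] / np.arange(n, 0, -1)
    ok = below & (suffix_frac >= 0.98)
    candidates = np.nonzero(ok)[0]
    if candidates.size == 0:
        return None
    bleach = int(candidates[0])
    return bleach if bleach < n else None


def smooth(traj: FretTrajectory, window: int = 5) -> FretTrajectory:
    """Centered moving average over valid frames only.

    Invalid frames stay invalid and do not contribute to their neighbors'
    averages; edges use the truncated window.  Constant series are fixed
    points.
    """
    if window not in (3, 5):
        raise ValueError("smoothing window must be 3 or 5")
    valid = traj.valid_mask
    filled = np.where(valid, traj.fret, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(counts > 0, sums / counts, np.nan)
    fret = np.where(valid, sm, np.nan)
    return replace(traj, fret=fret, smoothing_window=window)


# ---------------------------------------------------------------------------
# I/O: tab-separated text and HDF5 container
# ---------------------------------------------------------------------------

_COLUMNS = ["molecule_id", "frame", "time_s", "donor", "acceptor"]


def write_traces_tsv(traces: list[IntensityTrace], path) -> None:
    import pandas as pd

    frames = []
    for tr in traces:
        idx = np.arange(len(tr))
        frames.append(pd.DataFrame({
            "molecule_id": tr.molecule_id,
            "frame": idx,
            "time_s": np.round(idx * tr.frame_interval, 9),
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path) -> list[IntensityTrace]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        logger.warning("trace file %s is empty", path)
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        logger.warning("trace file %s contains no rows", path)
        return []
    traces = []
    for mol_id, grp in df.groupby("molecule_id", sort=False):
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise TraceFormatError(
                f"molecule {mol_id}: frame indices must run 0..n-1 without gaps")
        times = grp["time_s"].to_numpy()
        if len(times) > 1:
            dts = np.diff(times)
            if np.ptp(dts) > 1e-6 or dts[0] <= 0:
                raise TraceFormatError(
                    f"molecule {mol_id}: inconsistent frame_interval in time_s")
            dt = float(np.mean(dts))
        else:
            dt = float(times[0]) if times[0] > 0 else 0.08
        traces.append(IntensityTrace(
            molecule_id=str(mol_id),
            frame_interval=dt,
            donor=grp["donor"].to_numpy(float),
            acceptor=grp["acceptor"].to_numpy(float),
        ))
    return traces


def write_traces_hdf5(traces: list[IntensityTrace], path,
                      scenario_label: str = "") -> None:
    """One group per molecule with donor/acceptor datasets; frame_interval
    and scenario_label stored as attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["scenario_label"] = scenario_label
        for tr in traces:
            g = fh.create_group(tr.molecule_id)
            g.attrs["frame_interval"] = tr.frame_interval
            g.create_dataset("donor", data=tr.donor)
            g.create_dataset("acceptor", data=tr.acceptor)


def read_traces_hdf5(path) -> list[IntensityTrace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as fh:
        for mol_id in sorted(fh.keys()):
            g = fh[mol_id]
            for ds in ("donor", "acceptor"):
                if ds not in g:
                    raise TraceFormatError(f"molecule {mol_id}: missing '{ds}' dataset")
            traces.append(IntensityTrace(
                molecule_id=mol_id,
                frame_interval=float(g.attrs["frame_interval"]),
                donor=g["donor"][()],
                acceptor=g["acceptor"][()],
            ))
    return traces
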