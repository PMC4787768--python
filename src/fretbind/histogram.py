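"""Bound-state FRET histograms and their Gaussian decomposition.

Ensemble histograms pool the bound-classified frames of many molecules
(frame-weighted, so peak areas are dwell-proportional) and are decomposed by
nonlinear least squares into one or two Gaussian components — the binding
conformations of the polymerase.  Fitting works on the binned counts, the
way such histograms are drawn and fit in practice; a frame-level
Gaussian-mixture fit is available as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

HIST_RANGE = (-0.1, 1.1)
MIN_MOLECULES = 80  # ensemble-quality rule: warn below this

__all__ = [
    "FretHistogram",
    "GaussianComponent",
    "GaussianFitResult",
    "EmptyHistogramError",
    "GaussianFitError",
    "build_histogram",
    "fit_gaussians",
    "select_n_components",
    "bootstrap_centers",
    "fit_mixture_frames",
]


class EmptyHistogramError(ValueError):
    """No bound frames available to histogram."""


class GaussianFitError(RuntimeError):
    """Gaussian decomposition failed to converge; carries diagnostics."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class FretHistogram:
    """Frame-weighted FRET histogram over uniform bins spanning [-0.1, 1.1]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int
    n_frames: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if len(edges) != len(counts) + 1:
            raise ValueError("need one more edge than bins")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if abs(counts.sum() - self.n_frames) > 1e-6:
            raise ValueError("sum of counts must equal n_frames")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian peak of a FRET distribution."""

    center: float
    width: float
    area_fraction: float
    center_uncertainty: float | None = None


@dataclass(frozen=True)
class GaussianFitResult:
    components: tuple[GaussianComponent, ...]
    rss: float
    bic: float
    effectively_unimodal: bool = False

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.components])

    @property
    def predominant(self) -> GaussianComponent:
        return max(self.components, key=lambda c: c.area_fraction)


def build_histogram(
    bound_values_per_molecule: dict[str, np.ndarray] | list[np.ndarray],
    bin_width: float = 0.02,
    molecule_weighted: bool = False,
) -> FretHistogram:
    """Histogram the bound-state FRET frames of an ensemble.

    Each bound frame contributes one count to its half-open bin [lo, hi).
    With ``molecule_weighted`` each molecule's frames are normalized to unit
    total weight instead (counts then sum to the number of contributing
    molecules, scaled to ``n_frames`` for the invariant).
    """
    if isinstance(bound_values_per_molecule, dict):
        per_mol = list(bound_values_per_molecule.values())
    else:
        per_mol = list(bound_values_per_molecule)
    per_mol = [np.asarray(v, dtype=float) for v in per_mol]
    per_mol = [v[np.isfinite(v)] for v in per_mol]
    per_mol = [v for v in per_mol if v.size]
    n_molecules = len(per_mol)
    n_frames = int(sum(len(v) for v in per_mol))
    if n_frames == 0:
        raise EmptyHistogramError("no bound frames to histogram")
    if n_molecules < MIN_MOLECULES:
        logger.warning(
            "histogram built from %d molecules (< %d ensemble-quality rule)",
            n_molecules, MIN_MOLECULES)
    lo, hi = HIST_RANGE
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for v in per_mol:
        c, _ = np.histogram(v, bins=edges)
        counts += c / len(v) if molecule_weighted else c
    if molecule_weighted:
        counts *= n_frames / counts.sum()
    return FretHistogram(edges, counts, n_molecules=n_molecules, n_frames=n_frames)


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for amp, mu, sigma in zip(params[0::3], params[1::3], params[2::3]):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return y


def _initial_guess(hist: FretHistogram, n_components: int) -> list[float]:
    """Peak-based initialization; falls back to quantiles of the mass."""
    x, y = hist.centers, hist.counts
    width0 = 0.06
    sm = np.convolve(y, np.ones(3) / 3.0, mode="same")
    min_dist = max(1, int(0.1 / hist.bin_width))
    peaks, props = find_peaks(sm, distance=min_dist, height=0.05 * sm.max())
    peaks = sorted(peaks, key=lambda p: -sm[p])[:n_components]
    mus = sorted(x[p] for p in peaks)
    if len(mus) < n_components:  # quantile fallback
        mass = np.cumsum(y) / y.sum()
        qs = (np.arange(n_components) + 0.5) / n_components
        mus = sorted(float(x[np.searchsorted(mass, q)]) for q in qs)
    params = []
    for mu in mus:
        amp = float(max(y[np.argmin(np.abs(x - mu))], 1e-3))
        params += [amp, float(np.clip(mu, 0.0, 1.0)), width0]
    return params


def fit_gaussians(
    hist: FretHistogram,
    n_components: int = 2,
    init: list[float] | None = None,
) -> GaussianFitResult:
    """Least-squares fit of a sum of Gaussians to the binned counts.

    Parameters are bounded (0 <= center <= 1, 0.01 <= width <= 0.5,
    amplitude >= 0); components are returned in ascending center order with
    areas normalized to fractions.  A 2-component solution whose centers
    fall within one width of each other is flagged effectively unimodal.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if hist.counts.sum() == 0:
        raise EmptyHistogramError("cannot fit an all-zero histogram")
    x, y = hist.centers, hist.counts
    p0 = init if init is not None else _initial_guess(hist, n_components)
    lower = [0.0, 0.0, 0.01] * n_components
    upper = [np.inf, 1.0, 0.5] * n_components
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lower, upper),
                            maxfev=20000)
    except RuntimeError as exc:
        raise GaussianFitError(f"Gaussian fit did not converge: {exc}",
                               best_params=p0) from exc
    resid = y - _gauss_sum(x, *popt)
    rss = float(np.sum(resid**2))
    n_bins = len(y)
    k = 3 * n_components
    bic = n_bins * np.log(max(rss, 1e-300) / n_bins) + k * np.log(n_bins)

    triples = sorted(zip(popt[0::3], popt[1::3], popt[2::3]), key=lambda t: t[1])
    areas = np.array([amp * sigma for amp, _, sigma in triples])
    fracs = areas / areas.sum()
    comps = tuple(
        GaussianComponent(center=float(mu), width=float(sigma),
                          area_fraction=float(f))
        for (_, mu, sigma), f in zip(triples, fracs)
    )
    unimodal = False
    if n_components == 2:
        sep = abs(comps[1].center - comps[0].center)
        if sep < max(c.width for c in comps):
            unimodal = True
            logger.info("two-Gaussian fit effectively unimodal (separation %.3f)", sep)
    return GaussianFitResult(comps, rss=rss, bic=float(bic),
                             effectively_unimodal=unimodal)


def _has_dip(hist: FretHistogram, c_low: float, c_high: float) -> bool:
    """Empirical bimodality: the (3-bin-smoothed) histogram must drop below
    90% of the lower peak height somewhere between the two fitted centers.
    Guards against a least-squares split of a single peak, which always
    places its two components on the flanks with no dip between them."""
    sm = np.convolve(hist.counts, np.ones(3) / 3.0, mode="same")
    x = hist.centers

    def level(c):
        return sm[int(np.argmin(np.abs(x - c)))]

    between = (x > min(c_low, c_high)) & (x < max(c_low, c_high))
    if not between.any():
        return False
    return float(sm[between].min()) <= 0.9 * min(level(c_low), level(c_high))


def select_n_components(hist: FretHistogram) -> tuple[int, dict]:
    """Choose 1 vs 2 Gaussian components.

    Two components are accepted only when (a) they lower the Bayesian
    information criterion, (b) their centers are separated by at least the
    larger width, and (c) the histogram genuinely dips between the fitted
    centers; the scores and decision are returned for logging.
    """
    fit1 = fit_gaussians(hist, 1)
    try:
        fit2 = fit_gaussians(hist, 2)
    except GaussianFitError:
        return 1, {"bic1": fit1.bic, "bic2": np.inf, "reason": "2-component fit failed"}
    sep = abs(fit2.components[1].center - fit2.components[0].center)
    sep_ok = sep >= max(c.width for c in fit2.components)
    dip_ok = _has_dip(hist, fit2.components[0].center, fit2.components[1].center)
    choose2 = fit2.bic < fit1.bic and sep_ok and dip_ok
    info = {"bic1": fit1.bic, "bic2": fit2.bic, "separation": sep,
            "separation_ok": sep_ok, "dip_ok": dip_ok}
    info["reason"] = ("BIC, separation and dip favor 2" if choose2 else
                      "insufficient separation" if not sep_ok else
                      "no dip between centers" if not dip_ok else
                      "BIC favors 1")
    logger.info("component selection: %s (BIC1=%.1f BIC2=%.1f sep=%.3f dip=%s)",
                2 if choose2 else 1, fit1.bic, fit2.bic, sep, dip_ok)
    return (2 if choose2 else 1), info


def bootstrap_centers(
    bound_values_per_molecule: dict[str, np.ndarray],
    n_components: int,
    bin_width: float = 0.02,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap SD of each component center, resampling molecules.

    Molecules (not frames) are the exchangeable unit because frames within a
    molecule are autocorrelated.  Returns per-component center SDs in
    ascending-center order.
    """
    rng = rng if rng is not None else np.random.default_rng()
    ids = list(bound_values_per_molecule.keys())
    full = fit_gaussians(build_histogram(bound_values_per_molecule, bin_width),
                         n_components)
    init = []
    for c in full.components:
        init += [1.0, c.center, c.width]
    centers = []
    for _ in range(n_boot):
        take = rng.choice(len(ids), size=len(ids), replace=True)
        sample = [bound_values_per_molecule[ids[i]] for i in take]
        try:
            h = build_histogram(sample, bin_width)
            # rescale amplitude guesses to this sample's peak count
            guess = list(init)
            guess[0::3] = [h.counts.max()] * n_components
            fit = fit_gaussians(h, n_components, init=guess)
        except (EmptyHistogramError, GaussianFitError):
            continue
        centers.append(fit.centers)
    if not centers:
        return np.full(n_components, np.nan)
    return np.std(np.array(centers), axis=0, ddof=1)


def fit_mixture_frames(values: np.ndarray, n_components: int,
                       seed: int = 0) -> list[GaussianComponent]:
    """Frame-level Gaussian-mixture fit (EM on raw values, not bins).

    Cross-check utility for the histogram curve fit; uses scikit-learn.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=n_components, random_state=seed,
                         n_init=3).fit(v)
    order = np.argsort(gm.means_.ravel())
    return [
        GaussianComponent(
            center=float(gm.means_.ravel()[i]),
            width=float(np.sqrt(gm.covariances_.ravel()[i])),
            area_fraction=float(gm.weights_[i]),
        )
        for i in order
    ]
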