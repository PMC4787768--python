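"""Packaged library of simulation scenarios.

Each scenario file transcribes one experimental condition — a
primer-template construct (unmodified, AF-dG- or AAF-dG-modified; templating
position, terminal adduct, or terminal mismatch) with or without the next
nucleotide — into simulator ground truth: the bound-conformation FRET means,
their relative occupancies, and the dissociation rate.  Each state and rate
carries an ``anchored`` flag: anchored values are transcriptions of printed
measurements, unanchored ones are documented placeholders for quantities the
measurements left unprinted (see the scenario descriptions and the methods
note).

Quantities the experiments could not print at all are filled by fixed
conventions: the pseudo-first-order binding rate defaults to
``k_on = (2/3) k_off`` (~40% bound occupancy, matching typical traces) and
bound sub-states exchange with total rate ``shuttle_rate`` (default
1.0 /s, ~1 s shuttling) split so sub-state occupancies equal the target
weights.  Dissociation proceeds at the same ``k_off`` from every bound
sub-state, so the bound dwell time stays single-exponential at the quoted
rate regardless of shuttling.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from ..scheme import UNBOUND, KineticScheme, Photophysics, SimConfig

__all__ = [
    "ScenarioError",
    "list_scenarios",
    "load_scenario",
    "scenario_truth",
    "build_scheme",
]

DEFAULT_SHUTTLE_RATE = 1.0  # /s, total bound-manifold exchange rate
DEFAULT_KON_FACTOR = 2.0 / 3.0  # k_on = factor * k_off -> ~40% occupancy


class ScenarioError(KeyError):
    """Unknown scenario name; the message lists the registry."""


def _scenario_dir():
    return resources.files("fretbind.scenarios")


def list_scenarios() -> list[str]:
    """Names of all packaged scenarios, sorted."""
    return sorted(
        p.name[:-5] for p in _scenario_dir().iterdir() if p.name.endswith(".yaml")
    )


def _read_scenario(name: str) -> dict:
    path = _scenario_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        available = ", ".join(list_scenarios())
        raise ScenarioError(
            f"unknown scenario {name!r}; available scenarios: {available}"
        ) from None
    return yaml.safe_load(text)


def build_scheme(
    bound_states: list[dict],
    k_off: float,
    k_on: float | None = None,
    shuttle_rate: float = DEFAULT_SHUTTLE_RATE,
) -> KineticScheme:
    """Assemble the CTMC: U plus the listed bound sub-states.

    Entry from U splits across sub-states by weight; sub-states exchange at
    ``shuttle_rate`` x target-weight (detailed balance at the weights); each
    sub-state dissociates at ``k_off``.
    """
    weights = np.array([s["weight"] for s in bound_states], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("bound-state weights must be > 0")
    weights = weights / weights.sum()
    if k_on is None:
        k_on = DEFAULT_KON_FACTOR * k_off
    names = [UNBOUND] + [s["name"] for s in bound_states]
    fret = np.array([0.0] + [float(s["fret"]) for s in bound_states])
    n = len(names)
    q = np.zeros((n, n))
    for j, w in enumerate(weights, start=1):
        q[0, j] = k_on * w
        q[j, 0] = float(bound_states[j - 1].get("k_off", k_off))
        for i, wi in enumerate(weights, start=1):
            if i != j:
                q[i, j] = shuttle_rate * w
    return KineticScheme(tuple(names), fret, q)


def load_scenario(
    name: str,
    n_molecules: int | None = None,
    rng_seed: int = 0,
    max_duration: float | None = None,
) -> SimConfig:
    """Build the fully populated simulation config for a packaged scenario.

    ``n_molecules``, ``rng_seed`` and ``max_duration`` override the
    scenario-file values; everything else comes from the file and the
    packaged defaults.
    """
    doc = _read_scenario(name)
    scheme = build_scheme(
        doc["bound_states"],
        k_off=float(doc["k_off"]),
        k_on=doc.get("k_on"),
        shuttle_rate=float(doc.get("shuttle_rate", DEFAULT_SHUTTLE_RATE)),
    )
    ph = Photophysics(**doc.get("photophysics", {}))
    return SimConfig(
        scheme=scheme,
        photophysics=ph,
        frame_interval=float(doc.get("frame_interval", 0.08)),
        n_molecules=int(n_molecules if n_molecules is not None
                        else doc.get("n_molecules", 100)),
        max_duration=float(max_duration if max_duration is not None
                           else doc.get("max_duration", 60.0)),
        rng_seed=rng_seed,
        scenario_label=name,
    )


def scenario_truth(name: str) -> dict:
    """Ground-truth quantities of a scenario for recovery checks.

    Returns ``fret_means`` (ascending), ``weights`` (same order),
    ``anchored`` flags, ``k_off`` and ``k_off_anchored``.
    """
    doc = _read_scenario(name)
    states = sorted(doc["bound_states"], key=lambda s: s["fret"])
    w = np.array([s["weight"] for s in states], dtype=float)
    return {
        "fret_means": np.array([s["fret"] for s in states], dtype=float),
        "weights": w / w.sum(),
        "anchored": [bool(s.get("anchored", False)) for s in states],
        "k_off": float(doc["k_off"]),
        "k_off_anchored": bool(doc.get("k_off_anchored", False)),
        "description": doc.get("description", ""),
    }
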