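"""Experiment runners: null-model comparison, edge perturbation, phi sweep.

Each runner produces an :class:`ExperimentTable` of long-format records —
one row per (condition, method, realization) with the realization's derived
seed — plus a summary of means and standard deviations over realizations.
Every recorded value is recomputable by rerunning the corresponding
comparison with the recorded seed.

Seeds: realization r of a run with master seed s uses the derived seed
``SeedSequence([s, counter]).generate_state(1)[0] % 2**31`` with a counter
that increases over (condition, realization) in a fixed order, so conditions
never share streams and runs are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import baselines
from .dissimilarity import MotifProfile, dm, motif_profile
from .graph import DirectedGraph
from .motifs import MotifCatalogue, build_catalogue
from .nullmodels import dk1_rewire, dk2_rewire, dk25_rewire, perturb

__all__ = [
    "ExperimentTable",
    "derive_seed",
    "run_null_model_experiment",
    "run_perturbation_experiment",
    "run_phi_sweep",
    "NULL_MODELS",
    "METHODS",
]

NULL_MODELS: dict[str, Callable] = {
    "dk1.0": dk1_rewire,
    "dk2.0": dk2_rewire,
    "dk2.5": dk25_rewire,
}

DEFAULT_F_GRID = (-0.9, -0.7, -0.5, -0.3, -0.1, 0.1, 0.3, 0.5, 0.7, 0.9)
DEFAULT_PHI_SET = (0.1, 0.3, 0.5, 0.7, 0.9)


def derive_seed(master_seed: int, counter: int) -> int:
    """Collision-free per-realization seed from a master seed and a counter."""
    return int(
        np.random.SeedSequence([master_seed, counter]).generate_state(1)[0] % 2**31
    )


@dataclass
class ExperimentTable:
    """Long-format experiment records plus a recomputable summary."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        keys = [
            c
            for c in ("network", "method", "model", "f", "phi")
            if c in self.records.columns
        ]
        g = self.records.groupby(keys, dropna=False)["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _compare(
    method: str,
    G: DirectedGraph,
    H: DirectedGraph,
    phi: float,
    catalogue: MotifCatalogue,
    profile: MotifProfile | None,
) -> float:
    if method == "dm":
        base = profile if profile is not None else G
        return dm(base, H, phi=phi, catalogue=catalogue).dm_value
    if method == "portrait":
        return baselines.portrait_divergence(G, H)
    if method == "deltacon":
        return baselines.deltacon_distance(G, H)
    if method == "closeness":
        return baselines.closeness_distance(G, H)
    raise ValueError(f"unknown method {method!r}")


METHODS = ("dm", "portrait", "deltacon", "closeness")


def run_null_model_experiment(
    G: DirectedGraph,
    models: Sequence[str] = ("dk1.0", "dk2.0", "dk2.5"),
    realizations: int = 100,
    methods: Sequence[str] = ("dm",),
    phi: float = 0.5,
    seed: int = 0,
    network: str = "G",
    catalogue: MotifCatalogue | None = None,
) -> ExperimentTable:
    """Compare ``G`` with R realizations of each dk-series null model.

    Records one dissimilarity value per (model, method, realization); the
    mean over realizations is the heatmap cell of the null-model benchmark.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    for model in models:
        if model not in NULL_MODELS:
            raise ValueError(f"unknown null model {model!r}")
    if catalogue is None:
        catalogue = build_catalogue()
    profile = motif_profile(G, catalogue) if "dm" in methods else None
    rows = []
    counter = 0
    for model in models:
        rewire = NULL_MODELS[model]
        for r in range(realizations):
            s = derive_seed(seed, counter)
            counter += 1
            H, _ = rewire(G, seed=s)
            hp = motif_profile(H, catalogue) if "dm" in methods else None
            for method in methods:
                value = (
                    _compare(method, G, hp, phi, catalogue, profile)
                    if method == "dm"
                    else _compare(method, G, H, phi, catalogue, None)
                )
                rows.append(
                    {
                        "network": network,
                        "method": method,
                        "model": model,
                        "phi": phi if method == "dm" else np.nan,
                        "realization": r,
                        "seed": s,
                        "value": value,
                    }
                )
    return ExperimentTable(records=pd.DataFrame(rows))


def run_perturbation_experiment(
    G: DirectedGraph,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    realizations: int = 100,
    methods: Sequence[str] = METHODS,
    phi: float = 0.5,
    seed: int = 0,
    network: str = "G",
    catalogue: MotifCatalogue | None = None,
) -> ExperimentTable:
    """Compare ``G`` with randomly edge-perturbed copies over a grid of f."""
    if any(not -0.9 <= f <= 0.9 for f in f_grid):
        raise ValueError("f_grid values must lie in [-0.9, 0.9]")
    if catalogue is None:
        catalogue = build_catalogue()
    profile = motif_profile(G, catalogue) if "dm" in methods else None
    rows = []
    counter = 0
    for f in f_grid:
        for r in range(realizations):
            s = derive_seed(seed, counter)
            counter += 1
            H, _ = perturb(G, f, seed=s)
            hp = motif_profile(H, catalogue) if "dm" in methods else None
            for method in methods:
                value = (
                    _compare(method, G, hp, phi, catalogue, profile)
                    if method == "dm"
                    else _compare(method, G, H, phi, catalogue, None)
                )
                rows.append(
                    {
                        "network": network,
                        "method": method,
                        "f": f,
                        "phi": phi if method == "dm" else np.nan,
                        "realization": r,
                        "seed": s,
                        "value": value,
                    }
                )
    return ExperimentTable(records=pd.DataFrame(rows))


def run_phi_sweep(
    G: DirectedGraph,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    phi_set: Iterable[float] = DEFAULT_PHI_SET,
    realizations: int = 100,
    seed: int = 0,
    network: str = "G",
    catalogue: MotifCatalogue | None = None,
) -> ExperimentTable:
    """Dm-only sweep over the weight phi and the perturbation fraction f.

    Dm is affine in phi for a fixed realization, so the census runs once per
    realization and all phi values reuse its global and local terms.
    """
    phi_set = sorted(set(phi_set))
    if any(not 0.0 <= p <= 1.0 for p in phi_set):
        raise ValueError("phi values must lie in [0, 1]")
    if catalogue is None:
        catalogue = build_catalogue()
    profile = motif_profile(G, catalogue)
    rows = []
    counter = 0
    for f in f_grid:
        for r in range(realizations):
            s = derive_seed(seed, counter)
            counter += 1
            H, _ = perturb(G, f, seed=s)
            hp = motif_profile(H, catalogue)
            base = dm(profile, hp, phi=0.0, catalogue=catalogue)
            for phi in phi_set:
                value = phi * base.global_term + (1.0 - phi) * base.local_term
                rows.append(
                    {
                        "network": network,
                        "method": "dm",
                        "f": f,
                        "phi": phi,
                        "realization": r,
                        "seed": s,
                        "value": value,
                    }
                )
    return ExperimentTable(records=pd.DataFrame(rows))
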