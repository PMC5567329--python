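"""Pan-growth and core-decay rarefaction ("dilution") curves over strain
orderings, with fitted convergence models.

For each permutation of strains and each prefix length n, the pan size is
the number of clusters touching at least one of the first n strains and the
core size is the number present in all of them.  Per-n medians are fitted
with the Tettelin-style exponential decay C(n) = A exp(-n/tau) + Omega for
the core (Omega is the asymptotic core size) and the Heaps-law power law
P(n) = K n^gamma for the pan; a pan-genome is called open when the fitted
exponent gamma is positive with its standard error excluding zero.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .pangenome import PanGenomeResult

__all__ = ["RarefactionCurve", "DecayFit", "rarefy", "fit_core_decay", "fit_pan_growth"]


@dataclass
class RarefactionCurve:
    strain_ids: List[str]
    n_values: np.ndarray  # 1..N
    pan_sizes: np.ndarray  # (n_perm, N)
    core_sizes: np.ndarray  # (n_perm, N)
    permutations: List[tuple]
    seed: Optional[int]

    @property
    def n_perm(self) -> int:
        return self.pan_sizes.shape[0]

    def pan_median(self) -> np.ndarray:
        return np.median(self.pan_sizes, axis=0)

    def core_median(self) -> np.ndarray:
        return np.median(self.core_sizes, axis=0)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("perm_id\tn\tpan\tcore\n")
            for p in range(self.n_perm):
                for j, n in enumerate(self.n_values):
                    fh.write(f"{p}\t{n}\t{self.pan_sizes[p, j]}\t{self.core_sizes[p, j]}\n")


@dataclass
class DecayFit:
    model: str  # "core_exp_decay" or "pan_power_law"
    parameters: dict
    rss: float
    converged: bool
    classification: Optional[str] = None  # "open"/"closed" for the pan model

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": self.model,
                    "parameters": self.parameters,
                    "rss": self.rss,
                    "converged": self.converged,
                    "classification": self.classification,
                    "note": "functional forms are reimplementation choices; "
                    "exponential decay (core) and power law (pan)",
                },
                fh,
                indent=2,
            )


def rarefy(result: PanGenomeResult, n_perm: int = 200, seed: int = 0) -> RarefactionCurve:
    """Pan/core sizes for strain-count prefixes over sampled permutations.

    All N! orderings are enumerated when ``n_perm`` >= N!; otherwise
    ``n_perm`` permutations are drawn uniformly with a seeded generator.
    """
    if result.n_strains < 2:
        raise ValueError("rarefaction requires at least 2 strains")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    strains = result.strain_order
    N = len(strains)
    index = {s: i for i, s in enumerate(strains)}
    # presence sets as bitmasks for fast prefix queries
    masks = np.array(
        [sum(1 << index[s] for s in c.presence) for c in result.clusters], dtype=np.int64
    )

    total_orderings = math.factorial(N)
    if n_perm >= total_orderings:
        perms = [tuple(p) for p in itertools.permutations(range(N))]
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(N).tolist()) for _ in range(n_perm)]

    n_values = np.arange(1, N + 1)
    pan = np.zeros((len(perms), N), dtype=np.int64)
    core = np.zeros((len(perms), N), dtype=np.int64)
    for p, perm in enumerate(perms):
        prefix_mask = np.int64(0)
        for j, strain_idx in enumerate(perm):
            prefix_mask |= np.int64(1 << strain_idx)
            pan[p, j] = int(np.count_nonzero(masks & prefix_mask))
            core[p, j] = int(np.count_nonzero((masks & prefix_mask) == prefix_mask))
    return RarefactionCurve(
        strain_ids=strains,
        n_values=n_values,
        pan_sizes=pan,
        core_sizes=core,
        permutations=[tuple(strains[i] for i in perm) for perm in perms],
        seed=seed,
    )


def plot_curves(curve: RarefactionCurve, path) -> None:
    """Dilution-curve plot: per-permutation pan/core traces with medians."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    n = curve.n_values
    for p in range(curve.n_perm):
        ax.plot(n, curve.pan_sizes[p], color="tab:blue", alpha=0.15, lw=0.7)
        ax.plot(n, curve.core_sizes[p], color="tab:orange", alpha=0.15, lw=0.7)
    ax.plot(n, curve.pan_median(), color="tab:blue", lw=2, label="pan (median)")
    ax.plot(n, curve.core_median(), color="tab:orange", lw=2, label="core (median)")
    ax.set_xlabel("strains included")
    ax.set_ylabel("orthologue clusters")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _check_points(n: np.ndarray) -> None:
    if len(np.unique(n)) < 3:
        raise ValueError("at least 3 distinct strain counts are required to fit")


def fit_core_decay(curve: RarefactionCurve) -> DecayFit:
    """Fit C(n) = A exp(-n/tau) + Omega to per-n median core sizes.

    Omega is the asymptotic core-genome size.  Optimizer failure yields a
    result with ``converged=False`` rather than an exception.
    """
    n = np.asarray(curve.n_values, dtype=float)
    _check_points(n)
    y = curve.core_median().astype(float)
    return _fit_exp_decay(n, y)


def _fit_exp_decay(n: np.ndarray, y: np.ndarray) -> DecayFit:
    def model(x, A, tau, omega):
        return A * np.exp(-x / tau) + omega

    amp0 = max(float(y[0] - y[-1]), 1e-6)
    # tau is capped at the largest strain count: a decay constant beyond the
    # observed range is unidentifiable and lets A*exp(-n/tau) with tau -> inf
    # swallow the asymptote (omega -> 0) on nearly flat noisy curves
    tau_max = float(n[-1])
    p0 = (amp0, min(max(1.0, (n[-1] - n[0]) / 3.0), tau_max), max(float(y[-1]), 0.0))
    try:
        popt, _ = optimize.curve_fit(
            model, n, y, p0=p0,
            bounds=([0.0, 1e-9, 0.0], [np.inf, tau_max, np.inf]),
            maxfev=20000,
        )
        converged = True
    except (RuntimeError, ValueError):
        popt = np.array(p0)
        converged = False
    rss = float(np.sum((model(n, *popt) - y) ** 2))
    return DecayFit(
        model="core_exp_decay",
        parameters={"A": float(popt[0]), "tau": float(popt[1]), "omega": float(popt[2])},
        rss=rss,
        converged=converged,
    )


def fit_pan_growth(curve: RarefactionCurve) -> DecayFit:
    """Fit P(n) = K n^gamma to per-n median pan sizes (log-log regression).

    Classified "open" when gamma > 0 and the 95% interval of the slope
    excludes zero; "closed" otherwise.
    """
    n = np.asarray(curve.n_values, dtype=float)
    _check_points(n)
    y = curve.pan_median().astype(float)
    if np.any(y <= 0):
        raise ValueError("pan sizes must be positive for a power-law fit")
    res = stats.linregress(np.log(n), np.log(y))
    gamma = float(res.slope)
    K = float(np.exp(res.intercept))
    se = float(res.stderr) if res.stderr is not None else float("nan")
    open_pan = gamma > 0 and (np.isnan(se) or gamma - 1.96 * se > 0)
    fitted = K * n ** gamma
    rss = float(np.sum((fitted - y) ** 2))
    return DecayFit(
        model="pan_power_law",
        parameters={"K": K, "gamma": gamma, "gamma_stderr": se},
        rss=rss,
        converged=True,
        classification="open" if open_pan else "closed",
    )
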