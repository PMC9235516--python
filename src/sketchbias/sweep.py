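"""Experiment grids: empirical bias versus the analytical estimate.

A sweep row pairs, for one generated sequence pair, the true Jaccard J, the
hash-replicate average estimate J-bar (with 2.5/97.5 percentile band), the
analytical bias B, and the empirical error |J-bar - J - B|.  The same hash
seed list is shared across mutation replicates of one grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bias import bias_estimate
from .generate import random_duplicate_free, related_pair, unrelated_pair
from .matching import kmer_matching
from .oracle import monte_carlo

logger = logging.getLogger("sketchbias")

__all__ = ["SweepConfig", "run_sweep", "sweep_unrelated", "sweep_related",
           "fit_error_power_law"]


def default_k_for_j(j: float) -> int:
    """k-mer size used in the unrelated-pair grid: 7 for j <= 0.3, else 8."""
    return 7 if j <= 0.3 else 8


def _pair_row(A, B, w, n_hash, master_seed, **extra) -> dict:
    m = kmer_matching(A, B)
    rep = bias_estimate(A, B, w, matching=m)
    mc = monte_carlo(A, B, w, n_seeds=n_hash, master_seed=master_seed)
    bias_emp = mc.mean_J_hat - rep.J
    return dict(
        L=A.L, k=A.k, w=w, J=rep.J, J_bar=mc.mean_J_hat,
        p2_5=mc.percentile_2_5, p97_5=mc.percentile_97_5,
        C=rep.C, B=rep.B, empirical_bias=bias_emp,
        error=abs(bias_emp - rep.B), epsilon=rep.epsilon, **extra,
    )


def sweep_unrelated(j_values, w: int, master_seed: int, n_hash: int = 50,
                    k_for_j=default_k_for_j) -> pd.DataFrame:
    """One unrelated pair per target Jaccard j; 50 hash replicates by default."""
    root = np.random.SeedSequence(master_seed)
    gen_ss, hash_ss = root.spawn(2)
    hash_seed = int(hash_ss.generate_state(1)[0] % (2**31))
    rows = []
    for j, child in zip(j_values, gen_ss.spawn(len(list(j_values)))):
        rng = np.random.default_rng(child)
        k = k_for_j(j)
        A, B = unrelated_pair(j, k, rng, w=w)
        rows.append(_pair_row(A, B, w, n_hash, hash_seed, model="unrelated", j=j))
    return pd.DataFrame(rows)


def sweep_related(r1_values, L: int, k: int, w: int, master_seed: int,
                  n_hash: int = 50, n_mutation: int = 1) -> pd.DataFrame:
    """Related pairs from a random duplicate-free base.

    The same hash seed list serves every mutation replicate of a grid point.
    """
    root = np.random.SeedSequence(master_seed)
    gen_ss, hash_ss = root.spawn(2)
    hash_seed = int(hash_ss.generate_state(1)[0] % (2**31))
    rows = []
    children = gen_ss.spawn(len(list(r1_values)))
    for r1, child in zip(r1_values, children):
        rng = np.random.default_rng(child)
        base = random_duplicate_free(L, k, rng)
        for rep_idx in range(n_mutation):
            A, B = related_pair(base, r1, rng)
            rows.append(_pair_row(A, B, w, n_hash, hash_seed,
                                  model="related", r1=r1, mutation_rep=rep_idx))
    return pd.DataFrame(rows)


@dataclass
class SweepConfig:
    """Grid description expanding into fully specified pair models."""

    w: int = 20
    n_hash_replicates: int = 50
    master_seed: int = 0
    unrelated_j: list = field(default_factory=list)
    related_r1: list = field(default_factory=list)
    related_L: int = 10_000
    related_k: int = 16
    n_mutation_replicates: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        return cls(**d)


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """All grid points of a config; deterministic given the master seed."""
    frames = []
    if cfg.unrelated_j:
        frames.append(sweep_unrelated(cfg.unrelated_j, cfg.w, cfg.master_seed,
                                      n_hash=cfg.n_hash_replicates))
    if cfg.related_r1:
        frames.append(sweep_related(cfg.related_r1, cfg.related_L, cfg.related_k,
                                    cfg.w, cfg.master_seed,
                                    n_hash=cfg.n_hash_replicates,
                                    n_mutation=cfg.n_mutation_replicates))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def fit_error_power_law(L_values, errors) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of amplitude * L^exponent to error-vs-length data.

    Returns (amplitude, exponent, covariance).  Initialized from the log-log
    linear fit; needs at least 4 distinct L values with positive errors.
    """
    L_values = np.asarray(L_values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    ok = errors > 0
    if np.unique(L_values[ok]).size < 4:
        raise ValueError("need >= 4 distinct L values with positive errors")
    slope, intercept = np.polyfit(np.log(L_values[ok]), np.log(errors[ok]), 1)
    popt, pcov = curve_fit(lambda L, a, b: a * np.power(L, b),
                           L_values[ok], errors[ok],
                           p0=[np.exp(intercept), slope], maxfev=10_000)
    return float(popt[0]), float(popt[1]), pcov
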