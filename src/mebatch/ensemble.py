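"""keff perturbation ensembles.

Effective rate constants (keff, linking flux to enzyme concentration via
v = keff * e) are among the most uncertain ME-model parameters.
Prediction sensitivity is probed by sampling multiplicative keff
perturbations over a 0.1-10x range for a chosen set of couplings,
simulating each perturbed model, scoring it against measured
concentration profiles (sum of squared errors), and retaining the
well-fitting samples as an ensemble.

The sampling law is log-uniform on [0.1, 10] (symmetric multiplicative
noise with median 1); factors are i.i.d. across couplings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .memodel import MEModel, ModelError
from .validation import resample_profiles

__all__ = [
    "PerturbationSample",
    "perturb_keff",
    "score_fit",
    "select_ensemble",
    "write_samples_csv",
]

FACTOR_RANGE = (0.1, 10.0)


@dataclass
class PerturbationSample:
    sample_id: int
    factors: dict[tuple[str, str], float]  # (complex, reaction) -> factor
    sse: float | None = None

    def apply(self, model: MEModel) -> MEModel:
        return model.with_keff_factors(self.factors)


def perturb_keff(model: MEModel, targets: Sequence[tuple[str, str]],
                 n: int, seed: int = 0,
                 factor_range: tuple[float, float] = FACTOR_RANGE
                 ) -> list[PerturbationSample]:
    """Draw ``n`` independent log-uniform keff perturbation samples.

    Each sample carries one factor per target coupling, i.i.d.
    log-uniform over ``factor_range``; unlisted couplings keep factor 1
    (they are simply absent from the sample).  Reproducible under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    known = set(model.couplings())
    targets = [tuple(t) for t in targets]
    for t in targets:
        if t not in known:
            raise ModelError(f"unknown keff coupling {t!r}")
    lo, hi = factor_range
    if not (0 < lo <= hi):
        raise ValueError("factor range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    log_f = rng.uniform(np.log(lo), np.log(hi), size=(n, len(targets)))
    return [
        PerturbationSample(i, dict(zip(targets, np.exp(log_f[i]))))
        for i in range(n)
    ]


def score_fit(simulated: pd.DataFrame, measured: pd.DataFrame,
              species: Sequence[str] | None = None) -> float:
    """Sum of squared errors between two concentration tables.

    Both tables are time-indexed with species columns; they are resampled
    onto a common grid before differencing.  The score is summed over the
    given species subset (default: all shared species).
    """
    shared = [c for c in simulated.columns if c in set(measured.columns)]
    if species is not None:
        missing = [s for s in species if s not in shared]
        if missing:
            raise ValueError(f"species not in both tables: {missing}")
        shared = list(species)
    if not shared:
        raise ValueError("no shared species to score")
    s, m = resample_profiles(simulated[shared], measured[shared])
    return float(((s - m) ** 2).to_numpy().sum())


def select_ensemble(samples: Sequence[PerturbationSample],
                    threshold: float) -> list[int]:
    """Indices of samples with SSE <= threshold, ascending by SSE."""
    scored = [(s.sse, i) for i, s in enumerate(samples)]
    if any(e is None for e, _ in scored):
        raise ValueError("all samples must be scored before selection")
    return [i for e, i in sorted(scored) if e <= threshold]


def default_threshold(samples: Sequence[PerturbationSample],
                      factor: float = 1.5) -> float:
    """Default ensemble cut: 1.5x the best SSE among the samples."""
    best = min(s.sse for s in samples)
    return factor * best


def write_samples_csv(samples: Sequence[PerturbationSample],
                      path: str) -> None:
    rows = []
    for s in samples:
        for (cplx, rxn), f in sorted(s.factors.items()):
            rows.append({"sample_id": s.sample_id,
                         "coupling": f"{cplx}:{rxn}", "factor": f,
                         "sse": s.sse})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_samples_csv(path: str) -> list[PerturbationSample]:
    df = pd.read_csv(path)
    out: list[PerturbationSample] = []
    for sid, grp in df.groupby("sample_id", sort=True):
        factors = {}
        for _, row in grp.iterrows():
            cplx, rxn = str(row["coupling"]).split(":", 1)
            factors[(cplx, rxn)] = float(row["factor"])
        sse = grp["sse"].iloc[0]
        out.append(PerturbationSample(int(sid), factors,
                                      None if pd.isna(sse) else float(sse)))
    return out
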