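"""Archetypal analysis of flattened time-course ensembles.

Ensembles of perturbed-model simulations are summarized by a small
number of archetypes: extreme, "pure" time-course phenotypes on the
convex hull of the data.  The factorization is X ~ Z A with Z = X B,
where columns of A and B live on the probability simplex, so every
sample is a convex combination of archetypes and every archetype a
convex combination of samples.  Companion profiles (proteome, exchange
fluxes) map through B onto the same archetypes.

Fitting is alternating block-coordinate descent: the A step is a
simplex-constrained least-squares problem per sample column; the B step
updates one archetype at a time against the residual with the other
archetypes fixed, which keeps the residual sum of squares non-increasing.
Simplex-constrained least squares is solved by NNLS with a sum-to-one
penalty row.  Initialization picks well-separated data columns
(furthest-point greedy selection), seeded for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ArchetypeModel",
    "align_timecourses",
    "flatten_timecourses",
    "fit_archetypes",
    "choose_num_archetypes",
    "map_profiles",
]


def align_timecourses(runs: Sequence, interval: float | None = None
                      ) -> list[pd.DataFrame]:
    """Interpolate concentration tables onto one shared uniform grid.

    Simulated runs carry event-clipped, per-run time grids; archetypal
    analysis needs a common grid.  The grid spans the overlap of all runs
    at the smallest median native interval (or ``interval`` if given).
    """
    frames = [r.concentrations if hasattr(r, "concentrations") else r
              for r in runs]
    if not frames:
        raise ValueError("no runs given")
    t0 = max(float(f.index[0]) for f in frames)
    t1 = min(float(f.index[-1]) for f in frames)
    if t1 <= t0:
        raise ValueError("runs have no overlapping time support")
    if interval is None:
        interval = min(float(np.median(np.diff(f.index.to_numpy(dtype=float))))
                       for f in frames)
    grid = t0 + interval * np.arange(int(np.floor((t1 - t0) / interval
                                                  + 1e-9)) + 1)
    out = []
    for f in frames:
        t = f.index.to_numpy(dtype=float)
        out.append(pd.DataFrame(
            {c: np.interp(grid, t, f[c].to_numpy(dtype=float))
             for c in f.columns}, index=grid))
    return out


@dataclass
class ArchetypeModel:
    Z: np.ndarray    # features x p archetypes
    A: np.ndarray    # p x samples, columns on the simplex
    B: np.ndarray    # samples x p, columns on the simplex
    rss: float
    p: int
    n_iter: int = 0
    rss_trace: np.ndarray | None = None


def flatten_timecourses(runs: Sequence, species: Sequence[str]) -> pd.DataFrame:
    """Stack concentration time courses into a features x samples matrix.

    Each run contributes one column; rows are (timepoint, metabolite)
    pairs ordered time-major with metabolites lexicographic.  All runs
    must share the time grid (resample first if they do not).
    """
    species = sorted(species)
    if not species:
        raise ValueError("species subset must be non-empty")
    frames = [r.concentrations if hasattr(r, "concentrations") else r
              for r in runs]
    if not frames:
        raise ValueError("no runs given")
    t0 = frames[0].index.to_numpy(dtype=float)
    cols = {}
    index = [(float(t), m) for t in t0 for m in species]
    for i, df in enumerate(frames):
        t = df.index.to_numpy(dtype=float)
        if len(t) != len(t0) or not np.allclose(t, t0):
            raise ValueError(f"run {i}: time grid mismatch (resample first)")
        missing = [m for m in species if m not in df.columns]
        if missing:
            raise ValueError(f"run {i}: missing species {missing}")
        cols[i] = df[species].to_numpy(dtype=float).reshape(-1)
    return pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(index))


def _simplex_lstsq(M: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """argmin ||M b - y|| subject to b >= 0, sum(b) = 1 (penalty NNLS)."""
    k = M.shape[1]
    Mp = np.vstack([M, penalty * np.ones((1, k))])
    yp = np.concatenate([y, [penalty]])
    b, _ = nnls(Mp, yp)
    s = b.sum()
    if s <= 0:
        return np.full(k, 1.0 / k)
    return b / s


def _furthest_columns(X: np.ndarray, p: int, rng: np.random.Generator
                      ) -> list[int]:
    """Greedy max-min-distance selection of p data columns.

    Starts from the column furthest from the data mean (an extreme
    point), so hull vertices are preferred over interior points.
    """
    first = int(np.argmax(np.linalg.norm(X - X.mean(axis=1, keepdims=True),
                                         axis=0)))
    chosen = [first]
    d = np.linalg.norm(X - X[:, [first]], axis=0)
    while len(chosen) < p:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[:, [nxt]], axis=0))
    return chosen


def fit_archetypes(X: np.ndarray | pd.DataFrame, p: int, tol: float = 1e-6,
                   max_iter: int = 500, seed: int = 0,
                   penalty: float | None = None) -> ArchetypeModel:
    """Alternating minimization for the simplex-constrained factorization.

    Stops when the relative rss change drops below ``tol`` or after
    ``max_iter`` sweeps.  All simplex invariants (column sums of A and B
    equal to 1, entries >= 0, Z = X B) hold exactly at return.
    """
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim != 2:
        raise ValueError("X must be 2-D (features x samples)")
    m, n = Xv.shape
    if not 1 <= p <= n:
        raise ValueError(f"p must be in [1, n_samples={n}], got {p}")
    if not np.any(Xv != 0):
        raise ValueError("rank-0 (all-zero) data matrix")
    if penalty is None:
        penalty = 20.0 * max(1.0, float(np.abs(Xv).max()))

    rng = np.random.default_rng(seed)
    B = np.zeros((n, p))
    for j, col in enumerate(_furthest_columns(Xv, p, rng)):
        B[col, j] = 1.0
    Z = Xv @ B
    A = np.zeros((p, n))

    total = float((Xv ** 2).sum())
    rss_prev = np.inf
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(n):                       # A step
            A[:, j] = _simplex_lstsq(Z, Xv[:, j], penalty)
        for k in range(p):                       # B step, one archetype at a time
            a_k = A[k, :]
            norm2 = float(a_k @ a_k)
            if norm2 <= 1e-30:
                # unused archetype: re-seed at the worst-represented sample
                resid = Xv - Z @ A
                B[:, k] = 0.0
                B[int(np.argmax((resid ** 2).sum(axis=0))), k] = 1.0
                Z[:, k] = Xv @ B[:, k]
                continue
            R_k = Xv - Z @ A + np.outer(Z[:, k], a_k)
            y = R_k @ a_k / norm2
            B[:, k] = _simplex_lstsq(Xv, y, penalty)
            Z[:, k] = Xv @ B[:, k]
        rss = float(((Xv - Z @ A) ** 2).sum())
        trace.append(rss)
        if rss_prev - rss <= tol * max(rss_prev, 1e-30) or rss <= 1e-14 * max(total, 1.0):
            rss_prev = rss
            break
        rss_prev = rss
    for j in range(n):                           # final A refresh
        A[:, j] = _simplex_lstsq(Z, Xv[:, j], penalty)
    rss = float(((Xv - Z @ A) ** 2).sum())
    trace.append(rss)
    return ArchetypeModel(Z=Z, A=A, B=B, rss=rss, p=p, n_iter=it,
                          rss_trace=np.array(trace))


def choose_num_archetypes(rss_by_p: Mapping[int, float]) -> int:
    """Explicit elbow rule on a scree of (p, rss) points.

    Returns the interior p with the largest perpendicular distance from
    (p, rss_p) to the chord joining the first and last scree points;
    ties break to the smallest p.  Requires >= 3 contiguous p values.
    """
    ps = sorted(rss_by_p)
    if len(ps) < 3:
        raise ValueError("need at least 3 scree points for the elbow rule")
    if ps != list(range(ps[0], ps[-1] + 1)):
        raise ValueError("scree p values must be contiguous")
    p0, p1 = ps[0], ps[-1]
    r0, r1 = rss_by_p[p0], rss_by_p[p1]
    # distance from point to chord; the common denominator is constant
    dx, dy = p1 - p0, r1 - r0
    best_p, best_d = None, -np.inf
    for p in ps[1:-1]:
        d = abs(dy * (p - p0) - dx * (rss_by_p[p] - r0))
        if d > best_d + 1e-15:
            best_p, best_d = p, d
    return best_p


def map_profiles(B: np.ndarray, companion: np.ndarray | pd.DataFrame):
    """Map per-sample companion profiles onto the archetypes via B.

    ``companion`` has one column per sample in the same order as B's
    rows; the result ``companion @ B`` gives one convex combination of
    sample profiles per archetype (e.g. archetypal proteome or
    exchange-flux trajectories).
    """
    comp = companion.to_numpy() if isinstance(companion, pd.DataFrame) \
        else np.asarray(companion)
    B = np.asarray(B)
    if comp.shape[1] != B.shape[0]:
        raise ValueError(
            f"companion has {comp.shape[1]} samples but B has {B.shape[0]} rows")
    mapped = comp @ B
    if isinstance(companion, pd.DataFrame):
        return pd.DataFrame(mapped, index=companion.index,
                            columns=[f"archetype_{k}" for k in range(B.shape[1])])
    return mapped
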