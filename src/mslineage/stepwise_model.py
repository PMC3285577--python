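"""Symmetric stepwise mutation model and maximum-likelihood lineage distances.

Each cell division, each allele mutates with probability ``mu`` (default
1/30) by exactly one repeat unit, up or down with equal probability.  The net
repeat difference ``delta`` accumulated over ``t`` divisions is therefore a
lazy symmetric random walk:

    P(delta | t) = sum_m Binom(m; t, mu) * RW(delta; m)

with ``RW(delta; m) = C(m, (m+delta)/2) / 2^m`` when ``m >= |delta|`` and
``m = delta (mod 2)``, else 0.  The number of divisions separating two cells
is estimated by maximising the pooled log-likelihood of their per-allele
repeat differences over an integer grid ``t = 0..t_max``; that estimate fills
the distance matrix handed to neighbor joining.

The same likelihood, read the other way, calibrates the mutation rate from
cells of known depth (the ex-vivo calibration design), and a simple mean
squared deviation from the root is provided as the comparison depth
estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .signature_io import AlleleKey, CellSignature, RootSignature

MU_DEFAULT = 1.0 / 30.0
T_MAX_DEFAULT = 500
MIN_OVERLAP_DEFAULT = 10

ROOT_LABEL = "root_median"

#: stand-in for log(0) that still annihilates impossible separations without
#: propagating NaN through `0 * -inf` in vectorised likelihood sums
_LOG_FLOOR = -1e9


class InsufficientOverlapError(ValueError):
    """Two signatures share too few observed alleles for a defined distance."""


@dataclass(frozen=True)
class StepwiseModel:
    """Mutation-process parameters: per-allele per-division rate and ML grid."""

    mu: float = MU_DEFAULT
    t_max: int = T_MAX_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")

    def log_pmf_table(self, dmax: int) -> np.ndarray:
        """``log P(|delta| = d | t)`` for ``t = 0..t_max``, ``d = 0..dmax``."""
        full = _pmf_table(self.mu, self.t_max)
        cols = full[:, self.t_max : self.t_max + dmax + 1]
        with np.errstate(divide="ignore"):
            logs = np.log(cols)
        # impossible (d > t) cells get a finite floor so that a zero count
        # contributes exactly 0 to the pooled log-likelihood
        return np.maximum(logs, _LOG_FLOOR)


@lru_cache(maxsize=16)
def _pmf_table(mu: float, t_max: int) -> np.ndarray:
    """Full pmf over net delta in [-t_max, t_max] for every t, by dynamic
    programming: t-fold convolution of the single-division step kernel."""
    size = 2 * t_max + 1
    table = np.zeros((t_max + 1, size))
    table[0, t_max] = 1.0
    kernel = np.array([mu / 2.0, 1.0 - mu, mu / 2.0])
    for t in range(1, t_max + 1):
        table[t] = np.convolve(table[t - 1], kernel, mode="same")
    return table


def step_diff_pmf(delta: int, t: int, mu: float) -> float:
    """Exact probability of net repeat difference ``delta`` after ``t``
    divisions, by direct summation over mutation counts."""
    if t < 0:
        raise ValueError("t must be >= 0")
    delta = int(delta)
    if abs(delta) > t:
        return 0.0
    total = 0.0
    for m in range(abs(delta), t + 1):
        if (m - delta) % 2:
            continue
        rw = math.comb(m, (m + delta) // 2) / 2.0**m
        total += math.comb(t, m) * mu**m * (1.0 - mu) ** (t - m) * rw
    return total


def _shared_deltas(
    a: Mapping[AlleleKey, int], b: Mapping[AlleleKey, int]
) -> np.ndarray:
    shared = a.keys() & b.keys()
    return np.array([a[k] - b[k] for k in shared], dtype=int)


def _ml_t_from_counts(counts: np.ndarray, model: StepwiseModel) -> int:
    logp = model.log_pmf_table(len(counts) - 1)
    loglik = logp @ counts
    return int(np.argmax(loglik))  # ties resolve to the smallest t


def ml_pairwise_distance(
    a: CellSignature | RootSignature,
    b: CellSignature | RootSignature,
    model: StepwiseModel,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> tuple[int, int]:
    """ML estimate of the number of divisions separating two cells.

    Only alleles observed in both cells enter the likelihood (pairwise
    complete, no imputation).  Returns ``(t_hat, overlap)``; ties between
    equally likely separations resolve to the smallest ``t`` (parsimony).
    """
    deltas = _shared_deltas(a.deviations, b.deviations)
    overlap = len(deltas)
    if overlap < min_overlap:
        ida = getattr(a, "cell_id", ROOT_LABEL)
        idb = getattr(b, "cell_id", ROOT_LABEL)
        raise InsufficientOverlapError(
            f"{ida} vs {idb}: only {overlap} shared alleles (< {min_overlap})"
        )
    counts = np.bincount(np.abs(deltas))
    return _ml_t_from_counts(counts, model), overlap


@dataclass
class DistanceMatrix:
    """Symmetric matrix of ML lineage distances (in divisions) plus the
    per-pair count of shared observed alleles."""

    labels: list[str]
    d: np.ndarray
    overlap: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have zero diagonal")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "  " + " ".join(f"{x:.6f}" for x in row) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


def from_phylip(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.asarray(rows)
    return DistanceMatrix(labels=labels, d=d, overlap=np.zeros_like(d, dtype=int))


def build_distance_matrix(
    cells: Sequence[CellSignature],
    root: RootSignature,
    model: StepwiseModel | None = None,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> DistanceMatrix:
    """All pairwise ML distances among cells plus each cell's distance to the
    median pseudo-zygote, which competes as the extra taxon ``root_median``.

    The root signature covers every allele observed in any cell, so root
    distances are never overlap-limited.  Any cell pair below ``min_overlap``
    makes the matrix undefined and raises, listing the offending pairs.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells to build a distance matrix")
    model = model or StepwiseModel()
    order = np.argsort([c.cell_id for c in cells])
    cells = [cells[i] for i in order]
    labels = [c.cell_id for c in cells] + [ROOT_LABEL]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate cell_ids (or a cell named root_median)")

    keys = sorted({k for c in cells for k in c.deviations} | root.deviations.keys())
    idx = {k: j for j, k in enumerate(keys)}
    n = len(labels)
    X = np.zeros((n, len(keys)))
    present = np.zeros((n, len(keys)), dtype=bool)
    for i, c in enumerate(cells):
        for k, v in c.deviations.items():
            X[i, idx[k]] = v
            present[i, idx[k]] = True
    for k, v in root.deviations.items():
        X[-1, idx[k]] = v
        present[-1, idx[k]] = True

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dmax = 1
    counts = np.zeros((len(pairs), 0))
    raw: list[np.ndarray] = []
    bad: list[str] = []
    overlap = np.zeros((n, n), dtype=int)
    for i, j in pairs:
        m = present[i] & present[j]
        k = int(m.sum())
        overlap[i, j] = overlap[j, i] = k
        if k < min_overlap:
            bad.append(f"{labels[i]} vs {labels[j]} ({k} shared)")
            raw.append(np.zeros(1, dtype=int))
            continue
        deltas = np.abs(X[i, m] - X[j, m]).astype(int)
        c = np.bincount(deltas)
        dmax = max(dmax, len(c) - 1)
        raw.append(c)
    if bad:
        raise InsufficientOverlapError(
            "undefined distances for pairs: " + "; ".join(bad)
        )
    C = np.zeros((len(pairs), dmax + 1))
    for r, c in enumerate(raw):
        C[r, : len(c)] = c
    loglik = C @ model.log_pmf_table(dmax).T  # (pairs, t_max+1)
    t_hat = np.argmax(loglik, axis=1)
    d = np.zeros((n, n))
    for (i, j), t in zip(pairs, t_hat):
        d[i, j] = d[j, i] = float(t)
    return DistanceMatrix(labels=labels, d=d, overlap=overlap)


# ---------------------------------------------------------------------------
# mutation-rate calibration


def _rate_loglik(counts_by_depth: dict[int, np.ndarray], mu: float) -> float:
    total = 0.0
    for depth, counts in counts_by_depth.items():
        t_needed = max(depth, 1)
        table = _pmf_table(mu, t_needed)
        probs = table[depth, t_needed : t_needed + len(counts)]
        with np.errstate(divide="ignore"):
            logs = np.log(probs)
        if np.any((counts > 0) & ~np.isfinite(logs)):
            return -np.inf
        total += float(np.sum(counts * np.where(counts > 0, logs, 0.0)))
    return total


def estimate_mutation_rate(
    cells_with_known_depth: Sequence[tuple[CellSignature, int]],
    root: RootSignature,
    grid: np.ndarray | None = None,
) -> float:
    """Calibrate the per-allele per-division mutation rate from cells whose
    division depth is known (ex-vivo style calibration).

    Maximises the stepwise likelihood of each cell's deviations from the root
    at its known depth, first on a log-spaced grid and then by bounded
    refinement around the grid optimum.  If no allele deviates at all the
    likelihood is maximised at the boundary; the lower grid bound is returned
    with a warning.
    """
    if len(cells_with_known_depth) < 2:
        raise ValueError("need at least 2 cells for rate calibration")
    if any(depth < 1 for _, depth in cells_with_known_depth):
        raise ValueError("known depths must be >= 1")
    if grid is None:
        grid = 1.0 / np.geomspace(3.0, 1000.0, 60)
    grid = np.sort(np.asarray(grid, dtype=float))

    counts_by_depth: dict[int, np.ndarray] = {}
    any_mutation = False
    for cell, depth in cells_with_known_depth:
        deltas = _shared_deltas(cell.deviations, root.deviations)
        if deltas.size == 0:
            continue
        c = np.bincount(np.abs(deltas))
        any_mutation = any_mutation or len(c) > 1
        prev = counts_by_depth.get(depth)
        if prev is None:
            counts_by_depth[depth] = c
        else:
            size = max(len(prev), len(c))
            merged = np.zeros(size)
            merged[: len(prev)] += prev
            merged[: len(c)] += c
            counts_by_depth[depth] = merged
    if not counts_by_depth:
        raise ValueError("no alleles shared with the root")
    if not any_mutation:
        warnings.warn(
            "no mutations observed at positive depth; mutation rate is at the "
            "lower grid bound", RuntimeWarning,
        )
        return float(grid[0])

    lls = np.array([_rate_loglik(counts_by_depth, mu) for mu in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[best])
    res = minimize_scalar(
        lambda mu: -_rate_loglik(counts_by_depth, mu),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def squared_distance_depth(
    cell: CellSignature, root: RootSignature
) -> float:
    """Comparison depth estimator: mean squared deviation from the root over
    shared alleles, on the raw squared-step scale.

    Under the stepwise model the expectation is ``mu * depth``, so dividing
    by the assumed rate converts to divisions (a user-supplied linear
    calibration; see :func:`mslineage.synthetic_data.estimator_benchmark`).
    """
    deltas = _shared_deltas(cell.deviations, root.deviations)
    if deltas.size == 0:
        raise InsufficientOverlapError(
            f"{cell.cell_id}: no alleles shared with the root"
        )
    return float(np.mean(deltas.astype(float) ** 2))
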