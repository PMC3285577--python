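"""Cohort-level statistics on estimated cell depths.

Covers the depth-vs-age correlation with a permutation p-value and bootstrap
attenuation check, Kolmogorov-Smirnov contrasts (including the ovariectomy
young-vs-old design), the production-line resampling test with Fisher
combination across mice, the spontaneous-vs-replication mutation tally based
on >2-allele loci, and the mutation-rate sensitivity sweep that re-runs the
whole pipeline across assumed rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, ks_2samp, pearsonr

from .clade_enrichment import FDR_DATA, clustering_detected
from .pipeline import estimate_depths, reconstruct_lineage_tree
from .signature_io import CellSignature, RootSignature
from .stepwise_model import StepwiseModel


@dataclass
class MouseDepthSummary:
    """Per-mouse depth summary for one cell population."""

    mouse_id: str
    age_days: int
    depths: list[float]
    median_depth: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.depths:
            raise ValueError(f"mouse {self.mouse_id}: no depths")
        arr = np.asarray(self.depths, dtype=float)
        self.median_depth = float(np.median(arr))
        self.sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0


@dataclass
class MultiAlleleTally:
    """Spontaneous (>2-allele loci) vs replication-dependent mutation counts.

    GV oocytes carry four chromatid copies per locus, so a spontaneous
    mutation during meiotic arrest typically yields more than two alleles,
    whereas replication-coupled mutations at the two-copy progenitor stage
    yield at most two.  Flagged loci are therefore spontaneous candidates.
    """

    mouse_id: str
    n_multiallelic_loci: int
    n_total_mutations: int

    @property
    def fraction_spontaneous(self) -> float:
        tot = self.n_multiallelic_loci + self.n_total_mutations
        return self.n_multiallelic_loci / tot if tot else 0.0

    @property
    def fraction_replication(self) -> float:
        tot = self.n_multiallelic_loci + self.n_total_mutations
        return self.n_total_mutations / tot if tot else 0.0


# ---------------------------------------------------------------------------
# depth vs age


def depth_age_correlation(
    summaries: Sequence[MouseDepthSummary],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson correlation of per-mouse median depth with age, with a
    one-sided (positive-trend) permutation p-value.

    The p-value uses the add-one estimator ``(1 + b) / (1 + n_perm)`` over
    permutations of the median depth values, so it is never exactly zero.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 mice")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ages = np.array([s.age_days for s in summaries], dtype=float)
    medians = np.array([s.median_depth for s in summaries], dtype=float)
    if np.allclose(medians, medians[0]) or np.allclose(ages, ages[0]):
        raise ValueError("correlation undefined: constant medians or ages")
    r_obs = float(pearsonr(ages, medians)[0])
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        r_perm = float(pearsonr(ages, rng.permutation(medians))[0])
        if r_perm >= r_obs:
            b += 1
    return r_obs, (1 + b) / (1 + n_perm)


def bootstrap_correlation(
    cell_depths: Mapping[str, Sequence[float]],
    ages: Mapping[str, float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Bootstrap the depth-age Pearson R by resampling each mouse's cell
    depths with replacement and recomputing per-mouse medians (1000
    replicates by default).  Returns the mean and the full distribution."""
    mice = sorted(cell_depths)
    if any(len(cell_depths[m]) < 2 for m in mice):
        raise ValueError("need at least 2 cells per mouse")
    age_vec = np.array([ages[m] for m in mice], dtype=float)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    for b in range(n_boot):
        med = [
            float(np.median(rng.choice(cell_depths[m], size=len(cell_depths[m]))))
            for m in mice
        ]
        rs[b] = pearsonr(age_vec, med)[0]
    return float(rs.mean()), rs


def ks_compare(
    depths_a: Sequence[float], depths_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    if len(depths_a) < 3 or len(depths_b) < 3:
        raise ValueError("need at least 3 values per sample")
    res = ks_2samp(depths_a, depths_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ovariectomy_contrast(
    young: Sequence[float], old: Sequence[float]
) -> dict:
    """Depth contrast between oocytes of the ovary removed young and the
    contralateral ovary removed months later (longitudinal design)."""
    if not len(young) or not len(old):
        raise ValueError("both arms must be non-empty")
    young = np.asarray(young, dtype=float)
    old = np.asarray(old, dtype=float)
    out = {
        "median_difference": float(np.median(old) - np.median(young)),
        "mean_young": float(young.mean()),
        "mean_old": float(old.mean()),
        "sem_young": float(young.std(ddof=1) / np.sqrt(len(young))) if len(young) > 1 else 0.0,
        "sem_old": float(old.std(ddof=1) / np.sqrt(len(old))) if len(old) > 1 else 0.0,
    }
    if len(young) >= 3 and len(old) >= 3:
        out["ks_statistic"], out["ks_p"] = ks_compare(young, old)
    return out


# ---------------------------------------------------------------------------
# production-line test


def production_line_test(
    depths_by_age: Mapping[float, Sequence[float]],
    young_observed: Sequence[float],
    n_sim: int = 10_000,
    statistic: str = "median",
    direction: str = "smaller",
    seed: int | None = None,
) -> float:
    """Resampling test of the production-line (depth-guided maturation) model.

    A putative birth-time depth distribution is built by weighting each age
    group equally (uniform over groups, uniform within a group).  Each of the
    ``n_sim`` simulations draws ``len(young_observed)`` depths from it and
    records the chosen statistic (``median`` or ``max``); the p-value is the
    fraction of simulated statistics strictly smaller than the observed one
    (``direction="larger"`` flips the tail).  A young sample below the pooled
    minimum thus returns exactly 0, one above the pooled maximum exactly 1.
    """
    if not young_observed:
        raise ValueError("young_observed must be non-empty")
    groups = [np.asarray(v, dtype=float) for v in depths_by_age.values() if len(v)]
    if len(groups) < 2:
        raise ValueError("need depth values from at least 2 ages")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    stat_fn = {"median": np.median, "max": np.max}.get(statistic)
    if stat_fn is None:
        raise ValueError("statistic must be 'median' or 'max'")
    if direction not in ("smaller", "larger"):
        raise ValueError("direction must be 'smaller' or 'larger'")
    obs = float(stat_fn(np.asarray(young_observed, dtype=float)))
    rng = np.random.default_rng(seed)
    m = len(young_observed)
    which = rng.integers(len(groups), size=(n_sim, m))
    draws = np.empty((n_sim, m))
    for g, vals in enumerate(groups):
        mask = which == g
        draws[mask] = rng.choice(vals, size=int(mask.sum()))
    stats = stat_fn(draws, axis=1)
    if direction == "smaller":
        return float(np.mean(stats < obs))
    return float(np.mean(stats > obs))


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(ps > 1) or np.any(ps < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("p=0 clipped to smallest positive float", RuntimeWarning)
        ps = np.clip(ps, np.finfo(float).tiny, 1.0)
    x = -2.0 * np.sum(np.log(ps))
    return float(chi2.sf(x, df=2 * ps.size))


# ---------------------------------------------------------------------------
# spontaneous mutations and the rate sweep


def spontaneous_mutation_tally(
    cells: Sequence[CellSignature], root: RootSignature
) -> dict[str, MultiAlleleTally]:
    """Per-mouse counts of >2-allele loci (spontaneous candidates) against
    alleles deviating from the root (total observed mutations)."""
    tallies: dict[str, list[int]] = {}
    for cell in cells:
        multi = len(cell.multiallelic_loci)
        muts = sum(
            1
            for key, dev in cell.deviations.items()
            if dev != root.deviations.get(key, 0)
        )
        agg = tallies.setdefault(cell.mouse_id, [0, 0])
        agg[0] += multi
        agg[1] += muts
    return {
        mouse: MultiAlleleTally(mouse, multi, muts)
        for mouse, (multi, muts) in sorted(tallies.items())
    }


DEFAULT_RATE_SWEEP = (1 / 10, 1 / 30, 1 / 50, 1 / 100, 1 / 200)


def mutation_rate_sweep(
    cohort: Mapping[str, tuple[int, Sequence[CellSignature]]],
    rates: Sequence[float] = DEFAULT_RATE_SWEEP,
    population: str = "oocyte",
    q: float = FDR_DATA,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-run distances, trees and depths under each assumed mutation rate.

    ``cohort`` maps mouse_id to ``(age_days, cells)``.  For every rate the
    table reports the depth-age Pearson R (over per-mouse medians of the
    chosen population), its permutation p, and whether the population still
    clusters on any mouse tree that contains a second population -- the
    conclusion-stability check across the 1/10..1/200 range.
    """
    rows = []
    for rate in rates:
        model = StepwiseModel(mu=rate)
        summaries = []
        detected_any = False
        has_mixed = False
        for mouse_id, (age, cells) in sorted(cohort.items()):
            tree, _ = reconstruct_lineage_tree(cells, model)
            from .tree_reconstruction import leaf_depths

            depths = leaf_depths(tree)
            labels = {c.cell_id: c.population for c in cells}
            pop_depths = [
                d for cid, d in depths.items() if labels.get(cid) == population
            ]
            if pop_depths:
                summaries.append(MouseDepthSummary(mouse_id, age, pop_depths))
            if len(set(labels.values())) > 1:
                has_mixed = True
                if clustering_detected(tree, labels, population, q):
                    detected_any = True
        r, p = depth_age_correlation(summaries, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "rate": rate,
                "pearson_r": r,
                "r_positive": r > 0,
                "perm_p": p,
                "clustering_detected": detected_any if has_mixed else None,
            }
        )
    return pd.DataFrame(rows)


def cohort_depth_summaries(
    cohort: Mapping[str, tuple[int, Sequence[CellSignature]]],
    model: StepwiseModel | None = None,
    population: str = "oocyte",
) -> list[MouseDepthSummary]:
    """Run the reconstruction pipeline per mouse and summarise depths of the
    chosen population."""
    out = []
    for mouse_id, (age, cells) in sorted(cohort.items()):
        depths = estimate_depths(cells, model)
        labels = {c.cell_id: c.population for c in cells}
        pop = [d for cid, d in depths.items() if labels.get(cid) == population]
        if pop:
            out.append(MouseDepthSummary(mouse_id, age, pop))
    return out
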