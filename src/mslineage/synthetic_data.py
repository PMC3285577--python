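"""Generative simulator of cell-division genealogies with microsatellite
mutation, allelic dropout and sampling designs, plus the three simulation
studies built on it (depth-estimator benchmark, progenitor-number power
curve, cohort scenarios).

The complete genealogy is a binary tree of depth ``Td`` divisions, never
materialised: a sampled cell is a ``Td``-bit path string, ancestry of any
cell subset is given by pairwise longest common prefixes, and mutations are
laid down along the induced tree so that shared lineage segments mutate once.
A population descends from ``Np`` progenitors drawn without replacement from
the ``2^Tr`` nodes at the restriction division ``Tr`` (8 by default, i.e. 256
candidates); measurement applies per-allele allelic dropout (32.5% by
default) and optional PCR re-measurement duplicates and >2-allele
(spontaneous, four-chromatid stage) locus flags.

Cohort scenarios cover three post-natal models: ``static`` (all mice sample
oocytes at the embryonic depth), ``renewal`` (depth keeps growing with age
through continued progenitor divisions), and ``production_line`` (each mouse
samples an age-ranked quantile band of a fixed birth-time depth
distribution; pre-antral-age mice sample the full range).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clade_enrichment import FDR_SIMULATION, clustering_detected
from .pipeline import estimate_depths, reconstruct_lineage_tree
from .signature_io import (
    CellSignature,
    Locus,
    compute_root_signature,
)
from .stepwise_model import StepwiseModel, squared_distance_depth
from .tree_reconstruction import leaf_depths

DEFAULT_AGES_DAYS = (27, 57, 87, 117, 159, 186, 268, 303, 365)


@dataclass(frozen=True)
class SimScenario:
    """Full generative configuration for one simulated data set."""

    td: int = 25  # tree depth in divisions
    n_progenitors: int = 6  # Np, restricted at the restriction division
    restriction_division: int = 8  # Tr; 2^Tr candidate progenitors
    n_cells: int = 30  # cells sampled per population
    n_loci: int = 81  # diploid loci -> 162 alleles
    mu: float = 1.0 / 30.0  # per-allele per-division mutation rate
    dropout: float = 0.325  # per-allele amplification failure probability
    pcr_repeat_pairs: int = 0
    gv_multiallele_rate: float = 0.0  # per-cell per-locus >2-allele rate
    step_up_prob: float = 0.5  # +1 step probability (0.5 = symmetric)
    mode: str = "static"
    ages_days: tuple[int, ...] = DEFAULT_AGES_DAYS
    renewal_divisions_per_100d: float = 2.0
    birth_depth_range: tuple[int, int] = (13, 25)
    preantral_age_days: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.restriction_division < self.td:
            raise ValueError("need 0 < restriction_division < td")
        if not 1 <= self.n_progenitors <= 2**self.restriction_division:
            raise ValueError("need 1 <= n_progenitors <= 2^restriction_division")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.step_up_prob < 1.0:
            raise ValueError("step_up_prob must be in (0, 1)")


@dataclass
class SimCell:
    """A sampled cell: its root-to-cell path in the complete binary tree."""

    cell_id: str
    path: str  # bit string; len(path) = true depth in divisions
    population: str = "oocyte"
    ovary_side: Optional[str] = None

    @property
    def depth(self) -> int:
        return len(self.path)


@dataclass
class TrueGenealogy:
    """Sampled cells plus the ancestry they induce via common prefixes."""

    cells: list[SimCell]

    def divergence(self, i: int, j: int) -> int:
        """Number of divisions separating cells i and j (path through MRCA)."""
        a, b = self.cells[i].path, self.cells[j].path
        lcp = 0
        for x, y in zip(a, b):
            if x != y:
                break
            lcp += 1
        return (len(a) - lcp) + (len(b) - lcp)

    def true_depths(self) -> dict[str, int]:
        return {c.cell_id: c.depth for c in self.cells}


def _bits(value: int, width: int) -> str:
    return format(int(value), f"0{width}b") if width else ""


def simulate_genealogy(
    scn: SimScenario,
    rng: np.random.Generator | None = None,
    n_background: int = 0,
    depths: Sequence[int] | None = None,
    prefix: str = "c",
) -> TrueGenealogy:
    """Sample cells from the complete division tree under lineage restriction.

    The focal population draws its cells uniformly from the descendants of
    ``Np`` progenitors chosen without replacement at division ``Tr``;
    background cells (population ``other``) come from the complement of those
    progenitors.  ``depths`` overrides the per-cell depth (defaults to
    ``td`` for every cell); every depth must exceed ``Tr``.
    """
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    tr = scn.restriction_division
    n_nodes = 2**tr
    progenitors = rng.choice(n_nodes, size=scn.n_progenitors, replace=False)
    prog_set = set(int(p) for p in progenitors)
    if depths is None:
        depths = [scn.td] * scn.n_cells
    if len(depths) != scn.n_cells:
        raise ValueError("depths must have one entry per cell")
    if any(d <= tr for d in depths):
        raise ValueError("every cell depth must exceed the restriction division")
    cells = []
    for i, depth in enumerate(depths):
        head = _bits(progenitors[rng.integers(scn.n_progenitors)], tr)
        tail = "".join(map(str, rng.integers(0, 2, size=depth - tr)))
        cells.append(SimCell(f"{prefix}{i:03d}", head + tail, "oocyte"))
    if n_background:
        complement = np.array(
            [v for v in range(n_nodes) if v not in prog_set], dtype=int
        )
        if complement.size == 0:
            raise ValueError("no complement nodes left for background cells")
        for i in range(n_background):
            head = _bits(complement[rng.integers(len(complement))], tr)
            tail = "".join(map(str, rng.integers(0, 2, size=scn.td - tr)))
            cells.append(SimCell(f"{prefix}bg{i:03d}", head + tail, "other"))
    return TrueGenealogy(cells=cells)


def simulate_ovary_genealogy(
    scn: SimScenario,
    rng: np.random.Generator | None = None,
    coherent: bool = True,
    per_side: int = 15,
) -> TrueGenealogy:
    """Two-ovary sampling design for the left/right mixing analysis.

    ``coherent=True`` splits the progenitor pool disjointly between the
    ovaries (spatially coherent expansion-migration: sides should cluster);
    ``coherent=False`` lets every cell draw any progenitor (incoherent
    mixing: sides should not cluster beyond the FDR level).
    """
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    tr = scn.restriction_division
    if coherent and scn.n_progenitors < 2:
        raise ValueError("coherent migration needs at least 2 progenitors")
    progenitors = rng.choice(
        2**tr, size=scn.n_progenitors, replace=False
    )
    half = scn.n_progenitors // 2
    pools = {
        "left": progenitors[:half] if coherent else progenitors,
        "right": progenitors[half:] if coherent else progenitors,
    }
    cells = []
    for side in ("left", "right"):
        pool = pools[side]
        for i in range(per_side):
            head = _bits(pool[rng.integers(len(pool))], tr)
            tail = "".join(map(str, rng.integers(0, 2, size=scn.td - tr)))
            cells.append(
                SimCell(f"{side[0]}{i:03d}", head + tail, "oocyte", ovary_side=side)
            )
    return TrueGenealogy(cells=cells)


# ---------------------------------------------------------------------------
# mutation + measurement


def default_panel(n_loci: int = 81) -> list[Locus]:
    """Synthetic locus panel with well-separated strain reference sizes."""
    return [Locus(f"L{i:03d}", 2, 20, 40) for i in range(n_loci)]


def _walk(edge_len: int, n_alleles: int, mu: float, p_up: float,
          rng: np.random.Generator) -> np.ndarray:
    m = rng.binomial(edge_len, mu, size=n_alleles)
    return 2 * rng.binomial(m, p_up) - m


def _simulate_deviations(
    paths: Sequence[str],
    n_alleles: int,
    mu: float,
    p_up: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Deviation matrix for the sampled cells, mutating along the induced
    tree so that shared lineage segments receive a single shared walk."""
    dev = np.zeros((len(paths), n_alleles), dtype=np.int64)

    def rec(indices: list[int], at: int, inherited: np.ndarray) -> None:
        # extend the shared prefix as far as it goes
        l = at
        while True:
            if any(len(paths[i]) == l for i in indices):
                break
            bits = {paths[i][l] for i in indices}
            if len(bits) > 1:
                break
            l += 1
        if l > at:
            inherited = inherited + _walk(l - at, n_alleles, mu, p_up, rng)
        rest = []
        for i in indices:
            if len(paths[i]) == l:
                dev[i] = inherited
            else:
                rest.append(i)
        if not rest:
            return
        for bit in ("0", "1"):
            sub = [i for i in rest if paths[i][l] == bit]
            if sub:
                rec(sub, l, inherited)

    rec(list(range(len(paths))), 0, np.zeros(n_alleles, dtype=np.int64))
    return dev


def mutate_and_measure(
    gen: TrueGenealogy,
    scn: SimScenario,
    rng: np.random.Generator | None = None,
    mouse_id: str = "M0",
    age_days: int = 0,
) -> list[CellSignature]:
    """Accumulate stepwise mutations along the induced genealogy, then apply
    the measurement process: allelic dropout, optional >2-allele locus flags
    (spontaneous events at the four-chromatid GV stage, excluded from the
    deviations as the QC pipeline requires), and optional PCR re-measurement
    duplicates sharing the true genotype but with independent dropout."""
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    n_alleles = 2 * scn.n_loci
    keys = [(f"L{i:03d}", p) for i in range(scn.n_loci) for p in ("A", "B")]
    paths = [c.path for c in gen.cells]
    dev = _simulate_deviations(paths, n_alleles, scn.mu, scn.step_up_prob, rng)

    def build(cell: SimCell, row: np.ndarray, cell_id: str,
              repeat_of: Optional[str]) -> CellSignature:
        keep = rng.random(n_alleles) >= scn.dropout
        deviations = {
            keys[a]: int(row[a]) for a in range(n_alleles) if keep[a]
        }
        multi: set[str] = set()
        if scn.gv_multiallele_rate > 0:
            flags = rng.random(scn.n_loci) < scn.gv_multiallele_rate
            for li in np.nonzero(flags)[0]:
                locus = f"L{li:03d}"
                multi.add(locus)
                deviations.pop((locus, "A"), None)
                deviations.pop((locus, "B"), None)
        return CellSignature(
            cell_id=cell_id,
            mouse_id=mouse_id,
            age_days=age_days,
            population=cell.population,
            ovary_side=cell.ovary_side,
            plate_id="P1",
            is_pcr_repeat_of=repeat_of,
            deviations=deviations,
            multiallelic_loci=multi,
        )

    out = [
        build(cell, dev[i], cell.cell_id, None)
        for i, cell in enumerate(gen.cells)
    ]
    for r in range(min(scn.pcr_repeat_pairs, len(gen.cells))):
        cell = gen.cells[r]
        out.append(build(cell, dev[r], f"{cell.cell_id}_rep", cell.cell_id))
    return out


def corrupt_signals(
    cells: Sequence[CellSignature],
    fraction: float,
    rng: np.random.Generator,
) -> list[CellSignature]:
    """Signal-error model for robustness runs: each observed allele is
    independently corrupted by +-1 repeat with probability ``fraction``."""
    out = []
    for cell in cells:
        cell = cell.copy()
        for key in list(cell.deviations):
            if rng.random() < fraction:
                cell.deviations[key] += 1 if rng.random() < 0.5 else -1
        out.append(cell)
    return out


# ---------------------------------------------------------------------------
# cohort scenarios


def _mouse_depths(
    scn: SimScenario, age: int, rank: int, n_ranked: int,
    rng: np.random.Generator,
) -> list[int]:
    if scn.mode == "static":
        return [scn.td] * scn.n_cells
    if scn.mode == "renewal":
        extra = scn.renewal_divisions_per_100d * age / 100.0
        return [int(round(scn.td + extra))] * scn.n_cells
    if scn.mode == "production_line":
        lo, hi = scn.birth_depth_range
        if age <= scn.preantral_age_days or n_ranked <= 1:
            return [int(d) for d in rng.integers(lo, hi + 1, size=scn.n_cells)]
        band_lo = lo + (hi - lo) * rank / n_ranked
        band_hi = lo + (hi - lo) * (rank + 1) / n_ranked
        a, b = int(round(band_lo)), max(int(round(band_hi)), int(round(band_lo)) + 1)
        return [int(d) for d in rng.integers(a, b + 1, size=scn.n_cells)]
    raise ValueError(f"unknown cohort mode {scn.mode!r}")


def scenario_cohort(
    scn: SimScenario,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[int, list[CellSignature]]]:
    """Simulate one mouse per configured age under the scenario's post-natal
    model; each mouse gets its own genealogy, measured through the full
    noise model.  Returns ``mouse_id -> (age_days, cells)``."""
    if not scn.ages_days:
        raise ValueError("scenario has no ages_days")
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    ranked_ages = sorted(
        a for a in scn.ages_days if a > scn.preantral_age_days
    )
    cohort: dict[str, tuple[int, list[CellSignature]]] = {}
    for i, age in enumerate(scn.ages_days):
        rank = ranked_ages.index(age) if age in ranked_ages else 0
        depths = _mouse_depths(scn, age, rank, len(ranked_ages), rng)
        gen = simulate_genealogy(scn, rng, depths=depths)
        mouse_id = f"M{i:02d}_a{age}"
        cohort[mouse_id] = (
            age,
            mutate_and_measure(gen, scn, rng, mouse_id=mouse_id, age_days=age),
        )
    return cohort


# ---------------------------------------------------------------------------
# simulation studies


def estimator_benchmark(
    td_values: Sequence[int] = (25, 45),
    n_iter: int = 50,
    scn: SimScenario | None = None,
    corrupt_fraction: float = 0.0,
    step_up_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias and efficiency of the two depth estimators on known-depth trees.

    Cells are sampled uniformly from the whole binary tree (30 cells per
    iteration by default), measured with the full noise model, and each
    iteration's cohort-median depth is estimated by (a) the tree-ML pipeline
    and (b) the mean-squared-deviation estimator calibrated by ``1/mu``.
    Robustness variants corrupt a fraction of observed alleles by +-1 and/or
    skew the step direction away from symmetric.
    """
    scn = scn or SimScenario()
    rows = []
    for td in td_values:
        cfg = dataclasses.replace(
            scn,
            td=td,
            n_progenitors=2**scn.restriction_division,
            step_up_prob=step_up_prob,
        )
        # the estimation model needs a strictly positive rate even when the
        # generating process is the mutation-free corner case
        model = StepwiseModel(mu=cfg.mu if cfg.mu > 0 else 1.0 / 30.0)
        est = {"tree_ml": [], "squared_distance": []}
        rng = np.random.default_rng(seed + td)
        for _ in range(n_iter):
            gen = simulate_genealogy(cfg, rng)
            cells = mutate_and_measure(gen, cfg, rng)
            if corrupt_fraction > 0:
                cells = corrupt_signals(cells, corrupt_fraction, rng)
            depths = estimate_depths(cells, model)
            est["tree_ml"].append(float(np.median(list(depths.values()))))
            root = compute_root_signature(cells)
            sq = [squared_distance_depth(c, root) / model.mu for c in cells]
            est["squared_distance"].append(float(np.median(sq)))
        for name, vals in est.items():
            vals = np.asarray(vals)
            rows.append(
                {
                    "td": td,
                    "estimator": name,
                    "mean_estimate": vals.mean(),
                    "bias": vals.mean() - td,
                    "sem": vals.std(ddof=1) / np.sqrt(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def progenitor_power_study(
    np_grid: Sequence[int] = (1, 2, 4, 8, 16, 30),
    n_cells: int = 30,
    n_trees: int = 50,
    q: float = FDR_SIMULATION,
    scn: SimScenario | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of simulated trees in which the focal population clusters,
    as a function of its progenitor number Np.

    Each tree samples ``n_cells`` from the restricted population and
    ``n_cells`` from the rest of the division tree; detection uses the
    per-branch hypergeometric test at the simulation FDR (0.05).  Power
    falls as Np approaches the number of sampled cells.
    """
    scn = scn or SimScenario()
    rows = []
    for np_value in np_grid:
        cfg = dataclasses.replace(scn, n_progenitors=np_value, n_cells=n_cells)
        model = StepwiseModel(mu=cfg.mu)
        rng = np.random.default_rng(seed + 1000 * np_value)
        hits = 0
        for _ in range(n_trees):
            gen = simulate_genealogy(cfg, rng, n_background=n_cells)
            cells = mutate_and_measure(gen, cfg, rng)
            tree, _ = reconstruct_lineage_tree(cells, model)
            labels = {c.cell_id: c.population for c in cells}
            if clustering_detected(tree, labels, "oocyte", q):
                hits += 1
        frac = hits / n_trees
        rows.append(
            {
                "n_progenitors": np_value,
                "detection_fraction": frac,
                "se": np.sqrt(frac * (1 - frac) / n_trees),
                "n_trees": n_trees,
            }
        )
    return pd.DataFrame(rows)


def subsampled_power(
    cells: Sequence[CellSignature],
    population: str,
    sizes: Sequence[int],
    n_iter: int = 30,
    q: float = FDR_SIMULATION,
    model: StepwiseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Companion to the power study: subsample an existing cohort at sizes
    ``s`` (s cells of the population, s of the rest) and report the fraction
    of subsamples in which the population clusters."""
    model = model or StepwiseModel()
    pop = [c for c in cells if c.population == population]
    rest = [c for c in cells if c.population != population]
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        if s > len(pop) or s > len(rest):
            raise ValueError(f"subsample size {s} exceeds available cells")
        hits = 0
        for _ in range(n_iter):
            chosen = [pop[i] for i in rng.choice(len(pop), s, replace=False)]
            chosen += [rest[i] for i in rng.choice(len(rest), s, replace=False)]
            tree, _ = reconstruct_lineage_tree(chosen, model)
            labels = {c.cell_id: c.population for c in chosen}
            if clustering_detected(tree, labels, population, q):
                hits += 1
        frac = hits / n_iter
        rows.append(
            {"size": s, "detection_fraction": frac,
             "se": np.sqrt(frac * (1 - frac) / n_iter)}
        )
    return pd.DataFrame(rows)
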