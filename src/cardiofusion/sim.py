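"""Synthetic lineages, polyploid cells and targeted read counts.

The generator emulates the structure of a single-donor cardiomyocyte lineage
assay: a nested clade tree whose branches carry clonal sSNVs, a fixed
targeted panel of ~253 sites sequenced to ~7000X, MDA-style allelic and
locus dropout, ploidy-dependent cell fusion (two-cell events dominate;
three- and four-cell fusions only in the >4n class) and rare double-sorted
nuclei.  Full ground truth is retained so the downstream pipeline can be
audited cell by cell.

Dropout model
-------------
Per (cell, site) a single uniform draw is partitioned into mutually
exclusive events: locus dropout with probability ``locus_dropout`` (depth
resampled below the 30X genotyping floor), loss of all alt-allele copies
with probability ``allelic_dropout``, and loss of all reference copies with
probability ``beta = AD (1 - LD - AD) / (2 - AD)``.  Two consequences, by
construction: a carried sSNV is missed with probability exactly AD + LD
(the quantity the capture model ``r_i = sum S_in (1 - (AD+LD)^n)``
consumes), and the closed-form estimator ``AD = 2 P_althom /
(P_het + 2 P_althom)`` is consistent for ``allelic_dropout``.  A
``symmetric`` mode (ref and alt classes drop at the same rate, as physical
MDA dropout would) and a ``per_copy`` mode (each alt copy drops
independently) are available; under those the closed-form estimator is
biased, which is a limitation of the estimator, not of the generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PLOIDY_CLASSES = ("diploid", "tetraploid", "higher")
_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: a 9-clade, 253-site panel at 7000X depth,
    cohort sizes 182/173/127 (2n/4n/>4n), two-cell-dominated fusion."""

    n_clades: int = 9
    ssnvs_per_branch: int | tuple[int, int] = (1, 5)
    panel_size: int | None = 253  # None: no non-clonal filler sites
    n_cells_by_ploidy: dict[str, int] = field(
        default_factory=lambda: {"diploid": 182, "tetraploid": 173, "higher": 127}
    )
    fusion_fraction_by_ploidy: dict[str, float] = field(
        default_factory=lambda: {"diploid": 0.0, "tetraploid": 0.13, "higher": 0.63}
    )
    fusion_arity_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.84, 3: 0.10, 4: 0.06}
    )
    doublet_rate: float = 0.005
    clade_weights: tuple[float, ...] | None = None
    allelic_dropout: float = 0.25
    locus_dropout: float = 0.10
    mean_depth: float = 7000.0
    depth_dispersion: float = 5.0
    base_error: float = 0.003
    seed: int = 0
    dropout_mode: str = "model"  # model | symmetric | per_copy

    def __post_init__(self) -> None:
        if self.n_clades < 1:
            raise ValueError("n_clades must be >= 1")
        lo, hi = self.ssnv_range()
        if hi < 1:
            raise ValueError("terminal clades need >= 1 defining sSNV")
        if lo < 0 or hi < lo:
            raise ValueError("invalid ssnvs_per_branch")
        for name in ("doublet_rate", "allelic_dropout", "locus_dropout", "base_error"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for pc, f in self.fusion_fraction_by_ploidy.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fusion fraction for {pc} must lie in [0, 1]")
        if self.allelic_dropout + self.locus_dropout >= 1:
            raise ValueError("allelic_dropout + locus_dropout must be < 1")
        if self.clade_weights is not None:
            w = np.asarray(self.clade_weights, float)
            if len(w) != self.n_clades:
                raise ValueError("clade_weights length must equal n_clades")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("clade_weights must be a probability vector")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")
        if self.dropout_mode not in ("model", "symmetric", "per_copy"):
            raise ValueError("dropout_mode must be model, symmetric or per_copy")
        if not set(self.fusion_arity_weights) <= {2, 3, 4}:
            raise ValueError("fusion arities must be in {2, 3, 4}")

    def ssnv_range(self) -> tuple[int, int]:
        if isinstance(self.ssnvs_per_branch, int):
            return self.ssnvs_per_branch, self.ssnvs_per_branch
        lo, hi = self.ssnvs_per_branch
        return int(lo), int(hi)

    def weights(self) -> np.ndarray:
        if self.clade_weights is None:
            return np.full(self.n_clades, 1.0 / self.n_clades)
        return np.asarray(self.clade_weights, float)

    def ref_dropout(self) -> float:
        """Ref-class dropout rate implied by the chosen mode."""
        ad, ld = self.allelic_dropout, self.locus_dropout
        if self.dropout_mode == "symmetric":
            return ad
        if self.dropout_mode == "per_copy":
            return 0.0
        # model mode: rate that makes the closed-form AD estimator consistent
        return ad * (1.0 - ld - ad) / (2.0 - ad)


@dataclass
class TrueLineage:
    """Nested clade tree with per-branch sSNV sets."""

    children: dict[int, tuple[int, int]]  # internal node -> (left, right)
    leaf_clade: dict[int, int]  # leaf node -> clade index
    branch_ssnvs: dict[int, list[str]]  # node (== its parent branch) -> site_ids
    clade_defs: dict[int, list[str]]  # clade -> its terminal-branch (specific) sites
    clade_sites: dict[int, list[str]]  # clade -> all sites on root-to-leaf path
    panel: pd.DataFrame  # site_id, chrom, pos, ref, alt, truth_branch
    root: int

    @property
    def n_clades(self) -> int:
        return len(self.clade_defs)

    def informative_sites(self) -> list[str]:
        return [s for sites in self.branch_ssnvs.values() for s in sites]


@dataclass
class SimCell:
    cell_id: str
    ploidy_class: str
    origin_clades: tuple[int, ...]
    is_doublet: bool
    genome_copies: int
    true_sites: dict[str, int]  # site -> alt copy count
    component_sites: list[tuple[int, dict[str, int]]] | None = None  # doublets

    @property
    def is_fused(self) -> bool:
        return (not self.is_doublet) and len(self.origin_clades) >= 2

    @property
    def n_distinct_origins(self) -> int:
        return len(set(self.origin_clades))


@dataclass
class ObservationBundle:
    counts: pd.DataFrame  # cell_id, site_id, depth, alt_count, mean_base_error
    cells: pd.DataFrame  # per-cell ground truth
    panel: pd.DataFrame
    lineage: TrueLineage
    config: SimConfig
    dropout_stats: dict[str, int]


def build_lineage(config: SimConfig, rng: np.random.Generator) -> TrueLineage:
    """Random nested binary clade tree with per-branch clonal sSNVs.

    Every node below the root is a branch carrying a drawn number of sSNVs;
    terminal branches carry at least one, so every clade has one or more
    clade-specific sSNVs.  Remaining panel capacity is filled with
    non-clonal filler sites (alt reads arise only through base error).
    """
    lo, hi = config.ssnv_range()
    n = config.n_clades
    children: dict[int, tuple[int, int]] = {}
    leaf_clade: dict[int, int] = {}
    next_id = [0]

    def new_node() -> int:
        i = next_id[0]
        next_id[0] += 1
        return i

    def grow(clades: np.ndarray) -> int:
        node = new_node()
        if len(clades) == 1:
            leaf_clade[node] = int(clades[0])
            return node
        k = int(rng.integers(1, len(clades)))
        perm = rng.permutation(clades)
        left = grow(np.sort(perm[:k]))
        right = grow(np.sort(perm[k:]))
        children[node] = (left, right)
        return node

    root = grow(np.arange(n))

    branch_ssnvs: dict[int, list[str]] = {}
    counter = [0]

    def site_batch(k: int) -> list[str]:
        out = [f"s{counter[0] + i:04d}" for i in range(k)]
        counter[0] += k
        return out

    def assign(node: int) -> None:
        if node != root:
            is_terminal = node in leaf_clade
            low = max(lo, 1) if is_terminal else lo
            k = int(rng.integers(low, hi + 1)) if hi > low else low
            branch_ssnvs[node] = site_batch(k)
        for ch in children.get(node, ()):  # pre-order: stable ids
            assign(ch)

    # handle the degenerate single-clade lineage: the lone leaf is the root
    if n == 1:
        leaf = root
        branch_ssnvs[leaf] = site_batch(max(lo, 1))
    else:
        assign(root)

    total_informative = sum(len(v) for v in branch_ssnvs.values())
    if config.panel_size is not None and config.panel_size < total_informative:
        raise ValueError(
            f"panel_size {config.panel_size} < {total_informative} informative sSNVs"
        )

    # root-to-leaf accumulation
    clade_defs: dict[int, list[str]] = {}
    clade_sites: dict[int, list[str]] = {}

    def walk(node: int, acc: list[str]) -> None:
        acc = acc + branch_ssnvs.get(node, [])
        if node in leaf_clade:
            clade = leaf_clade[node]
            clade_defs[clade] = list(branch_ssnvs.get(node, []))
            clade_sites[clade] = acc
            return
        for ch in children[node]:
            walk(ch, acc)

    walk(root, [])

    n_filler = (
        0 if config.panel_size is None else config.panel_size - total_informative
    )
    filler = [f"f{j:04d}" for j in range(n_filler)]
    site_ids = [s for node in sorted(branch_ssnvs) for s in branch_ssnvs[node]] + filler
    truth_branch = {s: str(node) for node, sites in branch_ssnvs.items() for s in sites}
    refs = _BASES[rng.integers(0, 4, size=len(site_ids))]
    alts = np.array(
        [rng.choice([b for b in _BASES if b != r]) for r in refs]
    )
    panel = pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": [f"chr{1 + (i % 22)}" for i in range(len(site_ids))],
            "pos": 1000 + 500 * np.arange(len(site_ids)),
            "ref": refs,
            "alt": alts,
            "truth_branch": [truth_branch.get(s, "filler") for s in site_ids],
        }
    )
    return TrueLineage(
        children=children,
        leaf_clade=leaf_clade,
        branch_ssnvs=branch_ssnvs,
        clade_defs=clade_defs,
        clade_sites=clade_sites,
        panel=panel,
        root=root,
    )


def _origin_copy_number(ploidy_class: str, arity: int) -> int:
    """Haploid genome copies contributed by each origin cell.

    Unfused nuclei are endoreplicated diploids (het sSNVs keep allele
    fraction 0.5).  Two-cell >4n fusions merge two tetraploid nuclei (4
    copies each); all other fusion origins contribute a diploid genome.
    """
    if arity == 1:
        return {"diploid": 2, "tetraploid": 4, "higher": 8}.get(ploidy_class, 2)
    if ploidy_class == "higher" and arity == 2:
        return 4
    return 2


def sample_cells(
    lineage: TrueLineage, config: SimConfig, rng: np.random.Generator
) -> list[SimCell]:
    """Draw the configured cohort: unfused, fused and doublet nuclei.

    Fusion origin clades are sampled independently from the clade weights,
    so same-clade fusions occur with probability sum p_i^2 and are
    undetectable by design.  Doublets are two independent unfused nuclei
    merged only at the observation level.
    """
    if config.n_clades == 1 and any(
        f > 0 for f in config.fusion_fraction_by_ploidy.values()
    ):
        warnings.warn("single clade: all fusions are same-clade and undetectable")
    weights = config.weights()
    arities = np.array(sorted(config.fusion_arity_weights))
    arity_w = np.array([config.fusion_arity_weights[a] for a in arities], float)
    arity_w = arity_w / arity_w.sum()

    cells: list[SimCell] = []
    for pc, n_cells in config.n_cells_by_ploidy.items():
        f_fuse = config.fusion_fraction_by_ploidy.get(pc, 0.0)
        for i in range(n_cells):
            cell_id = f"{pc}_{i:05d}"
            u = rng.random()
            if u < config.doublet_rate:
                comp_origins = rng.choice(config.n_clades, size=2, p=weights)
                copies = _origin_copy_number(pc, 1)
                comps = []
                for oc in comp_origins:
                    sites = {s: copies // 2 for s in lineage.clade_sites[int(oc)]}
                    comps.append((copies, sites))
                merged: dict[str, int] = {}
                for _, sites in comps:
                    for s, c in sites.items():
                        merged[s] = merged.get(s, 0) + c
                cells.append(
                    SimCell(
                        cell_id=cell_id,
                        ploidy_class=pc,
                        origin_clades=tuple(int(o) for o in comp_origins),
                        is_doublet=True,
                        genome_copies=sum(c for c, _ in comps),
                        true_sites=merged,
                        component_sites=comps,
                    )
                )
                continue
            fused = rng.random() < f_fuse
            if fused:
                arity = (
                    int(rng.choice(arities, p=arity_w)) if pc == "higher" else 2
                )
            else:
                arity = 1
            origins = rng.choice(config.n_clades, size=arity, p=weights)
            per_origin = _origin_copy_number(pc, arity)
            true_sites: dict[str, int] = {}
            for oc in origins:
                for s in lineage.clade_sites[int(oc)]:
                    true_sites[s] = true_sites.get(s, 0) + per_origin // 2
            cells.append(
                SimCell(
                    cell_id=cell_id,
                    ploidy_class=pc,
                    origin_clades=tuple(int(o) for o in origins),
                    is_doublet=False,
                    genome_copies=per_origin * arity,
                    true_sites=true_sites,
                )
            )
    return cells


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_reads(
    cells: list[SimCell],
    lineage: TrueLineage,
    config: SimConfig,
    rng: np.random.Generator,
) -> ObservationBundle:
    """Draw per-(cell, site) depths and alt read counts.

    Depth is negative binomial around ``mean_depth``.  Dropout events are
    applied per (cell, site) as described in the module docstring; locus
    dropout resamples depth uniformly on [0, 29] so affected sites fail the
    30X rule exactly.  Alt reads are binomial with success probability
    ``f (1 - eps) + (1 - f) eps / 3`` where ``f`` is the post-dropout
    alt-copy fraction — non-carried sites accumulate alt reads only through
    ref->alt miscalls at rate eps/3.  Doublet observations are the read-level
    sum over the two component nuclei.
    """
    site_ids = list(lineage.panel["site_id"])
    site_index = {s: j for j, s in enumerate(site_ids)}
    n_sites = len(site_ids)

    # expand doublets into component "units"
    unit_cell: list[int] = []
    unit_alt: list[dict[str, int]] = []
    unit_copies: list[int] = []
    for ci, cell in enumerate(cells):
        if cell.is_doublet and cell.component_sites is not None:
            for copies, sites in cell.component_sites:
                unit_cell.append(ci)
                unit_alt.append(sites)
                unit_copies.append(copies)
        else:
            unit_cell.append(ci)
            unit_alt.append(cell.true_sites)
            unit_copies.append(cell.genome_copies)
    n_units = len(unit_cell)

    alt_copies = np.zeros((n_units, n_sites), dtype=np.int16)
    for ui, sites in enumerate(unit_alt):
        for s, c in sites.items():
            alt_copies[ui, site_index[s]] = c
    total_copies = np.asarray(unit_copies, dtype=np.int16)[:, None]

    depth = _nb_depth(rng, config.mean_depth, config.depth_dispersion, (n_units, n_sites))
    u = rng.random((n_units, n_sites))
    ld, ad = config.locus_dropout, config.allelic_dropout
    beta = config.ref_dropout()
    carried = alt_copies > 0

    locus = u < ld
    if config.dropout_mode == "per_copy":
        alt_drop = np.zeros_like(carried)
        post_alt = np.where(
            carried & ~locus,
            rng.binomial(alt_copies, 1.0 - ad),
            alt_copies,
        )
        n_alt_dropped = int(((alt_copies - post_alt) > 0).sum())
        ref_drop = np.zeros_like(carried)
    else:
        alt_drop = carried & (u >= ld) & (u < ld + ad)
        ref_drop = carried & (u >= ld + ad) & (u < ld + ad + beta)
        post_alt = np.where(alt_drop, 0, alt_copies)
        n_alt_dropped = int(alt_drop.sum())

    n_locus = int(locus.sum())
    if n_locus:
        depth = np.where(locus, rng.integers(0, 30, size=depth.shape), depth)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_copies > 0, post_alt / total_copies, 0.0)
    frac = np.where(ref_drop, 1.0, frac)
    eps = config.base_error
    theta = frac * (1.0 - eps) + (1.0 - frac) * (eps / 3.0)
    alt_reads = rng.binomial(depth, theta)

    # merge units back into cells
    n_cells = len(cells)
    cell_depth = np.zeros((n_cells, n_sites), dtype=np.int64)
    cell_alt = np.zeros((n_cells, n_sites), dtype=np.int64)
    for ui, ci in enumerate(unit_cell):
        cell_depth[ci] += depth[ui]
        cell_alt[ci] += alt_reads[ui]

    cell_ids = [c.cell_id for c in cells]
    counts = pd.DataFrame(
        {
            "cell_id": np.repeat(cell_ids, n_sites),
            "site_id": np.tile(site_ids, n_cells),
            "depth": cell_depth.ravel(),
            "alt_count": cell_alt.ravel(),
            "mean_base_error": eps,
        }
    )
    cells_df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "ploidy_class": [c.ploidy_class for c in cells],
            "is_doublet": [c.is_doublet for c in cells],
            "is_fused": [c.is_fused for c in cells],
            "n_origins": [len(c.origin_clades) for c in cells],
            "n_distinct_origins": [c.n_distinct_origins for c in cells],
            "origin_clades": [
                ",".join(str(o) for o in c.origin_clades) for c in cells
            ],
            "genome_copies": [c.genome_copies for c in cells],
        }
    )
    stats = {
        "n_entries": n_units * n_sites,
        "n_carried_entries": int(carried.sum()),
        "n_locus_dropout": n_locus,
        "n_alt_dropout": n_alt_dropped,
        "n_ref_dropout": int(np.asarray(ref_drop).sum()),
    }
    return ObservationBundle(
        counts=counts,
        cells=cells_df,
        panel=lineage.panel,
        lineage=lineage,
        config=config,
        dropout_stats=stats,
    )


def simulate_dataset(config: SimConfig) -> ObservationBundle:
    """Lineage -> cells -> reads with all randomness from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    lineage = build_lineage(config, rng)
    cells = sample_cells(lineage, config, rng)
    return simulate_reads(cells, lineage, config, rng)


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``config`` with fields replaced (validated)."""
    return replace(config, **kwargs)
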