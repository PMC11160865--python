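"""End-to-end orchestration: simulate/load -> genotype -> clade -> correct.

`run_pipeline` ties the stages together, writes every intermediate artifact
(sites.tsv, counts.tsv, genotypes.tsv, clades.tsv, assignments.tsv, a Newick
dendrogram) and produces a structured report with per-ploidy-class dropout
estimates, detection sensitivities, corrected fusion fractions and pairwise
proportion tests.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from . import fusion_stats as fs
from . import genotyping as gt
from . import lineage as lin
from . import sim as simmod


@dataclass
class RunConfig:
    out_dir: str = "cardiofusion_run"
    seed: int = 0
    counts_path: str | None = None  # when None, simulate
    sites_path: str | None = None
    cells_path: str | None = None  # per-cell ploidy labels when loading
    panel_format: str = "tsv"  # tsv | vcf
    min_depth: int = 30
    min_alt_reads: int = 5
    min_vaf: float = 0.05
    refhom_cutoff: float = 0.5
    min_carriers: int = 2
    target_clades: int | None = None
    s_in_mode: str = "deconvolved"  # deconvolved | observed
    test_methods: tuple[str, ...] = ("z", "z-cc", "fisher")
    priors: gt.GenotypePriors = field(default_factory=gt.GenotypePriors)
    sim: simmod.SimConfig | None = None
    doublet_screen_class: str = "diploid"
    write_artifacts: bool = True

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_alt_reads <= 0 or self.min_vaf <= 0:
            raise ValueError("calling thresholds must be positive")


def validate_inputs(
    counts: pd.DataFrame,
    sites: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    known_ploidy_classes: tuple[str, ...] = simmod.PLOIDY_CLASSES,
) -> list[dict]:
    """Structured diagnostics over input tables (fatal and warning levels)."""
    diags: list[dict] = []

    def diag(level: str, message: str) -> None:
        diags.append({"level": level, "message": message})

    dup_sites = sites["site_id"].duplicated()
    if dup_sites.any():
        diag("fatal", f"duplicated site_id(s): {sorted(sites.loc[dup_sites, 'site_id'])[:5]}")
    if (sites["pos"] < 1).any():
        diag("fatal", "site positions must be >= 1 (1-based coordinates)")
    bad_alleles = ~(
        sites["ref"].astype(str).str.fullmatch("[ACGT]")
        & sites["alt"].astype(str).str.fullmatch("[ACGT]")
        & (sites["ref"] != sites["alt"])
    )
    if bad_alleles.any():
        diag("fatal", f"{int(bad_alleles.sum())} sites with invalid ref/alt alleles")

    dup = counts.duplicated(subset=["cell_id", "site_id"])
    if dup.any():
        diag("fatal", f"{int(dup.sum())} duplicated (cell_id, site_id) rows in counts")
    if (counts["alt_count"] > counts["depth"]).any():
        diag("fatal", "alt_count exceeds depth in counts")
    if (counts["depth"] < 0).any() or (counts["alt_count"] < 0).any():
        diag("fatal", "negative depth or alt_count")
    eps = counts["mean_base_error"]
    if ((eps <= 0) | (eps >= 0.5)).any():
        diag("fatal", "mean_base_error must lie in (0, 0.5)")
    unknown_sites = set(counts["site_id"]) - set(sites["site_id"])
    if unknown_sites:
        diag("fatal", f"counts reference unknown site_id(s): {sorted(unknown_sites)[:5]}")

    if cells is not None:
        unknown_cells = set(counts["cell_id"]) - set(cells["cell_id"])
        if unknown_cells:
            diag("fatal", f"counts reference unknown cell_id(s): {sorted(unknown_cells)[:5]}")
        odd = ~cells["ploidy_class"].isin(known_ploidy_classes)
        if odd.any():
            diag(
                "warning",
                f"{int(odd.sum())} cells with unknown ploidy label excluded "
                "from per-class statistics",
            )
    return diags


def cohort_summary(
    per_class: dict[str, tuple[int, int]],
    n_cells: int,
    n_single: int,
    n_multi: int,
    n_two_clade_multi: int,
) -> dict:
    """Cohort-level percentages from clade-count tallies.

    Parameters
    ----------
    per_class
        ploidy class -> (multi-clade count, claded count).
    n_cells, n_single, n_multi
        Cohort totals: cells sequenced, single-clade and multi-clade cells.
    n_two_clade_multi
        Multi-clade cells with exactly two clades.
    """
    claded = n_single + n_multi
    out = {
        "pct_claded": 100.0 * claded / n_cells,
        "pct_single_clade_of_claded": 100.0 * n_single / claded,
        "pct_two_clade_of_multiclade": 100.0 * n_two_clade_multi / n_multi if n_multi else np.nan,
        "per_class_pct_multiclade": {
            pc: 100.0 * x / n for pc, (x, n) in per_class.items()
        },
    }
    return out


def _ploidy_block(
    pc: str,
    genotypes: pd.DataFrame,
    assignments: pd.DataFrame,
    clades: lin.CladeSet,
    summary_row: pd.Series,
    s_in_mode: str,
) -> dict:
    """Dropout, sensitivity and corrected fraction for one ploidy class."""
    cells = set(assignments.loc[assignments["ploidy_class"] == pc, "cell_id"])
    informative = {s for sites in clades.clades.values() for s in sites}
    block: dict = {
        "n_cells": int(summary_row["n_cells"]),
        "claded": int(summary_row["claded"]),
        "multi_clade": int(summary_row["multi_clade"]),
        "clade_number_distribution": summary_row["clade_number_distribution"],
        "presumptive_doublets": int(summary_row["presumptive_doublets"]),
    }
    claded = block["claded"]
    multi = block["multi_clade"]
    if claded:
        block["observed_fraction"] = multi / claded
        block["observed_ci95"] = list(fs.ci_95(multi, claded))
    else:
        block["observed_fraction"] = None
        block["observed_ci95"] = None

    try:
        dropout = fs.estimate_AD(genotypes, informative, cells, scope=pc)
        block["AD"] = dropout.AD
        block["LD"] = dropout.LD
        block["P_het"] = dropout.P_het
        block["P_althom"] = dropout.P_althom
    except ValueError as exc:
        block["AD"] = block["LD"] = None
        block["dropout_error"] = str(exc)
        return block

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inputs = fs.compute_S_in(
                assignments, genotypes, clades, cells, dropout=dropout, mode=s_in_mode
            )
        model = fs.fusion_sensitivity(inputs)
        block["p_i"] = inputs.clade_props
        block["r_i"] = model.r
        block["S_in"] = {c: list(map(float, v)) for c, v in inputs.S_in.items()}
        block["sensitivity"] = model.sensitivity
    except ValueError as exc:
        block["sensitivity"] = None
        block["sensitivity_error"] = str(exc)
        return block

    if claded and model.sensitivity > 0:
        corr = fs.corrected_fraction(multi, claded, model.sensitivity)
        block["corrected_fraction"] = {
            "estimate": corr.corrected,
            "ci95": [corr.ci_low, corr.ci_high],
            "capped": corr.capped,
            "numerator": corr.numerator,
            "denominator": corr.denominator,
        }
    return block


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    out = Path(config.out_dir)
    if config.write_artifacts:
        out.mkdir(parents=True, exist_ok=True)

    truth_cells = None
    if config.counts_path is None:
        sim_cfg = config.sim or simmod.SimConfig(seed=config.seed)
        bundle = simmod.simulate_dataset(sim_cfg)
        counts, sites = bundle.counts, bundle.panel
        cells = bundle.cells[["cell_id", "ploidy_class"]]
        truth_cells = bundle.cells
        if config.write_artifacts:
            cfio.write_tsv(bundle.panel, out / "sites.tsv")
            cfio.write_tsv(bundle.counts, out / "counts.tsv")
            cfio.write_tsv(bundle.cells, out / "cells.tsv")
            cfio.write_config_echo(asdict(sim_cfg), out / "sim_config.txt")
    else:
        counts = cfio.read_counts(config.counts_path)
        if config.panel_format == "vcf":
            sites = cfio.read_panel_vcf(config.sites_path)
        else:
            sites = cfio.read_sites(config.sites_path)
        if config.cells_path:
            cells = cfio.read_tsv(config.cells_path)[["cell_id", "ploidy_class"]]
        else:
            cells = pd.DataFrame(
                {"cell_id": sorted(set(counts["cell_id"])), "ploidy_class": "unknown"}
            )

    diagnostics = validate_inputs(counts, sites, cells)
    fatal = [d for d in diagnostics if d["level"] == "fatal"]
    if fatal:
        raise ValueError("fatal input diagnostics: " + "; ".join(d["message"] for d in fatal))

    genotypes = gt.genotype_matrix(
        counts,
        config.priors,
        min_depth=config.min_depth,
        min_alt_reads=config.min_alt_reads,
        min_vaf=config.min_vaf,
        refhom_cutoff=config.refhom_cutoff,
    )
    if config.write_artifacts:
        cfio.write_tsv(genotypes, out / "genotypes.tsv")

    filtered, removed_sites = gt.filter_panel(genotypes)
    profiles = lin.binarize(filtered)
    sim_mat = lin.cosine_similarity_matrix(profiles)
    z = lin.upgma_cluster(sim_mat)
    clades = lin.define_clades(
        z,
        profiles,
        min_carriers=config.min_carriers,
        target_clades=config.target_clades,
    )
    ploidy_map = cells.set_index("cell_id")["ploidy_class"]
    assignments = lin.assign_cells(clades, profiles, ploidy_map)
    summary = lin.detect_fusion(assignments, doublet_screen_class=config.doublet_screen_class)

    if config.write_artifacts:
        cfio.write_tsv(
            pd.DataFrame(
                {
                    "clade_id": list(clades.clades),
                    "defining_site_ids": [",".join(sorted(s)) for s in clades.clades.values()],
                    "n_members": [len(clades.members[c]) for c in clades.clades],
                }
            ),
            out / "clades.tsv",
        )
        cfio.write_tsv(assignments, out / "assignments.tsv")
        with open(out / "dendrogram.nwk", "w", encoding="utf-8") as fh:
            fh.write(lin.linkage_to_newick(z, list(profiles.index)) + "\n")

    per_ploidy = {}
    for _, row in summary.iterrows():
        pc = row["ploidy_class"]
        per_ploidy[pc] = _ploidy_block(
            pc, filtered, assignments, clades, row, config.s_in_mode
        )

    classes = [pc for pc in per_ploidy if per_ploidy[pc]["claded"]]
    tests = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            xa, na = per_ploidy[a]["multi_clade"], per_ploidy[a]["claded"]
            xb, nb = per_ploidy[b]["multi_clade"], per_ploidy[b]["claded"]
            tests[f"{a}_vs_{b}"] = {
                m: fs.proportion_test(xa, na, xb, nb, method=m)
                for m in config.test_methods
            }

    n_cells = int(summary["n_cells"].sum())
    claded = int(summary["claded"].sum())
    single = int(summary["single_clade"].sum())
    multi = int(summary["multi_clade"].sum())
    two_clade = int(
        sum(d.get(2, 0) for d in summary["clade_number_distribution"])
    )
    report = {
        "seed": config.seed,
        "n_cells": n_cells,
        "n_sites_panel": int(sites.shape[0]),
        "n_sites_removed_by_filter": len(removed_sites),
        "n_clades": len(clades.clades),
        "clades": {c: sorted(s) for c, s in clades.clades.items()},
        "summary": cohort_summary(
            {
                pc: (per_ploidy[pc]["multi_clade"], per_ploidy[pc]["claded"])
                for pc in per_ploidy
                if per_ploidy[pc]["claded"]
            },
            n_cells,
            single,
            multi,
            two_clade,
        ) if multi or single else {},
        "per_ploidy": per_ploidy,
        "pairwise_tests": tests,
        "diagnostics": diagnostics,
    }
    if truth_cells is not None:
        merged = assignments.merge(truth_cells, on=["cell_id", "ploidy_class"])
        detected = merged.loc[merged["n_clades"] >= 2, "cell_id"]
        true_fused = merged.loc[
            merged["is_fused"] & (merged["n_distinct_origins"] >= 2), "cell_id"
        ]
        report["truth"] = {
            "n_true_fused_distinct": int(len(true_fused)),
            "n_detected_multiclade": int(len(detected)),
            "n_detected_true_fused": int(len(set(detected) & set(true_fused))),
        }
    if config.write_artifacts:
        cfio.write_report(report, out / "report.json")
    return report
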