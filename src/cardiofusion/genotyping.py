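"""Per-cell, per-site Bayesian sSNV genotyping from targeted read counts.

Each (cell, site) observation is a read depth, an alt-allele read count and a
mean per-base error probability ``epsilon``.  Three genotype hypotheses are
scored — homozygous reference (ref-hom), heterozygous (het) and homozygous
alternative (alt-hom) — with binomial read-count likelihoods whose alt-read
success probabilities account for sequencing error:

* ref-hom:  theta = epsilon / 3           (only miscalls produce alt reads)
* het:      theta = 0.5 (1 - epsilon) + 0.5 (epsilon / 3)
* alt-hom:  theta = 1 - epsilon

Posteriors are the prior-weighted, normalised likelihoods.  An sSNV is then
called in a cell when the ref-hom posterior is below 0.5, at least 5 reads
support the alt allele and the alt-allele fraction is at least 0.05; sites
with fewer than 30 reads are ungenotypable (NO_DATA).  Ploidy does not change
the hypothesis set: a variant diluted to 25% in a fused tetraploid nucleus is
admitted by the 5% allele-fraction rule and an essentially zero ref-hom
posterior at typical depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

CALLED = "CALLED"
ABSENT = "ABSENT"
NO_DATA = "NO_DATA"

#: Default calling thresholds.
MIN_DEPTH = 30
MIN_ALT_READS = 5
MIN_VAF = 0.05
REFHOM_CUTOFF = 0.5


class EmptyPanelError(ValueError):
    """All panel sites were removed by filtering."""


@dataclass(frozen=True)
class GenotypePriors:
    """Prior probabilities for (ref-hom, het, alt-hom).

    The default is flat: the panel consists of pre-validated clonal sSNVs, so
    a cell either carries the variant (het, or alt-hom after reference-allele
    dropout) or does not, and there is no population allele frequency to
    justify an informative prior.  With a flat prior the ref-hom-posterior
    rule reduces to a likelihood-ratio rule.
    """

    ref_hom: float = 1.0 / 3.0
    het: float = 1.0 / 3.0
    alt_hom: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        p = np.array([self.ref_hom, self.het, self.alt_hom], dtype=float)
        if np.any(p < 0):
            raise ValueError("priors must be nonnegative")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("priors must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.ref_hom, self.het, self.alt_hom], dtype=float)


def genotype_success_probs(epsilon: np.ndarray | float) -> np.ndarray:
    """Alt-read success probability for each genotype, shape (..., 3)."""
    eps = np.asarray(epsilon, dtype=float)
    theta_ref = eps / 3.0
    theta_het = 0.5 * (1.0 - eps) + 0.5 * (eps / 3.0)
    theta_alt = 1.0 - eps
    return np.stack([theta_ref, theta_het, theta_alt], axis=-1)


def genotype_likelihoods(
    depth,
    alt_count,
    epsilon,
    priors: GenotypePriors | None = None,
) -> np.ndarray:
    """Posterior probabilities of (ref-hom, het, alt-hom).

    Vectorised: scalar or array inputs broadcast; output has a trailing axis
    of length 3 and rows summing to 1.

    Raises
    ------
    ValueError
        If any depth is zero (the caller must route zero-depth records to
        NO_DATA before asking for a genotype) or alt_count exceeds depth.
    """
    priors = priors or GenotypePriors()
    depth = np.asarray(depth, dtype=np.int64)
    alt = np.asarray(alt_count, dtype=np.int64)
    if np.any(depth < 1):
        raise ValueError("genotype posteriors are undefined at depth 0")
    if np.any(alt > depth) or np.any(alt < 0):
        raise ValueError("alt_count must lie in [0, depth]")
    theta = genotype_success_probs(epsilon)  # (..., 3)
    loglik = binom.logpmf(alt[..., None], depth[..., None], theta)
    logpost = loglik + np.log(priors.as_array())
    logpost -= logsumexp(logpost, axis=-1, keepdims=True)
    return np.exp(logpost)


def call_ssnv(
    depth,
    alt_count,
    p_refhom,
    *,
    min_depth: int = MIN_DEPTH,
    min_alt_reads: int = MIN_ALT_READS,
    min_vaf: float = MIN_VAF,
    refhom_cutoff: float = REFHOM_CUTOFF,
) -> np.ndarray:
    """Ternary call status per record: CALLED / ABSENT / NO_DATA.

    NO_DATA when depth < ``min_depth``; otherwise CALLED iff the ref-hom
    posterior is below ``refhom_cutoff`` AND at least ``min_alt_reads`` reads
    support the variant AND the alt fraction is at least ``min_vaf``.
    Calling is monotone in alt_count at fixed depth.
    """
    depth = np.asarray(depth, dtype=np.int64)
    alt = np.asarray(alt_count, dtype=np.int64)
    p_refhom = np.asarray(p_refhom, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    called = (p_refhom < refhom_cutoff) & (alt >= min_alt_reads) & (vaf >= min_vaf)
    out = np.where(called, CALLED, ABSENT)
    out = np.where(depth < min_depth, NO_DATA, out)
    return out


def genotype_matrix(
    counts: pd.DataFrame,
    priors: GenotypePriors | None = None,
    *,
    min_depth: int = MIN_DEPTH,
    min_alt_reads: int = MIN_ALT_READS,
    min_vaf: float = MIN_VAF,
    refhom_cutoff: float = REFHOM_CUTOFF,
) -> pd.DataFrame:
    """Genotype every (cell, site) record of a counts table.

    Parameters
    ----------
    counts
        Long-format table with columns ``cell_id, site_id, depth, alt_count,
        mean_base_error``.

    Returns
    -------
    DataFrame with the input keys plus ``vaf, p_refhom, p_het, p_althom,
    call``.  Records with depth below ``min_depth`` get NaN posteriors and a
    NO_DATA call.
    """
    required = {"cell_id", "site_id", "depth", "alt_count", "mean_base_error"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out = counts.copy()
    depth = out["depth"].to_numpy(np.int64)
    alt = out["alt_count"].to_numpy(np.int64)
    eps = out["mean_base_error"].to_numpy(float)

    post = np.full((len(out), 3), np.nan)
    ok = depth >= 1
    if ok.any():
        post[ok] = genotype_likelihoods(depth[ok], alt[ok], eps[ok], priors)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["vaf"] = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    out["p_refhom"] = post[:, 0]
    out["p_het"] = post[:, 1]
    out["p_althom"] = post[:, 2]
    # depth=0 rows: p_refhom NaN; comparisons with NaN are False, and the
    # NO_DATA overwrite in call_ssnv covers them (0 < min_depth always).
    out["call"] = call_ssnv(
        depth,
        alt,
        out["p_refhom"].to_numpy(float),
        min_depth=min_depth,
        min_alt_reads=min_alt_reads,
        min_vaf=min_vaf,
        refhom_cutoff=refhom_cutoff,
    )
    nan_post = ~ok
    if nan_post.any():
        out.loc[nan_post, "call"] = NO_DATA
    return out


def filter_panel(genotypes: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop panel sites never CALLED in any cell.

    Sites absent across the whole cohort carry no lineage information (in the
    simulator these are the non-clonal filler sites).  Site order is
    preserved for the survivors.

    Returns
    -------
    (filtered genotypes, list of removed site_ids)

    Raises
    ------
    EmptyPanelError
        If no site survives.
    """
    called_sites = set(genotypes.loc[genotypes["call"] == CALLED, "site_id"])
    all_sites = list(dict.fromkeys(genotypes["site_id"]))
    removed = [s for s in all_sites if s not in called_sites]
    if not called_sites:
        raise EmptyPanelError("no panel site is CALLED in any cell")
    kept = genotypes[genotypes["site_id"].isin(called_sites)].reset_index(drop=True)
    return kept, removed
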