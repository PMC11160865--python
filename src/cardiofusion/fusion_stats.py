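"""Dropout estimation, fusion-detection sensitivity and corrected fractions.

A two-cell fusion is observable only when (i) the two origin cells come from
genetically distinct clades and (ii) at least one clade-informative sSNV of
each origin survives amplification dropout and is called.  With per-clade
capture probabilities

    r_i = sum_n S_in (1 - (AD + LD)^n),

where S_in is the proportion of clade-i cells carrying n of the clade's
informative sSNVs and AD/LD are the allelic and locus dropout rates, the
overall detection sensitivity over random distinct-clade pairings is

    sensitivity = sum_ij p_i r_i p_j r_j c_ij / sum_ij p_i p_j c_ij,
    c_ij = 0 if i == j else 1.

Dividing the observed multi-clade fraction among claded cells by this
sensitivity yields the corrected fusion-fraction estimate.  Dropout rates
are estimated from the genotyping profile itself: LD as the fraction of
sites under the 30X depth floor and AD by attributing every alt-hom call at
a clonal het site to reference-allele dropout,

    AD = 2 P_alt-hom / (P_het + 2 P_alt-hom).

All quantities are estimated separately per ploidy class, whose dropout
behaviour and clade composition differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom, fisher_exact, norm
from statsmodels.stats.proportion import proportion_confint, proportions_ztest


@dataclass
class DropoutEstimates:
    AD: float
    LD: float
    P_het: float
    P_althom: float
    scope: str = "all"


@dataclass
class SensitivityInputs:
    clade_props: dict[str, float]  # p_i
    S_in: dict[str, np.ndarray]  # clade -> distribution over n=1..N_i (index 0 == n=1)
    N: dict[str, int]
    dropout: DropoutEstimates
    n_single_clade: dict[str, int] = field(default_factory=dict)


@dataclass
class SensitivityModel:
    r: dict[str, float]
    sensitivity: float
    inputs: SensitivityInputs


@dataclass
class CorrectedFraction:
    observed: float
    corrected: float
    ci_low: float
    ci_high: float
    capped: bool
    numerator: int
    denominator: int
    sensitivity: float


def estimate_LD(genotypes: pd.DataFrame, cells: set[str] | None = None, *, min_depth: int = 30) -> float:
    """Locus dropout rate: fraction of (cell, site) entries with depth < 30X."""
    g = genotypes if cells is None else genotypes[genotypes["cell_id"].isin(cells)]
    if len(g) == 0:
        raise ValueError("empty scope for LD estimation")
    return float((g["depth"] < min_depth).mean())


def estimate_AD(
    genotypes: pd.DataFrame,
    informative_sites: set[str],
    cells: set[str] | None = None,
    scope: str = "all",
) -> DropoutEstimates:
    """Allelic dropout from the het / alt-hom balance at clonal sites.

    Genotype class is the maximum-posterior genotype among CALLED entries at
    clade-informative sites.  Every alt-hom call at a clonal (germline-het-
    like) sSNV is attributed to dropout of the reference allele; with ref
    and alt alleles dropping with equal chance, AD = 2 P_alt-hom /
    (P_het + 2 P_alt-hom).
    """
    if not informative_sites:
        raise ValueError("informative_sites must be nonempty")
    g = genotypes[genotypes["site_id"].isin(informative_sites)]
    if cells is not None:
        g = g[g["cell_id"].isin(cells)]
    g = g[g["call"] == "CALLED"]
    ld = estimate_LD(genotypes[genotypes["site_id"].isin(informative_sites)]
                     if cells is None else
                     genotypes[genotypes["site_id"].isin(informative_sites)
                               & genotypes["cell_id"].isin(cells)])
    if len(g) == 0:
        raise ValueError("no CALLED clade-informative genotypes in scope")
    post = g[["p_refhom", "p_het", "p_althom"]].to_numpy(float)
    cls = post.argmax(axis=1)
    p_het = float((cls == 1).mean())
    p_althom = float((cls == 2).mean())
    denom = p_het + 2.0 * p_althom
    if denom == 0:
        raise ValueError("AD undefined: P_het + 2 P_althom = 0")
    ad = 2.0 * p_althom / denom
    return DropoutEstimates(AD=ad, LD=ld, P_het=p_het, P_althom=p_althom, scope=scope)


def compute_S_in(
    assignments: pd.DataFrame,
    genotypes: pd.DataFrame,
    clades,
    cells: set[str] | None = None,
    *,
    dropout: DropoutEstimates | None = None,
    mode: str = "deconvolved",
) -> SensitivityInputs:
    """Tabulate clade proportions p_i and carry-count distributions S_in.

    For each clade, S_in is the distribution over the number of that clade's
    defining sSNVs carried by its single-clade member cells.  Observed carry
    counts are post-dropout and therefore biased low; with
    ``mode="deconvolved"`` (default) the observed distribution is inverted
    through the binomial thinning implied by the dropout rates (non-negative
    least squares over n = 1..N_i), which removes the bias the naive
    tabulation inherits.  ``mode="observed"`` keeps the raw tabulation.

    Clades with no single-clade member in scope are excluded with a warning
    and p renormalised.
    """
    if mode not in ("observed", "deconvolved"):
        raise ValueError("mode must be 'observed' or 'deconvolved'")
    if mode == "deconvolved" and dropout is None:
        raise ValueError("deconvolved S_in needs dropout estimates")
    a = assignments
    if cells is not None:
        a = a[a["cell_id"].isin(cells)]
    single = a[a["status"] == "SINGLE_CLADE"]
    counts_by_clade: dict[str, int] = {}
    s_in: dict[str, np.ndarray] = {}
    n_sites: dict[str, int] = {}
    carrier = genotypes[genotypes["call"] == "CALLED"]
    carried = carrier.groupby("cell_id")["site_id"].agg(set)

    import warnings as _w

    for cid, def_sites in clades.clades.items():
        members = single.loc[single["clades"] == cid, "cell_id"]
        if len(members) == 0:
            _w.warn(f"clade {cid} has no single-clade member in scope; excluded")
            continue
        n_i = len(def_sites)
        ks = np.array(
            [len(def_sites & carried.get(c, set())) for c in members], dtype=int
        )
        ks = ks[ks >= 1]  # single-clade members carry >=1 by construction
        obs = np.bincount(ks, minlength=n_i + 1)[1:].astype(float)
        obs /= obs.sum()
        if mode == "deconvolved" and n_i > 1:
            s = _deconvolve_carry(obs, n_i, dropout.AD + dropout.LD)
        else:
            s = obs
        counts_by_clade[cid] = int(len(members))
        s_in[cid] = s
        n_sites[cid] = n_i

    if not counts_by_clade:
        raise ValueError("no clade has single-clade members in scope")
    total = sum(counts_by_clade.values())
    props = {cid: c / total for cid, c in counts_by_clade.items()}
    return SensitivityInputs(
        clade_props=props,
        S_in=s_in,
        N=n_sites,
        dropout=dropout or DropoutEstimates(np.nan, np.nan, np.nan, np.nan),
        n_single_clade=counts_by_clade,
    )


def _deconvolve_carry(obs: np.ndarray, n_max: int, miss: float) -> np.ndarray:
    """Invert binomial thinning of carry counts.

    obs[k-1] ~ sum_n S[n-1] C(n,k) (1-miss)^k miss^(n-k), conditioned on
    k >= 1.  Solved by NNLS with a simplex renormalisation.
    """
    if miss <= 0:
        return obs
    if miss >= 1:
        raise ValueError("AD + LD must be < 1")
    ks = np.arange(1, n_max + 1)
    a = np.zeros((n_max, n_max))
    for j, n in enumerate(range(1, n_max + 1)):
        a[:, j] = binom.pmf(ks, n, 1.0 - miss) / (1.0 - miss**n)
    sol, _ = nnls(a, obs)
    if sol.sum() == 0:
        return obs
    return sol / sol.sum()


def capture_probability(S_i: np.ndarray, AD: float, LD: float) -> float:
    """r_i = sum_n S_in (1 - (AD+LD)^n): chance any clade-i sSNV is captured."""
    miss = AD + LD
    if miss < 0 or miss >= 1:
        raise ValueError("AD + LD must lie in [0, 1)")
    s = np.asarray(S_i, dtype=float)
    n = np.arange(1, len(s) + 1)
    return float(np.sum(s * (1.0 - miss**n)))


def fusion_sensitivity(inputs: SensitivityInputs) -> SensitivityModel:
    """Overall probability of detecting a distinct-clade two-cell fusion.

    Ratio of capture-weighted to unweighted sums over ordered clade pairs
    with the distinct-clade indicator c_ij.  Undefined with fewer than two
    clades of nonzero weight (no distinct pairing exists).
    """
    clades = [c for c, p in inputs.clade_props.items() if p > 0]
    if len(clades) < 2:
        raise ValueError("sensitivity undefined with a single clade (denominator 0)")
    p = np.array([inputs.clade_props[c] for c in clades])
    r = np.array(
        [capture_probability(inputs.S_in[c], inputs.dropout.AD, inputs.dropout.LD) for c in clades]
    )
    # sum_ij p_i p_j c_ij = (sum p)^2 - sum p^2 ; numerator analogous with p*r
    num = np.sum(p * r) ** 2 - np.sum((p * r) ** 2)
    den = np.sum(p) ** 2 - np.sum(p**2)
    sens = float(num / den)
    return SensitivityModel(
        r={c: float(v) for c, v in zip(clades, r)}, sensitivity=sens, inputs=inputs
    )


def ci_95(x: int, n: int) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    # boundary cases are exact: no successes pins the lower bound at 0,
    # all successes the upper at 1
    lo = 0.0 if x == 0 else float(lo)
    hi = 1.0 if x == n else float(hi)
    return max(0.0, min(lo, 1.0)), max(0.0, min(hi, 1.0))


def corrected_fraction(
    observed_multiclade: int, claded: int, sensitivity: float
) -> CorrectedFraction:
    """Dropout-corrected fusion fraction with a sensitivity-scaled Wilson CI.

    Point estimate (x/n)/sensitivity; both Wilson bounds divided by the
    sensitivity; values above 1 are capped and flagged.
    """
    if claded <= 0:
        raise ValueError("claded count must be positive")
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must lie in (0, 1]")
    obs = observed_multiclade / claded
    lo, hi = ci_95(observed_multiclade, claded)
    est, lo_c, hi_c = obs / sensitivity, lo / sensitivity, hi / sensitivity
    capped = est > 1 or hi_c > 1
    return CorrectedFraction(
        observed=obs,
        corrected=min(est, 1.0),
        ci_low=min(lo_c, 1.0),
        ci_high=min(hi_c, 1.0),
        capped=capped,
        numerator=int(observed_multiclade),
        denominator=int(claded),
        sensitivity=float(sensitivity),
    )


def proportion_test(x1: int, n1: int, x2: int, n2: int, method: str = "z") -> float:
    """Two-sided test of equality of two binomial proportions.

    ``z``: pooled two-sample z-test without continuity correction (default).
    ``z-cc``: the same with Yates continuity correction.
    ``fisher``: Fisher's exact test.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within sample sizes")
    if method == "z":
        if x1 + x2 == 0 or x1 + x2 == n1 + n2:
            return 1.0
        _, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        return float(p)
    if method == "z-cc":
        p_pool = (x1 + x2) / (n1 + n2)
        if p_pool in (0.0, 1.0):
            return 1.0
        diff = abs(x1 / n1 - x2 / n2)
        cc = 0.5 * (1 / n1 + 1 / n2)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        z = max(diff - cc, 0.0) / se
        return float(2 * norm.sf(z))
    if method == "fisher":
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")
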