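"""Clade reconstruction from binarized sSNV profiles and multi-clade detection.

Cells are embedded as 0/1 vectors over the filtered panel (CALLED -> 1,
ABSENT or NO_DATA -> 0), compared by cosine similarity, and clustered by
UPGMA (average linkage) on the distance 1 - S.  Nested clades are carved out
of the dendrogram top-down: a node is split into its two children only when
each child has at least one sSNV that is common inside it and rare in its
sibling.  Defining sites are then refined so that, among single-clade cells,
every defining sSNV is carried exclusively within its own clade — the
field's notion of a clade-specific sSNV.  Cells carrying defining sSNVs of
two or more clades are multi-clade: in bare-nucleus data these are fusion
candidates (for diploids, presumptive double-sorted doublets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import betainc

UNCLADED = "UNCLADED"
SINGLE_CLADE = "SINGLE_CLADE"
MULTI_CLADE = "MULTI_CLADE"


@dataclass
class CladeSet:
    """Validated clades with their defining (clade-specific) sSNVs."""

    clades: dict[str, set[str]]  # clade_id -> defining site_ids
    members: dict[str, set[str]]  # clade_id -> member cell_ids (assigned)
    linkage_matrix: np.ndarray | None = None
    cell_ids: list[str] = field(default_factory=list)

    def defining_site_to_clade(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for cid, sites in self.clades.items():
            for s in sites:
                out[s] = cid
        return out


def binarize(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a genotyped long table to a cells x sites 0/1 matrix.

    CALLED -> 1; ABSENT and NO_DATA -> 0.  Missing data is collapsed to 0
    because the downstream sensitivity model absorbs missingness into the
    locus-dropout rate.
    """
    carrier = (genotypes["call"].to_numpy() == "CALLED")
    cell_codes, cells = pd.factorize(genotypes["cell_id"])  # first-appearance order
    site_codes, sites = pd.factorize(genotypes["site_id"])
    mat = np.zeros((len(cells), len(sites)), dtype=np.int8)
    np.maximum.at(mat, (cell_codes, site_codes), carrier.astype(np.int8))
    return pd.DataFrame(mat, index=list(cells), columns=list(sites))


def cosine_similarity_matrix(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of binary profiles; zero-norm rows -> 0."""
    x = np.asarray(profiles, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    xn = x / safe[:, None]
    s = xn @ xn.T
    s[norms == 0, :] = 0.0
    s[:, norms == 0] = 0.0
    np.fill_diagonal(s, np.where(norms == 0, 0.0, 1.0))
    return np.clip(s, 0.0, 1.0)


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two profiles (0 if either has zero norm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def upgma_cluster(similarity: np.ndarray) -> np.ndarray:
    """UPGMA dendrogram (scipy linkage matrix) on distance 1 - S.

    Average-linkage merge heights are monotone non-decreasing, so the result
    is an ultrametric tree.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if s.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    if s.shape[0] <= 1000:
        sym_ok = np.allclose(s, s.T, atol=1e-8)
    else:  # spot-check large matrices; a full check costs more than clustering
        idx = np.linspace(0, s.shape[0] - 1, 200).astype(int)
        sym_ok = np.allclose(s[np.ix_(idx, idx)], s[np.ix_(idx, idx)].T, atol=1e-8)
    if not sym_ok:
        raise ValueError("similarity must be symmetric")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Leaves carry the given labels; branch lengths are the difference between
    a node's merge height and its child's, so root-to-leaf path lengths equal
    the (ultrametric) merge heights.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        node = n + k
        heights[node] = h
        la = h - heights[a]
        lb = h - heights[b]
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
    return newick[n + len(z) - 1] + ";"


def _node_members(z: np.ndarray, n_leaves: int) -> dict[int, np.ndarray]:
    """Leaf index sets for every node of a linkage tree."""
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n_leaves)}
    for k, (a, b, _, _) in enumerate(z):
        members[n_leaves + k] = np.concatenate([members[int(a)], members[int(b)]])
    return members


def _binom_cdf(k, n, p) -> np.ndarray:
    """Binomial CDF via the regularised incomplete beta (vectorised, cheap)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    k, n, p = np.broadcast_arrays(k, n, p)
    out = np.ones(k.shape, dtype=float)
    interior = k < n
    if interior.any():
        ki, ni, pi = k[interior], n[interior], p[interior]
        out[interior] = betainc(ni - ki, ki + 1.0, 1.0 - pi)
    return np.where(k < 0, 0.0, out)


def _wilson_lower(k, n, z: float = 1.96) -> np.ndarray:
    """Wilson score lower bound for binomial proportions (vectorised)."""
    k = np.asarray(k, dtype=float)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = p + z**2 / (2 * n)
    margin = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return np.clip((centre - margin) / denom, 0.0, 1.0)


def _split_evidence(
    x: np.ndarray,
    child: np.ndarray,
    sibling: np.ndarray,
    min_carriers: int,
    min_cov: float,
    disc_ratio: float,
    alpha: float = 0.01,
) -> bool:
    """True if some sSNV is common in `child` and near-absent in `sibling`.

    Near-absence must be statistically incompatible with binomial thinning of
    the child's carrier rate (Wilson lower bound, one-sided ``alpha``):
    dropout fragments of one clonal clade then never justify a split, while a
    genuine clade boundary does.
    """
    inside = x[child].sum(axis=0)
    cov_in = inside / len(child)
    sib_counts = x[sibling].sum(axis=0)
    cov_sib = sib_counts / len(sibling)
    ok = (inside >= min_carriers) & (cov_in >= min_cov) & (cov_sib <= disc_ratio * cov_in)
    return bool(ok.any())


def define_clades(
    z: np.ndarray,
    profiles: pd.DataFrame,
    *,
    min_carriers: int = 2,
    min_inside_cov: float = 0.25,
    split_cov: float = 0.1,
    disc_ratio: float = 0.25,
    competitor_frac: float = 0.25,
    target_clades: int | None = None,
) -> CladeSet:
    """Carve validated clades out of a UPGMA dendrogram.

    The guiding evidence standard throughout is the clade-specific sSNV: a
    site common in one group of cells and (near-)absent in another.  "Near"
    absence — carrier coverage below ``disc_ratio`` times the coverage in the
    carrying group — is what tolerates the fused multi-clade cells that
    necessarily carry one clade's sSNVs while sitting outside it.

    Stage 1 — partition.  The dendrogram is split top-down wherever either
    child holds such a discriminating site against its sibling (coverage at
    least ``split_cov`` inside, ``min_carriers`` carriers).  With
    ``target_clades`` the tree is instead cut into a fixed number of groups.

    Stage 2 — reassembly.  Amplification dropout shatters a clonal clade
    into fragments whose coverage profiles differ only by binomial thinning;
    fragment pairs with no discriminating site in either direction are merged
    (largest first, so coverage estimates are stable before shards attach).

    Stage 3 — composite removal.  A cluster of fused cells carries the union
    of two clades' sSNVs and therefore covers *every* eligible site of some
    real clade at comparable coverage; such clusters are dropped (their cells
    are still assigned, and flagged multi-clade, through the surviving
    clades' sites).  A sister clade never satisfies this containment: it
    entirely lacks the other's clade-specific sites.

    Stage 4 — clade-specific sites.  A site (eligible where it has at least
    ``min_carriers`` carriers covering ``min_inside_cov`` of the cluster)
    defines the cluster with the most carriers, unless a rival cluster
    shares it materially (at least ``competitor_frac`` of the owner's
    carriers): shared internal-branch sSNVs sit on two or more sister clades
    and are pruned by this rule.  Rivals that fully contain the owner's
    signature are fused-cell groups that escaped stage 3 and do not count.
    Clusters left without defining sites are dropped.
    """
    x = profiles.to_numpy(dtype=np.int8)
    cell_ids = list(profiles.index)
    site_ids = list(profiles.columns)
    n = len(cell_ids)
    if z.shape[0] != n - 1:
        raise ValueError("linkage does not match profile matrix")

    if target_clades is not None:
        flat = fcluster(z, t=target_clades, criterion="maxclust")
        clusters = [np.flatnonzero(flat == c) for c in np.unique(flat)]
    else:
        members = _node_members(z, n)
        clusters = []
        stack = [2 * n - 2]  # root node id
        while stack:
            node = stack.pop()
            if node < n:
                clusters.append(members[node])
                continue
            a, b = int(z[node - n, 0]), int(z[node - n, 1])
            ca, cb = members[a], members[b]
            if _split_evidence(x, ca, cb, min_carriers, split_cov, disc_ratio) or _split_evidence(
                x, cb, ca, min_carriers, split_cov, disc_ratio
            ):
                stack.extend([a, b])
            else:
                clusters.append(members[node])

    clusters = [c for c in clusters if len(c) > 0]
    clusters.sort(key=lambda c: int(c.min()))

    # branch-mate structure of the sites across the whole cohort: two sSNVs
    # on one lineage branch co-occur (max-normalised) at the per-site capture
    # rate; sites of an ancestor/descendant branch pair at most half that
    # (the descendant clade is at most half the ancestor's carriers); sites
    # of unrelated branches only in the small fused minority of cells.
    tot = x.sum(axis=0).astype(np.int64)
    inter = x.T.astype(np.int64) @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        co_max = inter / np.maximum(np.maximum.outer(tot, tot), 1)
    related = (co_max >= 0.45) & (inter >= min_carriers)
    np.fill_diagonal(related, False)

    def stats(cls):
        c = np.stack([x[cl].sum(axis=0) for cl in cls])
        sz = np.array([len(cl) for cl in cls])
        cv = c / sz[:, None]
        el = (c >= min_carriers) & (cv >= min_inside_cov)
        return c, sz, cv, el

    def same_lineage(i: int, j: int) -> bool:
        """Clusters are dropout fragments of one clade when the sites private
        to each one's eligible set are cohort-wide branch-mates."""
        pi = eligible[i] & ~eligible[j]
        pj = eligible[j] & ~eligible[i]
        if not pi.any() or not pj.any():
            return False
        return bool(related[np.ix_(pi, pj)].any())

    counts, sizes, cov, eligible = stats(clusters)

    # drop clusters with no eligible site (noise, amplification failures);
    # their cells are still assigned through defining sites later
    keep = eligible.any(axis=1)
    clusters = [cl for cl, k in zip(clusters, keep) if k]
    if clusters:
        counts, sizes, cov, eligible = stats(clusters)

    disc_alpha = 0.01

    def disc_row(i: int) -> np.ndarray:
        """disc[j]: some eligible site of i is near-absent in j, with the
        deficit statistically incompatible with binomial thinning (the
        carrier count in j falls below the Wilson lower bound of i's carrier
        rate at the ``disc_alpha`` tail).  Small shards therefore cannot be
        discriminated *against* by coverage noise, while a cluster carrying
        another clade's sSNVs discriminates itself from that clade."""
        mask = eligible[i]
        out = np.zeros(len(clusters), dtype=bool)
        if not mask.any():
            return out
        q = _wilson_lower(counts[i, mask], sizes[i])
        ratio_ok = cov[:, mask] <= disc_ratio * cov[i, mask]
        sig = _binom_cdf(counts[:, mask], np.asarray(sizes)[:, None], q) < disc_alpha
        out = (ratio_ok & sig).any(axis=1)
        return out

    if len(clusters) > 1:
        disc = np.stack([disc_row(i) for i in range(len(clusters))])
        np.fill_diagonal(disc, True)  # a cluster never merges with itself
        while True:
            mergeable = ~disc & ~disc.T
            if not mergeable.any():
                break
            ii, jj = np.nonzero(mergeable)
            best = np.argmax(sizes[ii] + sizes[jj])
            i, j = int(ii[best]), int(jj[best])
            merged_cells = np.sort(np.concatenate([clusters[i], clusters[j]]))
            clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
            clusters.append(merged_cells)
            counts, sizes, cov, eligible = stats(clusters)
            # only the merged cluster's row and column change
            disc = np.delete(np.delete(disc, (i, j), axis=0), (i, j), axis=1)
            k = len(clusters)
            new_row = disc_row(k - 1)
            disc = np.vstack([disc, new_row[: k - 1][None, :]])
            # disc(t -> merged) for all t in one vectorised pass
            q_all = _wilson_lower(counts, sizes[:, None])
            ratio_ok = cov[k - 1][None, :] <= disc_ratio * cov
            sig = _binom_cdf(counts[k - 1][None, :], sizes[k - 1], q_all) < disc_alpha
            new_col = (eligible & ratio_ok & sig).any(axis=1)
            disc = np.hstack([disc, new_col[:, None]])
            disc[k - 1, k - 1] = True

    def contains(f: int, i: int) -> bool:
        sites_i = np.flatnonzero(eligible[i])
        if len(sites_i) == 0:
            return False
        return bool(np.all(cov[f, sites_i] >= 0.5 * cov[i, sites_i]))

    def claim() -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        masked = np.where(eligible, counts, 0)
        owner_sets = [set(cl.tolist()) for cl in clusters]
        for s in np.flatnonzero(eligible.any(axis=0)):
            owner = int(masked[:, s].argmax())
            # a genuinely shared (internal-branch) sSNV covers a rival at the
            # same per-site capture rate as the owner; a mixed group of fused
            # cells carries it only through its fused subset, at well under
            # half the owner's coverage, and does not rival the claim
            rivals = (
                eligible[:, s]
                & (counts[:, s] >= competitor_frac * counts[owner, s])
                & (cov[:, s] >= 0.5 * cov[owner, s])
            )
            rivals[owner] = False
            blocked = False
            for j in np.flatnonzero(rivals):
                if contains(j, owner):
                    continue  # fused-cell group that escaped the composite sweep
                if contains(owner, j):
                    continue  # rival is a dropout fragment of the owner's clade
                carriers_j = set(clusters[j][x[clusters[j], s] > 0].tolist())
                if carriers_j <= owner_sets[owner]:
                    continue  # overlap artifact: j's carriers are owner's own cells
                blocked = True
                break
            if not blocked:
                out.setdefault(owner, set()).add(int(s))
        return out

    # Stages 3-4, iterated with a cohort-level co-carrier check.  Dropout can
    # fracture a clade into clusters selected on *which* of its sSNVs
    # survived (the profiles are orthogonal, so the dendrogram separates
    # them and the deficit is real, not thinning noise).  The giveaway is in
    # the sites, not the cells: sSNVs of one clade still co-occur across the
    # cohort at the per-site capture rate, whereas sites of two genuinely
    # different clades co-occur only in the small fused minority.
    defining: dict[int, set[int]] = {}
    co_merge = 0.4

    def claim_and_co_merge(salvaged_idx: set[int] | None = None) -> dict[int, set[int]]:
        nonlocal clusters, counts, sizes, cov, eligible
        out: dict[int, set[int]] = {}
        while len(clusters) > 0:
            if salvaged_idx is None and len(clusters) > 2:
                # a composite (fused-cell) cluster covers the signatures of at
                # least two clusters that are themselves mutually
                # discriminated; a large dropout fragment covering a smaller
                # fragment of its own clade contains only one and is kept
                kk = len(clusters)
                disc_now = np.stack([disc_row(t) for t in range(kk)])
                composite = np.zeros(kk, dtype=bool)
                for f in range(kk):
                    inside = [
                        i for i in range(kk) if i != f and contains(f, i)
                    ]
                    composite[f] = any(
                        disc_now[i, j] and disc_now[j, i] and not same_lineage(i, j)
                        for ai, i in enumerate(inside)
                        for j in inside[ai + 1:]
                    )
                if composite.any() and not composite.all():
                    clusters = [cl for cl, c in zip(clusters, composite) if not c]
                    counts, sizes, cov, eligible = stats(clusters)
            out = claim()
            if len(out) < 2:
                break
            carr = {
                idx: x[:, sorted(sites)].any(axis=1) for idx, sites in out.items()
            }
            best, best_rate = None, co_merge
            keys = sorted(out)
            for a_i in range(len(keys)):
                for b_i in range(a_i + 1, len(keys)):
                    ka, kb = keys[a_i], keys[b_i]
                    if salvaged_idx is not None and not (
                        ka in salvaged_idx or kb in salvaged_idx
                    ):
                        continue
                    ca, cb = carr[ka], carr[kb]
                    denom = min(ca.sum(), cb.sum())
                    if denom < min_carriers:
                        continue
                    rate = (ca & cb).sum() / denom
                    if rate >= best_rate:
                        best, best_rate = (ka, kb), rate
            if best is None:
                break
            i, j = best
            merged_cells = np.unique(np.concatenate([clusters[i], clusters[j]]))
            clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
            clusters.append(merged_cells)
            counts, sizes, cov, eligible = stats(clusters)
            if salvaged_idx is not None:
                new_idx = len(clusters) - 1
                both_salvaged = i in salvaged_idx and j in salvaged_idx
                salvaged_idx = {
                    t - sum(1 for r in (i, j) if r < t)
                    for t in salvaged_idx
                    if t not in (i, j)
                }
                if both_salvaged:
                    salvaged_idx.add(new_idx)
        return out

    if clusters:
        defining = claim_and_co_merge()

    # salvage pass: a clade defined by few sSNVs can vanish from the
    # dendrogram entirely — its cells' profiles are dominated by
    # internal-branch sites shared with a sister clade, so they are absorbed
    # there and the clade-specific site ends up defining nothing.  Such an
    # orphan site is recognisable cohort-wide: enough carriers, but without
    # the high coverage of >= 2 clusters that marks a shared internal branch.
    # Its carrier set seeds a candidate clade; the claim/co-carrier loop then
    # either validates it or folds it back.
    if clusters and len(defining) >= 1:
        claimed_sites = {s for sites in defining.values() for s in sites}
        total_carriers = x.sum(axis=0)
        salvaged = []
        for s in np.flatnonzero(total_carriers >= min_carriers):
            if int(s) in claimed_sites:
                continue
            cov_s = counts[:, int(s)] / sizes
            if (cov_s >= 0.5).sum() >= 2:
                continue  # internal-branch pattern
            salvaged.append(np.flatnonzero(x[:, int(s)]))
        if salvaged:
            base = len(clusters)
            clusters = clusters + salvaged
            counts, sizes, cov, eligible = stats(clusters)
            defining = claim_and_co_merge(
                salvaged_idx={base + t for t in range(len(salvaged))}
            )

    # split chimeric defining sets: all sSNVs of one clade are cohort-wide
    # branch-mates, whereas a mixed cluster can claim terminal sites of two
    # different clades whose carriers barely overlap (fused cells only).
    # Components are separated only when clearly unrelated (cross co-carrier
    # below 0.25); the co-assignment merge below then reattaches any
    # component that in fact shares lineage with an existing clade.
    if defining:
        tot = x.sum(axis=0).astype(np.int64)
        inter = x.T.astype(np.int64) @ x
        with np.errstate(divide="ignore", invalid="ignore"):
            co_max = inter / np.maximum(np.maximum.outer(tot, tot), 1)
        split_defining: dict[int, set[int]] = {}
        next_key = 0
        for sites in defining.values():
            site_list = sorted(sites)
            comps = [{s} for s in site_list]
            merged_any = True
            while merged_any and len(comps) > 1:
                merged_any = False
                for a_i in range(len(comps)):
                    for b_i in range(a_i + 1, len(comps)):
                        cross = max(
                            co_max[s, t] for s in comps[a_i] for t in comps[b_i]
                        )
                        if cross >= 0.25:
                            comps[a_i] |= comps[b_i]
                            del comps[b_i]
                            merged_any = True
                            break
                    if merged_any:
                        break
            for comp in comps:
                split_defining[next_key] = comp
                next_key += 1
        defining = split_defining

    # final safety net on the output: two defining-site sets on the same
    # lineage path (a nested pseudo-clade built from internal-branch sSNVs,
    # or one clade split in two) co-assign cells at the per-site capture
    # rate, far above what fusion between two genuine clades produces even
    # in heavily fused cohorts.
    co_assign_merge = 0.45
    while len(defining) > 1:
        keys = sorted(defining)
        carr = {k: x[:, sorted(defining[k])].any(axis=1) for k in keys}
        best, best_rate = None, co_assign_merge
        for a_i in range(len(keys)):
            for b_i in range(a_i + 1, len(keys)):
                ca, cb = carr[keys[a_i]], carr[keys[b_i]]
                denom = min(ca.sum(), cb.sum())
                if denom == 0:
                    continue
                rate = (ca & cb).sum() / denom
                if rate >= best_rate:
                    best, best_rate = (keys[a_i], keys[b_i]), rate
        if best is None:
            break
        i, j = best
        defining[i] = defining[i] | defining.pop(j)

    if not defining:
        warnings.warn("no validated clade; returning single-clade degenerate result")
        all_cells = np.arange(n)
        carried = x.sum(axis=0)
        sites = set(int(s) for s in np.flatnonzero(carried >= min_carriers))
        defining = {0: sites}
        clusters = [all_cells]

    clade_ids = {idx: f"clade{chr(ord('A') + k)}" if k < 26 else f"clade{k}"
                 for k, idx in enumerate(sorted(defining))}
    clades = {clade_ids[idx]: {site_ids[s] for s in sites} for idx, sites in defining.items()}
    members_out: dict[str, set[str]] = {cid: set() for cid in clades}
    site_owner = {}
    for cid, sites in clades.items():
        for s in sites:
            site_owner[s] = cid
    for i, row in enumerate(x):
        for s in np.flatnonzero(row):
            cid = site_owner.get(site_ids[s])
            if cid is not None:
                members_out[cid].add(cell_ids[i])
    return CladeSet(clades=clades, members=members_out, linkage_matrix=z, cell_ids=cell_ids)


def assign_cells(
    clades: CladeSet,
    profiles: pd.DataFrame,
    ploidy: pd.Series | dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign every cell to the clades whose defining sSNVs it carries.

    Returns a table with one row per cell: ``cell_id, ploidy_class, clades``
    (comma-joined sorted clade ids), ``n_clades`` and ``status`` in
    {UNCLADED, SINGLE_CLADE, MULTI_CLADE}.  Cells carrying no defining sSNV
    are UNCLADED (in this assay, typically incomplete genome amplification).
    """
    site_owner = clades.defining_site_to_clade()
    site_ids = list(profiles.columns)
    owner_arr = np.array([site_owner.get(s, "") for s in site_ids])
    x = profiles.to_numpy(dtype=bool)
    if ploidy is None:
        ploidy_map = {}
    elif isinstance(ploidy, pd.Series):
        ploidy_map = ploidy.to_dict()
    else:
        ploidy_map = dict(ploidy)

    rows = []
    for i, cell in enumerate(profiles.index):
        owners = sorted({o for o in owner_arr[x[i]] if o})
        k = len(owners)
        status = UNCLADED if k == 0 else (SINGLE_CLADE if k == 1 else MULTI_CLADE)
        rows.append(
            {
                "cell_id": cell,
                "ploidy_class": ploidy_map.get(cell, "unknown"),
                "clades": ",".join(owners),
                "n_clades": k,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def detect_fusion(assignments: pd.DataFrame, *, doublet_screen_class: str = "diploid") -> pd.DataFrame:
    """Per-ploidy-class fusion summary from clade assignments.

    Columns: total cells, claded and multi-clade counts, the distribution
    over clade numbers, and the observed multi-clade fraction (multi-clade /
    claded; NaN when no cell was claded).  Multi-clade cells in the
    ``doublet_screen_class`` (bare diploid nuclei cannot fuse into a diploid)
    are additionally reported as presumptive double-sorted doublets.
    """
    out = []
    for pc, grp in assignments.groupby("ploidy_class", sort=False):
        claded = int((grp["n_clades"] >= 1).sum())
        multi = int((grp["n_clades"] >= 2).sum())
        dist = grp["n_clades"].value_counts().sort_index()
        out.append(
            {
                "ploidy_class": pc,
                "n_cells": int(len(grp)),
                "claded": claded,
                "uncladed": int((grp["n_clades"] == 0).sum()),
                "single_clade": int((grp["n_clades"] == 1).sum()),
                "multi_clade": multi,
                "clade_number_distribution": {int(k): int(v) for k, v in dist.items()},
                "observed_multiclade_fraction": (multi / claded) if claded else np.nan,
                "presumptive_doublets": multi if pc == doublet_screen_class else 0,
            }
        )
    return pd.DataFrame(out)
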