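"""Pairwise relatedness, duplicate detection and ordination.

IBS here is allele-sharing identity by state: at a jointly called site a
pair scores 1 for the same diploid genotype, 0.5 when sharing one allele
(het vs hom), and 0 for opposite homozygotes — PLINK "distance" semantics,
which on inbred panels is nearly equivalent to haploid matching.  IBD
(pi-hat) uses the Purcell method-of-moments estimator from IBS-sharing
counts and sample allele frequencies, computed on an LD-pruned site set to
respect the estimator's independence assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .matrix import HET, MISSING, GenotypeMatrix

DUPLICATE_IBS = 0.99
PRUNE_WINDOW = 100
PRUNE_STEP = 25
PRUNE_R2 = 0.2


@dataclass
class PairwiseMatrix:
    """Symmetric sample-by-sample relatedness values.

    ``values`` holds the reported (clamped, for IBD) matrix with unit
    diagonal; ``counts`` the per-pair supporting-site counts; ``raw`` the
    unclamped estimates where clamping applies.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    kind: str
    raw: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def _genotype_indicators(calls: np.ndarray):
    obs = (calls != MISSING).astype(np.float64)
    g = [(calls == c).astype(np.float64) for c in (0, 1, 2)]
    return obs, g


def ibs_matrix(matrix: GenotypeMatrix) -> PairwiseMatrix:
    """Mean allele-sharing over jointly non-missing sites, all pairs.

    Pairs with zero joint sites get NaN; the diagonal is 1 by definition.
    """
    if matrix.n_samples < 2:
        raise ValueError("IBS needs at least 2 samples")
    obs, g = _genotype_indicators(matrix.calls)
    joint = obs @ obs.T
    same = g[0] @ g[0].T + g[1] @ g[1].T + g[2] @ g[2].T
    opposite = g[0] @ g[2].T + g[2] @ g[0].T
    share = same + 0.5 * (joint - same - opposite)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = np.where(joint > 0, share / joint, np.nan)
    np.fill_diagonal(ibs, 1.0)
    ids = matrix.samples
    return PairwiseMatrix(
        values=pd.DataFrame(ibs, index=ids, columns=ids),
        counts=pd.DataFrame(joint.astype(np.int64), index=ids, columns=ids),
        kind="ibs",
    )


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _dosage_r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation between site columns."""
    df = pd.DataFrame(dosage)
    r = df.corr(min_periods=3).to_numpy()
    return r * r


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = PRUNE_WINDOW,
    step: int = PRUNE_STEP,
    r2_threshold: float = PRUNE_R2,
) -> np.ndarray:
    """Greedy within-window pairwise pruning, PLINK indep-pairwise style.

    Within each window of ``window`` adjacent SNPs, for every surviving pair
    with r2 above the threshold the later site is removed; the window then
    slides by ``step`` SNPs to the chromosome end.  Returns the boolean
    kept mask.  r2 is computed on haploidized dosage over pairwise-complete
    samples.
    """
    kept = np.ones(matrix.n_sites, dtype=bool)
    dosage = matrix.haploidized().dosage()
    for chrom, sl in matrix.chromosome_slices().items():
        idx = np.arange(sl.start, sl.stop)
        m = len(idx)
        starts = list(range(0, m, step)) if m else []
        for a in starts:
            win = idx[a : a + window]
            live = win[kept[win]]
            if len(live) < 2:
                continue
            r2 = _dosage_r2_matrix(dosage[:, live])
            alive = np.ones(len(live), dtype=bool)
            for i in range(len(live)):
                if not alive[i]:
                    continue
                for j in range(i + 1, len(live)):
                    if alive[j] and r2[i, j] > r2_threshold:
                        alive[j] = False
            kept[live[~alive]] = False
            if a + window >= m:
                break
    return kept


# ---------------------------------------------------------------------------
# IBD (pi-hat)
# ---------------------------------------------------------------------------

def ibd_estimate(
    matrix: GenotypeMatrix,
    pruned: np.ndarray | None = None,
    model: str = "inbred",
) -> PairwiseMatrix:
    """Method-of-moments pi-hat from IBS sharing counts and sample allele
    frequencies.

    Per pair, observed IBS-class counts are compared with their
    expectations under zero IBD, yielding P(Z=0,1,2) and pi-hat =
    P(Z=1)/2 + P(Z=2).  The expectations depend on the mating system:

    - ``model="inbred"`` (default): lines are treated as doubled haploids
      (calls haploidized), so a non-IBD pair shows opposite homozygotes
      with probability 2pq and sharing is all-or-nothing — pi-hat reduces
      to 1 - IBS0 / sum(2pq).  This matches the backcross expectation
      (a BC4 line shares 97% with its recurrent parent).
    - ``model="outbred"``: the classic HWE (Purcell) expectations.  On a
      fully homozygous panel these are biased (IBS1 never occurs) and
      pi-hat is underestimated; the mode exists for heterozygous material.

    Negative/overshooting raw estimates are clamped to [0, 1] in ``values``
    (raw kept in ``raw``).  ``pruned`` is a boolean site mask (LD-pruned
    set); polymorphic sites are required.
    """
    sub = matrix.take_sites(pruned) if pruned is not None else matrix
    if model == "inbred":
        return _ibd_inbred(sub)
    if model != "outbred":
        raise ValueError(f"unknown IBD model {model!r}")
    calls = sub.calls
    n_called = (calls != MISSING).sum(axis=0).astype(float)
    n_first = 2.0 * (calls == 0).sum(axis=0) + (calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, n_first / (2 * n_called), np.nan)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("IBD estimation requires polymorphic sites")
    calls = calls[:, poly]
    p = p[poly]
    q = 1.0 - p
    obs, g = _genotype_indicators(calls)
    joint = obs @ obs.T
    ibs2 = g[0] @ g[0].T + g[1] @ g[1].T + g[2] @ g[2].T
    ibs0 = g[0] @ g[2].T + g[2] @ g[0].T
    ibs1 = joint - ibs2 - ibs0
    # per-locus expected IBS-class probabilities given IBD state Z
    e00 = 2 * p**2 * q**2
    e10 = 4 * p**3 * q + 4 * p * q**3
    e20 = p**4 + q**4 + 4 * p**2 * q**2
    e11 = 2 * p**2 * q + 2 * p * q**2
    e21 = p**3 + q**3 + p * q
    obsw = obs  # joint-call weighting per pair via indicator products
    E00 = (obsw * e00) @ obsw.T
    E10 = (obsw * e10) @ obsw.T
    E20 = (obsw * e20) @ obsw.T
    E11 = (obsw * e11) @ obsw.T
    E21 = (obsw * e21) @ obsw.T
    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = np.where(E00 > 0, ibs0 / E00, np.nan)
        z1 = np.where(E11 > 0, (ibs1 - z0 * E10) / E11, np.nan)
        z2 = np.where(joint > 0, (ibs2 - z0 * E20 - z1 * E21) / joint, np.nan)
        pihat = z1 / 2.0 + z2
    np.fill_diagonal(pihat, 1.0)
    ids = sub.samples
    raw = pd.DataFrame(pihat, index=ids, columns=ids)
    return PairwiseMatrix(
        values=raw.clip(0.0, 1.0),
        counts=pd.DataFrame(joint.astype(np.int64), index=ids, columns=ids),
        kind="ibd",
        raw=raw,
    )


def _ibd_inbred(sub: GenotypeMatrix) -> PairwiseMatrix:
    """pi-hat for (near-)fully inbred lines: 1 - IBS0 / sum over joint
    sites of 2pq, on haploidized calls."""
    calls = sub.calls.copy()
    calls[calls == HET] = MISSING
    n_called = (calls != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, (calls == 0).sum(axis=0) / n_called, np.nan)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("IBD estimation requires polymorphic sites")
    calls = calls[:, poly]
    p = p[poly]
    q = 1.0 - p
    obs = (calls != MISSING).astype(np.float64)
    is0 = (calls == 0).astype(np.float64)
    is2 = (calls == 2).astype(np.float64)
    joint = obs @ obs.T
    ibs0 = is0 @ is2.T + is2 @ is0.T
    expected0 = (obs * (2 * p * q)) @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pihat = np.where(expected0 > 0, 1.0 - ibs0 / expected0, np.nan)
    np.fill_diagonal(pihat, 1.0)
    ids = sub.samples
    raw = pd.DataFrame(pihat, index=ids, columns=ids)
    return PairwiseMatrix(
        values=raw.clip(0.0, 1.0),
        counts=pd.DataFrame(joint.astype(np.int64), index=ids, columns=ids),
        kind="ibd",
        raw=raw,
    )


# ---------------------------------------------------------------------------
# Neighbors, duplicates, networks
# ---------------------------------------------------------------------------

def nearest_neighbors(ibs: PairwiseMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k most similar samples per sample, ties broken lexicographically.

    Long-format frame: sample, rank (1-based), neighbor, ibs.
    """
    rows = []
    ids = ibs.samples
    vals = ibs.values.to_numpy()
    for i, s in enumerate(ids):
        others = [(ids[j], vals[i, j]) for j in range(len(ids))
                  if j != i and not np.isnan(vals[i, j])]
        others.sort(key=lambda t: (-t[1], t[0]))
        for rank, (nb, v) in enumerate(others[:k], start=1):
            rows.append((s, rank, nb, v))
    return pd.DataFrame(rows, columns=["sample", "rank", "neighbor", "ibs"])


@dataclass
class MergeGroup:
    representative: str
    members: list[str]
    min_ibs: float


def merge_duplicates(
    matrix: GenotypeMatrix,
    ibs: PairwiseMatrix,
    threshold: float = DUPLICATE_IBS,
):
    """Single-linkage clustering of samples at IBS >= threshold, plus a
    consensus matrix with one line per cluster.

    The consensus call at a site is the unanimous non-missing member call,
    missing on conflict, or the sole non-missing call — so consensus
    coverage is at least any member's coverage.  Groups partition the
    panel (singletons included).  The representative is the
    lexicographically first member.
    """
    ids = ibs.samples
    vals = ibs.values.to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= threshold:
                graph.add_edge(ids[i], ids[j])
    groups: list[MergeGroup] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        idx = [ids.index(s) for s in members]
        if len(members) > 1:
            sub = vals[np.ix_(idx, idx)]
            tri = sub[np.triu_indices(len(idx), k=1)]
            min_ibs = float(np.nanmin(tri))
        else:
            min_ibs = 1.0
        groups.append(MergeGroup(members[0], members, min_ibs))
    groups.sort(key=lambda gr: gr.representative)
    cons_rows = []
    for gr in groups:
        sub = matrix.calls[[matrix.sample_index(s) for s in gr.members]]
        obs = sub != MISSING
        n_obs = obs.sum(axis=0)
        # a site is unanimous iff all observed calls equal the first observed
        first = np.where(n_obs > 0, sub[obs.argmax(axis=0), np.arange(sub.shape[1])],
                         MISSING)
        conflict = ((sub != first[None, :]) & obs).any(axis=0)
        cons = np.where((n_obs > 0) & ~conflict, first, MISSING).astype(np.int8)
        cons_rows.append(cons)
    consensus = GenotypeMatrix(
        [gr.representative for gr in groups],
        matrix.sites.copy(),
        np.stack(cons_rows),
    )
    return groups, consensus


def network_edges(ibs: PairwiseMatrix, threshold: float) -> pd.DataFrame:
    """Edge list of pairs with IBS strictly above the threshold,
    deterministically ordered, ready for graph-tool import."""
    ids = ibs.samples
    vals = ibs.values.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = vals[i, j]
            if not np.isnan(v) and v > threshold:
                a, b = sorted((ids[i], ids[j]))
                rows.append((a, b, v))
    rows.sort()
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "ibs"])


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def pcoa(ibs: PairwiseMatrix, dims: int = 2, method: str = "metric", seed: int = 0):
    """Ordinate samples from the 1 - IBS distance matrix.

    Metric mode is classical principal coordinates (Gower double-centering
    plus eigendecomposition); non-metric mode refines the metric solution
    by SMACOF stress minimization on ranks.  Returns coordinates (ordered
    by eigenvalue) and per-axis explained-variance shares (metric mode).
    """
    vals = ibs.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError(
            "IBS matrix has undefined pairs; impute or drop samples with no "
            "jointly called sites before ordination"
        )
    dist = 1.0 - vals
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(pos[:dims])
    explained = pos[:dims] / pos.sum() if pos.sum() > 0 else np.zeros(dims)
    if method == "nonmetric":
        from sklearn.manifold import smacof

        coords, _ = smacof(
            dist,
            metric=False,
            n_components=dims,
            init=coords,
            n_init=1,
            random_state=seed,
            normalized_stress=False,
        )
        explained = np.full(dims, np.nan)
    elif method != "metric":
        raise ValueError(f"unknown ordination method {method!r}")
    frame = pd.DataFrame(
        coords, index=ibs.samples, columns=[f"PCo{k + 1}" for k in range(dims)]
    )
    return frame, explained, eigval


# ---------------------------------------------------------------------------
# Call-set concordance
# ---------------------------------------------------------------------------

def concordance(calls_a: GenotypeMatrix, calls_b: GenotypeMatrix) -> dict:
    """Discrepancy rates between two call sets on their shared grid.

    Sites are matched by (chromosome, position), samples by id.  The
    all-calls rate divides differing by jointly non-missing calls; the
    het-excluded rate additionally drops cells heterozygous in either set.
    """
    shared_samples = [s for s in calls_a.samples if s in set(calls_b.samples)]
    key_a = list(zip(calls_a.sites["chrom"], calls_a.sites["pos"]))
    key_b = {k: j for j, k in enumerate(zip(calls_b.sites["chrom"], calls_b.sites["pos"]))}
    site_pairs = [(i, key_b[k]) for i, k in enumerate(key_a) if k in key_b]
    if not shared_samples or not site_pairs:
        raise ValueError("call sets share no (sample, site) grid")
    ia = [calls_a.sample_index(s) for s in shared_samples]
    ib = [calls_b.sample_index(s) for s in shared_samples]
    ja = [t[0] for t in site_pairs]
    jb = [t[1] for t in site_pairs]
    a = calls_a.calls[np.ix_(ia, ja)]
    b = calls_b.calls[np.ix_(ib, jb)]
    joint = (a != MISSING) & (b != MISSING)
    n_joint = int(joint.sum())
    if n_joint == 0:
        raise ValueError("no jointly non-missing calls between the two sets")
    differ = joint & (a != b)
    nonhet = joint & (a != HET) & (b != HET)
    n_nonhet = int(nonhet.sum())
    return {
        "n_joint": n_joint,
        "discrepancy_all": int(differ.sum()) / n_joint,
        "discrepancy_het_excluded": (
            int((differ & nonhet).sum()) / n_nonhet if n_nonhet else np.nan
        ),
    }
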