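"""Genome-windowed diversity statistics for inbred panels.

Every statistic here treats each inbred as a random sample of a single
haplotype from its population: heterozygous calls are set to missing before
computation (haploidization).  Provided are the minor-allele-frequency
spectrum, a two-carrier allele-presence rule for group sharing, per-site and
windowed Weir–Cockerham Fst, windowed nucleotide divergence (1 - mean IBS),
shared-haplotype-length sampling around random focal SNPs, LD decay with
distance, and Spearman rank correlations between per-window statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import HET, MISSING, GenotypeMatrix

MB = 1_000_000
RARE_MAF = 0.05


def _group_rows(matrix: GenotypeMatrix, group) -> np.ndarray:
    idx = np.array([matrix.sample_index(s) for s in group])
    if len(idx) == 0:
        raise ValueError("empty group")
    return idx


def _haploid(matrix: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """Haploid allele array for the given samples: 0/1, -1 missing."""
    calls = matrix.calls[rows].copy()
    calls[calls == HET] = MISSING
    out = calls.astype(np.int8)
    out[out == 2] = 1
    return out


def _window_starts(pos: np.ndarray, window_bp: int) -> np.ndarray:
    return (pos - 1) // window_bp * window_bp + 1


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def maf_spectrum(
    matrix: GenotypeMatrix,
    group,
    bin_edges=None,
):
    """Folded site-frequency spectrum of a group, on haploidized calls.

    Monomorphic-in-group sites are counted separately and excluded from the
    histogram.  Returns a dict with the histogram, bin edges, per-site MAF,
    the monomorphic count, and the rare-allele fraction (MAF < 0.05 among
    polymorphic sites).
    """
    rows = _group_rows(matrix, group)
    hap = _haploid(matrix, rows)
    called = (hap != MISSING).sum(axis=0).astype(float)
    ones = (hap == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, ones / called, np.nan)
    maf = np.minimum(p, 1.0 - p)
    informative = ~np.isnan(maf)
    poly = informative & (maf > 0)
    if bin_edges is None:
        bin_edges = np.arange(0.0, 0.55, 0.05)
    hist, edges = np.histogram(maf[poly], bins=bin_edges)
    return {
        "hist": hist,
        "bin_edges": edges,
        "maf": maf,
        "n_monomorphic": int((informative & (maf == 0)).sum()),
        "rare_fraction": float((maf[poly] < RARE_MAF).mean()) if poly.any() else np.nan,
    }


def allele_presence(
    matrix: GenotypeMatrix,
    groups: dict,
    min_carriers: int = 2,
):
    """Per-group allele presence under the two-carrier rule.

    An allele counts as present in a group only when carried by at least
    ``min_carriers`` distinct samples (a heterozygote carries both), which
    guards the sharing statistics against singleton sequencing errors.

    Returns per-group boolean presence arrays of shape (n_sites, 2) and a
    summary with each group's percentage of the union of present alleles
    and the percentage shared by all groups.
    """
    presence: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        rows = _group_rows(matrix, members)
        calls = matrix.calls[rows]
        carriers1 = ((calls == 0) | (calls == HET)).sum(axis=0)
        carriers2 = ((calls == 2) | (calls == HET)).sum(axis=0)
        presence[name] = np.stack(
            [carriers1 >= min_carriers, carriers2 >= min_carriers], axis=1
        )
    union = np.zeros_like(next(iter(presence.values())))
    for pres in presence.values():
        union |= pres
    n_union = int(union.sum())
    rows = []
    for name, pres in presence.items():
        rows.append(
            (name, 100.0 * (pres & union).sum() / n_union if n_union else np.nan)
        )
    shared = np.ones_like(union)
    for pres in presence.values():
        shared &= pres
    summary = pd.DataFrame(rows, columns=["group", "percent_of_union"])
    shared_pct = 100.0 * shared.sum() / n_union if n_union else np.nan
    return presence, summary, shared_pct


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-site theta with its variance components and window averages.

    ``fst_global`` is the standard multi-locus ratio-of-sums estimate;
    ``mean_theta`` the unweighted mean of per-site theta.  ``msp``, ``msg``
    and ``nc`` allow bootstrap resampling over sites.
    """

    theta: np.ndarray = field(repr=False)
    msp: np.ndarray = field(repr=False)
    msg: np.ndarray = field(repr=False)
    nc: np.ndarray = field(repr=False)
    windows: pd.DataFrame = field(repr=False)
    fst_global: float = np.nan
    mean_theta: float = np.nan


def fst_global_from_components(msp, msg, nc, idx=None) -> float:
    """Ratio-of-sums Weir–Cockerham estimate over (a subset of) sites."""
    if idx is not None:
        msp, msg, nc = msp[idx], msg[idx], nc[idx]
    ok = ~np.isnan(msp)
    num = np.nansum(msp[ok] - msg[ok])
    den = np.nansum(msp[ok] + (nc[ok] - 1.0) * msg[ok])
    return float(num / den) if den != 0 else np.nan

def weir_cockerham_fst(
    matrix: GenotypeMatrix,
    group_a,
    group_b,
    window_bp: int = MB,
    min_group_n: int = 2,
) -> FstResult:
    """Two-population Weir–Cockerham theta per SNP, on haploidized calls.

    The variance-components (ANOVA) estimator for haploid samples: with
    group allele counts n_i and frequencies p_i,

        MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        n_c = (n. - sum n_i^2 / n.) / (r - 1)
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    Sites with fewer than ``min_group_n`` called haploid samples in either
    group are skipped (NaN).  The window value is the unweighted mean of
    per-site theta over the window's usable sites; ``fst_global`` uses the
    ratio of sums.
    """
    rows_a = _group_rows(matrix, group_a)
    rows_b = _group_rows(matrix, group_b)
    hap_a = _haploid(matrix, rows_a)
    hap_b = _haploid(matrix, rows_b)
    n1 = (hap_a != MISSING).sum(axis=0).astype(float)
    n2 = (hap_b != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, (hap_a == 1).sum(axis=0) / n1, np.nan)
        p2 = np.where(n2 > 0, (hap_b == 1).sum(axis=0) / n2, np.nan)
        nsum = n1 + n2
        pbar = (n1 * p1 + n2 * p2) / nsum
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nsum - 2.0)
        nc = nsum - (n1**2 + n2**2) / nsum
        den = msp + (nc - 1.0) * msg
        theta = np.where(den != 0, (msp - msg) / den, np.nan)
    unusable = (n1 < min_group_n) | (n2 < min_group_n)
    theta[unusable] = np.nan
    msp[unusable] = np.nan
    msg[unusable] = np.nan
    pos = matrix.sites["pos"].to_numpy()
    win = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "start": _window_starts(pos, window_bp),
            "theta": theta,
        }
    )
    grouped = win.groupby(["chrom", "start"], sort=False)["theta"]
    windows = grouped.agg(fst="mean", snp_count=lambda s: s.notna().sum()).reset_index()
    windows["end"] = windows["start"] + window_bp - 1
    windows.loc[windows["snp_count"] == 0, "fst"] = np.nan
    ok = ~np.isnan(theta)
    return FstResult(
        theta=theta,
        msp=msp,
        msg=msg,
        nc=nc,
        windows=windows[["chrom", "start", "end", "fst", "snp_count"]],
        fst_global=fst_global_from_components(msp, msg, nc),
        mean_theta=float(np.mean(theta[ok])) if ok.any() else np.nan,
    )


# ---------------------------------------------------------------------------
# Windowed nucleotide divergence
# ---------------------------------------------------------------------------

def nucleotide_divergence(
    matrix: GenotypeMatrix,
    group_a,
    group_b,
    window_bp: int = MB,
    min_joint_sites: int = 10,
) -> pd.DataFrame:
    """Per-window average nucleotide difference, defined as 1 minus the
    average pairwise IBS across cross-group pairs of haploidized lines.

    Pair-window combinations with fewer than ``min_joint_sites`` jointly
    called sites are excluded.  When the two groups are the same sample
    set, within-group pairs (i < j) are used instead of cross pairs.
    """
    rows_a = _group_rows(matrix, group_a)
    rows_b = _group_rows(matrix, group_b)
    same = list(rows_a) == list(rows_b)
    hap_a = _haploid(matrix, rows_a)
    hap_b = _haploid(matrix, rows_b)
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    starts = _window_starts(pos, window_bp)
    out = []
    for chrom, sl in matrix.chromosome_slices().items():
        for start in np.unique(starts[sl.start : sl.stop]):
            cols = np.flatnonzero((chroms == chrom) & (starts == start))
            a = hap_a[:, cols]
            b = hap_b[:, cols]
            obs_a = (a != MISSING).astype(np.float64)
            obs_b = (b != MISSING).astype(np.float64)
            joint = obs_a @ obs_b.T
            match = (
                (a == 0).astype(np.float64) @ (b == 0).astype(np.float64).T
                + (a == 1).astype(np.float64) @ (b == 1).astype(np.float64).T
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                ibs = np.where(joint >= min_joint_sites, match / joint, np.nan)
            if same:
                iu = np.triu_indices(ibs.shape[0], k=1)
                vals = ibs[iu]
            else:
                vals = ibs.ravel()
            ok = ~np.isnan(vals)
            out.append(
                (
                    chrom,
                    int(start),
                    int(start + window_bp - 1),
                    1.0 - float(vals[ok].mean()) if ok.any() else np.nan,
                    len(cols),
                    int(ok.sum()),
                )
            )
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "divergence", "snp_count", "n_pairs"]
    )


# ---------------------------------------------------------------------------
# Haplotype length sampling
# ---------------------------------------------------------------------------

def _extend(a, b, start, stop, step, allowance):
    """Walk from ``start`` (exclusive) toward ``stop`` (inclusive bound),
    counting matching compared sites; missing-in-either sites are skipped.
    The first ``allowance`` mismatches are forgiven (not counted as
    matches); the next terminates the side.  Returns (n_matches,
    last_match_index or None)."""
    n = 0
    last = None
    i = start + step
    while (step > 0 and i <= stop) or (step < 0 and i >= stop):
        if a[i] != MISSING and b[i] != MISSING:
            if a[i] == b[i]:
                n += 1
                last = i
            elif allowance > 0:
                allowance -= 1
            else:
                break
        i += step
    return n, last


def haplotype_length_sample(
    matrix: GenotypeMatrix,
    group,
    n_draws: int,
    seed: int = 0,
    forgive: int = 1,
) -> pd.DataFrame:
    """Sample shared-haplotype extents around random focal SNPs.

    Each draw picks a random focal site and two random distinct lines from
    the group and extends outward in both directions until genotypes
    differ, on haploidized calls.  Missing-in-either sites are skipped
    (neither match nor mismatch).  ``forgive`` mismatches are permitted on
    each side before a side ends (default one, absorbing isolated
    sequencing errors); a mismatch at the focal site itself consumes the
    allowance of both sides.  No allele-frequency filtering is applied.

    ``length_sites`` counts the focal site plus compared-and-matching
    sites; ``length_bp`` spans the terminal matching sites (inclusive);
    ``median_site`` is the position of the middle site of the shared
    interval, used to assign draws to genome intervals.  Draws whose focal
    site is missing in either line are redrawn.
    """
    rows = _group_rows(matrix, group)
    if len(rows) < 2:
        raise ValueError("haplotype sampling needs a group of >= 2 lines")
    if matrix.n_sites == 0:
        raise ValueError("empty site list")
    rng = np.random.default_rng(seed)
    hap = _haploid(matrix, rows)
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    bounds = matrix.chromosome_slices()
    out = []
    attempts = 0
    max_attempts = 50 * n_draws + 1000
    while len(out) < n_draws and attempts < max_attempts:
        attempts += 1
        f = int(rng.integers(matrix.n_sites))
        i, j = rng.choice(len(rows), size=2, replace=False)
        a, b = hap[i], hap[j]
        if a[f] == MISSING or b[f] == MISSING:
            continue
        sl = bounds[chroms[f]]
        focal_mismatch = a[f] != b[f]
        allowance = forgive - 1 if focal_mismatch else forgive
        if focal_mismatch and forgive == 0:
            n_left = n_right = 0
            last_left = last_right = f
        else:
            n_right, last_r = _extend(a, b, f, sl.stop - 1, +1, allowance)
            n_left, last_l = _extend(a, b, f, sl.start, -1, allowance)
            last_right = last_r if last_r is not None else f
            last_left = last_l if last_l is not None else f
        length_sites = 1 + n_left + n_right
        mid = (last_left + last_right) // 2
        out.append(
            (
                chroms[f],
                f,
                matrix.samples[rows[i]],
                matrix.samples[rows[j]],
                bool(focal_mismatch),
                length_sites,
                int(pos[last_right] - pos[last_left] + 1),
                int(pos[mid]),
            )
        )
    if len(out) < n_draws:
        raise ValueError(
            "could not find enough comparable focal sites; panel too sparse"
        )
    return pd.DataFrame(
        out,
        columns=[
            "chrom", "focal_idx", "sample_a", "sample_b", "focal_mismatch",
            "length_sites", "length_bp", "median_site",
        ],
    )


def haplotype_interval_averages(
    draws: pd.DataFrame, window_bp: int = MB
) -> pd.DataFrame:
    """Average sampled haplotype length per genome interval, draws assigned
    by their median site (the sorting rule of the sampling procedure)."""
    df = draws.copy()
    df["start"] = _window_starts(df["median_site"].to_numpy(), window_bp)
    grouped = df.groupby(["chrom", "start"], sort=False)
    out = grouped.agg(
        mean_length_sites=("length_sites", "mean"),
        mean_length_bp=("length_bp", "mean"),
        n_draws=("length_sites", "size"),
    ).reset_index()
    out["end"] = out["start"] + window_bp - 1
    return out[["chrom", "start", "end", "mean_length_sites", "mean_length_bp", "n_draws"]]


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def _r2_one_vs_many(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared pairwise-complete Pearson correlation of x against columns of y."""
    ok = ~np.isnan(x)[:, None] & ~np.isnan(y)
    n = ok.sum(axis=0).astype(float)
    xs = np.where(ok, x[:, None], 0.0)
    ys = np.where(ok, y, 0.0)
    sx = xs.sum(axis=0)
    sy = ys.sum(axis=0)
    sxx = (xs * xs).sum(axis=0)
    syy = (ys * ys).sum(axis=0)
    sxy = (xs * ys).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = np.where((vx > 0) & (vy > 0) & (n >= 3), cov * cov / (vx * vy), np.nan)
    return r2


def ld_decay(
    matrix: GenotypeMatrix,
    group,
    max_missing: float = 0.25,
    min_maf: float = 0.05,
    subsample: int = 180,
    max_distance: int = MB,
    n_bins: int = 15,
    log_bins: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise r2 against physical distance, summarized per distance bin.

    Sites with more than ``max_missing`` missing data or MAF below
    ``min_maf`` within the group are removed first; ``subsample`` lines are
    drawn at random when the group is larger (all lines, with a warning
    suppressed, otherwise).  r2 is the squared Pearson correlation of
    haploidized dosages over pairwise-complete samples for within-chromosome
    site pairs up to ``max_distance``.  Each bin reports the mean, median,
    and the 50% and 90% bands.
    """
    rows = _group_rows(matrix, group)
    rng = np.random.default_rng(seed)
    if len(rows) > subsample:
        rows = rng.choice(rows, size=subsample, replace=False)
    hap = _haploid(matrix, rows).astype(np.float64)
    hap[hap == MISSING] = np.nan
    called = (~np.isnan(hap)).sum(axis=0).astype(float)
    ones = np.nansum(hap, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, ones / called, np.nan)
    maf = np.minimum(p, 1 - p)
    miss = 1.0 - called / len(rows)
    keep = (miss <= max_missing) & (maf >= min_maf)
    if not keep.any():
        raise ValueError("no SNPs pass the missingness/MAF filters")
    sub = matrix.take_sites(keep)
    hap = hap[:, keep]
    pos = sub.sites["pos"].to_numpy()
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for chrom, sl in sub.chromosome_slices().items():
        cpos = pos[sl.start : sl.stop]
        h = hap[:, sl.start : sl.stop]
        m = len(cpos)
        for i in range(m - 1):
            jmax = np.searchsorted(cpos, cpos[i] + max_distance, side="right")
            if jmax <= i + 1:
                continue
            cols = np.arange(i + 1, jmax)
            r2 = _r2_one_vs_many(h[:, i], h[:, cols])
            ok = ~np.isnan(r2)
            dists.append((cpos[cols] - cpos[i])[ok])
            r2s.append(r2[ok])
    if not dists:
        raise ValueError("no within-range site pairs for LD decay")
    d = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)
    if log_bins:
        edges = np.logspace(np.log10(max(d.min(), 1.0)), np.log10(max_distance), n_bins + 1)
    else:
        edges = np.linspace(d.min(), max_distance, n_bins + 1)
    edges[-1] = max(edges[-1], d.max())
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        v = r2[which == b]
        if len(v) == 0:
            out.append((edges[b], edges[b + 1], 0, *[np.nan] * 6))
            continue
        out.append(
            (
                edges[b], edges[b + 1], len(v),
                float(v.mean()), float(np.median(v)),
                float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)),
                float(np.quantile(v, 0.05)), float(np.quantile(v, 0.95)),
            )
        )
    return pd.DataFrame(
        out,
        columns=["dist_low", "dist_high", "n_pairs", "mean", "median",
                 "q25", "q75", "q05", "q95"],
    )


# ---------------------------------------------------------------------------
# Window rank correlation
# ---------------------------------------------------------------------------

def window_rank_correlation(stats_a, stats_b):
    """Spearman rho and rho^2 between two per-window statistics.

    Pairs with either value missing are dropped; fewer than 3 complete
    pairs leaves the correlation undefined (NaN, NaN).  Ties are
    mid-ranked.
    """
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan, np.nan
    rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho), float(rho * rho)
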