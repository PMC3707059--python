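"""Site-level SNP quality filters for inbred GBS panels.

Two filter stages are provided.  The discovery filter keeps sites by call
rate, coefficient of panmixia (1 - H_O/H_E, near 1 in inbred material and
low at paralog-collapsed sites) and minor allele frequency.  The biparental
error-correction filter exploits families present in the panel: a SNP that
shows an appreciable apparent MAF inside a family where it cannot truly
segregate is an error, and a SNP segregating in families should be in local
LD with its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import HET, MISSING, GenotypeMatrix

DISCOVERY_MIN_CALL_RATE = 0.10
DISCOVERY_MIN_PANMIXIA = 0.8
DISCOVERY_MIN_MAF = 0.002
SEGREGATING_MIN_MAF = 0.15
MAX_FAMILY_ERROR = 0.01
MIN_MEDIAN_R2 = 0.5
MIN_FAMILY_MEMBERS = 10


@dataclass
class FamilyDesign:
    """Biparental family membership: family_id -> member sample ids.

    Samples may belong to at most one family; every family needs at least
    two members.  Parent ids are optional bookkeeping.
    """

    members: dict[str, list[str]]
    parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam, ids in self.members.items():
            if len(ids) < 2:
                raise ValueError(f"family {fam!r} has fewer than 2 members")
            overlap = seen.intersection(ids)
            if overlap:
                raise ValueError(
                    f"sample(s) {sorted(overlap)} belong to more than one family"
                )
            seen.update(ids)

    @classmethod
    def from_tsv(cls, path) -> "FamilyDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        members: dict[str, list[str]] = {}
        for fam, grp in df.groupby("family_id", sort=False):
            members[fam] = grp["sample_id"].tolist()
        return cls(members)

    def to_tsv(self, path) -> None:
        rows = [
            {"family_id": fam, "sample_id": sid}
            for fam, ids in self.members.items()
            for sid in ids
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site summaries and discovery filter
# ---------------------------------------------------------------------------

def site_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site call rate, allele frequency, heterozygosity and panmixia.

    H_O is the fraction of heterozygous calls among non-missing calls; H_E =
    2p(1-p) with p the first-allele frequency (a heterozygote contributes one
    copy of each allele).  The coefficient of panmixia is 1 - H_O/H_E, and
    is defined as 1 at monomorphic sites (the fixation limit of complete
    inbreeding).  All-missing sites are flagged and excluded from filter
    decisions.
    """
    calls = matrix.calls
    n_called = (calls != MISSING).sum(axis=0).astype(float)
    n_het = (calls == HET).sum(axis=0).astype(float)
    # allele-1 copies: 2 per hom_first + 1 per het
    n_first = 2.0 * (calls == 0).sum(axis=0) + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, n_first / (2.0 * n_called), np.nan)
        call_rate = n_called / max(matrix.n_samples, 1)
        maf = np.minimum(p, 1.0 - p)
        obs_het = np.where(n_called > 0, n_het / n_called, np.nan)
        exp_het = 2.0 * p * (1.0 - p)
        panmixia = np.where(exp_het > 0, 1.0 - obs_het / exp_het, 1.0)
        panmixia = np.where(n_called > 0, panmixia, np.nan)
    return pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "pos": matrix.sites["pos"],
            "n_called": n_called.astype(int),
            "call_rate": call_rate,
            "p_first": p,
            "maf": maf,
            "obs_het": obs_het,
            "exp_het": exp_het,
            "panmixia": panmixia,
            "all_missing": n_called == 0,
        }
    )


def discovery_filter(
    table: pd.DataFrame,
    min_call_rate: float = DISCOVERY_MIN_CALL_RATE,
    min_panmixia: float = DISCOVERY_MIN_PANMIXIA,
    min_maf: float = DISCOVERY_MIN_MAF,
) -> np.ndarray:
    """Boolean kept mask: all three thresholds met (inclusive comparisons)."""
    keep = (
        (table["call_rate"].to_numpy() >= min_call_rate)
        & (table["panmixia"].to_numpy() >= min_panmixia)
        & (table["maf"].to_numpy() >= min_maf)
        & ~table["all_missing"].to_numpy()
    )
    return keep


# ---------------------------------------------------------------------------
# Biparental error correction
# ---------------------------------------------------------------------------

def _family_indices(matrix: GenotypeMatrix, families: FamilyDesign):
    out = {}
    for fam, ids in families.members.items():
        out[fam] = np.array([matrix.sample_index(s) for s in ids])
    return out


def apparent_family_maf(
    matrix: GenotypeMatrix,
    families: FamilyDesign,
    site: int,
    segregating_maf: float = SEGREGATING_MIN_MAF,
    min_members: int = MIN_FAMILY_MEMBERS,
):
    """Within-family MAF at one site, on haploidized calls.

    A family is *segregating* at the site iff its within-family MAF is at
    least ``segregating_maf`` (inclusive).  The site's apparent error rate
    is the maximum within-family MAF over non-segregating families — allele
    copies seen inside a family where the SNP is not truly segregating can
    only be errors.  Families with fewer than ``min_members`` genotyped
    members at the site are skipped.

    Returns a per-family DataFrame and the apparent error (NaN when no
    family is assessable).
    """
    idx = _family_indices(matrix, families)
    rows = []
    for fam, members in idx.items():
        calls = matrix.calls[members, site].copy()
        calls[calls == HET] = MISSING  # haploidize
        called = calls != MISSING
        n = int(called.sum())
        if n < min_members:
            rows.append((fam, n, np.nan, None))
            continue
        p = float((calls[called] == 0).mean())
        maf = min(p, 1.0 - p)
        rows.append((fam, n, maf, maf >= segregating_maf))
    df = pd.DataFrame(rows, columns=["family_id", "n_called", "maf", "segregating"])
    nonseg = df.loc[df["segregating"] == False, "maf"]  # noqa: E712
    apparent_error = float(nonseg.max()) if len(nonseg) else np.nan
    return df, apparent_error


def _window_indices(matrix: GenotypeMatrix, site: int, exclude_bp: int = 100_000):
    """Window SNPs for the local-LD test: the nearest one-twentieth of the
    chromosome's SNPs by index, centered on the focal SNP (focal excluded),
    minus SNPs within ``exclude_bp`` of the focal position."""
    chrom = matrix.sites["chrom"].iloc[site]
    sl = matrix.chromosome_slices()[chrom]
    idx = np.arange(sl.start, sl.stop)
    m_chr = len(idx)
    w = max(1, round(m_chr / 20))
    others = idx[idx != site]
    # nearest by index distance, ties to the smaller index
    order = np.lexsort((others, np.abs(others - site)))
    window = np.sort(others[order][:w])
    pos = matrix.sites["pos"].to_numpy()
    window = window[np.abs(pos[window] - pos[site]) > exclude_bp]
    return window


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation on pairwise-complete values."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def local_family_ld(
    matrix: GenotypeMatrix,
    families: FamilyDesign,
    site: int,
    segregating_maf: float = SEGREGATING_MIN_MAF,
    min_members: int = MIN_FAMILY_MEMBERS,
    exclude_bp: int = 100_000,
) -> float:
    """Median r2 between the focal SNP and its local window, per segregating
    family, then the median across families.

    NaN when no family segregates at the site or no window SNP is usable.
    """
    fam_df, _ = apparent_family_maf(
        matrix, families, site, segregating_maf, min_members
    )
    seg_fams = fam_df.loc[fam_df["segregating"] == True, "family_id"]  # noqa: E712
    if seg_fams.empty:
        return np.nan
    window = _window_indices(matrix, site, exclude_bp)
    if len(window) == 0:
        return np.nan
    idx = _family_indices(matrix, families)
    dosage = matrix.haploidized().dosage()
    medians = []
    for fam in seg_fams:
        members = idx[fam]
        focal = dosage[members, site]
        vals = [_r2(focal, dosage[members, j]) for j in window]
        vals = [v for v in vals if not np.isnan(v)]
        if vals:
            medians.append(float(np.median(vals)))
    if not medians:
        return np.nan
    return float(np.median(medians))


def error_correction_filter(
    matrix: GenotypeMatrix,
    families: FamilyDesign,
    max_error: float = MAX_FAMILY_ERROR,
    min_median_r2: float = MIN_MEDIAN_R2,
    segregating_maf: float = SEGREGATING_MIN_MAF,
    min_members: int = MIN_FAMILY_MEMBERS,
    fail_without_segregating_family: bool = False,
    sites: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean kept mask over sites (or the given site subset).

    A site is kept iff its apparent error over non-segregating families is
    at most ``max_error`` (sites assessable in no family pass vacuously) and
    the local-LD test passes (median r2 >= ``min_median_r2``) in segregating
    families.  When no family segregates, the LD test is skipped — the site
    passes that component — unless ``fail_without_segregating_family``.
    """
    site_iter = np.arange(matrix.n_sites) if sites is None else np.asarray(sites)
    keep = np.zeros(matrix.n_sites if sites is None else len(site_iter), dtype=bool)
    for k, s in enumerate(site_iter):
        fam_df, apparent_error = apparent_family_maf(
            matrix, families, int(s), segregating_maf, min_members
        )
        if not np.isnan(apparent_error) and apparent_error > max_error:
            continue
        any_seg = (fam_df["segregating"] == True).any()  # noqa: E712
        if any_seg:
            med = local_family_ld(
                matrix, families, int(s), segregating_maf, min_members
            )
            if np.isnan(med) or med >= min_median_r2:
                keep[k] = True
        else:
            keep[k] = not fail_without_segregating_family
    return keep
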