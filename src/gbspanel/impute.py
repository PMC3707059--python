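"""Window-based nearest-neighbor imputation with a mismatch veto.

The site list is divided into consecutive windows (1,024 SNPs by default,
never spanning a chromosome boundary).  For each sample and window, the
most similar donor line over jointly non-missing haploidized calls fills the
sample's missing calls — but only if the best donor differs by at most 5%;
otherwise the window is left unimputed.  The approach exploits short IBD
segments shared between inbred lines, so accuracy grows with the density of
close relatives in the donor panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .matrix import HET, MISSING, GenotypeMatrix

DEFAULT_WINDOW = 1024
DEFAULT_MAX_MISMATCH = 0.05
DEFAULT_MIN_OVERLAP = 32


@dataclass
class ImputationParams:
    """Tuning knobs of the nearest-neighbor imputer.

    ``min_overlap`` guards against spurious zero-mismatch matches decided on
    a handful of shared calls.  With ``haploidize=False`` a het-vs-hom
    comparison counts as half a mismatch instead of being dropped.
    ``donor_set`` restricts donors to the named samples (default: the whole
    panel; the target itself is always excluded).
    """

    window_size: int = DEFAULT_WINDOW
    max_mismatch: float = DEFAULT_MAX_MISMATCH
    min_overlap: int = DEFAULT_MIN_OVERLAP
    donor_set: list[str] | None = None
    haploidize: bool = True

    def validate(self) -> None:
        if self.window_size < 2:
            raise ValueError(f"window_size={self.window_size} must be >= 2")
        if not 0.0 <= self.max_mismatch <= 1.0:
            raise ValueError(f"max_mismatch={self.max_mismatch} outside [0, 1]")
        if self.min_overlap < 1:
            raise ValueError(f"min_overlap={self.min_overlap} must be >= 1")


class DonorChoice(NamedTuple):
    donor: str
    mismatch: float
    overlap: int


@dataclass
class ImputationReport:
    """Outcome bookkeeping over originally-missing calls."""

    n_missing_before: int
    n_imputed: int
    choices: pd.DataFrame = field(repr=False)

    @property
    def fraction_imputed(self) -> float:
        if self.n_missing_before == 0:
            return np.nan
        return self.n_imputed / self.n_missing_before

    @property
    def fraction_left_missing(self) -> float:
        if self.n_missing_before == 0:
            return np.nan
        return 1.0 - self.fraction_imputed


def partition_windows(sites: pd.DataFrame, window_size: int) -> list[np.ndarray]:
    """Consecutive non-overlapping index blocks of ``window_size`` sites;
    the final block of a chromosome may be shorter; windows never span
    chromosomes."""
    if window_size < 2:
        raise ValueError(f"window_size={window_size} must be >= 2")
    windows: list[np.ndarray] = []
    chroms = sites["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            for a in range(start, i, window_size):
                windows.append(np.arange(a, min(a + window_size, i)))
            start = i
    return windows


def _mismatch_table(matrix: GenotypeMatrix, window: np.ndarray, haploidize: bool):
    """All-pairs (mismatch fraction, overlap) over the window.

    Haploidized mode drops het calls; otherwise distance per site is
    |dosage difference| so het vs hom counts 0.5.
    """
    calls = matrix.calls[:, window]
    if haploidize:
        calls = calls.copy()
        calls[calls == HET] = MISSING
    obs = (calls != MISSING).astype(np.float64)
    overlap = obs @ obs.T
    if haploidize:
        is0 = ((calls == 0) & (calls != MISSING)).astype(np.float64)
        is2 = (calls == 2).astype(np.float64)
        mismatches = is0 @ is2.T + is2 @ is0.T
    else:
        # expected |d_i - d_j| via genotype-class cross counts
        g = [(calls == c).astype(np.float64) for c in (0, 1, 2)]
        mismatches = (
            0.5 * (g[0] @ g[1].T + g[1] @ g[0].T + g[1] @ g[2].T + g[2] @ g[1].T)
            + 1.0 * (g[0] @ g[2].T + g[2] @ g[0].T)
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(overlap > 0, mismatches / overlap, np.nan)
    return frac, overlap.astype(np.int64)


def nearest_donor(
    matrix: GenotypeMatrix,
    window: np.ndarray,
    target_sample: str,
    params: ImputationParams,
) -> DonorChoice | None:
    """Most similar donor line to the target within one window.

    The donor minimizes the mismatch fraction over jointly non-missing
    calls; ties go to the larger overlap, then the lexicographically
    smaller donor id.  ``None`` when no donor reaches ``min_overlap``.
    """
    params.validate()
    frac, overlap = _mismatch_table(matrix, window, params.haploidize)
    t = matrix.sample_index(target_sample)
    donors = params.donor_set or matrix.samples
    best: DonorChoice | None = None
    for d in donors:
        j = matrix.sample_index(d)
        if j == t or overlap[t, j] < params.min_overlap:
            continue
        cand = DonorChoice(d, float(frac[t, j]), int(overlap[t, j]))
        if (
            best is None
            or cand.mismatch < best.mismatch
            or (cand.mismatch == best.mismatch and cand.overlap > best.overlap)
            or (
                cand.mismatch == best.mismatch
                and cand.overlap == best.overlap
                and cand.donor < best.donor
            )
        ):
            best = cand
    return best


def impute_panel(matrix: GenotypeMatrix, params: ImputationParams | None = None):
    """Impute missing calls window by window from each sample's nearest donor.

    For every (sample, window) whose best donor passes the mismatch veto,
    missing calls are copied from the donor; cells missing in the donor too
    stay missing.  Observed calls are never altered.

    Returns the imputed matrix and an :class:`ImputationReport`.
    """
    params = params or ImputationParams()
    params.validate()
    windows = partition_windows(matrix.sites, params.window_size)
    out = matrix.calls.copy()
    donor_rows = []
    n_missing_before = int((matrix.calls == MISSING).sum())
    n_imputed = 0
    donor_idx = (
        np.array([matrix.sample_index(s) for s in params.donor_set])
        if params.donor_set
        else np.arange(matrix.n_samples)
    )
    donor_ids = np.array(
        params.donor_set if params.donor_set else matrix.samples, dtype=object
    )
    for w, window in enumerate(windows):
        frac, overlap = _mismatch_table(matrix, window, params.haploidize)
        for t in range(matrix.n_samples):
            hole = window[matrix.calls[t, window] == MISSING]
            if len(hole) == 0:
                continue
            f = frac[t, donor_idx].copy()
            o = overlap[t, donor_idx]
            usable = (o >= params.min_overlap) & (donor_idx != t)
            if not usable.any():
                continue
            f[~usable] = np.inf
            # min mismatch, then max overlap, then lexicographic donor id
            order = np.lexsort((donor_ids, -o, f))
            k = order[0]
            choice = DonorChoice(str(donor_ids[k]), float(f[k]), int(o[k]))
            accepted = choice.mismatch <= params.max_mismatch
            donor_rows.append(
                (w, matrix.samples[t], choice.donor, choice.mismatch,
                 choice.overlap, accepted)
            )
            if accepted:
                src = matrix.calls[donor_idx[k], hole]
                fill = src != MISSING
                out[t, hole[fill]] = src[fill]
                n_imputed += int(fill.sum())
    report = ImputationReport(
        n_missing_before=n_missing_before,
        n_imputed=n_imputed,
        choices=pd.DataFrame(
            donor_rows,
            columns=["window", "sample", "donor", "mismatch", "overlap", "accepted"],
        ),
    )
    return GenotypeMatrix(list(matrix.samples), matrix.sites.copy(), out), report


def evaluate_imputation(
    truth: GenotypeMatrix,
    mask_record: pd.DataFrame,
    imputed: GenotypeMatrix,
) -> dict:
    """Score imputation against masked ground truth.

    Returns the discrepancy rate over imputed (masked, now filled) cells,
    the rate excluding cells heterozygous in truth or imputation, and the
    fraction of masked cells left missing.  Rates are NaN when the mask is
    empty or nothing was imputed.
    """
    if len(mask_record) == 0:
        return {
            "n_masked": 0,
            "error_all": np.nan,
            "error_het_excluded": np.nan,
            "fraction_not_imputed": np.nan,
        }
    si = mask_record["sample_idx"].to_numpy()
    sj = mask_record["site_idx"].to_numpy()
    true_calls = mask_record["call"].to_numpy()
    got = imputed.calls[si, sj]
    filled = got != MISSING
    wrong = filled & (got != true_calls)
    nonhet = filled & (true_calls != HET) & (got != HET)
    n_filled = int(filled.sum())
    n_nonhet = int(nonhet.sum())
    return {
        "n_masked": len(mask_record),
        "n_imputed": n_filled,
        "error_all": (int(wrong.sum()) / n_filled) if n_filled else np.nan,
        "error_het_excluded": (
            int((wrong & nonhet).sum()) / n_nonhet if n_nonhet else np.nan
        ),
        "fraction_not_imputed": 1.0 - n_filled / len(mask_record),
    }
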