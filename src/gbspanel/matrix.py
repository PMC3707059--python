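"""Canonical in-memory representation of a diploid SNP genotype panel.

Every stage of the pipeline operates on a :class:`GenotypeMatrix`: an ordered
list of sample identifiers, a site table (chromosome, 1-based position, the
two alleles observed at the site) and a dense ``int8`` call array of shape
``(n_samples, n_sites)``.

Call encoding (module constants):

====================  =====  ========================================
state                 code   meaning
====================  =====  ========================================
``HOM_FIRST``         0      homozygous for the first (REF-like) allele
``HET``               1      heterozygous
``HOM_SECOND``        2      homozygous for the second allele
``MISSING``           -1     no call
====================  =====  ========================================

The integer code of a non-missing call equals the dosage of the second
allele, which makes frequency and distance computations direct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_FIRST: int = 0
HET: int = 1
HOM_SECOND: int = 2
MISSING: int = -1

SITE_COLUMNS = ("chrom", "pos", "allele1", "allele2")


@dataclass
class GenotypeMatrix:
    """Diploid genotype panel: samples x sites with site metadata.

    Parameters
    ----------
    samples : list of str
        Ordered, unique sample identifiers.
    sites : pandas.DataFrame
        One row per site with columns ``chrom`` (str), ``pos`` (int,
        1-based), ``allele1`` and ``allele2`` (single nucleotides).
        Sites of one chromosome must be contiguous and sorted by
        position; no duplicate (chrom, pos, alleles) sites (equal
        positions arise only from split multi-allelic records).
    calls : numpy.ndarray
        ``int8`` array of shape ``(len(samples), len(sites))``.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns {missing_cols}")
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"call array shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (HOM_FIRST, HET, HOM_SECOND, MISSING))
        if bad.any():
            raise ValueError("call array contains codes outside {-1, 0, 1, 2}")
        self._check_site_order()

    def _check_site_order(self) -> None:
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        if len(pos) and pos.min() < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        prev_alleles: tuple | None = None
        for c, p, a1, a2 in zip(
            chroms, pos, self.sites["allele1"], self.sites["allele2"]
        ):
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"sites of chromosome {c!r} are not contiguous")
                seen.add(c)
                prev_chrom, prev_pos, prev_alleles = c, -1, None
            if p < prev_pos:
                raise ValueError(
                    f"positions on chromosome {c!r} must be sorted "
                    f"(unsorted position {p})"
                )
            # equal positions only for split multi-allelic records, which
            # must then differ in their allele pair
            if p == prev_pos and (a1, a2) == prev_alleles:
                raise ValueError(f"duplicate site {c}:{p} with alleles {a1}/{a2}")
            prev_pos, prev_alleles = p, (a1, a2)

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous site-index slice for each chromosome."""
        out: dict[str, slice] = {}
        chroms = self.sites["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    # -- derived views -------------------------------------------------------

    def haploidized(self) -> "GenotypeMatrix":
        """Copy with every heterozygous call set to missing.

        Treating each inbred as a random sample of a single haplotype is the
        convention used throughout the diversity statistics.
        """
        calls = self.calls.copy()
        calls[calls == HET] = MISSING
        return GenotypeMatrix(list(self.samples), self.sites.copy(), calls)

    def dosage(self) -> np.ndarray:
        """Float dosage of the second allele (0, 0.5, 1), NaN where missing."""
        d = self.calls.astype(np.float64) / 2.0
        d[self.calls == MISSING] = np.nan
        return d

    def call_rate_per_sample(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def call_rate_per_site(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.calls != MISSING).mean(axis=0)

    # -- manipulation --------------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.sites.copy(), self.calls.copy())

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.sites.copy(), self.calls[idx])

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites[list(SITE_COLUMNS)].equals(other.sites[list(SITE_COLUMNS)])
            and np.array_equal(self.calls, other.calls)
        )


def make_sites(
    chrom,
    pos,
    allele1,
    allele2,
) -> pd.DataFrame:
    """Assemble a site table from per-site vectors."""
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "allele1": np.asarray(allele1, dtype=object),
            "allele2": np.asarray(allele2, dtype=object),
        }
    )
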