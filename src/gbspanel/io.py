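"""Reading and writing genotype panels in VCF and TASSEL HapMap text.

Both formats round-trip through :class:`~gbspanel.matrix.GenotypeMatrix`.
VCF parsing is delegated to :mod:`cyvcf2`; the TASSEL HapMap dialect
(11 metadata columns followed by one IUPAC single-letter diploid code per
sample) has no installed parser and is implemented here.

Coordinates are 1-based and inclusive everywhere.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import HET, HOM_FIRST, HOM_SECOND, MISSING, GenotypeMatrix, make_sites

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_hapmap",
    "write_hapmap",
    "haploidize",
    "read_sample_table",
    "write_sample_table",
    "ParseError",
]

# IUPAC ambiguity codes for unordered heterozygous allele pairs.
_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_HET_ALLELES = {v: k for k, v in _IUPAC_HET.items()}

HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _opener(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF file.

    Diploid calls are mapped to the canonical states regardless of phasing.
    Multi-allelic records are rejected unless ``split_multiallelic`` is set,
    in which case each alternate allele becomes its own biallelic site
    (non-carrier genotypes of the other alternates become missing).
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    a1: list[str] = []
    a2: list[str] = []
    rows: list[np.ndarray] = []
    for i, var in enumerate(vcf):
        alts = [a for a in var.ALT if a != "."]
        if len(alts) == 0:
            continue
        if len(alts) > 1 and not split_multiallelic:
            raise ParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} (record {i + 1}); "
                "pass split_multiallelic=True to split"
            )
        gts = var.genotype.array()  # (n_samples, ploidy+1); last column is phase
        alleles = gts[:, :2]
        for alt_index, alt in enumerate(alts, start=1):
            calls = np.full(len(samples), MISSING, dtype=np.int8)
            known = (alleles >= 0).all(axis=1)
            dose = (alleles == alt_index).sum(axis=1)
            other = ((alleles != 0) & (alleles != alt_index) & (alleles >= 0)).any(axis=1)
            calls[known & (dose == 0) & ~other] = HOM_FIRST
            calls[known & (dose == 1) & ~other] = HET
            calls[known & (dose == 2)] = HOM_SECOND
            chroms.append(var.CHROM)
            pos.append(var.POS)
            a1.append(var.REF)
            a2.append(alt)
            rows.append(calls)
    vcf.close()
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, make_sites(chroms, pos, a1, a2), calls)


_VCF_GT = {HOM_FIRST: "0/0", HET: "0/1", HOM_SECOND: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal, deterministic VCF 4.2 file."""
    with _opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gbspanel\n")
        slices = matrix.chromosome_slices()
        for chrom, sl in slices.items():
            length = int(matrix.sites["pos"].iloc[sl.stop - 1])
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        sites = matrix.sites
        for j in range(matrix.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(_VCF_GT[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.chrom}_{row.pos}\t"
                f"{row.allele1}\t{row.allele2}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TASSEL HapMap text
# ---------------------------------------------------------------------------

def _hapmap_code(call: int, a1: str, a2: str) -> str:
    if call == MISSING:
        return "N"
    if call == HOM_FIRST:
        return a1
    if call == HOM_SECOND:
        return a2
    pair = frozenset((a1, a2))
    try:
        return _IUPAC_HET[pair]
    except KeyError:
        raise ValueError(f"no IUPAC heterozygote code for allele pair {a1}/{a2}") from None


def write_hapmap(matrix: GenotypeMatrix, path) -> None:
    """Write TASSEL 3 HapMap text (.hmp.txt), one IUPAC code per call."""
    with _opener(path, "wt") as fh:
        fh.write("\t".join(HAPMAP_HEADER + list(matrix.samples)) + "\n")
        sites = matrix.sites
        for j in range(matrix.n_sites):
            row = sites.iloc[j]
            meta = [
                f"{row.chrom}_{row.pos}",
                f"{row.allele1}/{row.allele2}",
                str(row.chrom),
                str(row.pos),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            codes = [
                _hapmap_code(int(c), row.allele1, row.allele2)
                for c in matrix.calls[:, j]
            ]
            fh.write("\t".join(meta + codes) + "\n")


def read_hapmap(path) -> GenotypeMatrix:
    """Read TASSEL HapMap text into the canonical matrix."""
    with _opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12 or header[2] != "chrom" or header[3] != "pos":
            raise ParseError(
                f"{path}: not a HapMap header (expected 11 metadata columns "
                "starting 'rs#\talleles\tchrom\tpos...')"
            )
        samples = header[11:]
        chroms: list[str] = []
        pos: list[int] = []
        a1s: list[str] = []
        a2s: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 11 + len(samples):
                raise ParseError(
                    f"{path}:{lineno}: expected {11 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            alleles = fields[1].split("/")
            if len(alleles) != 2:
                raise ParseError(f"{path}:{lineno}: bad alleles field {fields[1]!r}")
            a1, a2 = alleles
            het_code = _IUPAC_HET.get(frozenset((a1, a2)))
            calls = np.empty(len(samples), dtype=np.int8)
            for k, code in enumerate(fields[11:]):
                if code == "N":
                    calls[k] = MISSING
                elif code == a1:
                    calls[k] = HOM_FIRST
                elif code == a2:
                    calls[k] = HOM_SECOND
                elif code == het_code:
                    calls[k] = HET
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unknown genotype code {code!r} for "
                        f"sample {samples[k]!r} at site with alleles {a1}/{a2}"
                    )
            chroms.append(fields[2])
            pos.append(int(fields[3]))
            a1s.append(a1)
            a2s.append(a2)
            rows.append(calls)
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, make_sites(chroms, pos, a1s, a2s), calls)


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def haploidize(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Set every heterozygous call to missing (see GenotypeMatrix.haploidized)."""
    return matrix.haploidized()


def read_sample_table(path) -> pd.DataFrame:
    """Read a TSV of per-sample metadata; first column must be sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
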