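"""Synthetic genotype panels with known ground truth.

The generators emulate the statistical structure a large inbred GBS panel
presents to the analysis stages: multiple subpopulations at a tunable
fixation index, inbred lines with residual heterozygosity, backcross-derived
near-duplicates, biparental families, genotype-dependent missingness and
base-call errors.  Each generator returns its ground truth (group labels,
ancestry fractions, mask records, error records) so downstream estimates can
be scored against known values.

Population structure follows the Balding–Nichols model: per-group allele
frequencies are Beta-distributed around an ancestral frequency with drift
parameter equal to the target fixation index, giving a closed-form link
between the generator parameter and the Weir–Cockerham expectation.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import HET, HOM_FIRST, HOM_SECOND, MISSING, GenotypeMatrix, make_sites

_NUCLEOTIDES = np.array(list("ACGT"))


def _check_range(name: str, value, lo, hi) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside allowed range [{lo}, {hi}]")


def _check_count(name: str, value, minimum=1) -> None:
    if int(value) != value or value < minimum:
        raise ValueError(f"{name}={value!r} must be an integer >= {minimum}")


@dataclass
class PanelConfig:
    """Configuration of a structured multi-group inbred panel.

    Defaults mirror the panel structure the pipeline is designed around:
    three subpopulations at moderate differentiation (Fst 0.06), inbred
    lines with sparse residual heterozygosity, and a ~0.2% base-call error
    rate.
    """

    n_groups: int = 3
    samples_per_group: int = 60
    n_chromosomes: int = 2
    sites_per_chromosome: int = 500
    chromosome_length: int = 10_000_000
    fst_target: float = 0.06
    residual_het_rate: float = 0.005
    error_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        _check_count("n_groups", self.n_groups)
        _check_count("samples_per_group", self.samples_per_group)
        _check_count("n_chromosomes", self.n_chromosomes)
        _check_count("sites_per_chromosome", self.sites_per_chromosome)
        _check_count("chromosome_length", self.chromosome_length)
        _check_range("fst_target", self.fst_target, 0.0, 0.99)
        _check_range("residual_het_rate", self.residual_het_rate, 0.0, 1.0)
        _check_range("error_rate", self.error_rate, 0.0, 1.0)
        if self.chromosome_length < self.sites_per_chromosome:
            raise ValueError(
                "chromosome_length must admit sites_per_chromosome distinct positions"
            )


@dataclass
class MissingnessModel:
    """Per-sample call-rate model with optional genotype dependence.

    Call rates are drawn uniformly between the two bounds (default 2–75%,
    the per-sample coverage range such panels exhibit).  ``genotype_bias``
    multiplies a sample's call rate down in proportion to its genotypic
    distance from a designated reference lineage, mimicking the effect of
    aligning reads against a single reference genome; realized rates are
    clipped back into [low, high].
    """

    per_sample_callrate_low: float = 0.02
    per_sample_callrate_high: float = 0.75
    genotype_bias: float = 0.0

    def validate(self) -> None:
        _check_range("per_sample_callrate_low", self.per_sample_callrate_low, 0.0, 1.0)
        _check_range("per_sample_callrate_high", self.per_sample_callrate_high, 0.0, 1.0)
        if self.per_sample_callrate_low > self.per_sample_callrate_high:
            raise ValueError(
                "per_sample_callrate_low exceeds per_sample_callrate_high"
            )
        if self.genotype_bias < 0:
            raise ValueError(f"genotype_bias={self.genotype_bias!r} must be >= 0")


@dataclass
class PedigreeSpec:
    """Backcross/selfing pedigree: b backcrosses to the recurrent parent
    followed by selfing, with a Poisson number of crossovers per chromosome
    per meiosis placed uniformly along the physical map."""

    n_backcrosses: int = 4
    n_self_generations: int = 3
    crossovers_per_chromosome: float = 2.0

    def validate(self) -> None:
        _check_count("n_backcrosses", self.n_backcrosses, minimum=0)
        _check_count("n_self_generations", self.n_self_generations, minimum=0)
        if self.crossovers_per_chromosome < 0:
            raise ValueError("crossovers_per_chromosome must be >= 0")


def expected_recurrent_fraction(n_backcrosses: int) -> float:
    """Expected recurrent-parent genome fraction after b backcrosses to it.

    The F1 carries 1/2 recurrent germplasm; every backcross halves the donor
    remainder, so the expectation is ``1 - (1/2)**(b + 1)``.  Selfing does
    not change the expectation.
    """
    return 1.0 - 0.5 ** (n_backcrosses + 1)


# ---------------------------------------------------------------------------
# Structured panel
# ---------------------------------------------------------------------------

def _random_sites(rng, n_chromosomes, sites_per_chromosome, chromosome_length):
    chroms, pos, a1, a2 = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        p = np.sort(
            rng.choice(
                np.arange(1, chromosome_length + 1),
                size=sites_per_chromosome,
                replace=False,
            )
        )
        chroms.extend([str(c)] * sites_per_chromosome)
        pos.extend(p.tolist())
        for _ in range(sites_per_chromosome):
            i, j = rng.choice(4, size=2, replace=False)
            a1.append(_NUCLEOTIDES[i])
            a2.append(_NUCLEOTIDES[j])
    return make_sites(chroms, pos, a1, a2)


def simulate_structured_panel(config: PanelConfig):
    """Simulate a multi-group inbred panel under Balding–Nichols drift.

    Returns
    -------
    matrix : GenotypeMatrix
        Diploid calls; lines are homozygous except at ``residual_het_rate``
        of calls, and ``error_rate`` of calls carry an injected error.
    labels : pandas.Series
        sample_id -> group label, the ground-truth stratification.
    ancestral_freq : numpy.ndarray
        Per-site ancestral frequency of the second allele.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_chromosomes * config.sites_per_chromosome
    sites = _random_sites(
        rng, config.n_chromosomes, config.sites_per_chromosome, config.chromosome_length
    )
    # keep ancestral frequencies away from the boundary so sites stay
    # polymorphic at desk-scale sample sizes
    anc = rng.uniform(0.1, 0.9, size=m)
    F = config.fst_target
    group_freq = np.empty((config.n_groups, m))
    for g in range(config.n_groups):
        if F == 0:
            group_freq[g] = anc
        else:
            a = anc * (1.0 - F) / F
            b = (1.0 - anc) * (1.0 - F) / F
            group_freq[g] = rng.beta(a, b)
    group_names = [f"group{string.ascii_uppercase[g % 26]}" for g in range(config.n_groups)]
    samples, labels = [], []
    n = config.n_groups * config.samples_per_group
    calls = np.empty((n, m), dtype=np.int8)
    row = 0
    for g, gname in enumerate(group_names):
        for k in range(config.samples_per_group):
            sid = f"{gname}_L{k:03d}"
            samples.append(sid)
            labels.append(gname)
            hap = (rng.random(m) < group_freq[g]).astype(np.int8)
            calls[row] = 2 * hap
            row += 1
    if config.residual_het_rate > 0:
        het_mask = rng.random(calls.shape) < config.residual_het_rate
        calls[het_mask] = HET
    matrix = GenotypeMatrix(samples, sites, calls)
    if config.error_rate > 0:
        matrix, _ = inject_errors(matrix, config.error_rate, seed=rng.integers(2**31))
    return matrix, pd.Series(labels, index=samples, name="group"), anc


# ---------------------------------------------------------------------------
# Meiosis machinery
# ---------------------------------------------------------------------------

def _gamete(hap_a, hap_b, matrix: GenotypeMatrix, crossovers: float, rng):
    """One recombinant gamete from a diploid pair of per-site arrays."""
    out = np.empty_like(hap_a)
    for chrom, sl in matrix.chromosome_slices().items():
        pos = matrix.sites["pos"].to_numpy()[sl]
        n_x = rng.poisson(crossovers)
        breaks = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        phase = (int(rng.integers(2)) + np.searchsorted(breaks, pos)) % 2
        seg = np.where(phase == 0, hap_a[sl], hap_b[sl])
        out[sl] = seg
    return out


def _haploid_pattern(matrix: GenotypeMatrix, sample_id: str) -> np.ndarray:
    """Haploid allele pattern of an inbred (het -> missing)."""
    row = matrix.calls[matrix.sample_index(sample_id)]
    pat = np.full(row.shape, MISSING, dtype=np.int8)
    pat[row == HOM_FIRST] = 0
    pat[row == HOM_SECOND] = 1
    return pat


def _calls_from_ancestry(anc1, anc2, pat_rec, pat_don):
    a1 = np.where(anc1 == 0, pat_rec, pat_don)
    a2 = np.where(anc2 == 0, pat_rec, pat_don)
    calls = (a1 + a2).astype(np.int8)
    calls[(a1 == MISSING) | (a2 == MISSING)] = MISSING
    return calls


@dataclass
class BackcrossResult:
    calls: np.ndarray
    realized_recurrent_fraction: float
    ancestry: tuple = field(repr=False, default=None)


def simulate_backcross_line(
    parents: GenotypeMatrix,
    recurrent: str,
    donor: str,
    spec: PedigreeSpec,
    seed: int,
) -> BackcrossResult:
    """Derive one inbred from ``donor`` by repeated backcrossing to
    ``recurrent`` followed by selfing, tracking ancestry per site.

    The realized recurrent-parent fraction is measured over sites where the
    two parents carry different (non-missing, haploidized) alleles; its
    expectation is ``1 - (1/2)**(n_backcrosses + 1)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    pat_rec = _haploid_pattern(parents, recurrent)
    pat_don = _haploid_pattern(parents, donor)
    m = parents.n_sites
    # ancestry coding: 0 = recurrent parent, 1 = donor
    anc1 = np.zeros(m, dtype=np.int8)  # gamete from recurrent
    anc2 = np.ones(m, dtype=np.int8)   # gamete from donor (F1)
    for _ in range(spec.n_backcrosses):
        gam = _gamete(anc1, anc2, parents, spec.crossovers_per_chromosome, rng)
        anc1, anc2 = np.zeros(m, dtype=np.int8), gam
    for _ in range(spec.n_self_generations):
        g1 = _gamete(anc1, anc2, parents, spec.crossovers_per_chromosome, rng)
        g2 = _gamete(anc1, anc2, parents, spec.crossovers_per_chromosome, rng)
        anc1, anc2 = g1, g2
    informative = (pat_rec != pat_don) & (pat_rec != MISSING) & (pat_don != MISSING)
    if not informative.any():
        warnings.warn(
            "recurrent and donor parents are identical at every comparable site; "
            "realized recurrent fraction reported as 1.0",
            stacklevel=2,
        )
        frac = 1.0
    else:
        frac = float(
            ((anc1[informative] == 0).mean() + (anc2[informative] == 0).mean()) / 2.0
        )
    calls = _calls_from_ancestry(anc1, anc2, pat_rec, pat_don)
    return BackcrossResult(calls=calls, realized_recurrent_fraction=frac,
                           ancestry=(anc1, anc2))


def simulate_biparental_family(
    parents: GenotypeMatrix,
    parent_a: str,
    parent_b: str,
    n_progeny: int,
    generations_of_selfing: int = 5,
    seed: int = 0,
    crossovers_per_chromosome: float = 2.0,
    error_rate: float = 0.0,
    progeny_prefix: str | None = None,
) -> GenotypeMatrix:
    """Simulate a biparental family: F1 of the two parents selfed by
    single-seed descent for the given number of generations.

    At sites where the parents are identical the progeny reproduce the
    parents (barring injected error); at segregating sites the allele
    frequency is ~0.5 after selfing.
    """
    if n_progeny < 2:
        raise ValueError(f"n_progeny={n_progeny} must be >= 2")
    rng = np.random.default_rng(seed)
    pat_a = _haploid_pattern(parents, parent_a)
    pat_b = _haploid_pattern(parents, parent_b)
    m = parents.n_sites
    prefix = progeny_prefix or f"{parent_a}x{parent_b}"
    rows, ids = [], []
    for k in range(n_progeny):
        anc1 = np.zeros(m, dtype=np.int8)
        anc2 = np.ones(m, dtype=np.int8)
        for _ in range(generations_of_selfing):
            g1 = _gamete(anc1, anc2, parents, crossovers_per_chromosome, rng)
            g2 = _gamete(anc1, anc2, parents, crossovers_per_chromosome, rng)
            anc1, anc2 = g1, g2
        rows.append(_calls_from_ancestry(anc1, anc2, pat_a, pat_b))
        ids.append(f"{prefix}_P{k:03d}")
    fam = GenotypeMatrix(ids, parents.sites.copy(), np.stack(rows))
    if error_rate > 0:
        fam, _ = inject_errors(fam, error_rate, seed=rng.integers(2**31))
    return fam


# ---------------------------------------------------------------------------
# Missingness and errors
# ---------------------------------------------------------------------------

def mask_genotypes(
    matrix: GenotypeMatrix,
    model: MissingnessModel,
    seed: int,
    reference: str | None = None,
):
    """Hide calls to emulate per-sample GBS coverage.

    Returns the masked matrix and a mask record listing every hidden call
    (sample, site index, original call) so imputation can later be scored.
    Restoring the record reconstitutes the input bit-exactly
    (:func:`restore_mask`).
    """
    model.validate()
    rng = np.random.default_rng(seed)
    n, m = matrix.calls.shape
    lo, hi = model.per_sample_callrate_low, model.per_sample_callrate_high
    rates = rng.uniform(lo, hi, size=n)
    if model.genotype_bias > 0:
        ref_idx = matrix.sample_index(reference) if reference else 0
        ref = matrix.calls[ref_idx]
        joint = (matrix.calls != MISSING) & (ref != MISSING)
        with np.errstate(invalid="ignore"):
            dist = np.where(
                joint.sum(axis=1) > 0,
                ((matrix.calls != ref) & joint).sum(axis=1) / joint.sum(axis=1),
                0.0,
            )
        rates = np.clip(rates * (1.0 - model.genotype_bias * dist), lo, hi)
    calls = matrix.calls.copy()
    rec_sample, rec_site, rec_call = [], [], []
    for i in range(n):
        observed = np.flatnonzero(calls[i] != MISSING)
        target = int(round(rates[i] * m))
        n_mask = max(0, len(observed) - target)
        if n_mask == 0:
            continue
        hide = rng.choice(observed, size=n_mask, replace=False)
        rec_sample.extend([i] * n_mask)
        rec_site.extend(hide.tolist())
        rec_call.extend(calls[i, hide].tolist())
        calls[i, hide] = MISSING
    record = pd.DataFrame(
        {
            "sample_idx": np.array(rec_sample, dtype=np.int64),
            "sample_id": [matrix.samples[i] for i in rec_sample],
            "site_idx": np.array(rec_site, dtype=np.int64),
            "call": np.array(rec_call, dtype=np.int8),
        }
    )
    return GenotypeMatrix(list(matrix.samples), matrix.sites.copy(), calls), record


def restore_mask(masked: GenotypeMatrix, record: pd.DataFrame) -> GenotypeMatrix:
    """Undo :func:`mask_genotypes` exactly."""
    calls = masked.calls.copy()
    calls[record["sample_idx"].to_numpy(), record["site_idx"].to_numpy()] = (
        record["call"].to_numpy()
    )
    return GenotypeMatrix(list(masked.samples), masked.sites.copy(), calls)


def inject_errors(matrix: GenotypeMatrix, error_rate: float, seed: int):
    """Perturb non-missing calls at the given rate.

    An erroneous call is replaced by one of the other two genotype states,
    chosen uniformly.  Returns the perturbed matrix and a record of altered
    cells (original and new call).
    """
    _check_range("error_rate", error_rate, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    hit = (rng.random(calls.shape) < error_rate) & (calls != MISSING)
    si, sj = np.nonzero(hit)
    original = calls[si, sj]
    # map each state to one of the other two, picked by a fair coin
    shift = rng.integers(1, 3, size=len(si)).astype(np.int8)
    new = (original + shift) % 3
    calls[si, sj] = new
    record = pd.DataFrame(
        {
            "sample_idx": si.astype(np.int64),
            "sample_id": [matrix.samples[i] for i in si],
            "site_idx": sj.astype(np.int64),
            "original": original.astype(np.int8),
            "new": new.astype(np.int8),
        }
    )
    return GenotypeMatrix(list(matrix.samples), matrix.sites.copy(), calls), record


# ---------------------------------------------------------------------------
# Haplotype-block constructions
# ---------------------------------------------------------------------------

def simulate_block_pair(
    n_sites: int,
    block_length: int,
    bp_per_site: int = 1000,
    seed: int = 0,
    chrom: str = "1",
):
    """Two inbred lines sharing haplotype blocks of a known length.

    The second line equals the first except at block boundaries placed every
    ``block_length`` sites, where two adjacent sites differ.  The double
    mismatch defeats the one-mismatch forgiveness of the haplotype-length
    sampler, so sampled shared-haplotype lengths concentrate at
    ``block_length - 2`` matching sites — a calibration target known by
    construction.
    """
    _check_count("n_sites", n_sites, minimum=4)
    _check_count("block_length", block_length, minimum=4)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, size=n_sites).astype(np.int8)
    other = base.copy()
    for k in range(block_length, n_sites, block_length):
        for j in (k - 1, k):
            if j < n_sites:
                other[j] = 1 - other[j]
    pos = (np.arange(n_sites) + 1) * bp_per_site
    sites = make_sites(
        [chrom] * n_sites, pos, ["A"] * n_sites, ["G"] * n_sites
    )
    calls = np.stack([2 * base, 2 * other]).astype(np.int8)
    return GenotypeMatrix(["blockA", "blockB"], sites, calls)


def simulate_mosaic_panel(
    n_lines: int = 30,
    n_founders: int = 8,
    n_sites: int = 1200,
    block_length: int = 40,
    bp_per_site: int = 1000,
    low_recomb_span: tuple[int, int] | None = None,
    low_recomb_factor: int = 8,
    seed: int = 0,
    chrom: str = "1",
):
    """Panel of inbreds built as founder-haplotype mosaics.

    Each line is a mosaic of ``n_founders`` random founder haplotypes with
    breakpoints every ``block_length`` sites; inside ``low_recomb_span``
    (site-index interval) blocks are ``low_recomb_factor`` times longer,
    emulating a recombination-suppressed (pericentromeric) region where
    haplotypes run longer and LD extends further.

    Returns the matrix and the (n_lines, n_sites) founder-of-origin array.
    """
    rng = np.random.default_rng(seed)
    founders = rng.integers(0, 2, size=(n_founders, n_sites)).astype(np.int8)
    boundaries = [0]
    while boundaries[-1] < n_sites:
        i = boundaries[-1]
        step = block_length
        if low_recomb_span is not None and low_recomb_span[0] <= i < low_recomb_span[1]:
            step = block_length * low_recomb_factor
        boundaries.append(min(n_sites, i + step))
    origin = np.empty((n_lines, n_sites), dtype=np.int32)
    calls = np.empty((n_lines, n_sites), dtype=np.int8)
    for i in range(n_lines):
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            f = int(rng.integers(n_founders))
            origin[i, a:b] = f
            calls[i, a:b] = 2 * founders[f, a:b]
    pos = (np.arange(n_sites) + 1) * bp_per_site
    sites = make_sites([chrom] * n_sites, pos, ["A"] * n_sites, ["G"] * n_sites)
    ids = [f"mosaic_L{i:03d}" for i in range(n_lines)]
    return GenotypeMatrix(ids, sites, calls), origin
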