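"""Instrument selection and strength.

Instruments for a trait are the variants passing a genome-wide significance
screen (default p < 1e-5), pruned for linkage disequilibrium by greedy
clumping (default r² <= 0.001 within 10,000 kb), with strength quantified by
the variance explained R² = 2·MAF·(1−MAF)·β² and the F-statistic
F = R²·(n−k−1) / (k·(1−R²)).  F > 10 is the conventional weak-instrument
screen.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateFrequencyError, SampleSizeError
from .io import LDTable, SNPAssociation, TraitRecord


@dataclass(frozen=True)
class InstrumentStrength:
    """Variance explained and F-statistic for one instrument (or one trait)."""

    variant_id: str
    maf: float
    r_squared: float
    f_statistic: float
    n: int
    k: int


def filter_by_pvalue(records: list[SNPAssociation], threshold: float = 1e-5) -> list[SNPAssociation]:
    """Keep records with p strictly below ``threshold``, order preserved."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    return [r for r in records if r.pvalue < threshold]


def _chrom_key(chromosome: str):
    # numeric chromosomes sort numerically, others (X, MT, ...) after
    try:
        return (0, int(chromosome), "")
    except ValueError:
        return (1, 0, chromosome)


def _genomic_key(rec: SNPAssociation):
    return (_chrom_key(rec.chromosome), rec.position, rec.variant_id)


def clump(records: list[SNPAssociation], ld: LDTable,
          r2_max: float = 0.001, window_kb: int = 10_000) -> list[SNPAssociation]:
    """Greedy LD clumping.

    Records are visited in order of ascending p-value (ties broken by
    chromosome, position, variant id for determinism); each retained index
    discards every not-yet-retained record on the same chromosome within
    ``window_kb`` kilobases whose r² with it exceeds ``r2_max``.  The
    retained set is returned in genomic order and is invariant to the input
    ordering.
    """
    if not 0.0 <= r2_max <= 1.0:
        raise ValueError(f"r2_max must be in [0,1], got {r2_max}")
    if window_kb <= 0:
        raise ValueError(f"window_kb must be > 0, got {window_kb}")
    window_bp = window_kb * 1000
    order = sorted(records, key=lambda r: (r.pvalue,) + _genomic_key(r))
    discarded: set[str] = set()
    kept: list[SNPAssociation] = []
    for i, rec in enumerate(order):
        if rec.variant_id in discarded:
            continue
        kept.append(rec)
        for other in order[i + 1:]:
            if other.variant_id in discarded:
                continue
            if other.chromosome != rec.chromosome:
                continue
            if abs(other.position - rec.position) > window_bp:
                continue
            if ld.lookup(rec.variant_id, other.variant_id) > r2_max:
                discarded.add(other.variant_id)
    return sorted(kept, key=_genomic_key)


def instrument_strength(record: SNPAssociation, k: int = 1) -> InstrumentStrength:
    """Variance explained and F-statistic for a single instrument.

    R² = 2·MAF·(1−MAF)·β² with MAF = min(eaf, 1−eaf);
    F = R²·(n−k−1) / (k·(1−R²)).  With ``k=1`` (the default) each variant is
    assessed alone; :func:`trait_strength` gives the per-trait aggregate.
    """
    if record.eaf in (0.0, 1.0):
        raise DegenerateFrequencyError(
            f"{record.variant_id}: eaf={record.eaf} leaves no allelic variance")
    if record.n <= k + 1:
        raise SampleSizeError(f"{record.variant_id}: n={record.n} <= k+1={k + 1}")
    maf = record.maf
    r_squared = 2.0 * maf * (1.0 - maf) * record.beta ** 2
    f_statistic = r_squared * (record.n - k - 1) / (k * (1.0 - r_squared))
    return InstrumentStrength(
        variant_id=record.variant_id, maf=maf, r_squared=r_squared,
        f_statistic=f_statistic, n=record.n, k=k)


def trait_strength(records: list[SNPAssociation]) -> InstrumentStrength:
    """Aggregate instrument strength for one trait.

    Sums per-variant R² over the k retained instruments and evaluates the
    F formula with that total and k; n is the smallest per-variant sample
    size (conservative when cohorts differ by SNP).
    """
    if not records:
        raise SampleSizeError("no instruments to aggregate")
    k = len(records)
    total_r2 = sum(instrument_strength(r, k=1).r_squared for r in records)
    n = min(r.n for r in records)
    if n <= k + 1:
        raise SampleSizeError(f"n={n} <= k+1={k + 1}")
    f_statistic = total_r2 * (n - k - 1) / (k * (1.0 - total_r2))
    return InstrumentStrength(
        variant_id="<trait>", maf=float("nan"), r_squared=total_r2,
        f_statistic=f_statistic, n=n, k=k)


def weak_instrument_filter(strengths: list[InstrumentStrength],
                           f_min: float = 10.0) -> list[InstrumentStrength]:
    """Keep instruments with F strictly above ``f_min``."""
    if f_min < 0:
        raise ValueError(f"f_min must be >= 0, got {f_min}")
    return [s for s in strengths if s.f_statistic > f_min]


def filter_unnamed_taxa(catalog: list[TraitRecord]) -> list[TraitRecord]:
    """Drop catalog entries whose taxon label has no specific name."""
    return [t for t in catalog if t.is_named]
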