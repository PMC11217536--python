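"""Reading and writing GWAS summary-statistics tables, LD tables and trait catalogs.

All tables are tab-separated UTF-8 text with a header row; "." or an empty
cell denotes a missing value.  One canonical column schema is used
internally (``CANONICAL_COLUMNS``); other dialects (MiBioGen, FinnGen
exports) are adapted at the boundary through a user-supplied column map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Canonical summary-statistics column names, in writing order.
CANONICAL_COLUMNS = (
    "SNP", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

VALID_ALLELES = frozenset("ACGT")

TAXONOMIC_LEVELS = ("phylum", "class", "order", "family", "genus")

#: Substrings (case-insensitive) marking a taxon label with no specific name.
UNNAMED_LABEL_PATTERNS = ("unknown", "unclassified", "incertae")

#: Smallest positive p-value substituted for an input p of exactly 0.
MIN_PVALUE = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class SNPAssociation:
    """One variant's summary statistics for one trait.

    ``beta`` is a log-odds effect for binary outcome traits and a per-allele
    abundance effect for exposures; ``eaf`` is the effect-allele frequency.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.variant_id}: effect and other allele are both {self.effect_allele}")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: non-ACGT allele "
                f"{self.effect_allele}/{self.other_allele}")
        if not self.se > 0:
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.variant_id}: eaf outside [0,1]: {self.eaf}")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.variant_id}: pvalue outside (0,1]: {self.pvalue}")
        if self.position < 1:
            raise ValidationError(f"{self.variant_id}: position must be >= 1")
        if self.n < 1:
            raise ValidationError(f"{self.variant_id}: n must be a positive integer")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class TraitRecord:
    """A catalog entry for one exposure trait (a bacterial taxon)."""

    trait_id: str
    trait_name: str
    taxonomic_level: str
    is_named: bool

    def __post_init__(self):
        if self.taxonomic_level not in TAXONOMIC_LEVELS:
            raise ValidationError(
                f"{self.trait_id}: taxonomic level {self.taxonomic_level!r} "
                f"not one of {TAXONOMIC_LEVELS}")


def is_unnamed_label(name: str) -> bool:
    """True when a taxon label denotes an unknown/unspecified group."""
    low = name.lower()
    return any(pat in low for pat in UNNAMED_LABEL_PATTERNS)


class LDTable:
    """Pairwise linkage-disequilibrium r² with symmetric lookup.

    An absent pair has r² = 0; a variant with itself always has r² = 1.
    """

    def __init__(self):
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r_squared: float) -> None:
        if not 0.0 <= r_squared <= 1.0:
            raise ValidationError(f"r_squared outside [0,1]: {r_squared}")
        if a == b:
            return  # self-pairs are fixed at 1 by construction
        self._r2[self._key(a, b)] = r_squared

    def lookup(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, na_values=["", "."], keep_default_na=False,
        encoding="utf-8",
    )


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValidationError(f"column {col!r}: unparsable numeric {raw[bad.idxmax()]!r}", row=row)
    missing = raw.isna()
    if missing.any():
        row = int(missing.idxmax()) + 1
        raise ValidationError(f"column {col!r}: missing value", row=row)
    return out


def read_summary_stats(path, column_map: dict[str, str] | None = None) -> list[SNPAssociation]:
    """Read a GWAS summary-statistics TSV into validated records.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from canonical column names (``CANONICAL_COLUMNS``)
        to the names used in the file, for non-canonical dialects.

    Row order is preserved.  Rows whose alleles are not single A/C/G/T bases
    (indels, multi-allelic codes) are dropped with a single warning carrying
    the count; every other malformed value raises :class:`ValidationError`
    with its 1-based data-row number.  Input p-values of exactly 0 are floored
    to the smallest positive float with a warning.
    """
    df = _read_tsv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return []

    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.strip().str.upper()

    # indels / non-SNV alleles: drop with a counted warning (harmonization
    # rules are defined for single-base variants only)
    ok_allele = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES)
    n_dropped = int((~ok_allele).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} row(s) with non-ACGT alleles", stacklevel=2)

    eaf = _numeric(df, "eaf")
    beta = _numeric(df, "beta")
    se = _numeric(df, "se")
    pval = _numeric(df, "pval")
    pos = _numeric(df, "pos")
    n = _numeric(df, "n")

    def _bad_row(mask, message):
        if mask.any():
            raise ValidationError(message, row=int(mask.idxmax()) + 1)

    _bad_row(se <= 0, "se must be > 0")
    _bad_row((eaf < 0) | (eaf > 1), "eaf outside [0,1]")
    _bad_row((pval < 0) | (pval > 1), "pval outside [0,1]")
    _bad_row(pos < 1, "position must be >= 1")
    _bad_row(ok_allele & (df["effect_allele"] == df["other_allele"]),
             "effect and other allele identical")

    zero_p = pval == 0
    if zero_p.any():
        warnings.warn(
            f"floored {int(zero_p.sum())} zero p-value(s) to {MIN_PVALUE:g}",
            stacklevel=2)
        pval = pval.mask(zero_p, MIN_PVALUE)

    records = []
    for i in df.index:
        if not ok_allele[i]:
            continue
        records.append(SNPAssociation(
            variant_id=str(df.at[i, "SNP"]),
            chromosome=str(df.at[i, "chr"]),
            position=int(pos[i]),
            effect_allele=df.at[i, "effect_allele"],
            other_allele=df.at[i, "other_allele"],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pval[i]),
            n=int(n[i]),
        ))
    return records


def write_summary_stats(records: list[SNPAssociation], path) -> None:
    """Write records as a canonical-schema TSV (round-trips through the reader)."""
    rows = [
        (r.variant_id, r.chromosome, r.position, r.effect_allele, r.other_allele,
         r.eaf, r.beta, r.se, r.pvalue, r.n)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_table(path) -> LDTable:
    """Read a 3-column (variant_id_1, variant_id_2, r_squared) TSV.

    Duplicate pairs collapse to the last value; self-pairs are ignored
    (the lookup for a variant with itself is 1 by construction).
    """
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise SchemaError("LD table needs 3 columns: variant_id_1, variant_id_2, r_squared")
    table = LDTable()
    if len(df) == 0:
        return table
    a_col, b_col, r_col = df.columns[:3]
    r2 = _numeric(df, r_col)
    for i in df.index:
        val = float(r2[i])
        if not 0.0 <= val <= 1.0:
            raise ValidationError(f"r_squared outside [0,1]: {val}", row=int(i) + 1)
        table.set(str(df.at[i, a_col]), str(df.at[i, b_col]), val)
    return table


def write_ld_table(table: LDTable, path) -> None:
    rows = sorted((a, b, r) for (a, b), r in table._r2.items())
    pd.DataFrame(rows, columns=["variant_id_1", "variant_id_2", "r_squared"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_trait_catalog(path) -> list[TraitRecord]:
    """Read a trait catalog TSV (trait_id, trait_name, level).

    ``is_named`` is computed on read from the label: names containing
    "unknown", "unclassified" or "incertae" (case-insensitive) are treated
    as unnamed groups.
    """
    df = _read_tsv(path)
    for col in ("trait_id", "trait_name", "level"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    records = []
    for i in df.index:
        name = str(df.at[i, "trait_name"])
        records.append(TraitRecord(
            trait_id=str(df.at[i, "trait_id"]),
            trait_name=name,
            taxonomic_level=str(df.at[i, "level"]).lower(),
            is_named=not is_unnamed_label(name),
        ))
    return records


def write_trait_catalog(records: list[TraitRecord], path) -> None:
    df = pd.DataFrame(
        [(t.trait_id, t.trait_name, t.taxonomic_level) for t in records],
        columns=["trait_id", "trait_name", "level"])
    df.to_csv(path, sep="\t", index=False)


RESULTS_COLUMNS = (
    "exposure", "method", "n_snp", "beta", "se", "or", "ci_low", "ci_high", "pvalue",
)


def write_results_table(estimates, path) -> None:
    """Serialize causal estimates as the results TSV.

    ``estimates`` is an iterable of :class:`~mrscreen.estimators.MREstimate`.
    Odds ratios and CI bounds are written with 6 decimals (at least the two
    the forest table displays); betas/SEs/p-values with 6 significant digits.
    """
    lines = ["\t".join(RESULTS_COLUMNS)]
    for est in estimates:
        lines.append("\t".join([
            est.exposure,
            est.method,
            str(est.n_snp),
            f"{est.beta:.6g}",
            f"{est.se:.6g}",
            f"{est.or_value:.6f}",
            f"{est.ci_low:.6f}",
            f"{est.ci_high:.6f}",
            f"{est.pvalue:.6g}",
        ]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")
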