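"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs each variant's exposure and outcome effects expressed
for the same effect allele.  Matching is by variant id; the exposure
orientation is never altered.  Palindromic variants (A/T or C/G), whose
strand is ambiguous across cohorts, are dropped unconditionally.  For
non-palindromic allele mismatches a strand flip (allele complementation) is
attempted before declaring the pair irreconcilable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .io import SNPAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# per-SNP log actions
KEPT = "kept"
SIGN_FLIPPED = "sign-flipped"
KEPT_STRAND_FLIP = "kept-strand-flip"
SIGN_FLIPPED_STRAND_FLIP = "sign-flipped-strand-flip"
DROPPED_PALINDROMIC = "dropped-palindromic"
DROPPED_UNMATCHED = "dropped-unmatched"
DROPPED_ALLELE_MISMATCH = "dropped-allele-mismatch"

ACTIONS = (KEPT, SIGN_FLIPPED, KEPT_STRAND_FLIP, SIGN_FLIPPED_STRAND_FLIP,
           DROPPED_PALINDROMIC, DROPPED_UNMATCHED, DROPPED_ALLELE_MISMATCH)

KEEP_ACTIONS = frozenset({KEPT, SIGN_FLIPPED, KEPT_STRAND_FLIP, SIGN_FLIPPED_STRAND_FLIP})


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True for A/T and C/G pairs (self-complementary, strand-ambiguous)."""
    return COMPLEMENT.get(allele_a) == allele_b


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effects after allele reconciliation.

    The four numeric arrays share length ``n_snp``; ``log`` records one
    (variant_id, action) entry for every input exposure SNP.
    """

    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        lengths = {len(self.variant_ids), self.beta_exposure.size,
                   self.se_exposure.size, self.beta_outcome.size, self.se_outcome.size}
        if len(lengths) != 1:
            raise InputError(f"harmonized arrays have mismatched lengths: {lengths}")
        if self.n_snp and (np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0)):
            raise InputError("standard errors must be > 0")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def subset(self, indices) -> "HarmonizedSet":
        """A new set restricted to the given positional indices (order kept)."""
        idx = np.asarray(sorted(indices), dtype=int)
        return HarmonizedSet(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            log=[(self.variant_ids[i], KEPT) for i in idx],
        )


def _check_unique(records: list[SNPAssociation], label: str) -> None:
    ids = [r.variant_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({v for v, c in Counter(ids).items() if c > 1})
        raise InputError(f"duplicate variant_id in {label}: {', '.join(dupes[:5])}")


def harmonize_pair(exposure: list[SNPAssociation], outcome: list[SNPAssociation],
                   exposure_name: str = "exposure",
                   outcome_name: str = "outcome") -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Per exposure SNP: a same-orientation outcome record is kept as-is;
    swapped alleles negate the outcome beta; a palindromic allele pair is
    dropped; an outcome record reconcilable only after complementing its
    alleles is rescued and logged as a strand flip; anything else is dropped
    as an allele mismatch.  SNPs absent from the outcome are dropped as
    unmatched.
    """
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    out_by_id = {r.variant_id: r for r in outcome}

    ids, bx, sx, by, sy, log = [], [], [], [], [], []
    for exp in exposure:
        action = _classify(exp, out_by_id.get(exp.variant_id))
        log.append((exp.variant_id, action))
        if action not in KEEP_ACTIONS:
            continue
        out = out_by_id[exp.variant_id]
        sign = -1.0 if action in (SIGN_FLIPPED, SIGN_FLIPPED_STRAND_FLIP) else 1.0
        ids.append(exp.variant_id)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(sign * out.beta)
        sy.append(out.se)

    return HarmonizedSet(
        variant_ids=ids,
        beta_exposure=np.array(bx, dtype=float),
        se_exposure=np.array(sx, dtype=float),
        beta_outcome=np.array(by, dtype=float),
        se_outcome=np.array(sy, dtype=float),
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        log=log,
    )


def _classify(exp: SNPAssociation, out: SNPAssociation | None) -> str:
    if out is None:
        return DROPPED_UNMATCHED
    ea, oa = exp.effect_allele, exp.other_allele
    if is_palindromic(ea, oa):
        return DROPPED_PALINDROMIC
    pair = (out.effect_allele, out.other_allele)
    if pair == (ea, oa):
        return KEPT
    if pair == (oa, ea):
        return SIGN_FLIPPED
    flipped = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if flipped == (ea, oa):
        return KEPT_STRAND_FLIP
    if flipped == (oa, ea):
        return SIGN_FLIPPED_STRAND_FLIP
    return DROPPED_ALLELE_MISMATCH


def harmonization_report(hset: HarmonizedSet) -> dict[str, int]:
    """Counts of each per-SNP action; values sum to the input SNP count."""
    counts = Counter(action for _, action in hset.log)
    report = {action: counts.get(action, 0) for action in ACTIONS}
    report["total"] = len(hset.log)
    return report
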