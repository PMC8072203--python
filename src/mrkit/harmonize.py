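"""Allele harmonization between exposure and outcome summary statistics.

Two GWAS report each variant's effect relative to an arbitrary effect allele,
possibly on opposite DNA strands. Before any instrumental-variable estimator
can combine them, every SNP must be oriented so that the exposure and outcome
betas refer to the same allele:

* identical allele pairs — keep the outcome effect as-is;
* swapped alleles (effect/other exchanged) — negate the outcome beta and
  complement its allele frequency;
* complementary-strand pairs (e.g. A/G reported as T/C) — base-complement,
  then resolve as above;
* palindromic SNPs (A/T or C/G) — the strand cannot be resolved from alleles
  alone. Under ``assume-forward`` both studies are taken to be forward-strand
  coded and the alleles matched literally. Under ``drop-noninferable`` the
  SNP is dropped when its minor-allele frequency is too close to 0.5 for
  frequency-based inference (MAF above ``maf_noninfer``) and otherwise
  oriented by whether the two studies' frequencies fall on the same side
  of 0.5.

When the outcome study reports no allele frequencies, the exposure frequency
stands in for palindromic inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import InstrumentSet, VariantAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTION_KEPT = "kept"
ACTION_SIGN_FLIPPED = "sign-flipped"
ACTION_STRAND_FLIPPED = "strand-flipped"
ACTION_STRAND_SIGN_FLIPPED = "strand-and-sign-flipped"
ACTION_DROPPED_PALINDROMIC = "dropped-palindromic"
ACTION_DROPPED_UNMATCHED = "dropped-unmatched"
ACTION_DROPPED_IRRECONCILABLE = "dropped-irreconcilable"


def is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass(slots=True)
class HarmonizedDataset:
    """Instruments aligned across exposure(s) and outcome.

    Arrays share row order: row j is one SNP. ``beta_exposure``/``se_exposure``
    are J x K (K = 1 for univariable use); outcome vectors are length J.
    ``actions`` records, per candidate SNP (including dropped ones), what
    harmonization did to it.
    """

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_ids: list[str]
    actions: dict[str, str] = field(default_factory=dict)
    eaf_exposure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_exposure = np.atleast_2d(np.asarray(self.beta_exposure, float))
        self.se_exposure = np.atleast_2d(np.asarray(self.se_exposure, float))
        if self.beta_exposure.shape[0] == 1 and len(self.snp_ids) > 1:
            self.beta_exposure = self.beta_exposure.T
            self.se_exposure = self.se_exposure.T
        self.beta_outcome = np.asarray(self.beta_outcome, float)
        self.se_outcome = np.asarray(self.se_outcome, float)
        j = len(self.snp_ids)
        if not (
            self.beta_exposure.shape == self.se_exposure.shape == (j, len(self.exposure_ids))
            and self.beta_outcome.shape == self.se_outcome.shape == (j,)
        ):
            raise ValueError("harmonized arrays have inconsistent shapes")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    def univariable(self, k: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (bx, sx, by, sy) vectors for exposure column ``k``."""
        return (
            self.beta_exposure[:, k],
            self.se_exposure[:, k],
            self.beta_outcome,
            self.se_outcome,
        )

    def subset(self, keep: list[str] | np.ndarray) -> "HarmonizedDataset":
        """Row subset by snp_id list or boolean mask, preserving order."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array([i for i, s in enumerate(self.snp_ids) if s in wanted], int)
        return HarmonizedDataset(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            exposure_ids=list(self.exposure_ids),
            actions=dict(self.actions),
            eaf_exposure=None if self.eaf_exposure is None else self.eaf_exposure[idx],
        )

    def drop_snps(self, snp_ids: list[str]) -> "HarmonizedDataset":
        drop = set(snp_ids)
        mask = np.array([s not in drop for s in self.snp_ids])
        return self.subset(mask)

    def to_frame(self) -> pd.DataFrame:
        cols: dict = {"SNP": self.snp_ids}
        for k, eid in enumerate(self.exposure_ids):
            cols[f"beta_{eid}"] = self.beta_exposure[:, k]
            cols[f"se_{eid}"] = self.se_exposure[:, k]
        cols["beta_outcome"] = self.beta_outcome
        cols["se_outcome"] = self.se_outcome
        cols["action"] = [self.actions.get(s, ACTION_KEPT) for s in self.snp_ids]
        return pd.DataFrame(cols)

    def report(self) -> dict:
        from collections import Counter
        return {
            "n_candidates": len(self.actions) or self.n_snps,
            "n_harmonized": self.n_snps,
            "actions": dict(Counter(self.actions.values())),
        }


def _orient_outcome(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindrome_mode: str,
    maf_noninfer: float,
) -> tuple[float, float | None, str] | tuple[None, None, str]:
    """Resolve one outcome record against the exposure orientation.

    Returns (oriented beta_outcome, oriented eaf_outcome, action) or
    (None, None, drop-action).
    """
    ea_x, oa_x = exp.effect_allele, exp.other_allele
    ea_y, oa_y = out.effect_allele, out.other_allele
    eaf_y = out.eaf

    if is_palindromic(ea_x, oa_x):
        # literal match is all that alleles can offer; {ea, oa} must agree
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return None, None, ACTION_DROPPED_IRRECONCILABLE
        swapped = ea_y != ea_x
        beta = -out.beta if swapped else out.beta
        eaf = None if eaf_y is None else (1.0 - eaf_y if swapped else eaf_y)
        if palindrome_mode == "assume-forward":
            return beta, eaf, ACTION_SIGN_FLIPPED if swapped else ACTION_KEPT
        # drop-noninferable: frequency-based strand inference
        eaf_x = exp.eaf
        freq = eaf if eaf is not None else eaf_x
        if freq is None or eaf_x is None:
            return None, None, ACTION_DROPPED_PALINDROMIC
        if min(eaf_x, 1 - eaf_x) > maf_noninfer or min(freq, 1 - freq) > maf_noninfer:
            return None, None, ACTION_DROPPED_PALINDROMIC
        same_side = (eaf_x - 0.5) * (freq - 0.5) >= 0
        if same_side:
            return beta, eaf, ACTION_SIGN_FLIPPED if swapped else ACTION_KEPT
        return -beta, None if eaf is None else 1.0 - eaf, ACTION_STRAND_SIGN_FLIPPED

    if {ea_y, oa_y} == {ea_x, oa_x}:
        if ea_y == ea_x:
            return out.beta, eaf_y, ACTION_KEPT
        return -out.beta, None if eaf_y is None else 1.0 - eaf_y, ACTION_SIGN_FLIPPED

    comp = {_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]}
    if comp == {ea_x, oa_x}:
        if _COMPLEMENT[ea_y] == ea_x:
            return out.beta, eaf_y, ACTION_STRAND_FLIPPED
        return (
            -out.beta,
            None if eaf_y is None else 1.0 - eaf_y,
            ACTION_STRAND_SIGN_FLIPPED,
        )

    return None, None, ACTION_DROPPED_IRRECONCILABLE


def _dedupe_by_p(assocs: list[VariantAssociation]) -> dict[str, VariantAssociation]:
    """Index by snp_id, keeping the smallest-p row among duplicates."""
    table: dict[str, VariantAssociation] = {}
    dups = 0
    for a in assocs:
        prev = table.get(a.snp_id)
        if prev is None or a.pvalue < prev.pvalue:
            if prev is not None:
                dups += 1
            table[a.snp_id] = a
        elif prev is not None:
            dups += 1
    if dups:
        logger.warning("%d duplicated snp_id row(s) resolved by smallest p", dups)
    return table


def harmonize_pair(
    exposure: InstrumentSet,
    outcome: list[VariantAssociation],
    palindrome_mode: str = "assume-forward",
    maf_noninfer: float = 0.40,
) -> HarmonizedDataset:
    """Harmonize one exposure's instruments against outcome summary stats.

    Instruments absent from the outcome table are dropped with a logged
    count; irreconcilable allele pairs and non-inferable palindromic SNPs
    (under ``drop-noninferable``) are dropped with per-SNP action tags.
    """
    if palindrome_mode not in ("assume-forward", "drop-noninferable"):
        raise ValueError(f"unknown palindrome_mode {palindrome_mode!r}")
    out_by_id = _dedupe_by_p(outcome)
    actions: dict[str, str] = {}
    rows: list[tuple[str, float, float, float, float, float | None]] = []
    for v in exposure.variants:
        out = out_by_id.get(v.snp_id)
        if out is None:
            actions[v.snp_id] = ACTION_DROPPED_UNMATCHED
            continue
        beta_y, _, action = _orient_outcome(v, out, palindrome_mode, maf_noninfer)
        actions[v.snp_id] = action
        if beta_y is None:
            continue
        rows.append((v.snp_id, v.beta, v.se, beta_y, out.se, v.eaf))
    n_unmatched = sum(1 for a in actions.values() if a == ACTION_DROPPED_UNMATCHED)
    if n_unmatched:
        logger.info(
            "%s: %d instrument(s) unmatched in outcome and dropped",
            exposure.exposure_id, n_unmatched,
        )
    if not rows:
        raise ValueError(f"{exposure.exposure_id}: no instruments survived harmonization")
    snp_ids = [r[0] for r in rows]
    eafs = [r[5] for r in rows]
    return HarmonizedDataset(
        snp_ids=snp_ids,
        beta_exposure=np.array([[r[1]] for r in rows]),
        se_exposure=np.array([[r[2]] for r in rows]),
        beta_outcome=np.array([r[3] for r in rows]),
        se_outcome=np.array([r[4] for r in rows]),
        exposure_ids=[exposure.exposure_id],
        actions=actions,
        eaf_exposure=None
        if any(e is None for e in eafs)
        else np.array(eafs, float),
    )


def harmonize_multi(
    exposures: list[InstrumentSet],
    outcome: list[VariantAssociation],
    proxy_table: dict[str, str] | None = None,
    palindrome_mode: str = "assume-forward",
    maf_noninfer: float = 0.40,
) -> HarmonizedDataset:
    """Build the complete J x K matrix for multivariable MR.

    The candidate SNP set is the union of all exposures' instruments. Every
    exposure must report an association for every retained SNP — directly or
    through ``proxy_table`` (a ``{snp_id: substitute_snp_id}`` map); SNPs
    unresolvable in any exposure, or in the outcome, are dropped. The result
    has no missing cells.
    """
    if len(exposures) < 2:
        raise ValueError("harmonize_multi needs at least 2 exposures; use harmonize_pair")
    proxy_table = proxy_table or {}
    k = len(exposures)
    exp_tables = [_dedupe_by_p(e.variants) for e in exposures]
    out_by_id = _dedupe_by_p(outcome)

    candidate_ids: list[str] = []
    seen: set[str] = set()
    for e in exposures:
        for v in e.variants:
            if v.snp_id not in seen:
                seen.add(v.snp_id)
                candidate_ids.append(v.snp_id)

    actions: dict[str, str] = {}
    snp_ids: list[str] = []
    bx_rows, sx_rows, by_rows, sy_rows = [], [], [], []
    for snp in candidate_ids:
        # reference orientation: first exposure that reports the SNP directly
        records: list[VariantAssociation | None] = []
        ok = True
        for t in exp_tables:
            rec = t.get(snp) or (t.get(proxy_table[snp]) if snp in proxy_table else None)
            if rec is None:
                ok = False
                break
            records.append(rec)
        if not ok:
            actions[snp] = ACTION_DROPPED_UNMATCHED
            continue
        out = out_by_id.get(snp) or (
            out_by_id.get(proxy_table[snp]) if snp in proxy_table else None
        )
        if out is None:
            actions[snp] = ACTION_DROPPED_UNMATCHED
            continue
        ref = records[0]
        bx = [ref.beta]
        sx = [ref.se]
        row_ok = True
        for rec in records[1:]:
            b, _, act = _orient_outcome(ref, rec, palindrome_mode, maf_noninfer)
            if b is None:
                actions[snp] = act
                row_ok = False
                break
            bx.append(b)
            sx.append(rec.se)
        if not row_ok:
            continue
        beta_y, _, act = _orient_outcome(ref, out, palindrome_mode, maf_noninfer)
        actions[snp] = act
        if beta_y is None:
            continue
        snp_ids.append(snp)
        bx_rows.append(bx)
        sx_rows.append(sx)
        by_rows.append(beta_y)
        sy_rows.append(out.se)

    if len(snp_ids) < k + 2:
        raise ValueError(
            f"only {len(snp_ids)} SNP(s) survive multi-exposure harmonization; "
            f"at least {k + 2} needed for {k} exposures"
        )
    return HarmonizedDataset(
        snp_ids=snp_ids,
        beta_exposure=np.array(bx_rows),
        se_exposure=np.array(sx_rows),
        beta_outcome=np.array(by_rows),
        se_outcome=np.array(sy_rows),
        exposure_ids=[e.exposure_id for e in exposures],
        actions=actions,
    )
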