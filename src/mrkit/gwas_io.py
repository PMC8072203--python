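"""Reading, writing and instrument-selection filtering of GWAS summary statistics.

Summary statistics are exchanged as tab- (or whitespace-) delimited tables with
one row per variant. The canonical column names are::

    SNP  CHR  BP  EA  OA  EAF  BETA  SE  P  N

where EA is the effect allele, BETA the per-allele effect (SD units for a
quantitative trait, log-odds for a binary one), and EAF the effect-allele
frequency. Files with other headers are mapped via a ``dialect`` dictionary
``{file_column: canonical_name}``.

Instrument selection applies the standard filters used to pick genetic
instruments for Mendelian randomization: genome-wide significance, a per-SNP
F-statistic floor against weak instruments, a minor-allele-frequency floor,
exclusion of a genomic region (e.g. the ApoE locus, which is pleiotropic for
dementia-adjacent traits), exclusion of variants genome-wide significant for
the outcome, and greedy LD clumping against a user-supplied r-squared table.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]

#: Named presets for the ApoE-region exclusion (chrom, start, end; 1-based,
#: closed interval). ``apoe-as-printed`` is the 4.5 Mb interval some reports
#: quote; ``apoe-grch37`` covers the conventional APOE locus near 45.4 Mb on
#: GRCh37. Which to use is a config choice; both are shipped so neither is
#: silently guessed.
REGION_PRESETS: dict[str, tuple[str, int, int]] = {
    "apoe-as-printed": ("19", 4_500_000, 4_580_000),
    "apoe-grch37": ("19", 45_380_000, 45_460_000),
}


class ConfigError(ValueError):
    """A configuration problem (missing column, bad dialect, bad threshold)."""


class ParseError(ValueError):
    """Rows of an input file failed numeric coercion; lines are listed."""

    def __init__(self, path: str, bad_lines: list[int]):
        self.bad_lines = bad_lines
        super().__init__(
            f"{path}: unparseable numeric value(s) on line(s) {bad_lines} "
            "(1-based, counting the header as line 1)"
        )


@dataclass(slots=True)
class VariantAssociation:
    """One SNP's summary association for one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def f_statistic(self) -> float:
        return per_snp_f_statistic(self.beta, self.se)


@dataclass(slots=True)
class InstrumentSet:
    """Selected instruments for one exposure plus an audit of filters run."""

    exposure_id: str
    variants: list[VariantAssociation]
    filters_applied: set[str] = field(default_factory=set)
    excluded: bool = False
    #: per-filter counts of variants removed, for the audit sidecar
    removed_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [v.snp_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.exposure_id}: duplicate snp_ids in instrument set")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def audit(self) -> dict:
        return {
            "exposure_id": self.exposure_id,
            "n_instruments": len(self.variants),
            "filters_applied": sorted(self.filters_applied),
            "removed_counts": dict(self.removed_counts),
            "excluded": self.excluded,
        }


def per_snp_f_statistic(beta: float, se: float) -> float:
    """Approximate single-SNP F-statistic from summary data, ``(beta/se)**2``.

    This is the standard approximation when the source GWAS reports no per-SNP
    variance explained; it equals the square of the Wald z-statistic and is
    close to ``(n-2) R^2 / (1-R^2)`` for a single regressor.
    """
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def read_summary_stats(
    path: str, dialect: dict[str, str] | None = None
) -> list[VariantAssociation]:
    """Read a summary-statistics table into :class:`VariantAssociation` records.

    Parameters
    ----------
    path:
        Tab- or whitespace-delimited file with a header row.
    dialect:
        Optional ``{file_column: canonical_name}`` mapping for files whose
        headers differ from the canonical ones.

    Raises
    ------
    ConfigError
        If a mandatory column is absent after applying the dialect.
    ParseError
        If any row has an unparseable numeric value; all offending line
        numbers are listed.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if dialect:
        unknown = set(dialect) - set(df.columns)
        if unknown:
            raise ConfigError(f"dialect refers to absent column(s): {sorted(unknown)}")
        df = df.rename(columns=dialect)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"mandatory column '{col}' missing from {path}")

    def _coerce(v):
        # python float() is correctly rounded, unlike the fast pandas parser
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return float("nan")
        try:
            return float(v)
        except ValueError:
            return float("nan")

    numeric_cols = [c for c in ("BP", "EAF", "BETA", "SE", "P", "N") if c in df.columns]
    coerced = {c: df[c].map(_coerce) for c in numeric_cols}
    bad_lines: set[int] = set()
    for c in ("BETA", "SE", "P"):
        mask = coerced[c].isna() & df[c].notna() | df[c].isna()
        # +2: header is line 1, data starts at line 2
        bad_lines.update(int(i) + 2 for i in df.index[mask])
    if bad_lines:
        raise ParseError(path, sorted(bad_lines))

    records: list[VariantAssociation] = []
    for i in range(len(df)):
        records.append(
            VariantAssociation(
                snp_id=str(df["SNP"].iloc[i]),
                chrom=str(df["CHR"].iloc[i]) if "CHR" in df.columns and pd.notna(df["CHR"].iloc[i]) else None,
                pos=int(coerced["BP"].iloc[i]) if "BP" in df.columns and pd.notna(coerced["BP"].iloc[i]) else None,
                effect_allele=str(df["EA"].iloc[i]),
                other_allele=str(df["OA"].iloc[i]),
                eaf=float(coerced["EAF"].iloc[i]) if "EAF" in df.columns and pd.notna(coerced["EAF"].iloc[i]) else None,
                beta=float(coerced["BETA"].iloc[i]),
                se=float(coerced["SE"].iloc[i]),
                pvalue=float(coerced["P"].iloc[i]),
                n=float(coerced["N"].iloc[i]) if "N" in df.columns and pd.notna(coerced["N"].iloc[i]) else None,
            )
        )
    return records


def to_frame(assocs: list[VariantAssociation]) -> pd.DataFrame:
    """Render records as a DataFrame with the canonical columns."""
    return pd.DataFrame(
        {
            "SNP": [a.snp_id for a in assocs],
            "CHR": [a.chrom for a in assocs],
            "BP": [a.pos for a in assocs],
            "EA": [a.effect_allele for a in assocs],
            "OA": [a.other_allele for a in assocs],
            "EAF": [a.eaf for a in assocs],
            "BETA": [a.beta for a in assocs],
            "SE": [a.se for a in assocs],
            "P": [a.pvalue for a in assocs],
            "N": [a.n for a in assocs],
        }
    )


def write_summary_stats(assocs: list[VariantAssociation], path: str) -> None:
    to_frame(assocs).to_csv(path, sep="\t", index=False)


def write_filter_audit(instruments: InstrumentSet, path: str) -> None:
    """Write the JSON filter-audit sidecar (counts removed per filter)."""
    with open(path, "w") as fh:
        json.dump(instruments.audit(), fh, indent=2)


def select_instruments(
    assocs: list[VariantAssociation],
    exposure_id: str = "exposure",
    p_max: float = 5e-8,
    f_min: float = 10.0,
    maf_min: float = 0.01,
    min_snps: int = 3,
) -> InstrumentSet:
    """Apply the genome-wide-significance, F-statistic and MAF filters.

    Variants are retained when ``pvalue < p_max``, ``(beta/se)^2 >= f_min``
    and ``min(eaf, 1-eaf) >= maf_min`` (the MAF filter passes variants with
    missing frequency). If fewer than ``min_snps`` survive, the exposure is
    flagged excluded — mirroring the removal of exposures too weakly
    instrumented for a powered analysis — but the survivors are still
    returned for the audit trail.
    """
    if min(p_max, f_min, maf_min) < 0 or p_max <= 0:
        raise ConfigError("selection thresholds must be positive")
    counts = {"gws": 0, "f10": 0, "maf": 0}
    kept: list[VariantAssociation] = []
    for v in assocs:
        if not v.pvalue < p_max:
            counts["gws"] += 1
        elif not v.f_statistic >= f_min:
            counts["f10"] += 1
        elif v.maf is not None and v.maf < maf_min:
            counts["maf"] += 1
        else:
            kept.append(v)
    excluded = len(kept) < min_snps
    if excluded:
        logger.warning(
            "%s: only %d instrument(s) survive selection (< %d); flagged excluded",
            exposure_id, len(kept), min_snps,
        )
    return InstrumentSet(
        exposure_id=exposure_id,
        variants=kept,
        filters_applied={"gws", "f10", "maf"},
        excluded=excluded,
        removed_counts=counts,
    )


def exclude_region(
    instruments: InstrumentSet, chrom: str, start: int, end: int
) -> InstrumentSet:
    """Drop instruments inside ``chrom:start-end`` (1-based, closed interval)."""
    if start > end:
        raise ConfigError(f"region start {start} > end {end}")
    chrom = str(chrom).lstrip("chr") if str(chrom).startswith("chr") else str(chrom)

    def inside(v: VariantAssociation) -> bool:
        if v.chrom is None or v.pos is None:
            return False
        vc = v.chrom[3:] if v.chrom.startswith("chr") else v.chrom
        return vc == chrom and start <= v.pos <= end

    kept = [v for v in instruments.variants if not inside(v)]
    removed = len(instruments.variants) - len(kept)
    counts = dict(instruments.removed_counts)
    counts["region_excl"] = counts.get("region_excl", 0) + removed
    return replace(
        instruments,
        variants=kept,
        filters_applied=instruments.filters_applied | {"region_excl"},
        removed_counts=counts,
    )


def exclude_outcome_associated(
    instruments: InstrumentSet,
    outcome_assocs: list[VariantAssociation],
    p_max: float = 5e-8,
) -> InstrumentSet:
    """Drop instruments genome-wide significant for the outcome.

    An instrument strongly associated with the outcome in its own right risks
    violating the exchangeability assumption (association via confounders or
    a direct path), so such SNPs are removed before estimation.
    """
    hot = {a.snp_id for a in outcome_assocs if a.pvalue < p_max}
    kept = [v for v in instruments.variants if v.snp_id not in hot]
    removed = len(instruments.variants) - len(kept)
    counts = dict(instruments.removed_counts)
    counts["outcome_excl"] = counts.get("outcome_excl", 0) + removed
    return replace(
        instruments,
        variants=kept,
        filters_applied=instruments.filters_applied | {"outcome_excl"},
        removed_counts=counts,
    )


def clump(
    assocs: list[VariantAssociation],
    ld_matrix: pd.DataFrame | dict[tuple[str, str], float],
    r2_max: float = 0.001,
) -> list[VariantAssociation]:
    """Greedy LD clumping against a user-supplied pairwise r-squared table.

    SNPs are visited in ascending p-value order; each is kept unless its
    r-squared with an already-kept SNP exceeds ``r2_max``. Pairs absent from
    ``ld_matrix`` are treated as independent (r2 = 0) with a logged warning.
    ``ld_matrix`` may be a square DataFrame indexed by snp_id or a dict keyed
    by (snp_a, snp_b) tuples (either order).
    """

    def r2(a: str, b: str) -> float:
        if isinstance(ld_matrix, pd.DataFrame):
            if a in ld_matrix.index and b in ld_matrix.columns:
                return float(ld_matrix.loc[a, b])
        else:
            if (a, b) in ld_matrix:
                return float(ld_matrix[(a, b)])
            if (b, a) in ld_matrix:
                return float(ld_matrix[(b, a)])
        logger.warning("LD for pair (%s, %s) missing; treated as r2=0", a, b)
        return 0.0

    order = sorted(assocs, key=lambda v: (v.pvalue, v.snp_id))
    kept: list[VariantAssociation] = []
    for v in order:
        if all(r2(v.snp_id, k.snp_id) <= r2_max for k in kept):
            kept.append(v)
    return kept
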