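"""Reading, validation, and allele alignment of GWAS summary statistics.

Summary association statistics are the per-variant marginal results of a
GWAS meta-analysis: effect size ``b`` of the effect allele, its standard
error ``se``, effect-allele frequency, p value and per-variant sample size
``N``.  The default on-disk dialect is the COJO ``.ma`` table
(``SNP A1 A2 freq b se p N``), the de-facto interchange format for
summary-level conditional analysis; optional ``CHR``/``BP`` columns carry
genomic coordinates when available.

The key quantity derived here is the variant-trait covariance

    Cov(Xj, y) = b_j * sigma2 / (se_j**2 * N_j),

which follows from the marginal OLS identities b_j ~ Cov(Xj,y)/Var(Xj) and
se_j**2 ~ sigma2 / (N_j * Var(Xj)) when single-variant effects are small
(the residual variance of the univariate fit is then close to the
phenotypic variance sigma2).  Every term except sigma2 is reported in the
meta-analysis; sigma2 = 1 is a valid convention when only selection or
variance explained is of interest, because the whole LASSO path scales
linearly in sigma2.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SummaryTable",
    "read_summary",
    "write_summary",
    "filter_maf",
    "filter_sample_size",
    "align_alleles",
    "marginal_covariance",
    "MA_COLUMNS",
]

#: canonical internal column names -> ``.ma`` header names
MA_COLUMNS: Mapping[str, str] = {
    "id": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "freq": "freq",
    "beta": "b",
    "se": "se",
    "pvalue": "p",
    "n": "N",
}

_OPTIONAL_MA = {"chrom": "CHR", "pos": "BP"}

_REQUIRED = ["id", "effect_allele", "other_allele", "freq", "beta", "se", "pvalue", "n"]

#: strand-ambiguous allele pairs (identical to their reverse complement)
_PALINDROMES = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SummaryFormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class SummaryInputError(ValueError):
    """The table is empty (or becomes empty) where records are required."""


@dataclass
class SummaryTable:
    """Validated, (chrom, pos)-ordered GWAS summary statistics.

    ``records`` is a DataFrame with columns
    ``id chrom pos effect_allele other_allele freq beta se n pvalue``.
    ``trait_sigma2`` is the phenotypic variance sigma2 (``None`` means
    "unset"; consumers fall back to 1.0).  ``report`` counts rows dropped
    during validation/filtering, by reason.
    """

    records: pd.DataFrame
    trait_sigma2: float | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> np.ndarray:
        return self.records["id"].to_numpy()

    def subset(self, mask_or_ids, reason: str | None = None) -> "SummaryTable":
        """Restrict to a boolean mask or an id collection, keeping order."""
        df = self.records
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
            mask_or_ids, "dtype", None
        ) == bool:
            keep = df[np.asarray(mask_or_ids)]
        else:
            wanted = set(mask_or_ids)
            keep = df[df["id"].isin(wanted)]
        rep = dict(self.report)
        if reason is not None:
            rep[reason] = rep.get(reason, 0) + (len(df) - len(keep))
        return SummaryTable(keep.copy(), self.trait_sigma2, rep)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating record invariants, counting each reason."""
    report: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n_bad = int(mask.sum())
        if n_bad:
            report[reason] = report.get(reason, 0) + n_bad
        return df[~mask]

    numeric = ["freq", "beta", "se", "n", "pvalue", "pos"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = drop(df[numeric].isna().any(axis=1), "non_numeric_or_missing")
    df = drop(~(df["se"] > 0), "nonpositive_se")
    df = drop(~(df["n"] > 0), "nonpositive_n")
    df = drop(~((df["freq"] > 0) & (df["freq"] < 1)), "freq_out_of_range")
    df = drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    df = drop(
        df["effect_allele"].astype(str).str.upper()
        == df["other_allele"].astype(str).str.upper(),
        "identical_alleles",
    )
    df = drop(df["id"].duplicated(keep="first"), "duplicate_id")
    return df, report


def _sort_genomic(df: pd.DataFrame) -> pd.DataFrame:
    key = pd.to_numeric(df["chrom"], errors="coerce")
    order = np.lexsort(
        (df["pos"].to_numpy(), df["chrom"].astype(str).to_numpy(), key.fillna(np.inf))
    )
    return df.iloc[order]


def read_summary(
    path,
    dialect: str = "ma",
    column_map: Mapping[str, str] | None = None,
    sigma2: float | None = None,
) -> SummaryTable:
    """Read a summary-statistics table into a validated :class:`SummaryTable`.

    Parameters
    ----------
    path
        Whitespace/tab-delimited text, optionally gzip-compressed.
    dialect
        ``"ma"`` for the COJO header (``SNP A1 A2 freq b se p N``, with
        optional ``CHR``/``BP``), or ``"custom"`` with ``column_map``
        mapping internal names (``id``, ``effect_allele``, ...) to headers.
    sigma2
        Phenotypic variance to attach; ``None`` leaves it unset.

    Rows violating the record invariants (se <= 0, freq outside (0,1), ...)
    are dropped and counted in ``table.report`` rather than raising, since
    meta-analysis tables routinely contain a few malformed rows.
    """
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=r"\s+")
    if dialect == "ma":
        mapping = dict(MA_COLUMNS)
        mapping.update(_OPTIONAL_MA)
    elif dialect in ("custom", "custom-column-map"):
        if column_map is None:
            raise SummaryFormatError("custom dialect requires a column_map")
        mapping = dict(column_map)
    else:
        raise SummaryFormatError(f"unknown dialect: {dialect!r}")

    lower = {c.lower(): c for c in raw.columns}
    renames = {}
    for internal, header in mapping.items():
        if header.lower() in lower:
            renames[lower[header.lower()]] = internal
    df = raw.rename(columns=renames)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SummaryFormatError(f"missing required column(s): {missing}")
    if "chrom" not in df.columns:
        df["chrom"] = "0"
    if "pos" not in df.columns:
        df["pos"] = np.arange(1, len(df) + 1)
    df = df[["id", "chrom", "pos"] + _REQUIRED[1:]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["id"] = df["id"].astype(str)

    df, report = _validate(df)
    if df.empty:
        raise SummaryInputError("no valid summary-statistic rows after validation")
    df = _sort_genomic(df)
    df["pos"] = df["pos"].astype(np.int64)
    return SummaryTable(df, trait_sigma2=sigma2, report=report)


def write_summary(table: SummaryTable, path, report_path=None) -> None:
    """Write the ``.ma`` dialect (plus CHR/BP) and an optional JSON report."""
    df = table.records.rename(
        columns={**{k: v for k, v in MA_COLUMNS.items()}, **_OPTIONAL_MA}
    )
    cols = ["SNP", "CHR", "BP", "A1", "A2", "freq", "b", "se", "p", "N"]
    df[cols].to_csv(path, sep="\t", index=False)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(table.report, fh, indent=2)


def filter_maf(table: SummaryTable, min_maf: float = 0.01) -> SummaryTable:
    """Exclude variants with minor-allele frequency below ``min_maf``."""
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    f = table.records["freq"]
    keep = np.minimum(f, 1.0 - f) >= min_maf
    return table.subset(keep.to_numpy(), reason="maf_below_threshold")


def filter_sample_size(table: SummaryTable, fraction: float = 2.0 / 3.0) -> SummaryTable:
    """Exclude variants with per-variant N below ``fraction`` of the maximum N.

    Variants genotyped/imputed in fewer contributing studies have less
    accurate variant-trait covariance estimates; the maximum is taken over
    the input table before filtering.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = table.records["n"]
    keep = n >= fraction * n.max()
    return table.subset(keep.to_numpy(), reason="low_sample_size")


def align_alleles(table: SummaryTable, panel, drop_palindromic: bool = False) -> SummaryTable:
    """Align effect alleles to the reference panel's counted alleles.

    For each variant shared with the panel: if the effect allele equals the
    panel's counted allele the record is unchanged; if the allele pair is
    swapped, the marginal effect is negated and the frequency complemented.
    Variants whose allele pair cannot be matched are dropped, as are
    strand-ambiguous A/T and C/G variants when ``drop_palindromic`` is set
    (matching is by allele pair; no strand complementing is attempted).
    The output is restricted to the intersection, in table order.
    """
    meta = panel.variant_meta.set_index("id")
    df = table.records
    shared = df["id"].isin(meta.index)
    df = df[shared].copy()
    if df.empty:
        raise SummaryInputError("no variants shared between summary table and panel")
    rep = dict(table.report)
    rep["not_in_panel"] = rep.get("not_in_panel", 0) + int((~shared).sum())

    counted = meta.loc[df["id"], "counted_allele"].astype(str).str.upper().to_numpy()
    other = meta.loc[df["id"], "other_allele"].astype(str).str.upper().to_numpy()
    ea = df["effect_allele"].astype(str).str.upper().to_numpy()
    oa = df["other_allele"].astype(str).str.upper().to_numpy()

    same = (ea == counted) & (oa == other)
    swapped = (ea == other) & (oa == counted)
    keep = same | swapped
    if drop_palindromic:
        pal = np.array([frozenset(p) in _PALINDROMES for p in zip(ea, oa)])
        keep &= ~pal
        rep["palindromic"] = rep.get("palindromic", 0) + int((same | swapped).sum() - keep.sum())
    rep["allele_mismatch"] = rep.get("allele_mismatch", 0) + int((~(same | swapped)).sum())

    df = df[keep].copy()
    if df.empty:
        raise SummaryInputError("no variants left after allele alignment")
    flip = swapped[keep]
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "freq"] = 1.0 - df.loc[flip, "freq"]
    df["effect_allele"] = counted[keep]
    df["other_allele"] = other[keep]
    return SummaryTable(df, table.trait_sigma2, rep)


def marginal_covariance(record, sigma2: float) -> float:
    """Variant-trait covariance reconstructed from marginal statistics.

    ``Cov(Xj, y) = b_j * sigma2 / (se_j**2 * N_j)``, evaluated with each
    variant's own sample size, so tables with heterogeneous per-variant N
    (imputation failures in contributing cohorts) remain valid inputs.
    ``record`` is any mapping with ``beta``, ``se`` and ``n`` entries
    (e.g. a DataFrame row).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return float(record["beta"]) * sigma2 / (float(record["se"]) ** 2 * float(record["n"]))


def marginal_covariances(table: SummaryTable, sigma2: float | None = None) -> np.ndarray:
    """Vectorized :func:`marginal_covariance` over a table."""
    if sigma2 is None:
        sigma2 = table.trait_sigma2 if table.trait_sigma2 is not None else 1.0
    df = table.records
    return (
        df["beta"].to_numpy() * sigma2 / (df["se"].to_numpy() ** 2 * df["n"].to_numpy())
    )
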