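"""Reading, validation and pairwise harmonization of GWAS summary statistics.

A summary-statistics table holds one row per variant with the effect estimate
(beta, on the log-odds scale for case-control traits), its standard error,
the association p-value and the allele pair the effect is expressed on.
Before two traits can be compared variant-by-variant their allele codings
must be reconciled: the same variant may be reported with effect and other
allele swapped (beta changes sign), and strand-ambiguous SNVs (A/T, C/G)
cannot be reconciled reliably across strand conventions, so they are removed.

The module also provides the two effective-sample-size conventions for
case-control GWAS: the per-variant form based on MAF, INFO, BETA and SE, and
the study-level harmonic form 4/(1/N_cases + 1/N_controls).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "MIN_P",
    "StudyMeta",
    "SumStatsTable",
    "HarmonizedPair",
    "read_sumstats",
    "write_sumstats",
    "is_strand_ambiguous",
    "harmonize_pair",
    "neff_per_variant",
    "neff_from_counts",
    "annotate_neff",
]

#: Canonical column order of the in-memory table and the on-disk dialect.
CANONICAL_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "beta", "se", "p", "maf", "info", "n_eff"]

#: Columns that must be present (directly or via a column map) in any input file.
MANDATORY_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "beta", "se", "p"]

#: Smallest p-value stored; p-values are kept and compared on the natural
#: scale, so anything below the smallest positive double collapses to this.
MIN_P = 5e-324

_BASES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass
class StudyMeta:
    """Study-level metadata for one GWAS."""

    trait_name: str
    n_cases: int | None = None
    n_controls: int | None = None
    build: str = "hg38"

    def __post_init__(self) -> None:
        if self.n_cases is not None and self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if self.n_controls is not None and self.n_controls <= 0:
            raise ValueError("n_controls must be positive")


@dataclass
class SumStatsTable:
    """Validated per-variant association records for one trait.

    ``df`` always carries :data:`CANONICAL_COLUMNS`; ``load_report`` counts
    rows dropped during validation, keyed by reason.
    """

    df: pd.DataFrame
    meta: StudyMeta
    load_report: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.df["id"])

    def write_load_report(self, path: str | Path) -> None:
        """Write the drop census as a two-column TSV (reason, count)."""
        rows = sorted(self.load_report.items())
        pd.DataFrame(rows, columns=["reason", "count"]).to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedPair:
    """Two traits' statistics on a shared, allele-reconciled variant set.

    ``df`` has one row per retained variant with columns id, chrom, pos,
    a1, a2 (the shared effect/other allele), beta_a/se_a/p_a,
    beta_b/se_b/p_b and a ``flipped`` flag marking variants whose trait-B
    record was reported on swapped alleles.  ``drops`` records excluded
    variants (id, reason).
    """

    df: pd.DataFrame
    trait_a: str
    trait_b: str
    drops: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def drop_counts(self) -> Counter:
        return Counter(self.drops["reason"]) if len(self.drops) else Counter()


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A, T} or {C, G}.

    Only single-base SNVs can be strand-ambiguous; indels and multi-base
    alleles return False by convention.
    """
    a1, a2 = str(a1).upper(), str(a2).upper()
    if len(a1) != 1 or len(a2) != 1 or a1 not in _BASES or a2 not in _BASES:
        return False
    return frozenset((a1, a2)) in _AMBIGUOUS_PAIRS


def _ambiguous_mask(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    pair = a1.str.upper() + a2.str.upper()
    return pair.isin(["AT", "TA", "CG", "GC"]).to_numpy()


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    meta: StudyMeta | None = None,
) -> SumStatsTable:
    """Load a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited text file with a header row; gzip is
        handled transparently by extension.
    column_map
        Optional mapping from canonical names (``id``, ``chrom``, ``pos``,
        ``a1``, ``a2``, ``beta``, ``se``, ``p``, and optionally ``maf``,
        ``info``, ``n_eff``) to the column names used in the file.
    meta
        Study metadata; defaults to a trait named after the file stem.

    Rows violating the record invariants (nonpositive SE, p outside (0, 1],
    identical alleles, MAF outside (0, 0.5], missing mandatory fields) are
    dropped and counted in the load report.  Duplicated variant ids keep the
    record with the smallest p.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary statistics file not found: {path}")
    df = pd.read_csv(path, sep=r"\s+", dtype={"id": str}, compression="infer")
    if df.empty:
        raise InputError(f"summary statistics file has no data rows: {path}")

    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        missing_sources = {canon: src for canon, src in column_map.items() if src not in df.columns}
        if missing_sources:
            raise ConfigurationError(f"mapped columns absent from {path.name}: {missing_sources}")
        df = df.rename(columns=rename)

    absent = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if absent:
        raise ConfigurationError(f"mandatory columns missing from {path.name}: {absent}")

    for col in ("maf", "info", "n_eff"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS].copy()

    df["id"] = df["id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("pos", "beta", "se", "p", "maf", "info", "n_eff"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    report: Counter = Counter()

    def _drop(mask: np.ndarray, reason: str) -> None:
        nonlocal df
        n = int(np.sum(mask))
        if n:
            report[reason] += n
            df = df.loc[~mask]

    _drop(df[["id", "chrom", "pos", "a1", "a2", "beta", "se", "p"]].isna().any(axis=1).to_numpy(), "missing mandatory field")
    _drop((df["se"] <= 0).to_numpy(), "nonpositive SE")
    _drop(((df["p"] <= 0) | (df["p"] > 1)).to_numpy(), "p out of range")
    _drop((df["a1"] == df["a2"]).to_numpy(), "identical alleles")
    _drop((df["pos"] < 1).to_numpy(), "nonpositive position")
    maf_bad = df["maf"].notna() & ((df["maf"] <= 0) | (df["maf"] > 0.5))
    _drop(maf_bad.to_numpy(), "MAF out of range")
    info_bad = df["info"].notna() & ((df["info"] <= 0) | (df["info"] > 1))
    _drop(info_bad.to_numpy(), "INFO out of range")

    # Duplicate ids: keep the most significant record, log the rest.  Allele
    # pairs at the same position keep distinct ids, so multi-allelic sites
    # survive as separate records.
    if df["id"].duplicated().any():
        before = len(df)
        df = df.sort_values("p", kind="stable").drop_duplicates("id", keep="first")
        df = df.sort_index()
        report["duplicate id"] += before - len(df)

    df["pos"] = df["pos"].astype(np.int64)
    df = df.reset_index(drop=True)
    if meta is None:
        meta = StudyMeta(trait_name=path.stem)
    return SumStatsTable(df=df, meta=meta, load_report=report)


def write_sumstats(table: SumStatsTable, path: str | Path) -> None:
    """Write a table in the canonical tab-delimited dialect."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _match_class(a1a: pd.Series, a2a: pd.Series, a1b: pd.Series, a2b: pd.Series) -> np.ndarray:
    """Classify each aligned allele pair: 1 = same, -1 = swapped, 0 = mismatch."""
    same = (a1a == a1b) & (a2a == a2b)
    swapped = (a1a == a2b) & (a2a == a1b)
    return np.where(same, 1, np.where(swapped, -1, 0))


def harmonize_pair(a: SumStatsTable, b: SumStatsTable) -> HarmonizedPair:
    """Reconcile two traits' tables onto a shared effect-allele coding.

    Variants are matched by id first; variants unmatched by id are then
    matched by (chrom, pos) with an allele-set compatibility check, since
    the same site may carry different ids across studies.  For each match:

    - identical allele pairs are retained as-is;
    - swapped pairs (B's effect allele equals A's other allele) are retained
      with B's beta sign flipped, so both traits report the effect of A's a1;
    - strand-ambiguous SNVs are dropped ("strand-ambiguous");
    - incompatible allele sets are dropped ("allele mismatch").
    """
    if a.meta.build != b.meta.build:
        raise ConfigurationError(
            f"genome builds differ: {a.meta.build} vs {b.meta.build}"
        )

    left = a.df.add_suffix("_a").rename(columns={"id_a": "id"})
    right = b.df.add_suffix("_b").rename(columns={"id_b": "id"})
    merged = left.merge(right, on="id", how="inner")

    # Positional rescue for variants unmatched by id on both sides.
    a_unmatched = left.loc[~left["id"].isin(merged["id"])]
    b_unmatched = right.loc[~right["id"].isin(merged["id"])]
    if len(a_unmatched) and len(b_unmatched):
        pos_merge = a_unmatched.merge(
            b_unmatched.rename(columns={"id": "id_b_side"}),
            left_on=["chrom_a", "pos_a"],
            right_on=["chrom_b", "pos_b"],
            how="inner",
        )
        if len(pos_merge):
            cls = _match_class(
                pos_merge["a1_a"], pos_merge["a2_a"], pos_merge["a1_b"], pos_merge["a2_b"]
            )
            pos_merge = pos_merge.loc[cls != 0].drop(columns=["id_b_side"])
            merged = pd.concat([merged, pos_merge], ignore_index=True)

    drops: list[tuple[str, str]] = []
    if merged.empty:
        empty = pd.DataFrame(columns=["id", "chrom", "pos", "a1", "a2",
                                      "beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b", "flipped"])
        return HarmonizedPair(empty, a.meta.trait_name, b.meta.trait_name,
                              pd.DataFrame(drops, columns=["id", "reason"]))

    amb = _ambiguous_mask(merged["a1_a"], merged["a2_a"]) | _ambiguous_mask(
        merged["a1_b"], merged["a2_b"]
    )
    drops += [(vid, "strand-ambiguous") for vid in merged.loc[amb, "id"]]
    merged = merged.loc[~amb]

    cls = _match_class(merged["a1_a"], merged["a2_a"], merged["a1_b"], merged["a2_b"])
    mismatch = cls == 0
    drops += [(vid, "allele mismatch") for vid in merged.loc[mismatch, "id"]]
    merged = merged.loc[~mismatch]
    cls = cls[~mismatch]

    flipped = cls == -1
    beta_b = np.where(flipped, -merged["beta_b"].to_numpy(), merged["beta_b"].to_numpy())

    out = pd.DataFrame(
        {
            "id": merged["id"].to_numpy(),
            "chrom": merged["chrom_a"].to_numpy(),
            "pos": merged["pos_a"].to_numpy(),
            "a1": merged["a1_a"].to_numpy(),
            "a2": merged["a2_a"].to_numpy(),
            "beta_a": merged["beta_a"].to_numpy(),
            "se_a": merged["se_a"].to_numpy(),
            "p_a": merged["p_a"].to_numpy(),
            "maf_a": merged["maf_a"].to_numpy(),
            "beta_b": beta_b,
            "se_b": merged["se_b"].to_numpy(),
            "p_b": merged["p_b"].to_numpy(),
            "maf_b": merged["maf_b"].to_numpy(),
            "flipped": flipped,
        }
    ).reset_index(drop=True)
    return HarmonizedPair(
        df=out,
        trait_a=a.meta.trait_name,
        trait_b=b.meta.trait_name,
        drops=pd.DataFrame(drops, columns=["id", "reason"]),
    )


def neff_per_variant(maf, info, beta, se):
    """Per-variant effective sample size from MAF, INFO, BETA and SE.

    Computes ((4 / (2*MAF*(1-MAF)*INFO)) - BETA^2) / SE^2.  ``info`` may be
    None/NaN, in which case it is taken as 1 (the convention when a study
    reports no imputation scores).  Accepts scalars or numpy arrays.
    Negative results (possible when BETA^2 dominates) are returned as NaN.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("maf must lie strictly between 0 and 1")
    if info is None:
        info = 1.0
    info = np.asarray(info, dtype=float)
    info = np.where(np.isnan(info), 1.0, info)
    if np.any((info <= 0) | (info > 1)):
        raise ValueError("info must lie in (0, 1]")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    val = (4.0 / (2.0 * maf * (1.0 - maf) * info) - beta**2) / se**2
    val = np.where(val < 0, np.nan, val)
    return float(val) if val.ndim == 0 else val


def neff_from_counts(n_cases: float, n_controls: float) -> float:
    """Study-level effective sample size 4 / (1/N_cases + 1/N_controls).

    Equals the total sample size for a balanced design and is smaller for
    imbalanced case-control ratios.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def annotate_neff(table: SumStatsTable) -> SumStatsTable:
    """Fill the n_eff column in place where missing.

    Variants with MAF use the per-variant formula (INFO defaulting to 1);
    if the study metadata carries case/control counts, remaining variants
    fall back to the study-level harmonic formula.  Negative per-variant
    values are left missing and counted in the load report.
    """
    df = table.df
    need = df["n_eff"].isna() & df["maf"].notna()
    if need.any():
        sub = df.loc[need]
        vals = neff_per_variant(sub["maf"].to_numpy(), sub["info"].to_numpy(),
                                sub["beta"].to_numpy(), sub["se"].to_numpy())
        n_clamped = int(np.isnan(vals).sum())
        if n_clamped:
            table.load_report["negative n_eff clamped to missing"] += n_clamped
        df.loc[need, "n_eff"] = vals
    meta = table.meta
    if meta.n_cases and meta.n_controls:
        fallback = df["n_eff"].isna()
        if fallback.any():
            df.loc[fallback, "n_eff"] = neff_from_counts(meta.n_cases, meta.n_controls)
    return table


def min_representable_p() -> float:
    """The smallest p-value the natural-scale representation can hold."""
    return MIN_P


def _two_sided_p(z):
    """Two-sided normal p-value from a z-score, floored at MIN_P."""
    from scipy.special import ndtr

    p = 2.0 * ndtr(-np.abs(np.asarray(z, dtype=float)))
    return np.maximum(p, MIN_P)
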