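"""End-to-end pair analysis: harmonize, gate, test, colocalize, report.

`run_pair_analysis` wires the modules together for one pair of traits:

1. read and harmonize both traits' summary statistics;
2. exclude MHC/HLA leads and pool the two lead lists;
3. resolve each pooled lead against the other trait's table, substituting
   the best LD proxy (r² > r2_min) when absent;
4. Bonferroni threshold alpha/m over the m testable variants, then look up
   each lead/proxy in the other trait and call significance (strict <);
5. for each significant hit, colocalize the two traits over the harmonized
   variants in the same approximately independent LD block as the hit.

The report has one row per significant cross-test with the hit's statistics
in both traits, its direction concordance, and the locus's five
colocalization posteriors; a structured run log records m, the threshold,
proxy substitutions and the drop census so the procedure applied can be
reconstructed from any run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .coloc import ColocPriors, LocusData, colocalize_locus, DEFAULT_PRIOR_SD
from .errors import PipelineError
from .gatekeeper import (
    MHC_HG38,
    LeadVariantSet,
    bonferroni_threshold,
    cross_test,
    exclude_region,
    pool_leads,
    resolve_testable,
)
from .ld import LDBlockSet, LDProxyTable
from .sumstats import HarmonizedPair, SumStatsTable, harmonize_pair, read_sumstats

__all__ = [
    "PairAnalysisConfig",
    "PairAnalysisResult",
    "run_pair_analysis",
    "sensitivity_join",
    "nearest_gene",
]

REPORT_COLUMNS = [
    "variant_id", "tested_id", "proxy_used", "source_trait", "target_trait",
    "chrom", "pos", "a1", "a2",
    "beta_source", "or_source", "p_source",
    "beta_target", "or_target", "p_target",
    "threshold", "significant", "direction",
    "block", "n_block_variants",
    "pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4", "pp_shared", "pp_distinct",
    "leads_sharing_block",
]


@dataclass
class PairAnalysisConfig:
    """All inputs and knobs for one pair analysis."""

    sumstats_a: str
    sumstats_b: str
    leads_a: str
    leads_b: str
    proxies: str
    blocks: str
    trait_a: str = "trait_a"
    trait_b: str = "trait_b"
    alpha: float = 0.05
    r2_min: float = 0.8
    exclusion_region: tuple[str, int, int] | None = MHC_HG38
    priors: ColocPriors = field(default_factory=ColocPriors)
    prior_sd: tuple[float, float] = (DEFAULT_PRIOR_SD, DEFAULT_PRIOR_SD)
    count_mode: str = "variants"  # or "tests": how a lead for both traits counts in m
    extra_leads_a: Sequence[dict] = ()  # each: {id, chrom, pos}; e.g. APOE rs429358
    extra_leads_b: Sequence[dict] = ()
    sensitivity_sumstats: str | None = None
    genes: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.count_mode not in ("variants", "tests"):
            raise ValueError("count_mode must be 'variants' or 'tests'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PairAnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "priors" in raw and isinstance(raw["priors"], dict):
            raw["priors"] = ColocPriors(**raw["priors"])
        if "exclusion_region" in raw and raw["exclusion_region"] is not None:
            raw["exclusion_region"] = tuple(raw["exclusion_region"])
        if "prior_sd" in raw:
            raw["prior_sd"] = tuple(raw["prior_sd"])
        return cls(**raw)


@dataclass
class PairAnalysisResult:
    report: pd.DataFrame
    cross_tests: pd.DataFrame
    pair: HarmonizedPair
    run_log: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
        self.cross_tests.to_csv(out_dir / "cross_tests.tsv", sep="\t", index=False)
        with open(out_dir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(self.run_log, fh, sort_keys=True)


def _positions_map(*tables: SumStatsTable) -> dict:
    out: dict = {}
    for t in tables:
        out.update(zip(t.df["id"], zip(t.df["chrom"], t.df["pos"])))
    return out


def run_pair_analysis(config: PairAnalysisConfig) -> PairAnalysisResult:
    """Run the full gatekeeper + colocalization analysis for one trait pair."""
    table_a = read_sumstats(config.sumstats_a, meta=None)
    table_a.meta.trait_name = config.trait_a
    table_b = read_sumstats(config.sumstats_b, meta=None)
    table_b.meta.trait_name = config.trait_b
    leads_a = LeadVariantSet.from_tsv(config.leads_a, trait=config.trait_a)
    leads_b = LeadVariantSet.from_tsv(config.leads_b, trait=config.trait_b)
    for extra in config.extra_leads_a:
        leads_a = leads_a.add_variant(**extra)
    for extra in config.extra_leads_b:
        leads_b = leads_b.add_variant(**extra)
    proxies = LDProxyTable.from_tsv(config.proxies)
    blocks = LDBlockSet.from_bed(config.blocks)

    pair = harmonize_pair(table_a, table_b)

    leads_a = exclude_region(leads_a, config.exclusion_region)
    leads_b = exclude_region(leads_b, config.exclusion_region)
    pooled = pool_leads(leads_a, leads_b)

    # No lead variants at all means no cross-trait hypotheses: an empty
    # report, not a failure.  (An m = 0 after resolution, below, is instead
    # a refusal: there were hypotheses but none could be looked up.)
    if pooled.empty:
        empty_tests = pd.DataFrame(columns=[c for c in REPORT_COLUMNS
                                            if c not in ("block", "n_block_variants", "pp_h0",
                                                         "pp_h1", "pp_h2", "pp_h3", "pp_h4",
                                                         "pp_shared", "pp_distinct",
                                                         "leads_sharing_block")])
        run_log = {
            "trait_a": config.trait_a, "trait_b": config.trait_b,
            "n_harmonized": len(pair), "n_pooled": 0, "m_testable": 0,
            "alpha": config.alpha, "threshold": None, "n_significant": 0,
        }
        result = PairAnalysisResult(report=pd.DataFrame(columns=REPORT_COLUMNS),
                                    cross_tests=empty_tests, pair=pair, run_log=run_log)
        if config.out_dir:
            result.write(config.out_dir)
        return result

    # Proxy search happens only for leads absent from the target table, per
    # direction: leads sourced from A (and "both") are resolved against B's
    # table, and vice versa.
    positions = _positions_map(table_a, table_b)
    toward_b = pooled.loc[pooled["source"].isin([config.trait_a, "both"])]
    toward_a = pooled.loc[pooled["source"].isin([config.trait_b, "both"])]
    res_b = resolve_testable(toward_b, table_b, proxies, config.r2_min, positions)
    res_a = resolve_testable(toward_a, table_a, proxies, config.r2_min, positions)

    # A "both" lead is tested in both directions; under count_mode
    # "variants" it still counts once toward the multiplicity m.
    resolved = pd.concat([res_b, res_a], ignore_index=True)
    testable = resolved.loc[resolved["status"] != "dropped"]
    if config.count_mode == "variants":
        m = testable["id"].nunique()
    else:
        m = len(testable)
    if m == 0:
        raise PipelineError(
            "no pooled lead variant is present (or has an LD proxy) in the "
            "other trait's summary statistics; nothing is testable"
        )
    threshold = bonferroni_threshold(m, config.alpha)

    # Deduplicate "both" rows so each (variant, direction) is tested once:
    # res_b carries source "both" rows (tested toward B) and res_a the same
    # ids (tested toward A); cross_test expands "both" into two directions,
    # so keep a single entry per id with the toward-B resolution and patch
    # in the toward-A resolution when only that direction resolved.
    both_ids = set(pooled.loc[pooled["source"] == "both", "id"])
    ct_rows = []
    for rid in both_ids:
        rb = res_b.loc[res_b["id"] == rid].iloc[0]
        ra = res_a.loc[res_a["id"] == rid].iloc[0]
        use = rb if rb["status"] != "dropped" else ra
        ct_rows.append(use)
    singles = resolved.loc[~resolved["id"].isin(both_ids)]
    ct_input = pd.concat([singles, pd.DataFrame(ct_rows)], ignore_index=True) if ct_rows else singles

    tests = cross_test(ct_input, pair, threshold)
    hits = tests.loc[tests["significant"]].copy() if len(tests) else tests

    # Colocalize each significant hit's LD block over the harmonized
    # variants it contains; hits sharing a block share one posterior.
    report_rows = []
    block_cache: dict = {}
    hdf = pair.df
    if len(hits):
        block_of = {}
        for rec in hits.itertuples(index=False):
            block_of[rec.tested_id] = blocks.assign(rec.chrom, rec.pos)
        block_members: dict = {}
        for tid, blk in block_of.items():
            if blk is not None:
                block_members.setdefault(blk, []).append(tid)
        for rec in hits.itertuples(index=False):
            blk = block_of[rec.tested_id]
            row = rec._asdict()
            if blk is None:
                row.update(block=None, n_block_variants=0,
                           pp_h0=np.nan, pp_h1=np.nan, pp_h2=np.nan,
                           pp_h3=np.nan, pp_h4=np.nan,
                           pp_shared=np.nan, pp_distinct=np.nan,
                           leads_sharing_block="")
            else:
                if blk not in block_cache:
                    chrom, start, end = blk
                    in_block = (hdf["chrom"] == chrom) & (hdf["pos"] - 1 >= start) & (hdf["pos"] - 1 < end)
                    sub = hdf.loc[in_block]
                    locus = LocusData(
                        label=f"{chrom}:{start}-{end}", block=blk,
                        beta1=sub["beta_a"].to_numpy(), se1=sub["se_a"].to_numpy(),
                        beta2=sub["beta_b"].to_numpy(), se2=sub["se_b"].to_numpy(),
                    )
                    block_cache[blk] = (colocalize_locus(locus, config.priors, config.prior_sd),
                                        len(sub))
                post, n_in_block = block_cache[blk]
                sharing = ",".join(sorted(t for t in block_members[blk] if t != rec.tested_id))
                row.update(block=f"{blk[0]}:{blk[1]}-{blk[2]}", n_block_variants=n_in_block,
                           pp_h0=post.pp_h0, pp_h1=post.pp_h1, pp_h2=post.pp_h2,
                           pp_h3=post.pp_h3, pp_h4=post.pp_h4,
                           pp_shared=post.pp_shared, pp_distinct=post.pp_distinct,
                           leads_sharing_block=sharing)
            report_rows.append(row)
    report = pd.DataFrame(report_rows, columns=REPORT_COLUMNS)

    run_log = {
        "trait_a": config.trait_a,
        "trait_b": config.trait_b,
        "n_variants_a": len(table_a),
        "n_variants_b": len(table_b),
        "n_harmonized": len(pair),
        "harmonization_drops": {k: int(v) for k, v in pair.drop_counts.items()},
        "n_leads_a_post_exclusion": len(leads_a),
        "n_leads_b_post_exclusion": len(leads_b),
        "leads_excluded": int(len(leads_a.excluded) + len(leads_b.excluded)),
        "n_pooled": int(len(pooled)),
        "count_mode": config.count_mode,
        "m_testable": int(m),
        "alpha": config.alpha,
        "threshold": float(threshold),
        "r2_min": config.r2_min,
        "proxy_substitutions": {
            str(r.id): str(r.tested_id)
            for r in resolved.itertuples(index=False) if r.status == "proxy"
        },
        "n_dropped_untestable": int((resolved["status"] == "dropped").sum()),
        "coloc_priors": {"p1": config.priors.p1, "p2": config.priors.p2,
                         "p12": config.priors.p12},
        "coloc_prior_sd": list(config.prior_sd),
        "n_significant": int(len(hits)),
    }

    result = PairAnalysisResult(report=report, cross_tests=tests, pair=pair, run_log=run_log)
    if config.sensitivity_sumstats:
        sens = read_sumstats(config.sensitivity_sumstats)
        result.report = sensitivity_join(result.report, sens)
    if config.genes:
        genes = pd.read_csv(config.genes, sep="\t", header=None, usecols=[0, 1, 2, 3],
                            names=["chrom", "start", "end", "name"], dtype={"chrom": str})
        result.report["nearest_gene"] = [
            nearest_gene((r.chrom, r.pos), genes) or ""
            for r in result.report.itertuples(index=False)
        ]
    if config.out_dir:
        result.write(config.out_dir)
    return result


def sensitivity_join(report: pd.DataFrame, sensitivity: SumStatsTable) -> pd.DataFrame:
    """Append a sensitivity trait's OR and p to each report row.

    The sensitivity beta is aligned to the report row's effect allele
    (flipped when the sensitivity table codes the alleles swapped); rows
    whose variant is absent from the sensitivity table, or whose alleles
    cannot be reconciled, keep missing values and a missing nominal flag
    rather than being dropped.  ``sens_nominal`` marks p < 0.05.
    """
    sdf = sensitivity.df.set_index("id")
    or_col, p_col, flag_col = [], [], []
    for row in report.itertuples(index=False):
        tid = row.tested_id
        if tid not in sdf.index:
            or_col.append(np.nan); p_col.append(np.nan); flag_col.append(pd.NA)
            continue
        s = sdf.loc[tid]
        if s["a1"] == row.a1 and s["a2"] == row.a2:
            beta = float(s["beta"])
        elif s["a1"] == row.a2 and s["a2"] == row.a1:
            beta = -float(s["beta"])
        else:
            or_col.append(np.nan); p_col.append(np.nan); flag_col.append(pd.NA)
            continue
        or_col.append(float(np.exp(beta)))
        p_col.append(float(s["p"]))
        flag_col.append(bool(s["p"] < 0.05))
    out = report.copy()
    out["sens_or"] = or_col
    out["sens_p"] = p_col
    out["sens_nominal"] = pd.array(flag_col, dtype="boolean")
    return out


def nearest_gene(variant: tuple[str, int], genes: pd.DataFrame) -> str | None:
    """Nearest gene to a 1-based variant position; ties joined with "/".

    ``genes`` is a BED-like frame (chrom, start, end, name) with 0-based
    half-open intervals.  Distance is 0 for a variant inside an interval.
    Returns None when no gene is on the variant's chromosome.
    """
    chrom, pos = variant
    sub = genes.loc[genes["chrom"] == str(chrom)]
    if sub.empty:
        return None
    p0 = int(pos) - 1
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.where(p0 < start, start - p0, np.where(p0 >= end, p0 - end + 1, 0))
    best = dist.min()
    names = sorted(sub.loc[dist == best, "name"].astype(str).unique())
    return "/".join(names)
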