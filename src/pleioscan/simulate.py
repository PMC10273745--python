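"""Synthetic paired GWAS summary statistics with known locus-level truth.

The generator emulates the statistical structure a summary-statistics
cross-trait analysis rests on, without any genotype-level simulation:

- LD within a locus follows an AR(1) correlation matrix R with entries
  rho^|i-j| — a deliberate simplification of haplotype structure that is
  nevertheless enough to exercise proxy lookup, block scoping, and the
  contrast between shared and distinct causal variants;
- per-variant standard errors follow the case-control GWAS approximation
  se_i = 1 / sqrt(2 * maf_i * (1 - maf_i) * N_eff), with N_eff from the
  harmonic case/control formula and MAF drawn uniformly on a common-variant
  range;
- marginal z-scores are multivariate normal with mean R @ lambda and
  covariance R, where lambda is nonzero only at causal indices
  (lambda_c = beta_c / se_c), so non-causal variants pick up association
  through LD exactly as in real data;
- each locus carries a ground-truth label: shared causal variant, distinct
  causal variants, one-trait-only, or null.

Everything is deterministic under a seed, and the emitted files round-trip
through the package's own readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from .ld import LDBlockSet, LDProxyTable
from .sumstats import (
    StudyMeta,
    SumStatsTable,
    _two_sided_p,
    neff_from_counts,
)

__all__ = [
    "GENOME_WIDE_SIG",
    "LocusSpec",
    "SimulatedLocus",
    "FixtureBundle",
    "simulate_ld_matrix",
    "simulate_locus_pair",
    "write_fixture_bundle",
]

#: Genome-wide significance threshold used for synthetic lead calling.
GENOME_WIDE_SIG = 5e-8

CONFIGS = ("shared", "distinct", "trait1_only", "trait2_only", "null")


@dataclass
class LocusSpec:
    """Recipe for one simulated locus pair.

    The causal signal is parameterized by its expected marginal z-score
    (``causal_z1``/``causal_z2``, default 6 — a clearly genome-wide
    significant signal); passing ``beta1``/``beta2`` instead expresses the
    causal effect on the log-odds scale, with the implied z then depending
    on the causal variant's MAF and the trait's effective sample size.
    Defaults emulate one approximately independent LD block: a few hundred
    harmonized variants with AR(1) decay rho = 0.95, which yields several
    r² > 0.8 neighbors per variant (exercising proxy rescue) while the two
    causal variants of a "distinct" locus, placed a quarter and three
    quarters of the way through, are essentially uncorrelated.
    """

    config: str = "null"
    n_variants: int = 300
    rho: float = 0.95
    causal_z1: float = 6.0
    causal_z2: float = 6.0
    beta1: float | None = None
    beta2: float | None = None
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_cases1: int = 25_000
    n_controls1: int = 50_000
    n_cases2: int = 25_000
    n_controls2: int = 50_000
    causal_index1: int | None = None
    causal_index2: int | None = None

    def __post_init__(self) -> None:
        if self.config not in CONFIGS:
            raise ValueError(f"config must be one of {CONFIGS}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")
        c1, c2 = self._default_indices()
        if self.config == "distinct" and c1 == c2:
            raise ValueError("distinct config requires two different causal indices")

    def _default_indices(self) -> tuple[int | None, int | None]:
        n = self.n_variants
        if self.config == "null":
            return None, None
        if self.config == "shared":
            c = self.causal_index1 if self.causal_index1 is not None else n // 2
            return c, c
        if self.config == "distinct":
            c1 = self.causal_index1 if self.causal_index1 is not None else n // 4
            c2 = self.causal_index2 if self.causal_index2 is not None else (3 * n) // 4
            return c1, c2
        if self.config == "trait1_only":
            return (self.causal_index1 if self.causal_index1 is not None else n // 2), None
        return None, (self.causal_index2 if self.causal_index2 is not None else n // 2)


@dataclass
class SimulatedLocus:
    """One simulated locus: aligned per-trait statistics plus ground truth."""

    spec: LocusSpec
    maf: np.ndarray
    beta1: np.ndarray
    se1: np.ndarray
    p1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    p2: np.ndarray
    R: np.ndarray
    causal_index1: int | None
    causal_index2: int | None

    def __len__(self) -> int:
        return len(self.maf)


def simulate_ld_matrix(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix with entries rho^|i-j|.

    Symmetric positive definite for any 0 <= rho < 1.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    return toeplitz(rho ** np.arange(n))


def simulate_locus_pair(spec: LocusSpec, rng: np.random.Generator) -> SimulatedLocus:
    """Draw one locus pair's summary statistics from the spec's model."""
    n = spec.n_variants
    R = simulate_ld_matrix(n, spec.rho)
    L = cholesky(R, lower=True)
    maf = rng.uniform(spec.maf_low, spec.maf_high, size=n)
    c1, c2 = spec._default_indices()

    def one_trait(n_cases, n_controls, beta_c, z_c, causal):
        neff = neff_from_counts(n_cases, n_controls)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * neff)
        lam = np.zeros(n)
        if causal is not None:
            lam[causal] = beta_c / se[causal] if beta_c is not None else z_c
        z = R @ lam + L @ rng.standard_normal(n)
        return z * se, se, _two_sided_p(z)

    beta1, se1, p1 = one_trait(spec.n_cases1, spec.n_controls1, spec.beta1, spec.causal_z1, c1)
    beta2, se2, p2 = one_trait(spec.n_cases2, spec.n_controls2, spec.beta2, spec.causal_z2, c2)
    return SimulatedLocus(
        spec=spec, maf=maf,
        beta1=beta1, se1=se1, p1=p1,
        beta2=beta2, se2=se2, p2=p2,
        R=R, causal_index1=c1, causal_index2=c2,
    )


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus its ground truth.

    Holds the in-memory tables and, after :func:`write_fixture_bundle`,
    the paths of the emitted files.
    """

    sumstats1: SumStatsTable
    sumstats2: SumStatsTable
    leads1: pd.DataFrame
    leads2: pd.DataFrame
    proxies: LDProxyTable
    blocks: LDBlockSet
    truth: pd.DataFrame
    loci: list = field(default_factory=list)
    paths: dict = field(default_factory=dict)


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                 ("C", "A"), ("G", "T"), ("C", "T")]  # non-ambiguous SNVs only


def _build_tables(
    specs: Sequence[LocusSpec],
    rng: np.random.Generator,
    trait1: str,
    trait2: str,
    locus_spacing: int,
    pos_step: int,
    r2_emit_min: float,
    withhold1: set,
    withhold2: set,
) -> FixtureBundle:
    rows1, rows2, truth_rows, proxy_rows, block_rows, loci = [], [], [], [], [], []
    for k, spec in enumerate(specs):
        locus = simulate_locus_pair(spec, rng)
        loci.append(locus)
        n = len(locus)
        base = 1 + k * locus_spacing
        pos = base + pos_step * np.arange(n)
        ids = [f"rs{k + 1:03d}{i + 1:04d}" for i in range(n)]
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
        a1 = [_ALLELE_PAIRS[j][0] for j in pair_idx]
        a2 = [_ALLELE_PAIRS[j][1] for j in pair_idx]

        for i in range(n):
            common = dict(id=ids[i], chrom="chr1", pos=int(pos[i]), a1=a1[i], a2=a2[i],
                          maf=locus.maf[i], info=1.0)
            rows1.append(dict(common, beta=locus.beta1[i], se=locus.se1[i], p=locus.p1[i],
                              n_eff=neff_from_counts(spec.n_cases1, spec.n_controls1)))
            rows2.append(dict(common, beta=locus.beta2[i], se=locus.se2[i], p=locus.p2[i],
                              n_eff=neff_from_counts(spec.n_cases2, spec.n_controls2)))

        # Block covering the locus with margin; loci are spaced far enough
        # apart that blocks never overlap.
        margin = pos_step // 2
        block_rows.append(("chr1", max(0, int(pos[0]) - 1 - margin), int(pos[-1]) + margin))

        # Pairwise r2 = (AR(1) correlation)^2 above the emission floor.
        max_lag = int(np.ceil(np.log(np.sqrt(max(r2_emit_min, 1e-12)))
                              / np.log(spec.rho))) if spec.rho > 0 else 0
        for i in range(n):
            for j in range(i + 1, min(i + max_lag + 1, n)):
                r2 = locus.R[i, j] ** 2
                if r2 > r2_emit_min:
                    proxy_rows.append((ids[i], ids[j], float(r2), "SYN"))

        truth_rows.append(
            dict(locus=k, config=spec.config,
                 causal_index1=locus.causal_index1, causal_index2=locus.causal_index2,
                 causal_id1=ids[locus.causal_index1] if locus.causal_index1 is not None else None,
                 causal_id2=ids[locus.causal_index2] if locus.causal_index2 is not None else None)
        )

    def table(rows, spec0_counts, trait):
        df = pd.DataFrame(rows)[["id", "chrom", "pos", "a1", "a2", "beta", "se", "p",
                                 "maf", "info", "n_eff"]]
        meta = StudyMeta(trait_name=trait, n_cases=spec0_counts[0], n_controls=spec0_counts[1])
        return SumStatsTable(df=df, meta=meta)

    if withhold1:
        rows1 = [r for r in rows1 if r["id"] not in withhold1]
    if withhold2:
        rows2 = [r for r in rows2 if r["id"] not in withhold2]
    t1 = table(rows1, (specs[0].n_cases1, specs[0].n_controls1), trait1)
    t2 = table(rows2, (specs[0].n_cases2, specs[0].n_controls2), trait2)

    def call_leads(tbl, trait):
        df = tbl.df
        lead_rows = []
        for k in range(len(specs)):
            in_locus = df["id"].str.startswith(f"rs{k + 1:03d}")
            sub = df.loc[in_locus & (df["p"] < GENOME_WIDE_SIG)]
            if len(sub):
                best = sub.loc[sub["p"].idxmin()]
                lead_rows.append(dict(id=best["id"], chrom=best["chrom"], pos=int(best["pos"]),
                                      a1=best["a1"], a2=best["a2"], locus=k))
        from .gatekeeper import LeadVariantSet  # local import to avoid a cycle

        cols = ["id", "chrom", "pos", "a1", "a2", "locus"]
        df_leads = pd.DataFrame(lead_rows, columns=cols)
        return LeadVariantSet(trait=trait, df=df_leads).df

    leads1 = call_leads(t1, trait1)
    leads2 = call_leads(t2, trait2)

    proxies = LDProxyTable(pd.DataFrame(proxy_rows,
                                        columns=["variant_a", "variant_b", "r2", "population"]))
    blocks = LDBlockSet(pd.DataFrame(block_rows, columns=["chrom", "start", "end"]))
    truth = pd.DataFrame(truth_rows)
    return FixtureBundle(sumstats1=t1, sumstats2=t2, leads1=leads1, leads2=leads2,
                         proxies=proxies, blocks=blocks, truth=truth, loci=loci)


def write_fixture_bundle(
    specs: Sequence[LocusSpec],
    out_dir: str | Path,
    seed: int | np.random.Generator = 0,
    trait1: str = "trait1",
    trait2: str = "trait2",
    withhold_from_trait1: Sequence[str] = (),
    withhold_from_trait2: Sequence[str] = (),
    locus_spacing: int = 1_000_000,
    pos_step: int = 1_000,
    r2_emit_min: float = 0.5,
) -> FixtureBundle:
    """Simulate all loci and write the full pipeline input set to disk.

    Emits per-trait summary statistics and lead lists, an LD proxy table
    (r² derived from the simulated correlation matrix), a block BED, and a
    ground-truth TSV.  Lead lists hold each trait's per-locus minimum-p
    variant among genome-wide significant variants (p < 5e-8).

    ``withhold_from_trait1``/``2`` remove the named variant ids from that
    trait's emitted summary statistics before lead calling (the other
    trait's lead list can still nominate them), which forces the
    gatekeeper's LD-proxy rescue path and lets it be tested end to end.
    """
    if not specs:
        raise ValueError("at least one locus spec is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    bundle = _build_tables(specs, rng, trait1, trait2, locus_spacing, pos_step, r2_emit_min,
                           set(withhold_from_trait1), set(withhold_from_trait2))

    from .sumstats import write_sumstats

    paths = {
        "sumstats1": out_dir / f"{trait1}.sumstats.tsv",
        "sumstats2": out_dir / f"{trait2}.sumstats.tsv",
        "leads1": out_dir / f"{trait1}.leads.tsv",
        "leads2": out_dir / f"{trait2}.leads.tsv",
        "proxies": out_dir / "proxies.tsv",
        "blocks": out_dir / "blocks.bed",
        "truth": out_dir / "truth.tsv",
    }
    write_sumstats(bundle.sumstats1, paths["sumstats1"])
    write_sumstats(bundle.sumstats2, paths["sumstats2"])
    bundle.leads1.to_csv(paths["leads1"], sep="\t", index=False)
    bundle.leads2.to_csv(paths["leads2"], sep="\t", index=False)
    bundle.proxies.to_tsv(paths["proxies"])
    bundle.blocks.to_bed(paths["blocks"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    bundle.paths = {k: str(v) for k, v in paths.items()}
    return bundle
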