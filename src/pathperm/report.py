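"""Stratified orchestration and table rendering.

Runs the full chain — cohort association, meta-analysis, LD feature
decomposition, architecture-matched permutation — across analysis strata
(gender crossed with outcome), applies the X-chromosome exclusion rule,
and renders the two headline tables: the per-stratum pathway table and
the per-gene table for a chosen gender, plus the nominally significant
SNP appendix.

Display conventions for permuted p-values: an empirical p of zero is
printed as ``<1/n_perm`` (``<0.001`` at 1,000 permutations) and values
above 0.99 print as ``>0.99``; everything else uses three significant
figures. Machine-readable output keeps full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import association, ld, meta, permutation
from .synthetic import ReferencePanel, StudyData
from .types import (
    FeatureSet,
    GeneAnnotation,
    LdBlock,
    PathwayDefinition,
    PermutationResult,
    StratumSpec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "apply_stratum",
    "bonferroni_threshold",
    "format_permuted_p",
    "stratum_pvalues",
    "AnalysisContext",
    "AnalysisReport",
    "analyze_stratum",
    "run_analysis",
    "render_table1",
    "render_table2",
    "nominal_snp_appendix",
    "DEFAULT_STRATA",
]

#: The nine strata of the headline pathway table.
DEFAULT_STRATA: Tuple[StratumSpec, ...] = tuple(
    StratumSpec(gender=g, outcome=o)
    for o in ("overall", "hpg", "npg")
    for g in ("all", "male", "female")
)


def apply_stratum(data: StudyData, spec: StratumSpec) -> StudyData:
    """Filter a cohort to one analysis stratum.

    Subjects are filtered by gender and, for the HPG/NPG outcomes, cases
    are restricted by IOP at diagnosis (HPG keeps IOP >= 22 mmHg, NPG
    IOP < 22); cases without a recorded IOP are excluded from the
    pressure-defined outcomes but retained in ``overall``. Controls are
    always retained. In male-only and combined strata, X-linked SNPs are
    removed from the data entirely (they are analysed only among women).
    """
    keep = np.ones(data.n_subjects, dtype=bool)
    if spec.gender != "all":
        keep &= data.sex == spec.gender
    if spec.outcome != "overall":
        classified = np.isfinite(data.iop)
        if spec.outcome == "hpg":
            case_ok = classified & (data.iop >= spec.iop_cut)
        else:
            case_ok = classified & (data.iop < spec.iop_cut)
        keep &= np.where(data.status, case_ok, True)
    out = data.filter_subjects(keep)
    if out.n_cases == 0 or out.n_controls == 0:
        raise ValueError(
            f"stratum '{spec.label}' is empty in cohort {data.name} "
            f"({out.n_cases} cases / {out.n_controls} controls)"
        )
    if not spec.includes_x:
        x_mask = np.array([s.chrom == "X" for s in out.snps])
        if x_mask.any():
            out = out.drop_snps(x_mask)
    return out


def bonferroni_threshold(n_snps: int, n_strata: int, alpha: float = 0.05) -> float:
    """Multiple-testing threshold alpha / (n_snps * n_strata), rounded to
    three significant figures."""
    if n_snps < 1 or n_strata < 1:
        raise ValueError("counts must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    raw = alpha / (n_snps * n_strata)
    return float(f"{raw:.3g}")


def format_permuted_p(p: float, n_perm: int = 1000) -> str:
    """Render an empirical p-value with the conventional display rules."""
    if not np.isfinite(p):
        return "NA"
    if p == 0.0:
        return f"<{1.0 / n_perm:g}"
    if p > 0.99:
        return ">0.99"
    return f"{p:.3g}"


# ---------------------------------------------------------------------------
# pipeline plumbing


def stratum_pvalues(
    studies: Sequence[StudyData],
    spec: StratumSpec,
    method: str = "logistic",
    meta_method: str = "ivw",
) -> Tuple[Dict[str, float], pd.DataFrame, Tuple[int, int]]:
    """Meta-analysed per-SNP p-values for one stratum.

    Each cohort is filtered to the stratum, scanned with the chosen
    association method, and the per-study tables are combined with the
    fixed-effect meta-analysis (intersection semantics). A single cohort
    passes through unchanged. Returns the SNP -> p mapping, the combined
    table, and the stratum's pooled (cases, controls) counts.
    """
    filtered = [apply_stratum(s, spec) for s in studies]
    tables = [association.scan_study(s, method=method) for s in filtered]
    if method == "trend" and len(tables) > 1:
        raise ValueError("the trend screen has no effect sizes to meta-analyse; "
                         "use 'logistic' or 'allelic' with multiple cohorts")
    if len(tables) == 1:
        combined = tables[0][np.isfinite(tables[0]["P"])].copy()
        combined["NSTUDIES"] = 1
    else:
        combined = meta.combine_studies(tables, method=meta_method)
    pvals = dict(zip(combined["SNP"], combined["P"].astype(float)))
    n_cases = sum(s.n_cases for s in filtered)
    n_controls = sum(s.n_controls for s in filtered)
    return pvals, combined, (n_cases, n_controls)


@dataclass
class AnalysisContext:
    """Everything fixed across strata: the panel, its LD blocks, the
    annotations and the pathway definition."""

    panel: ReferencePanel
    blocks: List[LdBlock]
    annotations: List[GeneAnnotation]
    pathway: PathwayDefinition

    @property
    def pathway_genes(self) -> List[GeneAnnotation]:
        by_symbol = {g.symbol: g for g in self.annotations}
        missing = [s for s in self.pathway.genes if s not in by_symbol]
        if missing:
            raise ValueError(f"pathway genes not annotated: {missing}")
        return [by_symbol[s] for s in self.pathway.genes]

    def features_for(self, spec: StratumSpec) -> Tuple[FeatureSet, Dict[str, FeatureSet]]:
        """Pathway- and gene-level feature sets under the stratum's
        X-inclusion rule."""
        snps = self.panel.snps
        if not spec.includes_x:
            snps = [s for s in snps if s.chrom != "X"]
        pw = ld.pathway_feature_set(
            snps, self.pathway_genes, self.blocks,
            name=self.pathway.name, flank=self.pathway.flank,
        )
        genes = ld.gene_feature_sets(
            snps, self.pathway_genes, self.blocks, flank=self.pathway.flank
        )
        return pw, genes

    def pool_for(
        self,
        spec: StratumSpec,
        pathway_features: FeatureSet,
        exclude_self: bool = False,
    ) -> permutation.GenomeFeaturePool:
        """Genome-wide pool under the stratum's X rule.

        The tested pathway's features stay in the pool unless
        ``exclude_self`` is set (see :class:`GenomeFeaturePool`).
        """
        return permutation.GenomeFeaturePool.build(
            self.panel.snps,
            self.blocks,
            exclude_snps=pathway_features.snps if exclude_self else (),
            include_x=spec.includes_x,
        )


@dataclass
class StratumResult:
    spec: StratumSpec
    n_cases: int
    n_controls: int
    pathway: PermutationResult
    genes: Dict[str, PermutationResult]
    snp_table: pd.DataFrame
    #: per gene: (chromosome, n simple features, n complex features)
    gene_shapes: Dict[str, Tuple[str, int, int]] = field(default_factory=dict)
    mean_age_cases: float = float("nan")
    mean_age_controls: float = float("nan")


@dataclass
class AnalysisReport:
    """Full stratified analysis: one StratumResult per stratum plus the
    multiple-testing threshold for the per-SNP appendix."""

    strata: List[StratumResult]
    n_pathway_snps: int
    bonferroni: float
    n_perm: int

    def result_for(self, gender: str, outcome: str) -> StratumResult:
        for r in self.strata:
            if r.spec.gender == gender and r.spec.outcome == outcome:
                return r
        raise KeyError(f"no stratum {gender}/{outcome}")


def analyze_stratum(
    ctx: AnalysisContext,
    studies: Sequence[StudyData],
    spec: StratumSpec,
    method: str = "logistic",
    meta_method: str = "ivw",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    estimator: str = "plugin",
    with_genes: bool = True,
) -> StratumResult:
    """Run the complete chain for one stratum."""
    pvals, _, (n_cases, n_controls) = stratum_pvalues(
        studies, spec, method=method, meta_method=meta_method
    )
    pw_features, gene_features = ctx.features_for(spec)
    pool = ctx.pool_for(spec, pw_features)
    pw_res = permutation.permutation_test(
        pw_features, pvals, pool, n_perm=n_perm, alpha=alpha, seed=seed,
        estimator=estimator,
    )
    if with_genes:
        gene_res, snp_table = permutation.investigate(
            gene_features, pvals, pool, n_perm=n_perm, alpha=alpha,
            seed=seed, estimator=estimator,
        )
    else:
        gene_res, snp_table = {}, pd.DataFrame(columns=["GENE", "SNP", "P"])

    chrom_of = {g.symbol: g.chrom for g in ctx.pathway_genes}
    gene_shapes = {
        name: (chrom_of[name], fs.n_simple, fs.n_complex)
        for name, fs in gene_features.items()
    }
    filtered = [apply_stratum(s, spec) for s in studies]
    age_cases = np.concatenate([s.age[s.status] for s in filtered])
    age_controls = np.concatenate([s.age[~s.status] for s in filtered])
    return StratumResult(
        spec=spec,
        n_cases=n_cases,
        n_controls=n_controls,
        pathway=pw_res,
        genes=gene_res,
        snp_table=snp_table,
        gene_shapes=gene_shapes,
        mean_age_cases=float(age_cases.mean()),
        mean_age_controls=float(age_controls.mean()),
    )


def run_analysis(
    ctx: AnalysisContext,
    studies: Sequence[StudyData],
    strata: Sequence[StratumSpec] = DEFAULT_STRATA,
    method: str = "logistic",
    meta_method: str = "ivw",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    estimator: str = "plugin",
    n_strata_bonferroni: int = 3,
) -> AnalysisReport:
    """Run every stratum and assemble the report.

    ``n_strata_bonferroni`` is the stratification multiplier applied to
    the per-SNP Bonferroni threshold alongside the pathway SNP count.
    """
    results = []
    for i, spec in enumerate(strata):
        sub_seed = None if seed is None else seed + 1000 * i
        results.append(
            analyze_stratum(
                ctx, studies, spec, method=method, meta_method=meta_method,
                n_perm=n_perm, alpha=alpha, seed=sub_seed, estimator=estimator,
            )
        )
    pw_features, _ = ctx.features_for(StratumSpec(gender="female"))
    n_snps = len(pw_features.snps)
    return AnalysisReport(
        strata=results,
        n_pathway_snps=n_snps,
        bonferroni=bonferroni_threshold(n_snps, n_strata_bonferroni, alpha),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# rendering


def render_table1(report: AnalysisReport) -> pd.DataFrame:
    """Pathway significance by stratum (the headline table)."""
    rows = []
    for r in report.strata:
        rows.append(
            {
                "Stratum": r.spec.label,
                "Cases": r.n_cases,
                "Controls": r.n_controls,
                "Mean age (cases)": round(r.mean_age_cases, 2),
                "Mean age (controls)": round(r.mean_age_controls, 2),
                "Pathway p-value": format_permuted_p(r.pathway.p_value, report.n_perm),
            }
        )
    return pd.DataFrame(rows)


def render_table2(report: AnalysisReport, gender: str = "female") -> pd.DataFrame:
    """Per-gene significance for one gender across the three outcomes."""
    outcomes = ("overall", "hpg", "npg")
    present = {o: report.result_for(gender, o)
               for o in outcomes
               if any(r.spec.gender == gender and r.spec.outcome == o
                      for r in report.strata)}
    if not present:
        raise ValueError(f"no strata computed for gender {gender!r}")
    first = next(iter(present.values()))
    rows = []
    for gene in first.genes:
        chrom, n_simple, n_complex = first.gene_shapes.get(gene, ("?", 0, 0))
        row = {
            "Gene": gene,
            "Chr": chrom,
            "Simple features": n_simple,
            "Complex features": n_complex,
        }
        for o, label in zip(outcomes, ("POAG overall", "HPG", "NPG")):
            if o in present:
                gres = present[o].genes.get(gene)
                row[f"Gene p-value, {label}"] = (
                    format_permuted_p(gres.p_value, report.n_perm)
                    if gres is not None and gres.testable else "NA"
                )
        rows.append(row)
    return pd.DataFrame(rows)


def nominal_snp_appendix(
    report: AnalysisReport, alpha: float = 0.05, gender: str = "female"
) -> pd.DataFrame:
    """Nominally significant SNPs (p < alpha) per gene per outcome."""
    frames = []
    for r in report.strata:
        if r.spec.gender != gender:
            continue
        t = r.snp_table.copy()
        t = t[t["P"] < alpha]
        t["Outcome"] = r.spec.outcome
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["GENE", "SNP", "P", "Outcome"])
    return pd.concat(frames, ignore_index=True)
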