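"""Synthetic GWAS data with block-structured linkage disequilibrium.

The generator emulates the data a pathway permutation analysis consumes:
a reference panel of haplotypes organised in LD blocks, two case-control
cohorts drawn from the same population, gene annotations tiling the
SNP-bearing regions, and a multi-chromosome pathway (optionally including
X-linked genes).

LD within a block is induced by a haplotype-copying scheme: every
haplotype draws one latent block allele ``Z ~ Bernoulli(f)`` and each
member SNP copies ``Z``, flipping it with a probability ``eps`` chosen so
that the pairwise squared correlation between member SNPs equals the
configured target. The flip-rate/r-squared relation is closed form (see
:func:`flip_rate_for_r2`), which makes the generator directly testable.
SNPs in different blocks, and singleton SNPs, are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .types import GeneAnnotation, LdBlock, PathwayDefinition, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PanelConfig",
    "CohortConfig",
    "CausalEffect",
    "PathwaySpec",
    "ReferencePanel",
    "StudyData",
    "flip_rate_for_r2",
    "generate_reference_panel",
    "generate_cohort",
    "generate_annotations",
    "ESTROGEN_PATHWAY_GENES",
]

#: Canonical 23-gene estrogen-metabolism pathway (two X-linked members),
#: used when the requested pathway shape matches.
ESTROGEN_PATHWAY_GENES: Tuple[Tuple[str, bool], ...] = (
    ("HSD11B1", False), ("HSD3B1", False), ("CYP1B1", False),
    ("SULT1E1", False), ("UGT2B11", False), ("SRD5A1", False),
    ("ESR1", False), ("AKR1D1", False), ("CYP3A4", False),
    ("CYP11B1", False), ("HSD17B3", False), ("AKR1C4", False),
    ("CYP17A1", False), ("ESR2", False), ("CYP11A1", False),
    ("CYP19A1", False), ("CYP1A1", False), ("CYP1A2", False),
    ("HSD17B1", False), ("SULT2B1", False), ("COMT", False),
    ("ARSD", True), ("STS", True),
)


def flip_rate_for_r2(r2: float, f: float) -> float:
    """Flip probability giving pairwise squared correlation ``r2`` between
    two SNPs copied (with independent flips) from one Bernoulli(``f``)
    latent allele.

    The correlation between two such SNPs is

        r = (1-2e)^2 f(1-f) / [ (1-2e)^2 f(1-f) + e(1-e) ]

    monotone decreasing in the flip rate ``e`` on [0, 1/2]; the flip rate
    is the root of ``r(e) = sqrt(r2)``.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must be in [0, 1]")
    if not 0.0 < f < 1.0:
        raise ValueError("latent allele frequency must be in (0, 1)")
    if r2 >= 1.0 - 1e-12:
        return 0.0
    if r2 <= 1e-12:
        return 0.5

    target = np.sqrt(r2)
    v = f * (1.0 - f)

    def g(eps: float) -> float:
        a = (1.0 - 2.0 * eps) ** 2
        return a * v / (a * v + eps * (1.0 - eps)) - target

    return float(brentq(g, 0.0, 0.5 - 1e-12, xtol=1e-12))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PanelConfig:
    """Shape of the synthetic reference panel.

    The last chromosome is labelled ``X`` when ``include_x`` is set; all
    others are numbered autosomes. ``singleton_fraction`` is the fraction
    of SNPs lying outside any LD block; with ``singleton_fraction=1.0``
    no blocks are generated and every SNP is independent.
    """

    n_haplotypes: int = 1000
    n_chromosomes: int = 16
    blocks_per_chromosome: int = 12
    block_size_range: Tuple[int, int] = (2, 8)
    singleton_fraction: float = 0.5
    within_block_r2: float = 0.9
    maf_range: Tuple[float, float] = (0.05, 0.5)
    snp_spacing: int = 5_000
    include_x: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least two haplotypes")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.block_size_range[0] < 2 or self.block_size_range[0] > self.block_size_range[1]:
            raise ValueError("block_size_range must satisfy 2 <= min <= max")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.singleton_fraction < 1.0 and self.blocks_per_chromosome < 1:
            raise ValueError("blocks_per_chromosome must be >= 1 unless singleton_fraction is 1")

    @property
    def chromosomes(self) -> Tuple[str, ...]:
        auto = self.n_chromosomes - 1 if self.include_x else self.n_chromosomes
        labels = [str(i + 1) for i in range(auto)]
        if self.include_x:
            labels.append("X")
        return tuple(labels)


@dataclass(frozen=True)
class CausalEffect:
    """A causal SNP with a per-dosage log odds ratio, optionally acting in
    one gender stratum only."""

    snp: str
    beta: float
    sex: str = "all"  # all | female | male

    def __post_init__(self) -> None:
        if self.sex not in ("all", "female", "male"):
            raise ValueError(f"unknown sex restriction {self.sex!r}")


@dataclass(frozen=True)
class CohortConfig:
    """A case-control cohort drawn from the panel's population.

    Disease status follows a logistic model on causal-SNP dosages and
    covariates; subjects are sampled conditional on status (rejection
    sampling) so realized case/control counts match exactly. Cases carry
    an IOP-at-diagnosis value (mmHg), missing for a configurable fraction.
    """

    name: str = "cohort"
    n_cases: int = 500
    n_controls: int = 500
    causal: Tuple[CausalEffect, ...] = ()
    baseline_logit: float = -0.5
    female_fraction: float = 0.55
    age_effect: float = 0.3
    sex_effect: float = 0.0
    n_sites: int = 3
    site_effects: Optional[Tuple[float, ...]] = None
    iop_mean: float = 24.0
    iop_sd: float = 4.0
    iop_missing_fraction: float = 0.24
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.site_effects is not None and len(self.site_effects) != self.n_sites:
            raise ValueError("site_effects length must equal n_sites")


@dataclass(frozen=True)
class PathwaySpec:
    """Requested shape of the designated pathway."""

    name: str = "estrogen_metabolism"
    n_genes: int = 23
    n_x_genes: int = 2
    flank: int = 50_000
    snps_per_gene: Tuple[int, int] = (10, 30)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_x_genes < 0 or self.n_x_genes > self.n_genes:
            raise ValueError("invalid gene counts")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValueError("invalid snps_per_gene range")


# ---------------------------------------------------------------------------
# panel


@dataclass
class ReferencePanel:
    """Reference haplotypes plus the generative parameters that produced
    them, so that cohort genotypes can be drawn from the same population."""

    config: PanelConfig
    snps: List[SnpRecord]
    haplotypes: np.ndarray  # (n_haplotypes, n_snps) int8
    blocks_truth: List[LdBlock]
    # generative parameters, aligned with `snps`
    block_of_snp: np.ndarray  # int, -1 for singletons
    snp_eps: np.ndarray  # flip rate per SNP (0 for singletons)
    snp_f: np.ndarray  # latent allele frequency per SNP
    block_f: np.ndarray  # latent frequency per block

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> List[str]:
        return [s.id for s in self.snps]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps])

    @property
    def chromosome_of(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    @property
    def x_mask(self) -> np.ndarray:
        return self.chromosome_of == "X"

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s.id: i for i, s in enumerate(self.snps)}
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def draw_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Fresh haplotypes from the panel's generative process."""
        out = np.empty((n, self.n_snps), dtype=np.int8)
        singles = self.block_of_snp < 0
        if singles.any():
            out[:, singles] = (
                rng.random((n, int(singles.sum()))) < self.snp_f[singles]
            ).astype(np.int8)
        for b in range(len(self.block_f)):
            cols = np.where(self.block_of_snp == b)[0]
            z = (rng.random((n, 1)) < self.block_f[b]).astype(np.int8)
            flips = rng.random((n, cols.size)) < self.snp_eps[cols]
            out[:, cols] = z ^ flips
        return out

    def draw_genotypes(
        self,
        n: int,
        rng: np.random.Generator,
        is_male: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Diploid dosages for ``n`` fresh subjects.

        Male X genotypes are hemizygous, coded 0/2 (single haplotype,
        dosage doubled); autosomes and female X are sums of two
        independent haplotypes.
        """
        h1 = self.draw_haplotypes(n, rng)
        h2 = self.draw_haplotypes(n, rng)
        geno = (h1 + h2).astype(np.int8)
        if is_male is not None and is_male.any():
            xcols = np.where(self.x_mask)[0]
            if xcols.size:
                males = np.where(is_male)[0]
                geno[np.ix_(males, xcols)] = 2 * h1[np.ix_(males, xcols)]
        return geno


def generate_reference_panel(config: PanelConfig) -> ReferencePanel:
    """Build a reference panel with ground-truth LD blocks.

    Returns the panel including block membership so downstream block
    finders can be checked against the truth.
    """
    rng = np.random.default_rng(config.seed)
    lo_maf, hi_maf = config.maf_range
    lo_b, hi_b = config.block_size_range

    snps: List[SnpRecord] = []
    blocks: List[LdBlock] = []
    block_of: List[int] = []
    eps_of: List[float] = []
    f_of: List[float] = []
    block_f: List[float] = []
    columns: List[np.ndarray] = []  # haplotype columns per SNP
    n_hap = config.n_haplotypes
    alleles = np.array(list("ACGT"))

    for chrom in config.chromosomes:
        if config.singleton_fraction >= 1.0:
            sizes: List[int] = []
        else:
            sizes = list(rng.integers(lo_b, hi_b + 1, size=config.blocks_per_chromosome))
        n_block_snps = int(sum(sizes))
        s = config.singleton_fraction
        if s >= 1.0:
            # no blocks: emit the same expected SNP volume as singletons
            n_singletons = config.blocks_per_chromosome * (lo_b + hi_b) // 2
        elif n_block_snps == 0:
            n_singletons = 0
        else:
            n_singletons = int(round(s / (1.0 - s) * n_block_snps)) if s > 0 else 0

        # lay out units (blocks and singletons) in random order along the
        # chromosome; positions are evenly spaced
        units: List[Tuple[str, int]] = [("block", k) for k in sizes]
        units += [("single", 1)] * n_singletons
        rng.shuffle(units)

        pos = 0
        idx_on_chrom = 0
        for kind, k in units:
            if kind == "block":
                f = float(rng.uniform(lo_maf, hi_maf))
                eps = flip_rate_for_r2(config.within_block_r2, f)
                z = (rng.random(n_hap) < f).astype(np.int8)
                member_ids: List[str] = []
                first_pos = pos + config.snp_spacing
                for _ in range(k):
                    pos += config.snp_spacing
                    idx_on_chrom += 1
                    flips = rng.random(n_hap) < eps
                    col = z ^ flips
                    sid = f"snp_{chrom}_{idx_on_chrom:05d}"
                    ref, alt = rng.choice(alleles, size=2, replace=False)
                    snps.append(
                        SnpRecord(sid, chrom, pos, str(ref), str(alt), float(col.mean()))
                    )
                    columns.append(col.astype(np.int8))
                    block_of.append(len(block_f))
                    eps_of.append(eps)
                    f_of.append(f)
                    member_ids.append(sid)
                blocks.append(LdBlock(chrom, tuple(member_ids), first_pos, pos))
                block_f.append(f)
            else:
                pos += config.snp_spacing
                idx_on_chrom += 1
                f = float(rng.uniform(lo_maf, hi_maf))
                col = (rng.random(n_hap) < f).astype(np.int8)
                sid = f"snp_{chrom}_{idx_on_chrom:05d}"
                ref, alt = rng.choice(alleles, size=2, replace=False)
                snps.append(SnpRecord(sid, chrom, pos, str(ref), str(alt), float(col.mean())))
                columns.append(col)
                block_of.append(-1)
                eps_of.append(0.0)
                f_of.append(f)

    if not snps:
        raise ValueError("configuration produced zero SNPs")

    return ReferencePanel(
        config=config,
        snps=snps,
        haplotypes=np.column_stack(columns).astype(np.int8),
        blocks_truth=blocks,
        block_of_snp=np.array(block_of, dtype=int),
        snp_eps=np.array(eps_of),
        snp_f=np.array(f_of),
        block_f=np.array(block_f),
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class StudyData:
    """One cohort: genotypes, phenotype, covariates and stratum labels."""

    name: str
    snps: List[SnpRecord]
    genotypes: np.ndarray  # (n_subjects, n_snps) int8
    status: np.ndarray  # bool, True = case
    sex: np.ndarray  # "female" / "male"
    age: np.ndarray  # standardized
    site: np.ndarray  # int labels
    iop: np.ndarray  # mmHg for classified cases, nan otherwise

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.status).sum())

    @property
    def snp_ids(self) -> List[str]:
        return [s.id for s in self.snps]

    def filter_subjects(self, mask: np.ndarray) -> "StudyData":
        return StudyData(
            name=self.name,
            snps=self.snps,
            genotypes=self.genotypes[mask],
            status=self.status[mask],
            sex=self.sex[mask],
            age=self.age[mask],
            site=self.site[mask],
            iop=self.iop[mask],
        )

    def drop_snps(self, drop_mask: np.ndarray) -> "StudyData":
        keep = ~np.asarray(drop_mask, dtype=bool)
        return StudyData(
            name=self.name,
            snps=[s for s, k in zip(self.snps, keep) if k],
            genotypes=self.genotypes[:, keep],
            status=self.status,
            sex=self.sex,
            age=self.age,
            site=self.site,
            iop=self.iop,
        )

    def covariate_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.age, "site": self.site, "sex": self.sex})


def generate_cohort(panel: ReferencePanel, config: CohortConfig) -> StudyData:
    """Draw a case-control cohort from the panel's population.

    Candidate subjects are generated in batches; status is drawn from the
    logistic disease model and subjects are kept conditional on status
    until both quotas are filled.
    """
    known = set(panel.snp_ids)
    for eff in config.causal:
        if eff.snp not in known:
            raise ValueError(f"causal SNP {eff.snp!r} not in panel")
    causal_idx = panel.index_of([e.snp for e in config.causal])
    causal_beta = np.array([e.beta for e in config.causal])
    causal_sex = np.array([e.sex for e in config.causal])

    rng = np.random.default_rng(config.seed)
    site_eff = (
        np.asarray(config.site_effects)
        if config.site_effects is not None
        else np.zeros(config.n_sites)
    )

    need_cases, need_controls = config.n_cases, config.n_controls
    kept: List[Tuple[np.ndarray, ...]] = []
    got_cases = got_controls = 0
    stalled_batches = 0
    batch = max(1000, int(1.5 * (need_cases + need_controls)))

    while got_cases < need_cases or got_controls < need_controls:
        is_male = rng.random(batch) >= config.female_fraction
        geno = panel.draw_genotypes(batch, rng, is_male=is_male)
        age = rng.standard_normal(batch)
        site = rng.integers(0, config.n_sites, size=batch)

        logit = np.full(batch, config.baseline_logit)
        if causal_idx.size:
            dose = geno[:, causal_idx].astype(float)
            active = np.ones((batch, causal_idx.size), dtype=bool)
            active[:, causal_sex == "female"] &= ~is_male[:, None]
            active[:, causal_sex == "male"] &= is_male[:, None]
            logit += (dose * causal_beta * active).sum(axis=1)
        logit += config.age_effect * age
        logit += config.sex_effect * is_male
        logit += site_eff[site]

        status = rng.random(batch) < expit(logit)
        n_new_cases = int(status.sum())
        n_new_controls = batch - n_new_cases
        if (got_cases < need_cases and n_new_cases == 0) or (
            got_controls < need_controls and n_new_controls == 0
        ):
            stalled_batches += 1
            if stalled_batches >= 20:
                raise RuntimeError(
                    f"{config.name}: requested case/control counts are infeasible "
                    "under the disease model (acceptance probability ~ 0)"
                )
            continue

        case_keep = np.where(status)[0][: need_cases - got_cases]
        ctrl_keep = np.where(~status)[0][: need_controls - got_controls]
        keep = np.sort(np.concatenate([case_keep, ctrl_keep]))
        kept.append((geno[keep], status[keep], is_male[keep], age[keep], site[keep]))
        got_cases += case_keep.size
        got_controls += ctrl_keep.size

    geno = np.concatenate([k[0] for k in kept])
    status = np.concatenate([k[1] for k in kept])
    is_male = np.concatenate([k[2] for k in kept])
    age = np.concatenate([k[3] for k in kept])
    site = np.concatenate([k[4] for k in kept])

    iop = np.full(geno.shape[0], np.nan)
    case_idx = np.where(status)[0]
    measured = rng.random(case_idx.size) >= config.iop_missing_fraction
    vals = rng.normal(config.iop_mean, config.iop_sd, size=case_idx.size)
    iop[case_idx[measured]] = np.clip(vals[measured], 8.0, None)

    sex = np.where(is_male, "male", "female")
    return StudyData(
        name=config.name,
        snps=panel.snps,
        genotypes=geno,
        status=status.astype(bool),
        sex=sex,
        age=age,
        site=site,
        iop=iop,
    )


# ---------------------------------------------------------------------------
# annotations and pathway


def generate_annotations(
    panel: ReferencePanel,
    n_genes: Optional[int] = None,
    pathway_spec: Optional[PathwaySpec] = None,
    seed: Optional[int] = None,
) -> Tuple[List[GeneAnnotation], PathwayDefinition]:
    """Tile genes over the panel's SNP-bearing regions and designate a
    pathway.

    Each gene's transcript span is anchored on a contiguous run of
    genotyped SNPs, so every pathway gene window is guaranteed to contain
    at least one SNP. When the requested shape matches the default
    23-gene / 2-X estrogen-metabolism pathway, the canonical gene symbols
    are used; otherwise genes are named ``GENE001``...
    """
    spec = pathway_spec or PathwaySpec()
    n_genes = n_genes if n_genes is not None else spec.n_genes
    if n_genes < spec.n_genes:
        raise ValueError("n_genes smaller than the pathway's gene count")
    rng = np.random.default_rng(seed)

    chroms = list(panel.config.chromosomes)
    autosomes = [c for c in chroms if c != "X"]
    has_x = "X" in chroms
    if spec.n_x_genes > 0 and not has_x:
        raise ValueError("pathway requests X-linked genes but panel has no X")

    if spec.n_genes == len(ESTROGEN_PATHWAY_GENES) and spec.n_x_genes == 2:
        symbols = [g for g, on_x in ESTROGEN_PATHWAY_GENES if not on_x]
        x_symbols = [g for g, on_x in ESTROGEN_PATHWAY_GENES if on_x]
    else:
        n_auto = spec.n_genes - spec.n_x_genes
        symbols = [f"GENE{i + 1:03d}" for i in range(n_auto)]
        x_symbols = [f"GENEX{i + 1:02d}" for i in range(spec.n_x_genes)]

    pos = panel.positions
    chrom_of = panel.chromosome_of
    lo, hi = spec.snps_per_gene
    used: dict = {c: [] for c in chroms}  # claimed index ranges per chromosome

    def place_gene(symbol: str, chrom: str) -> GeneAnnotation:
        idx = np.where(chrom_of == chrom)[0]
        if idx.size == 0:
            raise ValueError(f"chromosome {chrom} carries no SNPs")
        k = int(rng.integers(lo, min(hi, idx.size) + 1))
        for _ in range(200):
            start_i = int(rng.integers(0, idx.size - k + 1))
            lo_i, hi_i = start_i, start_i + k - 1
            # keep runs disjoint so gene spans do not nest
            if all(hi_i < a or lo_i > b for a, b in used[chrom]):
                break
        used[chrom].append((lo_i, hi_i))
        return GeneAnnotation(
            symbol=symbol,
            chrom=chrom,
            start=int(pos[idx[lo_i]]),
            end=int(pos[idx[hi_i]]),
        )

    annotations: List[GeneAnnotation] = []
    # spread autosomal pathway genes over distinct autosomes where possible
    order = rng.permutation(len(autosomes))
    for i, symbol in enumerate(symbols):
        chrom = autosomes[order[i % len(autosomes)]]
        annotations.append(place_gene(symbol, chrom))
    for symbol in x_symbols:
        annotations.append(place_gene(symbol, "X"))
    for j in range(n_genes - spec.n_genes):
        chrom = autosomes[int(rng.integers(0, len(autosomes)))]
        annotations.append(place_gene(f"BG{j + 1:04d}", chrom))

    pathway = PathwayDefinition(
        name=spec.name,
        genes=tuple(symbols + x_symbols),
        flank=spec.flank,
    )
    return annotations, pathway
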