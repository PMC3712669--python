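"""LD-block estimation and feature decomposition.

A gene or pathway is decomposed into *features*: LD blocks contributing
two or more mapped SNPs become complex features, every other mapped SNP
is a simple feature. Blocks are found by a greedy contiguous r-squared
agglomeration: walking the chromosome in position order, a SNP joins the
current block while its squared dosage correlation with at least one
block member reaches the threshold (default 0.8); blocks of size >= 2
are emitted, everything else is a singleton. The procedure is
deterministic and independent of input ordering beyond the positional
sort.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .synthetic import ReferencePanel
from .types import FeatureSet, GeneAnnotation, LdBlock, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_r2",
    "build_blocks",
    "panel_blocks",
    "map_snps_to_gene",
    "decompose",
    "gene_feature_sets",
    "pathway_feature_set",
]


def pairwise_r2(
    genotypes: np.ndarray,
    positions: Optional[np.ndarray] = None,
    max_distance: Optional[int] = None,
) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    Returns a symmetric matrix with unit diagonal. Monomorphic columns
    have undefined correlation; their entries are set to 0 (diagonal
    included) and a count is logged. With ``positions`` and
    ``max_distance`` set, pairs farther apart than the window are zeroed,
    giving a banded (sparse) map.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two SNPs")
    sd = g.std(axis=0)
    mono = sd == 0
    if mono.any():
        logger.info("pairwise_r2: %d monomorphic SNP(s); r2 set to 0", int(mono.sum()))
    centered = g - g.mean(axis=0)
    denom = np.where(mono, 1.0, sd) * np.sqrt(g.shape[0])
    z = centered / denom
    r2 = (z.T @ z) ** 2
    r2[mono, :] = 0.0
    r2[:, mono] = 0.0
    np.fill_diagonal(r2, np.where(mono, 0.0, 1.0))
    if positions is not None and max_distance is not None:
        dist = np.abs(positions[:, None] - positions[None, :])
        r2[dist > max_distance] = 0.0
    return r2


def build_blocks(
    r2: np.ndarray,
    snps: Sequence[SnpRecord],
    threshold: float = 0.8,
    max_span: Optional[int] = None,
) -> List[LdBlock]:
    """Greedy contiguous LD-block construction on one chromosome.

    ``snps`` must be position-sorted and ``r2`` aligned with them. A SNP
    extends the current block when its r-squared with any current member
    reaches ``threshold`` (and, if ``max_span`` is set, the block's
    genomic span stays within it). Blocks with >= 2 members are emitted;
    the rest remain singletons.
    """
    n = len(snps)
    if n == 0:
        return []
    if r2.shape != (n, n):
        raise ValueError("r2 matrix does not match the SNP list")
    pos = [s.pos for s in snps]
    if any(pos[i] > pos[i + 1] for i in range(n - 1)):
        raise ValueError("SNPs must be sorted by position")
    chroms = {s.chrom for s in snps}
    if len(chroms) > 1:
        raise ValueError("build_blocks operates on one chromosome at a time")

    blocks: List[LdBlock] = []
    current = [0]

    def flush() -> None:
        if len(current) >= 2:
            members = tuple(snps[i].id for i in current)
            blocks.append(
                LdBlock(snps[current[0]].chrom, members,
                        snps[current[0]].pos, snps[current[-1]].pos)
            )

    for i in range(1, n):
        linked = any(r2[i, j] >= threshold for j in current)
        within = max_span is None or (pos[i] - pos[current[0]]) <= max_span
        if linked and within:
            current.append(i)
        else:
            flush()
            current = [i]
    flush()
    return blocks


def panel_blocks(
    panel: ReferencePanel,
    threshold: float = 0.8,
    max_distance: Optional[int] = 250_000,
    max_span: Optional[int] = None,
) -> List[LdBlock]:
    """Estimate LD blocks genome-wide from a reference panel.

    Haplotypes are the correlation substrate; blocks are built per
    chromosome and concatenated in chromosome order.
    """
    blocks: List[LdBlock] = []
    chrom_of = panel.chromosome_of
    for chrom in panel.config.chromosomes:
        idx = np.where(chrom_of == chrom)[0]
        if idx.size < 2:
            continue
        sub_snps = [panel.snps[i] for i in idx]
        r2 = pairwise_r2(
            panel.haplotypes[:, idx],
            positions=np.array([s.pos for s in sub_snps]),
            max_distance=max_distance,
        )
        blocks.extend(build_blocks(r2, sub_snps, threshold=threshold, max_span=max_span))
    return blocks


def map_snps_to_gene(
    snps: Sequence[SnpRecord], gene: GeneAnnotation, flank: int = 50_000
) -> List[str]:
    """SNP ids falling in the gene's flanked window.

    A SNP maps iff it is on the gene's chromosome and its position lies
    in the closed interval [start - flank, end + flank]. A SNP may map to
    several overlapping genes.
    """
    lo, hi = gene.start - flank, gene.end + flank
    return [s.id for s in snps if s.chrom == gene.chrom and lo <= s.pos <= hi]


def decompose(
    mapped_snps: Sequence[str],
    blocks: Sequence[LdBlock],
    owner: str = "pathway",
) -> FeatureSet:
    """Split mapped SNPs into simple and complex features.

    The intersection of each LD block with the mapped set becomes a
    complex feature when it retains >= 2 SNPs; a block contributing a
    single mapped SNP demotes it to a simple feature, as are SNPs in no
    block. The result partitions the mapped SNPs exactly.
    """
    mapped = set(mapped_snps)
    order = {s: i for i, s in enumerate(mapped_snps)}
    complex_feats: List[Tuple[str, ...]] = []
    in_complex: Set[str] = set()
    for b in blocks:
        inter = [s for s in b.snps if s in mapped]
        if len(inter) >= 2:
            complex_feats.append(tuple(inter))
            in_complex.update(inter)
    simple = tuple(sorted(mapped - in_complex, key=lambda s: order[s]))
    return FeatureSet(owner=owner, simple=simple, complex=tuple(complex_feats))


def gene_feature_sets(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneAnnotation],
    blocks: Sequence[LdBlock],
    flank: int = 50_000,
) -> Dict[str, FeatureSet]:
    """Per-gene feature sets (SNPs shared by overlapping windows are
    counted in every gene that captures them)."""
    out: Dict[str, FeatureSet] = {}
    for gene in genes:
        mapped = map_snps_to_gene(snps, gene, flank=flank)
        if not mapped:
            logger.warning("gene %s: no SNPs in its flanked window", gene.symbol)
        out[gene.symbol] = decompose(mapped, blocks, owner=gene.symbol)
    return out


def pathway_feature_set(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneAnnotation],
    blocks: Sequence[LdBlock],
    name: str = "pathway",
    flank: int = 50_000,
) -> FeatureSet:
    """Pathway-level feature set: the union of the member genes' mapped
    SNPs (deduplicated) decomposed against the blocks."""
    seen: Set[str] = set()
    union: List[str] = []
    for gene in genes:
        for s in map_snps_to_gene(snps, gene, flank=flank):
            if s not in seen:
                seen.add(s)
                union.append(s)
    return decompose(union, blocks, owner=name)
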