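"""Fixed-effect meta-analysis of per-SNP summary statistics.

Two schemes are offered, mirroring the two classical modes of
summary-statistic meta-analysis software:

* inverse-variance weighting (the default): per-study log odds ratios are
  combined with weights 1/se^2, yielding a combined effect, standard
  error and normal p-value;
* sample-size-weighted z: per-study signed z-scores combined with
  sqrt(n) weights, yielding a direction-aware p-value only.

Allele harmonization flips a study's effect sign when its effect/other
alleles are swapped relative to the first study, accepts strand
complements, and drops irreconcilable SNPs with a log message.
Strand-ambiguous (A/T, C/G) SNPs are kept but reported through a warning
hook, since without frequency information their orientation cannot be
resolved.
"""

from __future__ import annotations

import logging
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssocResult, MetaResult

logger = logging.getLogger(__name__)

__all__ = [
    "inverse_variance_meta",
    "sample_size_weighted_z",
    "harmonize_effect",
    "combine_studies",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_P_FLOOR = 1e-300


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_effect(
    ref_a1: str,
    ref_a2: str,
    a1: str,
    a2: str,
    ambiguous_hook: Optional[Callable[[str, str], None]] = None,
) -> Optional[int]:
    """Orientation of one study's effect allele relative to a reference.

    Returns +1 (aligned), -1 (swapped: flip the effect sign) or ``None``
    when the allele pairs are irreconcilable. Strand complements are
    accepted; A/T and C/G pairs are intrinsically strand-ambiguous and are
    passed to ``ambiguous_hook`` when provided.
    """
    if _is_ambiguous(ref_a1, ref_a2) and ambiguous_hook is not None:
        ambiguous_hook(ref_a1, ref_a2)
    pairs = {(a1, a2): 1, (a2, a1): -1}
    c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if c1 and c2:
        pairs.setdefault((c1, c2), 1)
        pairs.setdefault((c2, c1), -1)
    return pairs.get((ref_a1, ref_a2))


def inverse_variance_meta(results: Sequence[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effect combination of one SNP's studies.

    Weights are 1/se_i^2; the combined estimate is the weighted mean of
    the per-study log odds ratios and the combined standard error is
    (sum of weights)^(-1/2). With a single study the input is passed
    through unchanged. Effect alleles must already be harmonized.
    """
    usable = [r for r in results if r.ok]
    if not usable:
        raise ValueError("no usable study results for this SNP")
    betas = np.array([r.beta for r in usable])
    ses = np.array([r.se for r in usable])
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR))
    return MetaResult(
        snp=usable[0].snp,
        beta=beta,
        se=se,
        p=p,
        weights=tuple(w),
        n_studies=len(usable),
        n=int(sum(r.n for r in usable)),
    )


def sample_size_weighted_z(results: Sequence[AssocResult]) -> MetaResult:
    """Sample-size-weighted z combination (direction-aware p only).

    Per-study z-scores are recovered from each p-value and the sign of
    the effect, then combined as sum(sqrt(n_i) z_i) / sqrt(sum n_i).
    """
    usable = [r for r in results if r.ok]
    if not usable:
        raise ValueError("no usable study results for this SNP")
    if any(r.n is None or r.n <= 0 for r in usable):
        raise ValueError("sample-size weighting requires per-study n")
    z = np.array(
        [np.sign(r.beta) * stats.norm.isf(r.p / 2.0) for r in usable]
    )
    n = np.array([r.n for r in usable], dtype=float)
    zc = float((np.sqrt(n) * z).sum() / np.sqrt(n.sum()))
    p = float(max(2.0 * stats.norm.sf(abs(zc)), _P_FLOOR))
    return MetaResult(
        snp=usable[0].snp,
        beta=None,
        se=None,
        p=p,
        weights=tuple(np.sqrt(n)),
        n_studies=len(usable),
        n=int(n.sum()),
    )


def combine_studies(
    tables: Sequence[pd.DataFrame],
    method: str = "ivw",
    intersection: bool = True,
    ambiguous_hook: Optional[Callable[[str, str], None]] = None,
) -> pd.DataFrame:
    """Meta-analyse per-study association tables (vectorized).

    ``tables`` are association summaries with columns SNP, CHR, BP, A1,
    A2, OR, SE, P, N. With ``intersection=True`` (the default, mirroring
    an overlapping-SNP combined set) only SNPs usable in every study are
    combined; otherwise SNPs usable in at least one study are kept.
    Rows whose alleles cannot be reconciled with the first study are
    dropped and logged.

    Returns a table with the same columns plus NSTUDIES.
    """
    if method not in ("ivw", "ssw"):
        raise ValueError(f"unknown meta method {method!r}")
    if not tables:
        raise ValueError("no study tables given")

    prepared = []
    for t in tables:
        t = t.copy()
        t["BETA"] = np.log(t["OR"].to_numpy(dtype=float))
        usable = np.isfinite(t["P"].to_numpy(dtype=float))
        if method == "ivw":
            usable &= np.isfinite(t["BETA"].to_numpy()) & (t["SE"].to_numpy(dtype=float) > 0)
        prepared.append(t[usable].set_index("SNP"))

    base = prepared[0]
    snps = base.index
    for t in prepared[1:]:
        snps = snps.intersection(t.index) if intersection else snps.union(t.index)
    snps = snps.sort_values()

    n_dropped = 0
    flips: List[np.ndarray] = []
    base_a1 = base.reindex(snps)["A1"].to_numpy(dtype=object)
    base_a2 = base.reindex(snps)["A2"].to_numpy(dtype=object)
    for t in prepared:
        sub = t.reindex(snps)
        # fast path: identical allele labels throughout (the common case
        # when studies were genotyped on one platform)
        if (
            np.array_equal(sub["A1"].to_numpy(dtype=object), base_a1)
            and np.array_equal(sub["A2"].to_numpy(dtype=object), base_a2)
        ):
            if ambiguous_hook is not None:
                for a1, a2 in zip(base_a1, base_a2):
                    if _is_ambiguous(str(a1), str(a2)):
                        ambiguous_hook(str(a1), str(a2))
            flips.append(np.ones(len(snps)))
            continue
        flip = np.ones(len(snps))
        present = sub["P"].notna().to_numpy()
        for i, snp in enumerate(snps):
            if not present[i]:
                flip[i] = np.nan
                continue
            orient = harmonize_effect(
                str(base["A1"].get(snp, sub["A1"].iloc[i])),
                str(base["A2"].get(snp, sub["A2"].iloc[i])),
                str(sub["A1"].iloc[i]),
                str(sub["A2"].iloc[i]),
                ambiguous_hook=ambiguous_hook,
            )
            if orient is None:
                flip[i] = np.nan
                n_dropped += 1
            else:
                flip[i] = orient
        flips.append(flip)
    if n_dropped:
        logger.warning("meta-analysis: dropped %d study rows with irreconcilable alleles", n_dropped)

    betas = np.stack([t.reindex(snps)["BETA"].to_numpy(dtype=float) * f
                      for t, f in zip(prepared, flips)])
    ses = np.stack([t.reindex(snps)["SE"].to_numpy(dtype=float) for t in prepared])
    ps = np.stack([t.reindex(snps)["P"].to_numpy(dtype=float) for t in prepared])
    ns = np.stack([t.reindex(snps)["N"].to_numpy(dtype=float) for t in prepared])

    valid = np.isfinite(ps) & np.isfinite(np.stack(flips))
    if method == "ivw":
        valid &= np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
        w = np.where(valid, 1.0 / ses**2, 0.0)
        wsum = w.sum(axis=0)
        beta_c = (w * np.nan_to_num(betas)).sum(axis=0) / wsum
        se_c = wsum**-0.5
        p_c = np.maximum(2.0 * stats.norm.sf(np.abs(beta_c / se_c)), _P_FLOOR)
    else:
        z = np.sign(np.nan_to_num(betas, nan=1.0)) * stats.norm.isf(
            np.where(valid, ps, 1.0) / 2.0
        )
        sw = np.where(valid, np.sqrt(ns), 0.0)
        zc = (sw * np.where(valid, z, 0.0)).sum(axis=0) / np.sqrt(
            np.where(valid, ns, 0.0).sum(axis=0)
        )
        p_c = np.maximum(2.0 * stats.norm.sf(np.abs(zc)), _P_FLOOR)
        beta_c = np.full(len(snps), np.nan)
        se_c = np.full(len(snps), np.nan)

    keep = valid.all(axis=0) if intersection else valid.any(axis=0)
    out = pd.DataFrame(
        {
            "SNP": snps,
            "CHR": base.reindex(snps)["CHR"].to_numpy(),
            "BP": base.reindex(snps)["BP"].to_numpy(),
            "A1": base.reindex(snps)["A1"].to_numpy(),
            "A2": base.reindex(snps)["A2"].to_numpy(),
            "OR": np.exp(beta_c),
            "SE": se_c,
            "P": p_c,
            "N": np.where(valid, ns, 0.0).sum(axis=0).astype(int),
            "NSTUDIES": valid.sum(axis=0),
        }
    )[keep]
    # restore the first study's ordering information
    missing_chr = out["CHR"].isna()
    if missing_chr.any() and not intersection:
        for t in prepared[1:]:
            fill = t.reindex(out.loc[missing_chr, "SNP"])
            for col in ("CHR", "BP", "A1", "A2"):
                out.loc[missing_chr, col] = fill[col].to_numpy()
            missing_chr = out["CHR"].isna()
    return out.reset_index(drop=True)
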