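"""Transcript-reduction cascade ahead of network and QTL analysis.

Three ordered filters applied to the detected-above-background set:

1. dominant isoforms — per gene keep the ``k`` (default 3) transcripts with
   the highest mean TPM across the retained panel libraries;
2. heritability — drop transcripts whose one-way-ANOVA R^2 (strain as
   predictor, individual library values as response) is at or below the
   median R^2 of the current set (median computed after the top-k filter);
3. annotation association — drop transcripts that share no exact splice
   junction with a reference transcript.

A ledger records totals, per-source counts, and the realized median at each
step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ledger import FilterLedger
from .transcriptome import JunctionIndex, TranscriptomeAnnotation


@dataclass
class HeritabilityEstimate:
    transcript_id: str
    r_squared: float
    n_groups: int
    residual_df: int
    undefined: bool = False


def heritability(values: pd.Series, strains: pd.Series) -> HeritabilityEstimate:
    """Panel-sense heritability: R^2 = SS_between / SS_total from the
    one-way ANOVA with strain as the factor."""
    strains = strains.reindex(values.index)
    groups = strains.unique()
    if len(groups) < 2 or len(values) < len(groups) + 1:
        raise ValueError("need >=2 strains and more animals than strains")
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    if sst == 0:
        return HeritabilityEstimate(str(values.name), float("nan"),
                                    len(groups), len(values) - len(groups),
                                    undefined=True)
    means = values.groupby(strains).transform("mean")
    ssb = float(((means - grand) ** 2).sum())
    return HeritabilityEstimate(
        str(values.name), ssb / sst, len(groups), len(values) - len(groups)
    )


def heritability_profile(expr: pd.DataFrame, strains: pd.Series) -> pd.DataFrame:
    """Vectorized per-transcript ANOVA R^2 over a transcripts x libraries
    matrix; zero-variance transcripts are flagged undefined (R^2 = NaN)."""
    strains = strains.reindex(expr.columns)
    X = expr.to_numpy(dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    sst = ((X - grand) ** 2).sum(axis=1)
    group_means = expr.T.groupby(strains).mean().T  # transcripts x strains
    sizes = strains.value_counts().reindex(group_means.columns).to_numpy(float)
    ssb = (
        (group_means.to_numpy() - grand) ** 2 * sizes[None, :]
    ).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssb / np.where(sst > 0, sst, 1.0), np.nan)
    k = group_means.shape[1]
    return pd.DataFrame(
        {
            "r_squared": r2,
            "n_groups": k,
            "residual_df": expr.shape[1] - k,
            "undefined": sst == 0,
        },
        index=expr.index,
    )


def top_k_isoforms(
    tpm_matrix: pd.DataFrame, annotation: TranscriptomeAnnotation, k: int = 3
) -> list[str]:
    """Per gene, the k transcripts of highest mean TPM across the designated
    libraries.  Ties at the boundary keep the lexicographically smaller id,
    so the result is independent of input order."""
    mean_tpm = tpm_matrix.mean(axis=1)
    kept: list[str] = []
    for _gene, tids in annotation.genes().items():
        tids = [t for t in tids if t in mean_tpm.index]
        ranked = sorted(tids, key=lambda t: (-mean_tpm[t], t))
        kept.extend(ranked[:k])
    return sorted(kept)


@dataclass
class PrefilterResult:
    retained: list[str]
    ledger: FilterLedger
    median_heritability: float
    heritabilities: pd.Series


def apply_prefilter(
    tpm_matrix: pd.DataFrame,
    herits: pd.Series,
    annotation: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation | JunctionIndex,
    k: int = 3,
) -> PrefilterResult:
    """Run the three-step cascade and return survivors plus the ledger.

    ``herits`` maps transcript id -> ANOVA R^2.  The median-heritability
    rule drops transcripts with R^2 *at or below* the median of the
    post-top-k set (boundary inclusive, as the cascade defines it).
    Transcripts with undefined heritability are dropped with the rule.
    """
    ledger = FilterLedger()
    ledger.record("input", annotation)

    step1 = top_k_isoforms(tpm_matrix, annotation, k=k)
    ledger.record("top_k_isoforms", annotation, step1, k=k)

    h = herits.reindex(step1)
    med = float(h.median(skipna=True))
    if h.nunique(dropna=True) <= 1:
        warnings.warn("all heritabilities identical: <=-median rule drops everything")
    step2 = [t for t in step1 if pd.notna(h[t]) and h[t] > med]
    ledger.record("heritability_above_median", annotation, step2,
                  median=round(med, 6))

    idx = reference if isinstance(reference, JunctionIndex) else JunctionIndex(reference)
    step3 = [t for t in step2 if idx.gene_for(annotation[t]) is not None]
    ledger.record("ensembl_gene_association", annotation, step3)

    return PrefilterResult(step3, ledger, med, herits.reindex(step3))
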