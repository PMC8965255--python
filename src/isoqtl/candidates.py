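"""Three-criterion candidate selection for transcripts and module eigengenes.

A feature (an individual transcript's strain-mean expression, or a module
eigengene) is a candidate for the strain-level trait when all of:

1. its Spearman correlation with the trait has p < 0.01;
2. its best expression QTL reaches empirical genome-wide p < 0.01;
3. that QTL's peak marker lies inside the 95% Bayesian credible interval of
   a trait QTL of at least suggestive tier (same chromosome, inclusive
   endpoints); any qualifying trait QTL suffices.

No multiple-testing correction is applied; an optional
Benjamini-Hochberg column on the correlation p-values is emitted for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .qtl import QtlPeak, classify_eqtl, find_peak, genome_scan, permutation_thresholds
from .quantify import tpm
from .transcriptome import TranscriptomeAnnotation


@dataclass
class CandidateCriteria:
    correlation_p_max: float = 0.01
    eqtl_genomewide_p_max: float = 0.01
    pqtl_tiers: dict = field(
        default_factory=lambda: {"significant": 0.05, "suggestive": 0.63}
    )

    def __post_init__(self) -> None:
        for v in (self.correlation_p_max, self.eqtl_genomewide_p_max,
                  *self.pqtl_tiers.values()):
            if not (0.0 < v < 1.0):
                raise ValueError("all thresholds must lie in (0,1)")


def spearman_assoc(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Spearman rho on average ranks with a two-sided t-approximation p
    (n - 2 df).  Requires >=5 paired strains; constant vectors are
    undefined."""
    common = x.index.intersection(y.index)
    if len(common) < 5:
        raise ValueError("need >=5 paired strains")
    xv, yv = x.loc[common], y.loc[common]
    if xv.nunique() <= 1 or yv.nunique() <= 1:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)


@dataclass
class CandidateRecord:
    feature_id: str
    kind: str  # "transcript" or "module"
    rho: float
    rho_p: float
    eqtl_peak: QtlPeak | None = None
    overlapping_pqtl: str | None = None
    locality: str | None = None
    isoform_context: dict | None = None

    def to_row(self) -> dict:
        row = {
            "feature_id": self.feature_id,
            "kind": self.kind,
            "rho": self.rho,
            "rho_p": self.rho_p,
        }
        if self.eqtl_peak is not None:
            row.update(
                eqtl_lod=self.eqtl_peak.lod,
                eqtl_p=self.eqtl_peak.genomewide_p,
                eqtl_chromosome=self.eqtl_peak.chromosome,
                eqtl_position=self.eqtl_peak.position,
                eqtl_ci_lo=self.eqtl_peak.ci_lo,
                eqtl_ci_hi=self.eqtl_peak.ci_hi,
            )
        row["overlapping_pqtl"] = self.overlapping_pqtl
        row["locality"] = self.locality
        if self.isoform_context:
            row.update(
                {f"context_{k}": v for k, v in self.isoform_context.items()}
            )
        return row


def _qualifying_pqtl(
    pqtl_peaks: list[QtlPeak], tiers: dict
) -> list[QtlPeak]:
    worst = max(tiers.values())
    return [p for p in pqtl_peaks if p.genomewide_p < worst]


def _select(
    features: pd.DataFrame,
    phenotype: pd.Series,
    genotypes: GenotypeMatrix,
    pqtl_peaks: list[QtlPeak],
    criteria: CandidateCriteria,
    kind: str,
    n_perm: int,
    seed: int,
    annotation: TranscriptomeAnnotation | None = None,
) -> list[CandidateRecord]:
    """Shared selection path.  ``features`` is features x strains.

    QTL scans (and their permutations) are run only for features passing
    the correlation criterion, mirroring the staged design of the analysis.
    """
    qualifying = _qualifying_pqtl(pqtl_peaks, criteria.pqtl_tiers)
    records: list[CandidateRecord] = []
    rng = np.random.default_rng(seed)
    for fid, values in features.iterrows():
        x = values.dropna()
        try:
            rho, p = spearman_assoc(x, phenotype)
        except ValueError:
            continue
        if p >= criteria.correlation_p_max:
            continue
        trait = x.copy()
        trait.name = fid
        scan = genome_scan(trait, genotypes)
        thresholds = permutation_thresholds(trait, genotypes, n_perm=n_perm, seed=rng)
        peak = find_peak(scan, thresholds)
        if peak.genomewide_p >= criteria.eqtl_genomewide_p_max:
            continue
        overlap = next(
            (q for q in qualifying if q.contains(peak.chromosome, peak.position)),
            None,
        )
        if overlap is None:
            continue
        locality = None
        if annotation is not None and kind == "transcript" and fid in annotation:
            locality = classify_eqtl(peak, annotation[fid])
        records.append(
            CandidateRecord(str(fid), kind, rho, p, peak,
                            overlapping_pqtl=overlap.marker, locality=locality)
        )
    records.sort(key=lambda r: r.rho_p)
    return records


def candidate_transcripts(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    genotypes: GenotypeMatrix,
    pqtl_peaks: list[QtlPeak],
    criteria: CandidateCriteria | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    annotation: TranscriptomeAnnotation | None = None,
) -> list[CandidateRecord]:
    """Individual-transcript candidates from strain-mean expression,
    sorted by correlation p ascending."""
    return _select(expr, phenotype, genotypes, pqtl_peaks,
                   criteria or CandidateCriteria(), "transcript", n_perm, seed,
                   annotation=annotation)


def candidate_modules(
    eigengenes: pd.DataFrame,
    phenotype: pd.Series,
    genotypes: GenotypeMatrix,
    pqtl_peaks: list[QtlPeak],
    criteria: CandidateCriteria | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CandidateRecord]:
    """Module candidates: same three criteria with the eigengene as the
    trait (its QTL being the module-eigengene QTL)."""
    return _select(eigengenes, phenotype, genotypes, pqtl_peaks,
                   criteria or CandidateCriteria(), "module", n_perm, seed)


def isoform_context(
    feature_id: str,
    annotation: TranscriptomeAnnotation,
    dabg_counts: pd.DataFrame,
    lengths: pd.Series | None = None,
) -> dict:
    """Sibling-isoform context of a candidate transcript within the
    detected-above-background set: isoform count, per-source counts, and
    whether the candidate is its gene's dominant isoform by mean TPM."""
    if feature_id not in annotation:
        raise KeyError(feature_id)
    t = annotation[feature_id]
    siblings = annotation.genes()[t.gene_id]
    if lengths is None:
        lengths = pd.Series({x: annotation[x].length for x in dabg_counts.index
                             if x in annotation})
    tpm_mean = tpm(dabg_counts, lengths).mean(axis=1)
    present = [s for s in siblings if s in tpm_mean.index]
    dominant = max(present, key=lambda s: (tpm_mean[s], s)) if present else None
    by_source = {s: 0 for s in ("ensembl", "stringtie", "aptardi")}
    for s in siblings:
        src = annotation[s].source
        if src in by_source:
            by_source[src] += 1
    return {
        "n_isoforms": len(siblings),
        "n_ensembl": by_source["ensembl"],
        "n_stringtie": by_source["stringtie"],
        "n_aptardi": by_source["aptardi"],
        "dominant_isoform": dominant,
        "is_dominant": dominant == feature_id,
    }


def bh_fdr(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (transparency column only)."""
    p = p.astype(float)
    n = p.notna().sum()
    order = p.dropna().sort_values()
    adj = order * n / np.arange(1, len(order) + 1)
    adj = pd.Series(np.minimum.accumulate(adj.to_numpy()[::-1])[::-1],
                    index=order.index)
    return adj.reindex(p.index)


def candidates_table(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = [r.to_row() for r in records]
    df = pd.DataFrame(rows)
    if not df.empty:
        df["rho_p_bh"] = bh_fdr(df["rho_p"])
    return df
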