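"""Single-marker regression genome scans with permutation thresholds and
Bayesian credible intervals.

The LOD score of a marker is the log10 likelihood ratio of the one-marker
linear model against the intercept-only model,

    LOD = (n/2) * log10(RSS0 / RSS1) = -(n/2) * log10(1 - r^2),

with ``r`` the trait-genotype correlation.  Genome-wide significance is
empirical: the trait's strain labels are permuted jointly across all markers
(preserving linkage), the genome-wide maximum LOD is recorded per
permutation, and thresholds are the upper quantiles of those maxima.  The
credible interval for a peak treats ``10^LOD`` (normalized within the
chromosome) as a posterior over marker positions and accumulates markers in
decreasing-LOD order until the requested coverage is reached, then expands
to the flanking markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .transcriptome import TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_LOD_CAP = 50.0
PQTL_TIERS = {"significant": 0.05, "suggestive": 0.63}


def lod_score(trait: np.ndarray, genotype: np.ndarray, cap: float = DEFAULT_LOD_CAP) -> float:
    """LOD of one marker from the RSS ratio of nested linear regressions.

    Computed by explicit least squares (intercept-only vs intercept+marker);
    the closed form ``-(n/2) log10(1 - r^2)`` is used only as an independent
    cross-check in the test suite.  Capped at ``cap`` (also the value when
    the marker fit is perfect).
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(genotype, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 strains")
    if np.ptp(x) == 0:
        raise ValueError("monomorphic marker: LOD undefined")
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 == 0:
        return 0.0
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    if rss1 <= 0:
        return float(cap)
    return float(min((n / 2.0) * np.log10(rss0 / rss1), cap))


def _lod_profile_matrix(
    Y: np.ndarray, G: np.ndarray, cap: float = DEFAULT_LOD_CAP
) -> np.ndarray:
    """Vectorized LOD for rows of ``Y`` (traits x strains) against columns of
    ``G`` (strains x markers) via the correlation closed form.

    Monomorphic markers and constant traits yield LOD 0 here; callers mask
    monomorphic markers out before peak-finding.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ys = np.sqrt((Yc**2).sum(axis=1))
    Gc = G - G.mean(axis=0, keepdims=True)
    gs = np.sqrt((Gc**2).sum(axis=0))
    denom = np.outer(ys, gs)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Yc @ Gc) / np.where(denom > 0, denom, 1.0), 0.0)
    r2 = np.clip(r * r, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(1.0 - r2)
    return np.minimum(lod, cap)


@dataclass
class QtlScan:
    """Per-marker LOD profile for one trait over SDP representatives."""

    trait_id: str
    table: pd.DataFrame  # columns: marker, chromosome, position, lod
    n_strains: int = 0

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> pd.Series:
        """Global maximum; ties broken by map order (first chromosome/position)."""
        return self.table.loc[self.table["lod"].idxmax()]

    def peaks_per_chromosome(self) -> pd.DataFrame:
        idx = self.table.groupby("chromosome", sort=False)["lod"].idxmax()
        return self.table.loc[idx].reset_index(drop=True)


@dataclass
class QtlPeak:
    trait_id: str
    marker: str
    chromosome: str
    position: int
    lod: float
    genomewide_p: float
    ci_lo: int | None = None
    ci_hi: int | None = None
    ci_coverage: float = 0.95
    tier: str = "none"

    def contains(self, chromosome: str, position: int) -> bool:
        """Inclusive credible-interval membership on the same chromosome."""
        return (
            self.chromosome == chromosome
            and self.ci_lo is not None
            and self.ci_lo <= position <= self.ci_hi
        )


@dataclass
class ThresholdSet:
    """Permutation genome-wide maxima and the alpha -> LOD threshold map."""

    maxima: np.ndarray
    alphas: tuple[float, ...] = (0.01, 0.05, 0.63)
    thresholds: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=float)
        if not self.thresholds:
            self.thresholds = {
                a: float(np.quantile(self.maxima, 1.0 - a)) for a in self.alphas
            }

    def empirical_p(self, observed_max: float) -> float:
        """(1 + #{permutation maxima >= observed}) / (n_perm + 1)."""
        n = len(self.maxima)
        return float((1 + np.sum(self.maxima >= observed_max)) / (n + 1))

    def tier(self, observed_max: float, tiers: dict[str, float] = PQTL_TIERS) -> str:
        p = self.empirical_p(observed_max)
        for name, alpha in sorted(tiers.items(), key=lambda kv: kv[1]):
            if p < alpha:
                return name
        return "none"


def _align(trait: pd.Series, g: GenotypeMatrix) -> tuple[np.ndarray, GenotypeMatrix]:
    strains = [s for s in g.strain_ids if s in trait.index]
    if len(strains) < 3:
        raise ValueError(
            f"only {len(strains)} strains shared between trait and genotypes"
        )
    if len(strains) < len(trait.dropna()):
        logger.info(
            "trait %s: using %d of %d phenotyped strains with genotypes",
            trait.name, len(strains), len(trait.dropna()),
        )
    sub = g.subset_strains(strains)
    return trait.loc[strains].to_numpy(dtype=float), sub


def genome_scan(
    trait: pd.Series, g: GenotypeMatrix, cap: float = DEFAULT_LOD_CAP
) -> QtlScan:
    """LOD at every polymorphic SDP marker for one strain-level trait.

    The strain sets of trait and genotypes are intersected (logged — e.g.
    a phenotype measured in 21 of 30 strains).  Monomorphic markers are
    skipped.
    """
    y, sub = _align(trait, g)
    poly = ~sub.monomorphic_mask()
    if not poly.any():
        raise ValueError("no polymorphic markers among the shared strains")
    G = sub.alleles[:, poly].astype(float)
    lod = _lod_profile_matrix(y[None, :], G, cap)[0]
    table = sub.markers.loc[poly, ["marker", "chromosome", "position"]].reset_index(
        drop=True
    )
    table["lod"] = lod
    return QtlScan(str(trait.name), table, n_strains=len(y))


def permutation_thresholds(
    trait: pd.Series,
    g: GenotypeMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alphas: tuple[float, ...] = (0.01, 0.05, 0.63),
    cap: float = DEFAULT_LOD_CAP,
) -> ThresholdSet:
    """Genome-wide maximum-LOD null distribution by strain-label permutation.

    Strain labels of the trait are permuted jointly across all markers, so
    linkage between markers is preserved under the null.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y, sub = _align(trait, g)
    poly = ~sub.monomorphic_mask()
    G = sub.alleles[:, poly].astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(y)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    Y = y[perm_idx]  # n_perm x n
    lod = _lod_profile_matrix(Y, G, cap)
    return ThresholdSet(lod.max(axis=1), alphas=tuple(alphas))


def bayes_credible_interval(
    scan: QtlScan, chromosome: str, coverage: float = 0.95, expand: bool = True
) -> tuple[int, int]:
    """Bayesian credible interval for a peak on one chromosome.

    Posterior mass proportional to ``10^LOD`` over the chromosome's markers;
    markers are accumulated in decreasing-LOD order until cumulative mass
    reaches ``coverage``; the interval spans the accumulated markers,
    expanded (by default) to the flanking markers.
    """
    chrom = scan.table[scan.table["chromosome"] == chromosome]
    if chrom.empty:
        raise ValueError(f"no markers on chromosome {chromosome}")
    chrom = chrom.sort_values("position").reset_index(drop=True)
    lod = chrom["lod"].to_numpy(dtype=float)
    w = np.power(10.0, lod - lod.max())
    w /= w.sum()
    order = np.argsort(-lod, kind="stable")
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, coverage)) + 1
    chosen = order[:k]
    lo_i, hi_i = int(chosen.min()), int(chosen.max())
    if expand:
        lo_i = max(lo_i - 1, 0)
        hi_i = min(hi_i + 1, len(chrom) - 1)
    return int(chrom.loc[lo_i, "position"]), int(chrom.loc[hi_i, "position"])


def find_peak(
    scan: QtlScan,
    thresholds: ThresholdSet,
    coverage: float = 0.95,
    tiers: dict[str, float] = PQTL_TIERS,
) -> QtlPeak:
    """Single global-maximum peak with empirical p, tier, and credible interval."""
    row = scan.peak()
    ci_lo, ci_hi = bayes_credible_interval(scan, row["chromosome"], coverage)
    return QtlPeak(
        trait_id=scan.trait_id,
        marker=row["marker"],
        chromosome=row["chromosome"],
        position=int(row["position"]),
        lod=float(row["lod"]),
        genomewide_p=thresholds.empirical_p(float(row["lod"])),
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        ci_coverage=coverage,
        tier=thresholds.tier(float(row["lod"]), tiers),
    )


def covariate_scan(
    trait: pd.Series,
    g: GenotypeMatrix,
    covariate_marker: str,
    cap: float = DEFAULT_LOD_CAP,
) -> QtlScan:
    """Genome scan conditioning on one marker's allele as a covariate.

    ``LOD = (n/2) log10(RSS_cov / RSS_cov+marker)``, both models containing
    the covariate term.  Markers collinear with the covariate (including
    the covariate itself) get LOD 0.
    """
    y, sub = _align(trait, g)
    ids = sub.marker_ids
    if covariate_marker not in ids:
        raise ValueError(f"unknown covariate marker {covariate_marker}")
    c = sub.alleles[:, ids.index(covariate_marker)].astype(float)
    if np.ptp(c) == 0:
        raise ValueError("covariate marker is monomorphic")
    poly = ~sub.monomorphic_mask()
    G = sub.alleles[:, poly].astype(float)
    n = len(y)
    # residualize trait and markers on [1, covariate]
    Xc = np.column_stack([np.ones(n), c])
    H, _, _, _ = np.linalg.lstsq(Xc, np.column_stack([y[:, None], G]), rcond=None)
    R = np.column_stack([y[:, None], G]) - Xc @ H
    ry = R[:, 0]
    RG = R[:, 1:]
    rss_cov = float(np.sum(ry**2))
    gnorm = np.sqrt((RG**2).sum(axis=0))
    collinear = gnorm < 1e-10 * np.sqrt(n)
    r = np.zeros(RG.shape[1])
    ok = (~collinear) & (rss_cov > 0)
    if ok.any():
        r[ok] = (ry @ RG)[ok] / (gnorm[ok] * np.sqrt(rss_cov))
    r2 = np.clip(r * r, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = np.minimum(-(n / 2.0) * np.log10(1.0 - r2), cap)
    lod = np.where(collinear, 0.0, lod)
    if int(collinear.sum()):
        logger.info("%d markers collinear with covariate: LOD set to 0",
                    int(collinear.sum()))
    table = sub.markers.loc[poly, ["marker", "chromosome", "position"]].reset_index(
        drop=True
    )
    table["lod"] = lod
    return QtlScan(f"{trait.name}|{covariate_marker}", table, n_strains=n)


def classify_eqtl(
    peak: QtlPeak, transcript: TranscriptModel, window: int = 10_000_000
) -> str:
    """'local' iff the peak is on the transcript's chromosome within
    ``window`` bp (inclusive) of the transcript midpoint, else 'distal'."""
    if peak.chromosome != transcript.chromosome:
        return "distal"
    return "local" if abs(peak.position - transcript.midpoint) <= window else "distal"
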