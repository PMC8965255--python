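"""Synthetic recombinant-inbred study generator.

Emulates the statistical structure the analysis assumes so every downstream
stage is testable without external data: an RI panel of ~30 strains derived
by sib-mating (genotypes are two-state Markov chains along each chromosome
with map-expanded switch probability R = 4r/(1+6r)), a three-source
transcript annotation (reference models, splice-reconstruction exon-skipping
isoforms, 3'-extension alternative-polyadenylation isoforms), negative-
binomial expression with strain, eQTL, batch, and depth structure, a
strain-level phenotype with planted QTL, and equivalence-class read counts
with ambiguity induced by shared exons.

Strain-effect variances are tuned per transcript so the *realized* one-way
ANOVA R^2 (strain as predictor) matches a target drawn from
``heritability_range``: with k strains of n replicates the ANOVA R^2 has a
null expectation of (k-1)/(N-1), so the biological variance ratio is solved
from the expected-sums-of-squares identity rather than set to the target
directly.  Targets below the null expectation floor at zero strain variance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, collapse_to_sdp
from .quantify import EquivalenceClasses
from .transcriptome import TranscriptModel, TranscriptomeAnnotation

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "collapse_to_sdp",
    "simulate_ri_genotypes",
    "simulate_phenotype",
    "simulate_annotation",
    "simulate_expression",
    "simulate_equivalence_classes",
    "simulate_study",
    "stage_rng",
]

_STAGE_KEYS = {
    "genotypes": 0,
    "annotation": 1,
    "phenotype": 2,
    "expression": 3,
    "equivalence_classes": 4,
    "analysis": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a per-stage generator from the study seed.

    One study seed fans out to independent per-stage streams via
    ``SeedSequence(seed, spawn_key=(stage index,))`` with a fixed stage
    table, so a stage can be rerun in isolation reproducibly.
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic RI panel.

    Defaults mirror the design the analysis targets: 30 strains x 3
    replicate libraries across 8 batches, a phenotype measured in 21
    strains, moderate bulk negative-binomial dispersion, and transcript
    heritabilities centered near 0.5.
    """

    n_strains: int = 30
    n_chromosomes: int = 20
    markers_per_chromosome: int = 25
    chromosome_length: int = 100_000_000
    meiotic_recomb_fraction_per_interval: float = 0.05
    n_replicates_per_strain: int = 3
    n_batches: int = 8
    planted_pqtl: list[tuple[int, float]] = field(default_factory=list)
    planted_eqtl: list[tuple[str, int, float]] = field(default_factory=list)
    heritability_range: tuple[float, float] = (0.33, 0.67)
    nb_dispersion: float = 0.05
    seed: int = 0
    # secondary design knobs
    n_genes: int = 1080  # ~2,000 transcripts across the three sources
    n_phenotyped_strains: int = 21
    n_animals_per_strain: int = 6
    phenotype_within_sd: float = 1.0
    within_strain_log_sd: float = 0.3
    batch_log_sd: float = 0.2
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 1.0
    median_read_pairs: float = 71e6
    read_pairs_log_sd: float = 0.45
    map_expansion: str = "sib"  # "sib" (R = 4r/(1+6r)) or "none" (R = r)
    contig_gene_fraction: float = 0.02
    short_transcript_fraction: float = 0.02
    control_strain: str = "SHR_CTRL"
    n_control_libraries: int = 3

    def __post_init__(self) -> None:
        r = self.meiotic_recomb_fraction_per_interval
        if not (0.0 <= r <= 0.5):
            raise ValueError("recombination fraction must lie in [0, 0.5]")
        for name in (
            "n_strains", "n_chromosomes", "markers_per_chromosome",
            "chromosome_length", "n_replicates_per_strain", "n_batches",
            "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.heritability_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("heritability_range must be an interval in [0,1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        total = sum(f for _, f in self.planted_pqtl)
        if total > 1.0:
            raise ValueError("planted pQTL variance fractions sum above 1")
        if self.map_expansion not in ("sib", "none"):
            raise ValueError("map_expansion must be 'sib' or 'none'")

    @property
    def strain_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_strains + 1)]


def ri_switch_probability(r: float, map_expansion: str = "sib") -> float:
    """Inter-marker switch probability in the inbred panel.

    Sib-mating RI map expansion: R = 4r / (1 + 6r); r = 0.5 is a fixed
    point (free recombination is preserved).
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if map_expansion == "none":
        return r
    return 4.0 * r / (1.0 + 6.0 * r)


def simulate_ri_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Homozygous RI genotypes: per strain and chromosome a two-state Markov
    chain with switch probability ``ri_switch_probability(r)``; chromosome
    starts are fair coins."""
    rng = rng if rng is not None else stage_rng(config.seed, "genotypes")
    R = ri_switch_probability(
        config.meiotic_recomb_fraction_per_interval, config.map_expansion
    )
    S, C, M = config.n_strains, config.n_chromosomes, config.markers_per_chromosome
    starts = rng.random((S, C)) < 0.5
    switches = rng.random((S, C, M - 1)) < R if M > 1 else np.zeros((S, C, 0), bool)
    alleles = np.zeros((S, C, M), dtype=np.int8)
    alleles[:, :, 0] = starts
    if M > 1:
        flips = np.cumsum(switches, axis=2) % 2
        alleles[:, :, 1:] = (starts[:, :, None] ^ (flips == 1)).astype(np.int8)

    rows = []
    for c in range(C):
        for j in range(M):
            pos = int(round((j + 0.5) * config.chromosome_length / M))
            rows.append({"marker": f"c{c + 1}_m{j + 1:03d}",
                         "chromosome": str(c + 1), "position": pos})
    markers = pd.DataFrame(rows)
    return GenotypeMatrix(config.strain_ids, markers, alleles.reshape(S, C * M))


@dataclass
class Phenotype:
    """Strain-level trait with per-animal replicates."""

    strain_means: pd.Series  # index: strain
    animals: pd.DataFrame  # columns: strain, animal, value

    def observed_means(self) -> pd.Series:
        """Mean of the measured animals per strain (feeds QTL mapping)."""
        return self.animals.groupby("strain")["value"].mean()


def simulate_phenotype(
    g: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Phenotype:
    """Strain mean = sum of planted marker effects + strain-level noise.

    Each planted (marker index, variance fraction f) contributes effect
    ``2 * sqrt(f)`` per allele so it explains fraction ``f`` of unit
    strain-level variance in expectation (allele variance 1/4 at allele
    frequency 1/2); residual strain noise has variance ``1 - sum(f)``.
    Replicate animals add within-strain noise.  The phenotype is measured
    in the first ``n_phenotyped_strains`` strains only.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "phenotype")
    for idx, _ in config.planted_pqtl:
        if not (0 <= idx < g.n_markers):
            raise ValueError(f"planted pQTL marker index {idx} out of range")
    strains = g.strain_ids[: config.n_phenotyped_strains]
    sub = g.subset_strains(strains)
    genetic = np.zeros(len(strains))
    for idx, frac in config.planted_pqtl:
        beta = 2.0 * math.sqrt(frac)
        genetic += beta * sub.alleles[:, idx].astype(float)
    resid_sd = math.sqrt(max(1.0 - sum(f for _, f in config.planted_pqtl), 0.0))
    means = genetic + resid_sd * rng.standard_normal(len(strains))
    strain_means = pd.Series(means, index=pd.Index(strains, name="strain"),
                             name="phenotype")
    rows = []
    for s, mu in strain_means.items():
        vals = mu + config.phenotype_within_sd * rng.standard_normal(
            config.n_animals_per_strain
        )
        for a, v in enumerate(vals, start=1):
            rows.append({"strain": s, "animal": f"{s}_a{a}", "value": float(v)})
    return Phenotype(strain_means, pd.DataFrame(rows))


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TranscriptomeAnnotation:
    """Three-source annotation with the isoform structure the pipeline sees.

    Every gene gets a reference (``ensembl``) transcript; about half
    additionally get an exon-skipping ``stringtie`` isoform (when the gene
    has an internal exon to skip) and about half a 3'-extension ``aptardi``
    isoform sharing all junctions but ending at a shifted terminus.  A small
    fraction of genes sit on an unplaced contig, and a small fraction of
    reference transcripts are shorter than the length filter, to exercise
    the background-detection cascade.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "annotation")
    ann = TranscriptomeAnnotation()
    for gidx in range(config.n_genes):
        gid = f"G{gidx:05d}"
        on_contig = rng.random() < config.contig_gene_fraction
        chrom = (
            "contig_un1"
            if on_contig
            else str(1 + int(rng.integers(config.n_chromosomes)))
        )
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(10_000, config.chromosome_length - 100_000))
        short = (not on_contig) and rng.random() < config.short_transcript_fraction
        if short:
            exons = [(start, start + int(rng.integers(80, 201)) - 1)]
        else:
            n_exons = int(rng.integers(2, 6))
            exons = []
            pos = start
            for _ in range(n_exons):
                elen = int(rng.integers(100, 401))
                exons.append((pos, pos + elen - 1))
                pos += elen + int(rng.integers(200, 2001))
        ann.add(TranscriptModel(f"{gid}.E1", gid, chrom, strand,
                                tuple(exons), source="ensembl"))
        if len(exons) >= 3 and rng.random() < 0.5:
            skip = 1 + int(rng.integers(len(exons) - 2))
            kept = tuple(e for i, e in enumerate(exons) if i != skip)
            ann.add(TranscriptModel(f"{gid}.S1", gid, chrom, strand,
                                    kept, source="stringtie"))
        if not short and rng.random() < 0.5:
            shift = int(rng.integers(150, 801))
            ext = [list(e) for e in exons]
            if strand == "+":
                ext[-1][1] += shift
            else:
                ext[0][0] = max(1, ext[0][0] - shift)
            ann.add(TranscriptModel(f"{gid}.A1", gid, chrom, strand,
                                    tuple(tuple(e) for e in ext), source="aptardi"))
    return ann


def library_metadata(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-library strain, batch, and raw read-pair depth.

    Panel strains get ``n_replicates_per_strain`` libraries; the loading-
    control strain gets technical replicates flagged ``is_control``.
    Batches rotate across libraries; depths are log-normal around the
    configured median.
    """
    rows = []
    for s in config.strain_ids:
        for r in range(1, config.n_replicates_per_strain + 1):
            rows.append({"library": f"{s}_L{r}", "strain": s, "is_control": False})
    for r in range(1, config.n_control_libraries + 1):
        rows.append({"library": f"{config.control_strain}_L{r}",
                     "strain": config.control_strain, "is_control": True})
    meta = pd.DataFrame(rows)
    meta["batch"] = [f"B{1 + i % config.n_batches}" for i in range(len(meta))]
    depth = config.median_read_pairs * np.exp(
        config.read_pairs_log_sd * rng.standard_normal(len(meta))
    )
    meta["read_pairs"] = depth.astype(np.int64)
    return meta


def _strain_sd_for_target_r2(
    h: np.ndarray, sigma_w2: np.ndarray, k: int, n: int
) -> np.ndarray:
    """Solve the expected-sums-of-squares identity for the strain-effect SD.

    E[SSB]/E[SST] = h with k groups of n gives
    sigma_b^2 = sigma_w^2 (h(N-1) - (k-1)) / (n(k-1)(1-h)), floored at 0;
    targets below the null expectation (k-1)/(N-1) are unreachable and
    floor at zero strain variance.
    """
    N = k * n
    num = h * (N - 1) - (k - 1)
    sigma_b2 = sigma_w2 * np.clip(num, 0.0, None) / (n * (k - 1) * (1.0 - h))
    return np.sqrt(sigma_b2)


def simulate_expression(
    g: GenotypeMatrix,
    annotation: TranscriptomeAnnotation,
    meta: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial transcript counts per library.

    ``log mean = baseline + strain effect + eQTL allele effect + batch
    effect + log depth offset``.  Returns (counts, per-transcript truth
    table with the planted heritability targets).
    """
    rng = rng if rng is not None else stage_rng(config.seed, "expression")
    meta = meta.reset_index(drop=True)
    tids = annotation.transcript_ids
    T, L = len(tids), len(meta)
    k, n = config.n_strains, config.n_replicates_per_strain

    baseline = config.baseline_log_mean + config.baseline_log_sd * rng.standard_normal(T)
    h_target = rng.uniform(*config.heritability_range, size=T)
    mu_bar = np.exp(baseline)
    # within-group log-scale variance: biological + NB counting noise approx
    sigma_w2 = config.within_strain_log_sd**2 + 1.0 / mu_bar + config.nb_dispersion
    strain_sd = _strain_sd_for_target_r2(h_target, sigma_w2, k, n)

    strain_list = list(dict.fromkeys(meta["strain"]))
    s_index = {s: i for i, s in enumerate(strain_list)}
    strain_eff = rng.standard_normal((T, len(strain_list))) * strain_sd[:, None]

    eqtl_eff = np.zeros((T, len(strain_list)))
    tid_index = {t: i for i, t in enumerate(tids)}
    geno_strains = set(g.strain_ids)
    for tid, midx, effect in config.planted_eqtl:
        ti = tid_index[tid] if isinstance(tid, str) else int(tid)
        for s in strain_list:
            if s in geno_strains:
                a = g.alleles[g.strain_ids.index(s), midx]
                eqtl_eff[ti, s_index[s]] += effect * float(a)

    batch_list = list(dict.fromkeys(meta["batch"]))
    b_index = {b: i for i, b in enumerate(batch_list)}
    batch_eff = config.batch_log_sd * rng.standard_normal((T, len(batch_list)))

    depth = meta["read_pairs"].to_numpy(dtype=float)
    offset = np.log(depth / np.median(depth))

    s_cols = np.array([s_index[s] for s in meta["strain"]])
    b_cols = np.array([b_index[b] for b in meta["batch"]])
    logmu = (
        baseline[:, None]
        + strain_eff[:, s_cols]
        + eqtl_eff[:, s_cols]
        + batch_eff[:, b_cols]
        + offset[None, :]
        + config.within_strain_log_sd * rng.standard_normal((T, L))
    )
    mu = np.exp(logmu)
    if config.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(counts.astype(np.int64), index=tids,
                             columns=list(meta["library"]))
    truth = pd.DataFrame(
        {"transcript_id": tids, "baseline_log_mean": baseline,
         "target_heritability": h_target, "strain_effect_sd": strain_sd}
    ).set_index("transcript_id")
    return counts_df, truth


def _exon_sharing_cells(
    annotation: TranscriptomeAnnotation,
) -> tuple[list[tuple[str, ...]], np.ndarray, list[int]]:
    """Cells = (transcript, exon) pairs; each cell's class is the set of
    transcripts carrying that exact exon (same chromosome and strand)."""
    exon_owner: dict[tuple, list[str]] = defaultdict(list)
    for t in annotation:
        for e in t.exons:
            exon_owner[(t.chromosome, t.strand) + e].append(t.transcript_id)
    classes: list[tuple[str, ...]] = []
    lens: list[int] = []
    owners: list[int] = []  # index of originating transcript in annotation order
    tid_index = {t: i for i, t in enumerate(annotation.transcript_ids)}
    for t in annotation:
        for e in t.exons:
            members = tuple(sorted(exon_owner[(t.chromosome, t.strand) + e]))
            classes.append(members)
            lens.append(e[1] - e[0] + 1)
            owners.append(tid_index[t.transcript_id])
    return classes, np.asarray(lens, dtype=float), owners


def simulate_equivalence_classes(
    annotation: TranscriptomeAnnotation,
    true_abundances: pd.Series | pd.DataFrame,
    n_reads: int | pd.Series,
    seed: int | np.random.Generator = 0,
) -> EquivalenceClasses:
    """Multinomial equivalence-class counts with shared-exon ambiguity.

    ``true_abundances`` are molar-scale abundances per transcript (one
    column per library when a DataFrame); a read picks a (transcript, exon)
    cell with probability proportional to ``abundance x exon length`` and is
    recorded against the class of all transcripts carrying that exact exon.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(true_abundances, pd.Series):
        true_abundances = true_abundances.to_frame("lib1")
        n_reads = pd.Series({"lib1": int(n_reads)})
    elif not isinstance(n_reads, pd.Series):
        raise ValueError("per-library n_reads required for a DataFrame of abundances")
    cells, cell_lens, owners = _exon_sharing_cells(annotation)
    tids = annotation.transcript_ids
    alpha = true_abundances.reindex(tids).to_numpy(dtype=float)
    if np.any(alpha < 0):
        raise ValueError("negative abundances")

    class_ids = sorted(set(cells))
    class_index = {c: i for i, c in enumerate(class_ids)}
    cell_class = np.array([class_index[c] for c in cells])

    out = np.zeros((len(class_ids), true_abundances.shape[1]), dtype=np.int64)
    for j, lib in enumerate(true_abundances.columns):
        w = alpha[owners, j] * cell_lens
        total = w.sum()
        if total <= 0:
            raise ValueError(f"zero total abundance in library {lib}")
        draws = rng.multinomial(int(n_reads[lib]), w / total)
        np.add.at(out[:, j], cell_class, draws)
    counts = pd.DataFrame(out, columns=list(true_abundances.columns))
    return EquivalenceClasses(list(class_ids), counts)


def plant_module_scenario(
    config: SimulationConfig,
    marker_index: int,
    n_module_transcripts: int = 6,
    eqtl_effect: float = 2.0,
    pqtl_fraction: float = 0.8,
) -> tuple[SimulationConfig, list[str]]:
    """Plant a trait-linked coexpression module.

    Picks ``n_module_transcripts`` reference transcripts of distinct,
    well-placed genes (on real chromosomes, above the length filter), gives
    each a shared local-in-trans eQTL at ``marker_index`` with the same
    effect sign, and plants the phenotype QTL at the same marker.  Returns
    the modified config plus the member transcript ids — the scenario the
    candidate-selection machinery should recover as the unique module
    candidate.
    """
    from dataclasses import replace

    ann = simulate_annotation(config)
    chroms = {str(c + 1) for c in range(config.n_chromosomes)}
    members: list[str] = []
    for t in ann:
        if (
            t.source == "ensembl"
            and t.chromosome in chroms
            and t.length > 200
        ):
            members.append(t.transcript_id)
        if len(members) == n_module_transcripts:
            break
    if len(members) < n_module_transcripts:
        raise ValueError("annotation too small to plant the module")
    cfg = replace(
        config,
        planted_pqtl=[(marker_index, pqtl_fraction)],
        planted_eqtl=[(tid, marker_index, eqtl_effect) for tid in members],
    )
    return cfg, members


@dataclass
class SyntheticStudy:
    """Everything one pipeline run consumes, generated from a single seed."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    annotation: TranscriptomeAnnotation
    meta: pd.DataFrame
    true_counts: pd.DataFrame
    truth: pd.DataFrame
    equivalence_classes: EquivalenceClasses
    phenotype: Phenotype


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full synthetic study with per-stage seed fan-out."""
    g = simulate_ri_genotypes(config)
    ann = simulate_annotation(config)
    meta_rng = stage_rng(config.seed, "expression")
    meta = library_metadata(config, meta_rng)
    counts, truth = simulate_expression(g, ann, meta, config, rng=meta_rng)
    lengths = pd.Series({t.transcript_id: t.length for t in ann})
    molar = counts.div(lengths.reindex(counts.index), axis=0)
    ec = simulate_equivalence_classes(
        ann, molar, counts.sum(axis=0),
        seed=stage_rng(config.seed, "equivalence_classes"),
    )
    phen = simulate_phenotype(g, config)
    return SyntheticStudy(config, g, ann, meta, counts, truth, ec, phen)
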