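"""End-to-end orchestration over a synthetic (or user-supplied) study.

Stages, in order: equivalence-class quantitation and the detected-above-
background cascade; depth/log/batch normalization and strain means;
heritability; the dominant-isoform / heritability / annotation-association
prefilter; coexpression modules and eigengenes; phenotype QTL with
permutation thresholds and credible intervals; and three-criterion
candidate selection for transcripts and modules.  Every stage's randomness
derives from the single study seed; a manifest records parameters, seeds,
and content digests of all outputs so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .candidates import (
    CandidateCriteria,
    CandidateRecord,
    candidate_modules,
    candidate_transcripts,
    candidates_table,
    isoform_context,
)
from .genotypes import collapse_to_sdp
from .ledger import FilterLedger
from .network import (
    ModuleSet,
    NetworkParams,
    adjacency,
    detect_modules,
    intramodular_connectivity,
    module_eigengene,
    tom_similarity,
)
from .prefilter import apply_prefilter, heritability_profile
from .qtl import QtlPeak, bayes_credible_interval, genome_scan, permutation_thresholds
from .quantify import DabgParams, build_dabg, tpm
from .normalize import batch_adjust, regularized_log, strain_means, upper_quartile_normalize
from .simulate import SimulationConfig, SyntheticStudy, simulate_study, stage_rng
from .transcriptome import JunctionIndex, summarize

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dabg: DabgParams = field(default_factory=DabgParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    criteria: CandidateCriteria = field(default_factory=CandidateCriteria)
    n_perm: int = 1000
    top_k_isoforms: int = 3
    quantification: str = "em"  # "em" (equivalence-class EM) or "true" counts

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = SimulationConfig(**d.get("simulation", {}))
        dabg = DabgParams(**d.get("dabg", {}))
        net = NetworkParams(**d.get("network", {}))
        crit = CandidateCriteria(**d.get("criteria", {}))
        return cls(sim, dabg, net, crit,
                   n_perm=int(d.get("n_perm", 1000)),
                   top_k_isoforms=int(d.get("top_k_isoforms", 3)),
                   quantification=str(d.get("quantification", "em")))


@dataclass
class PipelineResult:
    config: PipelineConfig
    study: SyntheticStudy
    dabg_ledger: FilterLedger
    prefilter_ledger: FilterLedger
    expression_strain_means: pd.DataFrame
    heritabilities: pd.Series
    modules: ModuleSet
    eigengenes: pd.DataFrame
    eigengene_varexp: dict
    module_connectivity: pd.DataFrame
    pqtl_peaks: list[QtlPeak]
    pqtl_scan_table: pd.DataFrame
    transcript_candidates: list[CandidateRecord]
    module_candidates: list[CandidateRecord]
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - typed re-raise
                raise StageError(name, exc) from exc
        return inner
    return wrap


def _pqtl_peaks(
    scan, thresholds, tiers: dict, coverage: float = 0.95
) -> list[QtlPeak]:
    """Per-chromosome peaks reaching at least the loosest tier, each with
    an empirical genome-wide p (against the genome-wide maxima null) and a
    credible interval on its chromosome."""
    worst = max(tiers.values())
    peaks = []
    for _, row in scan.peaks_per_chromosome().iterrows():
        p = thresholds.empirical_p(float(row["lod"]))
        if p >= worst:
            continue
        lo, hi = bayes_credible_interval(scan, row["chromosome"], coverage)
        peaks.append(
            QtlPeak(
                trait_id=scan.trait_id,
                marker=row["marker"],
                chromosome=row["chromosome"],
                position=int(row["position"]),
                lod=float(row["lod"]),
                genomewide_p=p,
                ci_lo=lo,
                ci_hi=hi,
                tier=thresholds.tier(float(row["lod"]), tiers),
            )
        )
    return peaks


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on a synthetic study defined by ``config.simulation``.

    When ``outdir`` is given, all stage outputs plus a manifest are written
    there; a rerun with the same config is byte-identical.
    """
    sim = config.simulation

    study = _stage("simulate")(simulate_study)(sim)
    ann, meta, ec = study.annotation, study.meta, study.equivalence_classes
    lengths = pd.Series({t.transcript_id: t.length for t in ann})

    # ---- detected above background
    @_stage("dabg")
    def _dabg():
        params = config.dabg
        if params.chromosomes is None:
            chroms = tuple(str(c + 1) for c in range(sim.n_chromosomes))
            params = dataclasses.replace(params, chromosomes=chroms)
        if config.quantification == "em":
            return build_dabg(ann, ec, meta, params)
        # "true"-count route: skip the EM, apply the same cascade to the
        # generator's counts (fast path for scaled-down studies)
        from .quantify import DabgResult, _zero_rule_failures
        ledger = FilterLedger()
        ledger.record("input", ann)
        deep = [l for l in meta["library"]
                if int(meta.set_index("library").loc[l, "read_pairs"]) >= params.min_read_pairs]
        ledger.record("library_depth", ann, min_read_pairs=params.min_read_pairs)
        keep = [t.transcript_id for t in ann if t.chromosome in set(params.chromosomes)]
        sub = ann.subset(keep)
        ledger.record("chromosome", sub)
        counts = study.true_counts.loc[keep, deep]
        qlibs = [l for l in deep
                 if not bool(meta.set_index("library").loc[l, "is_control"])]
        zero = _zero_rule_failures(counts, qlibs, params.zero_fraction)
        short = {t.transcript_id for t in sub if t.length < params.min_length}
        final = [t for t in keep if t not in zero and t not in short]
        sub = sub.subset(final)
        ledger.record("zero_count_and_length", sub, min_length=params.min_length)
        ledger.record("requantified_zero_count", sub)
        return DabgResult(sub, counts.loc[final], ledger, deep)

    dabg = _dabg()
    dabg_ann, dabg_counts = dabg.annotation, dabg.counts

    # ---- normalization chain
    @_stage("normalize")
    def _normalize():
        uq = upper_quartile_normalize(dabg_counts)
        logged = regularized_log(uq)
        batches = meta.set_index("library").loc[logged.columns, "batch"]
        adj = batch_adjust(logged, batches)
        means = strain_means(adj, meta)
        return adj, means

    expr_lib, expr_strain = _normalize()

    # ---- heritability on RI-panel library-level values
    @_stage("heritability")
    def _herit():
        m = meta.set_index("library")
        panel = [c for c in expr_lib.columns if not bool(m.loc[c, "is_control"])]
        prof = heritability_profile(expr_lib[panel], m["strain"])
        return prof["r_squared"]

    herits = _herit()

    # ---- prefilter cascade
    @_stage("prefilter")
    def _prefilter():
        m = meta.set_index("library")
        panel = [c for c in dabg_counts.columns if not bool(m.loc[c, "is_control"])]
        tpm_panel = tpm(dabg_counts[panel], lengths.reindex(dabg_counts.index))
        reference = JunctionIndex(
            ann.subset([t.transcript_id for t in ann if t.source == "ensembl"])
        )
        return apply_prefilter(tpm_panel, herits, dabg_ann, reference,
                               k=config.top_k_isoforms)

    pre = _prefilter()
    retained = pre.retained
    expr_retained = expr_strain.loc[[t for t in retained if t in expr_strain.index]]

    # ---- coexpression network
    @_stage("network")
    def _network():
        keep = expr_retained.index[expr_retained.std(axis=1) > 0]
        adj = adjacency(expr_retained.loc[keep], config.network)
        tom = tom_similarity(adj)
        modules = detect_modules(1.0 - tom, config.network)
        eig, varexp, conn = {}, {}, []
        for label in modules.labels:
            members = modules.members(label)
            me = module_eigengene(expr_retained, members, label)
            eig[label] = me.scores
            varexp[label] = me.variance_explained
            k = intramodular_connectivity(adj, [m for m in members if m in adj.index])
            conn.append(pd.DataFrame({"module": label, "k_within": k}))
        eigengenes = pd.DataFrame(eig).T  # modules x strains
        connectivity = (
            pd.concat(conn) if conn
            else pd.DataFrame(columns=["module", "k_within"])
        )
        return adj, modules, eigengenes, varexp, connectivity

    net_adj, modules, eigengenes, eigengene_varexp, connectivity = _network()

    # ---- phenotype QTL
    @_stage("pqtl")
    def _pqtl():
        sdp, _ = collapse_to_sdp(study.genotypes)
        phen = study.phenotype.observed_means()
        phen.name = "phenotype"
        scan = genome_scan(phen, sdp)
        thr = permutation_thresholds(
            phen, sdp, n_perm=config.n_perm,
            seed=stage_rng(sim.seed, "analysis"),
        )
        peaks = _pqtl_peaks(scan, thr, config.criteria.pqtl_tiers)
        return sdp, phen, scan, peaks

    sdp, phen, pqtl_scan, pqtl_peaks = _pqtl()

    # ---- candidates
    @_stage("candidates")
    def _candidates():
        seed_t = int(stage_rng(sim.seed, "analysis").integers(2**31))
        tc = candidate_transcripts(
            expr_retained, phen, sdp, pqtl_peaks, config.criteria,
            n_perm=config.n_perm, seed=seed_t, annotation=ann,
        )
        for rec in tc:
            rec.isoform_context = isoform_context(rec.feature_id, dabg_ann,
                                                  dabg_counts, lengths)
        mc = candidate_modules(
            eigengenes, phen, sdp, pqtl_peaks, config.criteria,
            n_perm=config.n_perm, seed=seed_t + 1,
        )
        return tc, mc

    transcript_cands, module_cands = _candidates()

    manifest = {
        "package_version": __version__,
        "seed": sim.seed,
        "simulation": dataclasses.asdict(sim),
        "dabg": dataclasses.asdict(config.dabg),
        "network": dataclasses.asdict(config.network),
        "criteria": dataclasses.asdict(config.criteria),
        "n_perm": config.n_perm,
        "quantification": config.quantification,
    }

    result = PipelineResult(
        config=config,
        study=study,
        dabg_ledger=dabg.ledger,
        prefilter_ledger=pre.ledger,
        expression_strain_means=expr_strain,
        heritabilities=herits,
        modules=modules,
        eigengenes=eigengenes,
        eigengene_varexp=eigengene_varexp,
        module_connectivity=connectivity,
        pqtl_peaks=pqtl_peaks,
        pqtl_scan_table=pqtl_scan.table,
        transcript_candidates=transcript_cands,
        module_candidates=module_cands,
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = result.study

    study.genotypes.write_tsv(outdir / "genotypes.tsv")
    study.genotypes.write_marker_bed(outdir / "markers.bed")
    study.annotation.write_gtf(outdir / "annotation.gtf")
    study.meta.to_csv(outdir / "libraries.tsv", sep="\t", index=False)
    # DABG annotation = transcripts surviving the cascade
    dabg_ids = result.heritabilities.index
    study.annotation.subset(list(dabg_ids)).write_gtf(outdir / "dabg.gtf")
    result.expression_strain_means.to_csv(outdir / "expression_strain_means.tsv", sep="\t")
    result.heritabilities.rename("r_squared").to_csv(outdir / "heritability.tsv", sep="\t")
    result.dabg_ledger.write_tsv(outdir / "dabg_ledger.tsv")
    result.prefilter_ledger.write_tsv(outdir / "prefilter_ledger.tsv")
    result.modules.assignments.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
    result.module_connectivity.to_csv(outdir / "module_connectivity.tsv", sep="\t")
    result.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    result.pqtl_scan_table.to_csv(outdir / "pqtl_scan.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(p) for p in result.pqtl_peaks]).to_csv(
        outdir / "pqtl_peaks.tsv", sep="\t", index=False
    )
    candidates_table(result.transcript_candidates).to_csv(
        outdir / "transcript_candidates.tsv", sep="\t", index=False
    )
    candidates_table(result.module_candidates).to_csv(
        outdir / "module_candidates.tsv", sep="\t", index=False
    )
    (outdir / "report.md").write_text(report(result))

    digests = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = dict(result.manifest, output_digests=digests)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def report(result: PipelineResult) -> str:
    """Human-readable run summary: ledgers, module overview, peak table,
    candidate tables."""
    lines = ["# Pipeline report", ""]
    lines += ["## Annotation", ""]
    s = summarize(result.study.annotation)
    lines.append(
        f"{s['n_transcripts']} transcripts / {s['n_genes']} genes "
        f"(ratio {s['transcript_gene_ratio']:.2f})"
    )
    lines += ["", "## Background-detection cascade", "",
              result.dabg_ledger.to_frame().to_string(index=False)]
    lines += ["", "## Prefilter cascade", "",
              result.prefilter_ledger.to_frame().to_string(index=False)]
    sizes = result.modules.sizes()
    lines += ["", "## Coexpression modules", "",
              f"{len(sizes)} modules (median size "
              f"{float(sizes.median()) if len(sizes) else float('nan'):.0f}), "
              f"{result.modules.n_unassigned} unassigned"]
    lines += ["", "## Phenotype QTL", ""]
    if result.pqtl_peaks:
        rows = pd.DataFrame([dataclasses.asdict(p) for p in result.pqtl_peaks])
        lines.append(rows.to_string(index=False))
    else:
        lines.append("No suggestive or significant phenotype QTL.")
    for kind, recs in (("transcript", result.transcript_candidates),
                       ("module", result.module_candidates)):
        lines += ["", f"## Candidate {kind}s", ""]
        if recs:
            lines.append(candidates_table(recs).to_string(index=False))
        else:
            lines.append(f"No candidate {kind}s passed all three criteria.")
    lines.append("")
    return "\n".join(lines)
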