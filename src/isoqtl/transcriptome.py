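"""Transcript models for a merged multi-source brain transcriptome.

The annotation this package analyses is merged from three sources: a
reference annotation (``ensembl``), a splice-graph reconstruction
(``stringtie``), and a 3'-terminus extension step (``aptardi``) that
enumerates alternative polyadenylation isoforms of existing transcripts.
Transcripts are represented at the exon level in native GTF coordinates
(1-based, inclusive); BED export converts to 0-based half-open at the
boundary only.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

SOURCES = ("ensembl", "stringtie", "aptardi")

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Malformed GTF input (message carries the 1-based line number)."""


class AnnotationError(ValueError):
    """Structurally invalid transcript model."""


@dataclass(frozen=True)
class TranscriptModel:
    """A single transcript: ordered exons on one strand of one chromosome.

    Exons are (start, end) pairs in 1-based inclusive coordinates, sorted in
    ascending genomic order, non-overlapping.  ``source`` records which
    annotation step produced the model.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s > e:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon start {s} > end {e}"
                )
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons at {e0}/{s1}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        """Spliced length in nucleotides (sum of exon spans)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Splice junctions as (donor exon end, acceptor exon start) pairs.

        Pairs are in genomic order; a single-exon transcript has none.
        Junction identity is exact — a one-base shift is a different junction.
        """
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def three_prime_terminus(self) -> int:
        """Strand-aware genomic coordinate of the transcript's last base.

        The polyadenylation-site coordinate: right-most base on '+', left-most
        on '-'.
        """
        if self.strand == "+":
            return self.exons[-1][1]
        return self.exons[0][0]


def infer_source(transcript_id: str, known_ids: Iterable[str] = ()) -> str:
    """Guess the annotation source from an id naming convention.

    Fallback only — an explicit ``source_label`` GTF attribute is
    authoritative.  A trailing ``.N`` duplicate of an id already present marks
    a 3'-extension (aptardi) isoform; ``MSTRG.<g>.<t>`` ids come from the
    splice reconstruction; ``ENS*`` ids from the reference.
    """
    known = set(known_ids)
    m = re.match(r"^(.*)\.(\d+)$", transcript_id)
    if m and m.group(1) in known:
        return "aptardi"
    if transcript_id.startswith("ENS"):
        return "ensembl"
    if transcript_id.startswith("MSTRG."):
        return "stringtie"
    return "unknown"


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


@dataclass
class TranscriptomeAnnotation:
    """Collection of transcript models with a gene index and source ledger."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise AnnotationError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.transcripts)

    def genes(self) -> dict[str, list[str]]:
        """gene id -> transcript ids, in insertion order."""
        idx: dict[str, list[str]] = defaultdict(list)
        for t in self:
            idx[t.gene_id].append(t.transcript_id)
        return dict(idx)

    def source_counts(self) -> Counter:
        return Counter(t.source for t in self)

    def subset(self, transcript_ids: Iterable[str]) -> "TranscriptomeAnnotation":
        keep = set(transcript_ids)
        sub = TranscriptomeAnnotation()
        for tid, t in self.transcripts.items():
            if tid in keep:
                sub.transcripts[tid] = t
        return sub

    # ---------------------------------------------------------------- I/O

    def write_gtf(self, path: str | Path) -> None:
        """Write exon features with ``source_label`` attributes.

        Round-trips through :func:`parse_gtf` identically.
        """
        with open(path, "w") as fh:
            for t in self:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'source_label "{t.source}";'
                    )
                    fh.write(
                        f"{t.chromosome}\tisoqtl\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )

    def write_termini_bed(self, path: str | Path) -> None:
        """BED6 of 3' termini (0-based half-open single-base intervals)."""
        with open(path, "w") as fh:
            for t in self:
                p = t.three_prime_terminus()
                fh.write(
                    f"{t.chromosome}\t{p - 1}\t{p}\t{t.transcript_id}\t0\t{t.strand}\n"
                )


def parse_gtf(
    path: str | Path,
    source_attribute: str = "source_label",
    infer_missing_source: bool = True,
) -> TranscriptomeAnnotation:
    """Assemble transcript models from GTF exon features.

    The source is taken from ``source_attribute`` when present; otherwise it
    is inferred from the id convention after all ids are known.  Raises
    :class:`GtfParseError` with the offending line number for exons missing a
    transcript_id, and :class:`AnnotationError` for overlapping exons.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    info: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(f"line {lineno}: exon feature without transcript_id")
            gid = attrs.get("gene_id")
            if not gid:
                raise GtfParseError(f"line {lineno}: exon feature without gene_id")
            rec = info.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "chromosome": chrom,
                    "strand": strand,
                    "source": attrs.get(source_attribute),
                },
            )
            if rec["chromosome"] != chrom or rec["strand"] != strand:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} spans chromosomes or strands"
                )
            exons[tid].append((int(start), int(end)))

    ann = TranscriptomeAnnotation()
    all_ids = set(info)
    for tid, rec in info.items():
        source = rec["source"]
        if source is None and infer_missing_source:
            source = infer_source(tid, all_ids - {tid})
        ann.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chromosome=rec["chromosome"],
                strand=rec["strand"],
                exons=tuple(exons[tid]),
                source=source or "unknown",
            )
        )
    return ann


# -------------------------------------------------------------- termini


def match_termini(a: int, b: int, tolerance: int = 100) -> bool:
    """True iff two 3'-terminus coordinates lie within ``tolerance`` bases.

    Inclusive at the boundary; chromosome/strand agreement is the caller's
    responsibility.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    return abs(int(a) - int(b)) <= tolerance


def terminus_pair_ledger(
    ann: TranscriptomeAnnotation, tolerance: int = 100
) -> tuple[pd.DataFrame, dict]:
    """Audit transcript/3'-terminus pairs added by the 3'-extension step.

    For every aptardi transcript, flag whether its terminus matches (same
    chromosome and strand, +/- ``tolerance``) the terminus of any ensembl or
    stringtie transcript.  The summary counts pairs, unique termini
    (exact-coordinate deduplication), mean pairs per terminus, and the matched
    fraction on both the pair and the unique-terminus scale.
    """
    existing: dict[tuple[str, str], list[int]] = defaultdict(list)
    for t in ann:
        if t.source in ("ensembl", "stringtie"):
            existing[(t.chromosome, t.strand)].append(t.three_prime_terminus())

    rows = []
    for t in ann:
        if t.source != "aptardi":
            continue
        term = t.three_prime_terminus()
        cands = existing.get((t.chromosome, t.strand), [])
        matched = any(match_termini(term, c, tolerance) for c in cands)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "chromosome": t.chromosome,
                "strand": t.strand,
                "terminus": term,
                "matched_existing_terminus": matched,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "chromosome",
            "strand",
            "terminus",
            "matched_existing_terminus",
        ],
    )
    n_pairs = len(table)
    uniq = (
        table.drop_duplicates(subset=["chromosome", "strand", "terminus"])
        if n_pairs
        else table
    )
    n_termini = len(uniq)
    summary = {
        "n_pairs": n_pairs,
        "n_unique_termini": n_termini,
        "mean_pairs_per_terminus": (n_pairs / n_termini) if n_termini else float("nan"),
        "matched_pair_fraction": (
            float(table["matched_existing_terminus"].mean()) if n_pairs else float("nan")
        ),
        "matched_terminus_fraction": (
            float(uniq["matched_existing_terminus"].mean()) if n_termini else float("nan")
        ),
    }
    return table, summary


# -------------------------------------------------------------- junctions


class JunctionIndex:
    """Exact splice-junction lookup over a reference annotation.

    Maps (chromosome, strand, donor end, acceptor start) -> gene ids.  Used
    to associate novel transcripts with reference genes: sharing one exact
    junction is sufficient.
    """

    def __init__(self, reference: TranscriptomeAnnotation):
        self._index: dict[tuple[str, str, int, int], set[str]] = defaultdict(set)
        for t in reference:
            for j in t.junctions():
                self._index[(t.chromosome, t.strand) + j].add(t.gene_id)
        # exonic intervals per gene for the opt-in single-exon fallback
        self._exons: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
        for t in reference:
            for s, e in t.exons:
                self._exons[(t.chromosome, t.strand)].append((s, e, t.gene_id))

    def gene_for(
        self, t: TranscriptModel, exonic_overlap_fallback: bool = False
    ) -> str | None:
        """Gene id of a reference transcript sharing >=1 exact junction.

        Single-exon transcripts have no junctions and are unassociated by
        default; ``exonic_overlap_fallback`` instead associates them to any
        reference gene with an overlapping exon on the same strand.
        """
        hits: set[str] = set()
        for j in t.junctions():
            hits |= self._index.get((t.chromosome, t.strand) + j, set())
        if hits:
            return sorted(hits)[0]
        if exonic_overlap_fallback and len(t.exons) == 1:
            s0, e0 = t.exons[0]
            genes = {
                g
                for s, e, g in self._exons.get((t.chromosome, t.strand), [])
                if s <= e0 and s0 <= e
            }
            if genes:
                return sorted(genes)[0]
        return None


def shares_splice_junction(
    t: TranscriptModel,
    reference: TranscriptomeAnnotation | JunctionIndex,
    exonic_overlap_fallback: bool = False,
) -> str | None:
    """Reference gene id sharing at least one exact splice junction, else None."""
    idx = reference if isinstance(reference, JunctionIndex) else JunctionIndex(reference)
    return idx.gene_for(t, exonic_overlap_fallback=exonic_overlap_fallback)


# -------------------------------------------------------------- summary


def summarize(ann: TranscriptomeAnnotation) -> dict:
    """Annotation bookkeeping: gene/transcript totals, per-source shares,
    transcript:gene ratio, and the isoforms-per-gene histogram."""
    if len(ann) == 0:
        raise AnnotationError("empty annotation")
    genes = ann.genes()
    n_genes = len(genes)
    n_transcripts = len(ann)
    counts = ann.source_counts()
    per_source = {s: counts.get(s, 0) for s in SOURCES}
    other = n_transcripts - sum(per_source.values())
    if other:
        per_source["unknown"] = other
    percents = {s: 100.0 * c / n_transcripts for s, c in per_source.items()}
    iso_hist = Counter(len(tids) for tids in genes.values())
    return {
        "n_genes": n_genes,
        "n_transcripts": n_transcripts,
        "transcript_gene_ratio": round(n_transcripts / n_genes, 2),
        "source_counts": per_source,
        "source_percents": percents,
        "isoforms_per_gene": dict(sorted(iso_hist.items())),
    }
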