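"""Equivalence-class EM quantitation and the detected-above-background cascade.

Reads that align to several transcripts are summarized as equivalence
classes (the set of compatible transcripts plus a count).  A lightweight EM
assigns each class's reads to its member transcripts in proportion to
abundance per unit length: the generative model is a mixture in which a read
picks transcript ``t`` with prior probability ``alpha_t / sum(alpha)`` and a
position uniformly along its length, so the posterior weight of ``t`` for a
read in class ``c`` is ``(alpha_t/l_t) / sum_{t' in c}(alpha_t'/l_t')``.
The EM update is exactly this posterior assignment, which monotonically
increases the class-count log likelihood

    LL(alpha) = sum_c n_c log( sum_{t in c} (alpha_t / sum(alpha)) / l_t ).

Effective length is the spliced transcript length (no fragment-length
correction).

The detected-above-background (DABG) cascade removes shallow libraries,
off-chromosome transcripts, weakly supported transcripts (zero counts in a
third or more of the quantitation libraries, or length <= a minimum), then
re-quantifies against the survivors so ambiguous reads flow to retained
isoforms, and re-applies the zero-count rule.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .ledger import FilterLedger
from .transcriptome import TranscriptomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_CHROMOSOMES = None  # None -> infer "no contigs" from annotation caller


@dataclass
class DabgParams:
    """Knobs of the background-detection cascade."""

    min_read_pairs: int = 10_000_000
    min_length: int = 201  # transcripts shorter than this (<= 200 nt) are removed
    zero_fraction: float = 1.0 / 3.0
    chromosomes: tuple[str, ...] | None = None  # allowed chromosomes; None = all
    quantitation_libraries: tuple[str, ...] | None = None  # zero-rule library set


@dataclass
class EquivalenceClasses:
    """Class membership plus a classes x libraries count table."""

    members: list[tuple[str, ...]]
    counts: pd.DataFrame  # index: class ordinal, columns: library ids

    def __post_init__(self) -> None:
        if len(self.members) != len(self.counts):
            raise ValueError("members and counts row count differ")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def restrict(self, transcript_ids: Iterable[str]) -> "EquivalenceClasses":
        """Drop non-retained members; classes left empty are discarded."""
        keep = set(transcript_ids)
        members, rows = [], []
        for i, mem in enumerate(self.members):
            new = tuple(t for t in mem if t in keep)
            if new:
                members.append(new)
                rows.append(i)
        return EquivalenceClasses(members, self.counts.iloc[rows].reset_index(drop=True))

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "members", [",".join(m) for m in self.members])
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EquivalenceClasses":
        df = pd.read_csv(path, sep="\t")
        members = [tuple(m.split(",")) for m in df.pop("members")]
        return cls(members, df)


def _membership_matrix(
    members: Sequence[tuple[str, ...]], transcript_ids: Sequence[str]
) -> sparse.csr_matrix:
    index = {t: i for i, t in enumerate(transcript_ids)}
    rows, cols = [], []
    for c, mem in enumerate(members):
        for t in mem:
            rows.append(c)
            cols.append(index[t])
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(members), len(transcript_ids))
    )


def em_log_likelihood(
    alpha: np.ndarray, lengths: np.ndarray, C: sparse.csr_matrix, n: np.ndarray
) -> float:
    """Class-count log likelihood of the read-assignment mixture model."""
    psi = alpha / lengths
    class_density = C @ psi
    total = alpha.sum()
    mask = n > 0
    return float(np.sum(n[mask] * (np.log(class_density[mask]) - math.log(total))))


def em_quantify(
    ec: EquivalenceClasses,
    lengths: pd.Series,
    transcript_ids: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Expected read counts per transcript per library.

    Runs the EM over all libraries simultaneously.  Classes whose members are
    all outside ``transcript_ids`` are dropped and their reads logged as
    discarded.  Converges when the largest absolute change in any expected
    count falls below ``tol``, or after ``max_iter`` iterations.
    """
    if transcript_ids is None:
        transcript_ids = sorted({t for mem in ec.members for t in mem})
    transcript_ids = list(transcript_ids)
    if not transcript_ids:
        raise ValueError("empty retained transcript set")

    known = set(transcript_ids)
    orphan = [i for i, mem in enumerate(ec.members) if not any(t in known for t in mem)]
    if orphan:
        dropped = float(ec.counts.iloc[orphan].to_numpy().sum())
        logger.info(
            "dropping %d classes (%.0f reads) with no retained member",
            len(orphan),
            dropped,
        )
    ecr = ec.restrict(transcript_ids)

    T = len(transcript_ids)
    L = len(ecr.libraries)
    ell = lengths.reindex(transcript_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(ell)) or np.any(ell <= 0):
        raise ValueError("every retained transcript needs a positive length")
    if len(ecr.members) == 0:
        return pd.DataFrame(
            np.zeros((T, L)), index=transcript_ids, columns=ec.libraries
        )

    C = _membership_matrix(ecr.members, transcript_ids)
    n = ecr.counts.to_numpy(dtype=float)  # classes x libraries
    totals = n.sum(axis=0)

    alpha = np.tile((totals / T)[None, :], (T, 1))  # transcripts x libraries
    inv_ell = (1.0 / ell)[:, None]
    for _ in range(max_iter):
        psi = alpha * inv_ell
        denom = C @ psi  # classes x libraries
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, n / np.where(denom > 0, denom, 1.0), 0.0)
        new = (C.T @ ratio) * psi
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return pd.DataFrame(alpha, index=transcript_ids, columns=ecr.libraries)


def requantify_after_removal(
    ec: EquivalenceClasses, retained_transcripts: Iterable[str], lengths: pd.Series
) -> pd.DataFrame:
    """Re-run the EM restricted to the retained transcript set.

    Reads in classes whose members were all removed are discarded; reads in
    mixed classes are reassigned entirely to the surviving members.
    """
    retained = list(retained_transcripts)
    if not retained:
        raise ValueError("empty retained transcript set")
    return em_quantify(ec, lengths, transcript_ids=retained)


def tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized abundances summing to 1e6
    per library."""
    ell = effective_lengths.reindex(counts.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(ell)) or np.any(ell <= 0):
        raise ValueError("effective lengths must be positive")
    rate = counts.to_numpy(dtype=float) / ell[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} all-zero libraries; their TPM columns are zero"
        )
        denom = np.where(zero, 1.0, denom)
    out = 1e6 * rate / denom[None, :]
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


@dataclass
class DabgResult:
    annotation: TranscriptomeAnnotation
    counts: pd.DataFrame  # final estimated counts, all retained libraries
    ledger: FilterLedger
    retained_libraries: list[str] = field(default_factory=list)


def _zero_rule_failures(
    counts: pd.DataFrame, libraries: Sequence[str], zero_fraction: float
) -> set[str]:
    """Transcripts with zero counts in at least ceil(N * fraction) of the
    designated libraries."""
    cols = [c for c in libraries if c in counts.columns]
    n = len(cols)
    threshold = math.ceil(n * zero_fraction)
    zeros = (counts[cols] == 0).sum(axis=1)
    return set(counts.index[zeros >= threshold])


def build_dabg(
    ann: TranscriptomeAnnotation,
    ec: EquivalenceClasses,
    meta: pd.DataFrame,
    params: DabgParams | None = None,
) -> DabgResult:
    """The ordered background-detection cascade.

    Steps: (1) drop shallow libraries; (2) drop transcripts on unplaced
    contigs; (3) quantify; (4) drop transcripts failing the zero-count rule
    or the length minimum (evaluated simultaneously); (5) re-quantify every
    retained library against the survivors; (6) re-apply the zero-count
    rule.  The ledger records totals and per-source counts at each step.

    ``meta`` must carry one row per library with columns ``library``,
    ``strain``, ``batch``, ``read_pairs`` and optionally ``is_control``
    (loading-control libraries are quantified but excluded from the
    zero-count rule's library set unless explicitly configured).
    """
    params = params or DabgParams()
    meta = meta.set_index("library") if "library" in meta.columns else meta
    missing = [c for c in ec.libraries if c not in meta.index]
    if missing:
        raise ValueError(f"libraries missing from metadata: {missing[:5]}")

    ledger = FilterLedger()
    ledger.record("input", ann)

    # step 1: library depth
    deep = [
        lib
        for lib in ec.libraries
        if int(meta.loc[lib, "read_pairs"]) >= params.min_read_pairs
    ]
    if not deep:
        raise ValueError("all libraries removed by the read-depth filter")
    ec = EquivalenceClasses(ec.members, ec.counts[deep])
    ledger.record("library_depth", ann, min_read_pairs=params.min_read_pairs,
                  n_libraries=len(deep))

    # step 2: chromosome filter
    if params.chromosomes is not None:
        allowed = set(params.chromosomes)
        keep = [t.transcript_id for t in ann if t.chromosome in allowed]
    else:
        keep = ann.transcript_ids
    ann = ann.subset(keep)
    if len(ann) == 0:
        raise ValueError("all transcripts removed by the chromosome filter")
    ledger.record("chromosome", ann, chromosomes=params.chromosomes)

    lengths = pd.Series({t.transcript_id: t.length for t in ann})

    # which libraries the zero-count rule is evaluated on (RI panel only by
    # default, not loading controls)
    if params.quantitation_libraries is not None:
        qlibs = [l for l in params.quantitation_libraries if l in deep]
    elif "is_control" in meta.columns:
        qlibs = [l for l in deep if not bool(meta.loc[l, "is_control"])]
    else:
        qlibs = deep

    # step 3: first quantitation
    counts = em_quantify(ec, lengths, transcript_ids=ann.transcript_ids)

    # step 4: zero-count rule OR length minimum, simultaneously
    zero_fail = _zero_rule_failures(counts, qlibs, params.zero_fraction)
    short = {t.transcript_id for t in ann if t.length < params.min_length}
    survivors = [t for t in ann.transcript_ids if t not in zero_fail and t not in short]
    if not survivors:
        raise ValueError("no transcripts survive the expression-support filter")
    ann = ann.subset(survivors)
    ledger.record(
        "zero_count_and_length",
        ann,
        zero_fraction=round(params.zero_fraction, 4),
        min_length=params.min_length,
        n_quantitation_libraries=len(qlibs),
    )

    # step 5: re-quantitation against survivors (all retained libraries)
    lengths = lengths.reindex(survivors)
    counts = requantify_after_removal(ec, survivors, lengths)

    # step 6: re-apply the zero-count rule
    zero_fail = _zero_rule_failures(counts, qlibs, params.zero_fraction)
    final = [t for t in survivors if t not in zero_fail]
    if not final:
        raise ValueError("no transcripts survive re-quantitation")
    ann = ann.subset(final)
    counts = counts.loc[final]
    ledger.record("requantified_zero_count", ann,
                  zero_fraction=round(params.zero_fraction, 4))

    return DabgResult(
        annotation=ann, counts=counts, ledger=ledger, retained_libraries=deep
    )
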