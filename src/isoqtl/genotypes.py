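"""Biallelic inbred-panel genotypes and strain-distribution-pattern collapsing.

Every strain in a recombinant inbred panel is fully homozygous, so a marker
is a 0/1 vector over strains (the strain distribution pattern, SDP).
Markers with identical — or, under the default complement rule, relabeled —
SDPs are statistically indistinguishable in single-marker regression and are
collapsed to their left-most representative before scanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """strains x markers allele matrix with a positional marker map.

    ``markers`` has columns ``marker``, ``chromosome``, ``position`` (bp),
    ordered by position within chromosome.  ``alleles`` is coded {0, 1}
    (homozygous progenitor origin).
    """

    strain_ids: list[str]
    markers: pd.DataFrame
    alleles: np.ndarray
    sdp_map: dict[str, str] | None = None  # original marker -> representative

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.strain_ids), len(self.markers)):
            raise ValueError("alleles shape does not match strains x markers")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be homozygous-coded {0,1}")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["marker"])

    def monomorphic_mask(self) -> np.ndarray:
        """Markers where a single allele is fixed across all strains."""
        return (self.alleles.min(axis=0) == self.alleles.max(axis=0))

    def subset_strains(self, strains: list[str]) -> "GenotypeMatrix":
        idx = [self.strain_ids.index(s) for s in strains]
        return GenotypeMatrix(
            list(strains), self.markers.copy(), self.alleles[idx], self.sdp_map
        )

    # ------------------------------------------------------------------ I/O

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.alleles, index=pd.Index(self.strain_ids, name="strain"),
            columns=self.marker_ids,
        )
        df.to_csv(path, sep="\t")

    def write_marker_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.markers.iterrows():
                p = int(row["position"])
                fh.write(f"{row['chromosome']}\t{p - 1}\t{p}\t{row['marker']}\n")

    @classmethod
    def read_tsv(cls, geno_path: str | Path, marker_bed: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(geno_path, sep="\t", index_col=0)
        bed = pd.read_csv(
            marker_bed, sep="\t", header=None,
            names=["chromosome", "start", "end", "marker"],
        )
        markers = pd.DataFrame(
            {
                "marker": bed["marker"],
                "chromosome": bed["chromosome"],
                "position": bed["end"].astype(int),
            }
        )
        df = df[markers["marker"]]
        return cls(list(df.index), markers, df.to_numpy())


def collapse_to_sdp(
    g: GenotypeMatrix, merge_complement: bool = True
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Collapse markers with identical strain distribution patterns.

    Two markers collapse when their allele vectors are equal or, with
    ``merge_complement`` (default), equal after the 0<->1 relabeling —
    marker-regression LOD is invariant to allele relabeling.  The
    representative is the left-most member in map order; the returned
    mapping (original marker -> representative) lets peaks be reported at
    genomic coordinates.  Monomorphic markers collapse into a single flagged
    pattern.
    """
    seen: dict[tuple, int] = {}
    reps: list[int] = []
    mapping: dict[str, str] = {}
    ids = g.marker_ids
    for j in range(g.n_markers):
        v = tuple(int(x) for x in g.alleles[:, j])
        if merge_complement:
            key = min(v, tuple(1 - x for x in v))
        else:
            key = v
        if key not in seen:
            seen[key] = j
            reps.append(j)
        mapping[ids[j]] = ids[seen[key]]

    markers = g.markers.iloc[reps].reset_index(drop=True)
    alleles = g.alleles[:, reps]
    mono = alleles.min(axis=0) == alleles.max(axis=0)
    markers = markers.assign(monomorphic=mono)
    collapsed = GenotypeMatrix(list(g.strain_ids), markers, alleles, sdp_map=mapping)
    return collapsed, mapping
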