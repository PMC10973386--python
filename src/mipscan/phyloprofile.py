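"""Family-by-species presence/absence profiling (Coulson-plot data).

A presence matrix records, per module family and species, whether at least
one protein of that species carries the family.  Concordance of a family's
distribution with ciliation is quantified with a one-sided hypergeometric
exact test (enrichment of presence among ciliated species) plus an odds
ratio with a Haldane 0.5 correction for zero cells — an added statistic that
turns the qualitative "co-evolved with cilia" pattern into something
testable; the underlying publication shows the chart only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .seqio import TaxaTable


@dataclass
class PresenceMatrix:
    """Binary family x species matrix with per-species ciliation flags."""

    families: list[str]
    species: list[str]
    cells: np.ndarray  # (n_families, n_species) of 0/1
    ciliated: np.ndarray  # (n_species,) bool

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        self.ciliated = np.asarray(self.ciliated, dtype=bool)
        if self.cells.shape != (len(self.families), len(self.species)):
            raise ValueError("cell matrix shape must be (families, species)")
        if self.ciliated.shape != (len(self.species),):
            raise ValueError("one ciliation flag per species required")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.families, columns=self.species)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="family")

    def to_coulson_json(self) -> str:
        """JSON payload ready for a Coulson-style plotting front end."""
        return json.dumps(
            {
                "families": self.families,
                "species": self.species,
                "ciliated": [bool(c) for c in self.ciliated],
                "presence": self.cells.tolist(),
            },
            indent=2,
        )


def build_presence_matrix(
    assignments: Mapping[str, Iterable[str]],
    taxa: TaxaTable,
    families: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Build the presence matrix from per-species family assignments.

    *assignments* maps species name to the family labels observed in that
    species (duplicates are fine: presence is idempotent).  Species must
    exist in the taxa table; species order follows the taxa table, family
    order is the given *families* sequence or the sorted union of observed
    labels.
    """
    known = set(taxa.species)
    unknown = set(assignments) - known
    if unknown:
        raise KeyError(f"species absent from taxa table: {sorted(unknown)}")
    if families is None:
        observed: set[str] = set()
        for fams in assignments.values():
            observed.update(fams)
        families = sorted(observed)
    families = list(families)
    species = list(taxa.species)
    cells = np.zeros((len(families), len(species)), dtype=int)
    fam_idx = {f: i for i, f in enumerate(families)}
    for sp_i, sp in enumerate(species):
        for fam in assignments.get(sp, ()):
            if fam in fam_idx:
                cells[fam_idx[fam], sp_i] = 1
    ciliated = np.array([taxa.is_ciliated(sp) for sp in species])
    return PresenceMatrix(families, species, cells, ciliated)


@dataclass(frozen=True)
class ConcordanceResult:
    family: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: present/absent, cols: ciliated/not
    odds_ratio: float
    p_value: float
    concordance_fraction: float


def ciliation_concordance(matrix: PresenceMatrix, family: str) -> ConcordanceResult:
    """Exact test of association between a family's presence and ciliation.

    The p-value is the upper tail of the hypergeometric distribution:
    probability of at least the observed number of ciliated species among the
    family-positive species, given the margins.  The odds ratio applies a
    Haldane 0.5 correction to every cell whenever any cell is zero.
    """
    if family not in matrix.families:
        raise KeyError(f"family {family!r} not in matrix")
    cil = matrix.ciliated
    if cil.all() or (~cil).all():
        raise ValueError("need at least one ciliated and one non-ciliated species")
    row = matrix.cells[matrix.families.index(family)].astype(bool)
    a = int(np.sum(row & cil))        # present, ciliated
    b = int(np.sum(row & ~cil))       # present, non-ciliated
    c = int(np.sum(~row & cil))       # absent, ciliated
    d = int(np.sum(~row & ~cil))      # absent, non-ciliated
    N, K, n = a + b + c + d, a + c, a + b
    p = float(hypergeom.sf(a - 1, N, K, n))
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b, c, d
    odds = (oa * od) / (ob * oc)
    concordance = (a + d) / N
    return ConcordanceResult(family, ((a, b), (c, d)), float(odds), p, concordance)
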