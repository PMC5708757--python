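"""InDel molecular index and seven-way indica/japonica classification.

For one accession scored at N InDel loci the indica- and japonica-specific
allele frequencies are

    F_i = (2*#II + #IJ + #IX) / (2*N_eff)
    F_j = (2*#JJ + #IJ + #JX) / (2*N_eff)

where N_eff counts the loci with a non-null call.  Null loci carry no scorable
allele and are excluded from the denominator; non-reference X alleles enter
the denominator but neither numerator, so they dilute F_i and F_j
symmetrically.  An accession scored only with I/J alleles satisfies
F_i + F_j = 1.

F_j alone then places the accession on a seven-class indica-japonica scale,
from typical indica (F_j < ~0.10) through intermediate (~0.40-0.60) to typical
japonica (F_j > ~0.90).  The published class bands are two-decimal roundings
with gaps (e.g. 0.25 vs 0.26); the map below closes each gap at its midpoint
so that every F_j in [0, 1] receives exactly one class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io import ComputationError, GenotypeMatrix, ValidationError

__all__ = [
    "Subspecies",
    "IndexResult",
    "PanelClassification",
    "allele_frequencies",
    "classify",
    "classify_panel",
    "het_proportion",
    "amova_partition",
]

log = logging.getLogger(__name__)


class Subspecies(str, Enum):
    """Seven-way indica/japonica class of an accession."""

    TYPICAL_INDICA = "typical_indica"
    INDICA = "indica"
    CLOSE_TO_INDICA = "close_to_indica"
    INTERMEDIATE = "intermediate"
    CLOSE_TO_JAPONICA = "close_to_japonica"
    JAPONICA = "japonica"
    TYPICAL_JAPONICA = "typical_japonica"


#: Upper bounds (on F_j, half-open) of the first six classes; the published
#: band edges 0.10/0.11, 0.25/0.26, 0.39/0.40, 0.60/0.61, 0.74/0.75, 0.89/0.90
#: are closed at their midpoints.
_CLASS_BOUNDS = np.array([0.105, 0.255, 0.395, 0.605, 0.745, 0.895])
_CLASS_ORDER = list(Subspecies)


@dataclass
class IndexResult:
    """Per-accession InDel molecular index.

    ``n_scored`` is the number of non-null loci (the frequency denominator
    uses 2 x n_scored chromosomes); ``n_het`` counts two-allele calls
    (IJ/IX/JX); ``n_x`` counts calls carrying a non-reference allele.
    """

    sample_id: str
    f_i: float
    f_j: float
    n_scored: int
    n_het: int
    n_null: int
    n_x: int = 0
    subspecies_class: Subspecies | None = None


def allele_frequencies(sample_id: str, calls: "pd.Series | list[str]") -> IndexResult:
    """Compute F_i and F_j for one accession from its genotype calls.

    Raises
    ------
    ComputationError
        If every locus is null (the index is undefined).
    """
    counts = Counter(calls)
    n_null = counts["NN"]
    n_eff = sum(counts.values()) - n_null
    if n_eff == 0:
        raise ComputationError(f"{sample_id}: all loci null, index undefined")
    f_i = (2 * counts["II"] + counts["IJ"] + counts["IX"]) / (2 * n_eff)
    f_j = (2 * counts["JJ"] + counts["IJ"] + counts["JX"]) / (2 * n_eff)
    n_het = counts["IJ"] + counts["IX"] + counts["JX"]
    n_x = counts["IX"] + counts["JX"] + counts["XX"]
    return IndexResult(
        sample_id=sample_id,
        f_i=f_i,
        f_j=f_j,
        n_scored=n_eff,
        n_het=n_het,
        n_null=n_null,
        n_x=n_x,
    )


def classify(f_j: float) -> Subspecies:
    """Map a japonica-allele frequency to its seven-way class.

    The map is total and single-valued on [0, 1]: contiguous half-open
    intervals [0, 0.105), [0.105, 0.255), [0.255, 0.395), [0.395, 0.605),
    [0.605, 0.745), [0.745, 0.895), [0.895, 1].
    """
    if not 0.0 <= f_j <= 1.0:
        raise ValidationError(f"F_j = {f_j} outside [0, 1]")
    return _CLASS_ORDER[int(np.searchsorted(_CLASS_BOUNDS, f_j, side="right"))]


def het_proportion(calls: "pd.Series | list[str]") -> float:
    """Percent of scored (non-null) loci with a heterozygous call, 1 decimal."""
    counts = Counter(calls)
    n_scored = sum(counts.values()) - counts["NN"]
    if n_scored == 0:
        raise ComputationError("no scored loci; heterozygosity undefined")
    n_het = counts["IJ"] + counts["IX"] + counts["JX"]
    return round(100.0 * n_het / n_scored, 1)


@dataclass
class PanelClassification:
    """Classification of a whole panel plus its class census."""

    results: list[IndexResult]
    census: Counter
    failed: list[str]  # samples whose index was undefined (all-null)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "F_i": r.f_i,
                "F_j": r.f_j,
                "n_scored": r.n_scored,
                "n_het": r.n_het,
                "n_null": r.n_null,
                "n_x": r.n_x,
                "class": r.subspecies_class.value if r.subspecies_class else "undefined",
            }
            for r in self.results
        ]
        return pd.DataFrame(rows).set_index("sample_id")


def classify_panel(g: GenotypeMatrix) -> PanelClassification:
    """Classify every accession of a panel; undefined samples are reported,
    not fatal.

    Returns per-sample :class:`IndexResult` rows (class attached) and a census
    of class counts.  The census drives the two-population split used by the
    AMOVA stage (see :func:`amova_partition`).
    """
    results: list[IndexResult] = []
    failed: list[str] = []
    census: Counter = Counter()
    for sid in g.sample_ids:
        try:
            res = allele_frequencies(sid, g.calls.loc[sid])
        except ComputationError:
            log.warning("sample %s: index undefined (all loci null)", sid)
            failed.append(sid)
            continue
        res.subspecies_class = classify(res.f_j)
        census[res.subspecies_class] += 1
        results.append(res)
    return PanelClassification(results=results, census=census, failed=failed)


#: Classes assigned to population 2 in the two-population divergence test:
#: the japonica-leaning side of the scale.
POPULATION_2_CLASSES = frozenset(
    {
        Subspecies.INTERMEDIATE,
        Subspecies.CLOSE_TO_JAPONICA,
        Subspecies.JAPONICA,
        Subspecies.TYPICAL_JAPONICA,
    }
)


def amova_partition(pc: PanelClassification) -> pd.Series:
    """Two-population split of a classified panel for the AMOVA stage.

    Intermediate, close-to-japonica, japonica and typical-japonica accessions
    form ``population_2``; all indica-side accessions form ``population_1``.
    """
    labels = {
        r.sample_id: (
            "population_2"
            if r.subspecies_class in POPULATION_2_CLASSES
            else "population_1"
        )
        for r in pc.results
    }
    return pd.Series(labels, name="population")
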