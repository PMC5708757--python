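"""Per-marker informativeness statistics for codominant InDel panels.

Implements the standard marker-utility measures for dominant/codominant PCR
marker systems:

* PIC (polymorphic information content)  ``1 - sum(p_i^2)`` over allele
  frequencies ``p_i`` (gene-count frequencies; a biallelic locus tops out at
  0.5).
* Band informativeness ``I_b = 1 - 2*|0.5 - p|`` where ``p`` is the
  proportion of genotypes containing the band, and resolving power
  ``R_p = sum(I_b)`` over a marker's bands.
* EMR (effective multiplex ratio) ``NPA x PPA`` — the number of polymorphic
  amplicons per assay times the polymorphic proportion — and the marker index
  ``MI = PIC x EMR``.
* A rare-allele rule flagging bands carried by strictly fewer than 5% of the
  samples.

The bundled reference table ships these columns as published for the
42-marker rice panel; :func:`published_consistency` recomputes MI from the
published PIC and EMR and flags discrepancies instead of silently matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    BandMatrix,
    ComputationError,
    GenotypeMatrix,
    ValidationError,
    to_band_matrix,
)

__all__ = [
    "MarkerStats",
    "allele_freq_per_marker",
    "pic",
    "band_informativeness",
    "resolving_power",
    "emr",
    "marker_index",
    "band_presence_proportions",
    "rare_alleles",
    "marker_report",
    "published_consistency",
]


def allele_freq_per_marker(g: GenotypeMatrix, marker_id: str) -> dict[str, float]:
    """Gene-count allele frequencies (I/J/X) at one marker.

    Each homozygote contributes two copies of its allele, each heterozygote
    one copy of each; null calls are excluded.
    """
    calls = g.calls[marker_id]
    counts = {"I": 0, "J": 0, "X": 0}
    n_scored = 0
    for call in calls:
        if call == "NN":
            continue
        n_scored += 1
        counts[call[0]] += 1
        counts[call[1]] += 1
    if n_scored == 0:
        raise ComputationError(f"{marker_id}: every call null, frequencies undefined")
    total = 2 * n_scored
    return {a: c / total for a, c in counts.items() if c > 0}


def pic(p: Sequence[float]) -> float:
    """Polymorphic information content ``1 - sum(p_i^2)``."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size and not np.isclose(arr.sum(), 1.0):
        raise ValidationError(f"allele frequencies sum to {arr.sum()}, not 1")
    return float(1.0 - np.sum(arr**2))


def band_informativeness(p_band: float) -> float:
    """Band informativeness ``I_b = 1 - 2*|0.5 - p|`` for presence proportion p."""
    if not 0.0 <= p_band <= 1.0:
        raise ValidationError(f"band proportion {p_band} outside [0, 1]")
    return 1.0 - 2.0 * abs(0.5 - p_band)


def resolving_power(band_proportions: Sequence[float]) -> float:
    """Resolving power ``R_p = sum(I_b)`` over a marker's bands."""
    return float(sum(band_informativeness(p) for p in band_proportions))


def emr(npa: int, ppa: float) -> float:
    """Effective multiplex ratio: polymorphic amplicons x polymorphic proportion."""
    if npa < 0:
        raise ValidationError("NPA must be >= 0")
    return float(npa) * float(ppa)


def marker_index(pic_value: float, emr_value: float) -> float:
    """Marker index ``MI = PIC x EMR``."""
    return float(pic_value) * float(emr_value)


def band_presence_proportions(b: BandMatrix) -> pd.Series:
    """Per band: fraction of unmasked samples whose genotype contains the band."""
    present = (b.values == 1) & ~b.mask
    observed = (~b.mask).sum(axis=0)
    with np.errstate(invalid="ignore"):
        props = np.where(observed > 0, present.sum(axis=0) / observed, np.nan)
    return pd.Series(props, index=b.band_ids, name="p_band")


def rare_alleles(b: BandMatrix, threshold: float = 0.05) -> list[str]:
    """Bands carried by strictly fewer than ``threshold`` of all samples.

    Presence is counted on unmasked cells only, but the denominator is the
    full sample count, matching the "present in less than 5% of the panel"
    reading of the rule.  Bands never observed at all are not rare — they are
    absent.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    present = ((b.values == 1) & ~b.mask).sum(axis=0)
    cutoff = threshold * b.n_samples
    return [
        band
        for band, count in zip(b.band_ids, present)
        if 0 < count < cutoff
    ]


@dataclass
class MarkerStats:
    """Informativeness statistics for one marker computed from a panel."""

    marker_id: str
    allele_freqs: dict[str, float]
    pic: float
    band_informativeness: dict[str, float]
    rp: float
    npa: int
    ppa_recomputed: float
    emr: float
    mi: float
    rare_allele_bands: list[str]


def marker_report(
    g: GenotypeMatrix, rare_threshold: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Per-marker informativeness table for a genotyped panel.

    NPA is the number of polymorphic bands actually observed (present in some
    but not all scored samples); ``ppa_recomputed`` = NPA / catalogued bands.
    This recomputed PPA convention differs from the published table, which
    lists PPA = NPA - 1 style values not derivable from a stated formula; the
    column name marks it as recomputed.  Returns the per-marker DataFrame and
    a summary dict (ranges and threshold counts).
    """
    bm = to_band_matrix(g)
    props = band_presence_proportions(bm)
    rare = set(rare_alleles(bm, rare_threshold))
    rows = []
    for m in g.markers:
        freqs = allele_freq_per_marker(g, m.marker_id)
        marker_bands = [
            band for band, owner in zip(bm.band_ids, bm.band_marker)
            if owner == m.marker_id
        ]
        p_bands = props[marker_bands]
        poly = int(((p_bands > 0) & (p_bands < 1)).sum())
        n_bands = len(marker_bands)
        ppa = poly / n_bands if n_bands else 0.0
        pic_val = pic(list(freqs.values()))
        emr_val = emr(poly, ppa)
        rows.append(
            {
                "marker_id": m.marker_id,
                "n_alleles": len(freqs),
                "pic": pic_val,
                "rp": resolving_power(p_bands.dropna()),
                "npa": poly,
                "ppa_recomputed": ppa,
                "emr": emr_val,
                "mi": marker_index(pic_val, emr_val),
                "rare_allele_bands": ";".join(b for b in marker_bands if b in rare),
            }
        )
    table = pd.DataFrame(rows).set_index("marker_id")
    summary = {
        "pic_min": float(table["pic"].min()),
        "pic_max": float(table["pic"].max()),
        "rp_min": float(table["rp"].min()),
        "rp_max": float(table["rp"].max()),
        "mi_min": float(table["mi"].min()),
        "mi_max": float(table["mi"].max()),
        "n_rp_gt_1": int((table["rp"] > 1.0).sum()),
        "n_pic_ideal": int(table["pic"].between(0.35, 0.50).sum()),
        "n_rare_allele_bands": len(rare),
    }
    return table, summary


def published_consistency(stats: pd.DataFrame, tol: float = 0.01) -> pd.DataFrame:
    """Recompute MI = PIC x EMR from a published statistics table.

    ``stats`` must carry ``pic``, ``emr`` and ``mi`` columns (as returned by
    :func:`indelpop.io.load_table1`).  Returns a frame with the recomputed MI,
    the absolute deviation from the printed value and a boolean
    ``consistent`` flag at tolerance ``tol`` — discrepancies are reported, not
    hidden.
    """
    for col in ("pic", "emr", "mi"):
        if col not in stats.columns:
            raise ValidationError(f"published table lacks column {col!r}")
    out = pd.DataFrame(index=stats.index)
    out["mi_printed"] = stats["mi"]
    out["mi_recomputed"] = stats["pic"] * stats["emr"]
    out["abs_dev"] = (out["mi_printed"] - out["mi_recomputed"]).abs()
    out["consistent"] = out["abs_dev"] <= tol + 1e-12
    return out
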