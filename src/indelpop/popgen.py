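"""Distance-based AMOVA with permutation-tested Phi-PT, and diversity indices.

The two-level analysis of molecular variance partitions the squared pairwise
distances of a panel among and within populations:

    SS_total  = (1/N) * sum_{i<j} d2_ij
    SS_within = sum_p (1/n_p) * sum_{i<j in p} d2_ij
    SS_among  = SS_total - SS_within
    MS        = SS / df,  df_among = P - 1,  df_within = N - P
    n0        = (N - sum_p n_p^2 / N) / (P - 1)
    Va        = (MS_among - MS_within) / n0      (among-population component)
    Vw        = MS_within                        (within-population component)
    Phi_PT    = Va / (Va + Vw)

Significance is assessed by randomly reassigning samples to populations
(sizes preserved).  The reported Phi_PT clamps a negative Va to zero — the
usual convention keeping the estimate in [0, 1] — but the permutation ranking
compares the *unclamped* statistic on both sides: with clamping on both sides
every panel whose observed estimate is exactly 0 would receive P = 1, piling
an atom of null P-values at 1 instead of leaving them uniform.  The P-value
uses the add-one estimator (1 + #exceedances) / (1 + n_perm), so it is never
exactly zero.

Per-population diversity indices (Na, Ne, Shannon's I, He, uHe) are computed
per locus from gene-count allele frequencies and summarised as mean +/- SE
across loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BandMatrix, ComputationError, GenotypeMatrix, ValidationError

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "DiversityStats",
    "band_sq_distance",
    "amova",
    "phi_from_components",
    "diversity_stats",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with a metric tag.

    ``metric`` names the substrate (``"squared-euclidean-band"``,
    ``"one-minus-jaccard"``, ``"geographic"``); matrices tagged as squared are
    consumed as-is by AMOVA, others are squared first.
    """

    ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if (self.data < -1e-12).any():
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def band_sq_distance(b: BandMatrix) -> DistanceMatrix:
    """Squared Euclidean distance between binary band profiles.

    d2(i, j) = number of band columns, unmasked in both samples, where
    presence differs.  Masked (null-call) columns are excluded pairwise.
    """
    if b.n_samples < 2:
        raise ValidationError("need at least 2 samples for distances")
    unmasked = ~b.mask
    present = ((b.values == 1) & unmasked).astype(float)
    absent = ((b.values == 0) & unmasked).astype(float)
    shared = unmasked.astype(float) @ unmasked.T.astype(float)
    off = ~np.eye(b.n_samples, dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ComputationError(
            f"samples {b.sample_ids[i]!r} and {b.sample_ids[j]!r} share no "
            f"mutually unmasked band columns"
        )
    d2 = present @ absent.T + absent @ present.T
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(ids=list(b.sample_ids), data=d2,
                          metric="squared-euclidean-band")


@dataclass
class AmovaResult:
    """Two-level AMOVA variance partition and permutation test."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    n0: float
    va: float  # among-population variance component (clamped at 0)
    vw: float  # within-population component
    pct_among: float
    pct_within: float
    phi_pt: float
    n_perm: int
    perm_p: float | None
    seed: int | None
    populations: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "df_among", "df_within", "ss_among", "ss_within", "ss_total",
                "ms_among", "ms_within", "n0", "va", "vw", "pct_among",
                "pct_within", "phi_pt", "n_perm", "perm_p", "seed",
            )
        }
        d["populations"] = dict(self.populations)
        return d

    def to_table(self) -> str:
        """Plain-text variance table (sources, df, SS, MS, est. var., %)."""
        lines = [
            f"{'Source':<18}{'df':>5}{'SS':>12}{'MS':>12}{'Est.Var.':>10}{'%':>7}",
            f"{'Among populations':<18}{self.df_among:>5}{self.ss_among:>12.2f}"
            f"{self.ms_among:>12.2f}{self.va:>10.2f}{self.pct_among:>6.0f}%",
            f"{'Within populations':<18}{self.df_within:>5}{self.ss_within:>12.2f}"
            f"{self.ms_within:>12.2f}{self.vw:>10.2f}{self.pct_within:>6.0f}%",
            f"{'Total':<18}{self.df_among + self.df_within:>5}"
            f"{self.ss_total:>12.2f}{'':>12}{self.va + self.vw:>10.2f}{'':>7}",
            "",
            f"Phi_PT = {self.phi_pt:.3f}",
        ]
        if self.perm_p is not None:
            lines.append(
                f"P(perm) = {self.perm_p:.4g}  ({self.n_perm} permutations, "
                f"seed={self.seed})"
            )
        return "\n".join(lines)


def phi_from_components(va: float, vw: float) -> float:
    """Phi_PT from variance components, with negative Va clamped to zero."""
    va = max(0.0, va)
    total = va + vw
    if total <= 0:
        return 0.0
    return va / total


def _group_indices(ids: list[str], partition) -> dict[str, np.ndarray]:
    if isinstance(partition, pd.Series):
        labels = [partition[i] for i in ids]
    elif isinstance(partition, dict):
        labels = [partition[i] for i in ids]
    else:
        labels = list(partition)
        if len(labels) != len(ids):
            raise ValidationError("partition length does not match samples")
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(str(lab), []).append(idx)
    return {k: np.asarray(v, dtype=np.intp) for k, v in groups.items()}


def _ss_parts(w: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    n = w.shape[0]
    ss_total = w.sum() / (2.0 * n)
    ss_within = sum(w[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)
    return ss_total, ss_within


def amova(
    d: DistanceMatrix,
    partition,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA of a distance matrix over a population partition.

    Parameters
    ----------
    d :
        Pairwise distances; matrices whose metric tag starts with
        ``"squared"`` are used as squared distances directly, anything else is
        squared element-wise.
    partition :
        Population label per sample (dict/Series keyed by sample id, or a
        sequence aligned with ``d.ids``).  Every population needs >= 2
        samples and there must be >= 2 populations.
    n_perm :
        Random label permutations for the Phi_PT test; 0 skips the test
        (``perm_p`` is None).
    seed :
        Seed for the permutation stream; identical seeds give identical
        P-values.
    """
    if n_perm < 0:
        raise ValidationError("n_perm must be >= 0")
    groups = _group_indices(d.ids, partition)
    if len(groups) < 2:
        raise ValidationError("need at least 2 populations")
    for label, idx in groups.items():
        if len(idx) < 2:
            raise ValidationError(f"population {label!r} has fewer than 2 samples")
    w = d.data if d.metric.startswith("squared") else d.data**2
    n = d.n
    p = len(groups)
    sizes = np.array([len(g) for g in groups.values()], dtype=float)
    group_list = list(groups.values())

    ss_total, ss_within = _ss_parts(w, group_list)
    ss_among = ss_total - ss_within
    df_among, df_within = p - 1, n - p
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / (p - 1)

    def raw_phi(ms_a: float, ms_w: float) -> float:
        va_raw = (ms_a - ms_w) / n0
        denom = va_raw + ms_w
        if denom <= 0:
            return 0.0
        return va_raw / denom

    phi_raw_obs = raw_phi(ms_among, ms_within)
    va = max(0.0, (ms_among - ms_within) / n0)
    vw = ms_within
    phi = phi_from_components(va, vw)
    total_var = va + vw
    pct_among = 100.0 * va / total_var if total_var > 0 else 0.0

    perm_p: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        bounds = np.cumsum([0] + [len(g) for g in group_list])
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            perm_groups = [perm[bounds[k]:bounds[k + 1]] for k in range(p)]
            sst_p, ssw_p = _ss_parts(w, perm_groups)
            ms_a_p = (sst_p - ssw_p) / df_among
            ms_w_p = ssw_p / df_within
            if raw_phi(ms_a_p, ms_w_p) >= phi_raw_obs - 1e-12:
                exceed += 1
        perm_p = (1 + exceed) / (1 + n_perm)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
        ms_among=ms_among,
        ms_within=ms_within,
        n0=n0,
        va=va,
        vw=vw,
        pct_among=pct_among,
        pct_within=100.0 - pct_among if total_var > 0 else 0.0,
        phi_pt=phi,
        n_perm=n_perm,
        perm_p=perm_p,
        seed=seed,
        populations={k: int(len(v)) for k, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    """Per-population diversity indices, per locus and averaged.

    ``per_locus`` columns: ``n`` (samples scored), ``na`` (observed alleles),
    ``ne`` (effective alleles, 1/sum(p^2)), ``i`` (Shannon information,
    -sum(p ln p)), ``he`` (expected heterozygosity, 1 - sum(p^2)) and ``uhe``
    (unbiased He, scaled by 2n/(2n-1)).  ``mean``/``se`` summarise across
    loci; SE is the sample standard deviation over loci divided by sqrt(L).
    """

    population: str
    n_samples: int
    per_locus: pd.DataFrame
    mean: pd.Series
    se: pd.Series


def _locus_stats(calls: pd.Series) -> dict[str, float] | None:
    counts = {"I": 0, "J": 0, "X": 0}
    n_scored = 0
    for call in calls:
        if call == "NN":
            continue
        n_scored += 1
        counts[call[0]] += 1
        counts[call[1]] += 1
    if n_scored == 0:
        return None
    p = np.array([c for c in counts.values() if c > 0], dtype=float)
    p /= 2 * n_scored
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    return {
        "n": n_scored,
        "na": float(len(p)),
        "ne": 1.0 / sum_p2,
        "i": float(-np.sum(p * np.log(p))),
        "he": he,
        "uhe": (2 * n_scored / (2 * n_scored - 1)) * he if n_scored >= 1 else he,
    }


def diversity_stats(g: GenotypeMatrix, partition) -> list[DiversityStats]:
    """Allele-frequency diversity indices per population.

    Loci with no scored sample in a population are skipped with a warning.
    Raises for an empty population.
    """
    groups = _group_indices(g.sample_ids, partition)
    out: list[DiversityStats] = []
    for label, idx in sorted(groups.items()):
        if len(idx) == 0:
            raise ValidationError(f"population {label!r} is empty")
        sub = g.calls.iloc[idx]
        rows = {}
        for mid in g.marker_ids:
            stats = _locus_stats(sub[mid])
            if stats is None:
                log.warning(
                    "population %s: locus %s has no scored sample, skipped",
                    label, mid,
                )
                continue
            rows[mid] = stats
        if not rows:
            raise ComputationError(f"population {label!r}: no scorable locus")
        per_locus = pd.DataFrame.from_dict(rows, orient="index")
        metrics = per_locus[["na", "ne", "i", "he", "uhe"]]
        nloci = len(per_locus)
        se = metrics.std(ddof=1) / math.sqrt(nloci) if nloci > 1 else metrics.std(ddof=0)
        out.append(
            DiversityStats(
                population=label,
                n_samples=len(idx),
                per_locus=per_locus,
                mean=metrics.mean(),
                se=se,
            )
        )
    return out
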