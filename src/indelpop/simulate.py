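"""Synthetic genotype-panel generator with recorded ground truth.

Emulates a selfing-species (rice landrace) InDel panel: samples are nearly
homozygous, with an explicit per-call heterozygote rate rather than
Hardy-Weinberg draws; one or more latent populations differ in their
per-locus japonica-allele frequency spectra (each locus frequency drawn from
a Beta distribution per population); sparse null alleles and a rare
non-reference allele at triallelic loci overlay the clean genotypes.

Truth is recorded at two levels: the Beta-drawn per-locus frequencies
(parameter level) and the realized per-sample japonica-allele proportion of
the emitted calls (realization level), so both exact bookkeeping identities
and statistical recovery can be tested downstream.

Generation is keyed per (seed, population, sample), so panels are
deterministic under a seed and individual samples do not depend on the order
in which others are drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .index import allele_frequencies
from .io import GenotypeMatrix, MarkerDef, ValidationError, write_genotype_table

__all__ = [
    "PopulationSpec",
    "SimPanelConfig",
    "TruthTable",
    "simulate_panel",
    "study_scale_preset",
    "divergent_preset",
    "write_panel",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One latent population: size and japonica-allele frequency spectrum.

    Per-locus japonica frequency q ~ Beta(alpha, beta); alpha/beta skew the
    population toward the japonica (large alpha) or indica (large beta) side.
    """

    label: str
    n_samples: int
    japonica_freq_alpha: float
    japonica_freq_beta: float

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError(f"population {self.label!r}: need >= 2 samples")
        if self.japonica_freq_alpha <= 0 or self.japonica_freq_beta <= 0:
            raise ValidationError(f"population {self.label!r}: Beta parameters must be > 0")


@dataclass(frozen=True)
class SimPanelConfig:
    """Study conditions for a simulated panel.

    Defaults mirror a 42-locus rice InDel survey: one triallelic locus, a low
    per-call heterozygote rate (landraces are selfers; observed per-sample
    rates span roughly 0-17%), sparse null alleles (~0.5% of calls) and a
    rare third allele at triallelic loci.
    """

    populations: tuple[PopulationSpec, ...]
    n_loci: int = 42
    n_triallelic: int = 1
    het_rate: float = 0.03
    null_rate: float = 0.005
    x_allele_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValidationError("need at least one population")
        if self.n_loci < 1:
            raise ValidationError("n_loci must be >= 1")
        if not 0 <= self.n_triallelic <= self.n_loci:
            raise ValidationError("n_triallelic outside [0, n_loci]")
        for name in ("het_rate", "null_rate", "x_allele_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} = {rate} outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.populations)


@dataclass
class TruthTable:
    """Ground truth aligned with a simulated panel.

    ``locus_freqs``: Beta-drawn japonica frequency per (population, locus).
    ``per_sample``: population label, the generating expectation of F_j
    (population mean of the locus frequencies) and the realized F_j computed
    from the emitted calls by the same bookkeeping the index stage uses.
    """

    locus_freqs: pd.DataFrame  # populations x loci
    per_sample: pd.DataFrame  # population, expected_f_j, realized_f_j

    def census(self) -> "pd.Series":
        """Class census implied by the realized per-sample F_j."""
        from .index import classify

        classes = self.per_sample["realized_f_j"].map(lambda f: classify(f).value)
        return classes.value_counts()


def _synthetic_markers(cfg: SimPanelConfig, rng: np.random.Generator) -> list[MarkerDef]:
    """Invent a plausible marker catalogue: band sizes 100-300 bp, InDels 6-68 bp."""
    markers = []
    triallelic = set(range(cfg.n_triallelic))  # first loci carry the third band
    for k in range(cfg.n_loci):
        indel = int(rng.integers(6, 69))
        japonica = int(rng.integers(100, 300 - indel))
        indica = japonica + indel
        bands = [indica, japonica]
        if k in triallelic:
            extra = japonica - int(rng.integers(10, 40))
            while extra in bands or extra <= 0:
                extra -= 3
            bands.append(extra)
        markers.append(
            MarkerDef(
                marker_id=f"S{k + 1:02d}M",
                chromosome=(k % 12) + 1,
                band_sizes_bp=tuple(bands),
                indica_ref_band_bp=indica,
                japonica_ref_band_bp=japonica,
                indel_size_bp=indel,
            )
        )
    return markers


def simulate_panel(cfg: SimPanelConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw a genotype panel and its truth table from the configured conditions.

    Per population and locus the japonica frequency q is a Beta draw; per
    sample-locus the call is IJ with probability ``het_rate``, otherwise JJ
    with probability q and II with probability 1-q.  A null overlay replaces
    calls with NN at ``null_rate`` and, at triallelic loci, one allele is
    substituted by the non-reference X allele at ``x_allele_rate``.
    """
    master = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
    marker_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=master.entropy, spawn_key=(0,)))
    markers = _synthetic_markers(cfg, marker_rng)
    triallelic_ids = {m.marker_id for m in markers if len(m.band_sizes_bp) > 2}

    all_calls: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    expected: dict[str, float] = {}
    locus_rows = {}
    for p_idx, pop in enumerate(cfg.populations):
        pop_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(1, p_idx)))
        q = pop_rng.beta(
            pop.japonica_freq_alpha, pop.japonica_freq_beta, size=cfg.n_loci
        )
        locus_rows[pop.label] = q
        for s_idx in range(pop.n_samples):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(2, p_idx, s_idx)))
            sid = f"{pop.label}_{s_idx + 1:03d}"
            u = rng.random((5, cfg.n_loci))
            calls = []
            for locus, m in enumerate(markers):
                if u[0, locus] < cfg.het_rate:
                    call = "IJ"
                elif u[1, locus] < q[locus]:
                    call = "JJ"
                else:
                    call = "II"
                if m.marker_id in triallelic_ids and u[2, locus] < cfg.x_allele_rate:
                    if call == "II":
                        call = "IX"
                    elif call == "JJ":
                        call = "JX"
                    else:  # IJ: replace either reference allele
                        call = "IX" if u[4, locus] < 0.5 else "JX"
                if u[3, locus] < cfg.null_rate:
                    call = "NN"
                calls.append(call)
            all_calls[sid] = calls
            labels[sid] = pop.label
            expected[sid] = float(q.mean())

    calls_df = pd.DataFrame.from_dict(
        all_calls, orient="index", columns=[m.marker_id for m in markers]
    )
    meta = pd.DataFrame({"population": pd.Series(labels)})
    g = GenotypeMatrix(markers=markers, calls=calls_df, sample_meta=meta)

    realized = {
        sid: allele_frequencies(sid, g.calls.loc[sid]).f_j for sid in g.sample_ids
    }
    per_sample = pd.DataFrame(
        {
            "population": pd.Series(labels),
            "expected_f_j": pd.Series(expected),
            "realized_f_j": pd.Series(realized),
        }
    ).loc[g.sample_ids]
    locus_freqs = pd.DataFrame(
        locus_rows, index=[m.marker_id for m in markers]
    ).T
    return g, TruthTable(locus_freqs=locus_freqs, per_sample=per_sample)


def study_scale_preset(seed: int | None = None) -> SimPanelConfig:
    """Study-scale conditions: 192 samples x 42 loci, one triallelic locus.

    Four latent populations: a 2-sample typical-indica extreme and a 2-sample
    typical-japonica extreme (reference-cultivar stand-ins), a dominant
    indica-like population (160 samples, locus frequencies Beta(5, 17),
    mean q = 0.23, spanning the indica / close-to-indica classes) and a
    japonica-leaning population (28 samples, Beta(12, 8), mean q = 0.60,
    spanning intermediate / close-to-japonica) — about 85% of the panel on
    the indica side.
    """
    return SimPanelConfig(
        populations=(
            PopulationSpec("indica_ref", 2, 0.2, 30.0),
            PopulationSpec("indica_like", 160, 5.0, 17.0),
            PopulationSpec("japonica_leaning", 28, 12.0, 8.0),
            PopulationSpec("japonica_ref", 2, 30.0, 0.2),
        ),
        n_loci=42,
        n_triallelic=1,
        seed=seed,
    )


def divergent_preset(
    n_per_pop: int = 30, seed: int | None = None
) -> SimPanelConfig:
    """Two strongly diverged populations: Beta(2, 18) vs Beta(18, 2) spectra."""
    return SimPanelConfig(
        populations=(
            PopulationSpec("pop_indica", n_per_pop, 2.0, 18.0),
            PopulationSpec("pop_japonica", n_per_pop, 18.0, 2.0),
        ),
        n_loci=42,
        n_triallelic=1,
        seed=seed,
    )


def write_panel(
    g: GenotypeMatrix,
    truth: TruthTable,
    outdir: str | Path,
    header_lines: tuple[str, ...] = (),
) -> dict[str, Path]:
    """Write genotypes.csv / markers.tsv / samples.tsv / truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.csv",
        "markers": outdir / "markers.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_genotype_table(g, paths["genotypes"], header_lines)
    rows = []
    for m in g.markers:
        rows.append(
            {
                "marker_id": m.marker_id,
                "chromosome": m.chromosome,
                "band_sizes": ",".join(str(b) for b in m.band_sizes_bp),
                "indica_band": m.indica_ref_band_bp or "",
                "japonica_band": m.japonica_ref_band_bp or "",
                "indel_size": m.indel_size_bp,
                "dominant": int(m.is_dominant),
            }
        )
    with open(paths["markers"], "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    with open(paths["samples"], "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        meta = g.sample_meta if g.sample_meta is not None else pd.DataFrame(
            index=g.sample_ids
        )
        meta.rename_axis("sample_id").to_csv(fh, sep="\t")
    truth_doc = {
        "locus_freqs": {
            pop: truth.locus_freqs.loc[pop].to_dict()
            for pop in truth.locus_freqs.index
        },
        "per_sample": truth.per_sample.to_dict(orient="index"),
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths
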