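"""Reading, validation and band-level encoding of codominant InDel genotype panels.

An InDel marker amplifies one band per allele; alleles are named after the
reference cultivar whose banding pattern they match — ``I`` for the indica
reference (Swarna-like band) and ``J`` for the japonica reference
(Dongjinbyeo-like band).  A third, non-reference band is coded ``X``.  Each
sample x locus cell therefore holds one of the codominant calls ``II``, ``JJ``,
``IJ``, ``IX``, ``JX``, ``XX`` or the null call ``NN`` (no amplification).

The module reads marker metadata (TSV) and genotype tables (CSV), scores raw
band-size profiles against the reference cultivars, and expands the calls into
the binary band presence/absence matrix that all distance-based stages consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ScoringError",
    "ComputationError",
    "MarkerDef",
    "GenotypeMatrix",
    "BandMatrix",
    "PanelSummary",
    "CALL_CODES",
    "read_marker_metadata",
    "load_table1",
    "table1_path",
    "read_genotype_table",
    "write_genotype_table",
    "read_sample_metadata",
    "score_bands",
    "to_band_matrix",
    "panel_summary",
]


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


class ScoringError(ValidationError):
    """A band profile that cannot be resolved into a genotype call."""


class ComputationError(RuntimeError):
    """A computation that is undefined for the given inputs."""


#: Vocabulary of codominant genotype calls.  Allele letters are ordered
#: I < J < X; heterozygous calls always use that order.
CALL_CODES: tuple[str, ...] = ("II", "JJ", "IJ", "NN", "IX", "JX", "XX")
_CALL_SET = frozenset(CALL_CODES)

#: Cell values treated as missing data in genotype CSV files.
MISSING_SYNONYMS = frozenset({"", "NA", "NN"})

#: Cell values meaning "band absent" at a dominant (presence/absence) marker.
ABSENT_SYNONYMS = frozenset({"-", "ABSENT"})

_ALLELE_ORDER = {"I": 0, "J": 1, "X": 2}

_BAND_CELL_RE = re.compile(r"\d+(/\d+)*")


# ---------------------------------------------------------------------------
# Marker metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDef:
    """One InDel locus: its catalogued band sizes and reference alleles.

    Parameters
    ----------
    marker_id :
        Unique marker name (e.g. ``"R2M37"``).
    chromosome :
        Rice chromosome number, 1-12.
    band_sizes_bp :
        Catalogued amplicon sizes in base pairs, unique and positive.
    indica_ref_band_bp, japonica_ref_band_bp :
        The band observed in the indica / japonica reference cultivar.  Both
        must be present for codominant markers; a dominant marker carries
        exactly one of them (the single scorable band).
    indel_size_bp :
        Insertion/deletion length distinguishing the reference alleles
        (0 when not applicable).
    is_dominant :
        True for a presence/absence marker with a single scorable band.
    """

    marker_id: str
    chromosome: int
    band_sizes_bp: tuple[int, ...]
    indica_ref_band_bp: int | None = None
    japonica_ref_band_bp: int | None = None
    indel_size_bp: int = 0
    is_dominant: bool = False

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValidationError("marker_id must be non-empty")
        if not 1 <= int(self.chromosome) <= 12:
            raise ValidationError(
                f"{self.marker_id}: chromosome {self.chromosome} outside 1-12"
            )
        bands = tuple(int(b) for b in self.band_sizes_bp)
        if len(bands) == 0:
            raise ValidationError(f"{self.marker_id}: no band sizes")
        if any(b <= 0 for b in bands):
            raise ValidationError(f"{self.marker_id}: band sizes must be positive")
        if len(set(bands)) != len(bands):
            raise ValidationError(f"{self.marker_id}: duplicate band sizes")
        object.__setattr__(self, "band_sizes_bp", bands)
        for ref in (self.indica_ref_band_bp, self.japonica_ref_band_bp):
            if ref is not None and ref not in bands:
                raise ValidationError(
                    f"{self.marker_id}: reference band {ref} not in catalogue {bands}"
                )
        if self.is_dominant:
            if len(bands) != 1:
                raise ValidationError(
                    f"{self.marker_id}: dominant marker must have exactly one band"
                )
            n_refs = (self.indica_ref_band_bp is not None) + (
                self.japonica_ref_band_bp is not None
            )
            if n_refs != 1:
                raise ValidationError(
                    f"{self.marker_id}: dominant marker needs exactly one reference band"
                )
        else:
            if self.indica_ref_band_bp is None or self.japonica_ref_band_bp is None:
                raise ValidationError(
                    f"{self.marker_id}: codominant marker needs both reference bands"
                )
            if self.indica_ref_band_bp == self.japonica_ref_band_bp:
                raise ValidationError(
                    f"{self.marker_id}: reference bands must differ"
                )
        if self.indel_size_bp < 0:
            raise ValidationError(f"{self.marker_id}: negative InDel size")

    @property
    def dominant_carrier(self) -> str:
        """Allele letter of the reference that carries a dominant marker's band."""
        if not self.is_dominant:
            raise ValidationError(f"{self.marker_id} is not dominant")
        return "I" if self.indica_ref_band_bp is not None else "J"

    def allele_of_band(self, band_bp: int) -> str:
        """Map a catalogued band size to its allele letter (I/J/X)."""
        if band_bp == self.indica_ref_band_bp:
            return "I"
        if band_bp == self.japonica_ref_band_bp:
            return "J"
        if band_bp in self.band_sizes_bp:
            return "X"
        raise ValidationError(f"{self.marker_id}: band {band_bp} not catalogued")

    def band_columns(self) -> tuple[int, ...]:
        """Catalogued bands in binary-matrix column order.

        Reference bands come first (indica before japonica), then any
        non-reference bands in decreasing size.
        """
        cols: list[int] = []
        if self.indica_ref_band_bp is not None:
            cols.append(self.indica_ref_band_bp)
        if self.japonica_ref_band_bp is not None:
            cols.append(self.japonica_ref_band_bp)
        extra = [b for b in self.band_sizes_bp if b not in cols]
        cols.extend(sorted(extra, reverse=True))
        return tuple(cols)


def _parse_optional_int(value: object) -> int | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in {"", "-", "nan", "NA"}:
        return None
    return int(float(s))


def read_marker_metadata(path: str | Path) -> list[MarkerDef]:
    """Parse a marker metadata TSV into validated :class:`MarkerDef` records.

    Required columns: ``marker_id``, ``chromosome``, ``band_sizes`` (comma
    separated bp sizes), ``indica_band``, ``japonica_band``, ``indel_size``,
    ``dominant`` (0/1).  Extra columns (e.g. published informativeness
    statistics) are ignored here; use :func:`load_table1` to retain them.
    File order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty marker metadata file") from exc
    if df.empty:
        raise ValidationError(f"{path}: no marker rows")
    required = {"marker_id", "chromosome", "band_sizes"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    markers: list[MarkerDef] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        mid = row["marker_id"].strip()
        if mid in seen:
            raise ValidationError(f"{path}: duplicate marker_id {mid!r}")
        seen.add(mid)
        try:
            bands = tuple(
                int(b) for b in re.split(r"[,;]\s*", row["band_sizes"].strip()) if b
            )
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unparseable band list {row['band_sizes']!r} for {mid}"
            ) from exc
        try:
            chrom = int(float(row["chromosome"]))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: bad chromosome {row['chromosome']!r} for {mid}"
            ) from exc
        markers.append(
            MarkerDef(
                marker_id=mid,
                chromosome=chrom,
                band_sizes_bp=bands,
                indica_ref_band_bp=_parse_optional_int(row.get("indica_band")),
                japonica_ref_band_bp=_parse_optional_int(row.get("japonica_band")),
                indel_size_bp=_parse_optional_int(row.get("indel_size")) or 0,
                is_dominant=str(row.get("dominant", "0")).strip() in {"1", "true", "True"},
            )
        )
    return markers


def table1_path() -> Path:
    """Filesystem path of the bundled 42-marker reference panel table."""
    return Path(resources.files("indelpop").joinpath("data/markers_table1.tsv"))


def load_table1() -> tuple[list[MarkerDef], pd.DataFrame]:
    """Load the bundled 42-marker panel: definitions plus published statistics.

    Returns the validated :class:`MarkerDef` list and a DataFrame (indexed by
    ``marker_id``) with the published per-marker columns ``pic``, ``rp``,
    ``npa``, ``ppa``, ``emr``, ``mi`` and ``indel_size``.
    """
    path = table1_path()
    markers = read_marker_metadata(path)
    df = pd.read_csv(path, sep="\t").set_index("marker_id")
    stats = df[["chromosome", "indel_size", "pic", "rp", "npa", "ppa", "emr", "mi"]]
    return markers, stats.astype(float)


# ---------------------------------------------------------------------------
# Band scoring
# ---------------------------------------------------------------------------

def score_bands(
    observed_bands_bp: Sequence[int],
    marker: MarkerDef,
    tolerance_bp: int = 0,
) -> str:
    """Score an observed band-size profile into a codominant genotype call.

    Each observed band is matched (within ``tolerance_bp``) to the nearest
    catalogued band of the marker and translated to its allele letter: the
    indica reference band -> I, the japonica reference band -> J, any other
    catalogued band -> X.  One distinct allele yields a homozygous call
    (II/JJ/XX), two distinct alleles a heterozygous call (IJ/IX/JX), no band a
    null call (NN).  For dominant markers, band presence is the call of the
    reference carrying the band and band absence the homozygote of the other
    reference (absence is an allele, not missing data).

    Raises
    ------
    ScoringError
        If a band matches no catalogued allele within tolerance, or more than
        two distinct alleles are matched (the cell should be reviewed).
    """
    if tolerance_bp < 0:
        raise ValidationError("tolerance_bp must be >= 0")
    alleles: set[str] = set()
    for band in observed_bands_bp:
        candidates = [
            b for b in marker.band_sizes_bp if abs(b - band) <= tolerance_bp
        ]
        if not candidates:
            raise ScoringError(
                f"{marker.marker_id}: band {band} bp matches no catalogued allele "
                f"{marker.band_sizes_bp} within {tolerance_bp} bp"
            )
        nearest = min(candidates, key=lambda b: (abs(b - band), b))
        alleles.add(marker.allele_of_band(nearest))
    if marker.is_dominant:
        carrier = marker.dominant_carrier
        other = "J" if carrier == "I" else "I"
        return carrier * 2 if alleles else other * 2
    if not alleles:
        return "NN"
    if len(alleles) > 2:
        raise ScoringError(
            f"{marker.marker_id}: profile {list(observed_bands_bp)} matches "
            f"{len(alleles)} distinct alleles; flag for manual review"
        )
    ordered = sorted(alleles, key=_ALLELE_ORDER.__getitem__)
    if len(ordered) == 1:
        return ordered[0] * 2
    return ordered[0] + ordered[1]


def call_alleles(call: str) -> tuple[str, str] | None:
    """The two allele letters of a call, or None for a null call."""
    if call == "NN":
        return None
    return call[0], call[1]


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """A sample x marker grid of codominant genotype calls.

    ``calls`` is a string DataFrame indexed by sample id with one column per
    marker, every cell a member of :data:`CALL_CODES`.  Optional per-sample
    metadata (population label, collection-site latitude/longitude in degrees,
    altitude in metres) rides along in ``sample_meta``.
    """

    markers: list[MarkerDef]
    calls: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = list(self.calls.index)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        marker_ids = [m.marker_id for m in self.markers]
        if len(set(marker_ids)) != len(marker_ids):
            raise ValidationError("duplicate marker ids")
        if list(self.calls.columns) != marker_ids:
            raise ValidationError("calls columns do not match marker list")
        bad = ~self.calls.isin(_CALL_SET)
        if bad.to_numpy().any():
            cell = next(
                (s, m)
                for s in self.calls.index
                for m in self.calls.columns
                if bad.at[s, m]
            )
            raise ValidationError(
                f"invalid call {self.calls.at[cell[0], cell[1]]!r} at sample "
                f"{cell[0]!r}, marker {cell[1]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def marker(self, marker_id: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)


def read_genotype_table(
    path: str | Path,
    markers: Iterable[MarkerDef],
    tolerance_bp: int = 0,
    sample_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a genotype CSV into a validated :class:`GenotypeMatrix`.

    The file is UTF-8, comma separated, first column ``sample_id``, one column
    per marker.  Cells may be call codes (``II``, ``JJ``, ...), raw band-size
    strings (``"211/151"`` or ``"151"``, scored via :func:`score_bands`),
    missing-data synonyms (``""``, ``"NA"``, ``"NN"``) or — at dominant markers
    only — the band-absence synonyms ``"-"``/``"ABSENT"``.
    """
    marker_map = {m.marker_id: m for m in markers}
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty genotype file") from exc
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected sample_id column plus markers")
    if df.columns[0] != "sample_id":
        raise ValidationError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    unknown = [c for c in df.columns[1:] if c not in marker_map]
    if unknown:
        raise ValidationError(f"{path}: unknown marker column(s) {unknown}")
    used = [marker_map[c] for c in df.columns[1:]]
    df = df.set_index("sample_id").rename_axis(None)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    for mid in df.columns:
        marker = marker_map[mid]
        for sid, raw in df[mid].items():
            parsed.at[sid, mid] = _parse_cell(str(raw), marker, tolerance_bp, sid)
    return GenotypeMatrix(markers=used, calls=parsed, sample_meta=sample_meta)


def _parse_cell(raw: str, marker: MarkerDef, tolerance_bp: int, sample_id: str) -> str:
    cell = raw.strip()
    if cell.upper() in MISSING_SYNONYMS:
        return "NN"
    if cell in _CALL_SET:
        return cell
    if marker.is_dominant and cell.upper() in ABSENT_SYNONYMS:
        return score_bands([], marker)
    if _BAND_CELL_RE.fullmatch(cell):
        bands = [int(b) for b in cell.split("/")]
        return score_bands(bands, marker, tolerance_bp)
    raise ValidationError(
        f"cell {raw!r} at sample {sample_id!r}, marker {marker.marker_id!r} is "
        f"neither a call code nor a band profile"
    )


def write_genotype_table(
    g: GenotypeMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write calls back to the genotype CSV dialect (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        g.calls.rename_axis("sample_id").to_csv(fh)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the optional per-sample metadata TSV.

    Columns: ``sample_id`` plus any of ``population``, ``latitude``,
    ``longitude``, ``altitude_m``.  Returns a DataFrame indexed by sample id,
    numeric coordinate columns coerced to float (blank -> NaN).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    for col in ("latitude", "longitude", "altitude_m"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# Binary band matrix
# ---------------------------------------------------------------------------

@dataclass
class BandMatrix:
    """Binary presence/absence expansion of a genotype panel.

    One column per catalogued band (``"<marker_id>:<size>"``); ``values`` holds
    0/1 presence, ``mask`` is True where a null call leaves band presence
    unknown (masked cells are excluded from all distance computations).
    """

    sample_ids: list[str]
    band_ids: list[str]
    values: np.ndarray  # (n_samples, n_bands) int8
    mask: np.ndarray  # (n_samples, n_bands) bool, True = missing
    band_marker: list[str]  # marker id owning each column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, b = self.values.shape
        if len(self.sample_ids) != n or len(self.band_ids) != b:
            raise ValidationError("band matrix dimensions do not match id lists")
        if self.mask.shape != (n, b):
            raise ValidationError("mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Presence as float DataFrame with NaN at masked cells."""
        arr = self.values.astype(float)
        arr[self.mask] = np.nan
        return pd.DataFrame(arr, index=self.sample_ids, columns=self.band_ids)


def to_band_matrix(g: GenotypeMatrix) -> BandMatrix:
    """Expand codominant calls into the binary band presence matrix.

    A non-null call at a codominant marker sets exactly one band (homozygote)
    or two bands (heterozygote) of that marker to 1; a null call masks all the
    marker's columns for that sample.  At a dominant marker the band column is
    1 when the carrier allele is present and 0 for the homozygote of the
    band-lacking reference.  An X allele sets the marker's non-reference
    band column(s).
    """
    band_ids: list[str] = []
    band_marker: list[str] = []
    col_of: dict[tuple[str, str], list[int]] = {}
    for m in g.markers:
        for band in m.band_columns():
            idx = len(band_ids)
            band_ids.append(f"{m.marker_id}:{band}")
            band_marker.append(m.marker_id)
            col_of.setdefault((m.marker_id, m.allele_of_band(band)), []).append(idx)
    n, b = g.n_samples, len(band_ids)
    values = np.zeros((n, b), dtype=np.int8)
    mask = np.zeros((n, b), dtype=bool)
    marker_cols = {
        m.marker_id: [i for i, mm in enumerate(band_marker) if mm == m.marker_id]
        for m in g.markers
    }
    calls = g.calls.to_numpy()
    for i in range(n):
        for j, m in enumerate(g.markers):
            call = calls[i, j]
            if call == "NN":
                mask[i, marker_cols[m.marker_id]] = True
                continue
            for letter in set(call):
                for c in col_of.get((m.marker_id, letter), []):
                    values[i, c] = 1
    return BandMatrix(
        sample_ids=g.sample_ids,
        band_ids=band_ids,
        values=values,
        mask=mask,
        band_marker=band_marker,
    )


# ---------------------------------------------------------------------------
# Panel summary
# ---------------------------------------------------------------------------

@dataclass
class PanelSummary:
    """Per-sample and per-marker call composition of a panel."""

    per_sample: pd.DataFrame  # n_ii, n_jj, n_ij, n_nn, n_x, n_het
    per_marker: pd.DataFrame  # n_null, n_het
    totals: dict[str, int]


def panel_summary(g: GenotypeMatrix) -> PanelSummary:
    """Count II/JJ/IJ/NN and X-coded calls per sample and nulls per marker.

    ``n_het`` counts calls with two distinct alleles (IJ, IX, JX); ``n_x``
    counts calls containing at least one non-reference X allele.
    """
    calls = g.calls
    het = calls.isin(["IJ", "IX", "JX"])
    has_x = calls.isin(["IX", "JX", "XX"])
    per_sample = pd.DataFrame(
        {
            "n_ii": (calls == "II").sum(axis=1),
            "n_jj": (calls == "JJ").sum(axis=1),
            "n_ij": (calls == "IJ").sum(axis=1),
            "n_nn": (calls == "NN").sum(axis=1),
            "n_x": has_x.sum(axis=1),
            "n_het": het.sum(axis=1),
        }
    )
    per_marker = pd.DataFrame(
        {
            "n_null": (calls == "NN").sum(axis=0),
            "n_het": het.sum(axis=0),
        }
    )
    totals = {
        "n_samples": g.n_samples,
        "n_markers": g.n_markers,
        "n_null_calls": int(per_sample["n_nn"].sum()),
        "n_het_calls": int(per_sample["n_het"].sum()),
        "n_samples_with_null": int((per_sample["n_nn"] > 0).sum()),
        "n_samples_with_het": int((per_sample["n_het"] > 0).sum()),
    }
    return PanelSummary(per_sample=per_sample, per_marker=per_marker, totals=totals)
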