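"""Data model and TSV/BED readers and writers shared by every pipeline stage.

Conventions
-----------
* Internal coordinates are 1-based closed intervals, matching SNP-array
  annotation files; BED export converts to 0-based half-open.
* Genotype calls are stored as small integers (:data:`HOM_A`, :data:`HOM_B`,
  :data:`HET`, :data:`NOCALL`); nucleotide identity lives only in the marker
  annotation, so merge logic can reason about alleles while call matrices
  stay platform-agnostic.
* Missing intensity values are permitted (NaN) and ignored downstream.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

# genotype call codes
HOM_A: int = 0
HOM_B: int = 1
HET: int = 2
NOCALL: int = -1

GENOTYPE_TOKENS = {"AA": HOM_A, "BB": HOM_B, "AB": HET, "NC": NOCALL}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_TOKENS.items()}

VALID_PROBE_CLASSES = ("snp", "intensity_only")
_NUCS = frozenset("ACGT")

ANNOTATION_COLUMNS = ["marker_id", "chrom", "pos", "allele_a", "allele_b", "probe_class"]


class FormatError(ValueError):
    """Raised when an input table violates its declared dialect."""


@dataclass
class MarkerAnnotation:
    """Per-platform marker map: id, position, alleles and probe class.

    ``df`` holds one row per marker with columns ``marker_id``, ``chrom``,
    ``pos`` (1-based), ``allele_a``, ``allele_b`` (empty strings for
    intensity-only probes) and ``probe_class``; rows are sorted by
    ``(chrom, pos, marker_id)``.
    """

    df: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.df["marker_id"])

    def subset(self, marker_ids: Sequence[str]) -> "MarkerAnnotation":
        keep = self.df[self.df["marker_id"].isin(set(marker_ids))].copy()
        return MarkerAnnotation(keep, self.platform)

    def positions(self) -> pd.DataFrame:
        """(chrom, pos) indexed by marker_id."""
        return self.df.set_index("marker_id")[["chrom", "pos"]]


@dataclass
class GenotypeMatrix:
    """Samples x markers call matrix over {homA, homB, het, nocall}."""

    samples: list[str]
    markers: list[str]
    calls: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), list(self.markers), self.calls.copy())

    def marker_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.markers)}

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.marker_index()
        cols = [idx[m] for m in marker_ids]
        return GenotypeMatrix(list(self.samples), list(marker_ids), self.calls[:, cols])

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.markers), self.calls[rows, :])

    def call_mask(self) -> np.ndarray:
        """Boolean mask of made calls (anything but nocall)."""
        return self.calls != NOCALL


@dataclass
class IntensityMatrix:
    """Samples x markers relative signal intensity (log2-ratio scale).

    Platform A supplies log2R, platform B supplies logRR; both are
    dimensionless log2 ratios against a reference intensity. NaN = missing.
    """

    samples: list[str]
    markers: list[str]
    values: np.ndarray  # float64, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"intensity matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )

    def marker_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.markers)}

    def subset_markers(self, marker_ids: Sequence[str]) -> "IntensityMatrix":
        idx = self.marker_index()
        cols = [idx[m] for m in marker_ids]
        return IntensityMatrix(list(self.samples), list(marker_ids), self.values[:, cols])

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return IntensityMatrix(list(sample_ids), list(self.markers), self.values[rows, :])


@dataclass
class GenomeMetadata:
    """Chromosome lengths and centromere intervals (1-based closed)."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (start, end) in self.centromeres.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise ValueError(f"centromere given for unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= length):
                raise ValueError(
                    f"centromere [{start}, {end}] outside [1, {length}] on {chrom}"
                )

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenomeMetadata":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        lengths = {str(c): int(v) for c, v in raw["chrom_lengths"].items()}
        cents = {
            str(c): (int(v[0]), int(v[1]))
            for c, v in (raw.get("centromeres") or {}).items()
        }
        return cls(lengths, cents)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "chrom_lengths": {c: int(v) for c, v in self.chrom_lengths.items()},
            "centromeres": {c: [int(s), int(e)] for c, (s, e) in self.centromeres.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    """Natural chromosome order: numeric chromosomes first, then X, then others."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    if name == "X":
        return (1, 0, "")
    return (2, 0, name)


def read_marker_annotation(path: str | Path, platform: str) -> MarkerAnnotation:
    """Read a tab-delimited marker annotation table.

    The file must carry a header with columns ``marker_id``, ``chrom``,
    ``pos``, ``allele_a``, ``allele_b``, ``probe_class``. Markers at
    duplicated positions are accepted here — duplicate handling is a QC
    decision made downstream. Malformed positions, unknown probe classes and
    duplicated marker ids are rejected with the offending line number.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in ANNOTATION_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing annotation columns {missing}")
        col = {c: header.index(c) for c in ANNOTATION_COLUMNS}
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: ragged row ({len(fields)} fields)")
            marker_id = fields[col["marker_id"]]
            if marker_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate marker_id {marker_id!r}")
            seen.add(marker_id)
            raw_pos = fields[col["pos"]]
            try:
                pos = int(raw_pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed position {raw_pos!r}") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position {pos} < 1")
            probe_class = fields[col["probe_class"]]
            if probe_class not in VALID_PROBE_CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: unknown probe_class {probe_class!r}"
                )
            allele_a = fields[col["allele_a"]]
            allele_b = fields[col["allele_b"]]
            if probe_class == "snp":
                if allele_a == allele_b or allele_a not in _NUCS or allele_b not in _NUCS:
                    raise FormatError(
                        f"{path}:{lineno}: invalid SNP alleles {allele_a!r}/{allele_b!r}"
                    )
            rows.append((marker_id, fields[col["chrom"]], pos, allele_a, allele_b, probe_class))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["_ck"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["_ck", "pos", "marker_id"], kind="mergesort").drop(columns="_ck")
    return MarkerAnnotation(df.reset_index(drop=True), platform)


def write_marker_annotation(ann: MarkerAnnotation, path: str | Path) -> None:
    ann.df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, kind: str) -> GenotypeMatrix | IntensityMatrix:
    """Read a samples x markers matrix (first column sample id, header = marker ids).

    ``kind`` selects decoding: ``genotype`` maps tokens AA/BB/AB/NC to call
    codes (anything else is an error); ``intensity`` parses floats with blank
    cells as missing.
    """
    if kind not in ("genotype", "intensity"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        markers = header[1:]
        samples: list[str] = []
        data_rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {len(header)})"
                )
            if fields[0] in samples:
                raise FormatError(f"{path}:{lineno}: duplicated sample id {fields[0]!r}")
            samples.append(fields[0])
            data_rows.append(fields[1:])
    if kind == "genotype":
        calls = np.empty((len(samples), len(markers)), dtype=np.int8)
        for i, row in enumerate(data_rows):
            for j, tok in enumerate(row):
                code = GENOTYPE_TOKENS.get(tok)
                if code is None:
                    raise FormatError(
                        f"{path}:{i + 2}: unknown genotype token {tok!r} at marker {markers[j]}"
                    )
                calls[i, j] = code
        return GenotypeMatrix(samples, markers, calls)
    values = np.empty((len(samples), len(markers)), dtype=np.float64)
    for i, row in enumerate(data_rows):
        for j, tok in enumerate(row):
            if tok == "":
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}:{i + 2}: malformed intensity {tok!r} at marker {markers[j]}"
                    ) from None
    return IntensityMatrix(samples, markers, values)


def write_matrix(matrix: GenotypeMatrix | IntensityMatrix, path: str | Path) -> None:
    """Write a matrix in the dialect :func:`read_matrix` reads (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(matrix.markers) + "\n")
        if isinstance(matrix, GenotypeMatrix):
            for i, sample in enumerate(matrix.samples):
                toks = [GENOTYPE_CODES[int(c)] for c in matrix.calls[i]]
                fh.write(sample + "\t" + "\t".join(toks) + "\n")
        else:
            for i, sample in enumerate(matrix.samples):
                toks = [
                    "" if np.isnan(v) else repr(float(v)) for v in matrix.values[i]
                ]
                fh.write(sample + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Serialize 1-based closed intervals as standard BED (0-based half-open).

    Each interval is ``(chrom, start, end[, name[, score[, extra...]]])`` with
    1-based closed coordinates; written lines use ``start - 1`` and ``end``.
    Output is sorted by (chrom, start). ``end < start`` is rejected.
    """
    recs = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end < start:
            raise ValueError(f"interval end {end} < start {start} on {chrom}")
        if start < 1:
            raise ValueError(f"interval start {start} < 1 on {chrom}")
        recs.append((chrom, start - 1, end) + tuple(iv[3:]))
    recs.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1], r[2]))
    with open(path, "w") as fh:
        for rec in recs:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED back into 1-based closed intervals (inverse of :func:`write_bed`)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            out.append((chrom, start0 + 1, end) + tuple(fields[3:]))
    return out
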