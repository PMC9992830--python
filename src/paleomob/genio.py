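"""Core sample data model and file I/O.

Reads and writes the formats the pipeline touches: per-sample metadata
tables (TSV/CSV), EIGENSTRAT genotype triples (.geno/.snp/.ind) and
long-format result tables.  Also projects geographic coordinates onto the
equal-area planar grid (default: the European ETRS89-LAEA grid) that all
downstream kernel math runs on.

Time is one continuous axis in calendar years, with calBC negative and
calAD positive; no year-zero correction is applied.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._laea import EUROPEAN_GRID, LaeaProjection

__all__ = [
    "MolecularSex",
    "SampleRecord",
    "GenotypeMatrix",
    "ResultTable",
    "FormatError",
    "ValidationError",
    "read_sample_table",
    "write_sample_table",
    "read_eigenstrat",
    "write_eigenstrat",
    "project_coordinates",
    "write_results",
    "read_results",
]

MISSING = -1  # internal code for a missing genotype call ('9' on disk)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class MolecularSex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNDETERMINED = "undetermined"


@dataclass
class SampleRecord:
    """One ancient individual's spatial, temporal and QC metadata.

    Ages are in years calBC/AD (negative = BC); ``age_lo``/``age_hi`` are the
    2-sigma bounds of the calibrated age distribution.  Planar ``x``/``y``
    (meters, equal-area) are filled by :func:`project_coordinates`.
    """

    sample_id: str
    lon: float
    lat: float
    age_median: float
    age_lo: float
    age_hi: float
    x: float | None = None
    y: float | None = None
    age_pmf: list[tuple[float, float]] | None = None
    n_autosomal_snps: int | None = None
    molecular_sex: MolecularSex = MolecularSex.UNDETERMINED
    x_contamination: float | None = None
    region_tag: str | None = None
    flagged_out_of_window: bool = False
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.age_lo <= self.age_median <= self.age_hi):
            raise ValidationError(
                f"sample {self.sample_id!r}: age bounds must satisfy "
                f"age_lo <= age_median <= age_hi "
                f"(got {self.age_lo}, {self.age_median}, {self.age_hi})"
            )
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: coordinates ({self.lon}, {self.lat}) "
                "outside geographic bounds"
            )
        if self.age_pmf is not None:
            probs = np.asarray([p for _, p in self.age_pmf], dtype=float)
            if (probs < 0).any():
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative age_pmf probability"
                )
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"sample {self.sample_id!r}: age_pmf probabilities sum to "
                    f"{probs.sum()!r}, expected 1"
                )
        if self.x_contamination is not None and not (
            0.0 <= self.x_contamination <= 1.0
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: contamination "
                f"{self.x_contamination} outside [0, 1]"
            )


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosage matrix over a fixed SNP panel.

    ``calls`` is loci x samples with values in {0, 1, 2, MISSING}.
    ``locus_ids`` carries (snp_id, chromosome, position) with 1-based
    positions following the EIGENSTRAT .snp convention.
    """

    sample_ids: list[str]
    locus_ids: list[tuple[str, str, int]]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples"
            )
        legal = np.isin(self.calls, (0, 1, 2, MISSING))
        if not legal.all():
            bad = np.unique(self.calls[~legal])
            raise ValidationError(f"illegal genotype call state(s): {bad.tolist()}")


# ---------------------------------------------------------------------------
# sample metadata tables

_REQUIRED_COLUMNS = ("id", "lon", "lat", "age_median", "age_lo", "age_hi")

_OPTIONAL_COLUMNS = {
    "n_autosomal_snps": "n_autosomal_snps",
    "molecular_sex": "molecular_sex",
    "x_contamination": "x_contamination",
    "region_tag": "region_tag",
    "x": "x",
    "y": "y",
}


def read_sample_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[SampleRecord]:
    """Read a sample metadata table into validated :class:`SampleRecord` s.

    ``dialect`` maps canonical column names (``id``, ``lon``, ``lat``,
    ``age_median``, ``age_lo``, ``age_hi``, optional ones) to the names used
    in the file.  Unknown columns are preserved in ``record.extras``.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep=sep, dtype={dialect.get("id", "id"): str})
    colmap = {canon: dialect.get(canon, canon) for canon in _REQUIRED_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise FormatError(
                f"{path}: required column {actual!r} (for {canon!r}) is missing"
            )
    opt = {
        canon: dialect.get(canon, default)
        for canon, default in _OPTIONAL_COLUMNS.items()
    }
    known = set(colmap.values()) | {c for c in opt.values() if c in df.columns}

    records = []
    for _, row in df.iterrows():
        extras = {c: row[c] for c in df.columns if c not in known}
        sex = MolecularSex.UNDETERMINED
        if opt["molecular_sex"] in df.columns and pd.notna(row[opt["molecular_sex"]]):
            sex = MolecularSex(str(row[opt["molecular_sex"]]).lower())
        contam = None
        if opt["x_contamination"] in df.columns and pd.notna(
            row[opt["x_contamination"]]
        ):
            contam = float(row[opt["x_contamination"]])
        rec = SampleRecord(
            sample_id=str(row[colmap["id"]]),
            lon=float(row[colmap["lon"]]),
            lat=float(row[colmap["lat"]]),
            age_median=float(row[colmap["age_median"]]),
            age_lo=float(row[colmap["age_lo"]]),
            age_hi=float(row[colmap["age_hi"]]),
            n_autosomal_snps=(
                int(row[opt["n_autosomal_snps"]])
                if opt["n_autosomal_snps"] in df.columns
                and pd.notna(row[opt["n_autosomal_snps"]])
                else None
            ),
            molecular_sex=sex,
            x_contamination=contam,
            region_tag=(
                str(row[opt["region_tag"]])
                if opt["region_tag"] in df.columns
                and pd.notna(row[opt["region_tag"]])
                else None
            ),
            x=(
                float(row[opt["x"]])
                if opt["x"] in df.columns and pd.notna(row[opt["x"]])
                else None
            ),
            y=(
                float(row[opt["y"]])
                if opt["y"] in df.columns and pd.notna(row[opt["y"]])
                else None
            ),
            extras=extras,
        )
        rec.validate()
        records.append(rec)
    return records


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records as UTF-8 TSV ('.' decimal, NA for missing)."""
    rows = []
    for r in records:
        row = {
            "id": r.sample_id,
            "lon": r.lon,
            "lat": r.lat,
            "age_median": r.age_median,
            "age_lo": r.age_lo,
            "age_hi": r.age_hi,
            "x": r.x,
            "y": r.y,
            "n_autosomal_snps": r.n_autosomal_snps,
            "molecular_sex": r.molecular_sex.value,
            "x_contamination": r.x_contamination,
            "region_tag": r.region_tag,
        }
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# EIGENSTRAT

_GENO_MAP = {"0": 0, "1": 1, "2": 2, "9": MISSING}
_GENO_INV = {0: "0", 1: "1", 2: "2", MISSING: "9"}


def read_eigenstrat(prefix: str | Path) -> GenotypeMatrix:
    """Read an EIGENSTRAT .geno/.snp/.ind triple.

    '9' is mapped to missing.  The .geno line length must match the .ind
    sample count and the .geno line count must match the .snp locus count.
    """
    prefix = Path(prefix)
    ind_path = prefix.with_suffix(".ind")
    snp_path = prefix.with_suffix(".snp")
    geno_path = prefix.with_suffix(".geno")

    sample_ids = []
    with open(ind_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                sample_ids.append(parts[0])

    locus_ids = []
    with open(snp_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            # .snp columns: id, chrom, genetic-pos, physical-pos, [ref, alt]
            locus_ids.append((parts[0], parts[1], int(parts[3])))

    n = len(sample_ids)
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n:
                raise FormatError(
                    f"{geno_path}: line {lineno} has {len(line)} calls, "
                    f"but .ind lists {n} samples"
                )
            try:
                rows.append([_GENO_MAP[c] for c in line])
            except KeyError as exc:
                raise FormatError(
                    f"{geno_path}: line {lineno} contains illegal character "
                    f"{exc.args[0]!r}"
                ) from None
    if len(rows) != len(locus_ids):
        raise FormatError(
            f"{geno_path}: {len(rows)} genotype lines but .snp lists "
            f"{len(locus_ids)} loci"
        )
    calls = np.array(rows, dtype=np.int8).reshape(len(locus_ids), n)
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def write_eigenstrat(G: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid}\tU\tIgnore\n")
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for sid, chrom, pos in G.locus_ids:
            fh.write(f"{sid}\t{chrom}\t0.0\t{pos}\n")
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for row in G.calls:
            fh.write("".join(_GENO_INV[int(v)] for v in row) + "\n")


# ---------------------------------------------------------------------------
# coordinate projection

def project_coordinates(
    records: Sequence[SampleRecord],
    projection: LaeaProjection | None = None,
) -> list[SampleRecord]:
    """Fill planar ``x``/``y`` (meters) from lon/lat.

    Defaults to the European equal-area grid (ETRS89-LAEA / EPSG:3035
    parameterization).  Records whose inverse projection does not recover
    lon/lat to 1e-6 degrees lie outside the projection's validity window;
    they are flagged (``flagged_out_of_window``) and warned about, not
    dropped.
    """
    proj = projection or EUROPEAN_GRID
    for rec in records:
        rec.x, rec.y = proj.forward(rec.lon, rec.lat)
        lon2, lat2 = proj.inverse(rec.x, rec.y)
        if math.hypot(lon2 - rec.lon, lat2 - rec.lat) > 1e-6:
            rec.flagged_out_of_window = True
            warnings.warn(
                f"sample {rec.sample_id!r} at ({rec.lon}, {rec.lat}) is outside "
                "the projection validity window; record flagged",
                stacklevel=2,
            )
    return list(records)


# ---------------------------------------------------------------------------
# result tables

_RESULT_COLUMNS = [
    "sample_id",
    "run",
    "slice_time",
    "origin_x",
    "origin_y",
    "length_km",
    "direction_deg",
    "tie",
]


@dataclass
class ResultTable:
    """Long-format per-sample, per-resampling-run mobility output."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _RESULT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"result table missing columns: {missing}")
        dup = self.df.duplicated(subset=["sample_id", "run"])
        if dup.any():
            pairs = self.df.loc[dup, ["sample_id", "run"]].values.tolist()
            raise ValidationError(f"duplicate (sample_id, run) pairs: {pairs}")

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "ResultTable":
        df = pd.DataFrame(list(rows), columns=_RESULT_COLUMNS)
        return cls(df)


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a ResultTable as deterministic TSV (fixed column order)."""
    df = table.df.loc[:, _RESULT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_results(path: str | Path) -> ResultTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ResultTable(df)
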