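"""Reading, validation and cross-linking of the four CSV inputs.

CSV dialect (documented, enforced):

* marker CSV: columns ``marker,chr,pos_cM`` (header required);
* genotype CSV: first column ``id``, remaining columns named by marker id;
* phenotype CSV: first column ``id``, remaining columns are time labels —
  numeric labels are used verbatim, otherwise labels like ``t1..t11`` map to
  times ``1..11``;
* covariate CSV: first column ``id``, remaining columns numeric.

Genotype coding: BC/DH/RIL use {0,1}; F2 uses {0,1,2} with 1 the
heterozygote.  Missing genotypes may be written as an empty cell, ``NA`` or
``-1``.  IDs are matched case-sensitively as strings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CROSS_CLASSES = {"BC": 2, "F2": 3, "RIL": 2, "DH": 2}


class DataFormatError(ValueError):
    """A CSV file does not follow the documented dialect."""


class ConsistencyError(ValueError):
    """Files cannot be linked (e.g. no overlapping individual IDs)."""


class MapError(ValueError):
    """Genetic-map invariant violated (ordering, duplicates)."""


@dataclass(frozen=True)
class CrossType:
    """Experimental cross design; fixes the number of genotype classes J."""

    name: str
    n_genotype_classes: int

    @staticmethod
    def from_name(name: str) -> "CrossType":
        key = name.upper()
        if key not in _CROSS_CLASSES:
            raise ValueError(f"unknown cross type {name!r}; expected one of {sorted(_CROSS_CLASSES)}")
        return CrossType(key, _CROSS_CLASSES[key])

    @property
    def prior(self) -> np.ndarray:
        """Population-expectation genotype frequencies (fallback prior)."""
        if self.n_genotype_classes == 2:
            return np.array([0.5, 0.5])
        return np.array([0.25, 0.5, 0.25])


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with chromosome assignment and cM positions."""

    marker_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions: np.ndarray  # cM, float

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions)):
            raise MapError("marker/chromosome/position lengths differ")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chromosome_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return list(seen)

    def marker_indices(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chromosomes) == chromosome)

    def index_of(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def validate(self) -> list["Diagnostic"]:
        out: list[Diagnostic] = []
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dupes = {m for m in self.marker_ids if self.marker_ids.count(m) > 1}
            out.append(Diagnostic("DUPLICATE_MARKER", "map", f"duplicated marker ids: {sorted(dupes)}"))
        for chrom in self.chromosome_names():
            pos = self.positions[self.marker_indices(chrom)]
            if np.any(np.diff(pos) <= 0):
                out.append(
                    Diagnostic(
                        "NON_INCREASING_MAP",
                        f"map:{chrom}",
                        f"positions not strictly increasing on chromosome {chrom}",
                    )
                )
            if np.any(pos < 0):
                out.append(Diagnostic("NEGATIVE_POSITION", f"map:{chrom}", "negative cM position"))
        return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x markers integer genotype codes; NaN marks missing."""

    individual_ids: tuple[str, ...]
    codes: np.ndarray  # n x n_markers float array, values in {0..J-1} or NaN

    def __post_init__(self):
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=float))

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Individuals x time points longitudinal trait, plus optional covariates."""

    individual_ids: tuple[str, ...]
    times: np.ndarray  # length m, strictly increasing
    values: np.ndarray  # n x m, NaN allowed
    covariates: Optional[np.ndarray] = None  # n x c

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.covariates is not None:
            object.__setattr__(self, "covariates", np.asarray(self.covariates, dtype=float))

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Diagnostic:
    code: str
    location: str
    message: str


@dataclass(frozen=True)
class Dataset:
    """The four linked inputs with identical, aligned individual IDs."""

    cross: CrossType
    gmap: GeneticMap
    geno: GenotypeMatrix
    pheno: PhenotypeMatrix

    @property
    def n_individuals(self) -> int:
        return self.pheno.n_individuals

    @property
    def individual_ids(self) -> tuple[str, ...]:
        return self.pheno.individual_ids


def _read_csv(path: Path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={0: str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise DataFormatError(f"{what} file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise DataFormatError(f"{what} file {path}: expected at least 2 columns")
    return df


def read_genetic_map(marker_path: str | Path) -> GeneticMap:
    df = _read_csv(Path(marker_path), "marker")
    cols = [c.strip().lower() for c in df.columns]
    required = ["marker", "chr", "pos_cm"]
    if cols[:3] != required:
        raise DataFormatError(
            f"marker file {marker_path}: header must be marker,chr,pos_cM (got {list(df.columns)[:3]})"
        )
    try:
        pos = df.iloc[:, 2].astype(float).to_numpy()
    except ValueError as exc:
        raise DataFormatError(f"marker file {marker_path}: non-numeric pos_cM: {exc}") from exc
    gmap = GeneticMap(
        tuple(df.iloc[:, 0].astype(str)),
        tuple(df.iloc[:, 1].astype(str)),
        pos,
    )
    diags = gmap.validate()
    bad = [d for d in diags if d.code in ("NON_INCREASING_MAP", "DUPLICATE_MARKER")]
    if bad:
        raise MapError("; ".join(d.message for d in bad))
    return gmap


_TIME_LABEL_RE = re.compile(r"^[A-Za-z_]*?(-?\d+(?:\.\d+)?)$")


def _parse_times(labels: Sequence[str]) -> np.ndarray:
    """Numeric labels verbatim; 't1'-style labels use their numeric suffix."""
    times = []
    for lab in labels:
        lab = str(lab).strip()
        try:
            times.append(float(lab))
            continue
        except ValueError:
            pass
        m = _TIME_LABEL_RE.match(lab)
        if not m:
            raise DataFormatError(f"phenotype column {lab!r} is not parseable as a time point")
        times.append(float(m.group(1)))
    return np.asarray(times, dtype=float)


def load_dataset(
    pheno_path: str | Path,
    covar_path: Optional[str | Path],
    geno_path: str | Path,
    marker_path: str | Path,
    cross: CrossType | str,
) -> Dataset:
    """Read, validate and link the four CSV files into one :class:`Dataset`.

    Individuals present in only one of the files are dropped with a logged
    warning; genotype codes outside the cross's alphabet become missing.
    """
    if isinstance(cross, str):
        cross = CrossType.from_name(cross)

    gmap = read_genetic_map(marker_path)

    gdf = _read_csv(Path(geno_path), "genotype")
    if gdf.columns[0].strip().lower() != "id":
        raise DataFormatError(f"genotype file {geno_path}: first column must be 'id'")
    geno_ids = [str(x) for x in gdf.iloc[:, 0]]
    marker_cols = list(gdf.columns[1:])
    if list(map(str, marker_cols)) != list(gmap.marker_ids):
        missing = set(gmap.marker_ids) - set(map(str, marker_cols))
        extra = set(map(str, marker_cols)) - set(gmap.marker_ids)
        if missing or extra:
            raise ConsistencyError(
                f"genotype columns disagree with map (missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]})"
            )
        gdf = gdf[[gdf.columns[0]] + list(gmap.marker_ids)]  # reorder to map order
    codes = gdf.iloc[:, 1:].replace({"NA": np.nan, "": np.nan}).apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    codes[codes == -1] = np.nan
    valid = np.isnan(codes) | np.isin(codes, np.arange(cross.n_genotype_classes))
    if not valid.all():
        n_bad = int((~valid).sum())
        logger.warning("genotype file %s: %d codes outside %s alphabet set to missing", geno_path, n_bad, cross.name)
        codes[~valid] = np.nan

    pdf = _read_csv(Path(pheno_path), "phenotype")
    if pdf.columns[0].strip().lower() != "id":
        raise DataFormatError(f"phenotype file {pheno_path}: first column must be 'id'")
    pheno_ids = [str(x) for x in pdf.iloc[:, 0]]
    times = _parse_times(pdf.columns[1:])
    values = pdf.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    covariates = None
    covar_ids = None
    if covar_path is not None:
        cdf = _read_csv(Path(covar_path), "covariate")
        if cdf.columns[0].strip().lower() != "id":
            raise DataFormatError(f"covariate file {covar_path}: first column must be 'id'")
        covar_ids = [str(x) for x in cdf.iloc[:, 0]]
        covariates = cdf.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    id_sets = [set(geno_ids), set(pheno_ids)]
    if covar_ids is not None:
        id_sets.append(set(covar_ids))
    common = set.intersection(*id_sets)
    if not common:
        raise ConsistencyError("no overlapping individual IDs across input files")
    dropped = set.union(*id_sets) - common
    if dropped:
        logger.warning("dropping %d individuals absent from at least one file: %s", len(dropped), sorted(dropped)[:10])

    # keep phenotype-file order for the retained individuals
    ids = tuple(i for i in pheno_ids if i in common)
    prow = {i: k for k, i in enumerate(pheno_ids)}
    grow = {i: k for k, i in enumerate(geno_ids)}
    values = values[[prow[i] for i in ids]]
    codes = codes[[grow[i] for i in ids]]
    if covariates is not None:
        crow = {i: k for k, i in enumerate(covar_ids)}
        covariates = covariates[[crow[i] for i in ids]]

    ds = Dataset(
        cross=cross,
        gmap=gmap,
        geno=GenotypeMatrix(ids, codes),
        pheno=PhenotypeMatrix(ids, times, values, covariates),
    )
    diags = validate_dataset(ds)
    if diags:
        raise ConsistencyError("; ".join(f"{d.code}: {d.message}" for d in diags))
    return ds


def validate_dataset(ds: Dataset) -> list[Diagnostic]:
    """Check every structural invariant; returns diagnostics, never raises."""
    out: list[Diagnostic] = list(ds.gmap.validate())
    if ds.geno.individual_ids != ds.pheno.individual_ids:
        out.append(Diagnostic("ID_MISMATCH", "dataset", "genotype/phenotype individual IDs not aligned"))
    if len(set(ds.pheno.individual_ids)) != len(ds.pheno.individual_ids):
        out.append(Diagnostic("DUPLICATE_ID", "phenotype", "duplicate individual IDs"))
    if ds.geno.codes.shape[1] != ds.gmap.n_markers:
        out.append(Diagnostic("MARKER_COUNT", "genotype", "genotype columns != map markers"))
    if np.any(np.diff(ds.pheno.times) <= 0):
        out.append(Diagnostic("NON_INCREASING_TIMES", "phenotype", f"times not strictly increasing: {ds.pheno.times}"))
    J = ds.cross.n_genotype_classes
    codes = ds.geno.codes
    ok = np.isnan(codes) | np.isin(codes, np.arange(J))
    if not ok.all():
        out.append(Diagnostic("BAD_GENOTYPE_CODE", "genotype", f"{int((~ok).sum())} codes outside 0..{J-1}"))
    if ds.pheno.covariates is not None and ds.pheno.covariates.shape[0] != ds.pheno.values.shape[0]:
        out.append(Diagnostic("COVARIATE_ROWS", "covariate", "covariate rows do not align with phenotype rows"))
    return out
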