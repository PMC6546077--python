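"""Synthetic inbred-cross datasets: genotypes by Haldane recombination along
a map, longitudinal phenotypes as genotype-specific curve plus structured
MVN noise.  The test bed for every other module."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .covariance import get_covariance
from .curves import get_curve
from .dataio import CrossType, Dataset, GeneticMap, GenotypeMatrix, PhenotypeMatrix
from .genetics import haldane_r, ril_expand


@dataclass(frozen=True)
class QTLSpec:
    chromosome: str
    position: float  # cM
    curve_params: np.ndarray  # (J, k): one row per genotype class

    def __post_init__(self):
        object.__setattr__(self, "curve_params", np.atleast_2d(np.asarray(self.curve_params, dtype=float)))


@dataclass(frozen=True)
class SimulationConfig:
    cross: CrossType
    gmap: GeneticMap
    qtl: QTLSpec
    curve: str
    cov: str
    cov_theta: np.ndarray
    times: np.ndarray
    n: int
    seed: int = 0
    covariate_sd: Optional[float] = None  # one N(0, sd) covariate when set
    covariate_alpha: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "cov_theta", np.asarray(self.cov_theta, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        J = self.cross.n_genotype_classes
        if self.qtl.curve_params.shape[0] != J:
            raise ValueError(f"qtl needs {J} curve-parameter rows for {self.cross.name}")
        idx = self.gmap.marker_indices(self.qtl.chromosome)
        if idx.size == 0:
            raise ValueError(f"QTL chromosome {self.qtl.chromosome!r} not on the map")
        pos = self.gmap.positions[idx]
        if not (pos[0] <= self.qtl.position <= pos[-1]):
            raise ValueError(f"QTL position {self.qtl.position} outside map span [{pos[0]}, {pos[-1]}]")
        m = len(self.times)
        get_curve(self.curve)
        covm = get_covariance(self.cov)
        covm.build(self.cov_theta, m, self.times)  # validates theta, PD


def uniform_map(n_chrom: int, n_markers: int, spacing_cm: float = 10.0) -> GeneticMap:
    """Convenience map: chromosomes c1..cN with equally spaced markers."""
    ids, chroms, pos = [], [], []
    for c in range(1, n_chrom + 1):
        for k in range(n_markers):
            ids.append(f"m{c}_{k + 1}")
            chroms.append(f"c{c}")
            pos.append(k * spacing_cm)
    return GeneticMap(tuple(ids), tuple(chroms), np.array(pos, dtype=float))


def _chain_states(rng: np.ndarray, n: int, loci_cm: np.ndarray, cross: CrossType) -> np.ndarray:
    """n x L gamete-chain states in {0,1} generated marker-to-marker."""
    L = len(loci_cm)
    r = haldane_r(np.diff(loci_cm))
    if cross.name == "RIL":
        r = ril_expand(r)
    states = np.empty((n, L), dtype=int)
    states[:, 0] = rng.random(n) < 0.5
    for k in range(1, L):
        flip = rng.random(n) < r[k - 1]
        states[:, k] = np.where(flip, 1 - states[:, k - 1], states[:, k - 1])
    return states


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Marker genotype matrix plus the hidden QTL genotype vector.

    The QTL is inserted as an extra locus at its map position while the
    chains are generated, then stripped from the returned marker matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6E0]))
    n = cfg.n
    ids = tuple(f"ind{i + 1}" for i in range(n))
    cols: list[np.ndarray] = []
    hidden = None
    for chrom in cfg.gmap.chromosome_names():
        idx = cfg.gmap.marker_indices(chrom)
        loci = cfg.gmap.positions[idx]
        has_qtl = chrom == cfg.qtl.chromosome
        if has_qtl:
            # insert the QTL as an extra locus; a zero-distance duplicate is
            # fine when it coincides with a marker (r=0 copies the state)
            qtl_at = int(np.searchsorted(loci, cfg.qtl.position))
            loci_aug = np.insert(loci, qtl_at, cfg.qtl.position)
        else:
            loci_aug = loci
            qtl_at = -1
        if cfg.cross.name == "F2":
            g = _chain_states(rng, n, loci_aug, cfg.cross) + _chain_states(rng, n, loci_aug, cfg.cross)
        else:
            g = _chain_states(rng, n, loci_aug, cfg.cross)
        if has_qtl:
            hidden = g[:, qtl_at].copy()
            g = np.delete(g, qtl_at, axis=1)
        cols.append(g)
    codes = np.concatenate(cols, axis=1).astype(float)
    assert hidden is not None
    return GenotypeMatrix(ids, codes), hidden


def simulate_phenotypes(cfg: SimulationConfig, hidden_qtl: np.ndarray) -> PhenotypeMatrix:
    """y_i = alpha x_i + g_{j(i)}(times) + MVN(0, Sigma(theta)) noise."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBE7A]))
    curve = get_curve(cfg.curve)
    covm = get_covariance(cfg.cov)
    times = cfg.times
    m = len(times)
    G = np.vstack([curve.value(p, times) for p in cfg.qtl.curve_params])
    sigma = covm.build(cfg.cov_theta, m, times)
    L = np.linalg.cholesky(sigma)
    noise = rng.standard_normal((cfg.n, m)) @ L.T
    values = G[np.asarray(hidden_qtl, dtype=int)] + noise
    covariates = None
    if cfg.covariate_sd is not None:
        x = rng.normal(0.0, cfg.covariate_sd, size=(cfg.n, 1))
        values = values + cfg.covariate_alpha * x
        covariates = x
    ids = tuple(f"ind{i + 1}" for i in range(cfg.n))
    return PhenotypeMatrix(ids, times, values, covariates)


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, dict]:
    """Full dataset plus a truth record (hidden genotypes, generating params)."""
    geno, hidden = simulate_genotypes(cfg)
    pheno = simulate_phenotypes(cfg, hidden)
    ds = Dataset(cross=cfg.cross, gmap=cfg.gmap, geno=geno, pheno=pheno)
    truth = {
        "cross": cfg.cross.name,
        "qtl_chromosome": cfg.qtl.chromosome,
        "qtl_position_cM": cfg.qtl.position,
        "curve": cfg.curve,
        "curve_params_per_genotype": cfg.qtl.curve_params.tolist(),
        "covariance": cfg.cov,
        "cov_theta": cfg.cov_theta.tolist(),
        "times": cfg.times.tolist(),
        "n": cfg.n,
        "seed": cfg.seed,
        "covariate_alpha": cfg.covariate_alpha,
        "hidden_qtl_genotypes": np.asarray(hidden, dtype=int).tolist(),
    }
    return ds, truth


def write_dataset(ds: Dataset, out_dir: str | Path, truth: Optional[dict] = None) -> dict[str, Path]:
    """Emit the CSV file set (and truth sidecar JSON) in the dataio dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    marker = out / "marker.csv"
    pd.DataFrame(
        {"marker": ds.gmap.marker_ids, "chr": ds.gmap.chromosomes, "pos_cM": ds.gmap.positions}
    ).to_csv(marker, index=False)
    paths["marker"] = marker

    geno = out / "geno.csv"
    gdf = pd.DataFrame(ds.geno.codes, columns=list(ds.gmap.marker_ids))
    gdf = gdf.astype("Int64")
    gdf.insert(0, "id", list(ds.geno.individual_ids))
    gdf.to_csv(geno, index=False, na_rep="NA")
    paths["geno"] = geno

    pheno = out / "pheno.csv"
    pdf = pd.DataFrame(ds.pheno.values, columns=[repr(float(t)) for t in ds.pheno.times])
    pdf.insert(0, "id", list(ds.pheno.individual_ids))
    pdf.to_csv(pheno, index=False, na_rep="NA", float_format="%.12g")
    paths["pheno"] = pheno

    if ds.pheno.covariates is not None:
        covar = out / "covar.csv"
        cdf = pd.DataFrame(ds.pheno.covariates, columns=[f"x{k + 1}" for k in range(ds.pheno.covariates.shape[1])])
        cdf.insert(0, "id", list(ds.pheno.individual_ids))
        cdf.to_csv(covar, index=False, float_format="%.12g")
        paths["covar"] = covar

    if truth is not None:
        sidecar = out / "truth.json"
        sidecar.write_text(json.dumps(truth, indent=2))
        paths["truth"] = sidecar
    return paths
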