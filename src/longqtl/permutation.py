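"""Genome-wide significance thresholds by permutation of phenotype rows,
with an optional dosage-correlation pre-filter to cut scan cost.

Each permutation reassigns phenotype rows (together with their covariates)
to genotype rows, re-runs the LR2 scan and records the genome-wide maximum.
Thresholds are empirical (1-alpha) quantiles with type-7 (linear)
interpolation.  Per-permutation RNG streams derive from (seed, index) so the
result does not depend on worker scheduling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .covariance import CovarianceModel, get_covariance
from .curves import CurveModel, get_curve
from .dataio import Dataset, PhenotypeMatrix
from .genetics import ScanPosition, conditional_probs, scan_grid
from .model import HypothesisFit, fit_null
from .scan import ScanResult, find_peaks, qtl_scan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    n_perm: int
    max_lr2_per_perm: np.ndarray
    seed: int
    alpha_default: float = 0.05

    def threshold(self, alpha: float = 0.05) -> float:
        """Empirical (1-alpha) quantile (type-7 linear interpolation)."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        return float(np.quantile(self.max_lr2_per_perm, 1.0 - alpha, method="linear"))


def permute_phenotypes(ds: Dataset, perm: np.ndarray) -> Dataset:
    """Dataset with phenotype rows (and covariates) reassigned by ``perm``."""
    ph = ds.pheno
    new_ph = PhenotypeMatrix(
        ph.individual_ids,
        ph.times,
        ph.values[perm],
        None if ph.covariates is None else ph.covariates[perm],
    )
    return dc_replace(ds, pheno=new_ph)


def prefilter_positions(
    ds: Dataset,
    sr: ScanResult,
    keep_fraction: float,
) -> list[ScanPosition]:
    """Rank positions by a cheap dosage-trait correlation score and keep the
    top fraction per chromosome, always retaining each chromosome's observed
    scan peak.

    Score: max over time points of the squared Pearson correlation between
    the expected genotype dosage sum_j j*p_ij and that time point's
    phenotype.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if keep_fraction == 1:
        return list(sr.positions)
    Y = ds.pheno.values
    J = ds.cross.n_genotype_classes
    jvec = np.arange(J, dtype=float)
    peaks = {(c, p) for c, p, _ in find_peaks(sr)}

    scores: list[float] = []
    for pos in sr.positions:
        probs = conditional_probs(pos, ds.geno, ds.gmap, ds.cross)
        dosage = probs @ jvec
        best = 0.0
        sd = dosage.std()
        if sd > 0:
            for t in range(Y.shape[1]):
                y = Y[:, t]
                ok = np.isfinite(y)
                if ok.sum() > 2 and y[ok].std() > 0 and dosage[ok].std() > 0:
                    r = np.corrcoef(dosage[ok], y[ok])[0, 1]
                    best = max(best, float(r * r))
        scores.append(best)

    keep: list[ScanPosition] = []
    by_chrom: dict[str, list[int]] = {}
    for i, pos in enumerate(sr.positions):
        by_chrom.setdefault(pos.chromosome, []).append(i)
    for chrom, idxs in by_chrom.items():
        k = max(1, int(np.ceil(keep_fraction * len(idxs))))
        order = sorted(idxs, key=lambda i: (-scores[i], sr.positions[i].position))
        chosen = set(order[:k])
        for i in idxs:
            pos = sr.positions[i]
            if i in chosen or (chrom, pos.position) in peaks:
                keep.append(pos)
    return keep


def _one_permutation(
    ds: Dataset,
    perm: np.ndarray,
    curve: CurveModel,
    cov: CovarianceModel,
    positions: Sequence[ScanPosition],
    h0: HypothesisFit,
    step: float,
    tol: float,
) -> float:
    ds_p = permute_phenotypes(ds, perm)
    # the null likelihood is permutation-invariant (no genotype term), so h0
    # carries over from the observed data
    sr = qtl_scan(ds_p, curve, cov, step=step, positions=list(positions), h0=h0, tol=tol)
    return sr.max_lr2()


def permute_scan(
    ds: Dataset,
    curve: CurveModel | str,
    cov: CovarianceModel | str,
    n_perm: int,
    seed: int,
    filter: bool = False,
    n_workers: int = 1,
    step: float = 1.0,
    keep_fraction: float = 0.2,
    observed: Optional[ScanResult] = None,
    tol: float = 1e-5,
) -> PermutationResult:
    """Genome-wide max-LR2 null distribution over ``n_perm`` reshuffles.

    With ``filter=True`` the scan is restricted to high-scoring positions
    (see :func:`prefilter_positions`), computed from the observed scan.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives unstable quantile thresholds; use >= 100", stacklevel=2)
    curve = get_curve(curve) if isinstance(curve, str) else curve
    cov = get_covariance(cov) if isinstance(cov, str) else cov

    h0 = observed.h0 if observed is not None else fit_null(ds, curve, cov)
    if filter:
        if observed is None:
            observed = qtl_scan(ds, curve, cov, step=step, h0=h0)
        positions = prefilter_positions(ds, observed, keep_fraction)
    else:
        positions = observed.positions if observed is not None else scan_grid(ds.gmap, step)

    n = ds.n_individuals
    perms = []
    for b in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        perms.append(rng.permutation(n))

    if n_workers > 1:
        maxima = Parallel(n_jobs=n_workers)(
            delayed(_one_permutation)(ds, p, curve, cov, positions, h0, step, tol) for p in perms
        )
    else:
        maxima = [_one_permutation(ds, p, curve, cov, positions, h0, step, tol) for p in perms]
    return PermutationResult(n_perm, np.asarray(maxima, dtype=float), seed)
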