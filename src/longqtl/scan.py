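"""Genome-wide LR2 profile and per-chromosome peak summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .covariance import CovarianceModel, get_covariance
from .curves import CurveModel, get_curve
from .dataio import Dataset
from .genetics import ScanPosition, conditional_probs, scan_grid
from .model import (
    ConvergenceError,
    HypothesisFit,
    MonotonicityError,
    fit_alternative,
    fit_null,
    lr_statistic,
)

logger = logging.getLogger(__name__)


class ScanError(RuntimeError):
    pass


@dataclass
class ScanResult:
    positions: list[ScanPosition]
    lr2: np.ndarray  # NaN where a position failed
    h1_fits: list[Optional[HypothesisFit]]
    h0: HypothesisFit
    curve_name: str
    cov_name: str
    step: float
    threshold: Optional[float] = None
    failures: list[tuple[ScanPosition, str]] = field(default_factory=list)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.positions:
            seen.setdefault(p.chromosome, None)
        return list(seen)

    def max_lr2(self) -> float:
        return float(np.nanmax(self.lr2))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos, lr2, fit in zip(self.positions, self.lr2, self.h1_fits):
            row = {"chr": pos.chromosome, "pos_cM": pos.position, "lr2": lr2}
            if fit is not None:
                for j, params in enumerate(np.atleast_2d(fit.curve_params)):
                    for k, v in enumerate(params):
                        row[f"g{j}_p{k}"] = v
                for k, v in enumerate(fit.cov_theta):
                    row[f"cov_p{k}"] = v
                for k, v in enumerate(fit.alpha):
                    row[f"alpha{k}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _scan_chromosome(
    ds: Dataset,
    positions: Sequence[ScanPosition],
    curve: CurveModel,
    cov: CovarianceModel,
    h0: HypothesisFit,
    tol: float,
    max_iter: int,
) -> tuple[list[float], list[Optional[HypothesisFit]], list[tuple[ScanPosition, str]]]:
    lr2s: list[float] = []
    fits: list[Optional[HypothesisFit]] = []
    failures: list[tuple[ScanPosition, str]] = []
    warm: Optional[HypothesisFit] = None
    for pos in positions:
        probs = conditional_probs(pos, ds.geno, ds.gmap, ds.cross)
        fit = None
        err = None
        for init in ([warm] if warm is not None else []) + [h0]:
            try:
                cand = fit_alternative(ds, probs, curve, cov, init, tol=tol, max_iter=max_iter)
                if cand.loglik < h0.loglik - 1e-6:
                    raise ConvergenceError("alternative fit below null", cand)
                fit = cand
                break
            except (ConvergenceError, MonotonicityError, FloatingPointError) as exc:
                err = str(exc)
        if fit is None:
            lr2s.append(np.nan)
            fits.append(None)
            failures.append((pos, err or "unknown failure"))
            continue
        warm = fit
        lr2s.append(lr_statistic(h0, fit))
        fits.append(fit)
    return lr2s, fits, failures


def qtl_scan(
    ds: Dataset,
    curve: CurveModel | str,
    cov: CovarianceModel | str,
    step: float = 1.0,
    n_workers: int = 1,
    positions: Optional[Sequence[ScanPosition]] = None,
    h0: Optional[HypothesisFit] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_failure_fraction: float = 0.2,
) -> ScanResult:
    """LR2 at every grid position.

    The null model is fitted once (it has no genotype term); each position
    then computes the flanking-marker genotype probabilities, runs EM from a
    warm start (previous position's fit, falling back to the null fit) and
    records LR2.  Positions are processed per chromosome, in map order, so
    results are independent of worker scheduling.
    """
    curve = get_curve(curve) if isinstance(curve, str) else curve
    cov = get_covariance(cov) if isinstance(cov, str) else cov
    if positions is None:
        positions = scan_grid(ds.gmap, step)
    if not positions:
        raise ScanError("empty scan grid")
    if h0 is None:
        h0 = fit_null(ds, curve, cov)

    by_chrom: dict[str, list[ScanPosition]] = {}
    for p in positions:
        by_chrom.setdefault(p.chromosome, []).append(p)
    chroms = list(by_chrom)

    if n_workers > 1 and len(chroms) > 1:
        parts = Parallel(n_jobs=n_workers)(
            delayed(_scan_chromosome)(ds, by_chrom[c], curve, cov, h0, tol, max_iter) for c in chroms
        )
    else:
        parts = [_scan_chromosome(ds, by_chrom[c], curve, cov, h0, tol, max_iter) for c in chroms]

    ordered_positions: list[ScanPosition] = []
    lr2_all: list[float] = []
    fits_all: list[Optional[HypothesisFit]] = []
    failures: list[tuple[ScanPosition, str]] = []
    for c, (lr2s, fits, fails) in zip(chroms, parts):
        ordered_positions.extend(by_chrom[c])
        lr2_all.extend(lr2s)
        fits_all.extend(fits)
        failures.extend(fails)
    lr2_arr = np.asarray(lr2_all, dtype=float)
    frac_failed = len(failures) / len(ordered_positions)
    if frac_failed > max_failure_fraction:
        raise ScanError(f"{frac_failed:.0%} of scan positions failed to fit")
    if failures:
        logger.warning("%d scan positions failed: %s", len(failures), [(p.chromosome, p.position) for p, _ in failures][:5])
    return ScanResult(
        positions=ordered_positions,
        lr2=lr2_arr,
        h1_fits=fits_all,
        h0=h0,
        curve_name=curve.name,
        cov_name=cov.name,
        step=step,
        failures=failures,
    )


def find_peaks(sr: ScanResult) -> list[tuple[str, float, float]]:
    """Per-chromosome (chromosome, position, lr2) at the LR2 maximum; ties
    break toward the smallest position."""
    if not sr.positions:
        raise ScanError("empty scan result")
    best: dict[str, tuple[float, float]] = {}
    for pos, lr2 in zip(sr.positions, sr.lr2):
        if not np.isfinite(lr2):
            continue
        cur = best.get(pos.chromosome)
        if cur is None or lr2 > cur[1] + 1e-12:
            best[pos.chromosome] = (pos.position, lr2)
    if not best:
        raise ScanError("no successfully fitted positions")
    return [(c, p, v) for c, (p, v) in best.items()]
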