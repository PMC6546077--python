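"""Genetic-map computations: Haldane map function, the scan grid, and
conditional QTL-genotype probabilities given flanking markers.

Assumptions (documented, see package README): the Haldane map function (no
crossover interference), selfed (F-infinity) RILs with the per-interval
expansion r* = 2r/(1+2r), and no extrapolation beyond terminal markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataio import CrossType, GeneticMap, GenotypeMatrix

_POS_TOL = 1e-9


class PositionError(ValueError):
    """Requested position lies outside every map interval."""


@dataclass(frozen=True)
class ScanPosition:
    """A test position on the map with its bracketing markers."""

    chromosome: str
    position: float  # cM
    left_marker: str
    right_marker: Optional[str]  # None when terminal

    @property
    def at_marker(self) -> bool:
        return self.right_marker is None or self.left_marker == self.right_marker


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Map distance in cM -> recombination fraction, r = (1 - e^(-2d/100))/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return float(r) if r.ndim == 0 else r


def haldane_d(r: float) -> float:
    """Inverse map function: recombination fraction -> cM."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * r)


def ril_expand(r: float | np.ndarray) -> float | np.ndarray:
    """Observed recombination fraction in selfed RILs: r* = 2r/(1+2r)."""
    return 2.0 * np.asarray(r) / (1.0 + 2.0 * np.asarray(r))


def scan_grid(gmap: GeneticMap, step: float = 1.0) -> list[ScanPosition]:
    """Per-chromosome grid from first to last marker at ``step`` spacing.

    Marker positions are always included (the grid is anchored at markers,
    not a global lattice); duplicates are removed and positions sorted.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    out: list[ScanPosition] = []
    for chrom in gmap.chromosome_names():
        idx = gmap.marker_indices(chrom)
        if idx.size == 0:
            continue
        mpos = gmap.positions[idx]
        mids = [gmap.marker_ids[i] for i in idx]
        lattice = np.arange(mpos[0], mpos[-1] + _POS_TOL, step)
        pos = np.union1d(np.round(lattice, 9), np.round(mpos, 9))
        for p in pos:
            k = int(np.searchsorted(mpos, p + _POS_TOL) - 1)  # last marker <= p
            k = max(k, 0)
            if abs(p - mpos[-1]) <= _POS_TOL:
                sp = ScanPosition(chrom, float(p), mids[-1], None)
            elif abs(p - mpos[k]) <= _POS_TOL:
                sp = ScanPosition(chrom, float(mpos[k]), mids[k], mids[k])
            else:
                sp = ScanPosition(chrom, float(p), mids[k], mids[k + 1])
            out.append(sp)
    return out


def _gamete_transition(r: float) -> np.ndarray:
    """2x2 transition between gamete allele states at recombination r."""
    return np.array([[1.0 - r, r], [r, 1.0 - r]])


def _f2_transition(r: float) -> np.ndarray:
    """3x3 genotype-class transition for F2: two independent gamete chains."""
    t = _gamete_transition(r)
    T = np.zeros((3, 3))
    pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}  # genotype -> gamete allele pair
    for g1, (a, b) in pair.items():
        for a2 in range(2):
            for b2 in range(2):
                T[g1, a2 + b2] += t[a, a2] * t[b, b2]
    return T


def transition_matrix(d_cm: float, cross: CrossType) -> np.ndarray:
    """Genotype-class transition matrix across a map interval of ``d_cm``."""
    r = haldane_r(d_cm)
    if cross.name == "F2":
        return _f2_transition(r)
    if cross.name == "RIL":
        return _gamete_transition(float(ril_expand(r)))
    return _gamete_transition(r)  # BC and DH share the 2-state chain


def conditional_probs(
    pos: ScanPosition,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    cross: CrossType,
) -> np.ndarray:
    """n x J matrix of P(QTL genotype | flanking marker genotypes).

    No-interference product rule: P(q | l, r) ∝ T_left[l, q] * T_right[q, r].
    A missing flanking genotype contributes the stationary population prior;
    at a marker position the row is the indicator of the observed class (or
    the prior when that marker is untyped).
    """
    J = cross.n_genotype_classes
    prior = cross.prior
    n = geno.n_individuals

    li = gmap.index_of(pos.left_marker)
    if abs(gmap.positions[li] - pos.position) <= _POS_TOL:
        # exactly at the left marker: that marker alone determines the row
        g = geno.codes[:, li]
        out = np.tile(prior, (n, 1))
        typed = ~np.isnan(g)
        out[typed] = np.eye(J)[g[typed].astype(int)]
        return out

    if pos.right_marker is None:
        raise PositionError(f"position {pos.position} beyond terminal marker {pos.left_marker}")
    ri = gmap.index_of(pos.right_marker)
    d1 = pos.position - gmap.positions[li]
    d2 = gmap.positions[ri] - pos.position
    if d1 < -_POS_TOL or d2 < -_POS_TOL:
        raise PositionError(f"position {pos.position} outside interval [{pos.left_marker}, {pos.right_marker}]")

    T1 = transition_matrix(max(d1, 0.0), cross)  # left marker -> QTL
    T2 = transition_matrix(max(d2, 0.0), cross)  # QTL -> right marker

    gl = geno.codes[:, li]
    gr = geno.codes[:, ri]
    A = np.tile(prior, (n, 1))
    tl = ~np.isnan(gl)
    A[tl] = T1[gl[tl].astype(int)]
    B = np.ones((n, J))
    trm = ~np.isnan(gr)
    B[trm] = T2[:, gr[trm].astype(int)].T
    W = A * B
    return W / W.sum(axis=1, keepdims=True)
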