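"""CSV/plot report generation: pure rendering of scan and permutation
results (analysis objects are never mutated)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import get_curve
from .dataio import Dataset
from .permutation import PermutationResult
from .scan import ScanResult, find_peaks

_GENOTYPE_COLORS = ["tab:blue", "tab:red", "tab:green"]


def plot_trait_trajectories(ds: Dataset, sr: Optional[ScanResult] = None, path: Optional[Path] = None):
    """Overlaid individual trajectories with the fitted population mean."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = ds.pheno.times
    for row in ds.pheno.values:
        ax.plot(t, row, color="grey", alpha=0.25, lw=0.7)
    if sr is not None:
        curve = get_curve(sr.curve_name)
        dense = np.linspace(t.min(), t.max(), 200)
        ax.plot(dense, curve.value(sr.h0.curve_params[0], dense), color="black", lw=2, label="fitted mean")
        ax.legend()
    ax.set_xlabel("time")
    ax.set_ylabel("trait")
    ax.set_title("Longitudinal trait trajectories")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_lr_profile(sr: ScanResult, ds: Dataset, threshold: Optional[float] = None, path: Optional[Path] = None):
    """Per-chromosome LR2 panels with marker ticks and names."""
    chroms = sr.chromosomes
    ncol = min(len(chroms), 4)
    nrow = int(np.ceil(len(chroms) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False, sharey=True)
    for k, chrom in enumerate(chroms):
        ax = axes[k // ncol][k % ncol]
        xs = [p.position for p in sr.positions if p.chromosome == chrom]
        ys = [v for p, v in zip(sr.positions, sr.lr2) if p.chromosome == chrom]
        ax.plot(xs, ys, color="tab:blue")
        midx = ds.gmap.marker_indices(chrom)
        mpos = ds.gmap.positions[midx]
        for i, mp in zip(midx, mpos):
            ax.axvline(mp, color="lightgrey", lw=0.5, zorder=0)
        ax.set_xticks(mpos)
        ax.set_xticklabels([ds.gmap.marker_ids[i] for i in midx], rotation=90, fontsize=5)
        if threshold is not None:
            ax.axhline(threshold, color="tab:red", ls="--", lw=1)
        ax.set_title(f"chromosome {chrom}", fontsize=9)
        ax.set_ylabel("LR2")
    for k in range(len(chroms), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_genotype_curves(sr: ScanResult, ds: Dataset, chromosome: str, position: float, path: Optional[Path] = None):
    """Genotype-specific fitted mean curves at one scan position."""
    idx = next(
        i
        for i, p in enumerate(sr.positions)
        if p.chromosome == chromosome and abs(p.position - position) < 1e-9
    )
    fit = sr.h1_fits[idx]
    if fit is None:
        raise ValueError(f"no fit stored at {chromosome}:{position}")
    curve = get_curve(sr.curve_name)
    t = ds.pheno.times
    dense = np.linspace(t.min(), t.max(), 200)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for row in ds.pheno.values:
        ax.plot(t, row, color="grey", alpha=0.2, lw=0.6)
    for j, params in enumerate(np.atleast_2d(fit.curve_params)):
        ax.plot(dense, curve.value(params, dense), color=_GENOTYPE_COLORS[j % 3], lw=2, label=f"genotype {j}")
    ax.set_xlabel("time")
    ax.set_ylabel("trait")
    ax.set_title(f"QTL at {chromosome}:{position:g} cM (LR2={sr.lr2[idx]:.2f})")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def report(
    sr: ScanResult,
    pr: Optional[PermutationResult],
    ds: Dataset,
    out_dir: str | Path,
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Emit the full CSV + plot bundle; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    threshold = pr.threshold(alpha) if pr is not None else None

    scan_csv = out / "scan.csv"
    df = sr.to_dataframe()
    header_lines = [f"# curve={sr.curve_name} covariance={sr.cov_name} step_cM={sr.step}"]
    if threshold is not None:
        header_lines.append(f"# permutation_threshold_alpha{alpha}={threshold:.6g} n_perm={pr.n_perm} seed={pr.seed}")
    with open(scan_csv, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    files["scan"] = scan_csv

    peaks = find_peaks(sr)
    peaks_csv = out / "peaks.csv"
    pk = pd.DataFrame(peaks, columns=["chr", "pos_cM", "lr2"])
    if threshold is not None:
        pk["significant"] = pk["lr2"] >= threshold
    pk.to_csv(peaks_csv, index=False, float_format="%.10g")
    files["peaks"] = peaks_csv

    if pr is not None:
        perm_csv = out / "permutations.csv"
        pd.DataFrame(
            {"perm_index": np.arange(pr.n_perm), "max_lr2": pr.max_lr2_per_perm}
        ).to_csv(perm_csv, index=False, float_format="%.10g")
        files["permutations"] = perm_csv

    files["trajectories"] = out / "trajectories.png"
    plot_trait_trajectories(ds, sr, files["trajectories"])
    files["lr_profile"] = out / "lr_profile.png"
    plot_lr_profile(sr, ds, threshold, files["lr_profile"])

    significant = [(c, p, v) for c, p, v in peaks if threshold is None or v >= threshold]
    if threshold is None:
        significant = []  # without a threshold no peak is declared significant
    for c, p, v in significant:
        key = f"qtl_{c}_{p:g}"
        files[key] = out / f"{key}.png"
        plot_genotype_curves(sr, ds, c, p, files[key])
    return files
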