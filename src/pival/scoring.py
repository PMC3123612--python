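"""Spectrum binning, the Jensen–Shannon similarity score, and FDR curves.

A spectrum is turned into a probability distribution by summing square-root
transformed peak intensities into fixed-width m/z bins and normalizing. The
square root damps the 2–3 dominant peaks that otherwise swamp an ion-trap
spectrum's divergence; it can be switched off. Similarity between the
experimental and theoretical distributions is 1 − JSD with log base 2, so
identical spectra score 1 and disjoint ones 0. Validation quality is
summarized by a target-decoy FDR curve over score thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy


@dataclass
class BinnedDistribution:
    """A spectrum as a probability vector over fixed m/z bins."""

    bin_width: float
    origin: float
    weights: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not self.degenerate and abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 (or set the degenerate flag)")


def _peak_arrays(spectrum) -> tuple[np.ndarray, np.ndarray]:
    peaks = spectrum.peaks
    return (np.array([p.mz for p in peaks], dtype=float),
            np.array([p.intensity for p in peaks], dtype=float))


def bin_spectrum(
    spectrum,
    bin_width: float = 1.0,
    origin: float = 0.0,
    mz_max: Optional[float] = None,
    sqrt_transform: bool = True,
) -> BinnedDistribution:
    """Bin a (theoretical or experimental) spectrum into a distribution.

    Peak intensities (square-root transformed unless disabled) are summed
    into bin ``floor((mz − origin)/bin_width)`` and normalized to total 1.
    Peaks below *origin* or above *mz_max* are clipped with a warning. A
    spectrum with no usable intensity comes back flagged degenerate.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mz, inten = _peak_arrays(spectrum)
    if sqrt_transform:
        inten = np.sqrt(inten)
    keep = mz >= origin
    if mz_max is not None:
        keep &= mz < mz_max
    if keep.size and not keep.all():
        warnings.warn("peaks outside the binning range were clipped", stacklevel=2)
    mz, inten = mz[keep], inten[keep]
    if mz.size == 0 or inten.sum() <= 0:
        n = 1 if mz_max is None else max(1, int(np.ceil((mz_max - origin) / bin_width)))
        return BinnedDistribution(bin_width, origin, np.zeros(n), degenerate=True)
    idx = np.floor((mz - origin) / bin_width).astype(np.intp)
    n_bins = idx.max() + 1
    if mz_max is not None:
        n_bins = max(n_bins, int(np.ceil((mz_max - origin) / bin_width)))
    weights = np.bincount(idx, weights=inten, minlength=n_bins)
    return BinnedDistribution(bin_width, origin, weights / weights.sum())


def _entropy2(w: np.ndarray) -> float:
    return float(-xlogy(w, w).sum() / np.log(2.0))


def jsd(p: BinnedDistribution, q: BinnedDistribution) -> float:
    """Jensen–Shannon divergence with log base 2: in [0, 1], symmetric,
    0 iff the distributions are equal, 1 iff their supports are disjoint."""
    if p.bin_width != q.bin_width or p.origin != q.origin:
        raise ValueError("distributions use different binning; re-bin explicitly")
    if p.degenerate or q.degenerate:
        raise ValueError("JSD is undefined for a degenerate (all-zero) distribution")
    n = max(len(p.weights), len(q.weights))
    wp = np.pad(p.weights, (0, n - len(p.weights)))
    wq = np.pad(q.weights, (0, n - len(q.weights)))
    m = 0.5 * (wp + wq)
    value = _entropy2(m) - 0.5 * (_entropy2(wp) + _entropy2(wq))
    return float(np.clip(value, 0.0, 1.0))


def pi_score(
    experimental,
    theoretical,
    bin_width: float = 1.0,
    sqrt_transform: bool = True,
) -> float:
    """The PI similarity score: 1 − JSD between the binned spectra.

    Lies in [0, 1]; 1 means the binned distributions coincide. An empty or
    all-zero spectrum on either side scores 0 with a warning.
    """
    exp_mz, _ = _peak_arrays(experimental)
    theo_mz, _ = _peak_arrays(theoretical)
    if exp_mz.size == 0 or theo_mz.size == 0:
        warnings.warn("degenerate spectrum: PI score set to 0", stacklevel=2)
        return 0.0
    mz_max = float(max(exp_mz.max(), theo_mz.max())) + bin_width
    p = bin_spectrum(experimental, bin_width, 0.0, mz_max, sqrt_transform)
    q = bin_spectrum(theoretical, bin_width, 0.0, mz_max, sqrt_transform)
    if p.degenerate or q.degenerate:
        warnings.warn("degenerate spectrum: PI score set to 0", stacklevel=2)
        return 0.0
    return 1.0 - jsd(p, q)


@dataclass
class FDRCurve:
    """Target-decoy FDR along descending score thresholds.

    Row i gives, at threshold ``thresholds[i]`` (score ≥ threshold accepted),
    the cumulative target and decoy counts and the estimated
    FDR = decoys / targets (0 when no targets are accepted). Equal scores are
    resolved conservatively: tied decoys are counted before tied targets.
    """

    thresholds: np.ndarray
    targets: np.ndarray
    decoys: np.ndarray
    fdr: np.ndarray


def fdr_curve(scores: Sequence[float], is_decoy: Sequence[bool]) -> FDRCurve:
    """Build the target-decoy FDR curve for a scored PSM collection."""
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape:
        raise ValueError("scores and is_decoy must have equal length")
    if not (~is_decoy).any():
        raise ValueError("at least one target PSM is required")
    if not is_decoy.any():
        warnings.warn("no decoy PSMs: estimated FDR is identically 0", stacklevel=2)
    # descending score; within ties decoys first (conservative)
    order = np.lexsort((~is_decoy, -scores))
    s = scores[order]
    d = is_decoy[order]
    cum_decoys = np.cumsum(d)
    cum_targets = np.cumsum(~d)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cum_targets > 0, cum_decoys / np.maximum(cum_targets, 1), 0.0)
    return FDRCurve(thresholds=s, targets=cum_targets, decoys=cum_decoys, fdr=fdr)


def count_at_fdr(curve: FDRCurve, level: float) -> int:
    """Maximum accepted-target count at any threshold with FDR ≤ *level*."""
    if level < 0:
        raise ValueError("FDR level must be >= 0")
    ok = curve.fdr <= level
    return int(curve.targets[ok].max()) if ok.any() else 0


def psm_scores(psms, by: str = "pi") -> tuple[np.ndarray, np.ndarray]:
    """Pull (scores, is_decoy) arrays out of PSMs, by PI score or XCorr."""
    if by == "pi":
        scores = [p.pi_score if p.pi_score is not None else 0.0 for p in psms]
    elif by == "xcorr":
        scores = [p.hit.xcorr for p in psms]
    else:
        raise ValueError("by must be 'pi' or 'xcorr'")
    return np.asarray(scores, dtype=float), np.array([p.is_decoy for p in psms])


def write_curve_tsv(curve: FDRCurve, path) -> None:
    """Export the curve as tab-separated (threshold, targets, decoys, fdr)."""
    lines = ["threshold\ttargets\tdecoys\tfdr"]
    for t, tg, dc, f in zip(curve.thresholds, curve.targets, curve.decoys, curve.fdr):
        lines.append(f"{t:.6f}\t{tg}\t{dc}\t{f:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def plot_curves(curves: dict, path, levels: Sequence[float] = ()) -> None:
    """Plot accepted targets vs estimated FDR for one or more rankings."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in curves.items():
        order = np.argsort(curve.fdr, kind="stable")
        ax.plot(curve.fdr[order], curve.targets[order], label=name)
    for lv in levels:
        ax.axvline(lv, color="0.8", linestyle=":")
    ax.set_xlabel("estimated FDR")
    ax.set_ylabel("accepted target PSMs")
    ax.set_xlim(0, min(0.1, ax.get_xlim()[1] or 0.1))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
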