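"""Theoretical MS/MS spectrum prediction and experimental-spectrum annotation.

Each cleavage event i of a peptide carries the model intensity v_i from
:func:`pival.fragmodel.event_vector`. The event's intensity is split between
its b_i and y_{L−i} ions (equally by default), each ion sheds water/ammonia
loss peaks according to the fitted per-residue probabilities with intensity
conserved within the ion, the a_i ion rides at a fixed fraction of b_i, and
every emitted peak gets +1/+2 isotope satellites at fixed fractions. The a-ion
fraction and isotope fractions are pragmatic constants adequate at ion-trap
resolution, not fitted quantities; both are configurable.

Fragment charge: only 1+ fragments are generated for precursor charge ≤ 2;
for precursor charge ≥ 3 each ion's intensity is shared between its 1+ and
2+ peaks, mirroring common ion-trap practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import neutral_loss
from .fragmodel import FragmentationParams, event_vector
from .masses import AMMONIA, ISOTOPE_SPACING, WATER, fragment_mz, peptide_mh
from .msio import Peak, Spectrum

#: ion types emitted, excluding isotope annotation
ION_TYPES = ("b", "y", "a", "b-H2O", "y-H2O", "b-NH3", "y-NH3")


@dataclass(frozen=True)
class TheoreticalPeak:
    mz: float
    intensity: float
    ion_type: str
    index: int
    charge: int = 1
    isotope_offset: int = 0

    def __post_init__(self):
        if self.ion_type not in ION_TYPES:
            raise ValueError(f"unknown ion type {self.ion_type!r}")
        if not self.mz > 0:
            raise ValueError("mz must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    @property
    def label(self) -> str:
        """Human-readable ion label, e.g. ``b3-H2O(+1, iso1)``."""
        series, _, loss = self.ion_type.partition("-")
        loss = f"-{loss}" if loss else ""
        return f"{series}{self.index}{loss}(+{self.charge}, iso{self.isotope_offset})"


@dataclass
class TheoreticalSpectrum:
    peptide: str
    charge: int
    peaks: list[TheoreticalPeak]

    def __post_init__(self):
        self.peaks = sorted(
            self.peaks,
            key=lambda p: (p.mz, p.ion_type, p.index, p.charge, p.isotope_offset),
        )


def predict_spectrum(
    peptide: str,
    charge: int,
    params: FragmentationParams,
    b_share: float = 0.5,
    a_fraction: float = 0.2,
    isotope_fractions: Sequence[float] = (0.5, 0.15),
    charge2_share: float = 0.3,
    fixed_cys_mod: bool = False,
) -> TheoreticalSpectrum:
    """Predict the annotated theoretical spectrum of *peptide*.

    ``b_share`` is the fraction of each event intensity given to the b ion
    (the rest goes to y). ``isotope_fractions`` are the +1/+2 isotope peak
    intensities relative to the monoisotopic peak; an empty sequence disables
    isotopes. Peaks with zero intensity are not emitted. Deterministic:
    equal inputs give identical output.
    """
    if not 0.0 <= b_share <= 1.0:
        raise ValueError("b_share must lie in [0, 1]")
    L = len(peptide)
    v = event_vector(peptide, params)
    charges = (1,) if charge <= 2 else (1, 2)
    charge_shares = (1.0,) if charge <= 2 else (1.0 - charge2_share, charge2_share)

    peaks: list[TheoreticalPeak] = []

    def emit(ion_type: str, index: int, base_mz_1plus_neutral_shift: float,
             series: str, series_index: int, intensity: float) -> None:
        if intensity <= 0:
            return
        for z, share in zip(charges, charge_shares):
            part = intensity * share
            if part <= 0:
                continue
            mz = fragment_mz(peptide, series, series_index, z, fixed_cys_mod)
            mz -= base_mz_1plus_neutral_shift / z
            peaks.append(TheoreticalPeak(mz, part, ion_type, index, z, 0))
            for k, frac in enumerate(isotope_fractions, start=1):
                if frac > 0:
                    peaks.append(TheoreticalPeak(
                        mz + k * ISOTOPE_SPACING / z, part * frac, ion_type, index, z, k))

    for i in range(1, L):
        vi = v[i - 1]
        prefix, suffix = peptide[:i], peptide[i:]
        b_parent, b_water, b_ammonia = neutral_loss.loss_peak_intensities(
            b_share * vi, prefix, params.water_loss, params.ammonia_loss)
        y_parent, y_water, y_ammonia = neutral_loss.loss_peak_intensities(
            (1.0 - b_share) * vi, suffix, params.water_loss, params.ammonia_loss)
        emit("b", i, 0.0, "b", i, b_parent)
        emit("b-H2O", i, WATER, "b", i, b_water)
        emit("b-NH3", i, AMMONIA, "b", i, b_ammonia)
        emit("y", L - i, 0.0, "y", L - i, y_parent)
        emit("y-H2O", L - i, WATER, "y", L - i, y_water)
        emit("y-NH3", L - i, AMMONIA, "y", L - i, y_ammonia)
        emit("a", i, 0.0, "a", i, a_fraction * b_parent)

    return TheoreticalSpectrum(peptide=peptide, charge=charge, peaks=peaks)


def render_spectrum(
    theoretical: TheoreticalSpectrum,
    source_id: str = "theoretical",
    scale: float = 1.0,
    fixed_cys_mod: bool = False,
) -> Spectrum:
    """Materialize a theoretical spectrum as an experimental-style peak list."""
    peaks = [Peak(p.mz, p.intensity * scale) for p in theoretical.peaks if p.intensity > 0]
    return Spectrum(
        source_id=source_id,
        precursor_mh=peptide_mh(theoretical.peptide, fixed_cys_mod),
        charge=theoretical.charge,
        peaks=peaks,
    )


def annotate_spectrum(
    spectrum: Spectrum,
    peptide: str,
    params: FragmentationParams,
    tolerance: float = 0.5,
    **predict_kwargs,
) -> list[tuple[Peak, TheoreticalPeak]]:
    """Match experimental peaks to predicted fragment ions.

    Greedy nearest-m/z matching within *tolerance*: theoretical peaks claim
    experimental peaks in order of descending predicted intensity, so when
    one experimental peak lies inside two windows it goes to the ion with
    the higher predicted intensity. Each experimental peak is used at most
    once. Returns (experimental, theoretical) pairs sorted by m/z.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    theo = predict_spectrum(peptide, spectrum.charge, params, **predict_kwargs)
    exp_mz = np.array([p.mz for p in spectrum.peaks])
    taken = np.zeros(len(exp_mz), dtype=bool)
    pairs: list[tuple[Peak, TheoreticalPeak]] = []
    order = sorted(theo.peaks, key=lambda p: (-p.intensity, p.mz))
    for tp in order:
        lo = np.searchsorted(exp_mz, tp.mz - tolerance, side="left")
        hi = np.searchsorted(exp_mz, tp.mz + tolerance, side="right")
        best, best_dist = -1, None
        for j in range(lo, hi):
            if taken[j]:
                continue
            d = abs(exp_mz[j] - tp.mz)
            if best_dist is None or d < best_dist:
                best, best_dist = j, d
        if best >= 0:
            taken[best] = True
            pairs.append((spectrum.peaks[best], tp))
    pairs.sort(key=lambda pr: pr[0].mz)
    return pairs


def annotation_report(pairs: Sequence[tuple[Peak, TheoreticalPeak]]) -> str:
    """Tab-separated annotation table: mz, intensity, ion label."""
    lines = ["mz\tintensity\tion"]
    for exp, theo in pairs:
        lines.append(f"{exp.mz:.4f}\t{exp.intensity:.4f}\t{theo.label}")
    return "\n".join(lines) + "\n"


def plot_annotated_spectrum(spectrum, pairs, path, peptide: str = "") -> None:
    """Save a labelled stick-plot of the spectrum (matched peaks highlighted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    mz = [p.mz for p in spectrum.peaks]
    inten = [p.intensity for p in spectrum.peaks]
    ax.vlines(mz, 0, inten, color="0.7", linewidth=0.8)
    for exp, theo in pairs:
        ax.vlines([exp.mz], 0, [exp.intensity], color="tab:blue", linewidth=1.2)
        if theo.isotope_offset == 0:
            ax.annotate(theo.label.split("(")[0], (exp.mz, exp.intensity),
                        fontsize=6, rotation=90, ha="center", va="bottom")
    ax.set_xlabel("m/z (Th)")
    ax.set_ylabel("intensity")
    if peptide:
        ax.set_title(peptide)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
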