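"""Synthetic peptides, spectra and .dta/.out fixture pairs.

Everything downstream is testable without external downloads: this module
draws tryptic-like peptides, renders their spectra from a known set of
fragmentation parameters, corrupts them with noise peaks, and writes
``.dta``/``.out`` pairs in the exact dialects :mod:`pival.msio` reads. With
``fraction_incorrect > 0`` a fraction of the reported peptides are interior
shuffles of the true one — composition and termini preserved, so the
precursor mass still matches: exactly the confusable case an
intensity-aware score has to resolve. A share of the incorrect reports is
assigned decoy protein references so decoy-estimated FDR can be compared
with the realized false-discovery proportion via the truth labels.

Everything is driven by a mandatory seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .fragmodel import DEFAULT_N_BINS, FragmentationParams, N_AA
from .masses import AA_LETTERS, AA_TO_INDEX, peptide_mh
from .specgen import predict_spectrum

#: residues with an elevated water-loss rate in the default truth
_WATER_RESIDUES = "STED"
#: residues with an elevated ammonia-loss rate in the default truth
_AMMONIA_RESIDUES = "RKNQ"


def default_true_params(seed: int = 20110615, n_bins: int = DEFAULT_N_BINS) -> FragmentationParams:
    """The fixed ground-truth parameters used by the simulator.

    Bond propensities are gamma-distributed around 1 (seeded), the position
    factors follow a middle-heavy sine profile so interior bonds cleave more
    readily than terminal ones, water loss is elevated on S/T/E/D (0.25) and
    ammonia loss on R/K/N/Q (0.20), with small background rates elsewhere.
    """
    rng = np.random.default_rng(seed)
    P = rng.gamma(shape=2.0, scale=0.5, size=(N_AA, N_AA))
    P = np.clip(P, 0.05, None)
    P /= P.mean()
    centers = (np.arange(n_bins) + 0.5) / n_bins
    f = 0.4 + 1.2 * np.sin(np.pi * centers)
    f /= f.mean()
    water = np.full(N_AA, 0.02)
    ammonia = np.full(N_AA, 0.01)
    for a in _WATER_RESIDUES:
        water[AA_TO_INDEX[a]] = 0.25
    for a in _AMMONIA_RESIDUES:
        ammonia[AA_TO_INDEX[a]] = 0.20
    return FragmentationParams(
        alpha=1.0, bond_propensity=P, position_factors=f,
        water_loss=water, ammonia_loss=ammonia,
    )


@dataclass
class SynthConfig:
    """Study conditions for one simulated dataset."""

    seed: int
    n_psms: int = 200
    length_range: tuple[int, int] = (7, 20)
    charge: int = 2
    fraction_incorrect: float = 0.0
    decoy_fraction: float = 0.5          # of incorrect PSMs, share marked decoy
    noise_peaks_lambda: float = 20.0
    noise_intensity_frac: float = 0.1    # exponential scale vs median signal
    noise_mz_min: float = 100.0
    signal_scale: float = 1000.0
    xcorr_correct: tuple[float, float] = (3.2, 0.5)    # normal mean, sd
    xcorr_incorrect: tuple[float, float] = (2.6, 0.5)
    dcn_correct: tuple[float, float] = (0.2, 0.5)      # uniform low, high
    dcn_incorrect: tuple[float, float] = (0.05, 0.3)
    params: Optional[FragmentationParams] = None

    def __post_init__(self):
        if not 0.0 <= self.fraction_incorrect <= 1.0:
            raise ValueError("fraction_incorrect must lie in [0, 1]")
        if self.params is None:
            self.params = default_true_params()


def sample_peptide(rng: np.random.Generator, config: SynthConfig) -> str:
    """Draw a tryptic-like peptide: uniform residues, C-terminal K or R."""
    lo, hi = config.length_range
    L = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(AA_LETTERS), size=L - 1))
    return body + str(rng.choice(["K", "R"]))


def shuffle_peptide(rng: np.random.Generator, peptide: str) -> str:
    """Shuffle interior residues, keeping composition and both termini."""
    interior = list(peptide[1:-1])
    for _ in range(20):
        rng.shuffle(interior)
        candidate = peptide[0] + "".join(interior) + peptide[-1]
        if candidate != peptide:
            return candidate
    return peptide  # degenerate composition: shuffle cannot differ


def _dta_text(peptide: str, config: SynthConfig, rng: np.random.Generator) -> str:
    theo = predict_spectrum(peptide, config.charge, config.params)
    mz = np.array([p.mz for p in theo.peaks])
    inten = np.array([p.intensity for p in theo.peaks]) * config.signal_scale
    mh = peptide_mh(peptide)
    n_noise = int(rng.poisson(config.noise_peaks_lambda))
    if n_noise > 0 and inten.size:
        noise_mz = rng.uniform(config.noise_mz_min, mh, size=n_noise)
        noise_int = rng.exponential(
            config.noise_intensity_frac * float(np.median(inten)), size=n_noise)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    order = np.argsort(mz)
    lines = [f"{mh:.6f} {config.charge}"]
    lines += [f"{m:.6f} {i:.6f}" for m, i in zip(mz[order], inten[order]) if i > 0]
    return "\n".join(lines) + "\n"


def _out_text(
    true_peptide: str,
    reported: str,
    protein: str,
    config: SynthConfig,
    rng: np.random.Generator,
    correct: bool,
) -> str:
    mh = peptide_mh(reported)
    mu, sd = config.xcorr_correct if correct else config.xcorr_incorrect
    xcorr1 = max(0.5, float(rng.normal(mu, sd)))
    lo, hi = config.dcn_correct if correct else config.dcn_incorrect
    dcn = float(rng.uniform(lo, hi))
    xcorr2 = xcorr1 * (1.0 - dcn)
    runner_up = shuffle_peptide(rng, true_peptide)
    sp1 = float(rng.uniform(200, 800))
    sp2 = sp1 * float(rng.uniform(0.5, 0.95))
    header = [
        "synthetic SEQUEST result",
        f" (M+H)+ mass = {mh:.6f}  charge = {config.charge}",
        "",
        "  Rank     (M+H)+    deltCn   XCorr       Sp   Ions  Reference        Peptide",
        "  ----     ------    ------   -----       --   ----  ---------        -------",
    ]
    rows = [
        f"  1    {mh:11.6f}   0.0000  {xcorr1:.4f}  {sp1:7.1f}  12/24  {protein:<15s}  K.{reported}.A",
        f"  2    {mh:11.6f}   {dcn:.4f}  {xcorr2:.4f}  {sp2:7.1f}  10/24  {'SYNX_0000':<15s}  K.{runner_up}.A",
    ]
    return "\n".join(header + rows) + "\n"


def generate_psm_pair(
    peptide: str,
    config: SynthConfig,
    rng: np.random.Generator,
    protein_index: int = 0,
) -> tuple[str, str, bool]:
    """Render one (.dta text, .out text, truth label) triple.

    The spectrum always comes from the true peptide; with probability
    ``fraction_incorrect`` the .out reports an interior shuffle instead
    (truth label False), and incorrect reports carry a decoy protein
    reference with probability ``decoy_fraction``.
    """
    incorrect = bool(rng.random() < config.fraction_incorrect)
    reported = shuffle_peptide(rng, peptide) if incorrect else peptide
    correct = reported == peptide
    decoy = bool(incorrect and rng.random() < config.decoy_fraction)
    protein = f"{'rev_' if decoy else ''}SYNP{protein_index:05d}"
    dta = _dta_text(peptide, config, rng)
    out = _out_text(peptide, reported, protein, config, rng, correct)
    return dta, out, correct


def generate_dataset(directory, config: SynthConfig) -> dict[str, bool]:
    """Write ``n_psms`` fixture pairs plus a truth manifest; return the manifest.

    Files are named ``synth_<i>.dta`` / ``synth_<i>.out``; the manifest maps
    each basename to whether the reported rank-1 peptide is the true one.
    Regeneration with the same config is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict[str, bool] = {}
    for i in range(config.n_psms):
        peptide = sample_peptide(rng, config)
        dta, out, correct = generate_psm_pair(peptide, config, rng, protein_index=i)
        stem = f"synth_{i:05d}"
        (directory / f"{stem}.dta").write_text(dta)
        (directory / f"{stem}.out").write_text(out)
        manifest[stem] = correct
    (directory / "truth.json").write_text(json.dumps(manifest, indent=0, sort_keys=True))
    return manifest


def load_truth(directory) -> dict[str, bool]:
    """Read back the truth manifest written by :func:`generate_dataset`."""
    return json.loads((Path(directory) / "truth.json").read_text())
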