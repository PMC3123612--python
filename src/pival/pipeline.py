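"""End-to-end validation of a directory of SEQUEST results.

Stages: pair ``.dta``/``.out`` files → filter PSMs on XCorr and ΔCn → build
the training set automatically from the top-XCorr confident targets → fit
the fragmentation event model (plus the two neutral-loss EMs when enabled)
→ predict a theoretical spectrum for every retained PSM and score it with
the PI similarity → export the pix file, the target-decoy FDR curve and a
machine-readable run summary. The whole run is deterministic for a fixed
configuration and input tree.

The filter defaults (XCorr ≥ 2.0, ΔCn ≥ 0.15) and the training-set size
(3000) match the reference operating point for ion-trap data; ranking for
the exported curve uses the PI score alone, with the SEQUEST scores
preserved in the pix records.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import msio, neutral_loss, scoring, specgen
from .fragmodel import (
    FragmentationParams,
    TrainingExample,
    extract_observed_bond_intensity,
    fit_params,
)

logger = logging.getLogger("pival")


class PipelineError(RuntimeError):
    """A fatal error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_dir: str
    output_pix: str
    xcorr_min: float = 2.0
    dcn_min: float = 0.15
    train_size: int = 3000
    min_train_examples: int = 50
    bin_width: float = 1.0
    tolerance: float = 0.5
    em_enabled: bool = True
    decoy_prefix: str = "rev_"
    sqrt_transform: bool = True
    fixed_cys_mod: bool = False
    max_iter: int = 1000
    fdr_levels: tuple[float, ...] = (0.005, 0.01)
    curve_path: Optional[str] = None
    summary_path: Optional[str] = None

    def __post_init__(self):
        if self.xcorr_min < 0 or self.dcn_min < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.train_size < 1:
            raise ValueError("train_size must be >= 1")


@dataclass
class RunResult:
    records: list[msio.PixRecord]
    params: FragmentationParams
    curve: scoring.FDRCurve
    summary: dict


def filter_psms(psms: Sequence[msio.PSM], xcorr_min: float, dcn_min: float) -> list[msio.PSM]:
    """Keep PSMs with XCorr ≥ xcorr_min and ΔCn ≥ dcn_min, order preserved."""
    return [p for p in psms if p.hit.xcorr >= xcorr_min and p.hit.delta_cn >= dcn_min]


def select_training_psms(psms: Sequence[msio.PSM], train_size: int) -> list[msio.PSM]:
    """Top *train_size* non-decoy PSMs by XCorr (ties: ΔCn, then spectrum id)."""
    targets = [p for p in psms if not p.is_decoy]
    targets.sort(key=lambda p: (-p.hit.xcorr, -p.hit.delta_cn, p.spectrum.source_id))
    if train_size < len(targets):
        return targets[:train_size]
    if train_size > len(targets):
        warnings.warn(
            f"train_size {train_size} exceeds the {len(targets)} available "
            "confident targets; using all of them", stacklevel=2)
    return targets


def build_training_set(
    psms: Sequence[msio.PSM],
    train_size: int,
    tolerance: float = 0.5,
    min_examples: int = 50,
    fixed_cys_mod: bool = False,
) -> list[TrainingExample]:
    """Convert the automatically selected confident PSMs to training examples.

    PSMs whose spectra match no b/y ion at all are dropped. Deterministic:
    the selection order is a total order over the inputs.
    """
    selected = select_training_psms(psms, train_size)
    examples = []
    for psm in selected:
        ex = extract_observed_bond_intensity(psm, tolerance, fixed_cys_mod)
        if ex is not None:
            examples.append(ex)
    if len(examples) < min_examples:
        raise PipelineError(
            "train",
            f"only {len(examples)} usable training examples (need {min_examples}); "
            "loosen the filters or provide more confident identifications")
    return examples


def _fit_loss_probs(
    training_psms: Sequence[msio.PSM],
    tolerance: float,
    fixed_cys_mod: bool,
) -> tuple[np.ndarray, np.ndarray, dict]:
    observations = []
    for psm in training_psms:
        observations.extend(neutral_loss.collect_loss_observations(
            psm.hit.peptide, psm.spectrum, tolerance, fixed_cys_mod))
    if not observations:
        raise PipelineError("em", "no b/y parent peaks matched; cannot fit loss model")
    water = neutral_loss.em_fit(observations, "water")
    ammonia = neutral_loss.em_fit(observations, "ammonia")
    diag = {
        "n_loss_observations": len(observations),
        "water_iterations": water.n_iter,
        "ammonia_iterations": ammonia.n_iter,
        "water_converged": water.converged,
        "ammonia_converged": ammonia.converged,
    }
    # unobserved residues keep probability 0 rather than NaN for prediction
    return (np.nan_to_num(water.probabilities),
            np.nan_to_num(ammonia.probabilities), diag)


def run_validation(config: RunConfig) -> RunResult:
    """Run the full validation pipeline and write pix/curve/summary files.

    On any fatal stage error, partially written outputs are removed and a
    :class:`PipelineError` naming the stage propagates.
    """
    outputs = [Path(config.output_pix)]
    if config.curve_path:
        outputs.append(Path(config.curve_path))
    if config.summary_path:
        outputs.append(Path(config.summary_path))
    try:
        return _run(config)
    except Exception:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig) -> RunResult:
    logger.info("pairing inputs in %s", config.input_dir)
    try:
        psms = msio.pair_inputs(config.input_dir, decoy_prefix=config.decoy_prefix)
    except (OSError, msio.FormatError) as exc:
        raise PipelineError("pair", str(exc)) from exc
    if not psms:
        raise PipelineError("pair", f"no .dta/.out pairs found in {config.input_dir}")

    retained = filter_psms(psms, config.xcorr_min, config.dcn_min)
    logger.info("filter: %d of %d PSMs retained (XCorr >= %g, dCn >= %g)",
                len(retained), len(psms), config.xcorr_min, config.dcn_min)
    if not retained:
        raise PipelineError("filter", "no PSMs pass the XCorr/deltaCn filter")

    training_psms = select_training_psms(retained, config.train_size)
    examples = build_training_set(
        retained, config.train_size, config.tolerance,
        config.min_train_examples, config.fixed_cys_mod)
    logger.info("training set: %d selected, %d usable", len(training_psms), len(examples))

    fit = fit_params(examples, max_iter=config.max_iter)
    logger.info("fit: objective %.6g, converged=%s (%d iterations)",
                fit.objective, fit.converged, fit.n_iter)

    params = fit.params
    em_diag: dict = {"enabled": config.em_enabled}
    if config.em_enabled:
        water, ammonia, diag = _fit_loss_probs(
            training_psms, config.tolerance, config.fixed_cys_mod)
        params = FragmentationParams(
            alpha=params.alpha,
            bond_propensity=params.bond_propensity,
            position_factors=params.position_factors,
            water_loss=water,
            ammonia_loss=ammonia,
        )
        em_diag.update(diag)

    records = []
    scored = []
    for psm in retained:
        theo = specgen.predict_spectrum(
            psm.hit.peptide, psm.spectrum.charge, params,
            fixed_cys_mod=config.fixed_cys_mod)
        score = scoring.pi_score(
            psm.spectrum, theo, config.bin_width, config.sqrt_transform)
        psm.pi_score = score
        scored.append(psm)
        records.append(msio.PixRecord(
            spectrum_id=psm.spectrum.source_id,
            peptide=psm.hit.peptide,
            xcorr=psm.hit.xcorr,
            delta_cn=psm.hit.delta_cn,
            sp=psm.hit.sp,
            pi_score=score,
            proteins=list(psm.hit.proteins),
        ))

    pi_sc, decoy = scoring.psm_scores(scored, "pi")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = scoring.fdr_curve(pi_sc, decoy)
        xcorr_curve = scoring.fdr_curve(*scoring.psm_scores(scored, "xcorr"))

    summary = {
        "config": {
            "input_dir": str(config.input_dir),
            "xcorr_min": config.xcorr_min,
            "dcn_min": config.dcn_min,
            "train_size": config.train_size,
            "bin_width": config.bin_width,
            "tolerance": config.tolerance,
            "em_enabled": config.em_enabled,
            "decoy_prefix": config.decoy_prefix,
            "sqrt_transform": config.sqrt_transform,
        },
        "counts": {
            "pairs": len(psms),
            "retained": len(retained),
            "filtered_out": len(psms) - len(retained),
            "training_selected": len(training_psms),
            "training_used": len(examples),
            "records": len(records),
            "decoys_retained": int(decoy.sum()),
        },
        "fit": {
            "objective": fit.objective,
            "converged": fit.converged,
            "iterations": fit.n_iter,
        },
        "em": em_diag,
        "targets_at_fdr": {
            f"{lv:g}": {
                "pi": scoring.count_at_fdr(curve, lv),
                "xcorr": scoring.count_at_fdr(xcorr_curve, lv),
            }
            for lv in config.fdr_levels
        },
    }

    msio.write_pix(records, config.output_pix, meta={
        "train_size": config.train_size,
        "xcorr_min": config.xcorr_min,
        "dcn_min": config.dcn_min,
    })
    if config.curve_path:
        scoring.write_curve_tsv(curve, config.curve_path)
    if config.summary_path:
        Path(config.summary_path).write_text(
            json.dumps(summary, indent=1, sort_keys=True))
    logger.info("wrote %d pix records to %s", len(records), config.output_pix)
    return RunResult(records=records, params=params, curve=curve, summary=summary)
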