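"""EM estimation of per-residue neutral-loss probabilities.

Fragment ions frequently shed a water (−H2O, dehydration) or an ammonia
(−NH3, deamination) molecule. We model each residue occurrence in a fragment
as an independent Bernoulli cause: residue a triggers the loss with
probability p_a, and the fragment shows the loss peak when at least one
occurrence fires, so

    q(fragment) = 1 − Π_{a in fragment} (1 − p_a)

Evidence per observed fragment is the matched loss-peak intensity as a
fraction of its parent peak, capped at 1. The per-residue probabilities are
estimated by expectation–maximization on this noisy-OR model:

* E-step: given that a loss was seen on a fragment, each residue occurrence
  was the (or a) cause with posterior p_a / q(fragment).
* M-step: p_a = (summed responsibilities for a) / (occurrences of a).

This latent-cause decomposition is the exact EM for the Bernoulli loss
model, so the observed-data log-likelihood never decreases. Water and
ammonia are fit in two independent runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .masses import AA_LETTERS, AA_TO_INDEX, AMMONIA, WATER, fragment_mz, validate_peptide

N_AA = len(AA_LETTERS)


@dataclass
class LossObservation:
    """Loss evidence for one fragment ion.

    ``fragment`` is the residue string of the parent fragment (a multiset —
    order is irrelevant); intensities are raw peak intensities, ≥ 0.
    """

    fragment: str
    parent_intensity: float
    loss_intensity_water: float = 0.0
    loss_intensity_ammonia: float = 0.0

    def __post_init__(self):
        validate_peptide(self.fragment)
        for name in ("parent_intensity", "loss_intensity_water", "loss_intensity_ammonia"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EMResult:
    """Fitted per-residue loss probabilities with the fit trace.

    ``probabilities[i]`` is NaN for residues never seen in any fragment
    (``observed_mask[i]`` False): with no occurrences the rate is undefined
    and is flagged rather than guessed.
    """

    probabilities: np.ndarray
    observed_mask: np.ndarray
    loglik_trace: list[float]
    n_iter: int
    converged: bool

    def as_dict(self) -> dict:
        return {a: float(self.probabilities[i]) for i, a in enumerate(AA_LETTERS)}


def expected_loss_fraction(fragment: str, loss_probs: np.ndarray) -> float:
    """Probability that at least one residue of *fragment* produces the loss."""
    validate_peptide(fragment)
    p = np.asarray(loss_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("loss probabilities must lie in [0, 1]")
    idx = [AA_TO_INDEX[a] for a in fragment]
    return float(1.0 - np.prod(1.0 - p[idx]))


def _evidence_weight(obs: LossObservation, kind: str) -> float:
    loss = obs.loss_intensity_water if kind == "water" else obs.loss_intensity_ammonia
    if obs.parent_intensity <= 0:
        return 1.0 if loss > 0 else 0.0
    return min(1.0, loss / obs.parent_intensity)


def _count_matrix(observations: Sequence[LossObservation]) -> np.ndarray:
    C = np.zeros((len(observations), N_AA))
    for k, obs in enumerate(observations):
        for a, n in Counter(obs.fragment).items():
            C[k, AA_TO_INDEX[a]] = n
    return C


def _loglik(C: np.ndarray, w: np.ndarray, p: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        log1mp = np.log(np.clip(1.0 - p, 1e-300, 1.0))
    q = 1.0 - np.exp(C @ log1mp)
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return float(w @ np.log(q) + (1.0 - w) @ np.log(1.0 - q))


def em_fit(
    observations: Sequence[LossObservation],
    loss_kind: str = "water",
    init: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EMResult:
    """Fit per-residue loss probabilities for one loss kind by EM.

    *init* is the common starting probability (deterministic). Iterates
    until max |Δp| < *tol* over observed residues or *max_iter* is reached.
    ``loglik_trace`` holds the observed-data log-likelihood after each
    iteration (plus the initial value); it is non-decreasing.
    """
    if loss_kind not in ("water", "ammonia"):
        raise ValueError("loss_kind must be 'water' or 'ammonia'")
    if not observations:
        raise ValueError("at least one observation is required")
    if not 0.0 < init < 1.0:
        raise ValueError("init must lie in (0, 1)")
    C = _count_matrix(observations)
    w = np.array([_evidence_weight(o, loss_kind) for o in observations])
    occurrences = C.sum(axis=0)
    observed = occurrences > 0

    p = np.full(N_AA, float(init))
    p[~observed] = 0.0
    trace = [_loglik(C, w, p)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log1mp = np.log(np.clip(1.0 - p, 1e-300, 1.0))
        q = 1.0 - np.exp(C @ log1mp)
        ratio = np.where(q > 0, w / np.where(q > 0, q, 1.0), 0.0)
        numer = p * (C.T @ ratio)
        p_new = np.where(observed, numer / np.where(observed, occurrences, 1.0), 0.0)
        p_new = np.clip(p_new, 0.0, 1.0)
        delta = np.max(np.abs(p_new - p)[observed]) if observed.any() else 0.0
        p = p_new
        trace.append(_loglik(C, w, p))
        if delta < tol:
            converged = True
            break
    probabilities = p.copy()
    probabilities[~observed] = np.nan
    return EMResult(
        probabilities=probabilities,
        observed_mask=observed,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )


def loss_peak_intensities(
    event_intensity: float,
    fragment: str,
    water_probs: np.ndarray,
    ammonia_probs: np.ndarray,
) -> tuple[float, float, float]:
    """Split a fragment ion's intensity into (parent, water-loss, ammonia-loss).

    The loss fractions come from :func:`expected_loss_fraction`; intensity is
    conserved exactly — the three parts always sum to *event_intensity*.
    Allocation is sequential (water first, ammonia from the remainder), which
    keeps every part non-negative for any probabilities in [0, 1].
    """
    if event_intensity < 0:
        raise ValueError("event intensity must be >= 0")
    qw = expected_loss_fraction(fragment, water_probs)
    qa = expected_loss_fraction(fragment, ammonia_probs)
    water = event_intensity * qw
    ammonia = event_intensity * (1.0 - qw) * qa
    parent = event_intensity * (1.0 - qw) * (1.0 - qa)
    return parent, water, ammonia


def collect_loss_observations(
    peptide: str,
    spectrum,
    tolerance: float = 0.5,
    fixed_cys_mod: bool = False,
) -> list[LossObservation]:
    """Match b/y parent and loss peaks in a spectrum to build EM evidence.

    For every bond of *peptide*, each singly-charged b/y parent peak found
    within *tolerance* Th yields one observation with the intensities of the
    −H2O and −NH3 peaks found (most intense in window, 0 if absent). The b
    fragment's residues are the peptide prefix, the y fragment's the suffix.
    """
    peaks = spectrum.peaks
    if not peaks:
        return []
    mz = np.array([p.mz for p in peaks])
    inten = np.array([p.intensity for p in peaks])

    def window_max(target: float) -> float:
        lo = np.searchsorted(mz, target - tolerance, side="left")
        hi = np.searchsorted(mz, target + tolerance, side="right")
        return float(inten[lo:hi].max()) if hi > lo else 0.0

    out = []
    L = len(peptide)
    for i in range(1, L):
        for ion, frag, idx in (("b", peptide[:i], i), ("y", peptide[i:], L - i)):
            parent_mz = fragment_mz(peptide, ion, idx, 1, fixed_cys_mod)
            parent = window_max(parent_mz)
            if parent <= 0:
                continue
            out.append(LossObservation(
                fragment=frag,
                parent_intensity=parent,
                loss_intensity_water=window_max(parent_mz - WATER),
                loss_intensity_ammonia=window_max(parent_mz - AMMONIA),
            ))
    return out
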