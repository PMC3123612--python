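"""The fragmentation event model.

Backbone cleavage intensity is modelled multiplicatively: for a peptide
A_1…A_L, bond i (between A_i and A_{i+1}) fragments with event intensity

    v_i = alpha * P(A_i, A_{i+1}) * f_i

where ``P`` is a 20x20 propensity for the bond's residue pair, ``f`` captures
the positional tendency of cleavage towards the middle of the peptide, and
``alpha`` is a global scale. ``f`` is shared across peptide lengths by
binning the relative bond position into B bins (default 10), so a bond
half-way along any peptide reads the same factor.

Parameters are trained by constrained least squares between the model's
normalized event vector and observed per-bond b/y intensity fractions
extracted from high-confidence identifications. Normalizing both sides makes
the objective comparable across peptides with different total ion current
and deliberately removes the overall scale (absorbed into ``alpha``).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .masses import AA_LETTERS, fragment_mz, residue_indices, validate_peptide

N_AA = len(AA_LETTERS)
DEFAULT_N_BINS = 10


@dataclass
class FragmentationParams:
    """Trainable parameters of the fragmentation event model.

    Identifiability: ``bond_propensity`` and ``position_factors`` are kept at
    mean 1; all scale lives in ``alpha``. ``water_loss`` / ``ammonia_loss``
    are per-residue neutral-loss probabilities in [0, 1], indexed in
    :data:`pival.masses.AA_LETTERS` order.
    """

    alpha: float = 1.0
    bond_propensity: np.ndarray = field(
        default_factory=lambda: np.ones((N_AA, N_AA)))
    position_factors: np.ndarray = field(
        default_factory=lambda: np.ones(DEFAULT_N_BINS))
    water_loss: np.ndarray = field(default_factory=lambda: np.zeros(N_AA))
    ammonia_loss: np.ndarray = field(default_factory=lambda: np.zeros(N_AA))

    def __post_init__(self):
        self.bond_propensity = np.asarray(self.bond_propensity, dtype=float)
        self.position_factors = np.asarray(self.position_factors, dtype=float)
        self.water_loss = np.asarray(self.water_loss, dtype=float)
        self.ammonia_loss = np.asarray(self.ammonia_loss, dtype=float)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.bond_propensity.shape != (N_AA, N_AA):
            raise ValueError("bond_propensity must be 20x20")
        for name in ("bond_propensity", "position_factors"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        for name in ("water_loss", "ammonia_loss"):
            arr = getattr(self, name)
            if arr.shape != (N_AA,) or np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must be a 20-vector of probabilities")

    @property
    def n_bins(self) -> int:
        return len(self.position_factors)

    @classmethod
    def identity(cls, n_bins: int = DEFAULT_N_BINS) -> "FragmentationParams":
        """All-ones propensities and position factors, zero loss probabilities."""
        return cls(position_factors=np.ones(n_bins))

    # -- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "bond_propensity": {
                a: {b: self.bond_propensity[i, j] for j, b in enumerate(AA_LETTERS)}
                for i, a in enumerate(AA_LETTERS)
            },
            "position_factors": self.position_factors.tolist(),
            "water_loss": {a: self.water_loss[i] for i, a in enumerate(AA_LETTERS)},
            "ammonia_loss": {a: self.ammonia_loss[i] for i, a in enumerate(AA_LETTERS)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentationParams":
        P = np.array([[d["bond_propensity"][a][b] for b in AA_LETTERS] for a in AA_LETTERS])
        return cls(
            alpha=float(d["alpha"]),
            bond_propensity=P,
            position_factors=np.array(d["position_factors"], dtype=float),
            water_loss=np.array([d["water_loss"][a] for a in AA_LETTERS]),
            ammonia_loss=np.array([d["ammonia_loss"][a] for a in AA_LETTERS]),
        )

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "FragmentationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainingExample:
    """One peptide with its observed per-bond intensity fractions (sum 1)."""

    peptide: str
    observed: np.ndarray

    def __post_init__(self):
        validate_peptide(self.peptide)
        self.observed = np.asarray(self.observed, dtype=float)
        if len(self.observed) != len(self.peptide) - 1:
            raise ValueError("observed vector must have length L-1")
        if np.any(self.observed < 0):
            raise ValueError("observed intensities must be non-negative")
        if abs(self.observed.sum() - 1.0) > 1e-9:
            raise ValueError("observed intensities must sum to 1")


@dataclass
class FitResult:
    params: FragmentationParams
    objective: float
    converged: bool
    n_iter: int
    message: str


def position_bin(i: int, L: int, n_bins: int = DEFAULT_N_BINS) -> int:
    """Bin index of bond i (1-based) in a peptide of length L."""
    if not 1 <= i <= L - 1:
        raise ValueError(f"bond index {i} out of range [1, {L - 1}]")
    b = int(np.floor(n_bins * (i - 0.5) / (L - 1)))
    return min(max(b, 0), n_bins - 1)


def position_factor(i: int, L: int, params: FragmentationParams) -> float:
    """Positional factor f_i for bond i of a length-L peptide."""
    return float(params.position_factors[position_bin(i, L, params.n_bins)])


def _bond_bin_indices(peptide: str, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    idx = residue_indices(peptide)
    L = len(idx)
    bonds = idx[:-1] * N_AA + idx[1:]
    bins = np.array([position_bin(i, L, n_bins) for i in range(1, L)], dtype=np.intp)
    return bonds, bins


def event_vector(peptide: str, params: FragmentationParams) -> np.ndarray:
    """Predicted cleavage event intensities v_1..v_{L-1}."""
    if len(peptide) < 2:
        raise ValueError("fragmentation needs a peptide of length >= 2")
    bonds, bins = _bond_bin_indices(peptide, params.n_bins)
    return params.alpha * params.bond_propensity.ravel()[bonds] * params.position_factors[bins]


def normalize_vector(v: np.ndarray) -> np.ndarray:
    """Divide by the sum; an all-zero vector stays all-zero."""
    s = v.sum()
    return v / s if s > 0 else np.zeros_like(v)


@dataclass
class _Design:
    """Flattened training set: one row per bond across all examples."""

    bonds: np.ndarray        # flat 20*20 bond-type index per bond
    bins: np.ndarray         # position-bin index per bond
    example_id: np.ndarray   # which example each bond belongs to
    observed: np.ndarray     # observed fraction per bond
    n_examples: int


def _build_design(training_set: Sequence[TrainingExample], n_bins: int) -> _Design:
    bonds, bins, eids, obs = [], [], [], []
    for k, ex in enumerate(training_set):
        b, bn = _bond_bin_indices(ex.peptide, n_bins)
        bonds.append(b)
        bins.append(bn)
        eids.append(np.full(len(b), k, dtype=np.intp))
        obs.append(ex.observed)
    return _Design(
        bonds=np.concatenate(bonds),
        bins=np.concatenate(bins),
        example_id=np.concatenate(eids),
        observed=np.concatenate(obs),
        n_examples=len(training_set),
    )


def _objective_and_grad(x: np.ndarray, design: _Design):
    P_flat = x[: N_AA * N_AA]
    f = x[N_AA * N_AA:]
    v = P_flat[design.bonds] * f[design.bins]
    sums = np.bincount(design.example_id, weights=v, minlength=design.n_examples)
    safe = np.where(sums > 0, sums, 1.0)
    u = v / safe[design.example_id]
    r = u - design.observed
    # examples with an all-zero event vector contribute ||observed||^2 with
    # zero gradient (u == 0 there regardless of x along feasible directions)
    obj = float(r @ r)
    ru = np.bincount(design.example_id, weights=r * u, minlength=design.n_examples)
    g_v = 2.0 * (r - ru[design.example_id]) / safe[design.example_id]
    g_v = np.where(sums[design.example_id] > 0, g_v, 0.0)
    grad = np.zeros_like(x)
    np.add.at(grad, design.bonds, g_v * f[design.bins])
    np.add.at(grad, N_AA * N_AA + design.bins, g_v * P_flat[design.bonds])
    return obj, grad


def objective(params: FragmentationParams, training_set: Sequence[TrainingExample]) -> float:
    """Sum of squared differences between normalized predictions and observations."""
    if not training_set:
        raise ValueError("training set is empty")
    design = _build_design(training_set, params.n_bins)
    x = np.concatenate([params.bond_propensity.ravel(), params.position_factors])
    return _objective_and_grad(x, design)[0]


def fit_params(
    training_set: Sequence[TrainingExample],
    init: Optional[FragmentationParams] = None,
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> FitResult:
    """Fit (alpha, P, f) to a training set by bounded least squares.

    Deterministic given the same init and training set: L-BFGS-B with an
    analytic gradient from the all-ones initialization (or *init*), bounds
    keeping every parameter non-negative. Afterwards P and f are renormalized
    to mean 1 with the scale folded into alpha, which leaves every normalized
    event vector — and hence the objective — unchanged.
    """
    if not training_set:
        raise ValueError("training set is empty")
    if all(np.all(ex.observed == 0) for ex in training_set):
        raise ValueError("degenerate training set: every observation is all-zero")
    if init is None:
        init = FragmentationParams.identity()
    design = _build_design(training_set, init.n_bins)
    x0 = np.concatenate([init.bond_propensity.ravel(), init.position_factors])
    obj0 = _objective_and_grad(x0, design)[0]
    res = minimize(
        _objective_and_grad, x0, args=(design,), jac=True, method="L-BFGS-B",
        bounds=[(1e-8, None)] * len(x0),
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": tol, "gtol": 1e-10},
    )
    x = res.x
    if res.fun > obj0:  # optimizer never worsens the fit
        x = x0
    P = x[: N_AA * N_AA].reshape(N_AA, N_AA).copy()
    f = x[N_AA * N_AA:].copy()
    mP, mf = P.mean(), f.mean()
    P /= mP
    f /= mf
    params = FragmentationParams(
        alpha=init.alpha * mP * mf,
        bond_propensity=P,
        position_factors=f,
        water_loss=init.water_loss,
        ammonia_loss=init.ammonia_loss,
    )
    final_obj = objective(params, training_set)
    return FitResult(
        params=params,
        objective=final_obj,
        converged=bool(res.success) and final_obj <= obj0 + 1e-12,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def _max_intensity_in_window(mz_sorted: np.ndarray, inten: np.ndarray,
                             target: float, tol: float) -> float:
    lo = np.searchsorted(mz_sorted, target - tol, side="left")
    hi = np.searchsorted(mz_sorted, target + tol, side="right")
    if hi <= lo:
        return 0.0
    return float(inten[lo:hi].max())


def extract_observed_bond_intensity(
    psm,
    tolerance: float = 0.5,
    fixed_cys_mod: bool = False,
) -> Optional[TrainingExample]:
    """Turn a PSM into a training example of per-bond b/y intensity fractions.

    For bond i the observed intensity is the most intense experimental peak
    within *tolerance* Th of the singly-charged b_i m/z plus the analogous
    y_{L-i} match; unmatched bonds contribute 0. The vector is normalized to
    sum 1. Returns None when no bond matches at all (caller should skip the
    example). Only singly-charged b/y ions are considered.
    """
    peptide = psm.hit.peptide
    if len(peptide) < 2:
        raise ValueError("peptide too short to fragment")
    peaks = psm.spectrum.peaks
    if not peaks:
        return None
    mz = np.array([p.mz for p in peaks])
    inten = np.array([p.intensity for p in peaks])
    L = len(peptide)
    obs = np.zeros(L - 1)
    for i in range(1, L):
        b_mz = fragment_mz(peptide, "b", i, 1, fixed_cys_mod)
        y_mz = fragment_mz(peptide, "y", L - i, 1, fixed_cys_mod)
        obs[i - 1] = (
            _max_intensity_in_window(mz, inten, b_mz, tolerance)
            + _max_intensity_in_window(mz, inten, y_mz, tolerance)
        )
    total = obs.sum()
    if total <= 0:
        return None
    return TrainingExample(peptide=peptide, observed=obs / total)
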