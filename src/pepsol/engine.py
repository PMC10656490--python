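"""Per-residue intrinsic-solubility profile and global score.

Each residue contributes a linear combination of four components:
hydrophilicity, the magnitude of its fractional charge at the solution pH,
and its α-helix and β-sheet propensities.  All four live on z-scored
(dimensionless) scales.  With the default weights

    raw_i = 1.0 * hydrophilicity_i + 0.5 * |q_i| - 0.3 * alpha_i - 0.5 * beta_i

high hydrophilicity and charge raise the score while secondary-structure
(especially β) propensity lowers it; higher score = more soluble.  The raw
profile is smoothed with a boundary-truncated moving average (default window
7 residues) and the global score is the mean of the smoothed profile, so
scores of peptides of different lengths are comparable.

Terminal charges: the first residue carries the free α-amine (pKa 9.0) and
the last the free α-carboxylate (pKa 3.5) unless the corresponding terminus
is capped by a terminal-modified residue (acetylated N-terminus or amidated
C-terminus), in which case that charge is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .errors import ParameterError, ResidueLookupError
from .parser import ParsedPeptide, parse_sequence, validate_tokens
from .registry import Registry, ScaleTable, default_scales

#: Component weights on z-scored scales (hydrophilicity, |charge|, alpha, beta).
DEFAULT_WEIGHTS = (1.0, 0.5, -0.3, -0.5)
DEFAULT_WINDOW = 7

#: Terminal ionizable groups of an uncapped peptide.
N_TERMINAL_AMINE_PKA = 9.0
C_TERMINAL_CARBOXYL_PKA = 3.5


@dataclass(frozen=True)
class EngineParams:
    """Tunable parameters of the solubility engine."""

    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS
    window: int = DEFAULT_WINDOW
    ph: float = chem.DEFAULT_PH

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ParameterError(f"window must be an odd integer >= 1, got {self.window}")
        if not 0.0 <= self.ph <= 14.0:
            raise ParameterError(f"pH must lie in [0, 14], got {self.ph}")
        if not all(np.isfinite(self.weights)) or len(self.weights) != 4:
            raise ParameterError("weights must be four finite scalars")


@dataclass(frozen=True)
class PredictionResult:
    """Per-residue profile plus global intrinsic-solubility score."""

    sequence: ParsedPeptide
    raw_profile: np.ndarray
    smooth_profile: np.ndarray
    global_score: float
    per_component: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per residue plus the per-component columns."""
        df = pd.DataFrame(
            {
                "position": np.arange(1, len(self.sequence) + 1),
                "token": list(self.sequence.tokens),
                "raw": self.raw_profile,
                "smooth": self.smooth_profile,
            }
        )
        for name, values in self.per_component.items():
            df[name] = values
        return df


def _terminal_charge(role: str | None, capped: bool, ph: float) -> float:
    if capped or role is None:
        return 0.0
    if role == "n_term":
        group = chem.IonizableGroup("n_terminal_amine", "basic", N_TERMINAL_AMINE_PKA)
    else:
        group = chem.IonizableGroup(
            "c_terminal_carboxyl", "acidic", C_TERMINAL_CARBOXYL_PKA
        )
    return chem.group_charge(group, ph)


def residue_component_vector(
    code: str,
    registry: Registry,
    params: EngineParams,
    terminal_role: str | None = None,
) -> tuple[float, float, float, float]:
    """(hydrophilicity, net charge at params.ph, alpha_prop, beta_prop).

    ``terminal_role`` is ``"n_term"``/``"c_term"`` when the residue sits at
    the corresponding sequence end; the free terminal charge is then added
    unless the residue itself caps that terminus.
    """
    d = registry.get(code)
    charge = d.side_chain_charge(params.ph)
    charge += _terminal_charge(terminal_role, d.terminal == terminal_role, params.ph)
    return (d.hydrophilicity, charge, d.alpha_prop, d.beta_prop)


def smooth_profile(raw, window: int) -> np.ndarray:
    """Boundary-truncated moving average.

    Position i averages raw[max(0, i-w//2) : i+w//2+1]; the profile length is
    preserved and a window of 1 is the identity.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be an odd integer >= 1, got {window}")
    if window > 2 * n - 1:
        raise ParameterError(
            f"window {window} too wide for a profile of length {n}"
        )
    # windowed sums as local dot products (not prefix-sum differences): each
    # position then depends only on the raw values inside its window, so a
    # change at one site cannot perturb positions outside it even in the
    # last floating-point bit
    half = window // 2
    kernel = np.ones(window)
    sums = np.convolve(raw, kernel, mode="full")[half : half + n]
    counts = np.convolve(np.ones(n), kernel, mode="full")[half : half + n]
    return sums / counts


def global_score(smooth, params: EngineParams | None = None) -> float:
    """Length-normalized sum (mean) of the smoothed profile."""
    smooth = np.asarray(smooth, dtype=float)
    if smooth.size == 0:
        raise ParameterError("profile must be nonempty")
    return float(smooth.mean())


def predict_peptide(
    peptide: ParsedPeptide, registry: Registry, params: EngineParams | None = None
) -> PredictionResult:
    """Score an already-parsed peptide (the fast path used by screening)."""
    params = params or EngineParams()
    n = len(peptide)
    hyd = np.empty(n)
    charge = np.empty(n)
    alpha = np.empty(n)
    beta = np.empty(n)
    for i, code in enumerate(peptide.tokens):
        role = "n_term" if i == 0 else ("c_term" if i == n - 1 else None)
        h, q, a, b = residue_component_vector(code, registry, params, role)
        hyd[i], charge[i], alpha[i], beta[i] = h, q, a, b
    w_h, w_q, w_a, w_b = params.weights
    raw = w_h * hyd + w_q * np.abs(charge) + w_a * alpha + w_b * beta
    smooth = smooth_profile(raw, _effective_window(params.window, n))
    return PredictionResult(
        sequence=peptide,
        raw_profile=raw,
        smooth_profile=smooth,
        global_score=global_score(smooth, params),
        per_component={
            "hydrophilicity": hyd,
            "charge": charge,
            "alpha_prop": alpha,
            "beta_prop": beta,
        },
    )


def _effective_window(window: int, n: int) -> int:
    # peptides shorter than the window get the widest admissible odd window
    return min(window, 2 * n - 1)


def predict(
    text: str, registry: Registry, params: EngineParams | None = None
) -> PredictionResult:
    """Parse, validate and score a sequence string."""
    peptide = parse_sequence(text)
    unknown = validate_tokens(peptide, registry)
    if unknown:
        raise ResidueLookupError(
            f"sequence {text!r} contains unregistered residue codes: {unknown}"
        )
    return predict_peptide(peptide, registry, params)


# ---------------------------------------------------------------------------
# legacy canonical-only path
#
# Computes the same score for canonical-only sequences straight from the
# scale table and a literal side-chain pKa dict, bypassing the structure /
# descriptor / calibration machinery entirely.  Exists as an independent
# reference: predict() on a canonical-only sequence must agree with it
# exactly.

_CANONICAL_SIDECHAIN_PKAS: dict[str, tuple[str, float]] = {
    "D": ("acidic", 4.0),
    "E": ("acidic", 4.0),
    "H": ("basic", 6.0),
    "C": ("acidic", 8.3),
    "Y": ("acidic", 10.0),
    "K": ("basic", 10.5),
    "R": ("basic", 12.5),
}


def predict_canonical(
    text: str,
    params: EngineParams | None = None,
    scales: ScaleTable | None = None,
) -> PredictionResult:
    """Score a canonical-only sequence without touching any structure-derived
    machinery (no SMILES, descriptors or calibration)."""
    params = params or EngineParams()
    scales = scales or default_scales()
    peptide = parse_sequence(text)
    bad = [t for t in peptide.tokens if len(t) != 1]
    if bad:
        raise ResidueLookupError(
            f"canonical-only path cannot score modified residues: {bad}"
        )
    n = len(peptide)
    hyd = np.array([scales.hydrophilicity[t] for t in peptide.tokens])
    alpha = np.array([scales.alpha_prop[t] for t in peptide.tokens])
    beta = np.array([scales.beta_prop[t] for t in peptide.tokens])
    charge = np.empty(n)
    for i, t in enumerate(peptide.tokens):
        q = 0.0
        if t in _CANONICAL_SIDECHAIN_PKAS:
            kind, pka = _CANONICAL_SIDECHAIN_PKAS[t]
            q += chem.group_charge(chem.IonizableGroup(t, kind, pka), params.ph)
        if i == 0:
            q += _terminal_charge("n_term", False, params.ph)
        if i == n - 1:
            q += _terminal_charge("c_term", False, params.ph)
        charge[i] = q
    w_h, w_q, w_a, w_b = params.weights
    raw = w_h * hyd + w_q * np.abs(charge) + w_a * alpha + w_b * beta
    smooth = smooth_profile(raw, _effective_window(params.window, n))
    return PredictionResult(
        sequence=peptide,
        raw_profile=raw,
        smooth_profile=smooth,
        global_score=global_score(smooth, params),
        per_component={
            "hydrophilicity": hyd,
            "charge": charge,
            "alpha_prop": alpha,
            "beta_prop": beta,
        },
    )
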