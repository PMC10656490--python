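"""Linear calibration of predicted physicochemical quantities onto the
canonical residue scales.

Modified amino acids arrive with descriptors and a logP estimate; canonical
residues have tabulated, dimensionless scale values.  Ordinary least squares
maps the former onto the latter so that a modified residue's hydrophilicity
and secondary-structure propensities land on the same scale as the canonical
table, which therefore never has to change.

Three models are fitted:

* hydrophilicity ~ logP, on all 20 canonical residues (hydrophilicity is
  closely related to inverse logP, so this is essentially a sign flip plus
  rescaling);
* α-helix propensity ~ descriptors, on 18 residues — glycine and proline are
  excluded because their backbone flexibility/rigidity gives them outlying
  propensities that would skew the fit;
* β-sheet propensity ~ descriptors, likewise on 18 residues.

For the propensity models an exhaustive search over all 31 nonempty subsets
of {mw, h_donors, h_acceptors, rot_bonds, tpsa} is available; the shipped
default pins {h_donors, tpsa} for the helix model and {mw, rot_bonds, tpsa}
for the sheet model, the subsets that also performed best against downstream
experimental solubility data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CollinearityError, UnfittedCalibratorError

#: Candidate features for the propensity-model subset search.
PROPENSITY_CANDIDATES = ("mw", "h_donors", "h_acceptors", "rot_bonds", "tpsa")

#: Default (pinned) feature subsets for the two propensity models.
DEFAULT_ALPHA_FEATURES = ("h_donors", "tpsa")
DEFAULT_BETA_FEATURES = ("mw", "rot_bonds", "tpsa")

#: Residues excluded from propensity fits for their outlying backbone behaviour.
PROPENSITY_EXCLUDED = ("G", "P")


@dataclass(frozen=True)
class LinearModel:
    """An ordinary-least-squares map from descriptor features to a scale."""

    features: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    fit_r: float
    trained_on: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.features):
            raise ValueError("one coefficient per feature required")
        if not -1.0 <= self.fit_r <= 1.0 + 1e-12:
            raise ValueError(f"fit_r outside [-1, 1]: {self.fit_r}")

    def predict(self, row: dict[str, float]) -> float:
        """Apply the model to one residue's feature dict."""
        return self.intercept + sum(
            c * float(row[f]) for f, c in zip(self.features, self.coefficients)
        )

    def as_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "fit_r": self.fit_r,
            "trained_on": list(self.trained_on),
        }


def _design_matrix(rows, features) -> np.ndarray:
    return np.array([[float(r[f]) for f in features] for r in rows], dtype=float)


def fit_linear_map(
    rows: list[dict[str, float]],
    y,
    features: tuple[str, ...],
    trained_on: tuple[str, ...] = (),
) -> LinearModel:
    """Ordinary least squares of ``y`` on the selected feature columns.

    Requires at least ``len(features) + 1`` rows and a full-rank design;
    a rank-deficient design raises :class:`CollinearityError` naming the
    offending feature columns.
    """
    y = np.asarray(y, dtype=float)
    X = _design_matrix(rows, features)
    if X.shape[0] < len(features) + 1:
        raise ValueError(
            f"need at least {len(features) + 1} rows to fit {len(features)} "
            f"features, got {X.shape[0]}"
        )
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in design or target")
    A = np.column_stack([X, np.ones(X.shape[0])])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        bad = [
            f
            for j, f in enumerate(features)
            if np.linalg.matrix_rank(np.delete(A, j, axis=1)) == rank
        ]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear features: {bad or list(features)}",
            features=bad or list(features),
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ beta
    if np.std(pred) == 0.0 or np.std(y) == 0.0:
        fit_r = 0.0
    else:
        fit_r = float(np.corrcoef(pred, y)[0, 1])
    return LinearModel(
        features=tuple(features),
        coefficients=tuple(float(b) for b in beta[:-1]),
        intercept=float(beta[-1]),
        fit_r=fit_r,
        trained_on=tuple(trained_on),
    )


def calibrate_hydrophilicity(
    descriptor_rows: dict[str, dict[str, float]],
    hydrophilicity: dict[str, float],
    extra_features: tuple[str, ...] = (),
) -> LinearModel:
    """Fit scale hydrophilicity on logP over all 20 canonical residues.

    ``descriptor_rows`` maps canonical code -> feature dict (must include
    ``logp``).  A second logP-variant column can be passed via
    ``extra_features`` when the caller supplies one.
    """
    codes = tuple(sorted(hydrophilicity))
    rows = [descriptor_rows[c] for c in codes]
    y = [hydrophilicity[c] for c in codes]
    return fit_linear_map(rows, y, ("logp",) + tuple(extra_features), trained_on=codes)


def select_propensity_features(
    descriptor_rows: dict[str, dict[str, float]],
    targets: dict[str, float],
    candidates: tuple[str, ...] = PROPENSITY_CANDIDATES,
) -> tuple[tuple[str, ...], LinearModel]:
    """Exhaustive best-subset search for one propensity model.

    Evaluates every nonempty subset of ``candidates`` (2^k - 1 fits) and
    returns the winner.  Ranking: highest fit correlation rounded to two
    decimals, then fewest features, then lexicographic feature order — the
    parsimony tie-break prefers models with as few parameters as possible.
    Training rows are whatever codes ``targets`` contains (callers exclude
    Gly and Pro).
    """
    codes = tuple(sorted(targets))
    rows = [descriptor_rows[c] for c in codes]
    y = [targets[c] for c in codes]
    results: list[tuple[float, int, tuple[str, ...], LinearModel]] = []
    for k in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            try:
                model = fit_linear_map(rows, y, subset, trained_on=codes)
            except CollinearityError as exc:
                warnings.warn(f"subset {subset} skipped: {exc}")
                continue
            results.append((round(model.fit_r, 2), len(subset), subset, model))
    if not results:
        raise CollinearityError("no feature subset produced a valid fit")
    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    _, _, subset, model = results[0]
    return subset, model


@dataclass
class CalibratorSet:
    """The three fitted models used when registering a new residue."""

    hydrophilicity: LinearModel | None = None
    alpha: LinearModel | None = None
    beta: LinearModel | None = None

    @property
    def fitted(self) -> bool:
        return None not in (self.hydrophilicity, self.alpha, self.beta)

    def require_fitted(self) -> None:
        if not self.fitted:
            raise UnfittedCalibratorError(
                "calibrator set has unfitted models; fit them on the canonical "
                "scale table first"
            )

    def report(self) -> dict:
        """JSON-serializable dump of each model's parameters."""
        self.require_fitted()
        return {
            "hydrophilicity": self.hydrophilicity.as_dict(),
            "alpha": self.alpha.as_dict(),
            "beta": self.beta.as_dict(),
        }


def fit_default_calibrators(
    descriptor_rows: dict[str, dict[str, float]],
    scales,
    alpha_features: tuple[str, ...] = DEFAULT_ALPHA_FEATURES,
    beta_features: tuple[str, ...] = DEFAULT_BETA_FEATURES,
) -> CalibratorSet:
    """Fit the shipped default calibrators against a canonical scale table.

    ``scales`` is a :class:`~pepsol.registry.ScaleTable`.  The propensity
    models use the pinned feature subsets (no search) and are trained on the
    18 canonical residues other than glycine and proline.
    """
    hyd = calibrate_hydrophilicity(descriptor_rows, scales.hydrophilicity)
    prop_codes = tuple(
        sorted(c for c in scales.hydrophilicity if c not in PROPENSITY_EXCLUDED)
    )
    rows = [descriptor_rows[c] for c in prop_codes]
    alpha = fit_linear_map(
        rows,
        [scales.alpha_prop[c] for c in prop_codes],
        alpha_features,
        trained_on=prop_codes,
    )
    beta = fit_linear_map(
        rows,
        [scales.beta_prop[c] for c in prop_codes],
        beta_features,
        trained_on=prop_codes,
    )
    return CalibratorSet(hydrophilicity=hyd, alpha=alpha, beta=beta)


def pearson_r(x, y) -> float:
    """Plain Pearson correlation (thin wrapper kept for report symmetry)."""
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float))[0])
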