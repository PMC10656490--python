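"""Agreement between predicted scores and experimental solubility data.

Relative-solubility assays report a precipitant midpoint (PEG or ammonium
sulfate concentration at half solubility) or a remaining supernatant
concentration; some outcomes are censored — fully soluble peptides never
precipitate ("S") and insoluble ones precipitate without precipitant.
Censored records carry a bound, not a value, so correlation supports two
policies: ``drop`` (exclude them, the default) and ``clamp`` (assign the
extreme observed value of the matching side).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from statistics import fmean

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, MeasurementParseError

CENSOR_KINDS = ("none", "fully_soluble", "insoluble")


@dataclass(frozen=True)
class Measurement:
    """One experimental record: a value or a censoring flag, per replicate."""

    variant_id: str
    value: float | None
    censor: str = "none"
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.censor not in CENSOR_KINDS:
            raise ValueError(f"invalid censor kind {self.censor!r}")
        if self.censor == "none":
            if self.value is None or self.value < 0:
                raise ValueError(
                    f"uncensored measurement needs a non-negative value, "
                    f"got {self.value!r}"
                )


def load_measurements(path) -> list[Measurement]:
    """Read a measurements CSV with header variant_id,value,censor,replicate.

    A value cell of ``S`` is shorthand for a fully-soluble censored outcome;
    an empty value is allowed only on censored rows.  Malformed rows raise
    :class:`MeasurementParseError` with their row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"variant_id", "value", "censor", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise MeasurementParseError(f"missing CSV columns: {sorted(missing)}")
    out: list[Measurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        censor = row.censor.strip() or "none"
        raw = row.value.strip()
        value: float | None
        if raw.upper() == "S":
            censor, value = "fully_soluble", None
        elif raw == "":
            value = None
        else:
            try:
                value = float(raw)
            except ValueError:
                raise MeasurementParseError(
                    f"row {i}: cannot parse value {raw!r}"
                ) from None
        try:
            out.append(
                Measurement(
                    variant_id=str(row.variant_id).strip(),
                    value=value,
                    censor=censor,
                    replicate=row.replicate.strip(),
                )
            )
        except ValueError as exc:
            raise MeasurementParseError(f"row {i}: {exc}") from None
    return out


def load_fixture_measurements() -> list[Measurement]:
    """The shipped GLP-1 ultracentrifugation dataset (supernatant mg/mL,
    two independent runs of the ten variants)."""
    with resources.as_file(
        resources.files("pepsol.data").joinpath("glp1_ultracentrifugation.csv")
    ) as path:
        return load_measurements(path)


def average_replicates(measurements: list[Measurement]) -> list[Measurement]:
    """Arithmetic mean of uncensored replicate values per variant.

    A variant whose replicates are all censored the same way stays censored;
    mixed censored/uncensored replicates keep only the uncensored mean.
    """
    by_variant: dict[str, list[Measurement]] = {}
    for m in measurements:
        by_variant.setdefault(m.variant_id, []).append(m)
    out = []
    for vid, group in by_variant.items():
        values = [m.value for m in group if m.censor == "none"]
        if values:
            out.append(Measurement(vid, fmean(values), "none", "mean"))
        else:
            out.append(Measurement(vid, None, group[0].censor, "mean"))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    spearman_rho: float
    n_used: int
    policy: str
    replicate_handling: str

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "n_used": self.n_used,
            "policy": self.policy,
            "replicate_handling": self.replicate_handling,
        }


def correlate(
    pred: dict[str, float],
    measurements: list[Measurement],
    policy: str = "drop",
    replicates: str = "mean",
) -> CorrelationResult:
    """Pearson and Spearman correlation of predictions against measurements.

    ``policy="drop"`` uses only uncensored overlapping variants;
    ``policy="clamp"`` additionally assigns fully-soluble records the maximum
    observed uncensored value and insoluble records the minimum.  Spearman
    uses average ranks for ties.  Fewer than three usable pairs raises
    :class:`EvaluationError`.
    """
    if policy not in ("drop", "clamp"):
        raise EvaluationError(f"unknown censor policy {policy!r}")
    meas = (
        average_replicates(measurements) if replicates == "mean" else measurements
    )
    observed = [m.value for m in meas if m.censor == "none" and m.variant_id in pred]
    pairs: list[tuple[float, float]] = []
    for m in meas:
        if m.variant_id not in pred:
            continue
        if m.censor == "none":
            pairs.append((pred[m.variant_id], m.value))
        elif policy == "clamp" and observed:
            clamp = max(observed) if m.censor == "fully_soluble" else min(observed)
            pairs.append((pred[m.variant_id], clamp))
    if len(pairs) < 3:
        raise EvaluationError(
            f"need at least 3 usable prediction/measurement pairs, got {len(pairs)}"
        )
    x = np.array([p for p, _ in pairs])
    y = np.array([m for _, m in pairs])
    pearson = float(stats.pearsonr(x, y)[0])
    spearman = float(stats.spearmanr(x, y)[0])
    return CorrelationResult(
        pearson_r=pearson,
        spearman_rho=spearman,
        n_used=len(pairs),
        policy=policy,
        replicate_handling=replicates,
    )
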