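"""Meta-analytic pooling of 1-year tooth-loss probabilities.

The annual tooth-loss probability among non-smokers in maintenance therapy
is pooled from published cohorts.  Studies report proportions over varying
follow-up windows, so each is first rescaled to a 1-year probability under
a constant-hazard assumption, then pooled by inverse-variance weighting on
the logit scale (the standard scale for proportion meta-analysis), either
fixed-effect or DerSimonian-Laird random-effects.  Zero or full event counts
receive the conventional 0.5 continuity correction, which requires counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .params import multi_year_to_annual_prob

__all__ = [
    "ProportionStudy",
    "PooledProportion",
    "rescale_study_to_annual",
    "pool_one_year_probabilities",
    "read_studies_csv",
]


@dataclass(frozen=True)
class ProportionStudy:
    """One study's tooth-loss proportion, from counts or a bare proportion."""

    label: str
    followup_years: float = 1.0
    events: int | None = None
    sample_size: int | None = None
    proportion: float | None = None

    def __post_init__(self) -> None:
        if self.followup_years <= 0:
            raise ValueError(f"study {self.label!r}: followup_years must be > 0")
        has_counts = self.events is not None
        if has_counts:
            if self.sample_size is None or self.sample_size < 1:
                raise ValueError(f"study {self.label!r}: counts need a positive sample_size")
            if not 0 <= self.events <= self.sample_size:
                raise ValueError(f"study {self.label!r}: events must lie in [0, sample_size]")
        elif self.proportion is None:
            raise ValueError(f"study {self.label!r}: give events/sample_size or proportion")
        if self.proportion is not None and not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"study {self.label!r}: proportion outside [0, 1]")

    def as_proportion(self) -> float:
        if self.events is not None:
            return self.events / self.sample_size
        return self.proportion


@dataclass(frozen=True)
class PooledProportion:
    estimate: float
    ci_low: float
    ci_high: float
    weights: np.ndarray  # normalised, sums to 1
    heterogeneity_tau2: float
    model: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "weights": self.weights.tolist(),
            "heterogeneity_tau2": self.heterogeneity_tau2,
            "model": self.model,
        }


def rescale_study_to_annual(study: ProportionStudy) -> ProportionStudy:
    """Convert a study's proportion to the 1-year scale.

    Counts are first turned into a proportion (they no longer apply after
    rescaling, so the result is proportion-based with the original sample
    size retained for weighting).  Studies already at 1 year pass through.
    """
    p = study.as_proportion()
    if study.followup_years == 1.0 and study.proportion is not None:
        return study
    if p >= 1.0:
        raise ValueError(f"study {study.label!r}: proportion 1 cannot be rescaled")
    p_annual = multi_year_to_annual_prob(p, study.followup_years)
    return replace(
        study, proportion=p_annual, followup_years=1.0, events=None,
        sample_size=study.sample_size,
    )


def _logit_and_variance(study: ProportionStudy) -> tuple[float, float]:
    """Per-study logit and its variance 1/(np) + 1/(n(1-p)).

    Uses the 0.5 continuity correction on zero/full cells when counts are
    available; bare proportions at 0 or 1 are rejected.  Bare proportions
    without a sample size cannot be variance-weighted and are rejected here
    (callers may supply equal weights via sample_size instead).
    """
    p = study.as_proportion()
    n = study.sample_size
    if n is None:
        raise ValueError(
            f"study {study.label!r}: a sample size is required for inverse-variance weighting"
        )
    if p in (0.0, 1.0):
        if study.events is None:
            raise ValueError(
                f"study {study.label!r}: proportion {p} needs counts for continuity correction"
            )
        x = study.events + 0.5
        m = n + 1.0
        p = x / m
        n = m
    logit = math.log(p / (1.0 - p))
    var = 1.0 / (n * p) + 1.0 / (n * (1.0 - p))
    return logit, var


def pool_one_year_probabilities(
    studies,
    model: str = "fixed_effect",
    alpha: float = 0.05,
) -> PooledProportion:
    """Inverse-variance pooling of 1-year proportions on the logit scale.

    ``model`` is ``"fixed_effect"`` or ``"random_effects"`` (DerSimonian-
    Laird between-study variance).  The estimate and its (1-alpha) CI are
    back-transformed to the probability scale; weights are reported on the
    pooling scale, normalised to 1.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("at least one study is required")
    if model not in ("fixed_effect", "random_effects"):
        raise ValueError(f"model must be fixed_effect or random_effects, got {model!r}")
    off_scale = [s.label for s in studies if s.followup_years != 1.0]
    if off_scale:
        raise ValueError(
            f"studies not on the 1-year scale (call rescale_study_to_annual): {off_scale}"
        )

    y = np.empty(len(studies))
    v = np.empty(len(studies))
    for i, s in enumerate(studies):
        y[i], v[i] = _logit_and_variance(s)

    w_fe = 1.0 / v
    mu_fe = float(np.sum(w_fe * y) / np.sum(w_fe))
    tau2 = 0.0
    if model == "random_effects" and len(studies) > 1:
        q = float(np.sum(w_fe * (y - mu_fe) ** 2))
        c = float(np.sum(w_fe) - np.sum(w_fe**2) / np.sum(w_fe))
        tau2 = max(0.0, (q - (len(studies) - 1)) / c)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = math.sqrt(1.0 / float(np.sum(w)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)

    def expit(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-x))

    return PooledProportion(
        estimate=expit(mu),
        ci_low=expit(mu - z * se),
        ci_high=expit(mu + z * se),
        weights=w / w.sum(),
        heterogeneity_tau2=tau2,
        model=model,
    )


def read_studies_csv(path) -> list[ProportionStudy]:
    """Read studies from a CSV with columns label, events, sample_size,
    proportion, followup_years (events/sample_size XOR proportion)."""
    import pandas as pd

    df = pd.read_csv(path)
    studies = []
    for row in df.itertuples(index=False):
        events = getattr(row, "events", None)
        prop = getattr(row, "proportion", None)
        events = None if events is None or (isinstance(events, float) and math.isnan(events)) else int(events)
        prop = None if prop is None or (isinstance(prop, float) and math.isnan(prop)) else float(prop)
        if events is not None and prop is not None:
            raise ValueError(f"study {row.label!r}: give counts or a proportion, not both")
        size = getattr(row, "sample_size", None)
        size = None if size is None or (isinstance(size, float) and math.isnan(size)) else int(size)
        studies.append(
            ProportionStudy(
                label=str(row.label),
                events=events,
                sample_size=size,
                proportion=prop,
                followup_years=float(getattr(row, "followup_years", 1.0)),
            )
        )
    return studies
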