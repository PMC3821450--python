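"""Synthetic judge panels for calibrating the agreement threshold and the
exact-binomial flagging test (type-I error and power) without human data.

Judges are exchangeable and independent across judges, segments, and
categories — the statistical structure of an undifferentiated assembly of
judges, with no semantic model of the text.  An optional per-judge leniency
multiplier (off by default) scales every probability of a judge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import exact_binomial_pvalue
from .corpus import (
    AttributionProtocol,
    CategoryScheme,
    SegmentationProtocol,
    ValidationError,
)

__all__ = [
    "PanelSpec",
    "simulate_segmentation_panel",
    "simulate_attribution_panel",
    "power_curve",
]


@dataclass
class PanelSpec:
    """Generative parameters for one synthetic panel; ``seed`` fixes all draws."""

    n_judges: int
    seed: int
    boundary_probs: np.ndarray | None = None  # (B,) for segmentation panels
    boundaries: list[int] | None = None
    attach_probs: np.ndarray | None = None  # (S, K) for attribution panels
    recognition_probs: np.ndarray | None = None  # (S,)
    leniency: np.ndarray | None = None  # (J,) optional multiplier, default 1
    text_id: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_judges < 1:
            raise ValidationError("panel needs at least one judge")
        for name in ("boundary_probs", "attach_probs", "recognition_probs"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if ((v < 0) | (v > 1)).any():
                    raise ValidationError(f"{name} must lie in [0, 1]")
        if self.leniency is not None:
            self.leniency = np.asarray(self.leniency, dtype=float)
            if self.leniency.shape != (self.n_judges,) or (self.leniency < 0).any():
                raise ValidationError("leniency must be a non-negative (J,) vector")


def _judge_probs(spec: PanelSpec, probs: np.ndarray) -> np.ndarray:
    """Broadcast cell probabilities to per-judge probabilities, clipped to 1."""
    out = np.broadcast_to(probs, (spec.n_judges,) + probs.shape).copy()
    if spec.leniency is not None:
        lean = spec.leniency.reshape((spec.n_judges,) + (1,) * probs.ndim)
        out = np.minimum(out * lean, 1.0)
    return out


def simulate_segmentation_panel(spec: PanelSpec) -> SegmentationProtocol:
    """Independent Bernoulli marks: ``marks[j, b] ~ Bern(boundary_probs[b])``."""
    if spec.boundary_probs is None:
        raise ValidationError("segmentation simulation needs boundary_probs")
    rng = np.random.default_rng(spec.seed)
    probs = _judge_probs(spec, spec.boundary_probs)
    marks = (rng.random(probs.shape) < probs).astype(int)
    B = spec.boundary_probs.shape[0]
    return SegmentationProtocol(
        text_id=spec.text_id,
        judges=[f"judge{j+1}" for j in range(spec.n_judges)],
        boundaries=list(spec.boundaries) if spec.boundaries else list(range(1, B + 1)),
        marks=marks,
    )


def simulate_attribution_panel(spec: PanelSpec, scheme: CategoryScheme) -> AttributionProtocol:
    """Two-stage draw: judge j recognizes segment s with ``recognition_probs[s]``;
    conditional on recognition, attributes category k with ``attach_probs[s, k]``."""
    if spec.attach_probs is None or spec.recognition_probs is None:
        raise ValidationError("attribution simulation needs attach_probs and recognition_probs")
    S, K = spec.attach_probs.shape
    if K != len(scheme.codes):
        raise ValidationError("attach_probs width does not match the scheme")
    if spec.recognition_probs.shape != (S,):
        raise ValidationError("recognition_probs length does not match attach_probs")
    rng = np.random.default_rng(spec.seed)
    rec_p = _judge_probs(spec, spec.recognition_probs)  # (J, S)
    recognized = (rng.random(rec_p.shape) < rec_p).astype(int)
    att_p = np.broadcast_to(spec.attach_probs, (spec.n_judges, S, K))
    indicators = (rng.random(att_p.shape) < att_p).astype(int)
    indicators *= recognized[:, :, None]
    return AttributionProtocol(
        text_id=spec.text_id,
        scheme=scheme,
        n_judges=spec.n_judges,
        n=recognized.sum(axis=0),
        counts=indicators.sum(axis=0),
        judges=[f"judge{j+1}" for j in range(spec.n_judges)],
        indicators=indicators,
        recognized=recognized,
    )


def power_curve(
    n_judges: int,
    p0: float,
    alpha: float,
    true_p: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo high-flag rate of the one-sided exact test per true proportion.

    For each value of ``true_p``, draws ``reps`` binomial counts k ~ B(n, p)
    and reports the fraction with ``P(X >= k | p0) < alpha`` plus its binomial
    standard error.  At ``true_p == p0`` the rate is bounded by ``alpha``
    (the exact test is conservative); the curve is monotone in ``true_p`` up
    to Monte-Carlo noise.
    """
    if reps < 100:
        raise ValidationError("power estimation needs reps >= 100")
    true_p = np.asarray(true_p, dtype=float)
    rng = np.random.default_rng(seed)
    # precompute the rejection region once: high-flag iff k >= k_crit
    k_crit = next(
        (k for k in range(n_judges + 1) if exact_binomial_pvalue(k, n_judges, p0, "greater") < alpha),
        n_judges + 1,
    )
    rows = []
    for p in true_p:
        ks = rng.binomial(n_judges, p, size=reps)
        rate = float(np.mean(ks >= k_crit))
        se = float(np.sqrt(rate * (1 - rate) / reps))
        rows.append({"true_p": float(p), "high_flag_rate": rate, "mc_se": se})
    return pd.DataFrame(rows)
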