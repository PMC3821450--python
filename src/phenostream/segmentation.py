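"""Inter-observer boundary agreement and mean-threshold consensus segmentation.

The agreement index of a candidate boundary is the plain fraction of judges
who marked it.  The consensus rule keeps every boundary whose index exceeds a
threshold — by default the arithmetic mean of all candidate indices, the
rationale being that the panel mean sits above one half of the judges — and
the kept boundaries tile the text into consensus segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import (
    PhenomenologicalText,
    Segment,
    SegmentationProtocol,
    ValidationError,
)

__all__ = [
    "AgreementVector",
    "ConsensusResult",
    "boundary_agreement",
    "mean_agreement",
    "consensus_segments",
]


@dataclass
class AgreementVector:
    """Per-candidate-boundary agreement fractions for a judge panel."""

    boundaries: list[int]
    indices: np.ndarray  # (B,) floats in [0, 1], full precision
    n_judges: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=float)
        if self.indices.shape != (len(self.boundaries),):
            raise ValidationError("agreement vector misaligned with boundary list")
        if ((self.indices < 0) | (self.indices > 1)).any():
            raise ValidationError("agreement indices must lie in [0, 1]")

    def display(self, decimals: int = 3) -> np.ndarray:
        """Presentation rounding only (half-up, like the published indices);
        computation always uses full precision."""
        scale = 10.0**decimals
        return np.floor(self.indices * scale + 0.5) / scale


@dataclass
class ConsensusResult:
    threshold: float
    kept_boundaries: list[int]
    segments: list[Segment]


def boundary_agreement(protocol: SegmentationProtocol) -> AgreementVector:
    """Fraction of judges marking each candidate boundary (column mean)."""
    if protocol.n_judges == 0:
        raise ValidationError("agreement undefined for an empty judge panel")
    return AgreementVector(
        boundaries=list(protocol.boundaries),
        indices=protocol.marks.mean(axis=0),
        n_judges=protocol.n_judges,
    )


def mean_agreement(v: AgreementVector) -> float:
    """Arithmetic mean of the per-boundary indices (the panel-level agreement)."""
    if len(v.boundaries) == 0:
        raise ValidationError("mean agreement undefined for an empty boundary set")
    return float(np.mean(v.indices))


def consensus_segments(
    text: PhenomenologicalText,
    v: AgreementVector,
    threshold: float | str = "mean",
) -> ConsensusResult:
    """Partition ``text`` at boundaries whose agreement strictly exceeds ``threshold``.

    ``threshold="mean"`` uses the unrounded mean of ``v`` (rounding is
    presentation, not computation).  Candidate boundaries of the text absent
    from ``v`` count as index 0.  A kept boundary at the terminal gap
    (position ``n_tokens``) coincides with the end of the text and adds no
    segment, so ``len(segments) == len(internal kept) + 1``.
    """
    unknown = set(v.boundaries) - set(text.candidate_boundaries)
    if unknown:
        raise ValidationError(
            f"agreement vector references boundaries absent from text: {sorted(unknown)}"
        )
    thr = mean_agreement(v) if threshold == "mean" else float(threshold)
    index_of = dict(zip(v.boundaries, v.indices))
    kept = [b for b in text.candidate_boundaries if index_of.get(b, 0.0) > thr]

    n = text.n_tokens
    cuts = [0] + [b for b in kept if b < n] + [n]
    segments = [
        Segment(index=i, token_span=(a, b), text=text.span_text(a, b))
        for i, (a, b) in enumerate(zip(cuts, cuts[1:]), start=1)
    ]
    return ConsensusResult(threshold=thr, kept_boundaries=kept, segments=segments)
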