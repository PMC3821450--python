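"""Attribution proportions and exact-binomial high/low flagging.

For each consensus segment ``s`` and mental category ``k`` the proportion is
``counts[s, k] / n_s`` where ``n_s`` is the number of judges who recognized
the segment (not the full panel).  A cell is flagged *high* when, under a
null attribution probability ``p0``, the upper exact binomial tail
``P(X >= k)`` falls below ``alpha``, and *low* when the lower tail
``P(X <= k)`` does — two separate one-sided tests, matching a protocol that
reports significantly present and significantly absent categories.

The null ``p0`` is a modelling choice: 0.5 treats each judge's attribution as
a fair coin (default); ``1/K`` models a judge spreading one attribution over
K categories.  No multiple-testing correction is applied by default (each
cell is tested at its own ``alpha``); a Bonferroni option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import AttributionProtocol, CategoryScheme, ValidationError

__all__ = [
    "ProportionMatrix",
    "FlagMatrix",
    "proportion_matrix",
    "exact_binomial_pvalue",
    "flag_matrix",
    "composite_states",
    "empty_segments",
    "flag_diff",
]

HIGH = "high"
LOW = "low"
NONE = "none"


@dataclass
class ProportionMatrix:
    """S × K attribution proportions with per-segment denominators ``n``."""

    scheme: CategoryScheme
    segment_indices: list[int]
    values: np.ndarray  # (S, K), full precision
    n: np.ndarray  # (S,)

    def display(self, decimals: int = 2) -> np.ndarray:
        # half-up, matching published-table convention (0.125 -> 0.13)
        scale = 10.0**decimals
        return np.floor(self.values * scale + 0.5) / scale

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        vals = self.values if decimals is None else self.display(decimals)
        df = pd.DataFrame(
            vals,
            index=pd.Index(self.segment_indices, name="segment"),
            columns=self.scheme.codes,
        )
        df.insert(0, "n", self.n)
        return df


@dataclass
class FlagMatrix:
    """S × K entries in {high, low, none} with the test configuration attached.

    ``source`` distinguishes flags recomputed by the package ("computed")
    from flags transcribed from a published table ("printed"); ``p0`` is
    ``None`` for printed flags, whose null was not stated.
    """

    scheme: CategoryScheme
    segment_indices: list[int]
    flags: np.ndarray  # (S, K) of {"high", "low", "none"}
    alpha: float
    p0: float | None
    source: str = "computed"
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flags,
            index=pd.Index(self.segment_indices, name="segment"),
            columns=self.scheme.codes,
        )


def proportion_matrix(protocol: AttributionProtocol) -> ProportionMatrix:
    """Exact ``counts / n`` per retained segment; segments nobody recognized are
    excluded with a warning (their proportion is undefined)."""
    keep = protocol.n > 0
    dropped = [protocol.segment_indices[s] for s in np.nonzero(~keep)[0]]
    if dropped:
        warnings.warn(
            f"segments {dropped} recognized by no judge; excluded from proportions",
            stacklevel=2,
        )
    values = protocol.counts[keep] / protocol.n[keep, None]
    return ProportionMatrix(
        scheme=protocol.scheme,
        segment_indices=[i for i, k in zip(protocol.segment_indices, keep) if k],
        values=values,
        n=protocol.n[keep],
    )


def exact_binomial_pvalue(k: int, n: int, p0: float, side: str) -> float:
    """One-sided exact binomial tail probability.

    ``side="greater"`` gives ``P(X >= k)`` and ``side="less"`` gives
    ``P(X <= k)`` for ``X ~ Binomial(n, p0)``.
    """
    if not 0 < p0 < 1:
        raise ValidationError(f"null proportion p0 must lie in (0, 1), got {p0}")
    if not 0 <= k <= n or n < 1:
        raise ValidationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if side == "greater":
        return float(stats.binom.sf(k - 1, n, p0))
    if side == "less":
        return float(stats.binom.cdf(k, n, p0))
    raise ValueError(f"side must be 'greater' or 'less', got {side!r}")


def flag_matrix(
    protocol: AttributionProtocol,
    p0: float = 0.5,
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> FlagMatrix:
    """Flag each retained cell high/low by two one-sided exact binomial tests.

    With ``bonferroni=True`` the per-cell level is ``alpha / (S * K)``.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    props = proportion_matrix(protocol)
    keep = protocol.n > 0
    counts = protocol.counts[keep]
    n = protocol.n[keep]
    S, K = counts.shape
    level = alpha / (S * K) if bonferroni else alpha
    flags = np.full((S, K), NONE, dtype=object)
    for s in range(S):
        for k in range(K):
            if exact_binomial_pvalue(counts[s, k], n[s], p0, "greater") < level:
                flags[s, k] = HIGH
            elif exact_binomial_pvalue(counts[s, k], n[s], p0, "less") < level:
                flags[s, k] = LOW
    return FlagMatrix(
        scheme=protocol.scheme,
        segment_indices=props.segment_indices,
        flags=flags,
        alpha=alpha,
        p0=p0,
        source="computed",
        notes={"bonferroni": bonferroni},
    )


def composite_states(flags: FlagMatrix) -> list[int]:
    """Segments flagged high in two or more categories: composite mental states
    exhibiting the binding character of a single conscious occasion."""
    high_per_seg = (flags.flags == HIGH).sum(axis=1)
    return [i for i, h in zip(flags.segment_indices, high_per_seg) if h >= 2]


def empty_segments(flags: FlagMatrix) -> list[int]:
    """Segments with no significantly high category: text the panel could not
    agree expresses any mental content."""
    high_per_seg = (flags.flags == HIGH).sum(axis=1)
    return [i for i, h in zip(flags.segment_indices, high_per_seg) if h == 0]


def flag_diff(computed: FlagMatrix, printed: FlagMatrix) -> pd.DataFrame:
    """Cell-by-cell comparison of computed flags against a published table.

    Returns a long DataFrame of the disagreeing cells only.
    """
    if computed.scheme.codes != printed.scheme.codes:
        raise ValidationError("flag matrices use different schemes")
    common = [i for i in computed.segment_indices if i in printed.segment_indices]
    rows = []
    for seg in common:
        ci = computed.segment_indices.index(seg)
        pi = printed.segment_indices.index(seg)
        for k, code in enumerate(computed.scheme.codes):
            if computed.flags[ci, k] != printed.flags[pi, k]:
                rows.append(
                    {
                        "segment": seg,
                        "category": code,
                        "computed": computed.flags[ci, k],
                        "printed": printed.flags[pi, k],
                    }
                )
    return pd.DataFrame(rows, columns=["segment", "category", "computed", "printed"])
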