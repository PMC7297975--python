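"""Divide MCMC coefficient draws into posterior-mode-like feature subsets.

Heavy-tailed priors split groups of correlated features across posterior
modes: in any one draw, typically a single representative per group carries a
large coefficient while the rest sit near zero.  Each retained draw is
therefore summarized by the set of features whose coefficient magnitude
exceeds a fraction (default 0.1) of that draw's largest magnitude; unique
indicator columns then correspond to distinct modes, and their relative
counts estimate posterior subset frequencies.  A per-feature frequency filter
(default 5%) first removes features that only enter through MCMC jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IndicatorMatrix",
    "FeatureSubsetReport",
    "indicator_matrix",
    "filter_low_frequency",
    "enumerate_subsets",
    "rank_subsets",
]


@dataclass
class IndicatorMatrix:
    """Boolean p x R matrix: feature j active in draw i. Intercept excluded."""

    I: np.ndarray
    rel_threshold: float
    discarded: list[int] = field(default_factory=list)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-feature selection frequency f_j (row means)."""
        return self.I.mean(axis=1)


@dataclass
class FeatureSubsetReport:
    """Unique feature subsets with their posterior frequencies.

    ``subsets`` is ordered by descending frequency (ties: lexicographic
    feature order); all-zero indicator columns are dropped and their share
    reported as ``unassigned_mass``.
    """

    subsets: list[tuple[tuple[int, ...], float]]
    n_draws: int
    discarded: list[int] = field(default_factory=list)
    unassigned_mass: float = 0.0


def indicator_matrix(beta_draws: np.ndarray, rel_threshold: float = 0.1) -> IndicatorMatrix:
    """Threshold each draw at ``rel_threshold`` times its own max magnitude.

    ``beta_draws`` is R x p with the intercept already excluded.  A draw
    whose coefficients are all exactly zero yields an all-zero column.
    """
    B = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    if B.shape[0] < 1:
        raise ValueError("need at least one draw")
    absB = np.abs(B)
    draw_max = absB.max(axis=1, keepdims=True)
    I = (absB > rel_threshold * draw_max) & (draw_max > 0)
    return IndicatorMatrix(I=I.T.copy(), rel_threshold=rel_threshold)


def filter_low_frequency(ind: IndicatorMatrix, min_freq: float = 0.05) -> IndicatorMatrix:
    """Zero out rows of features selected in fewer than ``min_freq`` of draws."""
    if not (0.0 <= min_freq <= 1.0):
        raise ValueError("min_freq must be in [0, 1]")
    freq = ind.frequencies
    drop = np.nonzero(freq < min_freq)[0]
    I = ind.I.copy()
    I[drop, :] = False
    discarded = sorted(set(ind.discarded) | set(int(j) for j in drop))
    return IndicatorMatrix(I=I, rel_threshold=ind.rel_threshold, discarded=discarded)


def enumerate_subsets(ind: IndicatorMatrix) -> FeatureSubsetReport:
    """Group identical indicator columns into subsets with frequencies."""
    I = ind.I
    R = I.shape[1]
    counts: dict[tuple[int, ...], int] = {}
    n_empty = 0
    for i in range(R):
        members = tuple(int(j) for j in np.nonzero(I[:, i])[0])
        if not members:
            n_empty += 1
            continue
        counts[members] = counts.get(members, 0) + 1
    subsets = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return FeatureSubsetReport(
        subsets=[(members, c / R) for members, c in subsets],
        n_draws=R,
        discarded=list(ind.discarded),
        unassigned_mass=n_empty / R,
    )


def rank_subsets(report: FeatureSubsetReport, metrics: dict):
    """Pick the *top* (highest-frequency) and *optimal* (lowest-AMLP) subsets.

    ``metrics`` maps each subset (tuple of feature indices) to an object with
    an ``amlp`` attribute (or a plain AMLP float).  Top ties prefer the
    smaller subset, then lexicographic order; optimal ties prefer the higher
    frequency.
    """
    if not report.subsets:
        raise ValueError("empty subset report")

    def amlp_of(members):
        m = metrics[members]
        return m.amlp if hasattr(m, "amlp") else float(m)

    top = min(report.subsets, key=lambda sf: (-sf[1], len(sf[0]), sf[0]))[0]
    optimal = min(report.subsets, key=lambda sf: (amlp_of(sf[0]), -sf[1], sf[0]))[0]
    return top, optimal
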