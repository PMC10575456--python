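"""Comprehensive growth indices from ground indicators.

Three ground-measured indicators — above-ground biomass (AGB, g per
quadrat), SPAD chlorophyll reading (unitless) and leaf water content (LWC,
fraction) — are combined into two scalar growth indices per quadrat:

* ``CGI_ewm`` — entropy-weight method (EWM).  Indicators are min–max
  normalized to [0, 1]; each indicator's weight derives from the information
  entropy of its normalized distribution across quadrats (low entropy =
  discriminative = high weight); the index is the weighted sum, in [0, 1],
  higher = better growth.

* ``CGI_fce`` — fuzzy comprehensive evaluation (FCE).  Each normalized
  indicator is mapped through trapezoidal membership functions onto five
  ordered growth levels (poor ... good); the 3 x 5 membership matrix is
  aggregated with the entropy weights and defuzzified with the score vector
  F = [100, 75, 50, 25, 0], giving a score in [0, 100], lower = better
  growth (so the two indices move in opposite directions by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Indicator order used everywhere: u1 = AGB, u2 = SPAD, u3 = LWC.
INDICATORS: tuple[str, ...] = ("AGB", "SPAD", "LWC")

#: Defuzzification scores of the five growth levels, best growth last.
SCORE_VECTOR: tuple[float, ...] = (100.0, 75.0, 50.0, 25.0, 0.0)


def normalize(raw: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise min–max normalization onto [0, 1], benefit-oriented.

    All three indicators are "more is better" growth signals, so larger raw
    values map to larger normalized values.

    Raises
    ------
    ValueError
        If a column is constant — its range is undefined and its entropy
        weight would be degenerate; the caller must drop or perturb it.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 2:
        raise ValueError("indicator matrix must be 2-D (quadrats x indicators)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 quadrats to normalize")
    if not np.all(np.isfinite(x)):
        raise ValueError("indicator matrix contains missing or non-finite values")
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        cols = np.nonzero(span == 0)[0].tolist()
        raise ValueError(
            f"constant indicator column(s) {cols}: min-max range is zero and the "
            "entropy weight would be degenerate; remove the column"
        )
    return (x - lo) / span


@dataclass
class EntropyWeights:
    """Entropy-weight decomposition of a normalized indicator matrix."""

    entropy: np.ndarray  # e_i per indicator, in [0, 1]
    weights: np.ndarray  # w_i, nonnegative, summing to 1
    k: float             # normalization constant 1 / ln(m)


def entropy_weights(norm: np.ndarray) -> EntropyWeights:
    """Information-entropy weights of normalized indicators.

    For m quadrats, each indicator column is converted to proportions
    ``p_ij = x'_ij / sum_j x'_ij``; its entropy is
    ``e_i = -(1/ln m) * sum_j p_ij ln p_ij`` (with ``0 ln 0 = 0``), and the
    weights are ``w_i = (1 - e_i) / sum_i (1 - e_i)``.  A uniform column has
    entropy 1 and carries no weight.
    """
    x = np.asarray(norm, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D normalized matrix with at least 2 rows")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("matrix must be normalized to [0, 1]")
    m = x.shape[0]
    col_sums = x.sum(axis=0)
    if np.any(col_sums == 0):
        cols = np.nonzero(col_sums == 0)[0].tolist()
        raise ValueError(f"indicator column(s) {cols} sum to zero")
    p = x / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    k = 1.0 / np.log(m)
    e = -k * plogp.sum(axis=0)
    e = np.clip(e, 0.0, 1.0)  # guard roundoff at the boundary
    d = 1.0 - e
    total = d.sum()
    if total == 0:
        raise ValueError("all indicators have entropy 1: no information to weight")
    return EntropyWeights(entropy=e, weights=d / total, k=k)


def cgi_ewm(norm_rows: np.ndarray, weights: np.ndarray) -> np.ndarray | float:
    """Entropy-weighted growth index: the weighted sum of normalized indicators.

    Accepts a single indicator triple or an (m, n) matrix; returns a scalar
    or an array in [0, 1] accordingly.
    """
    x = np.asarray(norm_rows, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(
            f"row length {x.shape[-1]} does not match weight length {w.shape[0]}"
        )
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("normalized indicators must lie in [0, 1]")
    out = x @ w
    return float(out) if out.ndim == 0 else out


@dataclass
class FuzzySystem:
    """Five ordered growth levels with trapezoidal membership functions.

    The unit interval is tiled by five trapezoids forming a partition of
    unity.  Adjacent levels meet at the boundary centers 0.2/0.4/0.6/0.8
    through complementary linear ramps of width 0.1 (center gap), and the
    head and tail plateaus extend to 0.15 and 0.85 (head/tail gap 0.15):

    * level 1 (poor):   plateau [0, 0.15], ramp down on [0.15, 0.25]
    * level 2:          ramp up [0.15, 0.25], plateau [0.25, 0.35], ramp down [0.35, 0.45]
    * level 3 (medium): shifted by 0.2
    * level 4:          shifted by 0.4
    * level 5 (good):   ramp up [0.75, 0.85], plateau [0.85, 1]

    ``scores`` maps levels to the defuzzification values [100, 75, 50, 25, 0]
    so a quadrat fully in the best level scores 0 and one fully in the worst
    scores 100: the fuzzy index is an inverse growth scale.
    """

    boundary_centers: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    transition_width: float = 0.1
    head_tail_plateau_edge: float = 0.15
    scores: tuple[float, ...] = SCORE_VECTOR

    @property
    def n_levels(self) -> int:
        return len(self.boundary_centers) + 1

    def _knots(self) -> list[tuple[float, float, float, float]]:
        """(ramp-up start, plateau start, plateau end, ramp-down end) per level."""
        half = self.transition_width / 2.0
        edges = [
            (c - half, c + half) for c in self.boundary_centers
        ]  # ramp intervals between consecutive levels
        knots = []
        for lvl in range(self.n_levels):
            up = (-np.inf, 0.0) if lvl == 0 else edges[lvl - 1]
            down = (1.0, np.inf) if lvl == self.n_levels - 1 else edges[lvl]
            knots.append((up[0], up[1], down[0], down[1]))
        return knots

    def membership(self, x: float | np.ndarray) -> np.ndarray:
        """Membership degrees of ``x`` in the five levels.

        For scalar ``x`` returns shape (5,); for an array of shape S returns
        S + (5,).  Degrees are in [0, 1] and sum to 1 for any x in [0, 1].
        """
        scalar = np.asarray(x).ndim == 0
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(xv < 0) or np.any(xv > 1):
            raise ValueError("membership is defined on [0, 1]")
        out = np.zeros(xv.shape + (self.n_levels,))
        for lvl, (a, b, c, d) in enumerate(self._knots()):
            mu = np.zeros_like(xv)
            if np.isfinite(a):
                rising = (xv > a) & (xv < b)
                mu[rising] = (xv[rising] - a) / (b - a)
            plateau = (xv >= b) & (xv <= c)
            mu[plateau] = 1.0
            if np.isfinite(d):
                falling = (xv > c) & (xv < d)
                mu[falling] = (d - xv[falling]) / (d - c)
            out[..., lvl] = mu
        return out[0] if scalar else out


def build_fuzzy_system() -> FuzzySystem:
    """The default five-level trapezoidal system used for winter wheat."""
    return FuzzySystem()


def fuzzy_matrix(norm_row: np.ndarray, system: FuzzySystem | None = None) -> np.ndarray:
    """Membership matrix R of one quadrat: row n holds the 5-level memberships
    of normalized indicator n.  Each row sums to 1."""
    system = system or build_fuzzy_system()
    row = np.asarray(norm_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("norm_row must be a 1-D indicator triple")
    return system.membership(row)


def fce_score(
    r_matrix: np.ndarray,
    weights: np.ndarray,
    scores: np.ndarray | tuple[float, ...] = SCORE_VECTOR,
) -> float:
    """Defuzzified evaluation value S = (W . R) . F^T, in [0, 100].

    ``W`` are the entropy weights of the indicators (rows of R), ``F`` the
    level score vector.  Lower S means better growth.
    """
    r = np.asarray(r_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    f = np.asarray(scores, dtype=float)
    if r.ndim != 2 or r.shape[0] != w.shape[0] or r.shape[1] != f.shape[0]:
        raise ValueError(
            f"shape mismatch: R {r.shape}, weights {w.shape}, scores {f.shape}"
        )
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    if np.any(np.abs(r.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("each row of R must sum to 1")
    b = w @ r
    return float(b @ f)


def compute_cgis(
    ground: pd.DataFrame, system: FuzzySystem | None = None
) -> tuple[pd.DataFrame, EntropyWeights]:
    """Both growth indices for a ground-measurement table.

    Parameters
    ----------
    ground : DataFrame
        Must contain columns ``quadrat_id``, ``AGB``, ``SPAD``, ``LWC``.

    Returns
    -------
    (DataFrame, EntropyWeights)
        Table with columns ``quadrat_id``, ``CGI_ewm``, ``CGI_fce`` plus the
        fitted entropy weights (order AGB, SPAD, LWC).
    """
    system = system or build_fuzzy_system()
    missing = [c for c in ("quadrat_id", *INDICATORS) if c not in ground.columns]
    if missing:
        raise ValueError(f"ground table is missing columns {missing}")
    norm = normalize(ground[list(INDICATORS)].to_numpy(dtype=float))
    ew = entropy_weights(norm)
    ewm = cgi_ewm(norm, ew.weights)
    fce = np.array(
        [fce_score(fuzzy_matrix(row, system), ew.weights, system.scores) for row in norm]
    )
    out = pd.DataFrame(
        {
            "quadrat_id": ground["quadrat_id"].to_numpy(),
            "CGI_ewm": ewm,
            "CGI_fce": fce,
        }
    )
    return out, ew
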