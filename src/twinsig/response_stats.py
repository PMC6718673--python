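"""Two-level random-effects analysis of twin-pair differences in calcium responses.

Level one pools all cells of one subject in one condition (stimulus x
treatment): after MAD-based outlier removal it reports the mean calibrated
response and the variance of that mean (unbiased sample variance / n). For each
discordant pair the contrast is ``y = mean(ST) - mean(HT)`` with variance
``v = var_of_mean(ST) + var_of_mean(HT)``.

Level two pools the per-pair contrasts with an inverse-variance-weighted
random-effects model, estimating the between-pair variance tau^2 by the
DerSimonian-Laird moment estimator, and reports the pooled twin difference, its
standard error, Z and a two-sided normal p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientCellsError, PairingError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierConfig:
    """MAD outlier rule: drop x with |x - median| > k * consistency * MAD.

    ``consistency = 1.4826`` rescales the median absolute deviation to a
    Gaussian standard deviation; ``k = 3`` is the usual "three sigma" cut.
    """

    k: float = 3.0
    consistency: float = 1.4826

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError("outlier multiplier k must be > 0")
        if self.consistency <= 0:
            raise ConfigError("consistency factor must be > 0")


@dataclass(frozen=True)
class SubjectSummary:
    """Sufficient statistics for one subject x treatment x stimulus stratum."""

    subject_id: str
    pair_id: str
    role: str  # "ST" or "HT"
    treatment: str
    agent: str
    mean: float
    var_of_mean: float
    n_cells: int


@dataclass(frozen=True)
class PairDifference:
    """One pair's ST - HT contrast with its first-level variance."""

    pair_id: str
    y: float
    v: float


@dataclass(frozen=True)
class RandomEffectsResult:
    """Pooled inverse-variance-weighted estimate with DerSimonian-Laird tau^2."""

    pooled: float
    se: float
    tau2: float
    Q: float
    z: float
    p: float
    k: int


@dataclass(frozen=True)
class TwinContrastResult:
    """Both levels of the hierarchical analysis for one stimulus x treatment."""

    agent: str
    treatment: str
    pairs: tuple[PairDifference, ...]
    pooled: RandomEffectsResult
    n_cells_used: int
    n_outliers_removed: int


def remove_outliers(values: Sequence[float], cfg: OutlierConfig | None = None) -> np.ndarray:
    """Keep values within ``k * consistency * MAD`` of the median.

    With MAD = 0 (at least half the values identical) the rule is degenerate
    and every value is kept.
    """
    cfg = cfg or OutlierConfig()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty list of values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x.copy()
    keep = np.abs(x - med) <= cfg.k * cfg.consistency * mad
    return x[keep]


def summarize_subject(
    values: Sequence[float],
    subject_id: str = "",
    pair_id: str = "",
    role: str = "",
    treatment: str = "",
    agent: str = "",
) -> SubjectSummary:
    """First-level sufficient statistics: mean and variance of the mean (s^2/n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientCellsError(
            f"subject {subject_id or '?'}: need >= 2 cells, got {x.size}"
        )
    var_of_mean = float(np.var(x, ddof=1)) / x.size
    if var_of_mean == 0:
        logger.warning("subject %s: zero variance of the mean (all %d cells identical)",
                       subject_id or "?", x.size)
    return SubjectSummary(subject_id=subject_id, pair_id=pair_id, role=role,
                          treatment=treatment, agent=agent,
                          mean=float(np.mean(x)), var_of_mean=var_of_mean,
                          n_cells=int(x.size))


def pair_difference(st: SubjectSummary, ht: SubjectSummary) -> PairDifference:
    """ST - HT contrast; variance is the sum of the first-level variances."""
    if (st.pair_id, st.agent, st.treatment) != (ht.pair_id, ht.agent, ht.treatment):
        raise PairingError(
            f"mismatched grouping keys: {st.pair_id}/{st.agent}/{st.treatment} vs "
            f"{ht.pair_id}/{ht.agent}/{ht.treatment}"
        )
    return PairDifference(pair_id=st.pair_id, y=st.mean - ht.mean,
                          v=st.var_of_mean + ht.var_of_mean)


def dersimonian_laird(pairs: Sequence[PairDifference]) -> RandomEffectsResult:
    """Inverse-variance-weighted random-effects pooling with DL tau^2.

    With fixed-effect weights ``w_i = 1/v_i`` and weighted mean ``ybar``, the
    heterogeneity statistic is ``Q = sum w_i (y_i - ybar)^2`` and

        tau^2 = max(0, (Q - (k - 1)) / (sum w_i - sum w_i^2 / sum w_i)).

    Random-effects weights ``w*_i = 1/(v_i + tau^2)`` give the pooled estimate,
    ``se = 1/sqrt(sum w*_i)``, ``z = pooled/se`` and a two-sided normal p.
    For a single pair tau^2 = 0 and the result reduces to that pair's y, sqrt(v).
    """
    k = len(pairs)
    if k == 0:
        raise ValueError("dersimonian_laird needs at least one pair")
    y = np.array([p.y for p in pairs], dtype=float)
    v = np.array([p.v for p in pairs], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all first-level variances must be > 0")
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RandomEffectsResult(pooled=pooled, se=se, tau2=tau2, Q=Q, z=z,
                               p=min(max(p, 0.0), 1.0) or np.nextafter(0, 1), k=k)


def twin_contrast_test(
    responses,
    agent: str,
    treatment: str,
    value_col: str = "final",
    outlier_cfg: OutlierConfig | None = None,
    variance_floor: float = 1e-12,
    neurons_only: bool = True,
) -> TwinContrastResult:
    """Full two-level twin-contrast test on a tidy response table.

    ``responses`` is a DataFrame with columns ``pair_id, subject_id, role,
    treatment, agent`` plus ``value_col`` (and ``is_neuron`` if
    ``neurons_only``). Cells are filtered to the requested stimulus x
    treatment stratum; outliers are removed within each subject; subjects are
    summarized; complete ST/HT pairs are contrasted and pooled. Pairs missing
    one twin are dropped with a logged warning. Subjects with zero variance of
    the mean get their weight capped via ``variance_floor``.
    """
    import pandas as pd

    df = responses
    mask = (df["agent"] == agent) & (df["treatment"] == treatment)
    if neurons_only and "is_neuron" in df.columns:
        mask &= df["is_neuron"].astype(bool)
    sub = df.loc[mask].dropna(subset=[value_col])
    if sub.empty:
        raise ValueError(f"no responses for agent={agent!r}, treatment={treatment!r}")

    summaries: dict[tuple[str, str], SubjectSummary] = {}
    n_used = 0
    n_removed = 0
    for (pair_id, subject_id, role), grp in sub.groupby(
        ["pair_id", "subject_id", "role"], sort=True
    ):
        values = grp[value_col].to_numpy(dtype=float)
        kept = remove_outliers(values, outlier_cfg)
        removed = len(values) - len(kept)
        if removed:
            logger.info("outlier filter: subject %s %s/%s removed %d of %d cells",
                        subject_id, agent, treatment, removed, len(values))
        n_removed += removed
        n_used += len(kept)
        try:
            summaries[(str(pair_id), str(role))] = summarize_subject(
                kept, subject_id=str(subject_id), pair_id=str(pair_id),
                role=str(role), treatment=treatment, agent=agent,
            )
        except InsufficientCellsError as exc:
            logger.warning("dropping subject %s: %s", subject_id, exc)

    pairs: list[PairDifference] = []
    for pid in sorted({p for p, _ in summaries}):
        st = summaries.get((pid, "ST"))
        ht = summaries.get((pid, "HT"))
        if st is None or ht is None:
            logger.warning("pair %s incomplete for %s/%s; dropped", pid, agent, treatment)
            continue
        d = pair_difference(st, ht)
        if d.v < variance_floor:
            logger.warning("pair %s: variance %.3g below floor %.3g; capped",
                           pid, d.v, variance_floor)
            d = PairDifference(pair_id=d.pair_id, y=d.y, v=variance_floor)
        pairs.append(d)
    if not pairs:
        raise ValueError(f"no complete twin pairs for agent={agent!r}, treatment={treatment!r}")
    pooled = dersimonian_laird(pairs)
    return TwinContrastResult(agent=agent, treatment=treatment, pairs=tuple(pairs),
                              pooled=pooled, n_cells_used=n_used,
                              n_outliers_removed=n_removed)
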