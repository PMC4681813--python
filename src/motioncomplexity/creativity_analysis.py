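"""Correlation of complexity scores with creativity rankings.

The jury protocol produces, per trial, an average creativity rank for each
subject's pattern (rank m = most creative among the m compared patterns).
This module correlates those ranks with any per-pattern complexity measure:

* trial-wise: one Spearman correlation pooling all (subject, trial) pairs;
* subject-wise: one correlation per subject across their trials, with
  significance bands (p < 0.001 / 0.01 / 0.05 / ns);
* rank-rank: within each trial both the measure and the jury average are
  converted to full ranks 1..m and accumulated into an m x m coincidence
  histogram.

It also scores divergent-thinking response lists (fluency, originality,
percentage, mean originality).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedCorrelationError",
    "spearman",
    "trialwise_correlation",
    "subjectwise_correlation",
    "rank_rank_analysis",
    "divergent_scores",
    "significance_band",
    "MEASURES",
    "RankRankResult",
]

MEASURES = ("gp", "pmp", "lzc", "emc", "var")


class UndefinedCorrelationError(ValueError):
    """Spearman correlation is undefined (constant input vector)."""


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    permutations: int | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    The p-value uses the standard t approximation with n - 2 degrees of
    freedom; pass ``permutations`` for a seeded permutation p-value
    instead (preferable at small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if permutations is not None:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(ry)
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (permutations + 1)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def significance_band(p: float) -> str:
    """Categorical significance band used in per-subject reports."""
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def _merge(records: pd.DataFrame, ranks: pd.DataFrame, measure: str) -> pd.DataFrame:
    if measure not in records.columns:
        raise ValueError(f"unknown measure {measure!r}")
    rec_keys = set(map(tuple, records[["subject", "trial"]].itertuples(index=False)))
    rank_keys = set(map(tuple, ranks[["subject", "trial"]].itertuples(index=False)))
    if rec_keys != rank_keys:
        missing = sorted(rec_keys ^ rank_keys)[:10]
        raise ValueError(f"records and ranks cover different (subject, trial) keys: {missing}")
    return records.merge(ranks, on=["subject", "trial"], validate="one_to_one")


def trialwise_correlation(
    records: pd.DataFrame, ranks: pd.DataFrame, measure: str
) -> tuple[float, float]:
    """Spearman correlation pooling all (subject, trial) pairs."""
    merged = _merge(records, ranks, measure)
    return spearman(merged["average_rank"], merged[measure])


def subjectwise_correlation(
    records: pd.DataFrame, ranks: pd.DataFrame, measure: str
) -> pd.DataFrame:
    """Per-subject Spearman correlations with significance bands.

    Subjects with a constant measure are flagged ``undefined`` (rho, p =
    NaN) without affecting the others.
    """
    merged = _merge(records, ranks, measure)
    rows = []
    for subject, group in merged.groupby("subject", sort=True):
        if len(group) < 3:
            raise ValueError(f"subject {subject} has fewer than 3 trials")
        try:
            rho, p = spearman(group["average_rank"], group[measure])
            band = significance_band(p)
        except UndefinedCorrelationError:
            rho, p, band = np.nan, np.nan, "undefined"
        rows.append((subject, rho, p, band))
    out = pd.DataFrame(rows, columns=["subject", "rho", "p", "band"])
    out.attrs["n_significant"] = int((out["p"] < 0.05).sum())
    return out


@dataclass(frozen=True)
class RankRankResult:
    """m x m rank-coincidence histogram plus per-subject rank correlations."""

    histogram: np.ndarray      # [complexity_rank - 1, jury_rank - 1] counts
    per_subject: pd.DataFrame  # subject, rho, p, band


def rank_rank_analysis(
    records: pd.DataFrame, ranks: pd.DataFrame, measure: str
) -> RankRankResult:
    """Within-trial rank pairs between a measure and the jury average.

    Every trial must compare the same m subjects.  Both the measure and
    the jury average are converted to full ranks 1..m inside each trial
    (ties broken by subject order) for the histogram; per-subject Spearman
    correlations use midranks.
    """
    merged = _merge(records, ranks, measure)
    subjects_per_trial = merged.groupby("trial")["subject"].apply(frozenset)
    if subjects_per_trial.nunique() != 1:
        raise ValueError("every trial must compare the same set of subjects")
    m = len(subjects_per_trial.iloc[0])
    hist = np.zeros((m, m), dtype=int)
    pair_rows = []
    for trial, group in merged.groupby("trial", sort=True):
        meas_full = stats.rankdata(group[measure], method="ordinal")
        jury_full = stats.rankdata(group["average_rank"], method="ordinal")
        meas_mid = stats.rankdata(group[measure])
        jury_mid = stats.rankdata(group["average_rank"])
        for subj, mf, jf, mm, jm in zip(
            group["subject"], meas_full, jury_full, meas_mid, jury_mid
        ):
            hist[mf - 1, jf - 1] += 1
            pair_rows.append((subj, trial, mm, jm))
    pairs = pd.DataFrame(pair_rows, columns=["subject", "trial", "measure_rank", "jury_rank"])
    rows = []
    for subject, group in pairs.groupby("subject", sort=True):
        try:
            rho, p = spearman(group["jury_rank"], group["measure_rank"])
            band = significance_band(p)
        except UndefinedCorrelationError:
            rho, p, band = np.nan, np.nan, "undefined"
        rows.append((subject, rho, p, band))
    per_subject = pd.DataFrame(rows, columns=["subject", "rho", "p", "band"])
    return RankRankResult(histogram=hist, per_subject=per_subject)


def _canonical(token: str) -> str:
    return re.sub(r"\s+", " ", token.strip().casefold())


def divergent_scores(responses: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Score divergent-thinking response lists per subject.

    * fluency: number of responses;
    * originality: responses given by fewer than 20% of subjects;
    * percentage: originality / fluency;
    * mean originality: mean over responses of (1 - fraction of subjects
      giving that response).

    Responses are canonicalised (case-folded, whitespace-trimmed) and each
    subject counts once per distinct response.  Empty lists yield fluency
    0 and NaN for the other metrics.
    """
    if not responses:
        raise ValueError("need at least one subject")
    canon = {s: [_canonical(r) for r in rs] for s, rs in responses.items()}
    n_subjects = len(canon)
    givers: dict[str, int] = {}
    for rs in canon.values():
        for r in set(rs):
            givers[r] = givers.get(r, 0) + 1
    rows = []
    for subject, rs in canon.items():
        fluency = len(rs)
        if fluency == 0:
            rows.append((subject, 0, np.nan, np.nan, np.nan))
            continue
        freqs = np.array([givers[r] / n_subjects for r in rs])
        originality = int((freqs < 0.2).sum())
        rows.append(
            (subject, fluency, originality, originality / fluency, float((1.0 - freqs).mean()))
        )
    return pd.DataFrame(
        rows, columns=["subject", "fluency", "originality", "percentage", "mean_originality"]
    )
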