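"""Survival-based scoring of a clustering.

A clustering is scored by the multi-group log-rank chi-squared between its
clusters and an empirical p-value obtained by permuting the cluster labels
(30,000 times by default) while keeping the label multiset fixed.  The
classification score is -log10 of the add-one-smoothed empirical p,

    empirical_p = (#{permutations with chi2 >= observed} + 1) / (n_perm + 1),

so a clustering never scores infinity and the maximum attainable score is
log10(n_perm + 1).  The log-rank statistic is computed with the standard
discrete-time hypergeometric (tie-corrected) variance; permutations compare
chi-squared values directly, which is equivalent to comparing asymptotic
p-values at fixed degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import ClusterAssignment, SurvivalTable

__all__ = ["ScoreResult", "logrank_statistic", "classification_score", "km_summary"]


@dataclass
class ScoreResult:
    """Observed log-rank statistic plus its permutation-based score."""

    chi_squared: float
    df: int
    asymptotic_p: float
    n_permutations: int
    n_as_extreme: int
    empirical_p: float
    classification_score: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class _LogrankData:
    """Precomputed risk/event structure reused across label permutations."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        if event.sum() == 0:
            raise ValueError("log-rank test undefined: all subjects censored")
        tau = np.unique(time[event == 1])  # distinct event times
        self.risk = (time[:, None] >= tau[None, :]).astype(float)  # (n, T)
        self.events = ((event[:, None] == 1) & (time[:, None] == tau[None, :])).astype(float)
        self.n_t = self.risk.sum(axis=0)
        self.d_t = self.events.sum(axis=0)
        # tie-corrected hypergeometric variance factor per event time
        denom = np.where(self.n_t > 1, self.n_t - 1, 1.0)
        self.c_t = np.where(
            self.n_t > 1, self.d_t * (self.n_t - self.d_t) / denom, 0.0
        )

    def chi_squared(self, labels: np.ndarray, k: int) -> np.ndarray:
        """Batched log-rank chi-squared for an (B, n) array of label vectors."""
        labels = np.atleast_2d(labels)
        B, n = labels.shape
        # per-group at-risk and observed-event counts at each event time
        N = np.empty((B, k, self.risk.shape[1]))
        O = np.empty((B, k))
        for j in range(k):
            mask = (labels == j).astype(float)  # (B, n)
            N[:, j, :] = mask @ self.risk
            O[:, j] = (mask @ self.events).sum(axis=1)
        E = (N * (self.d_t / self.n_t)[None, None, :]).sum(axis=2)
        z = (O - E)[:, : k - 1]
        # V_jl = sum_t c_t * (N_j/n_t) (delta_jl - N_l/n_t), over first k-1 groups
        A = (N * (self.c_t / self.n_t)[None, None, :]).sum(axis=2)  # (B, k)
        F = N * (np.sqrt(self.c_t) / self.n_t)[None, None, :]
        cross = np.einsum("bjt,blt->bjl", F, F)
        V = -cross
        idx = np.arange(k)
        V[:, idx, idx] += A
        V = V[:, : k - 1, : k - 1]
        try:
            sol = np.linalg.solve(V, z[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            sol = np.stack([np.linalg.pinv(v) @ x for v, x in zip(V, z)])
        return np.einsum("bj,bj->b", z, sol)


def _aligned_labels(
    assignment: ClusterAssignment, survival: SurvivalTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if assignment.k < 2:
        raise ValueError("survival comparison requires at least 2 clusters")
    sub = survival.subset(assignment.subject_ids)
    return assignment.labels, sub.time, sub.event


def logrank_statistic(
    assignment: ClusterAssignment, survival: SurvivalTable
) -> tuple[float, int, float]:
    """Multi-group log-rank: (chi-squared, df = k-1, asymptotic p)."""
    labels, time, event = _aligned_labels(assignment, survival)
    data = _LogrankData(time, event)
    chi = float(data.chi_squared(labels, assignment.k)[0])
    df = assignment.k - 1
    return chi, df, float(stats.chi2.sf(chi, df))


def classification_score(
    assignment: ClusterAssignment,
    survival: SurvivalTable,
    n_perm: int = 30_000,
    seed: int = 0,
    batch: int = 512,
) -> ScoreResult:
    """Permutation-based survival separation score of a clustering.

    Cluster labels are shuffled over subjects ``n_perm`` times (seeded,
    label multiset preserved); the score is -log10 of the smoothed fraction
    of permutations whose chi-squared is at least the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels, time, event = _aligned_labels(assignment, survival)
    data = _LogrankData(time, event)
    k = assignment.k
    observed = float(data.chi_squared(labels, k)[0])

    rng = np.random.default_rng(seed)
    n_as_extreme = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(labels) for _ in range(b)])
        chi = data.chi_squared(perms, k)
        n_as_extreme += int(np.sum(chi >= observed))
        done += b

    empirical_p = (n_as_extreme + 1) / (n_perm + 1)
    return ScoreResult(
        chi_squared=observed,
        df=k - 1,
        asymptotic_p=float(stats.chi2.sf(observed, k - 1)),
        n_permutations=n_perm,
        n_as_extreme=n_as_extreme,
        empirical_p=empirical_p,
        classification_score=float(-np.log10(empirical_p)),
        seed=seed,
    )


def km_summary(assignment: ClusterAssignment, survival: SurvivalTable):
    """Per-cluster Kaplan-Meier table (cluster, time, at-risk, events, S(t))."""
    import pandas as pd
    from lifelines import KaplanMeierFitter

    labels, time, event = _aligned_labels(assignment, survival)
    frames = []
    for j in range(assignment.k):
        sel = labels == j
        kmf = KaplanMeierFitter().fit(time[sel], event[sel])
        tbl = kmf.event_table.reset_index()
        frames.append(
            pd.DataFrame(
                {
                    "cluster": j,
                    "time": tbl["event_at"],
                    "at_risk": tbl["at_risk"],
                    "events": tbl["observed"],
                    "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
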