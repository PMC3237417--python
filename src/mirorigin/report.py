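"""Summary tables: origin-mode counts, pairwise relationship matrices, and
the printed-arithmetic helpers for genome-scale overlap expectations."""

from __future__ import annotations

import pandas as pd

from .config import PipelineConfig
from .stats import cv_similarity, monte_carlo_intersection

__all__ = [
    "random_overlap_expectation",
    "observed_to_expected_pct",
    "proportion_pct",
    "fig1_counts",
    "intersection_matrix",
    "accuracy_matrix",
]

_MODE_LABELS = ("TR", "PR", "ID", "TD", "SD")


def random_overlap_expectation(total_bp: float, genome_fraction: float) -> float:
    """Expected bp of overlap under random placement: total length of the
    gene set times the genomic fraction occupied by the feature class."""
    if total_bp < 0 or not 0 <= genome_fraction <= 1:
        raise ValueError("need total_bp >= 0 and fraction in [0, 1]")
    return total_bp * genome_fraction


def observed_to_expected_pct(
    observed_bp: float, total_bp: float, genome_fraction: float, ndigits: int = 2
) -> float:
    """Observed overlap as a percentage of the random-placement expectation."""
    expected = random_overlap_expectation(total_bp, genome_fraction)
    if expected == 0:
        raise ValueError("zero expectation")
    return round(100.0 * observed_bp / expected, ndigits)


def proportion_pct(count: int, total: int, ndigits: int = 1) -> float:
    """Category share as a rounded percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def fig1_counts(calls) -> pd.DataFrame:
    """Per-label counts: multi-label tally plus an exclusive primary tally
    (precedence TR > PR > ID > TD > SD > OT)."""
    rows = []
    for lab in _MODE_LABELS + ("OT",):
        multi = sum(1 for c in calls if lab in c.labels)
        primary = sum(1 for c in calls if c.primary_label == lab)
        rows.append({"label": lab, "multi_label_count": multi, "primary_count": primary})
    return pd.DataFrame(rows).set_index("label")


def intersection_matrix(
    calls, reps: int = 100_000, seed: int = 0, cfg: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Pairwise Monte Carlo intersection tests over the five origin modes."""
    M = len(calls)
    members = {lab: {c.mirna_id for c in calls if lab in c.labels} for lab in _MODE_LABELS}
    rows = []
    for i, la in enumerate(_MODE_LABELS):
        for lb in _MODE_LABELS[i + 1 :]:
            m, n = len(members[la]), len(members[lb])
            N = len(members[la] & members[lb])
            if M == 0 or min(m, n) == 0:
                continue
            t = monte_carlo_intersection(
                M, m, n, N, reps=reps, seed=seed, paper_literal=cfg.paper_literal_tail
            )
            rows.append(
                {
                    "set1": la,
                    "set2": lb,
                    "M": M,
                    "m": m,
                    "n": n,
                    "N": N,
                    "expected": round(t.expected, 2),
                    "mean_simulated": round(t.mean_simulated, 3),
                    "p_empirical": t.p_empirical,
                    "p_analytic": t.p_analytic,
                    "direction": t.direction,
                }
            )
    return pd.DataFrame(rows)


def accuracy_matrix(features_df: pd.DataFrame, calls, seed: int = 0) -> pd.DataFrame:
    """Pairwise classification accuracy between origin-mode sets.

    Members carrying both labels are excluded from both sides; pairs with
    fewer than 5 exclusive members on either side are reported as NaN.
    """
    members = {lab: {c.mirna_id for c in calls if lab in c.labels} for lab in _MODE_LABELS}
    rows = []
    for i, la in enumerate(_MODE_LABELS):
        for lb in _MODE_LABELS[i + 1 :]:
            only_a = sorted((members[la] - members[lb]) & set(features_df.index))
            only_b = sorted((members[lb] - members[la]) & set(features_df.index))
            if min(len(only_a), len(only_b)) < 5:
                acc = float("nan")
            else:
                acc = cv_similarity(
                    features_df.loc[only_a].to_numpy(dtype=float),
                    features_df.loc[only_b].to_numpy(dtype=float),
                    seed=seed,
                ).mean_accuracy
            rows.append(
                {
                    "set1": la,
                    "set2": lb,
                    "n1": len(only_a),
                    "n2": len(only_b),
                    "mean_accuracy": acc,
                }
            )
    return pd.DataFrame(rows)
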