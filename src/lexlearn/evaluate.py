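"""Scoring fitted mappings.

The central quantity is the per-word target correlation r: the Pearson
correlation between a word's predicted semantic vector ŝ = cF and its gold
vector s. A word is correct@k when its own gold vector is among the k gold
vectors most correlated with ŝ (correlation accuracy). Accuracy can be
averaged over types (each word counts once) or over tokens (each word
weighted by its frequency); 1 − r serves as a proxy for lexical decision
latency, and the same quantity computed between a prime's predicted vector
and a target's gold vector scores priming designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Lexicon
from .mappings import MappingMatrix

__all__ = [
    "PredictionResult",
    "predict",
    "target_correlations",
    "rank_of_target",
    "accuracy_at_k",
    "frequency_weighted_accuracy",
    "one_minus_r",
    "evaluate_mapping",
    "priming_measures",
]

#: ties in correlation within this tolerance resolve in the target's favor,
#: so sets of homophones (identical predictions) are not auto-failed
TIE_TOL = 1e-12


def _as_array(X) -> np.ndarray:
    if isinstance(X, MappingMatrix):
        return X.matrix
    if hasattr(X, "toarray"):
        return X.toarray()
    if hasattr(X, "matrix"):
        return np.asarray(X.matrix.toarray() if hasattr(X.matrix, "toarray")
                          else X.matrix, dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class PredictionResult:
    """Predicted matrix with per-word scores against the gold matrix."""

    predicted: np.ndarray
    r: np.ndarray               # per-word target correlation
    degenerate: np.ndarray      # zero-variance predicted rows (r is sentinel 0)
    rank: np.ndarray            # 1-based rank of the target among gold rows

    def correct_at(self, k: int) -> np.ndarray:
        m = self.rank.size
        if k < 1 or k > m:
            raise ValueError(f"k must be in 1..{m}, got {k}")
        return self.rank <= k


def predict(C, mapping) -> np.ndarray:
    """Predicted output rows, e.g. Ŝ = C F for comprehension."""
    C = _as_array(C)
    return C @ _as_array(mapping)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    degenerate = sd <= 0
    safe = np.where(degenerate, 1.0, sd)
    return centered / safe[:, None], degenerate


def target_correlations(Shat, S) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each predicted row with its own gold row.

    Returns ``(r, degenerate)``; a zero-variance row (in either matrix)
    yields the sentinel r = 0 with its degeneracy flag set.
    """
    Shat, S = _as_array(Shat), _as_array(S)
    if Shat.shape != S.shape:
        raise ValueError(f"shape mismatch: {Shat.shape} vs {S.shape}")
    zhat, deg_hat = _standardize_rows(Shat)
    zgold, deg_gold = _standardize_rows(S)
    r = (zhat * zgold).sum(axis=1) / Shat.shape[1]
    degenerate = deg_hat | deg_gold
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


def _correlation_matrix(Shat: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    zhat, deg_hat = _standardize_rows(Shat)
    zgold, deg_gold = _standardize_rows(S)
    corr = (zhat @ zgold.T) / Shat.shape[1]
    corr[deg_hat, :] = 0.0
    corr[:, deg_gold] = 0.0
    return np.clip(corr, -1.0, 1.0), deg_hat


def rank_of_target(Shat, S, tie_tol: float = TIE_TOL) -> PredictionResult:
    """Rank each word's gold row among all gold rows by correlation with ŝ.

    Rank 1 means the target is the (possibly tied) nearest gold vector;
    ties within ``tie_tol`` count in the target's favor. A degenerate
    (zero-variance) predicted row is assigned rank m: it can only be
    "correct" at k = m, which keeps accuracy@m = 1 an invariant.
    """
    Shat, S = _as_array(Shat), _as_array(S)
    if Shat.shape != S.shape:
        raise ValueError(f"shape mismatch: {Shat.shape} vs {S.shape}")
    m = Shat.shape[0]
    corr, deg_hat = _correlation_matrix(Shat, S)
    own = np.diag(corr)
    beats = (corr > (own[:, None] + tie_tol)).sum(axis=1)
    rank = beats + 1
    rank[deg_hat] = m
    r, degenerate = target_correlations(Shat, S)
    return PredictionResult(predicted=Shat, r=r, degenerate=degenerate,
                            rank=rank.astype(np.int64))


def accuracy_at_k(Shat, S, k: int = 1) -> tuple[float, np.ndarray]:
    """Type-level accuracy@k and the per-word correctness flags."""
    result = rank_of_target(Shat, S)
    flags = result.correct_at(k)
    return float(flags.mean()), flags


def frequency_weighted_accuracy(flags, f) -> float:
    """Token-level accuracy: Σ fᵢ·flagᵢ / Σ fᵢ.

    Each word is weighted by its token frequency, so misses on
    zero-frequency words cost nothing.
    """
    flags = np.asarray(flags, dtype=float)
    f = np.asarray(f, dtype=float)
    if flags.shape != f.shape:
        raise ValueError("flags and frequencies must have equal length")
    total = f.sum()
    if total <= 0:
        raise ValueError("total frequency is zero")
    return float((f * flags).sum() / total)


def one_minus_r(r) -> np.ndarray:
    """The latency proxy 1 − r (expected to correlate positively with RT)."""
    if isinstance(r, PredictionResult):
        r = r.r
    return 1.0 - np.asarray(r, dtype=float)


def evaluate_mapping(C, S, mapping, lexicon: Lexicon | None = None,
                     ks: tuple[int, ...] = (1,)) -> pd.DataFrame:
    """Per-word measure table for a fitted mapping.

    Columns: word_id, frequency (if a lexicon is given), target_correlation,
    one_minus_r, rank, correct@k for each requested k, degenerate.
    """
    Shat = predict(C, mapping)
    result = rank_of_target(Shat, S)
    table: dict = {}
    if lexicon is not None:
        table["word_id"] = lexicon.word_ids
        table["frequency"] = lexicon.frequencies
    table["target_correlation"] = result.r
    table["one_minus_r"] = one_minus_r(result)
    table["rank"] = result.rank
    for k in ks:
        table[f"correct@{k}"] = result.correct_at(k).astype(int)
    table["degenerate"] = result.degenerate.astype(int)
    return pd.DataFrame(table)


def priming_measures(
    items: pd.DataFrame,
    Shat,
    S,
    lexicon: Lexicon,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score a prime-target design with the 1 − r priming measure.

    ``items`` has columns prime, target, condition. The measure is
    1 − cor(ŝ_prime, s_target): the prime's *predicted* semantic vector
    against the target's *gold* vector, so an identity prime under a
    perfect mapping scores 0. Returns ``(items, by_condition, pairwise)``:
    per-pair measures, condition means/dispersion, and pairwise mean
    differences with label-permutation p-values (a toy-data analogue of
    post-hoc condition comparisons on empirical reaction times).
    """
    required = {"prime", "target", "condition"}
    if not required.issubset(items.columns):
        raise ValueError(f"items must have columns {sorted(required)}")
    Shat, S = _as_array(Shat), _as_array(S)
    zhat, deg_hat = _standardize_rows(Shat)
    zgold, deg_gold = _standardize_rows(S)
    q = S.shape[1]
    measures = []
    for row in items.itertuples(index=False):
        i = lexicon.index_of(str(row.prime))
        j = lexicon.index_of(str(row.target))
        if deg_hat[i] or deg_gold[j]:
            r = 0.0
        else:
            r = float(np.clip((zhat[i] * zgold[j]).sum() / q, -1.0, 1.0))
        measures.append(1.0 - r)
    out = items.copy()
    out["measure"] = measures

    by_cond = (
        out.groupby("condition")["measure"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )

    rng = np.random.default_rng(seed)
    conds = sorted(out["condition"].unique())
    labels = out["condition"].to_numpy()
    values = out["measure"].to_numpy()
    rows = []
    for a_i in range(len(conds)):
        for b_i in range(a_i + 1, len(conds)):
            a, b = conds[a_i], conds[b_i]
            mask = (labels == a) | (labels == b)
            v, l = values[mask], labels[mask]
            observed = v[l == a].mean() - v[l == b].mean()
            count = 0
            n_a = int((l == a).sum())
            for _ in range(n_permutations):
                perm = rng.permutation(v)
                if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= abs(observed):
                    count += 1
            rows.append(
                {"condition_a": a, "condition_b": b,
                 "mean_difference": observed,
                 "p_permutation": (count + 1) / (n_permutations + 1)}
            )
    return out, by_cond, pd.DataFrame(rows)
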