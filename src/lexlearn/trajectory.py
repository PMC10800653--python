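"""Ordered-learning analysis over token streams.

Widrow-Hoff learning is run over a temporally ordered token stream,
evaluating every word's target correlation after each batch of events and
keeping the within-batch token counts. A frequency-informed (FIL) mapping
fit on the stream's aggregate counts serves as the order-agnostic
comparison: per-word differences between the two expose where order
matters — words whose tokens cluster late in the stream favor incremental
learning, words that burst early and then share cues with later words get
partially unlearned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import target_correlations, predict
from .mappings import (
    EventSequence,
    MappingMatrix,
    solve_frequency_informed,
    train_incremental,
)

__all__ = [
    "TrajectoryResult",
    "run_trajectory",
    "occurrence_moments",
    "whl_fil_delta",
]

#: the supplementary-material transform of the original kurtosis analysis is
#: unavailable; this sign-preserving log is a labeled stand-in
KURTOSIS_TRANSFORM = "signed_log1p (stand-in)"


@dataclass
class TrajectoryResult:
    """Batchwise WHL evaluation plus the order-agnostic FIL comparison."""

    batch_size: int
    correlations: np.ndarray    # n_batches × m target correlations
    counts: np.ndarray          # n_batches × m within-batch token counts
    whl: MappingMatrix
    fil: MappingMatrix
    word_ids: list[str]
    eta: float

    @property
    def n_batches(self) -> int:
        return self.correlations.shape[0]

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def run_trajectory(stream, C, S, eta: float, batch: int = 5000,
                   word_ids: list[str] | None = None) -> TrajectoryResult:
    """Train WHL over a stream, evaluating after every ``batch`` events.

    ``stream`` is an ordered sequence of row indices into C/S (use
    ``Lexicon.index_of`` to resolve word ids). After every ``batch`` events
    (and once at stream end if it is not a batch boundary) all words'
    target correlations and the within-batch token counts are recorded.
    A FIL mapping fit on the stream's aggregate frequencies is attached
    for the order-sensitivity comparison.
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    idx = np.asarray(
        stream.indices if isinstance(stream, EventSequence) else stream,
        dtype=np.int64,
    )
    if idx.size == 0:
        raise ValueError("empty stream")
    m = C.shape[0]
    if idx.min() < 0 or idx.max() >= m:
        raise IndexError("stream contains word indices out of range")

    boundaries = list(range(batch, idx.size, batch)) + [idx.size]
    correlations, counts = [], []
    F: MappingMatrix | None = None
    start = 0
    for end in boundaries:
        chunk = idx[start:end]
        try:
            F = train_incremental(C, S, chunk, eta=eta, F0=F)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"divergence in batch {len(correlations) + 1}: {exc}"
            ) from exc
        r, _ = target_correlations(predict(C, F), S)
        correlations.append(r)
        counts.append(np.bincount(chunk, minlength=m))
        start = end

    total = np.bincount(idx, minlength=m)
    fil = solve_frequency_informed(C, S, total.astype(float))
    if word_ids is None:
        word_ids = getattr(C, "word_ids", [str(i) for i in range(m)])
    return TrajectoryResult(
        batch_size=batch,
        correlations=np.vstack(correlations),
        counts=np.vstack(counts),
        whl=F,
        fil=fil,
        word_ids=list(word_ids),
        eta=eta,
    )


def occurrence_moments(result: TrajectoryResult) -> pd.DataFrame:
    """Weighted moments of each word's occurrence-time distribution.

    The batch index (1-based) is treated as a random variable with mass
    proportional to the word's per-batch token count. Returns per word the
    weighted mean, mode (smallest maximizing batch on ties), skewness and
    excess kurtosis (sentinel 0 for zero-variance or unattested words, with
    a flag), a sign-preserving log-damped kurtosis, and the total count.
    High mean/mode and negative skew indicate tokens concentrated late in
    the stream.
    """
    n_batches, m = result.counts.shape
    batches = np.arange(1, n_batches + 1, dtype=float)
    rows = []
    for i in range(m):
        w = result.counts[:, i].astype(float)
        total = w.sum()
        if total == 0:
            rows.append(
                {"word_id": result.word_ids[i], "total_count": 0,
                 "mean": np.nan, "mode": np.nan, "skewness": 0.0,
                 "kurtosis": 0.0, "kurtosis_transformed": 0.0,
                 "degenerate": 1}
            )
            continue
        p = w / total
        mean = float(p @ batches)
        mode = int(batches[int(np.argmax(w))])
        var = float(p @ (batches - mean) ** 2)
        if var <= 0:
            skew = kurt = 0.0
            degenerate = 1
        else:
            sd = np.sqrt(var)
            skew = float(p @ ((batches - mean) / sd) ** 3)
            kurt = float(p @ ((batches - mean) / sd) ** 4) - 3.0
            degenerate = 0
        rows.append(
            {"word_id": result.word_ids[i], "total_count": int(total),
             "mean": mean, "mode": mode, "skewness": skew, "kurtosis": kurt,
             "kurtosis_transformed": float(np.sign(kurt) * np.log1p(abs(kurt))),
             "degenerate": degenerate}
        )
    df = pd.DataFrame(rows)
    df.attrs["kurtosis_transform"] = KURTOSIS_TRANSFORM
    return df


def normalized_batch_counts(result: TrajectoryResult) -> np.ndarray:
    """Per-batch counts normalized by each batch's maximum (for plotting)."""
    mx = result.counts.max(axis=1, keepdims=True).astype(float)
    mx[mx == 0] = 1.0
    return result.counts / mx


def whl_fil_delta(result: TrajectoryResult,
                  S=None, C=None) -> tuple[pd.DataFrame, float]:
    """Per-word r_WHL − r_FIL and the summary correlation between the two.

    Positive delta marks words the order-sensitive learner handles better
    (typically late-bursting words); negative delta marks unlearning
    (early-bursting words with cue overlap). The summary is the Pearson
    correlation between the final WHL and FIL per-word target-correlation
    vectors. The returned table joins the deltas with the occurrence-time
    moments for downstream regression.
    """
    if C is None or S is None:
        raise ValueError("whl_fil_delta needs the C and S matrices")
    r_whl, _ = target_correlations(predict(C, result.whl), S)
    r_fil, _ = target_correlations(predict(C, result.fil), S)
    if np.std(r_whl) > 0 and np.std(r_fil) > 0:
        summary = float(np.corrcoef(r_whl, r_fil)[0, 1])
    else:
        summary = 0.0
    table = occurrence_moments(result)
    table["r_whl"] = r_whl
    table["r_fil"] = r_fil
    table["delta"] = r_whl - r_fil
    return table, summary
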