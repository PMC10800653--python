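"""Estimating linear form-meaning mappings.

Three estimators for the mapping F in C F = S (comprehension; swap the
roles of C and S for production):

* **EL** (endstate learning): ordinary multivariate least squares via the
  normal equations, F = (CᵀC)⁻¹CᵀS — the frequency-free limit of infinite
  uniform training.
* **FIL** (frequency-informed learning): weighted least squares equivalent
  to EL on matrices whose rows are replicated according to each word's
  token frequency, obtained by scaling row i of C and S by √(fᵢ/max f).
* **WHL** (Widrow-Hoff learning): incremental error-driven updates, one
  learning event (word token) at a time, F ← F + cᵀ(s − cF)·η.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import LinAlgError, cho_solve

__all__ = [
    "MappingMatrix",
    "FrequencyWeights",
    "EventSequence",
    "solve_linear_mapping",
    "solve_frequency_informed",
    "frequencies_to_events",
    "train_incremental",
]


@dataclass
class MappingMatrix:
    """A fitted linear map (input-dimension × output-dimension).

    ``direction`` is "comprehension" (form→meaning, F) or "production"
    (meaning→form, G); ``method`` is one of {"EL", "FIL", "WHL"}.
    """

    matrix: np.ndarray
    method: str
    direction: str = "comprehension"
    params: dict = field(default_factory=dict)
    snapshots: list[tuple[int, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("mapping matrix contains non-finite entries")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class FrequencyWeights:
    """Per-word non-negative weights with a record of how they were derived."""

    values: np.ndarray
    transform: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("weights must be a vector")
        if (self.values < 0).any():
            raise ValueError("negative weight")
        if not (self.values > 0).any():
            raise ValueError("all weights are zero")


@dataclass
class EventSequence:
    """Ordered learning events: row indices into the lexicon."""

    indices: np.ndarray
    transform: str = "raw"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size == 0:
            raise ValueError("empty event sequence")

    def __len__(self) -> int:
        return int(self.indices.size)


def _as_matrix(X) -> np.ndarray | sp.spmatrix:
    if isinstance(X, MappingMatrix):
        return X.matrix
    if hasattr(X, "matrix"):  # CueMatrix
        return X.matrix
    if sp.issparse(X):
        return X
    return np.asarray(X, dtype=float)


def solve_linear_mapping(X, Y, ridge: float = 0.0) -> MappingMatrix:
    """Least-squares solution F of X F ≈ Y via the normal equations.

    (XᵀX + ridge·I) is factorized with a Cholesky decomposition; if the
    factorization fails (rank-deficient Gram matrix, e.g. duplicate
    homophone rows), the minimum-norm least-squares solution is returned
    instead. With ridge = 0 and a consistent full-column-rank system the
    solution reproduces Y exactly.
    """
    X = _as_matrix(X)
    Y = np.asarray(_as_matrix(Y), dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"row-count mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
        )
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    if not Xd.any():
        raise ValueError("all-zero input matrix")
    gram = Xd.T @ Xd
    if ridge > 0:
        gram = gram + ridge * np.eye(gram.shape[0])
    rhs = Xd.T @ Y
    try:
        L = np.linalg.cholesky(gram)
        # Cholesky can "succeed" on a numerically singular Gram matrix
        # (duplicate homophone rows) and return a huge-norm solution; the
        # relative pivot check is scale-invariant, so a weighted system and
        # its row-replicated equivalent always take the same branch.
        piv = np.diag(L)
        if piv.min() <= 1e-6 * piv.max():
            raise np.linalg.LinAlgError("ill-conditioned Gram matrix")
        F = cho_solve((L, True), rhs)
    except (LinAlgError, np.linalg.LinAlgError):
        F = np.linalg.lstsq(Xd, Y, rcond=None)[0]
    return MappingMatrix(matrix=F, method="EL", params={"ridge": ridge})


def solve_frequency_informed(C, S, f, ridge: float = 0.0) -> MappingMatrix:
    """Frequency-informed mapping: weighted least squares over words.

    Minimizes Σᵢ fᵢ‖cᵢF − sᵢ‖². Row i of both C and S is scaled by
    pᵢ = √(fᵢ / max f) — the normalization by the largest frequency keeps
    the scaled system numerically well-behaved and, since a positive
    constant on the weights does not change the minimizer, is harmless.
    For integer frequencies the result equals ordinary least squares on
    matrices with row i repeated fᵢ times. Zero-frequency rows get weight
    zero: they do not constrain the fit but remain evaluable.
    """
    if isinstance(f, FrequencyWeights):
        f = f.values
    f = np.asarray(f, dtype=float)
    C = _as_matrix(C)
    S = np.asarray(_as_matrix(S), dtype=float)
    if f.ndim != 1 or f.size != C.shape[0]:
        raise ValueError("frequency vector length must equal the row count")
    if (f < 0).any():
        raise ValueError("negative weight")
    if not (f > 0).any():
        raise ValueError("all weights are zero")
    p = np.sqrt(f / f.max())
    Cd = C.toarray() if sp.issparse(C) else np.asarray(C, dtype=float)
    Cw = Cd * p[:, None]
    Sw = S * p[:, None]
    fitted = solve_linear_mapping(Cw, Sw, ridge=ridge)
    return MappingMatrix(matrix=fitted.matrix, method="FIL",
                         params={"ridge": ridge})


def frequencies_to_events(
    f,
    transform: str = "raw",
    divisor: float = 100,
    order: str = "shuffled",
    seed: int | None = 0,
) -> EventSequence:
    """Translate token frequencies into a sequence of learning events.

    ``raw``: word i contributes fᵢ events (a word with frequency 100 is
    presented for learning 100 times). ``scaled``: ceil(fᵢ/divisor), so any
    attested word keeps at least one event. ``log_backoff``:
    round(ln(fᵢ+1)), floored at 1 for attested words. ``order`` is
    "shuffled" (seeded) or "as_given" (events grouped by word in row order).
    """
    if isinstance(f, FrequencyWeights):
        f = f.values
    f = np.asarray(f)
    if (f < 0).any():
        raise ValueError("negative frequency")
    if transform == "raw":
        counts = f.astype(np.int64)
    elif transform == "scaled":
        if divisor < 1:
            raise ValueError("divisor must be >= 1")
        counts = np.ceil(f / divisor).astype(np.int64)
    elif transform == "log_backoff":
        counts = np.round(np.log(f + 1.0)).astype(np.int64)
        counts[f >= 1] = np.maximum(counts[f >= 1], 1)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    indices = np.repeat(np.arange(f.size), counts)
    if indices.size == 0:
        raise ValueError("no learning events (all frequencies zero)")
    if order == "shuffled":
        rng = np.random.default_rng(seed)
        rng.shuffle(indices)
    elif order != "as_given":
        raise ValueError(f"unknown order {order!r}")
    return EventSequence(indices=indices, transform=transform,
                         seed=seed if order == "shuffled" else None)


def train_incremental(
    C,
    S,
    events: EventSequence | Sequence[int],
    eta: float,
    F0: np.ndarray | MappingMatrix | None = None,
    snapshot_every: int | None = None,
) -> MappingMatrix:
    """Widrow-Hoff learning: F ← F + cᵗᵀ·(sᵗ − cᵗF)·η, once per event.

    Starts from the zero matrix unless ``F0`` is given. With
    ``snapshot_every = N`` a copy of F is retained after every N events in
    ``result.snapshots`` as ``(event_count, F)`` pairs. Deterministic given
    the event sequence and F0. Raises on divergence, naming the event index.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    idx = events.indices if isinstance(events, EventSequence) else np.asarray(
        events, dtype=np.int64
    )
    if idx.size == 0:
        raise ValueError("empty event sequence")
    Cm = _as_matrix(C)
    S = np.asarray(_as_matrix(S), dtype=float)
    m = Cm.shape[0]
    if idx.min() < 0 or idx.max() >= m:
        bad = int(np.argmax((idx < 0) | (idx >= m)))
        raise IndexError(f"event {bad}: word index {idx[bad]} out of range")

    csr = sp.csr_matrix(Cm) if not sp.issparse(Cm) else Cm.tocsr()
    F = (
        np.zeros((csr.shape[1], S.shape[1]))
        if F0 is None
        else np.array(_as_matrix(F0), dtype=float, copy=True)
    )
    snapshots: list[tuple[int, np.ndarray]] | None = (
        [] if snapshot_every else None
    )
    indptr, cols, data = csr.indptr, csr.indices, csr.data
    with np.errstate(over="ignore", invalid="ignore"):
        for t, w in enumerate(idx):
            lo, hi = indptr[w], indptr[w + 1]
            active, vals = cols[lo:hi], data[lo:hi]
            pred = vals @ F[active]
            err = S[w] - pred
            if not np.isfinite(err).all():
                raise FloatingPointError(
                    f"non-finite update at event {t} (word index {w}); "
                    "reduce the learning rate"
                )
            F[active] += eta * np.outer(vals, err)
            if snapshot_every and (t + 1) % snapshot_every == 0:
                snapshots.append((t + 1, F.copy()))
    return MappingMatrix(
        matrix=F,
        method="WHL",
        params={"eta": eta, "n_events": int(idx.size),
                "snapshot_every": snapshot_every},
        snapshots=snapshots,
    )
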