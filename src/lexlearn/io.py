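"""Reading and writing lexicons, embeddings, token streams, and measure tables.

All tabular formats are tab-separated text with a header row. Embedding
tables carry a ``word_id`` column followed by ``q`` float columns. Token
streams are plain text, one word id per line, in learning order. Sparse cue
matrices are serialized in MatrixMarket coordinate format with a sidecar TSV
mapping column indices to cue strings (see :mod:`lexlearn.cues`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "read_lexicon",
    "write_lexicon",
    "read_embeddings",
    "write_embeddings",
    "read_token_stream",
    "write_token_stream",
    "read_measures",
    "write_measures",
    "write_mapping",
    "read_mapping",
]


@dataclass(frozen=True)
class LexiconEntry:
    """One word of the lexicon.

    ``form`` is the symbol sequence cues are extracted from (orthographic or
    phonological); ``frequency`` is a non-negative token count; ``condition``
    is an optional label (e.g., a priming condition).
    """

    word_id: str
    form: str
    frequency: int
    condition: str | None = None

    def __post_init__(self) -> None:
        if not self.word_id:
            raise ValueError("word_id must be non-empty")
        if not self.form:
            raise ValueError(f"form of {self.word_id!r} must be non-empty")
        if self.frequency < 0:
            raise ValueError(
                f"negative frequency {self.frequency} for {self.word_id!r}"
            )


@dataclass
class Lexicon:
    """An ordered word list; row i of every derived matrix is ``entries[i]``.

    Zero frequencies are legal: such words receive zero weight in
    frequency-informed fits and contribute no learning events, but they stay
    in the row universe and remain evaluable.
    """

    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("empty lexicon")
        seen: dict[str, int] = {}
        dupes = []
        for e in self.entries:
            if e.word_id in seen:
                dupes.append(e.word_id)
            seen[e.word_id] = 1
        if dupes:
            raise ValueError(f"duplicate word_id(s): {sorted(set(dupes))}")
        self._index = {e.word_id: i for i, e in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> LexiconEntry:
        return self.entries[i]

    @property
    def word_ids(self) -> list[str]:
        return [e.word_id for e in self.entries]

    @property
    def forms(self) -> list[str]:
        return [e.form for e in self.entries]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency for e in self.entries], dtype=np.int64)

    @property
    def conditions(self) -> list[str | None]:
        return [e.condition for e in self.entries]

    def index_of(self, word_id: str) -> int:
        try:
            return self._index[word_id]
        except KeyError:
            raise KeyError(f"unknown word_id {word_id!r}") from None

    def subset(self, keep: Sequence[str]) -> "Lexicon":
        """New lexicon restricted to ``keep``, preserving the current order."""
        keep_set = set(keep)
        return Lexicon([e for e in self.entries if e.word_id in keep_set])

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "word_id": self.word_ids,
            "form": self.forms,
            "frequency": self.frequencies,
        }
        conds = self.conditions
        if any(c is not None for c in conds):
            rows["condition"] = ["" if c is None else c for c in conds]
        return pd.DataFrame(rows)


def read_lexicon(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> Lexicon:
    """Read a lexicon TSV (columns word_id, form, frequency[, condition]).

    ``column_map`` renames file columns onto the canonical names, e.g.
    ``{"Word": "word_id", "Freq": "frequency"}``. Words with a missing
    frequency cell get frequency 0 and a logged warning. Duplicate ids,
    negative frequencies, and empty files raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, keep_default_na=False,
                     na_values=[""])
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("word_id", "form", "frequency"):
        if col not in df.columns:
            raise ValueError(f"lexicon file lacks required column {col!r}")
    if len(df) == 0:
        raise ValueError("empty lexicon")
    if df["frequency"].isna().any():
        missing = df.loc[df["frequency"].isna(), "word_id"].tolist()
        logger.warning(
            "words missing a frequency set to 0: %s", ", ".join(map(str, missing))
        )
        df["frequency"] = df["frequency"].fillna(0)
    freq = pd.to_numeric(df["frequency"])
    if (freq < 0).any():
        bad = df.loc[freq < 0, "word_id"].tolist()
        raise ValueError(f"negative frequency for: {bad}")
    has_cond = "condition" in df.columns
    entries = [
        LexiconEntry(
            word_id=str(r.word_id),
            form=str(r.form),
            frequency=int(f),
            condition=(str(r.condition) if has_cond and str(r.condition) else None),
        )
        for r, f in zip(df.itertuples(index=False), freq)
    ]
    return Lexicon(entries)


def write_lexicon(path: str | Path, lexicon: Lexicon) -> None:
    lexicon.to_frame().to_csv(path, sep="\t", index=False)


def read_embeddings(
    path: str | Path, lexicon: Lexicon, missing: str = "strict"
) -> tuple[np.ndarray, Lexicon, list[str]]:
    """Read an embedding TSV and align it to the lexicon row order.

    Returns ``(S, aligned_lexicon, dropped_ids)`` where ``S`` is the
    words-by-dimensions real matrix. Words absent from the table are handled
    per ``missing``: ``"strict"`` (default) raises naming them; ``"drop"``
    removes them from the returned lexicon and reports them — a library must
    not drop silently, so the dropped ids are always surfaced to the caller.
    """
    if missing not in ("strict", "drop"):
        raise ValueError(f"missing must be 'strict' or 'drop', got {missing!r}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    vec = df.drop(columns=[id_col])
    if vec.shape[1] < 1:
        raise ValueError("embedding table has no vector columns")
    try:
        values = vec.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric embedding cell: {exc}") from exc
    if not np.isfinite(values).all():
        raise ValueError("embedding table contains non-finite values")
    table = {str(w): row for w, row in zip(df[id_col], values)}
    absent = [w for w in lexicon.word_ids if w not in table]
    if absent:
        if missing == "strict":
            raise ValueError(f"no embedding for: {absent}")
        logger.warning("dropping %d word(s) without embeddings: %s",
                       len(absent), ", ".join(absent))
        lexicon = lexicon.subset([w for w in lexicon.word_ids if w in table])
    S = np.stack([table[w] for w in lexicon.word_ids])
    return S, lexicon, absent


def write_embeddings(
    path: str | Path, word_ids: Sequence[str], S: np.ndarray
) -> None:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != len(word_ids):
        raise ValueError("S must be 2-D with one row per word id")
    df = pd.DataFrame(S, columns=[f"d{j}" for j in range(S.shape[1])])
    df.insert(0, "word_id", list(word_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_token_stream(path: str | Path) -> list[str]:
    """Read one word id per line; order is learning order."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError("empty token stream")
    return ids


def write_token_stream(path: str | Path, word_ids: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for w in word_ids:
            fh.write(f"{w}\n")


def write_measures(path: str | Path, table: pd.DataFrame | list[dict]) -> None:
    """Write a per-word measure table as TSV (12 significant digits)."""
    df = pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_measures(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mapping(path: str | Path, matrix: np.ndarray,
                  provenance: dict | None = None) -> None:
    """Serialize a mapping matrix as TSV with a JSON provenance sidecar."""
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.17g")
    if provenance is not None:
        Path(str(path) + ".json").write_text(json.dumps(provenance, indent=2))


def read_mapping(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
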