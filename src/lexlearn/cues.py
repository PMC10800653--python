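"""Binary cue matrices from word forms.

Word forms are coded as binary vectors marking the presence or absence of
overlapping n-grams, padded with a single boundary marker on each side
(``aap`` with bigrams -> ``#a, aa, ap, p#``). For Mandarin-style tonal
transcriptions (``wen4ti2``), the ``tonal_union`` scheme combines three cue
families: segmental triphones, tritone cues over the tone-digit sequence,
and tone-segment triphones in which each vowel carries its syllable's tone
digit as part of a single compound symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .io import Lexicon

__all__ = [
    "CueInventory",
    "CueMatrix",
    "extract_ngrams",
    "parse_tonal_transcription",
    "tonal_union_cues",
    "build_cue_matrix",
    "save_cue_matrix",
    "load_cue_matrix",
]

_SYLLABLE_RE = re.compile(r"([a-zA-Z]+)([1-5])")


@dataclass(frozen=True)
class CueInventory:
    """Frozen cue-string -> column-index map for one cue scheme."""

    cues: tuple[str, ...]
    n: int
    scheme: str

    def __post_init__(self) -> None:
        if len(set(self.cues)) != len(self.cues):
            raise ValueError("cue strings must be unique")
        object.__setattr__(
            self, "_index", {c: j for j, c in enumerate(self.cues)}
        )

    def __len__(self) -> int:
        return len(self.cues)

    def __contains__(self, cue: str) -> bool:
        return cue in self._index

    def index_of(self, cue: str) -> int:
        return self._index[cue]


@dataclass
class CueMatrix:
    """Binary words-by-cues matrix C, row-aligned with a Lexicon.

    ``matrix`` is a scipy CSR matrix of 0/1 floats; ``word_ids`` records the
    row order. ``zero_rows`` flags held-out forms none of whose cues appear
    in the (frozen) inventory.
    """

    matrix: sp.csr_matrix
    inventory: CueInventory
    word_ids: list[str]
    zero_rows: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def extract_ngrams(form: str, n: int, boundary: str = "#") -> list[str]:
    """Overlapping n-grams of ``form`` padded with one boundary per side.

    Returns first-occurrence-ordered unique grams (presence/absence coding:
    repeated grams collapse to a single cue).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not form:
        raise ValueError("form must be non-empty")
    if boundary in form:
        raise ValueError(f"boundary {boundary!r} occurs inside form {form!r}")
    padded = boundary + form + boundary
    grams = [padded[i : i + n] for i in range(len(padded) - n + 1)]
    return list(dict.fromkeys(grams))


def parse_tonal_transcription(transcription: str) -> list[tuple[str, int]]:
    """Split ``wen4ti2`` into [("wen", 4), ("ti", 2)].

    Each syllable is a run of letters followed by one tone digit 1-5.
    """
    if not transcription:
        raise ValueError("empty transcription")
    pos = 0
    syllables: list[tuple[str, int]] = []
    for m in _SYLLABLE_RE.finditer(transcription):
        if m.start() != pos:
            break
        syllables.append((m.group(1), int(m.group(2))))
        pos = m.end()
    if pos != len(transcription) or not syllables:
        raise ValueError(
            f"malformed tonal transcription {transcription!r}: "
            "expected letters followed by a tone digit 1-5 per syllable"
        )
    return syllables


def _symbol_ngrams(symbols: Sequence[str], n: int, boundary: str) -> list[str]:
    # n-grams over a sequence of (possibly compound) symbols; a compound
    # symbol like "e4" occupies a single position
    padded = [boundary, *symbols, boundary]
    grams = ["".join(padded[i : i + n]) for i in range(len(padded) - n + 1)]
    return list(dict.fromkeys(grams))


def tonal_union_cues(
    transcription: str, vowels: Iterable[str], n: int = 3, boundary: str = "#"
) -> list[str]:
    """Union of segmental, tritone, and tone-segment cues for one word.

    For ``wen4ti2``: segmental triphones #we, wen, ent, nti, ti#; tritone
    cues #42, 42# over the tone-digit sequence; and tone-segment triphones
    #we4, we4n, e4nt, nti2, ti2#, where a tone-marked vowel such as ``e4``
    counts as one symbol position. The vowel set is language-specific and
    must be supplied.
    """
    vowel_set = set(vowels)
    if not vowel_set:
        raise ValueError("vowel set must be non-empty")
    syllables = parse_tonal_transcription(transcription)
    segments = "".join(seg for seg, _ in syllables)
    tones = "".join(str(t) for _, t in syllables)
    cues = extract_ngrams(segments, n, boundary)
    cues += extract_ngrams(tones, n, boundary)
    marked: list[str] = []
    for seg, tone in syllables:
        for ch in seg:
            marked.append(f"{ch}{tone}" if ch in vowel_set else ch)
    cues += _symbol_ngrams(marked, n, boundary)
    return list(dict.fromkeys(cues))


def _cues_for_form(
    form: str, n: int, scheme: str, vowels: Iterable[str] | None, boundary: str
) -> list[str]:
    if scheme == "plain":
        return extract_ngrams(form, n, boundary)
    if scheme == "tonal_union":
        if vowels is None:
            raise ValueError("scheme 'tonal_union' requires a vowel set")
        return tonal_union_cues(form, vowels, n=n, boundary=boundary)
    raise ValueError(f"unknown cue scheme {scheme!r}")


def build_cue_matrix(
    lexicon: Lexicon,
    n: int = 2,
    scheme: str = "plain",
    vowels: Iterable[str] | None = None,
    boundary: str = "#",
    inventory: CueInventory | None = None,
) -> CueMatrix:
    """Build the binary cue matrix C over a lexicon.

    Without a pre-built ``inventory``, the cue inventory is the union of
    cues over all forms in first-occurrence order. With one (built from a
    training lexicon), unseen cues in held-out forms map to nothing and
    all-zero rows are flagged in ``zero_rows``. Identical forms yield
    identical rows, so homophones share a cue vector by construction.
    """
    per_word: list[list[str]] = []
    for entry in lexicon:
        try:
            per_word.append(_cues_for_form(entry.form, n, scheme, vowels, boundary))
        except ValueError as exc:
            raise ValueError(
                f"cue extraction failed for word {entry.word_id!r}: {exc}"
            ) from exc

    if inventory is None:
        ordered: dict[str, None] = {}
        for cues in per_word:
            for c in cues:
                ordered.setdefault(c, None)
        inventory = CueInventory(tuple(ordered), n=n, scheme=scheme)

    rows, cols = [], []
    zero_rows: list[str] = []
    for i, cues in enumerate(per_word):
        hit = False
        for c in cues:
            if c in inventory:
                rows.append(i)
                cols.append(inventory.index_of(c))
                hit = True
        if not hit:
            zero_rows.append(lexicon[i].word_id)
    matrix = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(lexicon), len(inventory)),
    )
    return CueMatrix(matrix=matrix, inventory=inventory,
                     word_ids=list(lexicon.word_ids), zero_rows=zero_rows)


def save_cue_matrix(prefix: str | Path, cm: CueMatrix) -> None:
    """MatrixMarket coordinate file plus a sidecar TSV of cue strings."""
    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", cm.matrix)
    pd.DataFrame(
        {"column": range(len(cm.inventory)), "cue": list(cm.inventory.cues)}
    ).to_csv(str(prefix) + ".cues.tsv", sep="\t", index=False)
    pd.DataFrame({"row": range(len(cm.word_ids)), "word_id": cm.word_ids}).to_csv(
        str(prefix) + ".rows.tsv", sep="\t", index=False
    )


def load_cue_matrix(prefix: str | Path, n: int = 2,
                    scheme: str = "plain") -> CueMatrix:
    prefix = Path(prefix)
    matrix = sp.csr_matrix(mmread(str(prefix) + ".mtx"))
    cue_df = pd.read_csv(str(prefix) + ".cues.tsv", sep="\t")
    row_df = pd.read_csv(str(prefix) + ".rows.tsv", sep="\t")
    inventory = CueInventory(tuple(cue_df["cue"].astype(str)), n=n, scheme=scheme)
    zero = sorted(
        set(row_df["word_id"].astype(str))
        - set(row_df["word_id"].astype(str)[np.diff(matrix.indptr) > 0])
    )
    return CueMatrix(matrix=matrix, inventory=inventory,
                     word_ids=row_df["word_id"].astype(str).tolist(),
                     zero_rows=zero)
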