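"""Synthetic lexicons, embeddings, token streams, and priming designs.

The generators emulate the statistical structure of the empirical resources
the modeling framework is usually applied to: Zipfian token frequencies
over a rank-ordered vocabulary, high-dimensional real-valued semantic
vectors (optionally produced by a planted linear map from form cues plus
Gaussian noise, so that parameter recovery can be verified), homophone
pairs sharing a form under distinct ids, Mandarin-style tonal
transcriptions, and token streams whose per-word frequency drifts across
time (early or late bursts). Everything is a pure function of the config
and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Lexicon, LexiconEntry
from .cues import CueMatrix, parse_tonal_transcription

__all__ = [
    "GeneratorConfig",
    "generate_lexicon",
    "generate_semantics",
    "generate_token_stream",
    "generate_priming_design",
]

_DEFAULT_ONSETS = ("b", "ch", "d", "f", "g", "h", "j", "k", "l", "m",
                   "n", "p", "r", "s", "t", "w", "z")
_DEFAULT_RIMES = ("a", "e", "i", "o", "u", "an", "en", "un", "ang", "ong")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic lexicon.

    Defaults describe a mid-sized Zipfian lexicon (rank-1 frequency = m,
    exponent 1) over an 8-letter alphabet, with 20-dimensional semantics
    generated by a planted linear map from cues plus Gaussian noise of
    sd 3 — calibrated so that least-squares mappings are learnable but
    clearly imperfect (type accuracy in the tens of percent, not at
    ceiling), the regime real lexicon-embedding pairings occupy.
    """

    seed: int = 0
    m: int = 500
    alphabet: str = "abcdefgh"
    word_length: tuple[int, int] = (3, 7)
    zipf_exponent: float = 1.0
    max_frequency: int | None = None    # default: m (min frequency rounds to 1)
    q: int = 20
    semantic_model: str = "planted_linear"   # or "gaussian"
    noise_sd: float = 3.0
    homophone_pairs: int = 0
    form_scheme: str = "plain"               # or "tonal"
    onsets: tuple[str, ...] = _DEFAULT_ONSETS
    rimes: tuple[str, ...] = _DEFAULT_RIMES
    tones: tuple[int, ...] = (1, 2, 3, 4)
    max_syllables: int = 2
    stream_schedule: str = "stationary"      # or "early_burst" / "late_burst"
    burst_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.m < 1 or self.q < 1:
            raise ValueError("m and q must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.burst_fraction < 1:
            raise ValueError("burst_fraction must be in (0, 1)")
        if self.homophone_pairs < 0 or 2 * self.homophone_pairs > self.m:
            raise ValueError("homophone_pairs out of range")


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    # decouple the random streams of the different generators
    return np.random.default_rng([config.seed, stage])


def zipf_frequencies(m: int, exponent: float,
                     max_frequency: int | None = None) -> np.ndarray:
    """Deterministic rounded Zipf counts: f_i = round(f_max · i^(−a)) ≥ 1."""
    f_max = m if max_frequency is None else max_frequency
    ranks = np.arange(1, m + 1, dtype=float)
    return np.maximum(1, np.round(f_max * ranks ** (-exponent))).astype(np.int64)


def _random_form(rng: np.random.Generator, config: GeneratorConfig) -> str:
    lo, hi = config.word_length
    length = int(rng.integers(lo, hi + 1))
    letters = rng.choice(list(config.alphabet), size=length)
    return "".join(letters)


def _random_tonal_form(rng: np.random.Generator,
                       config: GeneratorConfig) -> str:
    n_syl = int(rng.integers(1, config.max_syllables + 1))
    parts = []
    for _ in range(n_syl):
        onset = config.onsets[rng.integers(len(config.onsets))]
        rime = config.rimes[rng.integers(len(config.rimes))]
        tone = config.tones[rng.integers(len(config.tones))]
        parts.append(f"{onset}{rime}{tone}")
    return "".join(parts)


def generate_lexicon(config: GeneratorConfig) -> Lexicon:
    """m words with unique forms and Zipfian frequencies by rank.

    The rank-i word (i = 1 is the most frequent) gets frequency
    round(f_max·i^(−a)), floored at 1. ``homophone_pairs`` entries at the
    end of the lexicon reuse the form of a randomly chosen earlier word
    under a fresh word id, creating exactly that many id pairs with
    identical forms (distinct lexical entries, identical cue vectors).
    """
    if len(set(config.alphabet)) < 2 and config.form_scheme == "plain":
        raise ValueError("alphabet must contain at least 2 symbols")
    rng = _rng(config, stage=1)
    n_unique = config.m - config.homophone_pairs
    make = (_random_tonal_form if config.form_scheme == "tonal"
            else _random_form)
    forms: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(forms) < n_unique:
        attempts += 1
        if attempts > 200 * config.m:
            raise ValueError(
                f"cannot generate {n_unique} unique forms from the "
                "configured form space"
            )
        form = make(rng, config)
        if form not in seen:
            seen.add(form)
            forms.append(form)
    if config.homophone_pairs:
        sources = rng.choice(n_unique, size=config.homophone_pairs,
                             replace=False)
        forms.extend(forms[int(s)] for s in sources)
    freq = zipf_frequencies(config.m, config.zipf_exponent,
                            config.max_frequency)
    width = len(str(config.m - 1))
    entries = [
        LexiconEntry(word_id=f"w{i:0{width}d}", form=form,
                     frequency=int(freq[i]))
        for i, form in enumerate(forms)
    ]
    return Lexicon(entries)


def generate_semantics(
    lexicon: Lexicon,
    C: CueMatrix | None,
    config: GeneratorConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Semantic matrix S (m × q); returns ``(S, F_star)``.

    ``gaussian``: rows are i.i.d. standard normal (F_star is None).
    ``planted_linear``: a ground-truth map F* with i.i.d. standard-normal
    entries generates S = C·F* + ε, ε ~ N(0, noise_sd²); F* is returned so
    recovery can be tested against it.
    """
    rng = _rng(config, stage=2)
    m, q = len(lexicon), config.q
    if config.semantic_model == "gaussian":
        return rng.standard_normal((m, q)), None
    if config.semantic_model == "planted_linear":
        if C is None:
            raise ValueError("planted_linear requires a cue matrix")
        Cd = C.matrix.toarray() if hasattr(C.matrix, "toarray") else np.asarray(C.matrix)
        F_star = rng.standard_normal((Cd.shape[1], q))
        S = Cd @ F_star
        if config.noise_sd > 0:
            S = S + config.noise_sd * rng.standard_normal((m, q))
        return S, F_star
    raise ValueError(f"unknown semantic model {config.semantic_model!r}")


def generate_token_stream(
    lexicon: Lexicon,
    T: int,
    config: GeneratorConfig,
    burst_words: list[str] | None = None,
) -> np.ndarray:
    """Ordered token stream of length T as row indices into the lexicon.

    ``stationary``: i.i.d. multinomial draws with probability proportional
    to frequency. ``early_burst``/``late_burst``: the designated words'
    tokens are confined to the first/last ``burst_fraction`` of the stream
    (positions uniform within that window); all other tokens are shuffled
    over the remaining positions. If ``burst_words`` is not given, the 5%
    of words with the highest ranks (lowest frequencies) among those with
    at least 2 tokens are designated.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = _rng(config, stage=3)
    f = lexicon.frequencies.astype(float)
    if f.sum() <= 0:
        raise ValueError("lexicon has no positive frequencies")
    p = f / f.sum()
    counts = rng.multinomial(T, p)
    tokens = np.repeat(np.arange(len(lexicon)), counts)
    if config.stream_schedule == "stationary":
        rng.shuffle(tokens)
        return tokens
    if config.stream_schedule not in ("early_burst", "late_burst"):
        raise ValueError(f"unknown stream schedule {config.stream_schedule!r}")

    if burst_words is None:
        eligible = [i for i in range(len(lexicon)) if counts[i] >= 2]
        n_burst = max(1, len(lexicon) // 20)
        burst_idx = np.array(eligible[-n_burst:], dtype=np.int64)
    else:
        burst_idx = np.array([lexicon.index_of(w) for w in burst_words],
                             dtype=np.int64)
    is_burst = np.isin(tokens, burst_idx)
    burst_tokens = tokens[is_burst]
    other_tokens = tokens[~is_burst]

    window = max(1, int(np.ceil(config.burst_fraction * T)))
    if config.stream_schedule == "early_burst":
        window_positions = np.arange(window)
    else:
        window_positions = np.arange(T - window, T)
    if burst_tokens.size > window_positions.size:
        raise ValueError(
            f"{burst_tokens.size} burst tokens do not fit in a window of "
            f"{window_positions.size} positions; shrink the burst set or "
            "grow burst_fraction"
        )
    chosen = rng.choice(window_positions, size=burst_tokens.size,
                        replace=False)
    stream = np.empty(T, dtype=np.int64)
    stream.fill(-1)
    rng.shuffle(burst_tokens)
    stream[chosen] = burst_tokens
    rest = np.flatnonzero(stream < 0)
    rng.shuffle(other_tokens)
    stream[rest] = other_tokens
    assert (stream >= 0).all()
    return stream


def generate_priming_design(
    lexicon: Lexicon, n_per_condition: int, seed: int = 0
) -> pd.DataFrame:
    """Prime-target pairs for the four auditory priming conditions.

    ST: prime and target are the same word. S: same segments, different
    tone sequence. T: same tone sequence, different segments. UR: unrelated
    (both differ). Requires tonal forms (e.g. ``chun1``). Raises naming the
    condition when the lexicon cannot supply enough pairs.
    """
    rng = np.random.default_rng(seed)
    segs, tones = {}, {}
    parsed = []
    for i, entry in enumerate(lexicon):
        syl = parse_tonal_transcription(entry.form)
        seg = "".join(s for s, _ in syl)
        tone = "".join(str(t) for _, t in syl)
        parsed.append((entry.word_id, seg, tone))
        segs.setdefault(seg, []).append(i)
        tones.setdefault(tone, []).append(i)

    def sample_pairs(candidates: list[tuple[str, str]], label: str):
        if len(candidates) < n_per_condition:
            raise ValueError(
                f"cannot satisfy condition {label}: only "
                f"{len(candidates)} candidate pairs, need {n_per_condition}"
            )
        picks = rng.choice(len(candidates), size=n_per_condition,
                           replace=False)
        return [candidates[int(k)] for k in picks]

    ids = [w for w, _, _ in parsed]
    st_candidates = [(w, w) for w in ids]

    s_candidates = []
    for group in segs.values():
        for a in group:
            for b in group:
                if a != b and parsed[a][2] != parsed[b][2]:
                    s_candidates.append((ids[a], ids[b]))

    t_candidates = []
    for group in tones.values():
        for a in group:
            for b in group:
                if a != b and parsed[a][1] != parsed[b][1]:
                    t_candidates.append((ids[a], ids[b]))

    ur_candidates = []
    max_tries = 50 * n_per_condition
    for _ in range(max_tries):
        a, b = rng.integers(len(ids)), rng.integers(len(ids))
        if a == b:
            continue
        if parsed[a][1] != parsed[b][1] and parsed[a][2] != parsed[b][2]:
            pair = (ids[int(a)], ids[int(b)])
            if pair not in ur_candidates:
                ur_candidates.append(pair)
        if len(ur_candidates) >= n_per_condition:
            break

    rows = []
    for label, cands in (("ST", st_candidates), ("S", s_candidates),
                         ("T", t_candidates), ("UR", ur_candidates)):
        for prime, target in sample_pairs(cands, label):
            rows.append({"prime": prime, "target": target,
                         "condition": label})
    return pd.DataFrame(rows)
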