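"""Song-syntax models: syllable-sequence statistics, Probability model, Markov model.

A song maps 1:1 to a sequence of 13-type syllable codes.  Two generative
models are compared against observed sequences:

* **Probability model (PM)** — syllable types drawn i.i.d. from the overall
  usage vector *p*; expected run-length law ``P_n = p^n`` (renormalised).
* **first-order Markov model (MM)** — a start vector, a 13 x 13 transition
  matrix and a per-type stop mass.  Because every type can terminate a
  sequence, transition rows do *not* sum to 1: ``sum_j T[i, j] + stop[i] = 1``.
  Expected run-length law ``P_n = r^(n-1) (1 - r)`` with *r* the self-transition
  probability.  Generated sequences are capped at 20 syllables (no recorded
  sequence was longer than 19).

Model fit is scored by summed absolute differences between observed and
model-generated distributions of repeat runs (``d_SUM``), type doublets
(``d_DUPL``) and type triplets (``d_TRIP``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .profiles import TYPE13, GroupProfile

__all__ = [
    "SyntaxModel",
    "SequenceStats",
    "ModelFit",
    "sequence_stats",
    "fit_pm",
    "fit_mm",
    "generate_pm",
    "generate_mm",
    "expected_repeats",
    "expected_ngrams",
    "model_distance",
    "compare_models",
    "profile_syntax_model",
    "read_sequences",
    "write_sequences",
]

MAX_SEQUENCE_LEN = 20


@dataclass
class SyntaxModel:
    """Start vector, transition matrix and stop masses over a type alphabet."""

    alphabet: tuple
    start: np.ndarray
    transition: np.ndarray
    stop: np.ndarray
    max_len: int = MAX_SEQUENCE_LEN
    unobserved: tuple = ()  # types with no occurrences in the fitted corpus

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        self.start = np.asarray(self.start, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        if self.start.shape != (k,) or self.stop.shape != (k,) or self.transition.shape != (k, k):
            raise ValueError("model dimensions do not match alphabet")
        if np.any(self.start < -1e-12) or np.any(self.transition < -1e-12) or np.any(self.stop < -1e-12):
            raise ValueError("negative probability in model")
        if abs(self.start.sum() - 1.0) > 1e-9:
            raise ValueError("start probabilities must sum to 1")
        rowtot = self.transition.sum(axis=1) + self.stop
        ok = np.isclose(rowtot, 1.0, atol=1e-9) | np.isclose(rowtot, 0.0, atol=1e-9)
        if not np.all(ok):
            raise ValueError("each transition row plus its stop mass must sum to 1 (or 0 if unobserved)")

    def index(self, code: str) -> int:
        return self.alphabet.index(code)

    def expected_usage(self) -> np.ndarray:
        """Model-implied type-visit distribution (cap ignored).

        Expected visits per type are ``start . (I - T)^-1``; normalising gives
        the marginal probability that a random emitted syllable is of each type.
        """
        k = len(self.alphabet)
        visits = self.start @ np.linalg.inv(np.eye(k) - self.transition)
        return visits / visits.sum()

    def length_pmf(self) -> np.ndarray:
        """Exact sequence-length distribution P(len = n), n = 1..max_len.

        ``P(len = n) = start . T^(n-1) . stop`` for n < max_len; the residual
        survival mass is assigned to the cap.
        """
        pmf = np.zeros(self.max_len)
        vec = self.start.copy()
        for n in range(1, self.max_len):
            pmf[n - 1] = vec @ self.stop
            vec = vec @ self.transition
        pmf[self.max_len - 1] = max(0.0, 1.0 - pmf.sum())
        return pmf

    def to_json(self, path) -> None:
        obj = {
            "alphabet": list(self.alphabet),
            "start": self.start.tolist(),
            "transition": self.transition.tolist(),
            "stop": self.stop.tolist(),
            "max_len": self.max_len,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntaxModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            alphabet=tuple(obj["alphabet"]),
            start=np.array(obj["start"]),
            transition=np.array(obj["transition"]),
            stop=np.array(obj["stop"]),
            max_len=int(obj.get("max_len", MAX_SEQUENCE_LEN)),
        )


@dataclass
class SequenceStats:
    """Empirical usage, boundary, run-length and n-gram statistics of a corpus."""

    alphabet: tuple
    usage: dict
    start: dict
    stop: dict
    repeat_dist: dict      # type -> {run_length: probability}, normalised per type
    doublet_freqs: dict    # (a, b) -> frequency over all doublet windows
    triplet_freqs: dict    # (a, b, c) -> frequency over all triplet windows
    lengths: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_sequences: int = 0
    n_syllables: int = 0


@dataclass
class ModelFit:
    model_kind: str  # "PM" | "MM"
    d_sum: float
    d_dupl: float
    d_trip: float


def sequence_stats(sequences, alphabet=TYPE13) -> SequenceStats:
    """Usage, start/stop, repeat-run and doublet/triplet statistics of sequences.

    Doublets and triplets are counted with overlapping sliding windows within
    (never across) sequences and normalised by the total window count of that
    order.  Repeat distributions are maximal-run lengths per type, normalised
    per type.
    """
    sequences = [list(s) for s in sequences]
    if not sequences:
        raise ValueError("no sequences")
    aset = set(alphabet)
    for seq in sequences:
        if not seq:
            raise ValueError("empty sequence")
        unknown = set(seq) - aset
        if unknown:
            raise ValueError(f"unknown type codes {sorted(unknown)}")

    usage_counts: dict = {}
    start_counts: dict = {}
    stop_counts: dict = {}
    run_counts: dict = {}
    dup_counts: dict = {}
    trip_counts: dict = {}
    n_dup = n_trip = n_syll = 0
    for seq in sequences:
        start_counts[seq[0]] = start_counts.get(seq[0], 0) + 1
        stop_counts[seq[-1]] = stop_counts.get(seq[-1], 0) + 1
        n_syll += len(seq)
        for c in seq:
            usage_counts[c] = usage_counts.get(c, 0) + 1
        # maximal runs
        i = 0
        while i < len(seq):
            j = i
            while j + 1 < len(seq) and seq[j + 1] == seq[i]:
                j += 1
            run_counts.setdefault(seq[i], {})
            run_len = j - i + 1
            run_counts[seq[i]][run_len] = run_counts[seq[i]].get(run_len, 0) + 1
            i = j + 1
        for a, b in zip(seq, seq[1:]):
            dup_counts[(a, b)] = dup_counts.get((a, b), 0) + 1
            n_dup += 1
        for a, b, c in zip(seq, seq[1:], seq[2:]):
            trip_counts[(a, b, c)] = trip_counts.get((a, b, c), 0) + 1
            n_trip += 1

    nseq = len(sequences)
    repeat_dist = {
        t: {n: c / sum(runs.values()) for n, c in sorted(runs.items())}
        for t, runs in run_counts.items()
    }
    return SequenceStats(
        alphabet=tuple(alphabet),
        usage={t: c / n_syll for t, c in usage_counts.items()},
        start={t: c / nseq for t, c in start_counts.items()},
        stop={t: c / nseq for t, c in stop_counts.items()},
        repeat_dist=repeat_dist,
        doublet_freqs={k: v / n_dup for k, v in dup_counts.items()} if n_dup else {},
        triplet_freqs={k: v / n_trip for k, v in trip_counts.items()} if n_trip else {},
        lengths=np.array([len(s) for s in sequences], dtype=int),
        n_sequences=nseq,
        n_syllables=n_syll,
    )


def fit_pm(stats: SequenceStats) -> np.ndarray:
    """The Probability model: exactly the overall usage vector, in alphabet order."""
    return np.array([stats.usage.get(t, 0.0) for t in stats.alphabet])


def fit_mm(sequences, alphabet=TYPE13, max_len: int = MAX_SEQUENCE_LEN) -> SyntaxModel:
    """Maximum-likelihood first-order Markov model with per-type stop masses.

    ``transition[i, j] = count(i -> j) / count(i)`` and ``stop[i] =
    count(i terminal) / count(i)``, so each row plus its stop sums to 1
    exactly.  Types never observed get a zero row and are flagged in
    ``model.unobserved``.
    """
    sequences = [list(s) for s in sequences]
    if not sequences:
        raise ValueError("no sequences")
    k = len(alphabet)
    idx = {t: i for i, t in enumerate(alphabet)}
    start = np.zeros(k)
    trans = np.zeros((k, k))
    stop = np.zeros(k)
    occ = np.zeros(k)
    for seq in sequences:
        start[idx[seq[0]]] += 1
        for c in seq:
            occ[idx[c]] += 1
        for a, b in zip(seq, seq[1:]):
            trans[idx[a], idx[b]] += 1
        stop[idx[seq[-1]]] += 1
    start /= start.sum()
    seen = occ > 0
    trans[seen] /= occ[seen, None]
    stop[seen] /= occ[seen]
    return SyntaxModel(
        alphabet=tuple(alphabet),
        start=start,
        transition=trans,
        stop=stop,
        max_len=max_len,
        unobserved=tuple(t for t, s in zip(alphabet, seen) if not s),
    )


def generate_pm(p, n_sequences: int, length_law, rng, alphabet=TYPE13,
                max_len: int = MAX_SEQUENCE_LEN) -> list:
    """I.i.d. sequences from usage vector ``p``; lengths from ``length_law``.

    ``length_law`` is either an array of lengths to resample from (e.g. the
    empirical lengths of the fitted corpus) or a callable ``(rng, size) ->
    int array``.
    """
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    if callable(length_law):
        lengths = np.asarray(length_law(rng, n_sequences), dtype=int)
    else:
        pool = np.asarray(length_law, dtype=int)
        lengths = rng.choice(pool, size=n_sequences, replace=True)
    lengths = np.clip(lengths, 1, max_len)
    codes = np.asarray(alphabet, dtype=object)
    return [list(rng.choice(codes, size=n, p=p)) for n in lengths]


def _pick(cum: np.ndarray, r: float) -> int:
    """Index of the first cumulative threshold exceeding r, -1 if past the total."""
    i = int(np.searchsorted(cum, r, side="right"))
    return i if i < cum.size or cum.size == 0 else -1


def generate_mm(model: SyntaxModel, n_sequences: int = 10000, rng=None) -> list:
    """Generate sequences by cumulative-threshold sampling from a Markov model.

    For each step a uniform random number r in [0, 1) walks the cumulative
    transition probabilities of the current type; r landing in the residual
    stop mass terminates the sequence.  A hard cap at ``model.max_len``
    syllables applies regardless of the stop draw.
    """
    if rng is None:
        rng = np.random.default_rng()
    cum_start = np.cumsum(model.start)
    cum_trans = np.cumsum(model.transition, axis=1)
    out = []
    for _ in range(n_sequences):
        r = rng.random()
        i = min(int(np.searchsorted(cum_start, r, side="right")), len(model.alphabet) - 1)
        seq = [model.alphabet[i]]
        while len(seq) < model.max_len:
            r = rng.random()
            row = cum_trans[i]
            j = int(np.searchsorted(row, r, side="right"))
            if j >= row.size or r >= row[-1]:
                break  # landed in the stop mass
            i = j
            seq.append(model.alphabet[i])
        out.append(seq)
    return out


def expected_repeats(model_kind: str, param: float, n_max: int = MAX_SEQUENCE_LEN) -> dict:
    """Closed-form run-length law, truncated at ``n_max`` and renormalised.

    PM: ``P_n propto p^n`` (p = usage probability of the type).
    MM: ``P_n = r^(n-1) (1 - r)`` (r = self-transition probability), a
    geometric law; both are strictly decreasing in n, so neither can place a
    mode at n > 1.
    """
    if not 0.0 <= param <= 1.0:
        raise ValueError("probability parameter must be in [0, 1]")
    n = np.arange(1, n_max + 1, dtype=float)
    if model_kind == "PM":
        if param == 0.0:
            return {1: 1.0}
        w = param ** n
    elif model_kind == "MM":
        if param >= 1.0:
            raise ValueError("degenerate MM: self-transition probability r = 1 never stops")
        w = param ** (n - 1) * (1.0 - param)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    w = w / w.sum()
    return {int(i + 1): float(w[i]) for i in range(n_max)}


def expected_ngrams(model, order: int, alphabet=TYPE13) -> dict:
    """Model-expected doublet (order 2) or triplet (order 3) frequencies.

    PM (``model`` a usage vector): product of marginals, e.g.
    ``p(a>b>c) = p_a p_b p_c``.  MM (``model`` a :class:`SyntaxModel`):
    marginal visit probability times chain transition products,
    ``p(a>b>c) propto usage_a T[a,b] T[b,c]``, normalised over all tuples so
    expected and observed frequency maps are comparable.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if isinstance(model, SyntaxModel):
        alphabet = model.alphabet
        u = model.expected_usage()
        t = model.transition
        if order == 2:
            w = u[:, None] * t
        else:
            w = u[:, None, None] * t[:, :, None] * t[None, :, :]
    else:
        p = np.asarray(model, dtype=float)
        p = p / p.sum()
        if order == 2:
            w = p[:, None] * p[None, :]
        else:
            w = p[:, None, None] * p[None, :, None] * p[None, None, :]
    tot = w.sum()
    if tot <= 0:
        raise ValueError("degenerate model: zero total n-gram mass")
    w = w / tot
    out = {}
    it = np.ndindex(*w.shape)
    for ix in it:
        if w[ix] > 0:
            out[tuple(alphabet[i] for i in ix)] = float(w[ix])
    return out


def _dist_map(obj, which: str) -> dict:
    """Flatten a SequenceStats or a raw map into {key: prob} for one statistic."""
    if isinstance(obj, SequenceStats):
        if which == "repeats":
            return {(t, n): p for t, d in obj.repeat_dist.items() for n, p in d.items()}
        if which == "doublets":
            return dict(obj.doublet_freqs)
        if which == "triplets":
            return dict(obj.triplet_freqs)
        raise ValueError(f"unknown statistic {which!r}")
    if which == "repeats" and obj and isinstance(next(iter(obj.values())), dict):
        return {(t, n): p for t, d in obj.items() for n, p in d.items()}
    return dict(obj)


def model_distance(observed, expected, which: str) -> float:
    """Summed absolute difference between two distributions over the union support.

    ``which`` selects repeats (summed over run lengths and types, d_SUM),
    doublets (d_DUPL) or triplets (d_TRIP).  Zero iff the distributions agree
    on the joint support; symmetric in its arguments.
    """
    o = _dist_map(observed, which)
    e = _dist_map(expected, which)
    keys = set(o) | set(e)
    return float(sum(abs(o.get(k, 0.0) - e.get(k, 0.0)) for k in keys))


def compare_models(sequences, n_generated: int = 10000, rng=None, alphabet=TYPE13) -> dict:
    """Fit PM and MM to a corpus, generate from both, and score all six distances.

    Mirrors the published protocol: 10,000 sequences per model, distances
    computed between the empirical distributions of the generated corpora and
    the observed corpus.
    """
    if rng is None:
        rng = np.random.default_rng()
    obs = sequence_stats(sequences, alphabet=alphabet)
    p = fit_pm(obs)
    mm = fit_mm(sequences, alphabet=alphabet)
    gen_pm_seqs = generate_pm(p, n_generated, obs.lengths, rng, alphabet=alphabet)
    gen_mm_seqs = generate_mm(mm, n_generated, rng)
    pm_stats = sequence_stats(gen_pm_seqs, alphabet=alphabet)
    mm_stats = sequence_stats(gen_mm_seqs, alphabet=alphabet)
    fits = {}
    for kind, gstats in (("PM", pm_stats), ("MM", mm_stats)):
        fits[kind] = ModelFit(
            model_kind=kind,
            d_sum=model_distance(obs, gstats, "repeats"),
            d_dupl=model_distance(obs, gstats, "doublets"),
            d_trip=model_distance(obs, gstats, "triplets"),
        )
    return {
        "observed": obs,
        "pm": p,
        "mm": mm,
        "pm_stats": pm_stats,
        "mm_stats": mm_stats,
        "fits": fits,
    }


DEFAULT_MEAN_SEQUENCE_LEN = 4.5


def _terminal_and_length(start, trans, stop, max_len):
    """Exact terminal-type distribution and mean length, cap included."""
    k = start.size
    term = np.zeros(k)
    mean_len = 0.0
    vec = start.copy()
    for n in range(1, max_len):
        term += vec * stop
        mean_len += n * float(vec @ stop)
        vec = vec @ trans
    term += vec  # sequences hitting the cap end at whatever type they occupy
    mean_len += max_len * float(vec.sum())
    return term, mean_len


_MODEL_CACHE: dict = {}


def profile_syntax_model(profile: GroupProfile, max_len: int = MAX_SEQUENCE_LEN,
                         mean_len: float = DEFAULT_MEAN_SEQUENCE_LEN) -> SyntaxModel:
    """Default Markov model for a group profile (transition matrices unpublished).

    The start vector is the group's start-probability column.  Transition rows
    are quasi-independent, ``T[i, j] = (1 - s_i) u_j`` with ``u`` the usage
    vector, so that emitted types follow the group's usage.  The per-occurrence
    stop masses ``s_i`` are solved so that (a) the model's terminal-type
    distribution (sequence-length cap included) equals the group's published
    per-sequence stop column and (b) the mean sequence length equals
    ``mean_len``.  Terminal-type shares alone do not pin down the overall stop
    scale, so the mean length is a free design parameter; recorded sequences
    ranged from 1 to 19 syllables.  Solved by iterative proportional fitting
    of working stop weights, with the scalar scale rebalanced by bisection at
    each sweep.
    """
    cache_key = (profile.fingerprint(), max_len, mean_len)
    if cache_key in _MODEL_CACHE:
        return _MODEL_CACHE[cache_key]
    start = profile.start_probs
    u = profile.type_probs
    q = profile.stop_probs

    def build(q_work, K):
        s = np.where(q_work > 0, q_work / np.maximum(start + u * K, 1e-12), 0.0)
        s = np.clip(s, 0.0, 0.97)
        trans = (1.0 - s)[:, None] * u[None, :]
        return s, trans

    q_work = q.copy()
    s = trans = None
    for _ in range(60):
        def len_err(logK):
            s_, t_ = build(q_work, np.exp(logK))
            return _terminal_and_length(start, t_, s_, max_len)[1] - mean_len

        lo, hi = np.log(1e-4), np.log(1e5)
        if len_err(lo) > 0:
            K = np.exp(lo)
        elif len_err(hi) < 0:
            K = np.exp(hi)
        else:
            from scipy.optimize import brentq
            K = np.exp(brentq(len_err, lo, hi, xtol=1e-10))
        s, trans = build(q_work, K)
        term, _ = _terminal_and_length(start, trans, s, max_len)
        err = np.max(np.abs(term - q))
        if err < 1e-10:
            break
        ratio = np.where((term > 1e-12) & (q > 0), q / np.maximum(term, 1e-12), 1.0)
        q_work = q_work * np.clip(ratio, 0.2, 5.0)
    model = SyntaxModel(alphabet=TYPE13, start=start, transition=trans, stop=s, max_len=max_len)
    _MODEL_CACHE[cache_key] = model
    return model


def write_sequences(sequences, path) -> None:
    """One sequence per line, whitespace-separated 3-letter type codes."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            fh.write(" ".join(seq) + "\n")


def read_sequences(path) -> list:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(line.split())
    return out
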