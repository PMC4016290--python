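# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `usvsong`.

## Units, conventions and thresholds

Times are milliseconds from recording start, 0-based; syllable and song
intervals are half-open `[onset, offset)`.  Frequencies are kHz.  The
defaults mirror the field's published criteria:

| parameter | default | meaning |
|---|---|---|
| syllable gap | 55 ms | elements separated by *less* than this merge; "at least 55 ms" keeps them distinct |
| song gap | 500 ms | bouts separated by at least this are different songs |
| low-frequency cutoff | 45 kHz | strict: mean frequency exactly 45.0 is kept |
| jump | ≥ 20 kHz in < 4 samples | accumulated over ≤ 3 inter-sample steps; at the 0.5 ms pitch this window is 1.5 ms |
| turn leg | ≥ 0.8 kHz in < 3 ms | both legs of a reversal must qualify |
| slope threshold | 0.05 kHz/ms | Up/Down classification, least-squares slope |
| standardized contour | 50 ms / 80 kHz / 100 points | for DTW clustering |
| sequence cap | 20 syllables | generator hard stop |

The mean frequency used by the 45 kHz filter is the amplitude-weighted
centre of gravity; an unweighted mean is available
(`segment_syllables(..., weighted_mean=False)`) because the original
convention is ambiguous.  The slope is a least-squares fit rather than the
endpoint difference (robust to contour jitter; `endpoint_slope=True` gives
the alternative).

## Event detectors

Jumps: the step sequence of the contour is split into maximal same-sign
runs; a run containing a window of ≤ 3 consecutive steps whose summed change
reaches 20 kHz yields exactly one event, positioned at its largest step —
overlapping qualifying windows collapse to one event per monotone excursion.
Turns: local extrema whose two legs each cover ≥ 0.8 kHz within < 3 ms;
steps already claimed by jump events are masked so no step is counted twice.
Consecutive opposite reversals count separately (a W-shape has three turns).

13-type decisions: early/late is relative to the temporal midpoint, an event
exactly at 0.5 counts as late; two jumps in opposite directions give JUD/JDU
by the first jump's direction; two jumps in the *same* direction fall into
the multi-jump class JPS (the published seven jump labels do not cover this
case); a single turn is TDU when its first leg falls (U-shape), TUD
otherwise.

## DTW validation

Standardization first linearly re-interpolates each contour to 100 points
over 50 ms, then shifts it additively to mean 80 kHz.  The DTW distance is
the classic unit-weight dynamic programme (insertion/deletion/diagonal all
cost the local |Δf|), no warping window, no path normalisation — the value
is the summed kHz difference of the aligned pairs, so two flat contours
1 kHz apart at 100 points are 100 apart.  This matches the description of
summing the distances of individually aligned elements; step patterns that
double-weight the diagonal would double that value.  DTW violates the
triangle inequality; it is used as a pseudo-metric only.  Typology
validation cuts an average-linkage dendrogram of the pairwise DTW matrix at
k = number of labelled types and scores the agreement by the adjusted Rand
index with a label-permutation null (the original analysis reports only that
clustering "was significant" without naming linkage or test; ARI +
permutation is this package's choice).

## Syntax models

Songs map 1:1 to type sequences.  The PM is the usage vector; PM corpora
draw i.i.d. types with sequence lengths resampled from the observed length
distribution (the PM has no stop mechanism of its own).  The MM stores a
start vector, a 13×13 transition matrix and per-type stop masses; since any
type may terminate a sequence, rows sum to 1 only together with their stop
mass.  Generation follows cumulative-threshold sampling: a uniform r walks
the cumulative row; r landing beyond the total transition mass stops the
sequence; a hard cap of 20 syllables applies.  Two stop notions are
deliberately distinct: the *per-sequence* stop column of a group profile is
the distribution of terminal types across songs; the *per-occurrence* stop
mass of the model is the probability that a given occurrence is terminal.

Doublets/triplets are counted in overlapping windows within (never across)
sequences and normalised by the total window count; model-expected n-gram
maps are normalised the same way so the two sides of `d_DUPL`/`d_TRIP` are
comparable, and the repeat distributions entering `d_SUM` are normalised per
type over run lengths.  Distances are summed absolute differences over the
union support — zero iff the distributions agree, symmetric, and at most 2
per normalised distribution.

## The built-in group Markov model

The original transition matrices are not published, so the default model for
a group is quasi-independent: `T[i,j] = (1 − s_i)·u_j` with `u` the usage
vector, i.e. the next type is drawn from usage regardless of the current
type, and only the stop masses `s_i` are type-specific.  The `s_i` are
solved (iterative proportional fitting with the overall scale rebalanced by
bisection, cap-aware) so that the model's terminal-type distribution equals
the group's per-sequence stop column exactly.  The terminal shares do not
identify the overall stop scale — a one-parameter family of models fits
them — so the mean sequence length is an explicit design parameter, set to
4.5 syllables for all groups (recorded sequences ranged from 1 to 19; no
mean is published).

## Synthetic corpus design

**Shape templates.**  Each of the 13 types is a piecewise-linear contour
constructed to satisfy exactly its own defining criteria: ramps at ≥ 0.08
kHz/ms for SUP/SDN (safely past the 0.05 threshold), flat SFL, reversals
flanked by steep legs (~0.9 kHz/ms for ≥ 2.6 ms, i.e. ≥ 2 kHz per leg) for
the turn types, and instantaneous 22–32 kHz steps between flat segments for
the jump types, three alternating steps for JPS.  Contours stay inside
42–122 kHz.  Durations and start frequencies are drawn from truncated
normals whose *truncated* means are solved to equal the group means (naive
truncation would bias, e.g., a 36.5 ± 26 ms duration law by several ms).
Smooth frequency jitter (Gaussian-filtered white noise, SD 0.2 kHz,
correlation 2 ms) is added by default; it is smooth so that it cannot by
itself manufacture 0.8 kHz reversals within 3 ms.  Amplitudes follow a soft
half-sine envelope.

**Song timing.**  The published group means are means over a strongly skewed
song population: 20 syllables/s together with 505.9 ms mean song duration is
geometrically impossible for any single song once gaps are ≥ 55 ms (nine
55 ms gaps alone fill the song), so the published rate mean must be carried
by brief single-syllable songs while the duration mean is carried by long
multi-syllable songs.  The generator therefore draws the type sequence from
the group Markov model and then realises timing as a calibrated mixture:
single-syllable songs use a short chirp-duration law (mean `delta_single`,
~10–25 ms depending on group); multi-syllable songs scale the syllable
duration law by `beta_multi` and target a total duration drawn from a
truncated normal with the published song-duration SD, distributing the
remainder over gaps confined to [55, 500) ms.  The three knobs are solved
per group so that E[duration] and E[syllables/second] simultaneously equal
the published means: an analytic quantile-grid moment solve, then up to two
correction rounds against a timing-only simulation (fixed internal seed)
that absorb the Jensen bias of E[n/duration].  The calibration is a
deterministic function of the profile and is cached.

**Sessions.**  Songs are placed with 0.7–3 s inter-song silences; ~20 kHz
contaminant elements (the exhaling cluster) are interleaved at the
configured rate; with crosstalk enabled a fraction of syllables is mirrored
onto a neighbouring channel with overlapping timing, attenuated amplitude
and ±2 ms offset.  Per-night song counts use a negative binomial matched to
the group mean/SD (counts are far over-dispersed relative to Poisson).

**What the generator does not emulate.**  Real contours are not piecewise
linear; real syllable shapes within a song are serially correlated; jump and
turn *count* means per group (e.g. 2.0 turns per German-female syllable) are
emergent from the templates rather than jointly calibrated with the type
frequencies — no published joint specification exists.  Derived spectral
moments (minimum frequency, band, COG) are likewise emergent.  Tests passing
on this corpus show that the pipeline implements its rules correctly and
recovers the statistics the generator does control (type usage, start/stop
columns, syllable/song durations, rates); they cannot show robustness to
tracker noise, overlapping callers, or real contour shapes.

## Numerical choices and degenerate inputs

Truncated-normal calibration brackets the location parameter adaptively and
solves by Brent's method; probability vectors are renormalised on profile
construction (printed columns sum to 0.98–1.01).  Empty segmentation input
yields empty output; a single-sample trace cannot be standardized (error);
all-zero amplitudes make the COG undefined (error); a type never observed in
a corpus gets a zero Markov row and is flagged.  The fraction-based 3-SE
checks in the test suite guard against multiplicity: ~200 binomial
comparisons at 3 SE are expected to produce ~0.5 chance misses even for a
correct implementation, so 97% must pass and none may exceed 6 SE, with a
small absolute floor absorbing the ~1% of sequences censored by the
20-syllable cap.

## Problem sizes

The test suite and the acceptance script use the original analysis sizes
where stated — 10,000 generated sequences per syntax model, 1,000 syllables
and 500 songs per recovered moment — and smaller corpora (tens of syllables,
a few thousand sequences) for property checks, chosen so the whole suite
runs in a few minutes on one CPU.
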