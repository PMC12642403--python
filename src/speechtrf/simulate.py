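"""Synthetic study generator with known ground truth.

Emulates every input the pipeline consumes at desk scale: a Zipf-frequency
toy lexicon with nontrivial cohorts, a bigram-grammar word corpus laid out
as a forced-alignment-style event table, ground-truth kernels in the span
of the fitting basis, responses generated by convolving those kernels with
the predictor tracks plus band-limited 1/f noise, and multi-subject
group studies with per-group (optionally hemisphere-specific) effect
multipliers.  All generators are pure functions of their arguments and a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import TRFBasis, build_design, standardize
from .cohort import cohort_features
from .features import PredictorTrack, feature_track, onset_tracks
from .lexicon import EventTable, Lexicon
from .sourcespace import GroupDataset, SourceSpace, make_grid_space

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "StudyData",
    "make_lexicon",
    "make_corpus_and_events",
    "make_ground_truth",
    "colored_noise",
    "simulate_responses",
    "simulate_group_study",
    "simulate_improvement_maps",
]


@dataclass
class SimulationSpec:
    """Parameters of a simulated listening study.

    Defaults describe the standard desk-scale study: 5-minute responses at
    100 Hz from 10 sources per hemisphere for three groups of 12
    listeners, speech-like event timing (mean phoneme duration 80 ms) over
    a 40-word Zipf lexicon on a 10-phoneme inventory, kernels with an
    early positive and a late negative peak, and pink noise at unit SNR
    band-limited to the 1-10 Hz analysis band.
    """

    inventory_size: int = 10
    lexicon_size: int = 40
    zipf_exponent: float = 1.0
    n_words: int = 900  # ~300 s at 4 phonemes/word x 80 ms
    phoneme_duration_mean: float = 0.08  # seconds
    phoneme_duration_sd: float = 0.02
    fs: float = 100.0
    kernel_peaks: dict = field(
        default_factory=lambda: {
            "word_onset": [(80.0, 1.0), (350.0, -0.6)],
            "phoneme_onset": [(60.0, 0.8), (250.0, -0.4)],
            "lexical_surprisal": [(110.0, 0.9), (400.0, -0.5)],
        }
    )
    amplitude_jitter: float = 0.1
    noise_exponent: float = 1.0
    noise_band: tuple = (1.0, 10.0)
    snr: float = 1.0
    n_sources_per_hemi: int = 10
    subjects_per_group: dict = field(
        default_factory=lambda: {"English": 12, "Mandarin": 12, "Sinhala": 12}
    )
    effect_multipliers: dict = field(default_factory=dict)
    # group -> (left multiplier, right multiplier); missing groups get (1, 1)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be > 0")
        if min(self.subjects_per_group.values()) < 2:
            raise ValueError("at least 2 subjects per group required")
        for g, (ml, mr) in self.effect_multipliers.items():
            if ml < 0 or mr < 0:
                raise ValueError(f"effect multipliers must be >= 0 ({g})")


@dataclass
class GroundTruth:
    """True kernels (basis coefficients) per predictor and source."""

    coef: np.ndarray  # (n_predictors, n_sources, n_elements)
    predictor_names: tuple[str, ...]
    basis: TRFBasis
    seed: int
    group_multipliers: dict = field(default_factory=dict)

    def kernels(self) -> np.ndarray:
        """(n_predictors, n_sources, n_lags) lag-domain kernels."""
        return self.coef @ self.basis.matrix.T


@dataclass
class StudyData:
    """A complete simulated multi-subject study."""

    spec: SimulationSpec
    lexicon: Lexicon
    events: EventTable
    tracks: list[PredictorTrack]
    space: SourceSpace
    responses: np.ndarray  # (n_subjects, n_samples, n_sources)
    labels: list[str]
    truth: GroundTruth


def make_lexicon(
    inventory_size: int = 10,
    lexicon_size: int = 40,
    zipf_exponent: float = 1.0,
    seed: int = 0,
    min_len: int = 2,
    max_len: int = 6,
) -> Lexicon:
    """Random toy lexicon with Zipf frequencies and shared-prefix pairs.

    Transcription lengths are uniform on [min_len, max_len]; the first two
    words are constructed to share their first phoneme so cohorts are
    never trivially singleton after one phoneme.
    """
    if inventory_size < 2 or lexicon_size < 2:
        raise ValueError("need at least 2 phonemes and 2 words")
    n_forms = sum(inventory_size**l for l in range(min_len, max_len + 1))
    if n_forms < lexicon_size:
        raise ValueError("inventory too small for that many unique words")
    rng = np.random.default_rng(seed)
    inventory = [f"p{i:02d}" for i in range(inventory_size)]
    seen: set[tuple[str, ...]] = set()
    forms: list[tuple[str, ...]] = []

    def draw(prefix: tuple[str, ...] = ()) -> tuple[str, ...]:
        while True:
            length = int(rng.integers(max(min_len, len(prefix) + 1), max_len + 1))
            body = tuple(
                inventory[j]
                for j in rng.integers(0, inventory_size, length - len(prefix))
            )
            form = prefix + body
            if form not in seen:
                seen.add(form)
                return form
    first = draw()
    forms.append(first)
    forms.append(draw(prefix=first[:1]))  # guaranteed shared first phoneme
    while len(forms) < lexicon_size:
        forms.append(draw())
    ranks = np.arange(1, lexicon_size + 1, dtype=float)
    freqs = 1000.0 * ranks ** (-zipf_exponent)
    order = rng.permutation(lexicon_size)  # decouple frequency from form order
    entries = [
        (f"w{i:03d}", forms[i], float(freqs[order[i]]))
        for i in range(lexicon_size)
    ]
    return Lexicon(entries, inventory)


def random_transition_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Row-stochastic bigram word-transition matrix with Dirichlet rows."""
    return rng.dirichlet(np.ones(n), size=n)


def make_corpus_and_events(
    lexicon: Lexicon,
    transition: np.ndarray,
    n_words: int,
    timing: tuple[float, float] = (0.08, 0.02),
    seed: int = 0,
) -> tuple[list[str], EventTable]:
    """Sample a word sequence from a bigram grammar and lay out its phonemes.

    Phoneme durations are gamma-distributed with the given (mean, sd);
    onsets are the cumulative durations.  Returns the word token sequence
    and the event table (total duration = end of the last phoneme).
    """
    transition = np.asarray(transition, dtype=float)
    V = len(lexicon)
    if transition.shape != (V, V):
        raise ValueError("transition matrix must be square over the lexicon")
    if np.any(transition < 0) or not np.allclose(transition.sum(axis=1), 1.0):
        raise ValueError("transition rows must be normalized probabilities")
    mean, sd = timing
    if mean <= 0 or sd <= 0:
        raise ValueError("timing parameters must be positive")
    rng = np.random.default_rng(seed)
    words = lexicon.words
    seq_idx = [int(rng.integers(V))]
    for _ in range(n_words - 1):
        seq_idx.append(int(rng.choice(V, p=transition[seq_idx[-1]])))
    tokens = [words[i] for i in seq_idx]

    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    onsets: list[float] = []
    word_col: list[str] = []
    ph_col: list[str] = []
    init_col: list[bool] = []
    t = 0.0
    for w in tokens:
        for j, ph in enumerate(lexicon.transcription(w)):
            onsets.append(t)
            word_col.append(w)
            ph_col.append(ph)
            init_col.append(j == 0)
            t += float(rng.gamma(shape, scale))
    events = EventTable(
        onset_s=np.array(onsets),
        word=word_col,
        phoneme=ph_col,
        word_initial=np.array(init_col),
        duration=t,
    )
    return tokens, events


def make_ground_truth(
    basis: TRFBasis,
    kernel_peaks: dict,
    n_sources: int,
    seed: int = 0,
    amplitude_jitter: float = 0.1,
) -> GroundTruth:
    """Kernels as sums of basis bumps at stated latencies and amplitudes.

    Peak amplitudes get per-source multiplicative jitter so sources are
    not identical.  Latencies must fall inside the basis window.
    """
    rng = np.random.default_rng(seed)
    names = tuple(kernel_peaks)
    coef = np.zeros((len(names), n_sources, basis.n_elements))
    centers_ms = basis.centers * 1000.0 / basis.fs
    for p, name in enumerate(names):
        for latency_ms, amplitude in kernel_peaks[name]:
            if not basis.tmin_ms <= latency_ms < basis.tmax_ms:
                raise ValueError(
                    f"peak latency {latency_ms} ms outside basis window"
                )
            j = int(np.argmin(np.abs(centers_ms - latency_ms)))
            jitter = 1.0 + amplitude_jitter * rng.standard_normal(n_sources)
            coef[p, :, j] += amplitude * jitter
    return GroundTruth(coef=coef, predictor_names=names, basis=basis, seed=seed)


def colored_noise(
    n: int,
    fs: float,
    exponent: float = 1.0,
    band: tuple | None = (1.0, 10.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, optionally band-limited."""
    rng = rng or np.random.default_rng()
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(len(freqs))
    pos = freqs > 0
    shape[pos] = freqs[pos] ** (-exponent / 2.0)
    if band is not None:
        lo, hi = band
        shape[(freqs < lo) | (freqs > hi)] = 0.0
    spec = shape * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("noise band contains no frequencies for this length")
    return x / sd


def simulate_responses(
    tracks: list[PredictorTrack],
    truth: GroundTruth,
    snr: float | None = 1.0,
    noise_exponent: float = 1.0,
    noise_band: tuple | None = (1.0, 10.0),
    seed: int = 0,
    multiplier: np.ndarray | None = None,
) -> np.ndarray:
    """Responses y = sum_p kernel_ps (*) x_p + colored noise, per source.

    Tracks are standardized before convolution so the true kernels live in
    the same representation the estimator fits.  ``snr=None`` disables
    noise; otherwise noise variance is signal variance / snr per source.
    ``multiplier`` scales the true kernels per source (group effects).
    Returns ``(n_samples, n_sources)``.
    """
    if snr is not None and snr <= 0:
        raise ValueError("SNR must be > 0 (or None for noiseless)")
    if len(tracks) != truth.coef.shape[0]:
        raise ValueError("one track per ground-truth predictor required")
    for t in tracks:
        if t.fs != truth.basis.fs:
            raise ValueError("track rate does not match the ground-truth basis")
    rng = np.random.default_rng(seed)
    n = len(tracks[0])
    n_pred, n_sources, _ = truth.coef.shape
    mult = np.ones(n_sources) if multiplier is None else np.asarray(multiplier)
    signal = np.zeros((n, n_sources))
    for p, track in enumerate(tracks):
        xs, _, _ = standardize(track.values)
        D = build_design(xs, truth.basis)
        signal += D @ (truth.coef[p] * mult[:, None]).T
    if snr is None:
        return signal
    out = np.empty_like(signal)
    for s in range(n_sources):
        noise = colored_noise(n, truth.basis.fs, noise_exponent, noise_band, rng)
        sig_var = signal[:, s].var()
        out[:, s] = signal[:, s] + noise * np.sqrt(sig_var / snr)
    return out


def study_predictors(
    events: EventTable, lexicon: Lexicon, names: tuple[str, ...], fs: float
) -> list[PredictorTrack]:
    """Build the named predictor tracks for a simulated study.

    Supports the onset tracks plus lexical-context feature tracks (the
    generator's default feature battery).
    """
    word_t, phon_t = onset_tracks(events, fs)
    tracks: dict[str, PredictorTrack] = {
        "word_onset": word_t,
        "phoneme_onset": phon_t,
    }
    lexical_names = {
        "lexical_surprisal": "surprisal",
        "lexical_phoneme_entropy": "phoneme_entropy",
        "lexical_cohort_entropy": "cohort_entropy",
    }
    if any(n in lexical_names for n in names):
        feats = cohort_features(events, lexicon, prior_mode="frequency")
        for name, attr in lexical_names.items():
            if name in names:
                tracks[name] = feature_track(
                    events, getattr(feats, attr), fs, name
                )
    missing = [n for n in names if n not in tracks]
    if missing:
        raise ValueError(f"unknown study predictors: {missing}")
    return [tracks[n] for n in names]


def simulate_group_study(spec: SimulationSpec) -> StudyData:
    """Full multi-subject study: shared stimulus, per-subject noisy responses.

    All subjects hear the same stimulus (the same event table and
    predictor tracks, as in a fixed audiobook); each subject gets
    independent noise, and each group's true kernels are scaled by its
    (left, right) effect multipliers.  Bit-identical for a fixed spec.
    """
    seed = spec.master_seed
    lexicon = make_lexicon(
        spec.inventory_size, spec.lexicon_size, spec.zipf_exponent, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    transition = random_transition_matrix(len(lexicon), rng)
    _, events = make_corpus_and_events(
        lexicon,
        transition,
        spec.n_words,
        (spec.phoneme_duration_mean, spec.phoneme_duration_sd),
        seed=seed + 2,
    )
    from .basis import make_basis

    basis = make_basis(fs=spec.fs)
    names = tuple(spec.kernel_peaks)
    tracks = study_predictors(events, lexicon, names, spec.fs)
    space = make_grid_space(spec.n_sources_per_hemi)
    n_sources = space.n_sources
    truth = make_ground_truth(
        basis, spec.kernel_peaks, n_sources, seed=seed + 3,
        amplitude_jitter=spec.amplitude_jitter,
    )
    truth.group_multipliers = dict(spec.effect_multipliers)

    labels: list[str] = []
    for g, n_subj in spec.subjects_per_group.items():
        labels.extend([g] * n_subj)
    n_samples = len(tracks[0])
    responses = np.empty((len(labels), n_samples, n_sources))
    left = space.hemisphere == "L"
    for i, g in enumerate(labels):
        ml, mr = spec.effect_multipliers.get(g, (1.0, 1.0))
        mult = np.where(left, ml, mr)
        responses[i] = simulate_responses(
            tracks,
            truth,
            snr=spec.snr,
            noise_exponent=spec.noise_exponent,
            noise_band=spec.noise_band,
            seed=seed + 100 + i,
            multiplier=mult,
        )
    return StudyData(
        spec=spec,
        lexicon=lexicon,
        events=events,
        tracks=tracks,
        space=space,
        responses=responses,
        labels=labels,
        truth=truth,
    )


def simulate_improvement_maps(
    space: SourceSpace,
    subjects_per_group: dict,
    base_effect: float = 0.0,
    noise_sd: float = 1.0,
    effect_multipliers: dict | None = None,
    seed: int = 0,
) -> GroupDataset:
    """Per-subject improvement maps drawn directly at the statistics layer.

    Each subject's map is ``base_effect x hemisphere multiplier + noise``;
    with all multipliers 1 and ``base_effect=0`` the groups are fully
    exchangeable (null calibration); hemisphere-specific multipliers mimic
    lateralized effects for LI-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    effect_multipliers = effect_multipliers or {}
    left = space.hemisphere == "L"
    labels: list[str] = []
    maps = []
    for g, n_subj in subjects_per_group.items():
        ml, mr = effect_multipliers.get(g, (1.0, 1.0))
        mean = base_effect * np.where(left, ml, mr)
        for _ in range(n_subj):
            maps.append(mean + noise_sd * rng.standard_normal(space.n_sources))
            labels.append(g)
    return GroupDataset(np.array(maps), labels, space)
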