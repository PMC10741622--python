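"""Synthetic exam-cohort generator with known ground truth.

No public recording of the oral-exam study exists, so every downstream
stage is exercised on simulated cohorts: two groups (experienced
fellows vs novice residents, n=8 each) recorded on the 14-channel
montage at 256 Hz over an 18-minute exam preceded by a 3-minute
eyes-open baseline.

Signal model
------------
Each channel is 1/f^alpha background noise (alpha=1) band-limited to the
headset's 0.2-45 Hz passband, plus — on posterior channels — an
independent low-amplitude 10 Hz alpha rhythm.  Designed functional
connectivity is produced by a power-preserving mixture of shared
band-limited sources: inside a coupled band, channel c's spectrum is

    X_c(f) = A(f) * [ sqrt(1 - sum_k rho_ck) * eps_c(f)
                      + sum_k sqrt(rho_ck) * S_k(f) ]

where A(f) is the common 1/f amplitude profile, eps_c is private noise
and S_k are unit-variance shared sources.  rho_ck is the coherent
fraction of channel c's power carried by source k, so the theoretical
coherence of a pair (c, d) coupled through source k is exactly

    gamma2_cd(f) = rho_ck * rho_dk

and the per-bin power spectral density is A(f)^2 regardless of the
coupling — connectivity differences leave the PSD untouched, matching
an expertise effect that appears in coherence but not in power.  The
symmetric split rho = sqrt(gamma2) hits any target in [0, 1); a target
of exactly 1 is unattainable with nonzero private noise and rejected.
When one channel serves several same-band effects the per-channel load
sum_k rho_ck is capped below 1 (independent shared sources cannot give
one channel more total coherent fraction than its whole variance); the
allocator rescales overloaded channels, recovers what it can through
partner slack, and records the realized products as ground truth.
The coupled band extends one 1-Hz bin past the analysis band so that
spectral smearing of the Kaiser analysis window does not dilute the
band-edge bins.

Roughly 10% of exam-task epochs receive a 0.5-s, ~500 µV raised-cosine
transient emulating head/muscle movement; the contaminated epoch indices
are recorded as ground truth so the artifact detector can be scored.

Behavioral outcomes (checklist performance, NASA-TLX, two raters) are
linear functions of named normalized EEG features plus Gaussian noise,
giving the model-recovery stages a known sparse truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import (CHANNELS, MARKER_TO_TASK, POSTERIOR_CHANNELS,
                      TASK_TO_MARKER, channel_index, normalize_marker, pair_name)
from .recording import Recording
from .spectral import DEFAULT_BANDS, band_by_name

GROUPS = ("novice", "experienced")
_GROUP_CODE = {"novice": 0, "experienced": 1}

#: Hardware analog passband of the headset (Hz).
PASSBAND = (0.2, 45.0)


@dataclass(frozen=True)
class Effect:
    """A designed group difference in band coherence at one channel pair."""

    pair: tuple[str, str]
    band: str
    task: str
    experienced: float
    novice: float

    def target(self, group: str) -> float:
        return self.experienced if group == "experienced" else self.novice


#: Designed effects: the study's significant coherence contrasts
#: (group mean coherence, experienced vs novice) across the three exam
#: phases.
DEFAULT_EFFECTS: tuple[Effect, ...] = (
    Effect(("FC5", "FC6"), "theta", "reading", 0.13, 0.52),
    Effect(("P7", "F8"), "theta", "reading", 0.30, 0.03),
    Effect(("F7", "FC6"), "alpha", "reading", 0.19, 0.52),
    Effect(("FC5", "FC6"), "alpha", "reading", 0.20, 0.51),
    Effect(("O1", "T8"), "gamma", "reading", 0.11, 0.41),
    Effect(("P8", "F8"), "gamma", "reading", 0.68, 0.32),
    Effect(("F7", "F8"), "theta", "answer1", 0.40, 0.14),
    Effect(("F7", "F8"), "beta", "answer1", 0.53, 0.27),
    Effect(("F7", "F8"), "gamma", "answer1", 0.51, 0.22),
    Effect(("P7", "T8"), "gamma", "answer1", 0.17, 0.50),
    Effect(("F3", "T7"), "beta", "answer2", 0.11, 0.40),
    Effect(("F3", "T7"), "gamma", "answer2", 0.06, 0.44),
    Effect(("O1", "T8"), "gamma", "answer2", 0.07, 0.34),
    Effect(("O1", "FC6"), "gamma", "answer2", 0.05, 0.31),
    Effect(("O1", "F4"), "gamma", "answer2", 0.15, 0.46),
    Effect(("O1", "AF4"), "gamma", "answer2", 0.05, 0.30),
)


@dataclass(frozen=True)
class Background:
    """Per-channel background spectrum parameters."""

    one_over_f_exponent: float = 1.0
    amplitude_uv: float = 20.0        # broadband RMS of the 1/f background
    alpha_osc_uv: float = 6.0         # RMS of the posterior 10 Hz rhythm
    alpha_osc_freq: float = 10.0
    alpha_osc_width: float = 0.6      # Gaussian half-width (Hz)


@dataclass(frozen=True)
class BehaviorModel:
    """Linear link from normalized EEG features to behavioral outcomes.

    Coefficients act on normalized (0-1) feature values; performance and
    TLX are on the 0-1 fraction scale before clipping.  Defaults are
    chosen so group means land near the study conditions: experienced
    ~93% vs novice ~54% checklist performance, and group-neutral
    cognitive load around 0.6-0.66.
    """

    performance_intercept: float = 0.70
    performance_terms: dict[str, float] = field(default_factory=lambda: {
        "answer1.beta.coh.F7-F8": 0.30,
        "reading.theta.coh.FC5-FC6": -0.22,
    })
    tlx_intercept: float = 0.594
    tlx_terms: dict[str, float] = field(default_factory=lambda: {
        "answer1.theta.coh.F4-F8": 0.168,
        "answer2.theta.coh.F7-AF4": -0.253,
        "answer2.alpha.psd.F3": 0.123,
    })
    noise_sd: float = 0.05            # fraction-scale outcome noise
    n_checklist_items: int = 20
    checklist_weights: tuple[float, ...] | None = None   # None -> all 1
    rater_flip_prob: float = 0.10     # chance a rater mis-scores an item by 1
    tlx_subscale_jitter: float = 1.0  # zero-sum spread across subscales (0-20 units)


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_per_group: int = 8
    sampling_rate: float = 256.0
    segment_plan: tuple[tuple[str, float], ...] = (
        ("eyes open", 180.0), ("reading", 180.0),
        ("answer 1", 720.0), ("answer 2", 180.0),
    )
    effect_table: tuple[Effect, ...] = DEFAULT_EFFECTS
    background: Background = field(default_factory=Background)
    artifact_rate: float = 0.10
    coupling_jitter_sd: float = 0.05
    behavior_model: BehaviorModel = field(default_factory=BehaviorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        for label, dur in self.segment_plan:
            if dur <= 0:
                raise ValueError(f"segment '{label}' has non-positive duration")
            if normalize_marker(label) not in MARKER_TO_TASK:
                raise ValueError(f"unknown segment label {label!r}")
        tasks = {MARKER_TO_TASK[normalize_marker(lab)] for lab, _ in self.segment_plan}
        seen: set[tuple[str, str, str]] = set()
        for e in self.effect_table:
            a, b = e.pair
            if a == b:
                raise ValueError(f"effect pair {e.pair} must be two distinct channels")
            channel_index(a), channel_index(b)  # raises for non-montage names
            band_by_name(e.band)                # raises for unknown band
            if e.task not in tasks:
                raise ValueError(f"effect targets task {e.task!r} absent from plan")
            for g, t in (("experienced", e.experienced), ("novice", e.novice)):
                if not 0.0 <= t <= 1.0:
                    raise ValueError(f"coherence target {t} ({g}) outside [0, 1]")
                if t >= 1.0:
                    raise ValueError(
                        "coherence target of exactly 1 is unattainable with "
                        "nonzero channel noise")
            key = (pair_name(a, b), e.band, e.task)
            if key in seen:
                raise ValueError(f"overlapping effect entries for {key}")
            seen.add(key)

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segment_plan)


@dataclass
class GroundTruth:
    """What the generator actually put into one participant's recording."""

    participant: str
    group: str
    #: (task, band, pair-name) -> realized band coherence target in [0, 1).
    coupling: dict[tuple[str, str, str], float] = field(default_factory=dict)
    #: (task, epoch-index-within-task) of contaminated 1-s epochs.
    artifact_epochs: list[tuple[str, int]] = field(default_factory=list)


def _spectrum_amplitude(freqs: np.ndarray, background: Background) -> np.ndarray:
    """1/f^(alpha/2) amplitude profile, zero outside the passband."""
    amp = np.zeros_like(freqs)
    inband = (freqs >= PASSBAND[0]) & (freqs <= PASSBAND[1])
    amp[inband] = freqs[inband] ** (-background.one_over_f_exponent / 2.0)
    return amp


def _complex_noise(rng: np.random.Generator, shape) -> np.ndarray:
    # complex64 is plenty for simulation and halves generation cost
    if np.isscalar(shape):
        shape = (shape,)
    z = rng.standard_normal((2, *shape), dtype=np.float32)
    return ((z[0] + 1j * z[1]) / np.float32(np.sqrt(2))).astype(np.complex64)


#: Maximum total coherent fraction a single channel may carry in one
#: band; keeps a little private noise in every channel.
_LOAD_CAP = 0.97


def _allocate_coherent_fractions(
        pairs: list[tuple[str, str]], gamma2: list[float],
        cap: float = _LOAD_CAP) -> list[tuple[float, float]]:
    """Per-channel coherent fractions realizing pairwise targets.

    Starts from the symmetric split rho = sqrt(gamma2) on both
    endpoints; channels whose summed load exceeds ``cap`` are rescaled,
    after which each under-target pair recovers as much as possible
    through slack on its partner channel.  Returns (rho_c, rho_d) per
    pair; the realized coherence is their product.
    """
    rho = [[float(np.sqrt(g)), float(np.sqrt(g))] for g in gamma2]

    def loads() -> dict[str, float]:
        out: dict[str, float] = {}
        for (c, d), r in zip(pairs, rho):
            out[c] = out.get(c, 0.0) + r[0]
            out[d] = out.get(d, 0.0) + r[1]
        return out

    load = loads()
    scale = {ch: min(1.0, cap / l) for ch, l in load.items() if l > 0}
    for (c, d), r in zip(pairs, rho):
        r[0] *= scale.get(c, 1.0)
        r[1] *= scale.get(d, 1.0)
    load = loads()
    for k, ((c, d), g) in enumerate(zip(pairs, gamma2)):
        for me, other, ch in ((0, 1, d), (1, 0, c)):
            prod = rho[k][0] * rho[k][1]
            if prod < g - 1e-12 and rho[k][me] > 0:
                want = g / rho[k][me] - rho[k][other]
                add = min(max(cap - load[ch], 0.0), max(want, 0.0))
                rho[k][other] += add
                load[ch] += add
    return [(r[0], r[1]) for r in rho]


#: The coupled band extends this many 1-Hz bins past the analysis band:
#: half the Kaiser (beta=8) analysis window's main lobe, so band-edge
#: bins keep their designed coherent fraction after spectral smearing.
_BAND_GUARD_HZ = 2.0


def _coupling_bins(freqs: np.ndarray, effect: Effect,
                   same_pair_bands: list[str]) -> np.ndarray:
    """Bins carrying the shared source for one effect.

    The analysis band extended by the window guard on each side (inside
    the passband), minus the analysis bins of any *other* effect on the
    same pair and task, so adjacent designed bands do not contaminate
    each other.
    """
    band = band_by_name(effect.band)
    lo = max(PASSBAND[0], band.lo - _BAND_GUARD_HZ)
    hi = min(PASSBAND[1], band.hi + _BAND_GUARD_HZ)
    sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    for other in same_pair_bands:
        if other == effect.band:
            continue
        ob = band_by_name(other)
        sel &= ~((freqs >= ob.lo - 1e-9) & (freqs <= ob.hi + 1e-9))
    return sel


def simulate_recording(config: CohortConfig, participant_index: int,
                       group: str) -> tuple[Recording, GroundTruth]:
    """Generate one participant's full-session recording (artifact-free).

    Deterministic given ``(config.seed, participant_index, group)``.
    Artifact transients are added separately by :func:`inject_artifacts`
    so the clean signal remains available to tests.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    fs = config.sampling_rate
    bg = config.background
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, participant_index,
                                _GROUP_CODE[group]]))
    pid = f"{'exp' if group == 'experienced' else 'nov'}{participant_index + 1:02d}"
    truth = GroundTruth(participant=pid, group=group)

    # Per-participant coherence targets (group target + jitter); the
    # allocator below may lower them where one channel carries several
    # same-band effects, and the realized products go into GroundTruth.
    targets: dict[tuple[str, str, str], float] = {}
    for e in config.effect_table:
        g = e.target(group)
        if config.coupling_jitter_sd > 0:
            g = float(np.clip(g + rng.normal(0.0, config.coupling_jitter_sd),
                              0.005, 0.98))
        targets[(e.task, e.band, pair_name(*e.pair))] = g

    posterior_idx = [channel_index(c) for c in POSTERIOR_CHANNELS]
    segments: list[np.ndarray] = []
    markers: list[tuple[str, float]] = []
    t0 = 0.0
    for label, dur in config.segment_plan:
        task = MARKER_TO_TASK[normalize_marker(label)]
        n = int(round(dur * fs))
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        amp = _spectrum_amplitude(freqs, bg)

        amp32 = amp.astype(np.float32)
        eps = _complex_noise(rng, (len(CHANNELS), len(freqs)))

        # Shared band-limited sources implementing the designed coherence
        # as a power-preserving mixture.
        task_effects = [e for e in config.effect_table if e.task == task]
        coh_amp = np.zeros((len(CHANNELS), len(freqs)), dtype=np.complex64)
        load = np.zeros((len(CHANNELS), len(freqs)), dtype=np.float32)
        by_band: dict[str, list[Effect]] = {}
        for e in task_effects:
            by_band.setdefault(e.band, []).append(e)
        for effs in by_band.values():
            g2 = [targets[(task, e.band, pair_name(*e.pair))] for e in effs]
            rhos = _allocate_coherent_fractions([e.pair for e in effs], g2)
            for e, (rc, rd) in zip(effs, rhos):
                same_pair = [o.band for o in task_effects
                             if pair_name(*o.pair) == pair_name(*e.pair)]
                sel = _coupling_bins(freqs, e, same_pair)
                shared = _complex_noise(rng, int(sel.sum()))
                for ch, r in zip(e.pair, (rc, rd)):
                    ci = channel_index(ch)
                    coh_amp[ci][sel] += np.sqrt(np.float32(r)) * shared
                    load[ci][sel] += np.float32(r)
                truth.coupling[(task, e.band, pair_name(*e.pair))] = rc * rd

        # Total per-bin power stays A(f)^2; in the rare case extension
        # bins of different bands overlap on one channel the mixture is
        # renormalized there.
        Z = amp32 * (np.sqrt(np.clip(1.0 - load, 0.0, None)) * eps
                     + coh_amp / np.sqrt(np.maximum(load, 1.0)))

        def spectrum_var(profile: np.ndarray) -> float:
            # Time-domain variance of irfft of unit-complex noise shaped
            # by `profile` (Hermitian symmetry accounted for).
            return float(2.0 * np.sum(profile[1:-1] ** 2)
                         + profile[0] ** 2 + profile[-1] ** 2) / n ** 2

        base_rms = np.sqrt(spectrum_var(amp))
        scale = bg.amplitude_uv / base_rms

        # Posterior resting alpha rhythm, independent per channel, with
        # RMS alpha_osc_uv after the final scaling.
        gauss = np.exp(-0.5 * ((freqs - bg.alpha_osc_freq)
                               / bg.alpha_osc_width) ** 2)
        gauss[amp == 0.0] = 0.0
        g_rms = np.sqrt(spectrum_var(gauss))
        if g_rms > 0:
            support = gauss > 1e-8
            osc = (gauss[support]
                   * (bg.alpha_osc_uv / (scale * g_rms))).astype(np.float32)
            for ci in posterior_idx:
                Z[ci][support] += _complex_noise(rng, int(support.sum())) * osc

        x = np.fft.irfft(Z, n=n, axis=1)
        # Scale so the 1/f background alone has RMS = amplitude_uv.
        x *= scale
        segments.append(x)
        markers.append((TASK_TO_MARKER[task], t0))
        t0 += n / fs

    rec = Recording(
        channel_labels=CHANNELS,
        sampling_rate=fs,
        data=np.concatenate(segments, axis=1),
        markers=markers,
        meta={"participant": pid, "group": group, "seed": config.seed,
              "participant_index": participant_index},
    )
    return rec, truth


#: Artifact transient parameters: 0.5-s raised cosine, ~500 µV peak,
#: emulating head/muscle movement.
ARTIFACT_DURATION_S = 0.5
ARTIFACT_PEAK_UV = 500.0

#: Tasks receiving artifacts (the baseline rest period stays clean; the
#: movement artifacts occur during the exam itself).
ARTIFACT_TASKS = ("reading", "answer1", "answer2")


def inject_artifacts(recording: Recording, rate: float,
                     seed: int) -> tuple[Recording, list[tuple[str, int]]]:
    """Contaminate a fraction of exam-task 1-s epochs with transients.

    Each selected epoch receives a raised-cosine burst (peak ~500 µV,
    at least 5x the background SD) on every channel, fully contained in
    that epoch.  Returns the contaminated copy and the sorted list of
    (task, epoch_index) hit.  ``rate=0`` returns an unmodified copy.
    """
    from .preprocess import segment_tasks

    if not 0.0 <= rate < 1.0:
        raise ValueError("artifact rate must be in [0, 1)")
    out = recording.copy()
    if rate == 0.0:
        return out, []

    rng = np.random.default_rng(seed)
    fs = recording.sampling_rate
    n_ep_samp = int(round(fs))
    bounds = segment_tasks(recording)
    slots: list[tuple[str, int, int]] = []   # (task, epoch idx, sample offset)
    for task in ARTIFACT_TASKS:
        start, end = bounds[task]
        n_ep = int(np.floor((end - start) * fs + 1e-9)) // n_ep_samp
        i0 = int(round(start * fs))
        slots.extend((task, k, i0 + k * n_ep_samp) for k in range(n_ep))

    n_hit = int(round(rate * len(slots)))
    chosen = rng.choice(len(slots), size=n_hit, replace=False)
    n_burst = int(round(ARTIFACT_DURATION_S * fs))
    burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n_burst) / n_burst))
    hit: list[tuple[str, int]] = []
    for idx in sorted(chosen):
        task, ep, samp0 = slots[idx]
        offset = rng.integers(0, n_ep_samp - n_burst + 1)
        sign = rng.choice((-1.0, 1.0))
        scale = ARTIFACT_PEAK_UV * rng.uniform(0.8, 1.2, size=out.n_channels)
        out.data[:, samp0 + offset: samp0 + offset + n_burst] += (
            sign * scale[:, None] * burst[None, :])
        hit.append((task, ep))
    return out, hit


@dataclass
class BehaviorTruth:
    """True linear model behind the simulated behavioral outcomes."""

    performance_intercept: float
    performance_terms: dict[str, float]
    tlx_intercept: float
    tlx_terms: dict[str, float]
    performance_true: pd.Series = None  # type: ignore[assignment]
    tlx_true: pd.Series = None          # type: ignore[assignment]


TLX_SUBSCALES = ("mental", "physical", "temporal", "performance_demand",
                 "effort", "frustration")


def simulate_behavior(config: CohortConfig, features,
                      seed: int) -> tuple[pd.DataFrame, BehaviorTruth]:
    """Simulate checklist and NASA-TLX data linked to EEG features.

    ``features`` must be a normalized-stage combined
    :class:`~examcoh.features.FeatureTable` containing every feature
    named in ``config.behavior_model``.  Returns a behavioral table (one
    row per participant: group, six TLX subscales on 0-20, and both
    raters' per-item checklist ratings in {0,1,2}) plus the generating
    truth.
    """
    bm = config.behavior_model
    rng = np.random.default_rng(seed)
    x = features.values
    for name in list(bm.performance_terms) + list(bm.tlx_terms):
        if name not in x.columns:
            raise ValueError(f"behavior model names unknown feature {name!r}")

    def linear(intercept: float, terms: dict[str, float]) -> pd.Series:
        y = pd.Series(intercept, index=x.index, dtype=float)
        for name, coef in terms.items():
            y = y + coef * x[name]
        return y

    perf = linear(bm.performance_intercept, bm.performance_terms)
    perf = (perf + rng.normal(0.0, bm.noise_sd, len(perf))).clip(0.0, 1.0)
    tlx = linear(bm.tlx_intercept, bm.tlx_terms)
    tlx = (tlx + rng.normal(0.0, bm.noise_sd, len(tlx))).clip(0.0, 1.0)

    rows = []
    for pid in x.index:
        row: dict[str, object] = {"participant": pid,
                                  "group": str(features.groups.loc[pid])}
        total = float(tlx.loc[pid]) * 120.0
        jitter = rng.normal(0.0, bm.tlx_subscale_jitter, len(TLX_SUBSCALES))
        jitter -= jitter.mean()
        for sub, j in zip(TLX_SUBSCALES, jitter):
            row[f"tlx_{sub}"] = float(np.clip(total / 6.0 + j, 0.0, 20.0))

        true_items = rng.binomial(2, float(perf.loc[pid]),
                                  size=bm.n_checklist_items)
        for rater in (1, 2):
            seen = true_items.copy()
            flips = rng.random(bm.n_checklist_items) < bm.rater_flip_prob
            steps = rng.choice((-1, 1), size=bm.n_checklist_items)
            seen[flips] = np.clip(seen[flips] + steps[flips], 0, 2)
            for i, v in enumerate(seen):
                row[f"rater{rater}_item{i + 1:02d}"] = int(v)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("participant")
    truth = BehaviorTruth(
        performance_intercept=bm.performance_intercept,
        performance_terms=dict(bm.performance_terms),
        tlx_intercept=bm.tlx_intercept,
        tlx_terms=dict(bm.tlx_terms),
        performance_true=perf,
        tlx_true=tlx,
    )
    return table, truth


@dataclass
class Cohort:
    """A complete simulated study: recordings, groups and ground truth."""

    config: CohortConfig
    recordings: dict[str, Recording]
    groups: dict[str, str]
    ground_truth: dict[str, GroundTruth]


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate all participants of both groups, artifacts included."""
    recordings: dict[str, Recording] = {}
    groups: dict[str, str] = {}
    truths: dict[str, GroundTruth] = {}
    for group in GROUPS:
        for i in range(config.n_per_group):
            rec, truth = simulate_recording(config, i, group)
            art_seed = int(np.random.SeedSequence(
                [config.seed & 0x7FFFFFFF, 1000 + i,
                 _GROUP_CODE[group]]).generate_state(1)[0] & 0x7FFFFFFF)
            rec, hit = inject_artifacts(rec, config.artifact_rate, art_seed)
            truth.artifact_epochs = hit
            pid = truth.participant
            recordings[pid] = rec
            groups[pid] = group
            truths[pid] = truth
    return Cohort(config=config, recordings=recordings, groups=groups,
                  ground_truth=truths)
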