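"""Synthetic labeled 12-lead ECG generator.

Records are built from *electrode potentials*, not from leads directly: each
of the nine non-ground electrodes (RA, LA, LL, RL, V1..V6 positions) carries
a potential trace synthesised as a train of Gaussian waves (P, Q, R, S, T)
per beat, and the 12 leads are then formed by the standard lead algebra

    I = LA - RA          aVR = RA - (LA + LL)/2
    II = LL - RA         aVL = LA - (RA + LL)/2
    III = LL - LA        aVF = LL - (RA + LA)/2
    Vi = vi - (RA + LA + LL)/3            (Wilson central terminal)

Building leads from potentials makes two things exact by construction:
Einthoven's identity (I + III = II), Goldberger's identity
(aVR + aVL + aVF = 0), and — crucial for the wearing-situation simulator —
electrode misplacement becomes a literal permutation of potentials followed
by the same lead algebra, so lead-reversal ground truth is algebraically
exact rather than approximated.

The label space is a deliberately small surrogate catalog of seven
rhythm/morphology classes (NORM, TACHY, BRADY, IRREG_RR, WIDE_BEAT,
ST_SHIFT, LOW_VOLT) whose distinguishing features a classifier can learn
from short records: heart rate, RR regularity, QRS width, ST-segment offset
and overall voltage.  This is a simulation device for testing the pipeline,
not a physiological model of real arrhythmias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (CANONICAL_LEADS, DatasetManifest, EcgRecord, LabelCatalog,
                 ManifestEntry, MultiLabelAnnotation, split_by_subject,
                 write_record)

SYNTHETIC_CLASSES: tuple[str, ...] = (
    "NORM", "TACHY", "BRADY", "IRREG_RR", "WIDE_BEAT", "ST_SHIFT", "LOW_VOLT",
)

#: long-tail default prevalences; NORM excludes all abnormal classes.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "NORM": 0.40, "TACHY": 0.20, "BRADY": 0.15, "IRREG_RR": 0.15,
    "WIDE_BEAT": 0.12, "ST_SHIFT": 0.10, "LOW_VOLT": 0.06,
}

WEARING_SITUATIONS: tuple[str, ...] = (
    "normal", "UL_left_right", "upper_lower", "left_upper_lower",
    "right_upper_lower", "chest",
)

ELECTRODES: tuple[str, ...] = ("RA", "LA", "LL", "RL",
                               "v1", "v2", "v3", "v4", "v5", "v6")

#: electrode-swap map per wearing situation (RL is the driven ground; a limb
#: reversal that involves it routes the near-indifferent RL potential into a
#: limb input, which is what physically happens with cable swaps).
_SITUATION_SWAPS: dict[str, list[tuple[str, str]]] = {
    "normal": [],
    "UL_left_right": [("LA", "RA")],
    "upper_lower": [("RA", "RL"), ("LA", "LL")],
    "left_upper_lower": [("LA", "LL")],
    "right_upper_lower": [("RA", "RL")],
}
#: chest reversal permutes V1..V6 -> V6..V1 (configurable convention).
CHEST_REVERSAL: tuple[str, ...] = ("v6", "v5", "v4", "v3", "v2", "v1")


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic dataset."""

    n_records: int = 100
    fs: float = 500.0
    duration_s: float = 15.0
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    hr_range: tuple[float, float] = (60.0, 95.0)
    artifact_levels: dict[str, dict] = field(default_factory=dict)
    records_per_subject: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        for cls, p in self.class_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {cls} outside [0,1]")
            if cls not in SYNTHETIC_CLASSES:
                raise ValueError(f"unknown synthetic class {cls!r}")


@dataclass
class GroundTruth:
    """Per-record generation truth: R peaks, labels, wearing situation and
    the raw electrode potentials the leads were computed from."""

    r_peaks: np.ndarray
    labels: MultiLabelAnnotation
    wearing_situation: str = "normal"
    heart_rate_bpm: float = 0.0
    potentials: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")


# ---------------------------------------------------------------------------
# beat model

@dataclass
class BeatModel:
    """Gaussian wave parameters per electrode.

    ``waves`` maps wave name -> (center offset s relative to the R peak,
    width s).  ``amplitudes`` maps electrode -> per-wave amplitude in mV.
    Amplitudes are chosen so the LL-RA projection (lead II) is R-dominant
    with upright P and T, and the chest potentials show the usual V1->V6
    R-wave progression.
    """

    waves: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "P": (-0.170, 0.022), "Q": (-0.024, 0.009), "R": (0.0, 0.011),
        "S": (0.024, 0.010), "T": (0.230, 0.055),
    })
    amplitudes: dict[str, dict[str, float]] = field(default_factory=lambda: {
        #           P       Q       R       S       T
        "RA": {"P": -0.08, "Q": 0.03, "R": -0.55, "S": 0.08, "T": -0.15},
        "LA": {"P": 0.02, "Q": -0.02, "R": 0.10, "S": -0.09, "T": 0.08},
        "LL": {"P": 0.07, "Q": -0.07, "R": 0.65, "S": -0.17, "T": 0.18},
        "RL": {"P": 0.01, "Q": 0.00, "R": 0.05, "S": -0.01, "T": 0.01},
        "v1": {"P": 0.03, "Q": 0.02, "R": 0.15, "S": -0.60, "T": -0.05},
        "v2": {"P": 0.04, "Q": 0.02, "R": 0.35, "S": -0.55, "T": 0.12},
        "v3": {"P": 0.04, "Q": 0.00, "R": 0.55, "S": -0.40, "T": 0.18},
        "v4": {"P": 0.05, "Q": -0.04, "R": 0.85, "S": -0.25, "T": 0.22},
        "v5": {"P": 0.05, "Q": -0.06, "R": 0.95, "S": -0.12, "T": 0.20},
        "v6": {"P": 0.05, "Q": -0.06, "R": 0.80, "S": -0.06, "T": 0.16},
    })

    def __post_init__(self) -> None:
        for name, (_, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name} width must be positive")
        # the R wave must dominate the lead II projection
        ii = {w: self.amplitudes["LL"][w] - self.amplitudes["RA"][w]
              for w in self.waves}
        if abs(ii["R"]) <= max(abs(v) for w, v in ii.items() if w != "R"):
            raise ValueError("R wave must dominate the LL-RA projection")


def _class_adjusted_model(base: BeatModel, classes: frozenset[str],
                          rng: np.random.Generator) -> BeatModel:
    waves = {k: list(v) for k, v in base.waves.items()}
    amps = {e: dict(a) for e, a in base.amplitudes.items()}
    if "WIDE_BEAT" in classes:
        for w in ("Q", "R", "S"):
            waves[w][1] *= 2.6          # broad QRS
        for e in amps:
            amps[e]["R"] *= 0.85
    if "IRREG_RR" in classes:
        for e in amps:
            amps[e]["P"] = 0.0          # absent P wave, AF-like stand-in
    scale = 1.0
    if "LOW_VOLT" in classes:
        scale = 0.35
    # mild inter-record morphology variation
    jitter = 1.0 + 0.05 * rng.standard_normal()
    for e in amps:
        for w in amps[e]:
            amps[e][w] *= scale * jitter
    return BeatModel(waves={k: (v[0], v[1]) for k, v in waves.items()},
                     amplitudes=amps)


def _draw_heart_rate(classes: frozenset[str], hr_range: tuple[float, float],
                     rng: np.random.Generator) -> float:
    if "TACHY" in classes:
        return rng.uniform(105.0, 150.0)
    if "BRADY" in classes:
        return rng.uniform(38.0, 55.0)
    return rng.uniform(*hr_range)


def compute_leads(potentials: dict[str, np.ndarray]) -> np.ndarray:
    """Standard 12-lead algebra from electrode potentials (canonical order)."""
    ra, la, ll = potentials["RA"], potentials["LA"], potentials["LL"]
    wct = (ra + la + ll) / 3.0
    rows = [
        la - ra, ll - ra, ll - la,
        ra - (la + ll) / 2.0, la - (ra + ll) / 2.0, ll - (ra + la) / 2.0,
    ]
    rows += [potentials[f"v{i}"] - wct for i in range(1, 7)]
    return np.stack(rows)


def generate_record(spec: SyntheticSpec, class_assignment: set[str] | None,
                    seed: int,
                    record_id: str = "synth") -> tuple[EcgRecord, GroundTruth]:
    """Generate one labeled record; deterministic under a fixed seed.

    ``class_assignment`` is a set drawn from :data:`SYNTHETIC_CLASSES`
    (``None`` or empty is an error; pass ``{"NORM"}`` for a normal record).
    """
    if not class_assignment:
        raise ValueError("class_assignment must name at least one class")
    classes = frozenset(class_assignment)
    unknown = classes - set(SYNTHETIC_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    if {"TACHY", "BRADY"} <= classes:
        raise ValueError("TACHY and BRADY are contradictory")
    if "NORM" in classes and len(classes) > 1:
        raise ValueError("NORM excludes abnormal classes")

    rng = np.random.default_rng(seed)
    n = int(round(spec.fs * spec.duration_s))
    t = np.arange(n) / spec.fs
    model = _class_adjusted_model(BeatModel(), classes, rng)
    hr = _draw_heart_rate(classes, spec.hr_range, rng)
    mean_rr = 60.0 / hr

    # beat times: small physiological jitter; lognormal jitter when irregular
    times = []
    pos = rng.uniform(0.1, min(0.9 * mean_rr, 0.6))
    while pos < spec.duration_s - 0.05:
        times.append(pos)
        if "IRREG_RR" in classes:
            rr = mean_rr * rng.lognormal(mean=0.0, sigma=0.25)
            rr = float(np.clip(rr, 0.3, 2.2))
        else:
            rr = mean_rr * (1.0 + 0.02 * rng.standard_normal())
        pos += rr
    times = np.asarray(times)

    potentials = {}
    for electrode in ELECTRODES:
        amps = model.amplitudes[electrode]
        trace = np.zeros(n)
        for wave, (offset, width) in model.waves.items():
            amp = amps[wave]
            if amp == 0.0:
                continue
            for bt in times:
                c = bt + offset
                lo = max(0, int((c - 5 * width) * spec.fs))
                hi = min(n, int((c + 5 * width) * spec.fs) + 1)
                if lo < hi:
                    trace[lo:hi] += amp * np.exp(
                        -0.5 * ((t[lo:hi] - c) / width) ** 2)
        st_profile = {"v1": 0.0, "v2": 0.18, "v3": 0.22, "v4": 0.18,
                      "v5": 0.06, "v6": 0.0}
        if "ST_SHIFT" in classes and st_profile.get(electrode, 0.0) > 0:
            # anterior ST elevation: plateau between S and T, localized to
            # V2-V4 as in an anterior-wall injury pattern
            st_amp = st_profile[electrode]
            for bt in times:
                lo = int((bt + 0.035) * spec.fs)
                hi = int((bt + 0.160) * spec.fs)
                lo, hi = max(lo, 0), min(hi, n)
                if lo < hi:
                    win = np.sin(np.linspace(0, np.pi, hi - lo)) ** 0.5
                    trace[lo:hi] += st_amp * win
        potentials[electrode] = trace

    signal = compute_leads(potentials)
    y = np.array([1 if c in classes else 0 for c in SYNTHETIC_CLASSES])
    r_peaks = np.round(times * spec.fs).astype(np.int64)
    r_peaks = r_peaks[(r_peaks >= 0) & (r_peaks < n)]
    rec = EcgRecord(signal, spec.fs, CANONICAL_LEADS, record_id)
    truth = GroundTruth(r_peaks=r_peaks,
                        labels=MultiLabelAnnotation(record_id, y),
                        heart_rate_bpm=hr, potentials=potentials)
    return rec, truth


# ---------------------------------------------------------------------------
# artifacts

DEFAULT_ARTIFACT_LEVELS: dict[str, dict] = {
    "myoelectric": {"prob": 0.6, "magnitude": 0.08},      # mV RMS
    "baseline_wander": {"prob": 0.6, "magnitude": 0.45},  # mV amplitude
    "shedding": {"prob": 0.25, "magnitude": 1.0},         # fraction of leads=1
}


def inject_artifacts(rec: EcgRecord, levels: dict[str, dict] | None = None,
                     seed: int = 0) -> tuple[EcgRecord, list[dict]]:
    """Add wearable-ECG artifact families to a record.

    Three families: *myoelectric* noise (zero-mean band-limited 30-150 Hz,
    added to a random subset of leads), *baseline wander* (sum of sinusoids
    below 0.5 Hz, shared drift pattern per affected lead), and *electrode
    shedding* (one lead held constant over a contiguous span).  Levels give
    per-family apply probability and magnitude; all-zero levels are the
    identity.  Returns the corrupted record and a log of what was injected.
    """
    levels = levels if levels is not None else DEFAULT_ARTIFACT_LEVELS
    rng = np.random.default_rng(seed)
    out = rec.copy()
    n, fs = rec.n_samples, rec.fs
    log: list[dict] = []

    myo = levels.get("myoelectric", {})
    if myo and rng.random() < myo.get("prob", 0.0) and myo.get("magnitude", 0):
        n_leads = int(rng.integers(1, max(2, rec.n_leads // 2)))
        leads = rng.choice(rec.n_leads, size=n_leads, replace=False)
        for li in leads:
            noise = band_limited_noise(n, fs, 30.0, min(150.0, 0.45 * fs),
                                       rng)
            noise *= myo["magnitude"] / max(noise.std(), 1e-12)
            out.signal[li] += noise
        log.append({"type": "myoelectric", "leads": sorted(int(x) for x in leads),
                    "magnitude": myo["magnitude"]})

    bw = levels.get("baseline_wander", {})
    if bw and rng.random() < bw.get("prob", 0.0) and bw.get("magnitude", 0):
        n_leads = int(rng.integers(1, max(2, rec.n_leads // 2)))
        leads = rng.choice(rec.n_leads, size=n_leads, replace=False)
        t = np.arange(n) / fs
        for li in leads:
            drift = baseline_wander_component(t, bw["magnitude"], rng)
            out.signal[li] += drift
        log.append({"type": "baseline_wander",
                    "leads": sorted(int(x) for x in leads),
                    "magnitude": bw["magnitude"]})

    shed = levels.get("shedding", {})
    if shed and rng.random() < shed.get("prob", 0.0):
        li = int(rng.integers(rec.n_leads))
        span = int(rng.uniform(0.2, 0.6) * n)
        start = int(rng.integers(0, n - span))
        out.signal[li, start:start + span] = out.signal[li, start]
        log.append({"type": "shedding", "lead": li,
                    "span": [start, start + span]})
    return out, log


def band_limited_noise(n: int, fs: float, f_lo: float, f_hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise with spectrum confined to [f_lo, f_hi]."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    noise = np.fft.irfft(spectrum, n)
    return noise - noise.mean()


def baseline_wander_component(t: np.ndarray, magnitude: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Motion-artifact drift: random-phase sum of sinusoids, all below
    0.5 Hz.

    Components sit on exact Fourier bins of the record length, so the
    drift is strictly band-limited (no spectral leakage above the band).
    """
    n = t.size
    dt = t[1] - t[0] if n > 1 else 1.0
    freqs = np.fft.rfftfreq(n, d=dt)
    spectrum = np.zeros(freqs.size, dtype=complex)
    band = (freqs > 0) & (freqs < 0.5)
    k = int(band.sum())
    if k == 0:
        return np.zeros_like(t)
    amps = rng.uniform(0.3, 1.0, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    spectrum[band] = amps * np.exp(1j * phases)
    drift = np.fft.irfft(spectrum, n)
    return magnitude * drift / max(np.abs(drift).max(), 1e-12)


# ---------------------------------------------------------------------------
# wearing situations (lead reversal)

def apply_wearing_situation(rec: EcgRecord, situation: str,
                            electrode_potentials: dict[str, np.ndarray],
                            chest_permutation: tuple[str, ...] = CHEST_REVERSAL,
                            ) -> EcgRecord:
    """Recompute the 12 leads after permuting electrodes per situation.

    ``situation`` is one of :data:`WEARING_SITUATIONS`; ``normal`` is the
    identity.  The chest situation applies ``chest_permutation`` (default:
    full V1..V6 order reversal) to the chest electrodes.
    """
    if situation not in WEARING_SITUATIONS:
        raise ValueError(f"unknown wearing situation {situation!r}")
    pot = dict(electrode_potentials)
    if situation == "chest":
        for i, src in enumerate(chest_permutation, start=1):
            pot[f"v{i}"] = electrode_potentials[src]
    else:
        for a, b in _SITUATION_SWAPS[situation]:
            pot[a], pot[b] = pot[b], pot[a]
    out = rec.copy()
    out.signal = compute_leads(pot)
    return out


# ---------------------------------------------------------------------------
# dataset generation

def draw_class_assignment(spec: SyntheticSpec,
                          rng: np.random.Generator) -> set[str]:
    """Draw a multilabel class set honouring the spec's marginal mix.

    NORM is drawn first at its stated prevalence; otherwise each abnormal
    class enters independently at its prevalence rescaled to condition on
    not-NORM, with the TACHY/BRADY contradiction resolved by coin flip and
    an empty abnormal draw backfilled from the abnormal marginals.
    """
    mix = spec.class_mix
    p_norm = mix.get("NORM", 0.0)
    if rng.random() < p_norm:
        return {"NORM"}
    abnormal = [c for c in SYNTHETIC_CLASSES if c != "NORM" and mix.get(c, 0) > 0]
    denom = max(1.0 - p_norm, 1e-9)
    chosen = {c for c in abnormal
              if rng.random() < min(1.0, mix[c] / denom)}
    if {"TACHY", "BRADY"} <= chosen:
        chosen.discard("TACHY" if rng.random() < 0.5 else "BRADY")
    if not chosen:
        weights = np.array([mix[c] for c in abnormal])
        chosen = {abnormal[rng.choice(len(abnormal),
                                      p=weights / weights.sum())]}
    return chosen


def synthetic_catalog(labels: np.ndarray) -> LabelCatalog:
    counts = labels.sum(axis=0).astype(int)
    return LabelCatalog(codes=SYNTHETIC_CLASSES,
                        positive_counts={c: int(n) for c, n in
                                         zip(SYNTHETIC_CLASSES, counts)})


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None,
                     test_fraction: float = 0.3, format: str = "csv",
                     ) -> tuple[DatasetManifest, list[EcgRecord],
                                list[GroundTruth]]:
    """Generate ``spec.n_records`` labeled records with subject structure.

    Subjects receive ``records_per_subject`` consecutive records so splits
    can be subject-disjoint.  When ``out_dir`` is given, records are written
    there (plus ground truth JSON and ``manifest.json``); otherwise the
    records stay in memory and manifest paths are symbolic.  Two runs with
    the same spec produce identical signals.
    """
    rng = np.random.default_rng(spec.seed)
    records, truths, entries_raw = [], [], []
    for i in range(spec.n_records):
        classes = draw_class_assignment(spec, rng)
        rec_seed = int(rng.integers(0, 2 ** 31 - 1))
        rid = f"rec{i:05d}"
        rec, truth = generate_record(spec, classes, rec_seed, record_id=rid)
        if spec.artifact_levels:
            rec, _ = inject_artifacts(rec, spec.artifact_levels,
                                      seed=rec_seed + 1)
        subject = f"subj{i // spec.records_per_subject:05d}"
        records.append(rec)
        truths.append(truth)
        entries_raw.append((rid, subject, truth.labels.y))

    split_map = split_by_subject([s for _, s, _ in entries_raw],
                                 test_fraction, spec.seed + 1)
    labels = np.stack([y for _, _, y in entries_raw])
    catalog = synthetic_catalog(labels)
    entries = []
    for rec, (rid, subject, y) in zip(records, entries_raw):
        path = f"{rid}.{format if format != 'wfdb' else 'hea'}"
        entries.append(ManifestEntry(
            path=path, record_id=rid, subject_id=subject,
            annotation=MultiLabelAnnotation(rid, y),
            split=split_map[subject]))
    manifest = DatasetManifest(entries, catalog)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, truth, entry in zip(records, truths, entries):
            write_record(rec, out_dir / entry.path, format=format)
            gt = {"r_peaks": truth.r_peaks.tolist(),
                  "labels": truth.labels.y.tolist(),
                  "wearing_situation": truth.wearing_situation,
                  "heart_rate_bpm": truth.heart_rate_bpm}
            (out_dir / f"{entry.record_id}.truth.json").write_text(
                json.dumps(gt))
        from .io import save_manifest
        save_manifest(manifest, out_dir / "manifest.json")
    return manifest, records, truths


def desk_spec(n_records: int = 600, seed: int = 0,
              **overrides) -> SyntheticSpec:
    """Desk-scale benchmark conditions: shorter, lower-rate records than the
    500 Hz / 15 s wearable format so the full pipeline trains in CPU minutes,
    with the same lead algebra and label structure."""
    kw = dict(n_records=n_records, fs=100.0, duration_s=6.0, seed=seed)
    kw.update(overrides)
    return SyntheticSpec(**kw)
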