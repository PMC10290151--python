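"""Data model and I/O for multi-lead ECG records.

The canonical in-memory object is :class:`EcgRecord`: a ``leads x samples``
float matrix in millivolts plus sampling rate and ordered lead names.  The
canonical 12-lead order is I, II, III, AVR, AVL, AVF, V1..V6 and every module
in the package indexes leads 0-11 in that order.  Records round-trip through
three on-disk dialects: CSV (header row of lead names, one row per sample),
NumPy ``.npy`` arrays, and WFDB ``.hea``/``.dat`` format-16 records.

Annotations are multilabel binary vectors against a :class:`LabelCatalog`
(an ordered, optionally two-level list of diagnostic-term codes with
per-class positive counts).  A :class:`DatasetManifest` ties records,
subjects and annotations together; train/test splits must be disjoint by
subject so no individual contributes to both sides.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "AVR", "AVL", "AVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: WFDB amplitude resolution used on write: ADC units per millivolt.
_WFDB_GAIN = 1000.0


class EcgIOError(ValueError):
    """Raised for malformed records, manifests or catalog files."""


@dataclass
class EcgRecord:
    """A multi-lead ECG signal in millivolts.

    Attributes
    ----------
    signal : ndarray of shape (leads, samples)
    fs : sampling rate in Hz
    lead_names : ordered lead names, one per signal row
    record_id : identifier string
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = CANONICAL_LEADS
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise EcgIOError("signal must be a leads x samples matrix")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.signal.shape[0]:
            raise EcgIOError(
                f"{len(self.lead_names)} lead names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            raise EcgIOError("signal contains non-finite samples")
        if self.fs <= 0:
            raise EcgIOError("sampling rate must be positive")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead by name."""
        try:
            return self.signal[self.lead_names.index(name)]
        except ValueError:
            raise EcgIOError(f"lead {name!r} not present") from None

    def copy(self) -> "EcgRecord":
        return EcgRecord(self.signal.copy(), self.fs, self.lead_names,
                         self.record_id)

    def reorder(self, order: tuple[str, ...] = CANONICAL_LEADS) -> "EcgRecord":
        """Return a copy with leads permuted into ``order``."""
        idx = [self.lead_names.index(name) for name in order]
        return EcgRecord(self.signal[idx].copy(), self.fs, order,
                         self.record_id)


@dataclass
class LabelCatalog:
    """Ordered diagnostic-term codes with an optional two-level hierarchy."""

    codes: tuple[str, ...]
    parents: dict[str, str] = field(default_factory=dict)
    positive_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = tuple(self.codes)
        if len(set(self.codes)) != len(self.codes):
            raise EcgIOError("catalog codes must be unique")
        for child, parent in self.parents.items():
            if parent not in self.codes:
                raise EcgIOError(f"parent {parent!r} of {child!r} not in codes")
        for code, n in self.positive_counts.items():
            if n < 0:
                raise EcgIOError(f"negative positive_count for {code!r}")

    def __len__(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def counts_vector(self) -> np.ndarray:
        return np.array([self.positive_counts.get(c, 0) for c in self.codes],
                        dtype=np.float64)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            {"code": c, "parent": self.parents.get(c),
             "positive_count": int(self.positive_counts.get(c, 0))}
            for c in self.codes
        ]
        path.write_text(json.dumps(rows, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelCatalog":
        rows = json.loads(Path(path).read_text())
        return cls(
            codes=tuple(r["code"] for r in rows),
            parents={r["code"]: r["parent"] for r in rows if r.get("parent")},
            positive_counts={r["code"]: int(r.get("positive_count", 0))
                             for r in rows},
        )


@dataclass
class MultiLabelAnnotation:
    """Binary label vector for one record, aligned with a catalog."""

    record_id: str
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise EcgIOError("label vector entries must be 0 or 1")
        self.y = self.y.astype(np.int8)


@dataclass
class ManifestEntry:
    path: str
    record_id: str
    subject_id: str
    annotation: MultiLabelAnnotation
    split: str = "train"


@dataclass
class DatasetManifest:
    """Record paths + subject ids + annotations + subject-disjoint splits."""

    entries: list[ManifestEntry]
    catalog: LabelCatalog

    def __post_init__(self) -> None:
        self.check_subject_disjoint()

    def check_subject_disjoint(self) -> None:
        by_subject: dict[str, set[str]] = {}
        for e in self.entries:
            by_subject.setdefault(e.subject_id, set()).add(e.split)
        bad = {s for s, splits in by_subject.items() if len(splits) > 1}
        if bad:
            raise EcgIOError(
                f"subjects appear in more than one split: {sorted(bad)[:5]}"
            )

    def subset(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def labels_matrix(self, split: str | None = None) -> np.ndarray:
        entries = self.entries if split is None else self.subset(split)
        return np.stack([e.annotation.y for e in entries])


# ---------------------------------------------------------------------------
# record readers / writers

def _read_csv_record(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
    names = tuple(h.strip() for h in header)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return data.T, names


def _normalize(signal: np.ndarray, names: tuple[str, ...],
               lead_map: dict[str, str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rename via lead_map, then permute to canonical order when possible."""
    if lead_map:
        names = tuple(lead_map.get(n, n) for n in names)
    names = tuple(n.upper() if n.upper() in CANONICAL_LEADS else n
                  for n in names)
    if set(names) == set(CANONICAL_LEADS):
        idx = [names.index(n) for n in CANONICAL_LEADS]
        return signal[idx], CANONICAL_LEADS
    return signal, names


def read_record(path: str | Path, format: str | None = None,
                fs: float = 500.0,
                lead_map: dict[str, str] | None = None) -> EcgRecord:
    """Read an ECG record from CSV, ``.npy`` or WFDB storage.

    ``format`` is one of ``{"csv", "npy", "wfdb"}``; when omitted it is
    inferred from the file suffix.  Lead order is normalised to the canonical
    12-lead order whenever all canonical names are present (``lead_map``
    translates nonstandard names first).  ``fs`` applies to dialects that do
    not store it (CSV/npy).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".npy": "npy", ".hea": "wfdb",
                  ".dat": "wfdb"}.get(suffix, "wfdb")
    if format == "wfdb":
        hea = path.with_suffix(".hea")
        if not hea.exists():
            raise FileNotFoundError(hea)
        return _read_wfdb(hea, lead_map)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        signal, names = _read_csv_record(path)
    elif format == "npy":
        signal = np.load(path)
        names = CANONICAL_LEADS if signal.shape[0] == 12 else tuple(
            f"CH{i}" for i in range(signal.shape[0]))
    else:
        raise EcgIOError(f"unknown record format {format!r}")
    signal, names = _normalize(np.asarray(signal, float), names, lead_map)
    if signal.shape[0] == 12 and set(names) != set(CANONICAL_LEADS) and lead_map is None \
            and names != CANONICAL_LEADS and not all(n.startswith("CH") for n in names):
        raise EcgIOError(
            "12 leads with unrecognised names; pass lead_map to identify them")
    return EcgRecord(signal, fs, names, record_id=path.stem)


def write_record(rec: EcgRecord, path: str | Path,
                 format: str | None = None) -> Path:
    """Write a record; the result reads back with identical lead names and fs.

    CSV stores full float precision (one column per lead, header row of lead
    names); WFDB format-16 quantises at 1000 ADC units per mV.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".npy": "npy"}.get(path.suffix.lower(), "wfdb")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(rec.lead_names)
            for row in rec.signal.T:
                writer.writerow([repr(float(v)) for v in row])
        return path
    if format == "npy":
        np.save(path, rec.signal)
        return path
    if format == "wfdb":
        return _write_wfdb(rec, path)
    raise EcgIOError(f"unknown record format {format!r}")


# -- WFDB format 16 (little-endian int16 .dat + text .hea header) -----------

def _write_wfdb(rec: EcgRecord, path: Path) -> Path:
    base = path.with_suffix("")
    name = base.name
    adc = np.round(rec.signal * _WFDB_GAIN)
    if np.abs(adc).max() > 32767:
        raise EcgIOError("signal exceeds int16 range at gain 1000/mV")
    adc = adc.astype("<i2")
    lines = [f"{name} {rec.n_leads} {rec.fs:g} {rec.n_samples}"]
    for i, lead in enumerate(rec.lead_names):
        first = int(adc[i, 0])
        lines.append(
            f"{name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 {first} 0 0 {lead}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    # sample-interleaved storage, the usual multiplexed layout
    adc.T.tofile(base.with_suffix(".dat"))
    return base.with_suffix(".hea")


def _read_wfdb(hea: Path, lead_map: dict[str, str] | None) -> EcgRecord:
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    names, gains = [], []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        if tok[1] not in ("16", "16+0"):
            raise EcgIOError(f"unsupported WFDB storage format {tok[1]!r}")
        gain_field = tok[2]
        gain = float(gain_field.split("(")[0].split("/")[0]) or 200.0
        gains.append(gain)
        names.append(tok[-1])
    dat = hea.with_suffix(".dat")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise EcgIOError(f"{dat} holds {raw.size} samples, "
                         f"expected {n_sig * n_samp}")
    signal = raw.reshape(n_samp, n_sig).T.astype(np.float64)
    signal /= np.asarray(gains, float)[:, None]
    signal, out_names = _normalize(signal, tuple(names), lead_map)
    return EcgRecord(signal, fs, out_names, record_id=hea.stem)


# ---------------------------------------------------------------------------
# manifests

def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "catalog": [
            {"code": c, "parent": manifest.catalog.parents.get(c),
             "positive_count": int(manifest.catalog.positive_counts.get(c, 0))}
            for c in manifest.catalog.codes
        ],
        "entries": [
            {"path": e.path, "record_id": e.record_id,
             "subject_id": e.subject_id, "split": e.split,
             "y": [int(v) for v in e.annotation.y]}
            for e in manifest.entries
        ],
    }
    path.write_text(json.dumps(payload))
    return path


def load_manifest(path: str | Path, check_paths: bool = False) -> DatasetManifest:
    """Load a manifest, re-verifying subject-disjointness of its splits."""
    path = Path(path)
    payload = json.loads(path.read_text())
    catalog = LabelCatalog(
        codes=tuple(r["code"] for r in payload["catalog"]),
        parents={r["code"]: r["parent"] for r in payload["catalog"]
                 if r.get("parent")},
        positive_counts={r["code"]: int(r.get("positive_count", 0))
                         for r in payload["catalog"]},
    )
    entries = []
    for r in payload["entries"]:
        if check_paths and not (path.parent / r["path"]).exists():
            raise EcgIOError(f"missing record file {r['path']}")
        entries.append(ManifestEntry(
            path=r["path"], record_id=r["record_id"],
            subject_id=r["subject_id"],
            annotation=MultiLabelAnnotation(r["record_id"],
                                            np.array(r["y"])),
            split=r["split"],
        ))
    return DatasetManifest(entries, catalog)


def split_by_subject(subject_ids: list[str], test_fraction: float,
                     seed: int) -> dict[str, str]:
    """Assign each subject to 'train' or 'test'; all of a subject's records
    follow the subject."""
    subjects = sorted(set(subject_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_test = int(round(test_fraction * len(subjects)))
    test = set(subjects[:n_test])
    return {s: ("test" if s in test else "train") for s in subjects}
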