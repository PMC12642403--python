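"""File formats: event/lexicon TSV, ARPA n-gram files, HDF5 containers, YAML config.

Small fixtures travel as delimited text; numeric array bundles (predictor
tracks, responses, group datasets, fit results) use a single hierarchical
named-array container (HDF5).  N-gram models interoperate with standard
LM tooling through the ARPA format (log10 probabilities and backoff
weights).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import yaml

from .features import PredictorTrack
from .lexicon import EventTable, Lexicon
from .ngram import NGramModel, _LOG_PLACEHOLDER
from .sourcespace import GroupDataset, SourceSpace

__all__ = [
    "read_events", "write_events", "read_lexicon", "write_lexicon",
    "read_arpa", "write_arpa", "save_tracks", "load_tracks",
    "write_tracks_tsv", "read_tracks_tsv",
    "save_fit_result", "load_fit_result",
    "save_group_dataset", "load_group_dataset", "RunConfig",
]


class ParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# event tables and lexica (TSV)

_EVENT_HEADER = ["onset_s", "word", "phoneme", "word_initial"]


def write_events(path, events: EventTable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# duration_s=%r\n" % float(events.duration))
        fh.write("\t".join(_EVENT_HEADER) + "\n")
        for t, w, p, init in zip(
            events.onset_s, events.word, events.phoneme, events.word_initial
        ):
            fh.write(f"{float(t)!r}\t{w}\t{p}\t{int(init)}\n")


def read_events(path) -> EventTable:
    duration = 0.0
    onsets: list[float] = []
    words: list[str] = []
    phonemes: list[str] = []
    initial: list[bool] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("# duration_s="):
        duration = float(lines[0].split("=", 1)[1])
        start = 1
    if start >= len(lines) or lines[start].strip().split("\t") != _EVENT_HEADER:
        raise ParseError(f"{path}: missing event-table header")
    for ln, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{ln}: expected 4 columns")
        t = float(parts[0])
        if onsets and t <= onsets[-1]:
            raise ParseError(f"{path}:{ln}: onsets must be strictly increasing")
        onsets.append(t)
        words.append(parts[1])
        phonemes.append(parts[2])
        initial.append(bool(int(parts[3])))
    return EventTable(
        np.array(onsets), words, phonemes, np.array(initial, dtype=bool), duration
    )


def write_lexicon(path, lexicon: Lexicon) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tfrequency\tphonemes\n")
        for w, p, f in lexicon.entries:
            fh.write(f"{w}\t{f!r}\t{' '.join(p)}\n")


def read_lexicon(path) -> Lexicon:
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header != ["word", "frequency", "phonemes"]:
            raise ParseError(f"{path}: missing lexicon header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 columns")
            entries.append((parts[0], tuple(parts[2].split()), float(parts[1])))
    return Lexicon(entries)


# --------------------------------------------------------------------------
# ARPA n-gram files


def write_arpa(path, model: NGramModel) -> None:
    by_order: dict[int, dict] = {n: {} for n in range(1, model.order + 1)}
    for gram, lp in model.logp.items():
        by_order[len(gram)][gram] = lp
    # contexts seen only as contexts still need their backoff weight on file
    for ctx in model.backoff:
        if ctx and ctx not in by_order.get(len(ctx), {}):
            by_order[len(ctx)][ctx] = _LOG_PLACEHOLDER
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for n in range(1, model.order + 1):
            fh.write(f"ngram {n}={len(by_order[n])}\n")
        for n in range(1, model.order + 1):
            fh.write(f"\n\\{n}-grams:\n")
            for gram in sorted(by_order[n]):
                lp = by_order[n][gram]
                lp_s = "-99" if lp == -np.inf or lp <= _LOG_PLACEHOLDER else f"{lp:.7f}"
                line = f"{lp_s}\t{' '.join(gram)}"
                bo = model.backoff.get(gram)
                if n < model.order and bo is not None:
                    bo_log = -99.0 if bo <= 0 else np.log10(bo)
                    line += f"\t{bo_log:.7f}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")


def read_arpa(path) -> NGramModel:
    logp: dict[tuple[str, ...], float] = {}
    backoff: dict[tuple[str, ...], float] = {}
    counts: dict[int, int] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh]
    it = iter(enumerate(lines, start=1))
    for ln, line in it:
        if line.strip() == "\\data\\":
            break
    else:
        raise ParseError(f"{path}: missing \\data\\ header")
    section = 0
    for ln, line in it:
        s = line.strip()
        if not s:
            continue
        if s.startswith("ngram "):
            try:
                n, c = s[6:].split("=")
                counts[int(n)] = int(c)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: malformed count line in \\data\\") from exc
        elif s.endswith("-grams:") and s.startswith("\\"):
            section = int(s[1:].split("-")[0])
        elif s == "\\end\\":
            break
        else:
            if section == 0:
                raise ParseError(f"{path}:{ln}: entry outside any n-gram section")
            parts = s.split("\t")
            if len(parts) not in (2, 3):
                parts = s.split()
                if len(parts) < section + 1:
                    raise ParseError(
                        f"{path}:{ln}: malformed entry in \\{section}-grams section"
                    )
                parts = [parts[0], " ".join(parts[1 : section + 1])] + parts[section + 1 :]
            lp = float(parts[0])
            gram = tuple(parts[1].split())
            if len(gram) != section:
                raise ParseError(
                    f"{path}:{ln}: {len(gram)}-gram in \\{section}-grams section"
                )
            logp[gram] = lp
            if len(parts) == 3:
                backoff[gram] = float(10.0 ** float(parts[2]))
    if not counts:
        raise ParseError(f"{path}: empty \\data\\ section")
    order = max(counts)
    special = {"<s>", "</s>", "<unk>"}
    vocab = tuple(
        sorted(g[0] for g in logp if len(g) == 1 and g[0] not in {"<s>", "</s>"})
    )
    pad = "<s>" if any("<s>" in g for g in logp) else None
    unk = "<unk>" if ("<unk>",) in logp else None
    return NGramModel(
        order=order, vocabulary=vocab, logp=logp, backoff=backoff,
        pad_symbol=pad, unk_symbol=unk,
    )


# --------------------------------------------------------------------------
# HDF5 named-array containers


def save_tracks(path, tracks: list[PredictorTrack]) -> None:
    with h5py.File(path, "w") as f:
        for i, t in enumerate(tracks):
            d = f.create_dataset(f"track_{i:03d}", data=t.values)
            d.attrs["name"] = t.name
            d.attrs["fs"] = t.fs
            d.attrs["kind"] = t.kind


def load_tracks(path) -> list[PredictorTrack]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            d = f[key]
            out.append(
                PredictorTrack(
                    str(d.attrs["name"]), float(d.attrs["fs"]),
                    d[()], str(d.attrs["kind"]),
                )
            )
    return out


def save_group_dataset(path, ds: GroupDataset, extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=ds.values)
        f.create_dataset("labels", data=np.array(ds.labels, dtype="S"))
        f.create_dataset("coords", data=ds.space.coords)
        f.create_dataset("edges", data=ds.space.edges)
        f.create_dataset("hemisphere", data=ds.space.hemisphere.astype("S"))
        if ds.space.pairs is not None:
            f.create_dataset("pairs", data=ds.space.pairs)
        if ds.roi is not None:
            f.create_dataset("roi", data=ds.roi)
        for key, arr in (extra or {}).items():
            f.create_dataset(key, data=np.asarray(arr))


def load_group_dataset(path) -> GroupDataset:
    with h5py.File(path, "r") as f:
        space = SourceSpace(
            coords=f["coords"][()],
            edges=f["edges"][()],
            hemisphere=f["hemisphere"][()].astype("U"),
            pairs=f["pairs"][()] if "pairs" in f else None,
        )
        return GroupDataset(
            values=f["values"][()],
            labels=[s.decode() for s in f["labels"][()]],
            space=space,
            roi=f["roi"][()].astype(bool) if "roi" in f else None,
        )


def write_tracks_tsv(path, tracks: list[PredictorTrack]) -> None:
    """Plain delimited text for small track fixtures (one column per track)."""
    fs = tracks[0].fs
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# fs=%r\n" % float(fs))
        fh.write("# kind=%s\n" % ",".join(t.kind for t in tracks))
        fh.write("\t".join(t.name for t in tracks) + "\n")
        for row in np.column_stack([t.values for t in tracks]):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_tracks_tsv(path) -> list[PredictorTrack]:
    with open(path, encoding="utf-8") as fh:
        fs_line = fh.readline()
        kind_line = fh.readline()
        if not fs_line.startswith("# fs=") or not kind_line.startswith("# kind="):
            raise ParseError(f"{path}: missing track header lines")
        fs = float(fs_line.split("=", 1)[1])
        kinds = kind_line.split("=", 1)[1].strip().split(",")
        names = fh.readline().strip().split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return [
        PredictorTrack(n, fs, values[:, i], kinds[i])
        for i, n in enumerate(names)
    ]


def save_fit_result(path, result, extra: dict | None = None) -> None:
    """Serialize a cross-validated fit: kernels, quality, standardization.

    Kernels are stored in the lag domain with the lag axis in ms, one
    dataset per source, alongside the basis coefficients, the freeze
    state where present, and the predictor/response standardization
    records needed to apply the mTRF to new data.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("quality", data=result.quality)
        f.create_dataset("l1_residuals", data=result.l1_residuals)
        f.create_dataset("l1_y", data=result.l1_y)
        f.create_dataset("predicted", data=result.predicted)
        m0 = result.mtrf[0]
        f.create_dataset("lags_ms", data=m0.basis.lags_ms)
        f.create_dataset(
            "predictor_names", data=np.array(m0.predictor_names, dtype="S")
        )
        f.create_dataset("coef", data=np.stack([m.coef for m in result.mtrf]))
        f.create_dataset(
            "kernels", data=np.stack([m.kernels() for m in result.mtrf])
        )
        f.create_dataset(
            "pred_center", data=np.stack([m.pred_center for m in result.mtrf])
        )
        f.create_dataset(
            "pred_scale", data=np.stack([m.pred_scale for m in result.mtrf])
        )
        f.create_dataset(
            "resp_center", data=np.array([m.resp_center for m in result.mtrf])
        )
        f.create_dataset(
            "resp_scale", data=np.array([m.resp_scale for m in result.mtrf])
        )
        for key, arr in (extra or {}).items():
            f.create_dataset(key, data=np.asarray(arr))


def load_fit_result(path) -> dict:
    """Load a serialized fit as a plain dict of arrays."""
    out = {}
    with h5py.File(path, "r") as f:
        for key in f:
            out[key] = f[key][()]
    out["predictor_names"] = [s.decode() for s in out["predictor_names"]]
    return out


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    out_dir: str = "results"
    fs: float = 100.0
    basis_tmin_ms: float = -100.0
    basis_tmax_ms: float = 1000.0
    basis_width_ms: float = 50.0
    step: float = 0.005
    cv_folds: int = 4
    full_features: list = field(
        default_factory=lambda: ["word_onset", "phoneme_onset", "lexical_surprisal"]
    )
    test_features: list = field(default_factory=lambda: ["lexical_surprisal"])
    sigma: float = 1.0
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_dh: float = 0.1
    n_perm: int = 1000
    seed: int = 0
    n_words: int = 200
    subjects_per_group: dict = field(
        default_factory=lambda: {"English": 3, "Mandarin": 3, "Sinhala": 3}
    )
    n_sources_per_hemi: int = 2
    snr: float = 1.0

    def __post_init__(self) -> None:
        missing = [f for f in self.test_features if f not in self.full_features]
        if missing:
            raise ValueError(
                f"test features not in the full model: {missing}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
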