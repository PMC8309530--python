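"""End-to-end acquisition-protocol studies on a labeled ECG cohort.

Four studies probe how the acquisition protocol degrades min-NRC
identification, each training per-subject reference models on session-1
rest data and testing on material the protocol varies:

* **movement** — test segments recorded during hand / feet / torso
  movement, per electrode placement (same session);
* **placement transfer** — chest-trained models tested on finger and wrist
  recordings acquired simultaneously;
* **session** — same-session vs different-session rest segments, per
  placement;
* **duration sweep** — rest test blocks divided into short segments
  (60 s down to 2 s and below), per placement and session variant, with one
  majority-vote decision per subject.

Training and test segments never overlap in time, and every segment is
quantized with its own quantizer, so no state flows between train and test
material.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace as _dc_replace

import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, ManifestError
from .identify import MetricsReport, ReferenceSet, build_reference_set, evaluate, identify
from .signal_prep import PrepConfig, RawECG, prepare
from .synthetic_ecg import Cohort

__all__ = [
    "ExperimentConfig",
    "StudyResult",
    "segment",
    "run_movement_study",
    "run_placement_transfer",
    "run_session_study",
    "run_duration_sweep",
    "report",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters shared by the four studies.

    Defaults follow the emulated protocol: 8 min of session-1 rest for
    training, 2 min for testing, order-20 single context model over a
    20-symbol alphabet, order-8 Butterworth low-pass at 40 Hz.
    """

    train_duration: float = 480.0  # s
    test_duration: float = 120.0  # s
    k: int = 20
    alpha: float | str = "auto"
    alphabet_size: int = 20
    filter_order: int = 8
    cutoff_hz: float = 40.0
    duration_grid: tuple[float, ...] = (60.0, 30.0, 15.0, 10.0, 8.0, 6.0, 4.0, 2.0)

    def prep_config(self) -> PrepConfig:
        return PrepConfig(
            filter_order=self.filter_order,
            cutoff_hz=self.cutoff_hz,
            alphabet_size=self.alphabet_size,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StudyResult:
    """Per-cell metrics for one study, plus provenance."""

    name: str
    cells: dict[tuple, MetricsReport]
    config: ExperimentConfig
    per_segment_accuracy: dict[tuple, float] = field(default_factory=dict)

    def cell(self, *key) -> MetricsReport:
        return self.cells[tuple(key)]


def segment(rec: RawECG, offset: float, duration: float) -> RawECG:
    """Contiguous slice of a recording, in seconds; labels preserved."""
    if duration <= 0 or offset < 0:
        raise InvalidInputError("segment offset must be >= 0 and duration > 0")
    start = int(round(offset * rec.fs))
    stop = start + int(round(duration * rec.fs))
    if stop > rec.samples.size:
        raise InvalidInputError(
            f"segment [{offset}, {offset + duration}) s exceeds the "
            f"{rec.duration:.1f} s recording"
        )
    return _dc_replace(rec, samples=rec.samples[start:stop])


def _get_rec(cohort: Cohort, sid: str, session: int, placement: str, condition: str) -> RawECG:
    try:
        return cohort.get(sid, session, placement, condition)
    except KeyError as exc:
        raise ManifestError(f"missing recording {exc.args[0]}") from exc


def _train_refs(cohort: Cohort, cfg: ExperimentConfig, placement: str) -> ReferenceSet:
    """Per-subject models from the first ``train_duration`` of session-1 rest."""
    prep = cfg.prep_config()
    seqs = {}
    for sid in cohort.templates:
        rec = _get_rec(cohort, sid, 1, placement, "rest")
        seqs[sid] = prepare(segment(rec, 0.0, cfg.train_duration), prep)
    return build_reference_set(seqs, cfg.k, cfg.alpha)


def _assign(refs: ReferenceSet, tests: dict[str, RawECG], prep: PrepConfig) -> dict[str, str]:
    """One min-NRC decision per subject from one test segment each."""
    assignments = {}
    for sid, rec in tests.items():
        seq = prepare(rec, prep)
        assignments[sid], _ = identify(seq, refs)
    return assignments


def run_movement_study(cohort: Cohort, cfg: ExperimentConfig) -> StudyResult:
    """Identification under movement, per placement x movement (same session).

    Models are trained on session-1 rest; each subject's test segment is the
    leading ``test_duration`` (clamped to the block) of the session-1
    movement block for that placement.
    """
    prep = cfg.prep_config()
    cells = {}
    for placement in cohort.spec.placements:
        refs = _train_refs(cohort, cfg, placement)
        for movement in cohort.spec.movements:
            tests = {}
            for sid in cohort.templates:
                rec = _get_rec(cohort, sid, 1, placement, movement)
                tests[sid] = segment(rec, 0.0, min(cfg.test_duration, rec.duration))
            cells[(movement, placement)] = evaluate(_assign(refs, tests, prep))
    return StudyResult(name="movement", cells=cells, config=cfg)


def run_placement_transfer(cohort: Cohort, cfg: ExperimentConfig) -> StudyResult:
    """Chest-trained models tested on simultaneously acquired other placements.

    The chest->chest cell is the same-placement baseline; the transfer cells
    test the rest-segment tail (after the training window) of the finger and
    wrist recordings, so train and test never overlap in time.
    """
    prep = cfg.prep_config()
    refs = _train_refs(cohort, cfg, "chest")
    cells = {}
    for target in cohort.spec.placements:
        tests = {}
        for sid in cohort.templates:
            rec = _get_rec(cohort, sid, 1, target, "rest")
            tests[sid] = segment(rec, cfg.train_duration, cfg.test_duration)
        cells[("chest", target)] = evaluate(_assign(refs, tests, prep))
    return StudyResult(name="placement_transfer", cells=cells, config=cfg)


def run_session_study(cohort: Cohort, cfg: ExperimentConfig) -> StudyResult:
    """Same-session vs different-session rest identification, per placement.

    Same-session tests use the non-overlapping tail of the session-1 rest
    block; different-session tests use the leading ``test_duration`` of
    session-2 rest.
    """
    prep = cfg.prep_config()
    cells = {}
    for placement in cohort.spec.placements:
        refs = _train_refs(cohort, cfg, placement)
        for variant in ("same", "different"):
            tests = {}
            for sid in cohort.templates:
                if variant == "same":
                    rec = _get_rec(cohort, sid, 1, placement, "rest")
                    tests[sid] = segment(rec, cfg.train_duration, cfg.test_duration)
                else:
                    rec = _get_rec(cohort, sid, 2, placement, "rest")
                    tests[sid] = segment(rec, 0.0, min(cfg.test_duration, rec.duration))
            cells[(placement, variant)] = evaluate(_assign(refs, tests, prep))
    return StudyResult(name="session", cells=cells, config=cfg)


def run_duration_sweep(
    cohort: Cohort,
    cfg: ExperimentConfig,
    variants: tuple[str, ...] = ("same", "different"),
) -> StudyResult:
    """Identification vs test-segment duration, per placement and session.

    The test block is divided into ``floor(test_duration / d)`` disjoint
    segments of duration ``d``; every segment is quantized and identified
    independently, and the per-subject decision is the majority vote over
    its segments (ties resolve to the candidate with the smallest summed
    NRC).  Per-segment accuracies are kept alongside the per-subject
    metrics.
    """
    prep = cfg.prep_config()
    cells: dict[tuple, MetricsReport] = {}
    per_segment: dict[tuple, float] = {}
    for placement in cohort.spec.placements:
        refs = _train_refs(cohort, cfg, placement)
        for variant in variants:
            blocks = {}
            for sid in cohort.templates:
                if variant == "same":
                    rec = _get_rec(cohort, sid, 1, placement, "rest")
                    blocks[sid] = segment(rec, cfg.train_duration, cfg.test_duration)
                else:
                    rec = _get_rec(cohort, sid, 2, placement, "rest")
                    blocks[sid] = segment(rec, 0.0, min(cfg.test_duration, rec.duration))
            for dur in cfg.duration_grid:
                block_len = min(b.duration for b in blocks.values())
                n_seg = int(block_len // dur)
                if n_seg < 1:
                    raise InvalidParameterError(
                        f"duration {dur} s exceeds the {block_len:.1f} s test block"
                    )
                assignments = {}
                seg_hits = seg_total = 0
                for sid, block in blocks.items():
                    votes: dict[str, int] = {}
                    nrc_sums: dict[str, float] = {}
                    for j in range(n_seg):
                        seq = prepare(segment(block, j * dur, dur), prep)
                        winner, scores = identify(seq, refs)
                        for s in scores:
                            nrc_sums[s.subject_id] = nrc_sums.get(s.subject_id, 0.0) + s.value
                        votes[winner] = votes.get(winner, 0) + 1
                        seg_hits += winner == sid
                        seg_total += 1
                    top = max(votes.values())
                    tied = sorted(w for w, c in votes.items() if c == top)
                    assignments[sid] = min(tied, key=lambda w: (nrc_sums[w], w))
                key = (placement, variant, dur)
                cells[key] = evaluate(assignments)
                per_segment[key] = seg_hits / seg_total
    return StudyResult(
        name="duration", cells=cells, config=cfg, per_segment_accuracy=per_segment
    )


_METRIC_COLS = ["Accuracy", "Error", "SEN", "SPEC", "F1score"]


def _metric_values(m: MetricsReport) -> list[float]:
    return [m.accuracy, m.error, m.sensitivity, m.specificity, m.f1]


def report(results: list[StudyResult], out_dir) -> list[str]:
    """Write one CSV per study plus a provenance sidecar; returns the paths.

    Movement and session tables mirror the placement-by-factor metric
    tables; the duration study emits the F1-vs-duration curve (per
    placement and session variant) with per-segment accuracy alongside.
    """
    from pathlib import Path

    if not results:
        raise InvalidInputError("no study results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    key_cols = {
        "movement": ["Movement", "Placement"],
        "placement_transfer": ["TrainPlacement", "TestPlacement"],
        "session": ["Placement", "Session"],
        "duration": ["Placement", "Session", "Duration"],
    }
    paths = []
    for res in results:
        rows = []
        for key, metrics in res.cells.items():
            row = dict(zip(key_cols[res.name], key))
            row.update(dict(zip(_METRIC_COLS, _metric_values(metrics))))
            if res.per_segment_accuracy:
                row["SegmentAccuracy"] = res.per_segment_accuracy[key]
            rows.append(row)
        path = out / f"{res.name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
        paths.append(str(path))
    provenance = {
        "config_digest": sorted({r.config.digest() for r in results}),
        "studies": [r.name for r in results],
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    paths.append(str(prov_path))
    return paths
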