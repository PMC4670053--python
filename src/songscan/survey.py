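"""Testing-phase application: scan recordings, report presence and
calls-per-minute relative abundance, and compare sites with mixed models.

``compare_sites`` fits two Gaussian linear mixed models of calls per minute
with a random intercept per recording point — one intercept-only, one adding
the site as a categorical fixed effect — by maximum likelihood (not REML,
since the models differ in fixed effects and are compared by AIC). Models
within 2 AIC units are treated as equally supported.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from . import classifier as clf
from .annotations import AnnotatedSelection, Selection, write_selection_table
from .audio_io import compute_spectrogram, read_audio
from .detector import DetectorConfig, detect_candidates
from .measurements import measure_all

__all__ = [
    "ScanResult",
    "AbundanceRecord",
    "SiteComparison",
    "scan_recordings",
    "presence_report",
    "abundance_table",
    "compare_sites",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-file outcome of detect -> measure -> classify."""

    source_id: str
    candidates: list[Selection]
    positives: list[Selection]
    scores: np.ndarray  # decision score per measurable candidate
    scored_ids: tuple[int, ...]  # selection ids aligned with ``scores``

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    def positive_scores(self) -> dict[int, float]:
        pos_ids = {s.selection_id for s in self.positives}
        return {
            sid: float(score)
            for sid, score in zip(self.scored_ids, self.scores)
            if sid in pos_ids
        }


@dataclass
class AbundanceRecord:
    """Calls-per-minute relative abundance for one recording file."""

    source_id: str
    site: str
    point: str
    n_detections: int
    minutes: float
    calls_per_minute: float = field(init=False)

    def __post_init__(self) -> None:
        if self.minutes <= 0:
            raise ValueError(f"minutes must be > 0, got {self.minutes}")
        self.calls_per_minute = self.n_detections / self.minutes


@dataclass
class SiteComparison:
    """AIC comparison of the point-only and point+site mixed models."""

    aic_null: float
    aic_site: float
    delta_aic: float
    preferred: str  # "null" | "site" | "equivalent"


def scan_recordings(
    paths,
    detector_cfg: DetectorConfig,
    model: clf.TrainedClassifier,
    window_length: int = 512,
    hop: int = 256,
    window_name: str = "hann",
    out_dir: str | os.PathLike | None = None,
) -> tuple[list[ScanResult], list[str]]:
    """Run the testing-phase pipeline over recordings.

    Returns ``(results, skipped_paths)``. Unreadable files are logged and
    skipped, not fatal. When ``out_dir`` is given, a selection table per file
    is written with the predicted class (1 = target present) per candidate.
    """
    results: list[ScanResult] = []
    skipped: list[str] = []
    for path in paths:
        try:
            clip = read_audio(path)
            gram = compute_spectrogram(clip, window_length, hop, window_name)
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped.append(os.fspath(path))
            continue
        candidates = detect_candidates(gram, detector_cfg)
        features = measure_all(gram, candidates)
        if len(features):
            scores = clf.decision_scores(model, features)
            pred = (scores > 0).astype(int)
            scored_ids = tuple(int(i) for i in features["selection_id"])
        else:
            scores = np.empty(0)
            pred = np.empty(0, dtype=int)
            scored_ids = ()
        positive_ids = {sid for sid, p in zip(scored_ids, pred) if p == 1}
        positives = [c for c in candidates if c.selection_id in positive_ids]
        result = ScanResult(
            source_id=clip.source_id,
            candidates=candidates,
            positives=positives,
            scores=scores,
            scored_ids=scored_ids,
        )
        results.append(result)
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            annotated = [
                AnnotatedSelection(
                    selection=c, class_label=1 if c.selection_id in positive_ids else 0
                )
                for c in candidates
            ]
            write_selection_table(
                annotated, os.path.join(os.fspath(out_dir), f"{clip.source_id}.selections.txt")
            )
    return results, skipped


def presence_report(
    results: list[ScanResult], top_n: int = 50
) -> tuple[dict, list[AnnotatedSelection]]:
    """Presence flags plus a review table of the top-scoring positives.

    The review table holds at most ``top_n`` positives across all files,
    ordered by decreasing decision score, for manual confirmation in a
    spectrogram viewer.
    """
    per_file = {
        r.source_id: {"present": r.n_positives > 0, "n_positives": r.n_positives}
        for r in results
    }
    scored = []
    for r in results:
        for sel in r.positives:
            scored.append((r.positive_scores()[sel.selection_id], r.source_id, sel))
    scored.sort(key=lambda item: (-item[0], item[1], item[2].selection_id))
    review = [
        AnnotatedSelection(selection=sel, class_label=1) for _, _, sel in scored[:top_n]
    ]
    report = {
        "present": any(info["present"] for info in per_file.values()),
        "n_files": len(results),
        "n_positives": sum(r.n_positives for r in results),
        "files": per_file,
    }
    return report, review


def abundance_table(
    results: list[ScanResult], metadata: pd.DataFrame
) -> tuple[list[AbundanceRecord], pd.DataFrame, pd.DataFrame]:
    """Per-file calls-per-minute records plus point and site means.

    ``results`` is a list of :class:`ScanResult` or a mapping
    ``source_id -> n_detections``. ``metadata`` must have columns source_id,
    site, point, minutes covering every scanned file.
    """
    meta = metadata.set_index("source_id")
    if isinstance(results, dict):
        counts = results
    else:
        counts = {r.source_id: r.n_positives for r in results}
    records = []
    for source_id, n_detections in counts.items():
        if source_id not in meta.index:
            raise KeyError(f"no metadata for source_id {source_id!r}")
        row = meta.loc[source_id]
        records.append(
            AbundanceRecord(
                source_id=source_id,
                site=str(row["site"]),
                point=str(row["point"]),
                n_detections=int(n_detections),
                minutes=float(row["minutes"]),
            )
        )
    frame = pd.DataFrame(
        {
            "source_id": [r.source_id for r in records],
            "site": [r.site for r in records],
            "point": [r.point for r in records],
            "calls_per_minute": [r.calls_per_minute for r in records],
        }
    )
    point_means = frame.groupby(["site", "point"], as_index=False)["calls_per_minute"].mean()
    site_means = frame.groupby("site", as_index=False)["calls_per_minute"].mean()
    return records, point_means, site_means


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records[["site", "point", "calls_per_minute"]].copy()
    else:
        frame = pd.DataFrame(
            {
                "site": [r.site for r in records],
                "point": [r.point for r in records],
                "calls_per_minute": [r.calls_per_minute for r in records],
            }
        )
    frame["site"] = frame["site"].astype(str)
    frame["point"] = frame["point"].astype(str)
    return frame


def _aic(fit) -> float:
    # ML fit: AIC = -2 logL + 2 k with k = fixed effects + variance components + residual
    k = fit.k_fe + fit.k_re2 + 1
    return float(-2.0 * fit.llf + 2.0 * k)


def compare_sites(records) -> SiteComparison:
    """AIC comparison of calls-per-minute mixed models with/without site."""
    frame = _records_frame(records)
    sites = frame["site"].unique()
    if len(sites) < 2:
        raise ValueError(f"need >= 2 sites, got {len(sites)}")
    for site, group in frame.groupby("site"):
        if group["point"].nunique() < 2:
            raise ValueError(f"site {site!r} has fewer than 2 points")
    for point, group in frame.groupby("point"):
        if len(group) < 2:
            raise ValueError(f"point {point!r} has fewer than 2 records")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_null = smf.mixedlm(
            "calls_per_minute ~ 1", frame, groups=frame["point"]
        ).fit(reml=False)
        fit_site = smf.mixedlm(
            "calls_per_minute ~ C(site)", frame, groups=frame["point"]
        ).fit(reml=False)
    aic_null = _aic(fit_null)
    aic_site = _aic(fit_site)
    delta = aic_null - aic_site
    if abs(delta) < 2.0:
        preferred = "equivalent"
    elif delta > 0:
        preferred = "site"
    else:
        preferred = "null"
    return SiteComparison(
        aic_null=aic_null, aic_site=aic_site, delta_aic=delta, preferred=preferred
    )
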