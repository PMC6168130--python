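"""End-user prediction: scan proteins for S/T sites, score them with a trained
model, and apply the named stringency thresholds; batch-annotate site lists."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .dataio import (
    PhosphoSite,
    ProteinRecord,
    ResidueMismatchError,
    extract_window,
)
from .model import THRESHOLD_LEVELS, TrainedModel


@dataclass(frozen=True)
class SitePrediction:
    """One scored S/T site.

    ``passed`` is upward-closed: passing the high threshold implies passing
    medium and low.  ``seen_in_training`` flags query windows whose 31-mer
    equals a positive training window, so memorized hits can be separated
    from generalization when a predictor is run on its own substrates.
    """

    accession: str
    position: int
    residue: str
    peptide: str
    score: float
    passed: frozenset[str]
    seen_in_training: bool = False


class ModelStateError(RuntimeError):
    """Model has no calibrated thresholds attached."""


def _training_peptides(model: TrainedModel) -> frozenset[str]:
    return frozenset(model.provenance.get("positive_training_peptides", ()))


def _predict(
    model: TrainedModel, windows, seen: frozenset[str]
) -> list[SitePrediction]:
    if model.thresholds is None:
        raise ModelStateError("model has no calibrated thresholds; run calibration first")
    if not windows:
        return []
    scores = model.decision_values(windows)
    return [
        SitePrediction(
            accession=w.accession,
            position=w.position,
            residue=w.center,
            peptide=w.peptide,
            score=float(s),
            passed=model.thresholds.levels_passed(float(s)),
            seen_in_training=w.peptide in seen,
        )
        for w, s in zip(windows, scores)
    ]


def predict_sites(
    model: TrainedModel,
    proteins: Sequence[ProteinRecord],
    level: str = "high",
    include_all: bool = False,
) -> list[SitePrediction]:
    """Score every S/T position of every protein; return the hits at ``level``
    (or every scored site when ``include_all``), ordered by (accession,
    position)."""
    if level not in THRESHOLD_LEVELS:
        raise ValueError(f"level must be one of {THRESHOLD_LEVELS}")
    windows = []
    for protein in sorted(proteins, key=lambda p: p.accession):
        for pos0, residue in enumerate(protein.sequence):
            if residue in "ST":
                windows.append(extract_window(protein, pos0 + 1))
    preds = _predict(model, windows, _training_peptides(model))
    if include_all:
        return preds
    return [p for p in preds if level in p.passed]


def annotate_site_list(
    model: TrainedModel,
    proteins: Sequence[ProteinRecord],
    sites: Sequence[tuple[str, int] | PhosphoSite],
    level: str = "high",
) -> tuple[list[SitePrediction], list[tuple[str, int, str]], dict[str, float]]:
    """Score an externally supplied site list against the model.

    Returns (predictions, rejects, summary): one prediction per resolvable
    site; rejects as (accession, position, reason) for sites that cannot be
    resolved to an S/T in the supplied sequences (the run continues); and the
    fraction of resolvable sites passing each threshold level.
    """
    if level not in THRESHOLD_LEVELS:
        raise ValueError(f"level must be one of {THRESHOLD_LEVELS}")
    by_acc = {p.accession: p for p in proteins}
    windows, rejects = [], []
    for s in sites:
        acc, pos = (s.accession, s.position) if isinstance(s, PhosphoSite) else s
        if acc not in by_acc:
            rejects.append((acc, pos, "accession not in supplied sequences"))
            continue
        try:
            windows.append(extract_window(by_acc[acc], pos))
        except (IndexError, ResidueMismatchError) as exc:
            rejects.append((acc, pos, str(exc)))
    preds = _predict(model, windows, _training_peptides(model))
    n = len(preds)
    summary = {
        lv: (sum(1 for p in preds if lv in p.passed) / n if n else 0.0)
        for lv in THRESHOLD_LEVELS
    }
    return preds, rejects, summary
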