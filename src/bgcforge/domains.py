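"""Domain annotation: scan ORFs against the knowledgebase's scoring
profiles, load precomputed annotation tables, and infer substrates.

The bundled detector is a position-specific scoring-matrix slider: each
model scores every window of the ORF with per-column log-odds (a match
bonus or mismatch penalty expanded from the model's consensus), and the
best window is reported iff it reaches the model's bit threshold.  The
:class:`Scanner` protocol isolates this choice so a profile-HMM engine
could be adapted in without touching downstream types.  Residues called
``X`` (ambiguous codons) take a strong penalty, so domains never match
across runs of ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .knowledgebase import DomainModel, Knowledgebase
from .seqio import Orf

X_PENALTY = -4.0


@dataclass
class DomainHit:
    orf: Orf
    model_id: str
    score: float
    env_start: int
    env_end: int
    substrate: str | None = None


class Scanner(Protocol):  # pragma: no cover - interface only
    def scan(self, orf: Orf, models: list[DomainModel]) -> list[DomainHit]:
        ...


def _window_scores(aa: str, model: DomainModel) -> np.ndarray:
    """Score of every window of ``aa`` against the model's profile."""
    L = model.length
    n = len(aa)
    if n < L:
        return np.empty(0)
    seq = np.frombuffer(aa.encode(), dtype=np.uint8)
    cons = np.frombuffer(model.consensus.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, L)
    eq = windows == cons
    is_x = windows == ord("X")
    return (model.match_score * (eq & ~is_x).sum(axis=1)
            + model.mismatch_score * (~eq & ~is_x).sum(axis=1)
            + X_PENALTY * is_x.sum(axis=1))


def scan_orf(orf: Orf, models: list[DomainModel] | Knowledgebase,
             kb: Knowledgebase | None = None) -> list[DomainHit]:
    """Best-scoring window per model, reported iff >= the bit threshold.

    Overlapping hits from different models are all reported; hits are
    sorted by window start.  One best hit per model per ORF.
    """
    if isinstance(models, Knowledgebase):
        kb = models
        models = list(kb.models.values())
    hits: list[DomainHit] = []
    for model in models:
        scores = _window_scores(orf.aa_sequence, model)
        if scores.size == 0:
            continue
        best = int(np.argmax(scores))
        score = float(scores[best])
        if score >= model.bit_threshold:
            hit = DomainHit(orf=orf, model_id=model.id, score=score,
                            env_start=best, env_end=best + model.length)
            hit.substrate = predict_substrate(hit, model)
            hits.append(hit)
    hits.sort(key=lambda h: (h.env_start, h.model_id))
    return hits


def predict_substrate(hit: DomainHit, model: DomainModel) -> str | None:
    """Signature-based substrate lookup; None means downstream wildcard."""
    if hit.model_id != model.id:
        raise ValueError("hit/model mismatch")
    if not model.signature_positions or not model.substrate_map:
        return None
    window = hit.orf.aa_sequence[hit.env_start:hit.env_end]
    signature = "".join(window[p] for p in model.signature_positions)
    return model.substrate_map.get(signature)


def load_annotation_table(path, kb: Knowledgebase,
                          orfs: list[Orf]) -> list[DomainHit]:
    """Load a precomputed TSV of domain hits (bypasses profile scanning).

    Columns: orf_id, model_id, score, env_start, env_end, substrate.
    """
    table = pd.read_csv(Path(path), sep="\t", dtype=str,
                        keep_default_na=False)
    required = ["orf_id", "model_id", "score", "env_start", "env_end",
                "substrate"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    by_id = {o.orf_id: o for o in orfs}
    hits: list[DomainHit] = []
    for row_num, row in enumerate(table.itertuples(index=False), start=2):
        if row.model_id not in kb.models:
            raise ValueError(
                f"row {row_num}: unknown model {row.model_id!r}")
        orf = by_id.get(row.orf_id)
        if orf is None:
            raise ValueError(f"row {row_num}: unknown ORF {row.orf_id!r}")
        start, end = int(row.env_start), int(row.env_end)
        if not (0 <= start < end <= len(orf.aa_sequence)):
            raise ValueError(
                f"row {row_num}: window [{start},{end}) outside ORF")
        hits.append(DomainHit(
            orf=orf, model_id=row.model_id, score=float(row.score),
            env_start=start, env_end=end,
            substrate=row.substrate or None))
    return hits


def save_annotation_table(hits: list[DomainHit], path) -> None:
    rows = [{"orf_id": h.orf.orf_id, "model_id": h.model_id,
             "score": h.score, "env_start": h.env_start,
             "env_end": h.env_end, "substrate": h.substrate or ""}
            for h in hits]
    pd.DataFrame(rows, columns=["orf_id", "model_id", "score", "env_start",
                                "env_end", "substrate"]).to_csv(
        path, sep="\t", index=False)
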