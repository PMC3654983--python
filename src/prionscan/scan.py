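"""Sliding-window scoring of protein sequences.

Every contiguous window of fixed length L (default 60 residues, the typical
length of a prion-domain core) is scored as the sum of per-residue log-odds
potentials plus the proline spacing correction, in bits.  A protein's
putative prion domain is its highest-scoring window; proteins whose best
window reaches the calibrated cutoff (default 50 bits) become predictions.

Scores are computed from integer residue counts per window (a cumulative
count matrix) dotted with the potential vector, so the incremental sliding
path is bitwise identical to scoring any window in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX, N_AA, encode
from .propensity import PropensityTable
from .proline import ProlineDistanceModel, _sum_pair_terms

logger = logging.getLogger(__name__)

_P_IDX = AA_INDEX["P"]


@dataclass
class ScanConfig:
    """Scanner settings.

    ``mode`` is ``"max"`` (one best window per protein) or ``"all"`` (every
    non-overlapping window above the cutoff).  ``ambiguity_policy`` is
    ``"zero"`` (ambiguity letters contribute 0 bits) or ``"skip"`` (windows
    containing any ambiguity letter are excluded).
    """

    window_length: int = 60
    cutoff: float = 50.0
    mode: str = "max"
    ambiguity_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not np.isfinite(self.cutoff) and self.mode == "all" and self.cutoff > 0:
            raise ValueError("cutoff must be finite or -inf")
        if self.mode not in ("max", "all"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.ambiguity_policy not in ("zero", "skip"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity_policy!r}")


@dataclass
class ScoredWindow:
    """One scored window; ``start`` is 1-based, the window is [start, end]."""

    protein_id: str
    start: int
    compositional_bits: float
    proline_bits: float
    score_bits: float
    window_sequence: str
    organism: str = ""

    def __post_init__(self) -> None:
        if self.score_bits != self.compositional_bits + self.proline_bits:
            raise ValueError("score_bits must equal compositional + proline bits")

    @property
    def length(self) -> int:
        return len(self.window_sequence)

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _window_counts(codes: np.ndarray) -> np.ndarray:
    """Integer composition of one window (ambiguity letters excluded)."""
    valid = codes[codes >= 0]
    return np.bincount(valid, minlength=N_AA).astype(np.int64)


def score_window(
    residues: str,
    table: PropensityTable,
    model: ProlineDistanceModel,
    window_length: int | None = None,
    ambiguity_policy: str = "zero",
) -> tuple[float, float, float]:
    """Score one window: (compositional_bits, proline_bits, score_bits).

    With ``window_length`` given, any other length is an error.  Under the
    ``"zero"`` policy ambiguity letters contribute nothing; under ``"skip"``
    a window containing one is an error (the scanner excludes such windows).
    """
    residues = residues.upper()
    if window_length is not None and len(residues) != window_length:
        raise ValueError(
            f"window has length {len(residues)}, expected {window_length}"
        )
    codes = encode(residues)
    if ambiguity_policy == "skip" and np.any(codes < 0):
        raise ValueError("window contains ambiguity letters (policy 'skip')")
    counts = _window_counts(codes)
    compositional = float(counts @ table.lor)
    dists = np.diff(np.flatnonzero(codes == _P_IDX))
    proline = _sum_pair_terms(dists, model) if dists.size else 0.0
    return compositional, proline, compositional + proline


def window_scores(
    residues: str,
    table: PropensityTable,
    model: ProlineDistanceModel,
    window_length: int = 60,
    ambiguity_policy: str = "zero",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scores of every window at stride 1, by incremental sliding counts.

    Returns ``(compositional, proline, total, usable)`` arrays indexed by
    0-based window start.  ``usable`` is False for windows excluded by the
    ``"skip"`` ambiguity policy.  The incremental path is bitwise identical
    to :func:`score_window` on each window in isolation: both dot the same
    integer count vector with the same potential vector, and both sum the
    same proline pair terms left to right.
    """
    residues = residues.upper()
    L = window_length
    n = len(residues)
    if n < L:
        raise ValueError(f"sequence of length {n} is shorter than the window {L}")
    codes = encode(residues)
    n_windows = n - L + 1

    # cumulative residue counts -> integer window compositions
    onehot = np.zeros((n, N_AA), dtype=np.int64)
    valid = codes >= 0
    onehot[np.flatnonzero(valid), codes[valid]] = 1
    cum = np.zeros((n + 1, N_AA), dtype=np.int64)
    np.cumsum(onehot, axis=0, out=cum[1:])

    lor = table.lor
    ppos = np.flatnonzero(codes == _P_IDX)
    comp = np.empty(n_windows)
    pro = np.empty(n_windows)
    for s in range(n_windows):
        counts = cum[s + L] - cum[s]
        comp[s] = float(counts @ lor)
        lo, hi = np.searchsorted(ppos, (s, s + L))
        dists = np.diff(ppos[lo:hi])
        pro[s] = _sum_pair_terms(dists, model) if dists.size else 0.0
    total = comp + pro

    usable = np.ones(n_windows, dtype=bool)
    if ambiguity_policy == "skip":
        amb = (~valid).astype(np.int64)
        amb_cum = np.concatenate([[0], np.cumsum(amb)])
        usable = (amb_cum[L:] - amb_cum[:-L]) == 0
    return comp, pro, total, usable


def scan_sequence(
    record,
    table: PropensityTable,
    model: ProlineDistanceModel,
    config: ScanConfig | None = None,
) -> list[ScoredWindow]:
    """Score every window of one protein at stride 1.

    ``max`` mode returns the single best window (leftmost on ties); ``all``
    mode returns every window at or above the cutoff, greedily reduced to a
    non-overlapping set in descending score order.  Proteins shorter than
    the window return an empty list with a logged notice.
    """
    config = config or ScanConfig()
    L = config.window_length
    if L > model.max_distance:
        raise ValueError(
            f"window_length {L} exceeds proline model max_distance "
            f"{model.max_distance}"
        )
    residues = record.residues if hasattr(record, "residues") else str(record).upper()
    rec_id = getattr(record, "id", "")
    organism = getattr(record, "organism", "")
    n = len(residues)
    if n < L:
        logger.info(
            "protein %s has length %d < window %d; skipped", rec_id or "?", n, L
        )
        return []

    comp, pro, total, usable = window_scores(
        residues, table, model, L, config.ambiguity_policy
    )
    n_windows = n - L + 1
    if not usable.any():
        logger.info("protein %s: every window contains ambiguity letters", rec_id)
        return []

    def make(s: int) -> ScoredWindow:
        return ScoredWindow(
            protein_id=rec_id,
            organism=organism,
            start=s + 1,
            compositional_bits=float(comp[s]),
            proline_bits=float(pro[s]),
            score_bits=float(comp[s]) + float(pro[s]),
            window_sequence=residues[s : s + L],
        )

    if config.mode == "max":
        masked = np.where(usable, total, -np.inf)
        best = int(np.argmax(masked))  # leftmost on exact ties
        return [make(best)]

    # all-above-cutoff, non-overlapping, greedy by descending score
    candidates = np.flatnonzero(usable & (total >= config.cutoff))
    order = candidates[np.lexsort((candidates, -total[candidates]))]
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for s in order:
        if not taken[s : s + L].any():
            chosen.append(int(s))
            taken[s : s + L] = True
    return [make(s) for s in sorted(chosen)]


def scan_proteome(
    records: Iterable,
    table: PropensityTable,
    model: ProlineDistanceModel,
    config: ScanConfig | None = None,
) -> list[ScoredWindow]:
    """Scan many proteins and keep windows at or above the cutoff.

    In ``max`` mode a protein contributes its best window only if that window
    reaches the cutoff.  Output preserves input order; per-organism counts
    are logged.
    """
    config = config or ScanConfig()
    predictions: list[ScoredWindow] = []
    n_proteins = 0
    for rec in records:
        n_proteins += 1
        windows = scan_sequence(rec, table, model, config)
        if config.mode == "max":
            windows = [w for w in windows if w.score_bits >= config.cutoff]
        predictions.extend(windows)
    for org, count in summarize_by_organism(predictions).items():
        logger.info("organism %s: %d prediction(s)", org or "(none)", count)
    logger.info(
        "scanned %d protein(s); %d prediction(s) at cutoff %g bits",
        n_proteins, len(predictions), config.cutoff,
    )
    return predictions


def summarize_by_organism(predictions: Sequence[ScoredWindow]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for p in predictions:
        counts[p.organism] = counts.get(p.organism, 0) + 1
    return counts


def best_score(
    record,
    table: PropensityTable,
    model: ProlineDistanceModel,
    config: ScanConfig | None = None,
) -> float:
    """Best-window score of one protein; -inf if shorter than the window."""
    config = replace(config or ScanConfig(), mode="max")
    windows = scan_sequence(record, table, model, config)
    return windows[0].score_bits if windows else float("-inf")


@dataclass
class ProteomeScoreDistribution:
    """Per-protein best scores of a reference proteome, for empirical p-values."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise ValueError("the score distribution needs at least one value")

    @property
    def n(self) -> int:
        return int(self.scores.size)

    @classmethod
    def from_records(
        cls,
        records: Iterable,
        table: PropensityTable,
        model: ProlineDistanceModel,
        config: ScanConfig | None = None,
    ) -> "ProteomeScoreDistribution":
        scores = []
        for rec in records:
            s = best_score(rec, table, model, config)
            if np.isfinite(s):
                scores.append(s)
        return cls(scores=np.array(scores))


def empirical_pvalue(score: float, dist: ProteomeScoreDistribution) -> float:
    """Add-one empirical tail probability: (1 + #{x >= score}) / (n + 1)."""
    return float((1 + np.count_nonzero(dist.scores >= score)) / (dist.n + 1))
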