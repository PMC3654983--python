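"""Proline spacing-pattern statistics and the proline score correction.

Prolines in prion-forming domains tend to occur in clusters, while scattered
(non-contiguous) prolines disrupt prion formation.  This module estimates the
frequency of P-(X)n-P patterns — consecutive proline pairs separated by a
given distance d (adjacent prolines have d = 1) — in a reference sequence
set, compares it with the expected spacing under independent placement, and
turns the ratio into per-distance log-likelihoods in bits::

    LOr(d) = log2(observed_freq(d) / expected_freq(d))

A window's proline correction is the sum of LOr(d) over its consecutive
proline pairs; it is added to the compositional score.  Only consecutive
pairs contribute: for prolines at positions q1 < q2 < q3 the pairs are
(q1,q2) and (q2,q3), never (q1,q3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import IO, Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX

logger = logging.getLogger(__name__)

_P = "P"
_SUM_TOL = 1e-9


@dataclass
class ProlineDistanceModel:
    """Log-likelihoods of proline-pair separations d = 1..max_distance."""

    max_distance: int
    observed_freq: np.ndarray  # index d-1
    expected_freq: np.ndarray
    lor: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        for name in ("observed_freq", "expected_freq", "lor"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.max_distance,):
                raise ValueError(
                    f"{name} must have length max_distance={self.max_distance}"
                )
            setattr(self, name, arr)
        if self.n_pairs > 0:
            for name in ("observed_freq", "expected_freq"):
                s = getattr(self, name).sum()
                if not math.isclose(s, 1.0, abs_tol=_SUM_TOL):
                    raise ValueError(f"{name} must sum to 1 (got {s!r})")
        if not np.all(np.isfinite(self.lor)):
            raise ValueError("lor must be finite everywhere (zero counts are floored)")

    def lor_at(self, d: int) -> float:
        if not 1 <= d <= self.max_distance:
            raise ValueError(f"distance {d} outside 1..{self.max_distance}")
        return float(self.lor[d - 1])

    def save(self, dest) -> None:
        close = False
        if not hasattr(dest, "write"):
            dest = open(dest, "w")
            close = True
        try:
            dest.write(f"# max_distance={self.max_distance}\tn_pairs={self.n_pairs}\n")
            dest.write("d\tobserved\texpected\tlor\n")
            for i in range(self.max_distance):
                dest.write(
                    f"{i + 1}\t{float(self.observed_freq[i])!r}\t"
                    f"{float(self.expected_freq[i])!r}\t{float(self.lor[i])!r}\n"
                )
        finally:
            if close:
                dest.close()

    @classmethod
    def load(cls, source) -> "ProlineDistanceModel":
        close = False
        if not hasattr(source, "read"):
            source = open(source)
            close = True
        try:
            meta = source.readline()
            if not meta.startswith("#"):
                raise ValueError("proline model file lacks its metadata header")
            fields = dict(
                item.split("=") for item in meta[1:].strip().split("\t")
            )
            max_distance = int(fields["max_distance"])
            n_pairs = int(fields["n_pairs"])
            source.readline()  # column header
            obs = np.zeros(max_distance)
            exp = np.zeros(max_distance)
            lor = np.zeros(max_distance)
            for line in source:
                if not line.strip():
                    continue
                d, o, e, l = line.rstrip("\n").split("\t")
                obs[int(d) - 1] = float(o)
                exp[int(d) - 1] = float(e)
                lor[int(d) - 1] = float(l)
            return cls(
                max_distance=max_distance,
                observed_freq=obs,
                expected_freq=exp,
                lor=lor,
                n_pairs=n_pairs,
            )
        finally:
            if close:
                source.close()


def proline_positions(residues: str) -> np.ndarray:
    """0-based positions of P in a residue string."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero(arr == ord(_P))


def consecutive_pair_distances(residues: str) -> np.ndarray:
    """Separations of consecutive proline pairs (adjacent prolines -> 1)."""
    pos = proline_positions(residues)
    return np.diff(pos)


def count_proline_pairs(
    records: Iterable, max_distance: int = 60
) -> tuple[np.ndarray, int]:
    """Count consecutive proline pairs per separation distance.

    Pairs separated by more than ``max_distance`` are ignored entirely.
    Returns the per-distance count vector (index d-1) and the total pair
    count used.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    counts = np.zeros(max_distance, dtype=np.int64)
    for rec in records:
        residues = rec.residues if hasattr(rec, "residues") else str(rec).upper()
        dists = consecutive_pair_distances(residues)
        dists = dists[dists <= max_distance]
        if dists.size:
            counts += np.bincount(dists - 1, minlength=max_distance)
    return counts, int(counts.sum())


def expected_distance_distribution(
    proline_freq: float, max_distance: int = 60
) -> np.ndarray:
    """Geometric spacing null for independently placed prolines.

    With per-residue proline probability q, the gap until the next proline is
    geometric: P(d) ∝ (1-q)^(d-1) q, renormalized over d = 1..max_distance.
    """
    if not 0 < proline_freq < 1:
        raise ValueError("proline frequency must lie strictly between 0 and 1")
    d = np.arange(1, max_distance + 1)
    w = (1.0 - proline_freq) ** (d - 1) * proline_freq
    return w / w.sum()


def shuffle_distance_distribution(
    records: Sequence, max_distance: int = 60, n_shuffles: int = 10, seed=None
) -> np.ndarray:
    """Empirical spacing null from residue-shuffled copies of the reference.

    A sensitivity-analysis alternative to the analytic geometric null.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(max_distance, dtype=np.int64)
    for rec in records:
        residues = rec.residues if hasattr(rec, "residues") else str(rec).upper()
        arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
        for _ in range(n_shuffles):
            rng.shuffle(arr)
            pos = np.flatnonzero(arr == ord(_P))
            dists = np.diff(pos)
            dists = dists[dists <= max_distance]
            if dists.size:
                counts += np.bincount(dists - 1, minlength=max_distance)
    total = counts.sum()
    if total == 0:
        raise ValueError("shuffled reference produced no proline pairs")
    return counts / total


def build_proline_model(
    observed_counts: np.ndarray, expected_freqs: np.ndarray
) -> ProlineDistanceModel:
    """Turn observed pair counts and an expected spacing law into log-odds.

    Distances never observed get the half-count floor
    ``log2((0.5/n_pairs) / expected)`` instead of -infinity.
    """
    counts = np.asarray(observed_counts, dtype=np.int64)
    expected = np.asarray(expected_freqs, dtype=float)
    if counts.shape != expected.shape:
        raise ValueError("observed and expected vectors must have equal length")
    if np.any(expected <= 0):
        raise ValueError("expected frequencies must be strictly positive")
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("no observed proline pairs; cannot build a model")
    obs = counts / n_pairs
    floored = np.where(counts > 0, obs, 0.5 / n_pairs)
    lor = np.log2(floored / expected)
    return ProlineDistanceModel(
        max_distance=len(counts),
        observed_freq=obs,
        expected_freq=expected / expected.sum(),
        lor=lor,
        n_pairs=n_pairs,
    )


def train_proline_model(
    records: Sequence,
    max_distance: int = 60,
    proline_freq: float | None = None,
    null: str = "geometric",
    n_shuffles: int = 10,
    seed=None,
) -> ProlineDistanceModel:
    """Estimate the spacing model from a reference sequence set.

    ``proline_freq`` defaults to the observed proline fraction of the
    reference.  ``null="shuffle"`` replaces the analytic geometric null with
    residue shuffling of the same reference.
    """
    records = list(records)
    counts, n_pairs = count_proline_pairs(records, max_distance)
    if n_pairs == 0:
        raise ValueError("reference set contains no proline pairs")
    if null == "geometric":
        if proline_freq is None:
            n_p = 0
            n_res = 0
            for rec in records:
                residues = rec.residues if hasattr(rec, "residues") else str(rec).upper()
                n_p += residues.count(_P)
                n_res += len(residues)
            proline_freq = n_p / n_res
        expected = expected_distance_distribution(proline_freq, max_distance)
    elif null == "shuffle":
        expected = shuffle_distance_distribution(
            records, max_distance, n_shuffles=n_shuffles, seed=seed
        )
        expected = np.maximum(expected, 0.5 / (n_pairs * n_shuffles))
        expected = expected / expected.sum()
    else:
        raise ValueError(f"unknown null model {null!r}")
    return build_proline_model(counts, expected)


def _sum_pair_terms(distances: np.ndarray, model: ProlineDistanceModel) -> float:
    """Left-to-right sum of per-pair log-odds (fixed order for exactness)."""
    total = 0.0
    lor = model.lor
    for d in distances:
        total += lor[d - 1]
    return total


def proline_correction(window_residues: str, model: ProlineDistanceModel) -> float:
    """Proline-pattern correction of one window, in bits.

    Sums the model log-odds of every consecutive proline pair in the window;
    0.0 for windows with fewer than two prolines.
    """
    if len(window_residues) > model.max_distance:
        raise ValueError(
            f"window of length {len(window_residues)} exceeds the model's "
            f"max_distance {model.max_distance}"
        )
    dists = consecutive_pair_distances(window_residues.upper())
    if dists.size == 0:
        return 0.0
    return _sum_pair_terms(dists, model)


@lru_cache(maxsize=None)
def default_model() -> ProlineDistanceModel:
    """The shipped spacing model.

    Trained on 5,000 synthetic background-composition sequences (a synthetic
    stand-in for a non-redundant protein reference set; see
    scripts/build_default_proline_model.py), so its corrections are close to
    neutral.  Retrain on a real non-redundant database for production scans.
    """
    text = resources.files("prionscan.data").joinpath("proline_model_default.tsv").read_text()
    import io

    return ProlineDistanceModel.load(io.StringIO(text))
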