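"""Amino-acid propensities for Q/N-rich prion-forming domains.

The model is purely compositional: for each amino acid *i* the observed
frequency ``f_i`` in a training set of prion-forming sequences is compared
with its background frequency ``p_i`` in the protein universe, and the
statistical potential is the log-odds in bits::

    LOr_i = log2(f_i / p_i)

Summed over a sequence window these potentials give an uncalibrated score:
positive bits mean the window's composition looks more like a prion domain
than like an average protein.

Two tables ship with the package: the published prion-domain odds ratios
(from in-vivo-validated yeast prion domains) and, for comparison only, the
odds ratios derived from the Sup35 random-mutagenesis library of Toombs et
al.  The background is a frozen Swiss-Prot release composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, AMBIGUITY, N_AA

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


@dataclass
class CompositionCounts:
    """Pooled residue counts over a collection of sequences."""

    counts: np.ndarray  # shape (20,), int64, ordered as AMINO_ACIDS
    n_sequences: int
    n_skipped_residues: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {aa: int(c) for aa, c in zip(AMINO_ACIDS, self.counts)}


def count_composition(records: Iterable) -> CompositionCounts:
    """Pooled composition of all residues of all records.

    Ambiguity letters are tallied in ``n_skipped_residues`` only.  Raises if
    the collection contains no standard residue.
    """
    counts = np.zeros(N_AA, dtype=np.int64)
    n_seq = 0
    skipped = 0
    for rec in records:
        residues = rec.residues if hasattr(rec, "residues") else str(rec).upper()
        n_seq += 1
        for aa, c in _tally(residues).items():
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += c
            elif aa in AMBIGUITY:
                skipped += c
            else:
                raise ValueError(f"illegal residue {aa!r} in sequence {n_seq}")
    if n_seq == 0 or counts.sum() == 0:
        raise ValueError("no standard residues to count")
    return CompositionCounts(counts=counts, n_sequences=n_seq, n_skipped_residues=skipped)


def _tally(residues: str) -> Mapping[str, int]:
    from collections import Counter

    return Counter(residues)


def estimate_frequencies(counts: CompositionCounts, pseudocount: float = 0.5) -> np.ndarray:
    """Smoothed frequency vector ``(count_i + a) / (total + 20 a)``.

    ``pseudocount=0.5`` (Jeffreys) by default; 0 gives the raw maximum
    likelihood estimate and may produce zero frequencies.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    total = counts.total
    if total <= 0:
        raise ValueError("cannot estimate frequencies from zero counts")
    return (counts.counts + pseudocount) / (total + N_AA * pseudocount)


@dataclass
class PropensityTable:
    """Per-amino-acid frequencies, odds ratios and log-odds in bits.

    Trained tables satisfy ``odds = f/p`` and hence ``sum(odds * p) == 1`` to
    1e-9; reference tables built from published (rounded) odds ratios keep
    the printed odds as primary, back-derive ``f = odds * p / Z`` and record
    the normalization ``Z`` in ``metadata``.
    """

    f: np.ndarray
    p: np.ndarray
    odds: np.ndarray
    lor: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("f", self.f), ("p", self.p), ("odds", self.odds), ("lor", self.lor)):
            arr = np.asarray(v, dtype=float)
            if arr.shape != (N_AA,):
                raise ValueError(f"{name} must have shape ({N_AA},)")
            setattr(self, name, arr)
        if not math.isclose(self.f.sum(), 1.0, abs_tol=_SUM_TOL):
            raise ValueError(f"f must sum to 1 (got {self.f.sum()!r})")
        if not math.isclose(self.p.sum(), 1.0, abs_tol=_SUM_TOL):
            raise ValueError(f"p must sum to 1 (got {self.p.sum()!r})")
        if np.any(self.p <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if not self.metadata.get("reference_odds", False):
            unity = float(np.dot(self.odds, self.p))
            if not math.isclose(unity, 1.0, abs_tol=_SUM_TOL):
                raise ValueError(
                    f"sum(odds * p) = {unity!r} differs from 1; inconsistent table"
                )

    def lor_of(self, aa: str) -> float:
        return float(self.lor[AA_INDEX[aa]])

    def odds_of(self, aa: str) -> float:
        return float(self.odds[AA_INDEX[aa]])

    def save(self, dest) -> None:
        """Write ``AA<TAB>f<TAB>p<TAB>odds<TAB>lor`` rows at full precision."""
        close = False
        if not hasattr(dest, "write"):
            dest = open(dest, "w")
            close = True
        try:
            dest.write("residue\tf\tp\todds\tlor\n")
            for i, aa in enumerate(AMINO_ACIDS):
                dest.write(
                    f"{aa}\t{float(self.f[i])!r}\t{float(self.p[i])!r}\t"
                    f"{float(self.odds[i])!r}\t{float(self.lor[i])!r}\n"
                )
        finally:
            if close:
                dest.close()

    @classmethod
    def load(cls, source) -> "PropensityTable":
        close = False
        if not hasattr(source, "read"):
            source = open(source)
            close = True
        try:
            rows: dict[str, tuple[float, float, float, float]] = {}
            header = source.readline()
            if not header.startswith("residue"):
                raise ValueError("propensity table file lacks the expected header")
            for line in source:
                if not line.strip() or line.startswith("#"):
                    continue
                aa, fs, ps, os_, ls = line.rstrip("\n").split("\t")
                rows[aa] = (float(fs), float(ps), float(os_), float(ls))
            if set(rows) != set(AMINO_ACIDS):
                raise ValueError("propensity table must cover the 20 standard residues")
            f = np.array([rows[a][0] for a in AMINO_ACIDS])
            p = np.array([rows[a][1] for a in AMINO_ACIDS])
            odds = np.array([rows[a][2] for a in AMINO_ACIDS])
            lor = np.array([rows[a][3] for a in AMINO_ACIDS])
            meta = {"reference_odds": bool(np.max(np.abs(odds * p / (odds * p).sum() - f)) < 1e-12
                                           and not np.allclose(odds, f / p, rtol=1e-12, atol=0))}
            # trust the stored numbers; flag as reference if odds != f/p
            meta["reference_odds"] = not np.allclose(odds, f / p, rtol=1e-9, atol=0)
            return cls(f=f, p=p, odds=odds, lor=lor, metadata=meta)
        finally:
            if close:
                source.close()

    @classmethod
    def from_frequencies(
        cls, f: np.ndarray, p: np.ndarray, metadata: dict | None = None
    ) -> "PropensityTable":
        return build_table(f, p, metadata=metadata)

    @classmethod
    def from_odds(
        cls, odds: np.ndarray, p: np.ndarray, metadata: dict | None = None
    ) -> "PropensityTable":
        """Build a reference table from published odds ratios.

        The odds are kept as given (so ``lor = log2(odds)`` reproduces the
        published potentials); ``f`` is back-derived as ``odds * p``
        renormalized, with the normalization recorded in metadata.
        """
        odds = np.asarray(odds, dtype=float)
        p = np.asarray(p, dtype=float)
        if np.any(odds <= 0):
            raise ValueError("odds ratios must be strictly positive")
        raw = odds * p
        z = float(raw.sum())
        meta = dict(metadata or {})
        meta.update(reference_odds=True, odds_p_normalization=z)
        with np.errstate(divide="ignore"):
            lor = np.log2(odds)
        return cls(f=raw / z, p=p, odds=odds, lor=lor, metadata=meta)


def build_table(
    train_freqs: np.ndarray,
    background_freqs: np.ndarray,
    metadata: dict | None = None,
) -> PropensityTable:
    """Log2-odds statistical potentials from training vs background frequencies.

    A zero training frequency (possible only under pseudocount 0) yields a
    ``-inf`` potential, flagged in metadata.
    """
    f = np.asarray(train_freqs, dtype=float)
    p = np.asarray(background_freqs, dtype=float)
    if f.shape != (N_AA,) or p.shape != (N_AA,):
        raise ValueError(f"frequency vectors must have length {N_AA}")
    if np.any(p <= 0):
        raise ValueError("background frequencies must be strictly positive")
    for name, v in (("training", f), ("background", p)):
        if not math.isclose(v.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"{name} frequencies must sum to 1 (got {v.sum()!r})")
    f = f / f.sum()
    p = p / p.sum()
    odds = f / p
    with np.errstate(divide="ignore"):
        lor = np.log2(odds)
    meta = dict(metadata or {})
    if np.any(f == 0):
        meta["has_infinite_potentials"] = True
        logger.warning(
            "training frequencies contain zeros; -inf potentials produced "
            "(use a positive pseudocount to avoid this)"
        )
    return PropensityTable(f=f, p=p, odds=odds, lor=lor, metadata=meta)


def train_table(
    records: Iterable,
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> PropensityTable:
    """Convenience pipeline: count, smooth, and build the log-odds table."""
    counts = count_composition(records)
    f = estimate_frequencies(counts, pseudocount)
    p = background if background is not None else background_frequencies()
    return build_table(
        f, p, metadata={"pseudocount": pseudocount, "n_training_sequences": counts.n_sequences}
    )


# ---------------------------------------------------------------------------
# shipped tables


def _read_data_table(name: str) -> dict[str, list[float]]:
    text = resources.files("prionscan.data").joinpath(name).read_text()
    rows: dict[str, list[float]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    if set(rows) != set(AMINO_ACIDS):
        raise ValueError(f"data file {name} must cover the 20 standard residues")
    return rows


@lru_cache(maxsize=None)
def background_frequencies() -> np.ndarray:
    """Frozen Swiss-Prot overall amino-acid composition, normalized to 1."""
    rows = _read_data_table("background_swissprot.tsv")
    p = np.array([rows[a][0] for a in AMINO_ACIDS])
    return p / p.sum()


@lru_cache(maxsize=None)
def builtin_table(which: str = "prd") -> PropensityTable:
    """The shipped propensity table.

    ``which="prd"`` is the prion-domain table used for scanning;
    ``which="library1"`` is the Sup35 mutagenesis-library table, shipped for
    comparison only and not wired into scoring.
    """
    fname = {"prd": "prion_domain_odds.tsv", "library1": "library1_odds.tsv"}.get(which)
    if fname is None:
        raise ValueError(f"unknown builtin table {which!r}")
    rows = _read_data_table(fname)
    odds = np.array([rows[a][0] for a in AMINO_ACIDS])
    printed_lor = np.array([rows[a][1] for a in AMINO_ACIDS])
    table = PropensityTable.from_odds(
        odds, background_frequencies(), metadata={"source": which}
    )
    dev = np.abs(table.lor - printed_lor)
    table.metadata["printed_lor"] = printed_lor
    table.metadata["max_printed_lor_deviation_bits"] = float(dev.max())
    table.metadata["printed_lor_deviating_residues"] = [
        AMINO_ACIDS[i] for i in np.flatnonzero(dev > 0.002)
    ]
    return table
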