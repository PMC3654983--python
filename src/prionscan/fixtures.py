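"""Synthetic sequences, benchmark sets and proteomes with known ground truth.

Everything downstream of the propensity table is testable without external
databases: sequences are drawn i.i.d. from a chosen composition, positive
examples carry one planted 60-residue prion-like core inside otherwise
background-composition flanks (real prion domains sit inside larger
proteins), and proteomes mix background proteins with a known set of
spiked ones.

Three compositions are available:

* ``background`` — the frozen Swiss-Prot background ``p``.
* ``prd`` — the training-set average composition ``f`` implied by the
  built-in odds table (``f = odds * p``, normalized).  Windows at this
  composition score ~45 bits: it is the average over *complete* training
  sequences, diluted by non-prion flanks.
* ``core`` — an exponentially tilted composition ``p * odds**1.5``
  (normalized; Q+N ~ 60%), emulating the dense Q/N core that validated
  prion domains present to the scanner.  Planted cores score ~84 +/- 10
  bits, the range real positives occupy, so they are detectable at the
  calibrated 50-bit cutoff.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, N_AA
from .propensity import background_frequencies, builtin_table
from .seqio import SequenceRecord

CORE_TILT = 1.5

_DEFAULT_ORGANISMS = (
    "Synthetica primus",
    "Synthetica secundus",
    "Synthetica tertius",
)


def prd_frequencies() -> np.ndarray:
    """Training-set average composition implied by the built-in table."""
    return builtin_table().f.copy()


def core_frequencies(tilt: float = CORE_TILT) -> np.ndarray:
    """Tilted prion-core composition ``p * odds**tilt``, normalized."""
    t = builtin_table()
    w = t.p * t.odds**tilt
    return w / w.sum()


@dataclass
class GeneratorSpec:
    """Parameters of the i.i.d. sequence generator.

    ``proline_mode="clustered"`` redistributes the prolines of each sequence
    into clusters with intra-cluster gaps <= ``cluster_gap`` instead of
    leaving them i.i.d.
    """

    frequencies: np.ndarray
    min_length: int = 60
    max_length: int = 250
    proline_mode: str = "iid"
    cluster_gap: int = 2

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (N_AA,):
            raise ValueError(f"frequencies must have length {N_AA}")
        if not math.isclose(self.frequencies.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("frequencies must sum to 1")
        if self.min_length > self.max_length or self.min_length < 1:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.proline_mode not in ("iid", "clustered"):
            raise ValueError(f"unknown proline mode {self.proline_mode!r}")

    @classmethod
    def background(cls, **kw) -> "GeneratorSpec":
        return cls(frequencies=background_frequencies(), **kw)

    @classmethod
    def prd(cls, **kw) -> "GeneratorSpec":
        return cls(frequencies=prd_frequencies(), **kw)

    @classmethod
    def core(cls, **kw) -> "GeneratorSpec":
        return cls(frequencies=core_frequencies(), **kw)


@dataclass
class SpikeTruth:
    """Ground truth of one planted prion-like core."""

    protein_id: str
    start: int  # 1-based position of the spike's first residue
    length: int
    flavor: str

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_residues(rng: np.random.Generator, freqs: np.ndarray, length: int) -> np.ndarray:
    return rng.choice(N_AA, size=length, p=freqs)


def _cluster_prolines(
    codes: np.ndarray, rng: np.random.Generator, gap: int
) -> np.ndarray:
    """Rearrange this sequence's prolines into clusters with gaps <= ``gap``.

    The multiset of residues is preserved: non-proline residues keep their
    relative order and the prolines are re-planted in clusters of 2-4 whose
    consecutive separations (in final coordinates) are drawn from 1..gap.
    """
    p_idx = AA_INDEX["P"]
    n_p = int(np.count_nonzero(codes == p_idx))
    if n_p < 2:
        return codes
    backbone = codes[codes != p_idx]
    total = len(codes)

    sizes: list[int] = []
    remaining = n_p
    while remaining > 0:
        size = min(int(rng.integers(2, 5)), remaining)
        if remaining - size == 1:  # avoid stranding a singleton proline
            size += 1
        sizes.append(size)
        remaining -= size

    occupied = np.zeros(total, dtype=bool)
    for size in sizes:
        gaps = rng.integers(1, gap + 1, size=size - 1)
        span = int(gaps.sum()) + 1
        # place the cluster away from occupied slots; fall back to any start
        for _ in range(50):
            start = int(rng.integers(0, max(total - span, 1)))
            cluster = start + np.concatenate([[0], np.cumsum(gaps)])
            cluster = cluster[cluster < total]
            if not occupied[cluster].any():
                break
        occupied[cluster] = True

    deficit = n_p - int(occupied.sum())
    if deficit > 0:  # rare collision fallback: drop stragglers anywhere free
        free = np.flatnonzero(~occupied)
        occupied[rng.choice(free, size=deficit, replace=False)] = True

    out = np.empty(total, dtype=codes.dtype)
    out[occupied] = p_idx
    out[~occupied] = backbone
    return out


def sample_sequences(
    spec: GeneratorSpec, n: int, seed=None, id_prefix: str = "SYN"
) -> list[SequenceRecord]:
    """Draw ``n`` i.i.d. sequences under ``spec``; pure in (spec, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    records = []
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for i in range(n):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        codes = _draw_residues(rng, spec.frequencies, length)
        if spec.proline_mode == "clustered":
            codes = _cluster_prolines(codes, rng, spec.cluster_gap)
        residues = alphabet[codes].tobytes().decode()
        records.append(SequenceRecord(id=f"{id_prefix}{i + 1:05d}", residues=residues))
    return records


def _spiked_record(
    rng: np.random.Generator,
    rec_id: str,
    length: int,
    spike_freqs: np.ndarray,
    spike_length: int,
    flavor: str,
    organism: str = "",
) -> tuple[SequenceRecord, SpikeTruth]:
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    bg = background_frequencies()
    codes = _draw_residues(rng, bg, length)
    start0 = int(rng.integers(0, length - spike_length + 1))
    codes[start0 : start0 + spike_length] = _draw_residues(rng, spike_freqs, spike_length)
    rec = SequenceRecord(
        id=rec_id, residues=alphabet[codes].tobytes().decode(), organism=organism
    )
    truth = SpikeTruth(
        protein_id=rec_id, start=start0 + 1, length=spike_length, flavor=flavor
    )
    return rec, truth


def make_benchmark_sets(
    n_pos: int = 18,
    n_neg: int = 18,
    contrast: float = 1.0,
    seed=None,
    spike_length: int = 60,
    min_length: int = 60,
    max_length: int = 250,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SpikeTruth]]:
    """Positive and negative benchmark sets with known truth.

    Positives carry one ``spike_length``-mer at the mixed composition
    ``contrast * f_core + (1 - contrast) * p`` inside background flanks;
    negatives are entirely background.  ``contrast=1`` emulates the
    validated-prion versus non-prion separation regime; ``contrast=0`` is
    the null.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    rng = _as_rng(seed)
    f_mix = contrast * core_frequencies() + (1.0 - contrast) * background_frequencies()
    f_mix = f_mix / f_mix.sum()
    positives = []
    truths = []
    for i in range(n_pos):
        length = int(rng.integers(max(min_length, spike_length), max_length + 1))
        rec, truth = _spiked_record(
            rng, f"POS{i + 1:03d}", length, f_mix, spike_length, flavor="core-mix"
        )
        positives.append(rec)
        truths.append(truth)
    negatives = sample_sequences(
        GeneratorSpec.background(min_length=min_length, max_length=max_length),
        n_neg,
        seed=rng,
        id_prefix="NEG",
    )
    return positives, negatives, truths


def make_proteome(
    n_proteins: int = 500,
    prd_fraction: float = 0.02,
    seed=None,
    min_length: int = 100,
    max_length: int = 800,
    spike_length: int = 60,
    organisms: Sequence[str] = _DEFAULT_ORGANISMS,
) -> tuple[list[SequenceRecord], list[SpikeTruth]]:
    """A synthetic proteome with ``ceil(prd_fraction * n)`` spiked proteins.

    Spike positions are uniform over admissible starts; organism labels are
    assigned round-robin; the truth table records every planted core.
    """
    if not 0.0 <= prd_fraction <= 1.0:
        raise ValueError("prd_fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    n_spiked = math.ceil(prd_fraction * n_proteins)
    spiked_idx = set(
        rng.choice(n_proteins, size=n_spiked, replace=False).tolist()
    ) if n_spiked else set()
    core = core_frequencies()
    bg_spec = GeneratorSpec.background(min_length=min_length, max_length=max_length)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records = []
    truths = []
    for i in range(n_proteins):
        organism = organisms[i % len(organisms)]
        rec_id = f"PROT{i + 1:05d}"
        length = int(rng.integers(min_length, max_length + 1))
        if i in spiked_idx:
            rec, truth = _spiked_record(
                rng, rec_id, length, core, spike_length, flavor="core",
                organism=organism,
            )
            truths.append(truth)
        else:
            codes = _draw_residues(rng, bg_spec.frequencies, length)
            rec = SequenceRecord(
                id=rec_id,
                residues=alphabet[codes].tobytes().decode(),
                organism=organism,
            )
        records.append(rec)
    return records, truths
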