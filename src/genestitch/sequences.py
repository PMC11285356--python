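"""Sequence substrate: validated DNA sequences, FASTA I/O, reverse
complement and duplex melting temperature.

Everything downstream (fragment partitioning, primer choice, assembly
simulation) works on plain ``str`` sequences over {A, C, G, T} plus the
:class:`GeneSequence` record type defined here.

The melting temperature is nearest-neighbor thermodynamics: the Allawi &
SantaLucia (1997) unified parameter set with the SantaLucia (1998) entropy
salt correction, at 50 mM Na+ and 25 nM per strand. These are the defaults
of :func:`Bio.SeqUtils.MeltingTemp.Tm_NN`, which does the computation; the
parameterization is frozen in :data:`DEFAULT_TM_CONFIG` so an alternative
model can be swapped in for sensitivity checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from types import MappingProxyType
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as _melt

__all__ = [
    "SequenceError",
    "GeneSequence",
    "MIN_DUPLEX_LEN",
    "DEFAULT_TM_CONFIG",
    "reverse_complement",
    "melting_temperature",
    "read_fasta",
    "write_fasta",
    "random_gene",
]

#: Shortest duplex for which the nearest-neighbor model is trusted.
#: Shorter queries are an error, not a fallback to another formula.
MIN_DUPLEX_LEN = 8

#: Nearest-neighbor Tm parameterization (see module docstring).
#: ``nn_table=None`` selects Tm_NN's default table (DNA_NN3, Allawi &
#: SantaLucia 1997); saltcorr=5 is the SantaLucia 1998 entropy correction.
DEFAULT_TM_CONFIG = MappingProxyType(
    dict(nn_table=None, dnac1=25.0, dnac2=25.0, Na=50.0, K=0.0,
         Tris=0.0, Mg=0.0, dNTPs=0.0, saltcorr=5)
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class SequenceError(ValueError):
    """Invalid nucleotide input (bad character, bad record, too short)."""


def _validate(seq: str) -> str:
    """Normalize to uppercase, strip whitespace, reject non-ACGT.

    Error messages carry 1-based positions (positions counted on the
    normalized sequence, i.e. after whitespace removal).
    """
    cleaned = "".join(seq.split()).upper()
    if not cleaned:
        raise SequenceError("empty sequence")
    for pos, base in enumerate(cleaned, start=1):
        if base not in _VALID:
            hint = " (DNA only; convert U to T upstream)" if base == "U" else ""
            raise SequenceError(
                f"invalid character {base!r} at position {pos}: "
                f"only A/C/G/T are accepted{hint}"
            )
    return cleaned


@dataclass(frozen=True)
class GeneSequence:
    """A validated nucleotide sequence with a record identifier.

    The sequence is normalized to uppercase A/C/G/T at construction;
    ambiguity codes and RNA are rejected.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate(self.seq))

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def slice1(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.seq)):
            raise SequenceError(
                f"coordinates {start}-{end} outside 1..{len(self.seq)}"
            )
        return self.seq[start - 1 : end]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1 << 18)
def _tm_nn_cached(seq: str) -> float:
    return float(_melt.Tm_NN(seq, **DEFAULT_TM_CONFIG))


def melting_temperature(seq: str, config: dict | None = None) -> float:
    """Duplex melting temperature in deg C (nearest-neighbor model).

    Strand-symmetric: ``Tm(s) == Tm(reverse_complement(s))``, because both
    strands describe the same duplex. Sequences shorter than
    :data:`MIN_DUPLEX_LEN` are rejected rather than approximated.

    ``config`` overrides :data:`DEFAULT_TM_CONFIG` (keyword arguments of
    ``Bio.SeqUtils.MeltingTemp.Tm_NN``); the default path is cached, since
    overlap screening re-evaluates the same suffixes many times.
    """
    seq = _validate(seq)
    if len(seq) < MIN_DUPLEX_LEN:
        raise SequenceError(
            f"sequence of length {len(seq)} too short for a nearest-neighbor "
            f"Tm (minimum duplex length {MIN_DUPLEX_LEN})"
        )
    if config is None:
        return _tm_nn_cached(seq)
    return float(_melt.Tm_NN(seq, **{**DEFAULT_TM_CONFIG, **config}))


def read_fasta(path: str | Path) -> GeneSequence:
    """Read a single-record FASTA file into a :class:`GeneSequence`.

    Exactly one record is required: a synthesis design targets one gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise SequenceError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise SequenceError(
            f"{path} contains {len(records)} records; exactly one target "
            f"gene is expected"
        )
    rec = records[0]
    try:
        return GeneSequence(id=rec.id, seq=str(rec.seq))
    except SequenceError as exc:
        raise SequenceError(f"{path}: {exc}") from exc


def write_fasta(gene: GeneSequence, path: str | Path) -> Path:
    """Write a :class:`GeneSequence` as a single-record FASTA file."""
    path = Path(path)
    SeqIO.write([SeqRecord(Seq(gene.seq), id=gene.id, description="")],
                str(path), "fasta")
    return path


def random_gene(length: int, gc_fraction: float = 0.5,
                seed: int = 0, id: str | None = None) -> GeneSequence:
    """Reproducible random gene with i.i.d. bases.

    P(G) = P(C) = ``gc_fraction``/2 and P(A) = P(T) = (1-``gc_fraction``)/2,
    the simplest composition model that exercises GC-dependent Tm spread.
    Same (length, gc_fraction, seed) always yields the same sequence.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = random.Random(seed)
    weights = [(1 - gc_fraction) / 2, gc_fraction / 2,
               gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(rng.choices("ACGT", weights=weights, k=length))
    return GeneSequence(id=id or f"random_gene_{length}nt_seed{seed}", seq=seq)
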