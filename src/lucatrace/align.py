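"""Alignment container and FASTA I/O.

Sequences are held as an integer matrix in the model residue order, with
-1 encoding a gap/unknown column entry. ``'.'`` is normalised to ``'-'``
on read; any character outside the 20-letter alphabet is treated as
missing data.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqmodels import AA_ALPHABET

GAP = -1

_CODE = np.full(128, GAP, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.replace(".", "-").encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def decode_sequence(row: np.ndarray) -> str:
    letters = np.array(list(AA_ALPHABET + "-"))
    return "".join(letters[row])


class Alignment:
    """An aligned (or equal-length unaligned) set of amino-acid sequences."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray) -> None:
        if len(ids) != matrix.shape[0]:
            raise ValueError("ids and matrix row count differ")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=np.int8)
        self._index = {name: i for i, name in enumerate(self.ids)}

    # ------------------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for name, seq in pairs:
            ids.append(name)
            seqs.append(encode_sequence(seq))
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        return cls(ids, np.vstack(seqs) if seqs else np.zeros((0, 0), dtype=np.int8))

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Alignment":
        records = SeqIO.parse(path_or_handle, "fasta")
        return cls.from_pairs((r.id, str(r.seq)) for r in records)

    def to_records(self) -> list[SeqRecord]:
        return [
            SeqRecord(Seq(decode_sequence(self.matrix[i])), id=name, description="")
            for i, name in enumerate(self.ids)
        ]

    def to_fasta(self, path_or_handle) -> None:
        SeqIO.write(self.to_records(), path_or_handle, "fasta")

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()

    # ------------------------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self._index[name]]

    def sequence(self, name: str) -> str:
        return decode_sequence(self.row(name))

    def subset(self, names: Sequence[str]) -> "Alignment":
        rows = [self._index[n] for n in names]
        return Alignment(list(names), self.matrix[rows])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_sequences} sequences x {self.n_sites} sites)"
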