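"""Multiple sequence alignments as integer-coded matrices.

Sequences are stored as an ``(n_taxa, n_sites)`` int8 matrix over a declared
alphabet; gaps and ambiguity codes are coded ``-1`` and treated as missing
(marginalized in likelihoods).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO

DNA = "ACGT"
AA = "ARNDCQEGHILKMFPSTWYV"
_DNA_AMBIG = set("RYSWKMBDHVNX?-.")
_AA_AMBIG = set("BZJUOX?-.*")


@dataclass(frozen=True)
class Alphabet:
    name: str
    symbols: str
    ambiguous: frozenset

    @property
    def n_states(self) -> int:
        return len(self.symbols)


DNA_ALPHABET = Alphabet("dna", DNA, frozenset(_DNA_AMBIG))
AA_ALPHABET = Alphabet("protein", AA, frozenset(_AA_AMBIG))


class Alignment:
    """Ordered taxa + integer-coded sequence matrix.

    ``codes[i, j]`` is the state index of taxon i at site j, or ``-1`` for a
    gap/ambiguous (missing) character.
    """

    def __init__(self, labels, codes, alphabet: Alphabet):
        self.labels = list(labels)
        self.codes = np.asarray(codes, dtype=np.int8)
        self.alphabet = alphabet
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels in alignment")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise ValueError("codes shape does not match labels")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, labels, seqs, alphabet: Alphabet) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal lengths: {sorted(lengths)}")
        lut = np.full(128, -2, dtype=np.int8)
        for i, c in enumerate(alphabet.symbols):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        for c in alphabet.ambiguous:
            lut[ord(c)] = -1
            lut[ord(c.lower())] = -1
        mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        codes = lut[mat].reshape(len(labels), -1)
        if np.any(codes == -2):
            bad = sorted({chr(b) for b in mat[codes.ravel() == -2]})
            raise ValueError(f"unknown symbols for {alphabet.name}: {bad}")
        return cls(labels, codes, alphabet)

    def sequences(self) -> list[str]:
        sym = np.array(list(self.alphabet.symbols + "-"))
        return ["".join(sym[row]) for row in self.codes]  # -1 indexes "-"

    def subset(self, labels) -> "Alignment":
        idx = [self.labels.index(l) for l in labels]
        return Alignment(labels, self.codes[idx], self.alphabet)

    def empirical_freqs(self, pseudocount: float = 1.0) -> np.ndarray:
        k = self.alphabet.n_states
        counts = np.bincount(self.codes[self.codes >= 0].ravel(), minlength=k)
        f = counts + pseudocount
        return f / f.sum()

    def __eq__(self, other):
        return (isinstance(other, Alignment)
                and self.labels == other.labels
                and self.alphabet.name == other.alphabet.name
                and np.array_equal(self.codes, other.codes))


def concatenate(alignments) -> Alignment:
    """Concatenate alignments over identical taxon sets (order of the first)."""
    alignments = list(alignments)
    base = alignments[0]
    mats = [base.codes]
    for a in alignments[1:]:
        if set(a.labels) != set(base.labels):
            raise ValueError("taxon sets differ between alignments")
        mats.append(a.subset(base.labels).codes)
    return Alignment(base.labels, np.hstack(mats), base.alphabet)


def _guess_alphabet(seqs) -> Alphabet:
    chars = set("".join(seqs).upper()) - set("-?.NX")
    return DNA_ALPHABET if chars <= set(DNA + "RYSWKMBDHV") else AA_ALPHABET


def read_alignment(path, format: str = "fasta", alphabet: Alphabet | None = None) -> Alignment:
    """Read a FASTA or (relaxed) PHYLIP alignment.

    Rows must be equal length, labels unique; symbols outside the alphabet +
    its ambiguity set are rejected.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported format: {format!r}")
    if format == "fasta":
        # Bio fasta parsing silently pads nothing; check raggedness ourselves
        from Bio import SeqIO
        recs = list(SeqIO.parse(path, "fasta"))
        if not recs:
            raise ValueError(f"no sequences in {path}")
        labels = [r.id for r in recs]
        seqs = [str(r.seq) for r in recs]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("unequal lengths across rows")
    else:
        aln = AlignIO.read(path, fmt)
        labels = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    if alphabet is None:
        alphabet = _guess_alphabet(seqs)
    return Alignment.from_sequences(labels, seqs, alphabet)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, seq in zip(aln.labels, aln.sequences()):
            fh.write(f">{label}\n{seq}\n")


def write_phylip(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
        for label, seq in zip(aln.labels, aln.sequences()):
            fh.write(f"{label}  {seq}\n")
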