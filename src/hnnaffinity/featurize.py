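"""Character-level featurization of ligands and binding pockets.

Ligand SMILES are treated as raw character strings over the printable
ASCII range ``'!'``..``'~'`` (codes 33-126): each of the 94 characters
gets a unique integer index ``ord(c) - 32``, so ``'!'`` -> 1 and
``'~'`` -> 94.  Binding-pocket sequences use the 20 standard one-letter
amino-acid codes in the conventional order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,
P,S,T,W,Y,V, indexed 1..20.  In both alphabets index 0 is reserved for
padding; encoded strings are truncated (head kept) or right-padded with
zeros to a fixed length, so a batch of K strings becomes an integer
matrix of shape K x L (SMILES, default L = 325) or K x M (pockets,
default M = 150).

Affinity labels (Kd / Ki / IC50) are normalised to pK = -log10 of the
molar value at ingest.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: default maximum encoded SMILES length
SMILES_MAX_LEN = 325
#: default maximum encoded pocket-sequence length
POCKET_MAX_LEN = 150
#: default interaction-descriptor vector width
DESCRIPTOR_WIDTH = 348

#: canonical ordering of the 20 standard amino acids
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_MOLAR_FACTOR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

QUALIFIERS = ("exact", "lower_bound", "upper_bound", "approximate")


class EncodingError(ValueError):
    """A string contains a character outside the model alphabet."""


@dataclass(frozen=True)
class SmilesVocabulary:
    """Bijection between the 94 printable ASCII characters and 1..94."""

    index_of: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.index_of)

    def char_of(self, index: int) -> str:
        return chr(index + 32)


@dataclass(frozen=True)
class PocketVocabulary:
    """Bijection between the 20 standard residue letters and 1..20."""

    index_of: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.index_of)

    def char_of(self, index: int) -> str:
        return AMINO_ACIDS[index - 1]


def build_smiles_vocab() -> SmilesVocabulary:
    """Index every printable ASCII character '!'..'~' as code - 32."""
    return SmilesVocabulary({chr(c): c - 32 for c in range(33, 127)})


def build_pocket_vocab() -> PocketVocabulary:
    return PocketVocabulary({aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)})


@dataclass(frozen=True)
class AffinityLabel:
    """A measured binding affinity, normalised to pK.

    ``kind`` is the measurement type (Kd, Ki or IC50), ``value_molar``
    the equilibrium constant in molar units, and ``pk`` its negative
    base-10 logarithm (larger pK = stronger binding).  ``qualifier``
    records whether the printed value was exact or censored
    (relational symbols <, >, ~ in index files).
    """

    kind: str
    value_molar: float
    pk: float
    qualifier: str = "exact"

    def __post_init__(self) -> None:
        if self.kind not in ("Kd", "Ki", "IC50"):
            raise ValueError(f"unknown affinity kind {self.kind!r}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")
        if not (self.value_molar > 0):
            raise ValueError("value_molar must be positive")

    @classmethod
    def from_measurement(
        cls, kind: str, value: float, unit: str, qualifier: str = "exact"
    ) -> "AffinityLabel":
        molar = value * _molar_factor(unit)
        return cls(kind=kind, value_molar=molar, pk=to_pk(value, unit),
                   qualifier=qualifier)

    @classmethod
    def from_pk(cls, kind: str, pk: float, qualifier: str = "exact") -> "AffinityLabel":
        return cls(kind=kind, value_molar=10.0 ** (-pk), pk=pk, qualifier=qualifier)


def _molar_factor(unit: str) -> float:
    unit = unit.replace("µ", "u")  # µM -> uM
    if unit not in _MOLAR_FACTOR:
        raise ValueError(f"unknown affinity unit {unit!r}")
    return _MOLAR_FACTOR[unit]


def to_pk(value: float, unit: str = "M") -> float:
    """Convert an affinity constant to pK = -log10(value in molar).

    >>> to_pk(1, "uM")
    6.0
    """
    if not (value > 0):
        raise ValueError(f"affinity value must be positive, got {value}")
    return -math.log10(value * _molar_factor(unit))


def encode_smiles(
    smiles: str,
    vocab: SmilesVocabulary | None = None,
    max_len: int = SMILES_MAX_LEN,
) -> np.ndarray:
    """Integer-encode a SMILES string to a fixed-length vector.

    Characters map through the 94-symbol vocabulary; strings longer
    than ``max_len`` keep their head, shorter ones are right-padded
    with the reserved index 0.
    """
    vocab = vocab or build_smiles_vocab()
    out = np.zeros(max_len, dtype=np.int32)
    for i, ch in enumerate(smiles[:max_len]):
        idx = vocab.index_of.get(ch)
        if idx is None:
            raise EncodingError(
                f"character {ch!r} (position {i}) is outside the SMILES "
                f"alphabet '!'..'~'"
            )
        out[i] = idx
    return out


def encode_pocket_sequence(
    seq: str,
    vocab: PocketVocabulary | None = None,
    max_len: int = POCKET_MAX_LEN,
    strict: bool = True,
) -> np.ndarray:
    """Integer-encode a one-letter residue sequence to length ``max_len``.

    In strict mode (default) a letter outside the 20 standard codes
    raises :class:`EncodingError`; lenient mode maps it to the padding
    index 0 and logs a warning.
    """
    vocab = vocab or build_pocket_vocab()
    out = np.zeros(max_len, dtype=np.int32)
    for i, ch in enumerate(seq[:max_len]):
        idx = vocab.index_of.get(ch)
        if idx is None:
            if strict:
                raise EncodingError(
                    f"residue {ch!r} (position {i}) is not one of the 20 "
                    f"standard one-letter codes"
                )
            logger.warning("nonstandard residue %r at position %d mapped to padding", ch, i)
            idx = 0
        out[i] = idx
    return out


@dataclass
class EncodedBatch:
    """Row-aligned model inputs for K complexes.

    ``smiles_codes`` is K x L, ``pocket_codes`` K x M, ``descriptors``
    K x D (D may be 0 when no descriptor vectors were supplied).
    """

    smiles_codes: np.ndarray
    pocket_codes: np.ndarray
    descriptors: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.smiles_codes.shape[0]

    @property
    def L(self) -> int:
        return self.smiles_codes.shape[1]

    @property
    def M(self) -> int:
        return self.pocket_codes.shape[1]

    @property
    def D(self) -> int:
        return self.descriptors.shape[1]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "EncodedBatch":
        rows = np.asarray(rows)
        return EncodedBatch(
            smiles_codes=self.smiles_codes[rows],
            pocket_codes=self.pocket_codes[rows],
            descriptors=self.descriptors[rows],
            ids=[self.ids[i] for i in rows] if self.ids else [],
        )


def encode_batch(
    records: Iterable,
    L: int = SMILES_MAX_LEN,
    M: int = POCKET_MAX_LEN,
    D: int | None = DESCRIPTOR_WIDTH,
    strict_residues: bool = True,
) -> EncodedBatch:
    """Encode a list of complex records into aligned input matrices.

    All-or-nothing: any malformed SMILES, sequence, or descriptor-width
    mismatch aborts the whole batch with an error naming the record.
    ``D=None`` infers the width from the first record carrying
    descriptors (0 if none do).
    """
    records = list(records)
    K = len(records)
    if D is None:
        D = next(
            (len(r.descriptors) for r in records if getattr(r, "descriptors", None) is not None),
            0,
        )
    smiles_codes = np.zeros((K, L), dtype=np.int32)
    pocket_codes = np.zeros((K, M), dtype=np.int32)
    descriptors = np.zeros((K, D), dtype=np.float32)
    ids: list[str] = []
    svocab, pvocab = build_smiles_vocab(), build_pocket_vocab()
    for i, rec in enumerate(records):
        try:
            smiles_codes[i] = encode_smiles(rec.smiles, svocab, L)
            pocket_codes[i] = encode_pocket_sequence(
                rec.pocket_seq, pvocab, M, strict=strict_residues
            )
        except EncodingError as exc:
            raise EncodingError(f"record {rec.id!r}: {exc}") from exc
        if D:
            if rec.descriptors is None or len(rec.descriptors) != D:
                found = 0 if rec.descriptors is None else len(rec.descriptors)
                raise ValueError(
                    f"record {rec.id!r}: expected descriptor width {D}, found {found}"
                )
            descriptors[i] = np.asarray(rec.descriptors, dtype=np.float32)
        ids.append(rec.id)
    return EncodedBatch(smiles_codes, pocket_codes, descriptors, ids)


def labels_of(records: Iterable) -> np.ndarray:
    """pK label vector aligned with ``encode_batch`` rows."""
    return np.array([r.label.pk for r in records], dtype=np.float64)


def read_pocket_fasta(path) -> dict[str, str]:
    """Pocket sequences from a FASTA file, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def extract_pocket_sequence(pdb_text: str, strict: bool = True) -> str:
    """Read the one-letter residue sequence out of a pocket PDB file.

    Residues are taken in order of first appearance (chains in file
    order), keyed by chain / residue number / insertion code, using
    Bio.PDB for the fixed-column parsing.  Unknown residue names raise
    in strict mode and become ``'X'`` in lenient mode (which the
    sequence encoder's lenient mode then treats as padding).
    """
    from Bio.PDB import PDBParser

    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        logger.warning("no ATOM records found in PDB text")
        return ""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("pocket", io.StringIO(pdb_text))
    letters: list[str] = []
    model = next(structure.get_models(), None)
    if model is None:
        logger.warning("no parseable ATOM records in PDB text")
        return ""
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname == "HOH":
                continue
            one = THREE_TO_ONE.get(resname)
            if one is None:
                if strict:
                    raise EncodingError(
                        f"unknown residue name {resname!r} in chain {chain.id!r}"
                    )
                logger.warning("unknown residue %r mapped to 'X'", resname)
                one = "X"
            letters.append(one)
    if not letters:
        logger.warning("no amino-acid residues found in PDB text")
    return "".join(letters)
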