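"""Clone tables and the fixed-length one-hot representation.

A clone is a CDR3 amino-acid string with an optional V gene and an optional
frequency (count or proportion, stored as given).  For the neural models each
clone is flattened into a single binary vector: per CDR3 position a 21-block
(20 amino acids + a stop symbol), then a stop block, right zero-padding up to
the maximal length ``m`` of the corpus, and finally an ``n_V``-dimensional
one-hot block for the V gene when V usage is encoded, giving
``n = 21 * (m + 1) + n_V`` dimensions in total.

The stop symbol occupies index 20 of every 21-block.  Decoding takes the
argmax of each 21-block and stops at the leftmost stop block; everything to
the right of it is ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.  Block index = position here.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Stop symbol appended to every CDR3 before one-hot encoding.
STOP_SYMBOL = "!"

#: Index of the stop symbol inside each 21-block.
STOP_INDEX = 20

BLOCK = 21

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


class FormatError(ValueError):
    """Input table does not match the declared column mapping."""


class EmptySampleError(ValueError):
    """No valid clones remain after filtering."""


class SchemeError(ValueError):
    """A clone cannot be represented under the given encoding scheme."""


@dataclass(frozen=True)
class TCRClone:
    """One T-cell clone: CDR3 amino-acid string, optional V gene / frequency."""

    cdr3: str
    v_gene: str | None = None
    frequency: float | None = None

    def __post_init__(self) -> None:
        if not self.cdr3:
            raise ValueError("CDR3 must be non-empty")
        bad = set(self.cdr3) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"CDR3 {self.cdr3!r} has non-standard characters {sorted(bad)}")
        if self.frequency is not None and not self.frequency > 0:
            raise ValueError("frequency must be positive when present")


@dataclass
class RepertoireSample:
    """A named, ordered collection of clones with a category tag.

    All clones in a sample share the same presence/absence pattern for
    ``v_gene`` and ``frequency``.
    """

    sample_id: str
    clones: list[TCRClone]
    category: str = ""

    def __post_init__(self) -> None:
        if self.clones:
            has_v = {c.v_gene is not None for c in self.clones}
            has_f = {c.frequency is not None for c in self.clones}
            if len(has_v) > 1:
                raise ValueError(f"sample {self.sample_id}: mixed V-gene presence")
            if len(has_f) > 1:
                raise ValueError(f"sample {self.sample_id}: mixed frequency presence")

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones)

    @property
    def has_v(self) -> bool:
        return bool(self.clones) and self.clones[0].v_gene is not None

    @property
    def has_frequency(self) -> bool:
        return bool(self.clones) and self.clones[0].frequency is not None

    def cdr3s(self) -> list[str]:
        return [c.cdr3 for c in self.clones]

    def subsample(self, r: int, rng: np.random.Generator, strict: bool = True) -> "RepertoireSample":
        """Seeded draw of ``r`` clones without replacement.

        With ``strict=False`` a sample smaller than ``r`` is returned whole.
        """
        if len(self.clones) < r:
            if strict:
                raise ValueError(f"sample {self.sample_id} has {len(self.clones)} < {r} clones")
            return replace(self, clones=list(self.clones))
        idx = rng.choice(len(self.clones), size=r, replace=False)
        return replace(self, clones=[self.clones[i] for i in sorted(idx)])


@dataclass(frozen=True)
class EncodingScheme:
    """Fixed geometry of the one-hot representation.

    m is the maximal CDR3 length; ``v_catalogue`` is the ordered list of V
    names (empty when V is not encoded); ``n = 21 * (m + 1) + n_V``.
    """

    m: int
    v_catalogue: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def n_v(self) -> int:
        return len(self.v_catalogue)

    @property
    def n_blocks(self) -> int:
        return self.m + 1

    @property
    def n(self) -> int:
        return BLOCK * (self.m + 1) + self.n_v

    @property
    def use_v(self) -> bool:
        return self.n_v > 0

    def v_index(self, v_gene: str) -> int:
        try:
            return self.v_catalogue.index(v_gene)
        except ValueError:
            raise SchemeError(f"V gene {v_gene!r} not in catalogue") from None

    def to_dict(self) -> dict:
        return {"m": self.m, "alphabet": AA_ALPHABET + STOP_SYMBOL, "v_catalogue": list(self.v_catalogue)}

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingScheme":
        if d.get("alphabet", AA_ALPHABET + STOP_SYMBOL) != AA_ALPHABET + STOP_SYMBOL:
            raise SchemeError("scheme was saved under a different alphabet order")
        return cls(m=int(d["m"]), v_catalogue=tuple(d.get("v_catalogue", ())))


# ---------------------------------------------------------------------------
# table / FASTA readers


def _clean_cdr3(raw: object) -> str | None:
    """Uppercase and validate one CDR3 string; None when the row must drop."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip().upper()
    if not s or set(s) - set(AA_ALPHABET):
        return None
    return s


def load_repertoire(
    path: str | Path,
    sample_id: str | None = None,
    category: str = "",
    cdr3_column: str = "cdr3",
    v_column: str | None = "v",
    frequency_column: str | None = "frequency",
    sep: str | None = None,
) -> RepertoireSample:
    """Read one clone table (TSV/CSV with a header) into a sample.

    Rows whose CDR3 contains any character outside the 20 standard amino
    acids — e.g. the non-IUPAC letters X, *, _, # — are dropped and the drop
    count logged.  Sequences are uppercased before validation.  The V and
    frequency columns are used only when present in the file.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if cdr3_column not in df.columns:
        raise FormatError(f"{path}: no column {cdr3_column!r} (columns: {list(df.columns)})")
    use_v = v_column is not None and v_column in df.columns
    use_f = frequency_column is not None and frequency_column in df.columns

    clones: list[TCRClone] = []
    dropped = 0
    for _, row in df.iterrows():
        cdr3 = _clean_cdr3(row[cdr3_column])
        if cdr3 is None:
            dropped += 1
            continue
        clones.append(
            TCRClone(
                cdr3=cdr3,
                v_gene=str(row[v_column]) if use_v else None,
                frequency=float(row[frequency_column]) if use_f else None,
            )
        )
    if dropped:
        logger.info("%s: dropped %d/%d rows with non-standard CDR3 characters", path, dropped, len(df))
    if not clones:
        raise EmptySampleError(f"{path}: no valid clones after filtering")
    return RepertoireSample(sample_id=sample_id or path.stem, clones=clones, category=category)


def load_fasta(path: str | Path, sample_id: str | None = None, category: str = "") -> RepertoireSample:
    """Read a headerless CDR3 list in FASTA form (one sequence per record)."""
    path = Path(path)
    clones = []
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        cdr3 = _clean_cdr3(str(rec.seq))
        if cdr3 is None:
            dropped += 1
            continue
        clones.append(TCRClone(cdr3=cdr3))
    if dropped:
        logger.info("%s: dropped %d records with non-standard characters", path, dropped)
    if not clones:
        raise EmptySampleError(f"{path}: no valid sequences")
    return RepertoireSample(sample_id=sample_id or path.stem, clones=clones, category=category)


def write_repertoire(sample: RepertoireSample, path: str | Path) -> None:
    """Write a sample as a TSV clone table (columns cdr3 / v / frequency)."""
    cols: dict[str, list] = {"cdr3": sample.cdr3s()}
    if sample.has_v:
        cols["v"] = [c.v_gene for c in sample.clones]
    if sample.has_frequency:
        cols["frequency"] = [c.frequency for c in sample.clones]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scheme construction and the one-hot map


def build_scheme(samples: Iterable[RepertoireSample], use_v: bool = False) -> EncodingScheme:
    """Fix m and the V catalogue from a training corpus.

    m is the maximal CDR3 length over all clones; the catalogue is the sorted
    set of distinct V names when ``use_v``.  m stays fixed afterwards: a
    longer CDR3 at inference is an error, never silently truncated.
    """
    m = 0
    v_names: set[str] = set()
    n_clones = 0
    for sample in samples:
        for clone in sample:
            n_clones += 1
            m = max(m, len(clone.cdr3))
            if use_v:
                if clone.v_gene is None:
                    raise SchemeError(f"use_v requested but clone {clone.cdr3} in {sample.sample_id} lacks a V gene")
                v_names.add(clone.v_gene)
    if n_clones == 0:
        raise EmptySampleError("cannot build a scheme from zero clones")
    return EncodingScheme(m=m, v_catalogue=tuple(sorted(v_names)))


def encode(clone: TCRClone, scheme: EncodingScheme) -> np.ndarray:
    """One-hot encode a clone: AA blocks, stop block, zero padding, V block."""
    l = len(clone.cdr3)
    if l > scheme.m:
        raise SchemeError(f"CDR3 {clone.cdr3!r} longer than scheme m={scheme.m}")
    x = np.zeros(scheme.n, dtype=np.float32)
    for pos, aa in enumerate(clone.cdr3):
        x[pos * BLOCK + _AA_INDEX[aa]] = 1.0
    x[l * BLOCK + STOP_INDEX] = 1.0
    if scheme.use_v:
        if clone.v_gene is None:
            raise SchemeError("scheme encodes V but clone has no V gene")
        x[BLOCK * scheme.n_blocks + scheme.v_index(clone.v_gene)] = 1.0
    return x


def encode_batch(clones: Sequence[TCRClone], scheme: EncodingScheme) -> np.ndarray:
    """Encode many clones into an (n_clones, n) float32 matrix."""
    out = np.zeros((len(clones), scheme.n), dtype=np.float32)
    for i, clone in enumerate(clones):
        out[i] = encode(clone, scheme)
    return out


def decode(vector: np.ndarray, scheme: EncodingScheme) -> tuple[str, str | None]:
    """Map any real vector of length n back to (cdr3, v_gene).

    Each 21-block contributes the argmax symbol; the sequence ends at the
    leftmost block whose argmax is the stop symbol (or at block m+1), and all
    blocks right of it are ignored.  Argmax ties break toward the lowest
    index.  The V gene is the argmax of the V block when the scheme has one.
    """
    vector = np.asarray(vector)
    if vector.shape != (scheme.n,):
        raise SchemeError(f"expected a vector of length {scheme.n}, got shape {vector.shape}")
    blocks = vector[: BLOCK * scheme.n_blocks].reshape(scheme.n_blocks, BLOCK)
    symbols = np.argmax(blocks, axis=1)
    chars: list[str] = []
    for sym in symbols:
        if sym == STOP_INDEX:
            break
        chars.append(AA_ALPHABET[sym])
    cdr3 = "".join(chars)
    v_gene = None
    if scheme.use_v:
        v_gene = scheme.v_catalogue[int(np.argmax(vector[BLOCK * scheme.n_blocks :]))]
    return cdr3, v_gene


def decode_batch(matrix: np.ndarray, scheme: EncodingScheme) -> list[tuple[str, str | None]]:
    return [decode(row, scheme) for row in np.asarray(matrix)]


def save_encoded(path: str | Path, matrix: np.ndarray, scheme: EncodingScheme) -> None:
    """Save an encoded matrix (.npz) with a JSON scheme sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), encoded=matrix)
    path.with_suffix(".scheme.json").write_text(json.dumps(scheme.to_dict(), indent=1))


def load_encoded(path: str | Path) -> tuple[np.ndarray, EncodingScheme]:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npz"))["encoded"]
    scheme = EncodingScheme.from_dict(json.loads(path.with_suffix(".scheme.json").read_text()))
    return matrix, scheme
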