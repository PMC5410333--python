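"""PSSM containers, PSI-BLAST ASCII I/O, pair lists, and synthetic data.

A position-specific scoring matrix (PSSM) summarises the evolutionary
conservation of one protein as an L x 20 matrix of integer log-odds
substitution scores, one row per residue position and one column per
amino acid. PSI-BLAST emits these as ASCII files (``-out_ascii_pssm``);
this module reads and writes that dialect, handles tab-separated
labelled pair lists, and synthesises PSSM-shaped data with controllable
texture so the downstream descriptor and classifier can be exercised
without any database search.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np
from scipy import ndimage

__all__ = [
    "PSSM",
    "PairRecord",
    "PssmFormatError",
    "parse_psiblast_pssm",
    "write_pssm",
    "read_pssm_dir",
    "read_pair_list",
    "write_pair_list",
    "read_fasta_ids",
    "synth_pssm",
    "synth_pair_dataset",
]

#: Amino-acid column order used by PSI-BLAST ASCII PSSM output.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWVY"

#: Integer score range typical of PSI-BLAST log-odds output; synthetic
#: matrices are clipped to it (real files are accepted unclipped).
SCORE_MIN, SCORE_MAX = -16, 13


class PssmFormatError(ValueError):
    """Raised when a PSSM file or pair list cannot be parsed."""


@dataclass(frozen=True)
class PSSM:
    """One protein's L x 20 integer log-odds score matrix."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.protein_id!r}: expected L x 20 scores, "
                f"got shape {scores.shape}"
            )
        if scores.shape[0] < 2:
            raise ValueError(
                f"PSSM {self.protein_id!r}: need at least 2 rows "
                f"(got {scores.shape[0]}); a 3x3 neighbourhood requires context"
            )
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(np.isfinite(scores)) or np.any(scores != np.round(scores)):
                raise ValueError(
                    f"PSSM {self.protein_id!r}: scores must be finite integers"
                )
            scores = scores.astype(np.int64)
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class PairRecord:
    """A labelled protein pair: 1 = interacting, 0 = non-interacting."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"pair label must be 0 or 1, got {self.label!r}")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM I/O
# ---------------------------------------------------------------------------

def parse_psiblast_pssm(stream: TextIO | str, protein_id: str = "") -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PSSM`.

    Data rows look like ``pos residue s1 .. s20 ...``; only the first 20
    score columns (the log-odds block) are consumed, so files with the
    trailing 20-column percentage block and footer statistics parse the
    same as bare ones.

    Parameters
    ----------
    stream:
        Open text handle or the file content as a string.
    protein_id:
        Identifier to attach; defaults to the stream's ``name`` stem when
        available.

    Raises
    ------
    PssmFormatError
        On a data row with fewer than 20 parseable score fields, or when
        the file contains no data rows at all.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if not protein_id:
        name = getattr(stream, "name", "")
        protein_id = Path(name).stem if name else "unnamed"

    rows: list[list[int]] = []
    expected_pos = 1
    for lineno, raw in enumerate(stream, start=1):
        parts = raw.split()
        # A data row starts "pos residue ..." where pos is the 1-based
        # position index; anything else is header/footer and is skipped.
        if len(parts) < 2 or not parts[0].isdigit() or int(parts[0]) != expected_pos:
            continue
        fields = parts[2:2 + 20]
        try:
            scores = [int(f) for f in fields]
        except ValueError as exc:
            raise PssmFormatError(
                f"line {lineno}: non-integer score field in PSSM row: {exc}"
            ) from None
        if len(scores) != 20:
            raise PssmFormatError(
                f"line {lineno}: expected 20 score fields, got {len(scores)}"
            )
        rows.append(scores)
        expected_pos += 1

    if not rows:
        raise PssmFormatError("no PSSM data rows found in input")
    return PSSM(protein_id=protein_id, scores=np.asarray(rows, dtype=np.int64))


def write_pssm(p: PSSM, stream: TextIO | None = None) -> str:
    """Serialise a :class:`PSSM` in PSI-BLAST ASCII layout.

    Only the 20-column log-odds block is written (residue column filled
    with ``X`` for synthetic matrices). The output round-trips through
    :func:`parse_psiblast_pssm`.
    """
    out = io.StringIO()
    out.write("\n")
    out.write("Last position-specific scoring matrix computed\n")
    header = " ".join(f"{aa:>3}" for aa in PSSM_ALPHABET)
    out.write(f"          {header}\n")
    for i, row in enumerate(p.scores, start=1):
        cells = " ".join(f"{int(v):>3d}" for v in row)
        out.write(f"{i:>5d} X  {cells}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_pssm_dir(directory: str | Path, suffix: str = ".pssm") -> dict[str, PSSM]:
    """Load every ``*.pssm`` file in a directory, keyed by file stem."""
    directory = Path(directory)
    collection: dict[str, PSSM] = {}
    for path in sorted(directory.glob(f"*{suffix}")):
        with open(path) as fh:
            collection[path.stem] = parse_psiblast_pssm(fh, protein_id=path.stem)
    if not collection:
        raise FileNotFoundError(f"no {suffix} files under {directory}")
    return collection


# ---------------------------------------------------------------------------
# Pair lists and FASTA bookkeeping
# ---------------------------------------------------------------------------

def read_pair_list(
    stream: TextIO | str | Path,
    pssms: Mapping[str, PSSM] | None = None,
) -> list[PairRecord]:
    """Read a tab-separated ``id_a<TAB>id_b<TAB>label`` pair list.

    Blank lines and ``#`` comments are skipped. When ``pssms`` is given,
    every referenced identifier must resolve to a loaded PSSM.
    """
    if isinstance(stream, Path):
        stream = stream.read_text()
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[PairRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise PssmFormatError(
                f"line {lineno}: expected 'id_a id_b label', got {line!r}"
            )
        id_a, id_b, label_str = parts
        try:
            label = int(label_str)
        except ValueError:
            raise PssmFormatError(
                f"line {lineno}: label must be 0 or 1, got {label_str!r}"
            ) from None
        rec = PairRecord(id_a=id_a, id_b=id_b, label=label)
        if pssms is not None:
            for pid in (rec.id_a, rec.id_b):
                if pid not in pssms:
                    raise KeyError(
                        f"line {lineno}: pair references unknown protein {pid!r}"
                    )
        records.append(rec)
    return records


def write_pair_list(records: Iterable[PairRecord], stream: TextIO) -> None:
    stream.write("# id_a\tid_b\tlabel\n")
    for rec in records:
        stream.write(f"{rec.id_a}\t{rec.id_b}\t{rec.label}\n")


def read_fasta_ids(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: sequence}`` for bookkeeping.

    Sequences are never used for feature extraction (features come from
    PSSMs); this exists so pair lists can be cross-checked against the
    sequence inventory.
    """
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

TEXTURES = ("smooth", "rough", "motif")


def _unit_smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Gaussian random field low-pass filtered to suppress local gradients,
    rescaled to unit standard deviation."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0, mode="nearest")
    sd = field.std()
    return field / sd if sd > 0 else field


def _stripe_field(rng: np.random.Generator, shape: tuple[int, int], period: int = 4) -> np.ndarray:
    """Periodic +/-1 row stripes with a random phase: a strong, oriented
    texture that the descriptor's Sobel orientation channel picks up."""
    phase = int(rng.integers(period))
    rows = (np.arange(shape[0]) + phase) % period
    stripe = np.where(rows < period // 2, 1.0, -1.0)
    return np.repeat(stripe[:, None], shape[1], axis=1)


def synth_pssm(
    length: int,
    seed: int,
    texture: str = "rough",
    amplitude: float = 5.0,
) -> PSSM:
    """Generate a synthetic PSSM with a controlled texture regime.

    ``smooth`` draws spatially correlated scores (low local gradients),
    ``rough`` i.i.d. integer noise (high local gradients), and ``motif``
    plants periodic row stripes. All three are deterministic in
    ``(length, seed, texture, amplitude)`` and clipped to the typical
    PSI-BLAST score range [-16, 13].
    """
    if length < 2:
        raise ValueError(f"length must be >= 2, got {length}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    if texture not in TEXTURES:
        raise ValueError(f"texture must be one of {TEXTURES}, got {texture!r}")

    rng = np.random.default_rng(seed)
    shape = (length, 20)
    if texture == "smooth":
        field = amplitude * _unit_smooth_field(rng, shape)
    elif texture == "rough":
        field = amplitude * rng.standard_normal(shape)
    else:  # motif
        field = amplitude * _stripe_field(rng, shape) + 0.5 * rng.standard_normal(shape)

    scores = np.clip(np.round(field), SCORE_MIN, SCORE_MAX).astype(np.int64)
    return PSSM(protein_id=f"synth_{texture}_L{length}_s{seed}", scores=scores)


def _regime_protein(
    rng: np.random.Generator,
    protein_id: str,
    length: int,
    regime: str,
    effect: float,
    base_amplitude: float = 3.0,
) -> PSSM:
    """One synthetic protein = base i.i.d. noise plus an ``effect``-scaled
    regime signal (A: smooth field, B: row stripes). At effect=0 the two
    regimes are statistically identical."""
    shape = (length, 20)
    base = base_amplitude * rng.standard_normal(shape)
    if regime == "A":
        signal = _unit_smooth_field(rng, shape)
    else:
        signal = _stripe_field(rng, shape)
    scores = np.clip(np.round(base + effect * signal), SCORE_MIN, SCORE_MAX)
    return PSSM(protein_id=protein_id, scores=scores.astype(np.int64))


def synth_pair_dataset(
    n_pairs: int,
    length_range: tuple[int, int] = (30, 80),
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, PSSM], list[PairRecord]]:
    """Synthesise a balanced labelled pair dataset with tunable separability.

    Positive (interacting) pairs join two regime-A proteins; negative
    pairs join one regime-A and one regime-B protein in random order, so
    the classes differ only through the texture contrast between regimes,
    whose strength scales with ``effect``. ``effect=0`` makes the label
    independent of the features (a null dataset).

    Returns the protein collection and ``n_pairs`` records, exactly half
    of them positive. Bit-reproducible for a fixed seed.
    """
    if n_pairs % 2 != 0:
        raise ValueError(f"n_pairs must be even, got {n_pairs}")
    if effect < 0:
        raise ValueError(f"effect must be >= 0, got {effect}")
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")

    rng = np.random.default_rng(seed)
    pssms: dict[str, PSSM] = {}
    records: list[PairRecord] = []

    def make(regime: str, idx: int) -> str:
        pid = f"P{idx:05d}{regime}"
        length = int(rng.integers(lo, hi + 1))
        pssms[pid] = _regime_protein(rng, pid, length, regime, effect)
        return pid

    idx = 0
    for _ in range(n_pairs // 2):
        a, b = make("A", idx), make("A", idx + 1)
        idx += 2
        records.append(PairRecord(a, b, 1))
    for _ in range(n_pairs // 2):
        a, b = make("A", idx), make("B", idx + 1)
        idx += 2
        if rng.random() < 0.5:
            a, b = b, a
        records.append(PairRecord(a, b, 0))
    return pssms, records
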