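"""Uncorrected p-distances, clade summaries and the mitochondrial NUMT screen.

COI barcoding of cryptic species complexes typically reports the
uncorrected proportion of differing sites (p-distance) between aligned
sequences, averaged within and between clades.  Nuclear copies of
mitochondrial fragments (NUMTs) are screened for by translating under the
invertebrate mitochondrial genetic code (NCBI table 5: TGA = Trp,
ATA = Met, AGA/AGG = Ser; stops TAA/TAG) and flagging unexpected internal
stop codons or gap-containing codons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ComputationError, ValidationError

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN-")
#: NCBI translation table 5, the invertebrate mitochondrial code.
INVERT_MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]

#: IUPAC ambiguity codes (beyond N) collapsed to N on ingest.
_AMBIGUITY = set("RYSWKMBDHV")


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length nucleotide sequences over {A, C, G, T, N, -}."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValidationError("empty sequence set")
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, s in zip(self.ids, self.sequences):
            bad = set(s) - VALID_CHARS
            if bad:
                raise ValidationError(f"{sid}: invalid characters {sorted(bad)}")

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "AlignedSequenceSet":
        """Build from (id, sequence) pairs, normalising case, U→T and
        ambiguity codes (collapsed to N with a logged count)."""
        ids, seqs = [], []
        n_ambig = 0
        for sid, seq in records:
            s = seq.upper().replace("U", "T")
            n_ambig += sum(c in _AMBIGUITY for c in s)
            s = "".join("N" if c in _AMBIGUITY else c for c in s)
            ids.append(sid)
            seqs.append(s)
        if n_ambig:
            logger.warning("collapsed %d IUPAC ambiguity bases to N", n_ambig)
        return cls(ids=tuple(ids), sequences=tuple(seqs))


@dataclass(frozen=True)
class DistanceSummary:
    """Within- and between-clade mean p-distances (unweighted over pairs)."""

    within: dict  # clade -> mean distance or None (singleton clade)
    between: dict  # frozenset({c1, c2}) -> mean distance

    def to_dict(self) -> dict:
        return {
            "within": dict(self.within),
            "between": {" vs ".join(sorted(k)): v for k, v in self.between.items()},
        }


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _comparable_mask(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    good = np.frombuffer(b"ACGT", dtype="S1")
    return np.isin(s1, good) & np.isin(s2, good)


def _to_array(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype="S1")


def p_distance(s1: str, s2: str, deletion: str = "pairwise") -> float:
    """Uncorrected proportion of differing sites between two sequences.

    Sites where either sequence carries N or '-' are excluded.  For a
    single pair the ``pairwise`` and ``complete-set`` deletion modes
    coincide; complete-set deletion differs only across a whole set (see
    :func:`distance_matrix`).
    """
    if deletion not in ("pairwise", "complete-set"):
        raise ValidationError(f"unknown deletion mode {deletion!r}")
    if len(s1) != len(s2):
        raise ValidationError(f"unequal sequence lengths ({len(s1)} vs {len(s2)})")
    a1, a2 = _to_array(s1.upper()), _to_array(s2.upper())
    mask = _comparable_mask(a1, a2)
    n = int(mask.sum())
    if n == 0:
        raise ComputationError("no comparable sites after deletion")
    return float((a1[mask] != a2[mask]).sum()) / n


def distance_matrix(seqs: AlignedSequenceSet, deletion: str = "pairwise") -> pd.DataFrame:
    """All-pairs p-distance matrix (symmetric, zero diagonal).

    ``complete-set`` deletion first drops every alignment column containing
    N or '-' in any sequence; ``pairwise`` excludes such sites per pair.
    """
    if deletion == "complete-set":
        arrs = np.vstack([_to_array(s) for s in seqs.sequences])
        good = np.frombuffer(b"ACGT", dtype="S1")
        keep = np.isin(arrs, good).all(axis=0)
        if not keep.any():
            raise ComputationError("complete-set deletion removed every column")
        strings = ["".join(row.astype(str)) for row in arrs[:, keep]]
        work = AlignedSequenceSet(ids=seqs.ids, sequences=tuple(strings))
        mode = "pairwise"
    elif deletion == "pairwise":
        work, mode = seqs, "pairwise"
    else:
        raise ValidationError(f"unknown deletion mode {deletion!r}")

    n = len(work)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = p_distance(work.sequences[i], work.sequences[j], mode)
        except ComputationError as exc:
            raise ComputationError(
                f"pair ({work.ids[i]}, {work.ids[j]}): {exc}") from exc
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=list(seqs.ids), columns=list(seqs.ids))


def clade_summary(matrix: pd.DataFrame, clades: Mapping[str, str]) -> DistanceSummary:
    """Unweighted within- and between-clade mean p-distances.

    ``within`` is None for singleton clades (undefined, not an error);
    ``between`` averages over all cross pairs of each clade pair.
    """
    unknown = set(clades) - set(matrix.index)
    if unknown:
        raise ValidationError(f"clade map references unknown ids: {sorted(unknown)}")
    members: dict[str, list[str]] = {}
    for sid, clade in clades.items():
        members.setdefault(clade, []).append(sid)

    within = {}
    for clade, ids in members.items():
        if len(ids) < 2:
            within[clade] = None
            continue
        vals = [matrix.at[i, j] for i, j in itertools.combinations(ids, 2)]
        within[clade] = float(np.mean(vals))

    between = {}
    for c1, c2 in itertools.combinations(sorted(members), 2):
        vals = [matrix.at[i, j] for i in members[c1] for j in members[c2]]
        between[frozenset((c1, c2))] = float(np.mean(vals))
    return DistanceSummary(within=within, between=between)


# ---------------------------------------------------------------------------
# translation screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenFlags:
    """NUMT-screen findings on one sequence/frame."""

    internal_stops: tuple[int, ...]  # 0-based codon indices, excluding the last codon
    terminal_stop: bool
    ambiguous_codons: tuple[int, ...]  # codons containing N or '-'

    @property
    def clean(self) -> bool:
        return not self.internal_stops and not self.ambiguous_codons

    def to_dict(self) -> dict:
        return {"internal_stops": list(self.internal_stops),
                "terminal_stop": self.terminal_stop,
                "ambiguous_codons": list(self.ambiguous_codons)}


def translate_and_screen(seq: str, frame: int = 0) -> tuple[str, ScreenFlags]:
    """Translate under the invertebrate mitochondrial code and flag NUMT signals.

    Codons start at ``frame`` (0–2); a trailing partial codon is dropped.
    Stop codons translate to ``*``, gap/ambiguity codons to ``X``; internal
    stops (any stop before the final codon) and ambiguity codons are the
    NUMT warning signs.
    """
    if frame not in (0, 1, 2):
        raise ValidationError(f"frame must be 0, 1 or 2, got {frame}")
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_CHARS
    if bad:
        raise ValidationError(f"invalid characters {sorted(bad)}")
    if len(s) < frame + 3:
        raise ValidationError("sequence too short for a single codon in this frame")
    codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]

    aa, stops, ambig = [], [], []
    for i, codon in enumerate(codons):
        if set(codon) - set("ACGT"):
            aa.append("X")
            ambig.append(i)
        elif codon in INVERT_MITO_TABLE.stop_codons:
            aa.append("*")
            stops.append(i)
        else:
            aa.append(INVERT_MITO_TABLE.forward_table[codon])
    last = len(codons) - 1
    flags = ScreenFlags(
        internal_stops=tuple(i for i in stops if i != last),
        terminal_stop=last in stops,
        ambiguous_codons=tuple(ambig),
    )
    return "".join(aa), flags


def best_reading_frame(seq: str) -> int:
    """Frame (0–2) with the fewest internal stop codons; ties take the lowest."""
    if len(seq) < 5:
        raise ValidationError("sequence too short to compare reading frames")
    counts = []
    for frame in (0, 1, 2):
        _, flags = translate_and_screen(seq, frame)
        counts.append(len(flags.internal_stops))
    return int(np.argmin(counts))


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> AlignedSequenceSet:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return AlignedSequenceSet.from_records(records)


def write_fasta(seqs: AlignedSequenceSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="")
               for sid, s in zip(seqs.ids, seqs.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Clade map TSV: ``sequence_id<TAB>clade`` with optional header."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected two tab-separated columns")
    if list(df.iloc[0]) == ["sequence_id", "clade"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_distance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
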