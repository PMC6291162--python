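"""Residue-position mapping between paralogous proteins.

Homologous-position claims ("Val25 of RALA corresponds to Val14 of KRAS")
are made explicit here through an optimal global pairwise alignment
(Needleman–Wunsch with affine gaps, BLOSUM62, gap open 11 / extend 1 —
the ubiquitous protein defaults) rather than inherited from published
numbering. Positions are 1-based on each sequence; a position aligned to
a gap maps to ``None``.
"""

from __future__ import annotations

import csv
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .cohort_io import ProteinVariant

__all__ = [
    "AlignmentMap",
    "ScoringConfig",
    "global_align",
    "map_position",
    "homolog_report",
    "read_fasta",
    "read_known_positions",
    "fetch_uniprot_fasta",
    "write_alignment",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZXUO")


@dataclass(frozen=True)
class ScoringConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass
class AlignmentMap:
    """A pairwise global alignment as a list of aligned columns.

    ``columns`` holds ``(a_pos, b_pos)`` pairs where each element is a
    1-based position or ``None`` for a gap in that sequence.
    """

    id_a: str
    seq_a: str
    id_b: str
    seq_b: str
    columns: list[tuple[int | None, int | None]]
    score: float
    scoring: ScoringConfig
    percent_identity: float

    def a_to_b(self) -> dict[int, int]:
        return {a: b for a, b in self.columns if a is not None and b is not None}

    def reversed(self) -> "AlignmentMap":
        return AlignmentMap(
            id_a=self.id_b, seq_a=self.seq_b, id_b=self.id_a, seq_b=self.seq_a,
            columns=[(b, a) for a, b in self.columns],
            score=self.score, scoring=self.scoring,
            percent_identity=self.percent_identity,
        )


def _validate(seq: str, label: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = sorted(set(seq) - VALID_AA)
    if bad:
        raise ValueError(f"{label}: invalid residue characters {bad}")
    return seq


def global_align(
    record_a: tuple[str, str],
    record_b: tuple[str, str],
    scoring: ScoringConfig = ScoringConfig(),
) -> AlignmentMap:
    """Optimal global alignment of two protein sequences.

    ``record_a`` / ``record_b`` are ``(id, sequence)`` pairs. Ties between
    equal-scoring optima are broken deterministically by taking the
    aligner's first reported alignment (match/mismatch preferred over
    opening a gap).
    """
    id_a, raw_a = record_a
    id_b, raw_b = record_b
    seq_a = _validate(raw_a, id_a)
    seq_b = _validate(raw_b, id_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -abs(scoring.gap_open)
    aligner.extend_gap_score = -abs(scoring.gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    columns: list[tuple[int | None, int | None]] = []
    matches = 0
    a_str, b_str = str(aln[0]), str(aln[1])
    ia = ib = 0
    for ca, cb in zip(a_str, b_str):
        a_pos = b_pos = None
        if ca != "-":
            ia += 1
            a_pos = ia
        if cb != "-":
            ib += 1
            b_pos = ib
        if ca != "-" and cb != "-" and ca == cb:
            matches += 1
        columns.append((a_pos, b_pos))
    identity = 100.0 * matches / len(columns) if columns else 0.0
    return AlignmentMap(
        id_a=id_a, seq_a=seq_a, id_b=id_b, seq_b=seq_b,
        columns=columns, score=float(aln.score), scoring=scoring,
        percent_identity=identity,
    )


def map_position(amap: AlignmentMap, a_pos: int) -> int | None:
    """Position in sequence B aligned to 1-based ``a_pos`` in sequence A."""
    if not 1 <= a_pos <= len(amap.seq_a):
        raise IndexError(
            f"position {a_pos} outside {amap.id_a} (length {len(amap.seq_a)})"
        )
    return amap.a_to_b().get(a_pos)


def homolog_report(
    cohort_variants: Iterable[ProteinVariant],
    maps: Sequence[AlignmentMap],
    known_disease_positions: Sequence[dict] = (),
) -> list[dict]:
    """Homologous residues (and known disease matches) per cohort variant.

    Each row gives the cohort variant, the paralog, the mapped residue
    (or a gap marker) and any known disease-associated position at that
    paralog residue.
    """
    known_by_gene: dict[str, dict[int, dict]] = {}
    for entry in known_disease_positions:
        known_by_gene.setdefault(entry["gene"], {})[int(entry["residue"])] = entry
    rows = []
    for v in cohort_variants:
        for amap in maps:
            if amap.id_a.split("|")[0] != v.gene_symbol:
                continue
            b_pos = map_position(amap, v.codon_index) if v.codon_index <= len(amap.seq_a) else None
            paralog = amap.id_b.split("|")[0]
            match = known_by_gene.get(paralog, {}).get(b_pos) if b_pos else None
            rows.append(
                {
                    "gene": v.gene_symbol,
                    "protein_change": v.protein_change,
                    "residue": v.codon_index,
                    "paralog": paralog,
                    "paralog_residue": b_pos if b_pos is not None else "gap",
                    "paralog_ref_residue": amap.seq_b[b_pos - 1] if b_pos else "",
                    "known_phenotype": match["phenotype"] if match else "",
                    "citation": match["citation"] if match else "",
                }
            )
    return rows


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_known_positions(path: str | Path) -> list[dict]:
    """Read the known disease-position TSV (gene, residue, phenotype, citation)."""
    with Path(path).open(encoding="utf-8") as fh:
        return [dict(row) for row in csv.DictReader(fh, delimiter="\t")]


def fetch_uniprot_fasta(accession: str, out_path: str | Path, timeout: float = 30.0) -> Path:
    """Fetch a canonical sequence from UniProt (network required).

    Canonical paralog sequences are deliberately not bundled with the
    package; fetch them once and pass the FASTA files in.
    """
    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    out_path = Path(out_path)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        out_path.write_bytes(resp.read())
    return out_path


def write_alignment(amap: AlignmentMap, fasta_path: str | Path, map_path: str | Path) -> None:
    """Write aligned FASTA plus a two-column position-map TSV."""
    a_gapped, b_gapped = [], []
    for a, b in amap.columns:
        a_gapped.append(amap.seq_a[a - 1] if a else "-")
        b_gapped.append(amap.seq_b[b - 1] if b else "-")
    Path(fasta_path).write_text(
        f">{amap.id_a}\n{''.join(a_gapped)}\n>{amap.id_b}\n{''.join(b_gapped)}\n",
        encoding="utf-8",
    )
    with Path(map_path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"{amap.id_a}\t{amap.id_b}\n")
        for a, b in amap.columns:
            fh.write(f"{a if a is not None else '-'}\t{b if b is not None else '-'}\n")
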