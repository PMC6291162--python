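"""Cohort variant and phenotype tables: reading, validation, summarization.

The cohort dialect mirrors a clinical genotype/phenotype table: one row per
proband with an HGVS-lite protein change, inheritance, sequencing site and
a set of phenotype flags coded ``+`` (present), ``-`` (absent), ``NR``
(not reported). Monozygotic twins share a ``monozygotic_set_id`` and a
``family_id`` and are collapsed to a single family-level allele, because
identical twins represent one germline mutational event.

Protein-change notation accepted here is deliberately a dialect, not full
HGVS: single-residue substitutions (``p.(V25M)``, ``p.(Val25Met)``),
single-residue in-frame deletions (``p.(A158del)``), and premature stops
written either as ``Ter``/``*`` or with the legacy ``X`` stop symbol
(``p.(R176X)``).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ProteinVariant",
    "GeneModel",
    "CohortTable",
    "ParseError",
    "CohortValidationError",
    "parse_protein_change",
    "format_protein_change",
    "collapse_families",
    "phenotype_fraction",
    "truncation_lengths",
    "read_cohort",
    "write_cohort",
    "read_phenotypes",
    "write_phenotypes",
    "RALA",
]

STOP = "*"
DELETION = "del"

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP, "Sec": "U",
}
AA1 = set("ACDEFGHIKLMNPQRSTVWYU")


class ParseError(ValueError):
    """Raised when a protein-change string does not match the dialect."""


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its structural invariants."""


@dataclass(frozen=True)
class ProteinVariant:
    """One allele observation in one proband.

    ``consequence`` is derived from the parsed protein change: a stop
    alternate residue means nonsense, a deletion marker means in-frame
    deletion, anything else missense. An identity substitution (same
    reference and alternate residue) is kept as missense but flagged
    ``synonymous_flag`` so callers can warn.
    """

    gene_symbol: str
    transcript_id: str
    cdna_change: str
    protein_change: str
    ref_residue: str
    codon_index: int
    alt_residue: str
    consequence: str
    inheritance: str
    proband_id: str
    family_id: str
    site: str = ""
    synonymous_flag: bool = False

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise CohortValidationError(
                f"codon_index must be >= 1, got {self.codon_index}"
            )
        if self.consequence not in {"missense", "nonsense", "inframe_deletion"}:
            raise CohortValidationError(
                f"unknown consequence {self.consequence!r}"
            )
        if self.inheritance not in {"de_novo", "inherited", "unknown"}:
            raise CohortValidationError(
                f"unknown inheritance {self.inheritance!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene-level constants: protein length and per-chromosome de novo rate.

    The rate is the expected probability of a qualifying (missense + LoF)
    de novo mutation per transmitted chromosome copy, taken from published
    trinucleotide-context mutation-rate models; it is consumed as a
    constant, never recomputed here.
    """

    gene_symbol: str
    protein_length: int
    denovo_rate_per_chromosome: float

    def __post_init__(self) -> None:
        if self.protein_length <= 0:
            raise ValueError("protein_length must be positive")
        if not 0.0 < self.denovo_rate_per_chromosome < 1.0:
            raise ValueError("denovo_rate_per_chromosome must be in (0, 1)")


#: RALA constants: 206-aa protein (NP_005393.2 numbering), published
#: missense+LoF de novo rate 6.16e-6 per chromosome.
RALA = GeneModel("RALA", 206, 6.16e-6)


@dataclass
class CohortTable:
    """Probands with phenotype flags plus their variant observations."""

    probands: list[dict] = field(default_factory=list)
    variants: list[ProteinVariant] = field(default_factory=list)

    def validate(self) -> None:
        fam_by_proband: dict[str, str] = {}
        mz_families: dict[str, set[str]] = {}
        for p in self.probands:
            fam_by_proband[p["proband_id"]] = p["family_id"]
            mz = p.get("monozygotic_set_id") or ""
            if mz:
                mz_families.setdefault(mz, set()).add(p["family_id"])
        for mz, fams in mz_families.items():
            if len(fams) > 1:
                raise CohortValidationError(
                    f"monozygotic set {mz!r} spans families {sorted(fams)}"
                )
        for v in self.variants:
            if v.proband_id in fam_by_proband and fam_by_proband[v.proband_id] != v.family_id:
                raise CohortValidationError(
                    f"proband {v.proband_id}: family_id mismatch between "
                    "variant and phenotype record"
                )

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.family_id)
        return list(seen)


_SUB_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z\*])"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|del|[A-Z\*])"
    r"\)?$"
)


def _residue_code(token: str, *, position: str, stop_context: bool) -> str:
    """Normalize a residue token to 1-letter code, '*' or 'del'."""
    if token == DELETION:
        return DELETION
    if len(token) == 3:
        if token not in AA3_TO_1:
            raise ParseError(f"unknown amino-acid code {token!r}")
        return AA3_TO_1[token]
    if token == "*":
        return STOP
    # Legacy stop: a trailing literal X after the position denotes a stop
    # (e.g. "R176X"); X is not a standard 1-letter amino-acid code.
    if token == "X" and stop_context:
        return STOP
    if token not in AA1:
        raise ParseError(f"unknown amino-acid code {token!r} at position {position}")
    return token


def parse_protein_change(text: str) -> tuple[str, int, str, str]:
    """Parse an HGVS-lite protein change.

    Returns ``(ref_residue, codon_index, alt_residue, consequence)`` where
    ``alt_residue`` is a 1-letter code, ``*`` for a stop, or ``del`` for a
    single-residue in-frame deletion.

    >>> parse_protein_change("p.(V25M)")
    ('V', 25, 'M', 'missense')
    >>> parse_protein_change("p.(Arg176Ter)")
    ('R', 176, '*', 'nonsense')
    """
    raw = text.strip()
    if not raw:
        raise ParseError("empty protein-change string")
    m = _SUB_RE.match(raw)
    if m is None:
        raise ParseError(f"unrecognized protein change {text!r}")
    pos = int(m.group("pos"))
    if pos == 0:
        raise CohortValidationError(f"codon index 0 in {text!r}")
    ref = _residue_code(m.group("ref"), position=m.group("pos"), stop_context=False)
    if ref in (STOP, DELETION):
        raise ParseError(f"reference residue may not be {ref!r} in {text!r}")
    alt = _residue_code(m.group("alt"), position=m.group("pos"), stop_context=True)
    if alt == STOP:
        consequence = "nonsense"
    elif alt == DELETION:
        consequence = "inframe_deletion"
    else:
        consequence = "missense"
    return ref, pos, alt, consequence


def format_protein_change(ref: str, pos: int, alt: str) -> str:
    """Render parsed fields back into the compact dialect, e.g. ``p.(V25M)``.

    Stops are rendered with the legacy ``X`` symbol to match the table
    transcription, deletions as ``del``.
    """
    alt_txt = "X" if alt == STOP else alt
    return f"p.({ref}{pos}{alt_txt})"


def truncation_lengths(stop_codon: int, protein_length: int) -> dict:
    """Residue counts removed by a premature stop.

    Reports both conventions — residues at-and-after the stop codon and
    residues strictly after it — since published summaries are sometimes
    off by one in either direction. ``consistent`` is True when the two
    differ by exactly one, as they must.
    """
    at_and_after = protein_length - stop_codon + 1
    strictly_after = protein_length - stop_codon
    return {
        "stop_codon": stop_codon,
        "protein_length": protein_length,
        "lost_at_and_after_stop": at_and_after,
        "lost_strictly_after_stop": strictly_after,
        "consistent": at_and_after - strictly_after == 1,
    }


def collapse_families(cohort: CohortTable) -> list[dict]:
    """Collapse proband-level variants to one allele record per family.

    Monozygotic sets contribute a single record carrying their shared
    variant; a set whose members carry discordant variants is an error.
    Returns records sorted by family_id with fields ``family_id``,
    ``variant`` (a :class:`ProteinVariant`), ``n_probands``,
    ``proband_ids`` and ``site``.
    """
    cohort.validate()
    by_family: dict[str, list[ProteinVariant]] = {}
    for v in cohort.variants:
        by_family.setdefault(v.family_id, []).append(v)
    records = []
    for fam in sorted(by_family, key=_natural_key):
        members = by_family[fam]
        keys = {
            (v.gene_symbol, v.protein_change, v.cdna_change, v.inheritance)
            for v in members
        }
        if len(keys) > 1:
            raise CohortValidationError(
                f"family {fam}: probands carry discordant variants {sorted(keys)}"
            )
        records.append(
            {
                "family_id": fam,
                "variant": members[0],
                "n_probands": len(members),
                "proband_ids": [v.proband_id for v in members],
                "site": members[0].site,
            }
        )
    return records


def _natural_key(s: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]


def phenotype_fraction(cohort: CohortTable, flag_label: str) -> tuple[int, int, int | None]:
    """Fraction of probands positive for a phenotype flag.

    Probands with value ``not_reported`` are excluded from the denominator.
    Returns ``(numerator, denominator, percent)`` with percent rounded to
    the nearest integer, or ``None`` for an empty denominator.
    """
    if not cohort.probands:
        raise KeyError(f"no probands loaded; cannot summarize {flag_label!r}")
    if flag_label not in cohort.probands[0].get("phenotypes", {}):
        raise KeyError(f"unknown phenotype flag {flag_label!r}")
    num = den = 0
    for p in cohort.probands:
        value = p["phenotypes"][flag_label]
        if value == "not_reported":
            continue
        den += 1
        if value == "present":
            num += 1
    percent = round(100 * num / den) if den else None
    return num, den, percent


# ---------------------------------------------------------------------------
# TSV dialect

VARIANT_COLUMNS = [
    "proband_id", "family_id", "monozygotic_set_id", "gene", "transcript",
    "cdna_change", "protein_change", "inheritance", "site",
]

_PHENO_CODE = {"+": "present", "-": "absent", "NR": "not_reported"}
_PHENO_CODE_INV = {v: k for k, v in _PHENO_CODE.items()}
_INHERITANCE_CODE = {"de novo": "de_novo", "de_novo": "de_novo",
                     "inherited": "inherited", "unknown": "unknown"}


def read_cohort(variants_path: str | Path, phenotypes_path: str | Path | None = None) -> CohortTable:
    """Read the tab-separated cohort dialect into a :class:`CohortTable`."""
    variants_path = Path(variants_path)
    text = variants_path.read_text(encoding="utf-8")
    if not text.strip():
        raise CohortValidationError(f"empty cohort file {variants_path}")
    rows = list(csv.DictReader(io.StringIO(text), delimiter="\t"))
    missing = set(VARIANT_COLUMNS) - set(rows[0] if rows else {})
    if missing:
        raise CohortValidationError(
            f"{variants_path}: missing columns {sorted(missing)}"
        )
    variants, probands = [], []
    for row in rows:
        ref, pos, alt, consequence = parse_protein_change(row["protein_change"])
        inheritance = _INHERITANCE_CODE.get(row["inheritance"].strip())
        if inheritance is None:
            raise CohortValidationError(
                f"bad inheritance {row['inheritance']!r} for {row['proband_id']}"
            )
        variants.append(
            ProteinVariant(
                gene_symbol=row["gene"],
                transcript_id=row["transcript"],
                cdna_change=row["cdna_change"],
                protein_change=row["protein_change"],
                ref_residue=ref,
                codon_index=pos,
                alt_residue=alt,
                consequence=consequence,
                inheritance=inheritance,
                proband_id=row["proband_id"],
                family_id=row["family_id"],
                site=row["site"],
                synonymous_flag=(ref == alt),
            )
        )
        probands.append(
            {
                "proband_id": row["proband_id"],
                "family_id": row["family_id"],
                "monozygotic_set_id": row["monozygotic_set_id"] or None,
                "phenotypes": {},
            }
        )
    cohort = CohortTable(probands=probands, variants=variants)
    if phenotypes_path is not None:
        _merge_phenotypes(cohort, read_phenotypes(phenotypes_path))
    cohort.validate()
    return cohort


def read_phenotypes(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a phenotype TSV (proband_id + one ``+/-/NR`` column per flag)."""
    rows = list(csv.DictReader(Path(path).open(encoding="utf-8"), delimiter="\t"))
    out: dict[str, dict[str, str]] = {}
    for row in rows:
        pid = row.pop("proband_id")
        decoded = {}
        for label, code in row.items():
            if code not in _PHENO_CODE:
                raise CohortValidationError(
                    f"phenotype value {code!r} for proband {pid}, flag {label!r}"
                    " is not one of +, -, NR"
                )
            decoded[label] = _PHENO_CODE[code]
        out[pid] = decoded
    return out


def _merge_phenotypes(cohort: CohortTable, phenos: Mapping[str, Mapping[str, str]]) -> None:
    for p in cohort.probands:
        p["phenotypes"] = dict(phenos.get(p["proband_id"], {}))


def write_cohort(cohort: CohortTable, variants_path: str | Path) -> None:
    """Write variants back to the TSV dialect (round-trips with read_cohort)."""
    mz_by_proband = {
        p["proband_id"]: p.get("monozygotic_set_id") or "" for p in cohort.probands
    }
    with Path(variants_path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in cohort.variants:
            w.writerow([
                v.proband_id, v.family_id, mz_by_proband.get(v.proband_id, ""),
                v.gene_symbol, v.transcript_id, v.cdna_change, v.protein_change,
                {"de_novo": "de novo"}.get(v.inheritance, v.inheritance), v.site,
            ])


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    labels: list[str] = []
    for p in cohort.probands:
        for label in p.get("phenotypes", {}):
            if label not in labels:
                labels.append(label)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["proband_id", *labels])
        for p in cohort.probands:
            w.writerow(
                [p["proband_id"]]
                + [_PHENO_CODE_INV[p["phenotypes"].get(l, "not_reported")] for l in labels]
            )
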